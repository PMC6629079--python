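import numpy as np
import pytest

from oddballeeg.containers import EOG, SCALP, EpochSet, make_times
from oddballeeg.montage import DEFAULT_SCALP_64, VEOG


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def build_epochs(data, sfreq=500.0, start_ms=-100.0, ch_names=None,
                 ch_roles=None, trial_labels=None, correct=None):
    """EpochSet from a raw (trials, channels, samples) array."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n_ch)]
    if ch_roles is None:
        ch_roles = [SCALP] * n_ch
    times = start_ms + (1000.0 / sfreq) * np.arange(n_samp)
    return EpochSet(data=data, times=times, sfreq=sfreq, ch_names=ch_names,
                    ch_roles=ch_roles, trial_labels=trial_labels,
                    correct=correct)


def build_montage_epochs(data, sfreq=500.0, start_ms=-100.0, with_veog=True,
                         **kw):
    """EpochSet over the standard 64-channel montage (+ optional VEOG)."""
    names = list(DEFAULT_SCALP_64) + ([VEOG] if with_veog else [])
    roles = [SCALP] * 64 + ([EOG] if with_veog else [])
    return build_epochs(data, sfreq=sfreq, start_ms=start_ms, ch_names=names,
                        ch_roles=roles, **kw)


@pytest.fixture
def epoch_times():
    return make_times((-100.0, 800.0), 500.0)
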