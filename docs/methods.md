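# Methods notes

This note records the models, conventions and numerical choices behind the
package, including the points where the underlying protocol leaves the
design genuinely open.

## Measurement model

One participant's data are visual-oddball epochs (−100..800 ms around target
onset, 500 Hz, 64 scalp channels plus a VEOG channel). The epoch grid is
left-closed: 450 samples at −100, −98, …, 798 ms; 0 ms is stimulus onset.
All window selections are closed intervals on the millisecond axis mapped to
nearest samples. Voltages are microvolts throughout.

Preprocessing follows the fixed order re-reference → EOG regression →
baseline correction → amplitude rejection → averaging:

* **Average reference** subtracts the instantaneous scalp mean from every
  scalp channel (EOG channels untouched). Idempotent.
* **EOG regression** removes ocular activity with a single pooled
  least-squares coefficient per scalp channel, `b_c = cov(c, EOG)/var(EOG)`
  estimated over all trials jointly. This is a deliberate simplification of
  blink-template approaches that fit separate blink/non-blink coefficients:
  the blink detector those need is under-determined here, and the synthetic
  fixtures control blink content explicitly. A zero-variance EOG channel
  makes the step a no-op with a warning.
* **Baseline** is the per-trial, per-channel mean over −100..0 ms.
* **Rejection** marks a trial when any scalp sample strictly exceeds
  ±75 µV. The boundary is strict (a 75.0 µV extreme is kept) because the
  protocol states limits without boundary semantics; the threshold is a
  parameter. Rejection is monotone in the threshold.
* **Averaging** uses artifact-free, behaviorally correct target trials and
  refuses to produce a waveform from fewer than 15 of them (the
  conventional floor for a usable individual P3 average). The surviving
  count is reported both in the error and in the per-participant log.

**P3**: global maximum positivity over the 6×7 analysis matrix within
300–450 ms (inclusive edges). Ties resolve to the earliest latency, then the
first electrode in matrix order, for determinism. A peak on a window edge
raises a warning since the component may be truncated. The matrix membership
is configuration (`data/matrix_6x7.tsv`), defaulting to rows F, FC, C, CP, P
at 10-10 positions 5/3/1/z/2/4/6 and a PO row at PO7..PO8; the exact grid of
the original montage is not recoverable from a text description, so the
default is an explicit, overridable assumption. The topography exported for
map scoring is the 42-electrode voltage vector at the single peak-latency
sample.

**Alpha ERD**: per artifact-free trial, band-pass 8–13 Hz, rectify, average
across trials, smooth, subtract the −100..0 ms baseline; the valley is the
maximum negativity over matrix × 250–700 ms, reported in µV relative to
baseline (a percent-of-baseline mode exists behind a flag).

Numerical choices in the ERD route, none of which are dictated by the
protocol:

* *Filter realization.* A Butterworth band-pass (order-2 prototype) applied
  forward–backward so measured latencies carry no phase delay. An 8–13 Hz
  band rings for longer than the 0.9 s epoch, so standard reflection
  padding leaves large edge transients that reach the baseline interval;
  the implementation uses Gustafsson's minimum-transient initial conditions
  (`scipy.signal.filtfilt(..., method="gust")`), which keeps a
  constant-envelope carrier flat to < 0.5 % of its amplitude across the
  epoch. The first/last ~150 ms remain the least reliable region; the
  default valley window stays clear of the right edge.
* *Smoothing.* The rectified average carries ripple at twice the alpha
  frequency; a centered 100 ms moving average (~one ripple-pair period at
  10 Hz, reflect-padded) suppresses it. Width configurable
  (`smoothing_halfwidth`, default 50 ms).
* *Amplitude calibration.* For a carrier of amplitude A with a fractional
  envelope dip `d`, the rectified mean is `(2A/π)(1 − d·g(t))`, so the
  ideal valley is `−d·2A/π`. Band-limiting smears a Gaussian dip of
  100 ms sigma to about 0.8 of that value (exact for slower dips); tests
  assert the closed form with this attenuation bounded rather than an
  unverified exact number.

**Map scores** are centered Pearson correlations over the 42 matrix
electrodes only (matching the exported topographies; average-referenced maps
are near-zero-mean, which the centered correlation handles regardless).
Deviation flags are strict: P3 score < 0.6, ERD score < 0.7.

**Profiles**: healthy-group norms use the sample SD (n−1) — recomputing the
cohort table's healthy RT/P3/ERD SDs this way reproduces the published
72.32/58.70/89.53 within rounding, which pins the convention. Z-scores use
unrounded norms internally; comparisons against a printed profile table
allow ±0.02 because printed values carry rounded means/SDs. A z strictly
greater than 1 flags a deviation. Z3 is the arithmetic mean of the RT,
P3-latency and ERD-latency z-scores. SDMT/PASAT age-education cutoff flags
are input data, not computed.

## Group statistics

Kruskal–Wallis uses the tie-corrected H against chi-square with k−1 degrees
of freedom (all-identical input degenerates to H = 0, p = 1). The post hoc
is the Dunn-type z on pooled mean ranks with tie-corrected standard error
and Bonferroni adjustment over the three pairs — the procedure standard
statistical packages attach to a Kruskal–Wallis pairwise follow-up.

The correlation screen pools the 20 patients (clinical scores exist for
patients only) and computes Pearson r with two-sided t-based p-values. The
default pair list is the three clinical variables (EDSS, SDMT, PASAT)
against each behavioral/EEG measure (RT, P3 latency, ERD latency, both map
scores, Z3) plus the three within-clinical pairs — 21 pairs.
Component-versus-own-composite pairs (e.g. P3 latency against Z3) are
excluded by default: they are correlated by construction and answer no
clinical question. The significance level is `alpha / family_size` with
`family_size` defaulting to 25 independently of the list length, so the
adjusted level (0.002) matches the convention of dividing by the nominal
size of the correlation family; both the list and the family size are
parameters.

## Synthetic data

The generator emulates the study conditions: 200-trial sessions (50 targets,
150 standards, SOA 1.5 s, pseudorandom order with no two consecutive
targets — placing targets in distinct gaps between standards, which makes
adjacency impossible without biasing admissible orders), 64-channel epochs
containing:

* a **P3 transient**: positive Gaussian (default 10 µV, sigma 40 ms) with a
  unit-peak parietal weight map centered at Pz;
* an **alpha carrier** (default 4 µV, 10 Hz, parieto-occipital weight map
  peaking at POz) whose envelope is multiplied by `1 − d·g(t)` with `g` a
  unit-peak Gaussian at the ERD latency (default depth 0.5, sigma 100 ms),
  active post-stimulus. Per-trial phases are marginally uniform on [0, 2π)
  but stratified (a shuffled equispaced set with one random offset per
  participant), so the non-phase-locked carrier cancels *exactly* in the
  ERP average — the behavior an infinite-trial average would show — while
  surviving rectification unchanged. With iid phases a residual of order
  A/√n survives averaging and injects ~10 ms of spurious P3 peak jitter,
  which would misrepresent the measurement chain rather than the noise;
* **white Gaussian noise** (default SD 2 µV; a 1/f option is out of scope);
* optional **blinks**: 200 ms half-sines, 150 µV on a simulated VEOG,
  propagated to the scalp with frontal weighting (default rate 0).

The default alpha amplitude (4 µV) was chosen so that the default depth
yields measured valley amplitudes near −1 µV, the magnitude the study
reports for its groups; an eyes-open active task suppresses posterior alpha
well below resting levels, so a few microvolts is the realistic regime.

Cohort presets draw per-participant RT, P3 latency/amplitude, ERD latency
and depth from normal distributions whose means/SDs are the published group
statistics (RT 418/457/494 ms; P3 latency 371/363/478 ms; ERD latency
444/499/568 ms for healthy/low/moderate). Latency draws are truncated to
260–690 ms so every injected component stays inside the filter-reliable part
of the epoch; amplitude and depth draws are truncated positive. The
published ERD *amplitude* group statistics have SDs larger than their means
and cannot serve directly as a depth distribution; depth is 0.5 ± 0.15 for
all groups (no group amplitude differences were reported). Trial RTs are
normal, truncated to [150 ms, SOA]; behavioral correctness is Bernoulli
(default 99.3 %). Inter-trial jitter and late-response discarding are
exposed as parameters without any claim of protocol fidelity.

What the generator does **not** emulate: volume-conducted source geometry
(weight maps are schematic grid Gaussians, not a head model), standard-
stimulus ERPs, non-blink ocular artifacts, heteroscedastic or 1/f noise,
and any dependence between clinical scores and EEG parameters — simulated
cohorts carry no EDSS/SDMT/PASAT. Passing recovery tests therefore shows
the measurement chain is faithful to its own forward model, not that the
clinical correlations would arise from real recordings.

A caveat carried visibly in the code: the nominal P3 search window
(300–450 ms) cannot contain the delayed peaks of strongly affected
patients — the published moderate-group latencies themselves reach 628 ms.
Cohort-level recovery checks therefore widen the search window to
250–700 ms; the default remains the nominal window.

## Known limitations and accuracy

* Raw argmax peak-picking is jitter-limited: with noise at a quarter of the
  alpha amplitude and 30-trial averages, P3 latency recovery is within
  ±8 ms (4 samples) in ≥95 % of runs, with a median error of one to two
  samples; it is sample-exact in the noise-free limit. Sharper components
  or more trials tighten this; no smoothing is applied before peak-picking.
* ERD valley latency recovery is accurate to well under the smoothing
  half-width (±60 ms is the guaranteed envelope) across 300–600 ms; valley
  *amplitude* is systematically shallowed by band-limiting (see above).
* The epoch exchange format stores trials as one stacked array; per-trial
  matrices of differing shape are rejected at read time.
* Statistics assume one row per participant and three fixed group labels;
  the screen skips (with a warning) any pair with fewer than three complete
  observations.

## Problem sizes in the test suite

Property tests use the sizes at which their claims are stated: 100 seeded
runs for noisy latency recovery, a 30-participant noise-free cohort (three
preset groups of ten, 50 target trials each) for pipeline recovery, 1000
random waveforms for the peak-finder oracles, and a 1000-replicate null
simulation (25 independent pairs, n = 20) for the family-wise error rate of
the screen, which is expected near 1 − 0.998²⁵ ≈ 4.9 %.
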