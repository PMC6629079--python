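# analysis matrix: label	row	col
F5	0	0
F3	0	1
F1	0	2
Fz	0	3
F2	0	4
F4	0	5
F6	0	6
FC5	1	0
FC3	1	1
FC1	1	2
FCz	1	3
FC2	1	4
FC4	1	5
FC6	1	6
C5	2	0
C3	2	1
C1	2	2
Cz	2	3
C2	2	4
C4	2	5
C6	2	6
CP5	3	0
CP3	3	1
CP1	3	2
CPz	3	3
CP2	3	4
CP4	3	5
CP6	3	6
P5	4	0
P3	4	1
P1	4	2
Pz	4	3
P2	4	4
P4	4	5
P6	4	6
PO7	5	0
PO5	5	1
PO3	5	2
POz	5	3
PO4	5	4
PO6	5	5
PO8	5	6
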