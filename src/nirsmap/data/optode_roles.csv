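# Source/detector role for every 10-10 position.  Reconstructed montage
# design: roles of optodes named in published channel examples are fixed;
# the remainder follow a left-right symmetric, row-alternating assignment
# giving the canonical 38/36 split over the 74 retained positions.
label,role
Nz,detector
N1,source
N2,source
Fp1,detector
Fpz,source
Fp2,detector
AF9,detector
AF7,source
AF3,detector
AFz,detector
AF4,detector
AF8,source
AF10,detector
F9,detector
F7,source
F5,detector
F3,source
F1,detector
Fz,source
F2,detector
F4,source
F6,detector
F8,source
F10,detector
FT9,source
FT7,detector
FC5,source
FC3,detector
FC1,source
FCz,detector
FC2,source
FC4,detector
FC6,source
FT8,detector
FT10,source
T9,source
T7,source
C5,detector
C3,source
C1,detector
Cz,source
C2,detector
C4,source
C6,detector
T8,source
T10,source
TP9,source
TP7,detector
CP5,source
CP3,detector
CP1,source
CPz,detector
CP2,source
CP4,detector
CP6,source
TP8,detector
TP10,source
P9,source
P7,source
P5,detector
P3,source
P1,detector
Pz,source
P2,detector
P4,source
P6,detector
P8,source
P10,source
PO9,source
PO7,detector
PO3,detector
POz,source
PO4,detector
PO8,detector
PO10,source
O1,source
Oz,detector
O2,source
I1,detector
Iz,source
I2,detector
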