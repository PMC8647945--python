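# The 130 source-detector channels of the packaged 10-10 montage design.
# Reconstructed neighbor pairing: each channel joins a source and detector
# whose great-circle separation on a spherical reference head is below
# 0.4386 x head radius (about 31 mm on a 70 mm sphere), the first two
# neighbor shells of the 10-10 layout.  Closed under left-right mirroring.
source,detector
Fpz,Fp1
Fpz,Fp2
Fpz,AF3
Fpz,AFz
Fpz,AF4
AF7,Fp1
AF7,AF3
AF7,F9
AF7,F5
AF8,Fp2
AF8,AF4
AF8,F6
AF8,F10
F7,F9
F7,F5
F7,FT7
F3,AF3
F3,F5
F3,F1
F3,FC3
Fz,AFz
Fz,F1
Fz,F2
Fz,FCz
F4,AF4
F4,F2
F4,F6
F4,FC4
F8,F6
F8,F10
F8,FT8
FT9,F9
FT9,FT7
FC5,F5
FC5,FT7
FC5,FC3
FC5,C5
FC1,F1
FC1,FC3
FC1,FCz
FC1,C1
FC2,F2
FC2,FCz
FC2,FC4
FC2,C2
FC6,F6
FC6,FC4
FC6,FT8
FC6,C6
FT10,F10
FT10,FT8
T7,FT7
T7,C5
T7,TP7
C3,FC3
C3,C5
C3,C1
C3,CP3
Cz,FCz
Cz,C1
Cz,C2
Cz,CPz
C4,FC4
C4,C2
C4,C6
C4,CP4
T8,FT8
T8,C6
T8,TP8
TP9,TP7
CP5,C5
CP5,TP7
CP5,CP3
CP5,P5
CP1,C1
CP1,CP3
CP1,CPz
CP1,P1
CP2,C2
CP2,CPz
CP2,CP4
CP2,P2
CP6,C6
CP6,CP4
CP6,TP8
CP6,P6
TP10,TP8
P9,TP7
P9,PO7
P7,TP7
P7,P5
P7,PO7
P3,CP3
P3,P5
P3,P1
P3,PO7
P3,PO3
Pz,CPz
Pz,P1
Pz,P2
P4,CP4
P4,P2
P4,P6
P4,PO4
P4,PO8
P8,TP8
P8,P6
P8,PO8
P10,TP8
P10,PO8
PO9,PO7
PO9,I1
POz,P1
POz,P2
POz,PO3
POz,PO4
POz,Oz
PO10,PO8
PO10,I2
O1,PO7
O1,PO3
O1,Oz
O1,I1
O2,PO4
O2,PO8
O2,Oz
O2,I2
Iz,Oz
Iz,I1
Iz,I2
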