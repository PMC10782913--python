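symbol	class
METTL3	writer
METTL5	writer
METTL14	writer
METTL16	writer
VIRMA	writer
WTAP	writer
ZC3H13	writer
ZCCHC4	writer
ALKBH5	eraser
FTO	eraser
YTHDF1	reader
YTHDF2	reader
YTHDF3	reader
YTHDC1	reader
YTHDC2	reader
HNRNPC	reader
IGF2BP1	reader
IGF2BP2	reader
IGF2BP3	reader
ELAVL1	reader
G3BP1	reader
RBMX	reader
FMR1	reader
EIF3A	reader
PRRC2A	reader
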