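genotype_label	cells
Doublet	416
Singlet0	391
Singlet1	868
Singlet2	71
Singlet3	130
Singlet4	447
Singlet5	28
Singlet6	118
Singlet7	232
Unassigned	63
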