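# Transmembrane helix ranges (author residue numbers, chain A protomer) for
# human TRPA1, PDB 3J9P, following the deposited cryo-EM model's
# secondary-structure annotation.  TM1-TM4 define the sensor bundle used by
# the aromatic-core procedure.
TM1: [718, 745]
TM2: [752, 775]
TM3: [782, 807]
TM4: [813, 835]
TM5: [841, 868]
TM6: [931, 958]
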