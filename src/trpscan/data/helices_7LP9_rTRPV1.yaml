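# Transmembrane helix ranges (author residue numbers, chain A protomer) for
# rat TRPV1, PDB 7LP9.  Boundaries follow the deposited secondary-structure
# annotation of the TRPV1 cryo-EM models; the aromatic-core procedure only
# uses TM1-TM4.
TM1: [433, 460]
TM2: [471, 499]
TM3: [507, 532]
TM4: [538, 560]
TM5: [572, 602]
TM6: [657, 690]
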