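[
 {
  "allowed": [
   "W"
  ],
  "label": "W",
  "align_col": 81,
  "rtrpv1_pos": 426
 },
 {
  "allowed": [
   "F"
  ],
  "label": "F",
  "align_col": 320,
  "rtrpv1_pos": 434
 },
 {
  "allowed": [
   "F",
   "Y"
  ],
  "label": "Φ",
  "align_col": 331,
  "rtrpv1_pos": 441
 },
 {
  "allowed": [
   "G"
  ],
  "label": "G",
  "align_col": 633,
  "rtrpv1_pos": 563
 },
 {
  "allowed": [
   "F",
   "Y"
  ],
  "label": "Φ",
  "align_col": 662,
  "rtrpv1_pos": 591
 },
 {
  "allowed": [
   "F",
   "Y"
  ],
  "label": "Φ",
  "align_col": 755,
  "rtrpv1_pos": 638
 },
 {
  "allowed": [
   "F",
   "Y"
  ],
  "label": "Φ",
  "align_col": 852,
  "rtrpv1_pos": 666
 },
 {
  "allowed": [
   "N"
  ],
  "label": "N",
  "align_col": 862,
  "rtrpv1_pos": 676
 },
 {
  "allowed": [
   "L"
  ],
  "label": "L",
  "align_col": 864,
  "rtrpv1_pos": 678
 },
 {
  "allowed": [
   "I"
  ],
  "label": "I",
  "align_col": 865,
  "rtrpv1_pos": 679
 },
 {
  "allowed": [
   "A"
  ],
  "label": "A",
  "align_col": 866,
  "rtrpv1_pos": 680
 },
 {
  "allowed": [
   "W"
  ],
  "label": "W",
  "align_col": 883,
  "rtrpv1_pos": 697
 }
]
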