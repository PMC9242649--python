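"""Score published consensus rows against the 12-slot TRP fingerprint.

The fingerprint W F Φ G Φ Φ Φ N L I A W (Φ = Phe or Tyr) sits at fixed
alignment columns.  A consensus row scores one point per slot whose
residue belongs to the slot's allowed set; the printed class symbol Φ
matches Φ slots; gaps never match.  The counts below are the number of
signature residues each channel retains — 12 means the full fingerprint.
"""

from trpscan import FingerprintDefinition, score_residues

fp = FingerprintDefinition.default()
print("signature:", fp.signature)
print("columns:  ", " ".join(map(str, fp.align_cols)))
print()

rows = {
    "TRPV":   list("WFYG") + ["Φ", "F", "Φ"] + list("NLIAW"),
    "TRPA1":  list("WFYGFFFNLIGR"),
    "TRPY":   list("WNSGFT") + ["Φ"] + list("NLIAY"),
    "CrTRP1": list("WWLGFQFNFIAF"),
    "KvAP":   list("WFYG----VVCW"),
    "Kv1.2":  list("YFGG---PLSS-"),
}
for name, residues in rows.items():
    s = score_residues(residues, fp)
    marks = "".join("*" if m else "." for m in s.match_mask)
    print(f"{name:8s} {''.join(s.residues_at_slots):14s} {marks}  count={s.count}")
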