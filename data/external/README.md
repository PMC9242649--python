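# External reference data (not redistributed)

Two acceptance checks consume externally deposited data that cannot be
bundled here.  To run them, place in this directory:

- `primary_msa.fasta` — the deposited 1481-sequence primary TRP alignment
  (Dryad, doi:10.5061/dryad.k6djh9w75), plus an optional
  `subfamily_labels.tsv` (two tab-separated columns: seq_id, subfamily).
- `7LP9.pdb` (or `.cif`) and `3J9P.pdb` (or `.cif`) — the rTRPV1 and
  hTRPA1 coordinates from the wwPDB.

Until these files exist the corresponding tests fail with a message
pointing here.
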