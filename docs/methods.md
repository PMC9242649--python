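# Methods

This note documents the models and procedures implemented in `trpscan`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic generators do and do not
emulate.

## Column conservation

An alignment is a rectangular matrix over the 20 amino acids, the unknown
code `X` and the gap `-`.  For each column we count residues, take the
most frequent residue as consensus (`X` is counted but never consensus;
alphabetical order breaks ties), and report

- `identity` = max residue count / N,
- `phi_identity` = (count F + count Y) / N,
- `gap_fraction` = gaps / N.

**Denominator.** The identity denominator includes gapped rows by
default, so a gap counts against conservation; this is the conservative
reading for alignments whose loop regions are variably gapped, and it
keeps a single `>90%` threshold meaningful across the whole alignment.  A
flag (`exclude_gaps_from_denominator`) restricts the denominator to
non-gap rows for sensitivity analysis.

**Scan rule.** A column is conserved when identity *strictly* exceeds the
threshold (default 0.90, i.e. ">90%"); with the Φ option a column whose
combined Phe+Tyr fraction strictly exceeds the threshold also qualifies,
reported as class `phi`.  Exact identity takes precedence when both fire.
Trp is deliberately excluded from the Φ class: Φ covers the six-carbon
aromatics only.

Logo data reports per-column non-gap frequencies and information content
`log2(20) − H` in bits, with all-gap columns flagged and assigned zero
information rather than NaN.

## The 12-slot fingerprint

The signature W F Φ G Φ Φ Φ N L I A W is anchored at alignment columns
(81, 320, 331, 633, 662, 755, 852, 862, 864, 865, 866, 883),
corresponding to rat TRPV1 positions
(426, 434, 441, 563, 591, 638, 666, 676, 678, 679, 680, 697).

Scoring rule: a slot matches iff the residue is a member of the slot's
allowed set — a single residue at the eight non-Φ slots, {F, Y} at the
four Φ slots.  The printed class symbol `Φ` is accepted as an input
character and matches Φ slots only; gaps never match.  This is the
maximal-agreement reading of the published per-subfamily totals: it
reproduces all of them except three non-TRP rows whose printed totals are
internally inconsistent with any single rule (those rows are not
asserted).  An optional `slot2_phi` mode relaxes slot 2 from strict Phe to
{F, Y}, which is how those three rows appear to have been counted; every
quantity this package reports is insensitive to the choice.

The census tabulates, over a set of scored sequences, the fraction with
exactly *k* and with at least *k* matches for k = 0…12.

## Emission entropy

Match columns are those with gap fraction strictly below 0.5.  Emissions
are estimated per column over the 20 amino acids as

    p(a) = (count_w(a) + c · b(a)) / (total_w + c)

with optional per-sequence weights `w`, pseudocount `c` (default 1.0) and
background `b` (default uniform 1/20).  Gaps and `X` are excluded from
the counts, following the match-state convention.  This deliberately
replaces a full profile-HMM builder: Dirichlet-mixture priors and internal
sequence weighting affect the absolute emission values but not the
entropy *ranking* of strongly versus weakly conserved columns, which is
the only quantity used downstream.  Entropy is Shannon entropy in bits
(0·log 0 = 0; the base only rescales, ranking is base-invariant), and the
fingerprint rank check reports each slot's entropy percentile among match
columns (fraction of match columns strictly below).

## Distograms

Feature selection keeps alignment columns whose non-gap presence strictly
exceeds 0.96, optionally intersected with a user-supplied region set
(e.g. transmembrane segments).  Each structure contributes a P×P matrix
of Euclidean distances between representative coordinates — Cβ, or Cα for
glycine, with a flagged Cα fallback when Cβ is missing; residues lacking
both are masked.  Sequence↔structure correspondence comes from a sidecar
TSV (column, chain, author number); a pairwise-alignment fallback exists
but warns, since curated maps are preferred.

Across the ensemble we report per cell: the count of structures where
both positions are present, the mean distance, the population variance
(the ensemble is treated as the full object of study; a sample-variance
flag exists), and the normalized variance `variance / mean²`.  Cells seen
in fewer than two structures have masked variance.  Normalizing by the
squared mean removes the bias toward large variances at large distances
and makes the statistic scale-free, which the tests verify to 1e-9 under
global coordinate scaling.  No superposition is ever performed: all
quantities are internal distances, hence rigid-motion invariant.

## Aromatic core and contacts

Within the TM1–TM4 bundle, helix pairs (TM1, TM3) and (TM2, TM4) oppose
each other.  For each residue r of a helix, the opposing residue o
minimizing d(Cα_r, Cα_o) is found; r faces the core iff that distance
*strictly* exceeds d(Cγ_r, Cα_o).  Both orderings of each pair are
evaluated and the union reported.  The gamma atom is the residue's
gamma-position heavy atom: CG for most side chains, CG1 for Ile/Val,
OG/OG1/SG for Ser/Thr/Cys; Gly and Ala have none and are never facing.
Core-facing aromatics ({F, Y, W, H} by default; His can be switched off)
are then clustered by single linkage: connected components of the graph
whose edges are residue pairs with minimal heavy-atom distance below 5 Å.
Minimal distances are taken over all heavy atoms (backbone included) by
default — deposited models rarely carry hydrogens — with a side-chain-only
flag.

Residue contacts use the minimal heavy-atom distance with a 4 Å general
threshold and a 5 Å threshold when both residues are aromatic (π–π);
sequence-adjacent pairs are excluded, and a cross-chain pass detects
inter-subunit contacts in multimeric assemblies.  Ring-geometry
classification (parallel vs T-shaped stacking) is out of scope.

Helix ranges are user-supplied configuration; ranges for the exemplar
structures 7LP9 (rTRPV1) and 3J9P (hTRPA1) ship as data files.

## Direct coupling analysis

The pairwise maximum-entropy (Potts) model over q = 21 states (gap first,
then the 20 amino acids; `X` is treated as a gap) is estimated by
asymmetric pseudo-likelihood maximization: for each column i the
conditional model

    P(x_i | x_\i) ∝ exp( h_i(x_i) + Σ_{j≠i} J_ij(x_i, x_j) )

is fitted by minimizing the weighted negative conditional log-likelihood
plus λ_h‖h_i‖² + λ_J Σ_j‖J_ij‖², with λ_h = λ_J = 0.01 used as printed,
i.e. unscaled.  Sequences are reweighted with w_s = 1/|{t :
hamming_fraction(s,t) < θ}| at θ = 0.1, so M_eff = Σ w is invariant under
duplicating the alignment.  Each column's convex problem is solved with
L-BFGS-B (analytic gradient, projected-gradient tolerance 1e-5, max 500
iterations; non-convergence raises with diagnostics, and the objective
history is retained so monotone decrease can be monitored).  The two
directed estimates are averaged, J_ij ← (J_ij + J_jiᵀ)/2.

Scores: each coupling block restricted to the 20 non-gap states is moved
to the zero-sum gauge (row/column means removed), scored by Frobenius
norm, and corrected with the average-product correction
`F_ij − F_i·F_·j / F_··`.  The APC means here include the full rows
(diagonal included), a minor variant chosen so that a rank-one score
matrix maps exactly to zero; because blocks are gauge-fixed before
scoring, reported scores are invariant under any additive gauge
transformation of (h, J).  A guard refuses L > 400 or N > 20000 without
an explicit override, since the per-column optimization is O(L·q²·N) per
gradient evaluation.

## Synthetic generators

All generators are pure functions of (spec, seed) and emit their ground
truth as machine-readable sidecars.

- **Structured MSAs**: a conserved column carries its designated residue
  with probability p (a Φ column draws Phe:Tyr at 3:1), background
  positions draw i.i.d. from a configurable distribution (uniform by
  default), subfamily indel blocks are emitted as all-gap, and remaining
  positions gap independently at a per-subfamily rate.  This emulates the
  statistical structure the conservation scanner and gap profiler are
  designed for — near-invariant fingerprint columns and subfamily-specific
  linker indels — but not phylogenetic correlation between rows: rows are
  exchangeable, so tests passing here say nothing about the effect of
  tree-structured redundancy (which reweighting addresses for DCA).
- **Potts MSAs**: Gibbs sampling with one independent chain per sequence
  (uniform random start, 300 full sweeps of burn-in by default) from
  planted ferromagnetic couplings `strength·(I − 1/q)`; states are emitted
  as amino-acid letters, gap-free.
- **Bundle ensembles**: Cα traces on ideal α-helices (1.5 Å rise,
  100°/residue, 2.3 Å helix radius) with axes on a circle (8.5 Å default
  radius, chosen so the facing geometry is unambiguous and the 3 Å clash
  guard passes); Cβ placed radially outward of the helix axis; planted
  residues become Phe with a gamma pseudo-atom 2.5 Å toward (inward) or
  away from (outward) the bundle axis plus a six-atom ring template.
  Conformers translate designated helices by a per-conformer factor in
  [-1, 1] times a displacement vector and add isotropic Gaussian noise; a
  tetramer option replicates the (noised) protomer by exact 4-fold
  rotation, so neighbor-protomer contact counts are exact multiples of
  four.  The geometry is minimal by design — no rotamers, no packing, no
  physical energetics — sufficient for the facing test, pair distances
  and distograms, and nothing else.

## Degenerate inputs and tie-breaks

- Consensus ties break alphabetically; `X` counts in denominators but is
  never consensus and never an emission state.
- All-gap columns: zero-information logo rows (flagged); emission
  estimation with pseudocount 0 raises.
- Alternate locations resolve to the highest occupancy (ties toward 'A');
  HETATMs and waters are excluded at parse time.
- Missing Cβ falls back to Cα with a warning; missing Cα drops the
  residue from matrices via masking; missing gamma atoms make a residue
  non-facing rather than raising.
- Strict inequalities throughout (conservation threshold, gap cutoffs,
  presence cutoff, facing test, clustering threshold), matching the
  published phrasings.

## Problem sizes used in the test suite

The suites run on synthetic data sized for a single CPU: alignments of
120–2000 rows, bundles of 4×18 residues, five-conformer ensembles, and
one DCA recovery problem at L = 30, q = 8, N = 2000 with five planted
pairs.  These sizes were chosen as the smallest at which the statistical
checks (binomial tolerances, top-5 coupling recovery) are stable across
seeds; the algorithms themselves are size-agnostic up to the DCA desk
guard.

## Known limitations

- The emission estimator is not hmmbuild: absolute emission values differ
  from HMMER profiles even though rankings agree on peaked columns.
- The census over real data depends on which rows count as "TRP"; the
  package takes subfamily labels as input rather than inferring them.
- Ensemble-level distogram values for the published heterogeneous
  structure set are not reproducible without that exact set; the package
  reproduces the statistics' properties, not those numbers.
- The aromatic-core counts on deposited structures depend on the helix
  ranges supplied; shipped ranges follow the deposited annotations but
  boundaries one or two residues off can move borderline aromatics in or
  out of the core.
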