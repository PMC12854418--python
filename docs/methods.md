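# Methods

## Scope and data model

`ppimodes` analyzes *predicted* dimer structures: two polymer chains with
per-residue pLDDT stored in the B-factor field and an aligned PAE matrix
in AlphaFold JSON layout (row i, column j = expected error at residue j
when aligned on residue i; asymmetric).  Structures are read with gemmi;
hydrogens are dropped, the first alternate location is kept, nonstandard
residues map to `X`, and residues are renumbered 1..n consecutively per
chain — matching AlphaFold outputs, where author numbering is already
consecutive.  Files with more than two polymer chains are rejected
rather than truncated: every downstream definition (inter-chain PAE,
pDockQ, binding modes) is dimer-specific.  Monomer secondary structure
and solvent accessibility come from DSSP output files (8-state codes,
absolute accessibility in Å²); when accessibility is absent an internal
Shrake–Rupley sampler (Fibonacci sphere, 960 points, probe 1.4 Å, Bondi
radii) supplies it.

## Interface extraction

Two residues on different chains interact if any pair of their heavy
atoms lies within **7 Å** (boundary inclusive).  The k-d-tree search is
required — and tested — to reproduce the all-pairs distance scan
exactly.  Each surviving contact is then screened by PAE: because the
matrix is asymmetric, the two directional entries are symmetrized by
their **mean** (configurable to min or max; the mean is the unbiased
middle ground) and the contact is discarded only when the combined
value is **strictly greater than 15 Å**, so a boundary value of exactly
15 survives.  Interface residues on each chain are merged into regions
whose internal gaps are at most 2 residues ("separated by fewer than 3
residues"); partner spans are grouped by the same rule.

## Confidence

pDockQ uses the sigmoid constants of its original publication
(L = 0.724, x0 = 152.611, k = 0.052, b = 0.018; natural logarithm), an
interface defined by Cβ–Cβ (Cα for glycine) distances ≤ 8 Å, and is 0
by definition with zero contacts.  This 8 Å Cβ interface is deliberately
distinct from the 7 Å heavy-atom interface above: the former belongs to
the score's calibration, the latter to the binding-mode analysis; both
coexist on every pair.  Tier assignment: high iff pDockQ ≥ 0.5,
acceptable iff ≥ 0.23, otherwise *possible* iff ipTM ≥ 0.5 **or**
minimal inter-chain PAE ≤ 10 Å, else low.  The or-combination is the
default because it matches the broader "possible interaction" notion of
transient complexes (high ipTM or locally confident PAE); a conjunctive
variant is a config switch.  ipTM is carried on [0, 1]; percent-style
inputs are rescaled.  iLIS, when present in input tables, is carried
through opaquely and never computed.

## Disorder, coil and conditional folding

Intrinsic structural disorder follows the AlphaFold-derived-disorder
idea: structure-based, not sequence-based.  The default score is the
centered moving average (window 25, shrinking at termini) of relative
solvent accessibility (absolute accessibility divided by the Tien et
al. 2013 theoretical maximum per residue type, clipped to [0, 1]).  A
windowed 1 − pLDDT/100 variant is provided.  The RSA window is the
default because conditional folding — ISD > 0.5 **and** pLDDT > 70 — is
unsatisfiable under a raw inverted-pLDDT score: a residue cannot
simultaneously have pLDDT > 70 and 1 − pLDDT/100 > 0.5.  Both
thresholds are strict inequalities and config-exposed.

Region segmentation is one primitive used three times: maximal
true-runs of a per-residue mask in which internal false-gaps of ≤ 2
residues are bridged *before* a minimum-length filter of 5.  IDRs use
the mask ISD > 0.5 (long iff ≥ 30 residues, short 5–29); coil regions
use 3-state coil (8→3 mapping: H/G/I→H, E/B→E, everything else→C);
CF regions use ISD > 0.5 ∧ pLDDT > 70.  Applying the same
min-length/gap rules to CF regions is a uniformity choice; the rule is
stated in the literature for disorder and coil segmentation only.
Ordered regions are the exact set-complement of the IDR union, so every
residue is either IDR or ordered, never both.

## Binding modes

Flags are assigned per interface region, non-exclusively, by overlap of
the region's member residues (the actual contacting residues, not the
filled span) with the monomer's annotation regions: `ordered`, `idr`
(plus `idr_short`/`idr_long` from the overlapped IDR's kind), `cf`.  A
region overlapping a monomer coil region by at least one residue is
eligible for the coil-to-order test: counts of helix+strand residues
among its members in monomer vs complex secondary structure form a 2×2
table, tested with a one-sided Fisher exact test (exact hypergeometric
tail; degenerate margins give p = 1).  The call requires p < 0.05 *and*
a strictly greater ordered fraction in the complex, so an interface
already fully ordered in the monomer can never be called coil-to-order.
No multiple-testing correction is applied across regions — the cutoff
is a plain per-test 0.05, documented as such.  `disordered` is the
residual IDR mode (IDR but neither CF nor coil-to-order).  When both CF
and coil-to-order criteria hold, both flags are kept; no precedence is
imposed.  PPI-level flags are the union over regions of both chains
(restricted to the ordered/idr/short/long/cf/coil-to-order vocabulary),
and pair-level mode counts are taken over high-tier pairs by default.

## Network analysis

The protein graph has one node per protein and one edge per pair with
pDockQ ≥ 0.5 (duplicates keep the maximum score; self-pairs are
ignored).  Components, degrees (mean = 2E/V) and singleton PPIs
(one-edge components) come from networkx.  Markov clustering is
implemented in-package with the published update rules: self-loops of
weight 1, column-stochastic normalization, expansion (matrix power 2)
alternating with inflation (elementwise power, default 2.0 — the
algorithm's customary default, as no value is fixed by the analysis
this package re-implements) plus pruning at 1e-6, iterated until the
matrix change falls below 1e-8.  Clusters are read from attractor rows;
nodes attached to several attractors go to the largest cluster (ties:
lexicographically smallest member set), so reported clusters always
partition the node set.

The failure-randomness test asks whether per-protein prediction
failures are compatible with chance: success labels are permuted (5,000
times by default) across all attempted pair-slots, holding the total
success count fixed; per-protein empirical p-values use the add-one
estimator (1 + hits)/(n_perm + 1) and are Benjamini–Hochberg adjusted.

## Synthetic data: what it emulates and what it does not

The generator produces complete, file-backed inputs — mmCIF with pLDDT
in B-factors, PAE JSON, DSSP-format records — for dimers whose
interface blocks carry designed modes.  Geometry is idealized
poly-alanine: residues 3.8 Å apart along the chain axis, five heavy
atoms per residue with fixed offsets.  Interface blocks are parallel
traces whose atom clouds sit 6.3 Å apart: directly opposed residues
fall inside the 7 Å cutoff while diagonal neighbours (one residue
along the chain, 3.8 Å away) fall just outside it, so designed spans
are recovered exactly, with no blur at block edges.  Non-interface
residues stay > 12 Å from the partner chain.  Designed ISD is encoded
as DSSP-style integer accessibility (ISD × 129 Å², the alanine
maximum), so the pipeline's windowed-RSA score reproduces the design;
pLDDT carries uniform ±2 noise to keep thresholds off knife edges.
Clean-margin validation requires disorder-carrying blocks to be ≥ 13
residues, ≥ 13 residues apart, and ≥ 13 residues from a terminus
(unless flush against it): inside those margins the 25-residue window
maps the designed 0.9/0.1 ISD contrast back to the exact block span.

Passing the synthetic-recovery tests therefore demonstrates that the
pipeline implements its own definitions exactly; it does *not*
demonstrate robustness to real-structure phenomena the generator omits:
non-ideal geometry, side-chain packing, partial interface occupancy,
correlated pLDDT/PAE noise, or DSSP assignments computed from
coordinates rather than emitted from the design.

Summary-table fixtures realize each requested network component as a
path (a tree with exactly the requested edge count), plus isolated
high-confidence pairs for singletons and sub-threshold decoy rows that
must never enter the graph.

## Numerical choices and problem sizes

Thresholds all live in one `PipelineConfig` and are echoed into every
network report.  The test suite and the acceptance script validate each
stage against independent oracles at sizes chosen to keep the full run
in seconds on one CPU: all 2×2 tables with N ≤ 12 against exhaustive
enumeration (tolerance 1e-12), 200 random dimers of ≤ 60 residues/chain
against all-pairs contact scans, 500 random masks of length ≤ 100
against a reference segmentation, 50 seeded toy dimers for full-mode
recovery, 100 random graphs for handshake/partition invariants, and
3-protein permutation toys against exact enumeration (within three
standard errors).  The internal Shrake–Rupley is cross-checked against
an independent SASA implementation (biotite) on identical radii to ~2%,
the resolution expected from different sphere-point layouts.

## Known limitations

- Binding-mode calls inherit every uncertainty of the upstream
  predictions; a coil-to-order call on a low-confidence interface is a
  hypothesis, not an observation.
- The coil-to-order test uses the full member-residue set of the
  interface region, not only the residues inside the coil region; with
  mixed regions the two choices can differ.
- ISD variant and window are configurable precisely because
  structure-derived disorder has no single canonical parameterization;
  results should cite the variant used.
- MCL on very large graphs uses dense matrices; the intended scale is
  networks of a few thousand proteins.
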