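# Methods

## Genome handling and composition

A genome is an ordered list of replicons; all statistics are taken over
their concatenation, so the reported length and G+C content of a strain
include plasmids and unplaced contigs.  G+C content is
(#G + #C) / (#unambiguous A/C/G/T): IUPAC ambiguity codes and N are
excluded from both numerator and denominator, so unknown bases cannot bias
the composition estimate.  Lowercase (soft-masked) input is uppercased and
U is mapped to T.  The G+C difference between two strains is reported in
percentage points; differences above 1 pp within a species are treated as
advisory conflicts, never as a veto — the dDDH call always stands.

## The matcher

The built-in matcher produces ungapped HSPs deterministically:

1. exact k-mer seeds (default k = 11), with k-mers occurring more than 64
   times in the indexed genome skipped as a low-complexity guard;
2. seeds merged into maximal exact runs along each diagonal;
3. X-drop extension (match +1, mismatch −2, X = 20) outward from each run,
   implemented so that only mismatch positions are visited — runtime is
   proportional to divergence, not genome length;
4. filters: minimum length 100 bp, minimum identity 0.70;
5. both strands (the second genome is also scanned as its reverse
   complement, with coordinates mapped back to the forward strand).

Replicons are concatenated with a spacer of 2k N's before matching so seeds
cannot span replicon joins; spacers contribute to coordinates but never to
the genome lengths used by the distance formulas.  All tie-breaks are fixed
(score desc, length desc, then coordinates), so results are
bit-reproducible.  The matcher is ungapped by design: trimming an ungapped
HSP is exact coordinate slicing and identities can be re-counted on any
slice directly from the sequences.  Gapped alignments from an external
aligner can be imported from BLAST tabular output, but only
ungapped-compatible rows are usable.  The known fidelity gap of the
ungapped design: at high divergence each indel splits an HSP, which
slightly biases per-HSP identity upward near the split; at the divergences
relevant to species and subspecies boundaries (≲ 10%) this bias is well
below the sampling noise of the identity fraction.

**Greedy-with-trimming.**  HSPs are visited in score order; the first is
accepted whole, and each later HSP has the sub-spans overlapping any
accepted footprint on *either* genome removed.  Surviving fragments shorter
than the minimum length are discarded; the accepted set is
footprint-disjoint on both genomes (asserted).  Identities of each fragment
are re-counted on its slice; a trimmed HSP may contribute several disjoint
fragments.

## Distances, dDDH, and the conversion model

With H = Σ HSP lengths, I = Σ identities, L = len_a + len_b over the
trimmed set: coverage d = 1 − 2H/L; identities-per-HSP d = 1 − I/H
("formula 2", the default, appropriate for draft genomes because it is
insensitive to incompleteness); identities-per-total d = 1 − 2I/L.  A pair
with no HSPs has distance 1 under every formula (no evidence of homology);
all distances are clamped to [0, 1].  HSP length is measured on the first
genome's span, which equals the second's for ungapped HSPs.

dDDH is y(d) = 1/(1 + exp(c0 + c1·d)) with c1 > 0.  The default formula-2
coefficients are solved at construction time from two published threshold
anchors of the formula-2 conversion — 70% dDDH at d = 0.0359 (species
boundary) and 79% dDDH at d = 0.0250 (subspecies boundary) — giving
c0 ≈ −2.4203, c1 ≈ 43.819.  The model is then validated against a third,
independent anchor (d = 0.0242 ↦ 79.3% ± 0.5) and construction fails
loudly if it is violated.  No calibrated conversion is provided for the
other two formulas; constructing one requires explicit coefficients.

Classification against the type strain uses ≥ on the dDDH fraction, so a
strain exactly at a boundary is classified as belonging.  The subspecies
threshold defaults to 0.79, the lower edge of the 79–80% band, and is
configurable.

## Clustering and threshold optimization

Threshold clustering starts from singletons and repeatedly merges the
cluster pair with the smallest average inter-cluster distance among pairs
passing the linkage test: the fraction of inter-cluster strain pairs with
d ≤ T must reach F, where F = 0 means "at least one pair" (single linkage;
the result provably equals connected components of {d ≤ T}, which the test
suite checks against an independent graph implementation) and F = 1 means
every pair (complete linkage).  Merge ties break toward the
lexicographically smallest combined member list, making results
deterministic.  Partition agreement is the adjusted Rand index; cluster
summaries exclude singletons and use the lower-middle median convention.

**Clustering consistency** is operationalized as the agreement between the
F = 0 and F = 1 partitions at the same threshold, averaged over the
within-species matrices, with identical partitions scoring 1 even where
the adjusted Rand index is undefined (all singletons, single cluster).
The rationale: on perfectly ultrametric data single and complete linkage
coincide at every threshold, and deviations from ultrametricity are
exactly what makes threshold clustering paradoxical; the F = 0 / F = 1
disagreement is that signal.  The criterion is isolated behind one
function so an alternative formula can be swapped in.

The subspecies threshold is the midpoint of the widest maximal-consistency
plateau over a threshold grid.  Trivial regimes — all singletons at low T,
one cluster at high T — are also perfectly consistent but say nothing
about substructure, so plateaus touching a grid end are only used when no
interior plateau exists, and the result then carries a `degenerate` flag.
A consequence worth knowing: resolving the plateau's lower edge requires
within-group chaining, so groups need at least 3 members; with 2-member
groups the criterion cannot distinguish "below the within-band" from "in
the gap".  A flat-zero profile yields a "no consistent threshold" result
rather than an exception.

## Trees and support

Trees are neighbor joining on the distance matrix (deterministic under
fixed input order), optionally refined by nearest-neighbor interchange
under balanced minimum evolution; this stands in for a full
minimum-evolution search and is adequate at the matrix sizes the package
targets.  Negative NJ branch-length estimates are clamped to zero.
Outgroup rooting places the root on the branch separating the outgroup
clade from the ingroup and errors if the outgroup is not monophyletic.
Branch support comes from pseudo-bootstrap replicates: per replicate and
genome pair, n = |HSPs| HSPs are resampled with replacement and the
distance recomputed; each (seed, replicate, pair) triple has its own RNG
stream, so replicate matrices are reproducible and independent of pair
processing order.  A branch's support is the percentage of replicate trees
containing its bipartition.  Supports ≤ 50 are hidden only at rendering
time; the data layer keeps all values.

## The synthetic cohort generator

The generator draws an ancestor at a configured G+C content (default 0.50)
and evolves it independently down a balanced hierarchy by per-branch
substitutions (uniform over the three alternatives — Jukes–Cantor-like and
composition-neutral), Poisson point indels with geometric lengths (default
rate 1e-5/base, mean 3 bp), and Poisson segment inversions (default 0.2
per branch, 500–2000 bp).  The expected pairwise mismatch between two
leaves is 3/4·(1 − Π(1 − 4p_i/3)) over the branch path, which the truth
record reports per pair.

The default cohort is 3 species × 2 subspecies × 4 strains at 50 kb, with
branch substitution probabilities (0.029, 0.00535, 0.0096) chosen once so
the three pairwise divergence bands map through the default dDDH model
onto the diagnostic ranges: within-subspecies dDDH > 0.80 (~0.019
divergence), between-subspecies 0.72–0.78 (~0.0295), between-species
< 0.60 (~0.084).  Genome length 50 kb keeps a full 276-pair cohort
analysis at interactive speed while leaving the identity-fraction sampling
noise (σ ≈ 0.0008) far smaller than the band separations.

What the simulation does *not* emulate — and hence what passing tests do
not show about real data: recombination and horizontal transfer, repeat
families and mobile elements, compositional heterogeneity along the
genome, assembly artifacts, and contamination.  Real genome cohorts can
violate ultrametricity far more strongly than the simulated ones; the
clustering-consistency plateau can then be narrow or absent, which is
exactly what the `degenerate` / "no consistent threshold" results are for.

## Numerical and interface choices

- Distance matrices are validated on construction (symmetry, zero
  diagonal, range) and are immutable.
- Matrix I/O is square relaxed PHYLIP (labels to 64 chars); partitions are
  two-column TSV; trees are Newick with supports as internal labels.
- One top-level seed drives everything; derived streams are obtained from
  (seed, replicate, pair-label hash), never from object identity or
  iteration order.
- The pipeline falls back to the configured subspecies threshold when the
  consistency scan is degenerate or no within-species matrix has ≥ 2
  members.
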