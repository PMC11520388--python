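# Methods

## Locus model and distance zoning

The locus is an ordered catalog of V, D, J and C segments with 0-based
start coordinates on the locus-forward strand. Distances are absolute
differences of start positions; no anchor convention beyond the start
coordinate is modeled, and strand is ignored (an inverted V gene such as a
TRBV30 ortholog is zoned purely by position).

Functional V genes are partitioned into distal/middle/proximal blocks by
the two largest gaps between consecutive functional V genes. The block
with the largest mean distance to the analysis D gene is distal, the
smallest proximal. Ties between equal gaps are resolved by preferring the
gap pair that maximizes the minimum block size, then the 5'-most gaps —
deterministic and biased toward balanced blocks. Explicit boundaries can
be supplied instead when a published per-species partition is to be
reproduced verbatim.

J zoning follows fixed positional rules per D–J cluster analysis. For
D1-J, the two first-cluster J genes closest to D1 are proximal and the
last J gene of the last reachable cluster is distal; for D2-J2 (and D3-J
on loci with a third cluster) the first and last J genes of that cluster
are proximal and distal respectively; everything else is middle.
Zoning is invariant under coordinate translation and positive scaling,
and zone blocks are always contiguous in locus order.

## RIC scoring

An RSS is stored heptamer-first (heptamer → spacer → nonamer), so V-3' and
D-3' RSSs are 23-spacer (39 nt) and D-5' and J-5' RSSs are 12-spacer
(28 nt). A J RSS written nonamer-first on the genome is reversed into this
order at ingest. Only `ACGT` is accepted; ambiguity codes are rejected
rather than marginalized.

The score of sequence *s* is `Σ_g ln P_g(s[g])` over the canonical
correlated-position partitions (18 groups over positions 1–39 for the
23-spacer model, 13 groups over 1–28 for the 12-spacer model). Training
estimates each group's tuple distribution by pseudocounted empirical
frequency: for a group of arity *k*,
`P(t) = (count(t) + c) / (n + c·4^k)`. The pseudocount *c* defaults to 1.0
(Laplace): the high-arity groups (up to arity 7, 4⁷ tuples) would
otherwise assign probability zero — and score −∞ — to any unseen tuple on
realistically small training sets. A zero-probability tuple under *c* = 0
is reported as a non-finite score with a distinct flag rather than a
label. Models are serializable to JSON (grouping, tables, pseudocount,
training-set size) so externally trained parameters can drive scoring.

Classification is strict: a score is *very low* iff it is below −45.0
(−45 itself is normal). By default one model per RSS kind (12/23) is
trained; per-species models are possible by training on per-species FASTA
catalogs.

The published parameter values of the original RIC service are not
shipped; scores computed from self-trained models share the scale and
ordering behaviour but not the exact printed per-gene values.

## Clonotype filtering and usage

The productive filter retains a clonotype iff its CDR3 amino-acid
sequence contains neither `_` nor `*`, starts with `C` and ends with `F`,
and both its V and J calls are IMGT-functionality `F`. Removed records
are attributed to the first violated rule in that order, so per-rule
removal counts are reproducible; the surviving set is independent of rule
order and the filter is idempotent. Genes absent from the functionality
map are conservatively treated as non-functional.

A *unique clonotype* is a distinct (sample, CDR3 aa, V call, J call)
tuple. Usage frequencies default to the unique-clonotype basis (each
tuple counts once); a count-weighted basis is available for sensitivity
analyses. Frequencies are computed per sample and averaged across samples
where a single per-gene value is needed, rather than pooling samples
first.

Recombination patterns: a J call in cluster 1 forces D1 (a downstream D
cannot join an upstream J under the 12/23 rule); in cluster ≥ 2 the D call
disambiguates between V-D1-J2 and V-D2-J2, a missing D call yields the
ambiguous `V-D?-J2` (counted toward V and J usage, excluded from per-D
pattern tallies), and a D call downstream of the J's cluster is flagged
`12/23-violating` instead of being silently classified.

## Statistics

- **Kruskal–Wallis** across zones: tie-corrected H with a chi-square
  (k−1 df) p-value; a fully constant input returns H = 0, p = 1.
- **Mann–Whitney U**: exact p by enumeration when n₁+n₂ ≤ 12 and the
  pooled sample is tie-free, otherwise the tie-corrected normal
  approximation with continuity correction. Both tests are computed with
  scipy behind the module surface and verified in the test suite against
  full-enumeration and rank-formula oracles on all small inputs.
- **Rank correlation**: Spearman's ρ (chosen over Pearson for the
  heavy-tailed frequency scale; Pearson selectable). For n < 30 the
  p-value is a seeded permutation test (10,000 permutations, add-one
  estimator); for larger n the t-approximation.
- Zone comparisons treat **each gene as one observation** (its frequency
  averaged over samples), matching per-gene granularity; per-sample
  observations can be formed by the caller from the usage profile.
- Significance stars: `*` < 0.05, `**` < 0.01, `***` < 0.001; raw
  p-values, no multiple-testing correction.
- The low-RIC test is one-sided (*less*): very-low-RIC genes are tested
  for reduced usage against normal-RIC genes; it is reported as
  not-testable when either side of the threshold is empty.

## Synthetic-data generator

The generator emulates the structure of a human-like TRB locus and a
multi-sample repertoire study:

- **Locus**: 24 functional V genes in three contiguous blocks of 8
  separated by 100 kb gaps (intra-block spacing ~5 kb, ≥ 10× smaller, so
  the gap-based zoning recovers the generative blocks), two interleaved V
  pseudogenes, then two D-J-C clusters with 6 + 7 J genes — mirroring the
  human D1/J1 and D2/J2 organization. A configuration whose gaps are
  smaller than 10× the intra-block spacing is flagged in the ground truth
  as not guaranteeing zone recovery.
- **RSSs**: consensus heptamer/nonamer around a uniform-random spacer,
  then per-position substitution at rate 0.05. A configurable subset of V
  genes is degraded at rate 0.65 instead; under the self-trained model
  these genes score well below −45 (normal-rate genes score about −40 ± 2
  and fall below −45 in roughly 1% of cases, degraded genes in ~99%).
  The two rates were chosen so that "degraded" reliably means *very low*
  on the −45 scale while normal genes stay clear of it.
- **Usage**: per-gene weight `w_g ∝ exp(α_zone(g) + β·RIC_g)` normalized
  within each segment; V and J draws are independent (no V–J pairing
  structure is modeled). Defaults: α = (distal 1.0, middle 0.0,
  proximal 1.2), β = 0.15, 50,000 clonotypes × 3 samples.
- **CDR3s** are random amino-acid strings of length 8–20 framed by C…F,
  distinct within a sample; they carry no biological motif content and
  exist to exercise the filters. Disjoint fractions are corrupted:
  unproductive (`_`/`*` inserted, 5%), frame-broken (3%), V call
  reassigned to a pseudogene (2%). Counts follow a geometric law; D calls
  are present for 70% of records.

Everything is deterministic given the seed; the ground truth (weights,
zones, degraded genes, per-gene scores) is serialized next to the outputs.

What passing tests on this generator do **not** show about real data: no
read-level error, PCR amplification bias, clonal expansion or thymic
selection is modeled; V–J usage is independent by construction; CDR3
content is biologically meaningless; and the self-trained RIC scale is
tied to the simulated catalog, not to the published model parameters.

## Problem sizes

The seed sweeps run 100 seeds at 50,000 clonotypes × 3 samples per seed
for both the zone-ordering and low-RIC recovery experiments, and 2,000
replicates for the null calibration of the zone test (three zones of 8
genes, flat-Dirichlet frequencies). Scorer/oracle agreement is checked on
200 random model/query pairs per RSS kind at training sizes ≤ 20.

## Known limitations

- The published per-species V-zone gap cutoffs are not shipped; the
  two-largest-gaps rule is a reconstruction, with explicit boundaries as
  the faithful fallback.
- Printed per-gene RIC values from the original service are reproducible
  only with its trained parameters (loadable via the model JSON format),
  not with self-trained models.
- `V-D?-J2` ambiguity is resolved by exclusion from per-D tallies, which
  undercounts D1/D2 pattern totals when D calls are sparse.
- The exact Mann–Whitney path requires tie-free data; heavily tied small
  samples fall back to the corrected normal approximation.
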