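# vdjbias

Analysis of V/J gene usage bias in the T-cell receptor β (TRB) locus.

During V(D)J recombination, the frequency with which a given TRBV or TRBJ
gene ends up in the CDR3 repertoire is shaped by at least two locus-level
factors: the gene's physical distance to the D gene it recombines with
(genes are grouped as **distal**, **middle**, or **proximal**), and the
quality of its flanking **recombination signal sequence** (RSS: conserved
heptamer `CACAGTG`, a 12- or 23-nt spacer, conserved nonamer `ACAAAAACC`).
RSS quality is summarized by the **RIC score** (Recombination Information
Content), a log-likelihood of the RSS under a grouped-position probability
model:

```
RIC = Σ_g ln P_g( s[g] )
```

where the positions of the 39-nt (23-spacer) or 28-nt (12-spacer) RSS are
partitioned into groups *g* of correlated sites and `P_g` is the joint
nucleotide-tuple probability of group *g* estimated from a training set of
RSSs (with a Laplace pseudocount). Scores run from very negative (poor
substrate) to 0; functional V RSSs scoring **below −45** are classified as
*very low* and are expected to recombine poorly.

The package provides, for bulk (MiXCR-style TSV) and single-cell
(10x-style CSV) clonotype tables:

- a TRB locus model with gene distances and distal/middle/proximal zoning
  (two-largest-gaps rule for V genes, fixed positional rules per D–J
  cluster for J genes) — `vdjbias.locus`;
- RIC training, scoring and classification for 12- and 23-spacer RSSs —
  `vdjbias.ric`;
- clonotype ingest, the productive-CDR3 filter chain (no `_`/`*`,
  `C…F` frame, functional V and J genes only), recombination-pattern
  classification (V-D1-J1 / V-D1-J2 / V-D2-J2), and per-sample usage
  frequencies over unique clonotypes — `vdjbias.clonotypes`;
- the bias statistics: Kruskal–Wallis across zones, pairwise Mann–Whitney,
  Spearman correlation of RIC with usage, and the one-sided test of reduced
  usage for very-low-RIC genes — `vdjbias.stats`;
- a synthetic-data generator with known ground truth (zone effects and an
  RSS-quality effect drive per-gene usage weights through a softmax) —
  `vdjbias.simulate`;
- pipeline orchestration with a deterministic report bundle —
  `vdjbias.pipeline`, driven by the numbered scripts under `analysis/`.

## Worked example

```bash
python analysis/01_simulate.py --seed 1     # synthetic locus, RSSs, 3 samples
python analysis/02_run_pipeline.py --seed 1 # filter -> zones -> RIC -> stats
```

prints (abridged):

```
locus: 43 genes (24 functional V, 13 J in 2 clusters)
catalog: 41 RSSs; degraded V genes: ['TRBV10', 'TRBV17', 'TRBV3', 'TRBV6', 'TRBV7']
V RSSs scoring below -45 under the self-trained model: 6
repertoire: 30000 clonotypes across 3 samples -> results/sim
filter removals: {'underscore_star': 1443, 'frame': 878, 'non_f_gene': 649}
recombination patterns: {'V-D1-J1': 13921, 'V-D1-J2': 4561, 'V-D2-J2': 4594, 'V-D?-J2': 3954}
V zones: frequency ordering P>D>M (KW p = 0.039), RIC ordering M>P>D
low-RIC effect: very_low mean 0.0146 vs normal 0.0507, one-sided p = 0.00077
```

Reading this: the simulation placed proximal and distal V genes at higher
generative usage than middle ones, and the pipeline recovers exactly that
ordering (`P>D>M`, P = proximal, D = distal, M = middle) from the filtered
clonotypes. Five V genes were given degraded RSSs; the genes whose
self-trained RIC score falls below −45 are used at a mean frequency of
1.5% versus 5.1% for normal-RSS genes, a significant reduction (one-sided
Mann–Whitney p = 7.7 × 10⁻⁴).

`analysis/03_recovery_sweeps.py` repeats this across seeds and
`analysis/04_null_calibration.py` checks the zone test's type-I error.

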