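# Methods

## The activation score

`pasflow` quantifies the activity of an intracellular signaling pathway (ISP)
in a case sample relative to a control group as a pathway activation strength

    PAS_p = Σ_n  ARR_{n,p} · BTIF_n · log10(CNR_n)

summed over the pathway's member genes *n*:

* **CNR** (case-to-normal ratio) — the gene's expression in the case sample
  divided by its mean expression across the control group. A pseudocount is
  added to numerator and denominator: 1 for raw counts, half the smallest
  nonzero value for pre-normalized input. This keeps ratios finite at zero
  counts without disturbing the ordering of expressed genes.
* **BTIF** (beyond-tolerance-interval flag) — a binary gate that admits a
  gene into the sum only when (i) its expression is significantly outside
  the control tolerance interval (two-sided Gaussian tail probability of the
  log value under the control-fitted normal, p < 0.05, strict) and (ii) its
  CNR leaves the indifference band, falling strictly below 0.66 or strictly
  above 1.5. Genes drifting within the band contribute nothing, which makes
  PAS robust to diffuse low-level noise but also discrete (see *Calibration*).
* **ARR** (activator/repressor role) — a signed weight from the knowledge
  base: positive for genes whose products activate the pathway, negative for
  repressors. The default magnitude is 1; the file formats accept graded
  weights (e.g. ±0.5 for non-rate-limiting members) and the engine honours
  them.

The logarithm base is 10, so one significant activator at 10-fold induction
contributes exactly +1. Any other base would rescale all PAS uniformly; the
0.1 threshold used for strong inverse regulation (below) presumes base 10.

A pathway's *group* PAS for an (arm, time point) is the mean of its per-case-
sample PAS values (median available via configuration). Members absent from
the expression matrix contribute 0 and are reported through a per-pathway
coverage fraction, logged as a warning by the pipeline rather than treated
as an error.

## Significance machinery

For each pathway, control samples are scored against the whole control set
(each control inside its own reference) to give a null PAS distribution; a
Gaussian fitted to it yields a two-sided per-sample p-value for each case
sample. Group-level significance comes from a two-sided Wilcoxon rank-sum
(Mann–Whitney) test of case-sample PAS against control-sample PAS, with
Benjamini–Hochberg FDR across all pathways of the profile.

One numerical subtlety matters here: a control sample scored against a
reference that contains itself has both its CNR and its tolerance z-score
shrunk toward null, so self-inclusive control PAS values are systematically
less dispersed than case PAS values. Under a global null this makes the
rank-sum anti-conservative (we measured ≈7% rejection at nominal 5%).
The control PAS values entering the rank-sum are therefore computed
leave-one-out (each control scored against the remaining controls), which
restores exchangeability and empirical calibration (≈4.6% mean rejection
over twelve seed batches). The *reported* control PAS keeps the
self-inclusive whole-set convention; `PASConfig.group_test_reference =
"whole"` restores it for the test as well. With only two controls
leave-one-out is impossible and the whole-set reference is used.

Degenerate cases: a pathway whose PAS values are all identical in both
groups gets group p = 1; a zero-spread control PAS distribution gives
per-sample p = 1 when the case PAS equals the constant and 0 otherwise.

## Differential expression

The upstream contrast is always (arm, time) vs sham at the same time point —
sham laparotomy is the baseline arm of the design. The default engine is a
Welch two-sample t-test on log2(x + c) per gene (pluggable via the `test`
argument), with log2FC = log2((mean_case + c)/(mean_sham + c)). Candidate
genes satisfy |log2FC| ≥ 1 and p ≤ 0.05, both boundaries inclusive. This is
a deliberately simple, reproducible stand-in for a count-model DE engine:
downstream pathway scoring consumes only fold changes and significance
flags, and dispersion-shrinkage methods are out of scope. Phase-overlap
sets intersect the candidate sets over the early (1, 8 h) or late (16, 32,
48 h) phase.

## Cross-arm classification

At each time point every pathway receives exactly one category from the
signs of its group PAS in the two arms: `common_activated`/`common_silenced`
(same sign), `unique_<arm>_activated`/`..._silenced` (signed in one arm,
neutral in the other), `inverse` (opposite signs), or `neutral`. By default
the status is the PAS sign alone (PAS exactly 0 is neutral); a stricter mode
additionally requires group FDR ≤ 0.05 (`gate="fdr"`). Cross-time totals of
unique counts are sums over time points — a pathway unique at two time
points counts twice.

An inverse pathway is *strongly* inversely regulated when its activation
magnitude reaches 0.1: the criterion is max(|PAS_nHx|, |PAS_eHx|) ≥ 0.1
(inclusive). The alternative reading — the arithmetic difference
|PAS_nHx − PAS_eHx| ≥ 0.1 — is available via `criterion="difference"`. The
per-arm-magnitude default was chosen because every published example of a
strongly inverse pathway in the reference hepatectomy study is quoted by a
single per-arm PAS magnitude ≥ 0.1.

Profile summaries: average-linkage hierarchical clustering of samples with
Pearson distance 1 − r (Euclidean selectable — the reference study describes
both), with columns pre-sorted lexicographically so equal-height merges are
deterministic; PCA via SVD on the column-centered matrix with an explicit
rank check; and a Pearson correlation matrix ordered by the clustering leaf
order. Constant columns are an error under correlation-based distances, and
the pipeline skips (with a warning) profile summaries at time points where a
sample's PAS vector is constant — typical when nothing is regulated and all
PAS are 0.

## miRNA projection

Target tables are consumed pre-built (mirna_id, target_gene, evidence);
no database is queried. A target is trusted only with expression support:
total raw read count across all samples ≥ 10 (inclusive; the permissive
reading of a per-study read filter, not scoped to any one sample). The
projection of a miRNA onto a pathway evaluates the PAS sum over only the
pathway members targeted by that miRNA, with each targeted member's CNR
inverted — the contribution enters as repression, reflecting the canonically
repressive action of a miRNA on its targets. This inversion is an explicit
modelling convention of this package. The projection is additive over
disjoint target sets by construction.

## Synthetic studies

The generator emulates the reference design — arms sham/nHx/eHx × time
points 1, 8, 16, 32, 48 h × 3 replicates — at a desk scale of 200 genes in
20 pathways (5–15 genes each, 70% activators). Baseline per-gene means are
log-normal (log2 mean 7, log2 sd 1.5); samples add multiplicative log-normal
noise with log2 sd 0.25. A planted "up" effect on a pathway multiplies its
activators' expected expression by the fold change and divides its
repressors by it (reversed for "down") in one arm at one time point, so the
planted pathway has a coherent expected PAS sign. A negative-binomial count
mode (dispersion 0.1) supports the paths needing integer reads (CPM, the
miRNA read filter). All outputs are fully determined by the seed.

What the generator does *not* emulate: mean–variance coupling of real
RNA-seq beyond the NB mode, library-size variation, correlated co-expression
outside planted pathways, and the temporal autocorrelation of a real
regeneration time course. Passing recovery tests therefore demonstrate the
engine's statistical behaviour under its own model assumptions, not
biological fidelity.

### Calibration and recovery settings

* Planted-effect recovery uses the default configuration above with a single
  4-fold effect and 50 seeded replicates; the planted pathway attains the
  largest |group PAS| in ≥ 90% of replicates (observed: 100%).
* The null-calibration run uses 8 replicates per arm and 40–60-gene
  pathways (10 pathways, 600 genes, 40 simulation replicates). Two features
  of the default design make the 5% level unreachable there and motivate
  this choice: the exact two-sided rank-sum on 3-vs-3 samples cannot produce
  p ≤ 0.05 at all (its minimum is 0.1), and with 5–15-gene pathways the
  BTIF gate leaves most per-sample PAS exactly 0, so the test statistic is
  dominated by ties. Larger groups and larger pathways make the statistic
  effectively continuous, which is what a calibration question presumes.

## Known limitations

* PAS is membership-and-role only; no signal propagation along pathway
  topology, and no gene-set enrichment statistics.
* The Gaussian tolerance interval uses the normal rather than a t
  distribution, so gene-level p-values are slightly liberal at very small
  control groups; the BTIF band condition masks most of this in practice.
* With 3 replicates per arm the group rank-sum is structurally conservative
  (see above); group FDR at that design is informative only as a ranking.
* The classification gate default (`sign`) counts any nonzero group PAS;
  with continuous expression input, exact zeros occur only when no member
  passes the BTIF gate.
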