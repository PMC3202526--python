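# Methods

This note records the models, estimators, defaults and numerical choices
behind `ricenet`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Network model

All-pairs Pearson correlation is computed across every individual array
(replicates are not averaged first: the correlation is meant to exploit
the full spatiotemporal resolution of the compendium, and averaging would
discard within-category variation). Rows are centered and scaled once so
the full matrix is an exact product of standardized rows; the product is
evaluated in row blocks with bounded working memory, and the result is
independent of the block size up to floating-point summation order
(~1e-15; edge sets are identical in practice and tested to be so).
The matrix is symmetrized, clipped to [−1, 1], and the diagonal forced to
exactly 1. Constant rows are rejected at correlation time and filtered
with a warning at load time.

The PCC cutoff is an empirical null quantile: `n_random` genes (default
1,000) are sampled uniformly without replacement with a mandatory seed,
all pairwise PCCs among them computed, and the requested percentile
(default 99, linear interpolation) returned together with its provenance
(sample size, pair count, percentile, seed). For iid normal profiles the
quantile has the closed form r\* = t\*/√(m − 2 + t\*²) with t\* the
matching one-sided t(m − 2) quantile; `analytic_null_pcc_quantile` exposes
it and the test suite checks the calibration against it at m = 176.

Mutual rank uses the full ranking: rank_i(j) is j's position when **all**
other genes on the platform are sorted by PCC(i, ·) descending, rank 1
being the strongest partner. Ranking only among pairs that already passed
the PCC cutoff would inflate ranks and is deliberately not done. Ties are
broken by stable gene order (deterministic); fractional (average) ranks
are available as an option. MR(i, j) = √(rank_i(j) · rank_j(i)) is
symmetric and lies in [1, N − 1], with MR = 1 exactly for reciprocal best
partners.

An edge is retained iff PCC > pcc_min **and** MR < mr_max, both strict
(defaults 0.64 and 10, the values used with the classical 176-array rice
compendium; the 0.64 default follows the figure-legend convention of that
analysis). Nodes are genes with at least one retained edge. Raising
pcc_min or lowering mr_max can only remove edges (tested monotonicity).

## Subnetwork extraction

The guide vicinity is a breadth-first search of radius `steps` (default 2)
from every resolvable guide over the undirected retained-edge set, and the
subgraph **induced** on the reached nodes: an edge between two peripheral
genes is kept even if neither is adjacent to a guide. The induced reading
was chosen because published subnetwork figures display interconnections
among non-guide genes; a BFS-tree-only reading would hide them.
Unresolvable guides are reported, and only an entirely unresolvable guide
set is an error. Components are reported largest-first with their guide
membership.

## Expression coherence and enrichment

EC of a set is the exceedance fraction of its pairs at the calibrated PCC
cutoff, over set members present in the matrix after duplicate removal
(≥ 2 required). Null distributions use size-matched uniform random sets,
1,000 draws by default; draws are shared between categories of equal size
(one seeded null per size) since the null depends on size only. The
empirical p is the plain fraction of null draws ≥ observed (0 is
possible by construction and means "none of the draws reached it").
Categories need ≥ 10 members to be EC-eligible; smaller categories stay
in the catalog for enrichment. The category-level curve reports, per
namespace and per threshold t, the fraction of categories with EC > t and
the paired null curve (mean over draws); both the curve comparison and
the per-category empirical p are emitted, since either can be used to
summarize coherence against the null.

Enrichment is the one-sided upper hypergeometric tail P(X ≥ k) computed
with `scipy.stats.hypergeom` (tested against exact rational enumeration
to 1e-12 for every instance with N ≤ 30). The background defaults to the
connected genes of the parent network and can be switched to all platform
genes. No multiple-testing correction is applied by default, matching the
classical protocol this pipeline follows; a Benjamini–Hochberg option
exists. Query genes outside the background are dropped with a warning.

## Tissue preference

Each gene takes the category of the single array with its maximal value
(the replicate-mean variant is available since single-array maxima are
noisy). Exact ties resolve to the lexicographically first category, then
first array in compendium order, and are logged. By default the
classification runs on normalized values.

## Variance-stabilizing normalization

The model family is the generalized-log (arsinh) transform with per-array
affine calibration, h_s(y) = glog((y − a_s)/b_s), glog(z) = arsinh(z)/ln 2.
Note glog(z) − log2(2z) → 0 for large z (within 0.01 beyond z ≈ 8), i.e.
the transform is log2-like up to a constant 1. The estimator is
deliberately simpler than a full robust maximum-likelihood fit and has
two stages:

1. **Relative calibration.** Per array, (a, b) minimize the trimmed
   (default trim 0.1, three refit rounds, Levenberg–Marquardt over
   (a, log b)) squared distance between glog((y − a)/b) and the
   glog-transformed median pseudo-array. This matches arrays to a common
   scale and is robust to a modest fraction of differentially expressed
   genes.
2. **Gauge fixing.** The affine family leaves one global offset/scale
   free, and the raw pseudo-array's gauge retains the shared background,
   which defeats variance stabilization. The per-gene SD across calibrated
   arrays is therefore binned by mean level (20 equal-count bins) and
   modelled as sd(m)² = (M·(m − α))² + A²; the stabilizing gauge is
   offset α (the intensity intercept of the multiplicative regime,
   clipped to at most 75% of the dimmest bin) and scale λ = A/M (floored
   at a quarter of the background-corrected dimmest-bin level so the low
   end never enters the steep near-linear region). Both are folded into
   every array: a_s ← a_s + b_s α, b_s ← b_s λ. When the data show no
   intensity-dependent variance (identical or noiseless arrays) the gauge
   falls back to the identity.

Because one global affine map on the glog argument is unidentifiable,
"parameter recovery" is assessed after aligning fitted to true parameters
by a single global scale and offset (medians across arrays). Under the
generator's intensity model at 5,000 genes the aligned gain is recovered
to ~1% (median) and the offset to ~3% (median); offsets of the weakest-
gain arrays are information-limited by the additive noise floor and can
individually deviate by ~20%. `passthrough` and plain `log2` modes exist
for pre-normalized matrices; the classical protocol's "log2 after VSN" is
read as a reporting convention (values on a log2-like scale), not a second
transform, with the transform choice exposed in config.

## Synthetic compendium generator

The generator emulates the shape of the spatiotemporal rice compendium:
176 arrays in 24 categories, each category receiving at least 3
replicates with the remaining 104 arrays distributed round-robin (the
real compendium is likewise uneven across categories). Module genes
follow a single-factor Gaussian model x = μ_g + σ(√ρ f + √(1 − ρ) ε)
with expected pair correlation exactly ρ (default 0.8, 10 modules of 20
genes in 2,000); each module's factor carries a standardized additive
mean shift (default effect 3.0 before standardization) in the module's
preferred category, so module genes are simultaneously co-expressed and
tissue-preferential without changing the pairwise correlation. Non-module
genes are iid across samples, so null-quantile checks transfer directly
to the analytic m = 176 formula.

Defaults on the intensity side: baseline natural-log level μ_g ~
N(7, 1.5²); per-sample biological variation σ = 0.4 (≈ 1.5-fold replicate
variation, chosen so replicate differences are biologically realistic
relative to technical noise); raw intensities y = b_s(k_s + exp(x +
ε_mult)) + ε_add with per-array gain b_s = exp(N(0, 0.25²)), background
k_s ~ U(80, 120), multiplicative noise sd 0.25 (natural log) and additive
noise sd 30 intensity units, floored at 0.5 to keep the matrix strictly
positive in the far additive tail. These values give a raw
replicate-difference SD spanning two orders of magnitude across intensity
deciles and a near-flat profile after normalization.

What the generator does **not** emulate: probe-level structure and
probe→gene multiplicity, spatial/dye array artifacts, batch effects
between data sources, heavy-tailed or non-Gaussian biological variation,
GO-term overlap/DAG structure (terms are disjoint module labels plus
random background sets), or correlated background genes. Passing the
planted-structure tests therefore demonstrates that the estimators do
what they claim under the stated model, not that thresholds tuned here
transfer to any particular real compendium — the calibration step exists
precisely because real null distributions are wider than the iid one.

## Degenerate inputs and other numerical choices

- Rows with > 20% missing values are dropped at load; remaining gaps are
  imputed with the row median so ranking sees a dense matrix (mutual rank
  needs a complete ordering; pairwise-complete correlation is not used).
- Constant rows are excluded from correlation with a warning; reaching
  the correlation step with one is a hard error.
- Probe collapsing aggregates per-sample by median (robust to one bad
  probe); mean and max are options. Unmapped probes are a hard error by
  default, droppable with a warning.
- Identifier handling trims whitespace and preserves case; non-RAP-DB-
  shaped identifiers only produce a warning so synthetic and foreign IDs
  pass.
- Every stochastic stage (calibration sampling, EC nulls, simulation)
  requires an explicit seed; the pipeline derives all stage seeds from
  the single config seed, and reruns with identical config and inputs are
  byte-identical.
- `log2` mode masks non-positive calibrated values to NaN and row-imputes
  them rather than emitting −inf.

## Problem sizes used in the checks

The acceptance script and test suite run at desk scale: oracle
equivalence on ≥ 100 randomized fixtures of up to 50 genes, calibration
checks on 1,000–1,200-gene iid compendia with 176 arrays, normalization
recovery at 5,000 genes, and planted-structure recovery at the generator
defaults (2,000 genes). The blockwise computation contract is what makes
the same code applicable to platform-scale matrices (~30k genes), where
the full PCC matrix is processed in row blocks.

## Known limitations

- The VSN estimator is a simplification; strongly unbalanced designs
  with many differentially expressed genes may exceed what a 10% trim
  absorbs, and the global gauge assumes a shared noise structure across
  arrays (per-array additive noise scales are not fitted individually).
- Flat GO catalogs only: no ancestor propagation over the GO DAG.
- Empirical p-values from 1,000 draws have a resolution floor of 1e-3.
- The mutual-rank stage materializes rank rows per block; at ~30k genes
  the full MR matrix is large, and the practical route is filtering to
  PCC-passing candidate pairs during the blockwise pass.
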