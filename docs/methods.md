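# Methods

## The weighted gene–lifespan screen

Each gene *j* is fitted marginally by weighted least squares:
lifespan change *yᵢ* (percent vs wild type) on expression log2
fold-change *xᵢⱼ*, over the strains present in both the phenotype table
and the compendium, minimising Σ wᵢ (yᵢ − β₀ − β₁ⱼxᵢⱼ)² with
wᵢ = nᵢ/(nᵢ + offset). The offset defaults to 50 cells: a strain assayed
on 50 cells gets weight 0.5, one on 150 cells 0.75, and the weight
approaches 1 for large assays, encoding that lifespan means from few
dissected mother cells are noisy.

Inference on β₁ⱼ follows standard WLS theory: with x centred at its
weighted mean, Var(β̂₁) = σ̂²/Σwᵢ(xᵢ−x̄_w)² where σ̂² = RSS_w/(m−2) and m is
the number of strains entering that gene's fit; a two-sided t test on m−2
degrees of freedom yields the ranking p-value. This choice makes every
reported statistic invariant to rescaling all weights by a positive
constant — only relative reliability matters. BH q-values are reported
but the ranking is by raw p; ties break by larger |slope|, then gene id,
so output is deterministic.

Per-gene missing expression values are handled by complete-case analysis;
genes with fewer than `min_strains` (default 10) informative strains, an
all-missing column, or zero expression variance are reported in a skipped
list with a reason rather than silently dropped. The screen is marginal by
design: one gene at a time, no joint or regularised model, and no causal
claim — it is a ranking device for follow-up experiments.

## Survival statistics

Lifespan records carry a group label, a positive lifespan in the assay's
unit (divisions, days or months) and an observed flag; `observed=False`
marks right-censoring (e.g. worms lost from a plate). Group means use
observed lifespans only; medians come from the sample when nothing is
censored and from the Kaplan–Meier curve otherwise. The KM estimator is
delegated to lifelines. Percent extension between group means is
100·(m_t − m_c)/m_c, reported rounded to one decimal (the headline
convention) alongside full precision.

The two-group log-rank test is implemented directly as the
counting-process tabulation — at each distinct event time, the
observed-minus-expected events in one group under the hypergeometric
null, with the hypergeometric variance and no continuity correction;
χ² = (ΣO−E)²/ΣV against χ²₁. The in-package implementation is vectorised
so thousands of simulated tests run in under a second; the test suite
cross-checks it against lifelines (agreement to 1e−9), a hand tabulation,
and a permutation oracle.

LOESS dose–response smoothing uses local linear fits with tricube weights,
span 0.75 and no robustness iterations by default (statsmodels `lowess`
with `it=0`). Local linear fitting reproduces straight-line input exactly,
which the tests assert; an independently coded local-regression oracle
pins the convention (neighbourhood size ⌈span·n⌉, bandwidth = distance to
the k-th nearest point).

## DEG calling and stratification

A gene is a DEG when |log2FC| > 1 and BH-adjusted p < 0.05 (both
configurable). The module prefers externally supplied per-gene statistics
(`gene_id  log2fc  p_value  q_value`), keeping the stratification
analyses independent of any particular DE engine; the built-in fallback
is a Welch two-sample t test on log2(FPKM+1), with log2FC defined on the
same transform. The +1 pseudocount means very low-abundance genes are
compressed toward zero fold change — a deliberate conservative property.

Stratification of a called DEG set:

* **Promoter state** — proportions of active promoters among up- and
  down-regulated DEGs, compared by a Pearson 2×2 chi-squared test
  (no continuity correction, 1 df). A zero margin leaves the test
  undefined (NaN) while the proportions are still returned. States come
  from a per-gene label table, or from BED4 chromatin-state segments
  mapped to genes by overlap with a TSS ± 1 kb window: BED coordinates
  are 0-based half-open, TSS positions 1-based, so TSS *t* spans the
  window [t−1−1000, t+1000); the segment with the largest overlap wins,
  ties preferring `active`, then the leftmost segment.
* **Abundance bins** — total control FPKM (sum over control replicates)
  assigns each gene to low/middle/high/extremely-high. The
  extremely-high class is *strictly* above its edge, 5000 by default;
  the two lower edges default to tertiles of the totals at or below
  5000, configurable. Per-bin up/down DEG counts and their ratio are
  reported, with an undefined ratio flagged as NaN when no gene is down.
* **Shared DEGs** — for every non-empty subset of tissues, the exact
  intersection size and the exclusive Venn-region size, separately for
  up and down; region sizes sum to the union cardinality.
* **Term enrichment** — one-sided Fisher exact p from the
  hypergeometric upper tail per term, BH across tested terms, sorted by
  p. One-sided because only over-representation is of interest.

## Synthetic data generators

All generators draw from `numpy.random.default_rng(seed)` (PCG64), so a
seed fully determines the output on any platform.

**Screen datasets.** Expression log2FC entries are standard normal;
lifespan change is y = Σ β_d x_d + ε with ε ~ N(0, σ²(n+50)/n) and cell
counts n uniform on 5–120 (typical microdissection assay sizes). Tying
the noise variance to (n+50)/n is the generator's own construction: it
makes w = n/(n+50) exactly the inverse-variance weight, so the screen is
evaluated under the conditions its weighting assumes. Defaults — driver
slope magnitudes uniform on 4–10 % lifespan change per log2 fold-change
with random sign, σ = 10 — reflect deletion-collection lifespan changes
spanning roughly ±50%. With several drivers each marginal per-gene fit
sees the other drivers as extra residual variance, so slope recovery is
exact only in the single-driver noiseless limit.

**Lifespan cohorts.** Gompertz-distributed lifespans (the standard
demographic mortality model), shape solved numerically so the
coefficient of variation equals `dispersion` (default 0.25, mouse-like)
and scale set so the distribution mean hits each group's target; a CV
outside the Gompertz-attainable range raises. Censoring is independent:
with probability `censor_frac` an individual is censored at a uniform
time before its death.

**Expression experiments.** Baseline FPKM is log-normal (natural-log
mean 2, sd 2.2), heavy-tailed so with four replicates roughly 1% of
genes exceed the 5000 total-FPKM class. Planted DEGs (default 100 at
|log2FC| = 2, 60% down) are drawn among genes with baseline ≥ 10 FPKM —
where a twofold-plus change is detectable on the log2(FPKM+1) transform;
replicate noise is multiplicative log-normal (sd 0.2, a typical
biological CV for bulk RNA-seq). Promoter activity is Bernoulli with
probability increasing in log10 baseline abundance and boosted for
planted-down genes; term annotation contains random background terms
plus one term planted to be enriched in the down set. The optional
`abundance_down_bias` makes the probability of a planted DEG being
down-regulated rise with abundance, reproducing the declining
up/down ratio across abundance bins.

What the generators do *not* emulate: read-level noise, FPKM
normalisation artefacts, batch effects, correlated genes, or
cell-type mixtures. Passing tests therefore demonstrate the statistical
machinery is correct under its stated model, not that any biological
dataset satisfies that model.

## Pipeline and numerical conventions

The end-to-end runner simulates each input type, executes
simulate→screen, cohort→survival, and experiment→DEGs→stratify→enrich,
and writes every result TSV plus a manifest recording the package
version, seed, per-stage substream seeds (via `SeedSequence.spawn`) and
all thresholds. TSVs are tab-separated UTF-8 with `NA` for missing and
floats printed at %.17g (lossless round trip); with a fixed config and
seed two runs produce byte-identical files.

Problem sizes used by the acceptance script — 20 screens of 200×500
genes, a 2000-gene null screen, 2000 log-rank null simulations, 100
power replicates at the mouse effect size, one 2000-gene expression
experiment — were chosen to bound Monte-Carlo error on each reported
rate at roughly the percent level while keeping a full run around ten
seconds.

## Known limitations

* The screen's t-based p-values assume Gaussian errors; heavy-tailed
  lifespan noise would call for a robust variant (not implemented).
* The log-rank p-value is asymptotic; for very small cohorts an exact
  permutation test (as used in the test-suite oracle) is preferable.
* The Welch-on-log2(FPKM+1) fallback is a generic DE test, not a
  count-model method; supply statistics from a dedicated caller when
  replicate-level modelling matters.
* Promoter-state mapping takes the chromatin annotation at face value;
  the TSS ± 1 kb window and largest-overlap rule are conventions, stated
  above, not inferences.
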