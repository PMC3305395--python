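# Methods

This note records the statistical model behind `gonadprime`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Data model and inclusion filter

A study is a log2 intensity matrix (transcript clusters × samples) with a
sample sheet (lineage, sex, stage, replicate) and a transcript-cluster
annotation (gene symbol, annotation quality, control flag). Analyses run
at the transcript-cluster level; every reported count is gene-level
deduplicated by symbol, because one gene may carry several clusters and
they occasionally disagree (such a gene may legitimately appear in more
than one list).

Before any analysis, clusters are removed unless they

1. carry the best annotation tier (cross-hybridization category 1 on Gene
   ST arrays; annotation grades A/B on 430 2.0 arrays — both map to one
   internal tier so downstream code has a single path),
2. have a non-empty gene symbol and are not control probes,
3. strictly exceed a log2 intensity of 6 in at least 2 of 3 replicates of
   at least one (lineage, sex, stage) group. For designs with n ≠ 3
   replicates the proportion is preserved as ceil(2n/3).

The filter only drops rows, never modifies values, and is idempotent. The
order of the quality and expression criteria does not affect the retained
set; quality is applied first.

## The pairwise comparison

For two groups of replicate arrays the per-cluster statistic is a
two-sided two-sample t-test on the log2 values, pooled-variance by default
(`ThresholdConfig.equal_variance=False` switches to Welch for sensitivity
analysis; the choice is not derivable from first principles and pooled is
the convention of ANOVA-style array suites). P-values are deliberately
left uncorrected: error control is applied to the composed lists by
permutation, not per cluster.

Fold changes use the signed convention: FC = 2^Δ for Δ ≥ 0 and −2^(−Δ)
otherwise, so |FC| ≥ 1 always and the "identical" window −1.5 < FC < 1.5
can be read literally. Degenerate zero-variance cases follow the limits of
the t statistic: equal constant groups give p = 1 (hence `identical`),
distinct constant groups give p = 0 (the call then decided by FC alone).

Thresholds (`ThresholdConfig`): p < 0.05 and |FC| ≥ 1.5 for difference
calls; p > 0.05 and |FC| < 1.5 for identity calls; values at the boundary
are `neither`. Exactly one of higher/lower/identical/neither is assigned.

## Recipes

Every gene list is an intersection of wanted calls, plus optional
comparison-based exclusions and list subtractions, encoded as a `Recipe`
so the observed list and its permutation re-runs share one evaluator.

* **Sex-specific enrichment** of a focal population: higher than the
  opposite-sex focal lineage, and higher than every other same-sex lineage
  at that stage. No cross-sex comparisons to other lineages are made, so a
  gene can be enriched in, say, both XY supporting cells and an XX
  lineage. Depletion reverses every direction.
* **Sex-independent enrichment** (the progenitor signature): higher than
  every other lineage within XY, within XX, and identical between XX and
  XY of the focal lineage.
* **Contaminant (Leydig) deduction**: the steroidogenic cells co-sort with
  the endothelial fraction in XY samples, so contaminant genes are deduced
  as higher in the XY interstitium than XY supporting and germ cells,
  higher in the XY endothelium than the same two, higher in the XY
  interstitium than the XX stroma, and higher in the XY endothelium than
  the XX endothelium (depleted variant reversed). The late-stage list is
  subtracted from the XY endothelial lists; the subtraction is recorded as
  a removal step and skipped during permutation runs, since the removal
  list is itself data-derived and fixed.
* **Single-comparison dimorphism**: one XY-vs-XX comparison per lineage.
  When clusters of one gene disagree about how many lineages it is
  dimorphic in, the gene is counted in the highest-overlap category (the
  cluster covering the most lineages; ties broken deterministically by
  sorted lineage tuple).

Intersections commute, so step order is irrelevant except that removals
apply last.

## Priming

A gene is primed toward one sex when the XX and XY progenitors express it
identically at the start stage and only that sex retains it at the end
stage. Three methods of increasing stringency:

1. **all**: start identity; higher in the retaining sex at the end;
   repressed between start and end in the other sex; minus genes also
   repressed in the retaining sex (differential repression required).
2. **enriched**: additionally lineage-enriched at the start in both sexes
   and at the end in the retaining sex.
3. **depleted**: the mirror for specifically repressed genes — start
   identity; lineage-depleted at the start in both sexes; still lower
   than the other sex and lineage-depleted at the end in the retaining
   sex; activated between start and end in the other sex; minus genes
   also activated in the retaining sex.

Level tags compare the retaining sex's start and end groups: `similar`
if identical, `intermediate` if higher at the end (or higher at the start
for the depleted method), `other` otherwise. At gene level, a symbol with
clusters in both defined categories counts as `other`; a symbol with one
categorised and one uncategorised cluster keeps the categorised tag.

Marker denominators ("what fraction of each sex's program is primed")
match the method: all end-stage dimorphic genes (method 1), additionally
end-stage lineage-enriched (method 2), or dimorphic-toward-the-other-sex
and lineage-depleted (method 3). Primed sets are subsets of their
denominators by construction.

Default stage pairs: germ cells E11.5 → E13.5; supporting cells
E11.5 → E12.5 (their transcriptome changes little after E12.5). Both are
arguments, not constants.

## Model tests

With n_m male-primed and n_f female-primed genes (gene-level counts):

* extreme models: one-tailed exact binomial against p₀ = 0.9 for the
  favoured sex — lower tail when k/n ≤ p₀, upper tail otherwise (the
  rejection direction is "the observed fraction is too far from the
  model's 90%");
* balanced model: two-tailed exact binomial at p₀ = 0.5, minimum-
  likelihood definition (sum of all outcomes with pmf ≤ the observed
  pmf), capped at 1.

Models with p < 0.05 are excluded. If all three are excluded, the
intermediate *biased* model in the majority direction is selected; if
exactly one survives it is selected; otherwise the result is
`indeterminate` with the survivors listed (a real outcome — stringent
methods on small lists often cannot exclude two models at once).

Independence of sex and priming uses the two-sided exact test on the 2×2
table of primed/not-primed counts per sex — Fisher's exact test, i.e. the
hypergeometric null with the probability-mass two-sided rule.

All of these are computed with exact integer/rational arithmetic
(`fractions.Fraction`, `math.comb`); ties in the two-sided definitions are
decided by exact comparison rather than floating-point tolerance. The
tests confirm agreement with independent integer-enumeration oracles to
≤ 1e−12 for every configuration up to n = 30, and with the scipy
implementations to their floating-point tie tolerance.

## Permutation FDR

For a recipe's FDR, only the arrays its comparisons reference
participate. Their assignment to groups is permuted uniformly (group
sizes preserved; draws with replacement from the permutation space), the
comparison and exclusion steps are re-evaluated, and the list size is
recorded; removal steps are skipped. With 200 permutations (default),
FDR = mean permuted gene count / observed gene count; mean and median are
reported at both cluster and gene level. FDR ≤ 20% is the acceptability
default. An observed count of zero leaves the FDR undefined (reported as
not applicable, never as zero).

Each named recipe derives its own random stream from the run seed and the
recipe name, so adding recipes to an analysis never reshuffles existing
results. A fixed seed reproduces permuted counts bit-exactly.

## Structure diagnostics

Sample clustering defaults to Ward linkage, which minimises the
within-cluster sum of squares — the classic Ward criterion on squared
Euclidean distances. Alternates: average linkage with Euclidean distance,
and complete linkage with Pearson's dissimilarity (1 − r across genes,
invariant to per-sample affine rescaling). Dendrograms export to Newick
with merge-height differences as branch lengths.

Sources of variation: a per-gene main-effects ANOVA (lineage + sex +
stage, no interactions), computed as vectorised least squares over the
shared design matrix; each factor's F compares the fit without that factor
(others retained) to the full model's residual. Mean and median F are
reported per factor. Under pure noise the per-gene F follows the central
F(df₁, df₂) distribution — the suite checks the mean (df₂/(df₂−2)) and the
Kolmogorov distance (< 0.05 at 5,000 genes).

## Cross-platform integration

A second study (e.g. a mixed-population sort reaching earlier stages) is
integrated by gene symbol only — transcript-cluster ids are never compared
across platforms. Symbols are normalised to mouse-style capitalisation;
empty symbols are dropped with a logged count. Primed genes from the
mixed population are restricted either to symbols in the reference
lineage-enriched lists (rigorous) or by a three-step removal of
interstitial/stromal-attributable genes (permissive): dimorphic in the
interstitium and not the supporting cells, plus dimorphic in both but
higher in the interstitium.

The overlap report partitions the second study's primed symbols into
primed-in-both / dimorphic-with-prior-priming-signature /
dimorphic-without / not-detected, where the *signature* relaxes the
start-identity condition to "the primed sex already higher at the start".
The start-point stability report compares two candidate start stages by
the fraction of primed genes still identical between the sexes at both,
and the fraction undergoing concordant shifts in both sexes between them.

## Synthetic data

The generator emulates the sorted-cell design: per-gene baselines
~N(8, 1) on the log2 scale, homoscedastic Gaussian replicate noise
(σ = 0.25 by default), 4 lineages × 2 sexes × 3 stages × 3 replicates,
10% of genes carrying a duplicate transcript cluster, and small fractions
of unannotated / poor-quality clusters to exercise the filter. Planted
genes (default 100 per pattern among 5,000) follow templates for every
detectable pattern: lineage enrichment/depletion (sex-specific and
sex-independent), single- and multi-lineage dimorphism, the
interstitium+endothelium contaminant, and primed genes. Planted baselines
are kept above the expression floor (the templates describe expressed
genes).

Every planted contrast carries the full effect size δ (default 2 log2
units). In particular, the *intermediate* priming template places the
progenitor δ above the repressed level with the retaining sex activating
a further δ — "between the two final levels" on the log scale with every
internal comparison at full effect; the *similar* template holds the
retaining sex flat. Optional per-factor random effects
(lineage/sex/stage SDs) generate global structure for the clustering and
ANOVA diagnostics; they default to zero in the planted study so identity
calls in the truth stay exact.

Ground truth stores each gene's true group means, so the expected
membership of any recipe is obtained by evaluating the recipe on the
noiseless means (difference calls at |Δ| ≥ log2 1.5, identity at Δ = 0) —
an oracle that shares the list algebra but none of the statistics.
Recovery is scored at gene level: sensitivity against the expected set,
false-positive rate against the remaining gene universe. Level-tag
recovery is scored as classification accuracy among the recovered primed
genes, separating the tagging operation's error from the priming
recipe's detection error: with two stochastic identity calls in series,
the unconditional product sits at the 0.95² boundary by t-test type-I
arithmetic alone, which measures the t-test rather than the tagger.

What the generator does **not** emulate: probe-level artifacts and RMA
itself (inputs are post-normalisation), intensity-dependent variance,
correlated genes/pathways, partial FACS contamination gradients (the
contaminant template is all-or-none), and batch effects. Passing recovery
tests therefore demonstrate the correctness and power of the list algebra
under the stated noise model, not robustness to those real-data
complications.

## Problem sizes and numerics

* Default planted study: 5,000 genes × 72 arrays — the full design at a
  desk-scale gene count.
* Null FDR calibration uses a 110,000-gene pure-noise study: the FDR
  ratio's Monte-Carlo error is dominated by the Poisson variation of the
  observed count (≈30 discoveries at 5,000 genes, ≈180 at 110,000), and
  the larger study brings that error to ~6%.
* Model-selection simulations plant 120 primed genes (90/30) among 1,500.
* Exact-test oracle scans cover every n ≤ 30.
* Sub-seeds for independent pipeline stages derive from one run seed via
  `numpy.random.SeedSequence`; all simulation and permutation streams are
  `default_rng`.

## Known limitations

* The t-test choice (pooled vs Welch) is a convention; results at the
  0.05/1.5 thresholds can differ slightly between them for heteroscedastic
  genes.
* Identity calls are acceptance-of-the-null at fixed thresholds; a truly
  identical gene fails the identity call ~5% of the time by construction,
  which propagates into recipe sensitivities (≈0.93–0.95 per identity
  step under default noise).
* The ANOVA is main-effects only; interaction variance is pooled into the
  residual.
* Symbol-based integration inherits all the ambiguity of gene symbols
  across platforms; conflicting annotations are dropped, not resolved.
* Permutation FDR assumes exchangeability of the participating arrays
  under the null; it permutes across stages/sexes exactly as the recipe
  uses them.
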