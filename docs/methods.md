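# Methods

## Model and procedure

The pipeline scores genes for association with a binary phenotype by how
much tree-ensemble classifiers rely on them, weighted by how well those
classifiers generalize.

1. **Preprocessing.** Four sequential steps on a raw genes × samples
   expression matrix: (i) rows are averaged per gene symbol under a
   user-supplied id map; (ii) columns are averaged per participant; (iii)
   every value x becomes log(x + pseudocount) (default log2, pseudocount 1,
   so zero expression maps to zero — the standard FPKM convention; the log
   base and pseudocount are config options because conventions differ);
   (iv) quantile normalization forces every sample onto the common
   reference formed by averaging rank-ordered values across samples. Ties
   receive the mean of the reference values at their tied ranks
   ("average-ties" dialect), which makes the operation idempotent and
   deterministic. An optional gene-universe file restricts the matrix to a
   fixed feature set before scoring. Unmapped ids are dropped with a logged
   count rather than raising, since real cohorts routinely contain
   transcripts outside the chosen universe.

2. **Scoring.** K classifiers are trained on independent, non-stratified
   random 80/20 holdout splits (simple random splitting, since the class
   imbalance of interest is mild; splits that land all of one class in a
   fold are redrawn and logged). Model k yields a per-gene importance
   vector FI·k — XGBoost total-gain, clipped at zero and normalized to sum
   1 per model so models contribute on a common scale — and a held-out
   AUC_k. The per-gene marker score is MS_n = Σ_k FI_nk · AUC_k. Genes no
   model ever splits on score exactly 0. Split-count ("weight") importance
   and impurity-based random-forest/AdaBoost backends are selectable behind
   the same fit/predict-proba/importances contract.

3. **Significance.** The full scoring procedure is rerun on cohorts whose
   label vector is permuted uniformly at random (class sizes preserved;
   shuffle and split seeds fan out deterministically from one master seed,
   with independent split seeds per shuffle). All per-gene scores from all
   shuffles form the background pool — n_shuffles × n_genes values. The
   empirical p-value is the inclusive exceedance fraction
   EP_n = #{b ≥ MS_n}/|pool|, floored at 1/|pool|; the inclusive (≥)
   convention is the conservative choice and keeps EP in (0, 1]. EP is
   nonincreasing in MS, so marker sets at increasing cutoffs are nested.

4. **Evaluation.** (a) Repeated-holdout AUC restricted to a marker set,
   with a null built from random equal-size gene subsets; (b) upper-tail
   hypergeometric overlap with reference gene sets, with the reference
   intersected with the analysis gene universe before testing (the universe
   is the scored gene set — the natural choice when the reference databases
   were assembled independently of it); (c) a per-gene survival screen
   splitting the cohort at the gene's median expression (values strictly
   below the median form the low group, which guarantees both groups are
   non-empty for non-constant genes; constant genes are skipped with a
   warning) and comparing groups by the log-rank test with Kaplan–Meier
   curves; (d) two-sided Welch t-tests (unequal variances — the safer
   default when class sizes differ) flagging markers with p above a
   threshold (default 0.1), i.e. markers invisible to univariate testing;
   zero-variance genes are defined to have p = 1; (e) adjacency counts of
   markers among markers in an undirected interaction network, with the
   mean count over a reference set as context. Raw p-values are reported
   throughout; a Benjamini–Hochberg column can be added by the caller via
   statsmodels but is not part of the default output.

## Synthetic data: what it emulates and what it does not

The generator simulates directly on the post-log scale: null genes are
i.i.d. Normal(5, noise_sd) in both classes; informative genes get a
constant +effect_size shift in the M1 class. This reproduces the features
the pipeline's statistics depend on — a two-class cohort with controllable
imbalance, a small planted signal on a large null background, and
exchangeability under label permutation — but deliberately omits
count-level (FPKM) noise, batch effects, co-expression structure, and
nodal substages. Passing tests therefore demonstrate the statistical
machinery (calibration, recovery, nestedness, power), not robustness to
real-data artifacts such as correlated genes, which can share or split
importance in ways independent genes do not.

Survival times are exponential with log-hazard linear in the standardized
mean expression of the chosen hazard genes
(rate = baseline_hazard · exp(lhr · z)); baseline hazard defaults to 1/730
per day (mean survival two years, a realistic order for a metastatic
cohort) with administrative censoring at a horizon that censors ~30% of a
null cohort. Gene sets contain round(planted_fraction × set_size) planted
genes, the rest uniform from the null background; networks place edges
independently with probability p_within among informative pairs and
p_between elsewhere. All four generators are deterministic given seed and
parameters.

## Numerical choices

- Seeds: one master seed fans out through `numpy.random.SeedSequence` to
  split, shuffle, and draw seeds; every stage is replayable and all derived
  seeds stay below 2^31.
- EP floor 1/|pool| avoids zero p-values from a finite permutation pool.
- The MS threshold reported per marker set is the smallest score among the
  selected genes (the score at the cutoff).
- Degenerate inputs: log-rank with no events in either group returns
  statistic 0, p 1; an all-constant gene is skipped in the survival screen
  and given p 1 in the t-test; a model that makes no split keeps an
  all-zero importance vector rather than being renormalized.
- Quantile normalization requires ≥ 2 samples; collapsing requires a
  non-empty id map.

## Problem sizes and the desk-scale profile

The library defaults mirror the design-case scale: 50 models, 10 shuffles,
EP cutoffs 0.001/0.005/0.01, train fraction 0.8, XGBoost with library
defaults. The test suite and `scripts/acceptance.py` run the same
algorithms on smaller synthetic cohorts (hundreds of genes, 100–200
samples, 10–20 models, 5 shuffles) with a lighter boosting profile
(n_estimators 30, max_depth 3, max_bin 64, single-threaded) chosen as this
package's standard desk-scale configuration: it keeps repeated-fit
experiments fast while preserving every statistical property under test,
because the background pool is always built with the same profile as the
real run, so the empirical p-values remain exactly calibrated whatever the
model configuration.

## Known limitations

- Importance-based scoring inherits tree-ensemble biases: redundant
  (correlated or jointly-planted) genes share importance unevenly, so a
  true marker can be shadowed by a stronger neighbour; the score is a
  ranking device, not an effect-size estimate.
- The permutation background conditions on the cohort and the model
  configuration; EPs are calibrated against "no label association", not
  against alternative model families.
- The survival screen is a univariate median-split log-rank scan; it makes
  no adjustment for covariates and reports raw p-values (Cox regression is
  out of scope).
- Real-cohort headline numbers depend on external data (TCGA-BRCA
  expression, curated marker databases, BIOGRID) and are reproducible only
  by supplying those inputs through the same file interfaces.
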