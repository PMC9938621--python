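# Methods

## Statistical model

Log2-scale expression of gene *g* in the sample of patient *j* under cycle
protocol *i* is modelled additively:

    Y_gij = mu_g + T_gi + S_gj + e_gij

with `mu_g` the gene baseline, `T` a gene-specific cycle-protocol (natural
vs HRT) effect, `S` the gene-specific receptivity-stage effect over the
three levels PR (LH+5), RE (LH+7), PO (LH+9), and `e` residual noise. The
stage effect is tested per gene with the F-ratio of the stage mean square to
the residual mean square. Although the decomposition can be read as a
variance-components model, the test is implemented as a fixed-effects
main-effects ANOVA: for a balanced stage-timed design without interaction
the F statistic coincides, and the fixed-effects fit is exact and fast (the
design matrix is shared across genes, so sums of squares come from two
projection matrices applied to the whole matrix at once). The treatment
term is dropped automatically when the protocol column is constant — the
training design is all natural-cycle, so the default fit is one-way.

Multiplicity is handled by Benjamini–Hochberg step-up q-values
(`statsmodels.stats.multitest`); the test suite checks the implementation
against an independent hand-rolled step-up oracle. Degenerate genes
(zero total variance) get p = 1 and are excluded from marker candidacy;
zero-residual genes get an infinite-F sentinel with p = 0 and a flag.

Post hoc, each stage pair is compared with Tukey's HSD using the
Tukey–Kramer statistic `|m_i - m_j| / sqrt((MSE/2)(1/n_i + 1/n_j))` referred
to the studentized-range distribution with k = 3 and the one-way error df.
Because the design — hence the df — is shared by all genes, large batches
evaluate the survival function through a monotone log-scale interpolant on a
dense grid (absolute accuracy ~1e-4 near the decision thresholds, far below
the Monte-Carlo tolerance the suite uses to validate it); small batches use
direct quadrature, which the suite cross-checks against
`statsmodels.pairwise_tukeyhsd` and a 10^6-draw Monte-Carlo null.

Volcano classification uses the raw ANOVA p (cutoff 0.05) and |log2 fold
change| ≥ 1 with an inclusive fold-change boundary; DEG calls feeding the
network and marker stages use q < 0.05. Both thresholds are configurable.

## Co-expression network

Unsigned soft-thresholded adjacency `|cor|^beta` with β = 6 (signed variant
available), topological overlap

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

and average-linkage hierarchical clustering of `1 - w` with a **static** cut
at height 0.25; clusters under 30 genes become grey. A static cut (rather
than dynamic tree cutting) keeps the algorithm fully specified and
deterministic; the practical consequence is that a module must maintain
within-module correlation around 0.96 or higher to survive β = 6 plus the
0.25 cut, which the synthetic generator respects (below). Modules are named
by the conventional size-ranked colour sequence. The eigengene is the first
right singular vector of the per-gene z-scored module submatrix, unit norm,
sign-oriented to correlate positively with its members on average.
Module–stage correlation is Pearson r of the eigengene against the ordinal
code PR = 1, RE = 2, PO = 3 (the receptivity axis is ordered, so an ordinal
code is the natural one-degree-of-freedom summary). Intramodular
connectivity `kWithin` sums a gene's adjacency to co-members; the hub is the
per-module argmax with lexicographic tie-break. The grey pseudo-module's
hub is reported but never enters the marker panel.

## Marker panel and classifier

Candidates must clear **all three** pairwise Tukey tests at alpha = 0.05
(conjunctive rule: a marker has to separate every pair of stages, not just
one). They are then scored by a bagged ensemble of decision trees
(features-per-split = sqrt, 500 trees by default) with two importances:
mean decrease accuracy — the drop in out-of-bag accuracy when one gene's
values are permuted, averaged over trees and 5 permutation repeats — and
mean decrease Gini — the unnormalized impurity decrease attributed to the
gene, averaged over trees. The bagging loop is explicit because per-tree
out-of-bag bookkeeping is what defines the accuracy measure; the final
classifier of record is scikit-learn's `RandomForestClassifier`.

The two importances are combined deterministically: rank by mean decrease
accuracy, but require membership in the top `2 * panel_size` genes by Gini;
if the intersection is too small, fall back to the pure accuracy ranking.
This honours both measures while keeping the panel size (default 87) an
explicit parameter. Non-grey module hubs are appended afterwards,
deduplicated (a hub already selected keeps its `tukey_rf` provenance).

The classifier predicts PR/RE/PO probabilities as forest vote fractions. A
call is made only when the maximum probability reaches τ = 0.6
(τ ∈ (1/3, 1]); otherwise the sample is NO_CALL. On transfer-day samples,
RE maps to a normal WOI, PR to delayed, PO to advanced, NO_CALL to
indeterminate; libraries failing QC carry `detection_failed` through the
report. Cross-validation folds partition **patients**, not samples, so the
three stage-timed samples of one woman never straddle a train/test split
(per-sample folding is available behind a flag for comparison).
Sensitivity, specificity, PPV and NPV are macro one-vs-rest averages over
the three classes. The LDA projection is a visualisation aid only, computed
with the SVD solver so singular within-class scatter degrades gracefully.

## Clinical association

The validation readout is a 2×2 table — normal WOI (RE call) vs displaced
(PR or PO pooled) against pregnancy success vs failure — tested with the
two-sided Fisher exact test under the sum-of-smaller-probabilities
convention (`scipy.stats.fisher_exact`; the suite checks it against full
margin enumeration). Detection failures and no-calls are excluded from the
table but retained in the overall-rate denominator, which is how a clinic
reports whole-cohort pregnancy rates. The odds ratio is the sample
`(ad)/(bc)` with zero cells reported as inf/NaN flags rather than silently
continuity-corrected. The hypergeometric over-representation test reports
fold enrichment `(k/n)/(K/N)` and the upper-tail p with BH correction
across sets.

## Synthetic cohorts

The generator realizes exactly the additive log2 decomposition above, plus
per-module latent factors:

* **Design**: 48 patients × 3 stage-timed samples (defaults), ~15,000 genes
  with baselines `mu_g ~ N(3, 1.5^2)` on the log2(FPKM+1) scale, residual
  sd 0.35.
* **Stage-associated genes**: 864 by default (the desk-scale configuration
  used in tests and the acceptance script plants 200 among 3000); offsets
  per stage are i.i.d. N(0, 0.8^2), centred per gene. The effect sd is
  about twice the residual sd so recovery at q < 0.05 is expected to be
  near-complete at the design's sample size.
* **Modules**: four by default, drawn from the planted DEG set. Each module
  has a latent factor `f_m = alpha * p_m(stage) + sqrt(1 - alpha^2) * eta`
  with alpha = 0.8 and `p_m` a centred stage pattern (linear or quadratic,
  alternating sign), so some modules track the receptivity axis strongly
  (eigengene |r| around 0.8, echoing real module–stage correlations) and
  others are stage-orthogonal. Member loadings are `U(0.9, 1.0) * 2.5`,
  giving within-module correlations around 0.98 — deliberately strong so
  the planted partition is recoverable under the static-cut network with
  β = 6; the hub's loading is 1.5× the factor scale, making it the
  max-connectivity gene by construction. Module baselines are raised so the
  planted swings are not truncated by the log2 floor at zero.
* **Counts**: optional negative-binomial emission with mean inverting the
  FPKM transform at gene lengths U(500, 5000) bp and ~5e6 fragments per
  library, dispersion 0.05. Log2(FPKM+1) recomputed from the counts
  correlates with the latent matrix at r ≥ 0.95 when the gene set is large
  enough that the planted modules do not dominate library composition.
* **Validation cohort**: 22 single-timepoint transfer-day samples with
  hidden true stages drawn as P(PR, RE, PO) = (0.14, 0.81, 0.05) (mirroring
  the observed 18/3/0 split of 21 analyzable libraries), pregnancy
  Bernoulli(0.78) when truly receptive and 0 otherwise, and one library
  degraded to ~3% gene detection to exercise the detection-failure path.

What the generator does **not** emulate: amplification and coverage biases,
batch effects beyond the protocol term, gene-length-dependent dispersion,
correlated stage effects outside modules, and any real biology of the
marker genes. Passing tests therefore demonstrate that the machinery is
correct and well calibrated under its stated model, not that the classifier
would reach the same operating characteristics on clinical cohorts.

## Numerical and design choices

* Pseudocount 1 in the log2 transform (zeros map to 0, invertible);
  library size = column sum of the provided counts.
* QC defaults: ≥ 5000 genes detected and ≥ 1e5 total fragments per library
  (loose, configurable; scaled runs use proportionally lower gates).
* Ties: hub selection and panel ordering break ties lexicographically by
  gene id; BH ties share the rank of the last tied position.
* All randomness flows from explicit seeds (`numpy.random.default_rng`,
  forest `random_state`); identical config + seed reproduces byte-identical
  serialized artifacts, which the run manifest verifies by SHA-256.
* Desk-scale problem sizes (3000 genes / 200 planted DEGs / 48 patients in
  the acceptance script; smaller in unit tests) were chosen so the whole
  chain exercises every code path at interactive runtimes while keeping the
  study's per-stage sample counts.
* Model persistence is JSON metadata plus a pickled forest; portability of
  the tree dump across library versions is not guaranteed, so reproducing a
  model from its config + seed is the supported path.

## Known limitations

* Cross-validation with a pre-selected (non-nested) marker panel leaks
  selection information; a nested mode is the honest estimate and the
  default panel mode is flagged in the CV report's provenance. On the
  synthetic cohorts the planted effects are strong enough that the two
  agree.
* The static tree cut requires strong module correlation; weak real-world
  modules would need dynamic cutting, which is out of scope.
* Fisher inference on 21-sample cohorts has low power; the Monte-Carlo
  power check in the suite documents the detection rate under the default
  outcome model rather than asserting significance for every cohort.
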