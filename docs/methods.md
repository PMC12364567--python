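# Methods

This note records the models, conventions and numerical choices behind
`lipidtraffic`, and what the bundled synthetic data can and cannot show.

## Presence model

A lipid variable is *present* in a (phenotype, compartment) group when the
fraction of the group's samples with signal strictly greater than zero —
the *occupancy* — is at least the threshold (default 0.66). The comparison
is a plain `>=` on the unrounded fraction, so 2-of-3 (0.6667) passes; this
matters because multi-tissue designs commonly run with only three animals
per group. Missing cells count as not-detected but still count toward the
group size: occupancy is conservative under missingness. Raising the
threshold can only shrink the presence set (threshold monotonicity), and
raising any signal from zero can only grow it; both properties are tested.

Quantitative stages (ENFC, CV, fold changes) exclude zeros and missing
cells from means by default, since a zero here means "below detection",
not "abundance zero"; a `missing_as_zero` flag inverts this.

## Switch classification

The six labels A / U / B / N2 / PARTIAL / ABSENT partition all subsets of
the compartment set, so per-phenotype type counts always sum to the number
of variables with a non-empty pattern. Two choices were genuinely open:

* **Patterns spanning more than two but not all compartments.** These get
  the global label PARTIAL, and are *additionally* enrolled in the B-set of
  every edge whose both endpoints they occupy. The edge-local criterion
  ("found in the pair of adjacent compartments") and the global taxonomy
  are thus both served: edge traffic counts reflect everything travelling
  that edge, while the global count table remains a partition.
* **A-type variables on edges.** Ubiquitous variables trivially satisfy
  every edge-local criterion. By default they are kept out of the per-edge
  B-sets (they are tabulated separately), so edge counts show only
  non-ubiquitous traffic; `include_a_in_edges=True` enrolls them.

DG species produced by in-source fragmentation of TGs can be counted with
the TG class via `group_dg_with_tg` (used for triglyceride traffic tables);
the default keeps DG separate.

All output sets are sorted by canonical lipid name, making files
deterministic.

## Jaccard–Tanimoto test

For presence lists with totals k1, k2 over a universe of N variables, the
null model reassigns each list's present labels uniformly at random,
preserving both totals. The intersection size m is then
Hypergeom(N, k1, k2), and J = m / (k1 + k2 − m) is monotone increasing in
m, so the exact dissimilarity-tail p-value is the hypergeometric CDF at
the observed m. This closed form is valid at any universe size, so the
exact method is the default everywhere; the Monte-Carlo route
(p = (count ≤ observed + 1) / (n_null + 1), seeded, ≥ 100 replicates) is
kept for cross-checking and for users who prefer a resampling account.
Both lists empty is reported as J = 1 with a warning. One caveat is
inherent: the test statistic is discrete, so for small universes the
attainable significance levels sit below nominal; the calibration check
therefore uses a large universe (100,000), where the attainable level is
0.0494 at α = 0.05.

The phenotype comparison computes J and p per scope: per node over U-sets,
per edge over B-sets, per non-adjacent pair over N2-sets, over the A-sets,
and globally over the aligned (variable × compartment) presence cells. The
universe for node/edge scopes is the variable universe; for the global
scope it is variables × compartments.

## ENFC convention

ENFC = ln(FC) / sqrt((σ1/μ1)² + (σ0/μ0)²), with FC = μ1/μ0 and σ the
sample SD of detected values. This form is dimensionless, antisymmetric
under swapping the groups, and is the standard error-propagation of ln FC
through a quotient; it is isolated in a single function (`stats.enfc`) so
an alternative convention is a one-line change. Records with a
non-positive mean in either group, or with both spreads zero, are flagged
incalculable and excluded from summaries with their count reported.

## Two-group test and significance tiers

Lipidomic abundances are treated as unequally distributed and
heteroscedastic, so the two-group comparison is the two-sided
Mann–Whitney rank-sum test: exact when the combined sample is under 20
without ties, normal approximation with tie correction otherwise. Tiers
follow `*` < 0.1, `+` < 0.05, `**` < 0.01, `***` < 0.001, `****` < 0.0001.
Reported p-values are floored at 2.2e-16 (printed `<2.2e-16`); a
Benjamini–Hochberg adjusted column is emitted alongside raw p-values, with
default significance still judged on the raw values.

## Fatty-acid profiles

Compositions are analysed as molar percent of the per-sample total, which
removes per-sample loading and internal-standard scale (doubling one
sample's raw amounts changes nothing downstream). The default error bar is
the SEM of per-sample mol% within the group; a quotient-rule alternative
(relative errors of the species mean and the total mean in quadrature) is
available via `error="quotient"`, since the propagation formula behind
published error bars is not uniquely determined by convention.

## Cohort stage

The balanced split draws n_per_class subjects per sex without replacement
(seeded, ids sorted before drawing so the partition is reproducible across
platforms); everything else is the test set. The classifier is a random
forest with fixed defaults — 500 trees, sqrt-features, seeded — recorded in
every report; no hyperparameter search is done. Accuracy uses a 0.5 score
threshold; because the test set is heavily imbalanced, balanced accuracy is
reported alongside, and AUC is computed from the continuous score.
Importances are permutation-based on the test set (5 repeats, AUC scoring).

BMI correction is leak-free residualization: a univariate least-squares fit
of each feature on BMI, coefficients estimated on training subjects only,
applied to all subjects, after which BMI leaves the feature set. The raw
scale is the default. Abundance covariate effects are typically
multiplicative, and a linear fit of an exponential dependence leaves
curvature that a forest can still exploit; for strictly positive features
`log_scale=True` residualizes log-abundance instead, which removes such
dependence completely. `method="drop"` simply removes the BMI column.

Fold changes are mean(other)/mean(reference) with reference = male, so a
value of 0.90 reads "10% lower in females".

## Synthetic data: what it emulates, what it does not

The traffic generator plants a panel of variables with known spatial types
(defaults: 10 each of A/U/B/N2 over a nine-compartment serum-hub network,
two phenotypes, 8 samples per group — the scale of a multi-tissue mouse
study), draws log-normal(meanlog 10, sdlog 1) signal where present, zeroes
each truly-present observation independently with probability ε
(detection dropout), and relocates a 25% share of non-A variables in the
second phenotype to create genuine between-phenotype differences. The
cohort generator mirrors a male-skewed biobank: 4176 males, 1105 females,
BMI normal at 25.68 ± 4.69 (M) and 27.91 ± 6.87 (F) kg/m², ages ~54 ± 8.7
years, and log-abundances with configurable per-feature sex effects and
BMI slopes over N(0, 0.5) residual noise. For a single informative feature
with standardized effect d and no BMI path, the Bayes AUC is Φ(d/√2) in
closed form, which anchors the classifier checks (d = 1.4657 gives 0.85).

Neither generator simulates intensity-dependent (left-censored)
missingness, chromatographic artifacts, adducts, isotopes, in-source
fragmentation, or correlated lipid panels; passing tests therefore
demonstrate the correctness of the analysis machinery under the stated
statistical structure, not robustness to those features of real platform
data. Dropout is independent Bernoulli per observation.

## Problem sizes used in verification

The verification suite exercises: all 143 non-isomorphic connected graphs
with up to six compartments × every presence pattern (7,958 cases) against
an enumeration oracle; 1,000 randomized tables for threshold monotonicity;
50 random universes (N ≤ 12) against full C(N,k1) × C(N,k2) enumeration;
10,000 null replicates for type-I calibration; ~10,000 planted cells for
dropout recovery (n = 3, ε = 0.5, expected recovery exactly
P(Bin(3,0.5) ≥ 2) = 0.5); and cohorts of 2,000–3,000 subjects for the
null / planted / BMI-mediated classifier loops. These sizes keep every
standard error small relative to the tolerance being checked while the
whole suite runs in well under a minute of compute per stage.

## Known limitations

* The default serum-hub network is a stand-in topology; analyses of real
  designs should supply the study's own adjacency.
* The exact role of binary-list *order* in some published JTC p-value
  accounts is ambiguous; the null here fixes list totals and ignores order
  beyond alignment, which is stated rather than guessed.
* PARTIAL-pattern handling (global partition + edge enrollment) is this
  package's documented convention; other implementations may tabulate
  multi-compartment variables differently.
* The rank-sum test controls location differences under heteroscedasticity
  imperfectly; with severe variance ratios a Brunner–Munzel-type test would
  be preferable.
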