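# Methods

This note documents the statistical and numerical procedures implemented in
`elenta`, the parameters that matter, the design choices made where the
procedure was genuinely open, and what the synthetic-data generators do and
do not emulate.

## Untargeted metabolomics processing (`feature_qc`)

**Presence calls.** A feature is *present* when its mean intensity across
non-blank samples strictly exceeds `blank_fold` (default 3) times its mean
blank intensity. The call is monotone in sample intensity. A grouping
argument allows evaluating presence per time point or condition instead of
on pooled samples.

**CV filter.** Replicate groups are samples sharing (role, group, time,
strain). Per group the coefficient of variation sd/mean of raw intensities
is computed (sample sd, ddof 1); groups with zero mean are skipped as
uninformative; a feature is removed when the **median** across-group CV
exceeds `cv_max` (default 0.5). The median was chosen over pooling because
it is robust to a single noisy condition; `pool_groups=True` provides the
alternative reading (one CV over all non-blank samples).

**Outlier samples.** A non-blank sample is dropped when its total feature
signal deviates from the assay median total by more than 50% (fractional
deviation). Blank samples are never dropped by this rule.

**Log transform.** Per feature, a pseudocount of 0.25× the minimum nonzero
intensity is added before log10. The transform is optional: datasets whose
raw intensities are already approximately normal (the strain panel) are
analyzed untransformed. All-zero features are an error, not silently
dropped, because they indicate an upstream filtering mistake.

**Cross-mode dereplication.** Neutral masses are derived from m/z via an
adduct offset table covering [M+H]+, [M−H]−, [M+Na]+, [M+Cl]− (proton mass
1.00728 Da); unknown adducts fall back to direct m/z comparison, which will
essentially never merge across modes — a deliberately conservative
fallback. A pair merges when |Δneutral| < 0.02 Da, |ΔRT| < 0.1 min, and
Pearson r ≥ 0.7 across ≥ 3 shared samples. The member with the lower
(more confident) MSI level is kept; ties keep the positive-mode feature.

**Differential abundance.** Welch's two-sample *t* per feature with
Benjamini–Hochberg adjustment across all tested features. The test runs on
the table's stored scale (log if transformed); the fold change is always
the difference of mean log2 pseudocounted intensities so calls are
comparable across datasets. Zero-variance identical groups get p = 1 (not
NaN) and a flag, keeping the BH family well defined. Calls use
p_adj < 0.1 and |log2FC| > 0.5 by default (0.75 is the stricter heatmap
threshold used for trajectory displays).

**Trajectory comparison.** Each replicate series is smoothed with a
least-squares cubic B-spline of `df` = 5 basis functions (interior knots at
time quantiles); the statistic is the mean absolute difference between the
two group mean curves on a 50-point uniform grid. Significance comes from
permuting whole replicate series across groups, p = (#perm ≥ obs + 1) /
(n_perm + 1), BH-adjusted, significant at p_adj < 0.25. Because the
statistic is symmetric under swapping groups, the smallest achievable p is
2/(number of distinct assignments); with *k* replicates per group that is
2/C(2k, k). Power analyses should size the feature set accordingly: with
5 replicates per group and 100 features of which 10 carry real divergence,
planted effects clear the 0.25 FDR threshold in ≥ 90% of draws.

**Strain variability.** A feature is *variable* when called increased (or
decreased) in at least one but fewer than `near_all` = 29 of 30 strains,
*conserved* at ≥ 29, *absent* at 0; directions are classified independently
and variability in either direction wins.

## Cross-dataset linking (`feature_linking`)

Fragment matching is greedy closest-pair within 0.01 Da; the cosine is the
dot product of matched intensities over the product of full-spectrum norms,
symmetric by construction. The cosine cutoff per ionization mode is the
99.5th percentile of cosines between two disjoint random sets of 200
features whose RT differs by ≥ 1 min and m/z by ≥ 0.01 Da (unrelated by
construction); at least 1000 eligible pairs are required. When no
calibration data exist, the published defaults 0.205 (positive) and 0.251
(negative) are used.

Links require same mode, same adduct annotation, |Δm/z| ≤ 0.007 Da,
|ΔRT| ≤ 0.5 min, and cosine ≥ cutoff; pairs lacking MS2 on either side use
the tighter 0.001 Da / 0.2 min gates instead. Multi-candidate resolution is
one-to-one greedy by descending cosine (ties by smaller |Δm/z|), preventing
identity chains; this resolution rule is this package's choice. The
conflict audit reports the fraction of doubly annotated links whose
annotations disagree, treating all MSI levels alike.

## Isotopologue correction (`sirm`)

The carbon-only natural-abundance matrix for an *n*-carbon compound has
column *i* equal to Binomial(n−i, p13) shifted by *i*, with p13 = 0.0107;
only ¹³C is corrected (the tracers are ¹³C and this matches vendor-software
defaults; an elemental-correction hook would extend the matrix product).
Correction solves the convolution by non-negative least squares and
renormalizes — NNLS rather than matrix inversion because inversion yields
negative fractions exactly in the low-signal regime where correction is
least certain. Forward convolution followed by correction is the identity
to < 1e-6 for n ≤ 30.

Enrichment is 1 − M+0. Classification requires enrichment ≥ 3% (the floor
guarding against spurious enrichment of weak peaks) **and** the reporting
criteria of the relevant preset: intracellular (labeled MID > 0.15, labeled
area ≥ 1e4) or extracellular (> 0.5, ≥ 5e4). The 3% floor alone is
necessary but not sufficient: additive channel noise of sd 2% of the M+0
area produces spurious post-correction enrichment above 3% in a large
fraction of draws (the sum of several zero-clipped half-normal channel
contributions), which is precisely why the area/MID criteria exist.
Specificity claims in the tests therefore use the preset-based
classification; the bare floor remains available as preset `methods-3pct`.
Area thresholds apply after the enrichment floor; the order is
configurable via direct keyword use.

## Constraint-based modeling (`cbm`)

Models carry metabolites, reactions (stoichiometry, bounds, GPR strings,
subsystem), one objective, and genes; exchange reactions are those touching
exactly one metabolite. I/O supports SBML Level 3 with the FBC package
(via libsbml) and a flat JSON dialect; writing then reading preserves
reactions, bounds, GPRs, and the objective.

Media conversion: a compound at concentration C mM with biomass density X
gDW/L over an exponential window Δt h gives maximum uptake
U = C/(X·Δt) mmol/gDW/h; the exchange lower bound is −U. Qualitatively
detected compounds get −1 mmol/gDW/h (a stated bound of "1 mM/gDW/h" is
read as mmol/gDW/h for dimensional consistency with flux units). All
unlisted exchanges are closed to uptake; secretion is never constrained.
Biomass density and window duration are experiment-specific and required
configuration; the defaults (0.01 gDW/L, 24 h) are placeholders, not
measurements.

FBA maximizes the objective subject to S·v = 0 and bounds; pFBA fixes the
objective at its optimum and minimizes Σ|v| with an auxiliary variable per
reaction (t ≥ v, t ≥ −v); FVA minimizes and maximizes each reaction's flux
subject to objective ≥ fraction·μ* (default 0.99). All LPs use the
deterministic HiGHS solver through `scipy.optimize.linprog`, so repeated
runs agree bitwise. Growth/no-growth is binarized at μ > 1e-6 h⁻¹ and a
reaction counts as *active* at |v| > 1e-9; both thresholds are package
choices where the underlying convention was unstated.

Knockouts zero both bounds per reaction; categories are essential
(μ ≤ 1e-6), reduced, neutral, plus a < 70%-of-wild-type flag feeding the
conservation comparison. Knockouts are reaction-level; GPR-mediated gene
knockouts are out of scope. Concordance scoring: MCC with a 0 convention
for degenerate denominators; Fisher tests are two-sided with the
conditional-MLE odds ratio (reported as infinite for degenerate tables);
expression concordance enumerates gene-reaction pairs through GPRs (a gene
in several reactions counts once per pairing) and reports top-half
enrichment plus Spearman ρ of expression vs |flux|.

## Strain association (`strain_assoc`)

Gene families collapse into distinct presence/absence patterns; constant
patterns are untestable. Each feature × pattern contrast is a Welch test of
per-strain log10 values (strains with vs without), BH-adjusted in one joint
family, significant at p_adj < 1e-4. The separability filter then requires,
in log10 units: |Δmedian| ≥ 0.4; 10th percentile of with-gene values at
least 0.4 above the maximum sterile-control value; 90th percentile of
without-gene values below that same threshold ("that value" is read as
max(control) + margin, configurable). Percentiles use numpy's linear
interpolation — pinned because percentile conventions differ across
implementations. The criteria as written assume the production direction
(gene carriers higher); mirrored criteria for depletion-direction
associations are applied only when `allow_depletion` is set, off by
default. Only the lowest-p association per feature survives. Pathway
enrichment is a one-sided hypergeometric test per term with BH q-values.

## Growth curves (`growth_curves`)

Wells are normalized by subtracting the mean of time-matched blank wells;
negative values are kept by default (clipping is opt-in) since clipping
biases early-phase AUC. Logistic fits use deterministic multi-start
nonlinear least squares: K from the max OD, N0 from the first positive
reading, r from the log-slope between 10% and 90% of K, plus bracketing
starts; sigma is the residual standard error √(RSS/(n−3)), and fits with
sigma > 0.1 are flagged excluded. Flat or non-growing wells get r = 0
rather than a failed fit. Replicate growth rates are averaged harmonically
for reporting. AUC is the trapezoidal integral of OD over time. Condition
effects are two-sided Wilcoxon rank-sum tests of AUC vs a reference
condition, exact for small tie-free samples, BH-adjusted, significant at
FDR 0.2; conditions with < 3 replicates are skipped with a warning.

## Synthetic data (`synth`)

All generators are pure functions of configuration + seed and emit a
machine-readable ground-truth sidecar. Intensities are log-normal with
multiplicative replicate noise (log-scale sd √(ln(1+cv²))), matching the
log-scale analyses; blanks are constant low background (1e3 against
baselines of 1e4–1e6); planted produced/depleted features shift by
`effect_log2` = 3 (8-fold) in the culture group, the regime the
differential pipeline is designed to detect at n = 3 and CV 10%. The
time-course mode drives planted features along a logistic-shaped
trajectory. Cross-mode duplicates share neutral mass, RT, and a common
log-normal profile with small independent noise (r ≥ 0.9). The strain
panel places with-gene strains `delta_log10` = 1.0 above a log10 = 1.0
control background with sd 0.05, giving clean separability margins; the
null variant (delta 0) yields zero final associations.

The toy metabolic network encodes the substrate-level phosphorylation
logic of the organism's energy metabolism: arginine (or agmatine, in the
variant) is deiminated to ornithine (putrescine) plus carbamoyl phosphate,
which carbamate kinase converts to 1 ATP; acetate activation to acetyl-CoA
costs 1 ATP; biomass consumes 1 acetyl-CoA + 2 ATP. ATP balance gives
3μ ≤ A + G and carbon balance μ ≤ C, hence μ = min((A+G)/3, C) — both
substrates are growth-limiting in overlapping regimes, reproducing the
qualitative dose dependence of growth on both arginine and acetate. An
optional two-reaction reversible loop exercises parsimonious-flux
minimality.

**What the generators do not emulate:** chromatographic drift, batch
effects, missing-value structure, heteroscedastic instrument noise,
correlated features (adducts/fragments of one compound beyond the planted
duplicates), realistic genome-scale network structure, or lag phases beyond
the logistic form. Passing tests demonstrate correctness of the statistical
machinery and recovery under the stated noise model, not performance on
real instrument data.

## Problem sizes and runtime

The test suite and the acceptance script use: 2,000 null features (type-I
calibration), 10 × 400 features (power), 20 seeds × 30 strains × 60
features (association recovery), MIDs to 30 carbons, 80-feature linking
panels with 450-spectrum null calibrations, and 100 noisy growth curves.
These sizes give stable estimates (binomial SE < 0.01 on the calibrated
rates) while keeping a full run under a minute on one CPU.

## Known limitations

- Elemental correction beyond carbon (N/H/O isotopes) is not implemented.
- Dereplication is pairwise greedy, not transitive-closure clustering;
  three-way adduct groups keep two members.
- The trajectory permutation test's resolution is bounded by the replicate
  count (smallest p = 2/C(2k, k)); small designs cannot reach stringent
  FDR levels.
- FVA solves 2 LPs per reaction serially; genome-scale models with tens of
  thousands of reactions would want a warm-started or parallel solver.
- The external-interface loaders assume well-formed inputs beyond the
  explicitly validated invariants (e.g., monotone time columns).
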