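# elenta

A Python toolkit for characterizing the metabolic niche of *Eggerthella
lenta*, an asaccharolytic human gut Actinobacterium that grows without
sugars, catabolizing arginine (or agmatine) for ATP while assimilating
acetate as a key carbon source. The package re-implements, as a tested and
reusable pipeline, the computational layers of that characterization:

- **Untargeted metabolomics** (`feature_qc`) — blank-based presence calls
  (sample mean > 3× blank mean), replicate-CV and outlier-sample filters,
  pseudocounted log transform, positive/negative ionization-mode
  dereplication, Welch *t* + Benjamini–Hochberg differential abundance, and
  a permutation spline test for diverging time trajectories.
- **Cross-dataset feature linking** (`feature_linking`) — MS2 cosine
  similarity with greedy fragment matching, a null-calibrated cosine cutoff
  (99.5th percentile of unrelated pairs), and m/z / RT / adduct-gated
  one-to-one linking with an identity-conflict audit.
- **Stable-isotope metabolomics** (`sirm`) — carbon-13 natural-abundance
  correction of mass-isotopologue distributions (MIDs) by non-negative
  least squares against a binomial mixing matrix, enrichment computation,
  and labeled/unlabeled classification with reporting presets.
- **Constraint-based modeling** (`cbm`) — FBA, parsimonious FBA, and flux
  variability analysis on genome-scale models (SBML-FBC or a JSON dialect),
  defined-media-to-uptake-bound conversion
  `U = C / (X · Δt)` (mM → mmol/gDW/h), leave-one-out media sweeps,
  single-reaction knockouts, and concordance scoring against growth
  (MCC + Fisher), metabolomics (FVA exchange directions), expression
  (Spearman ρ of |flux| vs expression), and gene-conservation data.
- **Strain association** (`strain_assoc`) — gene-family presence/absence
  pattern enumeration over a strain panel, Welch tests per
  (feature, pattern), separability filtering against sterile controls, and
  hypergeometric pathway enrichment.
- **Growth curves** (`growth_curves`) — blank normalization, deterministic
  multi-start logistic fits `N(t) = K / (1 + ((K−N0)/N0)·e^(−rt))`,
  empirical AUC, and Wilcoxon rank-sum media-component tests.
- **Synthetic data** (`synth`) — seeded generators with ground-truth
  sidecars for every stage, including a ten-reaction toy metabolic network
  whose optimum has the closed form `μ(A, C) = min(A/3, C)`.
- **Pipeline** (`pipeline`, `elenta` CLI) — YAML-configured end-to-end runs
  with a parameter manifest and a recomputable summary report.

## Worked example

```python
from elenta import cbm, feature_qc, synth

# constraint-based analysis of the packaged toy network
spec = synth.gen_toy_model(arginine_uptake=10.0, acetate_uptake=1.0)
sol = cbm.fba(spec.model)
print(f"max growth rate: {sol.mu:.3f} (closed form {spec.closed_form_mu(10, 1):.3f})")

kos = cbm.single_reaction_knockouts(spec.model)
print("essential:", sorted(k.reaction_id for k in kos if k.category == "essential"))

# differential metabolomics on synthetic culture-vs-control data
table, truth = synth.gen_feature_experiment(seed=1)
logt = feature_qc.log_transform(feature_qc.filter_features_by_cv(table))
res = feature_qc.differential_abundance(logt, "culture", "control")
inc = [r.feature_id for r in res if r.call == "increased"]
print(f"{len(inc)} features increased; "
      f"{len(set(inc) & set(truth.produced_features))}/{len(truth.produced_features)} planted recovered")
```

prints

```
max growth rate: 1.000 (closed form 1.000)
essential: ['ACS', 'ACt', 'ADI', 'ARGt', 'BIOMASS', 'CK', 'EX_ac_e', 'EX_arg_e', 'EX_orn_e', 'ORNt']
10 features increased; 10/10 planted recovered
```

The toy network is acetate-limited at these bounds (1 acetyl-CoA and 3 ATP
per unit biomass, 1 ATP per arginine through the deiminase chain), so
μ = min(10/3, 1) = 1; every reaction on the single arginine→ATP and
acetate→acetyl-CoA route is essential. The ten planted produced features
(8-fold shifts) are all recovered at FDR 0.1 with zero false calls among
the 185 null features.

An end-to-end run over all stages:

```sh
elenta run --config run.yaml   # see elenta.pipeline.RunConfig for the schema
```

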