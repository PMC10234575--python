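"""End-to-end orchestration of the analysis stages from a YAML config.

A run executes requested stages in dependency order on synthetic or on-disk
inputs, writing versioned outputs, a parameter manifest (every threshold
actually applied), and a summary report whose numbers are recomputable from
the written tables. Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cbm, feature_qc, growth_curves, sirm, strain_assoc, synth

logger = logging.getLogger("elenta")

STAGES = ["features", "cbm", "sirm", "growth", "assoc"]

_KNOWN_KEYS = {
    "stages", "seed", "out_dir",
    "features", "cbm", "sirm", "growth", "assoc",
}
_STAGE_KEYS = {
    "features": {"n_features", "n_samples_per_group", "n_produced", "n_depleted",
                 "effect_log2", "cv", "blank_level", "fdr_alpha", "lfc_min"},
    "cbm": {"arginine_uptake", "acetate_uptake", "fva_fraction"},
    "sirm": {"noise_sd", "min_enrich", "preset"},
    "growth": {"noise_sd", "n_replicates", "fdr_alpha"},
    "assoc": {"n_strains", "n_gene_families", "n_features", "n_linked_features",
              "delta_log10", "alpha_adj", "min_delta", "margin"},
}


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    out_dir: Path = Path("elenta_run")
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages", STAGES)
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}; valid: {STAGES}")
        params = {}
        for stage in STAGES:
            block = raw.get(stage, {}) or {}
            unknown = set(block) - _STAGE_KEYS[stage]
            if unknown:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(unknown)}")
            params[stage] = block
        return cls(stages=list(stages), seed=int(raw.get("seed", 0)),
                   out_dir=Path(raw.get("out_dir", "elenta_run")), params=params)


def run(config: RunConfig) -> pd.DataFrame:
    """Execute the configured stages; returns the summary report."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {"seed": config.seed, "stages": config.stages}
    report_rows: list[dict] = []

    for stage in config.stages:
        logger.info("stage %s starting", stage)
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        params = config.params.get(stage, {})
        try:
            rows, applied = _STAGE_FUNCS[stage](stage_dir, config.seed, params)
        except Exception as err:
            (out / "FAILED").write_text(f"stage {stage}: {err}\n")
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest[stage] = applied
        report_rows.extend(dict(stage=stage, **r) for r in rows)
        logger.info("stage %s done", stage)

    report = pd.DataFrame(report_rows, columns=["stage", "metric", "value"])
    report.to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return report


def _stage_features(stage_dir: Path, seed: int, params: dict):
    applied = dict(n_features=200, n_samples_per_group=3, n_produced=10, n_depleted=5,
                   effect_log2=3.0, cv=0.1, blank_level=1e3, fdr_alpha=0.1, lfc_min=0.5)
    applied.update(params)
    gen_keys = ["n_features", "n_samples_per_group", "n_produced", "n_depleted",
                "effect_log2", "cv", "blank_level"]
    table, truth = synth.gen_feature_experiment(
        seed=seed, **{k: applied[k] for k in gen_keys}
    )
    present = feature_qc.call_present(table)
    filtered = feature_qc.filter_features_by_cv(table)
    logt = feature_qc.log_transform(filtered)
    results = feature_qc.differential_abundance(
        logt, "culture", "control",
        fdr_alpha=applied["fdr_alpha"], lfc_min=applied["lfc_min"],
    )
    df = feature_qc.differential_to_frame(results)
    table.to_csv(stage_dir / "features.csv", stage_dir / "samples.tsv")
    df.to_csv(stage_dir / "differential.tsv", sep="\t")
    truth.to_json(stage_dir / "ground_truth.json")
    recovered = sum(
        df.loc[f, "call"] == "increased" for f in truth.produced_features if f in df.index
    )
    rows = [
        dict(metric="n_features", value=len(table.feature_ids)),
        dict(metric="n_present", value=int(present.sum())),
        dict(metric="n_after_cv_filter", value=len(filtered.feature_ids)),
        dict(metric="n_increased", value=int((df["call"] == "increased").sum())),
        dict(metric="n_decreased", value=int((df["call"] == "decreased").sum())),
        dict(metric="planted_produced_recovered", value=int(recovered)),
    ]
    return rows, applied


def _stage_cbm(stage_dir: Path, seed: int, params: dict):
    applied = dict(arginine_uptake=10.0, acetate_uptake=1.0, fva_fraction=0.99)
    applied.update(params)
    spec = synth.gen_toy_model(
        arginine_uptake=applied["arginine_uptake"],
        acetate_uptake=applied["acetate_uptake"],
    )
    sol = cbm.fba(spec.model)
    psol = cbm.pfba(spec.model)
    ranges = cbm.fva(spec.model, fraction=applied["fva_fraction"])
    kos = cbm.single_reaction_knockouts(spec.model)
    psol.flux_series().to_csv(stage_dir / "pfba_fluxes.tsv", sep="\t", header=["flux"])
    pd.DataFrame([
        dict(reaction_id=r.reaction_id, min_flux=r.min_flux, max_flux=r.max_flux)
        for r in ranges
    ]).to_csv(stage_dir / "fva.tsv", sep="\t", index=False)
    pd.DataFrame([
        dict(reaction_id=k.reaction_id, mu_ko=k.mu_ko, category=k.category)
        for k in kos
    ]).to_csv(stage_dir / "knockouts.tsv", sep="\t", index=False)
    mu_closed = spec.closed_form_mu(applied["arginine_uptake"], applied["acetate_uptake"])
    rows = [
        dict(metric="mu", value=sol.mu),
        dict(metric="mu_closed_form", value=mu_closed),
        dict(metric="n_essential", value=sum(k.category == "essential" for k in kos)),
    ]
    return rows, applied


def _stage_sirm(stage_dir: Path, seed: int, params: dict):
    applied = dict(noise_sd=0.01, min_enrich=0.03, preset=None)
    applied.update(params)
    mids = {"unlabeled": [1.0, 0, 0, 0], "half": [0.5, 0, 0.5, 0], "full": [0, 0, 0, 1.0]}
    ncarb = {k: 3 for k in mids}
    vectors, truth = synth.gen_isotopologues(mids, ncarb, noise_sd=applied["noise_sd"], seed=seed)
    rows = []
    recs = []
    for cid, vec in vectors.items():
        M = sirm.natural_abundance_matrix(vec.n_carbons)
        mid = sirm.correct_mid(vec, M)
        labeled, reason = sirm.classify_labeled(
            mid, vec, min_enrich=applied["min_enrich"], preset=applied["preset"]
        )
        recs.append(dict(compound=cid, enrichment=sirm.enrichment(mid),
                         labeled=labeled, reason=reason))
    df = pd.DataFrame(recs).set_index("compound")
    df.to_csv(stage_dir / "enrichment.tsv", sep="\t")
    truth.to_json(stage_dir / "ground_truth.json")
    rows.append(dict(metric="n_labeled", value=int(df["labeled"].sum())))
    return rows, applied


def _stage_growth(stage_dir: Path, seed: int, params: dict):
    applied = dict(noise_sd=0.01, n_replicates=4, fdr_alpha=0.2)
    applied.update(params)
    cond_params = {
        "full_media": (1.0, 0.01, 0.5),
        "dropout": (0.5, 0.01, 0.5),
    }
    raw, plate_map, truth = synth.gen_growth_curves(
        cond_params, n_replicates=applied["n_replicates"],
        noise_sd=applied["noise_sd"], seed=seed,
    )
    curves = growth_curves.blank_normalize(raw, plate_map)
    fits = [growth_curves.fit_logistic(c) for c in curves]
    aucs: dict[str, list[float]] = {}
    for c in curves:
        aucs.setdefault(c.condition, []).append(growth_curves.empirical_auc(c))
    tests = growth_curves.compare_conditions(aucs, "full_media", fdr_alpha=applied["fdr_alpha"])
    growth_curves.fits_to_frame(fits).to_csv(stage_dir / "fits.tsv", sep="\t")
    tests.to_csv(stage_dir / "auc_tests.tsv", sep="\t")
    truth.to_json(stage_dir / "ground_truth.json")
    rows = [
        dict(metric="n_fits_kept", value=int(sum(not f.excluded for f in fits))),
        dict(metric="n_significant_conditions", value=int(tests["significant"].sum())),
    ]
    return rows, applied


def _stage_assoc(stage_dir: Path, seed: int, params: dict):
    applied = dict(n_strains=30, n_gene_families=40, n_features=60,
                   n_linked_features=10, delta_log10=1.0, alpha_adj=1e-4,
                   min_delta=0.4, margin=0.4)
    applied.update(params)
    gen_keys = ["n_strains", "n_gene_families", "n_features", "n_linked_features", "delta_log10"]
    matrix, table, truth = synth.gen_strain_panel(seed=seed, **{k: applied[k] for k in gen_keys})
    strain_values, control_values = strain_assoc.strain_log10_summary(table)
    patterns = strain_assoc.enumerate_patterns(matrix)
    hits = strain_assoc.test_associations(
        patterns, strain_values, list(strain_values.columns), alpha_adj=applied["alpha_adj"]
    )
    final = strain_assoc.separability_filter(
        hits, strain_values, list(strain_values.columns), control_values,
        min_delta=applied["min_delta"], margin=applied["margin"],
    )
    strain_assoc.associations_to_frame(final).to_csv(stage_dir / "associations.tsv", sep="\t", index=False)
    matrix.to_tsv(stage_dir / "gene_presence.tsv")
    truth.to_json(stage_dir / "ground_truth.json")
    planted = truth.linked_gene_patterns
    recovered = sum(
        1 for r in final if planted.get(r.feature_id) == r.pattern_id
    )
    rows = [
        dict(metric="n_patterns", value=len(patterns)),
        dict(metric="n_final_associations", value=len(final)),
        dict(metric="planted_links_recovered", value=recovered),
    ]
    return rows, applied


_STAGE_FUNCS = {
    "features": _stage_features,
    "cbm": _stage_cbm,
    "sirm": _stage_sirm,
    "growth": _stage_growth,
    "assoc": _stage_assoc,
}
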