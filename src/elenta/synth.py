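"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator is a pure function of its configuration plus a seed and
returns both the data (in the same containers and file formats the analysis
stages consume) and a :class:`GroundTruth` sidecar naming the planted
structure, so recovery can be scored without reference to external data.

The intensity model is log-normal with multiplicative replicate noise
(matching log-scale analysis of peak heights); blanks carry a low constant
background; planted produced/depleted features are shifted by a stated
log2 effect. The toy metabolic network encodes a substrate-level ATP chain
from arginine (deiminase chain ending in a carbamate-kinase step) plus
acetate activation into acetyl-CoA, with biomass consuming acetyl-CoA and
ATP; its optimum has the closed form mu(A, C) = min((A + G)/3, C) for
arginine/agmatine uptake allowances A, G and acetate allowance C.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cbm import MediaDefinition, MetabolicModel, Metabolite, Reaction
from .feature_linking import Ms2Spectrum
from .feature_table import FeatureTable, make_feature_table
from .growth_curves import GrowthCurve, logistic
from .sirm import IsotopologueVector, Mid, natural_abundance_matrix
from .strain_assoc import GenePresenceMatrix

PROTON_MASS = 1.00728


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    produced_features: list[str] = field(default_factory=list)
    depleted_features: list[str] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    shared_features: list[tuple[str, str]] = field(default_factory=list)
    linked_gene_patterns: dict[str, str] = field(default_factory=dict)
    labeled_compounds: dict[str, list[float]] = field(default_factory=dict)
    logistic_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _lognormal_sigma(cv: float) -> float:
    """Log-scale sd giving the requested coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


# ---------------------------------------------------------------------------
# feature-table experiments
# ---------------------------------------------------------------------------

def gen_feature_experiment(
    n_features: int = 200,
    n_samples_per_group: int = 3,
    groups: tuple[str, str] = ("culture", "control"),
    n_produced: int = 10,
    n_depleted: int = 5,
    effect_log2: float = 3.0,
    blank_level: float = 1e3,
    cv: float = 0.1,
    n_blanks: int = 3,
    times: list[float] | None = None,
    seed: int = 0,
    mode: str = "positive",
) -> tuple[FeatureTable, GroundTruth]:
    """Synthetic culture-vs-control feature table with planted effects.

    Baseline feature intensities are log-normal (about 1e4-1e6); the first
    group of ``groups`` is the culture. Planted produced features are shifted
    up by ``effect_log2`` (log2 units) in the culture, depleted features
    down. With ``times`` set, a time-course design is generated instead:
    each group x replicate is sampled at every time and produced features
    rise along a logistic-shaped trajectory in the culture group only.
    """
    if n_produced + n_depleted > n_features:
        raise ValueError("more planted features than features")
    rng = np.random.default_rng(seed)
    fids = [f"F{i:05d}" for i in range(n_features)]
    produced = fids[:n_produced]
    depleted = fids[n_produced : n_produced + n_depleted]
    base = 10 ** rng.uniform(4.0, 6.0, size=n_features)
    sigma = _lognormal_sigma(cv)

    case, ctrl = groups
    columns: list[str] = []
    roles, grps, tcol, reps = {}, {}, {}, {}
    design: list[tuple[str, str, int, float | None]] = []
    for g in groups:
        for r in range(n_samples_per_group):
            if times is None:
                sid = f"{g}_r{r}"
                design.append((sid, g, r, None))
            else:
                for t in times:
                    sid = f"{g}_r{r}_t{t:g}"
                    design.append((sid, g, r, float(t)))
    for b in range(n_blanks):
        design.append((f"blank_{b}", "blank", b, None))

    data = np.empty((n_features, len(design)))
    for j, (sid, g, r, t) in enumerate(design):
        columns.append(sid)
        if g == "blank":
            mean = np.full(n_features, blank_level)
            roles[sid], grps[sid] = "blank", "blank"
        else:
            mean = base.copy()
            if g == case:
                if times is None:
                    mean[:n_produced] *= 2.0**effect_log2
                    mean[n_produced : n_produced + n_depleted] *= 2.0**-effect_log2
                else:
                    # logistic-shaped production over the time course
                    tmax = max(times)
                    frac = 1.0 / (1.0 + np.exp(-8.0 * (t / tmax - 0.5)))
                    mean[:n_produced] *= 2.0 ** (effect_log2 * frac)
                    mean[n_produced : n_produced + n_depleted] *= 2.0 ** (-effect_log2 * frac)
            roles[sid], grps[sid] = "sample", g
        tcol[sid] = t if t is not None else np.nan
        reps[sid] = r
        data[:, j] = mean * np.exp(rng.normal(0.0, sigma, size=n_features))

    intensities = pd.DataFrame(data, index=fids, columns=columns)
    mz = pd.Series(rng.uniform(80, 800, size=n_features), index=fids).round(4)
    rt = pd.Series(rng.uniform(0.5, 12.0, size=n_features), index=fids).round(3)
    table = make_feature_table(
        intensities,
        mz=mz,
        rt=rt,
        mode=mode,
        adduct="[M+H]+" if mode == "positive" else "[M-H]-",
        sample_roles=roles,
        sample_groups=grps,
        sample_times=tcol,
        sample_replicates=reps,
    )
    truth = GroundTruth(produced_features=list(produced), depleted_features=list(depleted))
    return table, truth


def gen_mode_pair(
    n_features: int = 60,
    n_duplicates: int = 10,
    n_samples: int = 8,
    cv: float = 0.1,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, GroundTruth]:
    """Positive/negative mode tables with planted cross-mode duplicates.

    Duplicate pairs share a neutral mass (pos observed as [M+H]+, neg as
    [M-H]-), retention time, and a correlated abundance profile (r >= 0.9 by
    construction: shared log-normal signal with small independent noise).
    """
    rng = np.random.default_rng(seed)
    sigma = _lognormal_sigma(cv)
    sids = [f"s{i}" for i in range(n_samples)]

    neutral = rng.uniform(100, 600, size=n_features)
    rt = rng.uniform(1, 10, size=n_features)
    base = 10 ** rng.uniform(4, 6, size=n_features)
    profile = base[:, None] * np.exp(rng.normal(0, 1.0, size=(n_features, n_samples)))

    pos_ids = [f"P{i:04d}" for i in range(n_features)]
    pos_int = pd.DataFrame(
        profile * np.exp(rng.normal(0, sigma / 3, size=profile.shape)),
        index=pos_ids, columns=sids,
    )
    pos = make_feature_table(
        pos_int,
        mz=pd.Series(neutral + PROTON_MASS, index=pos_ids),
        rt=pd.Series(rt, index=pos_ids),
        mode="positive", adduct="[M+H]+",
        sample_roles={s: "sample" for s in sids},
    )

    neg_ids = [f"N{i:04d}" for i in range(n_duplicates)]
    neg_int = pd.DataFrame(
        profile[:n_duplicates] * np.exp(rng.normal(0, sigma / 3, size=(n_duplicates, n_samples))),
        index=neg_ids, columns=sids,
    )
    neg = make_feature_table(
        neg_int,
        mz=pd.Series(neutral[:n_duplicates] - PROTON_MASS, index=neg_ids),
        rt=pd.Series(rt[:n_duplicates] + rng.uniform(-0.02, 0.02, n_duplicates), index=neg_ids),
        mode="negative", adduct="[M-H]-",
        sample_roles={s: "sample" for s in sids},
    )
    truth = GroundTruth(duplicate_pairs=list(zip(pos_ids[:n_duplicates], neg_ids)))
    return pos, neg, truth


def gen_spectrum(rng: np.random.Generator, n_frag_range=(6, 15)) -> list[tuple[float, float]]:
    n = int(rng.integers(*n_frag_range))
    mz = np.sort(rng.uniform(50, 500, size=n))
    # enforce distinct fragment m/z
    mz = np.unique(np.round(mz, 4))
    inten = 10 ** rng.uniform(2, 5, size=len(mz))
    return list(zip(mz.tolist(), inten.tolist()))


def gen_linking_pair(
    n_shared: int = 40,
    n_unique_each: int = 40,
    mz_jitter: float = 0.0,
    rt_jitter: float = 0.0,
    n_samples: int = 4,
    mode: str = "positive",
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable, dict[str, Ms2Spectrum], GroundTruth]:
    """Two datasets with planted shared features carrying identical spectra.

    Shared features appear in both tables at (optionally jittered) m/z and
    RT with the same MS2 spectrum; unique decoy features are well separated
    (> linking tolerances) and carry independent random spectra.
    """
    rng = np.random.default_rng(seed)
    sids = [f"s{i}" for i in range(n_samples)]
    spectra: dict[str, Ms2Spectrum] = {}

    def _table(prefix: str, mzs, rts, specs) -> FeatureTable:
        fids = [f"{prefix}{i:04d}" for i in range(len(mzs))]
        inten = pd.DataFrame(
            10 ** rng.uniform(4, 6, size=(len(fids), n_samples)), index=fids, columns=sids
        )
        for fid, sp in zip(fids, specs):
            spectra[fid] = Ms2Spectrum(fid, sp)
        return make_feature_table(
            inten,
            mz=pd.Series(mzs, index=fids),
            rt=pd.Series(rts, index=fids),
            mode=mode, adduct="[M+H]+" if mode == "positive" else "[M-H]-",
            sample_roles={s: "sample" for s in sids},
        )

    n_total = n_shared + n_unique_each
    # well-separated grid of true compounds: > tolerances apart
    mz_grid = 100 + 0.5 * np.arange(2 * n_total)
    rt_grid = 1 + 0.7 * (np.arange(2 * n_total) % 12)
    shared_specs = [gen_spectrum(rng) for _ in range(n_shared)]
    a_specs = shared_specs + [gen_spectrum(rng) for _ in range(n_unique_each)]
    b_specs = [list(s) for s in shared_specs] + [gen_spectrum(rng) for _ in range(n_unique_each)]
    a_mz = np.concatenate([mz_grid[:n_shared], mz_grid[n_total : n_total + n_unique_each]])
    a_rt = np.concatenate([rt_grid[:n_shared], rt_grid[n_total : n_total + n_unique_each]])
    b_mz = np.concatenate(
        [mz_grid[:n_shared] + rng.uniform(-mz_jitter, mz_jitter, n_shared) if mz_jitter else mz_grid[:n_shared],
         mz_grid[n_total + n_unique_each : n_total + 2 * n_unique_each]]
    )
    b_rt = np.concatenate(
        [rt_grid[:n_shared] + rng.uniform(-rt_jitter, rt_jitter, n_shared) if rt_jitter else rt_grid[:n_shared],
         rt_grid[n_total + n_unique_each : n_total + 2 * n_unique_each]]
    )
    table_a = _table("A", a_mz, a_rt, a_specs)
    table_b = _table("B", b_mz, b_rt, b_specs)
    truth = GroundTruth(
        shared_features=[(f"A{i:04d}", f"B{i:04d}") for i in range(n_shared)]
    )
    return table_a, table_b, spectra, truth


def gen_null_spectra(n: int = 500, seed: int = 0) -> dict[str, Ms2Spectrum]:
    """Random sparse fragment spectra for null cosine calibration."""
    rng = np.random.default_rng(seed)
    return {f"S{i:04d}": Ms2Spectrum(f"S{i:04d}", gen_spectrum(rng)) for i in range(n)}


# ---------------------------------------------------------------------------
# strain panel
# ---------------------------------------------------------------------------

def gen_strain_panel(
    n_strains: int = 30,
    n_gene_families: int = 40,
    n_features: int = 60,
    n_linked_features: int = 10,
    delta_log10: float = 1.0,
    margin_ok: bool = True,
    n_replicates: int = 3,
    n_controls: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[GenePresenceMatrix, FeatureTable, GroundTruth]:
    """Strain panel with gene-linked metabolite features.

    Presence patterns are random non-constant Bernoulli(0.5) columns over
    strains; each of the first ``n_linked_features`` features is tied to one
    gene family: strains carrying the gene produce it ``delta_log10`` above
    background with clean separability margins (when ``margin_ok``), strains
    without it sit at the sterile-control background. Remaining features are
    unlinked noise. The table carries per-strain replicates plus sterile
    controls and is analyzed on the raw scale.
    """
    if n_linked_features > n_gene_families:
        raise ValueError("n_linked_features must be <= n_gene_families")
    rng = np.random.default_rng(seed)
    strains = [f"EL{i:03d}" for i in range(n_strains)]
    fams = [f"fam{i:03d}" for i in range(n_gene_families)]
    pres = np.zeros((n_gene_families, n_strains), dtype=bool)
    for i in range(n_gene_families):
        while True:
            row = rng.random(n_strains) < 0.5
            if 2 <= row.sum() <= n_strains - 2:
                pres[i] = row
                break
    matrix = GenePresenceMatrix(pd.DataFrame(pres, index=fams, columns=strains))

    fids = [f"F{i:04d}" for i in range(n_features)]
    ctrl_log10 = 1.0  # sterile-control background, log10 units
    sep = delta_log10 if margin_ok else 0.1
    # per-sample log10 values
    cols, roles, strain_of, reps = [], {}, {}, {}
    log_vals = np.empty((n_features, n_strains * n_replicates + n_controls))
    j = 0
    for s_idx, s in enumerate(strains):
        for r in range(n_replicates):
            sid = f"{s}_r{r}"
            cols.append(sid)
            roles[sid], strain_of[sid], reps[sid] = "sample", s, r
            col = np.full(n_features, ctrl_log10) + rng.normal(0, noise_sd, n_features)
            for f in range(n_linked_features):
                if pres[f, s_idx]:
                    col[f] += sep
            # unlinked variable features: strain-random but pattern-free
            col[n_linked_features:] += rng.normal(0, 0.05, n_features - n_linked_features)
            log_vals[:, j] = col
            j += 1
    for c in range(n_controls):
        sid = f"control_{c}"
        cols.append(sid)
        roles[sid], strain_of[sid], reps[sid] = "control", None, c
        log_vals[:, j] = ctrl_log10 + rng.normal(0, noise_sd / 2, n_features)
        j += 1

    intensities = pd.DataFrame(10**log_vals, index=fids, columns=cols)
    table = make_feature_table(
        intensities,
        mz=pd.Series(rng.uniform(80, 800, n_features), index=fids),
        rt=pd.Series(rng.uniform(0.5, 12, n_features), index=fids),
        sample_roles=roles,
        sample_groups={c: (strain_of[c] or "control") for c in cols},
        sample_replicates=reps,
        sample_strains=strain_of,
    )
    linked = {}
    for f in range(n_linked_features):
        pattern = "".join("1" if v else "0" for v in pres[f])
        linked[fids[f]] = pattern
    truth = GroundTruth(linked_gene_patterns=linked)
    return matrix, table, truth


# ---------------------------------------------------------------------------
# toy metabolic network
# ---------------------------------------------------------------------------

@dataclass
class ToyModelSpec:
    """Toy network plus its hand-derived optimum.

    Biomass consumes 1 acetyl-CoA + 2 ATP; acetate activation costs 1 ATP;
    each arginine (or agmatine, in the variant) yields 1 ATP through the
    deiminase chain's carbamate-kinase step. Hence ATP balance gives
    3 mu <= A + G and carbon balance gives mu <= C:
    mu(A, C, G) = min((A + G) / 3, C).
    """

    model: MetabolicModel
    arginine_exchange: str = "EX_arg_e"
    acetate_exchange: str = "EX_ac_e"
    agmatine_exchange: str | None = None

    def closed_form_mu(self, arginine: float, acetate: float, agmatine: float = 0.0) -> float:
        return min((arginine + agmatine) / 3.0, acetate)


def gen_toy_model(
    arginine_uptake: float = 10.0,
    acetate_uptake: float = 1.0,
    agmatine_uptake: float | None = None,
    with_futile_cycle: bool = False,
) -> ToyModelSpec:
    """Ten-reaction toy network for arginine/acetate-dependent growth.

    Pass ``agmatine_uptake`` to include the alternative deiminase ATP
    pathway (agmatine -> putrescine + carbamoyl phosphate); pass
    ``with_futile_cycle`` to append a two-reaction reversible loop that an
    FBA optimum may carry but a parsimonious solution must zero.
    """
    mets = {
        m: Metabolite(m, compartment="e" if m.endswith("_e") else "c")
        for m in ["arg_e", "arg_c", "orn_c", "orn_e", "cbp_c", "atp_c",
                  "ac_e", "ac_c", "accoa_c"]
    }
    rxns = {
        "EX_arg_e": Reaction("EX_arg_e", {"arg_e": -1}, -arginine_uptake, 1000),
        "ARGt": Reaction("ARGt", {"arg_e": -1, "arg_c": 1}, 0, 1000, gpr="g_argT"),
        # lumped arginine deiminase + ornithine carbamoyltransferase:
        # arginine -> ornithine + carbamoyl phosphate
        "ADI": Reaction("ADI", {"arg_c": -1, "orn_c": 1, "cbp_c": 1}, 0, 1000,
                        gpr="g_adi", subsystem="arginine catabolism"),
        # carbamate kinase: substrate-level phosphorylation, 1 ATP per carbamoyl-P
        "CK": Reaction("CK", {"cbp_c": -1, "atp_c": 1}, 0, 1000,
                       gpr="g_ck", subsystem="arginine catabolism"),
        "ORNt": Reaction("ORNt", {"orn_c": -1, "orn_e": 1}, 0, 1000, gpr="g_ornT"),
        "EX_orn_e": Reaction("EX_orn_e", {"orn_e": -1}, 0, 1000),
        "EX_ac_e": Reaction("EX_ac_e", {"ac_e": -1}, -acetate_uptake, 1000),
        "ACt": Reaction("ACt", {"ac_e": -1, "ac_c": 1}, 0, 1000, gpr="g_acT"),
        # acetate activation to acetyl-CoA at the cost of 1 ATP
        "ACS": Reaction("ACS", {"ac_c": -1, "atp_c": -1, "accoa_c": 1}, 0, 1000,
                        gpr="g_ack and g_pta", subsystem="acetate activation"),
        "BIOMASS": Reaction("BIOMASS", {"accoa_c": -1, "atp_c": -2}, 0, 1000,
                            subsystem="biomass"),
    }
    if agmatine_uptake is not None:
        mets.update({m: Metabolite(m, compartment="e" if m.endswith("_e") else "c")
                     for m in ["agm_e", "agm_c", "ptrc_c", "ptrc_e"]})
        rxns.update({
            "EX_agm_e": Reaction("EX_agm_e", {"agm_e": -1}, -agmatine_uptake, 1000),
            "AGMt": Reaction("AGMt", {"agm_e": -1, "agm_c": 1}, 0, 1000, gpr="g_agmT"),
            # agmatine deiminase + putrescine carbamoyltransferase (lumped)
            "AGDI": Reaction("AGDI", {"agm_c": -1, "ptrc_c": 1, "cbp_c": 1}, 0, 1000,
                             gpr="g_agdi", subsystem="agmatine catabolism"),
            "PTRCt": Reaction("PTRCt", {"ptrc_c": -1, "ptrc_e": 1}, 0, 1000, gpr="g_ptrcT"),
            "EX_ptrc_e": Reaction("EX_ptrc_e", {"ptrc_e": -1}, 0, 1000),
        })
    if with_futile_cycle:
        mets.update({"fc1_c": Metabolite("fc1_c"), "fc2_c": Metabolite("fc2_c")})
        rxns.update({
            "FC1": Reaction("FC1", {"fc1_c": -1, "fc2_c": 1}, -1000, 1000),
            "FC2": Reaction("FC2", {"fc2_c": -1, "fc1_c": 1}, -1000, 1000),
        })
    model = MetabolicModel(
        id="toy_arg_ac", metabolites=mets, reactions=rxns,
        objective_reaction_id="BIOMASS",
    )
    return ToyModelSpec(
        model=model,
        agmatine_exchange="EX_agm_e" if agmatine_uptake is not None else None,
    )


def toy_media(
    arginine_mM: float = 57.0,
    acetate_mM: float = 1.0,
    biomass_density: float = 0.01,
    duration: float = 24.0,
) -> MediaDefinition:
    """Defined-media description matching the toy network's exchanges."""
    return MediaDefinition(
        quantitative={"EX_arg_e": arginine_mM, "EX_ac_e": acetate_mM},
        biomass_density=biomass_density,
        duration=duration,
    )


# ---------------------------------------------------------------------------
# isotopologues
# ---------------------------------------------------------------------------

def gen_isotopologues(
    true_mids: dict[str, list[float]],
    n_carbons: dict[str, int],
    noise_sd: float = 0.0,
    scale: float = 1e6,
    p13: float = 0.0107,
    seed: int = 0,
) -> tuple[dict[str, IsotopologueVector], GroundTruth]:
    """Observed isotopologue areas: scale x (NA-matrix . true MID) + noise.

    ``noise_sd`` is relative to the scaled M+0 channel; negative draws are
    truncated at zero.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for cid, mid in true_mids.items():
        n = n_carbons[cid]
        M = natural_abundance_matrix(n, p13)
        clean = scale * (M @ np.asarray(mid, dtype=float))
        noisy = clean + rng.normal(0.0, noise_sd * clean[0] if noise_sd else 0.0, size=n + 1)
        noisy = np.clip(noisy, 0.0, None)
        out[cid] = IsotopologueVector(cid, n, noisy)
    truth = GroundTruth(labeled_compounds={c: list(m) for c, m in true_mids.items()})
    return out, truth


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def gen_growth_curves(
    params: dict[str, tuple[float, float, float]],
    n_replicates: int = 4,
    times: np.ndarray | None = None,
    noise_sd: float = 0.01,
    blank_level: float = 0.09,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Plate of logistic growth curves plus constant-background blanks.

    ``params`` maps condition -> (K, N0, r). Returns (raw readings with a
    ``time`` column, plate map, ground truth of per-well parameters); feed
    through :func:`elenta.growth_curves.blank_normalize` as with real data.
    """
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(0.0, 48.0 + 1e-9, 0.5)
    times = np.asarray(times, dtype=float)
    data = {"time": times}
    rows = []
    truth = GroundTruth()
    for cond, (K, N0, r) in params.items():
        for rep in range(n_replicates):
            well = f"{cond}_r{rep}"
            clean = logistic(times, K, N0, r)
            data[well] = clean + blank_level + rng.normal(0, noise_sd, size=len(times))
            rows.append(dict(well=well, condition=cond, replicate=rep, is_blank=False))
            truth.logistic_params[well] = (K, N0, r)
    for b in range(3):
        well = f"blank_{b}"
        data[well] = blank_level + rng.normal(0, noise_sd / 2, size=len(times))
        rows.append(dict(well=well, condition="blank", replicate=b, is_blank=True))
    raw = pd.DataFrame(data)
    plate_map = pd.DataFrame(rows).set_index("well")
    return raw, plate_map, truth
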