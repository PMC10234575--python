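"""QC filters, transforms, and differential statistics for feature tables.

The processing chain mirrors common untargeted-metabolomics practice for
culture-supernatant experiments: blank-based presence calls, replicate-CV
filtering, outlier-sample removal, pseudocounted log transform, cross-mode
dereplication, Welch/BH differential abundance, permutation-based trajectory
comparison, and classification of strain-variable features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

PROTON_MASS = 1.00728  # Da

#: neutral-mass offsets: neutral = mz + offset for each adduct label
ADDUCT_OFFSETS = {
    "[M+H]+": -PROTON_MASS,
    "[M-H]-": +PROTON_MASS,
    "[M+Na]+": -22.98922,
    "[M+Cl]-": -34.96885,
}


@dataclass
class DifferentialResult:
    feature_id: str
    log2fc: float
    t_stat: float
    p: float
    p_adj: float
    call: str  # increased / decreased / unchanged
    flagged: bool = False  # zero-variance degenerate test


@dataclass
class TrajectoryTestResult:
    feature_id: str
    stat: float
    p_perm: float
    p_adj: float


# ---------------------------------------------------------------------------
# presence / QC filters
# ---------------------------------------------------------------------------

def call_present(
    table: FeatureTable,
    blank_fold: float = 3.0,
    group: str | None = None,
) -> pd.Series:
    """Per-feature presence mask: mean sample intensity strictly above
    ``blank_fold`` times the mean blank intensity.

    ``group`` optionally restricts the non-blank samples to one condition
    (presence can be evaluated per time point or per condition by passing
    the appropriate group label).
    """
    blanks = table.sample_ids_by_role("blank")
    if not blanks:
        raise ValueError("presence call requires blank samples; none found")
    nonblank = [s for s in table.sample_ids if s not in set(blanks)]
    if group is not None:
        grp = set(table.sample_ids_by_group(group))
        nonblank = [s for s in nonblank if s in grp]
    if not nonblank:
        raise ValueError("presence call requires at least one non-blank sample")
    mean_sample = table.intensities[nonblank].mean(axis=1)
    mean_blank = table.intensities[blanks].mean(axis=1)
    return mean_sample > blank_fold * mean_blank


def _replicate_groups(table: FeatureTable) -> list[list[str]]:
    """Samples sharing (role, group, time, strain) form one replicate group."""
    meta = table.samples
    keys = meta[["role", "group", "time_h", "strain"]].astype(str).agg("|".join, axis=1)
    return [list(meta.index[keys == k]) for k in keys.unique()]


def feature_cv(table: FeatureTable, pool_groups: bool = False) -> pd.Series:
    """Median across-replicate-group CV (sd/mean of raw intensities).

    With ``pool_groups`` the CV is computed once over all non-blank samples
    (the alternative reading of "across replicate samples").
    """
    if table.log_base is not None:
        raise ValueError("CV filter operates on raw intensities")
    if pool_groups:
        cols = table.sample_ids_by_role("sample", "control", "pool")
        groups = [cols] if len(cols) >= 2 else []
    else:
        groups = [g for g in _replicate_groups(table) if len(g) >= 2]
    if not groups:
        raise ValueError("CV undefined: no replicate group of size >= 2")
    cvs = []
    for g in groups:
        block = table.intensities[g]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cv = sd / mean
        cv[mean == 0] = np.nan  # zero-mean groups carry no information
        cvs.append(cv)
    return pd.concat(cvs, axis=1).median(axis=1, skipna=True)


def filter_features_by_cv(
    table: FeatureTable, cv_max: float = 0.5, pool_groups: bool = False
) -> FeatureTable:
    """Drop features whose median replicate-group CV exceeds ``cv_max``."""
    med = feature_cv(table, pool_groups=pool_groups)
    keep = ~(med > cv_max)  # NaN medians (all-zero feature) are kept
    return table.subset_features(table.feature_ids[keep])


def filter_outlier_samples(table: FeatureTable, dev_max: float = 0.5) -> FeatureTable:
    """Drop non-blank samples whose total signal deviates from the assay
    median total by more than ``dev_max`` (fractional deviation)."""
    nonblank = [s for s in table.sample_ids if table.samples.loc[s, "role"] != "blank"]
    if len(nonblank) < 3:
        raise ValueError("outlier filter requires at least 3 non-blank samples")
    totals = table.intensities[nonblank].sum(axis=0)
    med = float(totals.median())
    if med == 0:
        raise ValueError("median total signal is zero; outlier deviation undefined")
    dev = (totals - med).abs() / med
    drop = set(totals.index[dev > dev_max])
    keep = [s for s in table.sample_ids if s not in drop]
    return table.subset_samples(keep)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def feature_pseudocounts(table: FeatureTable, pseudocount_frac: float = 0.25) -> pd.Series:
    """Per-feature pseudocount: ``pseudocount_frac`` x minimum nonzero intensity."""
    vals = table.intensities
    masked = vals.where(vals > 0)
    min_nonzero = masked.min(axis=1)
    if min_nonzero.isna().any():
        bad = list(min_nonzero.index[min_nonzero.isna()])[:5]
        raise ValueError(f"all-zero features have no pseudocount: {bad}")
    return pseudocount_frac * min_nonzero


def log_transform(
    table: FeatureTable, pseudocount_frac: float = 0.25, base: float = 10.0
) -> FeatureTable:
    """Pseudocounted log transform: ``log_base(x + frac * min nonzero(x))``.

    The transform is skippable simply by not calling it; datasets analyzed on
    the raw scale (e.g. the strain panel) keep ``log_base=None``.
    """
    if table.log_base is not None:
        raise ValueError("table already log-transformed")
    pc = feature_pseudocounts(table, pseudocount_frac)
    shifted = table.intensities.add(pc, axis=0)
    out = np.log(shifted) / np.log(base)
    return FeatureTable(
        out, table.features.copy(), table.samples.copy(), log_base=base, pseudocounts=pc
    )


# ---------------------------------------------------------------------------
# cross-mode dereplication
# ---------------------------------------------------------------------------

def neutral_mass(mz: float, adduct: str | None) -> float | None:
    """Neutral monoisotopic mass from an observed m/z, or None for unknown adducts."""
    if adduct in ADDUCT_OFFSETS:
        return mz + ADDUCT_OFFSETS[adduct]
    return None


def dereplicate_modes(
    pos: FeatureTable,
    neg: FeatureTable,
    mass_tol: float = 0.02,
    rt_tol: float = 0.1,
    min_corr: float = 0.7,
) -> tuple[FeatureTable, dict[str, str]]:
    """Merge duplicate detections of one compound across ionization modes.

    A positive/negative pair is merged when adduct-corrected neutral masses
    agree within ``mass_tol`` Da, retention times within ``rt_tol`` min, and
    the Pearson correlation of intensities across shared samples is at least
    ``min_corr``. Unknown adducts fall back to direct m/z comparison. The
    member with the lower (more confident) MSI level is kept; ties keep the
    positive-mode feature. Returns the merged table and a dropped->kept map.
    """
    shared = [s for s in pos.sample_ids if s in set(neg.sample_ids)]
    if len(shared) < 3:
        raise ValueError("dereplication needs >= 3 shared samples for correlation")

    def _mass(tab: FeatureTable, fid: str) -> tuple[float, bool]:
        mz = float(tab.features.loc[fid, "mz"])
        nm = neutral_mass(mz, tab.features.loc[fid, "adduct"])
        return (mz, False) if nm is None else (nm, True)

    merge_map: dict[str, str] = {}
    drop_pos: set[str] = set()
    drop_neg: set[str] = set()
    neg_taken: set[str] = set()
    for pid in pos.feature_ids:
        pmass, p_has = _mass(pos, pid)
        prt = float(pos.features.loc[pid, "rt"])
        pvals = pos.intensities.loc[pid, shared].to_numpy(dtype=float)
        for nid in neg.feature_ids:
            if nid in neg_taken:
                continue
            nmass, n_has = _mass(neg, nid)
            if p_has != n_has:  # cannot compare neutral vs raw m/z
                continue
            if abs(pmass - nmass) >= mass_tol:
                continue
            if abs(prt - float(neg.features.loc[nid, "rt"])) >= rt_tol:
                continue
            nvals = neg.intensities.loc[nid, shared].to_numpy(dtype=float)
            if np.std(pvals) == 0 or np.std(nvals) == 0:
                continue
            r = float(np.corrcoef(pvals, nvals)[0, 1])
            if r < min_corr:
                continue
            p_msi = pos.features.loc[pid, "msi_level"]
            n_msi = neg.features.loc[nid, "msi_level"]
            p_msi = np.inf if pd.isna(p_msi) else float(p_msi)
            n_msi = np.inf if pd.isna(n_msi) else float(n_msi)
            if n_msi < p_msi:
                merge_map[pid] = nid
                drop_pos.add(pid)
            else:  # ties and unannotated pairs keep the positive-mode feature
                merge_map[nid] = pid
                drop_neg.add(nid)
            neg_taken.add(nid)
            break

    pos_keep = pos.subset_features([f for f in pos.feature_ids if f not in drop_pos])
    neg_keep = neg.subset_features([f for f in neg.feature_ids if f not in drop_neg])
    all_samples = list(pos.sample_ids) + [s for s in neg.sample_ids if s not in set(pos.sample_ids)]
    merged_int = pd.concat(
        [pos_keep.intensities.reindex(columns=all_samples),
         neg_keep.intensities.reindex(columns=all_samples)]
    ).fillna(0.0)
    merged_feat = pd.concat([pos_keep.features, neg_keep.features])
    samples = pd.concat(
        [pos.samples, neg.samples.loc[[s for s in neg.sample_ids if s not in set(pos.sample_ids)]]]
    )
    merged = FeatureTable(merged_int, merged_feat, samples)
    return merged, merge_map


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    table: FeatureTable,
    case_group: str,
    control_group: str,
    fdr_alpha: float = 0.1,
    lfc_min: float = 0.5,
    pseudocount_frac: float = 0.25,
) -> list[DifferentialResult]:
    """Welch t-test per feature (case vs control) with BH adjustment.

    The test statistic is computed on the table's stored values (log scale if
    transformed, raw otherwise, matching how each dataset is analyzed). The
    fold change is always the difference of mean log2 pseudocounted
    intensities, so calls are comparable across datasets.
    """
    case = table.sample_ids_by_group(case_group)
    ctrl = table.sample_ids_by_group(control_group)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("differential abundance requires >= 2 samples per group")

    vals = table.intensities
    if table.log_base is not None:
        # stored values are log_base(x + pc); mean log2 = mean log_base / log_base(2)
        scale = np.log2(table.log_base)
        log2_case = vals[case].mean(axis=1) * scale
        log2_ctrl = vals[ctrl].mean(axis=1) * scale
    else:
        pc = feature_pseudocounts(table, pseudocount_frac)
        log2_case = np.log2(vals[case].add(pc, axis=0)).mean(axis=1)
        log2_ctrl = np.log2(vals[ctrl].add(pc, axis=0)).mean(axis=1)
    log2fc = log2_case - log2_ctrl

    a = vals[case].to_numpy(dtype=float)
    b = vals[ctrl].to_numpy(dtype=float)
    t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate zero-variance features: identical constant groups -> p = 1
    flagged = np.zeros(len(p), dtype=bool)
    var0 = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same = var0 & (a.mean(axis=1) == b.mean(axis=1))
    t_stat = np.where(same, 0.0, t_stat)
    p = np.where(same, 1.0, p)
    flagged |= var0
    p = np.nan_to_num(p, nan=1.0)
    t_stat = np.nan_to_num(t_stat, nan=0.0)

    p_adj = bh_adjust(p)
    results = []
    for i, fid in enumerate(table.feature_ids):
        lfc = float(log2fc.iloc[i])
        call = "unchanged"
        if p_adj[i] < fdr_alpha and abs(lfc) > lfc_min:
            call = "increased" if lfc > 0 else "decreased"
        results.append(
            DifferentialResult(
                feature_id=str(fid),
                log2fc=lfc,
                t_stat=float(t_stat[i]),
                p=float(p[i]),
                p_adj=float(p_adj[i]),
                call=call,
                flagged=bool(flagged[i]),
            )
        )
    return results


def differential_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(feature_id=r.feature_id, log2fc=r.log2fc, t_stat=r.t_stat,
                 p=r.p, p_adj=r.p_adj, call=r.call)
            for r in results
        ]
    ).set_index("feature_id")


# ---------------------------------------------------------------------------
# trajectory comparison
# ---------------------------------------------------------------------------

def _spline_design(t: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` basis functions over t."""
    k = 3
    n_interior = df - (k + 1)
    if n_interior < 0:
        raise ValueError(f"df={df} too small for cubic basis; need df >= 4")
    t0, t1 = float(t.min()), float(t.max())
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[t0] * (k + 1), interior, [t1] * (k + 1)])
    return interpolate.BSpline.design_matrix(t, knots, k).toarray()


def _fit_curve(t: np.ndarray, y: np.ndarray, df: int, grid: np.ndarray) -> np.ndarray:
    X = _spline_design(t, df)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    Xg = _spline_design_eval(t, df, grid)
    return Xg @ coef


def _spline_design_eval(t: np.ndarray, df: int, grid: np.ndarray) -> np.ndarray:
    k = 3
    n_interior = df - (k + 1)
    t0, t1 = float(t.min()), float(t.max())
    interior = (
        np.quantile(t, np.linspace(0, 1, n_interior + 2)[1:-1])
        if n_interior > 0
        else np.array([])
    )
    knots = np.concatenate([[t0] * (k + 1), interior, [t1] * (k + 1)])
    g = np.clip(grid, t0, t1 - 1e-12 * max(1.0, abs(t1)))
    return interpolate.BSpline.design_matrix(g, knots, k).toarray()


def trajectory_difference(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    df: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    n_grid: int = 50,
    fdr_alpha: float = 0.25,
) -> list[TrajectoryTestResult]:
    """Permutation test for diverging time trajectories between two groups.

    Each replicate series (one replicate of one group over time) is smoothed
    with a least-squares cubic B-spline of ``df`` degrees of freedom; the test
    statistic is the mean absolute difference between the two group mean
    curves on a uniform time grid. The null distribution reassigns whole
    replicate series to groups.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1; permutation p undefined otherwise")
    meta = table.samples
    sel = meta[meta["group"].isin([group_a, group_b])]
    if sel["time_h"].isna().any():
        raise ValueError("trajectory test requires time_h for all samples")
    n_times = sel["time_h"].nunique()
    if n_times < 3:
        raise ValueError("trajectory test requires >= 3 time points")
    if n_times < df:
        raise ValueError(
            f"fewer time points ({n_times}) than spline df ({df}); lower df"
        )

    # one series per (group, replicate)
    series = []  # (group, [sample ids ordered by time], times)
    for (grp, rep), sub in sel.groupby(["group", "replicate"]):
        sub = sub.sort_values("time_h")
        series.append((grp, list(sub.index), sub["time_h"].to_numpy(dtype=float)))
    labels = np.array([s[0] for s in series])
    if (labels == group_a).sum() < 2 or (labels == group_b).sum() < 2:
        raise ValueError("trajectory test requires >= 2 replicates per group")

    tmin = sel["time_h"].min()
    tmax = sel["time_h"].max()
    grid = np.linspace(tmin, tmax, n_grid)

    # fitted curve per (series, feature): n_series x n_grid x n_features
    fids = table.feature_ids
    curves = np.empty((len(series), n_grid, len(fids)))
    for si, (_, ids, t) in enumerate(series):
        Y = table.intensities[ids].to_numpy(dtype=float).T  # times x features
        X = _spline_design(t, df)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Xg = _spline_design_eval(t, df, grid)
        curves[si] = Xg @ coef

    def _stat(lab: np.ndarray) -> np.ndarray:
        ma = curves[lab == group_a].mean(axis=0)
        mb = curves[lab == group_b].mean(axis=0)
        return np.abs(ma - mb).mean(axis=0)  # per feature

    obs = _stat(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(fids))
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        exceed += _stat(perm) >= obs
    p_perm = (exceed + 1) / (n_perm + 1)
    p_adj = bh_adjust(p_perm)
    return [
        TrajectoryTestResult(str(fid), float(obs[i]), float(p_perm[i]), float(p_adj[i]))
        for i, fid in enumerate(fids)
    ]


# ---------------------------------------------------------------------------
# strain variability
# ---------------------------------------------------------------------------

def classify_strain_variability(
    per_strain_results: dict[str, list[DifferentialResult]],
    near_all: int = 29,
) -> pd.DataFrame:
    """Label each feature variable / conserved / absent from per-strain calls.

    A feature is *variable* when called increased (resp. decreased) in at
    least one strain but fewer than ``near_all``; *conserved* at >= near_all;
    *absent* when never called. Directions are classified independently and
    combined (variable in either direction wins over conserved).
    """
    strains = list(per_strain_results)
    universes = [frozenset(r.feature_id for r in res) for res in per_strain_results.values()]
    if len(set(universes)) != 1:
        raise ValueError("per-strain results must share an identical feature set")
    fids = sorted(universes[0])
    inc = pd.Series(0, index=fids)
    dec = pd.Series(0, index=fids)
    for res in per_strain_results.values():
        for r in res:
            if r.call == "increased":
                inc[r.feature_id] += 1
            elif r.call == "decreased":
                dec[r.feature_id] += 1

    def _label(n: int) -> str:
        if n == 0:
            return "absent"
        if n < near_all:
            return "variable"
        return "conserved"

    rows = []
    for fid in fids:
        li, ld = _label(int(inc[fid])), _label(int(dec[fid]))
        if "variable" in (li, ld):
            overall = "variable"
        elif "conserved" in (li, ld):
            overall = "conserved"
        else:
            overall = "absent"
        rows.append(
            dict(feature_id=fid, n_increased=int(inc[fid]), n_decreased=int(dec[fid]),
                 label=overall)
        )
    return pd.DataFrame(rows).set_index("feature_id")
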