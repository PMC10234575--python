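"""Plate-reader growth-curve normalization, logistic fits, and media tests.

Wells are background-corrected against time-matched blank wells, fitted with
the logistic model N(t) = K / (1 + ((K - N0)/N0) e^(-rt)) by deterministic
multi-start nonlinear least squares, and summarized by the empirical area
under the curve (AUC, trapezoidal). Media-component effects are tested by
two-sided Wilcoxon rank-sum on AUC against a reference condition with BH
adjustment. Fits with residual standard error above 0.1 OD are flagged for
exclusion, screening out non-logistic or failed wells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .feature_qc import bh_adjust

SIGMA_MAX = 0.1  # residual standard error above which a fit is excluded


@dataclass
class GrowthCurve:
    well_id: str
    condition: str
    replicate: int
    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # background-normalized OD600

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.time) != len(self.od):
            raise ValueError(f"well {self.well_id}: time/od length mismatch")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError(f"well {self.well_id}: time must be strictly increasing")


@dataclass
class LogisticFit:
    well_id: str
    K: float
    N0: float
    r: float
    sigma: float
    converged: bool = True

    @property
    def excluded(self) -> bool:
        return (not self.converged) or self.sigma > SIGMA_MAX


def logistic(t: np.ndarray, K: float, N0: float, r: float) -> np.ndarray:
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def blank_normalize(
    raw: pd.DataFrame,
    plate_map: pd.DataFrame,
    clip_at_zero: bool = False,
) -> list[GrowthCurve]:
    """Subtract mean time-matched blank readings from each culture well.

    ``raw`` has a ``time`` column (hours) plus one column per well;
    ``plate_map`` is indexed by well with columns condition, replicate,
    is_blank. Negative normalized values are kept unless ``clip_at_zero``.
    """
    blanks = list(plate_map.index[plate_map["is_blank"].astype(bool)])
    if not blanks:
        raise ValueError("no blank wells in plate map")
    missing = [w for w in blanks if w not in raw.columns]
    if missing:
        raise ValueError(f"blank wells missing from readings: {missing}")
    if raw[blanks].isna().any().any():
        raise ValueError("blank wells have missing time points")
    background = raw[blanks].mean(axis=1)
    curves = []
    t = raw["time"].to_numpy(dtype=float)
    for well in plate_map.index:
        if well in blanks or well not in raw.columns:
            continue
        od = raw[well].to_numpy(dtype=float) - background.to_numpy()
        if clip_at_zero:
            od = np.clip(od, 0.0, None)
        curves.append(
            GrowthCurve(
                well_id=str(well),
                condition=str(plate_map.loc[well, "condition"]),
                replicate=int(plate_map.loc[well, "replicate"]),
                time=t,
                od=od,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# logistic fitting
# ---------------------------------------------------------------------------

def _initial_guesses(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Deterministic multi-start initialization.

    K from the max OD; N0 from the first positive reading (or K/100); r from
    the log-slope of the rise between 10% and 90% of K, plus bracketing
    alternatives to escape poor local minima.
    """
    K0 = max(float(y.max()), 1e-6)
    pos = y[y > 0]
    N00 = float(pos[0]) if len(pos) else K0 / 100.0
    N00 = min(max(N00, 1e-8), 0.9 * K0)
    lo, hi = 0.1 * K0, 0.9 * K0
    rise = np.where((y > lo) & (y < hi))[0]
    if len(rise) >= 2 and y[rise[-1]] > y[rise[0]] > 0:
        dt = t[rise[-1]] - t[rise[0]]
        r0 = float(np.log(y[rise[-1]] / y[rise[0]]) / dt) if dt > 0 else 0.5
    else:
        r0 = 0.5
    r0 = max(r0, 1e-3)
    return [
        (K0, N00, r0),
        (K0, N00, 2 * r0),
        (K0, N00, r0 / 2),
        (1.2 * K0, K0 / 100.0, r0),
    ]


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit; sigma is the residual standard error
    sqrt(RSS / (n - 3)). Flat or non-growing wells get the r = 0 convention."""
    t, y = curve.time, curve.od
    if len(t) < 5:
        raise ValueError(f"well {curve.well_id}: need >= 5 points to fit")
    if float(y.max()) <= 0 or np.allclose(y, y[0]):
        level = max(float(np.mean(y)), 1e-8)
        resid = y - np.mean(y)
        sigma = float(np.sqrt((resid**2).sum() / max(len(y) - 3, 1)))
        return LogisticFit(curve.well_id, K=level, N0=level, r=0.0, sigma=sigma)

    best = None
    for K0, N00, r0 in _initial_guesses(t, y):
        try:
            popt, _ = optimize.curve_fit(
                logistic, t, y, p0=[K0, N00, r0],
                bounds=([1e-9, 1e-10, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((logistic(t, *popt) - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return LogisticFit(curve.well_id, K=float(y.max()), N0=max(float(y[0]), 1e-8),
                           r=0.0, sigma=np.inf, converged=False)
    rss, (K, N0, r) = best
    sigma = float(np.sqrt(rss / max(len(y) - 3, 1)))
    return LogisticFit(curve.well_id, K=float(K), N0=float(N0), r=float(r), sigma=sigma)


def harmonic_mean_rate(rates: list[float]) -> float:
    """Harmonic mean of replicate growth rates (reporting convention)."""
    arr = np.asarray(rates, dtype=float)
    if (arr <= 0).any():
        return 0.0
    return float(len(arr) / np.sum(1.0 / arr))


# ---------------------------------------------------------------------------
# AUC and condition comparison
# ---------------------------------------------------------------------------

def empirical_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the normalized OD curve, in OD*h."""
    if len(curve.time) < 2:
        raise ValueError("AUC requires >= 2 points")
    return float(np.trapezoid(curve.od, curve.time))


def compare_conditions(
    auc_by_condition: dict[str, list[float]],
    reference: str,
    fdr_alpha: float = 0.2,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of AUC per condition vs the reference.

    Conditions with fewer than 3 replicates are skipped (reported with NaN
    p). Exact p-values are used at small n (no ties correction needed then).
    """
    if reference not in auc_by_condition:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = np.asarray(auc_by_condition[reference], dtype=float)
    rows = []
    for cond, vals in auc_by_condition.items():
        if cond == reference:
            continue
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3 or len(ref) < 3:
            rows.append(dict(condition=cond, n=len(vals), median_auc=float(np.median(vals)),
                             p=np.nan, skipped=True))
            continue
        method = "exact" if (len(vals) <= 25 and len(ref) <= 25
                             and len(np.unique(np.concatenate([vals, ref]))) == len(vals) + len(ref)) else "auto"
        res = stats.mannwhitneyu(vals, ref, alternative="two-sided", method=method)
        rows.append(dict(condition=cond, n=len(vals), median_auc=float(np.median(vals)),
                         p=float(res.pvalue), skipped=False))
    df = pd.DataFrame(rows)
    tested = df[~df["skipped"]]
    df["p_adj"] = np.nan
    if len(tested):
        df.loc[~df["skipped"], "p_adj"] = bh_adjust(tested["p"].to_numpy())
    df["significant"] = df["p_adj"] < fdr_alpha
    return df.set_index("condition")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_plate(readings_csv: str | Path, plate_map_tsv: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(readings_csv)
    if "time" not in raw.columns:
        raise ValueError("readings CSV must have a 'time' column (hours)")
    plate_map = pd.read_csv(plate_map_tsv, sep="\t", index_col="well")
    return raw, plate_map


def fits_to_frame(fits: list[LogisticFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(well_id=f.well_id, K=f.K, N0=f.N0, r=f.r, sigma=f.sigma,
                 converged=f.converged, excluded=f.excluded)
            for f in fits
        ]
    ).set_index("well_id")
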