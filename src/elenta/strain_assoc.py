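"""Associating strain-variable metabolites with accessory gene families.

Across a strain panel, gene families are collapsed into distinct
presence/absence patterns; each metabolite feature is Welch-tested against
each pattern (strains carrying the genes vs strains lacking them), BH
adjusted jointly, and filtered by separability against sterile-control
levels so that only features plausibly *dependent* on the genes survive.
An optional hypergeometric pathway enrichment summarizes the final gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .feature_qc import bh_adjust


@dataclass
class GenePresenceMatrix:
    """Boolean gene-family x strain presence matrix with annotations."""

    presence: pd.DataFrame  # gene families x strains, bool
    annotations: pd.Series | None = None  # gene_family -> term/KEGG id string

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)

    @property
    def strains(self) -> list[str]:
        return list(self.presence.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, annotations: str | Path | None = None) -> "GenePresenceMatrix":
        mat = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
        ann = None
        if annotations is not None:
            df = pd.read_csv(annotations, sep="\t", index_col=0)
            ann = df.iloc[:, 0]
        return cls(mat, ann)

    def to_tsv(self, path: str | Path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t")


@dataclass
class AssociationResult:
    feature_id: str
    pattern_id: str
    gene_families: list[str]
    p: float
    p_adj: float
    delta_median: float  # log10 units, with - without
    passes_separability: bool = False


def strain_log10_summary(table) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse a replicate-level feature table to per-strain log10 values.

    Returns (features x strains log10 of mean replicate intensity,
    features x control-samples log10 intensities). Requires a ``strain``
    column in the sample metadata and control-role samples.
    """
    meta = table.samples
    strain_cols: dict[str, list[str]] = {}
    for sid in table.sample_ids:
        strain = meta.loc[sid, "strain"]
        if meta.loc[sid, "role"] == "sample" and pd.notna(strain) and strain is not None:
            strain_cols.setdefault(str(strain), []).append(sid)
    if not strain_cols:
        raise ValueError("no strain-labeled samples in table")
    vals = {s: table.intensities[cols].mean(axis=1) for s, cols in strain_cols.items()}
    strain_values = np.log10(pd.DataFrame(vals))
    ctrl = table.sample_ids_by_role("control")
    control_values = np.log10(table.intensities[ctrl]) if ctrl else pd.DataFrame(index=table.feature_ids)
    return strain_values, control_values


def enumerate_patterns(matrix: GenePresenceMatrix) -> dict[str, list[str]]:
    """Group gene families by identical presence/absence pattern.

    Constant patterns (present or absent in every strain) carry no contrast
    and are excluded. Pattern ids encode the presence vector.
    """
    if matrix.presence.shape[1] < 2:
        raise ValueError("pattern enumeration requires >= 2 strains")
    groups: dict[str, list[str]] = {}
    for fam, row in matrix.presence.iterrows():
        if row.all() or not row.any():
            continue  # core or universally absent: untestable
        key = "".join("1" if v else "0" for v in row.to_numpy())
        groups.setdefault(key, []).append(fam)
    return groups


def test_associations(
    patterns: dict[str, list[str]],
    strain_values: pd.DataFrame,
    strains: list[str],
    alpha_adj: float = 1e-4,
) -> list[AssociationResult]:
    """Welch t-test of each feature against each presence pattern.

    ``strain_values`` is features x strains (one summary intensity per
    strain, log10 scale). BH adjustment is applied jointly across all
    (feature, pattern) tests. Patterns with fewer than 2 strains on either
    side are skipped.
    """
    tested = []
    stats_rows = []
    for pat_id, fams in sorted(patterns.items()):
        with_mask = np.array([c == "1" for c in pat_id])
        if with_mask.sum() < 2 or (~with_mask).sum() < 2:
            continue
        with_strains = [s for s, m in zip(strains, with_mask) if m]
        without_strains = [s for s, m in zip(strains, with_mask) if not m]
        a = strain_values[with_strains].to_numpy(dtype=float)
        b = strain_values[without_strains].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        same = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
        p = np.where(same, 1.0, np.nan_to_num(p, nan=1.0))
        dmed = np.median(a, axis=1) - np.median(b, axis=1)
        for i, fid in enumerate(strain_values.index):
            tested.append((str(fid), pat_id, fams))
            stats_rows.append((float(p[i]), float(dmed[i])))
    if not tested:
        return []
    pvals = np.array([r[0] for r in stats_rows])
    p_adj = bh_adjust(pvals)
    out = []
    for (fid, pat_id, fams), (p, dmed), pa in zip(tested, stats_rows, p_adj):
        if pa < alpha_adj:
            out.append(AssociationResult(fid, pat_id, list(fams), p, float(pa), dmed))
    return out


def separability_filter(
    results: list[AssociationResult],
    strain_values: pd.DataFrame,
    strains: list[str],
    control_values: pd.DataFrame,
    min_delta: float = 0.4,
    margin: float = 0.4,
    allow_depletion: bool = False,
) -> list[AssociationResult]:
    """Keep associations with clean gene-linked separation, best per feature.

    Criteria (values in log10 units): (a) |median(with) - median(without)|
    >= ``min_delta``; (b) the 10th percentile of with-gene strain values is
    at least ``margin`` above the maximum sterile-control value; (c) the
    90th percentile of without-gene values is below that same threshold.
    Written for the production direction (gene carriers higher); with
    ``allow_depletion`` the mirrored criteria are applied when the median
    difference is negative. Only the lowest-p association per feature is
    retained. Percentiles use linear interpolation (numpy default).
    """
    if control_values is None or control_values.size == 0:
        raise ValueError("separability filter requires sterile-control values")
    passed: list[AssociationResult] = []
    for res in results:
        vals = strain_values.loc[res.feature_id]
        ctrl_max = float(control_values.loc[res.feature_id].max())
        with_mask = np.array([c == "1" for c in res.pattern_id])
        wvals = vals[[s for s, m in zip(strains, with_mask) if m]].to_numpy(dtype=float)
        wovals = vals[[s for s, m in zip(strains, with_mask) if not m]].to_numpy(dtype=float)
        if allow_depletion and res.delta_median < 0:
            wvals, wovals = wovals, wvals  # mirrored: gene carriers deplete
        if abs(res.delta_median) < min_delta:
            continue
        if not allow_depletion and res.delta_median < 0:
            continue
        threshold = ctrl_max + margin
        if np.percentile(wvals, 10) < threshold:
            continue
        if np.percentile(wovals, 90) >= threshold:
            continue
        res.passes_separability = True
        passed.append(res)
    best: dict[str, AssociationResult] = {}
    for res in passed:
        cur = best.get(res.feature_id)
        if cur is None or res.p < cur.p:
            best[res.feature_id] = res
    return sorted(best.values(), key=lambda r: (r.feature_id, r.pattern_id))


def associations_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(feature_id=r.feature_id, pattern_id=r.pattern_id,
                 gene_families=";".join(r.gene_families), p=r.p, p_adj=r.p_adj,
                 delta_median=r.delta_median,
                 passes_separability=r.passes_separability)
            for r in results
        ],
        columns=["feature_id", "pattern_id", "gene_families", "p", "p_adj",
                 "delta_median", "passes_separability"],
    )


def pathway_enrichment(
    gene_set: set[str],
    annotation_universe: dict[str, set[str]],
    p_cutoff: float = 0.1,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of terms in a gene hit set.

    ``annotation_universe`` maps gene -> set of terms; the universe is its
    key set. Terms never annotated in the universe are not tested. Returns
    terms with BH-adjusted p below ``p_cutoff``.
    """
    if not gene_set:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p", "q"])
    universe = set(annotation_universe)
    hits = gene_set & universe
    terms: dict[str, set[str]] = {}
    for g, anns in annotation_universe.items():
        for t in anns:
            terms.setdefault(t, set()).add(g)
    N, n = len(universe), len(hits)
    rows = []
    for term, members in sorted(terms.items()):
        K = len(members)
        k = len(members & hits)
        # P(X >= k) with X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, k=k, K=K, n=n, N=N, p=p))
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df[df["q"] < p_cutoff].sort_values("q").reset_index(drop=True)
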