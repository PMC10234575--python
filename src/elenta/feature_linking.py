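"""Cross-dataset feature linking via m/z, retention time, and MS2 cosine.

Independently processed untargeted metabolomics datasets (e.g. culture
supernatants vs intestinal contents acquired on the same chromatography)
describe overlapping chemistry under different feature ids. Features are
linked when their m/z, retention time, adduct, and MS2 fragmentation agree;
the cosine cutoff is calibrated from a null sample of unrelated feature
pairs (99.5th percentile), so ~0.5% of null pairs exceed it by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .feature_table import FeatureTable

#: published cutoffs used when no calibration data are available
DEFAULT_COSINE_CUTOFFS = {"positive": 0.205, "negative": 0.251}


@dataclass
class Ms2Spectrum:
    """Fragment spectrum for one feature: (mz, intensity) pairs."""

    feature_id: str
    fragments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"spectrum {self.feature_id} has no fragments")
        frags = sorted(self.fragments, key=lambda f: f[0])
        if any(b[0] <= a[0] for a, b in zip(frags, frags[1:])):
            raise ValueError(f"spectrum {self.feature_id}: duplicate fragment m/z")
        if any(i < 0 for _, i in frags):
            raise ValueError(f"spectrum {self.feature_id}: negative intensity")
        self.fragments = frags

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments])


@dataclass
class Link:
    feature_a: str
    feature_b: str
    cosine: float | None
    delta_mz: float
    delta_rt: float
    merged_id: str


@dataclass
class LinkSet:
    links: list[Link]
    cutoffs: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(feature_a=l.feature_a, feature_b=l.feature_b, cosine=l.cosine,
                     delta_mz=l.delta_mz, delta_rt=l.delta_rt, merged_id=l.merged_id)
                for l in self.links
            ],
            columns=["feature_a", "feature_b", "cosine", "delta_mz", "delta_rt", "merged_id"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> dict[str, Ms2Spectrum]:
    """Read MS2 spectra keyed by the TITLE field of each MGF block."""
    spectra: dict[str, Ms2Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            fid = entry["params"].get("title")
            if fid is None:
                continue
            frags = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra[fid] = Ms2Spectrum(fid, frags)
    return spectra


def write_mgf(spectra: dict[str, Ms2Spectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": np.array(sp.mz),
            "intensity array": np.array(sp.intensity),
            "params": {"title": fid, "pepmass": float(sp.mz.max())},
        }
        for fid, sp in spectra.items()
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# cosine similarity
# ---------------------------------------------------------------------------

def spectral_cosine(a: Ms2Spectrum, b: Ms2Spectrum, frag_tol: float = 0.01) -> float:
    """Cosine similarity with greedy closest-pair fragment matching.

    Candidate fragment pairs within ``frag_tol`` Da are accepted in order of
    |delta m/z|, each fragment used at most once; the cosine is the dot
    product of matched intensities over the product of full-spectrum norms.
    Symmetric in its arguments.
    """
    amz, aint = a.mz, a.intensity
    bmz, bint = b.mz, b.intensity
    na = float(np.linalg.norm(aint))
    nb = float(np.linalg.norm(bint))
    if na == 0 or nb == 0:
        return 0.0
    pairs = []
    for i, m in enumerate(amz):
        d = np.abs(bmz - m)
        for j in np.nonzero(d < frag_tol)[0]:
            pairs.append((d[j], i, int(j)))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += float(aint[i]) * float(bint[j])
    return min(dot / (na * nb), 1.0)


def calibrate_cosine_cutoff(
    table: FeatureTable,
    spectra: dict[str, Ms2Spectrum],
    mode: str,
    n_per_set: int = 200,
    rt_min_diff: float = 1.0,
    mz_min_diff: float = 0.01,
    percentile: float = 99.5,
    seed: int = 0,
    frag_tol: float = 0.01,
    min_pairs: int = 1000,
) -> float:
    """Null-calibrated cosine cutoff for one ionization mode.

    Two disjoint random sets of ``n_per_set`` features with MS2 are drawn;
    pairs separated by at least ``rt_min_diff`` minutes and ``mz_min_diff``
    Da are treated as unrelated, and the cutoff is the stated percentile of
    their cosine similarities.
    """
    feats = [
        f
        for f in table.feature_ids
        if table.features.loc[f, "mode"] == mode and f in spectra
    ]
    if len(feats) < 2 * n_per_set:
        raise ValueError(
            f"need >= {2 * n_per_set} features with MS2 in mode {mode}; have {len(feats)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(feats), size=2 * n_per_set, replace=False)
    set_a = [feats[i] for i in chosen[:n_per_set]]
    set_b = [feats[i] for i in chosen[n_per_set:]]
    cosines = []
    fmeta = table.features
    for fa in set_a:
        for fb in set_b:
            if abs(fmeta.loc[fa, "rt"] - fmeta.loc[fb, "rt"]) < rt_min_diff:
                continue
            if abs(fmeta.loc[fa, "mz"] - fmeta.loc[fb, "mz"]) < mz_min_diff:
                continue
            cosines.append(spectral_cosine(spectra[fa], spectra[fb], frag_tol))
    if len(cosines) < min_pairs:
        raise ValueError(
            f"only {len(cosines)} eligible null pairs (< {min_pairs}); "
            "cutoff calibration unreliable"
        )
    return float(np.percentile(cosines, percentile))


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_features(
    table_a: FeatureTable,
    table_b: FeatureTable,
    spectra: dict[str, Ms2Spectrum],
    mz_tol: float = 0.007,
    rt_tol: float = 0.5,
    noms2_mz_tol: float = 0.001,
    noms2_rt_tol: float = 0.2,
    cutoffs: dict[str, float] | None = None,
    frag_tol: float = 0.01,
) -> LinkSet:
    """One-to-one cross-dataset links under m/z / RT / adduct / cosine rules.

    Pairs with MS2 on both sides require |dmz| <= mz_tol, |dRT| <= rt_tol and
    cosine >= the mode's cutoff; pairs lacking MS2 on either side instead use
    the tighter ``noms2`` tolerances. Same mode and same adduct annotation
    are always required. Each feature joins at most one merged identity; the
    best cosine wins, ties broken by smallest |dmz|.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_COSINE_CUTOFFS
    fa_meta = table_a.features
    fb_meta = table_b.features
    candidates = []  # (sort key, fa, fb, cosine, dmz, drt)
    for fa in table_a.feature_ids:
        mode = fa_meta.loc[fa, "mode"]
        adduct = fa_meta.loc[fa, "adduct"]
        mza, rta = float(fa_meta.loc[fa, "mz"]), float(fa_meta.loc[fa, "rt"])
        for fb in table_b.feature_ids:
            if fb_meta.loc[fb, "mode"] != mode:
                continue
            if fb_meta.loc[fb, "adduct"] != adduct:
                continue
            dmz = abs(mza - float(fb_meta.loc[fb, "mz"]))
            drt = abs(rta - float(fb_meta.loc[fb, "rt"]))
            has_ms2 = fa in spectra and fb in spectra
            if has_ms2:
                if dmz > mz_tol or drt > rt_tol:
                    continue
                cos = spectral_cosine(spectra[fa], spectra[fb], frag_tol)
                if cos < cutoffs[mode]:
                    continue
            else:
                if dmz > noms2_mz_tol or drt > noms2_rt_tol:
                    continue
                cos = None
            candidates.append((fa, fb, cos, dmz, drt))

    # best-cosine-first greedy one-to-one assignment; MS2-less links rank last
    candidates.sort(
        key=lambda c: (-(c[2] if c[2] is not None else -1.0), c[3], str(c[0]), str(c[1]))
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    links = []
    for fa, fb, cos, dmz, drt in candidates:
        if fa in used_a or fb in used_b:
            continue
        used_a.add(fa)
        used_b.add(fb)
        links.append(Link(str(fa), str(fb), cos, dmz, drt, f"M{len(links):05d}"))
    return LinkSet(links=links, cutoffs=dict(cutoffs))


def audit_identity_conflicts(
    links: LinkSet,
    annotations_a: pd.Series,
    annotations_b: pd.Series,
) -> tuple[float, pd.DataFrame]:
    """Fraction of doubly annotated links whose annotations disagree.

    Returns (conflict fraction, table of conflicting links). Links where
    either member lacks an annotation are excluded from the denominator.
    """
    n_annotated = 0
    conflicts = []
    for l in links.links:
        ann_a = annotations_a.get(l.feature_a)
        ann_b = annotations_b.get(l.feature_b)
        if pd.isna(ann_a) or pd.isna(ann_b) or ann_a is None or ann_b is None:
            continue
        n_annotated += 1
        if ann_a != ann_b:
            conflicts.append(
                dict(feature_a=l.feature_a, feature_b=l.feature_b,
                     annotation_a=ann_a, annotation_b=ann_b)
            )
    frac = len(conflicts) / n_annotated if n_annotated else 0.0
    return frac, pd.DataFrame(conflicts, columns=["feature_a", "feature_b", "annotation_a", "annotation_b"])
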