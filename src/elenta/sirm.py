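"""Natural-abundance correction and classification of 13C-labeled compounds.

In a stable-isotope tracing experiment the observed isotopologue peak areas
of a compound with n carbons convolve the tracer-derived labeling with the
~1.07% natural abundance of 13C. Correction inverts that convolution
(non-negative least squares against a binomial mixing matrix) to recover the
tracer-only mass-isotopologue distribution (MID); compounds are then called
labeled using enrichment and peak-area thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

P13C_NATURAL = 0.0107  # natural abundance of 13C

#: filter presets: (min labeled-MID fraction, min labeled peak area)
CLASSIFY_PRESETS = {
    "intracellular": dict(min_labeled_frac=0.15, min_labeled_area=1e4),
    "extracellular": dict(min_labeled_frac=0.5, min_labeled_area=5e4),
    "methods-3pct": dict(min_labeled_frac=None, min_labeled_area=0.0),
}


@dataclass
class IsotopologueVector:
    """Observed peak areas for M+0 .. M+n of one compound."""

    compound_id: str
    n_carbons: int
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")
        if len(self.areas) != self.n_carbons + 1:
            raise ValueError(
                f"{self.compound_id}: expected {self.n_carbons + 1} areas, "
                f"got {len(self.areas)}"
            )
        if (self.areas < 0).any():
            raise ValueError(f"{self.compound_id}: negative peak area")
        if not self.areas.any():
            raise ValueError(f"{self.compound_id}: all peak areas zero")


@dataclass
class Mid:
    """Mass-isotopologue distribution: fractions of M+0 .. M+n summing to 1."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if (self.fractions < -1e-12).any():
            raise ValueError("MID fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("MID fractions must sum to 1")


def natural_abundance_matrix(n_carbons: int, p13: float = P13C_NATURAL) -> np.ndarray:
    """Carbon-only natural-abundance mixing matrix, shape (n+1, n+1).

    Column i gives the probability of observing M+j given i tracer-labeled
    carbons: the remaining n-i carbons each carry a natural 13C with
    probability ``p13``, so the column is Binomial(n-i, p13) shifted by i.
    ``p13=0`` yields the identity.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not (0 <= p13 < 1):
        raise ValueError("p13 must be in [0, 1)")
    n = n_carbons
    M = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        k = np.arange(n - i + 1)
        M[i : n + 1, i] = stats.binom.pmf(k, n - i, p13)
    return M


def correct_mid(observed: IsotopologueVector, matrix: np.ndarray) -> Mid:
    """Invert natural-abundance convolution by NNLS and renormalize.

    NNLS (rather than direct inversion) keeps fractions non-negative at low
    signal, where correction of the M+1/M+2 channels is noisiest.
    """
    if matrix.shape != (observed.n_carbons + 1, observed.n_carbons + 1):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match compound with "
            f"{observed.n_carbons} carbons"
        )
    y = observed.areas / observed.areas.sum()
    x, residual = optimize.nnls(matrix, y)
    total = x.sum()
    if total <= 0:
        raise ValueError(
            f"{observed.compound_id}: degenerate correction (residual {residual:.3g})"
        )
    return Mid(x / total)


def enrichment(mid: Mid) -> float:
    """Combined enrichment: 1 - M+0 fraction."""
    return float(1.0 - mid.fractions[0])


def classify_labeled(
    mid: Mid,
    areas: IsotopologueVector,
    min_enrich: float = 0.03,
    min_labeled_area: float = 0.0,
    min_labeled_frac: float | None = None,
    preset: str | None = None,
) -> tuple[bool, str]:
    """Call a compound 13C-labeled, returning (flag, reason).

    Labeled requires: corrected enrichment >= ``min_enrich`` (default 3%,
    which guards against spurious enrichment from noisy natural-abundance
    correction of weak peaks), summed labeled-isotopologue area >=
    ``min_labeled_area``, and, when set, labeled MID >= ``min_labeled_frac``.
    Presets bundle the area/fraction thresholds used for intracellular
    (0.15 / 1e4) and extracellular (0.5 / 5e4) reporting.
    """
    if preset is not None:
        if preset not in CLASSIFY_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {list(CLASSIFY_PRESETS)}")
        min_labeled_frac = CLASSIFY_PRESETS[preset]["min_labeled_frac"]
        min_labeled_area = CLASSIFY_PRESETS[preset]["min_labeled_area"]
    e = enrichment(mid)
    if e < min_enrich:
        return False, f"enrichment {e:.4f} < {min_enrich}"
    labeled_area = float(areas.areas[1:].sum())
    if labeled_area < min_labeled_area:
        return False, f"labeled area {labeled_area:.3g} < {min_labeled_area:.3g}"
    if min_labeled_frac is not None and e < min_labeled_frac:
        return False, f"labeled MID {e:.4f} < {min_labeled_frac}"
    return True, "labeled"
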