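"""Feature-table container for untargeted metabolomics data.

A :class:`FeatureTable` couples a features x samples peak-intensity matrix
with per-feature metadata (m/z, retention time, ionization mode, adduct,
annotation, MSI confidence level) and per-sample metadata (role, group,
time, replicate, strain). It is the common currency of the QC, differential
analysis, dereplication, and cross-dataset linking stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

VALID_ROLES = {"sample", "blank", "pool", "control"}
VALID_MODES = {"positive", "negative"}
VALID_MSI = {1, 2, 3, 4}  # None (no annotation confidence) also allowed

FEATURE_COLUMNS = ["mz", "rt", "mode", "adduct", "annotation", "msi_level"]
SAMPLE_COLUMNS = ["role", "group", "time_h", "replicate", "strain"]


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with metadata.

    Parameters
    ----------
    intensities:
        DataFrame indexed by ``feature_id`` with one column per sample.
        Values are non-negative peak intensities (or log-transformed
        intensities when ``log_base`` is set).
    features:
        DataFrame indexed by ``feature_id`` carrying at least the columns in
        :data:`FEATURE_COLUMNS`.
    samples:
        DataFrame indexed by ``sample_id`` carrying at least the columns in
        :data:`SAMPLE_COLUMNS`. Every sample must have a role.
    log_base:
        ``None`` for raw intensities; otherwise the logarithm base of the
        stored values (set by :func:`elenta.feature_qc.log_transform`).
    pseudocounts:
        Per-feature pseudocount added before the log transform, if any.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    log_base: float | None = None
    pseudocounts: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate feature ids: {list(dups[:5])}")
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensity rows and feature metadata disagree")
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("intensity columns and sample metadata disagree")
        if self.log_base is None and (self.intensities.values < 0).any():
            raise ValueError("raw intensities must be non-negative")
        roles = set(self.samples["role"].unique())
        bad = roles - VALID_ROLES
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        msi = self.features["msi_level"].dropna()
        bad_msi = set(msi.unique()) - VALID_MSI
        if bad_msi:
            raise ValueError(f"invalid MSI levels: {sorted(bad_msi)}")

    # -- convenience accessors ----------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def sample_ids_by_role(self, *roles: str) -> list[str]:
        mask = self.samples["role"].isin(roles)
        return list(self.samples.index[mask])

    def sample_ids_by_group(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        idx = pd.Index(feature_ids)
        pc = self.pseudocounts.loc[idx] if self.pseudocounts is not None else None
        return FeatureTable(
            self.intensities.loc[idx].copy(),
            self.features.loc[idx].copy(),
            self.samples.copy(),
            log_base=self.log_base,
            pseudocounts=pc,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            self.intensities[ids].copy(),
            self.features.copy(),
            self.samples.loc[ids].copy(),
            log_base=self.log_base,
            pseudocounts=self.pseudocounts,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.features.copy(),
            self.samples.copy(),
            log_base=self.log_base,
            pseudocounts=None if self.pseudocounts is None else self.pseudocounts.copy(),
        )

    # -- I/O ------------------------------------------------------------
    def to_csv(self, feature_path: str | Path, sample_path: str | Path) -> None:
        """Write the feature table (wide CSV) and sample metadata (TSV)."""
        wide = pd.concat([self.features[FEATURE_COLUMNS], self.intensities], axis=1)
        wide.index.name = "feature_id"
        wide.to_csv(feature_path)
        out = self.samples.copy()
        out.index.name = "sample_id"
        out.to_csv(sample_path, sep="\t")

    @classmethod
    def from_csv(cls, feature_path: str | Path, sample_path: str | Path) -> "FeatureTable":
        wide = pd.read_csv(feature_path, index_col="feature_id")
        samples = pd.read_csv(sample_path, sep="\t", index_col="sample_id")
        for col in SAMPLE_COLUMNS:
            if col not in samples.columns:
                samples[col] = np.nan
        feat_cols = [c for c in FEATURE_COLUMNS if c in wide.columns]
        features = wide[feat_cols].copy()
        for col in FEATURE_COLUMNS:
            if col not in features.columns:
                features[col] = np.nan
        sample_cols = [c for c in wide.columns if c not in FEATURE_COLUMNS]
        intensities = wide[sample_cols].astype(float)
        # order intensity columns to match the sample sheet
        intensities = intensities[list(samples.index)]
        return cls(intensities, features[FEATURE_COLUMNS], samples)


def make_feature_table(
    intensities: pd.DataFrame,
    mz: pd.Series | None = None,
    rt: pd.Series | None = None,
    mode: str | pd.Series = "positive",
    adduct: str | pd.Series | None = None,
    annotation: pd.Series | None = None,
    msi_level: pd.Series | None = None,
    sample_roles: pd.Series | dict | None = None,
    sample_groups: pd.Series | dict | None = None,
    sample_times: pd.Series | dict | None = None,
    sample_replicates: pd.Series | dict | None = None,
    sample_strains: pd.Series | dict | None = None,
) -> FeatureTable:
    """Assemble a :class:`FeatureTable` from loose pieces (test/synthesis helper)."""
    fidx = intensities.index
    features = pd.DataFrame(index=fidx)
    features["mz"] = mz if mz is not None else np.nan
    features["rt"] = rt if rt is not None else np.nan
    features["mode"] = mode
    features["adduct"] = adduct
    features["annotation"] = annotation if annotation is not None else None
    features["msi_level"] = msi_level if msi_level is not None else np.nan

    sidx = intensities.columns
    samples = pd.DataFrame(index=sidx)

    def _col(val, default):
        if val is None:
            return default
        if isinstance(val, dict):
            return pd.Series(val).reindex(sidx)
        return val

    samples["role"] = _col(sample_roles, "sample")
    samples["group"] = _col(sample_groups, "all")
    samples["time_h"] = _col(sample_times, np.nan)
    samples["replicate"] = _col(sample_replicates, np.arange(len(sidx)))
    samples["strain"] = _col(sample_strains, None)
    return FeatureTable(intensities.astype(float), features, samples)
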