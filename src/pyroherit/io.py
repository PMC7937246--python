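"""Spectra and metadata I/O, TIC normalization, and replicate/ramet collapsing.

The central container is :class:`SpectraMatrix`: a samples x m/z intensity
table joined to per-sample metadata.  On disk the canonical format is a pair
of UTF-8 comma-separated files: a wide ``spectra.csv`` (``sample_id`` then one
column per integer m/z) and a ``metadata.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ions import validate_channels

#: Canonical metadata columns written by the simulator and expected by the
#: pipeline.  Only ``sample_id`` is mandatory for generic use.
METADATA_COLUMNS = (
    "sample_id",
    "ramet_id",
    "genotype_id",
    "mother_id",
    "father_id",
    "block",
    "row",
    "position",
    "x_m",
    "y_m",
    "tray",
    "vial",
    "replicate",
    "is_standard",
    "standard_id",
)


@dataclass
class SpectraMatrix:
    """Samples x m/z intensity matrix with aligned per-sample metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by ``sample_id`` with sorted integer m/z columns.
    metadata
        DataFrame indexed by ``sample_id`` covering every intensity row.
    normalized
        True once rows are TIC (sum) normalized.
    tray_corrected
        True once per-ion tray effects have been subtracted.  Corrected
        intensities live on a deviations scale and may be negative.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    normalized: bool = False
    tray_corrected: bool = False

    def __post_init__(self) -> None:
        inten = self.intensities
        if inten.index.has_duplicates:
            dups = inten.index[inten.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        channels = validate_channels(inten.columns)
        inten = inten.copy()
        inten.columns = [int(c) for c in inten.columns]
        inten = inten[channels].astype(float)
        missing = inten.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} sample(s) lack metadata, e.g. {list(missing[:5])}"
            )
        if not self.tray_corrected and (inten.to_numpy() < 0).any():
            raise ValueError("negative intensities in uncorrected spectra")
        self.intensities = inten
        self.metadata = self.metadata.loc[inten.index]

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def channels(self) -> list[int]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    def subset_ions(self, ions) -> "SpectraMatrix":
        ions = validate_channels(ions)
        return replace(self, intensities=self.intensities[ions], metadata=self.metadata)

    def subset_samples(self, mask_or_ids) -> "SpectraMatrix":
        inten = self.intensities.loc[mask_or_ids]
        return replace(self, intensities=inten, metadata=self.metadata.loc[inten.index])

    @property
    def samples(self) -> "SpectraMatrix":
        """Analysis samples only (standards and border ramets excluded)."""
        meta = self.metadata
        mask = pd.Series(True, index=meta.index)
        if "is_standard" in meta:
            mask &= ~meta["is_standard"].astype(bool)
        if "is_border" in meta:
            mask &= ~meta["is_border"].astype(bool)
        return self.subset_samples(mask)

    @property
    def standards(self) -> "SpectraMatrix":
        if "is_standard" not in self.metadata:
            raise ValueError("metadata has no is_standard column")
        return self.subset_samples(self.metadata["is_standard"].astype(bool))

    # -- persistence -----------------------------------------------------
    def write(self, spectra_path, metadata_path) -> None:
        wide = self.intensities.copy()
        wide.insert(0, "sample_id", wide.index)
        wide.to_csv(spectra_path, index=False)
        meta = self.metadata.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(metadata_path, index=False)


def read_spectra(spectra_path, metadata_path, *, normalized: bool = False) -> SpectraMatrix:
    """Load a wide spectra CSV and its metadata CSV into a :class:`SpectraMatrix`.

    Rows whose ``sample_id`` is missing from the metadata are rejected with an
    error naming the offending ids; m/z columns outside 30-450 are rejected.
    """
    spectra_path, metadata_path = Path(spectra_path), Path(metadata_path)
    wide = pd.read_csv(spectra_path)
    if "sample_id" not in wide.columns:
        raise ValueError(f"{spectra_path}: missing sample_id column")
    wide = wide.set_index("sample_id")
    meta = pd.read_csv(metadata_path)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{metadata_path}: missing sample_id column")
    meta = meta.set_index("sample_id")
    return SpectraMatrix(wide, meta, normalized=normalized)


def tic_normalize(matrix: SpectraMatrix) -> SpectraMatrix:
    """Divide each spectrum by its total ion current so rows sum to one.

    Idempotent and scale invariant.  A zero-total sample indicates an
    acquisition failure and raises rather than being dropped silently.
    """
    totals = matrix.intensities.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index[:5])}")
    inten = matrix.intensities.div(totals, axis=0)
    return replace(matrix, intensities=inten, normalized=True)


def _collapse_metadata(meta: pd.DataFrame, group_key: str) -> pd.DataFrame:
    """Keep metadata fields that are constant within every group, drop the rest."""
    g = meta.groupby(group_key, sort=True)
    keep = []
    for col in meta.columns:
        if col == group_key:
            continue
        if (g[col].nunique(dropna=False) <= 1).all():
            keep.append(col)
    out = g[keep].first() if keep else pd.DataFrame(index=pd.Index(sorted(g.groups), name=group_key))
    return out


def ramet_means(matrix: SpectraMatrix, group_key: str = "ramet_id") -> SpectraMatrix:
    """Average technical replicates (or ramets) into one row per group.

    ``group_key`` is ``ramet_id`` (collapse technical replicates) or
    ``genotype_id`` (collapse clonal ramets to genotype means).  The result is
    indexed by the group value; metadata fields that vary within a group
    (tray, vial, replicate...) are dropped.
    """
    if group_key not in ("ramet_id", "genotype_id"):
        raise ValueError(f"group_key must be ramet_id or genotype_id, got {group_key!r}")
    if group_key not in matrix.metadata.columns:
        raise ValueError(f"metadata has no {group_key} column")
    groups = matrix.metadata[group_key]
    if groups.isna().any():
        raise ValueError(f"{group_key} missing for some samples")
    inten = matrix.intensities.groupby(groups).mean()
    inten.index.name = "sample_id"
    meta = _collapse_metadata(matrix.metadata.reset_index(drop=True), group_key)
    meta.index.name = "sample_id"
    return replace(matrix, intensities=inten, metadata=meta)


@dataclass
class ReplicateAgreement:
    """Between-technical-replicate reproducibility summary."""

    pearson_r: pd.Series  #: per trait/ion, r across ramets between replicate vectors
    replicate_sd: pd.DataFrame  #: per ramet x trait, SD between its replicates
    n_ramets: int = 0


def replicate_agreement(matrix: SpectraMatrix) -> ReplicateAgreement:
    """Correlate replicate-1 against replicate-2 values across ramets, per ion.

    Only ramets measured in both replicates enter the correlation; the
    per-ramet between-replicate standard deviations are returned alongside.
    """
    meta = matrix.metadata
    for col in ("ramet_id", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"metadata has no {col} column")
    inten = matrix.intensities
    rep = meta["replicate"].astype(int)
    ramet = meta["ramet_id"]
    rep1 = inten[rep == 1].set_index(ramet[rep == 1])
    rep2 = inten[rep == 2].set_index(ramet[rep == 2])
    common = rep1.index.intersection(rep2.index)
    if len(common) == 0:
        raise ValueError("no ramets with both technical replicates")
    a, b = rep1.loc[common], rep2.loc[common]
    r = a.corrwith(b, axis=0)
    sd = (a - b).abs() / np.sqrt(2.0)  # SD of two values = |diff|/sqrt(2)
    return ReplicateAgreement(pearson_r=r, replicate_sd=sd, n_ramets=len(common))
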