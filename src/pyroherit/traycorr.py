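"""Batch ("tray") effect estimation and removal from replicated standards.

Samples are pyrolyzed in autosampler trays; instrument drift between trays
adds a shared per-ion offset to every spectrum in a tray.  Six standard
materials replicated across trays let us estimate those offsets with a
per-ion crossed random-effects model

    y[tray, standard] = mu + Tray + Standard + error,

with both tray and standard as random effects, fitted by EM-REML.  The
shrunken (BLUP) tray predictions, centered across trays, are subtracted from
every sample's TIC-normalized intensities.  Trays that carry no standards
get their offsets from a fallback model over the whole dataset with tray as
the only random effect (randomization of genotypes into trays makes the
in-tray genotype mean approximately zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import SpectraMatrix
from .reml import em_reml

__all__ = [
    "TrayEffectModel",
    "TrayEffectTable",
    "fit_tray_effects",
    "fit_tray_effects_fallback",
    "apply_tray_correction",
]


@dataclass
class TrayEffectTable:
    """Per (ion, tray) additive offsets plus per-ion variance summaries.

    Attributes
    ----------
    effects
        DataFrame indexed by tray, one column per ion (or trait name);
        each column is centered (mean over trays ~ 0).
    summary_table
        Per-ion rows: sigma2_tray, sigma2_standard, sigma2_resid, n_iter,
        converged, source ("standards" or "fallback").
    """

    effects: pd.DataFrame
    summary_table: pd.DataFrame

    @property
    def trays(self) -> pd.Index:
        return self.effects.index

    @property
    def ions(self) -> list:
        return list(self.effects.columns)

    def effect(self, ion, tray) -> float:
        return float(self.effects.at[tray, ion])

    def merge(self, other: "TrayEffectTable", trays=None) -> "TrayEffectTable":
        """Overlay ``other``'s effects (optionally only for given trays)."""
        eff = self.effects.copy()
        upd = other.effects if trays is None else other.effects.loc[list(trays)]
        eff = eff.reindex(eff.index.union(upd.index))
        eff.loc[upd.index, upd.columns] = upd
        summ = self.summary_table.copy()
        for ion in upd.columns:
            if ion in summ.index:
                summ.loc[ion, "source"] = summ.loc[ion, "source"] + "+fallback"
        return TrayEffectTable(eff, summ)

    def summary(self) -> str:
        s = self.summary_table
        lines = [
            f"Tray-effect model: {len(self.trays)} trays x {len(self.ions)} ions",
            s.to_string(max_rows=20, float_format=lambda v: f"{v:.3e}"),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Long form (ion, tray, effect) for CSV export."""
        long = self.effects.stack().rename("effect").reset_index()
        long.columns = ["tray", "ion", "effect"]
        return long[["ion", "tray", "effect"]]


def _fit_columns(values: pd.DataFrame, terms: dict, all_trays, source: str,
                 max_iter: int = 500, tol: float = 1e-8) -> TrayEffectTable:
    effects = {}
    rows = []
    for col in values.columns:
        res = em_reml(values[col].to_numpy(), terms, max_iter=max_iter, tol=tol)
        eff = pd.Series(res.blups["tray"], index=pd.Index(res.levels["tray"], name="tray"))
        eff = eff - eff.mean()
        effects[col] = eff.reindex(all_trays).fillna(0.0)
        row = {"ion": col, "sigma2_tray": res.sigma2["tray"], "sigma2_resid": res.sigma2_e,
               "n_iter": res.n_iter, "converged": res.converged, "source": source}
        if "standard" in res.sigma2:
            row["sigma2_standard"] = res.sigma2["standard"]
        rows.append(row)
    eff_df = pd.DataFrame(effects, index=pd.Index(all_trays, name="tray"))
    summ = pd.DataFrame(rows).set_index("ion")
    return TrayEffectTable(eff_df, summ)


class TrayEffectModel:
    """Mixed model ``y = mu + Tray + Standard + e`` per ion, on standards.

    Parameters
    ----------
    standards
        :class:`SpectraMatrix` restricted to standard runs (TIC-normalized),
        with ``tray`` and ``standard_id`` metadata, or any DataFrame of
        values plus explicit ``tray`` / ``standard`` label vectors.
    """

    def __init__(self, values: pd.DataFrame, tray, standard):
        self.values = values
        self.tray = pd.Series(np.asarray(tray), index=values.index)
        self.standard = pd.Series(np.asarray(standard), index=values.index)
        if self.tray.nunique() < 2:
            raise ValueError("need standards in at least 2 trays")
        if self.standard.isna().any():
            raise ValueError("standard identity missing for some runs")

    @classmethod
    def from_matrix(cls, standards: SpectraMatrix, ions=None) -> "TrayEffectModel":
        meta = standards.metadata
        for col in ("tray", "standard_id"):
            if col not in meta.columns:
                raise ValueError(f"standards metadata lacks {col!r}")
        values = standards.intensities if ions is None else standards.subset_ions(ions).intensities
        return cls(values, meta["tray"], meta["standard_id"])

    def fit(self, *, max_iter: int = 500, tol: float = 1e-8) -> TrayEffectTable:
        terms = {"tray": self.tray.to_numpy(), "standard": self.standard.to_numpy()}
        all_trays = sorted(self.tray.unique())
        return _fit_columns(self.values, terms, all_trays, "standards",
                            max_iter=max_iter, tol=tol)


def fit_tray_effects(standards: SpectraMatrix, ions=None, **kw) -> TrayEffectTable:
    """Estimate centered per-ion tray offsets from the replicated standards."""
    return TrayEffectModel.from_matrix(standards, ions=ions).fit(**kw)


def fit_tray_effects_fallback(matrix: SpectraMatrix, trays_without_standards,
                              ions=None, **kw) -> TrayEffectTable:
    """Tray offsets from the whole dataset, tray as the only random effect.

    Used for trays lacking standards; returns a table whose effects are
    meaningful for the named trays (other trays' entries exist only because
    the model is global and should be overlaid with standard-based effects
    via :meth:`TrayEffectTable.merge`).
    """
    meta = matrix.metadata
    if "tray" not in meta.columns:
        raise ValueError("metadata lacks 'tray'")
    missing = set(trays_without_standards) - set(meta["tray"])
    if missing:
        raise ValueError(f"unknown tray(s): {sorted(missing)}")
    values = matrix.intensities if ions is None else matrix.subset_ions(ions).intensities
    terms = {"tray": meta["tray"].to_numpy()}
    all_trays = sorted(meta["tray"].unique())
    table = _fit_columns(values, terms, all_trays, "fallback", **kw)
    keep = [t for t in all_trays if t in set(trays_without_standards)]
    return TrayEffectTable(table.effects.loc[keep], table.summary_table)


def apply_tray_correction(matrix: SpectraMatrix, effects: TrayEffectTable,
                          ions=None) -> SpectraMatrix:
    """Subtract each sample's tray offset per ion: corrected = observed - effect.

    Ions without an entry in ``effects`` (or outside ``ions``) pass through
    unchanged.  Raises if any sample sits in a tray the table does not cover.
    """
    meta = matrix.metadata
    if "tray" not in meta.columns:
        raise ValueError("metadata lacks 'tray'")
    target = [c for c in matrix.channels if c in set(effects.ions)]
    if ions is not None:
        requested = set(ions)
        missing_ion = requested - set(effects.ions)
        if missing_ion:
            raise KeyError(f"no tray effects for ions {sorted(missing_ion)[:5]}")
        target = [c for c in target if c in requested]
    sample_trays = meta["tray"]
    uncovered = set(sample_trays.unique()) - set(effects.trays)
    if uncovered:
        raise KeyError(f"no tray effects for tray(s) {sorted(uncovered)[:5]}")
    inten = matrix.intensities.copy()
    if target:
        offs = effects.effects.loc[sample_trays, target].to_numpy()
        inten[target] = inten[target].to_numpy() - offs
    return replace(matrix, intensities=inten, tray_corrected=True)


def correct_trait(values: pd.Series, tray: pd.Series, standard_values: pd.Series,
                  standard_tray: pd.Series, standard_id: pd.Series, **kw):
    """Tray-correct a scalar trait (e.g. lignin wt%%, S/G) via the same model.

    Fits ``trait = mu + Tray + Standard + e`` on the standards' trait values
    and subtracts the centered tray BLUPs from the sample trait.  Trays with
    no standards fall back to a tray-only model on the sample values.

    Returns (corrected sample Series, TrayEffectTable).
    """
    model = TrayEffectModel(standard_values.to_frame("trait"), standard_tray, standard_id)
    table = model.fit(**kw)
    no_std = sorted(set(tray.unique()) - set(table.trays))
    if no_std:
        terms = {"tray": tray.to_numpy()}
        fb = _fit_columns(values.to_frame("trait"), terms, sorted(tray.unique()), "fallback", **kw)
        table = table.merge(TrayEffectTable(fb.effects.loc[no_std], fb.summary_table))
    corrected = values - table.effects.loc[tray, "trait"].to_numpy()
    return corrected, table
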