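"""Lignin content and S/G ratio from TIC-normalized py-MBMS spectra.

Relative lignin content is the sum of 17 lignin-diagnostic ion intensities;
it is put on the weight-percent scale by a single multiplicative response
factor (RF) calibrated against standards of known lignin content.  The
monomer composition phenotype S/G is the ratio of syringyl-derived to
guaiacyl-derived ion sums.  Coumaryl (H) content is not reported because of
known overlaps with coumarate-derived ions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import SpectraMatrix
from .ions import G_IONS, LIGNIN_IONS, S_IONS

__all__ = [
    "lignin_index",
    "calibrate_response_factor",
    "lignin_content",
    "s_g_ratio",
    "composition_table",
]


def _as_frame(spectra) -> pd.DataFrame:
    """Accept a SpectraMatrix, DataFrame, or single Series keyed by m/z."""
    if isinstance(spectra, SpectraMatrix):
        return spectra.intensities
    if isinstance(spectra, pd.Series):
        return spectra.to_frame().T
    return pd.DataFrame(spectra)


def _ion_sum(frame: pd.DataFrame, ions, label: str) -> pd.Series:
    present = [c for c in frame.columns if int(c) in ions]
    missing = ions - {int(c) for c in present}
    if missing:
        warnings.warn(f"{label}: missing channels contribute 0: {sorted(missing)}", stacklevel=3)
    return frame[present].sum(axis=1)


def lignin_index(spectra) -> "pd.Series | float":
    """Sum of the 17 lignin-diagnostic ion intensities (dimensionless).

    Input should be TIC-normalized; missing channels contribute zero with a
    warning.  Scalar for a single spectrum, Series for a matrix.
    """
    frame = _as_frame(spectra)
    out = _ion_sum(frame, LIGNIN_IONS, "lignin_index")
    return float(out.iloc[0]) if isinstance(spectra, pd.Series) else out


def s_g_ratio(spectra) -> "pd.Series | float":
    """Syringyl over guaiacyl ion-sum ratio; invariant to spectrum rescaling."""
    frame = _as_frame(spectra)
    s = _ion_sum(frame, S_IONS, "s_g_ratio[S]")
    g = _ion_sum(frame, G_IONS, "s_g_ratio[G]")
    bad = g <= 0
    if bad.any():
        raise ZeroDivisionError(
            f"S/G undefined (zero G-ion sum) for sample(s) {list(frame.index[bad][:5])}"
        )
    out = s / g
    return float(out.iloc[0]) if isinstance(spectra, pd.Series) else out


def calibrate_response_factor(standard_spectra, known_lignin_wt_pct) -> float:
    """RF = mean over standards of known weight-percent / lignin index."""
    idx = lignin_index(standard_spectra)
    idx = pd.Series([idx]) if np.isscalar(idx) else idx
    known = np.asarray(known_lignin_wt_pct, dtype=float).ravel()
    if len(known) != len(idx):
        raise ValueError("one known lignin value per standard spectrum required")
    if (idx.to_numpy() <= 0).any():
        raise ValueError("standard with zero lignin index cannot calibrate RF")
    rf = float(np.mean(known / idx.to_numpy()))
    if not np.isfinite(rf) or rf <= 0:
        raise ValueError(f"invalid response factor {rf}")
    return rf


def lignin_content(spectra, rf: float) -> "pd.Series | float":
    """Lignin weight percent: RF x lignin index."""
    if rf <= 0:
        raise ValueError("response factor must be positive")
    idx = lignin_index(spectra)
    return rf * idx


def composition_table(matrix: SpectraMatrix, rf: float | None = None) -> pd.DataFrame:
    """Per-sample lignin index, optional wt%% lignin, and S/G ratio."""
    out = pd.DataFrame(index=matrix.sample_ids)
    out["lignin_index"] = lignin_index(matrix)
    if rf is not None:
        out["lignin_wt_pct"] = lignin_content(matrix, rf)
    out["s_g_ratio"] = s_g_ratio(matrix)
    return out
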