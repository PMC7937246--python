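"""Microspatial correction: thin-plate-spline field surfaces and Surface Complexity.

In a randomized clonal trial, genotype effects are spread uniformly across
the field, so a smooth surface fitted to per-position trait values estimates
the microspatial environmental component; the residuals carry genetics plus
error.  For every ion (or derived trait) we:

1. fit a thin plate spline over metric field coordinates, with the smoothing
   parameter chosen by generalized cross-validation (GCV);
2. summarize the fitted surface with the Surface Complexity statistic

       SC = -log10 prod_i | cor(yhat_i, t_i) |

   over field rows ``i``, where ``t_i`` is the within-row tree position --
   0 for any surface varying linearly along each row, large for patchy
   surfaces;
3. classify the ion as ``simple`` (SC <= 1: no spatial correction needed) or
   ``complex`` (SC > 1: replace values by residual + ion mean).

The spline minimizes ``sum (z - f)^2 + lambda J(f)`` with the 2-D bending
energy penalty; the radial basis is ``r^2 log r`` plus an affine (plane)
null space, so the ``lambda -> inf`` limit is an ordinary least-squares
plane and, with one knot per data point, ``lambda -> 0`` interpolates.
For large trials a reduced set of basis knots keeps the fit fast; the
affine null space stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr, solve_triangular

__all__ = [
    "ThinPlateSpline",
    "TPSResult",
    "fit_tps",
    "surface_complexity",
    "tps_correct",
    "classify_ions",
]

SC_MAX = 300.0
_COR_FLOOR = 1e-300


def _tps_kernel(d2: np.ndarray) -> np.ndarray:
    """eta(r) = r^2 log r, with eta(0) = 0 (via 0.5 * d2 * log(d2))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * d2 * np.log(d2)
    out[d2 == 0.0] = 0.0
    return out


def _pairwise_d2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


@dataclass
class TPSResult:
    """Fitted spatial surface for one trait/ion."""

    ion: object
    fitted: np.ndarray
    residual: np.ndarray
    lam: float
    edf: float  #: effective degrees of freedom of the smoother
    mean: float
    sc: float = np.nan
    sc_class: str = ""
    residual_correlation: float = np.nan
    gcv: float = np.nan
    model: "ThinPlateSpline | None" = field(default=None, repr=False)

    def predict(self, coords) -> np.ndarray:
        if self.model is None:
            raise ValueError("no model attached")
        return self.model.predict(coords)

    def summary(self) -> str:
        return (
            f"TPS fit [{self.ion}]: n={len(self.fitted)}, lambda={self.lam:.3g}, "
            f"edf={self.edf:.1f}, SC={self.sc:.3g} ({self.sc_class or 'unclassified'}), "
            f"cor(y, resid)={self.residual_correlation:.3f}"
        )


class ThinPlateSpline:
    """Penalized thin-plate regression spline over 2-D coordinates.

    Parameters
    ----------
    values
        Per-position trait values (one value per ramet position).
    coords
        (n, 2) array of metric coordinates (x_m, y_m).
    knots
        Basis knots; default all unique coordinates when there are at most
        ``max_knots`` of them, otherwise a deterministic uniform subsample.
    gcv_gamma
        Effective-df inflation in the GCV denominator; values around 1.4
        guard against the occasional marked undersmoothing of plain GCV on
        structureless fields.
    """

    def __init__(self, values, coords, *, knots=None, max_knots: int = 300,
                 gcv_gamma: float = 1.4):
        self.gcv_gamma = float(gcv_gamma)
        self.y = np.asarray(values, dtype=float).ravel()
        self.coords = np.asarray(coords, dtype=float).reshape(len(self.y), 2)
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) < 10:
            raise ValueError("need at least 10 distinct positions")
        if knots is None:
            if len(uniq) <= max_knots:
                knots = uniq
            else:
                rng = np.random.default_rng(180451)  # fixed: knot choice is part of the estimator
                knots = uniq[rng.choice(len(uniq), size=max_knots, replace=False)]
                knots = knots[np.lexsort(knots.T)]
        self.knots = np.asarray(knots, dtype=float)
        self._decompose()

    def _decompose(self) -> None:
        n, k = len(self.y), len(self.knots)
        T = np.column_stack([np.ones(n), self.coords])  # affine null space
        Tk = np.column_stack([np.ones(k), self.knots])
        # constraint Tk' c = 0 absorbed through the null space of Tk'
        Q_full, _ = qr(Tk, mode="full")
        Z = Q_full[:, 3:]
        Ekk = _tps_kernel(_pairwise_d2(self.knots, self.knots))
        Enk = _tps_kernel(_pairwise_d2(self.coords, self.knots))
        B = np.hstack([T, Enk @ Z])
        m = B.shape[1]
        P = np.zeros((m, m))
        P[3:, 3:] = Z.T @ Ekk @ Z
        Qb, Rb = qr(B, mode="economic")
        rdiag = np.abs(np.diag(Rb))
        if rdiag.min() < 1e-10 * max(rdiag.max(), 1.0):
            raise ValueError("degenerate layout: collinear or duplicate-only coordinates")
        Rinv = solve_triangular(Rb, np.eye(m), check_finite=False)
        M = Rinv.T @ P @ Rinv
        M = 0.5 * (M + M.T)
        s, U = np.linalg.eigh(M)
        s = np.clip(s, 0.0, None)
        self._Z, self._Rinv, self._U, self._s = Z, Rinv, U, s
        self._Qb = Qb
        self._qty = Qb.T @ self.y
        self._ystar = U.T @ self._qty
        self._yy = float(self.y @ self.y)
        self._n = n

    def _gcv(self, lam: float) -> tuple[float, float, float]:
        shrink = 1.0 / (1.0 + lam * self._s)
        df = float(shrink.sum())
        resid_in_span = (1.0 - shrink) * self._ystar
        rss = (self._yy - float(self._qty @ self._qty)) + float(resid_in_span @ resid_in_span)
        denom = max(self._n - self.gcv_gamma * df, 1e-10)
        return self._n * rss / denom**2, df, rss

    def lambda_grid(self, n_grid: int = 40) -> np.ndarray:
        """Log-spaced grid spanning 1e-6 .. 1e+6 times an eigenvalue scale."""
        pos = self._s[self._s > 0]
        scale = 1.0 / np.exp(np.mean(np.log(pos))) if len(pos) else 1.0
        return scale * np.logspace(-6, 6, n_grid)

    def fit(self, lam: float | None = None, *, n_grid: int = 40, ion=None) -> TPSResult:
        """Fit with fixed ``lam``, or select it by GCV over the log grid."""
        if lam is None:
            grid = self.lambda_grid(n_grid)
            scores = [self._gcv(l)[0] for l in grid]
            lam = float(grid[int(np.argmin(scores))])
        gcv, df, _ = self._gcv(lam)
        shrink = 1.0 / (1.0 + lam * self._s)
        w = shrink * self._ystar
        fitted = self._Qb @ (self._U @ w)
        resid = self.y - fitted
        self._theta = self._Rinv @ (self._U @ w)
        mean = float(self.y.mean())
        sd = float(self.y.std())
        if sd > 0 and fitted.std() > 0:
            rc = float(np.corrcoef(self.y, resid)[0, 1]) if resid.std() > 0 else 0.0
        else:
            rc = np.nan
        return TPSResult(
            ion=ion, fitted=fitted, residual=resid, lam=float(lam), edf=df,
            mean=mean, residual_correlation=rc, gcv=float(gcv), model=self,
        )

    def predict(self, coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        T = np.column_stack([np.ones(len(coords)), coords])
        Enk = _tps_kernel(_pairwise_d2(coords, self.knots))
        B = np.hstack([T, Enk @ self._Z])
        return B @ self._theta


def fit_tps(values, coords, *, lam=None, knots=None, max_knots=300, n_grid=40,
            ion=None, rows=None, positions=None, sc_threshold: float = 1.0) -> TPSResult:
    """Fit a TPS surface; if row/position labels are given, also compute SC.

    ``rows``/``positions`` are the field row index and within-row tree
    position of each value, used for the Surface Complexity statistic.
    """
    model = ThinPlateSpline(values, coords, knots=knots, max_knots=max_knots)
    result = model.fit(lam, n_grid=n_grid, ion=ion)
    if rows is not None and positions is not None:
        result.sc = surface_complexity(result.fitted, rows, positions)
        result.sc_class = "complex" if result.sc > sc_threshold else "simple"
    return result


def surface_complexity(fitted, rows, positions, *, min_row_size: int = 3,
                       sc_max: float = SC_MAX) -> float:
    """SC = -log10 of the product over field rows of |cor(fitted, position)|.

    Fitted surfaces that vary linearly along every row give |cor| = 1 in each
    row and SC = 0; patchy surfaces give small within-row correlations and
    large SC.  Rows with fewer than ``min_row_size`` trees, or with zero
    variance of either the fitted values or the positions, contribute a
    factor of 1 (no within-row structure to assess).  The result is clamped
    to ``[0, sc_max]``.
    """
    fitted = np.asarray(fitted, dtype=float).ravel()
    rows = np.asarray(rows).ravel()
    positions = np.asarray(positions, dtype=float).ravel()
    if not (len(fitted) == len(rows) == len(positions)):
        raise ValueError("fitted, rows and positions must be equally long")
    total = 0.0
    usable = 0
    for r in np.unique(rows):
        sel = rows == r
        if sel.sum() < min_row_size:
            continue
        f, t = fitted[sel], positions[sel]
        usable += 1
        if f.std() == 0.0 or t.std() == 0.0:
            continue  # no within-row structure: factor 1, SC contribution 0
        c = abs(float(np.corrcoef(f, t)[0, 1]))
        total += -np.log10(max(c, _COR_FLOOR))
    if usable == 0:
        raise ValueError("no usable rows for surface complexity")
    return float(np.clip(total, 0.0, sc_max))


def tps_correct(values, tps: TPSResult) -> np.ndarray:
    """Project residuals back to the original scale: residual + trait mean."""
    values = np.asarray(values, dtype=float).ravel()
    if len(values) != len(tps.residual):
        raise ValueError("length mismatch between values and TPS residuals")
    return tps.residual + float(values.mean())


def classify_ions(sc_table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Partition ions into simple (pass-through) vs complex (TPS-corrected).

    ``sc_table`` needs an ``SC`` column indexed by ion; returns a copy with
    ``sc_class`` and ``tps_corrected`` columns.
    """
    out = sc_table.copy()
    out["sc_class"] = np.where(out["SC"] > threshold, "complex", "simple")
    out["tps_corrected"] = out["SC"] > threshold
    return out
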