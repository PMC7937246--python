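"""Variance-component estimation primitives.

Three estimators live here and are shared by the tray-correction and
genetics modules:

* :func:`oneway_reml` -- exact REML for the one-way random-effects model
  ``y = mu + g_i + e`` via a profiled one-dimensional likelihood in the
  variance ratio.  On balanced designs the optimum coincides with the
  ANOVA method-of-moments estimator whenever that is nonnegative.
* :func:`anova_oneway` -- the closed-form ANOVA estimator, used both as an
  independent oracle and as the fast path inside permutation tests.
* :func:`em_reml` -- EM-REML for a general mean plus any number of crossed
  i.i.d. random effects (``y = Xb + sum_k Z_k u_k + e``) through Henderson's
  mixed-model equations, returning shrunken BLUPs of every effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

__all__ = ["OnewayFit", "oneway_reml", "anova_oneway", "h2_of_permutations", "EMResult", "em_reml"]


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = np.asarray(groups).ravel(), None
    import pandas as pd

    cat = pd.Categorical(codes)
    return np.asarray(cat.codes, dtype=np.intp), len(cat.categories)


@dataclass
class OnewayFit:
    """One-way random-effects fit: genotypic and residual variance."""

    sigma2_g: float
    sigma2_e: float
    mu: float
    h2: float
    n_groups: int
    n_obs: int
    converged: bool = True
    method: str = "reml"

    @property
    def total_variance(self) -> float:
        return self.sigma2_g + self.sigma2_e


def _oneway_stats(y, groups):
    y = np.asarray(y, dtype=float).ravel()
    codes, a = _group_codes(groups)
    if a < 2:
        raise ValueError("need at least 2 groups")
    n_i = np.bincount(codes, minlength=a).astype(float)
    if (n_i == 0).any():
        raise ValueError("empty group level")
    sums = np.bincount(codes, weights=y, minlength=a)
    ybar_i = sums / n_i
    ssw = float(y @ y - sums @ ybar_i)
    return y, codes, a, n_i, ybar_i, ssw


def oneway_reml(y, groups) -> OnewayFit:
    """Exact REML for ``y_ij = mu + g_i + e_ij`` with g, e independent normal.

    The residual variance is profiled out analytically, leaving a
    one-dimensional restricted likelihood in the ratio
    ``theta = sigma2_g / sigma2_e`` which is minimized on a log grid plus a
    bounded refinement; the ``theta = 0`` boundary is always also evaluated.
    """
    y, codes, a, n_i, ybar_i, ssw = _oneway_stats(y, groups)
    n = y.size
    if n == a:
        raise ValueError("all groups are singletons; sigma2_g is unidentifiable")
    if np.var(y) == 0.0:  # constant trait: all components zero, H2 := 0
        return OnewayFit(0.0, 0.0, float(y[0]), 0.0, a, n, converged=True, method="reml")

    def neg2_restricted(theta: float) -> tuple[float, float, float]:
        v = 1.0 + n_i * theta
        w = n_i / v
        sw = w.sum()
        mu = float(w @ ybar_i / sw)
        quad = ssw + float(n_i @ ((ybar_i - mu) ** 2 / v))
        if quad <= 0:  # degenerate constant data
            return -np.inf, 0.0, mu
        s2e = quad / (n - 1)
        val = (n - 1) * np.log(s2e) + np.log(v).sum() + np.log(sw)
        return val, s2e, mu

    # coarse log-grid, then local refinement around the best point
    ts = np.linspace(-25.0, 25.0, 51)
    vals = np.array([neg2_restricted(np.exp(t))[0] for t in ts])
    t0 = ts[int(np.argmin(vals))]
    res = minimize_scalar(
        lambda t: neg2_restricted(np.exp(t))[0],
        bounds=(t0 - 2.0, t0 + 2.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    best_t = float(res.x)
    val_int, s2e_int, mu_int = neg2_restricted(np.exp(best_t))
    val_0, s2e_0, mu_0 = neg2_restricted(0.0)
    if val_0 <= val_int:
        theta, s2e, mu = 0.0, s2e_0, mu_0
    else:
        theta, s2e, mu = np.exp(best_t), s2e_int, mu_int
    s2g = theta * s2e
    tot = s2g + s2e
    h2 = s2g / tot if tot > 0 else 0.0
    return OnewayFit(s2g, s2e, mu, h2, a, n, converged=True, method="reml")


def anova_oneway(y, groups) -> OnewayFit:
    """Closed-form ANOVA (method-of-moments) one-way variance components.

    ``sigma2_g = max(0, (MSB - MSW) / r_eff)`` with the effective replicate
    number ``r_eff = (N - sum n_i^2 / N) / (a - 1)``; equals the plain
    replicate count on balanced designs.
    """
    y, codes, a, n_i, ybar_i, ssw = _oneway_stats(y, groups)
    n = y.size
    if n == a:
        raise ValueError("all groups are singletons; sigma2_g is unidentifiable")
    grand = y.mean()
    ssb = float(n_i @ (ybar_i - grand) ** 2)
    msb = ssb / (a - 1)
    msw = ssw / (n - a)
    r_eff = (n - float(n_i @ n_i) / n) / (a - 1)
    s2g = max(0.0, (msb - msw) / r_eff)
    tot = s2g + msw
    h2 = s2g / tot if tot > 0 else 0.0
    return OnewayFit(s2g, msw, float(grand), h2, a, n, method="anova")


def h2_raw(y, groups) -> float:
    """Unclamped ANOVA heritability statistic ``s2g / (s2g + MSW)``.

    ``s2g = (MSB - MSW) / r_eff`` is left negative when MSB < MSW, making the
    statistic continuous -- the form needed for exact permutation p-values
    (the clamped H-squared has an atom at 0 under the null).
    """
    y, codes, a, n_i, ybar_i, ssw = _oneway_stats(y, groups)
    n = y.size
    grand = y.mean()
    msb = float(n_i @ (ybar_i - grand) ** 2) / (a - 1)
    msw = ssw / (n - a)
    r_eff = (n - float(n_i @ n_i) / n) / (a - 1)
    s2g = (msb - msw) / r_eff
    tot = s2g + msw
    return s2g / tot if tot > 0 else 0.0


def h2_of_permutations(y, groups, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Unclamped ANOVA heritability statistic for ``n_perm`` shuffles of ``y``.

    The design (group labels) stays fixed; only the trait is permuted, so the
    total sum of squares is invariant and each permutation costs one pass of
    per-group sums.  Clip at zero to obtain permuted H-squared values.
    """
    y, codes, a, n_i, _, _ = _oneway_stats(y, groups)
    n = y.size
    yy = float(y @ y)
    sy = float(y.sum())
    r_eff = (n - float(n_i @ n_i) / n) / (a - 1)
    out = np.empty(n_perm)
    yp = y.copy()
    for p in range(n_perm):
        rng.shuffle(yp)
        sums = np.bincount(codes, weights=yp, minlength=a)
        sb = float((sums * sums / n_i).sum())
        msb = (sb - sy * sy / n) / (a - 1)
        msw = (yy - sb) / (n - a)
        s2g = (msb - msw) / r_eff
        tot = s2g + msw
        out[p] = s2g / tot if tot > 0 else 0.0
    return out


@dataclass
class EMResult:
    """EM-REML fit of a crossed random-effects model."""

    sigma2: dict[str, float]  #: variance component per random term
    sigma2_e: float
    beta: np.ndarray  #: fixed-effect estimates (intercept by default)
    blups: dict[str, np.ndarray]  #: shrunken effect predictions per term
    levels: dict[str, list]  #: level labels aligned with each BLUP vector
    n_iter: int = 0
    converged: bool = False
    n_obs: int = 0

    @property
    def total_variance(self) -> float:
        return sum(self.sigma2.values()) + self.sigma2_e


def em_reml(
    y,
    terms: dict[str, "np.ndarray | list"],
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    floor_frac: float = 1e-12,
) -> EMResult:
    """EM-REML for ``y = mu + sum_k u_k[term_k] + e`` with crossed i.i.d. terms.

    Parameters
    ----------
    y
        Response vector.
    terms
        Mapping term name -> per-observation level labels.  Each term gets an
        independent normal effect per level with its own variance component.
    max_iter, tol
        EM stops when every variance component changes by a relative amount
        below ``tol``, or after ``max_iter`` sweeps (``converged=False``).
    floor_frac
        Variance floor as a fraction of var(y); keeps the mixed-model
        equations well posed when a component collapses to zero.

    Notes
    -----
    Each sweep solves Henderson's mixed-model equations by dense Cholesky and
    applies the classical EM updates
    ``sigma2_k <- (u_k'u_k + sigma2_e tr(C^kk)) / q_k`` and
    ``sigma2_e <- (y'y - s'W'y) / (n - p)``.
    """
    import pandas as pd

    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    names = list(terms)
    codes, qs, levels = [], [], {}
    for name in names:
        cat = pd.Categorical(np.asarray(terms[name]).ravel())
        codes.append(np.asarray(cat.codes, dtype=np.intp))
        qs.append(len(cat.categories))
        levels[name] = list(cat.categories)
        if cat.codes.min() < 0:
            raise ValueError(f"term {name!r} has missing levels")

    p = 1
    m = p + sum(qs)
    W = np.zeros((n, m))
    W[:, 0] = 1.0
    offsets = []
    off = p
    for c, q in zip(codes, qs):
        W[np.arange(n), off + c] = 1.0
        offsets.append(off)
        off += q

    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    vy = float(np.var(y))
    if vy == 0.0:
        return EMResult(
            {nm: 0.0 for nm in names}, 0.0, np.array([y[0] if n else 0.0]),
            {nm: np.zeros(q) for nm, q in zip(names, qs)}, levels, 0, True, n,
        )
    floor = floor_frac * vy

    k = len(names)
    s2 = np.full(k, vy / (2 * k))
    s2e = vy / 2.0
    eye = np.eye(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        for j, (offj, qj) in enumerate(zip(offsets, qs)):
            lam = s2e / max(s2[j], floor)
            idx = np.arange(offj, offj + qj)
            C[idx, idx] += lam
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            C[np.diag_indices_from(C)] += 1e-10 * np.trace(C) / m
            cf = cho_factor(C, lower=True, check_finite=False)
        sol = cho_solve(cf, Wty, check_finite=False)
        Cinv_diag = np.diag(cho_solve(cf, eye, check_finite=False))

        new_s2 = np.empty(k)
        for j, (offj, qj) in enumerate(zip(offsets, qs)):
            u = sol[offj : offj + qj]
            tr = float(Cinv_diag[offj : offj + qj].sum())
            new_s2[j] = max((float(u @ u) + s2e * tr) / qj, floor)
        new_s2e = max((yty - float(sol @ Wty)) / (n - p), floor)

        rel = max(
            float(np.max(np.abs(new_s2 - s2) / np.maximum(s2, floor))),
            abs(new_s2e - s2e) / max(s2e, floor),
        )
        s2, s2e = new_s2, new_s2e
        if rel < tol:
            converged = True
            break

    blups = {
        nm: sol[offj : offj + qj].copy()
        for nm, offj, qj in zip(names, offsets, qs)
    }
    sigma2 = {nm: (0.0 if s2[j] <= floor * (1 + 1e-9) else float(s2[j])) for j, nm in enumerate(names)}
    return EMResult(
        sigma2=sigma2,
        sigma2_e=float(s2e),
        beta=sol[:p].copy(),
        blups=blups,
        levels=levels,
        n_iter=it,
        converged=converged,
        n_obs=n,
    )
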