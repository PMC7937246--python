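"""Broad-sense heritability, permutation thresholds, and parental variance shares.

Clonal replication (each genotype planted as several ramets) identifies the
total genotypic variance directly: with genotype as a random effect,

    H^2 = sigma2_G / (sigma2_G + sigma2_resid).

Significance is calibrated per trait by permuting trait values across ramets
(the design stays fixed) and taking the empirical (1 - alpha) quantile of the
permuted H^2 as the threshold.  Maternal and paternal contributions come from
the extended crossed model ``value = mu + genotype + mother + father + e``;
each parental share is that component's variance over the total.  Genotypes
from open-pollinated families have an unknown pollen parent and are coded as
one distinct father level per mother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import anova_oneway, em_reml, h2_of_permutations, h2_raw, oneway_reml

__all__ = [
    "VarianceComponents",
    "VarCompResult",
    "PermutationResult",
    "fit_oneway_varcomp",
    "fit_parental_varcomp",
    "permutation_threshold",
    "heritability_table",
    "encode_open_pollinated",
]

UNKNOWN_FATHER = "OP"


@dataclass
class VarCompResult:
    """Variance components and heritability for one trait."""

    sigma2_G: float
    sigma2_M: float
    sigma2_F: float
    sigma2_resid: float
    H2: float
    maternal_share: float
    paternal_share: float
    n_genotypes: int
    n_ramets: int
    converged: bool = True
    model: str = "genotype-only"

    @property
    def total_variance(self) -> float:
        return self.sigma2_G + self.sigma2_M + self.sigma2_F + self.sigma2_resid

    def summary(self) -> str:
        lines = [
            f"Variance components ({self.model}; {self.n_genotypes} genotypes, "
            f"{self.n_ramets} ramets, converged={self.converged})",
            f"  sigma2_G     = {self.sigma2_G:.6g}",
        ]
        if self.model != "genotype-only":
            lines += [
                f"  sigma2_M     = {self.sigma2_M:.6g}  (maternal share {self.maternal_share:.3f})",
                f"  sigma2_F     = {self.sigma2_F:.6g}  (paternal share {self.paternal_share:.3f})",
            ]
        lines += [
            f"  sigma2_resid = {self.sigma2_resid:.6g}",
            f"  H2           = {self.H2:.4f}",
        ]
        return "\n".join(lines)


@dataclass
class PermutationResult:
    """Permutation-null calibration of one trait's heritability."""

    n_perm: int
    alpha: float
    threshold: float  #: (1 - alpha) quantile of permuted H^2
    p_value: float
    observed_h2: float
    seed: int
    significant: bool

    def summary(self) -> str:
        star = "significant" if self.significant else "not significant"
        return (
            f"H2 = {self.observed_h2:.4f} vs {self.n_perm}-permutation threshold "
            f"{self.threshold:.4f} (alpha={self.alpha}): {star} (p = {self.p_value:.4g})"
        )


class VarianceComponents:
    """Random-effects model of a clonally replicated trait.

    Parameters
    ----------
    values
        Per-ramet trait values (corrected scale).
    genotype
        Genotype (clone) label per ramet.
    mother, father
        Optional parental labels; supplying both switches ``fit`` to the
        crossed genotype + mother + father model.
    """

    def __init__(self, values, genotype, mother=None, father=None):
        self.values = np.asarray(values, dtype=float).ravel()
        self.genotype = np.asarray(genotype).ravel()
        if len(self.values) != len(self.genotype):
            raise ValueError("values and genotype labels differ in length")
        self.mother = None if mother is None else np.asarray(mother).ravel()
        self.father = None if father is None else np.asarray(father).ravel()
        if (self.mother is None) != (self.father is None):
            raise ValueError("supply both mother and father, or neither")
        if self.mother is not None:
            known = pd.notna(self.mother).mean()
            if known < 0.8:
                raise ValueError("mother known for fewer than 80% of ramets")

    def fit(self, method: str = "reml", **kw) -> VarCompResult:
        if self.mother is None:
            return self._fit_oneway(method)
        return self._fit_parental(**kw)

    def _fit_oneway(self, method: str) -> VarCompResult:
        fitfun = {"reml": oneway_reml, "anova": anova_oneway}[method]
        f = fitfun(self.values, self.genotype)
        return VarCompResult(
            sigma2_G=f.sigma2_g, sigma2_M=0.0, sigma2_F=0.0, sigma2_resid=f.sigma2_e,
            H2=f.h2, maternal_share=np.nan, paternal_share=np.nan,
            n_genotypes=f.n_groups, n_ramets=f.n_obs, converged=f.converged,
            model="genotype-only",
        )

    def _fit_parental(self, **kw) -> VarCompResult:
        mother, father = encode_parents(self.genotype, self.mother, self.father)
        res = em_reml(
            self.values,
            {"genotype": self.genotype, "mother": mother, "father": father},
            **kw,
        )
        s2g, s2m, s2f = res.sigma2["genotype"], res.sigma2["mother"], res.sigma2["father"]
        tot = s2g + s2m + s2f + res.sigma2_e
        h2 = (s2g + s2m + s2f) / tot if tot > 0 else 0.0
        return VarCompResult(
            sigma2_G=s2g, sigma2_M=s2m, sigma2_F=s2f, sigma2_resid=res.sigma2_e,
            H2=h2, maternal_share=s2m / tot if tot > 0 else 0.0,
            paternal_share=s2f / tot if tot > 0 else 0.0,
            n_genotypes=len(res.levels["genotype"]), n_ramets=res.n_obs,
            converged=res.converged, model="genotype+parents",
        )


def encode_open_pollinated(mother, father, unknown=UNKNOWN_FATHER) -> np.ndarray:
    """Give each mother's unknown-pollen offspring their own father level.

    Missing/``"OP"`` fathers become ``"OP:<mother>"`` so open-pollinated
    families are not pooled into one pseudo-father across mothers.
    """
    mother = np.asarray(mother, dtype=object)
    father = np.asarray(father, dtype=object)
    out = father.copy()
    unk = pd.isna(father) | (father == unknown)
    out[unk] = np.array([f"OP:{m}" for m in mother[unk]], dtype=object)
    return out


def encode_parents(genotype, mother, father) -> tuple[np.ndarray, np.ndarray]:
    """Encode parental labels for the crossed model, handling unknowns.

    Open-pollinated offspring get a per-mother unknown-father level; founder
    genotypes with no recorded parents (the crossing parents themselves) get
    their own singleton mother and father levels, so they inform neither
    parental component.
    """
    genotype = np.asarray(genotype, dtype=object)
    mother = np.asarray(mother, dtype=object).copy()
    father = np.asarray(father, dtype=object).copy()
    unk_m = pd.isna(mother)
    op = (pd.isna(father) | (father == UNKNOWN_FATHER)) & ~unk_m
    father[op] = np.array([f"OP:{m}" for m in mother[op]], dtype=object)
    unk_f = pd.isna(father) | unk_m
    father[unk_f] = np.array([f"UF:{g}" for g in genotype[unk_f]], dtype=object)
    mother[unk_m] = np.array([f"UM:{g}" for g in genotype[unk_m]], dtype=object)
    return mother, father


def fit_oneway_varcomp(values, genotype, method: str = "reml") -> VarCompResult:
    """Genotype-only variance components and broad-sense heritability.

    REML by default; ``method="anova"`` uses the balanced-design closed form
    ``sigma2_G = max(0, (MSB - MSW) / r)``, which REML reproduces exactly on
    balanced data.
    """
    return VarianceComponents(values, genotype).fit(method)


def fit_parental_varcomp(values, genotype, mother, father, **kw) -> VarCompResult:
    """Crossed model with genotype, mother and father random effects."""
    return VarianceComponents(values, genotype, mother, father).fit(**kw)


def permutation_threshold(
    values, genotype, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
    estimator: str = "anova",
) -> PermutationResult:
    """Null-calibrate H^2 by shuffling trait values across ramets.

    Permutations use the fast ANOVA closed form (matching REML on the
    near-balanced clonal design).  The p-value compares the *unclamped*
    variance-ratio statistic -- continuous under the null, so p is uniform --
    as ``(1 + #{perm >= observed}) / (n_perm + 1)``; the reported threshold
    is the (1 - alpha) quantile of the permuted (clamped) H^2 values.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives a meaningless threshold")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation threshold will be coarse", stacklevel=2)
    values = np.asarray(values, dtype=float).ravel()
    fitfun = {"reml": oneway_reml, "anova": anova_oneway}[estimator]
    observed = fitfun(values, genotype).h2
    observed_raw = h2_raw(values, genotype)
    rng = np.random.default_rng(seed)
    perms = h2_of_permutations(values, genotype, n_perm, rng)
    threshold = float(np.quantile(np.clip(perms, 0.0, None), 1.0 - alpha))
    p = (1.0 + float((perms >= observed_raw).sum())) / (n_perm + 1.0)
    return PermutationResult(
        n_perm=n_perm, alpha=alpha, threshold=threshold, p_value=p,
        observed_h2=float(observed), seed=seed, significant=observed >= threshold,
    )


def heritability_table(
    values: pd.DataFrame,
    genotype,
    mother=None,
    father=None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    parental: "bool | list" = False,
) -> pd.DataFrame:
    """Per-trait heritability with permutation thresholds and parental shares.

    ``values`` is a samples x traits frame (ion intensities and/or derived
    phenotypes on their corrected scale, one row per ramet).  Each column is
    fitted independently; per-trait errors are recorded, never raised.
    ``parental`` is False, True (all traits), or a list of columns for which
    the slower crossed parental model is also fitted.  No cross-trait
    multiple-testing adjustment is applied: each trait carries its own
    permutation threshold at level ``alpha``.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(values.shape[1])
    parental_cols = (
        set(values.columns) if parental is True else set(parental or [])
    )
    rows = []
    for j, col in enumerate(values.columns):
        row = {"trait": col}
        y = values[col].to_numpy(dtype=float)
        try:
            fit = fit_oneway_varcomp(y, genotype)
            perm = permutation_threshold(
                y, genotype, n_perm=n_perm, alpha=alpha, seed=int(child_seeds[j]) % (2**31)
            )
            row.update(
                sigma2_G=fit.sigma2_G, sigma2_resid=fit.sigma2_resid, H2=fit.H2,
                perm_threshold=perm.threshold, p=perm.p_value,
                significant=perm.significant, converged=fit.converged,
                n_genotypes=fit.n_genotypes, n_ramets=fit.n_ramets,
            )
            if col in parental_cols and mother is not None:
                pf = fit_parental_varcomp(y, genotype, mother, father)
                row.update(
                    sigma2_M=pf.sigma2_M, sigma2_F=pf.sigma2_F,
                    maternal_share=pf.maternal_share, paternal_share=pf.paternal_share,
                    parental_converged=pf.converged,
                )
        except Exception as exc:  # propagate per-trait, never abort the table
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
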