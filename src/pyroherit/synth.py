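"""Synthetic py-MBMS progeny-trial generator.

Emulates a clonally replicated factorial pedigree trial measured by
pyrolysis mass spectrometry, with the statistical structure the analysis
pipeline assumes, so that every downstream stage can be tested by parameter
recovery:

* a 7 x 7 full-factorial pedigree plus open-pollinated families and the 14
  parents (1000 genotypes by default, 986 of them offspring);
* three complete randomized blocks on a 30-row x 100-tree grid (3 m x 1 m
  spacing), uniform survival thinning to ~2721 live ramets, and a flagged
  double border that never enters analysis tables;
* per-genotype trait deviations composed of maternal, paternal, cross
  (SCA) and within-family (Mendelian-sampling) effects;
* a smooth microspatial environmental surface (planar or Gaussian-bump);
* spectra rendered from phenomenological component templates (S-lignin,
  G-lignin, C5/C6 carbohydrates, phenolics, acetyl, baseline), with
  additive per-tray instrumental offsets on designated fragment ions and
  multiplicative lognormal channel noise;
* six replicated standards (~509 runs) spread over 125 48-vial trays, two
  technical replicates per ramet (~5440 sample runs).

Every random draw funnels through one root seed, so a fixed config yields a
byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import SpectraMatrix
from .ions import ALL_CHANNELS, G_IONS, MZ_MAX, MZ_MIN, S_IONS

__all__ = [
    "PedigreeConfig",
    "FieldLayout",
    "TraitComponents",
    "GeneticArchitecture",
    "ComponentTemplate",
    "SimulationConfig",
    "SimulatedTrial",
    "build_pedigree",
    "layout_trial",
    "simulate_genetic_values",
    "simulate_environment",
    "render_spectrum",
    "simulate_trial",
    "default_templates",
    "default_architecture",
    "default_standards",
]

_N_CH = len(ALL_CHANNELS)
_CH_INDEX = {mz: i for i, mz in enumerate(ALL_CHANNELS)}

#: Internal truth: lignin weight percent per unit lignin-ion index.  The
#: diagnostic ions capture a fixed share of lignin mass, so wt% = 200 x index.
TRUE_RESPONSE_FACTOR = 200.0


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------
@dataclass
class PedigreeConfig:
    """Factorial mating design plus open-pollinated families."""

    n_mothers: int = 7
    n_fathers: int = 7
    offspring_per_cross: int = 19
    n_open_pollinated_per_mother: int = 8
    include_parents: bool = True
    #: optional exact offspring total; open-pollinated families are trimmed /
    #: topped up round-robin to hit it (the study design is not divisible
    #: into equal families).
    total_offspring: int | None = 986

    def __post_init__(self):
        if min(self.n_mothers, self.n_fathers, self.offspring_per_cross) < 1:
            raise ValueError("counts must be >= 1 (zero offspring requested?)")
        if self.n_open_pollinated_per_mother < 0:
            raise ValueError("n_open_pollinated_per_mother must be >= 0")


@dataclass
class FieldLayout:
    """Planting grid: rows x trees, contiguous block bands, metric spacing."""

    n_rows: int = 30
    trees_per_row: int = 100
    row_spacing: float = 3.0  # meters between rows
    tree_spacing: float = 1.0  # meters within rows
    n_blocks: int = 3
    survival_rate: float = 0.907
    include_border: bool = True  #: double border of extra ramets, flagged

    def __post_init__(self):
        if not (0.0 < self.survival_rate <= 1.0):
            raise ValueError("survival_rate must be in (0, 1]")
        if self.n_rows < self.n_blocks:
            raise ValueError("fewer rows than blocks")

    @property
    def capacity(self) -> int:
        return self.n_rows * self.trees_per_row


@dataclass
class TraitComponents:
    """Variance components and environmental loading for one latent trait."""

    mean: float = 0.0
    var_mother: float = 0.0
    var_father: float = 0.0
    var_sca: float = 0.0  #: mother x father cross interaction
    var_mendelian: float = 0.0  #: within-family genotype deviation
    var_residual: float = 0.0  #: ramet-level biological residual
    env_loading: float = 0.0  #: coefficient on the (unit-range) field surface

    def __post_init__(self):
        for name in ("var_mother", "var_father", "var_sca", "var_mendelian", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def var_genotypic(self) -> float:
        return self.var_mother + self.var_father + self.var_sca + self.var_mendelian

    @property
    def h2(self) -> float:
        tot = self.var_genotypic + self.var_residual
        return self.var_genotypic / tot if tot > 0 else 0.0


@dataclass
class GeneticArchitecture:
    """Per-trait variance components; keys are latent trait names."""

    traits: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, tc in list(self.traits.items()):
            if isinstance(tc, dict):
                self.traits[name] = TraitComponents(**tc)


@dataclass
class ComponentTemplate:
    """Normalized fragment-ion pattern of one biomass component class."""

    name: str
    intensities: dict  #: m/z -> relative intensity, sums to 1

    def __post_init__(self):
        bad = [mz for mz in self.intensities if not (MZ_MIN <= int(mz) <= MZ_MAX)]
        if bad:
            raise ValueError(f"template {self.name}: channels outside range: {bad}")
        total = float(sum(self.intensities.values()))
        if total <= 0 or any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"template {self.name}: intensities must be >= 0, sum > 0")
        self.intensities = {int(mz): v / total for mz, v in self.intensities.items()}
        v = np.zeros(_N_CH)
        for mz, x in self.intensities.items():
            v[_CH_INDEX[mz]] = x
        self._vector = v

    @property
    def vector(self) -> np.ndarray:
        return self._vector


def default_templates() -> dict[str, ComponentTemplate]:
    """Phenomenological fragment patterns for the seven component classes.

    S- and G-lignin templates live entirely on their diagnostic ion sets, so
    a noiseless spectrum's S/G ratio equals the composition-level ratio
    exactly; the baseline class fills non-diagnostic channels.
    """
    patterns = {
        "s_lignin": {154: 0.22, 167: 0.16, 168: 0.14, 182: 0.13, 194: 0.14, 208: 0.09, 210: 0.12},
        "g_lignin": {124: 0.22, 137: 0.20, 138: 0.13, 150: 0.14, 164: 0.13, 178: 0.18},
        "c5_carbohydrate": {85: 0.35, 96: 0.20, 114: 0.45},
        "c6_carbohydrate": {57: 0.18, 73: 0.30, 98: 0.22, 126: 0.30},
        "phenolics": {66: 0.25, 94: 0.45, 121: 0.30},
        "acetyl": {60: 1.0},
        "baseline": {
            **{mz: 1.0 for mz in range(31, 56) if mz not in (43,)},
            **{mz: 0.5 for mz in range(212, 300, 4)},
        },
    }
    assert set(patterns["s_lignin"]) == set(S_IONS) and set(patterns["g_lignin"]) == set(G_IONS)
    return {name: ComponentTemplate(name, d) for name, d in patterns.items()}


def default_architecture() -> GeneticArchitecture:
    """Study-scale architecture for the six latent composition traits.

    Lignin wt%% and S/G are calibrated so the population mean (SD) after
    corrections is ~25.5 (0.9) wt%% and ~2.10 (0.17), with genotypic shares
    0.56 and 0.81 of the post-correction variance; phenolics are strongly
    maternal, carbohydrates lean paternal.  Residuals are ramet-level
    biological variation; measurement noise is added per technical replicate
    at render time.
    """
    return GeneticArchitecture(
        {
            "lignin_wt_pct": TraitComponents(
                mean=25.5, var_mother=0.15, var_father=0.05, var_sca=0.05,
                var_mendelian=0.2036, var_residual=0.325, env_loading=1.8,
            ),
            "s_g_ratio": TraitComponents(
                mean=2.10, var_mother=0.008, var_father=0.003, var_sca=0.002,
                var_mendelian=0.0104, var_residual=0.0049, env_loading=0.30,
            ),
            "phenolics": TraitComponents(
                mean=0.020, var_mother=1.0e-5, var_father=0.5e-6, var_sca=0.4e-6,
                var_mendelian=1.74e-6, var_residual=3.4e-6, env_loading=0.002,
            ),
            "c5": TraitComponents(
                mean=0.15, var_mother=6e-6, var_father=1.0e-5, var_sca=2e-6,
                var_mendelian=1.0e-5, var_residual=3.6e-5, env_loading=0.008,
            ),
            "c6": TraitComponents(
                mean=0.30, var_mother=1.2e-5, var_father=1.6e-5, var_sca=4e-6,
                var_mendelian=1.4e-5, var_residual=9.8e-5, env_loading=-0.012,
            ),
            "acetyl": TraitComponents(
                mean=0.030, var_mother=1.5e-6, var_father=1.0e-6, var_sca=0.5e-6,
                var_mendelian=1.0e-6, var_residual=5.0e-6, env_loading=0.001,
            ),
        }
    )


def default_standards() -> pd.DataFrame:
    """Six fixed-composition QC standards spanning the trait ranges."""
    rows = [
        # id, lignin wt%, S/G, phenolics, c5, c6, acetyl
        ("STD1", 19.5, 2.30, 0.010, 0.16, 0.32, 0.030),
        ("STD2", 28.0, 0.10, 0.005, 0.12, 0.28, 0.015),
        ("STD3", 25.5, 2.10, 0.020, 0.15, 0.30, 0.030),
        ("STD4", 23.0, 1.80, 0.015, 0.17, 0.31, 0.035),
        ("STD5", 26.5, 2.40, 0.025, 0.14, 0.29, 0.028),
        ("STD6", 21.0, 1.50, 0.012, 0.16, 0.33, 0.032),
    ]
    return pd.DataFrame(
        rows, columns=["standard_id", "lignin_wt_pct", "s_g_ratio", "phenolics", "c5", "c6", "acetyl"]
    ).set_index("standard_id")


@dataclass
class SimulationConfig:
    """Full trial simulation settings; a fixed seed reproduces the dataset."""

    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    layout: FieldLayout = field(default_factory=FieldLayout)
    architecture: GeneticArchitecture = field(default_factory=default_architecture)
    surface_kind: str = "complex"  #: {planar, complex}
    surface_amplitude: float = 1.0  #: range of the unit surface multiplying env loadings
    n_trays: int = 125
    vials_per_tray: int = 48
    n_standards: int = 6
    standard_replicates_total: int = 509
    tray_drift_sd: float = 0.001  #: additive, TIC-normalized scale
    drift_ions: tuple = (167, 181, 193)
    technical_replicates: int = 2
    measurement_noise_sd: float = 0.03  #: lognormal sigma per channel
    tic_scale: float = 1.0e6  #: mean raw total ion current
    tic_scale_sd: float = 0.15  #: lognormal sigma of per-run TIC
    templates: dict | None = None  #: class -> ComponentTemplate; default set if None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.pedigree, dict):
            self.pedigree = PedigreeConfig(**self.pedigree)
        if isinstance(self.layout, dict):
            self.layout = FieldLayout(**self.layout)
        if isinstance(self.architecture, dict):
            self.architecture = GeneticArchitecture(self.architecture)
        for name in ("tray_drift_sd", "measurement_noise_sd", "tic_scale_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.surface_kind not in ("planar", "complex"):
            raise ValueError(f"unknown surface kind {self.surface_kind!r}")

    # -- YAML round trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture"] = {k: asdict(v) for k, v in self.architecture.traits.items()}
        d["drift_ions"] = list(self.drift_ions)
        d.pop("templates", None)  # template set is code, not config
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "drift_ions" in d:
            d["drift_ions"] = tuple(d["drift_ions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# pedigree and field layout
# --------------------------------------------------------------------------
def build_pedigree(config: PedigreeConfig, seed: int | None = None) -> pd.DataFrame:
    """Genotype table (genotype_id, mother_id, father_id, is_parent).

    Every factorial cross appears with ``offspring_per_cross`` members;
    open-pollinated offspring carry a missing ``father_id``; parents carry
    both parent fields missing.  Deterministic (the seed is accepted for API
    symmetry only).
    """
    mothers = [f"M{i + 1}" for i in range(config.n_mothers)]
    fathers = [f"F{j + 1}" for j in range(config.n_fathers)]
    rows = []
    for m in mothers:
        for f in fathers:
            for k in range(config.offspring_per_cross):
                rows.append((m, f))
    op_counts = {m: config.n_open_pollinated_per_mother for m in mothers}
    if config.total_offspring is not None:
        diff = config.total_offspring - (len(rows) + sum(op_counts.values()))
        order = list(mothers)
        i = 0
        while diff != 0:
            m = order[i % len(order)]
            if diff > 0:
                op_counts[m] += 1
                diff -= 1
            else:
                if op_counts[m] > 0:
                    op_counts[m] -= 1
                    diff += 1
                elif all(v == 0 for v in op_counts.values()):
                    raise ValueError("cannot trim factorial offspring to total_offspring")
            i += 1
    for m in mothers:
        rows.extend((m, None) for _ in range(op_counts[m]))
    out = pd.DataFrame(rows, columns=["mother_id", "father_id"])
    out.insert(0, "genotype_id", [f"G{i + 1:04d}" for i in range(len(out))])
    out["is_parent"] = False
    if config.include_parents:
        parents = pd.DataFrame(
            {"genotype_id": mothers + fathers, "mother_id": None, "father_id": None,
             "is_parent": True}
        )
        out = pd.concat([out, parents], ignore_index=True)
    return out


def layout_trial(pedigree: pd.DataFrame, layout: FieldLayout, seed: int = 0) -> pd.DataFrame:
    """Randomized complete-block planting map with survival thinning.

    Blocks are contiguous bands of rows; each genotype appears once per block
    before uniform random survival thinning.  When the layout asks for a
    border, a double ring of extra ramets (recycled genotypes) surrounds the
    grid, flagged ``is_border`` and excluded from analysis tables downstream.
    """
    genotypes = list(pedigree["genotype_id"])
    n_g = len(genotypes)
    rows_per_block = np.full(layout.n_blocks, layout.n_rows // layout.n_blocks)
    rows_per_block[: layout.n_rows % layout.n_blocks] += 1
    if (rows_per_block.min() * layout.trees_per_row) < n_g:
        raise ValueError(
            f"block capacity {rows_per_block.min() * layout.trees_per_row} < {n_g} genotypes"
        )
    rng = np.random.default_rng(seed)
    records = []
    row_start = 0
    for b in range(layout.n_blocks):
        band = range(row_start, row_start + rows_per_block[b])
        row_start += rows_per_block[b]
        positions = [(r, p) for r in band for p in range(layout.trees_per_row)]
        order = rng.permutation(n_g)
        for slot, gi in zip(positions, order):
            r, p = slot
            records.append((f"{genotypes[gi]}_b{b + 1}", genotypes[gi], b + 1, r, p, False))
    if layout.include_border:
        border_slots = []
        for r in (-2, -1, layout.n_rows, layout.n_rows + 1):
            border_slots += [(r, p) for p in range(-2, layout.trees_per_row + 2)]
        for r in range(layout.n_rows):
            border_slots += [(r, p) for p in (-2, -1, layout.trees_per_row, layout.trees_per_row + 1)]
        recycle = rng.integers(0, n_g, size=len(border_slots))
        for i, ((r, p), gi) in enumerate(zip(border_slots, recycle)):
            records.append((f"BD{i + 1:04d}", genotypes[gi], 0, r, p, True))
    out = pd.DataFrame(
        records, columns=["ramet_id", "genotype_id", "block", "row", "position", "is_border"]
    )
    out["x_m"] = out["row"] * layout.row_spacing
    out["y_m"] = out["position"] * layout.tree_spacing
    out["alive"] = rng.random(len(out)) < layout.survival_rate
    return out.merge(pedigree[["genotype_id", "mother_id", "father_id"]], on="genotype_id", how="left")


# --------------------------------------------------------------------------
# genetic values and environment
# --------------------------------------------------------------------------
def simulate_genetic_values(
    pedigree: pd.DataFrame, arch: GeneticArchitecture, seed: int = 0
) -> pd.DataFrame:
    """Per-genotype trait deviations G = mother + father + SCA + Mendelian.

    Open-pollinated genotypes draw a fresh father effect per genotype
    (unknown pollen parent); parents draw all terms fresh, preserving the
    total genotypic variance.  Returns genotypes x traits deviations.
    """
    rng = np.random.default_rng(seed)
    mothers = sorted({m for m in pedigree["mother_id"].dropna()})
    fathers = sorted({f for f in pedigree["father_id"].dropna()})
    out = pd.DataFrame(index=pd.Index(pedigree["genotype_id"], name="genotype_id"))

    def _std_draws(n: int, var: float) -> np.ndarray:
        # With few levels (7 parents) raw draws realize the target variance
        # very loosely (chi-square, 6 df); standardize to mean 0 / exact var
        # so simulated populations hit the configured components.
        z = rng.normal(size=n)
        if n < 2 or var == 0.0 or z.std(ddof=1) == 0.0:
            return np.zeros(n)
        return (z - z.mean()) / z.std(ddof=1) * np.sqrt(var)

    for trait, tc in arch.traits.items():
        m_eff = dict(zip(mothers, _std_draws(len(mothers), tc.var_mother)))
        f_eff = dict(zip(fathers, _std_draws(len(fathers), tc.var_father)))
        cells = [(m, f) for m in mothers for f in fathers]
        sca = dict(zip(cells, _std_draws(len(cells), tc.var_sca)))
        is_offspring = pedigree["mother_id"].notna().to_numpy()
        mend = np.zeros(len(pedigree))
        mend[is_offspring] = _std_draws(int(is_offspring.sum()), tc.var_mendelian)
        vals = np.empty(len(pedigree))
        for i, (_, row) in enumerate(pedigree.iterrows()):
            m, f = row["mother_id"], row["father_id"]
            if pd.isna(m):  # founder parent: total-variance-preserving fresh draw
                g = rng.normal(0, np.sqrt(tc.var_genotypic)) if tc.var_genotypic > 0 else 0.0
            elif pd.isna(f):  # open pollinated: fresh father + SCA effect
                g = (
                    m_eff[m]
                    + rng.normal(0, np.sqrt(tc.var_father))
                    + rng.normal(0, np.sqrt(tc.var_sca))
                    + mend[i]
                )
            else:
                g = m_eff[m] + f_eff[f] + sca[(m, f)] + mend[i]
            vals[i] = g
        out[trait] = vals
    return out


def simulate_environment(
    layout_df: pd.DataFrame, kind: str, amplitude: float, seed: int = 0, n_bumps: int = 5
) -> pd.Series:
    """Smooth environmental surface value per planted position.

    ``planar`` is an affine trend; ``complex`` a sum of at most ``n_bumps``
    seeded Gaussian bumps (patchy soil-moisture-like variation).  The field
    is centered to mean zero over live interior positions and scaled so its
    range equals ``amplitude``; zero amplitude gives a constant surface.
    """
    if kind not in ("planar", "complex"):
        raise ValueError(f"unknown surface kind {kind!r}")
    rng = np.random.default_rng(seed)
    x = layout_df["x_m"].to_numpy(dtype=float)
    y = layout_df["y_m"].to_numpy(dtype=float)
    if kind == "planar":
        b, c = rng.normal(size=2)
        raw = b * x + c * y
    else:
        xr = (x.min(), x.max())
        yr = (y.min(), y.max())
        raw = np.zeros(len(x))
        for _ in range(n_bumps):
            cx = rng.uniform(*xr)
            cy = rng.uniform(*yr)
            sx = rng.uniform(0.15, 0.35) * (xr[1] - xr[0])
            sy = rng.uniform(0.15, 0.35) * (yr[1] - yr[0])
            a = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            raw += a * np.exp(-((x - cx) ** 2 / (2 * sx**2) + (y - cy) ** 2 / (2 * sy**2)))
    span = raw.max() - raw.min()
    if span == 0 or amplitude == 0:
        vals = np.zeros(len(x))
    else:
        vals = raw * (amplitude / span)
        if "is_border" in layout_df and "alive" in layout_df:
            mask = ((~layout_df["is_border"]) & layout_df["alive"]).to_numpy()
        else:
            mask = np.ones(len(x), dtype=bool)
        vals = vals - vals[mask].mean()
    return pd.Series(vals, index=layout_df["ramet_id"].to_numpy(), name="surface")


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------
def render_spectrum(
    composition: dict,
    templates: dict[str, ComponentTemplate],
    tray_offsets: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one TIC-scale spectrum from class fractions.

    ``spectrum = (sum_class fraction x template) * lognormal noise + tray
    offsets``, clipped to be nonnegative.  Noise is mean-one multiplicative
    lognormal per channel; tray offsets are additive on the normalized scale
    (instrumental drift on fragment ions).
    """
    clean = np.zeros(_N_CH)
    total = 0.0
    for name, frac in composition.items():
        if frac < 0:
            raise ValueError(f"negative fraction for {name}")
        if frac > 0:
            clean += frac * templates[name].vector
            total += frac
    if total <= 0:
        raise ValueError("composition fractions must sum to a positive value")
    out = clean
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        out = out * np.exp(rng.normal(-0.5 * noise_sd**2, noise_sd, _N_CH))
    if tray_offsets is not None:
        out = out + tray_offsets
    return np.clip(out, 0.0, None)


def _composition_from_latents(lig, sg, phen, c5, c6, acetyl) -> dict:
    """Map latent traits to the seven class fractions (baseline fills up)."""
    lig_tot = max(lig, 1.0) / TRUE_RESPONSE_FACTOR
    sg = max(sg, 0.05)
    comp = {
        "s_lignin": lig_tot * sg / (1.0 + sg),
        "g_lignin": lig_tot / (1.0 + sg),
        "phenolics": max(phen, 0.0),
        "c5_carbohydrate": max(c5, 0.0),
        "c6_carbohydrate": max(c6, 0.0),
        "acetyl": max(acetyl, 0.0),
    }
    base = 1.0 - sum(comp.values())
    if base <= 0:
        raise ValueError("latent fractions exceed 1; check architecture scale")
    comp["baseline"] = base
    return comp


def simulate_clonal_trait(
    sigma2_g: float,
    sigma2_e: float,
    pedigree: pd.DataFrame | None = None,
    layout: FieldLayout | None = None,
    seed: int = 0,
    mean: float = 0.0,
) -> pd.DataFrame:
    """One trait on the study design: genotype deviations plus ramet residuals.

    Convenience wrapper for heritability calibration studies: builds the
    default pedigree/layout (unless given), simulates genotype deviations
    with total genotypic variance ``sigma2_g`` (all Mendelian-sampling) and
    i.i.d. ramet residuals with variance ``sigma2_e``, and returns a frame
    with one row per live interior ramet: ``genotype_id, mother_id,
    father_id, row, position, x_m, y_m, value``.
    """
    root = np.random.SeedSequence(seed)
    s_lay, s_gen, s_res = root.spawn(3)
    if pedigree is None:
        pedigree = build_pedigree(PedigreeConfig())
    if layout is None:
        layout = FieldLayout()
    lay = layout_trial(pedigree, layout, seed=s_lay)
    arch = GeneticArchitecture(
        {"trait": TraitComponents(var_mendelian=sigma2_g, var_residual=sigma2_e)}
    )
    g = simulate_genetic_values(pedigree, arch, seed=s_gen)
    interior = lay[(~lay["is_border"]) & lay["alive"]].set_index("ramet_id")
    rng = np.random.default_rng(s_res)
    out = interior[["genotype_id", "mother_id", "father_id", "row", "position", "x_m", "y_m"]].copy()
    out["value"] = (
        mean
        + g.loc[out["genotype_id"], "trait"].to_numpy()
        + rng.normal(0.0, np.sqrt(sigma2_e), len(out))
    )
    return out


@dataclass
class SimulatedTrial:
    """Simulated dataset: raw spectra + metadata + ground-truth tables."""

    spectra: SpectraMatrix  #: raw (count-scale) spectra, samples + standards
    truth: dict  #: genetic_values, ramet_traits, surface, tray_offsets, standards, pedigree, layout
    config: SimulationConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spectra.write(out / "spectra.csv", out / "metadata.csv")
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        for name, df in self.truth.items():
            obj = df if isinstance(df, pd.DataFrame) else df.to_frame()
            obj.to_csv(tdir / f"{name}.csv")
        self.config.to_yaml(out / "config.yaml")


def simulate_trial(config: SimulationConfig) -> SimulatedTrial:
    """Simulate the full trial: spectra for every live ramet x technical
    replicate assigned to randomized trays, replicated standards, and the
    ground-truth effect tables needed for parameter-recovery tests."""
    root = np.random.SeedSequence(config.seed)
    s_ped, s_lay, s_gen, s_env, s_tray, s_assign, s_noise = root.spawn(7)

    pedigree = build_pedigree(config.pedigree)
    layout_df = layout_trial(pedigree, config.layout, seed=s_lay)
    gvals = simulate_genetic_values(pedigree, config.architecture, seed=s_gen)
    surface = simulate_environment(
        layout_df, config.surface_kind, config.surface_amplitude, seed=s_env
    )

    interior = layout_df[(~layout_df["is_border"]) & layout_df["alive"]].reset_index(drop=True)
    rng_tray = np.random.default_rng(s_tray)
    rng_assign = np.random.default_rng(s_assign)
    rng_noise = np.random.default_rng(s_noise)

    # latent per-ramet traits: genotype deviation + environment + biological residual
    traits = list(config.architecture.traits)
    ramet_traits = pd.DataFrame(index=pd.Index(interior["ramet_id"], name="ramet_id"))
    g_by_geno = gvals.loc[interior["genotype_id"]]
    surf = surface.loc[interior["ramet_id"]].to_numpy()
    for trait in traits:
        tc = config.architecture.traits[trait]
        ramet_traits[trait] = (
            tc.mean
            + g_by_geno[trait].to_numpy()
            + tc.env_loading * surf
            + rng_noise.normal(0, np.sqrt(tc.var_residual), len(interior))
        )

    # tray drift offsets on designated fragment ions
    drift_cols = [i for i in config.drift_ions]
    offsets = pd.DataFrame(
        rng_tray.normal(0.0, config.tray_drift_sd, size=(config.n_trays, len(drift_cols))),
        index=pd.Index(range(1, config.n_trays + 1), name="tray"),
        columns=drift_cols,
    )
    offset_vectors = np.zeros((config.n_trays, _N_CH))
    for j, mz in enumerate(drift_cols):
        offset_vectors[:, _CH_INDEX[mz]] = offsets.iloc[:, j]

    # vial assignment: technical replicates in randomized order, standards
    # spread evenly over trays
    runs = []
    for rep in range(1, config.technical_replicates + 1):
        order = rng_assign.permutation(len(interior))
        runs += [("sample", idx, rep) for idx in order]
    n_std = config.standard_replicates_total
    std_ids = default_standards().index.to_list()[: config.n_standards]
    std_per_tray = np.full(config.n_trays, n_std // config.n_trays)
    std_per_tray[: n_std % config.n_trays] += 1
    capacity = config.n_trays * config.vials_per_tray
    if len(runs) + n_std > capacity:
        raise ValueError(
            f"{len(runs)} sample runs + {n_std} standards exceed "
            f"{config.n_trays} x {config.vials_per_tray} vials"
        )

    standards_table = default_standards().iloc[: config.n_standards]
    std_cycle = 0
    run_iter = iter(runs)
    meta_rows, spectra_rows, sample_ids = [], [], []
    run_counter = std_counter = 0
    templates = config.templates if config.templates is not None else default_templates()
    for tray in range(1, config.n_trays + 1):
        n_std_here = int(std_per_tray[tray - 1])
        std_slots = (
            set(np.linspace(0, config.vials_per_tray - 1, n_std_here, dtype=int))
            if n_std_here
            else set()
        )
        for vial in range(config.vials_per_tray):
            if vial in std_slots:
                sid = std_ids[std_cycle % len(std_ids)]
                std_cycle += 1
                row = standards_table.loc[sid]
                comp = _composition_from_latents(
                    row["lignin_wt_pct"], row["s_g_ratio"], row["phenolics"],
                    row["c5"], row["c6"], row["acetyl"],
                )
                std_counter += 1
                sample_id = f"Q{std_counter:04d}"
                meta = dict(sample_id=sample_id, ramet_id=None, genotype_id=None,
                            mother_id=None, father_id=None, block=None, row=None,
                            position=None, x_m=None, y_m=None, tray=tray, vial=vial + 1,
                            replicate=0, is_standard=True, standard_id=sid)
            else:
                try:
                    _, idx, rep = next(run_iter)
                except StopIteration:
                    continue  # vial stays empty once sample runs are exhausted
                ram = interior.iloc[idx]
                lat = ramet_traits.loc[ram["ramet_id"]]
                comp = _composition_from_latents(
                    lat["lignin_wt_pct"], lat["s_g_ratio"], lat["phenolics"],
                    lat["c5"], lat["c6"], lat["acetyl"],
                )
                run_counter += 1
                sample_id = f"S{run_counter:06d}"
                meta = dict(sample_id=sample_id, ramet_id=ram["ramet_id"],
                            genotype_id=ram["genotype_id"], mother_id=ram["mother_id"],
                            father_id=ram["father_id"], block=ram["block"], row=ram["row"],
                            position=ram["position"], x_m=ram["x_m"], y_m=ram["y_m"],
                            tray=tray, vial=vial + 1, replicate=rep, is_standard=False,
                            standard_id=None)
            spec = render_spectrum(
                comp, templates, offset_vectors[tray - 1],
                config.measurement_noise_sd, rng_noise,
            )
            tic = config.tic_scale
            if config.tic_scale_sd > 0:
                tic *= np.exp(
                    rng_noise.normal(-0.5 * config.tic_scale_sd**2, config.tic_scale_sd)
                )
            meta_rows.append(meta)
            spectra_rows.append(spec * tic)
            sample_ids.append(sample_id)

    intensities = pd.DataFrame(
        np.vstack(spectra_rows), index=pd.Index(sample_ids, name="sample_id"),
        columns=list(ALL_CHANNELS),
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = SpectraMatrix(intensities, metadata)

    truth = {
        "pedigree": pedigree.set_index("genotype_id"),
        "layout": layout_df.set_index("ramet_id"),
        "genetic_values": gvals,
        "ramet_traits": ramet_traits,
        "surface": surface,
        "tray_offsets": offsets,
        "standards": standards_table,
    }
    return SimulatedTrial(spectra=matrix, truth=truth, config=config)
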