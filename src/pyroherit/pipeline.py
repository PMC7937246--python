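"""End-to-end analysis pipeline.

Fixed stage order (matching how the measurements are nested):

1. TIC normalization of all runs;
2. per-ion tray-effect estimation from the replicated standards (fallback
   tray-only model for trays without standards) and subtraction;
3. collapse of technical replicates to ramet means;
4. per-ion thin-plate-spline surfaces, Surface Complexity, and spatial
   correction of complex ions;
5. derived traits (lignin wt%%, S/G) computed from normalized spectra prior
   to any spectral correction, then tray- and TPS-corrected as scalar traits;
6. heritability with permutation thresholds (all traits/ions) and parental
   variance shares (traits by default);
7. multivariate exploration of genotype means of corrected ions.

The stage order cannot be reconfigured; all randomness derives from one
root seed, so a re-run with the same config reproduces identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp_mod
from . import spatial, traycorr
from .genetics import fit_parental_varcomp, heritability_table
from .io import SpectraMatrix, ramet_means, read_spectra, replicate_agreement, tic_normalize
from .ions import LIGNIN_IONS
from .multivariate import kmeans_partition, pca_nipals, spearman_complete_hclust, ward_sample_clusters
from .synth import SimulationConfig, simulate_trial

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "DEFAULT_ANALYSIS_IONS"]

#: Ions carried through the per-ion stages by default: the 17 lignin ions
#: plus diagnostic carbohydrate, phenolic, fragment and dimer channels.
DEFAULT_ANALYSIS_IONS = tuple(
    sorted(
        LIGNIN_IONS
        | {57, 60, 66, 73, 85, 94, 96, 98, 109, 114, 121, 126, 135, 151, 193, 272, 286, 302}
    )
)


@dataclass
class PipelineConfig:
    """Settings for one pipeline run."""

    simulate: SimulationConfig | None = None  #: simulate inline if set ...
    spectra_path: str | None = None  #: ... else read these files
    metadata_path: str | None = None
    analysis_ions: "tuple | str" = "default"  #: per-ion stages: tuple, "default" or "all"
    sc_threshold: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    parental: str = "traits"  #: "traits", "all" or "none"
    multivariate: bool = True
    n_pca_components: int = 7
    n_ion_clusters: int = 8
    n_sample_clusters: int = 7
    response_factor: float | None = None  #: fixed RF; else calibrated from standards
    standard_lignin_wt_pct: dict | None = None  #: known lignin %% per standard id
    seed: int = 0
    out_dir: str | None = None

    def resolve_ions(self, channels) -> list[int]:
        if self.analysis_ions == "all":
            return list(channels)
        if self.analysis_ions == "default":
            return [c for c in DEFAULT_ANALYSIS_IONS if c in set(channels)]
        return [int(c) for c in self.analysis_ions]


@dataclass
class PipelineResult:
    """All pipeline artifacts plus the JSON-able run report."""

    report: dict
    tray_effects: traycorr.TrayEffectTable
    sc_table: pd.DataFrame
    heritability: pd.DataFrame
    composition: pd.DataFrame
    corrected_ions: pd.DataFrame  #: ramet x ion values after tray+TPS correction
    corrected_traits: pd.DataFrame  #: ramet x {lignin_wt_pct, s_g_ratio} after corrections
    multivariate: dict = field(default_factory=dict)
    truth: dict | None = None  #: ground-truth tables when simulated inline


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full corrected-heritability analysis; see the module docstring."""
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0]) % (2**31)
             for name, s in zip(["sim", "perm", "mv"], ss.spawn(3))}
    report: dict = {"seed": config.seed, "stages": {}}

    # -- stage 0: data ---------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim_cfg = config.simulate
        trial = simulate_trial(sim_cfg)
        raw = trial.spectra
        truth = trial.truth
    elif config.spectra_path and config.metadata_path:
        raw = read_spectra(config.spectra_path, config.metadata_path)
    else:
        raise ValueError("config needs either simulate or spectra/metadata paths")
    report["stages"]["input"] = {"n_runs": raw.n_samples, "n_channels": len(raw.channels)}

    # -- stage 1: TIC normalization --------------------------------------
    norm = tic_normalize(raw)
    samples = norm.samples
    standards = norm.standards
    report["stages"]["normalize"] = {
        "n_samples": samples.n_samples,
        "n_standards": standards.n_samples,
        "n_trays": int(norm.metadata["tray"].nunique()),
    }

    # replicate-agreement QC on the uncorrected data
    try:
        agree = replicate_agreement(samples)
        report["stages"]["replicate_qc"] = {
            "n_ramets_both_replicates": agree.n_ramets,
            "median_pearson_r": float(agree.pearson_r.median()),
        }
    except ValueError:
        agree = None

    ions = config.resolve_ions(samples.channels)

    # -- stage 2: tray correction ----------------------------------------
    effects = traycorr.fit_tray_effects(standards, ions=ions)
    no_std_trays = sorted(set(samples.metadata["tray"].unique()) - set(effects.trays))
    if no_std_trays:
        fb = traycorr.fit_tray_effects_fallback(samples, no_std_trays, ions=ions)
        effects = effects.merge(fb)
    corrected = traycorr.apply_tray_correction(samples, effects, ions=ions)
    report["stages"]["tray_correction"] = {
        "n_ions": len(ions),
        "n_trays": len(effects.trays),
        "fallback_trays": no_std_trays,
    }

    # -- stage 3: replicate collapse -------------------------------------
    by_ramet = ramet_means(corrected, "ramet_id")
    meta_r = by_ramet.metadata
    report["stages"]["collapse"] = {"n_ramets": by_ramet.n_samples}

    # -- stage 4: per-ion TPS --------------------------------------------
    coords = meta_r[["x_m", "y_m"]].to_numpy(dtype=float)
    rows_lab = meta_r["row"].to_numpy()
    pos_lab = meta_r["position"].to_numpy(dtype=float)
    sc_rows = []
    ion_values = by_ramet.intensities[ions].copy()
    for ion in ions:
        vals = ion_values[ion].to_numpy()
        if np.std(vals) == 0.0:
            sc_rows.append({"ion": ion, "SC": 0.0, "lambda": np.nan, "edf": np.nan,
                            "residual_correlation": np.nan})
            continue
        res = spatial.fit_tps(vals, coords, ion=ion, rows=rows_lab, positions=pos_lab,
                              sc_threshold=config.sc_threshold)
        sc_rows.append({"ion": ion, "SC": res.sc, "lambda": res.lam, "edf": res.edf,
                        "residual_correlation": res.residual_correlation})
        if res.sc > config.sc_threshold:
            ion_values[ion] = spatial.tps_correct(vals, res)
    sc_table = spatial.classify_ions(pd.DataFrame(sc_rows).set_index("ion"),
                                     config.sc_threshold)
    report["stages"]["tps"] = {
        "n_simple": int((~sc_table["tps_corrected"]).sum()),
        "n_complex": int(sc_table["tps_corrected"].sum()),
    }

    # -- stage 5: derived traits -----------------------------------------
    # traits are computed from normalized spectra prior to any spectral
    # correction, then corrected at trait level (tray, then TPS)
    if config.response_factor is not None:
        rf = config.response_factor
    elif config.standard_lignin_wt_pct:
        known = [config.standard_lignin_wt_pct[s] for s in standards.metadata["standard_id"]]
        rf = comp_mod.calibrate_response_factor(standards, known)
    else:
        rf = 200.0  # default instrument response factor
    comp_samples = comp_mod.composition_table(samples, rf=rf)
    comp_standards = comp_mod.composition_table(standards, rf=rf)
    trait_cols = ["lignin_wt_pct", "s_g_ratio"]
    trait_tray_tables = {}
    trait_ramet = {}
    for col in trait_cols:
        corrected_trait, table = traycorr.correct_trait(
            comp_samples[col], samples.metadata["tray"],
            comp_standards[col], standards.metadata["tray"],
            standards.metadata["standard_id"],
        )
        trait_tray_tables[col] = table
        trait_ramet[col] = corrected_trait.groupby(samples.metadata["ramet_id"]).mean()
    traits_df = pd.DataFrame(trait_ramet).loc[meta_r.index.intersection(trait_ramet[trait_cols[0]].index)]
    traits_df = traits_df.reindex(by_ramet.sample_ids)
    trait_sc = {}
    for col in trait_cols:
        vals = traits_df[col].to_numpy()
        res = spatial.fit_tps(vals, coords, ion=col, rows=rows_lab, positions=pos_lab,
                              sc_threshold=config.sc_threshold)
        trait_sc[col] = {"SC": res.sc, "class": res.sc_class}
        if res.sc > config.sc_threshold:
            traits_df[col] = spatial.tps_correct(vals, res)
    report["stages"]["traits"] = {
        "response_factor": rf,
        "lignin_mean_wt_pct": float(traits_df["lignin_wt_pct"].mean()),
        "lignin_sd_wt_pct": float(traits_df["lignin_wt_pct"].std()),
        "lignin_range": [float(traits_df["lignin_wt_pct"].min()),
                         float(traits_df["lignin_wt_pct"].max())],
        "s_g_mean": float(traits_df["s_g_ratio"].mean()),
        "s_g_sd": float(traits_df["s_g_ratio"].std()),
        "s_g_range": [float(traits_df["s_g_ratio"].min()),
                      float(traits_df["s_g_ratio"].max())],
        "surface_complexity": trait_sc,
    }

    # -- stage 6: heritability -------------------------------------------
    geno = meta_r["genotype_id"]
    mother = meta_r["mother_id"] if "mother_id" in meta_r else None
    father = meta_r["father_id"] if "father_id" in meta_r else None
    all_values = pd.concat([traits_df, ion_values], axis=1)
    all_values.columns = [str(c) for c in all_values.columns]
    parental_cols: "bool | list"
    if config.parental == "all":
        parental_cols = True
    elif config.parental == "traits":
        parental_cols = trait_cols
    else:
        parental_cols = []
    herit = heritability_table(
        all_values, geno.to_numpy(),
        mother=None if mother is None else mother.to_numpy(),
        father=None if father is None else father.to_numpy(),
        n_perm=config.n_perm, alpha=config.alpha, seed=seeds["perm"],
        parental=parental_cols,
    )
    report["stages"]["heritability"] = {
        "n_traits": len(herit),
        "n_significant": int(herit.get("significant", pd.Series(dtype=bool)).fillna(False).sum()),
        "perm_threshold_range": [float(herit["perm_threshold"].min()),
                                 float(herit["perm_threshold"].max())],
        "traits": {
            c: {
                "H2": float(herit.loc[c, "H2"]),
                "perm_threshold": float(herit.loc[c, "perm_threshold"]),
                "p": float(herit.loc[c, "p"]),
                **(
                    {"maternal_share": float(herit.loc[c, "maternal_share"]),
                     "paternal_share": float(herit.loc[c, "paternal_share"])}
                    if "maternal_share" in herit.columns
                    and pd.notna(herit.loc[c].get("maternal_share"))
                    else {}
                ),
            }
            for c in trait_cols
        },
    }

    # -- stage 7: multivariate -------------------------------------------
    mv: dict = {}
    if config.multivariate:
        geno_means = ion_values.groupby(geno).mean()
        active = geno_means.loc[:, geno_means.std(axis=0) > 0]
        n_comp = min(config.n_pca_components, min(active.shape) - 1)
        pca = pca_nipals(active, n_comp)
        ion_clusters = spearman_complete_hclust(active, config.n_ion_clusters)
        sample_clusters = ward_sample_clusters(active, config.n_sample_clusters)
        km = kmeans_partition(active, config.n_sample_clusters, seed=seeds["mv"])
        mv = {"pca": pca, "ion_clusters": ion_clusters,
              "sample_clusters": sample_clusters, "kmeans": km}
        report["stages"]["multivariate"] = {
            "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
            "n_ion_clusters": int(ion_clusters.k),
            "n_sample_clusters": int(sample_clusters.k),
        }

    report = _jsonable(report)
    result = PipelineResult(
        report=report, tray_effects=effects, sc_table=sc_table, heritability=herit,
        composition=comp_samples, corrected_ions=ion_values, corrected_traits=traits_df,
        multivariate=mv, truth=truth,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True))
    result.tray_effects.to_frame().to_csv(out / "tray_effects.csv", index=False)
    result.sc_table.to_csv(out / "sc_table.csv")
    result.heritability.to_csv(out / "heritability.csv")
    result.composition.to_csv(out / "composition.csv")
    result.corrected_traits.to_csv(out / "corrected_traits.csv")
    if result.multivariate:
        result.multivariate["pca"].scores.to_csv(out / "pca_scores.csv")
        result.multivariate["pca"].loadings.to_csv(out / "pca_loadings.csv")
        clusters = pd.DataFrame({
            "ion_cluster": result.multivariate["ion_clusters"].labels,
        })
        clusters.to_csv(out / "ion_clusters.csv")
        pd.DataFrame({
            "ward_cluster": result.multivariate["sample_clusters"].labels,
            "kmeans_cluster": result.multivariate["kmeans"].labels,
        }).to_csv(out / "sample_clusters.csv")
    (out / "report.md").write_text(_report_markdown(result.report))


def _report_markdown(report: dict) -> str:
    s = report["stages"]
    t = s["traits"]
    lines = [
        "# Pipeline run report",
        "",
        f"- runs: {s['input']['n_runs']} ({s['normalize']['n_samples']} samples, "
        f"{s['normalize']['n_standards']} standards, {s['normalize']['n_trays']} trays)",
        f"- ramets after replicate collapse: {s['collapse']['n_ramets']}",
        f"- tray-corrected ions: {s['tray_correction']['n_ions']}",
        f"- TPS: {s['tps']['n_simple']} simple, {s['tps']['n_complex']} complex ions",
        "",
        "## Cell-wall traits (corrected)",
        f"- lignin: {t['lignin_mean_wt_pct']:.2f} +/- {t['lignin_sd_wt_pct']:.2f} wt%",
        f"- S/G: {t['s_g_mean']:.3f} +/- {t['s_g_sd']:.3f}",
        "",
        "## Heritability",
    ]
    for name, row in s["heritability"]["traits"].items():
        extra = ""
        if "maternal_share" in row:
            extra = (f", maternal {row['maternal_share']:.2f} / "
                     f"paternal {row['paternal_share']:.2f}")
        lines.append(
            f"- {name}: H2 = {row['H2']:.3f} (threshold {row['perm_threshold']:.3f}, "
            f"p = {row['p']:.3g}{extra})"
        )
    tr = s["heritability"]["perm_threshold_range"]
    lines.append(f"- permutation thresholds across traits: {tr[0]:.3f} - {tr[1]:.3f}")
    return "\n".join(lines) + "\n"
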