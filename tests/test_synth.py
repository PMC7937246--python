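import numpy as np
import pandas as pd
import pytest

from pyroherit.ions import ALL_CHANNELS, G_IONS, S_IONS
from pyroherit.synth import (
    FieldLayout,
    GeneticArchitecture,
    PedigreeConfig,
    SimulationConfig,
    TraitComponents,
    build_pedigree,
    default_templates,
    layout_trial,
    render_spectrum,
    simulate_environment,
    simulate_genetic_values,
    simulate_trial,
)

S_IDX = [i for i, c in enumerate(ALL_CHANNELS) if c in S_IONS]
G_IDX = [i for i, c in enumerate(ALL_CHANNELS) if c in G_IONS]


class TestPedigree:
    def test_uniform_design_arithmetic(self):
        ped = build_pedigree(
            PedigreeConfig(offspring_per_cross=20, n_open_pollinated_per_mother=2,
                           total_offspring=None)
        )
        assert len(ped) == 7 * 7 * 20 + 7 * 2 + 14

    def test_minimal_design(self):
        ped = build_pedigree(
            PedigreeConfig(n_mothers=1, n_fathers=1, offspring_per_cross=1,
                           n_open_pollinated_per_mother=0, include_parents=False,
                           total_offspring=None)
        )
        assert len(ped) == 1
        assert ped.iloc[0]["mother_id"] == "M1" and ped.iloc[0]["father_id"] == "F1"

    def test_study_scale_totals(self):
        ped = build_pedigree(PedigreeConfig())
        assert len(ped) == 1000
        assert (~ped["is_parent"]).sum() == 986

    def test_every_cross_appears_and_op_father_missing(self):
        ped = build_pedigree(PedigreeConfig())
        fullsib = ped.dropna(subset=["father_id"])
        crosses = fullsib.groupby(["mother_id", "father_id"]).size()
        assert len(crosses) == 49 and (crosses > 0).all()
        op = ped[ped["mother_id"].notna() & ped["father_id"].isna()]
        assert len(op) == 986 - 49 * 19
        parents = ped[ped["is_parent"]]
        assert parents["mother_id"].isna().all() and parents["father_id"].isna().all()

    def test_zero_offspring_rejected(self):
        with pytest.raises(ValueError):
            PedigreeConfig(offspring_per_cross=0)


class TestLayout:
    def test_full_survival_count(self):
        ped = build_pedigree(PedigreeConfig())
        lay = layout_trial(ped, FieldLayout(survival_rate=1.0, include_border=False), seed=0)
        assert len(lay) == 3000 and lay["alive"].all()

    def test_each_genotype_once_per_block(self):
        ped = build_pedigree(PedigreeConfig())
        lay = layout_trial(ped, FieldLayout(include_border=False), seed=1)
        counts = lay.groupby(["block", "genotype_id"]).size()
        assert (counts == 1).all()

    def test_blocks_are_contiguous_row_bands(self):
        ped = build_pedigree(PedigreeConfig())
        lay = layout_trial(ped, FieldLayout(include_border=False), seed=1)
        spans = lay.groupby("block")["row"].agg(["min", "max"])
        spans = spans.sort_values("min")
        prev_max = -1
        for _, r in spans.iterrows():
            assert r["min"] == prev_max + 1
            prev_max = r["max"]

    def test_survival_thinning_seeded_and_near_rate(self):
        ped = build_pedigree(PedigreeConfig())
        lay1 = layout_trial(ped, FieldLayout(), seed=42)
        lay2 = layout_trial(ped, FieldLayout(), seed=42)
        pd.testing.assert_frame_equal(lay1, lay2)
        interior = lay1[~lay1["is_border"]]
        assert abs(interior["alive"].mean() - 0.907) < 0.02

    def test_capacity_error(self):
        ped = build_pedigree(PedigreeConfig())
        with pytest.raises(ValueError, match="capacity"):
            layout_trial(ped, FieldLayout(n_rows=6, trees_per_row=10), seed=0)

    def test_border_flagged_and_metric_coordinates(self):
        ped = build_pedigree(PedigreeConfig())
        lay = layout_trial(ped, FieldLayout(), seed=0)
        assert lay["is_border"].any()
        interior = lay[~lay["is_border"]]
        assert np.allclose(interior["x_m"], interior["row"] * 3.0)
        assert np.allclose(interior["y_m"], interior["position"] * 1.0)


class TestGeneticValues:
    def test_all_zero_variances_give_zero_deviations(self):
        ped = build_pedigree(PedigreeConfig())
        g = simulate_genetic_values(ped, GeneticArchitecture({"t": TraitComponents()}), seed=0)
        assert np.allclose(g["t"], 0.0)

    def test_maternal_twice_paternal_variance(self):
        ped = build_pedigree(PedigreeConfig())
        arch = GeneticArchitecture({"t": TraitComponents(var_mother=2.0, var_father=1.0)})
        g = simulate_genetic_values(ped, arch, seed=1)
        fullsib = ped[ped["father_id"].notna() & ~ped["is_parent"]]
        fam = g.loc[fullsib["genotype_id"]].join(fullsib.set_index("genotype_id"))
        m_eff = fam.groupby("mother_id")["t"].mean()
        # paternal means within mother bands: remove maternal mean first
        resid = fam["t"] - m_eff.loc[fam["mother_id"]].to_numpy()
        f_eff = resid.groupby(fam["father_id"]).mean()
        ratio = m_eff.var(ddof=1) / f_eff.var(ddof=1)
        assert 1.5 < ratio < 2.7  # target 2, tolerance from 6-df chi-square spread

    def test_variance_bookkeeping_within_3se(self):
        ped = build_pedigree(PedigreeConfig())
        tc = TraitComponents(var_mother=0.3, var_father=0.2, var_sca=0.1, var_mendelian=0.4)
        g = simulate_genetic_values(ped, GeneticArchitecture({"t": tc}), seed=9)
        offspring = ped[~ped["is_parent"]]["genotype_id"]
        realized = g.loc[offspring, "t"].var(ddof=1)
        target = tc.var_genotypic
        se = target * np.sqrt(2.0 / (len(offspring) - 1))
        assert abs(realized - target) < 3 * se


@pytest.fixture(scope="module")
def layout_df():
    ped = build_pedigree(PedigreeConfig())
    return layout_trial(ped, FieldLayout(), seed=0)


class TestEnvironment:

    def test_zero_amplitude_constant(self, layout_df):
        s = simulate_environment(layout_df, "complex", 0.0, seed=0)
        assert np.allclose(s, 0.0)

    def test_range_scaled_to_amplitude(self, layout_df):
        s = simulate_environment(layout_df, "complex", 2.5, seed=1)
        assert np.isclose(s.max() - s.min(), 2.5)

    def test_planar_is_affine_in_coordinates(self, layout_df):
        s = simulate_environment(layout_df, "planar", 1.0, seed=2)
        X = np.column_stack([np.ones(len(layout_df)), layout_df["x_m"], layout_df["y_m"]])
        beta, *_ = np.linalg.lstsq(X, s.to_numpy(), rcond=None)
        assert np.allclose(X @ beta, s.to_numpy(), atol=1e-10)

    def test_unknown_kind_rejected(self, layout_df):
        with pytest.raises(ValueError, match="kind"):
            simulate_environment(layout_df, "fractal", 1.0, seed=0)

    def test_seed_determinism(self, layout_df):
        a = simulate_environment(layout_df, "complex", 1.0, seed=5)
        b = simulate_environment(layout_df, "complex", 1.0, seed=5)
        pd.testing.assert_series_equal(a, b)


class TestRenderSpectrum:
    def test_pure_s_lignin_supported_on_s_channels_only(self):
        tmpl = default_templates()
        spec = render_spectrum({"s_lignin": 1.0}, tmpl)
        on = spec[S_IDX].sum()
        assert np.isclose(on, 1.0) and np.isclose(spec.sum(), 1.0)

    def test_noiseless_sg_ratio_matches_composition(self):
        tmpl = default_templates()
        comp = {"s_lignin": 0.084, "g_lignin": 0.040, "baseline": 0.876}
        spec = render_spectrum(comp, tmpl)
        spec = spec / spec.sum()
        assert np.isclose(spec[S_IDX].sum() / spec[G_IDX].sum(), 0.084 / 0.040)

    def test_same_seed_identical(self):
        tmpl = default_templates()
        comp = {"s_lignin": 0.1, "baseline": 0.9}
        a = render_spectrum(comp, tmpl, None, 0.05, np.random.default_rng(7))
        b = render_spectrum(comp, tmpl, None, 0.05, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            render_spectrum({"s_lignin": -0.1}, default_templates())


class TestSimulateTrial:
    def test_study_scale_counts(self, study_trial):
        meta = study_trial.spectra.metadata
        n_samples = int((~meta["is_standard"]).sum())
        n_standards = int(meta["is_standard"].sum())
        assert abs(n_samples - 5440) < 60  # 2 runs x ~2721 live ramets
        assert n_standards == 509
        assert meta["tray"].nunique() == 125

    def test_tiny_trial_run_count(self):
        cfg = SimulationConfig(
            pedigree=PedigreeConfig(n_mothers=2, n_fathers=5, offspring_per_cross=1,
                                    n_open_pollinated_per_mother=0, include_parents=False,
                                    total_offspring=None),
            layout=FieldLayout(n_rows=1, trees_per_row=10, n_blocks=1, survival_rate=1.0),
            technical_replicates=1, n_trays=1, standard_replicates_total=6, seed=0,
        )
        trial = simulate_trial(cfg)
        meta = trial.spectra.metadata
        assert int((~meta["is_standard"]).sum()) == 10

    def test_zero_drift_zero_noise_standards_identical(self):
        from conftest import tiny_config

        trial = simulate_trial(
            tiny_config(seed=5, tray_drift_sd=0.0, measurement_noise_sd=0.0, tic_scale_sd=0.0)
        )
        stds = trial.spectra.standards
        for sid, group in stds.intensities.groupby(stds.metadata["standard_id"]):
            arr = group.to_numpy()
            assert np.abs(arr - arr[0][None, :]).max() < 1e-12

    def test_seed_determinism_byte_identical(self):
        from conftest import tiny_config

        a = simulate_trial(tiny_config(seed=11))
        b = simulate_trial(tiny_config(seed=11))
        pd.testing.assert_frame_equal(a.spectra.intensities, b.spectra.intensities)
        pd.testing.assert_frame_equal(a.spectra.metadata, b.spectra.metadata)
        for key in a.truth:
            pd.testing.assert_frame_equal(
                pd.DataFrame(a.truth[key]), pd.DataFrame(b.truth[key])
            )

    def test_standards_never_thinned_and_border_never_measured(self, tiny_trial):
        meta = tiny_trial.spectra.metadata
        assert meta["is_standard"].sum() == 30
        measured = meta.loc[~meta["is_standard"], "ramet_id"]
        layout = tiny_trial.truth["layout"]
        assert not layout.loc[measured.unique(), "is_border"].any()
        assert layout.loc[measured.unique(), "alive"].all()
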