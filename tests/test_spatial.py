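import numpy as np
import pandas as pd
import pytest

from pyroherit.spatial import (
    ThinPlateSpline,
    classify_ions,
    fit_tps,
    surface_complexity,
    tps_correct,
)
from pyroherit.synth import FieldLayout, PedigreeConfig, build_pedigree, layout_trial, simulate_environment


def _complex_surface(coords, seed=0, amplitude=2.0):
    """Seeded Gaussian-bump field used as the complex-surface fixture."""
    rng = np.random.default_rng(seed)
    x, y = coords[:, 0], coords[:, 1]
    raw = np.zeros(len(coords))
    for _ in range(4):
        cx = rng.uniform(x.min(), x.max())
        cy = rng.uniform(y.min(), y.max())
        sx = rng.uniform(0.15, 0.3) * (x.max() - x.min())
        sy = rng.uniform(0.15, 0.3) * (y.max() - y.min())
        raw += rng.choice([-1, 1]) * np.exp(-((x - cx) ** 2 / (2 * sx**2) + (y - cy) ** 2 / (2 * sy**2)))
    return (raw - raw.min()) / (raw.max() - raw.min()) * amplitude


class TestFitTps:
    def test_constant_values_flat_fit(self, grid_30x100):
        _, _, coords = grid_30x100
        res = fit_tps(np.full(len(coords), 3.7), coords, max_knots=100)
        np.testing.assert_allclose(res.fitted, 3.7, atol=1e-8)
        np.testing.assert_allclose(res.residual, 0.0, atol=1e-8)

    def test_noiseless_plane_reproduced_exactly(self, grid_30x100):
        _, _, coords = grid_30x100
        z = 1.0 + 0.2 * coords[:, 0] - 0.1 * coords[:, 1]
        res = fit_tps(z, coords, max_knots=100)
        np.testing.assert_allclose(res.fitted, z, atol=1e-8)

    def test_lambda_inf_limit_is_least_squares_plane(self, grid_30x100):
        _, _, coords = grid_30x100
        rng = np.random.default_rng(4)
        z = 0.5 * coords[:, 0] + rng.normal(0, 1, len(coords))
        res = fit_tps(z, coords, lam=1e12, max_knots=100)
        X = np.column_stack([np.ones(len(z)), coords])
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        np.testing.assert_allclose(res.fitted, X @ beta, atol=1e-6)

    def test_bump_surface_recovered_under_noise(self, grid_30x100):
        """Gaussian-bump truth + noise at sd = amplitude/4: the GCV fit must
        correlate strongly with the true surface at the trial's scale."""
        _, _, coords = grid_30x100
        rng = np.random.default_rng(8)
        keep = rng.random(len(coords)) < 0.907  # ~2721 live positions
        truth = _complex_surface(coords, seed=1)
        z = truth + rng.normal(0, 0.5, len(coords))
        res = fit_tps(z[keep], coords[keep])
        assert np.corrcoef(res.fitted, truth[keep])[0, 1] > 0.9

    def test_too_few_positions_rejected(self):
        coords = np.array([[0.0, i] for i in range(5)])
        with pytest.raises(ValueError):
            ThinPlateSpline(np.arange(5.0), coords)

    def test_collinear_layout_rejected(self):
        coords = np.column_stack([np.zeros(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            ThinPlateSpline(np.arange(20.0), coords)

    def test_interpolation_limit_with_full_knots(self):
        rng = np.random.default_rng(0)
        coords = rng.random((40, 2)) * 10
        z = rng.normal(size=40)
        res = fit_tps(z, coords, lam=1e-12)
        np.testing.assert_allclose(res.fitted, z, atol=1e-4)


class TestSurfaceComplexity:
    def test_within_row_linear_gives_zero(self, grid_30x100):
        rows, pos, _ = grid_30x100
        yhat = 0.5 + 0.3 * pos + 0.05 * rows  # linear in position within every row
        assert surface_complexity(yhat, rows, pos) < 1e-9

    def test_constructed_cor_point_one_gives_thirty(self, grid_30x100):
        rows, pos, _ = grid_30x100
        n = 100
        t = np.arange(n, dtype=float)
        tc = (t - t.mean()) / np.linalg.norm(t - t.mean())
        rng = np.random.default_rng(3)
        g = rng.normal(size=n)
        g -= g.mean()
        g -= (g @ tc) * tc
        g /= np.linalg.norm(g)
        row_profile = 0.1 * tc + np.sqrt(1 - 0.01) * g  # |cor with t| = 0.1 exactly
        yhat = np.tile(row_profile, 30)
        assert abs(surface_complexity(yhat, rows, pos) - 30.0) < 1e-6

    def test_complex_fixture_exceeds_one(self, grid_30x100):
        rows, pos, coords = grid_30x100
        yhat = _complex_surface(coords, seed=2)
        assert surface_complexity(yhat, rows, pos) > 1.0

    def test_affine_invariance(self, grid_30x100):
        rows, pos, coords = grid_30x100
        yhat = _complex_surface(coords, seed=5)
        a = surface_complexity(yhat, rows, pos)
        b = surface_complexity(3.2 * yhat - 17.0, rows, pos)
        assert np.isclose(a, b)

    def test_affine_invariance_property(self, grid_30x100):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        rows, pos, coords = grid_30x100
        yhat = _complex_surface(coords, seed=15)
        base = surface_complexity(yhat, rows, pos)

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(a=st.floats(0.01, 100), b=st.floats(-50, 50),
               sign=st.sampled_from([-1.0, 1.0]))
        def check(a, b, sign):
            assert np.isclose(surface_complexity(sign * a * yhat + b, rows, pos), base)

        check()

    def test_monotone_in_bump_amplitude(self, grid_30x100):
        """Mixing a linear ramp with increasing bump weight makes within-row
        profiles less monotone, so SC must increase along the family."""
        rows, pos, coords = grid_30x100
        ramp = 0.01 * pos
        bump = _complex_surface(coords, seed=6)
        bump = bump - bump.mean()
        sc = [
            surface_complexity(ramp + w * bump, rows, pos)
            for w in (0.0, 0.02, 0.1, 0.5)
        ]
        assert all(b > a for a, b in zip(sc, sc[1:]))

    def test_short_or_flat_rows_contribute_nothing(self):
        rows = np.array([0, 0, 0, 1, 1])
        pos = np.array([0.0, 1.0, 2.0, 0.0, 1.0])
        yhat = np.array([1.0, 2.0, 3.0, 5.0, 9.0])  # row 1 too short
        assert surface_complexity(yhat, rows, pos) < 1e-9
        flat = np.array([1.0, 1.0, 1.0, 5.0, 9.0])  # row 0 zero variance
        assert surface_complexity(flat, rows, pos) < 1e-9

    def test_no_usable_rows_is_an_error(self):
        with pytest.raises(ValueError, match="usable"):
            surface_complexity([1.0, 2.0], [0, 1], [0.0, 0.0])


class TestTpsCorrect:
    def test_zero_residuals_give_constant_mean(self, grid_30x100):
        _, _, coords = grid_30x100
        z = 1.0 + 0.2 * coords[:, 0]
        res = fit_tps(z, coords, max_knots=100)
        corrected = tps_correct(z, res)
        np.testing.assert_allclose(corrected, z.mean(), atol=1e-8)

    def test_mean_preserved_and_surface_removed(self, grid_30x100):
        rows, pos, coords = grid_30x100
        rng = np.random.default_rng(12)
        truth = _complex_surface(coords, seed=7)
        z = truth + rng.normal(0, 0.5, len(coords))
        res = fit_tps(z, coords)
        corrected = tps_correct(z, res)
        assert abs(corrected.mean() - z.mean()) < 1e-8
        assert abs(np.corrcoef(corrected, truth)[0, 1]) < 0.1

    def test_refit_of_corrected_values_is_near_flat(self, grid_30x100):
        rows, pos, coords = grid_30x100
        rng = np.random.default_rng(13)
        z = _complex_surface(coords, seed=9) + rng.normal(0, 0.3, len(coords))
        corrected = tps_correct(z, fit_tps(z, coords))
        refit = fit_tps(corrected, coords)
        assert refit.edf < 10  # close to the 3-df affine null space

    def test_length_mismatch_rejected(self, grid_30x100):
        _, _, coords = grid_30x100
        res = fit_tps(coords[:, 0], coords, max_knots=100)
        with pytest.raises(ValueError, match="length"):
            tps_correct(np.zeros(5), res)


class TestClassifyIons:
    def test_threshold_partition(self):
        table = pd.DataFrame({"SC": [0.0, 0.5, 1.0, 1.5, 30.0]}, index=[30, 31, 32, 33, 34])
        out = classify_ions(table, threshold=1.0)
        assert list(out["sc_class"]) == ["simple", "simple", "simple", "complex", "complex"]

    def test_infinite_threshold_corrects_nothing(self):
        table = pd.DataFrame({"SC": [0.0, 300.0]}, index=[30, 31])
        out = classify_ions(table, threshold=np.inf)
        assert not out["tps_corrected"].any()

    def test_environment_loaded_vs_flat_ions_partition(self):
        """Ions carrying the field surface get SC > 1; pure-noise ions get
        SC ~ 0: the classification must match truth with <= 1 mistake."""
        ped = build_pedigree(PedigreeConfig())
        lay = layout_trial(ped, FieldLayout(include_border=False), seed=3)
        live = lay[lay["alive"]]
        coords = live[["x_m", "y_m"]].to_numpy()
        rows_lab = live["row"].to_numpy()
        pos_lab = live["position"].to_numpy(float)
        surface = simulate_environment(lay, "complex", 2.0, seed=4).loc[live["ramet_id"]].to_numpy()
        rng = np.random.default_rng(99)
        records = []
        for i in range(10):  # environment-loaded ions
            z = surface + rng.normal(0, 0.5, len(live))
            res = fit_tps(z, coords, rows=rows_lab, positions=pos_lab)
            records.append(("loaded", res.sc))
        for i in range(10):  # flat ions
            z = rng.normal(0, 0.5, len(live))
            res = fit_tps(z, coords, rows=rows_lab, positions=pos_lab)
            records.append(("flat", res.sc))
        wrong = sum(
            (kind == "loaded") != (sc > 1.0) for kind, sc in records
        )
        assert wrong <= 1
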