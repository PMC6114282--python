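import datetime as dt

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from premolt.habitat_kselect import (
    GridSpec,
    HabitatConfig,
    composite_layers,
    current_speed,
    derive_slope,
    destination_window_points,
    extract_used_available,
    kselect,
    resample_to_grid,
)
from premolt.synthetic_data import simulate_env

GRID = GridSpec(center=(168.188, -44.188), cell_km=57.4, nx=40, ny=40,
                x0_km=-1200, y0_km=-1200)


def layer(values, xs=None, ys=None):
    values = np.asarray(values, float)
    ny, nx = values.shape
    return xr.DataArray(
        values,
        coords={
            "y": ys if ys is not None else np.arange(ny, dtype=float),
            "x": xs if xs is not None else np.arange(nx, dtype=float),
        },
        dims=("y", "x"),
    )


class TestCompositing:
    def test_identical_layers_unchanged(self):
        a = layer(np.random.default_rng(0).normal(size=(5, 5)))
        out = composite_layers([a, a.copy(), a.copy()])
        np.testing.assert_allclose(out, a)

    def test_seven_layer_mean(self):
        rng = np.random.default_rng(1)
        layers = [layer(rng.normal(size=(6, 6))) for _ in range(7)]
        out = composite_layers(layers)
        np.testing.assert_allclose(
            out, np.mean([np.asarray(l) for l in layers], axis=0)
        )

    def test_masked_cells_ignored(self):
        vals = [np.ones((3, 3)), np.full((3, 3), 3.0), np.full((3, 3), 5.0)]
        vals[2][1, 1] = np.nan
        out = composite_layers([layer(v) for v in vals])
        assert float(out[1, 1]) == pytest.approx(2.0)  # mean of 1 and 3
        assert float(out[0, 0]) == pytest.approx(3.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            composite_layers([])


class TestSlope:
    def test_constant_depth_zero_slope(self):
        out = derive_slope(layer(np.full((6, 6), -4000.0)), cell_km=57.4)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_planar_ramp_exact(self):
        cell = 10.0
        x = np.arange(8) * cell
        z = np.tile(10.0 * x, (8, 1))  # 10 m per km eastward
        out = derive_slope(layer(z), cell_km=cell)
        np.testing.assert_allclose(np.asarray(out)[1:-1, 1:-1], 10.0, atol=1e-6)

    def test_seamount_flanks_steepest(self):
        n, cell = 21, 10.0
        yy, xx = np.mgrid[0:n, 0:n] * cell
        c = (n // 2) * cell
        z = -4000 + 3000 * np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * 40.0**2))
        out = np.asarray(derive_slope(layer(z), cell_km=cell))
        assert out[n // 2, n // 2] == pytest.approx(0.0, abs=1e-6)
        assert out.max() > 10 * out[n // 2, n // 2 + 1] or out.max() > 1.0

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            derive_slope(layer(np.zeros((2, 5))), cell_km=1.0)


class TestCurrentSpeed:
    def test_pythagoras(self):
        u, v = layer(np.full((4, 4), 3.0)), layer(np.full((4, 4), 4.0))
        np.testing.assert_allclose(current_speed(u, v), 5.0)

    def test_zero_v_gives_abs_u(self):
        u = layer(np.array([[-2.0, 1.0], [0.5, -0.25]]))
        np.testing.assert_allclose(
            current_speed(u, layer(np.zeros((2, 2)))), np.abs(np.asarray(u))
        )

    def test_random_fields_norm_oracle(self):
        rng = np.random.default_rng(2)
        u, v = rng.normal(size=(5, 5)), rng.normal(size=(5, 5))
        np.testing.assert_allclose(
            current_speed(layer(u), layer(v)), np.hypot(u, v)
        )

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            current_speed(layer(np.zeros((3, 3))), layer(np.zeros((4, 4))))


class TestResample:
    def test_constant_preserved(self):
        native = layer(np.full((30, 30), 7.5),
                       xs=np.linspace(-1300, 1300, 30),
                       ys=np.linspace(-1300, 1300, 30))
        out = resample_to_grid({"SST": native}, GRID, "bilinear")
        np.testing.assert_allclose(out["SST"], 7.5)

    def test_linear_gradient_preserved_bilinear(self):
        xs = np.linspace(-1400, 1400, 60)
        ys = np.linspace(-1400, 1400, 60)
        native = layer(np.add.outer(0.01 * ys, 0.02 * xs), xs=xs, ys=ys)
        out = resample_to_grid({"SST": native}, GRID, "bilinear")
        gx, gy = np.meshgrid(GRID.x_centers, GRID.y_centers)
        expected = 0.01 * gy + 0.02 * gx
        rng_span = expected.max() - expected.min()
        assert np.nanmax(np.abs(np.asarray(out["SST"]) - expected)) < 1e-6 * rng_span

    def test_nearest_stays_in_input_set(self):
        xs = np.linspace(-1300, 1300, 40)
        ys = np.linspace(-1300, 1300, 40)
        checker = np.indices((40, 40)).sum(axis=0) % 2 * 2.0 + 1.0  # values {1, 3}
        out = resample_to_grid({"C": layer(checker, xs=xs, ys=ys)}, GRID, "nearest")
        assert set(np.unique(np.asarray(out["C"]))) <= {1.0, 3.0}

    def test_no_overlap_rejected(self):
        native = layer(np.zeros((10, 10)), xs=np.linspace(5000, 6000, 10),
                       ys=np.linspace(5000, 6000, 10))
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid({"SST": native}, GRID)


class TestDestinationWindow:
    def test_window_arithmetic(self, cohort20):
        cfg = HabitatConfig(window_days=10)
        for b, t in cohort20["trips"].items():
            if t.reversal_date is None:
                continue
            pts = destination_window_points(t, cohort20["daily"][b], cfg)
            assert 1 <= len(pts) <= 21
            assert all(abs((p.date - t.reversal_date).days) <= 10 for p in pts)

    def test_no_reversal_rejected(self, cohort20):
        import dataclasses

        t = next(iter(cohort20["trips"].values()))
        bad = dataclasses.replace(t, reversal_date=None)
        with pytest.raises(ValueError, match="reversal"):
            destination_window_points(bad, cohort20["daily"][t.bird_id])


def _tables(marg_shift, n_animals=6, n_vars=4, seed=31):
    rng = np.random.default_rng(seed)
    cols = [f"v{i}" for i in range(n_vars)]
    used, avail = {}, {}
    for k in range(n_animals):
        av = pd.DataFrame(rng.normal(0, 1, (150, n_vars)), columns=cols)
        u = av.iloc[rng.integers(0, 150, 25)].copy()
        u += marg_shift(k)
        used[f"a{k}"] = u
        avail[f"a{k}"] = av
    return used, avail, cols


class TestKselect:
    def test_null_selection_zero_eigenvalues(self):
        used, avail, _ = _tables(lambda k: 0.0)
        for a in used:
            used[a] = avail[a].copy()  # used == available exactly
        res = kselect(used, avail)
        np.testing.assert_allclose(res.marginality, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_trace_identity(self):
        used, avail, _ = _tables(lambda k: np.array([1.0, -0.5, 0.2, 0.0]))
        res = kselect(used, avail)
        expected = sum(
            w * m @ m for w, m in zip(res.weights, res.marginality)
        )
        assert abs(res.eigenvalues.sum() - expected) < 1e-9

    def test_single_variable_preference_concentrates_axis1(self):
        shift = np.zeros(4)
        shift[2] = 2.0
        used, avail, cols = _tables(lambda k: shift)
        res = kselect(used, avail)
        assert abs(res.loadings[2, 0]) > 0.95
        assert res.explained()[0] > 0.95

    def test_two_regimes_in_opposite_half_planes(self):
        def shift(k):
            # regimes select opposing conditions along a shared gradient,
            # like chlorophyll-seekers vs eddy-seekers on either side of a
            # front: each prefers what the other avoids
            s = np.zeros(4)
            if k % 2 == 0:
                s[0], s[1] = 1.5, -1.0
            else:
                s[0], s[1], s[2] = -1.0, 1.5, 1.0
            return s

        used, avail, _ = _tables(shift, n_animals=8)
        res = kselect(used, avail)
        proj = res.projections[:, :2]
        g1 = proj[::2].mean(axis=0)
        g2 = proj[1::2].mean(axis=0)
        cos = g1 @ g2 / (np.linalg.norm(g1) * np.linalg.norm(g2))
        assert cos < 0

    def test_standardization_weighted_moments(self):
        used, avail, cols = _tables(lambda k: 0.3)
        res = kselect(used, avail)
        pooled = np.concatenate([np.asarray(avail[a]) for a in res.animals])
        pw = np.concatenate(
            [np.full(len(avail[a]), w / len(avail[a]))
             for a, w in zip(res.animals, res.weights)]
        )
        pw /= pw.sum()
        mu = pw @ pooled
        sd = np.sqrt(pw @ (pooled - mu) ** 2)
        z = (pooled - mu) / sd
        np.testing.assert_allclose(pw @ z, 0.0, atol=1e-9)
        np.testing.assert_allclose(pw @ z**2, 1.0, atol=1e-9)

    def test_axes_orthonormal_and_reconstruction(self):
        used, avail, _ = _tables(lambda k: np.array([0.8, -0.3, 0.1, 0.4]))
        res = kselect(used, avail, n_axes=4)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(4), atol=1e-9
        )
        np.testing.assert_allclose(
            res.projections @ res.loadings.T, res.marginality, atol=1e-9
        )

    def test_zero_variance_variable_named(self):
        used, avail, cols = _tables(lambda k: 0.1)
        for a in avail:
            avail[a]["v1"] = 5.0
            used[a]["v1"] = 5.0
        with pytest.raises(ValueError, match="v1"):
            kselect(used, avail)

    def test_weights_proportional_to_relocations(self):
        used, avail, _ = _tables(lambda k: 0.2)
        used["a0"] = used["a0"].iloc[:5]
        res = kselect(used, avail)
        n = np.array([len(used[a]) for a in res.animals], float)
        np.testing.assert_allclose(res.weights, n / n.sum())


class TestEndToEndExtraction:
    def test_depth_sign_convention(self, cohort20):
        """Birds placed over the shallow ridge get positive BATHY marginality
        (depth is negative down, so shallower = larger value)."""
        stack, _ = simulate_env(GRID, seed=9)
        trips = [t for t in cohort20["trips"].values() if t.reversal_date]
        used, avail = extract_used_available(
            trips, cohort20["daily"], stack, GRID, HabitatConfig()
        )
        assert len(used) >= 2
        res = kselect(used, avail)
        for i, a in enumerate(res.animals):
            shallow_pref = used[a]["BATHY"].mean() > avail[a]["BATHY"].mean()
            j = res.variables.index("BATHY")
            assert (res.marginality[i, j] > 0) == shallow_pref
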