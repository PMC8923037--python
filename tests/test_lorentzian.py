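import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arexcest as ax
from arexcest.lorentzian import (
    FitBounds,
    fit_two_pool,
    fit_two_pool_stack,
    lorentzian,
    mt_baseline,
    subtract_mt,
)
from arexcest.zspec import ZSpectrumStack, assemble_zspectra


class TestLineShape:
    def test_peak_value_at_center(self):
        # MT pool at its initial guess: amplitude 0.35, FWHM 55 ppm
        assert lorentzian(0.35, 55.0, -2.4, -2.4) == pytest.approx(0.35)

    @given(
        a=st.floats(0.01, 1.0),
        w=st.floats(0.2, 80.0),
        c=st.floats(-4.0, 4.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_half_maximum_at_half_width(self, a, w, c):
        assert lorentzian(a, w, c, c + w / 2) == pytest.approx(a / 2, rel=1e-12)
        assert lorentzian(a, w, c, c - w / 2) == pytest.approx(a / 2, rel=1e-12)

    def test_zero_amplitude_is_zero_everywhere(self):
        offs = np.linspace(-5, 5, 43)
        np.testing.assert_array_equal(lorentzian(0.0, 2.0, 0.0, offs), 0.0)

    def test_rejects_non_positive_width(self):
        with pytest.raises(ValueError):
            lorentzian(0.5, 0.0, 0.0, 1.0)


class TestFitBounds:
    def test_default_table_values(self):
        b = FitBounds()
        assert b.ds_amp == (0.20, 1.00, 0.60)
        assert b.mt_amp == (0.00, 0.90, 0.35)
        assert b.ds_width == (0.1, 5.0, 2.55)
        assert b.mt_width == (10.0, 100.0, 55.0)

    def test_initial_must_lie_within_bounds(self):
        with pytest.raises(ValueError):
            FitBounds(ds_amp=(0.3, 1.0, 0.2))


class TestTwoPoolFit:
    def test_recovers_initial_guess_truth_exactly(self, cest_offsets):
        z = (
            1.0
            - lorentzian(0.60, 2.55, 0.0, cest_offsets)
            - lorentzian(0.35, 55.0, -2.4, cest_offsets)
        )
        f = fit_two_pool(cest_offsets, z, exclude_ranges=())
        for got, want in (
            (f.ds.amplitude, 0.60),
            (f.mt.amplitude, 0.35),
            (f.ds.width, 2.55),
            (f.mt.width, 55.0),
        ):
            assert got == pytest.approx(want, rel=1e-6)
        assert f.converged and not f.at_bound

    def test_200_random_truths_recovered(self, cest_offsets):
        """Noiseless spectra drawn across the bound box (5% margin off the
        edges to keep both pools identifiable) are recovered to ~machine
        precision: amplitudes within 1e-4, widths within 1e-3 relative."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            ds_a = rng.uniform(0.24, 0.96)
            mt_a = rng.uniform(0.045, 0.855)
            if ds_a + mt_a >= 1.0:
                mt_a = 0.99 - ds_a
            ds_w = rng.uniform(0.345, 4.755)
            mt_w = rng.uniform(14.5, 95.5)
            z = (
                1.0
                - lorentzian(ds_a, ds_w, 0.0, cest_offsets)
                - lorentzian(mt_a, mt_w, -2.4, cest_offsets)
            )
            f = fit_two_pool(cest_offsets, z, exclude_ranges=())
            assert abs(f.ds.amplitude - ds_a) / ds_a <= 1e-4
            assert abs(f.mt.amplitude - mt_a) / mt_a <= 1e-4
            assert abs(f.ds.width - ds_w) / ds_w <= 1e-3
            assert abs(f.mt.width - mt_w) / mt_w <= 1e-3

    def test_noisy_amplitude_error_small(self, cest_offsets):
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(100):
            ds_a = rng.uniform(0.3, 0.9)
            mt_a = rng.uniform(0.05, min(0.6, 0.99 - ds_a))
            ds_w = rng.uniform(1.0, 4.0)
            mt_w = rng.uniform(20.0, 90.0)
            z = (
                1.0
                - lorentzian(ds_a, ds_w, 0.0, cest_offsets)
                - lorentzian(mt_a, mt_w, -2.4, cest_offsets)
                + rng.normal(0, 0.005, cest_offsets.shape)
            )
            f = fit_two_pool(cest_offsets, z, exclude_ranges=())
            errs += [abs(f.ds.amplitude - ds_a), abs(f.mt.amplitude - mt_a)]
        assert np.median(errs) <= 0.01

    def test_flat_spectrum_pins_ds_at_lower_bound(self, cest_offsets):
        f = fit_two_pool(cest_offsets, np.ones_like(cest_offsets))
        assert f.ds.amplitude == pytest.approx(0.20, abs=1e-9)
        assert f.at_bound

    def test_requires_offsets_on_both_sides(self):
        offs = np.linspace(0.2, 5.0, 25)
        with pytest.raises(ValueError):
            fit_two_pool(offs, np.ones_like(offs))

    def test_matches_exhaustive_grid_search(self):
        """Bounded least squares agrees with a brute-force 4D grid search
        (amplitude step 0.005, width step 0.25 ppm) on noisy toy spectra:
        the fit's residual must be at least as low as every grid point's,
        and the parameters agree at grid resolution.  The broad MT width is
        compared only loosely (5 ppm): its amplitude-width trade-off leaves
        a near-degenerate valley at toy sampling density, so the grid
        argmin wanders along it at the noise floor."""
        offs = np.array([-5.0, -4.0, -3.0, -2.4, -1.2, 0.0, 0.6, 1.2, 2.4, 4.0, 5.0])
        truths = [
            (0.55, 0.30, 2.5, 55.0),
            (0.62, 0.18, 2.0, 45.0),
            (0.48, 0.40, 3.0, 65.0),
            (0.70, 0.25, 1.5, 38.0),
            (0.52, 0.35, 2.8, 72.0),
        ]
        a_ds_grid = np.arange(0.40, 0.801, 0.005)
        a_mt_grid = np.arange(0.10, 0.501, 0.005)
        w_ds_grid = np.arange(1.0, 4.01, 0.25)
        w_mt_grid = np.arange(30.0, 80.01, 0.25)
        rng = np.random.default_rng(11)
        for ds_a, mt_a, ds_w, mt_w in truths:
            z = (
                1.0
                - lorentzian(ds_a, ds_w, 0.0, offs)
                - lorentzian(mt_a, mt_w, -2.4, offs)
                + rng.normal(0, 5e-4, offs.shape)
            )
            y = 1.0 - z
            best = None
            # expand ||y - a*u - b*v||^2 in the amplitudes so the inner 2D
            # amplitude grid is pure algebra on precomputed dot products
            aa = a_ds_grid[:, None]
            bb = a_mt_grid[None, :]
            for wd in w_ds_grid:
                u = 1.0 / (1.0 + 4.0 * (offs / wd) ** 2)
                uu, uy = u @ u, u @ y
                for wm in w_mt_grid:
                    v = 1.0 / (1.0 + 4.0 * ((offs + 2.4) / wm) ** 2)
                    vv, vy, uv = v @ v, v @ y, u @ v
                    cost = (
                        aa**2 * uu
                        + bb**2 * vv
                        + 2 * aa * bb * uv
                        - 2 * aa * uy
                        - 2 * bb * vy
                    )
                    i, j = np.unravel_index(np.argmin(cost), cost.shape)
                    c = cost[i, j]
                    if best is None or c < best[0]:
                        best = (c, a_ds_grid[i], a_mt_grid[j], wd, wm)
            f = fit_two_pool(offs, z, exclude_ranges=())
            fit_cost = float(np.sum((f.model(offs) - z) ** 2))
            grid_cost = best[0] + y @ y  # undo the expansion's constant term
            assert fit_cost <= grid_cost + 1e-12
            assert abs(f.ds.amplitude - best[1]) <= 0.005
            assert abs(f.mt.amplitude - best[2]) <= 0.005
            assert abs(f.ds.width - best[3]) <= 0.25
            assert abs(f.mt.width - best[4]) <= 5.0


class TestMTBaseline:
    def test_component_peak_and_half_width(self, cest_offsets):
        z = (
            1.0
            - lorentzian(0.6, 2.5, 0.0, cest_offsets)
            - lorentzian(0.3, 50.0, -2.4, cest_offsets)
        )
        f = fit_two_pool(cest_offsets, z, exclude_ranges=())
        peak = mt_baseline(f, np.array([-2.4]))
        assert peak[0] == pytest.approx(f.mt.amplitude, rel=1e-12)
        half = mt_baseline(f, np.array([-2.4 + f.mt.width / 2]))
        assert half[0] == pytest.approx(f.mt.amplitude / 2, rel=1e-9)

    def test_zero_amplitude_gives_zero_vector(self, cest_offsets):
        z = 1.0 - lorentzian(0.6, 2.5, 0.0, cest_offsets)
        f = fit_two_pool(
            cest_offsets,
            z,
            FitBounds(mt_amp=(0.0, 0.9, 0.0)),
            exclude_ranges=(),
        )
        assert f.mt.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_ds_component_even_mt_peak_fixed(self, cest_offsets):
        """The fitted DS component is symmetric about 0 ppm and the MT
        centre stays at -2.4 ppm exactly (centres are never fitted)."""
        z = (
            1.0
            - lorentzian(0.5, 3.0, 0.0, cest_offsets)
            - lorentzian(0.25, 40.0, -2.4, cest_offsets)
        )
        f = fit_two_pool(cest_offsets, z, exclude_ranges=())
        assert f.ds.center == 0.0 and f.mt.center == -2.4
        grid = np.linspace(-4, 4, 81)
        ds_comp = lorentzian(f.ds.amplitude, f.ds.width, f.ds.center, grid)
        np.testing.assert_allclose(ds_comp, ds_comp[::-1], rtol=1e-12)


def _stack_from_phantom(tissues_override=None, grid=(16, 16)):
    import dataclasses

    from arexcest.phantom import default_tissue_classes

    tissues = default_tissue_classes()
    if tissues_override:
        tissues.update(tissues_override)
    cfg = ax.PhantomConfig(
        grid_size=grid,
        tissues=tissues,
        noise_sd=0.0,
        b0_constant_ppm=0.0,
        b1_constant=1.0,
        drift_start=1.0,
        drift_end=1.0,
    )
    truth = ax.build_phantom(cfg, seed=9)
    sched = ax.canonical_cest_schedule()
    dyn = ax.simulate_cest_dynamics(truth, sched, seed=9)
    return truth, assemble_zspectra(dyn, sched)


class TestSubtractMT:
    def test_ds_mt_only_phantom_leaves_pure_ds_spectrum(self):
        from arexcest.phantom import PoolSpec, TissueClass

        two_pool = {
            label: TissueClass(
                label,
                (
                    PoolSpec("ds", 0.55, 2.3, 0.0),
                    PoolSpec("mt", 0.2 if label == "WM" else 0.1, 50.0, -2.4),
                ),
                r1=1.0,
            )
            for label in ("WM", "GM", "CSF", "WM_lesion", "cortical_lesion")
        }
        truth, z = _stack_from_phantom(two_pool)
        fits = fit_two_pool_stack(z)
        zc = subtract_mt(z, fits)
        pure_ds = 1.0 - lorentzian(0.55, 2.3, 0.0, z.offsets)
        sel = zc.mask
        assert np.nanmax(np.abs(zc.values[sel] - pure_ds[None, :])) <= 1e-8

    def test_zero_mt_amplitude_is_identity(self, cest_offsets):
        vals = np.tile(1.0 - lorentzian(0.5, 2.0, 0.0, cest_offsets), (2, 2, 1))
        stack = ZSpectrumStack(vals, cest_offsets, np.ones((2, 2), bool))
        fits = fit_two_pool_stack(stack, FitBounds(mt_amp=(0.0, 0.9, 0.0)))
        zc = subtract_mt(stack, fits)
        np.testing.assert_allclose(zc.values, stack.values, atol=1e-9)

    def test_gm_wm_separation_decreases_when_only_mt_differs(self):
        """Phantoms whose GM and WM differ only in MT amplitude: removing
        the fitted MT baseline shrinks the mean |Z_GM - Z_WM| separation."""
        from arexcest.phantom import PoolSpec, TissueClass

        def cls(label, mt_amp):
            return TissueClass(
                label,
                (PoolSpec("ds", 0.55, 2.3, 0.0), PoolSpec("mt", mt_amp, 55.0, -2.4)),
                r1=1.0,
            )

        override = {
            "WM": cls("WM", 0.30),
            "GM": cls("GM", 0.12),
            "CSF": cls("CSF", 0.12),
            "WM_lesion": cls("WM_lesion", 0.30),
            "cortical_lesion": cls("cortical_lesion", 0.12),
        }
        truth, z = _stack_from_phantom(override)
        fits = fit_two_pool_stack(z)
        zc = subtract_mt(z, fits)
        gm = truth.class_mask("GM") & zc.mask
        wm = truth.class_mask("WM") & zc.mask
        sep_before = np.mean(
            np.abs(z.values[gm].mean(axis=0) - z.values[wm].mean(axis=0))
        )
        sep_after = np.mean(
            np.abs(zc.values[gm].mean(axis=0) - zc.values[wm].mean(axis=0))
        )
        assert sep_after < sep_before

    def test_reference_side_unaffected_by_amine_pool(self, cest_offsets):
        """Adding a small amine pool at +3 ppm leaves the corrected value at
        the -3 ppm reference essentially unchanged."""
        base = 1.0 - lorentzian(0.55, 2.3, 0.0, cest_offsets) - lorentzian(
            0.15, 55.0, -2.4, cest_offsets
        )
        with_amine = base - lorentzian(0.02, 1.5, 3.0, cest_offsets)
        f0 = fit_two_pool(cest_offsets, base)
        fa = fit_two_pool(cest_offsets, with_amine)
        i = np.isclose(cest_offsets, -3.0)
        zc0 = base + mt_baseline(f0, cest_offsets)
        zca = with_amine + mt_baseline(fa, cest_offsets)
        assert abs(zca[i][0] - zc0[i][0]) <= 1e-3
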