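import dataclasses

import numpy as np
import pytest

import arexcest as ax
from arexcest.phantom import (
    ConfigurationError,
    PoolSpec,
    TissueClass,
    afi_signals,
    default_tissue_classes,
)


class TestValidation:
    def test_pool_invariants(self):
        with pytest.raises(ConfigurationError):
            PoolSpec("ds", -0.1, 1.0, 0.0)
        with pytest.raises(ConfigurationError):
            PoolSpec("ds", 0.5, 0.0, 0.0)
        with pytest.raises(ConfigurationError):
            PoolSpec("ds", 0.5, 1.0, float("inf"))

    def test_amplitude_sum_must_stay_below_baseline_naming_class(self):
        with pytest.raises(ConfigurationError, match="overfull"):
            TissueClass(
                "overfull",
                (PoolSpec("ds", 0.7, 2.0, 0.0), PoolSpec("mt", 0.4, 50.0, -2.4)),
                z_base=1.0,
                r1=1.0,
            )

    def test_grid_minimum(self):
        with pytest.raises(ConfigurationError):
            ax.PhantomConfig(grid_size=(4, 4))


class TestBuildPhantom:
    def test_deterministic_given_config_and_seed(self, clean_config):
        a = ax.build_phantom(clean_config, seed=3)
        b = ax.build_phantom(clean_config, seed=3)
        for fld in ("label_map", "z_base_map", "r1_map", "b0_field", "b1_field"):
            np.testing.assert_array_equal(getattr(a, fld), getattr(b, fld))

    def test_every_tissue_voxel_has_complete_truth(self, clean_phantom):
        m = clean_phantom.tissue_mask
        assert np.all(clean_phantom.r1_map[m] > 0)
        assert np.all(clean_phantom.z_base_map[m] > 0)
        assert np.all(clean_phantom.s0_map[m] > 0)

    def test_amine_ordering_preserved_voxelwise(self, clean_config):
        truth = ax.build_phantom(clean_config, seed=1)
        pools = truth.pool_maps()["amine"]["amplitude"]
        gm, wm = truth.class_mask("GM"), truth.class_mask("WM")
        assert np.all(pools[gm] > np.max(pools[wm]))

    def test_b0_field_bounded(self):
        cfg = ax.PhantomConfig(grid_size=(16, 16), b0_amplitude_ppm=0.25)
        truth = ax.build_phantom(cfg, seed=0)
        assert np.max(np.abs(truth.b0_field)) <= 0.3


class TestCESTForwardModel:
    def test_zero_noise_matches_analytic_model(self, clean_phantom, cest_schedule):
        dyn = ax.simulate_cest_dynamics(clean_phantom, cest_schedule, seed=0)
        offs = np.asarray(cest_schedule.saturated_offsets)
        ztrue = clean_phantom.z_true(offs)
        si = 0
        m = clean_phantom.tissue_mask
        for t, e in enumerate(cest_schedule.entries):
            if e is None:
                np.testing.assert_allclose(
                    dyn[..., t][m], clean_phantom.s0_map[m], rtol=1e-12
                )
            else:
                np.testing.assert_allclose(
                    dyn[..., t][m],
                    (clean_phantom.s0_map * ztrue[..., si])[m],
                    rtol=1e-12,
                )
                si += 1

    def test_single_ds_pool_peak_depth(self, cest_schedule):
        # one DS pool (A=0.60, FWHM=2.55): Z at 0 ppm is z_base - 0.60
        tissues = {
            "background": TissueClass("background", (), r1=0.0, s0=0.0),
            "WM": TissueClass("WM", (PoolSpec("ds", 0.60, 2.55, 0.0),), r1=1.0),
            "GM": TissueClass("GM", (PoolSpec("ds", 0.60, 2.55, 0.0),), r1=1.0),
        }
        cfg = ax.PhantomConfig(
            grid_size=(8, 8),
            tissues=tissues,
            noise_sd=0.0,
            b0_constant_ppm=0.0,
            b1_constant=1.0,
            drift_start=1.0,
            drift_end=1.0,
        )
        truth = ax.build_phantom(cfg, seed=0)
        z = truth.z_true(np.array([0.0]))
        m = truth.tissue_mask
        np.testing.assert_allclose(z[m, 0], 1.0 - 0.60, atol=1e-15)

    def test_constant_b0_shifts_spectrum_minimum(self, clean_config):
        cfg = dataclasses.replace(clean_config, b0_constant_ppm=0.1)
        truth = ax.build_phantom(cfg, seed=0)
        offs = np.arange(-1.0, 1.0001, 0.01)
        z = truth.z_true(offs)
        iy, ix = 8, 8
        assert offs[np.argmin(z[iy, ix])] == pytest.approx(0.1, abs=1e-9)

    def test_linear_drift_reproduced_exactly_on_references(
        self, clean_config, cest_schedule
    ):
        cfg = dataclasses.replace(clean_config, drift_start=1.0, drift_end=0.95)
        truth = ax.build_phantom(cfg, seed=0)
        dyn = ax.simulate_cest_dynamics(truth, cest_schedule, seed=0)
        drift = truth.drift_profile(cest_schedule.n_dynamics)
        iy, ix = 8, 8
        for t in cest_schedule.reference_indices:
            assert dyn[iy, ix, t] == pytest.approx(
                drift[t] * truth.s0_map[iy, ix], rel=1e-12
            )

    def test_determinism_and_seed_sensitivity(self, cest_schedule):
        cfg = ax.PhantomConfig(grid_size=(8, 8), noise_sd=0.01)
        truth = ax.build_phantom(cfg, seed=1)
        a = ax.simulate_cest_dynamics(truth, cest_schedule, seed=7)
        b = ax.simulate_cest_dynamics(truth, cest_schedule, seed=7)
        c = ax.simulate_cest_dynamics(truth, cest_schedule, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_monotone_amine_contrast(self, clean_config):
        """Raising only the amine amplitude strictly deepens saturation at
        +3 ppm (Z decreases) in every affected voxel."""
        t_lo = ax.build_phantom(clean_config, seed=0)
        tissues = dict(default_tissue_classes())
        tissues["GM"] = tissues["GM"].with_pool_amplitude("amine", 0.05)
        cfg_hi = dataclasses.replace(clean_config, tissues=tissues)
        t_hi = ax.build_phantom(cfg_hi, seed=0)
        z_lo = t_lo.z_true(np.array([3.0]))
        z_hi = t_hi.z_true(np.array([3.0]))
        gm = t_lo.class_mask("GM")
        assert np.all(z_hi[gm, 0] < z_lo[gm, 0])


class TestWASSRSimulation:
    def test_noiseless_symmetric_about_zero_without_shift(
        self, clean_phantom, wassr_schedule
    ):
        stack, meta = ax.simulate_wassr(clean_phantom, wassr_schedule, seed=0)
        assert meta["schedule_covers_shifts"]
        offs = np.asarray(wassr_schedule.saturated_offsets)
        z = clean_phantom.wassr_true(offs)
        iy, ix = 8, 8
        order = np.argsort(offs)
        zs = z[iy, ix][order]
        np.testing.assert_allclose(zs, zs[::-1], atol=1e-12)

    def test_schedule_must_span_one_ppm(self, clean_phantom):
        narrow = ax.OffsetSchedule.from_offsets(
            [round(-0.8 + 0.1 * i, 2) for i in range(17)], [0, 18]
        )
        with pytest.raises(ConfigurationError):
            ax.simulate_wassr(clean_phantom, narrow, seed=0)


class TestIRSimulation:
    def test_long_ti_recovers_equilibrium(self, clean_phantom):
        # TI = 8000 ms at R1 = 1/s: |1 - 2 e^-8| within 0.04% of 1
        ir = ax.simulate_ir_series(clean_phantom, [6, 100, 8000], seed=0, n_slices=1)
        m = clean_phantom.class_mask("WM")
        r1 = clean_phantom.tissues["WM"].r1
        expected = abs(1 - 2 * np.exp(-8.0 * r1)) * clean_phantom.tissues["WM"].s0
        np.testing.assert_allclose(ir[0][m][:, 2], expected, rtol=1e-12)

    def test_null_point_closed_form(self):
        # signal vanishes at TI = ln(1+eff)/r1 for perfect inversion
        tissues = {
            "background": TissueClass("background", (), r1=0.0, s0=0.0),
            "WM": TissueClass("WM", (PoolSpec("ds", 0.5, 2.0, 0.0),), r1=1.0),
            "GM": TissueClass("GM", (PoolSpec("ds", 0.5, 2.0, 0.0),), r1=1.0),
        }
        cfg = ax.PhantomConfig(
            grid_size=(8, 8), tissues=tissues, noise_sd=0.0,
            b0_constant_ppm=0.0, b1_constant=1.0, drift_start=1.0, drift_end=1.0,
        )
        truth = ax.build_phantom(cfg, seed=0)
        ti_null = 1000.0 * np.log(2.0)  # ms, r1 = 1/s
        ir = ax.simulate_ir_series(truth, [6, ti_null, 8000], seed=0, n_slices=1)
        m = truth.tissue_mask
        np.testing.assert_allclose(ir[0][m][:, 1], 0.0, atol=1e-12)

    def test_rejects_non_increasing_ti(self, clean_phantom):
        with pytest.raises(ConfigurationError):
            ax.simulate_ir_series(clean_phantom, [10, 10, 20], seed=0)


class TestAFISimulation:
    def test_ratio_tends_to_one_as_flip_vanishes(self):
        s1, s2 = afi_signals(1.0, 1e-4, 35.0, 160.0)
        assert s2 / s1 == pytest.approx(1.0, abs=1e-7)

    def test_ratio_matches_closed_form(self):
        n = 160.0 / 35.0
        for a in (10.0, 30.0, 60.0, 85.0):
            s1, s2 = afi_signals(2.0, a, 35.0, 160.0)
            c = np.cos(np.deg2rad(a))
            assert s2 / s1 == pytest.approx((1 + n * c) / (n + c), rel=1e-12)

    def test_requires_tr2_greater_tr1(self):
        with pytest.raises(ConfigurationError):
            afi_signals(1.0, 60.0, 160.0, 35.0)
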