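"""Synthetic multi-pool CEST phantom with complete ground truth.

The generator builds a 2D single-slice digital phantom with GM / WM / CSF /
lesion tissue classes, each carrying a set of saturation pools (direct
water saturation at 0 ppm, broad semisolid MT at -2.4 ppm, a glutamate-like
amine pool at +3.0 ppm and an optional relayed-NOE pool near -3.5 ppm), a
per-class longitudinal relaxation rate R1, smooth B0 and B1 inhomogeneity
fields, multiplicative scanner signal drift, and additive noise.

Spectra are simulated with the sum-of-Lorentzians forward model

    Z(dw) = z_base - sum_i  A_i / (1 + 4 ((dw - b0 - c_i) / s_i)^2)

so every downstream fitting stage has an analytic, exactly known truth.
All randomness is driven by explicit integer seeds; the same (config, seed)
always reproduces the same images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from arexcest.schedules import OffsetSchedule

__all__ = [
    "PoolSpec",
    "TissueClass",
    "PhantomConfig",
    "PhantomTruth",
    "ConfigurationError",
    "default_tissue_classes",
    "build_phantom",
    "simulate_cest_dynamics",
    "simulate_wassr",
    "simulate_ir_series",
    "simulate_afi_pair",
    "afi_signals",
    "lorentzian_value",
]

TISSUE_LABELS = ("background", "WM", "GM", "CSF", "WM_lesion", "cortical_lesion")


class ConfigurationError(ValueError):
    """Raised when phantom configuration violates tissue-class invariants."""


def lorentzian_value(
    amplitude: float | np.ndarray,
    width: float | np.ndarray,
    center: float | np.ndarray,
    offset: float | np.ndarray,
) -> np.ndarray:
    """Lorentzian line shape A / (1 + 4((dw - c)/s)^2).

    ``width`` is the full width at half maximum in ppm; peak value is
    ``amplitude`` at ``offset == center``.
    """
    return np.asarray(amplitude) / (
        1.0 + 4.0 * ((np.asarray(offset) - center) / width) ** 2
    )


@dataclass(frozen=True)
class PoolSpec:
    """One saturation pool of the Lorentzian forward/fit model.

    amplitude is the peak fractional saturation (dimensionless, of Z),
    width the FWHM in ppm, center the chemical shift in ppm from water.
    """

    name: str
    amplitude: float
    width: float
    center: float

    def __post_init__(self) -> None:
        if not (self.amplitude >= 0):
            raise ConfigurationError(f"pool {self.name!r}: amplitude must be >= 0")
        if not (self.width > 0):
            raise ConfigurationError(f"pool {self.name!r}: width must be > 0")
        if not math.isfinite(self.center):
            raise ConfigurationError(f"pool {self.name!r}: center must be finite")


@dataclass(frozen=True)
class TissueClass:
    """A tissue class: its saturation pools, baseline and relaxation rate."""

    label: str
    pools: tuple[PoolSpec, ...]
    z_base: float = 1.0
    r1: float = 1.0  # 1/s
    s0: float = 1.0  # unsaturated signal, arbitrary units

    def __post_init__(self) -> None:
        amp_sum = sum(p.amplitude for p in self.pools)
        if amp_sum >= self.z_base:
            raise ConfigurationError(
                f"tissue class {self.label!r}: sum of pool amplitudes "
                f"({amp_sum:.3f}) must be < z_base ({self.z_base:.3f}) so that "
                "simulated Z stays positive"
            )
        if self.label != "background" and not (self.r1 > 0):
            raise ConfigurationError(f"tissue class {self.label!r}: r1 must be > 0")

    def pool(self, name: str) -> PoolSpec:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(f"tissue class {self.label!r} has no pool {name!r}")

    def with_pool_amplitude(self, name: str, amplitude: float) -> "TissueClass":
        pools = tuple(
            replace(p, amplitude=amplitude) if p.name == name else p
            for p in self.pools
        )
        return replace(self, pools=pools)


def default_tissue_classes(include_rnoe: bool = False) -> dict[str, TissueClass]:
    """Default 7T-like tissue classes.

    Amine (glutamate-weighted) amplitude is higher in GM than WM, MT is
    largest in WM and absent in CSF, WM lesions carry elevated amine and
    reduced MT/R1 relative to normal-appearing WM.
    """

    def pools(ds_a, ds_w, mt_a, mt_w, am_a, am_w=1.5):
        ps = [PoolSpec("ds", ds_a, ds_w, 0.0)]
        if mt_a > 0:
            ps.append(PoolSpec("mt", mt_a, mt_w, -2.4))
        if am_a > 0:
            ps.append(PoolSpec("amine", am_a, am_w, 3.0))
        if include_rnoe:
            ps.append(PoolSpec("rnoe", 0.02, 3.0, -3.5))
        return tuple(ps)

    # amine amplitudes follow the ~2:1 GM:WM glutamate concentration ratio;
    # WM lesions carry ~1.5x the NAWM amine load with reduced MT and R1
    return {
        "background": TissueClass("background", (), z_base=1.0, r1=0.0, s0=0.0),
        "WM": TissueClass("WM", pools(0.60, 2.6, 0.30, 60.0, 0.018), r1=0.83, s0=0.80),
        "GM": TissueClass("GM", pools(0.55, 2.3, 0.15, 55.0, 0.036), r1=0.50, s0=0.90),
        "CSF": TissueClass("CSF", pools(0.85, 1.6, 0.0, 55.0, 0.004), r1=0.23, s0=1.00),
        "WM_lesion": TissueClass(
            "WM_lesion", pools(0.60, 2.6, 0.22, 60.0, 0.027), r1=0.70, s0=0.82
        ),
        "cortical_lesion": TissueClass(
            "cortical_lesion", pools(0.55, 2.3, 0.13, 55.0, 0.038), r1=0.45, s0=0.90
        ),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the synthetic phantom.

    B0 is a smooth in-plane field with maximum absolute shift
    ``b0_amplitude_ppm`` (or a constant if ``b0_constant_ppm`` is set);
    B1 is a smooth relative transmit field 1 +/- ``b1_variation`` (or
    constant ``b1_constant``).  Drift is multiplicative and linear across
    dynamics from ``drift_start`` to ``drift_end``.  ``noise_sd`` is the
    additive noise SD as a fraction of the unit S0 scale; ``rician`` draws
    magnitude (Rician) noise instead of plain Gaussian.
    """

    grid_size: tuple[int, int] = (64, 64)
    tissues: Mapping[str, TissueClass] = field(default_factory=default_tissue_classes)
    b0_amplitude_ppm: float = 0.10
    b0_constant_ppm: Optional[float] = None
    b0_bound_ppm: float = 0.3
    b1_variation: float = 0.10
    b1_constant: Optional[float] = None
    drift_start: float = 1.00
    drift_end: float = 0.97
    noise_sd: float = 0.005
    rician: bool = False

    def __post_init__(self) -> None:
        h, w = self.grid_size
        if h < 8 or w < 8:
            raise ConfigurationError("grid size must be at least 8x8")
        for name, tc in self.tissues.items():
            if not isinstance(tc, TissueClass):
                raise ConfigurationError(f"tissue entry {name!r} is not a TissueClass")
        if self.b0_constant_ppm is None and abs(self.b0_amplitude_ppm) > self.b0_bound_ppm:
            raise ConfigurationError("b0_amplitude_ppm exceeds b0_bound_ppm")
        if self.drift_start <= 0 or self.drift_end <= 0:
            raise ConfigurationError("drift profile must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Complete voxel-wise ground truth of a built phantom."""

    label_map: np.ndarray  # (H, W) int, index into `labels`
    labels: tuple[str, ...]
    tissues: Mapping[str, TissueClass]
    z_base_map: np.ndarray  # (H, W)
    r1_map: np.ndarray  # (H, W), 1/s (0 outside tissue)
    s0_map: np.ndarray  # (H, W)
    b0_field: np.ndarray  # (H, W), ppm
    b1_field: np.ndarray  # (H, W), relative transmit scale
    drift_start: float
    drift_end: float
    noise_sd: float
    rician: bool
    seed: int

    @property
    def grid_size(self) -> tuple[int, int]:
        return self.label_map.shape  # type: ignore[return-value]

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map != self.labels.index("background")

    def class_mask(self, label: str) -> np.ndarray:
        return self.label_map == self.labels.index(label)

    def drift_profile(self, n_dynamics: int) -> np.ndarray:
        """Multiplicative drift scalar per dynamic index (linear)."""
        return np.linspace(self.drift_start, self.drift_end, n_dynamics)

    def pool_maps(self) -> dict[str, dict[str, np.ndarray]]:
        """Per-voxel pool parameter maps keyed by pool name."""
        h, w = self.grid_size
        names = sorted(
            {p.name for tc in self.tissues.values() for p in tc.pools}
        )
        out: dict[str, dict[str, np.ndarray]] = {}
        for name in names:
            amp = np.zeros((h, w))
            wid = np.ones((h, w))
            cen = np.zeros((h, w))
            for li, label in enumerate(self.labels):
                tc = self.tissues.get(label)
                if tc is None:
                    continue
                sel = self.label_map == li
                for p in tc.pools:
                    if p.name == name:
                        amp[sel] = p.amplitude
                        wid[sel] = p.width
                        cen[sel] = p.center
            out[name] = {"amplitude": amp, "width": wid, "center": cen}
        return out

    def z_true(self, offsets: Sequence[float]) -> np.ndarray:
        """Analytic noiseless z-spectrum at the given offsets, including the
        per-voxel B0 shift; shape (H, W, n_offsets)."""
        offs = np.asarray(offsets, dtype=float)
        h, w = self.grid_size
        z = np.broadcast_to(self.z_base_map[..., None], (h, w, offs.size)).copy()
        dw = offs[None, None, :] - self.b0_field[..., None]
        for li, label in enumerate(self.labels):
            tc = self.tissues.get(label)
            if tc is None:
                continue
            sel = self.label_map == li
            if not np.any(sel):
                continue
            for p in tc.pools:
                z[sel] -= lorentzian_value(p.amplitude, p.width, p.center, dw[sel])
        return z

    def wassr_true(
        self, offsets: Sequence[float], amp_scale: float = 0.6, width_scale: float = 0.5
    ) -> np.ndarray:
        """Analytic noiseless WASSR spectrum: DS pool only, at reduced
        saturation power (weaker, narrower dip), shifted by B0."""
        offs = np.asarray(offsets, dtype=float)
        h, w = self.grid_size
        z = np.ones((h, w, offs.size))
        dw = offs[None, None, :] - self.b0_field[..., None]
        for li, label in enumerate(self.labels):
            tc = self.tissues.get(label)
            if tc is None or not tc.pools:
                if label == "background":
                    z[self.label_map == li] = 1.0
                continue
            sel = self.label_map == li
            ds = tc.pool("ds")
            z[sel] -= lorentzian_value(
                amp_scale * ds.amplitude, width_scale * ds.width, 0.0, dw[sel]
            )
        return z

    def to_json(self, path: str | Path) -> None:
        """Serialize the truth (arrays as nested lists) for provenance."""
        payload = {
            "labels": list(self.labels),
            "label_map": self.label_map.tolist(),
            "z_base_map": self.z_base_map.tolist(),
            "r1_map": self.r1_map.tolist(),
            "s0_map": self.s0_map.tolist(),
            "b0_field": self.b0_field.tolist(),
            "b1_field": self.b1_field.tolist(),
            "drift_start": self.drift_start,
            "drift_end": self.drift_end,
            "noise_sd": self.noise_sd,
            "rician": self.rician,
            "seed": self.seed,
            "tissues": {
                label: {
                    "z_base": tc.z_base,
                    "r1": tc.r1,
                    "s0": tc.s0,
                    "pools": [
                        {
                            "name": p.name,
                            "amplitude": p.amplitude,
                            "width": p.width,
                            "center": p.center,
                        }
                        for p in tc.pools
                    ],
                }
                for label, tc in self.tissues.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def _head_geometry(h: int, w: int) -> np.ndarray:
    """Deterministic label map: elliptical head with a GM rim, WM interior,
    central CSF, one WM lesion and one cortical lesion."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.45 * h, 0.45 * w
    rho = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)

    labels = np.zeros((h, w), dtype=np.int64)  # background
    inside = rho <= 1.0
    labels[inside] = TISSUE_LABELS.index("WM")
    labels[inside & (rho >= 0.78)] = TISSUE_LABELS.index("GM")
    labels[rho <= 0.18] = TISSUE_LABELS.index("CSF")

    # WM lesion: small disk in the WM interior, upper-right quadrant
    ly, lx = cy - 0.35 * ry, cx + 0.35 * rx
    lr = 0.10 * min(ry, rx)
    wm_lesion = (yy - ly) ** 2 + (xx - lx) ** 2 <= lr**2
    labels[wm_lesion & (labels == TISSUE_LABELS.index("WM"))] = TISSUE_LABELS.index(
        "WM_lesion"
    )

    # cortical lesion: small disk centered on the GM rim, bottom
    gy, gx = cy + 0.88 * ry, cx
    gr = 0.07 * min(ry, rx)
    c_lesion = (yy - gy) ** 2 + (xx - gx) ** 2 <= gr**2
    labels[c_lesion & (labels == TISSUE_LABELS.index("GM"))] = TISSUE_LABELS.index(
        "cortical_lesion"
    )
    return labels


def _smooth_field(h: int, w: int, amplitude: float, phase: float) -> np.ndarray:
    """Smooth, bounded in-plane field built from low-order harmonics;
    max |field| == amplitude (deterministic, no RNG)."""
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - (w - 1) / 2.0) / w
    v = (yy - (h - 1) / 2.0) / h
    f = (
        np.sin(2.1 * u + phase)
        + 0.6 * np.cos(1.7 * v - 0.5 * phase)
        + 0.4 * np.sin(3.0 * u * v + phase)
    )
    peak = np.max(np.abs(f))
    if peak == 0:
        return np.zeros((h, w))
    return amplitude * f / peak


def build_phantom(config: PhantomConfig, seed: int) -> PhantomTruth:
    """Build the deterministic ground truth for a phantom configuration.

    The label geometry and the smooth B0/B1 fields are deterministic
    functions of the configuration; ``seed`` is stored and seeds the noise
    streams of the simulators.
    """
    h, w = config.grid_size
    tissues = dict(config.tissues)
    for label in ("background", "WM", "GM"):
        if label not in tissues:
            raise ConfigurationError(f"tissue table must define {label!r}")
    labels = tuple(
        [l for l in TISSUE_LABELS if l in tissues]
        + [l for l in tissues if l not in TISSUE_LABELS]
    )
    label_map = _head_geometry(h, w)
    # remap geometry indices onto the configured label tuple
    remap = np.zeros(len(TISSUE_LABELS), dtype=np.int64)
    for gi, gl in enumerate(TISSUE_LABELS):
        remap[gi] = labels.index(gl) if gl in labels else labels.index("WM")
    label_map = remap[label_map]

    z_base = np.zeros((h, w))
    r1 = np.zeros((h, w))
    s0 = np.zeros((h, w))
    for li, label in enumerate(labels):
        tc = tissues[label]
        sel = label_map == li
        z_base[sel] = tc.z_base
        r1[sel] = tc.r1
        s0[sel] = tc.s0

    if config.b0_constant_ppm is not None:
        b0 = np.full((h, w), float(config.b0_constant_ppm))
    else:
        b0 = _smooth_field(h, w, config.b0_amplitude_ppm, phase=0.8)
    if np.max(np.abs(b0)) > config.b0_bound_ppm + 1e-12:
        raise ConfigurationError("B0 field exceeds its configured bound")
    if config.b1_constant is not None:
        b1 = np.full((h, w), float(config.b1_constant))
    else:
        b1 = 1.0 + _smooth_field(h, w, config.b1_variation, phase=2.3)

    return PhantomTruth(
        label_map=label_map,
        labels=labels,
        tissues=tissues,
        z_base_map=z_base,
        r1_map=r1,
        s0_map=s0,
        b0_field=b0,
        b1_field=b1,
        drift_start=config.drift_start,
        drift_end=config.drift_end,
        noise_sd=config.noise_sd,
        rician=config.rician,
        seed=int(seed),
    )


def _add_noise(signal: np.ndarray, sd: float, rng: np.random.Generator, rician: bool) -> np.ndarray:
    if sd == 0:
        return signal
    if rician:
        re = signal + rng.normal(0.0, sd, signal.shape)
        im = rng.normal(0.0, sd, signal.shape)
        return np.sqrt(re**2 + im**2)
    return signal + rng.normal(0.0, sd, signal.shape)


def simulate_cest_dynamics(
    phantom: PhantomTruth,
    schedule: OffsetSchedule,
    seed: int,
    noise_sd: Optional[float] = None,
) -> np.ndarray:
    """Simulate the raw CEST dynamic stack in acquisition order.

    Saturated dynamics are ``drift(t) * S0_true * Z_true(offset)``; reference
    dynamics are ``drift(t) * S0_true``; additive noise on top.  Returns an
    array of shape (H, W, n_dynamics).
    """
    sd = phantom.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    n = schedule.n_dynamics
    drift = phantom.drift_profile(n)
    h, w = phantom.grid_size
    out = np.empty((h, w, n))
    sat_offsets = np.asarray(schedule.saturated_offsets, dtype=float)
    z = phantom.z_true(sat_offsets)  # (H, W, n_sat)
    si = 0
    for t, entry in enumerate(schedule.entries):
        if entry is None:
            out[..., t] = drift[t] * phantom.s0_map
        else:
            out[..., t] = drift[t] * phantom.s0_map * z[..., si]
            si += 1
    return _add_noise(out, sd, rng, phantom.rician)


def simulate_wassr(
    phantom: PhantomTruth,
    schedule: OffsetSchedule,
    seed: int,
    noise_sd: Optional[float] = None,
) -> tuple[np.ndarray, dict]:
    """Simulate the WASSR dynamic stack (low-power DS-only spectrum shifted
    by the B0 field).  Returns (stack (H, W, n_dynamics), metadata)."""
    offs = np.asarray(schedule.saturated_offsets, dtype=float)
    if offs.min() > -1.0 or offs.max() < 1.0:
        raise ConfigurationError("WASSR schedule must span at least +/-1.0 ppm")
    sd = phantom.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    h, w = phantom.grid_size
    n = schedule.n_dynamics
    drift = phantom.drift_profile(n)
    z = phantom.wassr_true(offs)
    out = np.empty((h, w, n))
    si = 0
    for t, entry in enumerate(schedule.entries):
        if entry is None:
            out[..., t] = drift[t] * phantom.s0_map
        else:
            out[..., t] = drift[t] * phantom.s0_map * z[..., si]
            si += 1
    max_shift = float(np.max(np.abs(phantom.b0_field)))
    # schedule must comfortably bracket the true shifts for symmetry fitting
    covered = offs.min() + max_shift < 0 < offs.max() - max_shift
    meta = {
        "max_true_shift_ppm": max_shift,
        "schedule_covers_shifts": bool(covered),
    }
    if not covered:
        meta["warning"] = "WASSR schedule does not cover the true B0 shifts"
    return _add_noise(out, sd, rng, phantom.rician), meta


def simulate_ir_series(
    phantom: PhantomTruth,
    ti_ms: Sequence[float],
    seed: int,
    inv_efficiency: float = 1.0,
    n_slices: int = 5,
    noise_sd: Optional[float] = None,
) -> np.ndarray:
    """Simulate an inversion-recovery magnitude series.

    Signal model per voxel: ``m0 * |1 - (1 + eff) * exp(-TI * r1)|`` with
    ``eff`` in (-1, 1] (``eff = 1`` is perfect inversion, so the ratio of the
    inverted to equilibrium magnetization is -(1+eff) in [-2, 0)).  Returns
    shape (n_slices, H, W, n_TI); slices share the in-plane truth.
    """
    ti = np.asarray(ti_ms, dtype=float)
    if np.any(ti <= 0) or np.any(np.diff(ti) <= 0):
        raise ConfigurationError("TI list must be positive and strictly increasing")
    if not (-1.0 < inv_efficiency <= 1.0):
        raise ConfigurationError("inv_efficiency must be in (-1, 1]")
    sd = phantom.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    h, w = phantom.grid_size
    r1_s = phantom.r1_map  # 1/s
    decay = np.exp(-ti[None, None, :] * r1_s[..., None] / 1000.0)
    signal = phantom.s0_map[..., None] * np.abs(1.0 - (1.0 + inv_efficiency) * decay)
    series = np.broadcast_to(signal[None, ...], (n_slices, h, w, ti.size)).copy()
    return _add_noise(series, sd, rng, phantom.rician)


def afi_signals(
    s0: np.ndarray | float,
    actual_flip_deg: np.ndarray | float,
    tr1_ms: float,
    tr2_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal dual-TR AFI steady-state signal pair.

    Constructed so that S2/S1 = (1 + n cos a)/(n + cos a) with n = TR2/TR1,
    the relation inverted by :func:`arexcest.fieldmaps.compute_afi_b1`.
    """
    if not (tr2_ms > tr1_ms > 0):
        raise ConfigurationError("AFI requires TR2 > TR1 > 0")
    n = tr2_ms / tr1_ms
    a = np.deg2rad(np.asarray(actual_flip_deg, dtype=float))
    sin_a, cos_a = np.sin(a), np.cos(a)
    s1 = np.asarray(s0) * sin_a * (n + cos_a) / (n + 1.0)
    s2 = np.asarray(s0) * sin_a * (1.0 + n * cos_a) / (n + 1.0)
    return s1, s2


def simulate_afi_pair(
    phantom: PhantomTruth,
    tr1_ms: float,
    tr2_ms: float,
    nominal_flip_deg: float,
    seed: int,
    noise_sd: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the two-image AFI acquisition with actual flip angle
    ``nominal_flip_deg * b1_field`` per voxel."""
    sd = phantom.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    actual = nominal_flip_deg * phantom.b1_field
    s1, s2 = afi_signals(phantom.s0_map, actual, tr1_ms, tr2_ms)
    s1 = _add_noise(s1, sd, rng, phantom.rician)
    s2 = _add_noise(s2, sd, rng, phantom.rician)
    return s1, s2
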