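"""Z-spectrum assembly: S0 drift correction and normalization.

Raw CEST acquisitions interleave saturated dynamics with unsaturated S0
reference dynamics.  Scanner signal drifts slowly over the long acquisition,
so each saturated image is normalized to a voxel-wise spline interpolation
of the S0 references evaluated at that dynamic's acquisition index:

    Z(dw) = S(dw) / S0_hat(index of dw)

The assembled stack stores the spectra sorted by offset regardless of
acquisition order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline

from arexcest.schedules import OffsetSchedule

__all__ = ["ZSpectrumStack", "assemble_zspectra", "sample_at_offset", "AssemblyError"]


class AssemblyError(ValueError):
    """Raised when dynamics cannot be assembled into z-spectra."""


@dataclass
class ZSpectrumStack:
    """Per-voxel normalized z-spectra on a common ascending offset grid.

    ``values`` has shape (H, W, n_offsets); invalid samples are NaN.
    ``mask`` marks voxels with valid spectra.  ``provenance`` records the
    schedule and processing settings that produced the stack.
    """

    values: np.ndarray
    offsets: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[-1] != self.offsets.size:
            raise AssemblyError("values last axis must match offsets")
        if np.any(np.diff(self.offsets) <= 0):
            raise AssemblyError("offsets must be strictly increasing")

    @property
    def grid_size(self) -> tuple[int, int]:
        return self.values.shape[:-1]  # type: ignore[return-value]

    def copy_with(self, values: np.ndarray, **prov) -> "ZSpectrumStack":
        provenance = dict(self.provenance)
        provenance.update(prov)
        return ZSpectrumStack(values, self.offsets.copy(), self.mask.copy(), provenance)


def assemble_zspectra(
    dynamics: np.ndarray,
    schedule: OffsetSchedule,
    smoothing: Optional[float] = None,
    mask: Optional[np.ndarray] = None,
    min_s0_fraction: float = 0.05,
) -> ZSpectrumStack:
    """Drift-correct and normalize a raw dynamic stack into z-spectra.

    Parameters
    ----------
    dynamics:
        Raw images, shape (H, W, n_dynamics) in acquisition order.
    schedule:
        Which dynamics are saturated (and at which offset) vs S0 references.
    smoothing:
        If None (default), an interpolating cubic spline is fitted through
        the S0 references per voxel; a positive value switches to a
        smoothing spline with that smoothing factor.
    mask:
        Optional precomputed tissue mask; otherwise voxels whose mean S0 is
        below ``min_s0_fraction`` of the robust (99th percentile) maximum
        are excluded.
    """
    dynamics = np.asarray(dynamics, dtype=float)
    if dynamics.shape[-1] != schedule.n_dynamics:
        raise AssemblyError(
            f"dynamics count {dynamics.shape[-1]} does not match schedule "
            f"({schedule.n_dynamics})"
        )
    ref_idx = np.asarray(schedule.reference_indices)
    sat_idx = np.asarray(schedule.saturated_indices)
    if ref_idx.size < 2:
        raise AssemblyError("need >=2 reference dynamics")

    s0_refs = dynamics[..., ref_idx]  # (H, W, n_ref)
    mean_s0 = s0_refs.mean(axis=-1)
    if mask is None:
        robust_max = np.percentile(mean_s0, 99)
        mask = mean_s0 >= min_s0_fraction * robust_max
    else:
        mask = np.asarray(mask, dtype=bool)

    # voxel-wise spline of S0 vs dynamic index, evaluated at saturated indices
    k = min(3, ref_idx.size - 1)
    if smoothing is None:
        spline = make_interp_spline(ref_idx.astype(float), s0_refs, k=k, axis=-1)
        s0_hat = spline(sat_idx.astype(float))
    else:
        from scipy.interpolate import splev, splrep

        s0_hat = np.empty(mean_s0.shape + (sat_idx.size,))
        flat_refs = s0_refs.reshape(-1, ref_idx.size)
        flat_out = s0_hat.reshape(-1, sat_idx.size)
        for i in range(flat_refs.shape[0]):
            tck = splrep(ref_idx.astype(float), flat_refs[i], k=k, s=smoothing)
            flat_out[i] = splev(sat_idx.astype(float), tck)

    sat = dynamics[..., sat_idx]
    bad_s0 = np.any(s0_hat <= 0, axis=-1) & mask
    n_dropped_s0 = int(bad_s0.sum())
    mask = mask & ~bad_s0

    with np.errstate(divide="ignore", invalid="ignore"):
        z = sat / s0_hat
    z[~mask] = np.nan

    bad_z = np.any(~np.isfinite(z) | (z <= 0), axis=-1) & mask
    n_dropped_z = int(bad_z.sum())
    mask = mask & ~bad_z
    z[~mask] = np.nan

    offsets = np.asarray(schedule.saturated_offsets, dtype=float)
    order = np.argsort(offsets, kind="stable")
    stack = ZSpectrumStack(
        values=z[..., order],
        offsets=offsets[order],
        mask=mask,
        provenance={
            "drift_model": "interpolating_cubic_spline" if smoothing is None else f"smoothing_spline(s={smoothing})",
            "n_references": int(ref_idx.size),
            "n_saturated": int(sat_idx.size),
            "n_dropped_nonpositive_s0": n_dropped_s0,
            "n_dropped_nonpositive_z": n_dropped_z,
        },
    )
    return stack


def sample_at_offset(
    offsets: np.ndarray,
    values: np.ndarray,
    target: float,
    interp: str = "cubic",
) -> np.ndarray:
    """Sample spectra at an arbitrary in-range offset.

    Returns the stored value exactly when ``target`` coincides with a grid
    offset; otherwise a cubic-spline (or linear) interpolated value.
    ``values`` may be a single spectrum (n_offsets,) or a stack
    (..., n_offsets).
    """
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (offsets[0] <= target <= offsets[-1]):
        raise ValueError(
            f"target {target} ppm outside offset range "
            f"[{offsets[0]}, {offsets[-1]}]"
        )
    exact = np.nonzero(np.isclose(offsets, target, rtol=0, atol=1e-12))[0]
    if exact.size:
        return values[..., exact[0]]
    if interp == "linear":
        lo = np.searchsorted(offsets, target) - 1
        t = (target - offsets[lo]) / (offsets[lo + 1] - offsets[lo])
        return (1 - t) * values[..., lo] + t * values[..., lo + 1]
    if interp != "cubic":
        raise ValueError(f"unknown interpolation method {interp!r}")
    if values.ndim == 1:
        idx = np.nonzero(np.isfinite(values))[0]
        if idx.size < 4 or not (offsets[idx[0]] <= target <= offsets[idx[-1]]):
            raise ValueError("not enough finite samples around target")
        return CubicSpline(offsets[idx], values[idx])(target)
    # stack: vectorize fully finite spectra, fall back per voxel otherwise
    flat = values.reshape(-1, offsets.size)
    out = np.full(flat.shape[0], np.nan)
    row_finite = np.isfinite(flat).all(axis=1)
    if row_finite.any():
        out[row_finite] = CubicSpline(offsets, flat[row_finite], axis=-1)(target)
    for i in np.nonzero(~row_finite)[0]:
        idx = np.nonzero(np.isfinite(flat[i]))[0]
        if idx.size >= 4 and offsets[idx[0]] <= target <= offsets[idx[-1]]:
            out[i] = CubicSpline(offsets[idx], flat[i, idx])(target)
    return out.reshape(values.shape[:-1])
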