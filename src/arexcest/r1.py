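"""Inversion-recovery R1 mapping and thin-slice collapsing.

Magnitude IR data are fitted per voxel with the three-parameter model

    S(TI) = m0 * | 1 - f * exp(-TI * R1) |,    f = 1 + inv_efficiency,

f in [1, 2] (f = 2 is perfect inversion; the ratio of inverted to
equilibrium magnetization is -f).  Magnitude data lose the sign of the
recovering magnetization, so polarity is restored by a sign-flip search
over candidate null-point indices: for each candidate the early points are
negated, the signed model is fitted by bounded least squares, and the best
residual wins.  The signed curve crosses zero at TI = ln(f)/R1.

Thin-slice R1 maps and tissue masks acquired across the thick CEST slice
are collapsed by voxel-wise averaging (maps) and a k-of-n voting rule
(masks): normal-appearing tissue masks keep voxels present in at least
k = 2 of the n = 5 slices, small-lesion masks keep voxels present in any
slice (k = 1); lesion voxels are then excluded from the normal-appearing
masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R1Map",
    "fit_ir_r1",
    "fit_ir_r1_voxel",
    "collapse_slices_mean",
    "collapse_masks",
    "exclude_lesions",
]


@dataclass
class R1Map:
    """Voxel-wise longitudinal relaxation fit results (R1 in 1/s)."""

    r1: np.ndarray
    m0: np.ndarray
    inv_efficiency: np.ndarray
    residual_rms: np.ndarray
    mask: np.ndarray

    @property
    def t1_s(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.r1


def _fit_signed(
    ti_s: np.ndarray,
    signed: np.ndarray,
    r1_init: float,
    f_bounds: tuple[float, float],
    r1_bounds: tuple[float, float],
):
    m0_init = max(float(np.max(np.abs(signed))), 1e-12)
    f_init = 0.5 * (f_bounds[0] + f_bounds[1]) + 0.49 * (f_bounds[1] - f_bounds[0])

    def resid(x):
        m0, f, r1 = x
        return m0 * (1.0 - f * np.exp(-ti_s * r1)) - signed

    def jac(x):
        m0, f, r1 = x
        e = np.exp(-ti_s * r1)
        return np.stack([1.0 - f * e, -m0 * e, m0 * f * ti_s * e], axis=1)

    return least_squares(
        resid,
        x0=[m0_init, f_init, np.clip(r1_init, *r1_bounds)],
        jac=jac,
        bounds=([1e-12, f_bounds[0], r1_bounds[0]], [np.inf, f_bounds[1], r1_bounds[1]]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=400,
    )


def fit_ir_r1_voxel(
    ti_ms: np.ndarray,
    signal: np.ndarray,
    f_bounds: tuple[float, float] = (1.0, 2.0),
    r1_bounds: tuple[float, float] = (1e-3, 20.0),
) -> tuple[float, float, float, float]:
    """Fit one voxel's magnitude IR curve.

    Returns (r1 [1/s], m0, inv_efficiency, residual_rms).  Raises
    ValueError on degenerate (flat) series.
    """
    ti_s = np.asarray(ti_ms, dtype=float) / 1000.0
    s = np.asarray(signal, dtype=float)
    if s.max() <= 0 or (s.max() - s.min()) < 1e-9 * max(s.max(), 1.0):
        raise ValueError("degenerate flat IR series")

    jmin = int(np.argmin(s))
    candidates = range(max(0, jmin - 1), min(s.size, jmin + 2))
    best = None
    for k in candidates:
        signed = s.copy()
        signed[:k] *= -1.0
        # initialize R1 from the candidate null position, TI_null = ln(f)/R1
        ti_null = ti_s[k] if k < ti_s.size else ti_s[-1]
        r1_init = np.log(2.0) / max(ti_null, 1e-6)
        res = _fit_signed(ti_s, signed, r1_init, f_bounds, r1_bounds)
        cost = float(np.sum(res.fun**2))
        if best is None or cost < best[0]:
            best = (cost, res)
    assert best is not None
    res = best[1]
    m0, f, r1 = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return float(r1), float(m0), float(f - 1.0), rms


def fit_ir_r1(
    series: np.ndarray,
    ti_ms: Sequence[float],
    mask: Optional[np.ndarray] = None,
    f_bounds: tuple[float, float] = (1.0, 2.0),
    r1_bounds: tuple[float, float] = (1e-3, 20.0),
) -> R1Map:
    """Voxel-wise R1 map from a magnitude IR series, shape (..., n_TI).

    Requires at least 5 TIs spanning one decade.  Degenerate or
    non-convergent voxels are invalid in the output mask.
    """
    ti = np.asarray(ti_ms, dtype=float)
    if ti.size < 5 or np.any(np.diff(ti) <= 0) or np.any(ti <= 0):
        raise ValueError("need >=5 strictly increasing positive TIs")
    if ti[-1] / ti[0] < 10:
        raise ValueError("TI list must span at least one decade")
    series = np.asarray(series, dtype=float)
    spatial = series.shape[:-1]
    if mask is None:
        mask = series.max(axis=-1) > 0.05 * np.percentile(series.max(axis=-1), 99)
    out_r1 = np.full(spatial, np.nan)
    out_m0 = np.full(spatial, np.nan)
    out_eff = np.full(spatial, np.nan)
    out_rms = np.full(spatial, np.nan)
    valid = np.zeros(spatial, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        try:
            r1, m0, eff, rms = fit_ir_r1_voxel(ti, series[idx], f_bounds, r1_bounds)
        except ValueError:
            continue
        out_r1[idx] = r1
        out_m0[idx] = m0
        out_eff[idx] = eff
        out_rms[idx] = rms
        valid[idx] = True
    return R1Map(out_r1, out_m0, out_eff, out_rms, valid)


def collapse_slices_mean(stack: np.ndarray, valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Voxel-wise mean of thin-slice maps, ignoring invalid (NaN) slices.

    ``stack`` has shape (n_slices, H, W); a voxel invalid in every slice is
    NaN in the output.
    """
    stack = np.asarray(stack, dtype=float)
    if valid is not None:
        stack = np.where(np.asarray(valid, dtype=bool), stack, np.nan)
    n_valid = np.sum(np.isfinite(stack), axis=0)
    total = np.nansum(stack, axis=0)
    out = np.full(stack.shape[1:], np.nan)
    np.divide(total, n_valid, out=out, where=n_valid > 0)
    return out


def collapse_masks(stack: np.ndarray, k: int) -> np.ndarray:
    """k-of-n mask vote: voxel kept iff present in >= k of the n slices."""
    stack = np.asarray(stack).astype(bool)
    n = stack.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return stack.sum(axis=0) >= k


def exclude_lesions(mask: np.ndarray, *lesion_masks: np.ndarray) -> np.ndarray:
    """Remove lesion voxels from a normal-appearing tissue mask."""
    out = np.asarray(mask).astype(bool).copy()
    for lm in lesion_masks:
        out &= ~np.asarray(lm).astype(bool)
    return out
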