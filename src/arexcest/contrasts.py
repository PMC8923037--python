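"""CEST contrast maps: legacy asymmetry, MT-corrected MTRasym, MTR_Rex, AREX.

All contrasts compare the spectrum at the label offset +dw (default
+3.0 ppm, the glutamate amine resonance) with the reference at -dw:

    GluCEST         = 100 * (Z(-dw) - Z(+dw)) / Z(-dw)      (legacy, percent)
    MTRasym_corr    = Z_corr(-dw) - Z_corr(+dw)
    MTR_RexCorr     = 1/Z_corr(+dw) - 1/Z_corr(-dw)
    AREX_corr       = MTR_RexCorr * R1                       (1/s)

where Z_corr is the MT-subtracted spectrum.  The inverse (Rex) difference
removes the dilution of the CEST effect by spillover and residual MT, and
the R1 scaling removes the T1 weighting, leaving a quantity proportional to
the exchange-mediated relaxation contribution of the labelled pool.

Two MTR_Rex variants exist: the default subtracts the fitted MT component
in Z-space before inverting; the alternative subtracts inverses
(1/Z - 1/L_MT) directly.  The two are not algebraically equivalent; the
variant used is recorded with the maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from arexcest.lorentzian import TwoPoolFitStack, subtract_mt
from arexcest.zspec import ZSpectrumStack, sample_at_offset

__all__ = [
    "ContrastMaps",
    "legacy_glucest",
    "mtr_asym_corr",
    "mtr_rex_corr",
    "arex_corr",
    "compute_contrasts",
]


@dataclass
class ContrastMaps:
    """Voxel-wise CEST contrast maps at a single label offset."""

    mtr_asym_corr: np.ndarray  # fraction
    mtr_rex_corr: np.ndarray  # dimensionless
    arex_corr: np.ndarray  # 1/s
    legacy_glucest: np.ndarray  # percent
    valid: np.ndarray  # voxels where all corrected maps are defined
    target_offset: float
    variant: str


def _sample_pair(stack: ZSpectrumStack, target: float) -> tuple[np.ndarray, np.ndarray]:
    z_neg = sample_at_offset(stack.offsets, stack.values, -target)
    z_pos = sample_at_offset(stack.offsets, stack.values, +target)
    return np.asarray(z_neg, dtype=float), np.asarray(z_pos, dtype=float)


def legacy_glucest(zstack: ZSpectrumStack, target: float = 3.0) -> np.ndarray:
    """Legacy asymmetry contrast 100*(Z(-dw)-Z(+dw))/Z(-dw), percent.

    Voxels with non-positive reference signal Z(-dw) are invalid (NaN).
    """
    z_neg, z_pos = _sample_pair(zstack, target)
    out = np.full(z_neg.shape, np.nan)
    ok = zstack.mask & np.isfinite(z_neg) & np.isfinite(z_pos) & (z_neg > 0)
    out[ok] = 100.0 * (z_neg[ok] - z_pos[ok]) / z_neg[ok]
    return out


def mtr_asym_corr(zcorr: ZSpectrumStack, target: float = 3.0) -> np.ndarray:
    """MT-corrected asymmetry Z_corr(-dw) - Z_corr(+dw) (fraction)."""
    z_neg, z_pos = _sample_pair(zcorr, target)
    out = np.full(z_neg.shape, np.nan)
    ok = zcorr.mask & np.isfinite(z_neg) & np.isfinite(z_pos)
    out[ok] = z_neg[ok] - z_pos[ok]
    return out


def mtr_rex_corr(
    zstack: ZSpectrumStack,
    fits: TwoPoolFitStack,
    target: float = 3.0,
    variant: str = "z_space_subtraction",
) -> np.ndarray:
    """MT- and spillover-corrected inverse difference at the label offset.

    variant="z_space_subtraction" (default): the fitted MT component is
    subtracted from Z, then 1/Z_corr(+dw) - 1/Z_corr(-dw) is formed.
    variant="inverse_space_subtraction": the inverse spectra are differenced
    directly, (1/Z - 1/L_MT)(+dw) - (1/Z - 1/L_MT)(-dw).

    Voxels with non-positive Z_corr (or, for the inverse variant,
    non-positive Z or vanishing MT component) are set invalid rather than
    clipped, so downstream ROI means are not biased.
    """
    if variant == "z_space_subtraction":
        zcorr = subtract_mt(zstack, fits)
        c_neg, c_pos = _sample_pair(zcorr, target)
        out = np.full(c_neg.shape, np.nan)
        ok = (
            zcorr.mask
            & np.isfinite(c_neg)
            & np.isfinite(c_pos)
            & (c_neg > 0)
            & (c_pos > 0)
        )
        out[ok] = 1.0 / c_pos[ok] - 1.0 / c_neg[ok]
        return out
    if variant == "inverse_space_subtraction":
        # MT removal in inverse-z space: the MT pool's own z-spectrum is
        # Z_MT = Z_base - L_MT, and 1/Z_corr = 1/Z - 1/Z_MT differences out
        # the MT dilution to first order before the label/reference
        # subtraction.
        z_neg, z_pos = _sample_pair(zstack, target)
        offs = np.array([-target, target])
        lmt = fits.mt_component(offs)
        zmt_neg = fits.z_base - lmt[..., 0]
        zmt_pos = fits.z_base - lmt[..., 1]
        ok = (
            zstack.mask
            & fits.mask
            & np.isfinite(z_neg)
            & np.isfinite(z_pos)
            & (z_neg > 0)
            & (z_pos > 0)
            & (zmt_neg > 0)
            & (zmt_pos > 0)
        )
        out = np.full(z_neg.shape, np.nan)
        inv_pos = 1.0 / z_pos[ok] - 1.0 / zmt_pos[ok]
        inv_neg = 1.0 / z_neg[ok] - 1.0 / zmt_neg[ok]
        out[ok] = inv_pos - inv_neg
        return out
    raise ValueError(f"unknown MTR_Rex variant {variant!r}")


def arex_corr(mtr_rex_map: np.ndarray, r1_map: np.ndarray) -> np.ndarray:
    """AREX contrast: elementwise MTR_RexCorr * R1 (1/s).

    Invalid where R1 is missing or non-positive.
    """
    mtr_rex_map = np.asarray(mtr_rex_map, dtype=float)
    r1_map = np.asarray(r1_map, dtype=float)
    out = mtr_rex_map * r1_map
    out[~(np.isfinite(r1_map) & (r1_map > 0))] = np.nan
    return out


def compute_contrasts(
    zstack: ZSpectrumStack,
    fits: TwoPoolFitStack,
    r1_map: np.ndarray,
    target: float = 3.0,
    variant: str = "z_space_subtraction",
) -> ContrastMaps:
    """All four contrast maps at the label offset, plus a joint validity mask."""
    zcorr = subtract_mt(zstack, fits)
    asym = mtr_asym_corr(zcorr, target)
    rex = mtr_rex_corr(zstack, fits, target, variant)
    arex = arex_corr(rex, r1_map)
    legacy = legacy_glucest(zstack, target)
    valid = np.isfinite(asym) & np.isfinite(rex) & np.isfinite(arex)
    return ContrastMaps(
        mtr_asym_corr=asym,
        mtr_rex_corr=rex,
        arex_corr=arex,
        legacy_glucest=legacy,
        valid=valid,
        target_offset=float(target),
        variant=variant,
    )
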