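"""Saturation-offset schedules and canonical acquisition protocols.

An :class:`OffsetSchedule` records, for every dynamic (image acquired in
time order), either the saturation offset in ppm or the fact that the
dynamic is an unsaturated S0 reference.  The canonical CEST protocol uses
43 saturation offsets sampled asymmetrically between -5.0 and +5.0 ppm with
13 unsaturated reference dynamics interspersed to track scanner signal
drift (56 dynamics total).  The canonical WASSR protocol is a low-power,
direct-saturation-only spectrum spanning +/-1.5 ppm, densely sampled within
+/-1.0 ppm (51 offsets), used for voxel-wise B0 mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OffsetSchedule",
    "canonical_cest_schedule",
    "canonical_wassr_schedule",
    "CANONICAL_CEST_OFFSETS",
    "CANONICAL_TI_MS",
    "AFI_TR1_MS",
    "AFI_TR2_MS",
    "AFI_NOMINAL_FLIP_DEG",
]

#: The 43 asymmetrically sampled saturation offsets (ppm) of the canonical
#: glutamate-weighted CEST protocol, in acquisition order.  Negative offsets
#: are sampled more coarsely; the positive side is a uniform 0.2 ppm grid so
#: the +3.0 ppm amine resonance is densely covered.
CANONICAL_CEST_OFFSETS: tuple[float, ...] = (
    -5.0, -4.6, -4.3, -4.0, -3.6, -3.3, -3.0, -2.6, -2.3, -2.0,
    -1.6, -1.3, -1.0, -0.8, -0.6, -0.4, -0.2, 0.0,
    0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4,
    2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0, 4.2, 4.4, 4.6, 4.8, 5.0,
)

#: Inversion times (ms) of the canonical 14-point inversion-recovery protocol.
CANONICAL_TI_MS: tuple[float, ...] = (
    6, 10, 16, 26, 42, 68, 110, 178, 288, 468, 760, 1233, 2000, 8000,
)

#: Canonical dual-TR actual-flip-angle (AFI) B1-mapping parameters.
AFI_TR1_MS: float = 35.0
AFI_TR2_MS: float = 160.0
AFI_NOMINAL_FLIP_DEG: float = 60.0


class ScheduleError(ValueError):
    """Raised when an offset schedule violates its invariants."""


@dataclass(frozen=True)
class OffsetSchedule:
    """Ordered acquisition schedule of saturation offsets and S0 references.

    Parameters
    ----------
    entries:
        One element per dynamic, in acquisition order: the saturation offset
        in ppm, or ``None`` for an unsaturated S0 reference dynamic.
    """

    entries: tuple[Optional[float], ...]

    def __post_init__(self) -> None:
        if len(self.reference_indices) < 2:
            raise ScheduleError(
                "schedule needs >=2 unsaturated reference dynamics for drift "
                f"interpolation, got {len(self.reference_indices)}"
            )
        if len(self.saturated_indices) < 3:
            raise ScheduleError("schedule needs >=3 saturated offsets")
        offs = np.asarray(self.saturated_offsets, dtype=float)
        if not np.all(np.isfinite(offs)):
            raise ScheduleError("saturation offsets must be finite")

    @property
    def n_dynamics(self) -> int:
        return len(self.entries)

    @property
    def reference_indices(self) -> tuple[int, ...]:
        return tuple(i for i, e in enumerate(self.entries) if e is None)

    @property
    def saturated_indices(self) -> tuple[int, ...]:
        return tuple(i for i, e in enumerate(self.entries) if e is not None)

    @property
    def saturated_offsets(self) -> tuple[float, ...]:
        return tuple(e for e in self.entries if e is not None)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: columns ``index``, ``offset_ppm``, ``is_reference``."""
        return pd.DataFrame(
            {
                "index": np.arange(self.n_dynamics),
                "offset_ppm": [math.nan if e is None else e for e in self.entries],
                "is_reference": [e is None for e in self.entries],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OffsetSchedule":
        df = pd.read_csv(path, sep="\t")
        required = {"index", "offset_ppm", "is_reference"}
        if not required.issubset(df.columns):
            raise ScheduleError(f"schedule TSV must have columns {sorted(required)}")
        df = df.sort_values("index")
        idx = df["index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise ScheduleError("dynamic indices must be unique and contiguous from 0")
        entries: list[Optional[float]] = []
        for _, row in df.iterrows():
            entries.append(None if bool(row["is_reference"]) else float(row["offset_ppm"]))
        return cls(tuple(entries))

    @classmethod
    def from_offsets(
        cls,
        offsets: Sequence[float],
        reference_positions: Sequence[int],
    ) -> "OffsetSchedule":
        """Interleave saturated ``offsets`` with references at the given
        dynamic positions (positions refer to the combined acquisition)."""
        n_total = len(offsets) + len(reference_positions)
        ref_set = set(int(p) for p in reference_positions)
        if len(ref_set) != len(reference_positions):
            raise ScheduleError("reference positions must be unique")
        if ref_set and (min(ref_set) < 0 or max(ref_set) >= n_total):
            raise ScheduleError("reference positions out of range")
        entries: list[Optional[float]] = []
        it = iter(offsets)
        for i in range(n_total):
            entries.append(None if i in ref_set else float(next(it)))
        return cls(tuple(entries))


def canonical_cest_schedule() -> OffsetSchedule:
    """The canonical 56-dynamic CEST acquisition: 43 saturated offsets with
    13 S0 reference dynamics interspersed at evenly spaced positions."""
    n_total = len(CANONICAL_CEST_OFFSETS) + 13
    ref_positions = np.round(np.linspace(0, n_total - 1, 13)).astype(int)
    return OffsetSchedule.from_offsets(CANONICAL_CEST_OFFSETS, ref_positions.tolist())


def canonical_wassr_offsets() -> tuple[float, ...]:
    """WASSR offsets: +/-1.5 ppm, step 0.1 ppm outside +/-1.0 ppm and step
    0.05 ppm within +/-1.0 ppm (51 offsets)."""
    outer_neg = np.arange(-1.5, -1.0, 0.1)
    inner = np.arange(-1.0, 1.0 + 1e-9, 0.05)
    outer_pos = np.arange(1.1, 1.5 + 1e-9, 0.1)
    offs = np.concatenate([outer_neg, inner, outer_pos])
    return tuple(float(round(o, 3)) for o in offs)


def canonical_wassr_schedule() -> OffsetSchedule:
    """WASSR schedule with S0 references bracketing the 51 offset sweep."""
    offs = canonical_wassr_offsets()
    n_total = len(offs) + 2
    return OffsetSchedule.from_offsets(offs, [0, n_total - 1])
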