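"""Submembrane cisternae gap morphometry.

Outer hair cells carry ordered membranous cisternae beneath their lateral
plasma membrane.  Quantification starts from *annotated* segment intervals
along the membrane contour (detection from raw electron micrographs is out of
scope): each cisterna is an interval ``[start, end]`` in contour coordinates
(μm), and the measurement of interest is the lateral gap between consecutive
cisternae, ``gap_i = start_{i+1} − end_i``.  Only interior gaps are counted —
the runs from the contour endpoints to the first/last cisterna are not gaps
between adjacent cisternae.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "CisternaeProfile",
    "GapSet",
    "ProfileValidationError",
    "gap_lengths",
    "compare_gap_groups",
    "profiles_to_frame",
    "profiles_from_frame",
]


class ProfileValidationError(ValueError):
    """Raised for overlapping, unsorted or out-of-range cisternae segments."""


@dataclass(frozen=True)
class CisternaeProfile:
    """Ordered cisternae segments along one cell's membrane contour."""

    contour_length: float
    segments: tuple[tuple[float, float], ...]
    cell_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.contour_length <= 0:
            raise ProfileValidationError("contour_length must be positive")
        segs = tuple((float(s), float(e)) for s, e in self.segments)
        object.__setattr__(self, "segments", segs)
        for i, (s, e) in enumerate(segs):
            if not e > s:
                raise ProfileValidationError(
                    f"segment {i} of cell {self.cell_id!r} has end <= start: [{s}, {e}]"
                )
            if s < -1e-9 or e > self.contour_length + 1e-9:
                raise ProfileValidationError(
                    f"segment {i} of cell {self.cell_id!r} outside [0, "
                    f"{self.contour_length}]: [{s}, {e}]"
                )
        for i in range(len(segs) - 1):
            if segs[i + 1][0] < segs[i][1]:
                raise ProfileValidationError(
                    f"segments {i} and {i + 1} of cell {self.cell_id!r} overlap or "
                    f"are unsorted: {segs[i]} then {segs[i + 1]}"
                )


@dataclass(frozen=True)
class GapSet:
    """Interior gap lengths of one profile; mean is NaN for < 2 segments."""

    gaps: tuple[float, ...]
    cell_id: str = ""
    group: str = ""
    mean_gap: float = field(init=False)

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gaps):
            raise ProfileValidationError("negative gap length")
        mean = float(np.mean(self.gaps)) if self.gaps else math.nan
        object.__setattr__(self, "mean_gap", mean)


def gap_lengths(profile: CisternaeProfile) -> GapSet:
    """Lateral distances between consecutive cisternae segments.

    For n segments there are n − 1 interior gaps; a single segment yields an
    empty gap list with undefined (NaN) mean.
    """
    if len(profile.segments) < 1:
        raise ProfileValidationError("profile has no segments")
    gaps = tuple(
        profile.segments[i + 1][0] - profile.segments[i][1]
        for i in range(len(profile.segments) - 1)
    )
    return GapSet(gaps=gaps, cell_id=profile.cell_id, group=profile.group)


def compare_gap_groups(
    profiles_by_group: Mapping[str, Sequence[CisternaeProfile]],
) -> dict:
    """Two-group comparison of pooled gap lengths (two-sided Mann–Whitney).

    Returns per-group n/mean/SD of the pooled gaps plus the Mann–Whitney
    U statistic and two-sided p-value.
    """
    if len(profiles_by_group) != 2:
        raise ValueError(
            f"expected exactly two groups, got {sorted(profiles_by_group)}"
        )
    pooled: dict[str, np.ndarray] = {}
    for name, profiles in profiles_by_group.items():
        gaps = [g for prof in profiles for g in gap_lengths(prof).gaps]
        if not gaps:
            raise ValueError(
                f"group {name!r} contributes no interior gaps "
                "(profiles need at least two segments each)"
            )
        pooled[name] = np.asarray(gaps, dtype=float)

    (name_a, a), (name_b, b) = pooled.items()
    result = _stats.mann_whitney(a, b)
    summary = pd.DataFrame(
        {
            "group": [name_a, name_b],
            "n_gaps": [len(a), len(b)],
            "mean_gap_um": [a.mean(), b.mean()],
            "sd_gap_um": [a.std(ddof=1) if len(a) > 1 else math.nan,
                          b.std(ddof=1) if len(b) > 1 else math.nan],
        }
    )
    return {"summary": summary, "test": result}


# ---------------------------------------------------------------------------
# tabular interface: long-format profile CSV
# columns: cell_id, group, contour_length_um, segment_index, start_um, end_um

def profiles_to_frame(profiles: Sequence[CisternaeProfile]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": p.cell_id,
            "group": p.group,
            "contour_length_um": p.contour_length,
            "segment_index": i,
            "start_um": s,
            "end_um": e,
        }
        for p in profiles
        for i, (s, e) in enumerate(p.segments)
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "group", "contour_length_um",
                 "segment_index", "start_um", "end_um"],
    )


def profiles_from_frame(df: pd.DataFrame) -> list[CisternaeProfile]:
    profiles = []
    for (cell_id, group, clen), sub in df.groupby(
        ["cell_id", "group", "contour_length_um"], sort=False
    ):
        sub = sub.sort_values("segment_index")
        profiles.append(
            CisternaeProfile(
                contour_length=float(clen),
                segments=tuple(zip(sub["start_um"], sub["end_um"])),
                cell_id=str(cell_id),
                group=str(group),
            )
        )
    return profiles
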