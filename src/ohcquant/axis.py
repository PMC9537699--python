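"""Landmark-based cell-axis morphometry.

Outer hair cells are elongated, gently curved cells. Their main axis is
summarised by three anatomical reference points — the apical surface, the
nucleus centroid and the basal end — and a smooth curve fitted through them.
Two quantities derive from the fitted curve:

* ``total_length`` — arc length of the curve from apical to basal landmark,
  the estimate of total cell length (μm);
* ``nucleus_arc`` — arc length from the apical landmark to the nucleus
  centroid (μm).

Their ratio, the *relative nuclear position* ``p = nucleus_arc / total_length``,
is 0 at the apical surface and 1 at the basal pole; in wild-type outer hair
cells the nucleus sits basally (p ≈ 0.7–0.8), and nuclear-positioning defects
shift it apically.

The curve family is a single quadratic parametric polynomial (Lagrange
interpolation through the three landmarks) with the nucleus assigned the
chord-length parameter ``t_N = |AN| / (|AN| + |NB|)``.  This is the unique
quadratic through the points, is infinitely smooth, and degenerates exactly
to a straight segment when the landmarks are collinear.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CellLandmarks",
    "CellAxisCurve",
    "RelativePosition",
    "DegenerateAxisError",
    "fit_cell_axis",
    "relative_nuclear_position",
    "batch_positions",
    "read_landmarks",
    "LANDMARK_COLUMNS",
]

#: tolerance below which two landmarks are considered coincident (μm)
_COINCIDENT_TOL = 1e-12


class DegenerateAxisError(ValueError):
    """Raised when the landmarks do not define a usable cell axis."""


def _sqrt_quadratic_antideriv(A: float, B: float, C: float, t: float) -> float:
    """Antiderivative of sqrt(A t² + B t + C) at t, for A > 0.

    With u = 2At + B and k = 4AC − B² (k ≥ 0 whenever the quadratic is a
    squared speed), the antiderivative is
    ``u·sqrt(u² + k) / (8 A^{3/2}) + k·asinh(u / sqrt(k)) / (8 A^{3/2})``;
    the asinh form is numerically stable for u of either sign.  k = 0 means
    the velocity passes through zero (collinear degenerate parameterization)
    and the log/asinh term vanishes.
    """
    u = 2.0 * A * t + B
    k = max(4.0 * A * C - B * B, 0.0)
    s = math.sqrt(u * u + k)
    val = u * s
    if k > 0:
        val += k * math.asinh(u / math.sqrt(k))
    return val / (8.0 * A**1.5)


@dataclass(frozen=True)
class CellLandmarks:
    """Three anatomical reference points of one cell, in physical μm.

    Points are 3-vectors; 2D data is embedded at z = 0. The coordinate
    order within a point is irrelevant to the morphometry (all quantities
    are rotation invariant) but must be consistent across the three points.
    """

    apical: np.ndarray
    nucleus_centroid: np.ndarray
    basal: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        for name in ("apical", "nucleus_centroid", "basal"):
            pt = np.asarray(getattr(self, name), dtype=float)
            if pt.shape == (2,):
                pt = np.array([pt[0], pt[1], 0.0])
            if pt.shape != (3,):
                raise ValueError(f"{name} must be a 2- or 3-vector, got shape {pt.shape}")
            if not np.all(np.isfinite(pt)):
                raise ValueError(f"{name} contains non-finite coordinates: {pt}")
            object.__setattr__(self, name, pt)
        if np.linalg.norm(self.basal - self.apical) < _COINCIDENT_TOL:
            raise DegenerateAxisError(
                f"apical and basal landmarks coincide for cell {self.cell_id!r}"
            )


@dataclass(frozen=True)
class CellAxisCurve:
    """Quadratic parametric curve C(t) = a t² + b t + c through the landmarks.

    C(0) is the apical landmark, C(1) the basal landmark and C(t_nucleus) the
    nucleus centroid.  ``total_length`` and ``nucleus_arc`` are arc lengths in
    μm obtained by adaptive quadrature of ‖C′(t)‖.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    t_nucleus: float
    total_length: float
    nucleus_arc: float
    landmarks: CellLandmarks = field(repr=False)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (
            np.multiply.outer(t * t, self.a)
            + np.multiply.outer(t, self.b)
            + self.c
        )

    def speed(self, t):
        """‖C′(t)‖ — the integrand of the arc-length functional."""
        t = np.asarray(t, dtype=float)
        d = np.multiply.outer(2.0 * t, self.a) + self.b
        return np.linalg.norm(d, axis=-1)

    def arc_length(self, t0: float, t1: float) -> float:
        """Arc length between parameters t0 and t1.

        For a quadratic curve the speed is ``sqrt(A t² + B t + C)`` with
        A = 4‖a‖², B = 4 a·b, C = ‖b‖², and the arc-length integral has an
        exact closed-form antiderivative — no quadrature error enters.
        """
        if t1 < t0:
            t0, t1 = t1, t0
        A = 4.0 * float(self.a @ self.a)
        B = 4.0 * float(self.a @ self.b)
        C = float(self.b @ self.b)
        if A == 0.0:  # straight segment: constant speed ‖b‖
            return math.sqrt(C) * (t1 - t0)
        if abs(B) + A * max(1.0, t0 * t0, t1 * t1) <= 1e-8 * C:
            # nearly collinear: the closed form differences two almost equal
            # antiderivative values and loses all precision, while the speed
            # deviates from sqrt(C) by < 1e-8 relatively — the first-order
            # expansion is then exact to double precision
            corr = (B * (t1 * t1 - t0 * t0) / 2.0
                    + A * (t1 ** 3 - t0 ** 3) / 3.0) / (2.0 * math.sqrt(C))
            return math.sqrt(C) * (t1 - t0) + corr
        return _sqrt_quadratic_antideriv(A, B, C, t1) - _sqrt_quadratic_antideriv(
            A, B, C, t0
        )


@dataclass(frozen=True)
class RelativePosition:
    """Relative nuclear position p = nucleus_arc / total_length ∈ [0, 1]."""

    value: float
    nucleus_arc: float
    total_length: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"relative position out of [0,1]: {self.value}")


def fit_cell_axis(
    landmarks: CellLandmarks, *, off_axis_warn_ratio: float = 1.0
) -> CellAxisCurve:
    """Fit the smooth cell axis through apical, nucleus and basal landmarks.

    The nucleus is assigned the internal parameter
    ``t_N = |AN| / (|AN| + |NB|)`` (chord-length parameterization) and the
    unique quadratic interpolant through the three points is constructed.
    Arc lengths are evaluated with the exact closed-form antiderivative of
    the quadratic speed, so the only error in the metrics is landmark
    placement, not integration.

    A nucleus centroid whose perpendicular offset from the apical–basal chord
    exceeds ``off_axis_warn_ratio`` times the chord length triggers a warning
    (likely a mis-annotated landmark) but not an error.
    """
    A = landmarks.apical
    N = landmarks.nucleus_centroid
    B = landmarks.basal

    chord = B - A
    v = N - A
    w = B - N
    chord_len = math.sqrt(float(chord @ chord))
    d_an = math.sqrt(float(v @ v))
    d_nb = math.sqrt(float(w @ w))

    # perpendicular offset of the nucleus from the apical-basal chord,
    # via the Gram identity |v|² − (v·û)² (cheaper than a cross product)
    along = float(v @ chord) / chord_len
    perp = math.sqrt(max(d_an * d_an - along * along, 0.0))
    if perp > off_axis_warn_ratio * chord_len:
        warnings.warn(
            f"nucleus centroid of cell {landmarks.cell_id!r} lies "
            f"{perp:.2f} μm off a {chord_len:.2f} μm chord; check landmarks",
            stacklevel=2,
        )

    if d_an < _COINCIDENT_TOL or d_nb < _COINCIDENT_TOL:
        # nucleus coincides with an end landmark: the quadratic nodes collapse,
        # and the only smooth interpolant is the straight chord
        a = np.zeros(3)
        b = chord
        t_n = 0.0 if d_an < _COINCIDENT_TOL else 1.0
        curve = CellAxisCurve(
            a=a, b=b, c=A.copy(), t_nucleus=t_n,
            total_length=chord_len,
            nucleus_arc=0.0 if t_n == 0.0 else chord_len,
            landmarks=landmarks,
        )
        return curve

    t_n = d_an / (d_an + d_nb)
    # solve C(t_n) = N, C(1) = B with C(t) = a t² + b t + A
    a = ((N - A) - t_n * chord) / (t_n * t_n - t_n)
    b = chord - a

    partial = CellAxisCurve(
        a=a, b=b, c=A.copy(), t_nucleus=t_n,
        total_length=np.nan, nucleus_arc=np.nan, landmarks=landmarks,
    )
    # integrate the two sub-intervals separately so t_N is a node: the speed
    # is smooth but this keeps nucleus_arc + remainder == total_length exactly
    s_n = partial.arc_length(0.0, t_n)
    total = s_n + partial.arc_length(t_n, 1.0)
    return CellAxisCurve(
        a=a, b=b, c=A.copy(), t_nucleus=t_n,
        total_length=total, nucleus_arc=s_n, landmarks=landmarks,
    )


def relative_nuclear_position(curve: CellAxisCurve) -> RelativePosition:
    """p = nucleus_arc / total_length along the fitted axis."""
    if not curve.total_length > 0:
        raise DegenerateAxisError("fitted axis has zero length")
    p = curve.nucleus_arc / curve.total_length
    return RelativePosition(
        value=float(min(max(p, 0.0), 1.0)),
        nucleus_arc=curve.nucleus_arc,
        total_length=curve.total_length,
    )


# ---------------------------------------------------------------------------
# tabular interface

LANDMARK_COLUMNS = [
    "cell_id", "group", "age",
    "ax", "ay", "az", "nx", "ny", "nz", "bx", "by", "bz",
    "units", "voxel_z", "voxel_y", "voxel_x",
]


def read_landmarks(path) -> pd.DataFrame:
    """Read a landmark CSV, converting voxel-unit rows to physical μm.

    Expected columns: cell_id, group, age, ax..az, nx..nz, bx..bz, units
    (``um`` or ``voxel``), voxel_z, voxel_y, voxel_x.  Missing group/age/units
    columns default to "", "", "um".
    """
    df = pd.read_csv(path)
    for col, default in (("group", ""), ("age", ""), ("units", "um")):
        if col not in df.columns:
            df[col] = default
    vox_rows = df["units"].astype(str).str.lower().eq("voxel")
    if vox_rows.any():
        for axis, vcol in (("x", "voxel_x"), ("y", "voxel_y"), ("z", "voxel_z")):
            scale = df.loc[vox_rows, vcol].astype(float)
            for prefix in ("a", "n", "b"):
                df.loc[vox_rows, f"{prefix}{axis}"] = (
                    df.loc[vox_rows, f"{prefix}{axis}"].astype(float) * scale
                )
        df.loc[vox_rows, "units"] = "um"
    return df


def batch_positions(landmarks: pd.DataFrame | str) -> pd.DataFrame:
    """Compute per-cell axis metrics for a landmark table.

    Accepts a DataFrame in the landmark CSV schema or a path to such a CSV.
    Returns one row per input row, in input order, with columns cell_id,
    group, age, total_length_um, nucleus_arc_um, relative_position and error.
    Malformed rows yield NA metrics and a recorded reason instead of raising.
    """
    if not isinstance(landmarks, pd.DataFrame):
        landmarks = read_landmarks(landmarks)
    else:
        landmarks = landmarks.copy()
        for col, default in (("group", ""), ("age", "")):
            if col not in landmarks.columns:
                landmarks[col] = default

    records = []
    for _, row in landmarks.iterrows():
        rec = {
            "cell_id": row.get("cell_id", ""),
            "group": row.get("group", ""),
            "age": row.get("age", ""),
            "total_length_um": np.nan,
            "nucleus_arc_um": np.nan,
            "relative_position": np.nan,
            "error": "",
        }
        try:
            lm = CellLandmarks(
                apical=np.array([row["ax"], row["ay"], row["az"]], dtype=float),
                nucleus_centroid=np.array([row["nx"], row["ny"], row["nz"]], dtype=float),
                basal=np.array([row["bx"], row["by"], row["bz"]], dtype=float),
                cell_id=str(rec["cell_id"]),
            )
            curve = fit_cell_axis(lm)
            pos = relative_nuclear_position(curve)
        except (ValueError, KeyError) as exc:  # includes DegenerateAxisError
            rec["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("cell %s skipped: %s", rec["cell_id"], rec["error"])
        else:
            rec.update(
                total_length_um=pos.total_length,
                nucleus_arc_um=pos.nucleus_arc,
                relative_position=pos.value,
            )
        records.append(rec)
    return pd.DataFrame.from_records(
        records,
        columns=["cell_id", "group", "age", "total_length_um",
                 "nucleus_arc_um", "relative_position", "error"],
    )
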