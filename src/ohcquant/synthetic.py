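"""Ground-truthed synthetic data for the hair-cell quantification pipeline.

Generates the three kinds of input the analysis consumes, with known truth:

* **single-cell image stacks** — an elongated, optionally bent cell body
  (a tube of physical radius around a curved midline) containing a spheroid
  nucleus at a prescribed arc-length position, rendered into three channels
  (DAPI-like, cytoplasm/microtubule-like, and a reporter with optional
  nuclear-rim enrichment ``k``) on an anisotropic voxel grid with
  Poisson + Gaussian noise;
* **cohort tables** — per-cell relative nuclear positions drawn from
  truncated normals per group × age, supporting an "onset" design where the
  groups coincide at early ages and diverge later;
* **cisternae profiles** — ordered segment layouts along a membrane contour
  with prescribed gap lengths.

All generators are pure functions of (spec, seed).  The default midline is a
*sinusoidal* bend — deliberately outside the quadratic family the axis
fitter uses — so recovery tests measure genuine approximation error, not a
fit of the model to itself.  Ground-truth arc lengths are computed by dense
polyline integration of the generative midline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .axis import CellLandmarks
from .cisternae import CisternaeProfile
from .recruitment import ImageStack, segment_nucleus

__all__ = [
    "SyntheticCellSpec",
    "SyntheticCohortSpec",
    "GroundTruth",
    "generate_cell_image",
    "generate_cohort",
    "generate_cisternae_profile",
    "generate_cisternae_cohort",
    "onset_cohort_spec",
    "landmarks_from_ground_truth",
    "segmented_nucleus_landmarks",
    "cohort_to_landmark_frame",
]

#: spacing (μm) of the dense midline polyline used as the arc-length oracle
_MIDLINE_SAMPLING_UM = 0.01


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Physical description of one synthetic hair cell.

    ``axis_curvature`` is a dimensionless bend amplitude: the midline's peak
    lateral deflection as a fraction of its axial extent (0 = straight).
    ``ne_enrichment_factor`` (k) multiplies the cytoplasmic reporter
    intensity in a thin shell at the nuclear rim; k = 1 means no envelope
    enrichment.  Defaults emulate a postnatal outer hair cell: ~30 μm long,
    gently bent, nucleus of radius 2.2 μm near the basal pole, imaged with
    confocal-like anisotropic voxels.
    """

    cell_length: float = 30.0
    axis_curvature: float = 0.3
    true_relative_position: float = 0.75
    nucleus_radius: float = 2.2
    cell_radius: float = 3.0
    ne_enrichment_factor: float = 1.0
    ne_shell_thickness: float = 0.3
    cytoplasm_intensity: float = 100.0
    nucleus_intensity: float = 200.0
    background_intensity: float = 10.0
    photon_scaling: float = 50.0
    gaussian_sd: float = 2.0
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)
    midline_family: str = "sinusoidal"  # or "quadratic"

    def __post_init__(self) -> None:
        if self.cell_length <= 0:
            raise ValueError("cell_length must be positive")
        if not 0.0 <= self.true_relative_position <= 1.0:
            raise ValueError("true_relative_position must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        if self.nucleus_radius <= 0 or self.cell_radius <= 0:
            raise ValueError("radii must be positive")
        if self.nucleus_radius > self.cell_radius:
            raise ValueError(
                f"nucleus (radius {self.nucleus_radius} μm) does not fit inside "
                f"the cell body (radius {self.cell_radius} μm)"
            )
        if self.midline_family not in ("sinusoidal", "quadratic"):
            raise ValueError("midline_family must be 'sinusoidal' or 'quadratic'")
        if self.ne_enrichment_factor < 0:
            raise ValueError("ne_enrichment_factor must be >= 0")
        if self.photon_scaling < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """Noiseless truth recorded alongside a generated stack."""

    landmarks: CellLandmarks
    true_relative_position: float
    true_total_length: float
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    ne_enrichment_factor: float
    nucleus_center: np.ndarray       # (z, y, x) μm
    grid_origin: np.ndarray          # physical coords of voxel (0,0,0) center
    voxel_size: tuple[float, float, float]
    noiseless: dict[str, np.ndarray] = field(default_factory=dict)
    midline: np.ndarray | None = None


def _midline_polyline(spec: SyntheticCellSpec) -> np.ndarray:
    """Dense (z, y, x) polyline of the generative midline, total arc = cell_length.

    The lateral profile is ``amplitude · f(u)`` with f a half-sine (default)
    or parabolic bump; the axial extent is solved so the polyline arc length
    equals ``cell_length`` (lateral deflection scales with the extent, so
    the arc is linear in it).
    """
    n = max(int(spec.cell_length / _MIDLINE_SAMPLING_UM), 512) + 1
    u = np.linspace(0.0, 1.0, n)
    if spec.midline_family == "sinusoidal":
        f = np.sin(np.pi * u)
    else:
        f = 4.0 * u * (1.0 - u)
    # arc length of (u, c f(u)) scaled by axial extent X is X * g(c)
    unit = np.column_stack([u, spec.axis_curvature * f])
    g = float(np.sum(np.linalg.norm(np.diff(unit, axis=0), axis=1)))
    extent = spec.cell_length / g
    pts = np.zeros((n, 3))
    pts[:, 1] = spec.axis_curvature * f * extent   # y deflection
    pts[:, 2] = u * extent                          # x axial
    return pts


def _arc_position(polyline: np.ndarray, fraction: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = fraction * s[-1]
    out = np.empty(3)
    for d in range(3):
        out[d] = np.interp(target, s, polyline[:, d])
    return out


def generate_cell_image(
    spec: SyntheticCellSpec, seed: int
) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic cell into a 3-channel stack with ground truth.

    The cell body is the set of voxels within ``cell_radius`` of the midline
    polyline; the nucleus is a sphere of ``nucleus_radius`` centred on the
    midline at arc fraction ``true_relative_position``.  Channels (noiseless):
    DAPI = background outside / ``nucleus_intensity`` inside the nucleus;
    cell = background / ``cytoplasm_intensity`` over the whole cell body;
    reporter = cytoplasmic intensity over the cell, multiplied by k in a
    shell of ``ne_shell_thickness`` at the nuclear rim.  Noise is Poisson on
    photon-scaled intensities plus additive Gaussian.
    """
    rng = np.random.default_rng(seed)
    midline = _midline_polyline(spec)
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    total_length = float(np.sum(seg))
    center = _arc_position(midline, spec.true_relative_position)

    margin = spec.cell_radius + 1.0
    lo = midline.min(axis=0) - margin
    hi = midline.max(axis=0) + margin
    counts = np.maximum(np.ceil((hi - lo) / spec.voxel_size).astype(int) + 1, 1)
    origin = lo
    axes = [origin[d] + np.arange(counts[d]) * spec.voxel_size[d] for d in range(3)]

    # the generative midline is planar (constant z), so the 3D distance to it
    # decomposes into an in-plane distance plus a z offset: one 2D KDTree
    # query over the (y, x) grid instead of a 3D query over every voxel
    Yg, Xg = np.meshgrid(axes[1], axes[2], indexing="ij")
    tree = cKDTree(midline[:, 1:3])
    d_plane, _ = tree.query(np.column_stack([Yg.ravel(), Xg.ravel()]), workers=-1)
    d_plane = d_plane.reshape(Yg.shape)
    dz = axes[0] - midline[0, 0]
    dist_mid = np.sqrt(dz[:, None, None] ** 2 + d_plane[None, :, :] ** 2)
    cell_mask = dist_mid <= spec.cell_radius

    dist_nuc = np.sqrt(
        (axes[0] - center[0])[:, None, None] ** 2
        + (axes[1] - center[1])[None, :, None] ** 2
        + (axes[2] - center[2])[None, None, :] ** 2
    )
    nucleus_mask = dist_nuc <= spec.nucleus_radius
    nucleus_mask &= cell_mask  # r_n <= R guarantees this is a no-op
    shell = (
        ~nucleus_mask
        & (dist_nuc <= spec.nucleus_radius + spec.ne_shell_thickness)
        & cell_mask
    )

    bg, cyto = spec.background_intensity, spec.cytoplasm_intensity
    dapi = np.full(tuple(counts), bg, dtype=float)
    dapi[nucleus_mask] = spec.nucleus_intensity
    cell_ch = np.full(tuple(counts), bg, dtype=float)
    cell_ch[cell_mask] = cyto
    reporter = np.full(tuple(counts), bg, dtype=float)
    reporter[cell_mask] = cyto
    reporter[shell] = cyto * spec.ne_enrichment_factor

    noiseless = {"dapi": dapi, "cell": cell_ch, "reporter": reporter}
    channels = {name: _apply_noise(arr, spec, rng) for name, arr in noiseless.items()}
    stack = ImageStack(channels=channels, voxel_size=spec.voxel_size)

    landmarks = CellLandmarks(
        apical=midline[0], nucleus_centroid=center, basal=midline[-1],
        cell_id="synthetic",
    )
    truth = GroundTruth(
        landmarks=landmarks,
        true_relative_position=spec.true_relative_position,
        true_total_length=total_length,
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        ne_enrichment_factor=spec.ne_enrichment_factor,
        nucleus_center=center,
        grid_origin=origin,
        voxel_size=spec.voxel_size,
        noiseless=noiseless,
        midline=midline,
    )
    return stack, truth


def _apply_noise(
    intensity: np.ndarray, spec: SyntheticCellSpec, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on photon-scaled intensities plus Gaussian read noise.

    ``photon_scaling`` is the expected photon count at cytoplasmic intensity;
    zero disables the Poisson component.
    """
    out = intensity.astype(float)
    if spec.photon_scaling > 0:
        per_unit = spec.photon_scaling / spec.cytoplasm_intensity
        out = rng.poisson(out * per_unit) / per_unit
    if spec.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# landmark extraction helpers (for tests and the end-to-end pipeline)

def landmarks_from_ground_truth(truth: GroundTruth, cell_id: str = "") -> CellLandmarks:
    """True landmarks (apical, nucleus centroid, basal) of a generated cell."""
    lm = truth.landmarks
    return CellLandmarks(
        apical=lm.apical, nucleus_centroid=lm.nucleus_centroid, basal=lm.basal,
        cell_id=cell_id or lm.cell_id,
    )


def segmented_nucleus_landmarks(
    stack: ImageStack, truth: GroundTruth, cell_id: str = "", method: str = "otsu"
) -> CellLandmarks:
    """Landmarks with the nucleus centroid measured from the noisy image.

    Mimics the realistic annotation workflow: apical and basal poles are
    taken as marked (ground truth), while the nucleus centroid is the
    centroid of the auto-threshold DAPI segmentation converted to physical
    coordinates.
    """
    seg = segment_nucleus(stack.channels["dapi"], method=method)
    idx = np.argwhere(seg.mask)
    centroid_vox = idx.mean(axis=0)
    centroid = truth.grid_origin + centroid_vox * np.asarray(truth.voxel_size)
    return CellLandmarks(
        apical=truth.landmarks.apical,
        nucleus_centroid=centroid,
        basal=truth.landmarks.basal,
        cell_id=cell_id,
    )


def cohort_to_landmark_frame(landmarks: Sequence[CellLandmarks], groups=None,
                             ages=None) -> pd.DataFrame:
    """Assemble CellLandmarks (z,y,x μm points) into the landmark CSV schema."""
    rows = []
    for i, lm in enumerate(landmarks):
        rows.append(
            {
                "cell_id": lm.cell_id or f"cell{i:03d}",
                "group": groups[i] if groups is not None else "",
                "age": ages[i] if ages is not None else "",
                "ax": lm.apical[2], "ay": lm.apical[1], "az": lm.apical[0],
                "nx": lm.nucleus_centroid[2], "ny": lm.nucleus_centroid[1],
                "nz": lm.nucleus_centroid[0],
                "bx": lm.basal[2], "by": lm.basal[1], "bz": lm.basal[0],
                "units": "um",
                "voxel_z": np.nan, "voxel_y": np.nan, "voxel_x": np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort tables

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a synthetic nuclear-position cohort.

    ``group_means``/``group_sds`` map each group either to a single value
    (used at every age) or to a per-age mapping, which expresses onset
    designs where groups coincide early and diverge late.  Drawn positions
    follow a normal truncated to [0, 1].
    """

    n_cells_per_group: int
    group_means: Mapping[str, float | Mapping[str, float]]
    group_sds: Mapping[str, float | Mapping[str, float]]
    ages: tuple[str, ...] = ("P14",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_group < 1:
            raise ValueError("n_cells_per_group must be >= 1")
        if not self.group_means:
            raise ValueError("at least one group required")
        if set(self.group_means) != set(self.group_sds):
            raise ValueError("group_means and group_sds must share keys")
        for g in self.group_means:
            for age in self.ages:
                if self._param(self.group_sds, g, age) < 0:
                    raise ValueError(f"negative sd for group {g!r}, age {age!r}")
                mu = self._param(self.group_means, g, age)
                if not 0.0 <= mu <= 1.0:
                    raise ValueError(f"mean out of [0,1] for group {g!r}: {mu}")

    @staticmethod
    def _param(mapping, group, age) -> float:
        v = mapping[group]
        return float(v[age]) if isinstance(v, Mapping) else float(v)


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a per-cell cohort table of true relative nuclear positions.

    Returns the tidy table (cell_id, group, age, relative_position) plus a
    ground-truth dict of the generating means/sds per group × age.  Identical
    specs (including seed) produce bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth: dict[str, dict[str, tuple[float, float]]] = {}
    counter = 0
    for age in spec.ages:
        for group in spec.group_means:
            mu = spec._param(spec.group_means, group, age)
            sd = spec._param(spec.group_sds, group, age)
            truth.setdefault(group, {})[age] = (mu, sd)
            if sd == 0:
                draws = np.full(spec.n_cells_per_group, mu)
            else:
                a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
                draws = truncnorm.rvs(
                    a, b, loc=mu, scale=sd,
                    size=spec.n_cells_per_group, random_state=rng,
                )
            for value in draws:
                rows.append(
                    {
                        "cell_id": f"cell{counter:04d}",
                        "group": group,
                        "age": age,
                        "relative_position": float(value),
                    }
                )
                counter += 1
    return pd.DataFrame(rows), {"params": truth, "seed": spec.seed}


def onset_cohort_spec(
    n_per_group: int = 10,
    ages: tuple[str, ...] = ("P8", "P10", "P12", "P14"),
    onset_age: str | None = "P12",
    baseline: float = 0.75,
    delta: float = 0.25,
    control_sd: float = 0.05,
    mutant_sd: float = 0.08,
    seed: int = 0,
) -> SyntheticCohortSpec:
    """Cohort spec mimicking the developmental onset design.

    Control and mutant share the basal position (``baseline``) at ages
    before ``onset_age``; from ``onset_age`` on, the mutant mean shifts
    apically by ``delta``.  ``onset_age=None`` gives an all-null cohort.
    """
    onset_idx = len(ages) if onset_age is None else ages.index(onset_age)
    mutant_means = {
        age: baseline - (delta if i >= onset_idx else 0.0)
        for i, age in enumerate(ages)
    }
    return SyntheticCohortSpec(
        n_cells_per_group=n_per_group,
        group_means={"control": baseline, "mutant": mutant_means},
        group_sds={"control": control_sd, "mutant": mutant_sd},
        ages=tuple(ages),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cisternae profiles

def generate_cisternae_profile(
    contour_length: float,
    segment_lengths: Sequence[float],
    gap_lengths: Sequence[float],
    seed: int | None = None,
    *,
    random_start: bool = False,
    cell_id: str = "",
    group: str = "",
) -> tuple[CisternaeProfile, dict]:
    """Lay out ordered cisternae segments with prescribed gaps.

    Segments are packed from contour coordinate 0 (or from a random offset
    within the available slack when ``random_start``); ``gap_lengths`` must
    have one entry fewer than ``segment_lengths``.  Returns the profile and
    a ground-truth dict recording the requested gaps.
    """
    segment_lengths = [float(s) for s in segment_lengths]
    gap_lengths = [float(g) for g in gap_lengths]
    if not segment_lengths:
        raise ValueError("at least one segment required")
    if len(gap_lengths) != len(segment_lengths) - 1:
        raise ValueError(
            f"{len(segment_lengths)} segments need {len(segment_lengths) - 1} "
            f"gaps, got {len(gap_lengths)}"
        )
    if any(s <= 0 for s in segment_lengths) or any(g < 0 for g in gap_lengths):
        raise ValueError("segment lengths must be > 0 and gaps >= 0")
    total = sum(segment_lengths) + sum(gap_lengths)
    if total > contour_length + 1e-9:
        raise ValueError(
            f"segments + gaps ({total} μm) exceed contour length "
            f"({contour_length} μm)"
        )

    start = 0.0
    if random_start:
        rng = np.random.default_rng(seed)
        start = float(rng.uniform(0.0, contour_length - total))

    intervals = []
    pos = start
    for i, seg_len in enumerate(segment_lengths):
        intervals.append((pos, pos + seg_len))
        pos += seg_len
        if i < len(gap_lengths):
            pos += gap_lengths[i]
    profile = CisternaeProfile(
        contour_length=contour_length,
        segments=tuple(intervals),
        cell_id=cell_id,
        group=group,
    )
    return profile, {"gap_lengths": tuple(gap_lengths)}


def generate_cisternae_cohort(
    group_params: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    *,
    n_cells_per_group: int = 5,
    segments_per_cell: int = 7,
    segment_length: float = 2.0,
) -> list[CisternaeProfile]:
    """Profiles for two (or more) groups with genotype-dependent gap lengths.

    ``group_params`` maps group name to ``{"mean_gap": μm, "sd_gap": μm}``;
    per-cell gaps are normal draws truncated at zero.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for group in group_params:
        mean = float(group_params[group]["mean_gap"])
        sd = float(group_params[group]["sd_gap"])
        if sd < 0:
            raise ValueError(f"negative sd for group {group!r}")
        for c in range(n_cells_per_group):
            gaps = np.maximum(
                rng.normal(mean, sd, size=segments_per_cell - 1), 0.0
            )
            contour = segments_per_cell * segment_length + float(gaps.sum()) + 5.0
            profile, _ = generate_cisternae_profile(
                contour,
                [segment_length] * segments_per_cell,
                gaps.tolist(),
                cell_id=f"{group}_cell{c:02d}",
                group=group,
            )
            profiles.append(profile)
    return profiles
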