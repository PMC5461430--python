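"""Synthetic potted-rosette scenes with known fresh weight and volume.

Emulates a turntable phenotyping experiment on romaine-type lettuce: each
plant is a radial arrangement of upright half-ellipsoid leaves on a pot, with
an exact voxel ground-truth head volume. Fresh weight is drawn first
(lognormal around the group mean) and the head volume derived through the
generative linear density relation FW = a0 + a1 * V, so calibration-recovery
tests are exact by construction. Orthographic silhouettes are rendered at a
ring of azimuths, and the treatment experiment additionally emits raw assay
absorbances back-computed through each standard curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from . import assaycalc
from .errors import ConfigError, FrameOverflowError
from .silhouette import SilhouetteSet, ViewImage

__all__ = [
    "Leaf",
    "PlantShapeModel",
    "GrowthConfig",
    "CameraConfig",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_TISSUE_LEVELS",
    "sample_plant",
    "render_views",
    "pot_cut_row",
    "generate_calibration_cohort",
    "generate_experiment",
    "ExperimentData",
]


@dataclass(frozen=True)
class Leaf:
    """Solid half-ellipsoid leaf primitive.

    ``length`` is the semi-axis along the leaf axis (full leaf length from
    the crown), ``max_width``/``thickness`` the full cross-section diameters
    at the base; the leaf axis is tilted ``inclination`` degrees from
    vertical toward azimuth ``azimuth``.
    """

    length: float
    max_width: float
    thickness: float
    inclination: float  # deg from vertical
    azimuth: float      # deg

    def __post_init__(self):
        if min(self.length, self.max_width, self.thickness) <= 0:
            raise ConfigError("leaf dimensions must be > 0")

    @property
    def min_dimension(self) -> float:
        return min(self.length, self.max_width, self.thickness)

    def frame(self) -> tuple:
        """Orthonormal leaf frame (axis, width, thickness directions)."""
        inc = np.deg2rad(self.inclination)
        az = np.deg2rad(self.azimuth)
        d = np.array([np.sin(inc) * np.cos(az), np.sin(inc) * np.sin(az), np.cos(inc)])
        if abs(d[2]) > 0.999:
            w1 = np.array([1.0, 0.0, 0.0])
        else:
            w1 = np.cross([0.0, 0.0, 1.0], d)
            w1 /= np.linalg.norm(w1)
        w2 = np.cross(d, w1)
        return d, w1, w2


@dataclass
class PlantShapeModel:
    """Parametric rosette with an exact voxel ground-truth head volume.

    The head occupies z >= 0 in plant coordinates (z = 0 is the pot rim);
    the ground-truth head volume is the voxel count of the union of leaf
    primitives above the rim times voxel_pitch^3.
    """

    leaves: tuple
    pot_height: float = 8.0   # cm
    pot_radius: float = 5.0   # cm
    voxel_pitch: float = 0.15  # cm

    _points: np.ndarray | None = field(default=None, repr=False, compare=False)
    _volume: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.leaves) < 1:
            raise ConfigError("a plant needs at least one leaf")
        if self.pot_height <= 0 or self.pot_radius <= 0 or self.voxel_pitch <= 0:
            raise ConfigError("pot dimensions and voxel pitch must be > 0")
        min_dim = min(leaf.min_dimension for leaf in self.leaves)
        if self.voxel_pitch > min_dim / 10 + 1e-12:
            raise ConfigError(
                f"voxel_pitch {self.voxel_pitch} exceeds min leaf dimension/10 "
                f"({min_dim / 10:.4g})"
            )

    def voxelize(self) -> tuple:
        """Occupied voxel centres (N x 3, plant coords) and head volume (cm^3)."""
        if self._points is None:
            pts, vol = _voxelize_leaves(self.leaves, self.voxel_pitch)
            self._points, self._volume = pts, vol
        return self._points, self._volume

    @property
    def head_volume(self) -> float:
        return self.voxelize()[1]

    @property
    def head_height(self) -> float:
        pts, _ = self.voxelize()
        return float(pts[:, 2].max()) + self.voxel_pitch / 2

    def scaled(self, s: float) -> "PlantShapeModel":
        """Uniformly scale the plant (and its voxelization) by factor ``s``.

        Scaling the voxel pitch together with the geometry preserves the
        voxel occupancy pattern, so the ground-truth volume scales exactly
        by s^3.
        """
        if s <= 0:
            raise ConfigError("scale factor must be > 0")
        leaves = tuple(
            replace(l, length=l.length * s, max_width=l.max_width * s,
                    thickness=l.thickness * s)
            for l in self.leaves
        )
        model = PlantShapeModel(leaves, pot_height=self.pot_height,
                                pot_radius=self.pot_radius,
                                voxel_pitch=self.voxel_pitch * s)
        if self._points is not None:
            model._points = self._points * s
            model._volume = self._volume * s**3
        return model


def _voxelize_leaves(leaves: Sequence[Leaf], pitch: float) -> tuple:
    """Boolean union of half-ellipsoid leaves on a regular voxel grid."""
    # Conservative world-axis bounding box over all leaves.
    ext = np.zeros(3)
    for leaf in leaves:
        d, w1, w2 = leaf.frame()
        e = np.sqrt((leaf.length * d)**2 + (leaf.max_width / 2 * w1)**2
                    + (leaf.thickness / 2 * w2)**2)
        ext = np.maximum(ext, e)
    lo = np.array([-ext[0], -ext[1], 0.0])
    hi = np.array([ext[0], ext[1], ext[2]])
    n = np.maximum(np.ceil((hi - lo) / pitch).astype(int), 1)
    axes = [lo[i] + (np.arange(n[i]) + 0.5) * pitch for i in range(3)]
    occ = np.zeros(tuple(n), dtype=bool)
    for leaf in leaves:
        d, w1, w2 = leaf.frame()
        e = np.sqrt((leaf.length * d)**2 + (leaf.max_width / 2 * w1)**2
                    + (leaf.thickness / 2 * w2)**2)
        i0 = np.maximum(((-e - lo) / pitch).astype(int) - 1, 0)
        i1 = np.minimum(((e - lo) / pitch).astype(int) + 2, n)
        X = axes[0][i0[0]:i1[0]][:, None, None]
        Y = axes[1][i0[1]:i1[1]][None, :, None]
        Z = axes[2][i0[2]:i1[2]][None, None, :]
        u = X * d[0] + Y * d[1] + Z * d[2]
        v = X * w1[0] + Y * w1[1] + Z * w1[2]
        w = X * w2[0] + Y * w2[1] + Z * w2[2]
        inside = (u >= 0) & (
            (u / leaf.length)**2 + (v / (leaf.max_width / 2))**2
            + (w / (leaf.thickness / 2))**2 <= 1.0
        )
        occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    idx = np.argwhere(occ)
    pts = lo + (idx + 0.5) * pitch
    return pts, float(occ.sum()) * pitch**3


@dataclass
class VoxelSolid:
    """A bare voxelized solid (no leaf parametrisation).

    Used for geometric validation of the rendering/volumetry chain with
    shapes of known closed-form volume; quacks like
    :class:`PlantShapeModel` for :func:`render_views`.
    """

    points: np.ndarray
    voxel_pitch: float
    pot_height: float = 0.0
    pot_radius: float = 1.0

    def voxelize(self) -> tuple:
        return self.points, float(len(self.points)) * self.voxel_pitch**3

    @property
    def head_volume(self) -> float:
        return self.voxelize()[1]


def voxel_sphere(radius: float, pitch: float,
                 center_height: float | None = None) -> VoxelSolid:
    """Voxelized sphere; closed-form volume 4/3 pi r^3."""
    if center_height is None:
        center_height = radius + pitch
    n = int(np.ceil(radius / pitch)) + 1
    ax = (np.arange(-n, n + 1) + 0.5) * pitch
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= radius**2
    pts = np.column_stack([X[inside], Y[inside], Z[inside] + center_height])
    return VoxelSolid(pts, pitch)


def voxel_cylinder(radius: float, height: float, pitch: float,
                   base_height: float = 0.0) -> VoxelSolid:
    """Voxelized vertical cylinder; closed-form volume pi r^2 h."""
    n = int(np.ceil(radius / pitch)) + 1
    ax = (np.arange(-n, n + 1) + 0.5) * pitch
    nz = int(round(height / pitch))
    az = (np.arange(nz) + 0.5) * pitch
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    inside = X**2 + Y**2 <= radius**2
    pts = np.column_stack([X[inside], Y[inside], Z[inside] + base_height])
    return VoxelSolid(pts, pitch)


DEFAULT_GROUP_MEANS: Mapping[str, Mapping[int, float]] = {
    # Mean head fresh weight (g) per treatment group and day after
    # transplanting: ~20-24 g before treatment, ~34-38 g mid-cycle, and at
    # harvest a 55.9 g control with +4/+15/+13/+18% treatment effects.
    "control": {12: 22.0, 17: 35.0, 22: 55.9},
    "LE-1": {12: 22.0, 17: 34.0, 22: 55.9 * 1.04},
    "LE-10": {12: 23.0, 17: 38.0, 22: 55.9 * 1.15},
    "FE-1": {12: 22.0, 17: 34.0, 22: 55.9 * 1.13},
    "FE-10": {12: 23.0, 17: 38.0, 22: 55.9 * 1.18},
}


@dataclass(frozen=True)
class GrowthConfig:
    """Generative parameters of the synthetic cohorts.

    ``density_intercept``/``density_slope`` are the true coefficients of the
    fresh-weight/volume relation FW = a0 + a1 * V used in generation;
    ``fw_cv`` the between-plant coefficient of variation of fresh weight
    within a group; ``fw_measurement_sd`` the balance/handling error (g)
    added to the destructively measured weight of calibration plants.
    """

    timepoints: tuple = (12, 17, 22)
    group_mean_fw: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_GROUP_MEANS.items()}
    )
    fw_cv: float = 0.05
    density_slope: float = 0.013     # g / cm^3
    density_intercept: float = -1.97  # g
    calib_fw_range: tuple = (2.5, 155.8)
    fw_measurement_sd: float = 2.2   # g
    seed: int = 0

    @property
    def groups(self) -> tuple:
        return tuple(self.group_mean_fw)

    def __post_init__(self):
        if not 0.0 <= self.fw_cv < 0.5:
            raise ConfigError("fw_cv must lie in [0, 0.5)")
        for g, by_day in self.group_mean_fw.items():
            for day, m in by_day.items():
                if m <= 0:
                    raise ConfigError(f"mean fresh weight for {g}@{day} must be > 0")
        if self.density_slope == 0:
            raise ConfigError("density_slope must be nonzero")


@dataclass(frozen=True)
class CameraConfig:
    """Orthographic turntable camera: 11 views at 30 degree steps by default."""

    n_views: int = 11
    azimuth_step: float = 30.0
    image_width: int = 384
    image_height: int = 288
    pixel_scale: float = 0.2  # cm per pixel
    axis_column: int | None = None
    projection: str = "orthographic"

    def __post_init__(self):
        if self.n_views < 1:
            raise ConfigError("need at least one view")
        if self.n_views * self.azimuth_step > 360.0 + 1e-9:
            raise ConfigError("views must cover at most 360 degrees")
        if self.pixel_scale <= 0:
            raise ConfigError("pixel_scale must be > 0")
        if self.projection != "orthographic":
            raise ConfigError("only orthographic projection is supported")

    @property
    def axis(self) -> int:
        return self.image_width // 2 if self.axis_column is None else self.axis_column


def _sample_rosette(rng: np.random.Generator,
                    n_leaves: int | None = None) -> tuple:
    """Canonical-size rosette: outer whorl steep, inner whorl more upright."""
    if n_leaves is None:
        n_leaves = 10
    n_outer = max(int(round(n_leaves * 0.6)), 1)
    # Between-plant architectural jitter is kept small: a single-cultivar
    # cohort is morphologically uniform, and the silhouette-envelope to
    # true-volume ratio must stay near-constant across plants for the linear
    # weight calibration to hold the way it does on real heads.
    leaves = []
    base = rng.uniform(0, 360)  # one global turntable orientation per plant
    for ring, count, inc_mid, ring_offset in (
        ("outer", n_outer, 55.0, 0.0),
        ("inner", n_leaves - n_outer, 31.0, 30.0),
    ):
        if count <= 0:
            continue
        for k in range(count):
            az = (base + ring_offset + 360.0 * k / count + rng.uniform(-3, 3)) % 360.0
            length = float(np.clip(rng.normal(10.0, 0.25), 9.2, 10.8))
            leaves.append(Leaf(
                length=length,
                max_width=0.45 * length,
                thickness=float(np.clip(rng.normal(1.8, 0.05), 1.65, 1.95)),
                inclination=float(inc_mid + rng.uniform(-2, 2)),
                azimuth=az,
            ))
    return tuple(leaves)


def _plant_for_volume(true_volume: float, rng: np.random.Generator,
                      pot_height: float = 8.0,
                      pot_radius: float = 5.0) -> PlantShapeModel:
    """Rosette scaled so its voxel ground-truth volume equals true_volume."""
    leaves = _sample_rosette(rng)
    pitch = min(l.min_dimension for l in leaves) / 10.0
    canonical = PlantShapeModel(leaves, pot_height=pot_height,
                                pot_radius=pot_radius, voxel_pitch=pitch)
    v0 = canonical.head_volume
    return canonical.scaled((true_volume / v0) ** (1.0 / 3.0))


def _draw_fw(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Lognormal fresh weight with exact mean and coefficient of variation."""
    if cv <= 1e-12:
        return float(mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def sample_plant(config: GrowthConfig, group: str, dat: int,
                 rng: np.random.Generator,
                 build_shape: bool = True) -> tuple:
    """Draw one plant: (PlantShapeModel | None, true_fw g, true_volume cm^3).

    Fresh weight is lognormal around the configured group mean at day ``dat``
    with CV ``fw_cv``; the true head volume inverts the generative linear
    relation, and the rosette is scaled so its voxel volume matches exactly.
    """
    try:
        mean = config.group_mean_fw[group][dat]
    except KeyError:
        raise ConfigError(f"no configured mean for group '{group}' at day {dat}")
    fw = _draw_fw(mean, config.fw_cv, rng)
    volume = (fw - config.density_intercept) / config.density_slope
    if volume <= 0:
        raise ConfigError(
            f"fresh weight {fw:.3g} g implies non-positive volume under "
            f"FW = {config.density_intercept} + {config.density_slope} * V"
        )
    shape = _plant_for_volume(volume, rng) if build_shape else None
    return shape, fw, volume


def pot_cut_row(cam: CameraConfig, pot_height: float) -> int:
    """First image row at/below which the pot appears (head rows are above)."""
    return int(np.floor((cam.image_height - 1) - pot_height / cam.pixel_scale)) + 1


def render_views(shape: PlantShapeModel, cam: CameraConfig,
                 include_pot: bool = True, plant_id: str = "",
                 timepoint: float = 0.0) -> SilhouetteSet:
    """Orthographic binary silhouettes of the plant at each turntable azimuth.

    Voxel centres are rotated about the vertical axis and splatted onto the
    pixel grid; a single 3x3 closing plus hole filling removes sampling
    pinholes. The pot is a filled rectangle below the head. Background is 0,
    foreground 255.
    """
    pts, _ = shape.voxelize()
    ps = cam.pixel_scale
    H, W, axis = cam.image_height, cam.image_width, cam.axis
    r_max = float(np.sqrt(pts[:, 0]**2 + pts[:, 1]**2).max())
    h_max = float(pts[:, 2].max()) + shape.pot_height
    half_px = int(np.ceil(r_max / ps)) + 1
    height_px = int(np.ceil(h_max / ps)) + 1
    if (axis - half_px < 0 or axis + half_px > W - 1 or height_px > H - 1):
        raise FrameOverflowError(2 * half_px + 3, height_px + 2)

    heights = pts[:, 2] + shape.pot_height
    rows = (H - 1 - np.rint(heights / ps)).astype(np.intp)
    pot_rows = slice(pot_cut_row(cam, shape.pot_height), H)
    pot_half = int(round(shape.pot_radius / ps))
    views = []
    for k in range(cam.n_views):
        theta = np.deg2rad(k * cam.azimuth_step)
        x_img = pts[:, 0] * np.cos(theta) + pts[:, 1] * np.sin(theta)
        cols = (axis + np.rint(x_img / ps)).astype(np.intp)
        img = np.zeros((H, W), dtype=bool)
        img[rows, cols] = True
        img = ndimage.binary_closing(img, structure=np.ones((3, 3), bool))
        img = ndimage.binary_fill_holes(img)
        if include_pot:
            img[pot_rows, max(axis - pot_half, 0):min(axis + pot_half + 1, W)] = True
        views.append(ViewImage(
            raster=(img.astype(np.uint8) * 255),
            azimuth=(k * cam.azimuth_step) % 360.0,
            pixel_scale=ps,
            axis_column=axis,
        ))
    return SilhouetteSet(views=tuple(views), plant_id=plant_id, timepoint=timepoint)


def generate_calibration_cohort(config: GrowthConfig,
                                cam: CameraConfig | None = None,
                                plants_per_date: int = 6,
                                n_dates: int = 13,
                                seed: int | None = None,
                                render: bool | None = None):
    """The wide-range calibration cohort: subsets harvested every fourth day.

    Returns ``(silhouettes, truth)`` where ``truth`` is a DataFrame with one
    row per plant (plant_id, date, true_fw, measured_fw, true_volume). Date
    means are geometrically spaced so fresh weights span the configured
    range; the destructively measured weight adds Gaussian balance error.
    With ``render=False`` (the default when no camera is given) shapes and
    images are skipped and ``silhouettes`` is an empty list.
    """
    import pandas as pd

    if render is None:
        render = cam is not None
    if render and cam is None:
        raise ConfigError("rendering requires a CameraConfig")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.calib_fw_range
    date_means = np.geomspace(lo * 1.3, hi / 1.2, n_dates)
    rows, silhouettes = [], []
    for i in range(n_dates):
        day = 4 * (i + 1)
        for j in range(plants_per_date):
            fw = float(np.clip(_draw_fw(date_means[i], config.fw_cv, rng), lo, hi))
            volume = (fw - config.density_intercept) / config.density_slope
            measured = fw + rng.normal(0.0, config.fw_measurement_sd) \
                if config.fw_measurement_sd > 0 else fw
            measured = max(measured, 0.1)
            pid = f"cal-{day:02d}-{j}"
            if render:
                shape = _plant_for_volume(volume, rng)
                silhouettes.append(render_views(shape, cam, plant_id=pid,
                                                timepoint=day))
            rows.append(dict(plant_id=pid, date=day, true_fw=fw,
                             measured_fw=measured, true_volume=volume))
    return silhouettes, pd.DataFrame(rows)


#: Configured tissue levels per analyte and group at harvest. Treatments
#: raise the phenylpropanoid panel (phenolics, flavonoids, antioxidant
#: capacity), strongest for flower extracts; nitrate and sugars unchanged.
DEFAULT_TISSUE_LEVELS: Mapping[str, Mapping[str, float]] = {
    "nitrate": {g: 1500.0 for g in DEFAULT_GROUP_MEANS},          # mg/kg FW
    "sucrose": {g: 1.2 for g in DEFAULT_GROUP_MEANS},             # mg/g FW
    "total_sugars": {g: 8.0 for g in DEFAULT_GROUP_MEANS},        # mg/g FW
    "phenolics": {"control": 0.35, "LE-1": 0.45, "LE-10": 0.50,
                  "FE-1": 0.55, "FE-10": 0.60},                   # mg GAE/g
    "flavonoids": {"control": 250.0, "LE-1": 300.0, "LE-10": 330.0,
                   "FE-1": 370.0, "FE-10": 400.0},                # nmol RE/g
    "antioxidant": {"control": 1.0, "LE-1": 1.15, "LE-10": 1.25,
                    "FE-1": 1.3, "FE-10": 1.4},                   # umol AAE/g
}

_GROUP_DESIGN = {
    "control": ("water", 0.0),
    "LE-1": ("leaf extract", 1.0),
    "LE-10": ("leaf extract", 10.0),
    "FE-1": ("flower extract", 1.0),
    "FE-10": ("flower extract", 10.0),
}


class ExperimentData(NamedTuple):
    silhouettes: list
    truth: "pd.DataFrame"
    design: "pd.DataFrame"
    readings: "pd.DataFrame"
    fluorescence: "pd.DataFrame"


def generate_experiment(config: GrowthConfig, cam: CameraConfig | None = None,
                        n_per_group: int = 9, seed: int | None = None,
                        render: bool | None = None,
                        read_noise_sd: float = 0.005,
                        tissue_levels: Mapping | None = None,
                        assays: Mapping | None = None,
                        timepoints: Sequence[int] | None = None) -> ExperimentData:
    """Full factorial treatment experiment with ground truth and raw assays.

    Every group x timepoint x replicate combination yields one imaged plant
    visit. At the final timepoint (harvest) raw absorbance readings are
    back-computed from the configured tissue levels through each assay's
    standard curve with Gaussian read noise, and instrument-style
    fluorescence parameters are emitted, so the assay and statistics stages
    can be exercised end to end against known truth.
    """
    import pandas as pd

    if render is None:
        render = cam is not None
    if render and cam is None:
        raise ConfigError("rendering requires a CameraConfig")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tissue_levels = DEFAULT_TISSUE_LEVELS if tissue_levels is None else tissue_levels
    assays = assaycalc.DEFAULT_ASSAYS if assays is None else assays
    days = tuple(config.timepoints) if timepoints is None else tuple(timepoints)
    harvest = max(days)

    truth_rows, silhouettes, reading_rows, fluo_rows = [], [], [], []
    for day in days:
        for group in config.groups:
            if day not in config.group_mean_fw[group]:
                raise ConfigError(f"no configured mean for group '{group}' at day {day}")
            for rep in range(n_per_group):
                shape, fw, vol = sample_plant(config, group, day, rng,
                                              build_shape=render)
                pid = f"{group}-r{rep}"
                if render:
                    silhouettes.append(render_views(shape, cam, plant_id=pid,
                                                    timepoint=day))
                truth_rows.append(dict(plant_id=pid, group=group, timepoint=day,
                                       true_fw=fw, true_volume=vol))
                if day == harvest:
                    for analyte, spec in assays.items():
                        true_val = tissue_levels[analyte][group]
                        a = assaycalc.absorbance_for(spec, true_val)
                        if read_noise_sd > 0:
                            a += rng.normal(0.0, read_noise_sd)
                        reading_rows.append(dict(
                            plant_id=pid, group=group, timepoint=day,
                            assay=analyte, wavelength=spec.wavelength,
                            absorbance=a, blank=spec.blank,
                            tissue_mass_g=spec.tissue_mass,
                            extract_volume_ml=spec.extract_volume,
                            dilution=spec.dilution, true_value=true_val,
                            unit=spec.unit,
                        ))
                    rc_boost = 1.15 if group.startswith("FE") else 1.0
                    fluo_rows.append(dict(
                        plant_id=pid, group=group, timepoint=day,
                        fvfm=float(np.clip(rng.normal(0.845, 0.004), 0.0, 1.0)),
                        pi=float(rng.normal(3.0 * rc_boost, 0.3)),
                        rc_cs=float(rng.normal(550.0 * rc_boost, 40.0)),
                        dio_rc=float(rng.normal(0.45 / rc_boost, 0.04)),
                    ))
    design = pd.DataFrame(
        [dict(group=g, material=m, dose_ml_per_l=d, n=n_per_group)
         for g, (m, d) in _GROUP_DESIGN.items() if g in config.groups]
    )
    return ExperimentData(silhouettes, pd.DataFrame(truth_rows), design,
                          pd.DataFrame(reading_rows), pd.DataFrame(fluo_rows))
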