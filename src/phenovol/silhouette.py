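"""Silhouette segmentation and radial profile extraction.

A turntable rig images the potted plant from a ring of azimuths. Each
side-view raster is segmented into a head silhouette (largest connected
foreground component, pot rows removed), and reduced to a per-image-row
radial extent about the fixed rotation axis. The stack of per-view radii is
the input to the solid-of-revolution volume composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import InvalidInputError

__all__ = [
    "ViewImage",
    "SilhouetteSet",
    "RadialProfile",
    "segment_head",
    "projected_area",
    "extract_radial_profile",
    "profiles_from_set",
]

_STRUCT3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ViewImage:
    """One 8-bit side view with its turntable geometry."""

    raster: np.ndarray        # 2D uint8, row 0 = top
    azimuth: float            # deg in [0, 360)
    pixel_scale: float        # cm per pixel
    axis_column: int          # pixel column of the rotation axis

    def __post_init__(self):
        if self.raster.ndim != 2:
            raise InvalidInputError("view raster must be 2D")
        if not 0.0 <= self.azimuth < 360.0:
            raise InvalidInputError(f"azimuth {self.azimuth} outside [0, 360)")
        if self.pixel_scale <= 0:
            raise InvalidInputError("pixel_scale must be > 0")
        if not 0 <= self.axis_column < self.raster.shape[1]:
            raise InvalidInputError("axis_column outside the frame")


@dataclass(frozen=True)
class SilhouetteSet:
    """Ordered multi-azimuth views of one plant at one time point."""

    views: tuple
    plant_id: str = ""
    timepoint: float = 0.0

    def __post_init__(self):
        az = [v.azimuth for v in self.views]
        if any(b <= a for a, b in zip(az, az[1:])):
            raise InvalidInputError("view azimuths must be strictly increasing")
        shapes = {v.raster.shape for v in self.views}
        scales = {v.pixel_scale for v in self.views}
        if len(shapes) > 1 or len(scales) > 1:
            raise InvalidInputError("all views must share dimensions and pixel scale")

    def __len__(self) -> int:
        return len(self.views)


@dataclass(frozen=True)
class RadialProfile:
    """Per-view, per-row radial extents about the rotation axis, in cm."""

    radii: np.ndarray         # [n_views, n_rows], cm
    row_height: float         # cm per row (= pixel_scale)
    pot_cut_row: int | None = None
    plant_id: str = ""
    timepoint: float = 0.0

    def __post_init__(self):
        if np.any(self.radii < 0):
            raise InvalidInputError("radii must be >= 0")

    @property
    def n_views(self) -> int:
        return self.radii.shape[0]


def segment_head(view: ViewImage, threshold_policy: str = "otsu",
                 min_component_px: int = 25,
                 pot_cut_row: int | None = None) -> np.ndarray:
    """Segment the head silhouette from one side view.

    Thresholds the grayscale raster (Otsu by default, or ``"fixed:<value>"``),
    cleans it with a 3x3 morphological opening and closing, keeps the largest
    connected component above ``min_component_px``, and zeroes every row at
    and below ``pot_cut_row`` so the pot never contributes to the head
    profile. An empty mask is a valid result (uniform backgrounds, or plants
    entirely below the cut).
    """
    raster = np.asarray(view.raster)
    if raster.size == 0:
        raise InvalidInputError("empty raster")
    if threshold_policy == "otsu":
        if np.ptp(raster) == 0:
            return np.zeros(raster.shape, dtype=bool)
        thr = filters.threshold_otsu(raster)
    elif threshold_policy.startswith("fixed:"):
        thr = float(threshold_policy.split(":", 1)[1])
    else:
        raise InvalidInputError(f"unknown threshold policy '{threshold_policy}'")
    mask = raster > thr
    mask = ndimage.binary_opening(mask, structure=_STRUCT3)
    mask = ndimage.binary_closing(mask, structure=_STRUCT3)
    if pot_cut_row is not None:
        mask[pot_cut_row:, :] = False
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros(raster.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    if sizes[biggest] < min_component_px:
        return np.zeros(raster.shape, dtype=bool)
    return labels == biggest


def projected_area(mask: np.ndarray, pixel_scale: float) -> float:
    """Head-projected area in cm^2: foreground pixel count x pixel_scale^2."""
    if pixel_scale <= 0:
        raise InvalidInputError("pixel_scale must be > 0")
    return float(np.count_nonzero(mask)) * pixel_scale**2


def extract_radial_profile(mask: np.ndarray, axis_column: int,
                           pixel_scale: float,
                           mode: str = "max") -> np.ndarray:
    """Per-row radial extent of a silhouette about the rotation axis.

    For each image row the radius is the larger of the left and right
    foreground extents from ``axis_column`` (conservative against small axis
    mis-centering; ``mode="halfwidth"`` uses half the foreground width
    instead). Rows without foreground get radius 0.
    """
    mask = np.asarray(mask).astype(bool)
    n_rows, n_cols = mask.shape
    if not 0 <= axis_column < n_cols:
        raise InvalidInputError("axis_column outside the frame")
    if pixel_scale <= 0:
        raise InvalidInputError("pixel_scale must be > 0")
    any_fg = mask.any(axis=1)
    first = mask.argmax(axis=1)
    last = n_cols - 1 - mask[:, ::-1].argmax(axis=1)
    if mode == "max":
        r_px = np.maximum(np.abs(first - axis_column), np.abs(last - axis_column))
    elif mode == "halfwidth":
        r_px = (last - first + 1) / 2.0
    else:
        raise InvalidInputError(f"unknown radius mode '{mode}'")
    radii = np.where(any_fg, r_px * pixel_scale, 0.0)
    return radii.astype(float)


def profiles_from_set(sset: SilhouetteSet, threshold_policy: str = "otsu",
                      min_component_px: int = 25,
                      pot_cut_row: int | None = None,
                      mode: str = "max") -> RadialProfile:
    """Segment every view of a silhouette set and stack its radial profiles."""
    if len(sset) < 1:
        raise InvalidInputError("silhouette set has no views")
    rows = []
    for view in sset.views:
        mask = segment_head(view, threshold_policy=threshold_policy,
                            min_component_px=min_component_px,
                            pot_cut_row=pot_cut_row)
        rows.append(extract_radial_profile(mask, view.axis_column,
                                           view.pixel_scale, mode=mode))
    return RadialProfile(
        radii=np.vstack(rows),
        row_height=sset.views[0].pixel_scale,
        pot_cut_row=pot_cut_row,
        plant_id=sset.plant_id,
        timepoint=sset.timepoint,
    )
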