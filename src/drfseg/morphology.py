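"""Seed-driven nodule geometry estimation by morphological filtering.

Given global intensity constants learned from training nodules, the per-nodule
chain estimates an initial radius, extracts a lung subvolume, restricts the
thresholded segmentation to the seed's connected component, refines the center
on the seed slice via the 2D distance transform, and grows a sphere to obtain
the final radius estimate ``r``.  All physical quantities are in mm; the grid
may be anisotropic, so "spheres" (growth regions and structuring elements) are
defined by physical radius and rasterized by voxel-center inclusion, i.e. they
are ellipsoids in voxel units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, CtVolume, SeedPoint

__all__ = [
    "IntensityModel",
    "NoduleGeometry",
    "SmoothedSegmentation",
    "GeometryError",
    "fit_intensity_model",
    "denoise_and_threshold",
    "estimate_initial_radius",
    "extract_lung_mask",
    "filter_to_seed_component",
    "refine_center",
    "estimate_final_radius",
    "estimate_geometry",
    "crop_bounds",
]


class GeometryError(RuntimeError):
    """A geometry-estimation stage failed; the message names the stage."""


@dataclass(frozen=True)
class IntensityModel:
    """Global nodule-intensity constants fitted on training data.

    ``mu_int``/``sigma_int`` parameterize the Gaussian intensity cost and
    ``t_min``/``t_max`` the uniform (threshold) model; all in HU.
    """

    mu_int: float
    sigma_int: float
    t_min: float
    t_max: float

    def __post_init__(self):
        if not self.sigma_int > 0:
            raise GeometryError(
                f"intensity model: sigma_int must be > 0, got {self.sigma_int}"
            )
        if not self.t_min < self.t_max:
            raise GeometryError(
                f"intensity model: t_min < t_max required, got [{self.t_min}, {self.t_max}]"
            )


@dataclass(frozen=True)
class NoduleGeometry:
    """Estimated nodule geometry: initial/final radius (mm), refined center
    (physical mm) and the per-axis location scale in voxel units."""

    r_init: float
    center: np.ndarray  # mm
    r: float  # mm
    sigma_loc: np.ndarray  # voxels, componentwise r / spacing


@dataclass
class SmoothedSegmentation:
    initial_mask: BinaryMask
    lung_mask: BinaryMask
    filtered_mask: BinaryMask


def fit_intensity_model(training) -> IntensityModel:
    """Pool mask-positive voxel intensities across training volumes.

    ``mu_int``/``sigma_int`` are the pooled mean and sample standard
    deviation, ``t_min``/``t_max`` the pooled minimum and maximum.
    """
    values = []
    for vol, mask in training:
        if vol.shape != mask.shape:
            raise GeometryError("intensity model: volume/mask shape mismatch")
        values.append(vol.intensities[mask.positive])
    if not values:
        raise GeometryError("intensity model: empty training set")
    pooled = np.concatenate(values)
    if pooled.size == 0:
        raise GeometryError("intensity model: no positive voxels in training set")
    t_min, t_max = float(pooled.min()), float(pooled.max())
    sigma = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    if sigma == 0.0 or t_min == t_max:
        raise GeometryError(
            "intensity model: degenerate training intensities (all values equal)"
        )
    return IntensityModel(float(pooled.mean()), sigma, t_min, t_max)


def denoise_and_threshold(vol: CtVolume, model: IntensityModel) -> BinaryMask:
    """In-slice 2D Gaussian smoothing (1 voxel sd) then strict double threshold."""
    smoothed = ndimage.gaussian_filter(
        vol.intensities.astype(float), sigma=(1.0, 1.0, 0.0), mode="nearest"
    )
    pos = (smoothed > model.t_min) & (smoothed < model.t_max)
    return BinaryMask.from_bool(pos, spacing=vol.spacing, origin=vol.origin)


def _ball_offsets(radius_mm: float, spacing) -> np.ndarray:
    """Structuring element: physical-radius ball rasterized on the grid."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    elem = X * X + Y * Y + Z * Z <= radius_mm**2
    if not elem.any():
        warnings.warn(
            f"structuring element of radius {radius_mm:.2f} mm degenerates to one voxel"
        )
        elem = np.ones((1, 1, 1), dtype=bool)
    return elem


def _pad_morph(op, mask: np.ndarray, elem: np.ndarray) -> np.ndarray:
    """Apply a binary morphology op with edge-replicated padding.

    scipy's implicit zero border would erode regions touching the volume
    boundary (lung air almost always does); replication treats the volume as
    locally extended.
    """
    pad = tuple((s // 2, s // 2) for s in elem.shape)
    padded = np.pad(mask, pad, mode="edge")
    out = op(padded, structure=elem)
    sl = tuple(slice(p[0], padded.shape[i] - p[1]) for i, p in enumerate(pad))
    return out[sl]


# half edge of the cube in which a sphere of radius r occupies 25 percent:
# edge = (4/3 pi r^3 / 0.25)^(1/3), so r_init = edge/2 ~ 1.28 r
_BOX_FILL_FACTOR = ((4.0 / 3.0) * np.pi / 0.25) ** (1.0 / 3.0) / 2.0


def _slice_edt_peak(plane: np.ndarray, seed_xy, spacing_xy):
    """Nearest-to-seed 8-connected local maximum of the in-slice 2D EDT.

    Returns (ix, iy, distance_mm).  Ties go to the larger distance, then the
    lexicographically smaller index.
    """
    dt = ndimage.distance_transform_edt(plane, sampling=spacing_xy)
    neighborhood_max = ndimage.maximum_filter(dt, size=3, mode="constant", cval=0.0)
    is_max = (dt == neighborhood_max) & (dt > 0)
    xs, ys = np.nonzero(is_max)
    d_seed = np.hypot((xs - seed_xy[0]) * spacing_xy[0], (ys - seed_xy[1]) * spacing_xy[1])
    order = np.lexsort((ys, xs, -dt[xs, ys], d_seed))
    best = order[0]
    return int(xs[best]), int(ys[best]), float(dt[xs[best], ys[best]])


def estimate_initial_radius(mask: BinaryMask, seed: SeedPoint, spacing) -> float:
    """Grow a seed-centered, physically isotropic box until 75% of it is
    outside the initial segmentation; returns half the box edge length (mm).

    Near an in-threshold pleural wall the 0.75 criterion is unreachable (the
    wall keeps about half of any box positive), so if the box hits the volume
    bounds first, the radius is instead read off the in-slice distance
    transform at the peak nearest the seed and rescaled to the box-growth
    definition; an all-positive slice falls back to the half extent.
    """
    spacing = np.asarray(spacing, dtype=float)
    seed.check_bounds(mask.shape)
    pos = mask.positive
    if not pos[tuple(seed.index)]:
        raise GeometryError("initial radius: seed voxel is not inside the initial segmentation")
    step = float(spacing.min())
    shape = np.asarray(mask.shape)
    coord = [np.abs((np.arange(n) - seed.index[i]) * spacing[i]) for i, n in enumerate(shape)]
    max_half = float(max(c.max() for c in coord))
    # largest half-width at which the box is still fully inside the volume;
    # beyond it the box is clipped and its fill fraction is boundary-censored
    clip_half = float(min(min(seed.index[i] * spacing[i],
                              (n - 1 - seed.index[i]) * spacing[i])
                          for i, n in enumerate(shape)))
    half = step
    while True:
        sls = []
        for i in range(3):
            inside = np.nonzero(coord[i] <= half)[0]
            sls.append(slice(inside[0], inside[-1] + 1))
        box = pos[tuple(sls)]
        frac_neg = 1.0 - np.count_nonzero(box) / box.size
        if frac_neg >= 0.75 and half <= clip_half:
            return half
        if half >= max_half:
            warnings.warn("initial radius: box reached the volume bounds before the 0.75 criterion")
            plane = pos[:, :, int(seed.index[2])]
            if plane.all():
                return half
            _, _, r_edt = _slice_edt_peak(plane, seed.index[:2], spacing[:2])
            return min(max(_BOX_FILL_FACTOR * r_edt, step), half)
        half += step


def extract_lung_mask(initial_mask: BinaryMask, seed: SeedPoint, r_init: float,
                      spacing) -> BinaryMask:
    """Lung subvolume: close+open (6 mm ball) of the inverted initial
    segmentation, nodule area refilled with an r_init/2 ball at the seed,
    then a final close."""
    spacing = np.asarray(spacing, dtype=float)
    inv = ~initial_mask.positive
    elem6 = _ball_offsets(6.0, spacing)
    lung = _pad_morph(ndimage.binary_closing, inv, elem6)
    lung = _pad_morph(ndimage.binary_opening, lung, elem6)
    fill = _ball_offsets(r_init / 2.0, spacing)
    seed_blob = np.zeros_like(lung)
    seed_blob[tuple(seed.index)] = True
    lung |= ndimage.binary_dilation(seed_blob, structure=fill)
    lung = _pad_morph(ndimage.binary_closing, lung, elem6)
    return BinaryMask.from_bool(lung, spacing=spacing, origin=initial_mask.origin)


_CONN6 = ndimage.generate_binary_structure(3, 1)


def filter_to_seed_component(initial_mask: BinaryMask, lung_mask: BinaryMask,
                             seed: SeedPoint) -> BinaryMask:
    """Restrict to the lung, then keep the 6-connected component of the seed."""
    combined = initial_mask.positive & lung_mask.positive
    if not combined[tuple(seed.index)]:
        raise GeometryError("component filter: seed voxel excluded by lung restriction")
    lab, _ = ndimage.label(combined, structure=_CONN6)
    keep = lab == lab[tuple(seed.index)]
    return BinaryMask.from_bool(keep, spacing=initial_mask.spacing,
                                origin=initial_mask.origin)


def refine_center(filtered_mask: BinaryMask, seed: SeedPoint, spacing) -> np.ndarray:
    """Refined center: the 8-connected local maximum of the in-slice 2D
    Euclidean distance transform nearest the seed, on the seed's slice.

    Ties go to the larger distance value, then the lexicographically smaller
    index.  Returns the physical (mm) 3-vector.
    """
    spacing = np.asarray(spacing, dtype=float)
    z = int(seed.index[2])
    plane = filtered_mask.positive[:, :, z]
    if not plane.any():
        raise GeometryError("center refinement: no positive voxels on the seed slice")
    ix, iy, _ = _slice_edt_peak(plane, seed.index[:2], spacing[:2])
    return np.array([ix * spacing[0], iy * spacing[1], z * spacing[2]])


def estimate_final_radius(filtered_mask: BinaryMask, center_mm, spacing) -> float:
    """Expand a sphere from the refined center; stop when a shell adds no
    positive voxels or the in-sphere positive fraction drops below 0.5.

    Returns the last radius before the stop condition, in mm.
    """
    spacing = np.asarray(spacing, dtype=float)
    center_mm = np.asarray(center_mm, dtype=float)
    pos = filtered_mask.positive
    shape = pos.shape
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center_mm)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    dist = np.sqrt(X * X + Y * Y + Z * Z)
    step = float(spacing.min())
    r = step
    prev_r = step
    max_dist = float(dist.max())
    while True:
        in_sphere = dist <= r
        n_tot = int(np.count_nonzero(in_sphere))
        n_pos = int(np.count_nonzero(in_sphere & pos))
        if r == step and n_pos == 0:
            raise GeometryError("final radius: no positive voxels at the refined center")
        shell = in_sphere & (dist > r - step)
        shell_pos = int(np.count_nonzero(shell & pos))
        if r > step and shell_pos == 0:
            return prev_r
        if n_tot > 0 and n_pos / n_tot < 0.5:
            return prev_r
        if r - step > max_dist:  # sphere swallowed the whole volume
            return prev_r
        prev_r = r
        r += step


def crop_bounds(shape, spacing, seed_index, r_init: float,
                factor: float = 2.5, min_half_mm: float = 12.0):
    """Subvolume bounds (slices) for per-nodule processing: a physical cube of
    half-width max(factor * r_init, min_half_mm) around the seed, clipped to
    the volume."""
    spacing = np.asarray(spacing, dtype=float)
    half = max(factor * r_init, min_half_mm)
    lo = np.maximum(np.floor(np.asarray(seed_index) - half / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(seed_index) + half / spacing).astype(int) + 1,
                    np.asarray(shape))
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def estimate_geometry(vol: CtVolume, seed: SeedPoint, model: IntensityModel,
                      return_stages: bool = False):
    """Run the full geometry chain on one volume.

    Steps: in-slice denoise + threshold, initial radius by box growth, crop to
    a processing subvolume, lung extraction, seed-component filtering, center
    refinement on the seed slice, sphere-growth final radius.  ``sigma_loc``
    is ``r / spacing`` componentwise (the location feature is normalized by
    the estimated radius).
    """
    seed.check_bounds(vol.shape)
    spacing = np.asarray(vol.spacing, dtype=float)
    initial = denoise_and_threshold(vol, model)
    try:
        r_init = estimate_initial_radius(initial, seed, spacing)
    except GeometryError as exc:
        raise GeometryError(f"stage initial_radius: {exc}") from exc

    sls = crop_bounds(vol.shape, spacing, seed.index, r_init)
    offset = np.array([s.start for s in sls])
    sub_initial = BinaryMask.from_bool(initial.positive[sls], spacing=spacing)
    sub_seed = SeedPoint(seed.index - offset)

    try:
        lung = extract_lung_mask(sub_initial, sub_seed, r_init, spacing)
        filtered = filter_to_seed_component(sub_initial, lung, sub_seed)
        center_sub = refine_center(filtered, sub_seed, spacing)
        r = estimate_final_radius(filtered, center_sub, spacing)
    except GeometryError as exc:
        raise GeometryError(f"stage {exc}") from exc

    center = center_sub + offset * spacing
    geom = NoduleGeometry(r_init=r_init, center=center, r=r,
                          sigma_loc=r / spacing)
    if return_stages:
        full_lung = np.zeros(vol.shape, dtype=bool)
        full_lung[sls] = lung.positive
        full_filt = np.zeros(vol.shape, dtype=bool)
        full_filt[sls] = filtered.positive
        stages = SmoothedSegmentation(
            initial_mask=initial,
            lung_mask=BinaryMask.from_bool(full_lung, spacing=spacing),
            filtered_mask=BinaryMask.from_bool(full_filt, spacing=spacing),
        )
        return geom, stages
    return geom
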