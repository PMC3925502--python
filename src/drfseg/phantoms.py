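"""Synthetic CT phantoms: solid lung nodules in low-density parenchyma.

Each phantom is a small chest-window crop: a near-water-density solid nodule
(sphere, optionally lumpy) embedded in lung parenchyma around -850 HU, with
optional attached vessel (cylinder) and pleural wall (slab) compartments,
partial-volume blur and additive Gaussian scanner noise.  The ground-truth
mask is the voxel-center rasterization of the nodule solid *before* blur and
noise, so analytic sphere volumes can be checked against voxel counts.

Default intensity regime: lung -850 HU, nodule 0 HU, wall/vessel +50 HU,
noise sd 40 HU — solid nodules have near-water density while aerated lung is
close to air, and the 1000 HU scale of the pairwise-interaction attenuation
is then sensible for neighboring-voxel differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import BinaryMask, CtVolume, SeedPoint

__all__ = ["Vessel", "PleuralWall", "PhantomSpec", "make_phantom", "make_pair",
           "make_training_set"]

DEFAULT_SPACING = (0.7, 0.7, 1.25)


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically or physically invalid."""


@dataclass(frozen=True)
class Vessel:
    """A cylindrical vessel, optionally attached through the nodule center.

    ``direction`` is in physical (mm) coordinates; ``offset_mm`` shifts the
    axis away from the nodule center (0 = juxtavascular attachment).
    """

    radius: float = 1.5
    direction: tuple = (0.0, 0.0, 1.0)
    attached: bool = True
    offset_mm: float = 0.0
    hu: float = 50.0


@dataclass(frozen=True)
class PleuralWall:
    """A chest-wall slab occupying the low-x face of the volume."""

    thickness: float = 6.0
    hu: float = 50.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (40, 40, 24)
    spacing: tuple = DEFAULT_SPACING
    nodule_center: Optional[tuple] = None  # mm; default: volume center
    nodule_radius: float = 5.0  # mm
    lumpiness: float = 0.0  # radial perturbation amplitude, fraction of radius
    nodule_hu: float = 0.0
    lung_hu: float = -850.0
    noise_sd: float = 40.0  # HU
    vessel: Optional[Vessel] = None
    pleural_wall: Optional[PleuralWall] = None
    psf_sd: float = 0.0  # partial-volume blur, voxels
    rng_seed: int = 0

    def center(self) -> np.ndarray:
        if self.nodule_center is not None:
            return np.asarray(self.nodule_center, dtype=float)
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def validate(self) -> None:
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing, dtype=float)
        if shape.shape != (3,) or np.any(shape < 4):
            raise PhantomSpecError(f"shape must be 3 integers >= 4, got {self.shape}")
        if np.any(spacing <= 0):
            raise PhantomSpecError(f"spacing must be positive, got {self.spacing}")
        if self.nodule_radius <= 0:
            raise PhantomSpecError("nodule_radius must be > 0")
        if self.lumpiness < 0 or self.noise_sd < 0 or self.psf_sd < 0:
            raise PhantomSpecError("lumpiness, noise_sd and psf_sd must be >= 0")
        if self.nodule_hu <= self.lung_hu:
            raise PhantomSpecError("nodule_hu must exceed lung_hu")
        extent = (shape - 1) * spacing
        r_max = self.nodule_radius * (1.0 + self.lumpiness)
        c = self.center()
        if np.any(c - r_max < 0) or np.any(c + r_max > extent):
            raise PhantomSpecError(
                f"nodule (center {tuple(np.round(c, 2))}, max radius {r_max:.2f} mm) "
                f"does not fit inside the volume extent {tuple(np.round(extent, 2))} mm"
            )

    @classmethod
    def for_radius(cls, radius: float, margin: float = 9.0,
                   spacing=DEFAULT_SPACING, **kw) -> "PhantomSpec":
        """Build a spec whose volume comfortably contains a nodule of ``radius`` mm."""
        spacing = np.asarray(spacing, dtype=float)
        lump = kw.get("lumpiness", 0.0)
        half = radius * (1.0 + lump) + margin
        shape = tuple(int(np.ceil(2 * half / s)) + 1 for s in spacing)
        return cls(shape=shape, spacing=tuple(spacing), nodule_radius=radius, **kw)


def _physical_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _lumpy_radius(spec: PhantomSpec, ux, uy, uz, rng: np.random.Generator):
    """Direction-dependent nodule radius: bounded low-order radial perturbation.

    A deterministic (seeded) combination of degree-1..3 direction harmonics
    (products of the unit-vector components), normalized so the perturbation
    magnitude never exceeds ``lumpiness * nodule_radius``.
    """
    if spec.lumpiness == 0:
        return spec.nodule_radius
    coef = rng.standard_normal(7)
    basis = [ux * uy, uy * uz, ux * uz, ux * uy * uz,
             ux**2 - uy**2, uy**2 - uz**2, ux * uz**2]
    # each |basis term| <= 1 on the unit sphere, so sum |coef| bounds the sum
    scale = spec.lumpiness / np.sum(np.abs(coef))
    pert = sum(c * b for c, b in zip(coef, basis)) * scale
    return spec.nodule_radius * (1.0 + pert)


def make_phantom(spec: PhantomSpec):
    """Rasterize one phantom.

    Returns
    -------
    (CtVolume, BinaryMask, SeedPoint)
        Noisy volume, pre-blur ground-truth nodule mask, and the seed at the
        voxel nearest the nodule center.  Identical spec (incl. ``rng_seed``)
        gives bit-identical output.
    """
    spec.validate()
    spacing = np.asarray(spec.spacing, dtype=float)
    center = spec.center()
    rng = np.random.default_rng(spec.rng_seed)

    X, Y, Z = _physical_grid(spec.shape, spacing)
    dx, dy, dz = X - center[0], Y - center[1], Z - center[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = dx / dist, dy / dist, dz / dist
    at_center = dist == 0
    ux, uy, uz = (np.where(at_center, 0.0, u) for u in (ux, uy, uz))

    # geometry rng draws happen before noise so the mask is noise-independent
    r_dir = _lumpy_radius(spec, ux, uy, uz, rng)
    nodule = dist <= r_dir

    img = np.full(spec.shape, spec.lung_hu, dtype=float)
    if spec.pleural_wall is not None:
        wall = X < spec.pleural_wall.thickness
        img[np.broadcast_to(wall, img.shape)] = spec.pleural_wall.hu
    if spec.vessel is not None:
        v = spec.vessel
        d = np.asarray(v.direction, dtype=float)
        d = d / np.linalg.norm(d)
        axis_pt = center.copy()
        if not v.attached or v.offset_mm:
            perp = np.cross(d, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(d, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            off = v.offset_mm if v.offset_mm else spec.nodule_radius + 2 * v.radius
            axis_pt = center + off * perp
        rx, ry, rz = X - axis_pt[0], Y - axis_pt[1], Z - axis_pt[2]
        proj = rx * d[0] + ry * d[1] + rz * d[2]
        perp2 = (rx - proj * d[0]) ** 2 + (ry - proj * d[1]) ** 2 + (rz - proj * d[2]) ** 2
        img[perp2 <= v.radius**2] = v.hu
    img[nodule] = spec.nodule_hu

    if spec.psf_sd > 0:
        img = gaussian_filter(img, sigma=spec.psf_sd, mode="nearest")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    vol = CtVolume(img, spacing=spacing)
    mask = BinaryMask.from_bool(nodule, spacing=spacing)
    seed = SeedPoint(np.clip(np.round(center / spacing).astype(int), 0,
                             np.asarray(spec.shape) - 1))
    return vol, mask, seed


def make_pair(spec: PhantomSpec, growth: float):
    """Two phantoms of the same nodule at volume ratio ``1 + growth``.

    The second radius is ``r * (1+growth)**(1/3)`` so the true volume change
    equals ``growth`` up to rasterization error; the two time points get
    independent noise draws derived from ``spec.rng_seed``.
    """
    if growth <= -1:
        raise PhantomSpecError(f"growth must be > -1, got {growth}")
    s1, s2 = np.random.SeedSequence(spec.rng_seed).spawn(2)
    spec1 = replace(spec, rng_seed=int(s1.generate_state(1)[0] % 2**31))
    spec2 = replace(
        spec,
        nodule_radius=spec.nodule_radius * (1.0 + growth) ** (1.0 / 3.0),
        rng_seed=int(s2.generate_state(1)[0] % 2**31),
    )
    return make_phantom(spec1), make_phantom(spec2)


def make_training_set(
    n: int,
    radius_range: Sequence[float] = (4.0, 7.0),
    lumpiness_range: Sequence[float] = (0.0, 0.15),
    noise_sd: float = 40.0,
    psf_sd: float = 0.8,
    spacing=DEFAULT_SPACING,
    rng_seed: int = 0,
    vessel_fraction: float = 0.0,
    wall_fraction: float = 0.0,
):
    """Draw ``n`` phantoms with geometry sampled uniformly from the ranges.

    ``vessel_fraction`` / ``wall_fraction`` give the probability that a case is
    juxtavascular / juxtapleural (the stock training regime uses 0, mirroring
    an isolated-nodule training set; evaluation sets turn them on).
    """
    if n < 1:
        raise PhantomSpecError("n must be >= 1")
    lo, hi = radius_range
    llo, lhi = lumpiness_range
    if hi < lo or lhi < llo:
        raise PhantomSpecError("empty range")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        radius = float(rng.uniform(lo, hi))
        lump = float(rng.uniform(llo, lhi))
        case_seed = int(rng.integers(0, 2**31 - 1))
        vessel = None
        wall = None
        if rng.random() < vessel_fraction:
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            vessel = Vessel(radius=float(rng.uniform(1.0, 2.0)), direction=tuple(d))
        if rng.random() < wall_fraction:
            wall = PleuralWall()
        spec = PhantomSpec.for_radius(
            radius,
            spacing=spacing,
            lumpiness=lump,
            noise_sd=noise_sd,
            psf_sd=psf_sd,
            rng_seed=case_seed,
        )
        if wall is not None:
            # park the nodule against the low-x wall slab (juxtapleural)
            c = spec.center().copy()
            c[0] = wall.thickness + radius * (1.0 - 0.15)
            spec = replace(spec, pleural_wall=wall, nodule_center=tuple(c))
        if vessel is not None:
            spec = replace(spec, vessel=vessel)
        out.append(make_phantom(spec))
    return out
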