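"""Discriminative random field over the voxel grid.

The label field x (x_i in {-1,+1}) given observations y factorizes with a
per-voxel logistic association potential and a pairwise Ising interaction on
the 6-neighborhood graph:

    log Pr(x | y) = sum_i A(x_i, y) + sum_i sum_{j in N_i} I(x_i, x_j, y) - log Z

    A(x_i, y) = log sigmoid(x_i * w^T h_i),   h_i = [1, f_g, f_u, f_l]
    I(x_i, x_j, y) = beta * x_i * x_j * v * delta_ij,
    delta_ij = max(1 - |n_i - n_j| / 1000, 0)

Features per voxel: the squared z-score of its intensity under the Gaussian
nodule-intensity model (f_g), the indicator of falling outside the threshold
interval (f_u), and the squared distance from the estimated nodule center
normalized by the estimated radius (f_l).  MAP inference never needs Z, so it
is never computed; ``build_energy`` converts the log-potential into a
minimize-form pairwise energy whose arg-min is the MAP labeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import BinaryMask, CtVolume
from .morphology import IntensityModel, NoduleGeometry

__all__ = [
    "FeatureVolume",
    "DrfParams",
    "PairwiseEnergy",
    "SubmodularityError",
    "compute_features",
    "association_log_prob",
    "interaction_potential",
    "total_log_potential",
    "build_energy",
    "grid_edges",
]

PARAM_FILE_VERSION = 1


class SubmodularityError(ValueError):
    """The pairwise energy is not submodular; re-train with v >= 0."""


@dataclass
class FeatureVolume:
    """Per-voxel features f = [f_g, f_u, f_l] and h = [1, f] (bias prepended)."""

    f: np.ndarray  # (..., 3)

    @property
    def h(self) -> np.ndarray:
        ones = np.ones(self.f.shape[:-1] + (1,), dtype=self.f.dtype)
        return np.concatenate([ones, self.f], axis=-1)


@dataclass
class DrfParams:
    """Learned DRF parameters.

    ``w`` weights the 4-vector h in the association potential, ``v`` scales the
    Ising interaction, ``beta`` switches the interaction on/off, and
    ``delta_scale`` is the intensity-difference scale (HU) of the interaction
    attenuation.
    """

    w: np.ndarray
    v: float
    beta: float = 1.0
    model: IntensityModel = None
    delta_scale: float = 1000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (4,):
            raise ValueError(f"w must be a 4-vector, got shape {self.w.shape}")
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.v):
            raise ValueError("DRF parameters must be finite")

    def save(self, path) -> None:
        payload = {
            "format": "drfseg-params",
            "version": PARAM_FILE_VERSION,
            "w": [float(x) for x in self.w],
            "v": float(self.v),
            "beta": float(self.beta),
            "delta_scale": float(self.delta_scale),
            "intensity_model": None
            if self.model is None
            else {
                "mu_int": self.model.mu_int,
                "sigma_int": self.model.sigma_int,
                "t_min": self.model.t_min,
                "t_max": self.model.t_max,
            },
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "DrfParams":
        data = json.loads(Path(path).read_text())
        if data.get("format") != "drfseg-params":
            raise ValueError(f"{path} is not a drfseg parameter file")
        if data.get("version") != PARAM_FILE_VERSION:
            raise ValueError(
                f"parameter file version {data.get('version')} != {PARAM_FILE_VERSION}"
            )
        model = data.get("intensity_model")
        return cls(
            w=np.array(data["w"], dtype=float),
            v=float(data["v"]),
            beta=float(data.get("beta", 1.0)),
            model=None if model is None else IntensityModel(**model),
            delta_scale=float(data.get("delta_scale", 1000.0)),
            meta=data.get("meta", {}),
        )


@dataclass
class PairwiseEnergy:
    """Minimize-form energy on the 6-neighborhood grid.

    ``unary[i, k]`` is the cost of labeling voxel i with label index k
    (k=0 -> -1, k=1 -> +1); ``edges`` lists each raster-adjacent unordered
    pair once; ``pairwise[e, a, b]`` is the cost table of edge e.
    """

    unary: np.ndarray  # (N, 2)
    edges: np.ndarray  # (E, 2) int
    pairwise: np.ndarray  # (E, 2, 2)
    shape: tuple

    def total(self, labels_flat: np.ndarray) -> float:
        """Energy of a labeling given as a flat array over {-1,+1}."""
        k = (labels_flat > 0).astype(int)
        e = float(self.unary[np.arange(k.size), k].sum())
        if len(self.edges):
            e += float(self.pairwise[np.arange(len(self.edges)),
                                     k[self.edges[:, 0]], k[self.edges[:, 1]]].sum())
        return e


def compute_features(vol: CtVolume, geom: NoduleGeometry,
                     model: IntensityModel) -> FeatureVolume:
    """Feature volume from (pre-smoothed) intensities and estimated geometry."""
    if model.sigma_int <= 0:
        raise ValueError("sigma_int must be positive")
    n = vol.intensities.astype(float)
    f_g = (n - model.mu_int) ** 2 / model.sigma_int**2
    f_u = np.where((n > model.t_min) & (n < model.t_max), 0.0, 1.0)
    spacing = np.asarray(vol.spacing, dtype=float)
    l_vox = np.asarray(geom.center, dtype=float) / spacing
    sigma_loc = np.asarray(geom.sigma_loc, dtype=float)
    axes = [((np.arange(nn) - l) / s) ** 2 for nn, l, s in
            zip(vol.shape, l_vox, sigma_loc)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    f_l = X + Y + Z
    return FeatureVolume(np.stack([f_g, f_u, np.broadcast_to(f_l, n.shape)], axis=-1))


def association_log_prob(h, x, w):
    """log Pr(x | y) under the logistic association model, overflow-safe.

    Vectorized over leading dimensions of ``h`` and ``x``; always <= 0.
    """
    z = np.asarray(h, dtype=float) @ np.asarray(w, dtype=float)
    return -np.logaddexp(0.0, -np.asarray(x) * z)


def interaction_potential(n_i, n_j, x_i, x_j, v, beta=1.0, delta_scale=1000.0):
    """Ising interaction attenuated by the neighbors' intensity difference."""
    delta = np.maximum(1.0 - np.abs(np.asarray(n_i, float) - np.asarray(n_j, float))
                       / delta_scale, 0.0)
    return beta * np.asarray(x_i) * np.asarray(x_j) * v * delta


def grid_edges(shape):
    """All unordered 6-neighbor pairs of a raster, as flat indices (E, 2)."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    pairs = []
    for ax in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[ax] = slice(None, -1)
        b[ax] = slice(1, None)
        pairs.append(np.stack([idx[tuple(a)].ravel(), idx[tuple(b)].ravel()], axis=1))
    return np.concatenate(pairs, axis=0)


def total_log_potential(vol: CtVolume, labels: BinaryMask, params: DrfParams,
                        features: FeatureVolume) -> float:
    """Sum of association and (directed, double-counted) interaction potentials.

    Each unordered neighbor pair contributes twice — once per direction — so
    this matches the double sum over sites and their neighborhoods.
    """
    if vol.shape != labels.shape:
        raise ValueError("volume/labels shape mismatch")
    x = labels.labels.ravel().astype(float)
    h = features.h.reshape(-1, 4)
    total = float(association_log_prob(h, x, params.w).sum())
    edges = grid_edges(vol.shape)
    n = vol.intensities.ravel().astype(float)
    inter = interaction_potential(n[edges[:, 0]], n[edges[:, 1]],
                                  x[edges[:, 0]], x[edges[:, 1]],
                                  params.v, params.beta, params.delta_scale)
    return total + 2.0 * float(inter.sum())


def build_energy(vol: CtVolume, params: DrfParams,
                 features: FeatureVolume) -> PairwiseEnergy:
    """Convert the log-potential to a minimize-form pairwise energy.

    unary(x) = -A(x); each unordered edge gets cost -2 I(x_i, x_j) (the factor
    2 folds the directed double sum), so arg-min energy = arg-max posterior
    and energy(x) + log-potential(x) is constant in x.
    """
    if params.beta * params.v < 0:
        raise SubmodularityError(
            f"beta*v = {params.beta * params.v:.4g} < 0 makes the Ising energy "
            "non-submodular; re-train with v >= 0"
        )
    h = features.h.reshape(-1, 4)
    z = h @ params.w
    # unary[:,k] = -A(label k): softplus of +/- z
    unary = np.stack([np.logaddexp(0.0, z), np.logaddexp(0.0, -z)], axis=1)
    edges = grid_edges(vol.shape)
    n = vol.intensities.ravel().astype(float)
    delta = np.maximum(1.0 - np.abs(n[edges[:, 0]] - n[edges[:, 1]])
                       / params.delta_scale, 0.0)
    k = 2.0 * params.beta * params.v * delta  # equal-label gain per unordered edge
    pairwise = np.empty((len(edges), 2, 2))
    pairwise[:, 0, 0] = pairwise[:, 1, 1] = -k
    pairwise[:, 0, 1] = pairwise[:, 1, 0] = k
    return PairwiseEnergy(unary=unary, edges=edges, pairwise=pairwise,
                          shape=vol.shape)
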