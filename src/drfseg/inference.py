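"""Exact binary MAP inference by s-t min-cut, plus reference solvers.

The minimize-form energy from :func:`drfseg.drf.build_energy` is submodular
whenever beta*v >= 0, so its global minimum is found exactly by max-flow on
the standard graph construction (source side = label +1).  Capacities are
floats; they are scaled adaptively to integers such that the largest capacity
and an upper bound on the max-flow value both fit in int32, then solved with
scipy's C++ max-flow.  The energy of the returned labeling is always
recomputed in float64 from the original cost tables.

``solve_map_exhaustive`` enumerates all labelings of tiny instances and is the
independent oracle used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .drf import DrfParams, PairwiseEnergy, SubmodularityError, build_energy, compute_features
from .io import BinaryMask, CtVolume, SeedPoint
from .morphology import crop_bounds, estimate_geometry

__all__ = ["MapResult", "solve_map", "solve_map_exhaustive", "segment",
           "segment_threshold", "posterior_volume"]

_SUBMOD_TOL = 1e-9


@dataclass
class MapResult:
    labels: BinaryMask
    energy: float
    solver: str
    flow_stats: dict = field(default_factory=dict)


def _decompose(energy: PairwiseEnergy):
    """Reduce unary + 2x2 tables to t-link excesses and n-link capacities.

    For a table [[A, B], [C, D]] (row = label index of i, col = of j):
    E = A + (C-A)[x_i=1] + (D-C)[x_j=1] + (B+C-A-D)[x_i=0, x_j=1], requiring
    B + C >= A + D (submodularity).
    """
    c = energy.unary[:, 1] - energy.unary[:, 0]
    if len(energy.edges):
        A = energy.pairwise[:, 0, 0]
        B = energy.pairwise[:, 0, 1]
        C = energy.pairwise[:, 1, 0]
        D = energy.pairwise[:, 1, 1]
        ecap = B + C - A - D
        tol = _SUBMOD_TOL * max(1.0, float(np.abs(energy.pairwise).max()))
        if np.any(ecap < -tol):
            worst = float(ecap.min())
            raise SubmodularityError(
                f"non-submodular edge table (B+C-A-D = {worst:.4g} < 0); "
                "re-train with v >= 0"
            )
        ecap = np.maximum(ecap, 0.0)
        c = c.copy()
        np.add.at(c, energy.edges[:, 0], C - A)
        np.add.at(c, energy.edges[:, 1], D - C)
    else:
        ecap = np.zeros(0)
    return c, ecap


def solve_map(energy: PairwiseEnergy) -> MapResult:
    """Globally optimal labeling of a submodular pairwise energy via min-cut."""
    N = energy.unary.shape[0]
    c, ecap = _decompose(energy)

    src_cap = np.where(c < 0, -c, 0.0)  # s -> i, cut when i takes label -1
    snk_cap = np.where(c > 0, c, 0.0)  # i -> t, cut when i takes label +1
    flow_bound = min(src_cap.sum(), snk_cap.sum())
    max_cap = max(
        float(src_cap.max(initial=0.0)),
        float(snk_cap.max(initial=0.0)),
        float(ecap.max(initial=0.0)),
    )
    denom = max(flow_bound, max_cap)
    if denom <= 0:
        # every capacity is zero: nothing reachable from the source
        labels = np.full(N, -1, dtype=np.int8).reshape(energy.shape)
        mask = BinaryMask(labels)
        return MapResult(mask, energy.total(labels.ravel()), "graph-cut",
                         {"flow": 0.0, "scale": 1.0})
    scale = (2.0**31 - 8.0 * N - 256.0) / denom

    s, t = N, N + 1
    # the pair term (B+C-A-D)[x_i=0, x_j=1] cuts the arc j->i (source side = +1);
    # the zero-capacity reverse arc keeps residual BFS able to walk backwards
    rows = [energy.edges[:, 1], energy.edges[:, 0],
            np.full(N, s), np.arange(N)]
    cols = [energy.edges[:, 0], energy.edges[:, 1],
            np.arange(N), np.full(N, t)]
    caps = [np.round(ecap * scale),
            np.zeros(len(energy.edges)),
            np.round(src_cap * scale),
            np.round(snk_cap * scale)]
    graph = csr_matrix(
        (np.concatenate(caps).astype(np.int32),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(N + 2, N + 2),
    )
    res = maximum_flow(graph, s, t)
    residual = graph - res.flow
    residual.data = (residual.data > 0).astype(np.int8)
    residual.eliminate_zeros()
    order = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    reach = np.zeros(N + 2, dtype=bool)
    reach[order] = True
    labels = np.where(reach[:N], 1, -1).astype(np.int8).reshape(energy.shape)
    mask = BinaryMask(labels)
    return MapResult(mask, energy.total(labels.ravel()), "graph-cut",
                     {"flow": float(res.flow_value) / scale, "scale": scale})


def solve_map_exhaustive(energy: PairwiseEnergy, max_voxels: int = 20) -> MapResult:
    """Brute-force minimum over all labelings (oracle; <= ``max_voxels`` voxels).

    Ties return the lexicographically smallest labeling with -1 ordered
    before +1.
    """
    N = energy.unary.shape[0]
    if N > max_voxels:
        raise ValueError(f"exhaustive solver limited to {max_voxels} voxels, got {N}")
    k = np.arange(2**N, dtype=np.int64)
    bits = ((k[:, None] >> (N - 1 - np.arange(N))) & 1).astype(np.int8)
    tot = energy.unary[np.arange(N), bits].sum(axis=1)
    for e, (i, j) in enumerate(energy.edges):
        tot = tot + energy.pairwise[e, bits[:, i], bits[:, j]]
    best = int(np.argmin(tot))  # first occurrence = lexicographically smallest
    labels = np.where(bits[best] > 0, 1, -1).astype(np.int8).reshape(energy.shape)
    mask = BinaryMask(labels)
    return MapResult(mask, float(tot[best]), "exhaustive")


def _presmooth(vol: CtVolume) -> CtVolume:
    """3D Gaussian pre-smoothing, 1 voxel standard deviation."""
    return CtVolume(gaussian_filter(vol.intensities.astype(float), sigma=1.0,
                                    mode="nearest"),
                    spacing=vol.spacing, origin=vol.origin)


def _prepare(vol: CtVolume, seed: SeedPoint, params: DrfParams):
    if params.model is None:
        raise ValueError("params.model (intensity constants) is required for segmentation")
    smoothed = _presmooth(vol)
    geom = estimate_geometry(smoothed, seed, params.model)
    sls = crop_bounds(vol.shape, vol.spacing, seed.index, geom.r_init)
    offset = np.array([s.start for s in sls])
    sub = CtVolume(smoothed.intensities[sls], spacing=vol.spacing)
    from dataclasses import replace
    geom_sub = replace(geom, center=np.asarray(geom.center) - offset * np.asarray(vol.spacing, float))
    features = compute_features(sub, geom_sub, params.model)
    return smoothed, geom, sls, sub, features


def segment(vol: CtVolume, seed: SeedPoint, params: DrfParams,
            return_details: bool = False):
    """End-to-end segmentation of one nodule from one seed point.

    Pre-smooths the volume (3D Gaussian, 1 voxel sd), estimates geometry,
    computes features on the processing subvolume, builds the pairwise energy
    and solves the exact MAP by graph cut.  Voxels outside the subvolume are
    labeled -1.
    """
    _, geom, sls, sub, features = _prepare(vol, seed, params)
    energy = build_energy(sub, params, features)
    result = solve_map(energy)
    labels = np.full(vol.shape, -1, dtype=np.int8)
    labels[sls] = result.labels.labels
    mask = BinaryMask(labels, spacing=vol.spacing, origin=vol.origin)
    if return_details:
        return mask, {"geometry": geom, "crop": sls, "map_result": result}
    return mask


def segment_threshold(vol: CtVolume, seed: SeedPoint, params: DrfParams) -> BinaryMask:
    """Per-voxel logistic thresholding at Pr(x=+1|y) = 0.5 (no interaction).

    Runs the identical pipeline up to the unary potentials, then labels each
    subvolume voxel +1 iff w^T h > 0; the decoupled (v = 0) MAP reduces to
    exactly this rule.
    """
    _, _, sls, sub, features = _prepare(vol, seed, params)
    z = features.h.reshape(-1, 4) @ params.w
    labels = np.full(vol.shape, -1, dtype=np.int8)
    labels[sls] = np.where(z > 0, 1, -1).astype(np.int8).reshape(sub.shape)
    return BinaryMask(labels, spacing=vol.spacing, origin=vol.origin)


def posterior_volume(vol: CtVolume, seed: SeedPoint, params: DrfParams) -> CtVolume:
    """Per-voxel Pr(x=+1|y) under the association model (diagnostic export)."""
    _, _, sls, sub, features = _prepare(vol, seed, params)
    z = features.h.reshape(-1, 4) @ params.w
    prob = np.zeros(vol.shape, dtype=np.float32)
    prob[sls] = (1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))).reshape(sub.shape)
    return CtVolume(prob, spacing=vol.spacing, origin=vol.origin)
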