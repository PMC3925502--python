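"""Segmentation metrics and F-score simulated-annealing parameter learning.

Training maximizes the voxelwise F-score of full graph-cut inference results
on the training set over theta = (w, v).  The objective is non-convex and
piecewise constant (it depends on theta only through the discrete MAP
labeling), so a derivative-free global search is used: simulated annealing
with Gaussian proposals whose scale shrinks with the temperature.  Geometry
and features do not depend on theta and are computed once per case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .drf import DrfParams, PairwiseEnergy, compute_features, grid_edges
from .io import BinaryMask, CtVolume
from .morphology import IntensityModel, crop_bounds, estimate_geometry

__all__ = [
    "SegMetrics",
    "AnnealConfig",
    "TrainResult",
    "MetricError",
    "compute_metrics",
    "percent_volume_change",
    "prepare_training_cache",
    "objective_fscore",
    "train",
]


class MetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. empty ground truth)."""


@dataclass(frozen=True)
class SegMetrics:
    """Voxelwise overlap and volume metrics for one predicted mask."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float
    volume_mm3: float
    truth_volume_mm3: float
    relative_volume_error: float


def _counts(pred: BinaryMask, truth: BinaryMask):
    if pred.shape != truth.shape:
        raise MetricError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p, t = pred.positive, truth.positive
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return tp, fp, fn


def _prf(tp: int, fp: int, fn: int):
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    fscore = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
    return precision, recall, fscore


def compute_metrics(pred: BinaryMask, truth: BinaryMask, spacing=None) -> SegMetrics:
    """Precision, recall, F-score (= Dice for voxel sets) and volume metrics.

    Precision is defined as 0 for an empty prediction.  The relative volume
    error (V_pred - V_truth)/V_truth requires a nonempty ground truth.
    """
    tp, fp, fn = _counts(pred, truth)
    if tp + fn == 0:
        raise MetricError("ground truth mask is empty; recall and volume error undefined")
    precision, recall, fscore = _prf(tp, fp, fn)
    spacing = np.asarray(spacing if spacing is not None else pred.spacing, dtype=float)
    voxel = float(np.prod(spacing))
    v_pred = (tp + fp) * voxel
    v_truth = (tp + fn) * voxel
    return SegMetrics(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, fscore=fscore,
        volume_mm3=v_pred, truth_volume_mm3=v_truth,
        relative_volume_error=(v_pred - v_truth) / v_truth,
    )


def percent_volume_change(v1_mm3: float, v2_mm3: float) -> float:
    """(V2 - V1) / V1 between two time points of the same nodule."""
    if v1_mm3 <= 0:
        raise MetricError("percent volume change undefined for V1 <= 0")
    return (v2_mm3 - v1_mm3) / v1_mm3


@dataclass
class _CachedCase:
    """Theta-independent per-case precomputation for the training objective."""

    h: np.ndarray          # (N, 4) feature rows of the processing subvolume
    edges: np.ndarray      # (E, 2)
    delta: np.ndarray      # (E,) interaction attenuation
    truth_in: np.ndarray   # (N,) bool, ground truth inside the subvolume
    truth_outside: int     # positive truth voxels outside (counted as fn)
    shape: tuple


def prepare_training_cache(training, model: IntensityModel, beta: float = 1.0,
                           delta_scale: float = 1000.0):
    """Run geometry estimation + feature extraction once per training case."""
    cache = []
    for vol, truth, seed in training:
        smoothed = CtVolume(gaussian_filter(vol.intensities.astype(float), sigma=1.0,
                                            mode="nearest"),
                            spacing=vol.spacing, origin=vol.origin)
        geom = estimate_geometry(smoothed, seed, model)
        sls = crop_bounds(vol.shape, vol.spacing, seed.index, geom.r_init)
        offset = np.array([s.start for s in sls])
        sub = CtVolume(smoothed.intensities[sls], spacing=vol.spacing)
        geom_sub = replace(geom,
                           center=np.asarray(geom.center) - offset * np.asarray(vol.spacing, float))
        feats = compute_features(sub, geom_sub, model)
        edges = grid_edges(sub.shape)
        n = sub.intensities.ravel()
        delta = np.maximum(1.0 - np.abs(n[edges[:, 0]] - n[edges[:, 1]]) / delta_scale, 0.0)
        t_in = truth.positive[sls].ravel()
        t_out = int(np.count_nonzero(truth.positive)) - int(np.count_nonzero(t_in))
        cache.append(_CachedCase(h=feats.h.reshape(-1, 4), edges=edges, delta=delta,
                                 truth_in=t_in, truth_outside=t_out, shape=sub.shape))
    return cache


def _solve_cached(case: _CachedCase, theta: np.ndarray, beta: float) -> np.ndarray:
    """MAP labels (bool) of one cached case for theta = [w0..w3, v]."""
    from .inference import solve_map  # local import to avoid a cycle

    w, v = theta[:4], float(theta[4])
    z = case.h @ w
    unary = np.stack([np.logaddexp(0.0, z), np.logaddexp(0.0, -z)], axis=1)
    k = 2.0 * beta * v * case.delta
    pairwise = np.empty((len(case.edges), 2, 2))
    pairwise[:, 0, 0] = pairwise[:, 1, 1] = -k
    pairwise[:, 0, 1] = pairwise[:, 1, 0] = k
    energy = PairwiseEnergy(unary=unary, edges=case.edges, pairwise=pairwise,
                            shape=case.shape)
    return solve_map(energy).labels.labels.ravel() > 0


def objective_fscore(theta, cache, beta: float = 1.0, pooled: bool = True) -> float:
    """Training F-score of full MAP inference at parameters theta.

    Counts are pooled over cases by default (per-case averaging available via
    ``pooled=False``).  A non-submodular theta (v < 0) scores 0 so the search
    can move away from it instead of raising.
    """
    theta = np.asarray(theta, dtype=float)
    if beta * theta[4] < 0:
        return 0.0
    tps = fps = fns = 0
    scores = []
    for case in cache:
        pred = _solve_cached(case, theta, beta)
        tp = int(np.count_nonzero(pred & case.truth_in))
        fp = int(np.count_nonzero(pred & ~case.truth_in))
        fn = int(np.count_nonzero(~pred & case.truth_in)) + case.truth_outside
        if pooled:
            tps, fps, fns = tps + tp, fps + fp, fns + fn
        else:
            scores.append(_prf(tp, fp, fn)[2])
    if pooled:
        return _prf(tps, fps, fns)[2]
    return float(np.mean(scores))


@dataclass
class AnnealConfig:
    """Simulated-annealing schedule for F-score maximization.

    Proposals are Gaussian steps of sd ``step_scale * T`` per component;
    worse moves are accepted with probability exp(-dF * accept_scale / T);
    the temperature decays as T0 * cooling_rate**iteration.  Bounds are
    honored by rejection-resampling of proposals.

    Default bounds are one-sided: the three feature weights are bounded above
    by 0 because f_g, f_u and f_l are costs (the association probability of
    the nodule label must not increase with any of them; an unconstrained fit
    on easy training nodules can flip the location weight's sign and then
    grossly oversegment juxtapleural cases), and v (the last component) is
    bounded below by 0 so every visited energy stays submodular.  The bias
    w0 is free.
    """

    initial_params: np.ndarray = field(default_factory=lambda: np.zeros(5))
    bounds: Sequence = field(default_factory=lambda: [(-np.inf, np.inf)]
                             + [(-np.inf, 0.0)] * 3 + [(0.0, np.inf)])
    initial_temperature: float = 1.0
    cooling_rate: float = 0.97
    iterations: int = 500
    step_scale: float = 1.0
    accept_scale: float = 50.0
    reanneal_interval: Optional[int] = 50
    rng_seed: int = 0

    def validate(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.cooling_rate < 1:
            raise ValueError("cooling_rate must be in (0, 1)")
        lo = np.array([b[0] for b in self.bounds], dtype=float)
        hi = np.array([b[1] for b in self.bounds], dtype=float)
        theta0 = np.asarray(self.initial_params, dtype=float)
        if np.any(lo > hi) or np.any(theta0 < lo) or np.any(theta0 > hi):
            raise ValueError("inconsistent bounds / initial parameters")
        return theta0, lo, hi


@dataclass
class TrainResult:
    theta: np.ndarray
    best_fscore: float
    trace: list  # (iteration, theta, fscore, temperature)

    def to_params(self, model: IntensityModel, beta: float = 1.0,
                  delta_scale: float = 1000.0, meta=None) -> DrfParams:
        return DrfParams(w=self.theta[:4], v=float(self.theta[4]), beta=beta,
                         model=model, delta_scale=delta_scale, meta=meta or {})


def train(objective, config: AnnealConfig) -> TrainResult:
    """Maximize ``objective(theta)`` by simulated annealing.

    ``objective`` is any callable on a theta vector (the F-score objective in
    production; tests use analytic functions).  Returns the best-ever theta,
    so the result never scores below the starting point.

    The segmentation objective is piecewise constant in theta (it changes only
    when the discrete MAP labeling changes), so its maximum is a plateau and
    the point reached within it would otherwise be arbitrary.  Exact ties are
    therefore broken toward the smaller parameter norm, both for move
    acceptance and for the returned best: the minimum-norm point of an
    optimal plateau is the canonical representative of an underdetermined
    fit.
    """
    theta0, lo, hi = config.validate()
    rng = np.random.default_rng(config.rng_seed)
    theta = theta0.copy()
    f = float(objective(theta))
    best_theta, best_f = theta.copy(), f
    trace = [(0, theta.copy(), f, config.initial_temperature)]
    T = config.initial_temperature
    for it in range(1, config.iterations + 1):
        if config.reanneal_interval and it % config.reanneal_interval == 0:
            T = config.initial_temperature
            theta, f = best_theta.copy(), best_f
        for _ in range(100):
            prop = theta + rng.normal(0.0, config.step_scale * T, size=theta.shape)
            if np.all(prop >= lo) & np.all(prop <= hi):
                break
        else:  # no in-bounds proposal found; stay put this iteration
            prop = theta.copy()
        f_prop = float(objective(prop))
        if f_prop == f:
            accept = np.linalg.norm(prop) < np.linalg.norm(theta)
        elif f_prop > f:
            accept = True
        else:
            accept = rng.random() < np.exp(-(f - f_prop) * config.accept_scale / T)
        if accept:
            theta, f = prop, f_prop
            if f > best_f or (f == best_f
                              and np.linalg.norm(theta) < np.linalg.norm(best_theta)):
                best_theta, best_f = theta.copy(), f
        trace.append((it, theta.copy(), f, T))
        T *= config.cooling_rate
    return TrainResult(theta=best_theta, best_fscore=best_f, trace=trace)
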