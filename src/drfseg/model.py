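"""Model/Results facade over the full pipeline.

``NoduleDRF`` is built from labeled training cases; ``fit()`` learns the
intensity constants and the DRF parameters (w, v) by simulated annealing on
the training F-score and returns a ``NoduleDRFResults`` carrying the
estimates, the optimization trace and segmentation/evaluation methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import inference
from .drf import DrfParams
from .learning import (AnnealConfig, TrainResult, compute_metrics, objective_fscore,
                       prepare_training_cache, train)
from .morphology import IntensityModel, fit_intensity_model

__all__ = ["NoduleDRF", "NoduleDRFResults"]


class NoduleDRF:
    """A discriminative random field nodule-segmentation model.

    Parameters
    ----------
    training : list of (CtVolume, BinaryMask, SeedPoint)
        Labeled training nodules.
    intensity_model : IntensityModel, optional
        Global intensity constants; fitted from the training masks if omitted.
    beta : float
        Interaction on/off switch (fixed, not learned).
    pooled : bool
        Pool tp/fp/fn across training cases in the objective (default) or
        average per-case F-scores.
    """

    def __init__(self, training, intensity_model: Optional[IntensityModel] = None,
                 beta: float = 1.0, delta_scale: float = 1000.0, pooled: bool = True):
        if not training:
            raise ValueError("training set must be nonempty")
        self.training = list(training)
        self.beta = float(beta)
        self.delta_scale = float(delta_scale)
        self.pooled = bool(pooled)
        if intensity_model is None:
            intensity_model = fit_intensity_model([(v, m) for v, m, _ in self.training])
        self.intensity_model = intensity_model
        self._cache = None

    @classmethod
    def from_phantoms(cls, n: int = 4, rng_seed: int = 0, **phantom_kw) -> "NoduleDRF":
        """Convenience constructor: train on freshly generated phantoms."""
        from .phantoms import make_training_set

        return cls(make_training_set(n, rng_seed=rng_seed, **phantom_kw))

    def _ensure_cache(self):
        if self._cache is None:
            self._cache = prepare_training_cache(
                self.training, self.intensity_model, beta=self.beta,
                delta_scale=self.delta_scale)
        return self._cache

    def objective(self, theta) -> float:
        """Training F-score of full MAP inference at theta = [w0..w3, v]."""
        return objective_fscore(theta, self._ensure_cache(), beta=self.beta,
                                pooled=self.pooled)

    def fit(self, config: Optional[AnnealConfig] = None) -> "NoduleDRFResults":
        """Learn (w, v) by simulated annealing on the training F-score."""
        if config is None:
            config = AnnealConfig()
        result = train(self.objective, config)
        params = result.to_params(self.intensity_model, beta=self.beta,
                                  delta_scale=self.delta_scale,
                                  meta={"n_training": len(self.training),
                                        "anneal_iterations": config.iterations,
                                        "rng_seed": config.rng_seed})
        return NoduleDRFResults(self, params, result, config)


@dataclass
class NoduleDRFResults:
    """Fitted DRF parameters plus diagnostics and prediction methods."""

    model: NoduleDRF
    params: DrfParams
    train_result: TrainResult
    config: AnnealConfig

    @property
    def best_fscore(self) -> float:
        return self.train_result.best_fscore

    def trace_dataframe(self) -> pd.DataFrame:
        rows = [
            {"iteration": it, "fscore": f, "temperature": T,
             **{f"w{k}": th[k] for k in range(4)}, "v": th[4]}
            for it, th, f, T in self.train_result.trace
        ]
        return pd.DataFrame(rows)

    def segment(self, vol, seed, **kw):
        return inference.segment(vol, seed, self.params, **kw)

    def evaluate(self, cases) -> pd.DataFrame:
        """Segment each (vol, truth, seed) case and tabulate the metrics."""
        rows = []
        for i, (vol, truth, seed) in enumerate(cases):
            pred = self.segment(vol, seed)
            m = compute_metrics(pred, truth, vol.spacing)
            rows.append({"case": i, "precision": m.precision, "recall": m.recall,
                         "dice": m.fscore, "volume_mm3": m.volume_mm3,
                         "truth_volume_mm3": m.truth_volume_mm3,
                         "relative_volume_error": m.relative_volume_error})
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        self.params.save(path)

    def summary(self) -> str:
        w = self.params.w
        im = self.model.intensity_model
        lines = [
            "Discriminative random field nodule segmentation",
            "=" * 48,
            f"training cases:        {len(self.model.training)}",
            f"annealing iterations:  {self.config.iterations}",
            f"best training F-score: {self.best_fscore:.4f}",
            "",
            "Association weights w (bias, f_g, f_u, f_l):",
            "  " + "  ".join(f"{x: .4f}" for x in w),
            f"Interaction weight v:  {self.params.v:.4f}  (beta = {self.params.beta:g})",
            "",
            "Intensity model:",
            f"  mu_int = {im.mu_int:.2f} HU   sigma_int = {im.sigma_int:.2f} HU",
            f"  t_min  = {im.t_min:.2f} HU   t_max     = {im.t_max:.2f} HU",
        ]
        return "\n".join(lines)
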