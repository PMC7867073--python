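"""Weighted-average KPLS (WA-KPLS) ensemble.

Over-extraction of latent components makes a single KPLS model prone to
over-fitting.  The ensemble counters this by fitting D sub-models, each on a
random eta% subset of the training samples (drawn without replacement),
scoring every sub-model by its RMSEP, and combining predictions with
inverse-RMSEP weights:

    w_j = (1 / RMSEP_j) / sum_k (1 / RMSEP_k),   Y_p = sum_k w_k Y_kp

By default RMSEP_j is evaluated on the full training set; ``weight_basis
="oob"`` scores each sub-model on its own held-out samples instead, which
penalizes over-fit sub-models more sharply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kpls import KernelSpec, KPLSModel, KPLSError, fit_kpls, predict_kpls

__all__ = [
    "EnsembleModel",
    "subsample_indices",
    "submodel_weights",
    "fit_wa_kpls",
    "predict_wa_kpls",
]


class EnsembleError(ValueError):
    pass


def subsample_indices(n: int, eta: float, D: int, seed: int | None = None):
    """D index sets of size round(n * eta / 100), without replacement."""
    if not 0 < eta <= 100:
        raise EnsembleError(f"eta must be in (0, 100], got {eta}")
    if D < 1:
        raise EnsembleError("D must be >= 1")
    size = int(round(n * eta / 100.0))
    if size < 2:
        raise EnsembleError(
            f"eta={eta}% of n={n} gives subsets of size {size} (< 2)"
        )
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(D)]


def submodel_weights(rmseps, epsilon: float = 1e-12) -> np.ndarray:
    """Inverse-RMSEP weights, epsilon-floored, normalized to sum to one."""
    rmseps = np.asarray(rmseps, dtype=float)
    if rmseps.size == 0:
        raise EnsembleError("empty RMSEP vector")
    if np.any(rmseps < 0):
        raise EnsembleError("RMSEP values must be >= 0")
    inv = 1.0 / np.maximum(rmseps, epsilon)
    return inv / inv.sum()


@dataclass
class EnsembleModel:
    """D fitted KPLS sub-models with their inverse-RMSEP weights."""

    submodels: list[KPLSModel]
    weights: np.ndarray
    eta: float
    D: int
    seed: int | None
    weight_basis: str = "train"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.submodels) != self.D or self.weights.size != self.D:
            raise EnsembleError("submodel/weight count must equal D")
        if np.any(self.weights <= 0):
            raise EnsembleError("all weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise EnsembleError("weights must sum to 1")

    def to_dict(self) -> dict:
        return {
            "submodels": [m.to_dict() for m in self.submodels],
            "weights": self.weights.tolist(),
            "eta": self.eta,
            "D": self.D,
            "seed": self.seed,
            "weight_basis": self.weight_basis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            submodels=[KPLSModel.from_dict(s) for s in d["submodels"]],
            weights=np.array(d["weights"], dtype=float),
            eta=d["eta"], D=d["D"], seed=d["seed"],
            weight_basis=d["weight_basis"],
        )


def fit_wa_kpls(
    X,
    Y,
    spec: KernelSpec = KernelSpec(),
    n_components: int = 12,
    eta: float = 80.0,
    D: int = 20,
    seed: int | None = None,
    weight_basis: str = "train",
    **fit_kwargs,
) -> EnsembleModel:
    """Fit the WA-KPLS ensemble.

    Each of the D sub-models is a KPLS fit on a random eta% subset; its
    RMSEP is computed on the full training set (``weight_basis="train"``)
    or on its held-out complement (``"oob"``), and the ensemble weights are
    the normalized inverse RMSEPs.
    """
    if weight_basis not in ("train", "oob"):
        raise EnsembleError(f"unknown weight_basis {weight_basis!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(Y, dtype=float).reshape(-1)
    n = X.shape[0]
    if y.size != n:
        raise EnsembleError(f"X has {n} rows but Y has {y.size}")
    index_sets = subsample_indices(n, eta, D, seed)

    # resolve the rbf width once on the full training set so every sub-model
    # shares one feature space
    if spec.kind == "rbf" and spec.gamma is None:
        from .kpls import median_heuristic_gamma

        spec = KernelSpec("rbf", median_heuristic_gamma(X))

    submodels: list[KPLSModel] = []
    rmseps = np.empty(D)
    for j, idx in enumerate(index_sets):
        try:
            m = fit_kpls(
                X[idx], y[idx], spec,
                n_components=min(n_components, idx.size - 1),
                **fit_kwargs,
            )
        except KPLSError as exc:
            raise EnsembleError(f"sub-model {j} failed to fit: {exc}") from exc
        if weight_basis == "train" or idx.size == n:
            eval_idx = np.arange(n)
        else:
            eval_idx = np.setdiff1d(np.arange(n), idx)
        pred = predict_kpls(m, X[eval_idx])
        rmseps[j] = float(np.sqrt(np.mean((y[eval_idx] - pred) ** 2)))
        submodels.append(m)
    return EnsembleModel(
        submodels=submodels,
        weights=submodel_weights(rmseps),
        eta=eta, D=D, seed=seed, weight_basis=weight_basis,
    )


def predict_wa_kpls(model: EnsembleModel, X_new) -> np.ndarray:
    """Weighted-average prediction over the sub-models."""
    preds = np.stack(
        [np.asarray(predict_kpls(m, X_new)).reshape(-1) for m in model.submodels]
    )
    return model.weights @ preds
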