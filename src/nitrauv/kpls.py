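"""Kernel partial least squares (KPLS) regression.

PLS carried out in the implicit feature space of a kernel function
K(x_i, x_j) = <phi(x_i), phi(x_j)>.  Components are extracted by the NIPALS
iteration in kernel space:

    t = K u,  t <- t / ||t||,  c = Y' t,  u = Y c,  u <- u / ||u||

repeated to convergence, followed by deflation K <- (I - t t')K(I - t t')
and Y <- Y - t t'Y.  After A components the regression dual coefficients are

    alpha = U (T' K U)^-1 T' Y

with K the original (un-deflated) centered training kernel, so fitted values
are K alpha and test predictions are K_t alpha with K_t the centered test
kernel.  With the linear kernel this reproduces classical PLS regression.

Kernels must be centered in feature space; the standard formulas

    K_c  = (I - 1 1'/n) K (I - 1 1'/n)
    Kt_c = (K_t - (1/n) 1_m 1_n' K)(I - 1 1'/n)

are used for the training and test kernels respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KernelSpec",
    "KPLSModel",
    "kernel_matrix",
    "center_train_kernel",
    "center_test_kernel",
    "fit_kpls",
    "predict_kpls",
    "select_components",
    "median_heuristic_gamma",
]


class KPLSError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: ``linear`` (z'x) or ``rbf`` (exp(-gamma ||z - x||^2)).

    For the rbf kernel ``gamma`` may be left None, in which case it is set
    at fit time by the median-pairwise-squared-distance heuristic and the
    resolved value is recorded on the fitted model.
    """

    kind: str = "rbf"
    gamma: float | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "rbf"):
            raise KPLSError(f"unknown kernel kind {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise KPLSError("gamma must be positive")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(kind=d["kind"], gamma=d["gamma"])


def median_heuristic_gamma(X) -> float:
    """1 / median of pairwise squared Euclidean distances (zeros excluded)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = pdist(X, metric="sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        raise KPLSError("all training points coincide; cannot set rbf gamma")
    return 1.0 / float(np.median(d2))


def kernel_matrix(X, Z, spec: KernelSpec) -> np.ndarray:
    """Kernel between rows of Z (m x p) and rows of X (n x p): (m x n)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise KPLSError(
            f"dimension mismatch: X has {X.shape[1]} features, Z has {Z.shape[1]}"
        )
    if spec.kind == "linear":
        return Z @ X.T
    gamma = spec.gamma
    if gamma is None:
        raise KPLSError("rbf gamma unresolved; fit resolves it or pass it explicitly")
    return np.exp(-gamma * cdist(Z, X, metric="sqeuclidean"))


def center_train_kernel(K) -> np.ndarray:
    """Feature-space centering of a raw training kernel (n x n)."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise KPLSError(f"training kernel must be square, got {K.shape}")
    col = K.mean(axis=0)
    return K - col[None, :] - col[:, None] + col.mean()


def center_test_kernel(Kt, K) -> np.ndarray:
    """Center a raw test kernel (m x n) consistently with the training kernel."""
    Kt = np.atleast_2d(np.asarray(Kt, dtype=float))
    K = np.asarray(K, dtype=float)
    if Kt.shape[1] != K.shape[0]:
        raise KPLSError(
            f"test kernel has {Kt.shape[1]} columns for {K.shape[0]} training rows"
        )
    M = Kt - K.mean(axis=0)[None, :]
    return M - M.mean(axis=1, keepdims=True)


@dataclass
class KPLSModel:
    """A fitted kernel PLS regression.

    ``T`` and ``U`` hold the unit-norm score vectors column-wise; ``alpha``
    are the dual regression coefficients on the centered training kernel;
    ``k_col_means`` are the column means of the raw training kernel, needed
    to center test kernels.
    """

    spec: KernelSpec
    X: np.ndarray
    Y: np.ndarray            # training targets, original scale (n, m)
    y_mean: np.ndarray       # (m,)
    T: np.ndarray            # (n, A)
    U: np.ndarray            # (n, A)
    alpha: np.ndarray        # (n, m)
    k_col_means: np.ndarray  # (n,)
    n_components: int
    K: np.ndarray | None = None   # raw training kernel (kept in memory)
    Kc: np.ndarray | None = None  # centered training kernel

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "X": self.X.tolist(),
            "Y": self.Y.tolist(),
            "y_mean": self.y_mean.tolist(),
            "T": self.T.tolist(),
            "U": self.U.tolist(),
            "alpha": self.alpha.tolist(),
            "k_col_means": self.k_col_means.tolist(),
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KPLSModel":
        return cls(
            spec=KernelSpec.from_dict(d["spec"]),
            X=np.array(d["X"], dtype=float),
            Y=np.array(d["Y"], dtype=float),
            y_mean=np.array(d["y_mean"], dtype=float),
            T=np.array(d["T"], dtype=float),
            U=np.array(d["U"], dtype=float),
            alpha=np.array(d["alpha"], dtype=float),
            k_col_means=np.array(d["k_col_means"], dtype=float),
            n_components=int(d["n_components"]),
        )


def _as_2d_targets(Y):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def _extract_components(Kc, Yc, A, tol, max_iter, rng):
    """NIPALS component extraction with two-sided deflation of K."""
    n = Kc.shape[0]
    T = np.empty((n, A))
    U = np.empty((n, A))
    Kd = Kc.copy()
    Yd = Yc.copy()
    for a in range(A):
        if rng is not None:
            u = rng.standard_normal(n)
        else:
            u = Yd[:, 0].copy()
        nu = np.linalg.norm(u)
        if nu == 0:  # deflated Y exhausted; fall back to a fixed direction
            u = np.ones(n)
            nu = np.sqrt(n)
        u /= nu
        t_old = np.zeros(n)
        for it in range(max_iter):
            t = Kd @ u
            nt = np.linalg.norm(t)
            if nt < 1e-13:
                raise KPLSError(
                    f"score vector collapsed at component {a + 1}: "
                    "the kernel carries no further variation "
                    "(reduce n_components)"
                )
            t /= nt
            c = Yd.T @ t
            u = Yd @ c
            nu = np.linalg.norm(u)
            if nu < 1e-13:
                # Y residual orthogonal to the kernel directions; keep t
                break
            u /= nu
            if np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        else:
            warnings.warn(
                f"KPLS inner iteration did not converge for component {a + 1}; "
                "using the current score vector",
                stacklevel=3,
            )
        T[:, a] = t
        U[:, a] = u
        P = np.eye(n) - np.outer(t, t)
        Kd = P @ Kd @ P
        Yd = Yd - np.outer(t, t @ Yd)
    return T, U


def fit_kpls(
    X,
    Y,
    spec: KernelSpec = KernelSpec(),
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
    random_init_seed: int | None = None,
) -> KPLSModel:
    """Fit kernel PLS with ``n_components`` latent components.

    Y is mean-centered internally (the mean is restored at prediction).
    By default the score iteration starts from the first column of the
    current Y residual, which makes fits deterministic; pass
    ``random_init_seed`` for a seeded random start instead.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y2 = _as_2d_targets(Y)
    n = X.shape[0]
    if Y2.shape[0] != n:
        raise KPLSError(f"X has {n} rows but Y has {Y2.shape[0]}")
    if n < 2:
        raise KPLSError("need at least 2 training samples")
    if not 1 <= n_components <= n - 1:
        raise KPLSError(
            f"n_components must be in [1, {n - 1}], got {n_components}"
        )
    if spec.kind == "rbf" and spec.gamma is None:
        spec = KernelSpec("rbf", median_heuristic_gamma(X))

    K = kernel_matrix(X, X, spec)
    Kc = center_train_kernel(K)
    y_mean = Y2.mean(axis=0)
    Yc = Y2 - y_mean
    rng = (
        np.random.default_rng(random_init_seed)
        if random_init_seed is not None
        else None
    )
    T, U = _extract_components(Kc, Yc, n_components, tol, max_iter, rng)
    alpha = _dual_coefficients(Kc, Yc, T, U)
    return KPLSModel(
        spec=spec, X=X.copy(), Y=Y2.copy(), y_mean=y_mean,
        T=T, U=U, alpha=alpha, k_col_means=K.mean(axis=0),
        n_components=n_components, K=K, Kc=Kc,
    )


def _dual_coefficients(Kc, Yc, T, U):
    """alpha = U (T' Kc U)^-1 T' Yc with the original centered kernel."""
    M = T.T @ Kc @ U
    try:
        inner = np.linalg.solve(M, T.T @ Yc)
    except np.linalg.LinAlgError as exc:
        raise KPLSError(
            "singular (T' K U); reduce the number of components"
        ) from exc
    return U @ inner


def predict_kpls(model: KPLSModel, X_new) -> np.ndarray:
    """Predict responses for new inputs.

    Builds the raw test kernel against the stored training inputs, centers
    it consistently with the training kernel, and applies the dual
    coefficients; the training-response mean is added back.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X.shape[1]:
        raise KPLSError(
            f"expected {model.X.shape[1]} features, got {X_new.shape[1]}"
        )
    Kt = kernel_matrix(model.X, X_new, model.spec)
    M = Kt - model.k_col_means[None, :]
    Ktc = M - M.mean(axis=1, keepdims=True)
    pred = Ktc @ model.alpha + model.y_mean
    if model.Y.shape[1] == 1:
        return pred[:, 0]
    return pred


def select_components(
    X,
    Y,
    spec: KernelSpec = KernelSpec(),
    r2_threshold: float = 0.9995,
    a_max: int = 20,
    **fit_kwargs,
) -> int:
    """Smallest component count whose training R^2 reaches the threshold.

    Components are added until the coefficient of determination of the
    fitted training responses exceeds ``r2_threshold``; if it never does
    (or the kernel runs out of variation first), the largest attainable
    count is returned with a warning.
    """
    Y2 = _as_2d_targets(Y)
    n = Y2.shape[0]
    a_max = min(a_max, n - 1)
    sst = float(np.sum((Y2 - Y2.mean(axis=0)) ** 2))
    if sst == 0:
        raise KPLSError("Y has zero variance; component selection undefined")
    best_a = a_max
    for a in range(1, a_max + 1):
        try:
            model = fit_kpls(X, Y2, spec, n_components=a, **fit_kwargs)
        except KPLSError:
            best_a = a - 1
            break
        fitted = np.atleast_2d(predict_kpls(model, X))
        if fitted.shape[0] == 1 and Y2.shape[0] > 1:
            fitted = fitted.T
        fitted = fitted.reshape(Y2.shape)
        r2 = 1.0 - float(np.sum((Y2 - fitted) ** 2)) / sst
        if r2 >= r2_threshold:
            return a
    if best_a < 1:
        raise KPLSError("could not extract even one component")
    warnings.warn(
        f"training R^2 never reached {r2_threshold}; using {best_a} components",
        stacklevel=2,
    )
    return best_a
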