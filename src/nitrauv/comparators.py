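"""Baseline nitrate retrieval algorithms: TSC-MLR and ISUS-style retrieval.

MLR is ordinary least squares of the reference concentration on the
TSC-corrected absorbance over the modeling window, so the comparison with
WA-KPLS isolates the regressor.

The ISUS-style retrieval decomposes each measured spectrum over 217-240 nm
into (i) an empirical oligotrophic-seawater absorbance term

    A_OS(T, lambda) = (A + B T) exp((C + D T) (lambda - 210))

scaled by S/35, (ii) the nitrate extinction spectrum, and (iii) an affine
baseline; the nitrate coefficient of the per-sample linear least-squares
solve is the concentration estimate.  Because the empirical seawater term is
instrument-specific, raw ISUS estimates are usually recalibrated against
reference concentrations by a final linear correction.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .spectra import SampleTable

__all__ = [
    "MLRModel",
    "ISUSModel",
    "ISUS_DEFAULT_PARAMS",
    "fit_mlr",
    "predict_mlr",
    "isus_seawater_absorbance",
    "fit_isus",
    "predict_isus",
    "linear_recalibrate",
]


class ComparatorError(ValueError):
    pass


# Published empirical oligotrophic-seawater fit parameters (A, B, C, D)
ISUS_DEFAULT_PARAMS = (1.1500276, 0.02840, -0.3101349, 0.001222)
ISUS_WAVELENGTH_OFFSET_NM = 210.0
ISUS_WINDOW_NM = (217.0, 240.0)


@dataclass
class MLRModel:
    """OLS coefficients (umol/L per AU) over the modeling-window wavelengths."""

    wavelengths: np.ndarray
    coef: np.ndarray
    intercept: float

    def to_dict(self) -> dict:
        return {
            "wavelengths": self.wavelengths.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            wavelengths=np.array(d["wavelengths"], dtype=float),
            coef=np.array(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
        )


def fit_mlr(A_corrected, y, wavelengths=None) -> MLRModel:
    """Least-squares fit of concentration on corrected absorbance.

    When the design is rank-deficient (fewer samples than wavelengths) the
    minimum-norm solution is returned with a warning.
    """
    A = np.atleast_2d(np.asarray(A_corrected, dtype=float))
    y = np.asarray(y, dtype=float).reshape(-1)
    n, p = A.shape
    if y.size != n:
        raise ComparatorError(f"{n} spectra but {y.size} concentrations")
    X = np.column_stack([A, np.ones(n)])
    sol, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p + 1:
        warnings.warn(
            "rank-deficient MLR design; returning the minimum-norm solution",
            stacklevel=2,
        )
    wl = (np.asarray(wavelengths, dtype=float)
          if wavelengths is not None else np.arange(p, dtype=float))
    return MLRModel(wavelengths=wl, coef=sol[:p], intercept=float(sol[p]))


def predict_mlr(model: MLRModel, A_corrected) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A_corrected, dtype=float))
    if A.shape[1] != model.coef.size:
        raise ComparatorError(
            f"expected {model.coef.size} wavelengths, got {A.shape[1]}"
        )
    return A @ model.coef + model.intercept


def isus_seawater_absorbance(T, wl, params=ISUS_DEFAULT_PARAMS):
    """Empirical oligotrophic-seawater absorbance (A + BT) exp((C + DT) W).

    ``W`` is the wavelength minus 210 nm; T in degrees C.
    """
    A, B, C, D = params
    T = np.asarray(T, dtype=float)
    W = np.asarray(wl, dtype=float) - ISUS_WAVELENGTH_OFFSET_NM
    return (A + B * T) * np.exp((C + D * T) * W)


@dataclass
class ISUSModel:
    """ISUS-style retrieval configuration plus optional linear recalibration."""

    wavelengths: np.ndarray             # retrieval window grid, nm
    nitrate_extinction: np.ndarray      # AU per umol/L on that grid
    params: tuple = ISUS_DEFAULT_PARAMS
    recal_slope: float = 1.0
    recal_intercept: float = 0.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.nitrate_extinction = np.asarray(self.nitrate_extinction, dtype=float)
        if np.any(self.nitrate_extinction < 0):
            raise ComparatorError("nitrate extinction must be >= 0")
        if self.wavelengths.size != self.nitrate_extinction.size:
            raise ComparatorError("extinction grid length mismatch")

    def to_dict(self) -> dict:
        return {
            "wavelengths": self.wavelengths.tolist(),
            "nitrate_extinction": self.nitrate_extinction.tolist(),
            "params": list(self.params),
            "recal_slope": self.recal_slope,
            "recal_intercept": self.recal_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ISUSModel":
        return cls(
            wavelengths=np.array(d["wavelengths"], dtype=float),
            nitrate_extinction=np.array(d["nitrate_extinction"], dtype=float),
            params=tuple(d["params"]),
            recal_slope=float(d["recal_slope"]),
            recal_intercept=float(d["recal_intercept"]),
        )


def fit_isus(
    table: SampleTable,
    nitrate_extinction,
    params=ISUS_DEFAULT_PARAMS,
    window=ISUS_WINDOW_NM,
) -> ISUSModel:
    """Build the retrieval for a table's grid (restricted to the 217-240 nm
    window) and, when reference concentrations are present, recalibrate the
    raw estimates linearly against them."""
    mask = (table.wavelengths >= window[0]) & (table.wavelengths <= window[1])
    if mask.sum() < 3:
        raise ComparatorError(
            f"need >= 3 wavelengths in the ISUS window {window}"
        )
    eps = np.asarray(nitrate_extinction, dtype=float)
    if eps.size == table.wavelengths.size:
        eps = eps[mask]
    elif eps.size != mask.sum():
        raise ComparatorError("nitrate extinction does not match the grid")
    model = ISUSModel(
        wavelengths=table.wavelengths[mask], nitrate_extinction=eps,
        params=tuple(params),
    )
    labeled = np.isfinite(table.reference_conc)
    if labeled.sum() >= 2:
        raw = predict_isus(model, table, recalibrated=False)
        # degenerate sets (constant references or estimates) stay uncalibrated
        if np.ptp(raw[labeled]) > 0 and np.ptp(table.reference_conc[labeled]) > 0:
            a, b, _ = linear_recalibrate(
                raw[labeled], table.reference_conc[labeled]
            )
            model.recal_slope, model.recal_intercept = a, b
    return model


def predict_isus(model: ISUSModel, table: SampleTable,
                 recalibrated: bool = True) -> np.ndarray:
    """Per-sample nitrate estimate from the ISUS-style decomposition.

    Each spectrum (restricted to the retrieval window) is modeled as
    (S/35) * A_OS(T, lambda) + C * eps_NO3(lambda) + intercept + slope *
    lambda; C solves the linear least-squares problem.  The seawater term is
    fixed from the sample's recorded T and S (salinity is not a free
    parameter of the fit).
    """
    idx = _match_grid(table.wavelengths, model.wavelengths)
    wl = model.wavelengths
    design = np.column_stack([model.nitrate_extinction, np.ones(wl.size), wl])
    if np.linalg.matrix_rank(design) < 3:
        raise ComparatorError(
            "singular ISUS design: nitrate extinction is affine in wavelength "
            "over the retrieval window"
        )
    conc = np.empty(table.n_samples)
    for i in range(table.n_samples):
        a_sw = (table.salinity[i] / 35.0) * isus_seawater_absorbance(
            table.temperature[i], wl, model.params
        )
        rhs = table.absorbance[i, idx] - a_sw
        sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        conc[i] = sol[0]
    if recalibrated:
        conc = model.recal_slope * conc + model.recal_intercept
    return conc


def _match_grid(src, target):
    idx = np.searchsorted(src, target)
    idx = np.clip(idx, 0, src.size - 1)
    if not np.allclose(src[idx], target, atol=1e-9):
        raise ComparatorError("table grid does not contain the retrieval window")
    return idx


def linear_recalibrate(pred, ref):
    """OLS map ref ~ a * pred + b; returns (a, b, corrected predictions)."""
    pred = np.asarray(pred, dtype=float).reshape(-1)
    ref = np.asarray(ref, dtype=float).reshape(-1)
    if pred.size != ref.size or pred.size < 2:
        raise ComparatorError("need >= 2 aligned (pred, ref) pairs")
    if np.ptp(pred) == 0:
        raise ComparatorError("constant predictions cannot be recalibrated")
    X = np.column_stack([pred, np.ones(pred.size)])
    (a, b), *_ = np.linalg.lstsq(X, ref, rcond=None)
    return float(a), float(b), a * pred + b
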