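"""Prediction metrics and residual diagnostics.

RMSEP = sqrt(mean((y - y_p)^2)) and R^2 = 1 - SS_res / SS_tot are the two
headline figures of merit; :func:`residual_report` adds the error range, the
fraction of residuals within each tolerance (the +/-2 umol/L band is the
conventional field requirement), and Pearson correlations of the residuals
with temperature and salinity — a corrected retrieval should show none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "rmsep", "r_squared", "residual_report"]


class MetricError(ValueError):
    pass


def _aligned(ref, pred):
    ref = np.asarray(ref, dtype=float).reshape(-1)
    pred = np.asarray(pred, dtype=float).reshape(-1)
    if ref.size != pred.size:
        raise MetricError(f"length mismatch: {ref.size} vs {pred.size}")
    if ref.size == 0:
        raise MetricError("empty input")
    return ref, pred


def rmsep(ref, pred) -> float:
    """Root mean square error of prediction, in the units of the inputs."""
    ref, pred = _aligned(ref, pred)
    return float(np.sqrt(np.mean((ref - pred) ** 2)))


def r_squared(ref, pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot about mean(ref)."""
    ref, pred = _aligned(ref, pred)
    sst = float(np.sum((ref - ref.mean()) ** 2))
    if sst == 0:
        raise MetricError("reference values are all equal; R^2 undefined")
    return 1.0 - float(np.sum((ref - pred) ** 2)) / sst


@dataclass
class EvalReport:
    """Summary of prediction quality for one method on one sample set."""

    rmsep: float
    r2: float | None
    residuals: np.ndarray                  # pred - ref, umol/L
    error_range: tuple[float, float]
    frac_within: dict[float, float]
    corr_T: float | None = None
    corr_S: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "rmsep": self.rmsep,
            "r2": self.r2,
            "residuals": self.residuals.tolist(),
            "error_range": list(self.error_range),
            "frac_within": {str(k): v for k, v in self.frac_within.items()},
            "corr_T": self.corr_T,
            "corr_S": self.corr_S,
            "n": self.n,
        }


def _pearson_or_none(x, resid):
    if x is None:
        return None
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.size != resid.size:
        raise MetricError("covariate length mismatch")
    if np.ptp(x) == 0 or np.ptp(resid) == 0 or x.size < 2:
        return None  # correlation undefined for a constant vector
    return float(stats.pearsonr(x, resid).statistic)


def residual_report(ref, pred, T=None, S=None, tolerances=(2.0,)) -> EvalReport:
    """Full residual diagnostics; residual sign convention is pred - ref."""
    ref, pred = _aligned(ref, pred)
    resid = pred - ref
    frac = {
        float(tau): float(np.mean(np.abs(resid) <= tau)) for tau in tolerances
    }
    r2 = r_squared(ref, pred) if np.ptp(ref) > 0 else None
    return EvalReport(
        rmsep=rmsep(ref, pred),
        r2=r2,
        residuals=resid,
        error_range=(float(resid.min()), float(resid.max())),
        frac_within=frac,
        corr_T=_pearson_or_none(T, resid),
        corr_S=_pearson_or_none(S, resid),
        n=ref.size,
    )
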