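"""Temperature and salinity correction (TSC) of seawater UV absorbance.

The deep-UV absorbance of nitrate-free seawater is dominated by sea salt —
chiefly bromide, whose charge-transfer-to-solvent band grows with temperature
— plus a broadband CDOM tail.  The correction chain removes both so that the
residual spectrum carries the temperature-independent nitrate signal:

1. salinity normalization of calibration spectra to S = 35 psu
   (A = A_m * 35 / S_m);
2. a low-nutrient-seawater (LNS) absorbance model over wavelength and
   temperature, fitted on a thermostatted calibration sweep;
3. per-psu sea-salt molar absorptivity E(lambda, T) from the calibration,
   giving the sample's sea-salt absorbance A_ss = E(lambda, T) * S;
4. subtraction A' = A_meas - A_ss;
5. a straight-line CDOM baseline fitted on the 240-260 nm residual (where
   nitrate does not absorb) and extrapolated over the 208-240 nm modeling
   window, subtracted to give the corrected spectrum A''.

Two representations of the calibration are kept.  The bivariate polynomial
LNS surface (``LNSModel``) is the smooth, portable summary used for
diagnostics and drift ratios.  The sea-salt subtraction itself uses a
per-wavelength polynomial in temperature fitted at every calibration pixel
(``TSCModel.ecal_coeffs``): this stays exact for any smooth temperature law
at every measured wavelength, which a low-order wavelength polynomial cannot
guarantee for the steep bromide edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .spectra import SampleTable

__all__ = [
    "LNSModel",
    "TSCModel",
    "normalize_salinity",
    "fit_lns_surface",
    "predict_lns",
    "molar_absorptivity",
    "sea_salt_absorbance",
    "remove_sea_salt",
    "remove_cdom",
    "fit_tsc",
    "apply_tsc",
]

S_STANDARD = 35.0


class TSCError(ValueError):
    pass


def normalize_salinity(A, Sm: float) -> np.ndarray:
    """Scale absorbance to the S = 35 psu standard: A * 35 / Sm."""
    if Sm <= 0:
        raise TSCError(f"salinity must be positive, got {Sm}")
    return np.asarray(A, dtype=float) * (S_STANDARD / Sm)


@dataclass
class LNSModel:
    """Bivariate polynomial surface A(W, T) of salinity-normalized LNS.

    W and T are centered and scaled by the stored means/stds before the
    polynomial is evaluated; ``coeffs[a, b]`` multiplies W_n^a * T_n^b.
    """

    w_mean: float
    w_std: float
    t_mean: float
    t_std: float
    degrees: tuple[int, int]
    coeffs: np.ndarray  # (dW+1, dT+1)
    r2: float = np.nan
    rmse: float = np.nan
    sse: float = np.nan
    w_span: tuple[float, float] = (-np.inf, np.inf)
    t_span: tuple[float, float] = (-np.inf, np.inf)

    def to_dict(self) -> dict:
        return {
            "w_mean": self.w_mean, "w_std": self.w_std,
            "t_mean": self.t_mean, "t_std": self.t_std,
            "degrees": list(self.degrees),
            "coeffs": np.asarray(self.coeffs).tolist(),
            "r2": self.r2, "rmse": self.rmse, "sse": self.sse,
            "w_span": list(self.w_span), "t_span": list(self.t_span),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LNSModel":
        return cls(
            w_mean=d["w_mean"], w_std=d["w_std"],
            t_mean=d["t_mean"], t_std=d["t_std"],
            degrees=tuple(d["degrees"]),
            coeffs=np.array(d["coeffs"], dtype=float),
            r2=d["r2"], rmse=d["rmse"], sse=d["sse"],
            w_span=tuple(d["w_span"]), t_span=tuple(d["t_span"]),
        )


def fit_lns_surface(cal: SampleTable, degrees: tuple[int, int] = (3, 2)) -> LNSModel:
    """Least-squares polynomial surface fit to zero-nitrate calibration data.

    ``cal`` must already be salinity-normalized (Eq. of step 1); every
    (wavelength, temperature) pixel is one observation.  Requires at least
    two distinct temperatures and more observations than coefficients.
    """
    dW, dT = degrees
    if dW < 0 or dT < 0:
        raise TSCError("degrees must be non-negative")
    wl = cal.wavelengths
    T = cal.temperature
    if np.unique(T).size < 2 and dT > 0:
        raise TSCError("need >= 2 distinct temperatures to fit a T-dependent surface")
    Wg, Tg = np.meshgrid(wl, T)  # (nT, nW)
    y = cal.absorbance.ravel()
    n_terms = (dW + 1) * (dT + 1)
    if y.size < n_terms:
        raise TSCError(f"{y.size} points cannot determine {n_terms} coefficients")

    w_mean, w_std = float(np.mean(Wg)), float(np.std(Wg))
    t_mean, t_std = float(np.mean(Tg)), float(np.std(Tg))
    w_std = w_std if w_std > 0 else 1.0
    t_std = t_std if t_std > 0 else 1.0
    wn = ((Wg - w_mean) / w_std).ravel()
    tn = ((Tg - t_mean) / t_std).ravel()

    design = npoly.polyvander2d(wn, tn, (dW, dT))  # columns: W^a T^b
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < n_terms:
        raise TSCError(
            f"rank-deficient design (rank {rank} < {n_terms} terms); "
            "reduce the polynomial degrees"
        )
    fitted = design @ coef
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return LNSModel(
        w_mean=w_mean, w_std=w_std, t_mean=t_mean, t_std=t_std,
        degrees=(dW, dT), coeffs=coef.reshape(dW + 1, dT + 1),
        r2=r2, rmse=float(np.sqrt(sse / y.size)), sse=sse,
        w_span=(float(wl.min()), float(wl.max())),
        t_span=(float(T.min()), float(T.max())),
    )


def predict_lns(model: LNSModel, W, T):
    """Evaluate the LNS surface at wavelength(s) W nm and temperature(s) T C.

    Warns (without failing) when evaluated outside the fitted span.
    """
    W = np.asarray(W, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(W < model.w_span[0]) or np.any(W > model.w_span[1]) \
            or np.any(T < model.t_span[0]) or np.any(T > model.t_span[1]):
        warnings.warn("evaluating LNS surface outside its fitted span",
                      stacklevel=2)
    wn = (W - model.w_mean) / model.w_std
    tn = (T - model.t_mean) / model.t_std
    return npoly.polyval2d(wn, tn, model.coeffs)


def molar_absorptivity(E_cal, A_meas_norm, A_model, tol: float = 1e-9):
    """Transfer the calibration molar absorptivity to the measured matrix.

    E_m = E_cal * A_meas_norm / A_model, elementwise over the (W, T) grid.
    The ratio re-scales the per-psu calibration absorptivity by how the
    measured (normalized) absorbance deviates from the LNS-model prediction,
    e.g. to absorb lamp drift between calibration and measurement.
    """
    E_cal = np.asarray(E_cal, dtype=float)
    A_meas_norm = np.asarray(A_meas_norm, dtype=float)
    A_model = np.asarray(A_model, dtype=float)
    if np.any(np.abs(A_model) <= tol):
        raise TSCError("LNS model absorbance ~ 0; molar absorptivity ratio "
                       "would blow up")
    return E_cal * A_meas_norm / A_model


def sea_salt_absorbance(E_m, S: float):
    """Sea-salt absorbance A_ss = E_m * S for salinity S (psu)."""
    if S < 0:
        raise TSCError(f"salinity must be >= 0, got {S}")
    return np.asarray(E_m, dtype=float) * S


def remove_sea_salt(A_meas, A_ss):
    """A' = A_meas - A_ss elementwise; negative residuals are preserved."""
    A_meas = np.asarray(A_meas, dtype=float)
    A_ss = np.asarray(A_ss, dtype=float)
    if A_meas.shape != A_ss.shape:
        raise TSCError(f"grid mismatch: {A_meas.shape} vs {A_ss.shape}")
    return A_meas - A_ss


def remove_cdom(
    wavelengths,
    a_prime,
    fit_window: tuple[float, float] = (240.0, 260.0),
    apply_window: tuple[float, float] = (208.0, 240.0),
):
    """Subtract the straight-line CDOM baseline fitted beyond the nitrate band.

    An ordinary least-squares line e + f*lambda (raw nm) is fitted to the
    sea-salt-removed residual inside ``fit_window`` — a region where nitrate
    does not absorb — and extrapolated over ``apply_window``.

    Returns ``(window_wavelengths, corrected, (e, f))`` where ``corrected``
    has one row per input row restricted to the apply window.
    """
    wl = np.asarray(wavelengths, dtype=float)
    A = np.atleast_2d(np.asarray(a_prime, dtype=float))
    if A.shape[1] != wl.size:
        raise TSCError(f"{A.shape[1]} columns for {wl.size} wavelengths")
    fit_mask = (wl >= fit_window[0]) & (wl <= fit_window[1])
    if fit_mask.sum() < 2:
        raise TSCError(
            f"need >= 2 points in the CDOM fit window {fit_window}, "
            f"got {int(fit_mask.sum())}"
        )
    X = np.column_stack([np.ones(fit_mask.sum()), wl[fit_mask]])
    coefs, *_ = np.linalg.lstsq(X, A[:, fit_mask].T, rcond=None)  # (2, n)
    e, f = coefs[0], coefs[1]
    baseline = e[:, None] + f[:, None] * wl[None, :]
    corrected = A - baseline
    out_mask = (wl >= apply_window[0]) & (wl <= apply_window[1])
    if not out_mask.any():
        raise TSCError(f"no wavelengths in the apply window {apply_window}")
    result = corrected[:, out_mask]
    if np.asarray(a_prime).ndim == 1:
        return wl[out_mask], result[0], (float(e[0]), float(f[0]))
    return wl[out_mask], result, (e, f)


@dataclass
class TSCModel:
    """Fitted temperature/salinity correction.

    ``ecal_coeffs[:, k]`` are the degree-k coefficients of the per-psu
    sea-salt molar absorptivity E(lambda, T) as a polynomial in the
    normalized temperature (T - t_mean) / t_std, one row per calibration
    wavelength.  ``lns`` is the smooth bivariate surface kept for
    diagnostics.
    """

    lns: LNSModel
    wavelengths: np.ndarray
    ecal_coeffs: np.ndarray  # (n_wl, dT+1)
    t_mean: float
    t_std: float
    s_standard: float = S_STANDARD
    cdom_window: tuple[float, float] = (240.0, 260.0)
    model_window: tuple[float, float] = (208.0, 240.0)

    def ecal(self, T) -> np.ndarray:
        """E(lambda, T) in AU/psu on the calibration grid; rows follow T."""
        tn = np.atleast_1d((np.asarray(T, dtype=float) - self.t_mean) / self.t_std)
        # Horner evaluation across wavelengths: (nT, n_wl)
        out = np.zeros((tn.size, self.wavelengths.size))
        for k in range(self.ecal_coeffs.shape[1] - 1, -1, -1):
            out = out * tn[:, None] + self.ecal_coeffs[None, :, k]
        return out

    def to_dict(self) -> dict:
        return {
            "lns": self.lns.to_dict(),
            "wavelengths": self.wavelengths.tolist(),
            "ecal_coeffs": self.ecal_coeffs.tolist(),
            "t_mean": self.t_mean, "t_std": self.t_std,
            "s_standard": self.s_standard,
            "cdom_window": list(self.cdom_window),
            "model_window": list(self.model_window),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSCModel":
        return cls(
            lns=LNSModel.from_dict(d["lns"]),
            wavelengths=np.array(d["wavelengths"], dtype=float),
            ecal_coeffs=np.array(d["ecal_coeffs"], dtype=float),
            t_mean=d["t_mean"], t_std=d["t_std"],
            s_standard=d["s_standard"],
            cdom_window=tuple(d["cdom_window"]),
            model_window=tuple(d["model_window"]),
        )


def fit_tsc(
    cal: SampleTable,
    degrees: tuple[int, int] = (3, 2),
    cdom_window: tuple[float, float] = (240.0, 260.0),
    model_window: tuple[float, float] = (208.0, 240.0),
) -> TSCModel:
    """Fit the full correction from a zero-nitrate calibration sweep.

    The calibration absorbances are salinity-normalized to 35 psu, the LNS
    polynomial surface is fitted over the working range (modeling window up
    to the top of the CDOM window), and the per-wavelength temperature
    polynomials of E(lambda, T) = A_norm(lambda, T) / 35 are fitted at every
    calibration pixel with the temperature degree of ``degrees``.
    """
    dW, dT = degrees
    A_norm = np.vstack([
        normalize_salinity(cal.absorbance[i], cal.salinity[i])
        for i in range(cal.n_samples)
    ])
    norm_cal = cal.with_absorbance(A_norm)

    lo, hi = model_window[0], cdom_window[1]
    fit_mask = (cal.wavelengths >= lo) & (cal.wavelengths <= hi)
    if fit_mask.sum() < 2:
        raise TSCError("calibration grid does not cover the working range")
    surf_cal = norm_cal.with_absorbance(
        A_norm[:, fit_mask], wavelengths=cal.wavelengths[fit_mask]
    )
    lns = fit_lns_surface(surf_cal, degrees=degrees)

    T = cal.temperature
    if np.unique(T).size < dT + 1:
        raise TSCError(
            f"need >= {dT + 1} distinct calibration temperatures "
            f"for a degree-{dT} temperature law"
        )
    t_mean, t_std = float(T.mean()), float(T.std())
    t_std = t_std if t_std > 0 else 1.0
    tn = (T - t_mean) / t_std
    # per-wavelength polynomial in normalized T of the per-psu absorptivity
    ecal = npoly.polyfit(tn, A_norm / S_STANDARD, dT)  # (dT+1, n_wl)
    return TSCModel(
        lns=lns,
        wavelengths=cal.wavelengths.copy(),
        ecal_coeffs=ecal.T.copy(),
        t_mean=t_mean, t_std=t_std,
        cdom_window=cdom_window, model_window=model_window,
    )


def apply_tsc(model: TSCModel, table: SampleTable) -> SampleTable:
    """Apply the fitted correction to a measured table.

    Per sample: evaluate the sea-salt molar absorptivity at the sample
    temperature, scale by its salinity to get A_ss, subtract from the
    measured absorbance, remove the straight-line CDOM baseline fitted at
    240-260 nm, and restrict to the 208-240 nm modeling window.
    """
    # match the table's grid to the calibration grid
    idx = np.searchsorted(model.wavelengths, table.wavelengths)
    idx = np.clip(idx, 0, model.wavelengths.size - 1)
    if not np.allclose(model.wavelengths[idx], table.wavelengths, atol=1e-9):
        raise TSCError("sample wavelengths are not on the calibration grid")
    if np.any(table.salinity <= 0):
        raise TSCError("all samples must have positive salinity")

    E = model.ecal(table.temperature)[:, idx]          # (n, n_wl)
    A_ss = E * table.salinity[:, None]                 # Eq.-6 style scaling
    A_prime = remove_sea_salt(table.absorbance, A_ss)
    wl_out, corrected, _ = remove_cdom(
        table.wavelengths, A_prime,
        fit_window=model.cdom_window, apply_window=model.model_window,
    )
    return table.with_absorbance(corrected, wavelengths=wl_out)
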