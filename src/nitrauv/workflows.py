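"""Scripted experiment workflows.

``run_benchmark`` exercises the full pipeline on seeded synthetic seawater:
generate a labeled training/test split and a zero-nutrient calibration
sweep, fit the temperature/salinity correction, then fit and evaluate
TSC-WA-KPLS against the TSC-MLR and ISUS baselines.

``run_extrapolation_study`` probes behaviour outside the calibrated
concentration range: train on a restricted nitrate band, predict samples
below the band and in the 90-100 umol/L band, and report the fraction of
predictions within +/-2 umol/L per band.

Problem sizes default to a 600/200 train/test split over nitrate
0-100 umol/L, temperatures 4-25 C and salinities 30-35 psu with 1000:1-SNR
noise; the calibration sweep covers 4-25 C at 1 C intervals.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np

from . import synth
from .comparators import fit_isus, fit_mlr, predict_isus, predict_mlr
from .ensemble import fit_wa_kpls, predict_wa_kpls
from .kpls import KernelSpec
from .metrics import residual_report
from .spectra import SampleTable
from .tsc import apply_tsc, fit_tsc

__all__ = ["run_benchmark", "run_extrapolation_study", "config_hash"]

log = logging.getLogger(__name__)

# working grid: covers the 208-240 nm modeling window and the 240-260 nm
# CDOM window with margin, at the instrument's 0.4 nm pixel pitch
DEFAULT_GRID = synth.default_grid(200.0, 280.0, 0.4)
CAL_TEMPS = np.arange(4.0, 26.0)  # 4-25 C at 1 C intervals


def config_hash(config: dict) -> str:
    """Short deterministic digest of a run configuration (for provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _spawn_rngs(seed, n):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _prepare(seed, n_train, n_test, conc_range, T_range, S_range, noise,
             grid, cdom_shape, train_range=None):
    """Generate calibration/train/test tables and the fitted TSC model."""
    lib = synth.default_library(cdom_shape=cdom_shape)
    rng_cal, rng_train, rng_test = _spawn_rngs(seed, 3)
    cal = synth.generate_lns_calibration(
        lib, CAL_TEMPS, seed=rng_cal, noise=noise, grid=grid
    )
    train = synth.generate_samples(
        lib, n_train, conc_range=train_range or conc_range,
        T_range=T_range, S_range=S_range, noise=noise, seed=rng_train,
        grid=grid, id_prefix="train",
    )
    test = synth.generate_samples(
        lib, n_test, conc_range=conc_range, T_range=T_range, S_range=S_range,
        noise=noise, seed=rng_test, grid=grid, id_prefix="test",
    )
    tsc_model = fit_tsc(cal)
    return lib, tsc_model, train, test


def run_benchmark(
    seed: int = 0,
    n_train: int = 600,
    n_test: int = 200,
    conc_range=(0.0, 100.0),
    T_range=(4.0, 25.0),
    S_range=(30.0, 35.0),
    noise: bool = True,
    kernel: KernelSpec = KernelSpec(),
    n_components: int = 12,
    eta: float = 80.0,
    D: int = 20,
    methods=("wa-kpls", "mlr", "isus"),
    tolerances=(2.0,),
    grid=None,
    cdom_shape: str = "exponential",
) -> dict:
    """Fit and evaluate all requested methods on one seeded synthetic run.

    Returns a dict with, per method, the test-set :class:`EvalReport` (when
    reference concentrations exist) and the raw predictions, plus the TSC
    diagnostics and a provenance block (seed, config hash).
    """
    config = dict(
        seed=seed, n_train=n_train, n_test=n_test, conc_range=list(conc_range),
        T_range=list(T_range), S_range=list(S_range), noise=noise,
        kernel=kernel.to_dict(), n_components=n_components, eta=eta, D=D,
        methods=list(methods), tolerances=list(tolerances),
        cdom_shape=cdom_shape,
    )
    if grid is None:
        grid = DEFAULT_GRID
    lib, tsc_model, train, test = _prepare(
        seed, n_train, n_test, conc_range, T_range, S_range, noise,
        grid, cdom_shape,
    )
    log.info("TSC fitted: LNS surface R^2=%.6f", tsc_model.lns.r2)
    train_c = apply_tsc(tsc_model, train)
    test_c = apply_tsc(tsc_model, test)

    results: dict[str, dict] = {}
    has_ref = np.isfinite(test.reference_conc).all()
    for method in methods:
        pred = _fit_predict(
            method, lib, train, test, train_c, test_c,
            kernel, n_components, eta, D, seed,
        )
        entry: dict = {"pred": pred}
        if has_ref:
            entry["report"] = residual_report(
                test.reference_conc, pred,
                T=test.temperature, S=test.salinity, tolerances=tolerances,
            )
            log.info("%s: RMSEP=%.4f umol/L", method, entry["report"].rmsep)
        results[method] = entry
    return {
        "methods": results,
        "lns_r2": tsc_model.lns.r2,
        "lns_sse": tsc_model.lns.sse,
        "config": config,
        "config_hash": config_hash(config),
    }


def _fit_predict(method, lib, train, test, train_c, test_c,
                 kernel, n_components, eta, D, seed):
    y = train.reference_conc
    if method == "wa-kpls":
        model = fit_wa_kpls(
            train_c.absorbance, y, kernel,
            n_components=n_components, eta=eta, D=D, seed=seed,
        )
        return predict_wa_kpls(model, test_c.absorbance)
    if method == "mlr":
        model = fit_mlr(train_c.absorbance, y, wavelengths=train_c.wavelengths)
        return predict_mlr(model, test_c.absorbance)
    if method == "isus":
        eps = lib.nitrate_absorptivity_per_umol(train.wavelengths)
        model = fit_isus(train, eps)
        return predict_isus(model, test)
    raise ValueError(f"unknown method {method!r}")


def run_extrapolation_study(
    seed: int = 0,
    train_bands=((4.0, 80.0), (6.0, 80.0), (8.0, 80.0), (10.0, 80.0)),
    high_band=(90.0, 100.0),
    n_train: int = 300,
    n_test: int = 100,
    T_range=(4.0, 25.0),
    S_range=(30.0, 35.0),
    noise: bool = True,
    kernel: KernelSpec = KernelSpec(),
    n_components: int = 12,
    eta: float = 80.0,
    D: int = 20,
    tolerance: float = 2.0,
    grid=None,
    cdom_shape: str = "exponential",
) -> dict:
    """Out-of-range prediction study.

    For each training band (lo, 80) the model is trained in-band and asked
    to predict samples just below the band (0 to lo - 1 umol/L) and far
    above it (90-100 umol/L); the fraction of predictions within the
    tolerance is recorded per band.
    """
    config = dict(
        seed=seed, train_bands=[list(b) for b in train_bands],
        high_band=list(high_band), n_train=n_train, n_test=n_test,
        T_range=list(T_range), S_range=list(S_range), noise=noise,
        kernel=kernel.to_dict(), n_components=n_components, eta=eta, D=D,
        tolerance=tolerance, cdom_shape=cdom_shape,
    )
    if grid is None:
        grid = DEFAULT_GRID
    bands_out = []
    for k, (lo, hi) in enumerate(train_bands):
        if not lo < hi:
            raise ValueError(f"invalid training band ({lo}, {hi})")
        low_test = (0.0, lo - 1.0)
        if low_test[1] < low_test[0]:
            raise ValueError(f"empty low test band below training band {lo}")
        if high_band[0] <= hi:
            raise ValueError(
                f"high test band {high_band} overlaps training band ({lo}, {hi})"
            )
        lib, tsc_model, train, _ = _prepare(
            seed + k, n_train, 1, (lo, hi), T_range, S_range, noise,
            grid, cdom_shape, train_range=(lo, hi),
        )
        train_c = apply_tsc(tsc_model, train)
        model = fit_wa_kpls(
            train_c.absorbance, train.reference_conc, kernel,
            n_components=n_components, eta=eta, D=D, seed=seed + k,
        )
        band_entry = {"train_band": (lo, hi)}
        for bi, (name, band) in enumerate((("low", low_test), ("high", high_band))):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed + k, 1000 + bi])
            )
            test = synth.generate_samples(
                lib, n_test, conc_range=band, T_range=T_range,
                S_range=S_range, noise=noise, seed=rng, grid=grid,
                id_prefix=f"band{k}_{name}",
            )
            test_c = apply_tsc(tsc_model, test)
            pred = predict_wa_kpls(model, test_c.absorbance)
            report = residual_report(
                test.reference_conc, pred, T=test.temperature,
                S=test.salinity, tolerances=(tolerance,),
            )
            band_entry[name] = {
                "band": band,
                "frac_within": report.frac_within[tolerance],
                "rmsep": report.rmsep,
            }
        log.info(
            "train %s: frac within +/-%g = %.3f (low), %.3f (high)",
            (lo, hi), tolerance,
            band_entry["low"]["frac_within"], band_entry["high"]["frac_within"],
        )
        bands_out.append(band_entry)
    return {"bands": bands_out, "config": config, "config_hash": config_hash(config)}
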