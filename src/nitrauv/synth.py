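"""Synthetic seawater absorbance generator.

Emulates the deep-UV absorbance of artificial seawater as a multicomponent
Beer-Lambert mixture: A(lambda) = b * sum_j eps_j(lambda) * C_j, with a
temperature-sensitive bromide term (charge-transfer-to-solvent absorbance
increases with temperature), a salinity scaling of the sea-salt species, a
CDOM (humate) broadband tail, and Gaussian spectrometer noise derived from an
intensity signal-to-noise ratio.

The component recipe follows a standard artificial-seawater preparation:
NaCl 0.55 mol/L, MgSO4 28 mmol/L, NaHCO3 2.3 mmol/L, NaBr 0.8 mmol/L,
sodium humate 5 umol/L, NaH2PO4 2.26 umol/L, NaNO2 0.22 umol/L, plus nitrate
at the requested concentration.  The extinction shape functions are fixed,
versioned constants of this library: they reproduce the qualitative deep-UV
behaviour of each species (chloride dominating below 208 nm, bromide decaying
over 200-240 nm, a nitrate band vanishing above 240 nm, CDOM broadband) but
are not claims about real seawater optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .spectra import SampleTable, Spectrum

__all__ = [
    "SyntheticComponent",
    "ComponentLibrary",
    "default_library",
    "default_grid",
    "forward_absorbance",
    "generate_samples",
    "generate_lns_calibration",
]

T_REF_C = 20.0  # reference temperature of the linearized bromide law
S_STANDARD_PSU = 35.0


@dataclass(frozen=True)
class SyntheticComponent:
    """One dissolved species of the forward model.

    ``extinction`` maps a wavelength grid (nm) to molar absorptivity in
    AU.L.mol^-1.mm^-1.  ``temp_coeff`` is the fractional absorbance change per
    degree C about 20 C (zero for temperature-independent species).
    ``sea_salt`` species scale with salinity as S/35.
    """

    name: str
    extinction: Callable[[np.ndarray], np.ndarray]
    concentration: float  # mol/L
    temp_coeff: float = 0.0
    sea_salt: bool = False

    def absorptivity(self, grid: np.ndarray) -> np.ndarray:
        eps = np.asarray(self.extinction(np.asarray(grid, dtype=float)), dtype=float)
        if np.any(eps < 0):
            raise ValueError(f"negative extinction for component {self.name!r}")
        return eps


@dataclass(frozen=True)
class ComponentLibrary:
    """Component set plus instrument constants of the forward model."""

    components: tuple[SyntheticComponent, ...]
    path_length_mm: float = 10.0
    snr: float = 1000.0  # intensity signal-to-noise, single acquisition
    dark_noise_counts: float = 2.5
    reference_counts: float = 60000.0  # typical reference-beam level
    cdom_shape: str = "exponential"  # {"exponential", "linear"}
    cdom_slope: float = 0.015  # nm^-1, exponential spectral slope

    def __post_init__(self):
        if self.path_length_mm <= 0:
            raise ValueError("path length must be positive")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")

    def component(self, name: str) -> SyntheticComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"unknown component {name!r}")

    def noise_sigma_absorbance(self) -> float:
        """Absorbance-equivalent noise sigma (AU).

        First-order propagation of intensity noise through
        A = -log10(I/I0) at A = 0: both beams carry shot/read noise of
        relative size 1/SNR plus dark noise relative to the reference level,
        combining in quadrature (hence the sqrt(2)).
        """
        rel = 1.0 / self.snr + self.dark_noise_counts / self.reference_counts
        return np.sqrt(2.0) * rel / np.log(10.0)

    def nitrate_absorptivity_per_umol(self, grid) -> np.ndarray:
        """Nitrate absorbance per umol/L on this instrument (AU per umol/L)."""
        eps = self.component("sodium nitrate").absorptivity(np.asarray(grid, float))
        return self.path_length_mm * eps * 1e-6


def default_grid(lo: float = 200.0, hi: float = 385.0, step: float = 0.4) -> np.ndarray:
    """The spectrometer pixel grid: 200-385 nm at 0.4 nm resolution."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _gaussian_band(center: float, width: float, amplitude: float, zero_above=None):
    def eps(wl):
        out = amplitude * np.exp(-(((wl - center) / width) ** 2))
        if zero_above is not None:
            out = np.where(wl >= zero_above, 0.0, out)
        return out

    return eps


def _exp_decay(amplitude: float, onset: float, scale: float):
    def eps(wl):
        return amplitude * np.exp(-(wl - onset) / scale)

    return eps


def _cdom_extinction(shape: str, slope: float, amplitude: float = 400.0):
    if shape == "exponential":
        def eps(wl):
            return amplitude * np.exp(-slope * (wl - 240.0))
    elif shape == "linear":
        # affine down-ramp hitting zero at 300 nm; exactly affine over the
        # 208-260 nm working range, so a straight-line CDOM fit removes it
        def eps(wl):
            return amplitude * np.clip(300.0 - wl, 0.0, None) / 60.0
    else:
        raise ValueError(f"unknown CDOM shape {shape!r}")
    return eps


def default_library(cdom_shape: str = "exponential",
                    cdom_slope: float = 0.015) -> ComponentLibrary:
    """Artificial-seawater component library at the standard recipe.

    Concentrations are the recipe values; the 10 mm optical path and the
    1000:1 SNR / 2.5-count dark noise match the reference spectrometer
    configuration.  Only bromide carries a temperature coefficient
    (+0.6 %/C about 20 C); nitrate and the other species are
    temperature-independent.
    """
    comps = (
        SyntheticComponent(
            "sodium chloride", _exp_decay(0.909, 200.0, 3.5), 0.55, sea_salt=True
        ),
        SyntheticComponent(
            "magnesium sulfate", _exp_decay(0.005, 200.0, 8.0), 28e-3, sea_salt=True
        ),
        SyntheticComponent(
            "sodium bicarbonate", _exp_decay(0.02, 200.0, 10.0), 2.3e-3, sea_salt=True
        ),
        SyntheticComponent(
            "sodium bromide",
            _exp_decay(204.0, 200.0, 6.5),
            0.8e-3,
            temp_coeff=0.006,
            sea_salt=True,
        ),
        SyntheticComponent(
            "sodium nitrate",
            _gaussian_band(202.0, 10.0, 995.0, zero_above=240.0),
            0.0,
        ),
        SyntheticComponent(
            "sodium humate", _cdom_extinction(cdom_shape, cdom_slope), 5e-6
        ),
        SyntheticComponent(
            "sodium dihydrogen phosphate", _exp_decay(50.0, 200.0, 5.0), 2.26e-6
        ),
        SyntheticComponent(
            "sodium nitrite", _gaussian_band(210.0, 12.0, 1200.0), 0.22e-6
        ),
    )
    return ComponentLibrary(
        components=comps, cdom_shape=cdom_shape, cdom_slope=cdom_slope
    )


def forward_absorbance(
    lib: ComponentLibrary,
    conc_overrides: dict | None = None,
    T: float = T_REF_C,
    S: float = S_STANDARD_PSU,
    grid=None,
) -> Spectrum:
    """Exact (noiseless) mixture absorbance at temperature T and salinity S.

    ``conc_overrides`` maps component names to concentrations in mol/L; any
    component not named keeps its library value.  Sea-salt species scale with
    S/35; temperature enters as eps * (1 + temp_coeff * (T - 20)).
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if not (np.isfinite(T) and np.isfinite(S)):
        raise ValueError("temperature and salinity must be finite")
    overrides = dict(conc_overrides or {})
    known = {c.name for c in lib.components}
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(f"unknown component(s) in overrides: {sorted(unknown)}")

    total = np.zeros(grid.size)
    for comp in lib.components:
        conc = overrides.get(comp.name, comp.concentration)
        if conc == 0.0:
            continue
        scale = (1.0 + comp.temp_coeff * (T - T_REF_C))
        if comp.sea_salt:
            scale *= S / S_STANDARD_PSU
        total += comp.absorptivity(grid) * scale * conc
    return Spectrum(grid, lib.path_length_mm * total, kind="absorbance")


def generate_samples(
    lib: ComponentLibrary,
    n: int,
    conc_range=(0.0, 100.0),
    T_range=(4.0, 25.0),
    S_range=(30.0, 35.0),
    noise: bool = True,
    seed: int | None = None,
    grid=None,
    id_prefix: str = "syn",
) -> SampleTable:
    """Draw n labeled samples with uniform nitrate (umol/L), T (C), S (psu).

    With ``noise`` on, zero-mean Gaussian noise with the library's
    absorbance-equivalent sigma is added independently per pixel; the drawn
    nitrate concentration is recorded as the reference concentration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, rng_ in (("conc", conc_range), ("T", T_range), ("S", S_range)):
        if rng_[1] < rng_[0]:
            raise ValueError(f"invalid {name} range {rng_}")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    conc = rng.uniform(conc_range[0], conc_range[1], size=n)  # umol/L
    T = rng.uniform(T_range[0], T_range[1], size=n)
    S = rng.uniform(S_range[0], S_range[1], size=n)

    A = np.empty((n, grid.size))
    for i in range(n):
        A[i] = forward_absorbance(
            lib, {"sodium nitrate": conc[i] * 1e-6}, T=T[i], S=S[i], grid=grid
        ).values
    if noise:
        A += rng.normal(0.0, lib.noise_sigma_absorbance(), size=A.shape)
    return SampleTable(
        sample_ids=[f"{id_prefix}_{i:04d}" for i in range(n)],
        wavelengths=grid,
        absorbance=A,
        temperature=T,
        salinity=S,
        reference_conc=conc,
    )


def generate_lns_calibration(
    lib: ComponentLibrary,
    T_list,
    seed: int | None = None,
    salinity: float = S_STANDARD_PSU,
    noise: bool = False,
    grid=None,
) -> SampleTable:
    """Zero-nutrient calibration set: one sample per temperature.

    Emulates low nutrient seawater (LNS): the sea-salt matrix only, with
    nitrate, nitrite, phosphate and CDOM at zero.  Used to fit the
    temperature/salinity correction surface.  The grid design mirrors a
    thermostatted sweep (e.g. 4-25 C at 1 C intervals).
    """
    T_list = np.asarray(T_list, dtype=float)
    if T_list.size == 0:
        raise ValueError("T_list must be nonempty")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    zero = {
        "sodium nitrate": 0.0,
        "sodium humate": 0.0,
        "sodium dihydrogen phosphate": 0.0,
        "sodium nitrite": 0.0,
    }
    A = np.empty((T_list.size, grid.size))
    for i, T in enumerate(T_list):
        A[i] = forward_absorbance(lib, zero, T=T, S=salinity, grid=grid).values
    if noise:
        rng = np.random.default_rng(seed)
        A += rng.normal(0.0, lib.noise_sigma_absorbance(), size=A.shape)
    return SampleTable(
        sample_ids=[f"lns_{i:03d}" for i in range(T_list.size)],
        wavelengths=grid,
        absorbance=A,
        temperature=T_list,
        salinity=np.full(T_list.size, salinity),
        reference_conc=np.zeros(T_list.size),
    )
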