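"""Core spectral containers and wavelength-domain operations.

The two containers used throughout the package are :class:`Spectrum` (a single
wavelength-indexed trace, either raw detector intensity in counts or absorbance
in AU) and :class:`SampleTable` (a samples x wavelengths absorbance matrix with
per-sample temperature, salinity and optional reference nitrate concentration).

Units are fixed package-wide: wavelengths in nm, temperature in degrees C,
salinity in psu, nitrate concentration in umol/L.  No implicit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spectrum",
    "SampleTable",
    "compute_absorbance",
    "select_window",
    "align_nearest",
]


class SpectrumError(ValueError):
    """Invalid spectral data or an operation outside its numerical domain."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SpectrumError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single spectral trace on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelength grid in nm, strictly increasing.
    values : array-like
        Per-wavelength values: detector counts (``kind="intensity"``) or
        absorbance in AU (``kind="absorbance"``).
    kind : {"intensity", "absorbance"}
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"

    def __post_init__(self):
        wl = _as_float_vector(self.wavelengths, "wavelengths")
        vals = _as_float_vector(self.values, "values")
        if wl.size != vals.size:
            raise SpectrumError(
                f"wavelengths ({wl.size}) and values ({vals.size}) differ in length"
            )
        if wl.size and np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectrumError("wavelengths and values must be finite")
        if self.kind not in ("intensity", "absorbance"):
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SampleTable:
    """Absorbance matrix (samples x wavelengths) with per-sample metadata.

    ``reference_conc`` holds the reference nitrate concentration in umol/L;
    NaN marks an unlabeled sample.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    absorbance: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    reference_conc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.wavelengths = _as_float_vector(self.wavelengths, "wavelengths")
        if self.wavelengths.size > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        n, m = self.absorbance.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise SpectrumError(
                f"{len(self.sample_ids)} sample ids for {n} absorbance rows"
            )
        if m != self.wavelengths.size:
            raise SpectrumError(
                f"{m} absorbance columns for {self.wavelengths.size} wavelengths"
            )
        self.temperature = _as_float_vector(self.temperature, "temperature")
        self.salinity = _as_float_vector(self.salinity, "salinity")
        if self.reference_conc is None:
            self.reference_conc = np.full(n, np.nan)
        self.reference_conc = _as_float_vector(self.reference_conc, "reference_conc")
        for name, vec in (
            ("temperature", self.temperature),
            ("salinity", self.salinity),
            ("reference_conc", self.reference_conc),
        ):
            if vec.size != n:
                raise SpectrumError(f"{name} length {vec.size} != {n} samples")
        if not np.all(np.isfinite(self.temperature)):
            raise SpectrumError("temperature must be finite")
        if not np.all(np.isfinite(self.salinity)):
            raise SpectrumError("salinity must be finite")
        labeled = np.isfinite(self.reference_conc)
        if np.any(self.reference_conc[labeled] < 0):
            raise SpectrumError("reference_conc must be >= 0 where present")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as an absorbance :class:`Spectrum`."""
        return Spectrum(self.wavelengths, self.absorbance[i], kind="absorbance")

    def with_absorbance(self, absorbance, wavelengths=None) -> "SampleTable":
        """Copy of the table with a replaced absorbance matrix (and grid)."""
        wl = self.wavelengths if wavelengths is None else wavelengths
        return SampleTable(
            sample_ids=list(self.sample_ids),
            wavelengths=np.array(wl, dtype=float),
            absorbance=np.array(absorbance, dtype=float),
            temperature=self.temperature.copy(),
            salinity=self.salinity.copy(),
            reference_conc=self.reference_conc.copy(),
        )


def compute_absorbance(
    sample_intensity: Spectrum,
    reference_intensity: Spectrum,
    dark,
) -> Spectrum:
    """Absorbance from sample/reference intensities and detector dark current.

    A(lambda) = -log10((I - I_D) / (I_0 - I_D)) where I is the sample beam,
    I_0 the deionised-water reference beam and I_D the dark current (a scalar
    or a per-wavelength spectrum, in counts).

    Raises
    ------
    SpectrumError
        If the grids differ or any dark-corrected intensity is non-positive
        (the offending wavelength is named).
    """
    if sample_intensity.kind != "intensity" or reference_intensity.kind != "intensity":
        raise SpectrumError("compute_absorbance expects intensity spectra")
    wl = sample_intensity.wavelengths
    if wl.size != reference_intensity.wavelengths.size or not np.array_equal(
        wl, reference_intensity.wavelengths
    ):
        raise SpectrumError("sample and reference must share one wavelength grid")
    if isinstance(dark, Spectrum):
        if not np.array_equal(dark.wavelengths, wl):
            raise SpectrumError("dark spectrum must share the wavelength grid")
        dark_vals = dark.values
    else:
        dark_vals = np.full(wl.size, float(dark))

    numer = sample_intensity.values - dark_vals
    denom = reference_intensity.values - dark_vals
    for name, vec in (("sample", numer), ("reference", denom)):
        bad = np.nonzero(vec <= 0)[0]
        if bad.size:
            raise SpectrumError(
                f"non-positive dark-corrected {name} intensity at "
                f"{wl[bad[0]]:.3f} nm"
            )
    return Spectrum(wl, -np.log10(numer / denom), kind="absorbance")


def select_window(table: SampleTable, lo: float, hi: float) -> SampleTable:
    """Restrict a table to the closed wavelength interval [lo, hi] nm.

    The deep-UV modeling window used for nitrate retrieval is 208-240 nm,
    where bromide and nitrate absorb but chloride interference has decayed.
    """
    if not lo < hi:
        raise SpectrumError(f"empty window: lo={lo} must be < hi={hi}")
    mask = (table.wavelengths >= lo) & (table.wavelengths <= hi)
    if not mask.any():
        raise SpectrumError(f"no wavelengths inside [{lo}, {hi}] nm")
    return table.with_absorbance(
        table.absorbance[:, mask], wavelengths=table.wavelengths[mask]
    )


def align_nearest(table: SampleTable, target_grid) -> SampleTable:
    """Map each target wavelength to the nearest source column (no interpolation).

    Used when comparing against instruments with a different pixel grid: for
    every requested wavelength the single nearest measured wavelength is
    selected; exact distance ties resolve to the lower wavelength.
    """
    target = _as_float_vector(target_grid, "target_grid")
    src = table.wavelengths
    if target.size == 0:
        raise SpectrumError("target grid is empty")
    if target.min() < src[0] or target.max() > src[-1]:
        raise SpectrumError(
            f"target grid [{target.min()}, {target.max()}] outside source span "
            f"[{src[0]}, {src[-1]}]"
        )
    # upper insertion point, then compare with left neighbour; ties -> lower
    idx = np.searchsorted(src, target, side="left")
    idx = np.clip(idx, 0, src.size - 1)
    has_left = idx > 0
    left = np.where(has_left, idx - 1, idx)
    d_left = np.abs(target - src[left])
    d_right = np.abs(src[idx] - target)
    choose_left = has_left & (d_left <= d_right)
    cols = np.where(choose_left, left, idx)
    new_wl = src[cols]
    if np.any(np.diff(new_wl) <= 0):
        raise SpectrumError("aligned grid is not strictly increasing "
                            "(duplicate nearest columns)")
    return table.with_absorbance(table.absorbance[:, cols], wavelengths=new_wl)
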