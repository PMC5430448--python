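"""Dye spectra, laser excitation efficiency and multiband-filter crosstalk.

Multicolour localization microscopy with a single multiband filter cube
suffers spectral crosstalk on both sides of the light path: a laser line can
excite an off-target dye through the blue tail of its absorption spectrum,
and emission spectra leak into transmission windows intended for another
channel.  This module quantifies both effects from normalized absorption /
emission spectra and a set of filter passbands, so that crosstalk emerges in
the simulation without any special-casing: off-target dyes simply receive
small but nonzero photon budgets.

Bundled spectra are synthetic parametric stand-ins (sums of Gaussian bands)
calibrated to the published band positions and relative shoulder heights of
the real dyes; see ``SPECTRUM_PARAMS``.  The bundled filter set models a
quad-band emission filter for 405/488/561/635 nm laser excitation with
nominal rectangular passbands and a small out-of-band floor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "Spectrum",
    "FilterSet",
    "excitation_efficiency",
    "detection_efficiency",
    "channel_photon_split",
    "apply_extra_emission_filter",
    "load_dye_spectrum",
    "default_filter_set",
    "synthesize_spectrum",
    "write_bundled_spectra",
    "SPECTRUM_PARAMS",
]


@dataclass
class Spectrum:
    """A normalized absorption or emission spectrum on a wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray  # normalized so max = 1
    kind: str = "emission"  # absorption | emission

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be matching 1D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("spectrum values must be >= 0")
        vmax = self.values.max()
        if vmax <= 0:
            raise ValueError("spectrum must have positive values")
        self.values = self.values / vmax
        if self.kind not in ("absorption", "emission"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def __call__(self, wavelength):
        lam = np.asarray(wavelength, dtype=float)
        if np.any(lam < self.wavelengths[0]) or np.any(lam > self.wavelengths[-1]):
            raise ValueError("wavelength outside the spectrum grid")
        out = np.interp(lam, self.wavelengths, self.values)
        return float(out) if np.isscalar(wavelength) else out

    @classmethod
    def from_csv(cls, path_or_buffer, kind: str) -> "Spectrum":
        lam, val = [], []
        close = False
        if hasattr(path_or_buffer, "read"):
            fh = path_or_buffer
        else:
            fh = open(path_or_buffer, newline="")
            close = True
        try:
            reader = csv.reader(row for row in fh if not row.startswith("#"))
            header = next(reader)
            if header[0].strip() != "wavelength_nm":
                raise ValueError("expected header 'wavelength_nm,value'")
            for row in reader:
                if not row:
                    continue
                lam.append(float(row[0]))
                val.append(float(row[1]))
        finally:
            if close:
                fh.close()
        return cls(np.array(lam), np.array(val), kind=kind)


@dataclass(frozen=True)
class FilterSet:
    """Multiband emission filter: rectangular passbands plus a leak floor."""

    name: str = "quadband"
    transmission_bands: tuple = (
        (422.0, 464.0, 0.93),
        (500.0, 545.0, 0.93),
        (576.0, 619.0, 0.93),
        (657.0, 800.0, 0.93),
    )
    out_of_band: float = 1e-4

    def __post_init__(self):
        prev_hi = -np.inf
        for lo, hi, peak in self.transmission_bands:
            if not (lo < hi and 0 < peak <= 1):
                raise ValueError("invalid transmission band")
            if lo < prev_hi:
                raise ValueError("bands must be sorted and non-overlapping")
            prev_hi = hi
        if not 0 <= self.out_of_band <= 1:
            raise ValueError("out_of_band must be in [0, 1]")

    def transmission(self, wavelength) -> np.ndarray:
        lam = np.asarray(wavelength, dtype=float)
        t = np.full(lam.shape, self.out_of_band)
        for lo, hi, peak in self.transmission_bands:
            t = np.where((lam >= lo) & (lam <= hi), peak, t)
        return t


def excitation_efficiency(dye_absorption: Spectrum, laser_wavelength: float) -> float:
    """Excitation efficiency of a laser line, as a fraction of the maximum.

    Linear interpolation of the normalized absorption spectrum at the laser
    wavelength; raises if the wavelength falls outside the tabulated grid.
    """
    return float(dye_absorption(laser_wavelength))


def detection_efficiency(dye_emission: Spectrum, filters: FilterSet) -> float:
    """Fraction of emitted photons transmitted by the filter set.

    Trapezoid integration of em(lambda) * T(lambda) over the union of the
    spectrum grid and the band edges, divided by the emission integral.
    """
    eps = 1e-9
    edges = []
    for lo, hi, _ in filters.transmission_bands:
        edges += [lo - eps, lo, hi, hi + eps]
    lam = np.union1d(dye_emission.wavelengths, np.asarray(edges))
    lam = lam[(lam >= dye_emission.wavelengths[0]) & (lam <= dye_emission.wavelengths[-1])]
    em = dye_emission(lam)
    total = np.trapezoid(em, lam)
    if total <= 0:
        return filters.out_of_band
    passed = np.trapezoid(em * filters.transmission(lam), lam)
    return float(passed / total)


def channel_photon_split(
    photons: float,
    dye,
    excitation,
    filters: FilterSet,
    absorption: Spectrum | None = None,
    emission: Spectrum | None = None,
) -> float:
    """Detected photons of an event: emitted x excitation x detection.

    ``dye`` is a photophysics ``DyeModel``; its absorption / emission spectra
    are resolved from the bundled fixtures by id unless passed explicitly.
    Off-target dyes are handled identically, so crosstalk photon budgets
    (small excitation efficiency, partial filter transmission) arise
    naturally.
    """
    if photons < 0:
        raise ValueError("photons must be >= 0")
    if absorption is None:
        absorption = load_dye_spectrum(dye.absorption_spectrum_id)
    if emission is None:
        emission = load_dye_spectrum(dye.emission_spectrum_id)
    exc = excitation_efficiency(absorption, excitation.laser_wavelength)
    det = detection_efficiency(emission, filters)
    return photons * exc * det


def apply_extra_emission_filter(detected_photons: float, crosstalk_value: float,
                                on_target: bool = False) -> float:
    """Attenuate off-target photons by an extra filter's crosstalk value.

    The extra emission filter is described only by the fraction of
    off-target light it leaks (``crosstalk_value`` in [0, 1]); on-target
    photons pass unchanged.
    """
    if not 0.0 <= crosstalk_value <= 1.0:
        raise ValueError("crosstalk_value must be in [0, 1]")
    if on_target:
        return detected_photons
    return detected_photons * crosstalk_value


# ---------------------------------------------------------------------------
# Bundled synthetic spectra
# ---------------------------------------------------------------------------

#: Gaussian-band parameters (center nm, width nm, amplitude) of the synthetic
#: stand-in spectra.  Band positions and shoulder ratios follow the published
#: shapes of the dyes; the Alexa 647 absorption tail is calibrated so that
#: its value at 561 nm is ~7.5% of the maximum, the documented crosstalk
#: figure for that dye under 561 nm excitation.
SPECTRUM_PARAMS: dict[str, tuple[str, tuple]] = {
    "alexa647_absorption": (
        "absorption",
        ((650.0, 15.0, 1.0), (604.0, 21.0, 0.34), (555.0, 42.0, 0.035)),
    ),
    "alexa647_emission": (
        "emission",
        ((668.0, 16.0, 1.0), (715.0, 35.0, 0.35)),
    ),
    "alexa568_absorption": (
        "absorption",
        ((578.0, 14.0, 1.0), (540.0, 22.0, 0.45), (500.0, 40.0, 0.05)),
    ),
    "alexa568_emission": (
        "emission",
        ((603.0, 17.0, 1.0), (650.0, 35.0, 0.35)),
    ),
}


def synthesize_spectrum(spectrum_id: str, grid=None) -> Spectrum:
    """Build a bundled synthetic spectrum from its Gaussian-band parameters."""
    kind, bands = SPECTRUM_PARAMS[spectrum_id]
    lam = np.arange(400.0, 801.0) if grid is None else np.asarray(grid, float)
    vals = np.zeros_like(lam)
    for center, width, amp in bands:
        vals += amp * np.exp(-((lam - center) ** 2) / (2 * width * width))
    return Spectrum(lam, vals, kind=kind)


def write_bundled_spectra(directory) -> list[str]:
    """Regenerate the fixture CSVs (1 nm grid, 400-800 nm) into ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sid in SPECTRUM_PARAMS:
        spec = synthesize_spectrum(sid)
        path = directory / f"{sid}_synthetic.csv"
        with open(path, "w", newline="") as fh:
            fh.write("# synthetic parametric stand-in spectrum; see stormsim.spectral\n")
            fh.write("wavelength_nm,value\n")
            for lam, val in zip(spec.wavelengths, spec.values):
                fh.write(f"{lam:.0f},{val:.6g}\n")
        written.append(str(path))
    return written


def load_dye_spectrum(spectrum_id: str) -> Spectrum:
    """Load a bundled dye spectrum fixture by id (e.g. 'alexa647_absorption')."""
    if spectrum_id is None:
        raise ValueError("dye has no spectrum id configured")
    kind = SPECTRUM_PARAMS[spectrum_id][0]
    ref = resources.files("stormsim") / "data" / f"{spectrum_id}_synthetic.csv"
    with ref.open("r", newline="") as fh:
        return Spectrum.from_csv(fh, kind=kind)


def default_filter_set() -> FilterSet:
    """The bundled quad-band (405/488/561/635 laser) emission filter model."""
    return FilterSet()
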