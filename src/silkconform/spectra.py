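"""1D spectrum container and plain-text I/O.

A processed magic-angle-spinning NMR spectrum is represented as a strictly
monotone chemical-shift axis (ppm) plus an intensity vector, together with
the spectrometer frequency of the observed nucleus (MHz).  The frequency is
what converts linewidths between Hz and ppm: ``fwhm_ppm = fwhm_hz / freq``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default carbon-channel Larmor frequency (MHz) of a 9.4 T instrument.
DEFAULT_CARBON_FREQ_MHZ = 100.4

#: Proton frequency (MHz) of the ultra-high-field instrument used for the
#: double-quantum experiments.  Kept as metadata; proton peak lists carry
#: ppm coordinates only.
PROTON_FREQ_MHZ = 920.0


@dataclass
class Spectrum1D:
    """A processed 1D spectrum on a ppm grid.

    Parameters
    ----------
    ppm : ndarray
        Strictly monotone chemical-shift axis in ppm.
    intensity : ndarray
        Intensities (arbitrary units), same length as `ppm`.
    spectrometer_freq : float
        Larmor frequency of the observed nucleus in MHz; must be positive.
    meta : dict
        Free-form provenance (generating components, seed, ...).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    spectrometer_freq: float = DEFAULT_CARBON_FREQ_MHZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise ValueError("ppm axis must be 1D with at least 2 points")
        if self.intensity.shape != self.ppm.shape:
            raise ValueError("ppm and intensity must have the same length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not self.spectrometer_freq > 0:
            raise ValueError("spectrometer_freq must be positive (MHz)")

    # -- unit conversions -------------------------------------------------
    def hz_to_ppm(self, hz: float) -> float:
        """Convert a width/offset from Hz to ppm on this spectrometer."""
        return hz / self.spectrometer_freq

    def ppm_to_hz(self, ppm: float) -> float:
        """Convert a width/offset from ppm to Hz on this spectrometer."""
        return ppm * self.spectrometer_freq

    def covers(self, lo: float, hi: float) -> bool:
        """True if the axis spans the closed interval [lo, hi] (ppm)."""
        return self.ppm.min() <= lo and self.ppm.max() >= hi

    def crop(self, lo: float, hi: float) -> "Spectrum1D":
        """Return the sub-spectrum with lo <= ppm <= hi (order preserved)."""
        mask = (self.ppm >= lo) & (self.ppm <= hi)
        if mask.sum() < 2:
            raise ValueError(f"crop window [{lo}, {hi}] ppm selects <2 points")
        return Spectrum1D(self.ppm[mask], self.intensity[mask],
                          self.spectrometer_freq, dict(self.meta))


def write_ascii(spectrum: Spectrum1D, path) -> None:
    """Write a spectrum as two-column ASCII (ppm, intensity).

    Header lines are prefixed with '#' and record the spectrometer
    frequency so the Hz<->ppm conversion survives the round trip.
    """
    header = [f"# spectrometer_freq_mhz = {spectrum.spectrometer_freq!r}"]
    for key, val in spectrum.meta.items():
        if isinstance(val, (str, int, float, bool)):
            header.append(f"# {key} = {val}")
    header.append("# ppm intensity")
    data = np.column_stack([spectrum.ppm, spectrum.intensity])
    np.savetxt(path, data, header="\n".join(h[2:] for h in header),
               comments="# ", fmt="%.8g")


def read_ascii(path) -> Spectrum1D:
    """Read a two-column ASCII spectrum written by :func:`write_ascii`."""
    freq = DEFAULT_CARBON_FREQ_MHZ
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                if key == "spectrometer_freq_mhz":
                    freq = float(val)
                else:
                    meta[key] = val
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    return Spectrum1D(data[:, 0], data[:, 1], freq, meta)
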