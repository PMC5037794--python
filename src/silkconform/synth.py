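"""Synthetic-data generators for every stage of the pipeline.

Generates (a) Gaussian-mixture Ala Cβ spectra with the conformation
component centers/widths of the CP/MAS analysis, (b) carbonyl-region
spectra with or without the narrow 177 ppm marker of the silk I* form,
(c) concentration series in which the silk I* fraction rises linearly with
glycerol content and saturates near 30% from 9 wt % on, (d) DQ-SQ proton
peak lists whose DQ coordinate is the sum of the two single-quantum
shifts, and (e) candidate glycerol-fibroin complexes with seeded rigid
placements.

All randomness is seeded; noise-free outputs are bit-reproducible and
noisy outputs are reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .dqmas import DQPeak, ShiftTable, SiteKey, predict_correlations
from .spectra import DEFAULT_CARBON_FREQ_MHZ, Spectrum1D
from .structure import (
    GENERATION_CLASH_FLOOR,
    ComplexModel,
    glycerol_template,
)

__all__ = [
    "ComponentSpec",
    "SpectrumParams",
    "SeriesModel",
    "GlycPlacementParams",
    "CBETA_LABELS",
    "CBETA_CENTERS",
    "CBETA_WIDTHS_HZ",
    "gaussian_profile",
    "synth_cbeta_spectrum",
    "synth_carbonyl_spectrum",
    "synth_series",
    "synth_dq_peaklist",
    "synth_complex_candidates",
    "cbeta_components",
]

#: Conformation labels of the four-component Ala Cβ model, in canonical
#: order: random coil, silk I* (type II β-turn), β-sheet A, β-sheet B.
CBETA_LABELS = ("random_coil", "silkI*", "beta_A", "beta_B")

#: Ala Cβ component centers (ppm).  Random coil and silk I* coincide; the
#: two are separated by linewidth, not position.
CBETA_CENTERS = {"random_coil": 16.5, "silkI*": 16.5,
                 "beta_A": 19.6, "beta_B": 21.7}

#: Component half-height widths (Hz).  The ~300 vs ~100 Hz contrast between
#: random coil and silk I* is what makes the shared-center model
#: identifiable; the β-sheet widths are intermediate crystalline-like
#: values (not published — fractions are insensitive to them).
CBETA_WIDTHS_HZ = {"random_coil": 300.0, "silkI*": 100.0,
                   "beta_A": 250.0, "beta_B": 250.0}

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian mixture component of a synthetic spectrum."""

    label: str
    center: float  # ppm
    fwhm: float  # Hz
    area_fraction: float

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError(f"component {self.label!r}: fwhm must be positive")
        if self.area_fraction < 0:
            raise ValueError(f"component {self.label!r}: negative area fraction")


def _check_fractions(components: list[ComponentSpec]) -> None:
    if components:
        total = sum(c.area_fraction for c in components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"component area fractions sum to {total!r}, expected 1")


@dataclass(frozen=True)
class SpectrumParams:
    """Grid, noise and provenance parameters of a synthetic spectrum."""

    ppm_min: float = 12.0
    ppm_max: float = 26.0
    n_points: int = 2048
    spectrometer_freq: float = DEFAULT_CARBON_FREQ_MHZ
    noise_sd: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not self.spectrometer_freq > 0:
            raise ValueError("spectrometer_freq must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def grid(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)


def gaussian_profile(center: float, fwhm: float, area: float,
                     grid: np.ndarray,
                     spectrometer_freq: float = DEFAULT_CARBON_FREQ_MHZ,
                     ) -> np.ndarray:
    """Area-normalized Gaussian line on a ppm grid.

    `fwhm` is given in Hz and converted to ppm by dividing by the
    spectrometer frequency (MHz).  The analytic integral over the real
    line equals `area`, so component areas read directly as weights.
    """
    if not fwhm > 0:
        raise ValueError("fwhm must be positive")
    if not spectrometer_freq > 0:
        raise ValueError("spectrometer_freq must be positive")
    grid = np.asarray(grid, dtype=float)
    d = np.diff(grid)
    if grid.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("grid must be strictly monotone")
    if area == 0:
        return np.zeros_like(grid)
    sigma = (fwhm / spectrometer_freq) * _FWHM_TO_SIGMA
    return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
        -0.5 * ((grid - center) / sigma) ** 2)


def cbeta_components(fractions, widths_hz: dict | None = None,
                     ) -> list[ComponentSpec]:
    """Four-component Ala Cβ mixture from a fraction vector.

    `fractions` is indexable by the canonical labels (dict) or a sequence
    in CBETA_LABELS order; it must lie on the simplex.
    """
    if not isinstance(fractions, dict):
        fractions = dict(zip(CBETA_LABELS, fractions, strict=True))
    widths = dict(CBETA_WIDTHS_HZ)
    if widths_hz:
        widths.update(widths_hz)
    comps = [ComponentSpec(lab, CBETA_CENTERS[lab], widths[lab],
                           float(fractions[lab])) for lab in CBETA_LABELS]
    _check_fractions(comps)
    return comps


def synth_cbeta_spectrum(components: list[ComponentSpec],
                         params: SpectrumParams = SpectrumParams(),
                         ) -> Spectrum1D:
    """Sum of Gaussian components + baseline + seeded Gaussian noise."""
    grid = params.grid()
    for c in components:
        if not (params.ppm_min <= c.center <= params.ppm_max):
            raise ValueError(
                f"component {c.label!r} center {c.center} ppm outside grid "
                f"[{params.ppm_min}, {params.ppm_max}]")
    intensity = np.full_like(grid, params.baseline, dtype=float)
    for c in components:
        intensity += gaussian_profile(c.center, c.fwhm, c.area_fraction,
                                      grid, params.spectrometer_freq)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        intensity = intensity + rng.normal(0.0, params.noise_sd, grid.size)
    meta = {
        "components": [
            {"label": c.label, "center": c.center, "fwhm_hz": c.fwhm,
             "area_fraction": c.area_fraction} for c in components],
        "noise_sd": params.noise_sd,
        "seed": params.seed,
        "baseline": params.baseline,
    }
    return Spectrum1D(grid, intensity, params.spectrometer_freq, meta)


#: Carbonyl-region reference components (ppm): broad random-coil and
#: β-sheet Ala C=O lines, and the narrow silk I* marker at 177.0 ppm.
CARBONYL_BROAD = (("random_coil", 175.5, 300.0), ("silkII", 172.6, 300.0))
CARBONYL_SILKI = ("silkI*", 177.0, 100.0)


def synth_carbonyl_spectrum(silkI_present: bool,
                            params: SpectrumParams | None = None,
                            silkI_area: float = 0.30) -> Spectrum1D:
    """Ala carbonyl-region spectrum, with or without the silk I* marker.

    The appearance of a sharp (~100 Hz) line at 177.0 ppm on top of the
    broad 175.5/172.6 ppm carbonyl envelope is the independent fingerprint
    of the silk I* form.
    """
    if params is None:
        params = SpectrumParams(ppm_min=165.0, ppm_max=182.0)
    if silkI_present and not (params.ppm_min <= 177.0 <= params.ppm_max):
        raise ValueError("grid does not cover 177 ppm; cannot add the "
                         "silk I* carbonyl component")
    comps = []
    broad_total = 1.0 - (silkI_area if silkI_present else 0.0)
    for label, center, width in CARBONYL_BROAD:
        comps.append(ComponentSpec(label, center, width, broad_total / 2))
    if silkI_present:
        label, center, width = CARBONYL_SILKI
        comps.append(ComponentSpec(label, center, width, silkI_area))
    return synth_cbeta_spectrum(comps, params)


# ---------------------------------------------------------------------------
# concentration series
# ---------------------------------------------------------------------------

#: Default anchor table: glycerol wt % -> fractions in CBETA_LABELS order.
#: 0 and 29 wt % carry the reported film compositions (the 29 wt % trio is
#: constrained to the simplex: random coil is the complement of the silk I*
#: and β values).  The silk I* column follows the stated saturation curve —
#: a linear rise from zero reaching the 0.30 plateau at the 9 wt %
#: breakpoint — so the 5 wt % anchor sits on that line (0.30 * 5/9 ≈ 0.167).
#: The β A/B split (not published) keeps A > B at 0.60/0.40 of the β total,
#: and the unpublished 9/67 wt % anchors interpolate the stated trends
#: (random coil slowly decreasing, β dipping then rising again).
DEFAULT_SERIES_ANCHORS: dict[float, tuple[float, float, float, float]] = {
    0.0: (0.616, 0.0, 0.230, 0.154),
    5.0: (0.583, 0.167, 0.150, 0.100),
    9.0: (0.540, 0.300, 0.096, 0.064),
    29.0: (0.526, 0.299, 0.105, 0.070),
    67.0: (0.490, 0.300, 0.126, 0.084),
}


@dataclass
class SeriesModel:
    """Silk I* saturation behaviour vs glycerol concentration.

    Fraction vectors at intermediate concentrations are linear
    interpolations between the anchors; no extrapolation outside the
    anchor hull.  The silk I* fraction is non-decreasing up to the
    breakpoint (9 wt %) and constant within 0.01 above it (plateau 0.30).
    """

    anchors: dict[float, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SERIES_ANCHORS))
    silkI_breakpoint: float = 9.0
    silkI_plateau: float = 0.30

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchors")
        si = CBETA_LABELS.index("silkI*")
        concs = sorted(self.anchors)
        last = -np.inf
        for c in concs:
            vec = np.asarray(self.anchors[c], dtype=float)
            if vec.shape != (4,):
                raise ValueError(f"anchor at {c} wt % is not length 4")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"anchor at {c} wt % does not sum to 1")
            if c <= self.silkI_breakpoint:
                if vec[si] < last - 1e-12:
                    raise ValueError("silk I* fraction must be non-decreasing "
                                     "below the breakpoint")
                last = vec[si]
            elif abs(vec[si] - self.silkI_plateau) > 0.01:
                raise ValueError("silk I* fraction departs from the plateau "
                                 "above the breakpoint")

    def fractions_at(self, wt_percent: float) -> dict[str, float]:
        concs = np.array(sorted(self.anchors))
        if not (concs[0] <= wt_percent <= concs[-1]):
            raise ValueError(
                f"concentration {wt_percent} wt % outside anchor hull "
                f"[{concs[0]}, {concs[-1]}]; no extrapolation")
        mat = np.array([self.anchors[c] for c in concs])
        vec = np.array([np.interp(wt_percent, concs, mat[:, j])
                        for j in range(4)])
        vec /= vec.sum()  # interpolation of simplex points stays on it
        return dict(zip(CBETA_LABELS, vec.tolist()))


def synth_series(model: SeriesModel, concentrations: list[float],
                 params: SpectrumParams = SpectrumParams(),
                 ) -> list[tuple[float, Spectrum1D]]:
    """One Ala Cβ spectrum per glycerol concentration.

    Each spectrum gets an independent noise stream derived from
    params.seed and its position in the series.
    """
    out = []
    for k, conc in enumerate(concentrations):
        fracs = model.fractions_at(conc)
        p = SpectrumParams(
            ppm_min=params.ppm_min, ppm_max=params.ppm_max,
            n_points=params.n_points,
            spectrometer_freq=params.spectrometer_freq,
            noise_sd=params.noise_sd, baseline=params.baseline,
            seed=params.seed + 1000 * k)
        spec = synth_cbeta_spectrum(cbeta_components(fracs), p)
        spec.meta["glyc_wt_percent"] = conc
        out.append((conc, spec))
    return out


# ---------------------------------------------------------------------------
# DQ-SQ peak lists
# ---------------------------------------------------------------------------

def synth_dq_peaklist(shift_table: ShiftTable,
                      pairs: list[tuple[SiteKey, SiteKey]],
                      noise_sd: float = 0.0,
                      seed: int = 0) -> list[DQPeak]:
    """Synthetic DQ-SQ peak list for a set of site pairs.

    A pair (A, B) with A != B yields two peaks, (δA, δA+δB) and
    (δB, δA+δB); a self-pair yields the single diagonal peak (δA, 2δA).
    With noise_sd > 0 each coordinate is jittered by seeded Gaussian noise;
    at noise_sd = 0 the DQ coordinate equals the sum of the SQ shifts
    exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    predicted = predict_correlations(shift_table, pairs)
    rng = np.random.default_rng(seed)
    peaks = []
    for pos in predicted:
        sq, dq = pos.sq, pos.dq
        if noise_sd > 0:
            sq += rng.normal(0.0, noise_sd)
            dq += rng.normal(0.0, noise_sd)
        peaks.append(DQPeak(sq=float(sq), dq=float(dq), intensity=1.0))
    return peaks


def peaklist_to_frame(peaks: list[DQPeak]) -> pd.DataFrame:
    """Peak list as a table with columns sq_ppm, dq_ppm, intensity."""
    return pd.DataFrame(
        [{"sq_ppm": p.sq, "dq_ppm": p.dq, "intensity": p.intensity}
         for p in peaks],
        columns=["sq_ppm", "dq_ppm", "intensity"])


def peaklist_from_frame(frame: pd.DataFrame) -> list[DQPeak]:
    return [DQPeak(sq=float(r.sq_ppm), dq=float(r.dq_ppm),
                   intensity=float(getattr(r, "intensity", 1.0)))
            for r in frame.itertuples()]


# ---------------------------------------------------------------------------
# candidate complex generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycPlacementParams:
    """Seeded rigid glycerol placement around a fibroin scaffold.

    Desk-scale defaults: 16 candidate models x 8 glycerols each (the full
    experiment used 500 glycerols around a 24-chain crystal; the placement
    logic is identical).  Each glycerol centroid lands within
    [shell_min, shell_max] Å of the nearest fibroin atom, with no atom
    pair closer than 2.0 Å at generation time.
    """

    n_candidates: int = 16
    n_glyc_per_model: int = 8
    shell_min: float = 3.0
    shell_max: float = 6.0
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self):
        if not 0 < self.shell_min < self.shell_max:
            raise ValueError("need 0 < shell_min < shell_max")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.n_glyc_per_model < 1:
            raise ValueError("n_glyc_per_model must be >= 1")


def _place_one_glycerol(rng: np.random.Generator, sf_xyz: np.ndarray,
                        placed: list[np.ndarray],
                        params: GlycPlacementParams) -> np.ndarray:
    template_xyz = glycerol_template()[["x", "y", "z"]].to_numpy()
    occupied = (np.vstack([sf_xyz] + placed) if placed else sf_xyz)
    for _ in range(params.max_retries):
        anchor = sf_xyz[rng.integers(len(sf_xyz))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(params.shell_min, params.shell_max)
        centroid = anchor + radius * direction
        d_near = np.linalg.norm(sf_xyz - centroid, axis=1).min()
        if not (params.shell_min <= d_near <= params.shell_max):
            continue
        rot = Rotation.random(rng=rng).as_matrix()
        xyz = template_xyz @ rot.T + centroid
        if cdist(xyz, occupied).min() < GENERATION_CLASH_FLOOR:
            continue
        return xyz
    raise RuntimeError(
        f"could not place a glycerol in shell [{params.shell_min}, "
        f"{params.shell_max}] Å without a clash after "
        f"{params.max_retries} retries")


def synth_complex_candidates(scaffold: ComplexModel,
                             params: GlycPlacementParams = GlycPlacementParams(),
                             ) -> list[ComplexModel]:
    """Seeded candidate glycerol-fibroin complexes around a scaffold.

    Returns n_candidates models, each the scaffold plus n_glyc_per_model
    rigid glycerols at random positions/orientations in the shell.  Fixed
    seed -> bit-identical coordinates across calls.
    """
    sf_xyz = scaffold.sf_coords()
    if len(sf_xyz) == 0:
        raise ValueError("scaffold has no fibroin atoms")
    rng = np.random.default_rng(params.seed)
    models = []
    for k in range(params.n_candidates):
        placed: list[np.ndarray] = []
        for _ in range(params.n_glyc_per_model):
            placed.append(_place_one_glycerol(rng, sf_xyz, placed, params))
        model = scaffold.with_glycerols(placed)
        model.provenance.update({"candidate_index": k, "seed": params.seed,
                                 "shell": (params.shell_min, params.shell_max)})
        models.append(model)
    return models


def synth_filtering_candidates(scaffold: ComplexModel, restraints,
                               n_total: int = 16, n_satisfying: int = 4,
                               seed: int = 0,
                               refine_max_moves: int = 4000,
                               ) -> tuple[list[ComplexModel], list[bool]]:
    """Candidate set with a controlled number of restraint-satisfying models.

    The satisfying models start from glycerols in a near surface shell and
    are annealed against the restraints until accepted; the remainder are
    placed in a far shell (9-12 Å) from which every glycerol proton is
    geometrically beyond the 4 Å bounds.  Returns (models, ground-truth
    satisfaction labels) in a seeded random order.
    """
    from .structure import RefinementParams, evaluate_restraints, refine_complex

    if not 0 <= n_satisfying <= n_total:
        raise ValueError("need 0 <= n_satisfying <= n_total")
    rng = np.random.default_rng(seed)
    good: list[ComplexModel] = []
    attempt = 0
    while len(good) < n_satisfying:
        if attempt > 20 * max(n_satisfying, 1):
            raise RuntimeError("could not construct enough restraint-"
                               "satisfying candidates")
        cand = synth_complex_candidates(
            scaffold, GlycPlacementParams(
                n_candidates=1, n_glyc_per_model=8,
                seed=int(rng.integers(2 ** 31))))[0]
        refined = refine_complex(
            cand, restraints,
            RefinementParams(max_moves=refine_max_moves,
                             seed=int(rng.integers(2 ** 31))))
        if evaluate_restraints(refined, restraints).accepted:
            good.append(refined)
        attempt += 1
    bad = synth_complex_candidates(
        scaffold, GlycPlacementParams(
            n_candidates=n_total - n_satisfying, n_glyc_per_model=8,
            shell_min=9.0, shell_max=12.0,
            seed=int(rng.integers(2 ** 31)))) if n_total > n_satisfying else []
    models = good + list(bad)
    labels = [True] * len(good) + [False] * len(bad)
    order = rng.permutation(len(models))
    return [models[i] for i in order], [labels[i] for i in order]
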