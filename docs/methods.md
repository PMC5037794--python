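# Methods

This note records the models, numerical choices and limitations behind
`silkconform`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Four-conformation deconvolution of the Ala Cβ region

### Model

The alanine Cβ peak (fit window 12–26 ppm; serine/glycine resonances lie
outside it) is modelled as a sum of four Gaussians plus a constant
baseline:

    I(δ) = b + Σᵢ aᵢ · G(δ; cᵢ, wᵢ),   G area-normalized,

with components (random coil, silk I\*, β-sheet A, β-sheet B).  Widths are
carried internally in ppm and reported in Hz via `fwhm_hz = fwhm_ppm ×
spectrometer_freq` (default carbon frequency 100.4 MHz, so 100 Hz ≙
0.996 ppm).  Conformational fractions are areas normalized over the four
components only.

Box constraints encode the physics:

| component   | center (ppm) | width bounds (Hz) |
|-------------|--------------|-------------------|
| random coil | 16.5 ± 0.2   | [200, 450]        |
| silk I\*    | 16.5 ± 0.2   | [50, 180]         |
| β-sheet A   | 19.6 ± 0.2   | [150, 400]        |
| β-sheet B   | 21.7 ± 0.2   | [150, 400]        |

Random coil and silk I\* share a center and are separated **only** by
linewidth (~300 vs ~100 Hz); the deliberate gap between the silk I\* upper
width bound (180 Hz) and the random-coil lower bound (200 Hz) is what
keeps the two labels attached to the right components.  The ±0.2 ppm
center play absorbs referencing drift on real spectra.  One shift-table
discrepancy is worth recording: the package's ¹³C reference table lists
the random-coil Ala Cβ at 16.7 ppm, while the deconvolution model uses the
shared 16.5 ppm center that the width-based separation requires; the
0.2 ppm difference is inside the allowed center play.

### Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective, ftol = xtol = gtol = 1e-14), with 5 seeded restarts
jittering the initial amplitudes log-normally (σ = 0.7).  The best
residual wins; ties are broken toward the **lower** silk I\* area, which
steers the fit away from the local minimum that dumps broad intensity into
the narrow shared-center component.  Width initial guesses are the
geometric mean of each component's bounds; the baseline starts at the
median of the spectrum edges.

### Uncertainties and the identifiability diagnostic

Parameter standard errors come from the jacobian at the solution,
`cov = s² (JᵀJ)⁻¹` (pseudo-inverse, rcond 1e-12).  On noise-free synthetic
data the residual variance collapses to machine noise, so s² is floored at
(1e-3 × peak intensity)²; the reported uncertainties are then a
sensitivity measure rather than a statistical one.

The shared-center decomposition is flagged **non-identifiable** when

* a shared-center component carrying more than 1% of the total area has
  its fitted width pinned within 2 Hz of the silk I\*/random-coil gap
  boundary (silk I\* at 180 Hz or random coil at 200 Hz) — the operational
  signature that the data lack the narrow/broad contrast the model needs —
  or
* the areas of both shared-center components carry more than 50% relative
  uncertainty.

A spectrum generated with both components at 200 Hz reproducibly raises
the flag (the optimizer then explains all 16.5 ppm mass as a 200 Hz
random-coil line, pinned at its bound); ordinary film compositions,
including the degenerate-but-benign cases of zero silk I\* or zero random
coil, do not.

### Carbonyl confirmation

`detect_silkI_carbonyl` fits the 165–182 ppm region twice: a background of
two broad Gaussians (centers near 175.5 and 172.6 ppm, widths 150–600 Hz)
plus baseline, and the same background plus a narrow component constrained
to 177.0 ± 0.3 ppm with width ≤ 150 Hz.  The marker is declared present
iff the narrow component improves the residual RMS by at least 20%.  The
20% margin is deliberately coarse — the check is a presence/absence
confirmation, not a quantification.

## 2. Saturation analysis

The silk I\* fraction vs glycerol concentration is summarized by
f(c) = min(s·c, p) with breakpoint b = p/s.  For fixed b the optimal slope
is closed-form (`s = Σ mᵢfᵢ / Σ mᵢ²`, `mᵢ = min(cᵢ, b)`), so the fit is a
1-D grid search over b (800 points spanning the data) refined by bounded
scalar minimization (xatol 1e-10).  The breakpoint is declared
unidentifiable when the fractions do not vary, when fewer than two points
fall strictly on either side of the fitted bend, or when the bend lands at
the edge of the data — all of which mean the series does not span both
regimes.

## 3. Synthetic data: what the generators emulate

The generators state the world the analysis is tested in:

* **Ala Cβ spectra** — Gaussian mixtures on a 2048-point, 12–26 ppm grid at
  100.4 MHz with component parameters as in §1 and area weights on the
  simplex.  Noise, when requested, is additive i.i.d. Gaussian on the
  intensities (seeded); no lineshape distortion, phase error, sidebands or
  baseline roll.  β widths (250 Hz) are a chosen default between the
  published 100 and 300 Hz values — fractions are insensitive to them.
* **Concentration series** — fraction vectors linearly interpolated between
  anchors at 0, 5, 9, 29 and 67 wt % glycerol.  The 0 and 29 wt % anchors
  carry the reported film compositions, with two package-level choices:
  (a) reported percentages are constrained to the simplex, which fixes the
  29 wt % random-coil share at 52.6% (complement of 29.9% silk I\* and
  17.5% β); (b) the silk I\* column follows the stated saturation curve —
  a linear rise from zero hitting the 0.30 plateau at 9 wt % — so the
  5 wt % silk I\* anchor is 0.30 × 5/9 ≈ 0.167.  The β A/B split is not
  published; it is fixed once at 0.60/0.40 of the β total (A > B at every
  concentration).  The unpublished 9 and 67 wt % anchors
  (0.540/0.300/0.096/0.064 and 0.490/0.300/0.126/0.084) interpolate the
  stated trends: random coil slowly decreasing, β dipping on first
  glycerol addition and rising gradually past the breakpoint.
* **DQ-SQ peak lists** — each pair (A, B) yields peaks (δ_A, δ_A+δ_B) and
  (δ_B, δ_A+δ_B) (one diagonal peak for A = B); the DQ coordinate is the
  exact SQ sum at zero noise, and coordinate noise is seeded Gaussian.
  Peak intensities are uniform: no buildup dynamics, no distance-dependent
  intensity.
* **Candidate complexes** — rigid glycerol copies (template built once from
  internal coordinates) placed with seeded random position/orientation so
  the centroid lies 3–6 Å from the nearest fibroin atom, with no atom pair
  below 2.0 Å; 16 candidates × 8 glycerols around a 4-chain scaffold is
  the desk-scale default (the full-scale experiment used 500 glycerols
  around 24 chains; the logic is identical and a `copies` argument restores
  the larger scaffold).

A green test on this world therefore establishes that the estimators
recover what the generators put in, at the stated noise — not that the
generators reproduce every feature of a real CP/MAS or DQMAS measurement.

## 4. Chain building, packing and the glycerol refinement

* **Builder.**  Chains grow by internal-coordinate (NeRF) placement with a
  fixed geometry table (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231, N–H
  1.010, C–H 1.090 Å; standard backbone angles), supplied φ/ψ, ω = 180°
  everywhere and Ser χ₁ = −60°.  Serine, absent from the published torsion
  sets, takes the Ala values (it occupies an Ala-like position in the
  AGSGAG repeat).  All protons are explicit — methyls as three protons, no
  pseudo-atoms — and recomputing φ/ψ from the coordinates returns the
  inputs to ~1e-10 degrees (tested at 1e-4).
* **Packing.**  `pack_crystal` replicates a chain over lattice translations
  of the given cell, with optional per-copy rigid transforms for
  antiparallel/screw arrangements; full space-group expansion is out of
  scope.  Which cell axis is the chain axis is not published; the default
  scaffolds align the chain's principal axis with c.  The idealized
  uniform-torsion chain cannot interdigitate at the crystallographic
  4.65 Å in-sheet spacing without the screw symmetry (neighbouring chains
  overlap below 0.5 Å at any axial rotation), so the default silk I\*
  scaffold places in-sheet neighbours two cells (2a = 9.30 Å) apart —
  still a lattice translation — and inter-sheet neighbours one b apart.
  Surface chemistry, site distances within a chain and the restraint logic
  are unaffected.
* **Refinement.**  A deliberate substitute for the original force-field MD
  plus semi-empirical minimization: seeded Metropolis annealing over
  rigid-body glycerol moves (translation ≤ 0.5 Å, rotation ≤ 10° per move;
  geometric temperature schedule 1.0 → 0.01 over 6000 moves).  The energy
  is Σ flat-bottom restraint penalties ((d − 4 Å)² above the bound, zero
  below) plus a soft-sphere clash term ((2.2 − d)², weight 10) over
  glycerol-involving atom pairs; moves that push the closest contact below
  2.2 Å are additionally hard-rejected unless they improve it.  Half of
  the moves translate a glycerol along the direction that closes the
  worst-violated restraint, which is what makes the desk-scale schedule
  reliable (from a 6–10 Å start, 10/10 seeds reach acceptance in the test
  configuration).  The best model by (violation count, energy) is
  returned, so refinement never increases the number of violated
  restraints.  Because the selection criterion in the end is purely the
  six ≤ 4 Å distances, the substitute optimizes exactly the quantity used
  to accept or reject a model; it carries no energetic meaning beyond
  that.
* **Distances.**  `min_site_distance` is the package's measurement
  primitive: the minimum over all proton-instance pairs of two labelled
  groups, with methyl/methylene/hydroxyl protons enumerated individually.
  Self-distances of a group count only pairs on distinct residues.  The
  implementation is checked against an independent brute-force double loop
  in the tests.

## 5. Fixtures and conventions

Shift tables (¹H and ¹³C), the per-film correlation-signal inventory and
the six glycerol–fibroin restraints ship as checksum-verified CSVs.  Two
inventory notes: the source text counts six intermolecular glycerol
correlations while the printed inventory block lists seven (adding
Glyc OH–Gly Hα①) — the restraint list follows the six, the inventory keeps
all seven rows; and the blend film's random-coil block is described as
three signals in the text but prints four rows — the fixture follows the
printed table.  The glycerol proton shifts are CH₂/CH 3.4 ppm and OH
4.4 ppm; the OH resonance overlaps water, so an OH-derived restraint is
intrinsically less specific — the package treats it like any other, as the
original selection did.  Gly Hα① vs Hα② stereo-labels are treated as
opaque (mapped to HA2/HA3 by convention).  Assignment tolerance defaults
to 0.15 ppm, below every inter-site gap in the shift tables except the
genuine Ala Hα/Gly Hα② overlap at 4.1 ppm, which surfaces as an ambiguity
list on the affected assignments rather than an error.  Referencing
constants (adamantane CH₂ at 28.8 ppm for ¹³C, silicone rubber at
0.12 ppm for ¹H) are carried as metadata; all inputs are assumed
pre-referenced.

## 6. Known limitations

* No raw-FID processing, phasing, baseline rolls, CP dynamics, MAS
  sidebands or relaxation — inputs are processed spectra and peak lists.
* No intensity-to-distance quantification: a DQ-SQ cross-peak is
  presence/absence evidence at the ~4 Å level only.
* The two-term refinement score is not a force field; accepted models are
  restraint-consistent poses, not energy-ranked structures, and no
  solvent or β-sheet A/B energetics are computed.
* The crystal scaffold is translational only (no space-group symmetry
  operators), with the in-sheet spacing doubled as described in §4.
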