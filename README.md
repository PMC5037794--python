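# silkconform

Quantitative conformational analysis of glycerol-plasticized *Bombyx mori*
silk fibroin films from solid-state NMR, for structural-NMR practitioners
and silk-biomaterial researchers.

Silk fibroin (SF) film is stiff and brittle when dry; blending in glycerol
plasticizes it and, as solid-state NMR shows, drives part of the protein
into **silk I\*** — a repeated type II β-turn structure of the (AGSGAG)ₙ
crystalline repeat, distinct from both the disordered random coil and the
β-sheet-rich silk II form.  This package implements the quantitative chain
from spectra to a restraint-validated structural model:

1. **Constrained Gaussian deconvolution** (`AlaCbetaModel`).  The alanine
   Cβ region of a ¹³C CP/MAS spectrum is fit as a four-component Gaussian
   mixture: random coil and silk I\* share the same center (δ = 16.5 ppm)
   and are separated purely by linewidth (FWHM ≈ 300 Hz broad vs ≈ 100 Hz
   narrow), while β-sheet packing variants A and B sit at 19.6 and
   21.7 ppm.  Conformational fractions are the areas aᵢ normalized as
   fᵢ = aᵢ / Σⱼ aⱼ.  A narrow carbonyl line at 177.0 ppm provides an
   independent confirmation of silk I\* (`detect_silkI_carbonyl`), and the
   silk I\* fraction vs glycerol content follows a rise-then-plateau law
   f(c) = min(s·c, p) fitted by `SaturationModel` (plateau p ≈ 0.30 from a
   breakpoint of ≈ 9 wt % on).
2. **DQ-SQ proton correlation assignment** (`silkconform.dqmas`).  In a ¹H
   double-quantum/single-quantum (DQMAS) spectrum a proton pair (A, B)
   appears at (δ_A, δ_A+δ_B) and (δ_B, δ_A+δ_B); observable cross-peaks
   imply ¹H–¹H distances ≲ 4 Å.  Peaks are matched to conformation-specific
   shift tables, counted into per-conformation correlation inventories, and
   intermolecular glycerol–fibroin correlations become distance restraints
   (upper bound 4 Å).
3. **Restraint-filtered model building** (`silkconform.structure`).
   Capped Acetyl-(AGAGSG)₂-NHCH₃ chains are built from backbone torsions
   (silk I\*: Ala (φ,ψ) = (−62°, 125°), Gly (77°, 10°); β-sheet:
   (−140°, 140°)), packed into a crystal scaffold, and decorated with rigid
   glycerol molecules.  A seeded rigid-body simulated annealing
   (`refine_complex`) moves the glycerols against a flat-bottom restraint
   penalty plus a soft-sphere clash floor; `evaluate_restraints` accepts a
   model iff all six glycerol–fibroin proton distances are ≤ 4 Å.  This is
   a deliberate desk-scale substitute for force-field molecular dynamics:
   the selection criterion is purely the six distance bounds, which the
   annealing optimizes directly.

A first-class synthetic-data module (`silkconform.synth`) generates every
input — mixture spectra, concentration series, DQ-SQ peak lists, candidate
complexes — so the full pipeline runs and is tested without any external
data.

## Worked example

```python
import silkconform as sc

# synthesize the 29 wt % glycerol film's Ala C-beta region and fit it
spec = sc.synth_cbeta_spectrum(sc.cbeta_components((0.526, 0.299, 0.105, 0.070)))
res = sc.AlaCbetaModel(spec).fit()
print(res.summary())
```

```
Ala C-beta four-conformation deconvolution
==========================================================
component      center/ppm   fwhm/Hz     area  fraction
random_coil        16.500     300.0   0.5260    52.60%
silkI*             16.500     100.0   0.2990    29.90%
beta_A             19.600     250.0   0.1050    10.50%
beta_B             21.700     250.0   0.0700     7.00%
----------------------------------------------------------
baseline 2.313e-19   residual RMS 1.29e-17   starts 5
```

The fit recovers the generating composition exactly: 29.9% of the alanine
residues are in the silk I\* β-turn form, 52.6% remain random coil and
17.5% sit in β-sheets (A larger than B).  Deconvolving a whole
concentration series and fitting the saturation law:

```python
series = sc.synth_series(sc.SeriesModel(), [0, 3, 5, 9, 17, 29, 40])
rep = sc.fractions_report([(c, sc.AlaCbetaModel(s).fit()) for c, s in series])
print(rep.saturation.summary())
```

```
silk I* saturation fit: f(c) = min(slope*c, plateau)
  slope      0.03340 /wt%
  breakpoint 8.966 wt%
  plateau    0.2995 (29.9%)
  rms        0.0002806  (n = 7)
```

i.e. the silk I\* fraction rises linearly with glycerol content and
saturates near 30% — the fraction of alanines in long (AGSGAG)ₙ repeats —
from about 9 wt % glycerol on.

A command-line interface mirrors the library:

```sh
silkconform simulate --kind cbeta --out spec.txt
silkconform deconvolve --spectrum spec.txt --out fit.json
silkconform series --out report.csv
silkconform build-model --out scaffold.pdb
silkconform run --seed 1 --out results/
```

## Acceptance script

`scripts/acceptance.py` re-derives the pipeline's headline numbers from
scratch: it synthesizes the noise-free film spectra from the stated
component parameters and reports the recovered fractions, linewidth and
center from the constrained deconvolution, then builds the silk I\*
scaffold, places glycerols, refines against the six distance restraints
and reports the largest restrained distance of an accepted complex model.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
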