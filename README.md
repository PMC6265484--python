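# dimersig

Quantitative analyses for establishing that a transcription factor acts as a
**dimer**, bundled as one Python package. The toolkit covers the three
desk-side readouts such a study rests on, together with synthetic-data
generators that emulate every experimental input, so the whole pipeline runs
and is testable without wet-lab data:

1. **Single-molecule two-colour coincidence detection (TCCD).** Complexes
   carrying GFP- and mCherry-tagged subunits diffuse through a confocal
   volume; each transit produces a photon burst in the green and/or red
   channel. Per burst, the coincidence ratio

   *C* = *n*<sub>red</sub> / (*n*<sub>red</sub> + *n*<sub>green</sub>)

   reads out the labelling stoichiometry: a 1:1 dimer peaks at *C* = 0.5, a
   2:1 complex at *C* = 2/3. The package simulates binned two-channel photon
   traces, segments them into bursts, histograms P(*C*), decomposes the
   histogram into green-only / coincident / red-only Gaussian populations,
   and reduces the mean coincident *C* to a small-integer red:green ratio.

2. **Binding-curve analytics.** AlphaScreen titrations show a bell-shaped
   "hook" for interacting pairs; the curve maximum *I* is normalized as a
   binding index BI = (*I* − *I*<sub>neg</sub>) / (*I*<sub>ref</sub> −
   *I*<sub>neg</sub>) × 100. Inhibitor titrations are summarized as percent
   interaction (*I*<sub>cpd</sub>/*I*<sub>DMSO</sub>) × 100 and fitted with a
   three-parameter log-logistic model for the IC50. Fluorescence-polarization
   series are fitted to the Hill equation
   mP(*c*) = mP<sub>free</sub> + (mP<sub>bound</sub> − mP<sub>free</sub>)
   *c*<sup>n</sup> / (K<sub>d</sub><sup>n</sup> + *c*<sup>n</sup>);
   the amplitude ratio of two probes compares their protein occupancy.
   Fits follow the statsmodels convention: Model objects whose `fit()`
   returns a Results object with estimates, uncertainties and `summary()`.

3. **Spaced-motif enrichment and inverted-repeat scanning.** Over a set of
   ChIP-seq peak sequences, the best match of a secondary PWM near each
   primary motif site is binned by gap length and quadrant
   (upstream/downstream × same/opposite strand) and tested with a binomial
   tail against a uniform null, Bonferroni-corrected. An enriched cell at an
   opposite-strand gap is the genomic signature of a dimer contacting an
   inverted repeat of its half-site (e.g. `AACAAT` … 5 bp … `ATTGTT`, "IR5").
   An exact-string scanner locates and counts such spaced half-site pairs;
   the three 37-bp IR1/IR5/IR10 probe sequences used to validate the motif
   are built in.

## Worked example

```python
from dimersig import (Species, simulate_photon_trace, detect_bursts,
                      coincidence_histogram, fit_components,
                      infer_stoichiometry)
from dimersig.coincidence import mean_coincident_C

# 500 s of 1-ms-binned trace: every complex carries 1 GFP + 2 mCherry
trace = simulate_photon_trace([Species(1, 2, 1.0)], duration_s=500, seed=7)
events = detect_bursts(trace)
mean_c, se = mean_coincident_C(events)
print(f"{len(events)} events; mean coincident C = {mean_c:.3f}")
print(f"stoichiometry: {infer_stoichiometry(mean_c, se=se)}")
print(fit_components(coincidence_histogram(events)).summary())
```

prints

```
4702 events; mean coincident C = 0.666
stoichiometry: 2:1 (C = 0.666)
Coincidence histogram: three-Gaussian decomposition
  events: 4702    residual SS: 3.259e-04
  component       mean      sd  weight
  green_only     0.000   0.005   0.000
  coincident     0.666   0.027   0.951
  red_only       0.800   0.218   0.049
```

The coincident population centres at *C* = 0.666 — two red fluorophores for
every green one — and `infer_stoichiometry` reduces that to the 2:1 call.
With `Species(1, 1, 1.0)` the same pipeline returns *C* ≈ 0.50 and 1:1.

The motif side in three lines:

```python
from dimersig import PWM, PlantSpec, generate_peak_set, spacing_analysis

peaks, truth = generate_peak_set(
    300, PlantSpec(half_site="AACAAT", gap=5, spacer="gcggc",
                   plant_fraction=0.4), seed=42)
pwm = PWM.from_consensus("AACAAT")
(table,) = spacing_analysis(peaks, pwm, [pwm], margin=150, gap_range=20,
                            minscore=5).values()
print(table.best["gap"], table.best["quadrant"], table.best["p_corrected"])
# 5 downstream-opposite 6.21e-208
```

The planted inverted repeat with a 5-bp spacer is recovered as the most
significant (gap, quadrant) cell.

A `dimersig` command-line tool exposes every generator and analysis
(`dimersig --help`); generators write a JSON provenance sidecar beside each
output file.

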