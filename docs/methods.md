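# Methods

This note documents the models behind each analysis, the synthetic-data
generators that stand in for the instruments, the defaults and numerical
choices, and what the tests do and do not demonstrate about real data.

## Photon-burst simulation

The simulator emulates fluorescently labelled protein complexes diffusing
through a confocal excitation volume at single-molecule dilution (~100 pM),
recorded as photon counts in two spectral channels at a fixed bin width
(default 1 ms).

Model, per trace:

- **Transits** arrive as a homogeneous Poisson process (default 10 events/s).
  The expected number of concurrently active transits λ = rate × mean
  duration must keep P(≥2 active) = 1 − (1+λ)e<sup>−λ</sup> below 1%;
  the simulator refuses rates that violate this, because chance coincidence
  of two independent molecules would mimic dimers.
- **Transit profile** is Gaussian in time. No diffusion constant or beam
  waist is modelled; the transit duration is drawn log-normally (median
  2 ms, σ<sub>log</sub> 0.5, interpreted as the FWHM of the profile), which
  reproduces millisecond-scale bursts phenomenologically.
- **Brightness.** A single fluorophore at the beam centre emits
  `per_fluorophore_peak_rate` photons/ms (default 95, within the 90–100
  photons/ms calibration band of the instrument being emulated). Each
  transit draws a peak attenuation uniform in (0.2, 1] to mimic off-axis
  passage. The per-bin mean in a channel is (fluorophores in that channel) ×
  peak rate × attenuation × profile, plus background (default 1 photon/ms
  per channel) and optional green→red crosstalk (default 0, since band-pass/
  long-pass filtering separates the channels); counts are Poisson draws.

The generator is a pure function of (parameters, seed). What it does *not*
model: 3-D Brownian motion in a Gaussian beam, blinking, bleaching, FRET,
and fluorophore maturation. Consequently, passing tests show that the
*analysis* correctly recovers stoichiometry from bursts with the stated
brightness statistics, not that a real instrument is free of photophysical
artifacts.

## Burst detection and coincidence analysis

The detector finds maximal runs of bins whose summed two-channel count
reaches a threshold (default 10 photons/bin), merges runs separated by at
most `max_gap_bins` (default 1) sub-threshold bins, and discards merged runs
with fewer than `min_event_photons` (default 30) total photons. Per-channel
background is estimated as the mean count of sub-threshold bins and
subtracted (event length × rate, floored at zero) before the coincidence
ratio C = red/(red+green) is formed. Defaults were chosen so that
background-only traces at the default rates yield essentially no events;
none of them is sharp, and all are exposed on the CLI. Background
subtraction precedes C on the grounds that the ratio should reflect burst
photons, not solvent counts.

The P(C) histogram (default 25 bins over [0, 1]) is decomposed by bounded
least squares into three Gaussians with means constrained to [0, 0.2]
(green-only), [0.2, 0.8] (coincident) and [0.8, 1.0] (red-only); component
weights are the normalized Gaussian areas. Initialization takes each
component's starting mean/sd from the histogram mass inside its band, which
avoids local minima when one population dominates. The decomposition is a
smoothing description of the histogram; the quantitative stoichiometry call
uses the *empirical* mean of C over events strictly inside the coincident
window 0.25 < C < 0.75 (strict inequalities), reduced to the small-integer
red:green ratio a:b (a, b ≤ 4) minimizing |a/(a+b) − C̄|, rejected if the
residual exceeds 0.06.

Burst-size classification uses the *per-bin* peak of an event: at a
calibration rate R per fluorophore, peak ≤ R is a single fluorophore,
(R, 2R] two, > 2R an oligomer/aggregate. Per-bin (rather than per-event)
intensity is used because the calibration is stated in photons per
millisecond. Whether real instruments' "photons" are per-bin or per-event is
ambiguous in general; the choice is configurable only through the bin width.

## AlphaScreen and dose-response analytics

Hook curves: replicates are averaged first; the curve maximum I and minimum
I<sub>neg</sub> come from the replicate means, with ties resolved to the
lowest dilution (warning) and a maximum at the highest concentration flagged
as "no hook". I<sub>neg</sub> defaults to the same titration's minimum; an
external negative-control curve can be supplied instead. The binding index
BI = (I − I<sub>neg</sub>)/(I<sub>ref</sub> − I<sub>neg</sub>) × 100 is
affine-invariant in its three arguments. Classification is rule-based:
positive iff I ≥ 3 × I<sub>neg</sub> *and* the final point has descended to
≤ 80% of I (both factors configurable); this encodes "bell-shaped rises then
falls", and a monotone rise is negative. No mechanistic bead-saturation
model is fitted.

IC50: "three-parameter" regression is interpreted as top fixed at 100%,
Hill slope fixed at 1, fitting {IC50, bottom}:
y = bottom + (100 − bottom)/(1 + d/IC50), least squares on log10(IC50).
An alternative parameterization (bottom fixed at 0, slope free) is available
behind a flag, since curve-fitting packages differ in which three parameters
they mean. The confidence interval is profile-based: the SSR profile over
log10(IC50) is thresholded at SSR<sub>min</sub>(1 + F<sub>0.95;1,n−2</sub>/(n−2)).
Flat data (mean span < 1 percentage point, or fitted amplitude < 1) raise a
"no dose dependence" error rather than returning an unbounded IC50.

FP: the Hill model is fitted over (log Kd, n ∈ [0.2, 6], mP_free, mP_bound)
with mP_free initialized from the free-DNA control and the competition
control used as a plausibility floor (warning if violated). Standard errors
are asymptotic (Jacobian-based). The fitted curve is monotone by
construction. Occupancy comparison is the amplitude ratio
(mP_bound − mP_free)<sub>A</sub>/(mP_bound − mP_free)<sub>B</sub> with
first-order error propagation — the polarization amplitude is proportional
to the bound-complex size, so a two-site probe saturating with two proteins
shows roughly twice the amplitude of a one-site probe.

## Spaced-motif enrichment

PWMs score in log2-odds bits against their background (pseudocount 1e-4);
`PWM.from_consensus` assigns 0.85 to the consensus base (a perfect 6-mer
match then scores ≈ 10.6 bits, one mismatch ≈ 6.1, so the conventional
5-bit threshold admits at most one mismatch). Motifs are trimmed of flanking
columns with information content 2 + Σp·log2 p < 1 bit before scanning,
mirroring standard spaced-motif practice. Windows containing masked bases
(lowercase or N, the repeat-masking convention) are disqualified entirely
rather than scored at background — masked sequence is unreliable, not
average.

For each peak whose best primary-motif match (both strands; ties to the
lower start, then + strand) reaches `minscore` (default 5 bits), the best
secondary match whose window lies entirely within `margin` (default 150) bp
of the primary and does not overlap it is assigned a gap (bases strictly
between the windows — the convention fixed by the IR5 probe, which has
exactly 5 bases between its half-sites) and a quadrant. Quadrants are
defined in the *primary's frame*: the primary is oriented to +, upstream/
downstream follow that orientation, and same/opposite strand is relative.
This convention makes the whole analysis invariant under
reverse-complementing the peak set, which the test suite checks.

Significance: each (gap, quadrant) cell with gap < `gap_range` (default 20)
gets a binomial upper-tail p-value with n = number of peaks contributing a
(primary, secondary) pair and null rate p0 = 1/(4·(margin+1)) — the best
secondary match placed uniformly over quadrant × gap slots. The Bonferroni
factor is 4·gap_range. This null is simpler than the full alignment-based
null of dedicated spaced-motif tools; it ignores sequence composition and
the non-uniform geometry of allowed placements, and the tests therefore
check it empirically for conservativeness on background-only peaks rather
than for exact calibration. Counting uses the full margin; only the short
gaps are tested, mirroring the usual margin/range split. A `keep_primary`
flag includes the primary motif among the secondaries, which is what allows
primary–primary spacings (the inverted-repeat case) to be detected.

The composite motif for an enriched cell stacks the contributing windows
(primary + gap + secondary, oriented to the primary's + frame) and returns
column frequencies with a pseudocount.

The inverted-repeat scanner is exact-string and case-insensitive:
half-site + g bases + reverse-complement(half-site). Such an element reads
identically (up to the spacer) on both strands, so one forward pass finds
every site; direct repeats are additionally scanned on the minus strand.
PWM-based scanning with per-half thresholds remains available through the
spacing machinery for degenerate consensi.

## Synthetic peak sets

Peaks are i.i.d. background nucleotides (default uniform; user frequencies
or an order-1 chain optional) of length 500 bp. Exactly
round(plant_fraction × n) randomly chosen peaks receive one planted element
at a uniform offset; elements never overlap each other (one per positive
sequence) and the truth table records every planted position. Repeat
masking is not simulated by default. Real ChIP-seq peaks differ in
composition bias, motif degeneracy and co-occurring motifs; recovery of a
planted element therefore validates the statistics and bookkeeping, not
performance on genomic sequence.

## Problem sizes and reproducibility

The package's standard demonstration sizes are 500 s traces at 1-ms bins
(~5,000 events), 300 peaks × 500 bp for planted-motif recovery, 100-peak
null sets over 100 seeds for calibration, and 50-seed replicate sets for
the IC50 and Hill recovery properties; these sizes give stable statistics
at interactive runtimes. Every stochastic component takes an explicit seed
and is reproducible bit-for-bit; `scripts/acceptance.py` derives all of its
seeds from a single `--seed` argument.

## Known limitations

- No photophysics or diffusion in the trace simulator (see above); the
  coincident-window analysis slightly censors dim events, which is visible
  only as a sub-SE bias in population-fraction estimates at default rates.
- The spacing null is deliberately simple and conservative; printed
  p-values are not comparable to those of alignment-based spaced-motif
  tools, only the identity of the enriched cell is.
- The IC50 confidence interval profiles only log IC50; bottom is treated as
  a nuisance refit per grid point.
- `-numgen`-style generative backgrounds for the spacing analysis are not
  implemented.
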