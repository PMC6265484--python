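"""Synthetic-data generators emulating every experimental input.

Five generators stand in for the wet-lab assays:

* ``simulate_photon_trace`` — two-channel photon-count traces from labelled
  complexes diffusing through a confocal volume at single-molecule dilution;
* ``generate_hook_curve`` — bell-shaped AlphaScreen titrations (hook effect)
  and flat negative controls;
* ``generate_inhibition_curve`` — sigmoidal percent-interaction dose-responses
  with a known IC50;
* ``generate_fp_series`` — Hill-model fluorescence-polarization binding series
  with the three standard plate controls;
* ``generate_peak_set`` — peak sequences over a background nucleotide model
  with spaced motif pairs planted at known positions (sidecar truth table).

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dimersig.io import SequenceRecord, TraceTable
from dimersig.motifs import revcomp

_BASES = "ACGT"


@dataclass(frozen=True)
class Species:
    """One complex type in a labelled mixture: fluorophore counts and abundance."""

    n_green: int
    n_red: int
    fraction: float

    def __post_init__(self) -> None:
        if self.n_green < 0 or self.n_red < 0 or self.n_green + self.n_red < 1:
            raise ValueError("a species must carry at least one fluorophore")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class OpticsCalibration:
    """Detection-path calibration for the photon-burst simulator.

    ``per_fluorophore_peak_rate`` is the photons/ms a single fluorophore emits
    at the centre of the focal volume (a single GFP or mCherry tops out around
    90-100 photons/ms on the calibrated instrument; default 95).  Background
    rates are dark/solvent counts per channel; crosstalk is the fraction of
    green photons leaking into the red channel (0 with proper band-pass /
    long-pass filtering).
    """

    per_fluorophore_peak_rate: float = 95.0
    background_rate_green: float = 1.0
    background_rate_red: float = 1.0
    crosstalk_green_to_red: float = 0.0
    plausible_band: tuple[float, float] = (50.0, 150.0)

    def __post_init__(self) -> None:
        if min(self.per_fluorophore_peak_rate, self.background_rate_green,
               self.background_rate_red) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.crosstalk_green_to_red < 1.0:
            raise ValueError("crosstalk must lie in [0, 1)")
        lo, hi = self.plausible_band
        if not lo <= self.per_fluorophore_peak_rate <= hi:
            raise ValueError(
                f"per_fluorophore_peak_rate {self.per_fluorophore_peak_rate} "
                f"outside plausible band [{lo}, {hi}]")


def assemble_label_mixture(oligomer_size: int, red_fraction: float) -> list[Species]:
    """Species distribution from random label assembly during co-expression.

    Co-expressing green- and red-tagged subunits at red fraction ``f`` yields
    oligomers with k red / (size-k) green subunits at binomial frequencies
    C(size, k) f^k (1-f)^(size-k).  For dimers the dual-colour fraction is
    exactly 2 f (1 - f).
    """
    if oligomer_size < 1:
        raise ValueError("oligomer_size must be >= 1")
    if not 0.0 <= red_fraction <= 1.0:
        raise ValueError("red_fraction must lie in [0, 1]")
    species = []
    for k in range(oligomer_size + 1):
        frac = float(stats.binom.pmf(k, oligomer_size, red_fraction))
        if frac > 0.0:
            species.append(Species(oligomer_size - k, k, frac))
    return species


def simulate_photon_trace(
    mixture: Sequence[Species],
    calib: OpticsCalibration | None = None,
    duration_s: float = 500.0,
    bin_width_ms: float = 1.0,
    event_rate: float = 10.0,
    seed: int | None = None,
    transit_median_ms: float = 2.0,
    transit_sigma_log: float = 0.5,
    attenuation_range: tuple[float, float] = (0.2, 1.0),
) -> TraceTable:
    """Simulate a binned two-channel photon trace of diffusing complexes.

    Complex transits arrive as a Poisson process at ``event_rate``; each
    transit draws a species (by mixture fraction), a log-normal duration
    (median ``transit_median_ms``), and a uniform peak attenuation mimicking
    off-axis passage.  The per-bin photon mean is
    ``n_fluorophores × per_fluorophore_peak_rate × attenuation`` shaped by a
    Gaussian transit profile (duration = FWHM), plus background and
    crosstalk; counts are Poisson draws.  Identical (inputs, seed) give an
    identical trace.

    Raises if the chance of two transits overlapping in a bin exceeds 1%
    (single-molecule dilution precondition).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    calib = calib or OpticsCalibration()
    fractions = np.array([s.fraction for s in mixture])
    if not math.isclose(fractions.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mixture fractions must sum to 1")

    # single-molecule dilution check: expected concurrent transits
    mean_transit_s = transit_median_ms * math.exp(transit_sigma_log ** 2 / 2) / 1000.0
    lam = event_rate * mean_transit_s
    p_overlap = 1.0 - (1.0 + lam) * math.exp(-lam)
    if p_overlap >= 0.01:
        raise ValueError(
            f"event_rate {event_rate}/s gives overlap probability "
            f"{p_overlap:.3f} >= 1%; lower the rate or shorten transits")

    rng = np.random.default_rng(seed)
    n_bins = int(round(duration_s * 1000.0 / bin_width_ms))
    mean_g = np.full(n_bins, calib.background_rate_green * bin_width_ms)
    mean_r = np.full(n_bins, calib.background_rate_red * bin_width_ms)

    n_events = rng.poisson(event_rate * duration_s)
    t0 = rng.uniform(0.0, duration_s * 1000.0, n_events)  # ms
    idx = rng.choice(len(mixture), size=n_events, p=fractions)
    durations = rng.lognormal(math.log(transit_median_ms), transit_sigma_log, n_events)
    atten = rng.uniform(*attenuation_range, n_events)

    rate = calib.per_fluorophore_peak_rate
    n_green = np.array([s.n_green for s in mixture])
    n_red = np.array([s.n_red for s in mixture])
    for k in range(n_events):
        sigma = durations[k] / 2.355  # FWHM -> sd, in ms
        lo = max(0, int((t0[k] - 4 * sigma) / bin_width_ms))
        hi = min(n_bins, int((t0[k] + 4 * sigma) / bin_width_ms) + 1)
        if hi <= lo:
            continue
        centers = (np.arange(lo, hi) + 0.5) * bin_width_ms
        profile = np.exp(-0.5 * ((centers - t0[k]) / sigma) ** 2)
        peak = rate * atten[k] * bin_width_ms
        mean_g[lo:hi] += n_green[idx[k]] * peak * profile
        mean_r[lo:hi] += n_red[idx[k]] * peak * profile

    if calib.crosstalk_green_to_red > 0:
        bg_g = calib.background_rate_green * bin_width_ms
        mean_r += calib.crosstalk_green_to_red * (mean_g - bg_g)

    green = rng.poisson(mean_g)
    red = rng.poisson(mean_r)
    return TraceTable(bin_width_ms, green, red)


@dataclass
class HookModel:
    """Parametric bell-shaped (hook-effect) AlphaScreen titration.

    The noiseless signal is ``background + amplitude * exp(-0.5 z^2)`` with
    ``z = (log10(d) - log10(peak_dilution)) / width``, using ``rise_width``
    below the peak and ``fall_width`` above it.  Amplitude 0 gives the flat
    line of a non-interacting pair.
    """

    background: float = 1000.0
    amplitude: float = 9000.0
    peak_dilution: float = 1e-2
    rise_width: float = 1.0
    fall_width: float = 0.7

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if min(self.peak_dilution, self.rise_width, self.fall_width) <= 0:
            raise ValueError("peak_dilution and widths must be positive")

    def signal(self, dilutions) -> np.ndarray:
        d = np.asarray(dilutions, dtype=float)
        logd = np.log10(d)
        logp = math.log10(self.peak_dilution)
        width = np.where(logd < logp, self.rise_width, self.fall_width)
        return self.background + self.amplitude * np.exp(
            -0.5 * ((logd - logp) / width) ** 2)


def generate_hook_curve(model: HookModel, dilutions: Sequence[float],
                        noise_cv: float = 0.05, replicates: int = 3,
                        seed: int | None = None):
    """Simulate an AlphaScreen titration from a HookModel.

    Returns a :class:`dimersig.binding.TitrationCurve` with ``replicates``
    multiplicative-noise draws per dilution (CV ``noise_cv``).
    """
    from dimersig.binding import TitrationCurve

    d = np.asarray(dilutions, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 dilution points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("dilutions must be sorted ascending")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    clean = model.signal(d)
    noise = rng.normal(1.0, noise_cv, (d.size, replicates)) if noise_cv > 0 \
        else np.ones((d.size, replicates))
    signals = np.clip(clean[:, None] * noise, 0.0, None)
    return TitrationCurve(d, signals)


def inhibition_percent(dose, ic50: float, bottom: float) -> np.ndarray:
    """Noiseless three-parameter inhibition model (top 100, Hill slope 1)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (100.0 - bottom) / (1.0 + dose / ic50)


def generate_inhibition_curve(ic50: float, bottom: float, doses: Sequence[float],
                              noise_cv: float = 0.05, replicates: int = 3,
                              seed: int | None = None):
    """Simulate a percent-interaction dose-response with known IC50.

    The noiseless curve is ``bottom + (100 - bottom) / (1 + dose/ic50)`` —
    100% at zero dose, the midpoint (for bottom 0) at dose = IC50.
    """
    from dimersig.binding import DoseResponse

    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if not 0.0 <= bottom <= 100.0:
        raise ValueError("bottom must lie in [0, 100]")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    clean = inhibition_percent(doses, ic50, bottom)
    noise = rng.normal(1.0, noise_cv, (doses.size, replicates)) if noise_cv > 0 \
        else np.ones((doses.size, replicates))
    return DoseResponse(doses, clean[:, None] * noise)


def hill_mp(conc, kd: float, hill_n: float, mp_free: float, mp_bound: float):
    """Noiseless Hill binding curve in polarization units (mP)."""
    c = np.asarray(conc, dtype=float)
    return mp_free + (mp_bound - mp_free) * c ** hill_n / (kd ** hill_n + c ** hill_n)


def generate_fp_series(kd: float, hill_n: float, mp_free: float, mp_bound: float,
                       concs: Sequence[float], noise_sd: float = 0.0,
                       seed: int | None = None):
    """Simulate a fluorescence-polarization binding series (Hill model).

    Includes the three plate controls: free labelled DNA (low mP), DNA +
    saturating protein (high mP), and DNA + protein + excess unlabelled
    competitor (low mP).
    """
    from dimersig.binding import FPSeries

    if kd <= 0:
        raise ValueError("kd must be positive")
    if mp_bound <= mp_free:
        raise ValueError("mp_bound must exceed mp_free")
    concs = np.asarray(concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    clean = hill_mp(concs, kd, hill_n, mp_free, mp_bound)
    mp = clean + (rng.normal(0.0, noise_sd, concs.size) if noise_sd > 0 else 0.0)
    jitter = (lambda: rng.normal(0.0, noise_sd)) if noise_sd > 0 else (lambda: 0.0)
    controls = {
        "free_dna": mp_free + jitter(),
        "protein": mp_bound + jitter(),
        "competition": mp_free + jitter(),
    }
    return FPSeries(concs, np.asarray(mp, dtype=float), controls=controls)


@dataclass
class PlantSpec:
    """Specification of the spaced element planted into peak sequences.

    The element is ``half_site`` + spacer of ``gap`` bases + partner, where
    the partner is the reverse complement of the half-site for ``inverted``
    orientation (a palindromic dimer site) or the half-site itself for
    ``direct``.  ``spacer`` fixes the spacer string; None draws it from the
    background model.
    """

    half_site: str = "AACAAT"
    gap: int = 5
    orientation: str = "inverted"
    plant_fraction: float = 0.4
    peak_length: int = 500
    spacer: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("inverted", "direct"):
            raise ValueError("orientation must be 'inverted' or 'direct'")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if 2 * len(self.half_site) + self.gap > self.peak_length:
            raise ValueError("planted element longer than the peak")
        if self.spacer is not None and len(self.spacer) != self.gap:
            raise ValueError("spacer length must equal gap")

    @property
    def element_length(self) -> int:
        return 2 * len(self.half_site) + self.gap


def generate_peak_set(
    n_peaks: int,
    plant: PlantSpec,
    background: Sequence[float] | None = None,
    seed: int | None = None,
    transition: np.ndarray | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate peak sequences with planted spaced elements and a truth table.

    Exactly ``round(plant_fraction * n_peaks)`` sequences carry one element at
    a uniformly random offset; the returned truth table records (peak, start,
    end, gap, orientation).  Background is i.i.d. at the given frequencies
    (default uniform) or an order-1 chain if ``transition`` (4x4 row-stochastic
    matrix) is supplied.  Identical seed gives identical output.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    freqs = np.full(4, 0.25) if background is None else np.asarray(background, float)
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    L = plant.peak_length

    def draw_bases(n: int) -> str:
        if transition is None:
            return "".join(_BASES[i] for i in rng.choice(4, size=n, p=freqs))
        T = np.asarray(transition, dtype=float)
        out = [int(rng.choice(4, p=freqs))]
        for _ in range(n - 1):
            out.append(int(rng.choice(4, p=T[out[-1]])))
        return "".join(_BASES[i] for i in out)

    n_plant = int(round(plant.plant_fraction * n_peaks))
    planted_idx = set(rng.choice(n_peaks, size=n_plant, replace=False).tolist())
    half = plant.half_site.upper()
    partner = revcomp(half) if plant.orientation == "inverted" else half

    records: list[SequenceRecord] = []
    truth_rows = []
    for i in range(n_peaks):
        seq = draw_bases(L)
        if i in planted_idx:
            spacer = plant.spacer if plant.spacer is not None else draw_bases(plant.gap)
            element = half + spacer + partner
            offset = int(rng.integers(0, L - len(element) + 1))
            seq = seq[:offset] + element + seq[offset + len(element):]
            truth_rows.append({
                "peak": f"peak_{i:05d}", "start": offset,
                "end": offset + len(element), "gap": plant.gap,
                "orientation": plant.orientation,
            })
        records.append(SequenceRecord(f"peak_{i:05d}", seq))
    truth = pd.DataFrame(truth_rows,
                         columns=["peak", "start", "end", "gap", "orientation"])
    return records, truth
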