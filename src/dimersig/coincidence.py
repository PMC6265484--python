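"""Two-colour coincidence detection on binned photon traces.

A trace is segmented into single-molecule burst events (threshold runs of the
summed channel counts), each event gets a coincidence ratio
``C = red / (red + green)``, and the ensemble of ratios is histogrammed and
decomposed into three Gaussian populations: green-only complexes near C = 0,
coincident (dual-labelled) complexes in the middle, and red-only complexes
near C = 1.  A complex carrying one green and one red fluorophore sits at
C = 0.5; one green and two red at C = 2/3 — so the mean C of the coincident
population reads out the labelling stoichiometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from dimersig.io import TraceTable
from dimersig.simulate import OpticsCalibration


@dataclass
class BurstEvent:
    """One detected single-molecule transit.

    Photon sums are background-corrected (trace-wide sub-threshold mean rate
    times event length, floored at zero); ``peak_bin_total`` is the maximum
    raw summed count in any single bin of the event.
    """

    start_bin: int
    end_bin: int
    green_photons: float
    red_photons: float
    peak_bin_total: float
    C: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("end_bin must exceed start_bin")
        if self.green_photons < 0 or self.red_photons < 0:
            raise ValueError("photon sums must be >= 0")


def coincidence_ratio(green_photons: float, red_photons: float) -> float:
    """C = red / (red + green); the fraction of red in the total signal."""
    total = green_photons + red_photons
    if total <= 0:
        raise ValueError("cannot form a coincidence ratio from zero photons")
    return red_photons / total


def detect_bursts(trace: TraceTable, threshold_photons_per_bin: float = 10.0,
                  min_event_photons: float = 30.0,
                  max_gap_bins: int = 1) -> list[BurstEvent]:
    """Segment a trace into burst events.

    Maximal runs of bins whose summed (green + red) count reaches
    ``threshold_photons_per_bin`` are found; runs separated by at most
    ``max_gap_bins`` sub-threshold bins are merged; merged runs with fewer
    than ``min_event_photons`` total photons are discarded.  Per-channel
    background (mean rate of sub-threshold bins times event length) is
    subtracted from the stored photon sums, floored at zero.  Events whose
    corrected sums are both zero are dropped (no ratio is defined for them).

    An empty trace yields an empty list.  A trace with every bin above
    threshold cannot support a background estimate; its events are flagged
    ``saturated`` (background taken as zero) and a warning is issued.
    """
    if threshold_photons_per_bin <= 0 or min_event_photons <= 0:
        raise ValueError("thresholds must be positive")
    total = trace.green + trace.red
    if total.size == 0:
        return []
    above = total >= threshold_photons_per_bin

    saturated = bool(above.all())
    if saturated:
        warnings.warn("every bin exceeds the threshold; background set to 0 "
                      "and events flagged saturated", stacklevel=2)
        bg_g = bg_r = 0.0
    else:
        sub = ~above
        bg_g = float(trace.green[sub].mean())
        bg_r = float(trace.red[sub].mean())

    # maximal runs of above-threshold bins
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]

    # merge runs separated by <= max_gap_bins
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= max_gap_bins:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    events: list[BurstEvent] = []
    for s, e in merged:
        raw_g = float(trace.green[s:e].sum())
        raw_r = float(trace.red[s:e].sum())
        if raw_g + raw_r < min_event_photons:
            continue
        n = e - s
        g = max(0.0, raw_g - bg_g * n)
        r = max(0.0, raw_r - bg_r * n)
        if g + r <= 0:
            continue
        events.append(BurstEvent(s, e, g, r, float(total[s:e].max()),
                                 coincidence_ratio(g, r), saturated))
    return events


@dataclass
class CoincidenceHistogram:
    """Normalized histogram of event coincidence ratios over [0, 1]."""

    edges: np.ndarray
    fractions: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("histogram requires at least one event")
        if not math.isclose(float(np.sum(self.fractions)), 1.0, abs_tol=1e-9):
            raise ValueError("histogram fractions must sum to 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def coincidence_histogram(events, n_bins: int = 25) -> CoincidenceHistogram:
    """Histogram P(C): the fraction of events per coincidence-ratio bin."""
    if len(events) == 0:
        raise ValueError("no events detected")
    ratios = np.array([ev.C for ev in events])
    counts, edges = np.histogram(ratios, bins=n_bins, range=(0.0, 1.0))
    return CoincidenceHistogram(edges, counts / counts.sum(), len(events))


def coincident_fraction(events, window: tuple[float, float] = (0.25, 0.75)) -> float:
    """Fraction of events with coincidence ratio strictly inside ``window``."""
    if len(events) == 0:
        raise ValueError("no events detected")
    lo, hi = window
    ratios = np.array([ev.C for ev in events])
    return float(np.mean((ratios > lo) & (ratios < hi)))


def mean_coincident_C(events, window: tuple[float, float] = (0.25, 0.75)
                      ) -> tuple[float, float]:
    """Mean and standard error of C over events inside the coincident window."""
    lo, hi = window
    ratios = np.array([ev.C for ev in events])
    inside = ratios[(ratios > lo) & (ratios < hi)]
    if inside.size == 0:
        raise ValueError("no coincident events in the window")
    se = float(inside.std(ddof=1) / math.sqrt(inside.size)) if inside.size > 1 else 0.0
    return float(inside.mean()), se


class CoincidenceMixture:
    """Three-Gaussian decomposition of a coincidence histogram.

    The model is a sum of three Gaussian components with means constrained to
    the green-only ([0, 0.2]), coincident ([0.2, 0.8]) and red-only
    ([0.8, 1.0]) bands.  ``fit()`` performs bounded least squares on the
    histogram fractions and returns a results object with the component
    parameters and area weights normalized to 1.
    """

    MEAN_BOUNDS = ((0.0, 0.2), (0.2, 0.8), (0.8, 1.0))
    COMPONENTS = ("green_only", "coincident", "red_only")

    def __init__(self, hist: CoincidenceHistogram):
        self.hist = hist
        if hist.n_events < 50:
            warnings.warn(f"only {hist.n_events} events; the three-component "
                          "fit is unreliable below ~50", stacklevel=2)

    @staticmethod
    def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
        a = params[0:3]
        m = params[3:6]
        s = params[6:9]
        return sum(a[k] * np.exp(-0.5 * ((x - m[k]) / s[k]) ** 2) for k in range(3))

    def fit(self) -> "CoincidenceMixtureResults":
        x = self.hist.centers
        y = self.hist.fractions
        bands = [(x >= lo) & (x <= hi) for lo, hi in self.MEAN_BOUNDS]
        a0, m0, s0 = [], [], []
        for (lo, hi), b, fallback in zip(self.MEAN_BOUNDS, bands,
                                         (0.1, 0.5, 0.9)):
            yb, xb = y[b], x[b]
            mass = yb.sum()
            if mass > 0:
                mu = float(np.clip(np.dot(xb, yb) / mass, lo + 1e-6, hi - 1e-6))
                sd = float(np.sqrt(np.dot((xb - mu) ** 2, yb) / mass))
            else:
                mu, sd = fallback, 0.05
            a0.append(max(float(yb.max()) if yb.size else 0.0, 1e-6))
            m0.append(mu)
            s0.append(min(max(sd, 0.02), 0.4))
        p0 = np.concatenate([a0, m0, s0])
        lower = np.concatenate([[0.0] * 3, [b[0] for b in self.MEAN_BOUNDS],
                                [0.005] * 3])
        upper = np.concatenate([[2.0] * 3, [b[1] for b in self.MEAN_BOUNDS],
                                [0.5] * 3])
        sol = least_squares(lambda p: self._model(p, x) - y, p0,
                            bounds=(lower, upper), xtol=1e-10, ftol=1e-10,
                            max_nfev=20000)
        if not sol.success:
            raise RuntimeError(
                f"component fit failed: {sol.message}; final residual norm "
                f"{np.linalg.norm(sol.fun):.3g}")
        a, m, s = sol.x[0:3], sol.x[3:6], sol.x[6:9]
        areas = a * s * math.sqrt(2 * math.pi)
        weights = areas / areas.sum() if areas.sum() > 0 else np.full(3, 1 / 3)
        comps = {name: {"mean": float(m[k]), "sd": float(s[k]),
                        "weight": float(weights[k])}
                 for k, name in enumerate(self.COMPONENTS)}
        return CoincidenceMixtureResults(comps, float(np.sum(sol.fun ** 2)),
                                         self.hist.n_events)


@dataclass
class CoincidenceMixtureResults:
    """Fitted three-component decomposition: per-component mean/sd/weight."""

    components: dict
    rss: float
    n_events: int

    @property
    def coincident_weight(self) -> float:
        return self.components["coincident"]["weight"]

    @property
    def coincident_mean(self) -> float:
        return self.components["coincident"]["mean"]

    def summary(self) -> str:
        lines = [
            "Coincidence histogram: three-Gaussian decomposition",
            f"  events: {self.n_events}    residual SS: {self.rss:.3e}",
            f"  {'component':<12} {'mean':>7} {'sd':>7} {'weight':>7}",
        ]
        for name, c in self.components.items():
            lines.append(
                f"  {name:<12} {c['mean']:>7.3f} {c['sd']:>7.3f} {c['weight']:>7.3f}")
        return "\n".join(lines)


def fit_components(hist: CoincidenceHistogram) -> CoincidenceMixtureResults:
    """Convenience wrapper: fit the three-Gaussian model to a histogram."""
    return CoincidenceMixture(hist).fit()


@dataclass
class StoichiometryCall:
    """Inferred red:green fluorophore ratio behind a mean coincidence ratio."""

    red: int
    green: int
    mean_C: float
    residual: float
    confidence: float = float("nan")

    @property
    def ratio(self) -> tuple[int, int]:
        return (self.red, self.green)

    def __str__(self) -> str:
        return f"{self.red}:{self.green} (C = {self.mean_C:.3f})"


def infer_stoichiometry(mean_C: float, max_denominator: int = 4,
                        tolerance: float = 0.06,
                        se: float = float("nan")) -> StoichiometryCall:
    """Reduce a mean coincidence ratio to a small-integer red:green ratio.

    Searches ratios a:b with a, b <= ``max_denominator`` for the one whose
    expected C = a/(a+b) is closest to ``mean_C``; rejects if the best
    residual exceeds ``tolerance``.  C = 0.5 gives 1:1; C = 0.66 gives 2:1.
    """
    if not 0.0 < mean_C < 1.0:
        raise ValueError("mean_C must lie strictly between 0 and 1")
    best = None
    for a in range(1, max_denominator + 1):
        for b in range(1, max_denominator + 1):
            g = math.gcd(a, b)
            ar, br = a // g, b // g
            resid = abs(ar / (ar + br) - mean_C)
            if best is None or resid < best[0]:
                best = (resid, ar, br)
    resid, a, b = best
    if resid > tolerance:
        raise ValueError(
            f"ambiguous stoichiometry: mean C {mean_C:.3f} is {resid:.3f} from "
            f"the nearest small-integer ratio {a}:{b} (tolerance {tolerance})")
    return StoichiometryCall(a, b, mean_C, resid, se)


def classify_burst_size(event: BurstEvent,
                        calib: OpticsCalibration | None = None) -> str:
    """Classify a burst by its peak per-bin intensity.

    With the single-fluorophore peak emission rate R (photons per bin at 1 ms
    bins; 100 by default), a peak at or below R is a ``single`` fluorophore,
    in (R, 2R] a ``dual`` complex, and above 2R an ``oligomer`` or aggregate.
    """
    rate = calib.per_fluorophore_peak_rate if calib is not None else 100.0
    peak = event.peak_bin_total
    if peak <= rate:
        return "single"
    if peak <= 2 * rate:
        return "dual"
    return "oligomer"
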