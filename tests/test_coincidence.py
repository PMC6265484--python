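import math

import numpy as np
import pytest

from dimersig import (
    BurstEvent,
    OpticsCalibration,
    Species,
    classify_burst_size,
    coincidence_histogram,
    coincidence_ratio,
    coincident_fraction,
    detect_bursts,
    fit_components,
    infer_stoichiometry,
    simulate_photon_trace,
)
from dimersig.coincidence import CoincidenceHistogram, mean_coincident_C
from dimersig.io import TraceTable


def brute_force_bursts(trace, threshold, min_photons, max_gap):
    """Independent run-enumeration oracle for the burst detector."""
    total = trace.green + trace.red
    above = [bool(t >= threshold) for t in total]
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    sub = [k for k in range(len(above)) if not above[k]]
    bg_g = np.mean(trace.green[sub]) if sub else 0.0
    bg_r = np.mean(trace.red[sub]) if sub else 0.0
    out = []
    for s, e in merged:
        raw_g, raw_r = trace.green[s:e].sum(), trace.red[s:e].sum()
        if raw_g + raw_r < min_photons:
            continue
        g = max(0.0, raw_g - bg_g * (e - s))
        r = max(0.0, raw_r - bg_r * (e - s))
        if g + r <= 0:
            continue
        out.append((s, e, g, r))
    return out


def _events(*ratios):
    return [BurstEvent(0, 1, 100 * (1 - c), 100 * c, 50, c) for c in ratios]


class TestCoincidenceRatio:
    @pytest.mark.parametrize("g,r,expect", [
        (120, 120, 0.5), (80, 160, 2 / 3), (100, 0, 0.0),
    ])
    def test_values(self, g, r, expect):
        assert coincidence_ratio(g, r) == pytest.approx(expect, abs=1e-4)

    def test_zero_photons_rejected(self):
        with pytest.raises(ValueError):
            coincidence_ratio(0, 0)


class TestDetectBursts:
    def test_background_only_trace_yields_no_events(self, rng):
        tr = TraceTable(1.0, rng.integers(0, 5, 2000), rng.integers(0, 5, 2000))
        assert detect_bursts(tr, threshold_photons_per_bin=10) == []

    def test_hand_built_single_burst(self):
        g = np.ones(100, dtype=int)
        r = np.ones(100, dtype=int)
        g[50:53] = 25
        r[50:53] = 25
        events = detect_bursts(TraceTable(1.0, g, r), 10, 30, 1)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_bin, ev.end_bin) == (50, 53)
        assert ev.C == pytest.approx(0.5, abs=0.01)

    def test_two_separated_bursts(self):
        g = np.ones(100, dtype=int)
        r = np.ones(100, dtype=int)
        for lo in (20, 70):
            g[lo:lo + 3] = 25
            r[lo:lo + 3] = 25
        events = detect_bursts(TraceTable(1.0, g, r), 10, 30, 1)
        assert len(events) == 2

    def test_gap_merging(self):
        g = np.zeros(30, dtype=int)
        g[10:12] = 30
        g[13:15] = 30  # one sub-threshold bin between runs
        events = detect_bursts(TraceTable(1.0, g, np.zeros(30, dtype=int)),
                               10, 30, max_gap_bins=1)
        assert len(events) == 1
        assert (events[0].start_bin, events[0].end_bin) == (10, 15)

    def test_empty_trace(self):
        tr = TraceTable(1.0, np.zeros(2, dtype=int), np.zeros(2, dtype=int))
        assert detect_bursts(tr) == []

    def test_matches_brute_force_oracle_on_random_traces(self, rng):
        for _ in range(10):
            n = int(rng.integers(100, 2000))
            g = rng.poisson(1.5, n)
            r = rng.poisson(1.5, n)
            spikes = rng.integers(0, n - 5, 10)
            for s in spikes:
                g[s:s + 3] += rng.integers(5, 40)
                r[s:s + 3] += rng.integers(5, 40)
            tr = TraceTable(1.0, g, r)
            got = detect_bursts(tr, 10, 30, 1)
            expect = brute_force_bursts(tr, 10, 30, 1)
            assert [(e.start_bin, e.end_bin) for e in got] \
                == [(s, e) for s, e, *_ in expect]
            for ev, (_, _, eg, er) in zip(got, expect):
                assert ev.green_photons == pytest.approx(eg)
                assert ev.red_photons == pytest.approx(er)


class TestHistogram:
    def test_single_occupied_bin(self):
        hist = coincidence_histogram(_events(0.5, 0.5, 0.5, 0.5))
        assert hist.fractions.max() == pytest.approx(1.0)
        assert np.count_nonzero(hist.fractions) == 1

    def test_quarter_fractions(self):
        hist = coincidence_histogram(_events(0.1, 0.5, 0.9, 0.6))
        assert sorted(hist.fractions[hist.fractions > 0]) == [0.25] * 4

    def test_order_invariance(self):
        a = coincidence_histogram(_events(0.1, 0.5, 0.9, 0.6))
        b = coincidence_histogram(_events(0.6, 0.9, 0.5, 0.1))
        np.testing.assert_array_equal(a.fractions, b.fractions)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            coincidence_histogram([])


class TestCoincidentFraction:
    def test_counting(self):
        assert coincident_fraction(_events(0.1, 0.5, 0.9, 0.6)) == 0.5

    def test_strict_boundary(self):
        assert coincident_fraction(_events(0.25, 0.25)) == 0.0

    def test_all_inside(self):
        assert coincident_fraction(_events(0.5, 0.5)) == 1.0


class TestComponentFit:
    def test_symmetric_histogram_gives_equal_flank_weights(self):
        edges = np.linspace(0, 1, 26)
        centers = 0.5 * (edges[:-1] + edges[1:])
        y = (np.exp(-0.5 * ((centers - 0.08) / 0.04) ** 2)
             + np.exp(-0.5 * ((centers - 0.92) / 0.04) ** 2)
             + 2 * np.exp(-0.5 * ((centers - 0.5) / 0.06) ** 2))
        hist = CoincidenceHistogram(edges, y / y.sum(), 1000)
        fit = fit_components(hist)
        assert fit.components["green_only"]["weight"] == pytest.approx(
            fit.components["red_only"]["weight"], abs=1e-6)

    def test_pure_green_simulation_has_no_coincident_weight(self):
        tr = simulate_photon_trace([Species(1, 0, 1.0)], duration_s=100.0,
                                   seed=21)
        events = detect_bursts(tr)
        fit = fit_components(coincidence_histogram(events))
        assert fit.coincident_weight < 0.05

    def test_dual_label_simulation_centres_at_half(self, dimer_events):
        fit = fit_components(coincidence_histogram(dimer_events))
        assert 0.45 <= fit.coincident_mean <= 0.55
        assert fit.coincident_weight > 0.8


class TestStoichiometry:
    @pytest.mark.parametrize("c,expect", [
        (0.5, (1, 1)), (0.66, (2, 1)), (0.75, (3, 1)),
    ])
    def test_ratio_calls(self, c, expect):
        call = infer_stoichiometry(c)
        assert call.ratio == expect

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infer_stoichiometry(1.0)

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            infer_stoichiometry(0.41, max_denominator=1, tolerance=0.05)


class TestBurstSize:
    @pytest.mark.parametrize("peak,expect", [
        (95, "single"), (150, "dual"), (250, "oligomer"),
    ])
    def test_photon_boundaries(self, peak, expect):
        ev = BurstEvent(0, 2, 60, 60, peak, 0.5)
        calib = OpticsCalibration(per_fluorophore_peak_rate=100.0)
        assert classify_burst_size(ev, calib) == expect


def test_mean_coincident_c_converges_to_fluorophore_ratio():
    # species with g green, r red: mean C -> r/(g+r) within 3 SE
    tr = simulate_photon_trace([Species(2, 1, 1.0)], duration_s=100.0, seed=31)
    events = detect_bursts(tr)
    mean_c, se = mean_coincident_C(events)
    assert abs(mean_c - 1 / 3) < 3 * max(se, 1e-3)
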