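import numpy as np
import pytest

from dimersig import (
    PWM,
    PlantSpec,
    SequenceRecord,
    best_match,
    builtin_probes,
    count_ir_regions,
    generate_peak_set,
    infer_composite_pwm,
    read_meme_motif,
    scan_inverted_repeats,
    spacing_analysis,
    spacing_pvalue,
    trim_motif,
    write_meme_motif,
)
from dimersig.motifs import IRSite, revcomp


def brute_force_best(seq, pwm, minscore):
    """Exhaustive enumeration over all windows and both strands."""
    lo = pwm.log_odds
    w = len(pwm)
    best = None
    s = seq.sequence
    for strand, motif_lo in (("+", lo), ("-", pwm.reverse_complement().log_odds)):
        for i in range(len(s) - w + 1):
            window = s[i:i + w]
            if any(b not in "ACGT" for b in window):
                continue
            score = sum(motif_lo[j]["ACGT".index(b)]
                        for j, b in enumerate(window))
            cand = (score, i, 0 if strand == "+" else 1)
            if best is None or cand[0] > best[0] or (
                    cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])):
                best = cand
    if best is None or best[0] < minscore:
        return None
    return (best[1], "+-"[best[2]], best[0])


class TestPWM:
    def test_from_consensus_columns_normalized(self):
        pwm = PWM.from_consensus("AACAAT")
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0)
        assert pwm.consensus() == "AACAAT"

    def test_bad_columns_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PWM(np.array([[0.5, 0.5, 0.5, 0.5]] * 4))

    def test_n_column_is_uniform(self):
        pwm = PWM.from_consensus("ANT")
        np.testing.assert_allclose(pwm.matrix[1], 0.25)


class TestMemeFormat:
    def test_round_trip(self, tmp_path, sox_pwm):
        path = tmp_path / "m.meme"
        write_meme_motif([sox_pwm], path)
        (back,) = read_meme_motif(path)
        assert len(back) == 6
        np.testing.assert_allclose(back.matrix, sox_pwm.matrix, atol=1e-12)
        np.testing.assert_allclose(back.background, sox_pwm.background)

    def test_unsupported_alphabet_rejected(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text("MEME version 4\n\nALPHABET= ACGU\n")
        with pytest.raises(Exception, match="alphabet"):
            read_meme_motif(path)

    def test_bad_column_sum_rejected(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF broken\n"
            "letter-probability matrix: alength= 4 w= 2\n"
            "0.25 0.25 0.25 0.25\n0.9 0.3 0.1 0.1\n")
        with pytest.raises(Exception, match="column 1"):
            read_meme_motif(path)


class TestTrim:
    def test_uniform_flanks_removed(self):
        core = PWM.from_consensus("ACGT", p_consensus=1.0).matrix
        flank = np.full((2, 4), 0.25)
        pwm = PWM(np.vstack([flank, core, flank]))
        trimmed = trim_motif(pwm, bits=1.0)
        assert len(trimmed) == 4
        np.testing.assert_allclose(trimmed.matrix, core)

    def test_one_hot_column_never_trimmed(self):
        pwm = PWM.from_consensus("ACGT", p_consensus=1.0)
        assert np.all(pwm.information_content == pytest.approx(2.0))
        assert trim_motif(pwm, bits=1.0) is pwm

    def test_idempotent(self, sox_pwm):
        once = trim_motif(sox_pwm)
        assert trim_motif(once) is once

    def test_all_trimmed_rejected(self):
        pwm = PWM(np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            trim_motif(pwm)


class TestBestMatch:
    def test_one_hot_motif_position(self):
        pwm = PWM.from_consensus("ACGT", p_consensus=0.97)
        seq = SequenceRecord("s", "TTACGTTT")
        m = best_match(seq, pwm, minscore=1.0)
        assert (m.start, m.strand) == (2, "+")

    def test_matches_brute_force_on_random_sequences(self, rng, sox_pwm):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            s = "".join(rng.choice(bases, size=int(rng.integers(10, 120))))
            seq = SequenceRecord("s", s)
            got = best_match(seq, sox_pwm, minscore=-100.0)
            expect = brute_force_best(seq, sox_pwm, -100.0)
            assert (got.start, got.strand) == expect[:2]
            assert got.score == pytest.approx(expect[2])

    def test_palindromic_pwm_strand_symmetric_scores(self):
        pal = PWM.from_consensus("ACGT")  # self-reverse-complementary
        seq = SequenceRecord("s", "GGGACGTGGG")
        fwd = best_match(seq, pal, minscore=-100.0)
        rc = best_match(seq.reverse_complement(), pal, minscore=-100.0)
        assert fwd.score == pytest.approx(rc.score)

    def test_masked_sequence_returns_none(self, sox_pwm):
        seq = SequenceRecord("s", "aacaataacaataacaat")
        assert best_match(seq, sox_pwm, minscore=-100.0) is None


class TestSpacingPvalue:
    def test_zero_hits_gives_one(self):
        p, pc = spacing_pvalue(0, 10, 0.01, 80)
        assert p == 1.0 and pc == 1.0

    def test_all_hits_closed_form(self):
        p, _ = spacing_pvalue(10, 10, 0.5, 1)
        assert p == pytest.approx(0.5 ** 10)

    def test_bonferroni_cap(self):
        _, pc = spacing_pvalue(3, 10, 0.3, 80)
        assert pc == 1.0

    def test_bad_p0_rejected(self):
        with pytest.raises(ValueError):
            spacing_pvalue(1, 2, 0.0, 1)


class TestSpacingAnalysis:
    def test_hand_built_gap3_downstream_opposite(self, sox_pwm):
        # secondary (ATTGTT = revcomp half-site) always 3 bases downstream
        seqs = [SequenceRecord(f"s{i}", "C" * 30 + "AACAAT" + "CCC" + "ATTGTT"
                               + "C" * 30) for i in range(10)]
        (table,) = spacing_analysis(seqs, sox_pwm, [sox_pwm],
                                    minscore=5).values()
        assert table.n_sequences_with_both == 10
        counts = table.table.set_index(["gap", "quadrant"])["count"]
        assert counts[(3, "downstream-opposite")] == 10
        assert counts.sum() == 10

    def test_planted_ir5_recovered(self, planted_peaks, sox_pwm):
        peaks, _ = planted_peaks
        (table,) = spacing_analysis(peaks, sox_pwm, [sox_pwm], margin=150,
                                    gap_range=20, minscore=5).values()
        assert table.best["gap"] == 5
        assert table.best["quadrant"].endswith("opposite")
        assert table.best["p_corrected"] < 0.05

    def test_null_peaks_not_significant(self, sox_pwm):
        peaks, _ = generate_peak_set(150, PlantSpec(plant_fraction=0.0),
                                     seed=13)
        (table,) = spacing_analysis(peaks, sox_pwm, [sox_pwm],
                                    minscore=5).values()
        assert table.significant(0.05).empty

    def test_strand_symmetry(self, planted_peaks, sox_pwm):
        # the primary-frame quadrant convention makes the analysis invariant
        # under reverse-complementing every peak
        peaks, _ = planted_peaks
        fwd = spacing_analysis(peaks[:100], sox_pwm, [sox_pwm], minscore=5)
        rc_peaks = [p.reverse_complement() for p in peaks[:100]]
        rc = spacing_analysis(rc_peaks, sox_pwm, [sox_pwm], minscore=5)
        (tf,), (tr,) = fwd.values(), rc.values()
        assert tf.best["gap"] == tr.best["gap"]
        assert tf.best["count"] == tr.best["count"]

    def test_monotone_in_plant_fraction(self, sox_pwm):
        counts = []
        for frac in (0.1, 0.3, 0.5):
            spec = PlantSpec(plant_fraction=frac, spacer="gcggc")
            peaks, _ = generate_peak_set(150, spec, seed=99)
            (table,) = spacing_analysis(peaks, sox_pwm, [sox_pwm],
                                        minscore=5).values()
            cell = table.table.query(
                "gap == 5 and quadrant == 'downstream-opposite'")
            counts.append(int(cell["count"].iloc[0]))
        assert counts == sorted(counts)

    def test_no_primary_match_rejected(self, sox_pwm):
        seqs = [SequenceRecord("s", "GC" * 100)]
        with pytest.raises(ValueError, match="primary"):
            spacing_analysis(seqs, sox_pwm, [sox_pwm], minscore=5)


class TestCompositeInference:
    def test_identical_contributors_give_one_hot(self, sox_pwm):
        seqs = [SequenceRecord(f"s{i}", "C" * 10 + "AACAATGCGGCATTGTT" + "C" * 10)
                for i in range(5)]
        (table,) = spacing_analysis(seqs, sox_pwm, [sox_pwm],
                                    minscore=5).values()
        comp = infer_composite_pwm(table.best["contributors"],
                                   table.primary_len, table.secondary_len,
                                   pseudocount=0.0)
        assert comp.consensus() == "AACAATGCGGCATTGTT"
        assert np.all(comp.matrix.max(axis=1) == 1.0)

    def test_planted_core_consensus_recovered(self, planted_peaks, sox_pwm):
        peaks, _ = planted_peaks
        (table,) = spacing_analysis(peaks, sox_pwm, [sox_pwm],
                                    minscore=5).values()
        comp = infer_composite_pwm(table.best["contributors"],
                                   table.primary_len, table.secondary_len)
        consensus = comp.consensus()
        assert consensus.startswith("AACAAT") and consensus.endswith("ATTGTT")

    def test_single_contributor_rejected(self):
        with pytest.raises(ValueError):
            infer_composite_pwm([], 6, 6)


class TestIRScanner:
    def test_printed_probes(self, probes):
        sites = scan_inverted_repeats(list(probes.values()))
        gaps = {s.sequence_id: s.gap for s in sites}
        assert gaps == {"IR1": 1, "IR5": 5, "IR10": 10}

    def test_gc_only_sequence_has_no_sites(self):
        seq = SequenceRecord("gc", "GCGCCCGGGC" * 4)
        assert scan_inverted_repeats([seq]) == []

    def test_case_insensitive_and_sorted(self):
        seq = SequenceRecord("s", "ttaacaatGGGGGattgttAAaacaatCattgttTT")
        sites = scan_inverted_repeats([seq], gaps=range(0, 6))
        assert [s.left[0] for s in sites] == sorted(s.left[0] for s in sites)
        assert {s.gap for s in sites} == {1, 5}

    def test_direct_orientation_scans_both_strands(self):
        seq = SequenceRecord("s", "AACAATGGAACAAT" + "G" * 5
                             + revcomp("AACAATCCAACAAT"))
        sites = scan_inverted_repeats([seq], gaps=range(0, 3),
                                      orientation="direct")
        strands = {s.strand for s in sites}
        assert strands == {"+", "-"}

    def test_recovers_every_planted_site(self, planted_peaks):
        records, truth = planted_peaks
        sites = scan_inverted_repeats(records, gaps=[5])
        found = {(s.sequence_id, s.left[0]) for s in sites}
        for row in truth.itertuples():
            assert (row.peak, row.start) in found


class TestRegionCounts:
    def test_unique_counts_regions_once(self):
        sites = [
            IRSite("r1", (0, 6), (11, 17), 5, "inverted", "+", "IR5a"),
            IRSite("r1", (30, 36), (41, 47), 5, "inverted", "+", "IR5b"),
            IRSite("r2", (0, 6), (11, 17), 5, "inverted", "+", "IR5c"),
        ]
        counts = count_ir_regions(sites)
        assert counts["unique"] == 2
        assert counts["per_label"] == {"IR5a": 1, "IR5b": 1, "IR5c": 1}

    def test_empty_input(self):
        counts = count_ir_regions([])
        assert counts == {"per_label": {}, "unique": 0}

    def test_generator_truth_unique_count(self, planted_peaks):
        records, truth = planted_peaks
        sites = scan_inverted_repeats(records, gaps=[5], label="IR5")
        truth_ids = set(truth["peak"])
        found = {s.sequence_id for s in sites}
        assert truth_ids <= found
        # planted regions dominate; chance sites are rare
        assert count_ir_regions(
            [s for s in sites if s.sequence_id in truth_ids])["unique"] == 120
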