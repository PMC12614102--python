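"""Tests for vocal-segment consolidation, statistics and the generator.

The statistics are cross-checked against an independent brute-force recount
implemented here with plain loops over the segment lists.
"""

import numpy as np
import pytest

from fmtelem.vocseg import (
    ConsolidatedSegment,
    VocalSegment,
    bin_duration_s,
    consolidate,
    generate_annotations,
    read_selection_table,
    spectrogram,
    voc_statistics,
    write_selection_table,
)

BIN_S = 0.004


def brute_force_stats(consolidated, raw_tr, raw_mic, mic1, bin_s):
    """Independent recount with nested loops (the oracle)."""
    counts = dict(
        n_vocalizations=len(consolidated),
        n_missed_transmitter=0,
        n_missed_all_mics=0,
        n_missed_mic1=0,
        n_unassigned=0,
        n_overlapping=0,
        n_crosstalk=0,
        n_uncertain=0,
    )
    for s in consolidated:
        if s.transmitter is None:
            counts["n_missed_transmitter"] += 1
        if s.firstmic is None:
            counts["n_missed_all_mics"] += 1
        elif s.firstmic != mic1:
            counts["n_missed_mic1"] += 1
        if s.bird is None:
            counts["n_unassigned"] += 1
        overlaps = False
        for o in consolidated:
            if o is s or s.bird is None or o.bird is None or o.bird == s.bird:
                continue
            lo = max(s.onset_s, o.onset_s)
            hi = min(s.offset_s, o.offset_s)
            if hi - lo >= bin_s:
                overlaps = True
        if overlaps:
            counts["n_overlapping"] += 1
    for seg in raw_tr:
        if seg.crosstalk != "No":
            counts["n_crosstalk"] += 1
        if seg.unsure:
            counts["n_uncertain"] += 1
    for seg in raw_mic:
        if seg.unsure:
            counts["n_uncertain"] += 1
    return counts


class TestConsolidate:
    def test_empty_inputs(self):
        assert consolidate([], [], BIN_S) == []

    def test_one_to_one_pair_takes_union(self):
        tr = [VocalSegment("bird1", 1.0, 1.4)]
        mic = [VocalSegment("Mic1", 1.05, 1.5)]
        out = consolidate(tr, mic, BIN_S)
        assert out == [ConsolidatedSegment(1.0, 1.5, "bird1", "bird1", "Mic1")]

    def test_unpaired_transmitter(self):
        out = consolidate([VocalSegment("bird1", 1.0, 1.4)], [], BIN_S)
        assert out == [ConsolidatedSegment(1.0, 1.4, "bird1", "bird1", None)]

    def test_unpaired_mic_with_and_without_guess(self):
        mic = [VocalSegment("Mic2", 2.0, 2.2)]
        out = consolidate([], mic, BIN_S)
        assert out == [ConsolidatedSegment(2.0, 2.2, None, None, "Mic2")]
        guessed = consolidate([], mic, BIN_S, bird_guess={(2.0, 2.2): "bird2"})
        assert guessed[0].bird == "bird2" and guessed[0].transmitter is None

    def test_mic_spanning_two_transmitters_splits(self):
        tr = [VocalSegment("bird1", 1.0, 1.3), VocalSegment("bird2", 1.35, 1.7)]
        mic = [VocalSegment("Mic1", 0.95, 1.75)]
        out = consolidate(tr, mic, BIN_S)
        assert len(out) == 2
        assert out[0] == ConsolidatedSegment(0.95, 1.3, "bird1", "bird1", "Mic1")
        assert out[1] == ConsolidatedSegment(1.35, 1.75, "bird2", "bird2", "Mic1")

    def test_transmitter_paired_with_two_mics_raises(self):
        tr = [VocalSegment("bird1", 1.0, 2.0)]
        mic = [VocalSegment("Mic1", 1.0, 1.4), VocalSegment("Mic2", 1.5, 2.0)]
        with pytest.raises(ValueError, match="multiple microphone"):
            consolidate(tr, mic, BIN_S)

    def test_overlapping_segments_within_source_rejected(self):
        tr = [VocalSegment("bird1", 1.0, 1.4), VocalSegment("bird1", 1.3, 1.6)]
        with pytest.raises(ValueError, match="overlapping segments within"):
            consolidate(tr, [], BIN_S)

    def test_unsure_and_crosstalk_excluded(self):
        tr = [
            VocalSegment("bird1", 1.0, 1.4),
            VocalSegment("bird2", 1.0, 1.4, crosstalk="bird1"),
            VocalSegment("bird1", 3.0, 3.2, unsure=True),
        ]
        out = consolidate(tr, [], BIN_S)
        assert len(out) == 1 and out[0].bird == "bird1"

    def test_sub_bin_overlap_does_not_pair(self):
        tr = [VocalSegment("bird1", 1.0, 1.4)]
        mic = [VocalSegment("Mic1", 1.399, 1.6)]  # 1 ms < bin
        out = consolidate(tr, mic, BIN_S)
        assert len(out) == 2
        assert {s.firstmic for s in out} == {None, "Mic1"}

    def test_idempotent_on_own_output(self):
        # single bird: no cross-bird overlap, so re-consolidation is 1:1
        tr, mic, _ = generate_annotations(
            1, 2, rates=0.5, miss_probs={"transmitter": 0.2, "mic": 0.1, "mic_shift": 0.2},
            seed=3, duration_s=120, bin_s=BIN_S,
        )
        first = consolidate(tr, mic, BIN_S)
        tr2 = [
            VocalSegment(c.transmitter, c.onset_s, c.offset_s)
            for c in first
            if c.transmitter is not None
        ]
        mic2 = [
            VocalSegment(c.firstmic, c.onset_s, c.offset_s)
            for c in first
            if c.firstmic is not None
        ]
        second = consolidate(tr2, mic2, BIN_S)
        assert [(c.onset_s, c.offset_s, c.transmitter, c.firstmic) for c in second] == [
            (c.onset_s, c.offset_s, c.transmitter, c.firstmic) for c in first
        ]

    def test_every_transmitter_segment_covered_once(self):
        tr, mic, _ = generate_annotations(
            3, 2, rates=0.6, overlap_prob=0.2, crosstalk_prob=0.1, seed=9,
            duration_s=60, bin_s=BIN_S,
        )
        out = consolidate(tr, mic, BIN_S)
        for seg in tr:
            if seg.unsure or seg.crosstalk != "No":
                continue
            covering = [
                c
                for c in out
                if c.transmitter == seg.source
                and c.onset_s <= seg.onset_s + 1e-9
                and c.offset_s >= seg.offset_s - 1e-9
            ]
            assert len(covering) == 1, seg


class TestVocStatistics:
    def test_all_zero_on_empty(self):
        stats = voc_statistics([], [], [], ["Mic1"], BIN_S)
        assert stats.n_vocalizations == 0
        assert stats.as_dict()["pct_missed_transmitter"] == 0.0

    def test_overlap_counts_both_members(self):
        disjoint = [
            ConsolidatedSegment(1.0, 1.2, "bird1", "bird1", "Mic1"),
            ConsolidatedSegment(2.0, 2.2, "bird2", "bird2", "Mic1"),
        ]
        assert voc_statistics(disjoint, [], [], ["Mic1"], BIN_S).n_overlapping == 0
        touching = disjoint + [ConsolidatedSegment(2.196, 2.4, "bird1", "bird1", "Mic1")]
        assert voc_statistics(touching, [], [], ["Mic1"], BIN_S).n_overlapping == 2

    def test_missed_transmitter_percentage(self):
        cons = [ConsolidatedSegment(i, i + 0.1, "bird1", "bird1", "Mic1") for i in range(97)]
        cons += [ConsolidatedSegment(100 + i, 100 + i + 0.1, None, None, "Mic1") for i in range(3)]
        stats = voc_statistics(cons, [], [], ["Mic1"], BIN_S)
        assert stats.n_missed_transmitter == 3
        assert stats.percent(stats.n_missed_transmitter) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        tr, mic, _ = generate_annotations(
            3, 3, rates=0.6, overlap_prob=0.25,
            miss_probs={"transmitter": 0.15, "mic": 0.1, "mic_shift": 0.15},
            crosstalk_prob=0.1, seed=seed, duration_s=90, bin_s=BIN_S,
        )
        cons = consolidate(tr, mic, BIN_S)
        stats = voc_statistics(cons, tr, mic, ["Mic1", "Mic2", "Mic3"], BIN_S)
        expected = brute_force_stats(cons, tr, mic, "Mic1", BIN_S)
        assert stats.as_dict() | expected == stats.as_dict()


class TestGenerator:
    def test_perfect_conditions_recover_ground_truth(self):
        tr, mic, gt = generate_annotations(2, 2, rates=0.5, seed=1, duration_s=60)
        out = consolidate(tr, mic, bin_s=BIN_S)
        assert out == gt.consolidated

    def test_identical_seeds_identical_tables(self):
        a = generate_annotations(2, 2, rates=0.5, overlap_prob=0.2, seed=7, duration_s=30)
        b = generate_annotations(2, 2, rates=0.5, overlap_prob=0.2, seed=7, duration_s=30)
        assert a[0] == b[0] and a[1] == b[1]

    def test_ground_truth_counts_match_measured_stats(self):
        tr, mic, gt = generate_annotations(
            3, 3, rates=0.5, overlap_prob=0.3,
            miss_probs={"transmitter": 0.1, "mic": 0.05, "mic_shift": 0.1},
            crosstalk_prob=0.05, seed=11, duration_s=120, bin_s=BIN_S,
        )
        cons = consolidate(tr, mic, BIN_S)
        stats = voc_statistics(cons, tr, mic, ["Mic1", "Mic2", "Mic3"], BIN_S)
        assert cons == gt.consolidated
        assert stats.n_vocalizations == gt.n_events
        assert stats.n_missed_transmitter == gt.n_missed_transmitter
        assert stats.n_missed_all_mics == gt.n_missed_mic
        assert stats.n_missed_mic1 == gt.n_missed_mic1
        assert stats.n_overlapping == gt.n_overlapping
        assert stats.n_crosstalk == gt.n_crosstalk

    def test_miss_probability_recovery(self):
        # long run; measured percentages within a binomial CI of the model
        # single bird: every event draws its misses (overlap components
        # suppress misses and would dilute the rate)
        p_tr, p_mic = 0.12, 0.08
        tr, mic, gt = generate_annotations(
            1, 2, rates=1.0, miss_probs={"transmitter": p_tr, "mic": p_mic},
            seed=13, duration_s=2000,
        )
        cons = consolidate(tr, mic, bin_s=BIN_S)
        stats = voc_statistics(cons, tr, mic, ["Mic1", "Mic2"], BIN_S)
        n = stats.n_vocalizations
        # documented model: transmitter missed w.p. p_tr; mic missed w.p.
        # p_mic*(1 - p_tr) (a double miss keeps the mic segment)
        for count, p in (
            (stats.n_missed_transmitter, p_tr),
            (stats.n_missed_all_mics, p_mic * (1 - p_tr)),
        ):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(count / n - p) < 4 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_annotations(0, 1, rates=1.0)
        with pytest.raises(ValueError):
            generate_annotations(1, 1, rates=1.0, overlap_prob=0.5)


class TestSelectionTableIO:
    def test_round_trip(self, tmp_path):
        segs = [
            VocalSegment("bird1", 1.0, 1.5),
            VocalSegment("bird2", 2.0, 2.5, crosstalk="bird1"),
            VocalSegment("bird1", 3.0, 3.5, unsure=True),
        ]
        path = str(tmp_path / "sel.tsv")
        write_selection_table(path, segs)
        assert read_selection_table(path) == segs
        header = open(path).readline().strip().split("\t")
        assert header == ["Begin Time (s)", "End Time (s)", "Channel", "Crosstalk", "Unsure"]


class TestSpectrogram:
    RATE = 24414.0625

    def test_pure_tone_dominant_row(self):
        t = np.arange(int(0.5 * self.RATE)) / self.RATE
        x = np.sin(2 * np.pi * 3000.0 * t)
        f, _, s, bin_s = spectrogram(x, self.RATE)
        assert abs(f[np.argmax(s.mean(axis=1))] - 3000.0) < self.RATE / 384
        assert bin_s == pytest.approx(96 / self.RATE)

    def test_frame_count_arithmetic(self):
        n = 5000
        _, t, s, _ = spectrogram(np.random.default_rng(0).standard_normal(n), self.RATE)
        assert s.shape[1] == (n - 384) // 96 + 1

    def test_tone_exceeds_noise_floor(self):
        rng = np.random.default_rng(1)
        t = np.arange(int(0.5 * self.RATE)) / self.RATE
        x = np.sin(2 * np.pi * 3000.0 * t) + 0.01 * rng.standard_normal(t.size)
        f, _, s, _ = spectrogram(x, self.RATE)
        tone_row = np.argmin(np.abs(f - 3000.0))
        power = (s**2).mean(axis=1)
        floor = np.median(power)
        assert power[tone_row] > 100 * floor

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="shorter"):
            spectrogram(np.zeros(100), self.RATE)
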