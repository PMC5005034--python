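"""Demultiplexing, trimming, assignment, viewpoint filtering, accounting."""

import numpy as np
import pytest

from conftest import BARCODES, run_pipeline, simulate_lane
from fourc.demux_assign import (
    FragmentCountVector,
    assign_reads,
    assign_sam,
    demultiplex,
    filter_bait_proximal,
    read_counts_tsv,
    trim_bait,
    trim_bait_reads,
    write_counts_tsv,
)
from fourc.fragment_map import BaitDescriptor, digest, locate_bait
from fourc.synthetic_data import BarcodeSpec, ReadRecord, SimulationConfig


class TestDemultiplex:
    def test_exact_match_strips_barcode(self):
        result = demultiplex(
            [ReadRecord("r1", "ACGTGGTTTT")], [BarcodeSpec("S1", "ACGTGG")]
        )
        assert result.per_sample["S1"] == [ReadRecord("r1", "TTTT")]
        assert result.unassigned == []

    def test_empty_read_set(self):
        result = demultiplex([], BARCODES)
        assert result.total == 0
        assert all(n == 0 for n in result.per_sample_counts.values())

    def test_nonmatching_read_unassigned(self):
        result = demultiplex([ReadRecord("r1", "GGGGGGGGGG")], BARCODES)
        assert result.unassigned == [ReadRecord("r1", "GGGGGGGGGG")]

    def test_one_mismatch_tolerated_when_enabled(self):
        read = ReadRecord("r1", "ACGTGATTTT")  # one substitution in S1's barcode
        assert demultiplex([read], BARCODES).unassigned == [read]
        result = demultiplex([read], BARCODES, max_mismatches=1)
        assert result.per_sample["S1"] == [ReadRecord("r1", "TTTT")]

    def test_equidistant_tie_goes_unassigned(self):
        table = [BarcodeSpec("S1", "AAAAAA"), BarcodeSpec("S2", "AAAATT")]
        read = ReadRecord("r1", "AAAAAT" + "C" * 10)  # distance 1 to both
        result = demultiplex([read], table, max_mismatches=2)
        assert result.unassigned == [read]

    def test_prefix_nested_barcodes_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], [BarcodeSpec("S1", "ACGT"), BarcodeSpec("S2", "ACGTGG")])

    def test_duplicate_sample_names_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], [BarcodeSpec("S1", "ACGTGG"), BarcodeSpec("S1", "TGCACC")])

    def test_counts_match_simulator_truth(self, small_config, small_reference, small_profile):
        reads, truth = simulate_lane(
            small_config, small_reference, small_profile, BARCODES, shuffle_seed=1
        )
        result = demultiplex(reads, BARCODES)
        expected = truth["sample"].value_counts().to_dict()
        assert result.per_sample_counts == expected
        assert result.unassigned == []


class TestTrimBait:
    def test_returns_captured_remainder(self):
        assert trim_bait(
            ReadRecord("r", "AACATGTTTT"), "AACATG"
        ) == ReadRecord("r", "TTTT")

    def test_non_bait_read_flagged(self):
        assert trim_bait(ReadRecord("r", "GGGGGGGG"), "AACATG") is None

    def test_bait_end_must_end_in_motif(self):
        with pytest.raises(ValueError):
            trim_bait(ReadRecord("r", "AAAA"), "AAGG")

    def test_simulated_contact_reads_trim_to_fragment_prefix(
        self, small_config, small_reference, small_profile
    ):
        reads, truth = simulate_lane(
            small_config, small_reference, small_profile, BARCODES[:1]
        )
        demuxed = demultiplex(reads, BARCODES[:1]).per_sample["S1"]
        bait_end = small_reference.bait_end_sequence()
        trimmed, n_non_bait = trim_bait_reads(demuxed, bait_end)
        assert n_non_bait == 0
        fmap = small_reference.fragment_map
        contacts = truth[truth.category == "contact"]
        by_id = {r.read_id: r.sequence for r in trimmed}
        for row in contacts.head(300).itertuples():
            frag_seq = fmap.fragment_sequence(
                small_reference.sequence, int(row.fragment_index)
            )
            captured = by_id[row.read_id]
            span = min(len(frag_seq), len(captured))
            assert captured[:span] == frag_seq[:span]


class TestAssignReads:
    def test_unique_prefix_counts_once(self, small_reference):
        fmap = small_reference.fragment_map
        frag = int(np.argmax(fmap.lengths))
        read = ReadRecord("r", small_reference.fragment_map.fragment_sequence(
            small_reference.sequence, frag)[:40])
        vector = assign_reads([read], fmap, small_reference.sequence)
        assert vector.counts[frag] == 1 and vector.total_assigned == 1

    def test_ambiguous_prefix_not_counted(self):
        # two fragments starting with the same 20-mer
        stem = "ACGTAC" * 5
        seq = stem + "TTTTTTCATG" + stem + "GGGGGG"
        fmap = digest(seq, "CATG")
        read = ReadRecord("r", stem)
        vector = assign_reads([read], fmap, seq, min_match_length=20)
        assert vector.n_ambiguous == 1 and vector.total_assigned == 0

    def test_short_and_alien_reads_unmapped(self, small_reference):
        vector = assign_reads(
            [ReadRecord("short", "ACGT"), ReadRecord("alien", "T" * 30)],
            small_reference.fragment_map,
            small_reference.sequence,
        )
        assert vector.n_unmapped == 2

    def test_counts_equal_truth_for_noise_free_simulation(self, small_reference):
        cfg = SimulationConfig(
            sequence_length=100_000,
            undigested_fraction=0.0,
            self_ligation_fraction=0.0,
            reads_per_sample=50_000,
            seed=11,
        )
        from fourc.synthetic_data import build_profile, simulate_reads

        profile = build_profile(small_reference.fragment_map, cfg, "A", small_reference.bait)
        reads, truth = simulate_reads(
            small_reference, small_reference.fragment_map, profile,
            BarcodeSpec("S1", "ACGTGG"), cfg,
        )
        demuxed = demultiplex(reads, [BarcodeSpec("S1", "ACGTGG")]).per_sample["S1"]
        trimmed, _ = trim_bait_reads(demuxed, small_reference.bait_end_sequence())
        vector = assign_reads(trimmed, small_reference.fragment_map, small_reference.sequence)
        expected = np.bincount(
            truth.fragment_index, minlength=len(small_reference.fragment_map)
        )
        np.testing.assert_array_equal(vector.counts, expected)

    def test_both_ends_mode_matches_reverse_strand_read(self, small_reference):
        fmap = small_reference.fragment_map
        frag = int(np.argmax(fmap.lengths))
        frag_seq = fmap.fragment_sequence(small_reference.sequence, frag)
        tail_rc = frag_seq[-30:].translate(str.maketrans("ACGT", "TGCA"))[::-1]
        read = ReadRecord("r", tail_rc)
        forward_only = assign_reads([read], fmap, small_reference.sequence)
        assert forward_only.n_unmapped == 1
        both = assign_reads([read], fmap, small_reference.sequence, both_ends=True)
        assert both.counts[frag] == 1


class TestFilterBaitProximal:
    def test_moves_bait_and_adjacent_counts(self):
        counts = np.array([5, 7, 11, 3])
        bait = BaitDescriptor(1, frozenset({0, 2}))
        vector = filter_bait_proximal(FragmentCountVector("S", counts), bait)
        assert vector.counts.tolist() == [0, 0, 0, 3]
        assert vector.n_filtered_self == 7
        assert vector.n_filtered_undigested == 16
        assert vector.total_assigned == 3

    def test_idempotent(self):
        bait = BaitDescriptor(1, frozenset({0, 2}))
        once = filter_bait_proximal(
            FragmentCountVector("S", np.array([5, 7, 11, 3])), bait
        )
        twice = filter_bait_proximal(once, bait)
        assert twice.counts.tolist() == once.counts.tolist()
        assert twice.n_filtered_self == once.n_filtered_self
        assert twice.n_filtered_undigested == once.n_filtered_undigested

    def test_all_bait_proximal_input_empties_vector(self):
        bait = BaitDescriptor(0, frozenset({1}))
        vector = filter_bait_proximal(FragmentCountVector("S", np.array([4, 6])), bait)
        assert vector.total_assigned == 0

    def test_inconsistent_descriptor_rejected(self):
        with pytest.raises(ValueError):
            filter_bait_proximal(
                FragmentCountVector("S", np.array([1, 2])), BaitDescriptor(5, frozenset())
            )


class TestPipelineAccounting:
    def test_every_read_accounted_exactly_once(
        self, small_config, small_reference, small_profile
    ):
        reads, truth = simulate_lane(
            small_config, small_reference, small_profile, BARCODES, shuffle_seed=2
        )
        result = run_pipeline(small_config, small_reference, reads, BARCODES)
        categories = result.n_unassigned + sum(
            v.total_assigned + v.n_non_bait + v.n_unmapped + v.n_ambiguous
            + v.n_filtered_undigested + v.n_filtered_self
            for v in result.count_vectors.values()
        )
        assert categories == len(reads)
        # noise-free simulation: counts equal per-fragment truth exactly
        for sample, vector in result.count_vectors.items():
            contacts = truth[(truth["sample"] == sample) & (truth.category == "contact")]
            expected = np.bincount(
                contacts.fragment_index, minlength=len(small_reference.fragment_map)
            )
            np.testing.assert_array_equal(vector.counts, expected)


class TestCountsRoundTrip:
    def test_tsv_round_trip(self, tmp_path):
        vector = FragmentCountVector(
            "S1", np.array([0, 3, 9]), n_filtered_undigested=4,
            n_filtered_self=2, n_unmapped=1, n_ambiguous=5, n_non_bait=6,
        )
        path = tmp_path / "counts.tsv"
        write_counts_tsv(vector, path)
        back = read_counts_tsv(path)
        np.testing.assert_array_equal(back.counts, vector.counts)
        assert back.sample_name == "S1"
        assert back.n_filtered_undigested == 4 and back.n_ambiguous == 5


class TestSamAdapter:
    def test_mapq_filter_and_position_assignment(self, tmp_path, small_reference):
        import pysam

        fmap = small_reference.fragment_map
        header = {
            "HD": {"VN": "1.6"},
            "SQ": [{"LN": fmap.sequence_length, "SN": "chrS"}],
        }
        path = tmp_path / "aln.sam"
        with pysam.AlignmentFile(path, "w", header=header) as sam:
            for name, pos, mapq in [
                ("keep1", int(fmap.starts[5]), 42),
                ("keep2", int(fmap.starts[5]) + 2, 60),
                ("lowq", int(fmap.starts[8]), 30),
            ]:
                aln = pysam.AlignedSegment()
                aln.query_name = name
                aln.query_sequence = "A" * 30
                aln.reference_id = 0
                aln.reference_start = pos
                aln.mapping_quality = mapq
                aln.cigarstring = "30M"
                aln.query_qualities = pysam.qualitystring_to_array("I" * 30)
                sam.write(aln)
        vector = assign_sam(path, fmap, sample_name="S1")
        assert vector.counts[5] == 2
        assert vector.total_assigned == 2
        assert vector.n_unmapped == 1
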