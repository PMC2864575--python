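"""Mapability, effective lengths, junction library and the multi-step mapper."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from devocompare.datatypes import Exon, Gene, Genome
from devocompare.errors import MissingDataError
from devocompare.mapping import (
    EffectiveLengths,
    build_junction_library,
    compute_mapability,
    effective_lengths,
    map_reads_multistep,
    revcomp,
)


def count_overlapping(haystack: str, needle: str) -> int:
    n = 0
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def oracle_mapability(chroms: dict[str, str], k: int, strand_mode: str) -> dict[str, np.ndarray]:
    """Independent oracle: per-position substring counting over the genome."""
    out = {}
    for name, seq in chroms.items():
        track = np.zeros(len(seq), dtype=bool)
        for p in range(len(seq) - k + 1):
            w = seq[p : p + k]
            if set(w) - set("ACGT"):
                continue
            occ = sum(count_overlapping(s, w) for s in chroms.values())
            if strand_mode == "both_strands":
                rc = revcomp(w)
                if rc != w:
                    occ += sum(count_overlapping(s, rc) for s in chroms.values())
            track[p] = occ == 1
        out[name] = track
    return out


class TestComputeMapability:
    def test_repeated_kmer_and_end_convention(self):
        # "ACGT" occurs at 0 and 4; the last k-1 positions are unmapable
        track = compute_mapability({"c": "ACGTACGT"}, k=4, strand_mode="forward_only")
        expected = np.array([False, True, True, True, False, False, False, False])
        np.testing.assert_array_equal(track.tracks["c"], expected)

    def test_genome_of_length_k_has_one_mapable_position(self):
        track = compute_mapability({"c": "ACGTG"}, k=5, strand_mode="forward_only")
        assert track.tracks["c"].sum() == 1 and track.tracks["c"][0]

    def test_homopolymer_has_no_mapable_positions(self):
        track = compute_mapability({"c": "AAAAAA"}, k=3, strand_mode="forward_only")
        assert track.tracks["c"].sum() == 0

    def test_both_strands_counts_reverse_complement(self):
        # "AC" at 0; its reverse complement "GT" occurs at 2 -> ambiguous
        track = compute_mapability({"c": "ACGT"}, k=2, strand_mode="both_strands")
        assert not track.tracks["c"][0] and not track.tracks["c"][2]
        fwd = compute_mapability({"c": "ACGT"}, k=2, strand_mode="forward_only")
        assert fwd.tracks["c"][0]

    def test_non_acgt_positions_unmapable(self):
        track = compute_mapability({"c": "ACGTNACGTT"}, k=3, strand_mode="forward_only")
        assert not track.tracks["c"][3] and not track.tracks["c"][4]

    def test_mask_excludes_positions(self):
        plain = compute_mapability({"c": "ACGTTTGCA"}, k=3, strand_mode="forward_only")
        masked = compute_mapability(
            {"c": "ACGTTTGCA"}, k=3, strand_mode="forward_only", mask={"c": [(0, 3)]}
        )
        assert plain.tracks["c"][0]
        assert not masked.tracks["c"][:3].any()

    @settings(max_examples=40, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=6, max_size=120),
        k=st.sampled_from([3, 4, 8]),
        mode=st.sampled_from(["forward_only", "both_strands"]),
    )
    def test_matches_oracle_on_random_genomes(self, seq, k, mode):
        track = compute_mapability({"c": seq}, k=k, strand_mode=mode)
        np.testing.assert_array_equal(
            track.tracks["c"], oracle_mapability({"c": seq}, k, mode)["c"]
        )

    def test_monotone_in_k_on_repeat_free_genome(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        prev = None
        for k in (8, 9, 10):
            track = compute_mapability({"c": seq}, k=k, strand_mode="forward_only")
            # verified against the oracle, then checked for monotonicity
            np.testing.assert_array_equal(
                track.tracks["c"], oracle_mapability({"c": seq}, k, "forward_only")["c"]
            )
            if prev is not None:
                n = len(seq) - k + 1
                assert not (prev[:n] & ~track.tracks["c"][:n]).any()
            prev = track.tracks["c"]


class TestEffectiveLengths:
    def _genome(self, track_len=600):
        genes = [
            Gene("g1", "c", [Exon(0, 500)]),
            Gene("g2", "c", [Exon(500, 550)]),
        ]
        return genes

    def test_fully_mapable_gene(self):
        from devocompare.mapping import MapabilityTrack

        track = MapabilityTrack(35, "forward_only", {"c": np.ones(600, dtype=bool)})
        eff = effective_lengths(track, self._genome())
        assert eff.per_gene["g1"] == 500

    def test_unmapable_gene_has_zero_length(self):
        from devocompare.mapping import MapabilityTrack

        t = np.ones(600, dtype=bool)
        t[500:550] = False
        track = MapabilityTrack(35, "forward_only", {"c": t})
        eff = effective_lengths(track, self._genome())
        assert eff.per_gene["g2"] == 0

    @pytest.mark.parametrize(
        "lengths,expected", [([100, 200, 400], 200.0), ([100, 200, 300, 400], 250.0)]
    )
    def test_median_definition(self, lengths, expected):
        from devocompare.mapping import MapabilityTrack

        genes = []
        pos = 0
        t = np.zeros(2000, dtype=bool)
        for i, L in enumerate(lengths):
            genes.append(Gene(f"g{i}", "c", [Exon(pos, pos + L)]))
            t[pos : pos + L] = True
            pos += L
        track = MapabilityTrack(35, "forward_only", {"c": t})
        assert effective_lengths(track, genes).median == expected

    def test_missing_chromosome_names_gene(self):
        from devocompare.mapping import MapabilityTrack

        track = MapabilityTrack(35, "forward_only", {"other": np.ones(10, bool)})
        with pytest.raises(MissingDataError, match="g1"):
            effective_lengths(track, [Gene("g1", "c", [Exon(0, 5)])])


class TestJunctionLibrary:
    def test_exon_counts(self):
        seq = "A" * 300
        single = Genome("t", {"c": seq}, [Gene("g", "c", [Exon(0, 100)])])
        assert build_junction_library(single, 35) == []
        three = Genome(
            "t", {"c": seq}, [Gene("g", "c", [Exon(0, 50), Exon(80, 130), Exon(160, 220)])]
        )
        entries = build_junction_library(three, 35)
        assert len(entries) == 2
        assert [e.junction_index for e in entries] == [0, 1]

    def test_flank_truncation_at_short_exon(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        g = Genome("t", {"c": seq}, [Gene("g", "c", [Exon(0, 10), Exon(50, 100)])])
        (entry,) = build_junction_library(g, read_length=35)
        assert entry.flank_up == 10
        assert len(entry.sequence) == 44
        assert entry.sequence == seq[0:10] + seq[50:84]

    def test_exon_skipping_option(self):
        seq = "A" * 300
        g = Genome(
            "t", {"c": seq}, [Gene("g", "c", [Exon(0, 50), Exon(80, 130), Exon(160, 220)])]
        )
        assert len(build_junction_library(g, 35, include_skipping=True)) == 3


class TestMapReadsMultistep:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genes = [
            Gene("g1", "c", [Exon(100, 400)]),
            Gene("g2", "c", [Exon(600, 700), Exon(800, 950)]),
        ]
        genome = Genome("t", {"c": seq}, genes)
        junctions = build_junction_library(genome, 35)
        return genome, junctions, seq

    def test_unique_exonic_read_counts_for_gene(self, toy):
        genome, junctions, seq = toy
        res = map_reads_multistep([seq[150:185]], genome, junctions)
        assert res.gene_counts["g1"] == 1 and res.total == 1

    def test_junction_spanning_read_matches_at_stage_two(self, toy):
        genome, junctions, seq = toy
        transcript = seq[600:700] + seq[800:950]
        read = transcript[85:120]  # spans the junction at offset 100
        assert read not in seq
        res = map_reads_multistep([read], genome, junctions)
        assert res.gene_counts["g2"] == 1

    def test_trimming_recovers_corrupted_tail(self, toy):
        genome, junctions, seq = toy
        clean = seq[200:235]
        corrupted = clean[:31] + "TTTT" if clean[31] != "T" else clean[:31] + "GGGG"
        res = map_reads_multistep([corrupted], genome, junctions)
        assert res.gene_counts["g1"] == 1  # matched at length 31 after two trims
        short_clean = seq[200:223] + "G" * 12  # only 23 clean bases: below the floor
        res2 = map_reads_multistep([short_clean], genome, junctions)
        assert res2.unmapped == 1

    def test_intergenic_and_conservation(self, toy):
        genome, junctions, seq = toy
        reads = [seq[0:35], seq[150:185], "T" * 35, seq[620:655]]
        res = map_reads_multistep(reads, genome, junctions)
        assert res.total == len(reads)
        assert res.intergenic >= 1
        assert res.unmapped >= 1

    def test_empty_read_set(self, toy):
        genome, junctions, _ = toy
        res = map_reads_multistep([], genome, junctions)
        assert res.total == 0
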