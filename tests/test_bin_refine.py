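"""Coverage profiling and the contig retention rule (full coverage AND
(marker OR reference similarity))."""

import numpy as np
import pytest

from cobiontscan.bin_refine import (coverage_profile, find_markers,
                                    reference_similarity, refine_bin)
from cobiontscan.sequence_io import ContigSet, SeqRecord, revcomp
from cobiontscan.synthetic_community import mutate


def _random_seq(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def tile_reads(genome: str, coverage: int, read_len: int, prefix="r"
               ) -> ContigSet:
    """Deterministic even tiling of a linear sequence, end-anchored."""
    g = len(genome)
    n = max(2, int(round(coverage * g / read_len)))
    starts = [round(i * (g - read_len) / (n - 1)) for i in range(n)]
    return ContigSet(SeqRecord(f"{prefix}{i}", genome[s:s + read_len])
                     for i, s in enumerate(starts))


class TestCoverageProfile:
    def test_tiled_contig_fully_covered(self, rng):
        genome = _random_seq(20_000, rng)
        contig = SeqRecord("c", genome)
        reads = tile_reads(genome, 20, 4_000)
        profile = coverage_profile(contig, reads)
        assert profile.breadth == 1.0
        assert profile.fully_covered()
        assert profile.n_reads_placed == len(reads)

    def test_host_insertion_not_fully_covered(self, rng):
        """A host contig carrying a 500 bp cobiont-like insert is covered
        only across the insert by the cobiont bin's reads."""
        cobiont = _random_seq(15_000, rng)
        host_contig = SeqRecord(
            "h", _random_seq(8_000, rng) + cobiont[4_000:4_500]
            + _random_seq(8_000, rng))
        bin_reads = tile_reads(cobiont, 10, 3_000)
        profile = coverage_profile(host_contig, bin_reads)
        assert 0.0 < profile.breadth < 0.1
        assert not profile.fully_covered()

    def test_zero_reads_zero_breadth(self, rng):
        profile = coverage_profile(SeqRecord("c", _random_seq(5_000, rng)),
                                   ContigSet())
        assert profile.breadth == 0.0

    def test_reverse_strand_reads_placed(self, rng):
        genome = _random_seq(10_000, rng)
        reads = ContigSet(SeqRecord(f"r{i}", revcomp(r.seq))
                          for i, r in enumerate(
                              tile_reads(genome, 10, 2_500)))
        profile = coverage_profile(SeqRecord("c", genome), reads)
        assert profile.breadth == 1.0

    def test_end_tolerance(self, rng):
        genome = _random_seq(10_000, rng)
        # reads cover all but the outermost 20 bases on each side
        inner = genome[20:-20]
        reads = tile_reads(inner, 10, 2_500)
        profile = coverage_profile(SeqRecord("c", genome), reads)
        assert profile.breadth < 1.0
        assert profile.fully_covered(end_tolerance=25)
        assert not profile.fully_covered(end_tolerance=0)


class TestFindMarkers:
    def test_unmutated_marker_found(self, rng):
        marker = SeqRecord("m", _random_seq(600, rng))
        contig = SeqRecord("c", _random_seq(3_000, rng) + marker.seq
                           + _random_seq(3_000, rng))
        assert find_markers(contig, [marker])

    def test_minus_strand_marker_found(self, rng):
        marker = SeqRecord("m", _random_seq(600, rng))
        contig = SeqRecord("c", _random_seq(1_000, rng)
                           + revcomp(marker.seq) + _random_seq(1_000, rng))
        assert find_markers(contig, [marker])

    def test_random_contig_no_marker(self, rng):
        marker = SeqRecord("m", _random_seq(600, rng))
        assert not find_markers(SeqRecord("c", _random_seq(10_000, rng)),
                                [marker])

    def test_threshold_sweep_on_diverged_marker(self, rng):
        marker = SeqRecord("m", _random_seq(600, rng))
        diverged = mutate(marker.seq, 0.15, rng)   # ~85% identity
        contig = SeqRecord("c", _random_seq(2_000, rng) + diverged
                           + _random_seq(2_000, rng))
        assert not find_markers(contig, [marker], min_identity=0.90)
        assert find_markers(contig, [marker], min_identity=0.80)

    def test_empty_panel_false_with_warning(self, rng, caplog):
        contig = SeqRecord("c", _random_seq(1_000, rng))
        with caplog.at_level("WARNING"):
            assert not find_markers(contig, [])
        assert "empty marker panel" in caplog.text


class TestReferenceSimilarity:
    def test_verbatim_cut_is_similar(self, rng):
        ref = SeqRecord("ref", _random_seq(40_000, rng))
        contig = SeqRecord("c", ref.seq[5_000:25_000])
        assert reference_similarity(contig, ContigSet([ref]))

    def test_unrelated_contig_not_similar(self, rng):
        ref = SeqRecord("ref", _random_seq(30_000, rng))
        contig = SeqRecord("c", _random_seq(15_000, rng))
        assert not reference_similarity(contig, ContigSet([ref]))

    def test_forty_percent_breadth_fails_default(self, rng):
        ref = SeqRecord("ref", _random_seq(30_000, rng))
        contig = SeqRecord("c", ref.seq[:4_000] + _random_seq(6_000, rng))
        assert not reference_similarity(contig, ContigSet([ref]),
                                        min_breadth=0.50)
        assert reference_similarity(contig, ContigSet([ref]),
                                    min_breadth=0.30)

    def test_empty_reference_set(self, rng):
        assert not reference_similarity(
            SeqRecord("c", _random_seq(5_000, rng)), ContigSet())


class TestRefineBin:
    def test_rule_table(self, rng):
        """4 covered contigs with markers retained; the partially covered
        one dropped; similarity substitutes for a missing marker; no
        evidence at all means dropped."""
        genome = _random_seq(60_000, rng)
        marker = SeqRecord("m", genome[10_000:10_600])
        contigs = ContigSet([
            SeqRecord("full_marker", genome[:15_000]),
            SeqRecord("full_marker2", genome[5_000:20_000]),
            SeqRecord("full_sim", genome[20_000:35_000]),
            SeqRecord("full_sim2", genome[35_000:50_000]),
            SeqRecord("partial", genome[40_000:55_000]
                      + _random_seq(5_000, rng)),
        ])
        reads = tile_reads(genome, 15, 5_000)
        refs = ContigSet([SeqRecord("ref", genome)])
        retained, decisions, _ = refine_bin(contigs, reads, [marker], refs)
        by_id = {d.contig_id: d for d in decisions}
        assert set(retained.ids()) == {"full_marker", "full_marker2",
                                       "full_sim", "full_sim2"}
        assert not by_id["partial"].fully_covered
        assert by_id["full_sim"].similar_to_reference
        assert by_id["full_marker"].has_marker

    def test_similarity_branch_without_marker(self, rng):
        genome = _random_seq(20_000, rng)
        contig = SeqRecord("c", genome)
        reads = tile_reads(genome, 15, 5_000)
        refs = ContigSet([SeqRecord("ref", genome[:12_000])])  # 60% breadth
        retained, decisions, _ = refine_bin(
            ContigSet([contig]), reads, [], refs)
        (d,) = decisions
        assert d.fully_covered and not d.has_marker
        assert d.similar_to_reference and d.retained

    def test_no_evidence_dropped(self, rng):
        genome = _random_seq(20_000, rng)
        contig = SeqRecord("c", genome)
        reads = tile_reads(genome, 15, 5_000)
        retained, decisions, _ = refine_bin(
            ContigSet([contig]), reads, [], ContigSet())
        assert len(retained) == 0
        assert decisions[0].fully_covered and not decisions[0].retained

    def test_monotone_in_evidence(self, rng):
        """Adding reads can only gain coverage; adding references can only
        gain similarity."""
        genome = _random_seq(20_000, rng)
        contig = SeqRecord("c", genome)
        half_reads = tile_reads(genome[:10_000], 10, 2_500)
        all_reads = ContigSet(list(half_reads)
                              + list(tile_reads(genome[9_000:], 10, 2_500,
                                                prefix="q")))
        p_half = coverage_profile(contig, half_reads)
        p_all = coverage_profile(contig, all_reads)
        assert p_all.breadth >= p_half.breadth
        assert p_all.fully_covered() and not p_half.fully_covered()
        refs0, refs1 = ContigSet(), ContigSet([SeqRecord("ref", genome)])
        assert not reference_similarity(contig, refs0)
        assert reference_similarity(contig, refs1)

    def test_empty_bin_rejected(self, rng):
        with pytest.raises(ValueError):
            refine_bin(ContigSet(), ContigSet(), [], ContigSet())
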