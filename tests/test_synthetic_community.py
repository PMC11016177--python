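"""Properties of the mock-community generator: composition control,
element bookkeeping, abundance-proportional coverage, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from cobiontscan.sequence_io import SeqRecord, revcomp
from cobiontscan.synthetic_community import (CommunitySpec, SpeciesSpec,
                                             default_community_spec,
                                             embed_elements, mutate,
                                             simulate_community,
                                             simulate_genome, simulate_reads)


def gc_of(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestSimulateGenome:
    @pytest.mark.parametrize("gc", [0.30, 0.50, 0.65])
    def test_gc_within_two_percent(self, gc, rng):
        g = simulate_genome(100_000, gc, bias_seed=5, rng=rng)
        assert abs(gc_of(g.seq) - gc) < 0.02

    def test_deterministic_per_seed(self):
        a = simulate_genome(30_000, 0.4, 5, np.random.default_rng(9))
        b = simulate_genome(30_000, 0.4, 5, np.random.default_rng(9))
        assert a.seq == b.seq

    def test_zero_bias_tetranucleotides_uniform(self, rng):
        g = simulate_genome(200_000, 0.5, 5, rng, bias_scale=0.0)
        counts = {}
        seq = g.seq
        for i in range(len(seq) - 3):
            counts[seq[i:i + 4]] = counts.get(seq[i:i + 4], 0) + 1
        observed = np.array([counts.get(t, 0) for t in sorted(counts)])
        assert len(observed) == 256
        chi = stats.chisquare(observed)
        assert chi.pvalue > 1e-4   # uniform within sampling error

    def test_bias_separates_species(self, rng):
        """Different bias seeds give distinguishable trinucleotide spectra."""
        a = simulate_genome(50_000, 0.5, 1, np.random.default_rng(0))
        b = simulate_genome(50_000, 0.5, 2, np.random.default_rng(0))

        def tri_spectrum(seq):
            c = {}
            for i in range(len(seq) - 2):
                c[seq[i:i + 3]] = c.get(seq[i:i + 3], 0) + 1
            total = sum(c.values())
            return np.array([c.get(t, 0) / total for t in sorted(c)])

        assert np.abs(tri_spectrum(a.seq) - tri_spectrum(b.seq)).max() > 0.002

    def test_invalid_gc_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_genome(30_000, 1.5, 1, rng)


class TestMutate:
    def test_exact_divergence(self, rng):
        seq = simulate_genome(20_000, 0.5, 3, rng).seq
        mut = mutate(seq, 0.05, rng)
        diffs = sum(a != b for a, b in zip(seq, mut))
        assert diffs == round(0.05 * len(seq))


class TestEmbedElements:
    def test_length_and_coordinates(self, rng):
        genome = simulate_genome(100_000, 0.5, 7, rng, name="g")
        ssu = SeqRecord("ssu", "ACGT" * 375)  # 1,500 nt
        final, elements = embed_elements(genome, [ssu], [], rng)
        assert len(final) == 101_500
        (e,) = elements
        extracted = final.seq[e.genome_start:e.genome_end]
        if e.strand == "-":
            extracted = revcomp(extracted)
        assert extracted == ssu.seq

    def test_elements_never_overlap(self, rng):
        genome = simulate_genome(60_000, 0.5, 7, rng)
        markers = [SeqRecord(f"m{i}", "ACGTTGCA" * 75) for i in range(12)]
        ssu = SeqRecord("ssu", "AC" * 700)
        _, elements = embed_elements(genome, [ssu], markers, rng)
        spans = sorted((e.genome_start, e.genome_end) for e in elements)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 <= s1

    def test_minus_strand_recovers_input(self, rng):
        genome = simulate_genome(50_000, 0.5, 7, rng)
        ssu = SeqRecord("ssu", simulate_genome(20_000, 0.5, 8,
                                               rng).seq[:1_500])
        for _ in range(10):
            final, elements = embed_elements(genome, [ssu], [], rng)
            e = elements[0]
            if e.strand == "-":
                seg = final.seq[e.genome_start:e.genome_end]
                assert revcomp(seg) == ssu.seq
                return
        pytest.skip("no minus-strand draw in 10 tries (p < 1e-3)")

    def test_short_ssu_rejected(self, rng):
        genome = simulate_genome(50_000, 0.5, 7, rng)
        with pytest.raises(ValueError, match="1,200"):
            embed_elements(genome, [SeqRecord("s", "ACGT" * 100)], [], rng)

    def test_genome_too_short(self, rng):
        genome = SeqRecord("tiny", "ACGT" * 300)
        markers = [SeqRecord(f"m{i}", "A" * 600) for i in range(5)]
        with pytest.raises(ValueError, match="too short"):
            embed_elements(genome, [], markers, rng)


class TestSimulateReads:
    def _two_species(self, w1, w2, coverage):
        return CommunitySpec(
            [SpeciesSpec("Major dominans", "Hospitidae", "Eukaryota",
                         50_000, 0.5, 1, w1, fragments=1),
             SpeciesSpec("Minor rarus", "Symbiontaceae", "Bacteria",
                         50_000, 0.5, 2, w2, fragments=1)],
            coverage_total=coverage, rng_seed=11)

    def test_coverage_ratio_tracks_weights(self, rng):
        spec = self._two_species(9.0, 1.0, 100.0)
        genomes = [simulate_genome(50_000, 0.5, s.bias_seed, rng, s.name)
                   for s in spec.species]
        reads, truth = simulate_reads(spec, genomes)
        bases = {"Major dominans": 0, "Minor rarus": 0}
        for rid, rt in truth.reads.items():
            bases[rt.species] += len(reads[rid])
        ratio = bases["Major dominans"] / bases["Minor rarus"]
        assert abs(ratio - 9.0) / 9.0 < 0.15

    def test_realized_coverage_near_target(self, rng):
        spec = self._two_species(1.0, 1.0, 40.0)  # 20x each
        genomes = [simulate_genome(50_000, 0.5, s.bias_seed, rng, s.name)
                   for s in spec.species]
        reads, truth = simulate_reads(spec, genomes)
        for sp in spec.species:
            total = sum(len(reads[rid]) for rid, rt in truth.reads.items()
                        if rt.species == sp.name)
            assert abs(total / 50_000 - 20.0) / 20.0 < 0.15

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            SpeciesSpec("Nullus species", "Hospitidae", "Eukaryota",
                        50_000, 0.5, 1, 0.0)

    def test_fixed_seed_identical_multiset(self, rng):
        spec = self._two_species(3.0, 1.0, 30.0)
        genomes = [simulate_genome(50_000, 0.5, s.bias_seed,
                                   np.random.default_rng(4), s.name)
                   for s in spec.species]
        r1, _ = simulate_reads(spec, genomes)
        r2, _ = simulate_reads(spec, genomes)
        assert sorted(r.seq for r in r1) == sorted(r.seq for r in r2)

    def test_every_read_labelled(self, default_bundle):
        bundle, _ = default_bundle
        assert set(bundle.truth.reads) == set(bundle.reads.ids())


class TestSimulateAssemblyAndBundle:
    def test_fragments_concatenate_to_genome(self, default_bundle):
        bundle, _ = default_bundle
        for sp in bundle.spec.species:
            if sp.omit_from_assembly:
                continue
            pieces = sorted(
                ((ct.genome_start, ct.genome_end, cid)
                 for cid, ct in bundle.truth.contigs.items()
                 if ct.species == sp.name))
            joined = "".join(bundle.assembly[cid].seq
                             for _, _, cid in pieces)
            assert joined == bundle.genomes[sp.name].seq
            assert len(pieces) == sp.fragments

    def test_omitted_species_reads_only(self, default_bundle):
        bundle, _ = default_bundle
        omitted = [sp.name for sp in bundle.spec.species
                   if sp.omit_from_assembly]
        assert omitted
        contig_species = {ct.species for ct in bundle.truth.contigs.values()}
        read_species = {rt.species for rt in bundle.truth.reads.values()}
        for name in omitted:
            assert name not in contig_species
            assert name in read_species

    def test_bundle_reproducible_from_seed(self):
        a = simulate_community(default_community_spec(rng_seed=5))
        b = simulate_community(default_community_spec(rng_seed=5))
        assert [r.seq for r in a.reads] == [r.seq for r in b.reads]
        assert [c.seq for c in a.assembly] == [c.seq for c in b.assembly]
        c = simulate_community(default_community_spec(rng_seed=6))
        assert [r.seq for r in a.reads] != [r.seq for r in c.reads]

    def test_truth_rows_cover_reads_and_contigs(self, default_bundle):
        bundle, _ = default_bundle
        assert len(bundle.truth.reads) == len(bundle.reads)
        assert len(bundle.truth.contigs) == len(bundle.assembly)
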