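"""k-mer database construction and read classification, cross-checked
against a brute-force string-set oracle."""

import numpy as np
import pytest

from cobiontscan.family_classifier import (HOST, UNCLASSIFIED, bin_reads,
                                           build_database,
                                           canonical_kmer_arrays,
                                           classify_read)
from cobiontscan.sequence_io import ContigSet, SeqRecord, revcomp
from cobiontscan.taxonomy import TaxonomyTree


def _random_seq(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture()
def tree():
    t = TaxonomyTree()
    t.add_node(1, "root", "root", 1)
    t.add_node(2, "Bacteria", "domain", 1)
    t.add_node(3, "Eukaryota", "domain", 1)
    for i, fam in enumerate(["Aceae", "Bceae", "Cceae", "Dceae"]):
        t.add_node(10 + i, fam, "family", 2)
    t.add_node(30, "Hostidae", "family", 3)
    return t


def kmer_set(seq: str, k: int) -> set[str]:
    """Brute-force canonical k-mer string set."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if "N" not in km:
            out.add(min(km, revcomp(km)))
    return out


class TestCanonicalKmers:
    def test_count_without_masking(self, rng, tree):
        genome = ContigSet([SeqRecord("g", _random_seq(10_000, rng))])
        db = build_database({10: genome}, {}, tree, k=50, mask=False)
        assert len(db) <= 10_000 - 50 + 1
        assert len(db) == len(kmer_set(genome["g"].seq, 50))

    def test_matches_string_oracle_with_ns(self, rng):
        seq = _random_seq(500, rng)
        seq = seq[:100] + "N" + seq[101:300] + "NN" + seq[302:]
        hi, lo, n_valid = canonical_kmer_arrays(seq, 31)
        got = {(int(h), int(l)) for h, l in zip(hi, lo)}
        exp = set()
        for km in kmer_set(seq, 31):
            h2, l2, _ = canonical_kmer_arrays(km, 31)
            exp.add((int(h2[0]), int(l2[0])))
        assert got == exp

    def test_strand_invariance(self, rng):
        seq = _random_seq(300, rng)
        a = canonical_kmer_arrays(seq, 50)
        b = canonical_kmer_arrays(revcomp(seq), 50)
        assert sorted(zip(a[0].tolist(), a[1].tolist())) == \
            sorted(zip(b[0].tolist(), b[1].tolist()))


class TestBuildDatabase:
    def test_shared_genome_lca_labelled(self, rng, tree):
        g = _random_seq(5_000, rng)
        db = build_database({10: ContigSet([SeqRecord("a", g)]),
                             11: ContigSet([SeqRecord("b", g)])},
                            {}, tree, k=50, mask=False)
        # every key is shared by both families -> labelled at their LCA
        assert set(db.labels[i] for i in db.label_idx.tolist()) == {2}

    def test_fully_masked_genome_contributes_nothing(self, tree, caplog):
        g = ContigSet([SeqRecord("m", "AT" * 200)])
        db = build_database({10: g}, {}, tree, k=50)
        assert len(db) == 0

    def test_order_independent(self, rng, tree):
        g1 = ContigSet([SeqRecord("a", _random_seq(3_000, rng))])
        g2 = ContigSet([SeqRecord("b", _random_seq(3_000, rng))])
        d1 = build_database({10: g1, 11: g2}, {}, tree, k=50, mask=False)
        d2 = build_database({11: g2, 10: g1}, {}, tree, k=50, mask=False)
        assert np.array_equal(d1.hi, d2.hi)
        assert np.array_equal(d1.lo, d2.lo)
        assert np.array_equal(d1.label_idx, d2.label_idx)
        assert d1.labels == d2.labels

    def test_k_longer_than_genome_rejected(self, tree):
        with pytest.raises(ValueError):
            build_database({10: ContigSet([SeqRecord("s", "ACGT" * 10)])},
                           {}, tree, k=50)


class TestClassifyRead:
    @pytest.fixture()
    def genomes(self, rng):
        return {fam: _random_seq(8_000, rng) for fam in (10, 11, 12)}

    @pytest.fixture()
    def db(self, genomes, tree, rng):
        host = _random_seq(8_000, rng)
        genomes["host"] = host
        sets = {fam: ContigSet([SeqRecord(f"g{fam}", seq)])
                for fam, seq in genomes.items() if fam != "host"}
        return build_database(sets, {30: ContigSet([SeqRecord("h", host)])},
                              tree, k=50, mask=False)

    def test_verbatim_read_confidence_one(self, genomes, db):
        read = SeqRecord("r", genomes[10][1_000:4_000])
        rc = classify_read(db, read)
        assert rc.family == 10 and rc.confidence == 1.0

    def test_host_read_labelled_host(self, genomes, db):
        rc = classify_read(db, SeqRecord("r", genomes["host"][:3_000]))
        assert rc.label == HOST

    def test_foreign_read_unclassified(self, rng, genomes, db):
        foreign = _random_seq(3_000, rng)
        for fam in (10, 11, 12):
            assert not (kmer_set(foreign, 50) & kmer_set(genomes[fam], 50))
        rc = classify_read(db, SeqRecord("r", foreign))
        assert rc.label == UNCLASSIFIED and not rc.votes

    def test_chimeric_read_resolves_to_lca(self, genomes, db):
        half = 1_525
        chimera = genomes[10][:half] + genomes[11][-half:]
        rc = classify_read(db, SeqRecord("r", chimera))
        assert rc.label == UNCLASSIFIED        # binned to neither family
        assert rc.raw_label == 2               # LCA of the two families
        assert rc.votes[10] == rc.votes[11]

    def test_short_read_unclassified(self, db):
        rc = classify_read(db, SeqRecord("r", "ACGT" * 10))
        assert rc.label == UNCLASSIFIED and rc.n_kmers == 0

    def test_confidence_floor(self, rng, genomes, db):
        # 300 matching bases in a 8 kb read: confidence ~ 250/7951 << 0.10
        read = genomes[10][:300] + _random_seq(7_700, rng)
        rc = classify_read(db, SeqRecord("r", read))
        assert rc.label == UNCLASSIFIED and rc.confidence < 0.10

    def test_matches_bruteforce_oracle(self, rng, tree):
        """classify_read equals explicit per-genome k-mer set intersection
        on a 5-genome database and randomized reads."""
        fams = [10, 11, 12, 13, 30]
        genomes = {f: _random_seq(6_000, rng) for f in fams}
        db = build_database(
            {f: ContigSet([SeqRecord(f"g{f}", genomes[f])]) for f in
             fams[:4]},
            {30: ContigSet([SeqRecord("h", genomes[30])])},
            tree, k=50, mask=False)
        sets = {f: kmer_set(genomes[f], 50) for f in fams}
        for i in range(60):
            kind = i % 3
            if kind == 0:     # verbatim slice, possibly reverse strand
                f = fams[int(rng.integers(0, 5))]
                s = int(rng.integers(0, 4_000))
                seq = genomes[f][s:s + int(rng.integers(100, 2_000))]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
            elif kind == 1:   # random foreign read
                seq = _random_seq(int(rng.integers(100, 2_000)), rng)
            else:             # chimera
                f1, f2 = rng.choice(fams, size=2, replace=False)
                n = int(rng.integers(200, 1_500))
                seq = genomes[f1][:n] + genomes[f2][-n:]
            read = SeqRecord(f"r{i}", seq)
            rc = classify_read(db, read)
            read_kmers = kmer_set(seq, 50)
            votes = {f: len(read_kmers & sets[f]) for f in fams}
            votes = {f: v for f, v in votes.items() if v}
            if not votes:
                assert rc.label == UNCLASSIFIED
                continue
            best = max(votes.values())
            winners = [f for f, v in votes.items() if v == best]
            total = sum(rc.votes.values())
            assert total == len(read_kmers & set().union(*sets.values()))
            if best / max(1, rc.n_kmers) < 0.10:
                assert rc.label == UNCLASSIFIED
            elif len(winners) == 1:
                expected = winners[0]
                assert (rc.label == HOST) == (expected == 30)
                if expected != 30:
                    assert rc.family == expected
            else:
                assert rc.family is None   # tie -> above-family LCA

    def test_no_family_without_matched_kmers(self, rng, tree, genomes, db):
        """A read is never assigned to a family for which it has zero
        matching k-mers."""
        for i in range(50):
            seq = _random_seq(int(rng.integers(60, 1_500)), rng)
            rc = classify_read(db, SeqRecord(f"x{i}", seq))
            if rc.family is not None:
                assert rc.votes.get(rc.family, 0) > 0


class TestBinReads:
    def test_empty_read_set(self, rng, tree):
        db = build_database(
            {10: ContigSet([SeqRecord("g", _random_seq(2_000, rng))])},
            {}, tree, k=50, mask=False)
        result = bin_reads(db, ContigSet())
        assert result.bins == {10: []}
        assert result.host_reads == [] and result.unclassified_reads == []

    def test_each_read_in_at_most_one_bin(self, rng, tree):
        g1, g2 = _random_seq(4_000, rng), _random_seq(4_000, rng)
        db = build_database(
            {10: ContigSet([SeqRecord("a", g1)]),
             11: ContigSet([SeqRecord("b", g2)])}, {}, tree, k=50,
            mask=False)
        reads = ContigSet(
            [SeqRecord("r1", g1[:1_000]), SeqRecord("r2", g2[:1_000]),
             SeqRecord("r3", _random_seq(1_000, rng))])
        result = bin_reads(db, reads)
        assigned = [rid for ids in result.bins.values() for rid in ids]
        assert sorted(assigned + result.unclassified_reads
                      + result.host_reads) == ["r1", "r2", "r3"]
        assert result.bins[10] == ["r1"] and result.bins[11] == ["r2"]
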