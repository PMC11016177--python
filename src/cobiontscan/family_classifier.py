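"""Masked k-mer LCA database and family-level read classification.

Reference genomes of the detected cobiont families (plus relatives of the
host) are low-complexity-masked and decomposed into canonical k-mers
(k = 50 by default).  A k-mer observed in more than one family is stored
under the lowest common ancestor of those families.  A read is classified
by tallying the taxon votes of its canonical k-mers and taking the best
root-to-leaf path, Kraken-style; reads whose winning clade attracts fewer
than a configurable fraction of the queried k-mers stay unclassified.

k-mers are packed two bits per base into a pair of 64-bit halves, so all
extraction and database lookup is vectorized; a brute-force string-set
oracle in the test-suite checks the arithmetic independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cobiontscan.sequence_io import ContigSet, SeqRecord, mask_low_complexity
from cobiontscan.taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

DEFAULT_K = 50
DEFAULT_MIN_CONFIDENCE = 0.10

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def canonical_kmer_arrays(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Canonical k-mers of `seq` as (hi, lo) packed halves.

    Returns (hi, lo, n_valid) where hi/lo are uint64 arrays (one entry per
    valid window, in sequence order) and n_valid counts windows free of N.
    The canonical form is the lexicographic minimum of a k-mer and its
    reverse complement, compared as the 2k-bit number (hi, lo).
    """
    if not 4 <= k <= 62:
        raise ValueError("k must lie in [4, 62]")
    c = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = c.size
    m = n - k + 1
    if m <= 0:
        return (np.empty(0, np.uint64), np.empty(0, np.uint64), 0)
    invalid = (c > 3).astype(np.int64)
    bad = np.convolve(invalid, np.ones(k, dtype=np.int64), mode="valid") > 0
    cc = np.where(c > 3, 0, c)
    r = 3 - cc
    k1, k2 = k // 2, k - k // 2
    wbe1 = 4 ** np.arange(k1 - 1, -1, -1, dtype=np.int64)
    wbe2 = 4 ** np.arange(k2 - 1, -1, -1, dtype=np.int64)
    wle1 = 4 ** np.arange(k1, dtype=np.int64)
    wle2 = 4 ** np.arange(k2, dtype=np.int64)
    P1 = sliding_window_view(cc, k1) @ wbe1      # big-endian halves, forward
    P2 = sliding_window_view(cc, k2) @ wbe2
    Q1 = sliding_window_view(r, k1) @ wle1       # little-endian halves, rc
    Q2 = sliding_window_view(r, k2) @ wle2
    f_hi, f_lo = P1[:m], P2[k1:k1 + m]
    r_hi, r_lo = Q1[k2:k2 + m], Q2[:m]
    use_f = (f_hi < r_hi) | ((f_hi == r_hi) & (f_lo <= r_lo))
    hi = np.where(use_f, f_hi, r_hi).astype(np.uint64)
    lo = np.where(use_f, f_lo, r_lo).astype(np.uint64)
    valid = ~bad
    return hi[valid], lo[valid], int(valid.sum())


@dataclass
class ManifestEntry:
    genome_id: str
    family: int
    is_host: bool
    n_kmers: int
    masked_fraction: float


class KmerDatabase:
    """Sorted canonical-k-mer index mapping k-mer -> taxon label."""

    def __init__(self, k: int, tree: TaxonomyTree, hi: np.ndarray,
                 lo: np.ndarray, label_idx: np.ndarray, labels: list[int],
                 host_families: set[int],
                 manifest: list[ManifestEntry]) -> None:
        self.k = k
        self.tree = tree
        self.hi = hi                      # sorted lexicographically (hi, lo)
        self.lo = lo
        self.label_idx = label_idx        # per-kmer index into `labels`
        self.labels = labels              # distinct taxon ids (families + LCAs)
        self.host_families = host_families
        self.manifest = manifest
        # hi values shared by several keys (vanishingly rare for random
        # genomes); queries hitting them fall back to a linear scan
        if hi.size:
            dup = np.zeros(hi.size, dtype=bool)
            dup[1:] |= hi[1:] == hi[:-1]
            dup[:-1] |= hi[1:] == hi[:-1]
            self.dup_hi = np.unique(hi[dup])
        else:
            self.dup_hi = np.empty(0, np.uint64)
        # leaf labels = family-or-host labels reads can be binned to
        self.leaf_labels = sorted(
            {e.family for e in manifest})
        # ancestry matrix: path_mask[i, j] == True iff labels[j] is an
        # ancestor-or-self of leaf_labels[i]; best-path scoring is a matmul.
        self.path_mask = np.zeros((len(self.leaf_labels), len(labels)),
                                  dtype=np.int64)
        for i, leaf in enumerate(self.leaf_labels):
            anc = {n.tax_id for n in tree.lineage(leaf)}
            for j, lab in enumerate(labels):
                if lab in anc:
                    self.path_mask[i, j] = 1

    def __len__(self) -> int:
        return self.hi.size

    def lookup(self, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        """Label index per queried k-mer; -1 where absent from the database."""
        out = np.full(hi.size, -1, dtype=np.int64)
        if hi.size == 0 or self.hi.size == 0:
            return out
        left = np.searchsorted(self.hi, hi, side="left")
        idx = np.clip(left, 0, self.hi.size - 1)
        present = self.hi[idx] == hi
        match = present & (self.lo[idx] == lo)
        out[match] = self.label_idx[idx[match]]
        if self.dup_hi.size:
            maybe = present & ~match & np.isin(hi, self.dup_hi)
            for q in np.flatnonzero(maybe):
                j = left[q]
                while j < self.hi.size and self.hi[j] == hi[q]:
                    if self.lo[j] == lo[q]:
                        out[q] = self.label_idx[j]
                        break
                    j += 1
        return out


def _genome_kmers(record: SeqRecord, k: int, mask: bool,
                  dust_window: int, dust_threshold: float
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    if mask:
        masked = mask_low_complexity(record, dust_window, dust_threshold)
        seq = masked.hard_masked()
        frac = masked.masked_fraction
    else:
        seq, frac = record.seq, 0.0
    hi, lo, _ = canonical_kmer_arrays(seq, k)
    return hi, lo, frac


def build_database(family_genomes: Mapping[int, ContigSet],
                   host_genomes: Mapping[int, ContigSet],
                   tree: TaxonomyTree, *, k: int = DEFAULT_K,
                   mask: bool = True, dust_window: int = 64,
                   dust_threshold: float = 20.0) -> KmerDatabase:
    """Build the masked canonical k-mer LCA database.

    family_genomes / host_genomes map a family tax_id to that family's
    reference genomes; host families are remembered so their reads can be
    reported as HOST rather than as a cobiont bin.  The build is input-order
    independent: k-mers are sorted and label conflicts folded to the LCA.
    """
    if not family_genomes and not host_genomes:
        raise ValueError("database requires at least one genome")
    sources: list[tuple[int, bool, ContigSet]] = (
        [(fam, False, cs) for fam, cs in sorted(family_genomes.items())]
        + [(fam, True, cs) for fam, cs in sorted(host_genomes.items())])
    his, los, labs = [], [], []
    manifest: list[ManifestEntry] = []
    host_families = {fam for fam, is_host, _ in sources if is_host}
    for fam, is_host, contigs in sources:
        for rec in contigs:
            if len(rec) < k:
                raise ValueError(
                    f"genome {rec.id!r} shorter than k={k}")
            hi, lo, frac = _genome_kmers(rec, k, mask, dust_window,
                                         dust_threshold)
            if hi.size == 0:
                logger.warning("genome %s contributed zero k-mers "
                               "(fully masked?)", rec.id)
            his.append(hi)
            los.append(lo)
            labs.append(np.full(hi.size, fam, dtype=np.int64))
            manifest.append(ManifestEntry(rec.id, fam, is_host, int(hi.size),
                                          frac))
    hi = np.concatenate(his)
    lo = np.concatenate(los)
    lab = np.concatenate(labs)
    # sort lexicographically by (hi, lo, label) and collapse duplicates
    order = np.lexsort((lab, lo, hi))
    hi, lo, lab = hi[order], lo[order], lab[order]
    if hi.size:
        new_key = np.empty(hi.size, dtype=bool)
        new_key[0] = True
        new_key[1:] = (hi[1:] != hi[:-1]) | (lo[1:] != lo[:-1])
        starts = np.flatnonzero(new_key)
        ends = np.append(starts[1:], hi.size)
        u_hi, u_lo = hi[starts], lo[starts]
        u_lab = lab[starts].copy()
        lca_cache: dict[tuple[int, ...], int] = {}
        for s, e in zip(starts, ends):
            if e - s > 1:
                taxa = tuple(sorted(set(lab[s:e].tolist())))
                if len(taxa) > 1:
                    if taxa not in lca_cache:
                        lca_cache[taxa] = tree.lca(taxa)
                    u_lab[np.searchsorted(starts, s)] = lca_cache[taxa]
    else:
        u_hi, u_lo, u_lab = hi, lo, lab
    labels = sorted(set(u_lab.tolist()) | {fam for fam, _, _ in sources})
    label_index = {t: i for i, t in enumerate(labels)}
    label_idx = np.array([label_index[t] for t in u_lab.tolist()],
                         dtype=np.int64)
    return KmerDatabase(k, tree, u_hi, u_lo, label_idx, labels,
                        host_families, manifest)


HOST = "HOST"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class ReadClassification:
    read_id: str
    label: str                     # family tax_id as str, HOST, or UNCLASSIFIED
    family: int | None             # set when label is a cobiont family
    raw_label: int | None          # winning taxon (may sit above family rank)
    votes: dict[int, int] = field(default_factory=dict)
    confidence: float = 0.0
    n_kmers: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence outside [0, 1]")
        if sum(self.votes.values()) > self.n_kmers:
            raise ValueError("votes exceed queried k-mers")


def classify_read(db: KmerDatabase, read: SeqRecord,
                  min_confidence: float = DEFAULT_MIN_CONFIDENCE
                  ) -> ReadClassification:
    """Classify one read against the database.

    Votes are tallied over all canonical k-mers; the winning label is the
    leaf (family or host family) with the highest root-to-leaf path vote
    sum.  Ties resolve to the LCA of the tied leaves, which may sit above
    family rank, in which case the read is binned to no family.  Reads
    shorter than k, with zero votes, or with confidence below
    `min_confidence` are UNCLASSIFIED.
    """
    hi, lo, n_valid = canonical_kmer_arrays(read.seq, db.k) \
        if len(read) >= db.k else (np.empty(0, np.uint64),
                                   np.empty(0, np.uint64), 0)
    if n_valid == 0:
        return ReadClassification(read.id, UNCLASSIFIED, None, None, {}, 0.0, 0)
    lab_idx = db.lookup(hi, lo)
    matched = lab_idx[lab_idx >= 0]
    if matched.size == 0:
        return ReadClassification(read.id, UNCLASSIFIED, None, None, {},
                                  0.0, n_valid)
    vote_vec = np.bincount(matched, minlength=len(db.labels))
    votes = {db.labels[i]: int(v) for i, v in enumerate(vote_vec) if v}
    path_scores = db.path_mask @ vote_vec
    best = int(path_scores.max())
    confidence = best / n_valid
    if best == 0 or confidence < min_confidence:
        return ReadClassification(read.id, UNCLASSIFIED, None, None, votes,
                                  confidence, n_valid)
    winners = [db.leaf_labels[i] for i in np.flatnonzero(path_scores == best)]
    raw = winners[0] if len(winners) == 1 else db.tree.lca(winners)
    fam = db.tree.family_of(raw)
    if fam is None:
        # ambiguous above family rank: binned to neither family
        return ReadClassification(read.id, UNCLASSIFIED, None, raw, votes,
                                  confidence, n_valid)
    if fam in db.host_families:
        return ReadClassification(read.id, HOST, None, raw, votes,
                                  confidence, n_valid)
    return ReadClassification(read.id, str(fam), fam, raw, votes,
                              confidence, n_valid)


@dataclass
class BinningResult:
    bins: dict[int, list[str]]          # family tax_id -> read ids
    host_reads: list[str]
    unclassified_reads: list[str]
    classifications: list[ReadClassification]

    def summary(self) -> dict[str, int]:
        out = {f"family_{fam}": len(ids) for fam, ids in sorted(self.bins.items())}
        out["host"] = len(self.host_reads)
        out["unclassified"] = len(self.unclassified_reads)
        return out


def bin_reads(db: KmerDatabase, reads: ContigSet | Iterable[SeqRecord],
              min_confidence: float = DEFAULT_MIN_CONFIDENCE) -> BinningResult:
    """Assign every read to at most one family bin (HOST and UNCLASSIFIED
    are tracked separately)."""
    bins: dict[int, list[str]] = {}
    host: list[str] = []
    unclassified: list[str] = []
    classifications: list[ReadClassification] = []
    for read in reads:
        rc = classify_read(db, read, min_confidence)
        classifications.append(rc)
        if rc.label == HOST:
            host.append(read.id)
        elif rc.family is not None:
            bins.setdefault(rc.family, []).append(read.id)
        else:
            unclassified.append(read.id)
    # families known to the database always appear, even when empty
    for entry in db.manifest:
        if not entry.is_host:
            bins.setdefault(entry.family, [])
    return BinningResult(dict(sorted(bins.items())), host, unclassified,
                         classifications)
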