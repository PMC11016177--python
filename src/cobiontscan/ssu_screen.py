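"""SSU rRNA detection in assembly contigs, retention and redundancy collapse.

Candidate SSU loci are found by seed-and-extend search of a multi-domain
SSU reference panel against both strands of every contig (exact 15-mer
seeds clustered by diagonal, edlib infix extension).  Hits are then put
through the retention rule — aligned length strictly greater than 1,000
nucleotides, OR an alignment score floor standing in for a profile-HMM
e-value cutoff — and the retained SSU sequences are collapsed so that no
two representatives exceed 99% global identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cobiontscan._align import _infix_align, global_identity
from cobiontscan.sequence_io import ContigSet, SeqRecord, revcomp

# Retention defaults: the aligned-length rule is strict ">"; the score rule
# (identity * aligned_length, an approximate match count) is calibrated so
# that a near-exact match of >= ~950 nt passes even when shorter than the
# length threshold.
MIN_ALIGNED = 1000
MIN_SCORE = 950.0

CANDIDATE_MIN_IDENTITY = 0.75
CANDIDATE_MIN_SPAN = 300
SEED_LEN = 15
MIN_SEEDS = 3
BAND_PAD = 120

COLLAPSE_IDENTITY = 0.99


@dataclass
class SSUHit:
    """One detected SSU locus on a contig (0-based half-open coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str                 # '+' or '-'
    aligned_length: int
    identity: float             # vs the named panel reference
    panel_ref_id: str
    retained: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("bad hit coordinates")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")

    @property
    def score(self) -> float:
        """Approximate match count of the alignment."""
        return self.identity * self.aligned_length


def scan_ssu(contigs: ContigSet, panel: ContigSet, *,
             seed_len: int = SEED_LEN,
             min_identity: float = CANDIDATE_MIN_IDENTITY,
             min_span: int = CANDIDATE_MIN_SPAN,
             min_seeds: int = MIN_SEEDS,
             band_pad: int = BAND_PAD) -> list[SSUHit]:
    """Report every candidate SSU locus in the contigs.

    Both strands are searched; identity is measured against the panel
    sequence that seeded the locus (1 - editdist / panel length).  The
    candidate thresholds (identity >= 0.75, span >= 300) deliberately
    over-collect; `retain_hits` applies the publication-grade rule.
    """
    if len(panel) == 0:
        raise ValueError("empty SSU reference panel")
    # seed index over both strands of every panel sequence
    index: dict[str, list[tuple[str, str, int]]] = {}
    panel_seq: dict[tuple[str, str], str] = {}
    for ref in panel:
        for strand, seq in (("+", ref.seq), ("-", revcomp(ref.seq))):
            panel_seq[(ref.id, strand)] = seq
            for qpos in range(len(seq) - seed_len + 1):
                kmer = seq[qpos:qpos + seed_len]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ref.id, strand, qpos))

    hits: list[SSUHit] = []
    for contig in contigs:
        tseq = contig.seq
        # (ref, strand) -> list of (diag, tpos)
        seeds: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for tpos in range(len(tseq) - seed_len + 1):
            entry = index.get(tseq[tpos:tpos + seed_len])
            if not entry:
                continue
            for ref_id, strand, qpos in entry:
                seeds.setdefault((ref_id, strand), []).append(
                    (tpos - qpos, tpos))
        for (ref_id, strand) in sorted(seeds):
            qseq = panel_seq[(ref_id, strand)]
            clusters: list[list[tuple[int, int]]] = []
            for d, tpos in sorted(seeds[(ref_id, strand)]):
                if clusters and abs(d - clusters[-1][-1][0]) <= band_pad:
                    clusters[-1].append((d, tpos))
                else:
                    clusters.append([(d, tpos)])
            for cl in clusters:
                if len(cl) < min_seeds:
                    continue
                d_lo = min(d for d, _ in cl)
                d_hi = max(d for d, _ in cl)
                w0 = max(0, d_lo - band_pad)
                w1 = min(len(tseq), d_hi + len(qseq) + band_pad)
                dist, locations = _infix_align(qseq, tseq[w0:w1])
                if dist < 0 or not locations:
                    continue
                identity = 1.0 - dist / len(qseq)
                if identity < min_identity:
                    continue
                loc_s, loc_e = locations[0]
                start, end = w0 + loc_s, w0 + loc_e + 1
                if end - start < min_span:
                    continue
                hits.append(SSUHit(contig.id, start, end, strand,
                                   end - start, identity, ref_id))
    hits.sort(key=lambda h: (h.contig_id, h.start, h.end,
                             -h.identity, h.panel_ref_id))
    return hits


def retain_hits(hits: list[SSUHit], min_aligned: int = MIN_ALIGNED,
                min_score: float = MIN_SCORE) -> list[SSUHit]:
    """Flag hits that satisfy the retention rule; nothing is deleted.

    A hit is retained iff aligned_length > min_aligned (strict, so a hit of
    exactly 1,000 nt with a sub-threshold score is rejected) OR its
    alignment score reaches min_score.
    """
    for h in hits:
        h.retained = h.aligned_length > min_aligned or h.score >= min_score
    return hits


def best_hit_per_locus(hits: list[SSUHit]) -> list[SSUHit]:
    """Collapse hits of the same contig locus to the best panel match.

    Hits on one contig whose intervals overlap by more than half of the
    shorter interval describe the same locus; the hit with the highest
    identity (ties: longer span, then panel ref id) represents it.
    """
    best: list[SSUHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity, -h.aligned_length,
                                         h.panel_ref_id, h.contig_id, h.start)):
        clashes = False
        for kept in best:
            if kept.contig_id != h.contig_id:
                continue
            ov = min(kept.end, h.end) - max(kept.start, h.start)
            if ov > 0.5 * min(kept.end - kept.start, h.end - h.start):
                clashes = True
                break
        if not clashes:
            best.append(h)
    best.sort(key=lambda h: (h.contig_id, h.start))
    return best


def extract_ssu_sequences(contigs: ContigSet, hits: list[SSUHit]
                          ) -> list[SeqRecord]:
    """Extract strand-normalized SSU sequences for the given hits."""
    out = []
    for h in hits:
        seq = contigs[h.contig_id].seq[h.start:h.end]
        if h.strand == "-":
            seq = revcomp(seq)
        out.append(SeqRecord(f"{h.contig_id}:{h.start}-{h.end}{h.strand}", seq))
    return out


@dataclass
class SSUSet:
    """All SSU hits plus the non-redundant representative sequences."""

    hits: list[SSUHit]
    representatives: list[SeqRecord]
    clusters: dict[str, list[str]] = field(default_factory=dict)


def collapse_redundant(seqs: list[SeqRecord],
                       identity_threshold: float = COLLAPSE_IDENTITY,
                       hits: list[SSUHit] | None = None) -> SSUSet:
    """Greedy longest-first clustering at the given global identity.

    Sequences are visited longest first (ties broken lexicographically by
    id); a sequence joins the first existing representative whose global
    identity with it exceeds the threshold, else founds a new cluster.  The
    resulting representatives are pairwise <= threshold identical.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity threshold must lie in (0.5, 1.0]")
    reps: list[SeqRecord] = []
    clusters: dict[str, list[str]] = {}
    for seq in sorted(seqs, key=lambda s: (-len(s), s.id)):
        home = None
        for rep in reps:
            if global_identity(seq.seq, rep.seq) > identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(seq)
            clusters[seq.id] = [seq.id]
        else:
            clusters[home.id].append(seq.id)
    return SSUSet(hits or [], reps, clusters)
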