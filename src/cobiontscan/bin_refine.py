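"""Contig retention filters for each family bin.

A contig survives in a cobiont family's bin only when (a) the family's
classified reads cover it end to end — the guard against binning host
chromosome pieces that merely carry a horizontally transferred insertion —
and (b) it shows direct evidence of belonging to the family: a single-copy
marker gene from the clade panel, or sufficient alignment breadth against
a family reference genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from cobiontscan._align import _infix_align, query_breadth_in_target
from cobiontscan.sequence_io import ContigSet, SeqRecord, revcomp

logger = logging.getLogger(__name__)

ANCHOR_K = 31
END_TOLERANCE = 25      # bp of slack at each contig terminus
MARKER_MIN_IDENTITY = 0.90
MARKER_MIN_COV = 0.80
SIMILARITY_MIN_IDENTITY = 0.90
SIMILARITY_MIN_BREADTH = 0.50


@dataclass
class CoverageProfile:
    """Per-base depth of a contig under one bin's classified reads."""

    contig_id: str
    depth: np.ndarray
    n_reads_placed: int

    @property
    def breadth(self) -> float:
        if self.depth.size == 0:
            return 0.0
        return float((self.depth > 0).mean())

    def fully_covered(self, end_tolerance: int = END_TOLERANCE) -> bool:
        """Breadth 1.0 up to `end_tolerance` bp of slack at each terminus
        (reads cannot overhang contig ends)."""
        n = self.depth.size
        lo = min(end_tolerance, n)
        hi = max(lo, n - end_tolerance)
        core = self.depth[lo:hi]
        if core.size == 0:
            return bool((self.depth > 0).any())
        return bool((core > 0).all())


def _place_read(contig_bytes: np.ndarray, index: dict[str, int],
                read_seq: str, anchor_k: int, stride: int
                ) -> tuple[int, int] | None:
    """Best exact placement of a read on the contig.

    Finds an exact anchor k-mer shared by read and contig (either read
    orientation), then extends the exact match outward.  Returns the
    covered contig interval, or None when the read has no anchor.
    """
    n_contig = contig_bytes.size
    for oriented in (read_seq, revcomp(read_seq)):
        anchor = None
        limit = len(oriented) - anchor_k
        positions = list(range(0, limit + 1, stride))
        if positions and positions[-1] != limit:
            positions.append(limit)
        for rpos in positions:
            cpos = index.get(oriented[rpos:rpos + anchor_k])
            if cpos is not None:
                anchor = (rpos, cpos)
                break
        if anchor is None:
            continue
        rpos, cpos = anchor
        rbytes = np.frombuffer(oriented.encode(), dtype=np.uint8)
        # extend right from the anchor end
        i, j = rpos + anchor_k, cpos + anchor_k
        span = min(rbytes.size - i, n_contig - j)
        if span > 0:
            neq = rbytes[i:i + span] != contig_bytes[j:j + span]
            ext = int(np.argmax(neq)) if neq.any() else span
        else:
            ext = 0
        right = j + ext
        # extend left from the anchor start
        span = min(rpos, cpos)
        if span > 0:
            a = rbytes[rpos - span:rpos][::-1]
            b = contig_bytes[cpos - span:cpos][::-1]
            neq = a != b
            ext = int(np.argmax(neq)) if neq.any() else span
        else:
            ext = 0
        left = cpos - ext
        return left, right
    return None


def coverage_profile(contig: SeqRecord, bin_reads: ContigSet,
                     anchor_k: int = ANCHOR_K, stride: int = 16
                     ) -> CoverageProfile:
    """Depth profile of `contig` under the bin's reads.

    Each read is placed at its best location by exact-seed anchoring and
    maximal exact extension; deterministic for fixed inputs.  Reads sharing
    no anchor k-mer with the contig (e.g. reads of another species) simply
    do not contribute.
    """
    n = len(contig)
    index: dict[str, int] = {}
    seq = contig.seq
    for i in range(n - anchor_k + 1):
        kmer = seq[i:i + anchor_k]
        if "N" not in kmer and kmer not in index:
            index[kmer] = i
    contig_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)
    diff = np.zeros(n + 1, dtype=np.int64)
    placed = 0
    for read in bin_reads:
        interval = _place_read(contig_bytes, index, read.seq, anchor_k, stride)
        if interval is None:
            continue
        left, right = interval
        diff[max(0, left)] += 1
        diff[min(n, right)] -= 1
        placed += 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(contig.id, depth, placed)


def _marker_present(contig_seq: str, contig_rc: str, marker: SeqRecord,
                    min_identity: float, min_cov: float) -> bool:
    candidates = [marker.seq]
    t = int(len(marker) * min_cov)
    if 0 < t < len(marker):
        candidates += [marker.seq[:t], marker.seq[-t:]]
    for cand in candidates:
        if len(cand) > len(contig_seq):
            continue
        for target in (contig_seq, contig_rc):
            dist, _ = _infix_align(cand, target)
            if dist >= 0 and 1.0 - dist / len(cand) >= min_identity:
                return True
    return False


def find_markers(contig: SeqRecord, marker_panel: list[SeqRecord],
                 min_identity: float = MARKER_MIN_IDENTITY,
                 min_cov: float = MARKER_MIN_COV) -> bool:
    """True iff any panel marker aligns to the contig at >= min_identity
    over >= min_cov of the marker's length (either strand)."""
    if not marker_panel:
        logger.warning("empty marker panel for contig %s", contig.id)
        return False
    rc = revcomp(contig.seq)
    return any(_marker_present(contig.seq, rc, m, min_identity, min_cov)
               for m in marker_panel)


def marker_presence_table(contigs: ContigSet, marker_panel: list[SeqRecord],
                          min_identity: float = MARKER_MIN_IDENTITY,
                          min_cov: float = MARKER_MIN_COV
                          ) -> dict[str, list[str]]:
    """marker id -> ids of contigs containing it (used for completeness)."""
    table: dict[str, list[str]] = {m.id: [] for m in marker_panel}
    cache = {c.id: (c.seq, revcomp(c.seq)) for c in contigs}
    for m in marker_panel:
        for cid, (fwd, rc) in cache.items():
            if _marker_present(fwd, rc, m, min_identity, min_cov):
                table[m.id].append(cid)
    return table


def reference_similarity(contig: SeqRecord, family_refs: ContigSet,
                         min_identity: float = SIMILARITY_MIN_IDENTITY,
                         min_breadth: float = SIMILARITY_MIN_BREADTH) -> bool:
    """True iff alignments to any single family reference cover at least
    `min_breadth` of the contig at >= `min_identity`.  An empty reference
    set (novel family) yields False."""
    if len(contig) == 0:
        return False
    for ref in family_refs:
        breadth = query_breadth_in_target(contig.seq, ref.seq,
                                          min_identity=min_identity)
        if breadth >= min_breadth:
            return True
    return False


@dataclass
class RetentionDecision:
    contig_id: str
    fully_covered: bool
    has_marker: bool
    similar_to_reference: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return self.fully_covered and (self.has_marker
                                       or self.similar_to_reference)


def refine_bin(bin_contigs: ContigSet, bin_reads: ContigSet,
               marker_panel: list[SeqRecord], family_refs: ContigSet,
               *, end_tolerance: int = END_TOLERANCE,
               marker_min_identity: float = MARKER_MIN_IDENTITY,
               marker_min_cov: float = MARKER_MIN_COV,
               similarity_min_identity: float = SIMILARITY_MIN_IDENTITY,
               similarity_min_breadth: float = SIMILARITY_MIN_BREADTH
               ) -> tuple[ContigSet, list[RetentionDecision],
                          list[CoverageProfile]]:
    """Apply the retention rule to every candidate contig of one bin."""
    if len(bin_contigs) == 0:
        raise ValueError("refine_bin requires a non-empty candidate set")
    retained = ContigSet()
    decisions: list[RetentionDecision] = []
    profiles: list[CoverageProfile] = []
    for contig in bin_contigs:
        profile = coverage_profile(contig, bin_reads)
        profiles.append(profile)
        covered = profile.fully_covered(end_tolerance)
        has_marker = find_markers(contig, marker_panel,
                                  marker_min_identity, marker_min_cov)
        similar = reference_similarity(contig, family_refs,
                                       similarity_min_identity,
                                       similarity_min_breadth)
        reasons = []
        if not covered:
            reasons.append(f"breadth {profile.breadth:.4f} < full coverage")
        if not has_marker:
            reasons.append("no marker gene")
        if not similar:
            reasons.append("insufficient reference similarity")
        decision = RetentionDecision(contig.id, covered, has_marker,
                                     similar, reasons)
        decisions.append(decision)
        if decision.retained:
            retained.add(contig)
    return retained, decisions, profiles
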