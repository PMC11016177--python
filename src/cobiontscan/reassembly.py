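"""Greedy overlap reassembly of family read bins and circularity detection.

With near-exact long reads, a bin reassembles by iteratively merging the
pair of sequences with the longest exact suffix-prefix overlap above a
floor (default 500 bp).  The result is deterministic under the tie-break
(longest overlap first, then lexicographic read id).  Contigs whose ends
overlap themselves are reported circular and trimmed of the duplicated
copy, mirroring the recovery of complete circular endosymbiont genomes.
Repeats longer than the overlap floor can fragment assemblies; a hook for
an external assembler exists at the pipeline level for real data.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from cobiontscan._align import global_identity
from cobiontscan.sequence_io import ContigSet, SeqRecord

MIN_OVERLAP = 500
_SEED = 32  # exact anchor used to locate candidate overlaps


@dataclass
class AssemblyResult:
    contigs: ContigSet
    topology: dict[str, str]                  # contig id -> linear|circular
    constituents: dict[str, list[str]] = field(default_factory=dict)


def detect_circularity(contig: SeqRecord, min_overlap: int = MIN_OVERLAP,
                       min_identity: float = 1.0
                       ) -> tuple[bool, SeqRecord]:
    """Detect a suffix-prefix self-overlap and trim the duplicated copy.

    Exact overlaps are found by scanning occurrences of the leading
    `_SEED`-mer in the tail half of the sequence; with min_identity < 1 a
    near-exact overlap is additionally accepted when the global identity of
    the overlapping copies reaches the threshold.  The trimmed sequence
    keeps one copy of the overlap; the longest qualifying overlap wins.
    """
    seq = contig.seq
    n = len(seq)
    if n <= 2 * min_overlap:
        return False, contig
    seed = seq[:_SEED]
    best_o = 0
    p = seq.find(seed, n // 2)
    while p != -1:
        o = n - p
        if o >= min_overlap and seq[p:] == seq[:o]:
            best_o = max(best_o, o)
        p = seq.find(seed, p + 1)
    if best_o == 0 and min_identity < 1.0:
        # near-exact path: compare the terminal window against the head
        o = min_overlap
        if global_identity(seq[n - o:], seq[:o]) >= min_identity:
            best_o = o
    if best_o == 0:
        return False, contig
    trimmed = SeqRecord(contig.id, seq[:n - best_o])
    return True, trimmed


def _remove_contained(reads: list[SeqRecord]) -> list[SeqRecord]:
    """Drop reads fully contained in a longer (or identical earlier) read."""
    by_size = sorted(reads, key=lambda r: (-len(r), r.id))
    kept: list[SeqRecord] = []
    for r in by_size:
        if any(r.seq in k.seq for k in kept):
            continue
        kept.append(r)
    kept.sort(key=lambda r: r.id)
    return kept


def _overlap_candidates(reads: list[SeqRecord], min_overlap: int
                        ) -> list[tuple[int, str, str]]:
    """All exact suffix(A)-prefix(B) overlaps >= min_overlap as
    (overlap, a_id, b_id); one entry per pair (the longest)."""
    prefix_index: dict[str, list[SeqRecord]] = {}
    for r in reads:
        if len(r) >= _SEED:
            prefix_index.setdefault(r.seq[:_SEED], []).append(r)
    best: dict[tuple[str, str], int] = {}
    for a in reads:
        seq = a.seq
        for p in range(0, len(seq) - min_overlap + 1):
            for b in prefix_index.get(seq[p:p + _SEED], ()):
                if b.id == a.id:
                    continue
                o = len(seq) - p
                if o > len(b):
                    continue  # would imply containment, handled already
                if seq[p:] == b.seq[:o]:
                    key = (a.id, b.id)
                    if o > best.get(key, 0):
                        best[key] = o
    return [(o, a, b) for (a, b), o in best.items()]


def greedy_assemble(reads: ContigSet, min_overlap: int = MIN_OVERLAP
                    ) -> AssemblyResult:
    """Merge reads by longest exact suffix-prefix overlap until none remain.

    Containment-removed reads seed one contig each; a heap of candidate
    overlaps is consumed best-first ((overlap desc, a_id, b_id) ordering).
    A self-overlap popped for an already-closed chain marks a candidate
    circular contig, verified and trimmed by `detect_circularity`.
    """
    kept = _remove_contained(list(reads))
    overlaps = _overlap_candidates(kept, min_overlap)
    heap = [(-o, a, b) for o, a, b in overlaps]
    heapq.heapify(heap)

    seqs = {r.id: r.seq for r in kept}
    members: dict[str, list[str]] = {r.id: [r.id] for r in kept}
    head_contig = {r.id: r.id for r in kept}   # head read -> contig key
    tail_contig = {r.id: r.id for r in kept}   # tail read -> contig key
    contig_head = {r.id: r.id for r in kept}
    contig_tail = {r.id: r.id for r in kept}

    while heap:
        neg_o, a_id, b_id = heapq.heappop(heap)
        o = -neg_o
        ca = tail_contig.get(a_id)
        cb = head_contig.get(b_id)
        if ca is None or cb is None:
            continue
        if ca == cb:
            continue  # closing a circle: left for detect_circularity
        seqs[ca] = seqs[ca] + seqs[cb][o:]
        members[ca].extend(members[cb])
        new_tail = contig_tail[cb]
        del tail_contig[a_id]
        del head_contig[b_id]
        del seqs[cb], members[cb]
        contig_tail[ca] = new_tail
        tail_contig[new_tail] = ca
        del contig_head[cb], contig_tail[cb]

    pieces = sorted(seqs.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    contigs = ContigSet()
    topology: dict[str, str] = {}
    constituents: dict[str, list[str]] = {}
    for i, (key, seq) in enumerate(pieces):
        name = f"reasm_{i:04d}"
        rec, topo = SeqRecord(name, seq), "linear"
        circular, trimmed = detect_circularity(rec, min_overlap)
        if circular:
            rec, topo = trimmed, "circular"
        contigs.add(rec)
        topology[name] = topo
        constituents[name] = members[key]
    return AssemblyResult(contigs, topology, constituents)


def filter_reassembly(result: AssemblyResult, marker_panel: list[SeqRecord],
                      family_refs: ContigSet, **thresholds) -> ContigSet:
    """Keep reassembled contigs with a marker gene or reference similarity."""
    from cobiontscan.bin_refine import find_markers, reference_similarity

    marker_kw = {k: thresholds[k] for k in ("min_identity", "min_cov")
                 if k in thresholds}
    sim_kw = {}
    if "similarity_min_identity" in thresholds:
        sim_kw["min_identity"] = thresholds["similarity_min_identity"]
    if "similarity_min_breadth" in thresholds:
        sim_kw["min_breadth"] = thresholds["similarity_min_breadth"]
    retained = ContigSet()
    for contig in result.contigs:
        if (marker_panel and find_markers(contig, marker_panel, **marker_kw)) \
                or reference_similarity(contig, family_refs, **sim_kw):
            retained.add(contig)
    return retained
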