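"""Sequence containers, FASTA/FASTQ I/O and low-complexity (SDUST) masking.

All coordinates everywhere in this package are 0-based, half-open.
Sequences are stored uppercase; any character outside {A, C, G, T, N} is
converted to N on load.  N never contributes a k-mer anywhere downstream.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map every non-ACGTN code (IUPAC ambiguity etc.) to N."""
    return _NON_ACGTN.sub("N", seq.upper())


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with per-base qualities.

    Qualities are carried through FASTQ round-trips but ignored by all
    downstream computation (reads are treated as high-accuracy).
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = normalize_seq(self.seq)
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"quality length mismatch for {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(self.id, revcomp(self.seq), None)


class ContigSet:
    """An ordered collection of SeqRecords with unique ids."""

    def __init__(self, records: Iterable[SeqRecord] = ()) -> None:
        self._records: dict[str, SeqRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SeqRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self._records.values())

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._records

    def __getitem__(self, rec_id: str) -> SeqRecord:
        return self._records[rec_id]

    def ids(self) -> list[str]:
        return list(self._records)

    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self}

    def total_span(self) -> int:
        return sum(len(r) for r in self)

    def subset(self, ids: Iterable[str]) -> "ContigSet":
        return ContigSet(self._records[i] for i in ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContigSet):
            return NotImplemented
        return [(r.id, r.seq) for r in self] == [(r.id, r.seq) for r in other]


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    return "fasta"


def read_fasta(path: str | Path) -> ContigSet:
    """Read FASTA or FASTQ (optionally gzipped) into a ContigSet.

    Order is preserved; duplicate ids and empty files raise ValueError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path)
    contigs = ContigSet()
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if not first:
            raise ValueError(f"empty sequence file: {path}")
        if fmt == "fasta" and first != ">":
            raise ValueError(f"malformed FASTA (does not start with '>'): {path}")
        fh.seek(0)
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                phred = rec.letter_annotations.get("phred_quality")
                if phred is not None:
                    qual = (np.asarray(phred, dtype=np.uint8) + 33) \
                        .tobytes().decode("ascii")
            contigs.add(SeqRecord(rec.id, str(rec.seq), qual))
    if len(contigs) == 0:
        raise ValueError(f"no sequences parsed from {path}")
    return contigs


def write_fasta(records: ContigSet | Iterable[SeqRecord], path: str | Path,
                width: int = 60) -> Path:
    """Write records as (optionally gzipped) FASTA with 60-column wrapping."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty sequence set")
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
    return path


def write_fastq(records: ContigSet | Iterable[SeqRecord], path: str | Path) -> Path:
    """Write records as (optionally gzipped) FASTQ; missing quals become 'I'."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty sequence set")
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
    return path


# --- SDUST low-complexity masking -----------------------------------------

@dataclass
class MaskedSeq:
    """A sequence with sorted, non-overlapping low-complexity intervals."""

    source: SeqRecord
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.source)
        prev_end = 0
        for start, end in self.mask_intervals:
            if not (0 <= start < end <= n):
                raise ValueError(f"mask interval ({start},{end}) outside [0,{n})")
            if start < prev_end:
                raise ValueError("mask intervals overlap or are unsorted")
            prev_end = end

    @property
    def masked_fraction(self) -> float:
        return sum(e - s for s, e in self.mask_intervals) / len(self.source)

    def hard_masked(self) -> str:
        """Sequence with masked intervals replaced by N."""
        seq = list(self.source.seq)
        for s, e in self.mask_intervals:
            seq[s:e] = "N" * (e - s)
        return "".join(seq)

    def soft_masked(self) -> str:
        seq = list(self.source.seq)
        for s, e in self.mask_intervals:
            seq[s:e] = self.source.seq[s:e].lower()
        return "".join(seq)


_TRI_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _window_dust_score(seq: str, start: int, end: int) -> float:
    """Symmetric-DUST score of one window, from scratch (oracle-grade).

    Score is 10 * sum_t c_t*(c_t-1)/2 / (k-1) over triplet counts c_t, where
    k is the number of ACGT-only triplets in the window.  Triplets containing
    N are excluded, so hard-masked runs never raise the score.
    """
    counts: dict[int, int] = {}
    k = 0
    for i in range(start, end - 2):
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        if a == "N" or b == "N" or c == "N":
            continue
        t = (_TRI_CODE[a] << 4) | (_TRI_CODE[b] << 2) | _TRI_CODE[c]
        counts[t] = counts.get(t, 0) + 1
        k += 1
    if k < 2:
        return 0.0
    raw = sum(c * (c - 1) // 2 for c in counts.values())
    return 10.0 * raw / (k - 1)


def mask_low_complexity(record: SeqRecord, window: int = 64,
                        score_threshold: float = 20.0) -> MaskedSeq:
    """Flag low-complexity regions with a symmetric-DUST windowed score.

    A position is masked iff it lies inside at least one length-`window`
    window whose DUST score exceeds `score_threshold`; the mask is the union
    of all high-scoring windows.  Triplet counts roll across windows, so the
    scan is O(n); `_window_dust_score` recomputes any window from scratch and
    serves as the exhaustive oracle in tests.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    seq = record.seq
    n = len(seq)
    if n < window:
        logger.warning("sequence %s shorter than DUST window; empty mask", record.id)
        return MaskedSeq(record, [])

    counts = [0] * 64
    k = 0          # ACGT-only triplets in current window
    raw = 0        # sum c*(c-1)/2, maintained incrementally
    flagged: list[bool] = [False] * (n - window + 1)

    def triplet(i: int) -> int | None:
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        if a == "N" or b == "N" or c == "N":
            return None
        return (_TRI_CODE[a] << 4) | (_TRI_CODE[b] << 2) | _TRI_CODE[c]

    # initial window [0, window): triplets start at 0 .. window-3
    for i in range(window - 2):
        t = triplet(i)
        if t is not None:
            raw += counts[t]
            counts[t] += 1
            k += 1
    for w0 in range(n - window + 1):
        if k >= 2 and 10.0 * raw / (k - 1) > score_threshold:
            flagged[w0] = True
        # roll: drop triplet at w0, add triplet at w0+window-2
        t_out = triplet(w0)
        if t_out is not None:
            counts[t_out] -= 1
            raw -= counts[t_out]
            k -= 1
        i_in = w0 + window - 2
        if i_in <= n - 3:
            t_in = triplet(i_in)
            if t_in is not None:
                raw += counts[t_in]
                counts[t_in] += 1
                k += 1

    intervals: list[tuple[int, int]] = []
    for w0, hit in enumerate(flagged):
        if not hit:
            continue
        s, e = w0, w0 + window
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], e)
        else:
            intervals.append((s, e))
    return MaskedSeq(record, intervals)


def write_bed(masked: MaskedSeq, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s, e in masked.mask_intervals:
            fh.write(f"{masked.source.id}\t{s}\t{e}\n")
    return path
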