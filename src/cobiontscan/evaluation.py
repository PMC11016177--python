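"""Bin scoring against truth: length-normalized precision/recall/F1,
assembly span and N50, and a marker-based completeness proxy.

Precision and recall are base-weighted: a contig contributes its length,
so one long mis-binned contig costs more than many short ones.  F1 is
(2 x precision x recall) / (precision + recall), zero when both are zero.
Completeness counts each panel marker as missing, single or duplicated
across the bin's contigs (fragmented markers count as missing in this
nucleotide-level proxy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

from cobiontscan.bin_refine import (MARKER_MIN_COV, MARKER_MIN_IDENTITY,
                                    marker_presence_table)
from cobiontscan.sequence_io import ContigSet, SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from cobiontscan.synthetic_community import TruthTable


def length_weighted_prf(bin_contigs: ContigSet, truth: "TruthTable",
                        family: str) -> tuple[float, float, float]:
    """Length-normalized precision, recall and F1 of a family bin.

    precision = correctly assigned bases / total bases in the bin (0 for an
    empty bin, by convention); recall = correctly assigned bases / total
    truth bases of the family.  Raises when the family has no truth contigs.
    """
    truth_bases = sum(ct.length for ct in truth.contigs.values()
                      if ct.family == family)
    if truth_bases == 0:
        raise ValueError(f"family {family!r} absent from the contig truth")
    bin_bases = 0
    correct = 0
    for contig in bin_contigs:
        bin_bases += len(contig)
        ct = truth.contigs.get(contig.id)
        if ct is not None and ct.family == family:
            correct += len(contig)
    precision = correct / bin_bases if bin_bases else 0.0
    recall = correct / truth_bases
    f1 = f1_score(precision, recall)
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def n50(contigs: ContigSet | Iterable[SeqRecord] | Iterable[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the span."""
    lengths = sorted((x if isinstance(x, int) else len(x) for x in contigs),
                     reverse=True)
    if not lengths:
        raise ValueError("N50 of an empty contig set")
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    return lengths[-1]  # unreachable


@dataclass
class CompletenessCounts:
    single: int
    duplicated: int
    missing: int

    @property
    def panel_size(self) -> int:
        return self.single + self.duplicated + self.missing

    @property
    def fractions(self) -> tuple[float, float, float]:
        n = self.panel_size
        if n == 0:
            return (0.0, 0.0, 0.0)
        return (self.single / n, self.duplicated / n, self.missing / n)

    @property
    def complete_fraction(self) -> float:
        n = self.panel_size
        return (self.single + self.duplicated) / n if n else 0.0


def completeness_proxy(contigs: ContigSet, marker_panel: list[SeqRecord],
                       min_identity: float = MARKER_MIN_IDENTITY,
                       min_cov: float = MARKER_MIN_COV) -> CompletenessCounts:
    """Count panel markers found zero / one / multiple times in the bin."""
    if not marker_panel:
        raise ValueError("completeness requires a non-empty marker panel")
    single = duplicated = missing = 0
    if len(contigs) == 0:
        return CompletenessCounts(0, 0, len(marker_panel))
    table = marker_presence_table(contigs, marker_panel, min_identity, min_cov)
    for marker in marker_panel:
        hits = len(table[marker.id])
        if hits == 0:
            missing += 1
        elif hits == 1:
            single += 1
        else:
            duplicated += 1
    return CompletenessCounts(single, duplicated, missing)


@dataclass
class BinAssessment:
    """Evaluation record of one family bin."""

    family: str
    precision: float
    recall: float
    f1: float
    span: int
    n50: int
    completeness: CompletenessCounts
    reassembly_span: int = 0
    reassembly_n50: int = 0
    n_circular: int = 0

    def __post_init__(self) -> None:
        expected = f1_score(self.precision, self.recall)
        if abs(self.f1 - expected) > 1e-9:
            raise ValueError("f1 inconsistent with precision/recall")
        if self.n50 > self.span:
            raise ValueError("n50 exceeds span")

    def row(self) -> list[str]:
        s, d, m = self.completeness.fractions
        return [self.family, f"{self.precision:.6f}", f"{self.recall:.6f}",
                f"{self.f1:.6f}", str(self.span), str(self.n50),
                f"{s:.4f}", f"{d:.4f}", f"{m:.4f}",
                str(self.reassembly_span), str(self.reassembly_n50),
                str(self.n_circular)]

    HEADER = ["family", "precision", "recall", "f1", "span", "n50",
              "markers_single", "markers_duplicated", "markers_missing",
              "reassembly_span", "reassembly_n50", "n_circular"]


def assess_bin(family: str, retained: ContigSet, truth: "TruthTable",
               marker_panel: list[SeqRecord],
               reassembly: ContigSet | None = None,
               topology: dict[str, str] | None = None) -> BinAssessment:
    """Score one refined family bin against truth labels."""
    precision, recall, f1 = length_weighted_prf(retained, truth, family)
    span = retained.total_span()
    bin_n50 = n50(retained) if len(retained) else 0
    completeness = (completeness_proxy(retained, marker_panel)
                    if marker_panel else CompletenessCounts(0, 0, 0))
    re_span = re_n50 = n_circ = 0
    if reassembly is not None and len(reassembly):
        re_span = reassembly.total_span()
        re_n50 = n50(reassembly)
        if topology:
            n_circ = sum(1 for c in reassembly
                         if topology.get(c.id) == "circular")
    return BinAssessment(family, precision, recall, f1, span, bin_n50,
                         completeness, re_span, re_n50, n_circ)
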