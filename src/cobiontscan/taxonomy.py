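"""Rank-aware taxonomy with dual label systems and the family consensus rule.

A single harmonized node set carries two label systems (an NCBI-style
numeric one and a SILVA-style path-string one) mapped onto the same nodes
via a synonym table.  SSU classification assigns a family by a consensus
vote: hits above a nucleotide-identity floor are sorted, the top N are
considered, and a family is called only when a sufficient fraction of the
considered hits agree on one harmonized family node under both systems.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

UNASSIGNED = None

#: Default thresholds for the consensus family call: hits must exceed 90%
#: nucleotide identity; up to the 20 best hits vote; 80% concordance
#: (equality passes, i.e. 16 of 20) is required for an assignment.
MIN_IDENTITY = 0.90
TOP_N = 20
CONCORDANCE = 0.80


@dataclass(frozen=True)
class TaxNode:
    tax_id: int
    name: str
    rank: str
    parent: int  # parent == tax_id marks the root


class TaxonomyTree:
    """Node graph with rank lookup and synonym-based label resolution."""

    def __init__(self) -> None:
        self.nodes: dict[int, TaxNode] = {}
        self._by_name: dict[str, int] = {}
        # (system, label) -> tax_id
        self.synonyms: dict[tuple[str, str], int] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, tax_id: int, name: str, rank: str, parent: int) -> None:
        if tax_id in self.nodes:
            raise ValueError(f"duplicate tax_id {tax_id}")
        self.nodes[tax_id] = TaxNode(tax_id, name, rank, parent)
        self._by_name[name] = tax_id

    def add_synonym(self, system: str, label: str, tax_id: int) -> None:
        if tax_id not in self.nodes:
            raise KeyError(f"unknown tax_id {tax_id} for synonym {label!r}")
        self.synonyms[(system, label)] = tax_id

    @property
    def root(self) -> int:
        for node in self.nodes.values():
            if node.parent == node.tax_id:
                return node.tax_id
        raise ValueError("taxonomy has no root")

    # -- lookup ------------------------------------------------------------
    def resolve(self, label: str, system: str | None = None) -> int | None:
        """Resolve a label (taxid string, node name, or synonym) to a node.

        Returns None when the label is unresolvable in the given system.
        """
        if label is None:
            return None
        label = str(label).strip()
        if not label or label.upper() in {"NA", "NONE", ""}:
            return None
        if system is not None:
            hit = self.synonyms.get((system, label))
            if hit is not None:
                return hit
        if label.lstrip("-").isdigit() and int(label) in self.nodes:
            return int(label)
        return self._by_name.get(label)

    def lineage(self, tax_id: int) -> list[TaxNode]:
        """Path from the root down to tax_id (inclusive)."""
        if tax_id not in self.nodes:
            raise KeyError(f"unknown taxon {tax_id}")
        path = []
        cur = tax_id
        seen = set()
        while True:
            if cur in seen:
                raise ValueError(f"taxonomy cycle at {cur}")
            seen.add(cur)
            node = self.nodes[cur]
            path.append(node)
            if node.parent == cur:
                break
            cur = node.parent
        return path[::-1]

    def rank_ancestor(self, tax_id: int, rank: str) -> int | None:
        """Ancestor-or-self of the given rank, or None when the lineage
        skips that rank (absence, not an error)."""
        for node in self.lineage(tax_id):
            if node.rank == rank:
                return node.tax_id
        return None

    def family_of(self, tax_id: int) -> int | None:
        return self.rank_ancestor(tax_id, "family")

    def depth(self, tax_id: int) -> int:
        return len(self.lineage(tax_id)) - 1

    def is_ancestor(self, anc: int, tax_id: int) -> bool:
        return any(n.tax_id == anc for n in self.lineage(tax_id))

    def lca(self, taxa: Iterable[int]) -> int:
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of empty taxon set")
        common: list[int] | None = None
        for t in taxa:
            path = [n.tax_id for n in self.lineage(t)]
            if common is None:
                common = path
            else:
                shared = []
                for a, b in zip(common, path):
                    if a != b:
                        break
                    shared.append(a)
                common = shared
        assert common
        return common[-1]

    # -- persistence -------------------------------------------------------
    def to_tsv(self, nodes_path: str | Path, synonyms_path: str | Path) -> None:
        with open(nodes_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["tax_id", "name", "rank", "parent"])
            for tid in sorted(self.nodes):
                n = self.nodes[tid]
                w.writerow([n.tax_id, n.name, n.rank, n.parent])
        with open(synonyms_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["system", "label", "tax_id"])
            for (system, label), tid in sorted(self.synonyms.items()):
                w.writerow([system, label, tid])

    @classmethod
    def from_tsv(cls, nodes_path: str | Path,
                 synonyms_path: str | Path | None = None) -> "TaxonomyTree":
        tree = cls()
        with open(nodes_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                tree.add_node(int(row["tax_id"]), row["name"], row["rank"],
                              int(row["parent"]))
        if synonyms_path is not None and Path(synonyms_path).exists():
            with open(synonyms_path) as fh:
                reader = csv.DictReader(fh, delimiter="\t")
                for row in reader:
                    tree.add_synonym(row["system"], row["label"],
                                     int(row["tax_id"]))
        return tree


@dataclass
class ClassificationCall:
    """Family assignment of one SSU representative."""

    ssu_id: str
    family: int | None            # harmonized family tax_id, or None
    support: float                # fraction of considered hits agreeing
    n_hits_considered: int
    table: list[tuple[str, float, int | None]] = field(default_factory=list)
    # rows: (ref_id, identity, per-hit harmonized family or None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 1.0:
            raise ValueError("support must lie in [0, 1]")
        if self.family is not None and self.n_hits_considered < 1:
            raise ValueError("assigned call requires at least one hit")


def _hit_family(tree: TaxonomyTree, labels: Mapping[str, str]) -> int | None:
    """Harmonized family of one hit given its per-system labels.

    A hit counts toward a family only when every system in which its label
    resolves maps it to the same harmonized family node; disagreement or
    total unresolvability yields None.
    """
    families = []
    for system, label in labels.items():
        tid = tree.resolve(label, system)
        if tid is None:
            continue
        families.append(tree.family_of(tid))
    families = [f for f in families if f is not None]
    if not families:
        return None
    if any(f != families[0] for f in families[1:]):
        return None
    return families[0]


def consensus_family(hits: Sequence[tuple[str, float]], tree: TaxonomyTree,
                     ref_taxa: Mapping[str, Mapping[str, str]],
                     *, min_identity: float = MIN_IDENTITY,
                     top_n: int = TOP_N,
                     concordance: float = CONCORDANCE,
                     ssu_id: str = "") -> ClassificationCall:
    """Assign a family to an SSU query from its reference-panel hits.

    hits: (panel ref_id, nucleotide identity) pairs.  Hits with identity
    strictly above `min_identity` are sorted by (identity desc, ref_id asc);
    the best `top_n` vote.  A family is called iff at least `concordance`
    of the considered hits map to one harmonized family (>= comparison, so
    16/20 passes at the 0.80 default); otherwise the call is unassigned.
    When fewer than `top_n` hits survive the filter, all of them vote.
    """
    kept = [(ref_id, ident) for ref_id, ident in hits if ident > min_identity]
    kept.sort(key=lambda h: (-h[1], h[0]))
    considered = kept[:top_n]
    table: list[tuple[str, float, int | None]] = []
    counts: dict[int, int] = {}
    for ref_id, ident in considered:
        fam = _hit_family(tree, ref_taxa.get(ref_id, {}))
        table.append((ref_id, ident, fam))
        if fam is not None:
            counts[fam] = counts.get(fam, 0) + 1
    n = len(considered)
    if n == 0 or not counts:
        return ClassificationCall(ssu_id, UNASSIGNED, 0.0, n, table)
    best_family = min(counts, key=lambda f: (-counts[f], f))
    support = counts[best_family] / n
    if support >= concordance:
        return ClassificationCall(ssu_id, best_family, support, n, table)
    return ClassificationCall(ssu_id, UNASSIGNED, support, n, table)


@dataclass
class FamilyCatalogue:
    """Distinct cobiont families detected in an assembly."""

    cobiont_families: list[int]
    host_family: int
    host_calls: list[ClassificationCall]
    unassigned_calls: list[ClassificationCall]
    assigned_calls: list[ClassificationCall]


def family_catalogue(calls: Sequence[ClassificationCall],
                     host_family: int) -> FamilyCatalogue:
    """Split classification calls into cobiont families, host, unassigned.

    Unassigned calls are excluded from the catalogue but kept for the
    report, so sparse or conflicting SSU evidence stays visible.
    """
    cobionts: list[int] = []
    host_calls, unassigned, assigned = [], [], []
    for call in calls:
        if call.family is None:
            unassigned.append(call)
        elif call.family == host_family:
            host_calls.append(call)
            assigned.append(call)
        else:
            assigned.append(call)
            if call.family not in cobionts:
                cobionts.append(call.family)
    return FamilyCatalogue(sorted(cobionts), host_family, host_calls,
                           unassigned, assigned)
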