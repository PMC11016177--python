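"""End-to-end orchestration: configuration, reference bundle, stage order,
persistence of every intermediate, and the final report.

Stage order: SSU scan -> retention -> redundancy collapse -> consensus
family calls -> cobiont catalogue -> k-mer database build -> read binning
-> per-family contig refinement -> per-family reassembly + filtering ->
assessment.  Identical configuration and seed give byte-identical tables;
stages communicate only through the files they persist, and a rerun with
``resume=True`` reloads completed stages instead of recomputing them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cobiontscan import bin_refine, evaluation, family_classifier, reassembly
from cobiontscan import ssu_screen
from cobiontscan.sequence_io import ContigSet, SeqRecord, read_fasta, \
    write_fasta, write_fastq
from cobiontscan.synthetic_community import TruthTable
from cobiontscan.taxonomy import (ClassificationCall, TaxonomyTree,
                                  consensus_family, family_catalogue)
from cobiontscan._align import global_identity

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid configuration (detected before any stage runs)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    assembly_path: str
    reads_path: str
    host_species_name: str
    reference_bundle_path: str
    output_dir: str
    rng_seed: int = 0
    truth_dir: str | None = None
    params: dict = field(default_factory=dict)

    #: tunable parameters and their defaults; overrides outside the
    #: documented ranges are rejected at validation time
    DEFAULTS = {
        "k": 50,
        "min_confidence": 0.10,
        "ssu_min_aligned": 1000,
        "ssu_min_score": 950.0,
        "collapse_identity": 0.99,
        "consensus_min_identity": 0.90,
        "consensus_top_n": 20,
        "consensus_concordance": 0.80,
        "candidate_min_votes": 5,
        "end_tolerance": 25,
        "marker_min_identity": 0.90,
        "marker_min_cov": 0.80,
        "similarity_min_identity": 0.90,
        "similarity_min_breadth": 0.50,
        "min_overlap": 500,
    }
    RANGES = {
        "k": (4, 62), "min_confidence": (0.0, 1.0),
        "ssu_min_aligned": (0, 10_000), "ssu_min_score": (0.0, 1e6),
        "collapse_identity": (0.5, 1.0),
        "consensus_min_identity": (0.0, 1.0),
        "consensus_top_n": (1, 1000), "consensus_concordance": (0.0, 1.0),
        "candidate_min_votes": (1, 10_000), "end_tolerance": (0, 1000),
        "marker_min_identity": (0.0, 1.0), "marker_min_cov": (0.0, 1.0),
        "similarity_min_identity": (0.0, 1.0),
        "similarity_min_breadth": (0.0, 1.0),
        "min_overlap": (50, 100_000),
    }

    def param(self, name: str):
        return self.params.get(name, self.DEFAULTS[name])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        params = data.pop("params", {}) or {}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(params=params, **data)

    def validate(self) -> "LoadedInputs":
        for key in ("assembly_path", "reads_path", "reference_bundle_path"):
            if not Path(getattr(self, key)).exists():
                raise ConfigError(f"{key} does not exist: {getattr(self, key)}")
        if self.truth_dir is not None and not Path(self.truth_dir).exists():
            raise ConfigError(f"truth_dir does not exist: {self.truth_dir}")
        for name, value in self.params.items():
            if name not in self.DEFAULTS:
                raise ConfigError(f"unknown parameter {name!r}")
            lo, hi = self.RANGES[name]
            if not lo <= value <= hi:
                raise ConfigError(
                    f"parameter {name}={value} outside [{lo}, {hi}]")
        bundle = ReferenceBundle.load(self.reference_bundle_path)
        host_tid = bundle.tree.resolve(self.host_species_name)
        if host_tid is None:
            raise ConfigError(
                f"host species {self.host_species_name!r} not in taxonomy")
        host_family = bundle.tree.family_of(host_tid)
        if host_family is None:
            raise ConfigError(
                f"host species {self.host_species_name!r} has no family rank")
        return LoadedInputs(bundle, host_tid, host_family)


@dataclass
class ReferenceBundle:
    """On-disk reference bundle: SSU panel with dual taxonomy labels,
    harmonized taxonomy, family reference genomes and marker panels."""

    tree: TaxonomyTree
    panel: ContigSet
    ref_taxa: dict[str, dict[str, str]]
    family_refs: dict[str, ContigSet]       # family name -> genomes
    marker_panels: dict[str, list[SeqRecord]]
    host_refs: ContigSet

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceBundle":
        path = Path(path)
        tree = TaxonomyTree.from_tsv(path / "taxonomy_nodes.tsv",
                                     path / "taxonomy_synonyms.tsv")
        panel = read_fasta(path / "ssu_panel.fasta")
        ref_taxa: dict[str, dict[str, str]] = {}
        with open(path / "ssu_taxonomy.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                ref_taxa[row["ref_id"]] = {"ncbi": row["ncbi"],
                                           "silva": row["silva"]}
        family_refs = {}
        for fasta in sorted((path / "family_refs").glob("*.fasta")):
            family_refs[fasta.stem] = read_fasta(fasta)
        marker_panels = {}
        for fasta in sorted((path / "markers").glob("*.fasta")):
            marker_panels[fasta.stem] = list(read_fasta(fasta))
        host_path = path / "host_refs.fasta"
        host_refs = read_fasta(host_path) if host_path.exists() else ContigSet()
        return cls(tree, panel, ref_taxa, family_refs, marker_panels,
                   host_refs)


@dataclass
class LoadedInputs:
    bundle: ReferenceBundle
    host_taxid: int
    host_family: int


@dataclass
class PipelineResult:
    run_dir: Path
    catalogue_families: list[str]
    assessments: list[evaluation.BinAssessment]
    n_host_reads: int
    n_unclassified_reads: int
    bins: dict[str, list[str]]
    retained: dict[str, ContigSet]
    reassemblies: dict[str, ContigSet]
    topology: dict[str, dict[str, str]]


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _load_hits(path: Path) -> list[ssu_screen.SSUHit]:
    return [ssu_screen.SSUHit(r["contig_id"], int(r["start"]), int(r["end"]),
                              r["strand"], int(r["aligned_length"]),
                              float(r["identity"]), r["panel_ref"],
                              bool(int(r["retained"])))
            for r in _read_tsv(path)]


def run_pipeline(config: PipelineConfig, resume: bool = False
                 ) -> PipelineResult:
    """Run every stage; persist intermediates under ``output_dir``."""
    loaded = config.validate()
    bundle, tree = loaded.bundle, loaded.bundle.tree
    run = Path(config.output_dir)
    run.mkdir(parents=True, exist_ok=True)

    assembly = read_fasta(config.assembly_path)
    reads = read_fasta(config.reads_path)

    # --- SSU screen -------------------------------------------------------
    hits_path = run / "ssu_hits.tsv"
    if resume and hits_path.exists():
        hits = _load_hits(hits_path)
    else:
        hits = ssu_screen.scan_ssu(assembly, bundle.panel)
        hits = ssu_screen.retain_hits(hits,
                                      config.param("ssu_min_aligned"),
                                      config.param("ssu_min_score"))
        _write_tsv(hits_path,
                   ["contig_id", "start", "end", "strand", "aligned_length",
                    "identity", "panel_ref", "retained"],
                   [[h.contig_id, h.start, h.end, h.strand, h.aligned_length,
                     f"{h.identity:.6f}", h.panel_ref_id, int(h.retained)]
                    for h in hits])
    retained_hits = [h for h in hits if h.retained]
    loci = ssu_screen.best_hit_per_locus(retained_hits)
    ssu_seqs = ssu_screen.extract_ssu_sequences(assembly, loci)
    ssu_set = ssu_screen.collapse_redundant(
        ssu_seqs, config.param("collapse_identity"), hits=hits)
    if ssu_set.representatives:
        write_fasta(ssu_set.representatives, run / "ssu_representatives.fasta")

    # --- consensus classification ----------------------------------------
    calls: list[ClassificationCall] = []
    for rep in ssu_set.representatives:
        rep_hits = [(ref.id, global_identity(rep.seq, ref.seq))
                    for ref in bundle.panel]
        calls.append(consensus_family(
            rep_hits, tree, bundle.ref_taxa,
            min_identity=config.param("consensus_min_identity"),
            top_n=config.param("consensus_top_n"),
            concordance=config.param("consensus_concordance"),
            ssu_id=rep.id))
    _write_tsv(run / "classification.tsv",
               ["ssu_id", "family_id", "family_name", "support",
                "n_hits_considered"],
               [[c.ssu_id,
                 "" if c.family is None else c.family,
                 "UNASSIGNED" if c.family is None
                 else tree.nodes[c.family].name,
                 f"{c.support:.4f}", c.n_hits_considered] for c in calls])

    catalogue = family_catalogue(calls, loaded.host_family)
    fam_name = {tid: tree.nodes[tid].name for tid in catalogue.cobiont_families}
    fam_name[loaded.host_family] = tree.nodes[loaded.host_family].name
    _write_tsv(run / "catalogue.tsv",
               ["family_id", "family_name", "role"],
               [[tid, fam_name[tid], "cobiont"]
                for tid in catalogue.cobiont_families]
               + [[loaded.host_family, fam_name[loaded.host_family], "host"]])

    result = PipelineResult(run, [fam_name[t] for t in
                                  catalogue.cobiont_families], [],
                            0, 0, {}, {}, {}, {})

    # --- k-mer database, read binning, candidate contigs -------------------
    bins_path = run / "read_bins.tsv"
    cand_path = run / "contig_candidates.tsv"
    name_to_tid = {v: k for k, v in fam_name.items()}
    candidate_votes: dict[str, dict[int, int]] = {}
    if resume and bins_path.exists() and cand_path.exists():
        bins: dict[int, list[str]] = {t: [] for t in
                                      catalogue.cobiont_families}
        host_ids, unclassified = [], []
        for row in _read_tsv(bins_path):
            label = row["label"]
            if label == family_classifier.HOST:
                host_ids.append(row["read_id"])
            elif label in name_to_tid and \
                    name_to_tid[label] != loaded.host_family:
                bins.setdefault(name_to_tid[label], []).append(row["read_id"])
            else:
                unclassified.append(row["read_id"])
        binning = family_classifier.BinningResult(bins, host_ids,
                                                  unclassified, [])
        for row in _read_tsv(cand_path):
            candidate_votes.setdefault(row["contig_id"], {})[
                int(row["family_id"])] = int(row["votes"])
    else:
        if catalogue.cobiont_families:
            family_genomes = {}
            for tid in catalogue.cobiont_families:
                name = fam_name[tid]
                if name not in bundle.family_refs:
                    raise StageError(
                        "database", f"no reference genomes for family {name}")
                family_genomes[tid] = bundle.family_refs[name]
            host_genomes = {loaded.host_family: bundle.host_refs} \
                if len(bundle.host_refs) else {}
            db = family_classifier.build_database(
                family_genomes, host_genomes, tree, k=config.param("k"))
            binning = family_classifier.bin_reads(
                db, reads, config.param("min_confidence"))
            for contig in assembly:
                rc = family_classifier.classify_read(db, contig, 0.0)
                candidate_votes[contig.id] = rc.votes
        else:
            binning = family_classifier.BinningResult({}, [], reads.ids(), [])
        _write_tsv(bins_path, ["read_id", "label", "confidence"],
                   [[rc.read_id,
                     rc.label if rc.family is None else fam_name.get(
                         rc.family, str(rc.family)),
                     f"{rc.confidence:.4f}"] for rc in
                    binning.classifications])
        _write_tsv(cand_path, ["contig_id", "family_id", "votes"],
                   [[cid, tid, n] for cid, votes in candidate_votes.items()
                    for tid, n in sorted(votes.items())])
    result.n_host_reads = len(binning.host_reads)
    result.n_unclassified_reads = len(binning.unclassified_reads)
    truth = TruthTable.load_dir(config.truth_dir) if config.truth_dir else None

    bins_dir = run / "bins"
    for tid in catalogue.cobiont_families:
        name = fam_name[tid]
        fam_dir = bins_dir / name.replace(" ", "_")
        fam_dir.mkdir(parents=True, exist_ok=True)
        read_ids = binning.bins.get(tid, [])
        result.bins[name] = read_ids
        with open(fam_dir / "read_ids.txt", "w") as fh:
            fh.write("".join(rid + "\n" for rid in read_ids))
        bin_reads_set = reads.subset(read_ids)
        if len(bin_reads_set):
            write_fastq(bin_reads_set, fam_dir / "reads.fastq")
        min_votes = config.param("candidate_min_votes")
        candidates = ContigSet(
            c for c in assembly
            if candidate_votes.get(c.id, {}).get(tid, 0) >= min_votes)
        markers = bundle.marker_panels.get(name, [])
        refs = bundle.family_refs.get(name, ContigSet())
        decisions_path = fam_dir / "decisions.tsv"
        retained_path = fam_dir / "retained.fasta"
        if resume and decisions_path.exists():
            retained = read_fasta(retained_path) \
                if retained_path.exists() else ContigSet()
        else:
            if len(candidates):
                retained, decisions, profiles = bin_refine.refine_bin(
                    candidates, bin_reads_set, markers, refs,
                    end_tolerance=config.param("end_tolerance"),
                    marker_min_identity=config.param("marker_min_identity"),
                    marker_min_cov=config.param("marker_min_cov"),
                    similarity_min_identity=config.param(
                        "similarity_min_identity"),
                    similarity_min_breadth=config.param(
                        "similarity_min_breadth"))
            else:
                retained, decisions, profiles = ContigSet(), [], []
            _write_tsv(decisions_path,
                       ["contig_id", "fully_covered", "has_marker",
                        "similar_to_reference", "retained", "reasons"],
                       [[d.contig_id, int(d.fully_covered), int(d.has_marker),
                         int(d.similar_to_reference), int(d.retained),
                         ";".join(d.reasons)] for d in decisions])
            _write_tsv(fam_dir / "coverage.tsv",
                       ["contig_id", "breadth", "reads_placed"],
                       [[p.contig_id, f"{p.breadth:.6f}", p.n_reads_placed]
                        for p in profiles])
            if len(retained):
                write_fasta(retained, retained_path)
        result.retained[name] = retained

        # --- reassembly ---------------------------------------------------
        manifest_path = fam_dir / "reassembly_manifest.tsv"
        reasm_path = fam_dir / "reassembly.fasta"
        if resume and manifest_path.exists():
            topo_all = {r["contig_id"]: r["topology"]
                        for r in _read_tsv(manifest_path)}
            re_retained = read_fasta(reasm_path) \
                if reasm_path.exists() else ContigSet()
            topo = {cid: topo_all.get(cid, "linear")
                    for cid in re_retained.ids()}
        elif len(bin_reads_set):
            asm = reassembly.greedy_assemble(bin_reads_set,
                                             config.param("min_overlap"))
            re_retained = reassembly.filter_reassembly(
                asm, markers, refs,
                min_identity=config.param("marker_min_identity"),
                min_cov=config.param("marker_min_cov"),
                similarity_min_identity=config.param(
                    "similarity_min_identity"),
                similarity_min_breadth=config.param(
                    "similarity_min_breadth"))
            topo = {cid: asm.topology[cid] for cid in re_retained.ids()}
            if len(re_retained):
                circ = {True: "true", False: "false"}
                recs = [SeqRecord(
                    f"{c.id} circular={circ[topo[c.id] == 'circular']}",
                    c.seq) for c in re_retained]
                write_fasta(recs, fam_dir / "reassembly.fasta")
            _write_tsv(manifest_path,
                       ["contig_id", "topology", "length", "n_reads"],
                       [[cid, asm.topology[cid], len(asm.contigs[cid]),
                         len(asm.constituents[cid])]
                        for cid in asm.contigs.ids()])
        else:
            re_retained, topo = ContigSet(), {}
        result.reassemblies[name] = re_retained
        result.topology[name] = topo

        if truth is not None:
            try:
                assessment = evaluation.assess_bin(
                    name, retained, truth, markers, re_retained, topo)
                result.assessments.append(assessment)
            except ValueError as exc:
                logger.warning("assessment skipped for %s: %s", name, exc)

    # --- assessment table and report ---------------------------------------
    if truth is not None:
        _write_tsv(run / "assessment.tsv", evaluation.BinAssessment.HEADER,
                   [a.row() for a in result.assessments])
    _write_report(run / "report.txt", config, result, catalogue, fam_name,
                  len(reads), truth)
    return result


def _write_report(path: Path, config: PipelineConfig, result: PipelineResult,
                  catalogue, fam_name: dict[int, str], n_reads: int,
                  truth: TruthTable | None) -> None:
    lines = []
    lines.append("cobiontscan run report")
    lines.append(f"seed: {config.rng_seed}")
    lines.append(f"cobiont families detected via SSU: "
                 f"{len(catalogue.cobiont_families)}")
    for tid in catalogue.cobiont_families:
        name = fam_name[tid]
        lines.append(f"  - {name}: {len(result.bins.get(name, []))} reads, "
                     f"{len(result.retained.get(name, []))} retained contigs")
    lines.append(f"host family: {fam_name.get(catalogue.host_family, '?')} "
                 f"({result.n_host_reads} reads)")
    lines.append(f"unassigned SSU calls: {len(catalogue.unassigned_calls)}")
    frac = result.n_unclassified_reads / n_reads if n_reads else 0.0
    lines.append(f"unclassified reads: {result.n_unclassified_reads} "
                 f"({frac:.1%}) — may include taxa present in the reads but "
                 "absent from the assembly (no SSU detected, e.g. species "
                 "below the assembler's coverage floor)")
    if truth is not None:
        undetected = sorted(
            {ct.family for ct in truth.reads.values()}
            - {fam_name[t] for t in catalogue.cobiont_families}
            - {fam_name.get(catalogue.host_family)})
        for fam in undetected:
            lines.append(f"undetected family (reads-only, no catalogue "
                         f"entry): {fam}")
    for a in result.assessments:
        s, d, m = a.completeness.fractions
        lines.append(f"assessment {a.family}: precision={a.precision:.4f} "
                     f"recall={a.recall:.4f} f1={a.f1:.4f} span={a.span} "
                     f"n50={a.n50} markers S/D/M={s:.2f}/{d:.2f}/{m:.2f} "
                     f"reassembly_span={a.reassembly_span} "
                     f"circular={a.n_circular}")
    path.write_text("".join(line + "\n" for line in lines))
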