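"""Truth-labelled mixed-species fixtures: host plus cobionts at staggered
abundance, with embedded SSU genes, single-copy markers, an optional
horizontally transferred insert, error-free long reads, a fragmented draft
assembly, and a full reference bundle (SSU panel with dual taxonomy
labels, family reference genomes, marker panels).

The generator emulates the intended use case: a deeply sequenced eukaryote
host co-sequenced with a handful of microbial cobionts whose abundances
span two orders of magnitude, the lowest of which fails to assemble and is
present only in the reads.  Reads are error-free surrogates for
high-accuracy long reads; start positions are stratified with jitter
(end-anchored on linear genomes) so that realized coverage is even and the
full-coverage contig filter measures binning, not library sampling noise.
Everything is reproducible from (CommunitySpec, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from cobiontscan.sequence_io import (ContigSet, SeqRecord, revcomp,
                                     write_fasta, write_fastq)
from cobiontscan.taxonomy import TaxonomyTree

_BASES = "ACGT"


# --------------------------------------------------------------------------
# specs

@dataclass
class SpeciesSpec:
    name: str
    family: str
    domain: str                      # Bacteria | Eukaryota
    genome_length: int
    gc: float
    bias_seed: int
    abundance_weight: float
    circular: bool = False
    omit_from_assembly: bool = False
    ssu_copies: int = 1
    fragments: int = 2

    def __post_init__(self) -> None:
        if self.genome_length < 20_000:
            raise ValueError("genome_length must be >= 20 kb")
        if self.abundance_weight <= 0:
            raise ValueError("abundance_weight must be > 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")


@dataclass
class CommunitySpec:
    species: list[SpeciesSpec]
    read_length_mean: int = 8_000
    read_length_sd: int = 800
    coverage_total: float = 137.0
    rng_seed: int = 7
    host_index: int = 0
    hgt_insert_bp: int = 500
    marker_length: int = 600
    marker_spacing: int = 10_000
    ssu_panel_refs: int = 5
    ssu_panel_outliers: int = 1

    @property
    def host(self) -> SpeciesSpec:
        return self.species[self.host_index]

    def coverage_of(self, sp: SpeciesSpec) -> float:
        total_w = sum(s.abundance_weight for s in self.species)
        return self.coverage_total * sp.abundance_weight / total_w


def default_community_spec(rng_seed: int = 7) -> CommunitySpec:
    """The default mock community: one host eukaryote surrogate plus three
    bacterial cobionts and one divergent eukaryotic cobiont, abundances
    staggered 100:20:10:5:2.  The least abundant species fails to assemble
    (reads only), emulating taxa below the assembler's coverage floor."""
    species = [
        SpeciesSpec("Hospes communis", "Hospitidae", "Eukaryota",
                    500_000, 0.38, 11, 100.0, ssu_copies=2, fragments=6),
        SpeciesSpec("Symbiodex primus", "Symbiontaceae", "Bacteria",
                    120_000, 0.45, 23, 20.0, circular=True, fragments=3),
        SpeciesSpec("Commensalus secundus", "Commensalaceae", "Bacteria",
                    90_000, 0.55, 37, 10.0, fragments=2),
        SpeciesSpec("Epibion tertius", "Epibiontaceae", "Bacteria",
                    60_000, 0.62, 41, 5.0, fragments=2),
        SpeciesSpec("Cryptomyces quartus", "Cryptomycetaceae", "Eukaryota",
                    40_000, 0.30, 53, 2.0, omit_from_assembly=True,
                    fragments=1),
    ]
    return CommunitySpec(species, rng_seed=rng_seed)


# --------------------------------------------------------------------------
# truth bookkeeping

@dataclass
class ReadTruth:
    species: str
    family: str
    start: int
    end: int            # genome coordinates; end may exceed G for wrapped reads


@dataclass
class ContigTruth:
    species: str
    family: str
    genome_start: int
    genome_end: int

    @property
    def length(self) -> int:
        return self.genome_end - self.genome_start


@dataclass
class ElementTruth:
    species: str
    kind: str           # ssu | marker | hgt
    element_id: str
    genome_start: int
    genome_end: int
    strand: str
    contig_id: str | None = None
    contig_start: int | None = None
    contig_end: int | None = None


@dataclass
class TruthTable:
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    elements: list[ElementTruth] = field(default_factory=list)

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "reads.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["read_id", "species", "family", "start", "end"])
            for rid, rt in self.reads.items():
                w.writerow([rid, rt.species, rt.family, rt.start, rt.end])
        with open(path / "contigs.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["contig_id", "species", "family",
                        "genome_start", "genome_end"])
            for cid, ct in self.contigs.items():
                w.writerow([cid, ct.species, ct.family,
                            ct.genome_start, ct.genome_end])
        with open(path / "elements.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["species", "kind", "element_id", "genome_start",
                        "genome_end", "strand", "contig_id",
                        "contig_start", "contig_end"])
            for e in self.elements:
                w.writerow([e.species, e.kind, e.element_id, e.genome_start,
                            e.genome_end, e.strand, e.contig_id or "",
                            "" if e.contig_start is None else e.contig_start,
                            "" if e.contig_end is None else e.contig_end])

    @classmethod
    def load_dir(cls, path: str | Path) -> "TruthTable":
        path = Path(path)
        truth = cls()
        with open(path / "reads.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                truth.reads[row["read_id"]] = ReadTruth(
                    row["species"], row["family"],
                    int(row["start"]), int(row["end"]))
        with open(path / "contigs.tsv") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                truth.contigs[row["contig_id"]] = ContigTruth(
                    row["species"], row["family"],
                    int(row["genome_start"]), int(row["genome_end"]))
        elements_path = path / "elements.tsv"
        if elements_path.exists():
            with open(elements_path) as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    truth.elements.append(ElementTruth(
                        row["species"], row["kind"], row["element_id"],
                        int(row["genome_start"]), int(row["genome_end"]),
                        row["strand"], row["contig_id"] or None,
                        int(row["contig_start"]) if row["contig_start"] else None,
                        int(row["contig_end"]) if row["contig_end"] else None))
        return truth


# --------------------------------------------------------------------------
# sequence simulation primitives

def simulate_genome(length: int, gc: float, bias_seed: int,
                    rng: np.random.Generator, name: str = "genome",
                    bias_scale: float = 0.6) -> SeqRecord:
    """Sample a genome from an order-2 Markov chain with a species-specific
    trinucleotide bias.

    The per-context transition probabilities are perturbed by Gaussian
    weights drawn from `bias_seed`, then renormalized so that every context
    assigns exactly `gc` probability mass to G+C: realized GC tracks the
    target while the trinucleotide spectrum stays species-specific, making
    genomes compositionally separable.  `bias_scale` 0 gives i.i.d. bases.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    bias_rng = np.random.default_rng(bias_seed)
    eps = bias_rng.normal(0.0, 1.0, size=(16, 4)) * bias_scale
    w = np.exp(eps)
    probs = np.empty((16, 4))
    for ctx in range(16):
        at = w[ctx, 0] + w[ctx, 3]
        cg = w[ctx, 1] + w[ctx, 2]
        probs[ctx, 0] = (1 - gc) * w[ctx, 0] / at
        probs[ctx, 3] = (1 - gc) * w[ctx, 3] / at
        probs[ctx, 1] = gc * w[ctx, 1] / cg
        probs[ctx, 2] = gc * w[ctx, 2] / cg
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    base_cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = np.empty(length, dtype=np.uint8)
    out[0] = np.searchsorted(base_cum, u[0])
    if length > 1:
        out[1] = np.searchsorted(base_cum, u[1])
    for i in range(2, length):
        ctx = out[i - 2] * 4 + out[i - 1]
        row = cum[ctx]
        x = u[i]
        out[i] = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
    seq = "".join(_BASES[b] for b in out)
    return SeqRecord(name, seq)


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute an exact fraction of positions with a different base."""
    n = len(seq)
    n_mut = int(round(divergence * n))
    if n_mut == 0:
        return seq
    positions = rng.choice(n, size=n_mut, replace=False)
    arr = list(seq)
    for p in positions:
        cur = arr[p]
        choices = [b for b in _BASES if b != cur]
        arr[p] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def _random_seq(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))


def embed_elements(genome: SeqRecord, ssu: list[SeqRecord],
                   markers: list[SeqRecord], rng: np.random.Generator,
                   extra: list[tuple[str, SeqRecord]] | None = None
                   ) -> tuple[SeqRecord, list[ElementTruth]]:
    """Insert SSU genes, marker genes and extra elements at distinct points.

    Every element goes in at its own insertion point (drawn without
    replacement, min 200 bp apart), on a random strand for SSUs and
    markers, so inserted elements can never overlap.  Coordinates and
    strands of every element in the final genome are returned.
    """
    for s in ssu:
        if len(s) < 1_200:
            raise ValueError("SSU sequences must be >= 1,200 bases")
    items: list[tuple[str, str, SeqRecord]] = (
        [("ssu", s.id, s) for s in ssu]
        + [("marker", m.id, m) for m in markers]
        + [(kind, rec.id, rec) for kind, rec in (extra or [])])
    n_items = len(items)
    if len(genome) < 1_000 * n_items:
        raise ValueError("genome too short to host the requested elements")
    # distinct insertion points with spacing
    while True:
        points = np.sort(rng.integers(500, len(genome) - 500, size=n_items))
        if n_items < 2 or np.diff(points).min() >= 200:
            break
    order = rng.permutation(n_items)
    placed = [(int(points[i]), items[order[i]]) for i in range(n_items)]
    placed.sort(key=lambda t: t[0])
    pieces: list[str] = []
    elements: list[ElementTruth] = []
    prev = 0
    offset = 0
    for point, (kind, elt_id, rec) in placed:
        pieces.append(genome.seq[prev:point])
        strand = "+" if kind == "hgt" or rng.random() < 0.5 else "-"
        seq = rec.seq if strand == "+" else revcomp(rec.seq)
        start = point + offset
        pieces.append(seq)
        elements.append(ElementTruth("", kind, elt_id, start,
                                     start + len(seq), strand))
        offset += len(seq)
        prev = point
    pieces.append(genome.seq[prev:])
    return SeqRecord(genome.id, "".join(pieces)), elements


def simulate_reads(community: CommunitySpec, genomes: list[SeqRecord]
                   ) -> tuple[ContigSet, TruthTable]:
    """Error-free long reads at per-species coverage proportional to
    abundance weight.

    Start positions are stratified with jitter; on linear genomes the first
    and last reads are anchored to the termini, on circular genomes reads
    wrap the origin.  Read ids are opaque and globally sequential.
    """
    if community.coverage_total <= 0:
        raise ValueError("coverage_total must be > 0")
    by_name = {g.id: g for g in genomes}
    reads = ContigSet()
    truth = TruthTable()
    counter = 0
    ss = np.random.SeedSequence([community.rng_seed, 1])
    streams = {sp.name: np.random.default_rng(child)
               for sp, child in zip(community.species,
                                    ss.spawn(len(community.species)))}
    for sp in community.species:
        genome = by_name[sp.name]
        g = len(genome)
        rng = streams[sp.name]
        cov = community.coverage_of(sp)
        mean = community.read_length_mean
        n = max(1, int(round(cov * g / mean)))
        lengths = np.clip(
            rng.normal(mean, community.read_length_sd, size=n),
            int(0.6 * mean), int(1.4 * mean)).astype(int)
        lengths = np.minimum(lengths, g - 1)
        if sp.circular:
            spacing = g / n
            starts = (np.floor(np.arange(n) * spacing)
                      + rng.integers(0, max(1, int(spacing)), size=n)) % g
            starts = starts.astype(int)
        else:
            if n == 1:
                starts = np.array([0])
            else:
                span = g - lengths.mean()
                base = np.arange(n) * span / (n - 1)
                jitter = rng.uniform(-0.4, 0.4, size=n) * span / (n - 1)
                starts = np.clip((base + jitter).round().astype(int),
                                 0, g - lengths)
                starts[0] = 0
                starts[-1] = g - lengths[-1]
        for i in range(n):
            s, ln = int(starts[i]), int(lengths[i])
            if sp.circular and s + ln > g:
                seq = genome.seq[s:] + genome.seq[:s + ln - g]
            else:
                ln = min(ln, g - s)
                seq = genome.seq[s:s + ln]
            rid = f"read_{counter:06d}"
            counter += 1
            reads.add(SeqRecord(rid, seq))
            truth.reads[rid] = ReadTruth(sp.name, sp.family, s, s + ln)
    return reads, truth


def simulate_assembly(community: CommunitySpec, genomes: list[SeqRecord],
                      elements: dict[str, list[ElementTruth]],
                      rng: np.random.Generator
                      ) -> tuple[ContigSet, TruthTable]:
    """Fragment each genome into contiguous contigs; omitted species stay
    out of the assembly (present in reads only).

    Cut points avoid embedded elements by a 200 bp margin so a fixture
    SSU or marker is never split across contigs.
    """
    by_name = {g.id: g for g in genomes}
    contigs = ContigSet()
    truth = TruthTable()
    counter = 0
    for sp in community.species:
        if sp.omit_from_assembly:
            continue
        genome = by_name[sp.name]
        g = len(genome)
        n_frag = max(1, sp.fragments)
        forbidden = [(max(0, e.genome_start - 200), e.genome_end + 200)
                     for e in elements.get(sp.name, [])]

        def ok(cut: int) -> bool:
            return all(not (lo < cut < hi) for lo, hi in forbidden)

        cuts: list[int] = []
        attempts = 0
        while len(cuts) < n_frag - 1 and attempts < 10_000:
            attempts += 1
            c = int(rng.integers(10_000, g - 10_000))
            if ok(c) and all(abs(c - c0) >= 10_000 for c0 in cuts):
                cuts.append(c)
        bounds = [0] + sorted(cuts) + [g]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cid = f"ctg_{counter:04d}"
            counter += 1
            contigs.add(SeqRecord(cid, genome.seq[lo:hi]))
            truth.contigs[cid] = ContigTruth(sp.name, sp.family, lo, hi)
        # map element genome coordinates onto contigs
        for e in elements.get(sp.name, []):
            entry = replace(e)
            for cid, ct in truth.contigs.items():
                if (ct.species == sp.name
                        and ct.genome_start <= e.genome_start
                        and e.genome_end <= ct.genome_end):
                    entry.contig_id = cid
                    entry.contig_start = e.genome_start - ct.genome_start
                    entry.contig_end = e.genome_end - ct.genome_start
                    break
            truth.elements.append(entry)
    # elements of omitted species keep genome coordinates only
    for sp in community.species:
        if sp.omit_from_assembly:
            truth.elements.extend(elements.get(sp.name, []))
    return contigs, truth


# --------------------------------------------------------------------------
# taxonomy and reference-bundle fixtures

def build_fixture_taxonomy(spec: CommunitySpec
                           ) -> tuple[TaxonomyTree, dict[str, int]]:
    """Harmonized fixture taxonomy with NCBI-style ids and SILVA-style
    path synonyms for every family."""
    tree = TaxonomyTree()
    tree.add_node(1, "root", "root", 1)
    domains = sorted({sp.domain for sp in spec.species})
    next_id = 2
    domain_ids: dict[str, int] = {}
    for dom in domains:
        tree.add_node(next_id, dom, "domain", 1)
        tree.add_synonym("silva", dom, next_id)
        domain_ids[dom] = next_id
        next_id += 1
    family_ids: dict[str, int] = {}
    for sp in sorted(spec.species, key=lambda s: s.family):
        if sp.family in family_ids:
            continue
        stem = sp.family[:-4] if sp.family.endswith("ceae") else sp.family
        order_name = stem + "ales"
        tree.add_node(next_id, order_name, "order", domain_ids[sp.domain])
        order_id = next_id
        next_id += 1
        tree.add_node(next_id, sp.family, "family", order_id)
        family_ids[sp.family] = next_id
        tree.add_synonym("ncbi", str(next_id), next_id)
        tree.add_synonym(
            "silva", f"{sp.domain};{order_name};{sp.family}", next_id)
        next_id += 1
    for sp in spec.species:
        tree.add_node(next_id, sp.name, "species", family_ids[sp.family])
        next_id += 1
    return tree, family_ids


@dataclass
class CommunityBundle:
    """Everything the pipeline needs, with truth attached."""

    spec: CommunitySpec
    tree: TaxonomyTree
    family_ids: dict[str, int]
    genomes: ContigSet                       # final, element-embedded
    reads: ContigSet
    assembly: ContigSet
    truth: TruthTable
    panel: ContigSet
    ref_taxa: dict[str, dict[str, str]]
    family_refs: dict[str, ContigSet]        # family name -> reference genomes
    marker_panels: dict[str, list[SeqRecord]]
    host_refs: ContigSet
    species_ssu: dict[str, list[SeqRecord]]

    @property
    def host_family(self) -> str:
        return self.spec.host.family


def simulate_community(spec: CommunitySpec | None = None,
                       outdir: str | Path | None = None) -> CommunityBundle:
    """Generate the full fixture bundle; optionally persist it to disk."""
    if spec is None:
        spec = default_community_spec()
    tree, family_ids = build_fixture_taxonomy(spec)
    ss = np.random.SeedSequence([spec.rng_seed, 0])
    (panel_child, genome_child, embed_child, asm_child,
     ref_child) = ss.spawn(5)
    panel_rng = np.random.default_rng(panel_child)
    genome_rng = np.random.default_rng(genome_child)
    embed_rng = np.random.default_rng(embed_child)
    asm_rng = np.random.default_rng(asm_child)
    ref_rng = np.random.default_rng(ref_child)

    # SSU panel: one base sequence per domain, one derived base per family,
    # panel references at 1-4% divergence plus a distant outlier per family
    domain_base = {
        dom: _random_seq(1_550 if dom == "Bacteria" else 1_600, panel_rng)
        for dom in sorted({sp.domain for sp in spec.species})}
    families = sorted({(sp.family, sp.domain) for sp in spec.species})
    panel = ContigSet()
    ref_taxa: dict[str, dict[str, str]] = {}
    family_base: dict[str, str] = {}
    for fam, dom in families:
        base = mutate(domain_base[dom], 0.15, panel_rng)
        family_base[fam] = base
        silva = None
        for (system, label), tid in tree.synonyms.items():
            if system == "silva" and tid == family_ids[fam]:
                silva = label
        divergences = [0.01, 0.02, 0.03, 0.04, 0.015][:spec.ssu_panel_refs]
        for i, div in enumerate(divergences, start=1):
            rid = f"{fam}_p{i}"
            panel.add(SeqRecord(rid, mutate(base, div, panel_rng)))
            # one reference per family is resolvable only in the SILVA
            # system, exercising the single-system voting path
            ncbi = "NA" if i == len(divergences) else str(family_ids[fam])
            ref_taxa[rid] = {"ncbi": ncbi, "silva": silva or fam}
        for j in range(spec.ssu_panel_outliers):
            rid = f"{fam}_px{j}"
            panel.add(SeqRecord(rid, mutate(base, 0.12, panel_rng)))
            ref_taxa[rid] = {"ncbi": str(family_ids[fam]), "silva": silva or fam}

    # genomes with embedded elements
    genomes = ContigSet()
    elements: dict[str, list[ElementTruth]] = {}
    species_ssu: dict[str, list[SeqRecord]] = {}
    host = spec.host
    cobionts_first = [sp for sp in spec.species if sp.name != host.name]
    for sp in cobionts_first + [host]:
        raw = simulate_genome(sp.genome_length, sp.gc, sp.bias_seed,
                              genome_rng, name=sp.name)
        tag = sp.name.replace(" ", "_")
        ssu_seqs = []
        first = mutate(family_base[sp.family], 0.04, embed_rng)
        ssu_seqs.append(SeqRecord(f"{tag}_ssu1", first))
        for c in range(2, sp.ssu_copies + 1):
            ssu_seqs.append(SeqRecord(f"{tag}_ssu{c}",
                                      mutate(first, 0.005, embed_rng)))
        species_ssu[sp.name] = ssu_seqs
        n_markers = max(3, sp.genome_length // spec.marker_spacing)
        markers = [SeqRecord(f"{tag}_m{i:02d}",
                             _random_seq(spec.marker_length, embed_rng))
                   for i in range(n_markers)]
        extra: list[tuple[str, SeqRecord]] = []
        if sp.name == host.name and spec.hgt_insert_bp > 0 and cobionts_first:
            donor = genomes[cobionts_first[0].name]
            start = int(embed_rng.integers(
                0, len(donor) - spec.hgt_insert_bp))
            extra.append(("hgt", SeqRecord(
                f"hgt_from_{cobionts_first[0].name.replace(' ', '_')}",
                donor.seq[start:start + spec.hgt_insert_bp])))
        final, elts = embed_elements(raw, ssu_seqs, markers, embed_rng,
                                     extra=extra)
        for e in elts:
            e.species = sp.name
        elements[sp.name] = elts
        genomes.add(final)

    # reads and assembly
    genome_list = [genomes[sp.name] for sp in spec.species]
    reads, read_truth = simulate_reads(spec, genome_list)
    assembly, truth = simulate_assembly(spec, genome_list, elements, asm_rng)
    truth.reads = read_truth.reads

    # reference bundle: family reference genomes (diverged relatives),
    # marker panels cut from those references, and a host relative
    family_refs: dict[str, ContigSet] = {}
    marker_panels: dict[str, list[SeqRecord]] = {}
    host_refs = ContigSet()
    for sp in spec.species:
        divergence = 0.01 if sp.name == host.name else 0.02
        ref_seq = mutate(genomes[sp.name].seq, divergence, ref_rng)
        ref_id = f"{sp.family}_ref1" if sp.name != host.name \
            else f"{sp.family}_rel1"
        ref_rec = SeqRecord(ref_id, ref_seq)
        if sp.name == host.name:
            host_refs.add(ref_rec)
        else:
            family_refs.setdefault(sp.family, ContigSet()).add(ref_rec)
        panel_markers = []
        for e in elements[sp.name]:
            if e.kind == "marker":
                m_seq = ref_seq[e.genome_start:e.genome_end]
                if e.strand == "-":
                    m_seq = revcomp(m_seq)
                panel_markers.append(SeqRecord(e.element_id, m_seq))
        marker_panels.setdefault(sp.family, []).extend(panel_markers)
    # the host family also gets a marker panel (host bins are assessed too)
    bundle = CommunityBundle(spec, tree, family_ids, genomes, reads,
                             assembly, truth, panel, ref_taxa, family_refs,
                             marker_panels, host_refs, species_ssu)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: CommunityBundle, outdir: str | Path) -> Path:
    """Persist the fixture: assembly, reads, truth tables, reference bundle
    and a ready-to-run pipeline configuration."""
    out = Path(outdir)
    (out / "bundle" / "family_refs").mkdir(parents=True, exist_ok=True)
    (out / "bundle" / "markers").mkdir(parents=True, exist_ok=True)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.assembly, out / "assembly.fasta")
    write_fastq(bundle.reads, out / "reads.fastq")
    for g in bundle.genomes:
        write_fasta([g], out / "genomes" / (g.id.replace(" ", "_") + ".fasta"))
    bundle.truth.write_dir(out / "truth")
    write_fasta(bundle.panel, out / "bundle" / "ssu_panel.fasta")
    with open(out / "bundle" / "ssu_taxonomy.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ref_id", "ncbi", "silva"])
        for rid in sorted(bundle.ref_taxa):
            labels = bundle.ref_taxa[rid]
            w.writerow([rid, labels.get("ncbi", "NA"),
                        labels.get("silva", "NA")])
    bundle.tree.to_tsv(out / "bundle" / "taxonomy_nodes.tsv",
                       out / "bundle" / "taxonomy_synonyms.tsv")
    for fam, refs in bundle.family_refs.items():
        write_fasta(refs, out / "bundle" / "family_refs" / f"{fam}.fasta")
    for fam, markers in bundle.marker_panels.items():
        write_fasta(markers, out / "bundle" / "markers" / f"{fam}.fasta")
    write_fasta(bundle.host_refs, out / "bundle" / "host_refs.fasta")
    config = {
        "assembly_path": str(out / "assembly.fasta"),
        "reads_path": str(out / "reads.fastq"),
        "host_species_name": bundle.spec.host.name,
        "reference_bundle_path": str(out / "bundle"),
        "truth_dir": str(out / "truth"),
        "output_dir": str(out / "run"),
        "rng_seed": bundle.spec.rng_seed,
    }
    import yaml
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out
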