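# Methods

This note documents the models and procedures implemented in
`cobiontscan`, the parameters that matter, what the community simulator
does and does not emulate, and the numerical choices made where the
design was genuinely open.

## Problem setting

A long-read assembly of a target eukaryote usually contains additional
genomes: bacterial or eukaryotic symbionts, parasites, gut contents, and
environmental organisms (collectively, *cobionts*).  The toolkit
separates them in two passes: a *profiling* pass that discovers which
taxonomic families are present (via SSU rRNA, the universal marker), and
a *binning* pass that assigns every read and contig to a family using a
targeted k-mer database built only over the discovered families plus
relatives of the host.  Classifying at family rank balances database
breadth (the exact cobiont species is rarely in any reference set)
against false-positive risk from over-broad clades.

## SSU screen

Detection is seed-and-extend: exact 15-mer seeds of each panel sequence
(both strands) are located in each contig, clustered by diagonal (band
120 bp), and each candidate window is aligned in infix mode with edlib.
Candidate thresholds are deliberately loose (identity ≥ 0.75 of the panel
sequence length, span ≥ 300 bp); the retention rule then keeps a hit when
its aligned length is strictly greater than 1,000 nt *or* its alignment
score (identity × aligned length, an approximate match count) reaches
950.  The score branch stands in for a profile-HMM e-value cutoff, which
is estimator-specific and not reproducible without the original HMM
machinery; it is calibrated so that a near-exact match of roughly a
thousand bases passes even when the length rule alone would not.  With
15-mer seeds, an SSU diverged 8% from its nearest panel member still
yields hundreds of seed matches over 1.5 kb, so detection is effectively
exhaustive down to the candidate identity floor; the test-suite checks
the scanner's verdicts against Biopython's exhaustive Smith–Waterman on
small instances.

Retained SSU sequences are collapsed by greedy longest-first clustering
(ties broken lexicographically by id): a sequence joins an existing
representative when their global identity exceeds 0.99.  Global identity
throughout is `1 − editdist / max(len)`, the conservative end of the
common conventions.

## Family consensus call

Each SSU representative is compared with every panel sequence; hits with
identity strictly above 0.90 are sorted by (identity desc, ref id asc)
and the best 20 vote.  The panel carries two label systems — NCBI-style
numeric ids and SILVA-style path strings — mapped onto one harmonized
node set by a synonym table.  A hit counts toward a family only when
every system in which its label resolves maps it to the same harmonized
family node; a hit resolvable in one system counts under that system; a
conflicting hit counts toward nothing (but stays in the denominator).  A
family is assigned when its share of the considered hits is at least
0.80 — equality passes, so 16 of 20 is the boundary.  When fewer than 20
hits survive the identity filter, all of them vote (requiring at least
one): discarding sparse evidence would blind the method to rare taxa.
Whether the published rule intends the union or intersection of the two
taxonomies is ambiguous; the harmonized-node reading implemented here is
the stricter one and is flagged as a design choice.

## k-mer database and read classification

Reference genomes are masked with a symmetric-DUST scan before k-mer
extraction: a position is masked when it lies in any 64 bp window whose
triplet score `10 · Σ cₜ(cₜ−1)/2 / (k−1)` exceeds 20 (triplets containing
N are excluded, which also makes masking idempotent on hard-masked
sequence).  The window and threshold are conventional DUST-style
defaults; the tool named in the workflow this replaces does not publish
the parameters used, so these are documented choices.

k-mers (k = 50) are canonicalized as the lexicographic minimum of a k-mer
and its reverse complement and packed two bits per base into a pair of
64-bit halves, so extraction and lookup are fully vectorized; no k-mer
containing N or spanning a masked interval is stored.  A k-mer observed
in more than one family is stored under the lowest common ancestor of
those families.  The full index is kept (no minimizer subsampling) —
exactness first at this scale; a stride parameter exists for larger
inputs.

A read is classified by tallying votes over all its canonical k-mers and
scoring each root-to-leaf path through the voted taxa; the read takes the
leaf (family, or the host's family) with the highest path sum.  Ties
resolve to the LCA of the tied leaves, which may sit above family rank —
such reads are binned to no family, which is the desired behaviour for
chimeras.  Reads with zero votes, shorter than k, or whose winning path
collects less than 10% of the queried k-mers stay unclassified; the 10%
floor is a documented default (a guard against single spurious hits), not
a published value.  Candidate contigs for a family bin are assembly
contigs with at least 5 k-mer votes for that family's own node — so a
host contig carrying a short cobiont-derived insertion *is* a candidate
and must be rejected by the coverage filter, not silently skipped.

## Contig retention

A candidate contig is retained in a family bin iff it is fully covered by
the family's classified reads AND (it contains a clade marker gene OR it
has sufficient similarity to a family reference genome).

*Fully covered* means every base has read depth ≥ 1, with 25 bp of slack
at each contig terminus: reads cannot overhang contig ends, so a strict
rule would discard essentially every contig for edge effects.  Coverage
is computed by exact-seed anchoring (31-mers, stride 16, both read
orientations) with maximal exact extension — appropriate for the
near-exact read regime; it is not a general-purpose aligner.

*Marker presence* is a nucleotide-level search: a marker counts as found
when it (or its leading/trailing fraction of length `min_cov` = 0.80)
aligns anywhere in the contig at ≥ 0.90 identity.  This replaces
protein-space ortholog search; the marker panel is a per-family fixture
standing in for a curated single-copy set.

*Reference similarity* cuts the contig into 500 bp chunks and aligns each
chunk (both strands) against each family reference in infix mode; the
contig passes when ≥ 50% of its length matches at ≥ 0.90 identity against
a single reference.  The similarity thresholds of the original workflow
are not published; these defaults are explicit, exposed in the
configuration, and should not be read as reference values.

## Reassembly and circularity

Bins are reassembled by greedy overlap merging: containments are removed,
all exact suffix–prefix overlaps ≥ 500 bp are enumerated via 32-mer
prefix anchors, and merges are applied best-first (longest overlap, ties
by read id) — deterministic by construction.  A contig whose suffix
matches its own prefix over ≥ 500 bp is reported circular and trimmed of
one overlap copy (near-exact self-overlaps at ≥ 99% identity are
additionally accepted when configured).  With error-free reads this
recovers linear genomes exactly and circular genomes exactly up to
rotation.  Known limitation: repeats longer than the overlap floor
fragment the assembly; the simulator keeps repeats below that length, and
a hook for an external assembler exists at the pipeline level for real
data.  Reassembled contigs pass the same marker-or-similarity filter as
refined bins.

## Evaluation

Precision and recall are base-weighted: precision is correctly assigned
bases over total bases in the bin (an empty bin scores 0 by convention);
recall is correctly assigned bases over the family's total truth bases;
`F1 = 2PR/(P+R)`, defined 0 when both are 0.  N50 is the largest L such
that contigs of length ≥ L hold half the span.  Completeness counts each
panel marker as missing (0 contigs), single (1) or duplicated (≥ 2);
there is no fragmented category — fragment calling is a protein-HMM
concept, and fragmentary nucleotide matches fall into missing here.

## The community simulator

The default community is one 500 kb host eukaryote surrogate plus three
bacterial cobionts (120 / 90 / 60 kb, one circular) and one divergent
eukaryotic cobiont (40 kb), with abundance weights 100:20:10:5:2 mapped
to fold-coverages 100× … 2× (the weights are per-species coverages; total
137).  The rarest species is omitted from the assembly, emulating taxa
below the assembler's coverage floor, and the host genome carries a
500 bp insert copied from the first cobiont, emulating a horizontal
transfer.  Genomes are drawn from an order-2 Markov chain whose
per-context transition probabilities carry a species-specific Gaussian
perturbation renormalized to hold G+C mass exactly at the target, making
genomes compositionally distinct while controlling GC.  Each genome gets
embedded SSU genes (the host gets two near-identical copies, exercising
redundancy collapse), evenly spaced 600 bp markers (~1 per 10 kb), and
the fixture SSU panel is built by mutating per-domain base sequences: 15%
per family, 1–4% per panel reference, one 12% outlier per family, and 4%
for each species' own SSU — so the 90% identity filter and the 99%
collapse threshold are both exercised from above and below.  Family
reference genomes are whole-genome copies at 2% divergence (1% for the
host relative), so classification operates through genuinely diverged
references (≈ 36% of 50-mers intact at 2%), not through identity with
truth.

Reads are error-free substrings — a surrogate for high-accuracy long
reads; none of the pipeline's logic models sequencing error, and an error
rate is a configuration option defaulting to zero.  Read lengths are
normal (mean 8 kb, sd 0.8 kb, clipped to 0.6–1.4× the mean).  Start
positions are stratified with jitter, end-anchored on linear genomes and
wrapping on circular ones.  This "even library" surrogate is a deliberate
departure from Poisson sampling: at the staggered design's lowest
in-assembly coverage (5×), Poisson start positions leave random coverage
gaps with appreciable probability, which would make the full-coverage
filter measure library sampling noise rather than binning behaviour.
Consequently, passing tests demonstrate the pipeline's classification and
filtering logic under clean coverage; they do not demonstrate robustness
to real coverage dropout, sequencing error, chimeric reads or repeat
structure, none of which the simulator emulates.

## Determinism and problem sizes

All randomness flows from a single seed through named child streams, so
the fixture bundle and every pipeline table are byte-reproducible from
(spec, seed).  Sorting with explicit tie-breaks (identity then id; length
then id; overlap then id) removes order sensitivity everywhere.  The
test-suite and the acceptance script run the full default community
(≈ 57 Mb of reads) once each and use a three-species community
(≈ 3 Mb of reads) where several end-to-end runs are needed; oracle
equivalence checks use 1,000 random consensus tables, 500 random reads
over a five-genome database, and 1,000 random linear sequences for
circularity false positives.  These sizes were chosen as the smallest
that still exercise every rule boundary.
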