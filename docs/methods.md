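# Methods

## The model

`stagpipe` operates on bi-allelic SNP tag loci from a reduced-representation
genotyping design: each locus is a pair of equal-length tag sequences
(≤ 69 bp, anchored at the 5' end by the restriction-site remnant ``TGCAG``)
differing at exactly one position, genotyped across a diploid population.
The central object is the *concatenated hypothetical genome*: tags, with
their SNP replaced by an IUPAC ambiguity code, are concatenated in ascending
allele-ID order and collapsed across individuals into a single consensus
sequence that stands in for a (very sparse, ~0.1–0.3%) genome sample. All
downstream analysis — repeat masking, homology search, gene association —
runs on this consensus, with a coordinate registry mapping every interval
back to its source tags.

The price of concatenation is a specific artifact class, and its treatment
is the methodological core of the package: a local alignment spanning the
boundary between two concatenated tags can continue into the next tag's
restriction motif and present as one long homology. The screening model
quantifies this: under a uniform random base model, the first k bases of the
motif recur at a junction with probability (1/4)^k (1 in 4, 16, 64, 256,
1024 for k = 1…5). Hits are therefore classified false positives only when
three conditions coincide — length greater than the tag length, query
sequence starting with the motif, and a motif run-on of at least k_min bases
after a spanned junction — with k_min = 3 chosen because one-base (``T``,
p = 1/4) and two-base (``TG``, p = 1/16, further confounded with
dinucleotide repeats) run-ons are too probable to be diagnostic. When a hit
spans several junctions the maximum run-on over junctions is used; the
classification is deliberately per-hit, not per-junction.

## Consensus construction without an aligner

Every individual's concatenation has, by construction, identical locus
order and identical per-locus length: homozygotes emit the called allele,
heterozygotes the ambiguity code, and missing calls an N-run of the full
tag length. Positional homology across individuals is therefore exact and a
gap-tolerant global multiple alignment of these sequences is the identity
on columns. The consensus is computed directly per column as the most
frequent non-N symbol — N only where every individual is missing — with
ties broken deterministically in the fixed order A < C < G < T < two-base
ambiguity codes (alphabetical). GC content is computed over unambiguous
bases only. Allele-ID order uses a numeric-aware natural sort ("2" < "10"),
falling back to lexicographic comparison for non-numeric segments.

## Alignment statistics

The built-in searcher is an ungapped seed-and-extend method: exact-word
seeding (default word size 11 — long words suppress seeds on ≤ 69 bp tags),
X-drop extension (default X = 20 raw score units) on both strands, with
soft-masked (lowercase) and ambiguous query positions excluded from seeding
but crossable during extension. Ambiguity codes match their base set during
extension (a consensus Y matches subject C or T), so a planted allele scores
as identity at its own SNP. Overlapping hits to the same subject locus and
strand are merged keeping the best raw score. Gapped extension is out of
scope; 69 bp tags essentially never need gaps at these identity levels.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with raw sequence
lengths (no edge correction — a documented simplification); the built-in
searcher counts both subject strands in the search space (n doubled), since
a two-strand search doubles the chance-alignment expectation. λ is the unique
positive root of Σᵢⱼ pᵢpⱼ·e^(λ·sᵢⱼ) = 1, solved by Brent's method to
residual < 1e−12. K is computed exactly for the +1/−b lattice this scoring
scheme lives on, by renewal/ladder theory: writing z = e^(−λ), q for the
mismatch probability and b for the mismatch magnitude, the density of
strict descending ladder points of the score walk is q·(1 − z^b); the
walk's per-excursion maximum has tail (1 − Σⱼ πⱼ·z^j)·z^x, where π is the
undershoot distribution at first passage below zero (solved as a small
linear system over walk levels with a reflecting tail at level 200); K is
their product. For +1/−1 this reduces to the closed form (q − p)²/q, and
for +1/−3 on uniform background it gives 0.7106, matching the published
ungapped constant (0.711) to three figures — both serve as oracles in the
test suite. Schemes with match ≠ +1 are rejected rather than approximated.

## Repeat detection

Two library-free detectors replace library-based repeat annotation, which
cannot be shipped: an exact maximal-run finder for perfect tandem repeats
(unit lengths 1–4, runs reported at their primitive period under the
lexicographically smallest unit rotation, defaults min_copies = 5 and
min_span = 10 bp — partial trailing copies count toward the span), and a
DUST-style low-complexity scan (64 bp windows sliding by one, score
Σ c_t(c_t−1)/2 / (w−3) over triplet counts, windows above threshold 2.0
merged). The threshold was calibrated on uniform random sequence, where the
false-mask rate of a 64 bp window is well under 1% (checked empirically in
the test suite). Ambiguity codes and N break tandem runs and are excluded
from scored triplets, keeping masking conservative around SNP sites. A tag
is *repetitive* when at least min_overlap_bp (default 1 — "full or
partially repetitive") of it lies in a mask interval. An `external` BED
channel ingests third-party mask intervals for users who hold a repeat
library licence; transposable-element family classification is explicitly
out of scope, which is also why dataset-level masked fractions of real
libraries are not reproduced here.

## Conserved-gene selection

Per species, false-positive hits are dropped, gene-associated hits
(≥ 1 bp subject overlap with a gene interval, strand-agnostic, gene-level
features only) are kept, and genes whose only support is repetitive tags
are removed. Genes are matched across species by a user-supplied orthology
map (gene_id → ortholog group), falling back to exact gene-name identity;
groups present in at least n_species_required (default 3) per-species sets
form the conserved set, reported with supporting tags and best E-value per
species. One guard applies when the coordinate registry is available: a tag
counts as *supporting* a hit only if the hit covers ≥ 10 bp of it (capped
at the hit length). Ungapped extension routinely overshoots a tag junction
by one or two chance-matching bases, and such slivers are concatenation
artifacts, not homologies of the neighbouring tag; without the guard a
sliver of a non-repetitive neighbour can launder support for a gene whose
real evidence is repetitive. Interval back-mapping itself (`map_to_stags`,
hit `stag_ids`) keeps ≥ 1 bp semantics.

Per-species summaries mirror the standard multi-species homology table:
three mutually exclusive hit categories (gene-associated first, else
repetitive, else non-repeat), each with hit count, unique-tag count and
aligned bp (query intervals union-collapsed, so percentages cannot exceed
100), plus the proportion of the hypothetical genome covered.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design at desk scale: a diploid
population (default 90 individuals) genotyped at motif-anchored ≤ 69 bp tag
loci with missing calls, and annotated reference genomes for three species.
Genotypes follow Hardy–Weinberg proportions at per-locus allele frequencies
(default Uniform(0.1, 0.9)); calls go missing independently (default 5%);
per-locus mean depth is Normal(90, 15) truncated at 1. Defaults of a few
hundred loci and 0.1–0.2 Mb references keep full runs under a minute while
preserving the design's structure. All randomness flows through one integer
seed; identical seeds give byte-identical files, and every planted feature
is verifiable by direct string or interval search against the emitted files.

The multi-species scenario plants one dedicated tag inside each conserved
gene in every species, one tag per species-private gene, and a decoy gene
shared across species whose only support is a tag that is half (AC)n
repeat — the repeat-exclusion path must remove it. Two generator choices
keep the scenario a clean test of conservation recovery rather than of
orthogonal attrition: planted homologies are followed by a 5 bp
junction-breaking context (bases position-wise different from the motif) so
that an "exact tag homology" ends at the tag boundary instead of being
occasionally screened out as a junction false positive after a chance
3-base overshoot; and scenario read depths are Normal(100, 10), placing
essentially no mass under the depth > 60 screen, whose attrition behaviour
is tested separately at the QC stage. The decoy's repeat tract is (AC)₉
(18 bp): long enough for the tandem detector, short enough that the
whole-window low-complexity mask does not swallow the tag's unique,
seedable prefix.

What the generator does *not* emulate: linkage and demography, sequencing
error and read-level data, gapped or diverged homology (plantings are
exact up to the SNP), transposable-element repeat structure, and real
annotation complexity (one gene-level interval per gene, no exons or
isoforms). Passing the end-to-end tests therefore demonstrates the
correctness of the pipeline's logic under its stated model, not its
sensitivity on diverged real-genome homology, which is governed by the
external search engine a user substitutes via the BLAST-tabular channel.

## Numerical and boundary choices

* QC boundaries: missing-proportion ≤ 0.25 inclusive (the "call ratio"
  threshold glossed as the least proportion of missing values); PIC and
  depth strictly greater-than, as printed. PIC uses Botstein's bi-allelic
  form by default; an expected-heterozygosity variant is available for
  platform compatibility, since vendor formulas are not published.
* Allele frequencies come from genotype calls (heterozygotes contribute one
  copy of each allele), not read counts, which are not part of the input.
* All internal coordinates are 0-based half-open; BLAST tabular (1-based
  inclusive, minus-strand subjects as sstart > send) and GFF3 are converted
  at the boundary.
* Degenerate inputs fail loudly: all-missing loci, empty FASTA records,
  zero unambiguous bases for GC content, empty query intervals,
  out-of-bounds registry lookups.
* The pipeline driver executes qc → build → mask → search/ingest → screen →
  genes → summarize; each stage reads the previous stage's files, so the
  chained driver equals manual stage invocation, and reruns with identical
  config and inputs are byte-identical (a manifest records package version,
  config hash and seed).

## Known limitations

* The built-in searcher is an acknowledged approximation to a full
  BLAST/BLAT service: ungapped only, no translated search, raw-length
  E-values. Per-species hit counts against real genome snapshots are
  therefore not comparable quantity-for-quantity; the tabular-ingestion
  path exists precisely so real search output can be substituted.
* K is exact only for match = +1 integer-mismatch schemes; other lattices
  are rejected.
* Conserved-gene identity across species depends on the supplied orthology
  map; the gene-name fallback assumes shared naming, which real annotation
  sets only partially satisfy.
* Consensus length equals the sum of tag lengths; per-tag trimming rules of
  real pipelines (which shorten some tags below 69 bp) are accepted as
  input but not inferred.
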