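# stagpipe

Comparative genome analysis from the *unused* part of SNP genotyping data.

Reduced-representation genotyping platforms (DArTseq and similar
genotyping-by-sequencing designs) score thousands of bi-allelic SNPs on short
restriction-site-anchored sequence tags — usually 69 bp, with a common 5'
``TGCAG`` left by the Pst I cut site. Population studies use only the single
polymorphic nucleotide; the flanking ~68 bp per tag are discarded. For
non-model species with no reference genome, those flanks are the only genomic
sequence available, and collectively they cover ~0.1–0.3% of the genome.

`stagpipe` turns them into something a comparative genomicist can use:

1. **Marker QC** — tag loci are screened on missing-call proportion
   (≤ 0.25), polymorphic information content (> 0.025, Botstein's bi-allelic
   PIC = 1 − p² − q² − 2p²q²) and mean read depth (> 60).
2. **STAG assembly** — each locus becomes a *STAG*: the tag sequence with the
   SNP replaced by its IUPAC ambiguity code (C/T → Y, A/G → R, …). STAGs are
   concatenated in ascending allele-ID order into one pseudo-contig per
   individual (missing calls become N-runs so columns stay aligned), and the
   per-column majority over individuals gives the population consensus — a
   concatenated *hypothetical genome*. A coordinate registry records every
   tag's offset.
3. **Repeat masking** — exact maximal-run detection of short-period tandem
   repeats (the (AC)n/(TG)n/(CT)n class that dominates tag data) plus a
   DUST-style low-complexity scan; externally produced mask intervals (e.g.
   library-based transposable-element annotation) can be ingested as BED.
4. **Homology search** — the masked consensus is searched against reference
   genomes either by ingesting standard 12-column BLAST tabular output or
   with a built-in ungapped seed-and-extend searcher (word size 11, X-drop
   20, both strands) under +1/−3 scoring. Hits carry Karlin–Altschul
   E-values E = K·m·n·e^(−λS) and are kept at E ≤ 1e−10.
5. **Junction false-positive screening** — concatenation creates a specific
   artifact: an alignment running across a tag junction can pick up a fresh
   ``TGCAG`` and masquerade as one long homology. A hit is a false positive
   iff (i) it is longer than the tag length, (ii) its query sequence starts
   with the motif, and (iii) the motif prefix continues ≥ k_min = 3 bases
   immediately after a spanned junction. Under a uniform base model a k-base
   run-on occurs by chance with probability (1/4)^k — 1 in 4 for ``T``,
   1 in 16 for ``TG``, …, 1 in 1024 for the full motif — so one- and
   two-base run-ons are too probable to be diagnostic and are excluded.
6. **Conserved genes** — hits are annotated with overlapping genes; genes
   supported in ≥ 3 species by non-repetitive, non-false-positive tag
   homologies (matched across species through an orthology map) form the
   evolutionarily conserved gene set, with per-species summary tables of
   hits / unique tags / aligned bp / % of genome.

A seeded synthetic-data module generates the whole study design at desk
scale — reference genomes with planted genes and repeat tracts, motif-
anchored tag loci, Hardy–Weinberg diploid genotypes with missing calls — with
ground truth for every planting, so the pipeline is testable end to end.

## Worked example

Simulate a three-species scenario with 5 planted conserved ortholog groups,
20 species-private genes and one repeat-borne decoy gene, then run the whole
pipeline:

```bash
stagpipe simulate --seed 7 --outdir data
stagpipe run --config config.yaml     # config points at the files in data/
```

The run directory then contains, among other stage outputs
(`consensus_stats.json`, `conserved_genes.tsv`, `species_summary.tsv`):

```
{
  "length_bp": 3864,
  "gc_content": 0.5096354166666667,
  "n_individuals": 90,
  "n_stags": 56
}
```

— 56 tags survived QC and were concatenated into a 3,864 bp consensus —

```
group_id  species  gene_id   supporting_stags  best_evalue
OG001     spA      spA_g002  1000047           4.4e-33
OG001     spB      spB_g013  1000047           4.4e-33
OG001     spC      spC_g010  1000047           4.4e-33
OG002     spA      spA_g007  1000022           4.4e-33
...
```

— exactly the five planted ortholog groups OG001–OG005 are recovered, each
supported in all three species by its planted tag; the decoy group, whose
only support overlaps a masked (AC)n tract, is excluded — and

```
species  ...  gene_hits  gene_stags  gene_bp  total_hits  total_stags  total_bp  pct_of_genome
spA      ...  13         16          900      13          16           900       23.29
spB      ...  13         16          901      13          16           901       23.32
spC      ...  12         17          834      12          17           834       21.58
```

— the per-species homology summary (hits vs. unique tag fragments vs.
aligned bp per category, and the proportion of the hypothetical genome with
homology in that species).

Each stage is also independently invokable (`stagpipe qc|build|mask|search|
screen|genes|summarize --config …`), and `blast_hits:` in the config
substitutes externally produced BLAST tabular files for the built-in
searcher.

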