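# homeoscan

Untangling successive whole-genome duplications (WGDs) in a genome.

Polyploid lineages — salmonids are the textbook vertebrate case — carry the
remains of several stacked genome duplications: two rounds shared by all
vertebrates, the teleost-specific round (~300 Mya), and, in salmonids, a
lineage-specific autotetraploidization (~80–90 Mya). Understanding any one of
these requires separating it from the others. `homeoscan` implements a
positional, reference-proteome-based methodology for doing so:

1. **Gene models from translated hits.** A genome is aligned (externally,
   e.g. with BLASTX) against a single well-annotated reference proteome; the
   12-column tabular hits are the pipeline's input. Within each (chromosome,
   strand, protein) group, only the best of genomically overlapping hits is
   retained, and hits are chained left-to-right into gene models whenever
   they advance in both genome and protein coordinates, lie within 50 kb and
   300 aa of each other, and re-cover at most 40 aa of protein. Each model is
   scored as *coverage × identity* (fraction of the reference protein covered
   times the length-weighted mean alignment identity). At each locus the best
   model plus any within 0.05 score units survive; models scoring < 0.3 are
   discarded. These are positional gene surrogates — fast, standardized
   across species, and deliberately tolerant of pseudogenes.
2. **Homeolog pairs and regions.** Models built from the same reference
   protein at different loci form homeolog candidate pairs. A window of 10
   consecutive gene models slides along each chromosome; windows containing
   enough partnered models are "dense", and merged runs of dense windows
   become homeologous regions (Table-style parameters: window size, required
   homeologs per window, minimum dense windows, boundary width).
3. **Tier separation.** Region calling runs twice — a stringent pass (≥ 3
   partnered models per window) that isolates the *most recent* duplication,
   whose duplicates are retained at the highest density, and a permissive
   pass (≥ 1) that also recovers older tiers. Where calls overlap, the
   densest relationship is labelled `recent`; the rest `older`.
4. **Ps/Pn per pair.** For every pair, exons are extracted, translated, and
   aligned back to the shared reference protein; codons paired through the
   protein are scored with Nei–Gojobori (1986) site and pathway counting
   (equal pathway weights, stop-codon paths excluded), giving the raw
   proportions of synonymous (Ps = Sd/S) and nonsynonymous (Pn = Nd/N)
   substitutions. No saturation correction is applied: between old
   duplicates, corrected rates can exceed 1 and become uninterpretable,
   while raw proportions stay comparable across genomes.
5. **Statistics.** Per-region homeolog density corrected by total gene
   density, per-tier summaries, two-tailed Welch's t-tests between groups, a
   literal "rp"-prefix ribosomal-protein filter, per-region Ps-vs-density
   scatter tables, and circos link/ribbon export.

A fully seeded simulator (`homeoscan.synthetic_data`) generates toy genomes
with planted serial WGDs — per-event retention probabilities and calibrated
synonymous/nonsynonymous divergence targets — so the entire pipeline is
testable without downloading genomes.

## Worked example

Simulate a two-duplication genome (one ancestral chromosome, 60 genes; an
old WGD with 20% duplicate retention and synonymous divergence 0.57, a
recent WGD with 55% retention and divergence 0.19 — a planted 3× contrast),
then run the pipeline:

```bash
homeoscan simulate --seed 3 --genes 60 -o demo/
cd demo
homeoscan gene-models --hits hits.tsv --proteome proteome.fa -o models.gff3
homeoscan ps --models models.gff3 --genome genome.fa --proteome proteome.fa -o pairs.tsv
homeoscan summarize --genome genome.fa --proteome proteome.fa --hits hits.tsv --tier recent
```

which prints (abridged):

```
wrote 105 gene models to models.gff3
wrote 53 pairs to pairs.tsv
{
  "tier": "recent",
  "n_pairs": 30,
  "n_pairs_reciprocal": 60,
  "mean_ps": 0.2089,
  "mean_pn": 0.0211,
  "mean_pn_over_ps": 0.1069,
  ...
}
```

105 gene models are built at the 105 planted loci; 30 of the 53 homeolog
pairs fall in the dense recent-tier regions, with mean Ps ≈ 0.21 against the
planted 0.19, while the older tier averages Ps ≈ 0.54 against the planted
0.57. `pairs.tsv` carries per-pair tier, Ps, Pn and exon counts;
`homeoscan export-circos` turns pairs or regions into circos link files.

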