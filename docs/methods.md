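# Methods

## The model

`homeoscan` treats homeolog detection as a purely positional problem. A
single reference proteome stands in for the gene complement of the analysed
genome: every place the genome can be tiled by translated-alignment hits to
a reference protein is a *gene model*, and two gene models of the same
reference protein at distinct loci are a candidate homeolog pair. Because a
whole-genome duplication (WGD) copies genes in blocks, true homeologous
regions show *runs* of paired models, and successive WGDs are distinguished
by two monotone signals: the most recent duplication has retained duplicates
at the highest density, and its pairs have accumulated the fewest synonymous
substitutions.

The unit conventions are fixed package-wide: 1-based inclusive coordinates
(GFF3/BLAST tabular style), minus-strand tabular hits identified by reversed
query coordinates, and alignment identity stored as a fraction in [0, 1]
even though the tabular dialect prints percent — the model score must live
in [0, 1] for the published-style 0.3 cutoff and 0.05 tie window to be
meaningful.

## Gene modelling

* **Best hit per locus.** Within a (chromosome, strand, protein) group,
  among genomically overlapping hits only the best survives; priority is bit
  score, then e-value, then position. The survivor set is the unique set in
  which no two kept hits overlap and every dropped hit overlaps a kept hit
  of higher priority.
* **Chaining.** Hits are visited in reading order (increasing genome
  coordinate on `+`, decreasing on `-`) and appended to the open chain when
  the protein advances, the nucleotide gap is ≤ 50,000, the protein gap
  ≤ 300 aa, and the protein overlap ≤ 40 aa. Greedy immediate commitment is
  used: because all three constraints bind only adjacent hits, breaking
  exactly at incompatible adjacencies yields the unique coarsest (fewest-
  chains) valid partition, which the tests confirm against exhaustive
  enumeration. Opposite-strand hits are never chained.
* **Scoring.** Score = (distinct reference positions covered / protein
  length) × (segment-length-weighted mean identity). "Average alignment
  score" is interpreted as mean identity fraction rather than raw bit
  score — bit scores are unbounded and would make a 0.3 threshold
  dimensionless. Coverage counts distinct positions, so double-covered
  protein (chains may re-cover ≤ 40 aa) is not double-counted.
* **Overlap resolution.** Locus overlap means ≥ 1 shared nucleotide on the
  same chromosome, strand-agnostic. The tie window is applied first (keep
  everything within 0.05 of the cluster best), the 0.3 cutoff second; with
  the other order a cluster whose best scores 0.33 would keep a 0.29 rival.
  Equal scores are both kept (they fall inside the window by construction).

## Region calling and tier assignment

Windows slide one gene model at a time (overlapping windows); a window is
dense when it contains at least `min_homeologs_per_window` models with a
partner on the paired chromosome. `min_homeologs_per_window` is an integer
count, not a fraction: the working parameter values (1 and 3 against windows
of 10–15) only make sense as counts. Runs of dense windows separated by
fewer than `boundary` consecutive sparse windows are merged; merged runs
with at least `min_windows` dense windows become regions. A region's scanned
interval spans the models of its first through last dense window; the
partner interval is the minimal span of the partners of its member models
and is not re-scanned. Only dense windows count toward `min_windows`, and a
run is closed only by a full `boundary`-length sparse stretch.

Tier separation runs the scan twice, with the stringent preset
(window 10 / ≥ 3 per window / ≥ 10 windows / boundary 9) and the permissive
preset (same but ≥ 1 per window), and reconciles: a stringent-scan region is
labelled `recent` iff no overlapping region of a *different* chromosome-pair
relationship out-ranks it on (density, then size, then partner name).
Overlap is tested on both of a region's intervals — a dense relationship
must also defend its partner chromosome, otherwise moderately dense old-tier
relationships on chromosomes that are only reached through a partner
interval would steal the `recent` label. Permissive-scan duplicates of a
winning relationship are dropped; everything else is `older`. Pairs inherit
the tier of the regions that contain both their loci, with `recent` taking
precedence.

## Ps / Pn estimation

Each exon (chained segment) is extracted, reverse-complemented if needed,
required to be a whole number of codons (the frame/length check — exons
failing it are dropped with a logged reason), translated, and aligned to the
shared reference protein with BLOSUM62 (gap open −11 / extend −1, free end
gaps, i.e. one best placement of the exon within the protein). Reference
positions covered ungapped by both models pair one codon from each.

Counting follows the classic Nei–Gojobori (1986) scheme as popularised by
SNAP:

* per codon position, each of the three possible single-nucleotide changes
  contributes 1/3 site, synonymous or nonsynonymous by its effect;
  stop-creating changes are excluded from the site totals entirely;
* sites are averaged between the two sequences;
* multi-position codon differences are averaged over all stop-free
  orderings of the single steps with equal weight; codon pairs with no
  stop-free pathway, a stop codon, or an ambiguous base are skipped whole;
* Ps = Sd/S and Pn = Nd/N with **no** multiple-hit correction (by design:
  near saturation, corrections can push rates past 1; raw proportions remain
  comparable if back-mutation rates are similar across the genomes
  compared). S = 0 yields a missing Ps, never 0.

Per-pair Ps is the *unweighted* mean over per-exon estimates (one estimate
per (exon_a, exon_b) group of the codon alignment); a codon-count-weighted
mean is available behind `length_weighted=True` but off by default. Pairs
with no usable exon carry missing values, excluded pairwise downstream.

## Statistics

Per-region quantities (homeolog density, gene density, their ratio) are
computed first and averaged across regions, never pooling genes; spreads are
standard deviations across regions. Welch's t-test (two-tailed,
Welch–Satterthwaite degrees of freedom) backs all group comparisons; no
multiple-testing correction is applied, matching the raw-reporting style of
the analyses this package supports. The ribosomal filter removes protein
symbols starting with "rp" literally and case-insensitively — it knowingly
catches the occasional rp-prefixed kinase, and therefore always logs what it
removed. Each region counts once per (interval_a, interval_b) relationship
when a chromosome segment participates in several relationships.

## The simulator

`synthetic_data` plants the structure the detector assumes: ancestral genes
of 150–300 codons on one or more chromosomes; per event, every chromosome
duplicates and each *new* gene copy survives with the event's retention
probability (the original copy always survives — a simplification that
keeps lineage bookkeeping exact); gene order is conserved across copies (no
rearrangements by default). Genes get 1–3 pseudo-exons of ≥ ~15 codons with
introns of 0.2–5 kb and intergenic spacers of 2–20 kb, on either strand.

Divergence is planted as single-nucleotide codon edits with disjoint codon
pools across all branches of a gene's copy tree, so a pair split at event
*i* differs at exactly the edits on its separating branches. Per-branch edit
counts are binomial with closed-form calibration: the branch between events
*i* and *i+1* carries (dᵢ − dᵢ₊₁)/2 of the gene's synonymous site total,
terminal branches d_last/2, making the expected pairwise difference
proportion of an event-*i* pair exactly dᵢ. Calibration holds to ±0.02 for
targets up to ~0.6; beyond that the disjoint-pool budget runs out — which is
also the regime where real sequences saturate. Emitted hit tables compute
identities from the actual sequences and report minus-strand hits with
reversed query coordinates.

The default two-tier fixture uses 400 ancestral genes, an old event
(retention 0.20, syn divergence 0.57, nonsyn 0.06) and a recent event
(retention 0.55, syn 0.19, nonsyn 0.02) — retention and divergence regimes
chosen to match what is reported for salmonid genomes, with the planted 3×
Ps contrast between tiers. What passing tests on this fixture do **not**
show: robustness to rearrangements (an optional concern exercised only via
mirrored-orientation tests), assembly gaps, tandem duplications,
heterogeneous substitution rates along genes, or alignment noise from an
actual translated aligner — hit identities here are exact by construction.

## Numerical and scale choices

* Degenerate inputs: empty hit files warn and return empty; chromosomes
  with fewer models than one window warn and yield no regions; zero-variance
  equal-mean Welch inputs give p = 1.
* Test and acceptance problem sizes (≤ 400 ancestral genes, 100-codon
  oracle alignments, 500-replicate calibrations) were chosen so the whole
  suite runs in well under a minute while keeping binomial confidence bands
  tight enough for the properties asserted.
* Determinism: all simulator randomness flows from one `numpy` generator
  seeded by the spec; identical seeds give byte-identical fixture files.
  Model ids are assigned after canonical (chrom, start) sorting, so any
  input row order yields the same model set.

## Known limitations

* Gene models are positional surrogates: no splice sites, no start/stop
  validation, pseudogenes included by design.
* The oldest duplications cannot be partitioned from each other — the
  method separates the *most recent* tier from the pooled rest, which is
  exactly what the density/Ps signals support.
* The `recent` label is relative: a genome without a recent WGD will still
  label its densest relationships `recent` under the stringent preset if
  they pass it.
* Ps saturates; between very old tiers it measures "old" but not "how old".
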