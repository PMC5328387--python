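"""Build positioned gene models from translated-alignment hits.

A gene model is a chain of local hits to one reference protein at one locus:
a positional gene surrogate, not a splice-aware prediction.  The pipeline is

1. :func:`best_hit_per_locus` — among genomically overlapping hits to the
   same protein (same chromosome and strand), keep only the best one;
2. :func:`chain_hits` — greedily chain hits that are sequential in both
   genome and protein coordinates, within 50 kb and 300 aa of each other and
   overlapping by at most 40 aa on the protein;
3. :func:`score_model` — score = protein coverage x mean alignment identity;
4. :func:`resolve_overlapping_models` — at each genomic locus keep the best
   model plus any within 0.05 score units of it, then drop models scoring
   below 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import AlignmentHit, ProteinRecord

logger = logging.getLogger("homeoscan")

MAX_NT_GAP = 50_000
MAX_AA_GAP = 300
MAX_AA_OVERLAP = 40
SCORE_THRESHOLD = 0.3
TIE_WINDOW = 0.05


@dataclass
class Segment:
    """One chained hit of a gene model (a pseudo-exon)."""

    genome_start: int
    genome_end: int
    prot_start: int
    prot_end: int
    identity_fraction: float

    @property
    def aa_length(self) -> int:
        return self.prot_end - self.prot_start + 1


@dataclass
class GeneModel:
    """An ordered chain of hits to one reference protein at one locus."""

    model_id: str
    chrom: str
    strand: str
    protein_id: str
    segments: list[Segment] = field(default_factory=list)
    coverage_fraction: float = 0.0
    mean_identity: float = 0.0
    score: float = 0.0

    @property
    def locus(self) -> tuple[int, int]:
        """Genomic interval spanning all segments (1-based inclusive)."""
        return (
            min(s.genome_start for s in self.segments),
            max(s.genome_end for s in self.segments),
        )

    @property
    def start(self) -> int:
        return self.locus[0]

    @property
    def end(self) -> int:
        return self.locus[1]


def _hit_priority(h: AlignmentHit) -> tuple:
    # higher bit score wins; ties: lower e-value, then lower genome_start
    return (-h.bit_score, h.evalue, h.genome_start, h.prot_start)


def best_hit_per_locus(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Keep only the best of genomically overlapping hits.

    Hits are grouped by (chromosome, strand, protein); within a group a hit
    is retained iff no already-retained hit of higher priority overlaps it on
    the genome.  Priority is bit score, then e-value, then position.
    """
    groups: dict[tuple, list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.chrom, h.strand, h.protein_id), []).append(h)
    kept: list[AlignmentHit] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=_hit_priority)
        accepted: list[AlignmentHit] = []
        for h in group:
            if not any(
                h.genome_start <= a.genome_end and a.genome_start <= h.genome_end
                for a in accepted
            ):
                accepted.append(h)
        kept.extend(accepted)
    kept.sort(key=lambda h: (h.chrom, h.strand, h.protein_id, h.genome_start, h.prot_start))
    return kept


def chainable(prev: AlignmentHit, nxt: AlignmentHit, max_nt_gap: int = MAX_NT_GAP,
              max_aa_gap: int = MAX_AA_GAP, max_aa_overlap: int = MAX_AA_OVERLAP) -> bool:
    """Can ``nxt`` extend a chain ending in ``prev``?

    ``prev``/``nxt`` are consecutive in reading order (increasing genome
    position on the plus strand, decreasing on minus).  The protein must
    advance, the nucleotide gap must be in [0, max_nt_gap], the protein gap
    at most ``max_aa_gap`` and the protein overlap at most ``max_aa_overlap``.
    """
    if prev.strand != nxt.strand or prev.chrom != nxt.chrom or prev.protein_id != nxt.protein_id:
        return False
    if prev.strand == "+":
        nt_gap = nxt.genome_start - prev.genome_end - 1
    else:
        nt_gap = prev.genome_start - nxt.genome_end - 1
    if nt_gap < 0 or nt_gap > max_nt_gap:
        return False
    if not (nxt.prot_start > prev.prot_start and nxt.prot_end > prev.prot_end):
        return False
    aa_gap = nxt.prot_start - prev.prot_end - 1
    if aa_gap > max_aa_gap:
        return False
    aa_overlap = prev.prot_end - nxt.prot_start + 1
    if aa_overlap > max_aa_overlap:
        return False
    return True


def chain_hits(hits: Sequence[AlignmentHit], max_nt_gap: int = MAX_NT_GAP,
               max_aa_gap: int = MAX_AA_GAP,
               max_aa_overlap: int = MAX_AA_OVERLAP) -> list[GeneModel]:
    """Greedily chain hits into gene models, left to right in reading order.

    Within each (chromosome, strand, protein) group, hits are visited in
    reading order and appended to the open chain whenever
    :func:`chainable` holds; otherwise the chain is closed and a new one
    started.  This yields the coarsest partition of the ordered hits into
    runs whose every adjacent pair satisfies the chaining constraints.
    """
    groups: dict[tuple, list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.chrom, h.strand, h.protein_id), []).append(h)
    models: list[GeneModel] = []
    for key in sorted(groups):
        chrom, strand, protein_id = key
        group = sorted(
            groups[key],
            key=lambda h: (h.genome_start, h.prot_start),
            reverse=(strand == "-"),
        )
        chain: list[AlignmentHit] = []
        for h in group:
            if chain and chainable(chain[-1], h, max_nt_gap, max_aa_gap, max_aa_overlap):
                chain.append(h)
            else:
                if chain:
                    models.append(_chain_to_model(chain))
                chain = [h]
        if chain:
            models.append(_chain_to_model(chain))
    models.sort(key=lambda m: (m.chrom, m.start, m.end, m.protein_id))
    for i, m in enumerate(models):
        m.model_id = f"gm{i:06d}"
    return models


def _chain_to_model(chain: list[AlignmentHit]) -> GeneModel:
    # chain is in reading order == increasing protein order
    segs = [
        Segment(h.genome_start, h.genome_end, h.prot_start, h.prot_end, h.identity_fraction)
        for h in chain
    ]
    return GeneModel(
        model_id="",
        chrom=chain[0].chrom,
        strand=chain[0].strand,
        protein_id=chain[0].protein_id,
        segments=segs,
    )


def score_model(model: GeneModel, protein_length: int) -> float:
    """Score a model: protein coverage times length-weighted mean identity.

    Coverage counts distinct covered amino-acid positions over the reference
    protein length; identity is the mean of per-segment identity fractions
    weighted by segment protein length.  Both factors lie in [0, 1], so the
    score does too.  The model's cached fields are updated in place.
    """
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    covered: set[int] = set()
    wsum = ident = 0.0
    for s in model.segments:
        covered.update(range(s.prot_start, s.prot_end + 1))
        wsum += s.aa_length
        ident += s.identity_fraction * s.aa_length
    model.coverage_fraction = len(covered) / protein_length
    model.mean_identity = ident / wsum
    model.score = model.coverage_fraction * model.mean_identity
    return model.score


def resolve_overlapping_models(models: Sequence[GeneModel], tie_window: float = TIE_WINDOW,
                               threshold: float = SCORE_THRESHOLD) -> list[GeneModel]:
    """Resolve competing models at each genomic locus.

    Models whose loci share at least one nucleotide on the same chromosome
    (strand-agnostic) compete: within each connected overlap cluster only
    models scoring within ``tie_window`` of the cluster best survive.  Models
    scoring below ``threshold`` are then removed.  Survivors are sorted by
    (chrom, start) and given stable sequential ids.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    kept: list[GeneModel] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.model_id))
        # sweep into connected overlap clusters
        cluster: list[GeneModel] = []
        cluster_end = -1
        clusters: list[list[GeneModel]] = []
        for m in ms:
            if cluster and m.start > cluster_end:
                clusters.append(cluster)
                cluster = []
                cluster_end = -1
            cluster.append(m)
            cluster_end = max(cluster_end, m.end)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            best = max(m.score for m in cl)
            kept.extend(m for m in cl if m.score >= best - tie_window)
    kept = [m for m in kept if m.score >= threshold]
    kept.sort(key=lambda m: (m.chrom, m.start, m.end, m.protein_id))
    for i, m in enumerate(kept):
        m.model_id = f"gm{i:06d}"
    return kept


def build_gene_models(hits: Iterable[AlignmentHit], proteome: Sequence[ProteinRecord],
                      max_nt_gap: int = MAX_NT_GAP, max_aa_gap: int = MAX_AA_GAP,
                      max_aa_overlap: int = MAX_AA_OVERLAP, threshold: float = SCORE_THRESHOLD,
                      tie_window: float = TIE_WINDOW) -> list[GeneModel]:
    """Full hit-to-model pipeline: best-hit filter, chaining, scoring,
    overlap resolution.  Hits to proteins absent from the proteome raise
    ``KeyError``."""
    lengths = {p.protein_id: p.length_aa for p in proteome}
    best = best_hit_per_locus(list(hits))
    models = chain_hits(best, max_nt_gap, max_aa_gap, max_aa_overlap)
    for m in models:
        if m.protein_id not in lengths:
            raise KeyError(f"protein {m.protein_id!r} absent from proteome")
        score_model(m, lengths[m.protein_id])
    return resolve_overlapping_models(models, tie_window=tie_window, threshold=threshold)
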