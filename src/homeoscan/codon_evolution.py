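"""Proportions of synonymous (Ps) and nonsynonymous (Pn) substitutions per
homeolog pair, via protein-guided codon alignment and Nei-Gojobori-style
site/pathway counting.

The estimates are deliberately *raw* proportions (observed differences over
potential sites), with no multiple-hit correction: between duplicates old
enough to approach mutational saturation, saturation corrections can push
rates above 1 and make values hard to interpret, whereas raw proportions
remain comparable across genomes if back-mutation rates are similar.

Counting conventions (the classic 1986 scheme as popularised by the SNAP
program):

* Each codon position contributes ``s/3`` synonymous and ``(v - s)/3``
  nonsynonymous sites, where ``v`` of its three possible single-nucleotide
  changes do not create a stop codon and ``s`` of those are synonymous.
  Stop-creating changes are excluded from the site counts entirely.
* Site totals are averaged between the two sequences of a pair.
* For codons differing at several positions, differences are classified by
  enumerating every order of the single-step mutations, discarding pathways
  passing through a stop codon, and averaging the remaining pathways with
  equal weight.  Codon pairs with no stop-free pathway, containing a stop
  codon, or containing an ambiguous nucleotide are skipped entirely.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .gene_modeling import GeneModel
from .io_formats import ProteinRecord

logger = logging.getLogger("homeoscan")

_NUCS = "ACGT"
_STOPS = frozenset(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)
_AA.update({c: "*" for c in _STOPS})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Returns (0, 0) for stop or ambiguous codons (callers skip those pairs).
    """
    if codon in _STOPS or any(c not in _NUCS for c in codon):
        return (0.0, 0.0)
    syn = nonsyn = 0.0
    aa = _AA[codon]
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1:]
            if mut in _STOPS:
                continue  # excluded from site counts
            if _AA[mut] == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return (syn, nonsyn)


@lru_cache(maxsize=None)
def codon_pair_diffs(codon_a: str, codon_b: str) -> Optional[tuple[float, float]]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averages over all stop-free minimal mutational pathways with equal
    weight; ``None`` when no stop-free pathway exists.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    syn_total = nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        cur = codon_a
        syn = nonsyn = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                break
            if _AA[cur] == _AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        else:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return (syn_total / n_paths, nonsyn_total / n_paths)


@dataclass
class CodonAlignment:
    """Paired codons of two gene models, tagged by source exon pair."""

    columns: list[tuple[str, str, tuple[int, int]]] = field(default_factory=list)
    dropped_exons: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.columns)

    def exon_groups(self) -> dict[tuple[int, int], list[tuple[str, str]]]:
        groups: dict[tuple[int, int], list[tuple[str, str]]] = {}
        for a, b, key in self.columns:
            groups.setdefault(key, []).append((a, b))
        return groups


@dataclass
class SubstitutionEstimate:
    """Nei-Gojobori site and difference counts with derived proportions."""

    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    n_codons: int = 0
    n_skipped: int = 0

    @property
    def ps(self) -> Optional[float]:
        return None if self.syn_sites == 0 else self.syn_diffs / self.syn_sites

    @property
    def pn(self) -> Optional[float]:
        return None if self.nonsyn_sites == 0 else self.nonsyn_diffs / self.nonsyn_sites

    @property
    def pn_over_ps(self) -> Optional[float]:
        if self.ps is None or self.pn is None or self.ps == 0:
            return None
        return self.pn / self.ps


def ng86_estimate(alignment: CodonAlignment | Sequence[tuple[str, str]]) -> SubstitutionEstimate:
    """Estimate Ps/Pn from paired codons.

    Accepts a :class:`CodonAlignment` or a plain sequence of
    ``(codon_a, codon_b)`` pairs.  Symmetric in its two sequences.
    """
    if isinstance(alignment, CodonAlignment):
        cols = [(a, b) for a, b, _ in alignment.columns]
    else:
        cols = list(alignment)
    est = SubstitutionEstimate()
    for a, b in cols:
        a, b = a.upper(), b.upper()
        if (
            len(a) != 3 or len(b) != 3
            or any(c not in _NUCS for c in a + b)
            or a in _STOPS or b in _STOPS
        ):
            est.n_skipped += 1
            continue
        diffs = codon_pair_diffs(a, b)
        if diffs is None:
            est.n_skipped += 1
            continue
        sa, na = codon_sites(a)
        sb, nb = codon_sites(b)
        # diffs are path-symmetric only after averaging both directions
        dba = codon_pair_diffs(b, a)
        sd = (diffs[0] + dba[0]) / 2
        nd = (diffs[1] + dba[1]) / 2
        est.syn_sites += (sa + sb) / 2
        est.nonsyn_sites += (na + nb) / 2
        est.syn_diffs += sd
        est.nonsyn_diffs += nd
        est.n_codons += 1
    return est


def extract_exon_sequences(model: GeneModel, genome: dict[str, str]) -> list[str]:
    """Extract each segment's nucleotide sequence, in protein order.

    Minus-strand segments are reverse-complemented so every returned string
    reads in the protein's direction.
    """
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} absent from genome")
    chrom_seq = genome[model.chrom]
    out = []
    for seg in model.segments:
        if seg.genome_start < 1 or seg.genome_end > len(chrom_seq):
            raise IndexError(
                f"segment {seg.genome_start}-{seg.genome_end} outside {model.chrom} "
                f"(length {len(chrom_seq)})"
            )
        seq = chrom_seq[seg.genome_start - 1:seg.genome_end]
        if model.strand == "-":
            seq = reverse_complement(seq)
        out.append(seq)
    return out


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    # free end gaps: each translated exon aligns locally within the protein
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _exon_codon_map(nt_seq: str, protein: str) -> Optional[dict[int, str]]:
    """Map 0-based reference-protein positions to this exon's codons.

    Returns None when the exon fails the frame/length check (nucleotide
    count not a multiple of three) or cannot be aligned.
    """
    if len(nt_seq) < 3 or len(nt_seq) % 3 != 0:
        return None
    peptide = str(Seq(nt_seq).translate())
    # aligner scores cannot handle stops cleanly; mask them
    masked = peptide.replace("*", "X")
    if set(masked) == {"X"}:
        return None
    try:
        aln = _ALIGNER.align(protein, masked)[0]
    except Exception:  # no valid alignment
        return None
    mapping: dict[int, str] = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            ref_pos = t0 + off
            q_pos = q0 + off
            mapping[ref_pos] = nt_seq[3 * q_pos:3 * q_pos + 3]
    return mapping


def align_pair_codons(model_a: GeneModel, model_b: GeneModel,
                      proteome: dict[str, ProteinRecord] | Sequence[ProteinRecord],
                      genome: dict[str, str]) -> CodonAlignment:
    """Protein-guided codon alignment of two gene models.

    Each exon of each model is translated in its hit frame and aligned to the
    shared reference protein; reference positions covered ungapped by both
    models contribute one codon column, tagged by the (exon_a, exon_b) index
    pair so per-exon estimates can be averaged.  Exons failing the
    frame/length check are dropped with a logged reason.
    """
    if model_a.protein_id != model_b.protein_id:
        raise ValueError("models must share a reference protein")
    if not isinstance(proteome, dict):
        proteome = {p.protein_id: p for p in proteome}
    protein = proteome[model_a.protein_id].sequence
    alignment = CodonAlignment()
    maps: list[dict[int, tuple[int, str]]] = []
    for which, model in (("a", model_a), ("b", model_b)):
        merged: dict[int, tuple[int, str]] = {}
        for idx, nt_seq in enumerate(extract_exon_sequences(model, genome)):
            m = _exon_codon_map(nt_seq, protein)
            if m is None:
                alignment.dropped_exons.append(f"{model.model_id}.seg{idx}")
                logger.debug("align_pair_codons: dropped exon %s.seg%d", model.model_id, idx)
                continue
            for ref_pos, codon in m.items():
                merged.setdefault(ref_pos, (idx, codon))  # first exon wins on overlap
        maps.append(merged)
    map_a, map_b = maps
    for ref_pos in sorted(set(map_a) & set(map_b)):
        ia, ca = map_a[ref_pos]
        ib, cb = map_b[ref_pos]
        alignment.columns.append((ca, cb, (ia, ib)))
    return alignment


def model_pair_ps(pair, genome: dict[str, str],
                  proteome: dict[str, ProteinRecord] | Sequence[ProteinRecord],
                  length_weighted: bool = False) -> tuple[Optional[float], Optional[float]]:
    """Attach Ps/Pn to a homeolog pair.

    Per-exon estimates (one per (exon_a, exon_b) group of the codon
    alignment) are averaged -- unweighted by default, optionally weighted by
    the number of codons compared.  Pairs with no usable exon get missing
    values, which downstream averages exclude.
    """
    alignment = align_pair_codons(pair.model_a, pair.model_b, proteome, genome)
    ps_parts: list[tuple[float, int]] = []
    pn_parts: list[tuple[float, int]] = []
    groups = alignment.exon_groups()
    for key in sorted(groups):
        est = ng86_estimate(groups[key])
        if est.ps is not None:
            ps_parts.append((est.ps, est.n_codons))
        if est.pn is not None:
            pn_parts.append((est.pn, est.n_codons))

    def _mean(parts: list[tuple[float, int]]) -> Optional[float]:
        if not parts:
            return None
        if length_weighted:
            wsum = sum(w for _, w in parts)
            return sum(v * w for v, w in parts) / wsum if wsum else None
        return sum(v for v, _ in parts) / len(parts)

    pair.ps = _mean(ps_parts)
    pair.pn = _mean(pn_parts)
    pair.n_exons_used = len(ps_parts)
    return pair.ps, pair.pn


def attach_ps_to_pairs(pairs, genome: dict[str, str],
                       proteome: dict[str, ProteinRecord] | Sequence[ProteinRecord]) -> None:
    """Compute Ps/Pn for every pair in place."""
    if not isinstance(proteome, dict):
        proteome = {p.protein_id: p for p in proteome}
    for pair in pairs:
        model_pair_ps(pair, genome, proteome)
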