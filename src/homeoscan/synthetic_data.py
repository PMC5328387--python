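"""Toy genomes with planted serial whole-genome duplications (WGDs).

The generator emulates the structure the detection pipeline assumes: a set
of ancestral protein-coding genes laid out on chromosomes; one or more WGD
events, each duplicating every chromosome and then dropping each *new* gene
copy independently with probability ``1 - retention``; and codon-level
divergence accumulating between copies, with separate synonymous and
nonsynonymous budgets per event so that pairs split at a recent event show
low Ps and pairs split at an old event show high Ps.

Divergence is introduced by single-nucleotide codon edits rather than a full
codon-substitution model.  Within each gene, every edit hits a codon no
other edit in the gene's whole copy tree touches, so the pairwise difference
count between two copies is exactly the sum of the edit counts on the
branches separating them; per-branch edit counts are binomial draws whose
expectations are calibrated in closed form against the gene's synonymous /
nonsynonymous site totals.  This keeps the planted pairwise difference
proportions on target (within sampling noise) without any iteration, at the
price of evolutionary realism the detection tests do not need.

The translated ancestral genes double as the reference proteome, mirroring
the single-reference-species design of the pipeline itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codon_evolution import _AA, _NUCS, _STOPS, codon_sites, reverse_complement
from .io_formats import ProteinRecord

logger = logging.getLogger("homeoscan")

NON_STOP_CODONS = sorted(set(_AA) - _STOPS)

# per-codon single-nucleotide neighbours, split by effect (stops excluded)
_SYN_CHOICES: dict[str, list[str]] = {}
_NONSYN_CHOICES: dict[str, list[str]] = {}
for _c in NON_STOP_CODONS:
    syn, nonsyn = [], []
    for _pos in range(3):
        for _n in _NUCS:
            if _n == _c[_pos]:
                continue
            _m = _c[:_pos] + _n + _c[_pos + 1:]
            if _m in _STOPS:
                continue
            (syn if _AA[_m] == _AA[_c] else nonsyn).append(_m)
    _SYN_CHOICES[_c] = syn
    _NONSYN_CHOICES[_c] = nonsyn


class ConfigurationError(ValueError):
    """Raised for infeasible simulation settings."""


@dataclass(frozen=True)
class WgdEvent:
    """One whole-genome duplication.

    ``retention`` is the probability that the new copy of a gene survives;
    ``syn_divergence`` / ``nonsyn_divergence`` are the target pairwise
    difference proportions (per synonymous / nonsynonymous site) between the
    two copies a pair split at this event shows today.
    """

    retention: float
    syn_divergence: float
    nonsyn_divergence: float

    def __post_init__(self) -> None:
        for name in ("retention", "syn_divergence", "nonsyn_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class WgdSpec:
    """Full simulation settings.  ``events`` are ordered oldest to newest;
    divergence targets must be nonincreasing along the list (older splits
    are at least as diverged as newer ones)."""

    n_ancestral_genes: int = 400
    n_chromosomes: int = 1
    gene_length_codons: tuple[int, int] = (150, 300)
    intergenic_length: tuple[int, int] = (2_000, 20_000)
    exons_per_gene: tuple[int, int] = (1, 3)
    intron_length: tuple[int, int] = (200, 5_000)
    minus_strand_prob: float = 0.3
    ribosomal_symbol_prob: float = 0.05
    events: list[WgdEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("need at least one gene and one chromosome")
        for older, newer in zip(self.events, self.events[1:]):
            if newer.syn_divergence > older.syn_divergence or \
               newer.nonsyn_divergence > older.nonsyn_divergence:
                raise ConfigurationError("divergence must be nonincreasing from old to new events")
        # closed-form budget check: expected codons edited per gene must fit.
        # ~0.7 syn sites and ~2.2 nonsyn sites per random codon; each edit
        # consumes one codon and codons are never reused within a gene.
        if self.events:
            d_syn = [e.syn_divergence for e in self.events] + [0.0]
            d_non = [e.nonsyn_divergence for e in self.events] + [0.0]
            copies = 1.0
            frac = 0.0
            for i, _ in enumerate(self.events):
                copies *= 2  # worst case: all duplicates retained
                frac += copies * ((d_syn[i] - d_syn[i + 1]) / 2 * 0.75
                                  + (d_non[i] - d_non[i + 1]) / 2 * 2.3)
            if frac > 0.92:
                raise ConfigurationError(
                    f"divergence targets need ~{frac:.2f} edited codons per codon; "
                    "infeasible without reusing sites"
                )


@dataclass
class TrueLocus:
    """One emitted gene copy and where it lives."""

    locus_id: str
    gene_id: int
    protein_id: str
    chrom: str
    start: int
    end: int
    strand: str
    path: str  # one '0'/'1' per event: '1' = the new copy at that event
    exons: list[tuple[int, int, int, int]]  # (genome_start, genome_end, prot_start, prot_end)
    cds: str  # spliced coding sequence, protein direction


@dataclass
class TruePair:
    gene_id: int
    protein_id: str
    locus_a: str
    locus_b: str
    split_event: int  # index into spec.events (0 = oldest)
    tier: str  # "recent" for the final event, else "older"
    syn_diffs: int
    nonsyn_diffs: int
    ps_planted: float
    pn_planted: float


@dataclass
class WgdTruthSet:
    """The simulator's planted record of lineages and pairs."""

    spec: WgdSpec
    loci: dict[str, TrueLocus] = field(default_factory=dict)
    pairs: list[TruePair] = field(default_factory=list)

    def pairs_of_tier(self, tier: str) -> list[TruePair]:
        return [p for p in self.pairs if p.tier == tier]


@dataclass
class SimulatedGenome:
    """Complete pipeline input bundle."""

    genome: dict[str, str]
    proteome: list[ProteinRecord]
    truth: WgdTruthSet


@dataclass
class _Copy:
    path: str
    muts: dict  # codon index -> (new_codon, is_syn)


def _random_symbol(rng: np.random.Generator, gid: int, ribosomal: bool) -> str:
    if ribosomal:
        return f"rp{'ls'[int(rng.integers(2))]}{gid % 40 + 1}"
    letters = "abcdefghijklmnopqrstuvwxyz"
    return "".join(letters[int(i)] for i in rng.integers(0, 26, size=4)) + str(gid % 10)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _mutate_copies(codons: list[str], copies: list[_Copy], rng: np.random.Generator,
                   e_syn: float, e_non: float, syn_order: list[int],
                   non_order: list[int], used: set[int],
                   s_total: float, n_total: float) -> None:
    """Apply one inter-event interval's edits to each copy independently."""
    for c in copies:
        k_syn = int(rng.binomial(max(1, round(s_total)), e_syn)) if e_syn > 0 else 0
        k_non = int(rng.binomial(max(1, round(n_total)), e_non)) if e_non > 0 else 0
        for k, order, choices, is_syn in (
            (k_syn, syn_order, _SYN_CHOICES, True),
            (k_non, non_order, _NONSYN_CHOICES, False),
        ):
            taken = 0
            while taken < k and order:
                idx = order.pop()
                if idx in used:
                    continue
                used.add(idx)
                options = choices[codons[idx]]
                c.muts[idx] = (options[int(rng.integers(len(options)))], is_syn)
                taken += 1
            if taken < k:
                logger.debug("edit budget truncated (%d of %d)", taken, k)


def simulate_genome(spec: WgdSpec) -> SimulatedGenome:
    """Run the simulation.  Deterministic for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    K = len(spec.events)
    d_syn = [e.syn_divergence for e in spec.events] + [0.0]
    d_non = [e.nonsyn_divergence for e in spec.events] + [0.0]

    proteome: list[ProteinRecord] = []
    gene_codons: list[list[str]] = []
    gene_copies: list[list[_Copy]] = []

    for gid in range(spec.n_ancestral_genes):
        lo, hi = spec.gene_length_codons
        length = int(rng.integers(lo, hi + 1))
        codons = [NON_STOP_CODONS[int(i)] for i in rng.integers(0, len(NON_STOP_CODONS), length)]
        protein = "".join(_AA[c] for c in codons)
        pid = f"anc{gid:05d}"
        symbol = _random_symbol(rng, gid, rng.random() < spec.ribosomal_symbol_prob)
        proteome.append(ProteinRecord(pid, protein, symbol=symbol,
                                      description=f"{symbol} synthetic ancestral protein"))
        s_total = sum(codon_sites(c)[0] for c in codons)
        n_total = sum(codon_sites(c)[1] for c in codons)
        syn_order = [i for i in rng.permutation(length) if _SYN_CHOICES[codons[i]]]
        non_order = [i for i in rng.permutation(length) if _NONSYN_CHOICES[codons[i]]]
        used: set[int] = set()

        copies = [_Copy(path="", muts={})]
        for ei, event in enumerate(spec.events):
            duplicated: list[_Copy] = []
            for c in copies:
                duplicated.append(_Copy(path=c.path + "0", muts=dict(c.muts)))
                if rng.random() < event.retention:
                    duplicated.append(_Copy(path=c.path + "1", muts=dict(c.muts)))
            copies = duplicated
            e_syn = (d_syn[ei] - d_syn[ei + 1]) / 2
            e_non = (d_non[ei] - d_non[ei + 1]) / 2
            _mutate_copies(codons, copies, rng, e_syn, e_non,
                           syn_order, non_order, used, s_total, n_total)
        gene_codons.append(codons)
        gene_copies.append(copies)

    # --- lay copies out on chromosomes -----------------------------------
    chrom_paths = [""]
    for _ in range(K):
        chrom_paths = [p + b for p in chrom_paths for b in "01"]

    truth = WgdTruthSet(spec=spec)
    genome: dict[str, str] = {}
    gene_locus_ids: list[dict[str, str]] = [dict() for _ in range(spec.n_ancestral_genes)]

    for c in range(spec.n_chromosomes):
        gids = [g for g in range(spec.n_ancestral_genes)
                if g * spec.n_chromosomes // spec.n_ancestral_genes == c]
        for path in chrom_paths:
            chrom = f"chr{c + 1}" + "".join("ab"[int(bit)] for bit in path)
            parts: list[str] = []
            pos = 1
            for gid in gids:
                copy = next((cp for cp in gene_copies[gid] if cp.path == path), None)
                if copy is None:
                    continue
                ig = int(rng.integers(*spec.intergenic_length)) if spec.intergenic_length[1] else 0
                parts.append(_random_nt(rng, ig))
                pos += ig
                codons = [copy.muts.get(i, (anc, None))[0]
                          for i, anc in enumerate(gene_codons[gid])]
                cds = "".join(codons)
                locus = _place_gene(rng, spec, chrom, pos, gid, path, codons, cds, truth)
                parts.append(locus_nt(locus, cds))
                pos = locus.end + 1
                gene_locus_ids[gid][path] = locus.locus_id
            parts.append(_random_nt(rng, int(rng.integers(200, 1000))))
            genome[chrom] = "".join(parts)

    # --- planted pairs ----------------------------------------------------
    for gid in range(spec.n_ancestral_genes):
        copies = gene_copies[gid]
        s_total = sum(codon_sites(c)[0] for c in gene_codons[gid])
        n_total = sum(codon_sites(c)[1] for c in gene_codons[gid])
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                a, b = copies[i], copies[j]
                split = next(k for k in range(K) if a.path[k] != b.path[k])
                sd = nd = 0
                for idx in set(a.muts) ^ set(b.muts):
                    _, is_syn = a.muts.get(idx) or b.muts[idx]
                    if is_syn:
                        sd += 1
                    else:
                        nd += 1
                truth.pairs.append(
                    TruePair(
                        gene_id=gid,
                        protein_id=f"anc{gid:05d}",
                        locus_a=gene_locus_ids[gid][a.path],
                        locus_b=gene_locus_ids[gid][b.path],
                        split_event=split,
                        tier="recent" if split == K - 1 else "older",
                        syn_diffs=sd,
                        nonsyn_diffs=nd,
                        ps_planted=sd / s_total if s_total else 0.0,
                        pn_planted=nd / n_total if n_total else 0.0,
                    )
                )
    return SimulatedGenome(genome=genome, proteome=proteome, truth=truth)


def _place_gene(rng: np.random.Generator, spec: WgdSpec, chrom: str, pos: int,
                gid: int, path: str, codons: list[str], cds: str,
                truth: WgdTruthSet) -> TrueLocus:
    """Choose exon/intron structure and strand, register the locus."""
    length = len(codons)
    lo, hi = spec.exons_per_gene
    n_exons = min(int(rng.integers(lo, hi + 1)), max(1, length // 30))
    # near-equal exon sizes with jitter; keeps every exon >= ~15 codons so
    # each pseudo-exon remains independently alignable
    chunk = length / n_exons
    cuts = [
        int(round(k * chunk + rng.integers(-int(chunk // 4), int(chunk // 4) + 1)))
        for k in range(1, n_exons)
    ]
    bounds = [0] + cuts + [length]
    exon_codon_ranges = list(zip(bounds[:-1], bounds[1:]))
    introns = [int(rng.integers(*spec.intron_length)) for _ in range(n_exons - 1)]
    strand = "-" if rng.random() < spec.minus_strand_prob else "+"

    # forward-sense gene string with introns; physical placement may be
    # reverse-complemented below
    gene_len = 3 * length + sum(introns)
    exons: list[tuple[int, int, int, int]] = []
    offset = 0  # nt offset within forward-sense gene string
    for k, (c0, c1) in enumerate(exon_codon_ranges):
        exon_nt = 3 * (c1 - c0)
        if strand == "+":
            gs = pos + offset
            ge = gs + exon_nt - 1
        else:
            ge = pos + gene_len - 1 - offset
            gs = ge - exon_nt + 1
        exons.append((gs, ge, c0 + 1, c1))
        offset += exon_nt
        if k < n_exons - 1:
            offset += introns[k]
    locus = TrueLocus(
        locus_id=f"{chrom}:g{gid:05d}",
        gene_id=gid,
        protein_id=f"anc{gid:05d}",
        chrom=chrom,
        start=pos,
        end=pos + gene_len - 1,
        strand=strand,
        path=path,
        exons=exons,
        cds=cds,
    )
    # stash intron sequences on the locus for genome assembly
    locus._introns = [_random_nt(rng, n) for n in introns]  # type: ignore[attr-defined]
    locus._exon_codon_ranges = exon_codon_ranges  # type: ignore[attr-defined]
    truth.loci[locus.locus_id] = locus
    return locus


def locus_nt(locus: TrueLocus, cds: str) -> str:
    """Physical nucleotide string of a locus (genome forward strand)."""
    parts = []
    ranges = locus._exon_codon_ranges  # type: ignore[attr-defined]
    introns = locus._introns  # type: ignore[attr-defined]
    for k, (c0, c1) in enumerate(ranges):
        parts.append(cds[3 * c0:3 * c1])
        if k < len(introns):
            parts.append(introns[k])
    forward = "".join(parts)
    return forward if locus.strand == "+" else reverse_complement(forward)


def emit_hits(sim: SimulatedGenome) -> list[tuple]:
    """Tabular alignment rows for every exon of every locus.

    Identities are computed from the actual sequences (translated exon vs
    the reference protein slice).  Minus-strand rows carry reversed genome
    coordinates, as a translated aligner would report them.  Returns rows as
    12-tuples in the standard column order.
    """
    proteins = {p.protein_id: p.sequence for p in sim.proteome}
    rows: list[tuple] = []
    for locus_id in sorted(sim.truth.loci):
        locus = sim.truth.loci[locus_id]
        protein = proteins[locus.protein_id]
        for gs, ge, ps, pe in locus.exons:
            nt = sim.genome[locus.chrom][gs - 1:ge]
            if locus.strand == "-":
                nt = reverse_complement(nt)
            pep = "".join(_AA.get(nt[i:i + 3], "X") for i in range(0, len(nt), 3))
            ref = protein[ps - 1:pe]
            matches = sum(1 for x, y in zip(pep, ref) if x == y)
            aa_len = pe - ps + 1
            ident = matches / aa_len
            bit = round(2.0 * aa_len * max(ident, 0.05), 1)
            evalue = 10.0 ** -min(180.0, bit / 5.0)
            qstart, qend = (gs, ge) if locus.strand == "+" else (ge, gs)
            rows.append(
                (locus.chrom, locus.protein_id, round(100.0 * ident, 2), aa_len,
                 aa_len - matches, 0, qstart, qend, ps, pe, f"{evalue:.2e}", bit)
            )
    return rows


def write_hits_tsv(rows: Sequence[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_fixture(sim: SimulatedGenome, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, proteome.fa, truth.gff3, hits.tsv, truth_pairs.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("genome", "genome.fa"), ("proteome", "proteome.fa"),
        ("truth", "truth.gff3"), ("hits", "hits.tsv"), ("pairs", "truth_pairs.tsv"),
    ]}
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(sim.genome):
            fh.write(f">{chrom}\n")
            seq = sim.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    with open(paths["proteome"], "w") as fh:
        for p in sim.proteome:
            fh.write(f">{p.protein_id} {p.description}\n")
            for i in range(0, len(p.sequence), 80):
                fh.write(p.sequence[i:i + 80] + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("##gff-version 3\n")
        for locus_id in sorted(sim.truth.loci):
            l = sim.truth.loci[locus_id]
            fh.write(
                f"{l.chrom}\thomeoscan-sim\tgene\t{l.start}\t{l.end}\t.\t{l.strand}\t.\t"
                f"ID={l.locus_id};gene_id=g{l.gene_id:05d};protein_id={l.protein_id};"
                f"path={l.path}\n"
            )
            for k, (gs, ge, ps, pe) in enumerate(l.exons):
                fh.write(
                    f"{l.chrom}\thomeoscan-sim\texon\t{gs}\t{ge}\t.\t{l.strand}\t.\t"
                    f"ID={l.locus_id}.e{k};Parent={l.locus_id};prot_start={ps};prot_end={pe}\n"
                )
    write_hits_tsv(emit_hits(sim), paths["hits"])
    with open(paths["pairs"], "w") as fh:
        fh.write("gene_id\tprotein_id\tlocus_a\tlocus_b\tsplit_event\ttier\t"
                 "syn_diffs\tnonsyn_diffs\tps_planted\tpn_planted\n")
        for p in sim.truth.pairs:
            fh.write(
                f"g{p.gene_id:05d}\t{p.protein_id}\t{p.locus_a}\t{p.locus_b}\t"
                f"{p.split_event}\t{p.tier}\t{p.syn_diffs}\t{p.nonsyn_diffs}\t"
                f"{p.ps_planted:.6f}\t{p.pn_planted:.6f}\n"
            )
    return paths


def default_two_tier_fixture(seed: int = 0, n_genes: int = 400) -> SimulatedGenome:
    """The standard two-duplication test genome.

    One ancestral chromosome, two WGDs: an old event with 20% duplicate
    retention and near-saturation synonymous divergence (0.57), and a recent
    event with 55% retention and low divergence (0.19) -- a 3:1 divergence
    contrast between tiers at realistic retention levels.  Four final
    chromosomes.
    """
    spec = WgdSpec(
        n_ancestral_genes=n_genes,
        n_chromosomes=1,
        events=[
            WgdEvent(retention=0.20, syn_divergence=0.57, nonsyn_divergence=0.06),
            WgdEvent(retention=0.55, syn_divergence=0.19, nonsyn_divergence=0.02),
        ],
        seed=seed,
    )
    return simulate_genome(spec)


def simulate_codon_pairs(n_pairs: int, n_codons: int, p_syn: float,
                         p_nonsyn: float = 0.0, seed: int = 0
                         ) -> list[list[tuple[str, str]]]:
    """Independent codon-sequence pairs with a planted per-site synonymous
    difference proportion ``p_syn`` (and optionally ``p_nonsyn``).

    Each pair is a random stop-free ancestor and a copy carrying
    ``Binomial(round(S), p_syn)`` synonymous single-nucleotide edits at
    distinct codons (likewise for nonsynonymous edits), so the expected
    difference proportion per synonymous site equals ``p_syn``.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        codons = [NON_STOP_CODONS[int(i)]
                  for i in rng.integers(0, len(NON_STOP_CODONS), n_codons)]
        s_total = sum(codon_sites(c)[0] for c in codons)
        n_total = sum(codon_sites(c)[1] for c in codons)
        order = list(rng.permutation(n_codons))
        other = list(codons)
        for p, choices, total in ((p_syn, _SYN_CHOICES, s_total),
                                  (p_nonsyn, _NONSYN_CHOICES, n_total)):
            if p <= 0:
                continue
            k = int(rng.binomial(round(total), p))
            taken = 0
            while taken < k and order:
                idx = order.pop()
                options = choices[codons[idx]]
                if not options:
                    continue
                other[idx] = options[int(rng.integers(len(options)))]
                taken += 1
        pairs.append(list(zip(codons, other)))
    return pairs
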