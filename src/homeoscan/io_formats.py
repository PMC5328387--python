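"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive throughout the package, matching GFF3
and the 12-column tabular alignment dialect (``qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore``) in which the
query is a genomic sequence and the subject a reference protein.  Translated
hits on the minus strand arrive with ``qstart > qend``; they are normalised
on ingest and the strand recorded.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("homeoscan")

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ProteinRecord:
    """One entry of the reference proteome.

    ``symbol`` is the short gene symbol (lower-cased on access for the
    ribosomal-protein filter); by convention it is the first whitespace
    token of the FASTA description, or empty when absent.
    """

    protein_id: str
    sequence: str
    symbol: str = ""
    description: str = ""

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """A single local translated-alignment hit (genome segment vs protein)."""

    chrom: str
    genome_start: int
    genome_end: int
    strand: str
    protein_id: str
    prot_start: int
    prot_end: int
    identity_fraction: float
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.genome_start > self.genome_end:
            raise ValueError("genome_start must be <= genome_end after normalisation")
        if self.prot_start > self.prot_end:
            raise ValueError("prot_start must be <= prot_end")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` pairs.

    Raises :class:`FormatError` (with a line number) for an empty file, a
    malformed first header, or duplicate record ids.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        first = None
        for line in fh:
            lineno += 1
            if line.strip():
                first = line
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: malformed FASTA header at line {lineno}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    seen: set[str] = set()
    dups = []
    for rid, _ in records:
        if rid in seen:
            dups.append(rid)
        seen.add(rid)
    if dups:
        raise FormatError(f"{path}: duplicate FASTA ids: {sorted(set(dups))}")
    for rid, seq in records:
        if not seq:
            raise FormatError(f"{path}: record {rid!r} has an empty sequence")
    return records


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA as ``{chrom: sequence}`` (uppercased)."""
    return {name: seq.upper() for name, seq in read_fasta(path)}


def load_proteome(path: str | Path, dedupe: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Header convention: ``>protein_id symbol free text...``.  With
    ``dedupe=True`` the records are passed through :func:`dedupe_proteome`.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        # description repeats the id as its first token
        rest = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
        symbol = rest.split()[0] if rest else ""
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_LETTERS
        if bad:
            raise FormatError(f"{path}: record {rec.id!r} has non-amino-acid letters {sorted(bad)}")
        records.append(ProteinRecord(rec.id, seq, symbol=symbol, description=rest))
    if not records:
        raise FormatError(f"{path}: empty FASTA file (line 1)")
    return dedupe_proteome(records) if dedupe else records


def dedupe_proteome(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop partial and redundant proteins from a reference set.

    A record whose description contains the word "partial" is removed; among
    records with identical sequences only the first is retained.
    """
    out: list[ProteinRecord] = []
    seen_seqs: set[str] = set()
    n_partial = n_redundant = 0
    for rec in records:
        if re.search(r"\bpartial\b", rec.description, flags=re.IGNORECASE):
            n_partial += 1
            continue
        if rec.sequence in seen_seqs:
            n_redundant += 1
            continue
        seen_seqs.add(rec.sequence)
        out.append(rec)
    if n_partial or n_redundant:
        logger.info(
            "dedupe_proteome: removed %d partial and %d redundant records", n_partial, n_redundant
        )
    return out


def read_alignment_hits(path: str | Path, evalue_cutoff: float = 1e-4) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file into :class:`AlignmentHit` rows.

    Rows with ``evalue > evalue_cutoff`` are dropped (count logged).  Rows
    with ``qstart > qend`` are minus-strand translated hits; coordinates are
    swapped and strand set to ``-``.  Identity is converted from percent to a
    fraction in [0, 1].
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: expected 12 tab-separated columns")
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bit = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric field ({exc})") from None
            if evalue > evalue_cutoff:
                n_dropped += 1
                continue
            strand = "+"
            if qstart > qend:
                strand = "-"
                qstart, qend = qend, qstart
            if sstart > send:
                sstart, send = send, sstart
            hits.append(
                AlignmentHit(
                    chrom=fields[0],
                    genome_start=qstart,
                    genome_end=qend,
                    strand=strand,
                    protein_id=fields[1],
                    prot_start=sstart,
                    prot_end=send,
                    identity_fraction=pident / 100.0,
                    bit_score=bit,
                    evalue=evalue,
                )
            )
    if n_dropped:
        logger.info("read_alignment_hits: dropped %d rows above e-value %g", n_dropped, evalue_cutoff)
    if not hits:
        logger.warning("read_alignment_hits: no hits retained from %s", path)
    return hits


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_gff3(models: Iterable, path: str | Path) -> None:
    """Write gene models as GFF3: one ``gene`` feature per model, one ``CDS``
    child per chained segment.  Output is sorted by (chrom, start) and
    round-trips losslessly through :func:`read_gff3`.
    """
    from .gene_modeling import GeneModel  # local import to avoid a cycle

    path = Path(path)
    models = sorted(models, key=lambda m: (m.chrom, m.locus[0], m.locus[1], m.model_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            if not m.segments:
                raise ValueError(f"model {m.model_id} has no segments")
            attrs = (
                f"ID={m.model_id};protein_id={m.protein_id};"
                f"coverage={_fmt(m.coverage_fraction)};mean_identity={_fmt(m.mean_identity)};"
                f"model_score={_fmt(m.score)}"
            )
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        "homeoscan",
                        "gene",
                        str(m.locus[0]),
                        str(m.locus[1]),
                        _fmt(m.score),
                        m.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for i, seg in enumerate(m.segments):
                cattrs = (
                    f"ID={m.model_id}.seg{i};Parent={m.model_id};"
                    f"prot_start={seg.prot_start};prot_end={seg.prot_end};"
                    f"identity={_fmt(seg.identity_fraction)}"
                )
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            "homeoscan",
                            "CDS",
                            str(seg.genome_start),
                            str(seg.genome_end),
                            ".",
                            m.strand,
                            "0",
                            cattrs,
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.split(";"):
        if part:
            k, _, v = part.partition("=")
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list:
    """Read gene models written by :func:`write_gff3`."""
    from .gene_modeling import GeneModel, Segment

    path = Path(path)
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            attrs = _parse_attrs(f[8])
            if f[2] == "gene":
                mid = attrs["ID"]
                genes[mid] = GeneModel(
                    model_id=mid,
                    chrom=f[0],
                    strand=f[6],
                    protein_id=attrs["protein_id"],
                    segments=[],
                    coverage_fraction=float(attrs["coverage"]),
                    mean_identity=float(attrs["mean_identity"]),
                    score=float(attrs["model_score"]),
                )
                order.append(mid)
            elif f[2] == "CDS":
                parent = attrs["Parent"]
                genes[parent].segments.append(
                    Segment(
                        genome_start=int(f[3]),
                        genome_end=int(f[4]),
                        prot_start=int(attrs["prot_start"]),
                        prot_end=int(attrs["prot_end"]),
                        identity_fraction=float(attrs["identity"]),
                    )
                )
    return [genes[mid] for mid in order]


def write_pairs_tsv(pairs: Iterable, path: str | Path) -> None:
    """Write homeolog pairs as a TSV keyed by model ids."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("model_a\tmodel_b\tprotein_id\ttier\tps\tpn\tn_exons_used\n")
        for p in pairs:
            ps = "" if p.ps is None else _fmt(p.ps)
            pn = "" if p.pn is None else _fmt(p.pn)
            fh.write(
                f"{p.model_a.model_id}\t{p.model_b.model_id}\t{p.protein_id}\t"
                f"{p.tier}\t{ps}\t{pn}\t{p.n_exons_used}\n"
            )


def read_pairs_tsv(path: str | Path, models_by_id: dict) -> list:
    """Read a pairs TSV back, resolving model ids against ``models_by_id``."""
    from .homeology import HomeologPair

    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("model_a"):
            raise FormatError(f"{path}: missing pairs header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            p = HomeologPair(
                model_a=models_by_id[f[0]],
                model_b=models_by_id[f[1]],
                protein_id=f[2],
                tier=f[3],
                ps=float(f[4]) if f[4] else None,
                pn=float(f[5]) if f[5] else None,
            )
            p.n_exons_used = int(f[6]) if len(f) > 6 and f[6] else 0
            pairs.append(p)
    return pairs


def write_circos_links(items: Iterable, path: str | Path, granularity: str = "gene",
                       annotate_ps: bool = False) -> None:
    """Write a plain-text circos link file.

    ``granularity='gene'`` expects homeolog pairs (one link per gene pair);
    ``granularity='region'`` expects homeologous regions (one ribbon per
    region pair).  With ``annotate_ps`` a ``ps=<value>`` option column is
    appended where the value is available; links lacking it are emitted bare
    with a warning.
    """
    if granularity not in ("gene", "region"):
        raise ValueError(f"unknown granularity {granularity!r}")
    path = Path(path)
    n_missing = 0
    with open(path, "w") as fh:
        for item in items:
            if granularity == "gene":
                a = (item.model_a.chrom, *item.model_a.locus)
                b = (item.model_b.chrom, *item.model_b.locus)
                ps = item.ps
            else:
                a = item.interval_a
                b = item.interval_b
                ps = item.mean_ps()
            line = f"{a[0]} {a[1]} {a[2]} {b[0]} {b[1]} {b[2]}"
            if annotate_ps:
                if ps is None:
                    n_missing += 1
                else:
                    line += f" ps={_fmt(ps)}"
            fh.write(line + "\n")
    if n_missing:
        logger.warning("write_circos_links: %d links lacked a Ps annotation", n_missing)


_LINK_RE = re.compile(
    r"^(\S+) (\d+) (\d+) (\S+) (\d+) (\d+)( [A-Za-z_]+=\S+)*$"
)


def read_circos_links(path: str | Path) -> list[tuple]:
    """Parse a circos link file written by :func:`write_circos_links`.

    Returns tuples ``(chrom_a, start_a, end_a, chrom_b, start_b, end_b,
    options_dict)``; raises :class:`FormatError` on any malformed line.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if not _LINK_RE.match(line):
                raise FormatError(f"{path}: line {lineno}: malformed circos link")
            f = line.split(" ")
            opts = dict(part.split("=", 1) for part in f[6:])
            out.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), opts))
    return out


def load_region_params_config(path: str | Path) -> dict:
    """Load named region-calling parameter sets from a YAML document.

    The document maps set names to ``{window, min_homeologs_per_window,
    min_windows, boundary}`` mappings.
    """
    from .homeology import RegionParams

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a mapping of parameter-set names")
    return {
        name: RegionParams(
            window=int(v["window"]),
            min_homeologs_per_window=int(v["min_homeologs_per_window"]),
            min_windows=int(v["min_windows"]),
            boundary=int(v["boundary"]),
        )
        for name, v in doc.items()
    }
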