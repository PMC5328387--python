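"""Homeolog pairing, windowed region calling, and duplication-tier labelling.

Gene models built from the same reference protein at different loci form
homeolog pairs.  Homeologous regions are called by sliding a window of
``window`` consecutive gene models along a chromosome (one model at a time)
and flagging windows in which at least ``min_homeologs_per_window`` models
have a partner on the paired chromosome; maximal runs of dense windows,
merged across interruptions shorter than ``boundary`` windows, become
regions when they contain at least ``min_windows`` dense windows.

Regions are called twice, with a stringent parameter set tuned to the most
recent whole-genome duplication and a permissive one that also picks up the
older duplications; where the two calls overlap, the densest relationship is
labelled ``recent`` and the rest ``older`` (density of retained duplicates
is highest for the youngest duplication).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .gene_modeling import GeneModel

logger = logging.getLogger("homeoscan")

TIER_RECENT = "recent"
TIER_OLDER = "older"
TIER_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RegionParams:
    """Windowed region-calling parameters (all in units of gene models).

    ``min_homeologs_per_window`` is an integer count of partnered models per
    window; ``boundary`` is the number of consecutive low-density windows
    that closes a region.
    """

    window: int
    min_homeologs_per_window: int
    min_windows: int
    boundary: int

    def __post_init__(self) -> None:
        for name in ("window", "min_homeologs_per_window", "min_windows", "boundary"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.min_homeologs_per_window > self.window:
            raise ValueError("min_homeologs_per_window cannot exceed window")


#: Parameter sets mirroring the published per-tier tuning for a salmonid
#: genome: the stringent set isolates the most recent duplication, the
#: permissive set also recovers older tiers; ``uniform`` is the single set
#: used for the region-level Ps-vs-density scatter.
PRESET_PARAMS: dict[str, RegionParams] = {
    "recent": RegionParams(window=10, min_homeologs_per_window=3, min_windows=10, boundary=9),
    "older": RegionParams(window=10, min_homeologs_per_window=1, min_windows=10, boundary=9),
    "uniform": RegionParams(window=10, min_homeologs_per_window=1, min_windows=10, boundary=10),
}


@dataclass
class HomeologPair:
    """Two gene models sharing a reference protein at distinct loci.

    Stored canonically with ``model_a`` <= ``model_b`` in (chrom, start)
    order.  ``ps``/``pn`` are filled in by the codon_evolution module.
    """

    model_a: GeneModel
    model_b: GeneModel
    protein_id: str
    tier: str = TIER_UNASSIGNED
    ps: Optional[float] = None
    pn: Optional[float] = None
    n_exons_used: int = 0

    def __post_init__(self) -> None:
        if self.model_a.protein_id != self.model_b.protein_id:
            raise ValueError("paired models must share a reference protein")
        ka = (self.model_a.chrom, *self.model_a.locus)
        kb = (self.model_b.chrom, *self.model_b.locus)
        if ka == kb:
            raise ValueError("a pair needs two distinct loci")
        if kb < ka:
            self.model_a, self.model_b = self.model_b, self.model_a

    @property
    def pn_over_ps(self) -> Optional[float]:
        if self.ps is None or self.pn is None or self.ps == 0:
            return None
        return self.pn / self.ps

    @property
    def chrom_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.model_a.chrom, self.model_b.chrom)))

    def models(self) -> tuple[GeneModel, GeneModel]:
        return (self.model_a, self.model_b)


@dataclass
class HomeologousRegion:
    """A pair of genomic intervals with mutually paired gene models at
    sufficient windowed density."""

    interval_a: tuple[str, int, int]
    interval_b: tuple[str, int, int]
    pairs: list[HomeologPair] = field(default_factory=list)
    n_windows: int = 0
    density: float = 0.0  # member pairs per gene model in interval_a
    n_models_a: int = 0
    tier: str = TIER_UNASSIGNED

    @property
    def length_a(self) -> int:
        return self.interval_a[2] - self.interval_a[1] + 1

    @property
    def size(self) -> int:
        return self.length_a

    def mean_ps(self) -> Optional[float]:
        vals = [p.ps for p in self.pairs if p.ps is not None]
        return sum(vals) / len(vals) if vals else None


def pair_models(models: Sequence[GeneModel]) -> list[HomeologPair]:
    """Form one pair per unordered pair of distinct loci sharing a protein.

    A protein modelled at k loci yields k(k-1)/2 pairs.  Pairs are returned
    sorted by (chrom_a, start_a, chrom_b, start_b).
    """
    by_protein: dict[str, list[GeneModel]] = {}
    for m in models:
        by_protein.setdefault(m.protein_id, []).append(m)
    pairs: list[HomeologPair] = []
    for pid in sorted(by_protein):
        loci = sorted(by_protein[pid], key=lambda m: (m.chrom, m.start, m.end))
        for a, b in itertools.combinations(loci, 2):
            pairs.append(HomeologPair(model_a=a, model_b=b, protein_id=pid))
    pairs.sort(key=lambda p: (p.model_a.chrom, p.model_a.start, p.model_b.chrom, p.model_b.start))
    return pairs


def _partner_map(pairs: Iterable[HomeologPair], chrom_a: str, chrom_b: str
                 ) -> dict[str, list[tuple[HomeologPair, GeneModel]]]:
    """model_id on chrom_a -> [(pair, partner model on chrom_b), ...]."""
    out: dict[str, list[tuple[HomeologPair, GeneModel]]] = {}
    for p in pairs:
        for m, partner in ((p.model_a, p.model_b), (p.model_b, p.model_a)):
            if m.chrom == chrom_a and partner.chrom == chrom_b:
                if chrom_a == chrom_b and m is partner:
                    continue
                out.setdefault(m.model_id, []).append((p, partner))
    return out


def scan_regions(models: Sequence[GeneModel], pairs: Sequence[HomeologPair],
                 params: RegionParams,
                 chrom_pair: tuple[str, str]) -> list[HomeologousRegion]:
    """Call homeologous regions between one chromosome pair.

    ``models`` are all retained gene models (any chromosome); the scan runs
    along ``chrom_pair[0]`` and considers a model partnered iff some pair
    links it to a model on ``chrom_pair[1]``.  See the module docstring for
    the window/boundary semantics.  The partner interval spans the partner
    models of the region's members; the partner chromosome is not re-scanned.
    """
    chrom_a, chrom_b = chrom_pair
    ms = sorted((m for m in models if m.chrom == chrom_a), key=lambda m: (m.start, m.end))
    n = len(ms)
    w = params.window
    if n < w:
        logger.warning(
            "scan_regions: %s has %d models, fewer than window %d; no regions", chrom_a, n, w
        )
        return []
    partners = _partner_map(pairs, chrom_a, chrom_b)
    partnered = [m.model_id in partners for m in ms]
    # prefix sums of partnered flags -> per-window counts
    prefix = [0]
    for flag in partnered:
        prefix.append(prefix[-1] + flag)
    dense = [prefix[i + w] - prefix[i] >= params.min_homeologs_per_window
             for i in range(n - w + 1)]
    dense_idx = [i for i, d in enumerate(dense) if d]
    regions: list[HomeologousRegion] = []
    run: list[int] = []
    for idx in dense_idx + [None]:
        if run and (idx is None or idx - run[-1] - 1 >= params.boundary):
            if len(run) >= params.min_windows:
                regions.append(
                    _make_region(ms, pairs, partners, run, w, chrom_a, chrom_b)
                )
            run = []
        if idx is not None:
            run.append(idx)
    return regions


def _make_region(ms: list[GeneModel], pairs: Sequence[HomeologPair],
                 partners: dict, run: list[int], w: int,
                 chrom_a: str, chrom_b: str) -> HomeologousRegion:
    first, last = run[0], run[-1] + w - 1
    start = min(m.start for m in ms[first:last + 1])
    end = max(m.end for m in ms[first:last + 1])
    member_pairs: list[HomeologPair] = []
    b_lo, b_hi = None, None
    seen: set[int] = set()
    for m in ms[first:last + 1]:
        for pair, partner in partners.get(m.model_id, ()):  # partner on chrom_b
            if id(pair) not in seen:
                seen.add(id(pair))
                member_pairs.append(pair)
            lo, hi = partner.locus
            b_lo = lo if b_lo is None else min(b_lo, lo)
            b_hi = hi if b_hi is None else max(b_hi, hi)
    n_models = last - first + 1
    return HomeologousRegion(
        interval_a=(chrom_a, start, end),
        interval_b=(chrom_b, b_lo, b_hi),
        pairs=member_pairs,
        n_windows=len(run),
        density=len(member_pairs) / n_models,
        n_models_a=n_models,
    )


def scan_all_regions(models: Sequence[GeneModel], pairs: Sequence[HomeologPair],
                     params: RegionParams) -> list[HomeologousRegion]:
    """Scan every chromosome pair linked by at least one homeolog pair.

    Each unordered chromosome pair is scanned once, along its
    lexicographically smaller chromosome.
    """
    chrom_pairs = sorted({p.chrom_pair for p in pairs})
    regions: list[HomeologousRegion] = []
    for cp in chrom_pairs:
        regions.extend(scan_regions(models, pairs, params, cp))
    return regions


def _overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


def _regions_touch(r: HomeologousRegion, o: HomeologousRegion) -> bool:
    """Do two regions claim overlapping genomic territory on any interval?"""
    return any(
        _overlap(x, y)
        for x in (r.interval_a, r.interval_b)
        for y in (o.interval_a, o.interval_b)
    )


def _chrom_pair(r: HomeologousRegion) -> tuple[str, str]:
    return tuple(sorted((r.interval_a[0], r.interval_b[0])))


def assign_tiers(recent_regions: Sequence[HomeologousRegion],
                 older_regions: Sequence[HomeologousRegion]) -> list[HomeologousRegion]:
    """Reconcile the two parameter scans into tier-labelled regions.

    A region from the stringent (recent) scan keeps the ``recent`` label iff
    no overlapping region of a *different* chromosome-pair relationship has
    higher density (ties broken by larger region size, then by lexicographic
    partner chromosome); otherwise it is demoted to ``older``.  Overlap is
    tested on both intervals of both regions, so a dense relationship also
    defends its partner chromosome against sparser claims.  Permissive-scan
    regions that duplicate a recent region's relationship (same chromosome
    pair, overlapping on both intervals) are dropped; all remaining
    permissive-scan regions are labelled ``older``.
    """
    recent_regions = list(recent_regions)
    older_regions = list(older_regions)

    def rank(r: HomeologousRegion) -> tuple:
        # higher density, then larger size, then earlier partner chromosome
        return (r.density, r.size, tuple(-ord(c) for c in r.interval_b[0]))

    out: list[HomeologousRegion] = []
    claimed: list[HomeologousRegion] = []
    for r in recent_regions:
        rivals = [
            o for o in list(older_regions) + list(recent_regions)
            if o is not r and _chrom_pair(o) != _chrom_pair(r) and _regions_touch(r, o)
        ]
        if all(rank(r) >= rank(o) for o in rivals):
            r.tier = TIER_RECENT
            claimed.append(r)
        else:
            r.tier = TIER_OLDER
        out.append(r)
    for o in older_regions:
        dup = any(
            c.interval_b[0] == o.interval_b[0]
            and _overlap(c.interval_a, o.interval_a)
            and _overlap(c.interval_b, o.interval_b)
            for c in claimed
        )
        if dup:
            continue
        o.tier = TIER_OLDER
        out.append(o)
    return out


def _member_of(pair: HomeologPair, region: HomeologousRegion) -> bool:
    a, b = pair.model_a, pair.model_b
    for m1, m2 in ((a, b), (b, a)):
        if (
            m1.chrom == region.interval_a[0]
            and region.interval_a[1] <= m1.start and m1.end <= region.interval_a[2]
            and m2.chrom == region.interval_b[0]
            and region.interval_b[1] <= m2.start and m2.end <= region.interval_b[2]
        ):
            return True
    return False


def assign_pair_tiers(pairs: Sequence[HomeologPair],
                      regions: Sequence[HomeologousRegion]) -> None:
    """Label each pair with its region's tier (recent takes precedence over
    older when a pair falls in regions of both tiers); pairs in no region
    stay unassigned."""
    recent = [r for r in regions if r.tier == TIER_RECENT]
    older = [r for r in regions if r.tier == TIER_OLDER]
    for p in pairs:
        if any(_member_of(p, r) for r in recent):
            p.tier = TIER_RECENT
        elif any(_member_of(p, r) for r in older):
            p.tier = TIER_OLDER
        else:
            p.tier = TIER_UNASSIGNED


def categorize_copy_number(models: Sequence[GeneModel],
                           pairs: Sequence[HomeologPair]) -> Counter:
    """Histogram of loci by (has recent-tier partner, number of older-tier
    partners).  Every model contributes exactly one category, so the counts
    sum to the model count."""
    has_recent: dict[str, bool] = {m.model_id: False for m in models}
    n_older: dict[str, int] = {m.model_id: 0 for m in models}
    for p in pairs:
        for m in p.models():
            if p.tier == TIER_RECENT:
                has_recent[m.model_id] = True
            elif p.tier == TIER_OLDER:
                n_older[m.model_id] += 1
    return Counter(
        (int(has_recent[m.model_id]), n_older[m.model_id]) for m in models
    )
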