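"""Density metrics, tier summaries, and group comparisons.

Per-region quantities are computed first and then averaged across regions
(never pooling genes directly), so each homeologous region contributes one
observation regardless of its gene count; spreads are reported as standard
deviations across regions.  Homeolog density is corrected by total gene
density so that genomes with different overall gene packing remain
comparable: ``corrected_fraction`` is simply the fraction of a region's gene
models that are homeologous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gene_modeling import GeneModel
from .homeology import HomeologPair, HomeologousRegion
from .io_formats import ProteinRecord

logger = logging.getLogger("homeoscan")


@dataclass
class DensityStats:
    """Per-region homeolog/gene densities (per Mb) and their ratio."""

    region: HomeologousRegion
    homeolog_density: float
    gene_density: float
    corrected_fraction: float
    mean_ps: Optional[float]


@dataclass
class WelchResult:
    t_statistic: float
    dof: float
    p_value: float


def region_density(region: HomeologousRegion, all_models: Sequence[GeneModel]) -> DensityStats:
    """Homeolog and total gene density for one region (per Mb).

    Homeolog density counts the region's member-pair models falling in
    ``interval_a``; gene density counts all models there.  The corrected
    fraction is their ratio, in [0, 1].
    """
    chrom, start, end = region.interval_a
    length = end - start + 1
    if length <= 0:
        raise ValueError("region has a non-positive length")
    in_region = [
        m for m in all_models
        if m.chrom == chrom and start <= m.start and m.end <= end
    ]
    if not in_region:
        raise ValueError("region contains no gene models")
    partnered_ids = set()
    for p in region.pairs:
        for m in p.models():
            if m.chrom == chrom and start <= m.start and m.end <= end:
                partnered_ids.add(m.model_id)
    n_partnered = sum(1 for m in in_region if m.model_id in partnered_ids)
    mb = length / 1e6
    return DensityStats(
        region=region,
        homeolog_density=n_partnered / mb,
        gene_density=len(in_region) / mb,
        corrected_fraction=n_partnered / len(in_region),
        mean_ps=region.mean_ps(),
    )


def filter_ribosomal(items: Sequence, proteome: Sequence[ProteinRecord] | dict
                     ) -> tuple[list, int]:
    """Remove entries whose protein symbol starts with "rp" (case-insensitive).

    Works on anything carrying a ``protein_id`` (gene models, homeolog
    pairs).  The rule is applied literally, so the occasional non-ribosomal
    rp-prefixed symbol is removed too; removed symbols are logged to keep the
    filter auditable.  Returns (kept items, removed count).
    """
    if not isinstance(proteome, dict):
        proteome = {p.protein_id: p for p in proteome}
    kept, removed_symbols = [], []
    for item in items:
        symbol = proteome[item.protein_id].symbol if item.protein_id in proteome else ""
        if symbol.lower().startswith("rp"):
            removed_symbols.append(symbol)
        else:
            kept.append(item)
    if removed_symbols:
        logger.info(
            "filter_ribosomal: removed %d entries (%s)",
            len(removed_symbols), ", ".join(sorted(set(removed_symbols))),
        )
    return kept, len(removed_symbols)


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-tailed Welch's t-test (unequal variances, Welch-Satterthwaite dof)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(t_statistic=0.0, dof=float(len(a) + len(b) - 2), p_value=1.0)
        raise ValueError("both groups have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t_statistic=float(res.statistic), dof=float(res.df),
                       p_value=float(res.pvalue))


@dataclass
class TierSummary:
    tier: str
    n_pairs: int
    n_pairs_reciprocal: int
    n_pairs_with_ps: int
    mean_ps: Optional[float]
    mean_pn: Optional[float]
    mean_pn_over_ps: Optional[float]
    n_regions: int
    mean_corrected_fraction: Optional[float]
    sd_corrected_fraction: Optional[float]


def summarize_tier(pairs: Sequence[HomeologPair], regions: Sequence[HomeologousRegion],
                   all_models: Sequence[GeneModel], tier: str) -> TierSummary:
    """Aggregate one duplication tier.

    Pair counts are reported both once per unordered pair and doubled (the
    reciprocal-pair convention some reports use).  Corrected density is
    averaged across the tier's regions; missing Ps values are excluded
    pairwise, never imputed.
    """
    tier_pairs = [p for p in pairs if p.tier == tier]
    tier_regions = [r for r in regions if r.tier == tier]
    ps_vals = [p.ps for p in tier_pairs if p.ps is not None]
    pn_vals = [p.pn for p in tier_pairs if p.pn is not None]
    ratio_vals = [p.pn_over_ps for p in tier_pairs if p.pn_over_ps is not None]
    fractions = [region_density(r, all_models).corrected_fraction for r in tier_regions]
    if not tier_pairs:
        logger.warning("summarize_tier: no pairs in tier %r", tier)
    return TierSummary(
        tier=tier,
        n_pairs=len(tier_pairs),
        n_pairs_reciprocal=2 * len(tier_pairs),
        n_pairs_with_ps=len(ps_vals),
        mean_ps=float(np.mean(ps_vals)) if ps_vals else None,
        mean_pn=float(np.mean(pn_vals)) if pn_vals else None,
        mean_pn_over_ps=float(np.mean(ratio_vals)) if ratio_vals else None,
        n_regions=len(tier_regions),
        mean_corrected_fraction=float(np.mean(fractions)) if fractions else None,
        sd_corrected_fraction=float(np.std(fractions, ddof=1)) if len(fractions) > 1 else None,
    )


def scatter_table(regions: Sequence[HomeologousRegion],
                  all_models: Sequence[GeneModel]) -> pd.DataFrame:
    """One row per region: location, pair count, mean Ps, corrected density.

    This is the data behind the region-level Ps-vs-density scatter; write it
    with ``df.to_csv(path, sep="\\t", index=False)``.
    """
    rows = []
    for r in regions:
        d = region_density(r, all_models)
        rows.append(
            {
                "chrom_a": r.interval_a[0],
                "start_a": r.interval_a[1],
                "end_a": r.interval_a[2],
                "chrom_b": r.interval_b[0],
                "start_b": r.interval_b[1],
                "end_b": r.interval_b[2],
                "n_pairs": len(r.pairs),
                "mean_ps": d.mean_ps,
                "homeolog_density_per_mb": d.homeolog_density,
                "gene_density_per_mb": d.gene_density,
                "corrected_fraction": d.corrected_fraction,
            }
        )
    columns = [
        "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
        "n_pairs", "mean_ps", "homeolog_density_per_mb", "gene_density_per_mb",
        "corrected_fraction",
    ]
    return pd.DataFrame(rows, columns=columns)


def compare_ps_subsets(ps_values: Sequence[float], mask: Sequence[bool]) -> WelchResult:
    """Welch's t-test between Ps values inside vs outside a mask.

    Typical use: do pairs overlapping some genomic subset (for instance
    older-tier pairs falling inside low-divergence recent-tier regions)
    differ in Ps from the rest?  Missing values must be filtered out first.
    """
    ps = np.asarray(ps_values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if ps.shape != mask.shape:
        raise ValueError("ps_values and mask must have the same length")
    inside = ps[mask]
    outside = ps[~mask]
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("both subsets need at least two observations")
    return welch_t_test(inside, outside)
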