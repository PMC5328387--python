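"""End-to-end orchestration: hits -> models -> pairs -> regions -> tiers -> Ps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .codon_evolution import attach_ps_to_pairs
from .gene_modeling import GeneModel, build_gene_models
from .homeology import (
    PRESET_PARAMS,
    HomeologPair,
    HomeologousRegion,
    RegionParams,
    assign_pair_tiers,
    assign_tiers,
    pair_models,
    scan_all_regions,
)
from .io_formats import AlignmentHit, ProteinRecord


@dataclass
class TwoTierResult:
    models: list[GeneModel]
    pairs: list[HomeologPair]
    regions: list[HomeologousRegion]

    def pairs_of_tier(self, tier: str) -> list[HomeologPair]:
        return [p for p in self.pairs if p.tier == tier]

    def regions_of_tier(self, tier: str) -> list[HomeologousRegion]:
        return [r for r in self.regions if r.tier == tier]


def run_two_tier_analysis(
    hits: Sequence[AlignmentHit],
    proteome: Sequence[ProteinRecord],
    genome: Optional[dict[str, str]] = None,
    recent_params: RegionParams = PRESET_PARAMS["recent"],
    older_params: RegionParams = PRESET_PARAMS["older"],
    compute_ps: bool = True,
) -> TwoTierResult:
    """Run the full detection pipeline on pre-filtered alignment hits.

    Region calling runs twice -- once with the stringent (recent-tier)
    parameters and once with the permissive (older-tier) parameters -- and
    the two calls are reconciled into tier labels.  With ``compute_ps`` and a
    genome, Ps/Pn are attached to every pair.
    """
    models = build_gene_models(hits, proteome)
    pairs = pair_models(models)
    recent_regions = scan_all_regions(models, pairs, recent_params)
    older_regions = scan_all_regions(models, pairs, older_params)
    regions = assign_tiers(recent_regions, older_regions)
    assign_pair_tiers(pairs, regions)
    if compute_ps and genome is not None:
        attach_ps_to_pairs(pairs, genome, proteome)
    return TwoTierResult(models=models, pairs=pairs, regions=regions)
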