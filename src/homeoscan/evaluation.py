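"""Scoring pipeline output against a simulator truth set."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pipeline import TwoTierResult
from .synthetic_data import SimulatedGenome


@dataclass
class TierRecovery:
    """How well the detected pairs match the planted ones."""

    n_planted_recent: int
    n_recovered_recent: int  # planted recent pairs found and labelled recent
    n_planted_older: int
    n_recovered_older: int
    mean_ps_recent: Optional[float]
    mean_ps_older: Optional[float]

    @property
    def recent_recovery(self) -> float:
        return self.n_recovered_recent / self.n_planted_recent if self.n_planted_recent else 0.0

    @property
    def older_recovery(self) -> float:
        return self.n_recovered_older / self.n_planted_older if self.n_planted_older else 0.0

    @property
    def ps_ratio_older_over_recent(self) -> Optional[float]:
        if not self.mean_ps_recent or self.mean_ps_older is None:
            return None
        return self.mean_ps_older / self.mean_ps_recent


def match_models_to_loci(result: TwoTierResult, sim: SimulatedGenome) -> dict[str, str]:
    """Map each detected model to the planted locus it overlaps most."""
    by_chrom: dict[str, list] = {}
    for locus in sim.truth.loci.values():
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for loci in by_chrom.values():
        loci.sort(key=lambda l: l.start)
    mapping: dict[str, str] = {}
    for m in result.models:
        best, best_ov = None, 0
        for locus in by_chrom.get(m.chrom, ()):  # loci per chromosome are few
            ov = min(m.end, locus.end) - max(m.start, locus.start) + 1
            if ov > best_ov:
                best, best_ov = locus, ov
        if best is not None:
            mapping[m.model_id] = best.locus_id
    return mapping


def score_tier_recovery(result: TwoTierResult, sim: SimulatedGenome) -> TierRecovery:
    """Compare detected, tier-labelled pairs against the planted pair list."""
    model2locus = match_models_to_loci(result, sim)
    detected: dict[frozenset, str] = {}
    for p in result.pairs:
        la = model2locus.get(p.model_a.model_id)
        lb = model2locus.get(p.model_b.model_id)
        if la and lb:
            detected[frozenset((la, lb))] = p.tier
    counts = {"recent": [0, 0], "older": [0, 0]}  # [planted, recovered]
    for tp in sim.truth.pairs:
        counts[tp.tier][0] += 1
        if detected.get(frozenset((tp.locus_a, tp.locus_b))) == tp.tier:
            counts[tp.tier][1] += 1
    ps_by_tier = {}
    for tier in ("recent", "older"):
        vals = [p.ps for p in result.pairs if p.tier == tier and p.ps is not None]
        ps_by_tier[tier] = float(np.mean(vals)) if vals else None
    return TierRecovery(
        n_planted_recent=counts["recent"][0],
        n_recovered_recent=counts["recent"][1],
        n_planted_older=counts["older"][0],
        n_recovered_older=counts["older"][1],
        mean_ps_recent=ps_by_tier["recent"],
        mean_ps_older=ps_by_tier["older"],
    )
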