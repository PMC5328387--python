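import random

import pytest

from homeoscan.io_formats import AlignmentHit
from homeoscan.synthetic_data import default_two_tier_fixture, emit_hits, write_hits_tsv


@pytest.fixture(scope="session")
def small_sim():
    """A compact two-duplication genome reused across module tests."""
    return default_two_tier_fixture(seed=7, n_genes=120)


@pytest.fixture(scope="session")
def small_pipeline(small_sim, tmp_path_factory):
    """Full pipeline result on the small fixture (models, pairs, regions)."""
    from homeoscan.io_formats import read_alignment_hits
    from homeoscan.pipeline import run_two_tier_analysis

    d = tmp_path_factory.mktemp("fixture")
    write_hits_tsv(emit_hits(small_sim), d / "hits.tsv")
    hits = read_alignment_hits(d / "hits.tsv")
    return run_two_tier_analysis(hits, small_sim.proteome, small_sim.genome)


def random_hit_group(rng: random.Random, n: int, strand: str = "+") -> list[AlignmentHit]:
    """Random non-overlapping hits for one (chrom, strand, protein) group,
    in reading order, with gaps and protein coordinates spanning the
    chaining thresholds."""
    hits = []
    genome_pos = rng.randrange(1, 10_000)
    prot_pos = rng.randrange(1, 50)
    for _ in range(n):
        aa_len = rng.randrange(10, 120)
        nt_len = 3 * aa_len
        hits.append(
            dict(
                genome_start=genome_pos,
                genome_end=genome_pos + nt_len - 1,
                prot_start=prot_pos,
                prot_end=prot_pos + aa_len - 1,
            )
        )
        genome_pos += nt_len + rng.choice([0, 1, 100, 30_000, 49_999, 50_001, 70_000])
        step = rng.choice([-30, -5, 1, 2, 50, 290, 301, 400])
        prot_pos = max(1, prot_pos + aa_len - 1 + step)
    out = []
    for h in hits:
        out.append(
            AlignmentHit(
                chrom="c1",
                strand=strand,
                protein_id="p1",
                identity_fraction=rng.uniform(0.4, 1.0),
                bit_score=round(rng.uniform(50, 500), 1),
                evalue=1e-30,
                **h,
            )
        )
    if strand == "-":
        # reading order on minus strand is decreasing genome coordinate:
        # mirror the genome axis so protein order advances leftwards
        hi = max(h.genome_end for h in out) + 100
        for h in out:
            h.genome_start, h.genome_end = hi - h.genome_end, hi - h.genome_start
    return out
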