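import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeoscan.codon_evolution import (
    CodonAlignment,
    align_pair_codons,
    extract_exon_sequences,
    model_pair_ps,
    ng86_estimate,
    reverse_complement,
)
from homeoscan.gene_modeling import GeneModel, Segment
from homeoscan.homeology import HomeologPair
from homeoscan.io_formats import ProteinRecord
from homeoscan.synthetic_data import NON_STOP_CODONS, simulate_codon_pairs

from _oracles import GENETIC_CODE, bf_ng86

_STOPS = ("TAA", "TAG", "TGA")
CODONS_NO_STOP_NEIGHBOURS = [
    c for c in NON_STOP_CODONS
    if all(c[:i] + n + c[i + 1:] not in _STOPS for i in range(3) for n in "ACGT")
]


def random_codon(rng):
    return NON_STOP_CODONS[rng.randrange(len(NON_STOP_CODONS))]


class TestNg86:
    def test_identical_sequences_zero(self):
        est = ng86_estimate([("ATG", "ATG"), ("GGC", "GGC")])
        assert est.ps == 0.0 and est.pn == 0.0

    def test_hand_checked_glycine_case(self):
        """GGGGGG vs GGAGGG: one third-position Gly<->Gly change; the GGA
        first position reaches a stop (TGA), which is excluded from sites."""
        est = ng86_estimate([("GGG", "GGA"), ("GGG", "GGG")])
        assert est.syn_diffs == pytest.approx(1.0)
        assert est.syn_sites == pytest.approx(2.0)
        assert est.ps == pytest.approx(0.5)
        assert est.pn == pytest.approx(0.0)

    def test_sites_conserved_without_stop_neighbours(self):
        """S + N = 3 x codons when no mutation of either codon reaches a stop."""
        rng = random.Random(0)
        pairs = [(rng.choice(CODONS_NO_STOP_NEIGHBOURS), rng.choice(CODONS_NO_STOP_NEIGHBOURS))
                 for _ in range(50)]
        est = ng86_estimate(pairs)
        assert est.syn_sites + est.nonsyn_sites == pytest.approx(3 * 50)

    def test_undefined_ps_reported_missing(self):
        # Met/Trp codons have no synonymous sites at all
        est = ng86_estimate([("ATG", "ATG")])
        assert est.ps is None and est.pn == 0.0

    def test_ambiguous_codons_skipped(self):
        est = ng86_estimate([("ANG", "ATG"), ("GGG", "GGA")])
        assert est.n_skipped == 1 and est.n_codons == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = random.Random(seed)
        pairs = []
        for _ in range(60):
            a = random_codon(rng)
            if rng.random() < 0.5:
                b = a
            else:
                b = random_codon(rng)
            pairs.append((a, b))
        est = ng86_estimate(pairs)
        S, N, Sd, Nd, ps, pn = bf_ng86(pairs)
        assert est.syn_sites == pytest.approx(S, abs=1e-12)
        assert est.nonsyn_sites == pytest.approx(N, abs=1e-12)
        assert est.syn_diffs == pytest.approx(Sd, abs=1e-12)
        assert est.nonsyn_diffs == pytest.approx(Nd, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(NON_STOP_CODONS),
                              st.sampled_from(NON_STOP_CODONS)), min_size=1, max_size=30))
    def test_symmetry(self, pairs):
        fwd = ng86_estimate(pairs)
        rev = ng86_estimate([(b, a) for a, b in pairs])
        assert fwd.syn_sites == pytest.approx(rev.syn_sites)
        assert fwd.syn_diffs == pytest.approx(rev.syn_diffs)
        assert fwd.nonsyn_diffs == pytest.approx(rev.nonsyn_diffs)

    def test_saturation_monotone_and_bounded(self):
        """Under a synonymous-only process the estimate rises with the true
        edit count and never exceeds one."""
        estimates = []
        for p in (0.05, 0.2, 0.5, 0.8):
            pairs = [c for chunk in simulate_codon_pairs(20, 200, p, seed=42) for c in chunk]
            est = ng86_estimate(pairs)
            estimates.append(est.ps)
            assert 0.0 <= est.ps <= 1.0
        assert estimates == sorted(estimates)

    @pytest.mark.parametrize("p", [0.05, 0.2, 0.5])
    def test_recovers_planted_proportion(self, p):
        per_pair = [ng86_estimate(pair).ps
                    for pair in simulate_codon_pairs(60, 300, p, seed=9)]
        mean = np.mean(per_pair)
        se = np.std(per_pair, ddof=1) / np.sqrt(len(per_pair))
        assert abs(mean - p) <= 3 * max(se, 1e-4)


GENOME = {"chrX": "A" * 9 + "ATGGGTCACTAA" + "C" * 9}


class TestExtractExons:
    def test_plus_strand_slice(self):
        m = GeneModel("m", "chrX", "+", "p", [Segment(10, 18, 1, 3, 1.0)])
        assert extract_exon_sequences(m, GENOME) == ["ATGGGTCAC"]

    def test_minus_strand_reverse_complement(self):
        m = GeneModel("m", "chrX", "-", "p", [Segment(10, 18, 1, 3, 1.0)])
        assert extract_exon_sequences(m, GENOME) == [reverse_complement("ATGGGTCAC")]

    def test_out_of_bounds_rejected(self):
        m = GeneModel("m", "chrX", "+", "p", [Segment(25, 40, 1, 5, 1.0)])
        with pytest.raises(IndexError):
            extract_exon_sequences(m, GENOME)


def _toy_pair(rng, n_codons=90, n_mut=6, frame_break=False):
    """Two single-exon models of the same protein on one toy chromosome."""
    codons_a = [random_codon(rng) for _ in range(n_codons)]
    codons_b = list(codons_a)
    from homeoscan.synthetic_data import _SYN_CHOICES
    mutated = 0
    for idx in rng.sample(range(n_codons), n_codons):
        if mutated == n_mut:
            break
        if _SYN_CHOICES[codons_b[idx]]:
            codons_b[idx] = _SYN_CHOICES[codons_b[idx]][0]
            mutated += 1
    protein = "".join(GENETIC_CODE[c] for c in codons_a)
    seq_a, seq_b = "".join(codons_a), "".join(codons_b)
    spacer = "ATATATAT"
    chrom = spacer + seq_a + spacer + seq_b + (spacer if not frame_break else spacer[1:])
    start_a = len(spacer) + 1
    start_b = len(spacer) * 2 + len(seq_a) + 1
    ma = GeneModel("ma", "c", "+", "p0",
                   [Segment(start_a, start_a + len(seq_a) - 1, 1, n_codons, 1.0)])
    end_b = start_b + len(seq_b) - 1 + (1 if frame_break else 0)
    mb = GeneModel("mb", "c", "+", "p0", [Segment(start_b, end_b, 1, n_codons, 1.0)])
    proteome = {"p0": ProteinRecord("p0", protein)}
    return ma, mb, {"c": chrom + "A" * 10}, proteome, mutated


class TestAlignPairCodons:
    def test_identical_models_pair_all_codons(self):
        rng = random.Random(1)
        ma, mb, genome, proteome, _ = _toy_pair(rng, n_mut=0)
        aln = align_pair_codons(ma, mb, proteome, genome)
        assert len(aln) == 90 and aln.dropped_exons == []
        assert all(a == b for a, b, _ in aln.columns)

    def test_frame_broken_exon_dropped(self):
        rng = random.Random(2)
        ma, mb, genome, proteome, _ = _toy_pair(rng, frame_break=True)
        aln = align_pair_codons(ma, mb, proteome, genome)
        assert "mb.seg0" in aln.dropped_exons and len(aln) == 0

    def test_different_proteins_rejected(self):
        rng = random.Random(3)
        ma, mb, genome, proteome, _ = _toy_pair(rng)
        mb.protein_id = "other"
        with pytest.raises(ValueError):
            align_pair_codons(ma, mb, proteome, genome)

    def test_planted_synonymous_changes_recovered(self):
        rng = random.Random(4)
        ma, mb, genome, proteome, n_mut = _toy_pair(rng, n_mut=6)
        est = ng86_estimate(align_pair_codons(ma, mb, proteome, genome))
        assert est.syn_diffs == pytest.approx(n_mut)
        assert est.nonsyn_diffs == pytest.approx(0.0)


class TestModelPairPs:
    def test_multi_exon_average_is_unweighted(self):
        """Ps is the plain mean of per-exon values regardless of exon size."""
        rng = random.Random(5)
        codons = [random_codon(rng) for _ in range(120)]
        protein = "".join(GENETIC_CODE[c] for c in codons)
        from homeoscan.synthetic_data import _SYN_CHOICES
        other = list(codons)
        # mutate only within the first 30 codons (exon 1 of model b)
        n_mut = 0
        for idx in range(30):
            if _SYN_CHOICES[other[idx]] and n_mut < 8:
                other[idx] = _SYN_CHOICES[other[idx]][0]
                n_mut += 1
        seq_a, seq_b = "".join(codons), "".join(other)
        intron = "GGGG"
        chrom = "AT" + seq_a + "AT" + seq_b[:90] + intron + seq_b[90:] + "AT"
        ma = GeneModel("ma", "c", "+", "p0", [Segment(3, 2 + 360, 1, 120, 1.0)])
        b0 = 2 + 360 + 2 + 1
        mb = GeneModel("mb", "c", "+", "p0",
                       [Segment(b0, b0 + 89, 1, 30, 1.0),
                        Segment(b0 + 90 + len(intron), b0 + 90 + len(intron) + 269, 31, 120, 1.0)])
        pair = HomeologPair(model_a=ma, model_b=mb, protein_id="p0")
        proteome = {"p0": ProteinRecord("p0", protein)}
        ps, pn = model_pair_ps(pair, {"c": chrom}, proteome)
        ests = []
        aln = align_pair_codons(ma, mb, proteome, {"c": chrom})
        for key, cols in sorted(aln.exon_groups().items()):
            ests.append(ng86_estimate(cols).ps)
        assert len(ests) == 2
        assert ps == pytest.approx(sum(ests) / 2)
        assert ests[0] > 0 and ests[1] == 0
        assert pair.n_exons_used == 2

    def test_all_exons_dropped_gives_missing(self):
        rng = random.Random(6)
        ma, mb, genome, proteome, _ = _toy_pair(rng, frame_break=True)
        # break model a too
        ma.segments[0].genome_end += 1
        pair = HomeologPair(model_a=ma, model_b=mb, protein_id="p0")
        ps, pn = model_pair_ps(pair, genome, proteome)
        assert ps is None and pn is None and pair.n_exons_used == 0
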