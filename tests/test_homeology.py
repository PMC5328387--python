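import random

import pytest

from homeoscan.gene_modeling import GeneModel, Segment
from homeoscan.homeology import (
    HomeologPair,
    RegionParams,
    assign_pair_tiers,
    assign_tiers,
    categorize_copy_number,
    pair_models,
    scan_regions,
)

from _oracles import bf_scan_regions


def make_model(mid, chrom, start, protein="p", length=900, score=0.9):
    m = GeneModel(model_id=mid, chrom=chrom, strand="+", protein_id=protein,
                  segments=[Segment(start, start + length - 1, 1, length // 3, 0.95)])
    m.score = score
    return m


def make_instance(partnered, chrom_a="A", chrom_b="B", spacing=10_000):
    """Models along chrom_a (one per flag) plus partner models on chrom_b for
    each True flag, and the linking pairs."""
    models, pairs = [], []
    for i, flag in enumerate(partnered):
        prot = f"p{i}"
        a = make_model(f"a{i}", chrom_a, 1 + i * spacing, protein=prot)
        models.append(a)
        if flag:
            b = make_model(f"b{i}", chrom_b, 1 + i * spacing, protein=prot)
            models.append(b)
            pairs.append(HomeologPair(model_a=a, model_b=b, protein_id=prot))
    return models, pairs


class TestPairModels:
    def test_two_loci_one_pair(self):
        models = [make_model("a", "A", 1), make_model("b", "B", 1)]
        assert len(pair_models(models)) == 1

    def test_four_loci_six_pairs(self):
        models = [make_model(f"m{i}", "A", 1 + i * 10_000) for i in range(4)]
        pairs = pair_models(models)
        assert len(pairs) == 6
        assert all(p.model_a is not p.model_b for p in pairs)

    def test_single_locus_proteins_unpaired(self):
        models = [make_model("a", "A", 1, protein="p1"), make_model("b", "B", 1, protein="p2")]
        assert pair_models(models) == []


class TestScanRegions:
    PARAMS = RegionParams(window=10, min_homeologs_per_window=1, min_windows=10, boundary=9)

    def test_contiguous_block_one_region(self):
        flags = [False] * 5 + [True] * 20 + [False] * 5
        models, pairs = make_instance(flags)
        regions = scan_regions(models, pairs, self.PARAMS, ("A", "B"))
        assert len(regions) == 1
        (r,) = regions
        assert {p.model_a.model_id for p in r.pairs} == {f"a{i}" for i in range(5, 25)}
        # breakpoints match the naive enumerator
        spans = bf_scan_regions(flags, 10, 1, 10, 9)
        a_models = [m for m in models if m.chrom == "A"]
        assert r.interval_a == ("A", a_models[spans[0][0]].start, a_models[spans[0][1]].end)

    def test_no_pairs_no_regions(self):
        models, _ = make_instance([False] * 30)
        assert scan_regions(models, [], self.PARAMS, ("A", "B")) == []

    def test_fewer_models_than_window_warns(self, caplog):
        models, pairs = make_instance([True] * 5)
        import logging
        with caplog.at_level(logging.WARNING, logger="homeoscan"):
            assert scan_regions(models, pairs, self.PARAMS, ("A", "B")) == []
        assert any("fewer than window" in r.message for r in caplog.records)

    def test_two_runs_split_by_wide_gap(self):
        flags = [True] * 25 + [False] * 30 + [True] * 25
        models, pairs = make_instance(flags)
        params = RegionParams(window=10, min_homeologs_per_window=3, min_windows=10, boundary=9)
        regions = scan_regions(models, pairs, params, ("A", "B"))
        assert len(regions) == 2

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_naive_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randrange(5, 120)
        flags = [rng.random() < rng.choice([0.2, 0.5, 0.8]) for _ in range(n)]
        params = RegionParams(
            window=rng.randrange(2, 15),
            min_homeologs_per_window=1,
            min_windows=rng.randrange(1, 8),
            boundary=rng.randrange(1, 10),
        )
        params = RegionParams(params.window, rng.randrange(1, params.window + 1),
                              params.min_windows, params.boundary)
        models, pairs = make_instance(flags)
        got = scan_regions(models, pairs, params, ("A", "B"))
        want = bf_scan_regions(flags, params.window, params.min_homeologs_per_window,
                               params.min_windows, params.boundary)
        a_models = [m for m in models if m.chrom == "A"]
        got_spans = [(r.interval_a[1], r.interval_a[2]) for r in got]
        want_spans = [(a_models[i].start, a_models[j].end) for i, j in want]
        assert got_spans == want_spans

    def test_mirror_invariance(self):
        """Reversing chromosome orientation mirrors intervals but keeps
        membership identical."""
        rng = random.Random(11)
        flags = [rng.random() < 0.5 for _ in range(60)]
        models, pairs = make_instance(flags)
        regions = scan_regions(models, pairs, self.PARAMS, ("A", "B"))
        L = 2_000_000
        mirrored = []
        id_map = {}
        for m in models:
            mm = make_model(m.model_id, m.chrom,
                            L - m.end + 1 if m.chrom == "A" else m.start,
                            protein=m.protein_id)
            mirrored.append(mm)
            id_map[m.model_id] = mm
        mpairs = [HomeologPair(model_a=id_map[p.model_a.model_id],
                               model_b=id_map[p.model_b.model_id],
                               protein_id=p.protein_id) for p in pairs]
        mregions = scan_regions(mirrored, mpairs, self.PARAMS, ("A", "B"))
        got = sorted(frozenset(q.protein_id for q in r.pairs) for r in regions)
        want = sorted(frozenset(q.protein_id for q in r.pairs) for r in mregions)
        assert got == want
        assert sorted((L - r.interval_a[2] + 1, L - r.interval_a[1] + 1) for r in regions) == \
               sorted((r.interval_a[1], r.interval_a[2]) for r in mregions)

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_density_never_enlarges_regions(self, seed):
        rng = random.Random(seed + 100)
        flags = [rng.random() < 0.6 for _ in range(100)]
        models, pairs = make_instance(flags)
        loose = RegionParams(10, 2, 5, 5)
        strict = RegionParams(10, 5, 5, 5)
        big = scan_regions(models, pairs, loose, ("A", "B"))
        small = scan_regions(models, pairs, strict, ("A", "B"))
        for s in small:
            assert any(
                b.interval_a[1] <= s.interval_a[1] and s.interval_a[2] <= b.interval_a[2]
                for b in big
            )


class TestAssignTiers:
    def _region(self, density, size, chrom_a="A", chrom_b="B", start=1):
        from homeoscan.homeology import HomeologousRegion
        return HomeologousRegion(
            interval_a=(chrom_a, start, start + size - 1),
            interval_b=(chrom_b, 1, size),
            pairs=[], n_windows=10, density=density, n_models_a=10,
        )

    def test_densest_relationship_wins(self):
        dense = self._region(0.8, 1_000_000)
        sparse = self._region(0.2, 1_000_000, chrom_b="C")
        out = assign_tiers([dense], [sparse])
        assert dense.tier == "recent" and sparse.tier == "older"

    def test_density_tie_broken_by_size(self):
        big = self._region(0.5, 5_000_000)
        small = self._region(0.5, 2_000_000, chrom_b="C")
        assign_tiers([small], [big])
        assert small.tier == "older" and big.tier == "older"

    def test_non_overlapping_regions_keep_scan_labels(self):
        r1 = self._region(0.5, 100, start=1)
        r2 = self._region(0.5, 100, start=10_000, chrom_b="C")
        assign_tiers([r1], [r2])
        assert r1.tier == "recent" and r2.tier == "older"

    def test_duplicate_relationship_deduplicated(self):
        winner = self._region(0.8, 1_000_000)
        duplicate = self._region(0.3, 1_000_000)  # same chrom pair, same span
        out = assign_tiers([winner], [duplicate])
        assert duplicate not in out and winner.tier == "recent"


class TestCopyNumberCategories:
    def test_histogram_conserves_loci(self):
        models, pairs = make_instance([True, True, False, False, True])
        for p in pairs:
            p.tier = "recent"
        hist = categorize_copy_number(models, pairs)
        assert sum(hist.values()) == len(models)
        assert hist[(1, 0)] == 6  # both sides of each recent pair
        assert hist[(0, 0)] == 2

    def test_mixed_tiers(self):
        a = make_model("a", "A", 1)
        b = make_model("b", "B", 1)
        c = make_model("c", "C", 1)
        p1 = HomeologPair(model_a=a, model_b=b, protein_id="p")
        p1.tier = "recent"
        p2 = HomeologPair(model_a=a, model_b=c, protein_id="p")
        p2.tier = "older"
        hist = categorize_copy_number([a, b, c], [p1, p2])
        assert hist[(1, 1)] == 1  # locus a: recent partner + one older partner
        assert hist[(1, 0)] == 1  # locus b
        assert hist[(0, 1)] == 1  # locus c
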