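"""CpG enumeration, dense-region chaining, bisulfite conversion and calling."""

import re

import numpy as np
import pytest

import xistkit as xk
from xistkit._util import random_dna
from xistkit.methylome import BisulfiteCallMatrix, CpGSiteMap


class TestScanCpg:
    def test_desk_window_has_78_sites(self, desk_window):
        win, tss = desk_window
        assert len(xk.scan_cpg(win, tss).sites) == 78

    def test_cg_free_window_empty(self):
        seq = ("AT" * 2100)
        assert xk.scan_cpg(seq, 2100, 2000).sites == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 900)
        got = xk.scan_cpg(seq, 450, 400).sites
        idx = [m.start() for m in re.finditer("(?=CG)", seq)
               if 49 <= m.start() < 849]
        expect = [i - 449 + 1 if i >= 449 else i - 449 for i in idx]
        assert got == expect

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="window"):
            xk.scan_cpg("ACGT" * 10, 20, 2000)


class TestDenseRegions:
    def test_desk_layout_two_regions(self, desk_bundle, desk_window):
        win, tss = desk_window
        regions = xk.dense_regions(xk.scan_cpg(win, tss))
        assert [(r.interval, r.site_count) for r in regions] == \
            [((-284, 53), 13), ((285, 1727), 54)]

    def test_all_sites_close_one_region(self):
        m = CpGSiteMap(sites=[-10, -4, 2, 8], window=(-200, 200), tss_index=300)
        regions = xk.dense_regions(m, max_gap=50, min_sites=2)
        assert len(regions) == 1
        assert regions[0].interval == (-10, 8)
        assert regions[0].site_count == 4

    def test_permutation_invariance(self, desk_window):
        win, tss = desk_window
        m = xk.scan_cpg(win, tss)
        rng = np.random.default_rng(0)
        shuffled = list(m.sites)
        rng.shuffle(shuffled)
        m2 = CpGSiteMap(shuffled, m.window, m.tss_index)
        assert xk.dense_regions(m2) == xk.dense_regions(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_single_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(np.arange(0, 2000), 40, replace=False))
        sites = [int(i) - 1000 if i < 1000 else int(i) - 1000 + 1 for i in idx]
        m = CpGSiteMap(sites, (-1000, 1000), 1000)
        got = xk.dense_regions(m, max_gap=60, min_sites=3)
        # brute-force single linkage on indices
        chains, cur = [], [idx[0]]
        for i in idx[1:]:
            if i - cur[-1] <= 60:
                cur.append(i)
            else:
                chains.append(cur)
                cur = [i]
        chains.append(cur)
        expect = [len(c) for c in chains if len(c) >= 3]
        assert [r.site_count for r in got] == expect


class TestBisulfiteConvert:
    def test_all_methylated_converts_only_noncpg(self):
        ref = "ACGCTACGAC"
        states = {i: True for i in range(len(ref) - 1) if ref[i:i+2] == "CG"}
        out = xk.bisulfite_convert(ref, states)
        assert out == "ACGTTACGAT"

    def test_none_methylated_is_c_free(self):
        ref = "ACGCTACGACCC"
        states = {i: False for i in range(len(ref) - 1) if ref[i:i+2] == "CG"}
        assert "C" not in xk.bisulfite_convert(ref, states)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_positional_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_dna(rng, 300)
        cpg = [i for i in range(299) if ref[i:i+2] == "CG"]
        states = {i: bool(rng.integers(2)) for i in cpg}
        out = xk.bisulfite_convert(ref, states)
        for i, (a, b) in enumerate(zip(ref, out)):
            if a != "C":
                assert b == a
            elif i in states and states[i]:
                assert b == "C"
            else:
                assert b == "T"

    def test_uncovered_cpg_rejected(self):
        with pytest.raises(ValueError, match="state"):
            xk.bisulfite_convert("AACGAA", {})


class TestCallMethylation:
    def test_fully_methylated_clone_row(self, desk_bundle, desk_window):
        win, tss = desk_window
        cmap = xk.scan_cpg(win, tss)
        region = win[1700: 2100]          # promoter -300..+100
        states = {i: True for i in range(len(region) - 1)
                  if region[i:i+2] == "CG"}
        clone = xk.bisulfite_convert(region, states)
        mat = xk.call_methylation([("c1", clone)], win, cmap)
        covered = mat.calls[0][mat.calls[0] >= 0]
        assert len(covered) > 0 and (covered == 1).all()

    def test_calls_equal_generator_truth(self, desk_bundle, desk_window):
        win, tss = desk_window
        cmap = xk.scan_cpg(win, tss)
        for sex in ("male", "female"):
            sim = xk.simulate_bisulfite_clones(desk_bundle, sex, 10,
                                               conversion_rate=1.0, seed=3)
            mat = xk.call_methylation(sim.clones, win, cmap)
            assert mat.excluded_clones == []
            for cid, states in sim.states.items():
                i = mat.clone_ids.index(cid)
                for off, methylated in states.items():
                    j = mat.sites.index(off)
                    assert mat.calls[i, j] == (1 if methylated else 0)

    def test_six_regions_cover_67_dense_sites(self, desk_bundle, desk_window):
        win, tss = desk_window
        cmap = xk.scan_cpg(win, tss)
        regions = xk.default_bisulfite_regions(desk_bundle)
        assert len(regions) == 6
        dense = xk.dense_regions(cmap)
        dense_sites = {s for r in dense
                       for s in cmap.sites if r.interval[0] <= s <= r.interval[1]}
        assert len(dense_sites) == 67
        sim = xk.simulate_bisulfite_clones(desk_bundle, "female", 2,
                                           conversion_rate=1.0, seed=0)
        for lo, hi in regions:
            from xistkit.coords import promoter_span
            assert 8 <= len([s for s in cmap.sites if lo <= s <= hi]) <= 16
            assert 250 <= promoter_span(lo, hi) <= 450
        mat = xk.call_methylation(sim.clones, win, cmap)
        covered = {s for j, s in enumerate(mat.sites)
                   if (mat.calls[:, j] >= 0).any()}
        assert dense_sites <= covered

    def test_poorly_converted_clone_excluded(self, desk_bundle, desk_window):
        win, tss = desk_window
        cmap = xk.scan_cpg(win, tss)
        region = win[1700: 2100]
        states = {i: False for i in range(len(region) - 1)
                  if region[i:i+2] == "CG"}
        good = xk.bisulfite_convert(region, states)
        # the raw, unconverted region places fine but fails conversion QC
        mat = xk.call_methylation([("good", good), ("raw", region)], win, cmap,
                                  min_conversion=0.95)
        assert mat.clone_ids == ["good"]
        assert mat.excluded_clones == ["raw"]


class TestSummaries:
    @staticmethod
    def _matrix_with_mean(total, n_clones=10, n_sites=67):
        calls = np.zeros((n_clones, n_sites), dtype=np.int8)
        per, extra = divmod(total, n_clones)
        for i in range(n_clones):
            calls[i, : per + (1 if i < extra else 0)] = 1
        return BisulfiteCallMatrix([f"c{i}" for i in range(n_clones)],
                                   list(range(n_sites)), calls,
                                   [1.0] * n_clones)

    def test_female_mean_gives_4985(self):
        s = xk.summarize_methylation(self._matrix_with_mean(334))
        assert s.aggregate_percent == 49.85
        assert s.mean_methylated_sites_per_clone == 33.4

    def test_male_mean_gives_9627(self):
        s = xk.summarize_methylation(self._matrix_with_mean(645))
        assert abs(s.aggregate_percent - 96.26) <= 0.02
        assert s.mean_methylated_sites_per_clone == 64.5

    def test_all_methylated_is_100(self):
        m = self._matrix_with_mean(670)
        assert xk.summarize_methylation(m).aggregate_percent == 100.00

    @pytest.mark.parametrize("seed", range(10))
    def test_aggregate_matches_tally_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([1, 0, -1], size=(8, 20)).astype(np.int8)
        if not ((calls == 1) | (calls == 0)).any():
            calls[0, 0] = 1
        m = BisulfiteCallMatrix([f"c{i}" for i in range(8)], list(range(20)),
                                calls, [1.0] * 8)
        s = xk.summarize_methylation(m)
        meth = int((calls == 1).sum())
        un = int((calls == 0).sum())
        assert s.n_methylated == meth and s.n_unmethylated == un
        assert abs(s.aggregate_percent - 100 * meth / (meth + un)) < 0.005
        # conservation
        assert meth + un + int((calls == -1).sum()) == calls.size

    def test_all_missing_rejected(self):
        calls = np.full((3, 4), -1, dtype=np.int8)
        m = BisulfiteCallMatrix(["a", "b", "c"], [1, 2, 3, 4], calls, [1] * 3)
        with pytest.raises(ValueError):
            xk.summarize_methylation(m)


class TestLollipop:
    def test_small_grid(self):
        calls = np.array([[1, 0, -1], [0, 1, 1]], dtype=np.int8)
        m = BisulfiteCallMatrix(["c1", "c2"], [1, 5, 9], calls, [1.0, 1.0])
        grid = xk.lollipop_report(m)
        lines = grid.splitlines()
        assert len(lines) == 2
        assert lines[0].endswith("*o.")
        assert lines[1].endswith("o**")

    def test_glyph_counts_match_states(self, desk_bundle, desk_window):
        win, tss = desk_window
        cmap = xk.scan_cpg(win, tss)
        sim = xk.simulate_bisulfite_clones(desk_bundle, "female", 4,
                                           conversion_rate=1.0, seed=1)
        mat = xk.call_methylation(sim.clones, win, cmap)
        grid = xk.lollipop_report(mat)
        assert len(grid.splitlines()) == len(mat.clone_ids)
        assert grid.count("*") == int((mat.calls == 1).sum())
        assert grid.count("o") == int((mat.calls == 0).sum())


class TestParameterRecovery:
    def test_per_site_probability_within_3se(self, desk_bundle, desk_window):
        win, tss = desk_window
        cmap = xk.scan_cpg(win, tss)
        for sex, p in (("male", 0.96), ("female", 0.50)):
            sim = xk.simulate_bisulfite_clones(desk_bundle, sex, 200,
                                               conversion_rate=0.99, seed=8)
            mat = xk.call_methylation(sim.clones, win, cmap,
                                      min_conversion=0.95)
            for j in range(mat.calls.shape[1]):
                col = mat.calls[:, j]
                n = int((col >= 0).sum())
                if n == 0:
                    continue
                phat = float((col == 1).sum()) / n
                se = np.sqrt(p * (1 - p) / n)
                assert abs(phat - p) <= 3 * se + 1e-12
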