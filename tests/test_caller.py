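"""Island caller: binning arithmetic, eligibility, island finding, threshold
calibration, both calling modes, and the post-merge rule."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from oriscan import (
    CallerConfig,
    GenomeModel,
    ReadLibrary,
    bin_reads,
    calibrate_score_threshold,
    call_islands_no_input,
    call_islands_with_input,
    eligibility_threshold,
    find_islands,
    merge_adjacent,
)
from oriscan.caller import WindowCounts

from oracles import eligibility_by_tail_scan, linear_scan_islands

GENOME = GenomeModel(chromosomes={"chrA": 15_000})


def _lib(rows, name="ip"):
    return ReadLibrary(name, pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]))


def _uniform_lib(rng, genome, n, name="ip"):
    chroms = list(genome.chromosomes)
    lens = np.array([genome.chromosomes[c] for c in chroms], dtype=float)
    ci = rng.integers(0, len(chroms), size=n)
    starts = np.array([rng.integers(0, lens[i] - 50) for i in ci], dtype=np.int64)
    return ReadLibrary(
        name,
        pd.DataFrame(
            {
                "chrom": [chroms[i] for i in ci],
                "start": starts,
                "end": starts + 50,
                "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            }
        ),
    )


class TestBinReads:
    def test_plus_tag_midpoint_shift(self):
        cfg = CallerConfig()
        wc = bin_reads(_lib([("chrA", 0, 36, "+")]), GENOME, cfg)
        assert wc.counts["chrA"][0] == 1  # midpoint 100 -> window 0
        wc = bin_reads(_lib([("chrA", 60, 96, "+")]), GENOME, cfg)
        assert wc.counts["chrA"][1] == 1  # midpoint 160 -> window 1

    def test_minus_tag_shifts_left_from_end(self):
        cfg = CallerConfig()
        wc = bin_reads(_lib([("chrA", 264, 300, "-")]), GENOME, cfg)
        assert wc.counts["chrA"][1] == 1  # 300 - 100 = 200 -> window 1

    def test_tag_conservation_random(self):
        rng = np.random.default_rng(0)
        lib = _uniform_lib(rng, GENOME, 10_000)
        wc = bin_reads(lib, GENOME, CallerConfig())
        assert int(sum(v.sum() for v in wc.counts.values())) == 10_000
        # brute-force per-tag counting oracle
        expect = np.zeros_like(wc.counts["chrA"])
        for r in lib.df.itertuples(index=False):
            mid = r.start + 100 if r.strand == "+" else r.end - 100
            mid = min(max(mid, 0), 14_999)
            expect[mid // 150] += 1
        assert np.array_equal(wc.counts["chrA"], expect)

    def test_window_larger_than_chromosome(self):
        g = GenomeModel(chromosomes={"c": 100})
        wc = bin_reads(_lib([("c", 0, 50, "+")]), g, CallerConfig(window_size=1000))
        assert len(wc.counts["c"]) == 1 and wc.counts["c"][0] == 1


class TestEligibility:
    def test_tiny_lambda_any_tag_surprising(self):
        assert eligibility_threshold(1e-9, 0.2) == 1

    def test_p_one_all_windows_eligible(self):
        assert eligibility_threshold(2.0, 1.0) == 0

    def test_matches_tail_scan_oracle(self):
        # frozen from the oracle: lam=2, p=0.2 -> 4 (P(X>=4)=0.143 < 0.2)
        assert eligibility_by_tail_scan(2.0, 0.2) == 4
        for lam in [0.1, 0.5, 1.0, 1.891, 2.0, 5.0]:
            for p in [0.5, 0.2, 0.05, 0.01]:
                assert eligibility_threshold(lam, p) == eligibility_by_tail_scan(lam, p)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            eligibility_threshold(0.0, 0.2)


def _window_counts(vec, lam_tags=None, window=150):
    vec = np.asarray(vec, dtype=np.int64)
    total = int(vec.sum()) if lam_tags is None else lam_tags
    return WindowCounts(
        counts={"chrA": vec},
        window_size=window,
        total_tags=total,
        effective_length=len(vec) * window,
        chrom_lengths={"chrA": len(vec) * window},
    )


class TestFindIslands:
    def test_no_eligible_windows(self):
        wc = _window_counts([0, 1, 0, 1], lam_tags=2)
        cfg = CallerConfig(eligibility_p=0.01)
        assert len(find_islands(wc, cfg)) == 0

    def test_single_eligible_window_identity(self):
        vec = np.zeros(10, dtype=int)
        vec[4] = 9
        wc = _window_counts(vec)
        cfg = CallerConfig()
        lam = wc.lam
        islands = find_islands(wc, cfg)
        assert len(islands) == 1
        row = islands.iloc[0]
        assert (row["start"], row["end"]) == (600, 750)
        assert row["score"] == pytest.approx(float(-poisson.logpmf(9, lam)))
        assert row["tag_count"] == 9

    @pytest.mark.parametrize("gap", [0, 2])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan_oracle(self, gap, seed):
        rng = np.random.default_rng(seed)
        vec = rng.poisson(1.0, size=200)
        vec[rng.integers(0, 200, size=10)] += rng.integers(3, 12, size=10)
        wc = _window_counts(vec)
        cfg = CallerConfig(gap_size=gap)
        lam = wc.lam
        l0 = eligibility_threshold(lam, cfg.eligibility_p)
        got = find_islands(wc, cfg)
        expected = linear_scan_islands(vec, lam, l0, gap, 150)
        assert len(got) == len(expected)
        for row, (s, e, score, tags) in zip(got.itertuples(index=False), expected):
            assert (row.start, row.end, row.tag_count) == (s, e, tags)
            assert row.score == pytest.approx(score)


class TestCalibration:
    def test_infinite_e_value_gives_zero_threshold(self):
        cfg = CallerConfig(e_value=np.inf)
        assert calibrate_score_threshold(cfg, 1.0, 1000) == 0.0

    def test_huge_e_value_warns_and_returns_zero(self):
        cfg = CallerConfig(e_value=1e9)
        with pytest.warns(UserWarning):
            assert calibrate_score_threshold(cfg, 1.0, 100) == 0.0

    def test_recursion_agrees_with_monte_carlo(self):
        lam, n_win = 1.0, 20_000
        rec = calibrate_score_threshold(CallerConfig(e_value=1.0), lam, n_win)
        mc = calibrate_score_threshold(
            CallerConfig(e_value=1.0, null_method="monte_carlo",
                         mc_replicates=200, seed=11),
            lam, n_win,
        )
        assert rec == pytest.approx(mc, rel=0.1)


class TestCallingModes:
    def test_empty_library_empty_islands(self):
        assert len(call_islands_no_input(ReadLibrary("e"), GENOME, CallerConfig())) == 0

    def test_extreme_single_window_signal(self):
        rng = np.random.default_rng(1)
        bg = _uniform_lib(rng, GENOME, 200)
        spike = pd.DataFrame(
            {"chrom": "chrA", "start": np.full(100, 300) + np.arange(100),
             "end": np.full(100, 350) + np.arange(100), "strand": "+"}
        )
        lib = ReadLibrary("ip", pd.concat([bg.df, spike], ignore_index=True))
        cfg = CallerConfig(e_value=0.1, effective_genome_fraction=1.0)
        islands = call_islands_no_input(lib, GENOME, cfg)
        assert len(islands) == 1
        assert islands.iloc[0]["start"] <= 450 <= islands.iloc[0]["end"]

    def test_with_input_requires_input(self):
        with pytest.raises(ValueError):
            call_islands_with_input(
                ReadLibrary("ip"), ReadLibrary("in"), GENOME, CallerConfig()
            )

    def test_with_input_zero_input_strong_ip_retained(self):
        rng = np.random.default_rng(2)
        spike = pd.DataFrame(
            {"chrom": "chrA", "start": np.full(150, 300) + np.arange(150) % 50,
             "end": np.full(150, 350) + np.arange(150) % 50, "strand": "+"}
        )
        ip = ReadLibrary("ip", pd.concat(
            [_uniform_lib(rng, GENOME, 100).df, spike], ignore_index=True))
        # input with no tags anywhere near the spike
        inp = ReadLibrary("in", pd.DataFrame(
            {"chrom": "chrA", "start": np.arange(100) * 100 + 5_000,
             "end": np.arange(100) * 100 + 5_050, "strand": "+"}))
        out = call_islands_with_input(ip, inp, GENOME, CallerConfig(fdr=0.05))
        hit = out[(out["start"] <= 400) & (out["end"] >= 400)]
        assert len(hit) == 1

    def test_identical_ip_and_input_yield_nothing(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lib = _uniform_lib(rng, GENOME, 2_000)
            out = call_islands_with_input(
                lib, lib, GENOME, CallerConfig(fdr=0.05, eligibility_p=0.5)
            )
            hits += len(out) > 0
        assert hits <= 1  # no island at q<=0.05 in >=9/10 seeds

    def test_bh_qvalues_monotone_in_pvalue_order(self):
        rng = np.random.default_rng(3)
        sig = []
        for c in range(30):
            s = int(rng.integers(0, 14_000))
            n = int(rng.integers(5, 40))
            sig.append(pd.DataFrame(
                {"chrom": "chrA", "start": s + np.arange(n), "end": s + 50 + np.arange(n),
                 "strand": "+"}))
        ip = ReadLibrary("ip", pd.concat(sig, ignore_index=True))
        inp = _uniform_lib(rng, GENOME, 1_000, "in")
        cfg = CallerConfig(fdr=0.999, eligibility_p=0.5)
        out = call_islands_with_input(ip, inp, GENOME, cfg)
        assert len(out) > 2
        # recompute p-values implied by ordering: q sorted by q equals q sorted
        q = np.sort(out["significance"].to_numpy())
        assert (np.diff(q) >= -1e-12).all()


class TestMergeAdjacent:
    CFG = CallerConfig()

    def _df(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "tag_count"])

    def test_one_window_gap_merges(self):
        # separated by exactly one window (150 bp): merge
        out = merge_adjacent(
            self._df([("c", 0, 150, 1.0, 3), ("c", 300, 450, 2.0, 4)]), self.CFG
        )
        assert out[["start", "end"]].values.tolist() == [[0, 450]]
        assert out.iloc[0]["score"] == pytest.approx(3.0)
        assert out.iloc[0]["tag_count"] == 7

    def test_two_window_gap_untouched(self):
        out = merge_adjacent(
            self._df([("c", 0, 150, 1.0, 3), ("c", 450, 600, 2.0, 4)]), self.CFG
        )
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 100) * 150, size=30, replace=False))
        df = self._df(
            [("c", int(s), int(s) + 150, 1.0, 2) for s in starts]
        )
        once = merge_adjacent(df, self.CFG)
        twice = merge_adjacent(once, self.CFG)
        pd.testing.assert_frame_equal(once, twice)


class TestThresholdMonotonicity:
    def test_relaxed_threshold_is_coverage_superset(self):
        rng = np.random.default_rng(9)
        lib = _uniform_lib(rng, GENOME, 3_000)
        strict = call_islands_no_input(lib, GENOME, CallerConfig(e_value=1e-5))
        relaxed = call_islands_no_input(lib, GENOME, CallerConfig(e_value=0.1))
        strict_set = set(map(tuple, strict[["chrom", "start", "end"]].values))
        relaxed_set = set(map(tuple, relaxed[["chrom", "start", "end"]].values))
        assert strict_set <= relaxed_set
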