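"""Synthetic-data generator: planted structure, library statistics, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, truncnorm

from oriscan import (
    SimConfig,
    generate_genome,
    plant_origins,
    simulate_libraries,
    read_intervals_bed,
    write_truth,
)
from oriscan.core import merge_intervals

SMALL = dict(n_chromosomes=1, chrom_length=2_880_000, n_genes=150, n_origins=40,
             reads_input=5_000)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(frac_origins_at_tss=1.5)

    def test_fragment_order(self):
        with pytest.raises(ValueError):
            SimConfig(fragment_min=500, fragment_max=100)

    def test_lag_within_labelling_time(self):
        with pytest.raises(ValueError):
            SimConfig(max_lag=20, labelling_time=15)


class TestGenerateGenome:
    def test_no_genes_still_tiles_timing(self):
        cfg = SimConfig(seed=3, n_genes=0, **{k: v for k, v in SMALL.items()
                                              if k != "n_genes"})
        g = generate_genome(cfg)
        assert len(g.tracks["genes"]) == 0
        cov = merge_intervals(g.tracks["timing"].df)
        assert len(cov) == 1
        assert cov.iloc[0]["start"] == 0 and cov.iloc[0]["end"] == cfg.chrom_length

    def test_chromosome_too_short_for_genes(self):
        with pytest.raises(ValueError, match="too short"):
            generate_genome(SimConfig(seed=0, n_chromosomes=1, chrom_length=50_000,
                                      n_genes=40))

    def test_deterministic_outputs(self, tmp_path):
        from oriscan.io import write_fasta

        cfg = SimConfig(seed=4, **SMALL)
        g1, g2 = generate_genome(cfg), generate_genome(cfg)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(g1, p1)
        write_fasta(g2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for label in g1.tracks:
            pd.testing.assert_frame_equal(g1.tracks[label].df, g2.tracks[label].df)

    def test_planted_g4_coordinates_carry_the_motif(self):
        cfg = SimConfig(seed=5, **SMALL)
        g = generate_genome(cfg)
        for r in g.tracks["g4"].df.itertuples(index=False):
            sub = g.sequences[r.chrom][r.start : r.end]
            assert sub.startswith("GGG") and sub.endswith("GGG")


class TestPlantOrigins:
    def test_all_origins_at_tss_when_fraction_one(self):
        cfg = SimConfig(seed=6, frac_origins_at_tss=1.0, **SMALL)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        tss = g.tracks["tss"].df
        for r in truth.origins.itertuples(index=False):
            sub = tss[tss["chrom"] == r.chrom]
            assert (np.abs(sub["start"] - r.position) <= cfg.tss_halfwidth).any()

    def test_no_early_origins_when_fraction_zero(self):
        cfg = SimConfig(seed=7, frac_origins_early=0.0, **SMALL)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        early = g.tracks["timing"].df.query("name in ['S1', 'S2']")
        for r in truth.origins.itertuples(index=False):
            sub = early[early["chrom"] == r.chrom]
            assert not ((sub["start"] <= r.position) & (sub["end"] > r.position)).any()

    def test_tss_fraction_binomial_at_1000_origins(self):
        cfg = SimConfig(seed=8, n_origins=1_000, n_genes=2_400,
                        frac_origins_at_tss=0.5)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        tss_by_chrom = {
            c: np.sort(s["start"].to_numpy())
            for c, s in g.tracks["tss"].df.groupby("chrom")
        }
        near = 0
        for r in truth.origins.itertuples(index=False):
            pos = tss_by_chrom[r.chrom]
            i = np.searchsorted(pos, r.position)
            d = min(
                abs(int(pos[j]) - r.position)
                for j in (max(i - 1, 0), min(i, len(pos) - 1))
            )
            near += d <= cfg.tss_halfwidth
        frac = near / 1_000
        sd = np.sqrt(0.5 * 0.5 / 1_000)
        assert abs(frac - 0.5) <= 3 * sd

    def test_germline_origins_emit_positive_jumps(self, sim_bundle):
        truth = sim_bundle.truth
        plus = truth.jumps[truth.jumps["polarity"] == "+"]
        germ = truth.origins[truth.origins["germline"]]
        assert len(plus) == len(germ)
        assert set(zip(plus["chrom"], plus["position"])) == set(
            zip(germ["chrom"], germ["position"])
        )

    def test_origin_positions_within_chromosomes(self, sim_bundle):
        g = sim_bundle.genome
        o = sim_bundle.truth.origins
        for r in o.itertuples(index=False):
            assert 0 <= r.position < g.chromosomes[r.chrom]

    def test_some_origin_pairs_closer_than_5kb(self, sim_bundle):
        o = sim_bundle.truth.origins
        close = 0
        for _, sub in o.groupby("chrom"):
            d = np.diff(np.sort(sub["position"].to_numpy()))
            close += int((d < 5_000).sum())
        assert close >= 10


class TestSimulateLibraries:
    def test_no_signal_sources_gives_empty_ip(self):
        cfg = SimConfig(seed=9, firing_probability=0.0,
                        s_phase_background_fraction=0.0, **SMALL)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        a, b, inp = simulate_libraries(g, truth, cfg)
        assert len(a) == 0 and len(b) == 0
        assert len(inp) == cfg.reads_input

    def test_support_bound_single_origin(self):
        cfg = SimConfig(seed=10, n_chromosomes=1, chrom_length=2_880_000,
                        n_genes=20, n_origins=1, firing_probability=1.0,
                        s_phase_background_fraction=0.0, frac_origins_clustered=0,
                        reads_input=100)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        a, b, _ = simulate_libraries(g, truth, cfg)
        pos = truth.origins.iloc[0]["position"]
        reach = cfg.labelling_time * (cfg.fork_rate_mean + 4 * cfg.fork_rate_sd)
        for lib in (a, b):
            mid = (lib.df["start"] + lib.df["end"]) // 2
            assert (np.abs(mid - pos) <= reach + cfg.fragment_max).all()

    def test_mean_fragment_distance_matches_monte_carlo_oracle(self):
        cfg = SimConfig(seed=11, n_chromosomes=1, chrom_length=2_880_000,
                        n_genes=20, n_origins=1, firing_probability=1.0,
                        s_phase_background_fraction=0.0, frac_origins_clustered=0,
                        n_nuclei=3_000, reads_input=100)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        # keep the origin away from chromosome ends so no tract is clipped
        truth.origins.loc[0, "position"] = 1_440_000
        _, b, _ = simulate_libraries(g, truth, cfg)
        mid = (b.df["start"] + b.df["end"]) // 2
        observed = np.abs(mid - 1_440_000).mean()
        # independent Monte-Carlo oracle over (t, rate, u) draws; fragments
        # are sampled uniformly along a tract, weighted by tract length
        rng = np.random.default_rng(123)
        n = 100_000
        t = rng.uniform(0, cfg.max_lag, n)
        aa = (1 - cfg.fork_rate_mean) / cfg.fork_rate_sd
        rate = truncnorm.rvs(aa, np.inf, loc=cfg.fork_rate_mean,
                             scale=cfg.fork_rate_sd, size=n, random_state=rng)
        tract = rate * (cfg.labelling_time - t)
        expected = (0.5 * tract * tract).sum() / tract.sum()  # length-weighted
        assert observed == pytest.approx(expected, rel=0.05)

    def test_ip_a_has_roughly_half_the_depth_of_ip_b(self, sim_bundle):
        ratio = len(sim_bundle.lib_a) / len(sim_bundle.lib_b)
        assert 0.4 < ratio < 0.6

    def test_enrichment_at_efficient_origins(self, sim_bundle):
        """Read density within +/-1 kb of efficient origins >= 5x genome average."""
        sim = sim_bundle.sim
        eff = sim_bundle.truth.origins.query(
            "firing_probability >= @sim.firing_probability"
        )
        lib = sim_bundle.lib_b
        mids = {c: np.sort(((s["start"] + s["end"]) // 2).to_numpy())
                for c, s in lib.df.groupby("chrom")}
        near = 0
        for r in eff.itertuples(index=False):
            m = mids[r.chrom]
            near += np.searchsorted(m, r.position + 1_000) - np.searchsorted(
                m, r.position - 1_000
            )
        density_near = near / (2_000 * len(eff))
        density_genome = len(lib) / sim_bundle.genome.total_length
        assert density_near >= 5 * density_genome

    def test_input_library_uniform_chi_squared(self):
        """Input density passes a 10-kb-bin chi-squared test in >=19/20 seeds."""
        ok = 0
        base = dict(SMALL)
        base["reads_input"] = 20_000
        for seed in range(20):
            cfg = SimConfig(seed=seed, firing_probability=0.0,
                            s_phase_background_fraction=0.0, **base)
            g = generate_genome(cfg)
            truth = plant_origins(g, cfg)
            _, _, inp = simulate_libraries(g, truth, cfg)
            mid = ((inp.df["start"] + inp.df["end"]) // 2).to_numpy()
            n_bins = cfg.chrom_length // 10_000
            hist = np.bincount(np.minimum(mid // 10_000, n_bins - 1), minlength=n_bins)
            _, p = chisquare(hist)
            ok += p > 0.01
        assert ok >= 19

    def test_libraries_deterministic_per_seed(self):
        cfg = SimConfig(seed=12, **SMALL)
        g = generate_genome(cfg)
        truth = plant_origins(g, cfg)
        a1, b1, i1 = simulate_libraries(g, truth, cfg)
        a2, b2, i2 = simulate_libraries(g, truth, cfg)
        for x, y in ((a1, a2), (b1, b2), (i1, i2)):
            pd.testing.assert_frame_equal(x.df, y.df)


class TestWriteTruth:
    def test_empty_truth_valid_files(self, tmp_path):
        from oriscan.simulate import SimulationTruth

        empty = SimulationTruth(
            origins=pd.DataFrame(columns=["chrom", "position", "firing_probability",
                                          "timing_class", "at_tss", "has_g4",
                                          "germline"]),
            jumps=pd.DataFrame(columns=["chrom", "position", "polarity"]),
        )
        paths = write_truth(empty, tmp_path)
        assert len(read_intervals_bed(paths["origins_bed"])) == 0

    def test_round_trip_coordinates(self, sim_bundle, tmp_path):
        paths = write_truth(sim_bundle.truth, tmp_path)
        back = read_intervals_bed(paths["origins_bed"])
        got = set(zip(back.df["chrom"], back.df["start"]))
        expect = set(zip(sim_bundle.truth.origins["chrom"],
                         sim_bundle.truth.origins["position"]))
        assert got == expect
        jumps = read_intervals_bed(paths["jumps_bed"])
        assert set(jumps.df["strand"]) <= {"+", "-"}

    def test_line_level_parse_oracle(self, tmp_path):
        rng = np.random.default_rng(13)
        chrom_len = 1_000_000
        origins = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=500),
                "position": rng.integers(0, chrom_len, size=500),
                "firing_probability": rng.uniform(0, 1, size=500),
                "timing_class": "S1",
                "at_tss": False,
                "has_g4": False,
                "germline": False,
            }
        )
        from oriscan.simulate import SimulationTruth

        truth = SimulationTruth(origins=origins,
                                jumps=pd.DataFrame(columns=["chrom", "position",
                                                            "polarity"]))
        paths = write_truth(truth, tmp_path)
        rows = []
        for line in open(paths["origins_bed"]):
            f = line.rstrip("\n").split("\t")
            assert len(f) == 6
            rows.append((f[0], int(f[1]), int(f[2])))
        assert len(rows) == 500
        for chrom, start, end in rows:
            assert 0 <= start < end <= chrom_len
        # sorted by (chrom, start)
        assert rows == sorted(rows)
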