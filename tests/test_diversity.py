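"""Heterozygosity, windowed pi, Weir-Cockerham F_ST, folded SFS, LD decay."""

import itertools

import numpy as np
import pandas as pd
import pytest

import deerload as dl
from conftest import make_gm
from oracles import pi_brute, project_site, wc_theta_oracle


class TestHeterozygosity:
    def test_arithmetic(self):
        g = np.zeros((200, 1), dtype=np.int8)
        g[:100, 0] = 1
        h = dl.heterozygosity(make_gm(g), {"s0": 1_000_000})
        assert h["s0"] == pytest.approx(1.0e-4)

    def test_fully_homozygous_zero(self):
        g = np.full((50, 1), 2, dtype=np.int8)
        assert dl.heterozygosity(make_gm(g), {"s0": 1e6})["s0"] == 0

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError, match="s0"):
            dl.heterozygosity(make_gm(np.zeros((5, 1), dtype=np.int8)), {})

    def test_neutral_theta_expectation(self):
        """Mean H across panmictic samples tracks 4*Ne*mu within 10%."""
        reps = []
        for seed in range(20):
            cfg = dl.ScenarioConfig(
                n_chrom=2, chrom_length_bp=200_000, mu=5e-7, rec_rate=8.0,
                ne_ancestral=80, split_gen=5, ne_pops={"A": 80},
                migration_epoch=(5, 4, 0, 0), sample_sizes={"A": 10},
                seed=seed, init="sfs", burn_in=80,
                class_mix={"neutral": 1.0},
                sel_coeff={"neutral": (0.0, 0.5)},
            )
            ds = dl.simulate_scenario(cfg)
            reps.append(dl.heterozygosity(ds.gm, ds.effective_length).mean())
        theta = 4 * 80 * 5e-7
        assert np.mean(reps) == pytest.approx(theta / (1 + theta), rel=0.10)


class TestWindowedPi:
    def test_single_site_worked_example(self):
        """Derived count 2 of 4 alleles: pi_site = 4/6; window pi over 50 kb."""
        g = np.array([[1, 1]], dtype=np.int8)
        gm = make_gm(g, positions=[10_000])
        out = dl.windowed_pi(gm, window=50_000, step=20_000)
        assert out["pi"].iloc[0] == pytest.approx((4 / 6) / 50_000)
        assert out["pi"].iloc[0] == pytest.approx(1.3333e-5, rel=1e-3)

    def test_monomorphic_window_zero(self):
        g = np.zeros((5, 4), dtype=np.int8)
        out = dl.windowed_pi(make_gm(g), window=50_000, step=20_000)
        assert (out["pi"] == 0).all()

    def test_windows_never_cross_chromosomes(self):
        g = np.ones((4, 2), dtype=np.int8)
        gm = make_gm(
            g,
            positions=[49_000, 50_500, 1_000, 2_000],
            chrom=["chr1", "chr1", "chr2", "chr2"],
        )
        out = dl.windowed_pi(gm, window=50_000, step=20_000)
        assert set(out["chrom"]) == {"chr1", "chr2"}
        chr2 = out[out["chrom"] == "chr2"]
        assert chr2["n_snps"].iloc[0] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = rng.integers(-1, 3, size=(50, 5)).astype(np.int8)
            gm = make_gm(g, positions=np.sort(rng.choice(49_000, 50, replace=False)) + 1)
            total = dl.site_pi(gm).sum()
            assert total == pytest.approx(pi_brute(g), abs=1e-9)


class TestFstWC:
    def test_fixed_difference_is_one(self):
        g = np.concatenate([np.zeros((1, 5)), np.full((1, 5), 2)], axis=1).astype(np.int8)
        gm = make_gm(g, populations={f"s{i}": "A" if i < 5 else "B" for i in range(10)})
        theta, mean, _ = dl.fst_wc(gm)
        assert mean == pytest.approx(1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 10_000)
        g = rng.binomial(2, p[:, None], size=(10_000, 20)).astype(np.int8)
        gm = make_gm(g, populations={f"s{i}": "A" if i < 10 else "B" for i in range(20)})
        _, mean, _ = dl.fst_wc(gm)
        assert abs(mean) < 0.02

    def test_worked_site_vs_oracle(self):
        # A: 3 AA, 2 Aa; B: 1 AA, 4 aa
        ga = [0, 0, 0, 1, 1]
        gb = [0, 2, 2, 2, 2]
        g = np.array([ga + gb], dtype=np.int8)
        gm = make_gm(g, populations={f"s{i}": "A" if i < 5 else "B" for i in range(10)})
        theta, _, _ = dl.fst_wc(gm)
        expect = wc_theta_oracle([(3, 2, 0), (1, 0, 4)])
        assert theta[0] == pytest.approx(expect, abs=1e-12)

    def test_all_small_tables_vs_oracle(self):
        """Every 2-population genotype table with <= 4 per pop matches WC84."""
        tables = [
            (a, h, n - a - h)
            for n in range(2, 5)
            for a in range(n + 1)
            for h in range(n + 1 - a)
        ]
        for ta, tb in itertools.product(tables, repeat=2):
            ga = [0] * ta[0] + [1] * ta[1] + [2] * ta[2]
            gb = [0] * tb[0] + [1] * tb[1] + [2] * tb[2]
            g = np.array([ga + gb], dtype=np.int8)
            pops = {f"s{i}": ("A" if i < len(ga) else "B") for i in range(len(ga) + len(gb))}
            theta, _, _ = dl.fst_wc(make_gm(g, populations=pops))
            expect = wc_theta_oracle([ta, tb])
            if expect is None:
                assert np.isnan(theta[0])
            else:
                assert theta[0] == pytest.approx(expect, abs=1e-10)


class TestFoldedSfs:
    def test_fold_rule(self):
        """8 alleles, derived count 5 -> folded class 3."""
        g = np.array([[2, 1, 1, 1]], dtype=np.int8)
        sfs, skipped = dl.folded_sfs(make_gm(g), projection_n=8)
        assert skipped == 0
        assert sfs[3] == pytest.approx(1.0)

    def test_sum_equals_sites_used(self, two_pop_dataset):
        gm = two_pop_dataset.gm
        sfs, skipped = dl.folded_sfs(gm, pop="A", projection_n=12)
        g = gm.genotypes[:, gm.sample_indices("A")]
        called = g != -1
        d = np.where(called, g, 0).sum(axis=1)
        m = 2 * called.sum(axis=1)
        seg = (d > 0) & (d < m)
        used = int((seg & (m >= 12)).sum())
        assert sfs.sum() == pytest.approx(used)
        assert skipped == int(seg.sum()) - used

    def test_projection_matches_enumeration(self):
        g = np.array([[1, 2, 1, 0]], dtype=np.int8)  # m=8, d=4
        sfs, _ = dl.folded_sfs(make_gm(g), projection_n=4)
        probs = project_site(8, 4, 4)
        expect = np.array(
            [probs[0] + probs[4], probs[1] + probs[3], probs[2]]
        )
        np.testing.assert_allclose(sfs, expect, atol=1e-12)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
        sfs1, _ = dl.folded_sfs(make_gm(g), projection_n=8)
        sfs2, _ = dl.folded_sfs(make_gm(2 - g), projection_n=8)
        np.testing.assert_allclose(sfs1, sfs2, atol=1e-9)

    def test_bad_projection_rejected(self):
        gm = make_gm(np.ones((3, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            dl.folded_sfs(gm, projection_n=1)
        with pytest.raises(ValueError):
            dl.folded_sfs(gm, projection_n=3)


class TestLdDecay:
    def test_duplicated_adjacent_sites(self):
        rng = np.random.default_rng(3)
        row = rng.integers(0, 3, 20).astype(np.int8)
        g = np.stack([row, row])
        gm = make_gm(g, positions=[1000, 2000])
        out = dl.ld_decay(gm, max_dist=10_000, bin_width=10_000)
        assert out["mean_r2"].iloc[0] == pytest.approx(1.0)
        assert out["n_pairs"].iloc[0] == 1

    def test_free_recombination_plateau(self):
        """Unlinked sites: mean r2 ~ the 1/n sampling floor."""
        rng = np.random.default_rng(4)
        n = 50
        p = rng.uniform(0.2, 0.8, 300)
        g = rng.binomial(2, p[:, None], size=(300, n)).astype(np.int8)
        gm = make_gm(g, positions=np.arange(1, 301) * 100)
        out = dl.ld_decay(gm, max_dist=30_000, bin_width=10_000)
        grand = (out["mean_r2"] * out["n_pairs"]).sum() / out["n_pairs"].sum()
        assert grand == pytest.approx(1 / n, rel=0.35)

    def test_smaller_population_decays_slower(self):
        """Matched theta: the small-Ne population keeps higher mid-range r2
        in expectation over seeds."""
        totals = {40: [], 160: []}
        for seed in range(6):
            r2 = {}
            for ne, mu in ((40, 1.6e-6), (160, 4e-7)):
                cfg = dl.ScenarioConfig(
                    n_chrom=2, chrom_length_bp=300_000, mu=mu, rec_rate=8.0,
                    ne_ancestral=ne, split_gen=5, ne_pops={"A": ne},
                    migration_epoch=(5, 4, 0, 0), sample_sizes={"A": 10},
                    seed=seed, burn_in=2 * ne,
                )
                ds = dl.simulate_scenario(cfg)
                dec = dl.ld_decay(ds.gm, max_dist=60_000, bin_width=20_000)
                mid = dec[dec["dist_lo"] >= 20_000]
                r2[ne] = (mid["mean_r2"] * mid["n_pairs"]).sum() / mid["n_pairs"].sum()
            totals[40].append(r2[40])
            totals[160].append(r2[160])
        assert np.mean(totals[40]) > np.mean(totals[160])
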