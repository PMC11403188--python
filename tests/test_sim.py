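"""Forward Wright-Fisher simulator: reproducibility, demography, selection."""

import numpy as np
import pandas as pd
import pytest

import deerload as dl
from deerload.sim import ExtinctionError


def tiny_config(**kw):
    base = dict(
        n_chrom=2,
        chrom_length_bp=100_000,
        mu=8e-7,
        rec_rate=8.0,
        ne_ancestral=40,
        split_gen=10,
        ne_pops={"A": 40},
        migration_epoch=(10, 9, 0.0, 0.0),
        sample_sizes={"A": 8},
        seed=0,
        burn_in=30,
    )
    base.update(kw)
    return dl.ScenarioConfig(**base)


class TestConfigValidation:
    def test_class_mix_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_config(class_mix={"neutral": 0.5})

    def test_deleterious_s_sign(self):
        with pytest.raises(ValueError):
            tiny_config(sel_coeff={"neutral": (0.0, 0.5), "lof": (0.1, 0.2)})
        with pytest.raises(ValueError):
            tiny_config(sel_coeff={"synonymous": (-0.1, 0.5)})

    def test_events_must_postdate_split(self):
        with pytest.raises(ValueError):
            tiny_config(bottleneck=[("A", 50, 20)])

    def test_migration_fraction_bounds(self):
        with pytest.raises(ValueError):
            tiny_config(migration_epoch=(10, 9, 1.5, 0.0))


class TestReproducibility:
    def test_identical_seeds_byte_identical_vcf(self, tmp_path):
        cfg = tiny_config(seed=9)
        a = dl.simulate_scenario(cfg, out_dir=tmp_path / "a")
        b = dl.simulate_scenario(cfg, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "sim.vcf").read_bytes() == (
            tmp_path / "b" / "sim.vcf"
        ).read_bytes()

    def test_truth_covers_every_site(self, two_pop_dataset):
        ds = two_pop_dataset
        key_vcf = list(zip(ds.gm.sites["chrom"], ds.gm.sites["pos"]))
        key_truth = list(zip(ds.truth["chrom"], ds.truth["pos"]))
        assert key_vcf == key_truth
        assert len(set(key_truth)) == len(key_truth)

    def test_effective_length_bounded(self, two_pop_dataset):
        cfg = two_pop_dataset.config
        for v in two_pop_dataset.effective_length.values():
            assert v <= cfg.n_chrom * cfg.chrom_length_bp


class TestDemography:
    def test_drift_increases_fst_with_split_time(self):
        """Deeper splits without migration give larger mean F_ST."""
        means = {}
        for split in (5, 60):
            vals = []
            for seed in range(5):
                cfg = tiny_config(
                    split_gen=split,
                    ne_pops={"A": 50, "B": 50},
                    migration_epoch=(split, split - 1, 0.0, 0.0),
                    sample_sizes={"A": 8, "B": 8},
                    seed=seed,
                )
                ds = dl.simulate_scenario(cfg)
                _, mean, _ = dl.fst_wc(ds.gm)
                vals.append(mean)
            means[split] = np.mean(vals)
        assert means[60] > means[5]

    def test_founder_split_reduces_heterozygosity(self):
        """New founder subpopulations lose diversity relative to the source."""
        diffs = []
        for seed in range(8):
            cfg = tiny_config(
                split_gen=12,
                ne_pops={"A": 60},
                migration_epoch=(12, 11, 0.0, 0.0),
                founder_splits=[("A", 8, 4, "F")],
                sample_sizes={"A": 8, "F": 4},
                seed=seed,
            )
            ds = dl.simulate_scenario(cfg)
            h = dl.heterozygosity(ds.gm, ds.effective_length)
            pops = pd.Series(ds.gm.populations)
            diffs.append(h[pops == "F"].mean() - h[pops == "A"].mean())
        assert np.mean(diffs) < 0

    def test_extinction_reported_with_generation(self):
        cfg = tiny_config(
            class_mix={"lof": 1.0},
            sel_coeff={"lof": (-1.0, 1.0)},  # dominant lethal
            mu=5e-5,
            burn_in=200,
        )
        with pytest.raises(ExtinctionError, match="generation"):
            dl.simulate_scenario(cfg)


class TestSelection:
    def test_deleterious_rarer_than_neutral(self):
        """With s<0, h=0.5 the deleterious class has lower mean frequency."""
        del_f, neu_f = [], []
        for seed in range(20):
            cfg = tiny_config(
                class_mix={"neutral": 0.5, "missense_deleterious": 0.5},
                sel_coeff={
                    "neutral": (0.0, 0.5),
                    "missense_deleterious": (-0.08, 0.5),
                },
                burn_in=60,
                seed=seed,
            )
            ds = dl.simulate_scenario(cfg)
            derived = dl.polarize(ds.gm, ds.truth)
            g = np.where(derived[:, None] == 1, ds.gm.genotypes, 2 - ds.gm.genotypes)
            freq = g.sum(axis=1) / (2 * ds.gm.n_samples)
            cls = ds.truth["class"].to_numpy()
            if (cls == "missense_deleterious").any() and (cls == "neutral").any():
                del_f.append(freq[cls == "missense_deleterious"].mean())
                neu_f.append(freq[cls == "neutral"].mean())
        assert np.mean(del_f) < np.mean(neu_f)


class TestNeutralSfs:
    def test_folded_sfs_matches_coalescent_expectation(self):
        """From-empty neutral runs reproduce E[xi_i] ~ 1/i + 1/(2n-i), folded."""
        n_hap = 16
        sfs_sum = None
        for seed in range(20):
            cfg = dl.ScenarioConfig(
                n_chrom=10, chrom_length_bp=10_000, mu=2e-6, rec_rate=10.0,
                ne_ancestral=50, split_gen=4, ne_pops={"A": 50},
                migration_epoch=(4, 3, 0, 0), sample_sizes={"A": n_hap // 2},
                class_mix={"neutral": 1.0}, sel_coeff={"neutral": (0.0, 0.5)},
                seed=seed, init="empty", burn_in=1200,
            )
            ds = dl.simulate_scenario(cfg)
            sfs, _ = dl.folded_sfs(ds.gm, projection_n=n_hap)
            sfs_sum = sfs if sfs_sum is None else sfs_sum + sfs
        observed = sfs_sum / sfs_sum.sum()
        i = np.arange(1, n_hap)
        xi = 1.0 / i
        folded = np.zeros(n_hap // 2 + 1)
        for j, x in zip(i, xi):
            folded[min(j, n_hap - j)] += x
        expected = folded / folded.sum()
        # linkage inflates per-class Monte-Carlo variance; compare the whole
        # spectrum by total-variation distance
        tv = 0.5 * np.abs(observed[1:] - expected[1:]).sum()
        assert tv < 0.08, (observed, expected)


class TestPedigreePanel:
    def test_shapes_and_relations(self):
        gm, pairs = dl.simulate_pedigree_panel(n_founders=10, n_sites=500, seed=0)
        assert gm.n_sites == 500
        assert len(pairs["parent_offspring"]) == 10
        assert len(pairs["duplicate"]) == 1
        dup_a, dup_b = pairs["duplicate"][0]
        ia, ib = gm.samples.index(dup_a), gm.samples.index(dup_b)
        np.testing.assert_array_equal(gm.genotypes[:, ia], gm.genotypes[:, ib])
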