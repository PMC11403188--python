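"""End-to-end validation experiments: pedigree calibration of kinship, null
calibration of R_A/B, and directional recovery of the two-population
bottleneck signatures on the desk-scale study scenario.

These functions are the package's own reproducibility harness: each builds its
inputs with the simulator, runs the analysis modules, and reports summary
numbers. They are deliberately deterministic given a seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diversity, load, relatedness, roh
from .io import GenotypeMatrix
from .sim import ScenarioConfig, simulate_pedigree_panel, simulate_scenario, study_scenario


# ---------------------------------------------------------------------------
# KING-robust calibration on pedigrees
# ---------------------------------------------------------------------------

def king_calibration(seed: int = 0, n_sites: int = 10_000, n_founders: int = 30) -> dict:
    """Kinship estimates on known relationships + threshold separation.

    Returns mean parent-offspring and unrelated kinship, the duplicate-pair
    estimate, and the number of classification errors made by the 0.177
    first-degree threshold.
    """
    gm, pairs = simulate_pedigree_panel(
        n_founders=n_founders, n_sites=n_sites, seed=seed
    )
    km = relatedness.king_kinship(gm)
    idx = {s: i for i, s in enumerate(km.samples)}

    def phis(rel):
        return np.array([km.phi[idx[a], idx[b]] for a, b in pairs[rel]])

    po = phis("parent_offspring")
    un = phis("unrelated")
    dup = phis("duplicate")
    errors = int((po <= relatedness.FIRST_DEGREE_KINSHIP).sum())
    errors += int((un > relatedness.FIRST_DEGREE_KINSHIP).sum())
    errors += int((dup <= relatedness.FIRST_DEGREE_KINSHIP).sum())
    return {
        "po_mean": float(po.mean()),
        "unrelated_mean": float(un.mean()),
        "duplicate_phi": float(dup[0]),
        "threshold_errors": errors,
        "n_pairs": len(po) + len(un) + len(dup),
    }


# ---------------------------------------------------------------------------
# R_A/B null calibration
# ---------------------------------------------------------------------------

def _null_config(seed: int) -> ScenarioConfig:
    # a well-mixed source population: large enough (and burnt in long
    # enough) that identity disequilibrium among sampled individuals is
    # negligible, so the block jackknife captures the dominant (site-level)
    # variance and its CIs are calibrated
    return ScenarioConfig(
        n_chrom=4,
        chrom_length_bp=500_000,
        mu=1.5e-7,
        rec_rate=16.0,
        ne_ancestral=400,
        split_gen=5,
        ne_pops={"A": 400},
        migration_epoch=(5, 4, 0.0, 0.0),
        sample_sizes={"A": 40},
        seed=seed,
        burn_in=300,
    )


def rab_null_replicate(seed: int, klass: str = "missense_deleterious",
                       zygosity: str = "het") -> tuple:
    """One null draw: split a panmictic sample into two arbitrary halves.

    Returns (r, ci_low, ci_high) for the requested class/zygosity; under the
    null the true R is 1 for every class.
    """
    ds = simulate_scenario(_null_config(seed))
    gm = ds.gm
    half = gm.n_samples // 2
    labels = {
        s: ("X" if i < half else "Y") for i, s in enumerate(gm.samples)
    }
    gm2 = GenotypeMatrix(gm.sites, gm.genotypes, gm.samples, labels)
    rep = load.rab(
        gm2,
        ds.truth["class"].to_numpy(),
        load.polarize(gm2, ds.truth),
        pops=("X", "Y"),
        n_blocks=50,
    )
    row = rep.table.set_index(["class", "zygosity"]).loc[(klass, zygosity)]
    return float(row["r"]), float(row["ci_low"]), float(row["ci_high"])


def rab_null_coverage(n_replicates: int = 100, seed: int = 0) -> dict:
    """95% CI coverage of R = 1 across independent null replicates."""
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(n_replicates) % (2**31)
    hits, used, rs = 0, 0, []
    for s in seeds:
        r, lo, hi = rab_null_replicate(int(s))
        if np.isnan(lo):
            continue
        used += 1
        rs.append(r)
        hits += lo <= 1.0 <= hi
    return {
        "coverage_pct": 100.0 * hits / used if used else np.nan,
        "n_used": used,
        "mean_r": float(np.mean(rs)) if rs else np.nan,
    }


# ---------------------------------------------------------------------------
# study-scenario directional signatures
# ---------------------------------------------------------------------------

def study_directions(seed: int) -> dict:
    """Run one study-scenario seed and measure the bottleneck signatures.

    Compares the mainland population A against the island group (B + the two
    founder subpopulations): per-sample heterozygosity, F_ROH, the fraction
    of ROH longer than 500 kb, mid-range LD (mean r2 at 10-100 kb, equal
    sample sizes: the youngest founder subpopulation vs A), and the
    synonymous-normalized R_island/mainland for homozygous LoF and
    heterozygous deleterious (missense-deleterious + LoF pooled) load.
    """
    cfg = study_scenario(seed=seed)
    ds = simulate_scenario(cfg)
    gm, eff = ds.gm, ds.effective_length
    pops = pd.Series(gm.populations)
    grp = {s: ("mainland" if p == "A" else "island") for s, p in pops.items()}

    h = diversity.heterozygosity(gm, eff)
    h_mainland = h[[s for s in h.index if grp[s] == "mainland"]].mean()
    h_island = h[[s for s in h.index if grp[s] == "island"]].mean()

    segs = roh.call_roh(gm)
    f = roh.froh(segs, eff)
    f_mainland = f[[s for s in f.index if grp[s] == "mainland"]].mean()
    f_island = f[[s for s in f.index if grp[s] == "island"]].mean()
    # the scenario compresses the genetic map by rescale_r, shrinking IBD
    # segments in bp by the same factor; the length-class comparison uses
    # map-equivalent thresholds (100 kb and 500 kb at the nominal map)
    rr = cfg.nominal.get("rescale_r", 1.0)
    segs_cls = roh.call_roh(
        gm, window_snp=25, min_snps=25, min_kb=100.0 / rr
    )
    frac = roh.roh_length_classes(segs_cls, cut_kb=500.0 / rr, populations=grp)
    long_mainland = frac.get("mainland", (0.0, 0, 0))[0]
    long_island = frac.get("island", (0.0, 0, 0))[0]

    a_samples = [s for s in gm.samples if pops[s] == "A"]
    b2_samples = [s for s in gm.samples if pops[s] == "B2"]
    r2 = {}
    for key, names in (("mainland", a_samples), ("island", b2_samples)):
        dec = diversity.ld_decay(
            gm.take_samples(names), max_dist=100_000, bin_width=10_000,
            max_snps_per_chrom=400, seed=0,
        )
        mid = dec[dec["dist_lo"] >= 10_000]
        r2[key] = float(
            (mid["mean_r2"] * mid["n_pairs"]).sum() / max(mid["n_pairs"].sum(), 1)
        )

    derived = load.polarize(gm, ds.truth)
    classes = ds.truth["class"].to_numpy()
    gm2 = GenotypeMatrix(gm.sites, gm.genotypes, gm.samples, grp)
    rep = load.rab(gm2, classes, derived, pops=("island", "mainland"), n_blocks=50)
    tb = rep.table.set_index(["class", "zygosity"])
    pooled = np.where(
        np.isin(classes, ["missense_deleterious", "lof"]), "deleterious", classes
    )
    repp = load.rab(
        gm2, pooled, derived, pops=("island", "mainland"),
        classes=("synonymous", "deleterious"), n_blocks=50,
    )
    tbp = repp.table.set_index(["class", "zygosity"])

    return {
        "h_mainland": float(h_mainland),
        "h_island": float(h_island),
        "froh_mainland": float(f_mainland),
        "froh_island": float(f_island),
        "long_roh_mainland": float(long_mainland),
        "long_roh_island": float(long_island),
        "r2_mainland": r2["mainland"],
        "r2_island": r2["island"],
        "rhom_lof": float(tb.loc[("lof", "hom"), "r_norm"]),
        "rhet_deleterious": float(tbp.loc[("deleterious", "het"), "r_norm"]),
    }


def study_direction_rates(n_seeds: int = 20, seed: int = 0) -> dict:
    """Fraction of seeds recovering each qualitative bottleneck signature."""
    rng = np.random.SeedSequence(seed)
    seeds = rng.generate_state(n_seeds) % (2**31)
    wins = {k: 0 for k in ("h", "froh", "long_roh", "ld", "rhom_lof", "rhet_del")}
    n_rhom = 0
    for s in seeds:
        d = study_directions(int(s))
        wins["h"] += d["h_island"] < d["h_mainland"]
        wins["froh"] += d["froh_island"] > d["froh_mainland"]
        wins["long_roh"] += d["long_roh_island"] > d["long_roh_mainland"]
        wins["ld"] += d["r2_island"] > d["r2_mainland"]
        if not np.isnan(d["rhom_lof"]):
            n_rhom += 1
            wins["rhom_lof"] += d["rhom_lof"] < 1
        wins["rhet_del"] += d["rhet_deleterious"] > 1
    out = {k: v / n_seeds for k, v in wins.items()}
    out["rhom_lof"] = wins["rhom_lof"] / n_rhom if n_rhom else np.nan
    out["n_seeds"] = n_seeds
    out["n_rhom_defined"] = n_rhom
    return out
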