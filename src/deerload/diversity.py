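"""Genetic-diversity statistics: heterozygosity, windowed pi, Weir-Cockerham
F_ST, the folded site-frequency spectrum with hypergeometric projection, and
LD-decay curves.

Conventions follow the common resequencing toolchain: per-sample H is
heterozygous-site count over the alignment-covered ("effective") genome
length; windowed pi uses the full window length as denominator (the vcftools
convention); F_ST is the Weir & Cockerham (1984) per-site theta-hat summarized
as mean +- SD over informative sites with negative values retained; the folded
SFS projects each site's derived count down to a fixed allele number by
hypergeometric sampling without replacement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import MISSING, GenotypeMatrix
from .relatedness import genotype_r2


def heterozygosity(gm: GenotypeMatrix, effective_length: dict) -> pd.Series:
    """Per-sample heterozygosity H = het sites / effective genome length (bp)."""
    missing = [s for s in gm.samples if s not in effective_length]
    if missing:
        raise ValueError(f"no effective genome length for samples: {missing}")
    bad = [s for s in gm.samples if effective_length[s] <= 0]
    if bad:
        raise ValueError(f"effective length must be > 0: {bad}")
    het = (gm.genotypes == 1).sum(axis=0)
    return pd.Series(
        {s: het[i] / effective_length[s] for i, s in enumerate(gm.samples)},
        name="H",
    )


def site_pi(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site nucleotide diversity among non-missing alleles.

    pi_site = (pairwise allelic differences) / C(n_alleles, 2)
            = d (m - d) / C(m, 2)  for derived count d of m called alleles.
    Sites with < 2 called alleles get 0.
    """
    alt, m = gm.allele_counts()
    pairs = m * (m - 1) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, alt * (m - alt) / np.maximum(pairs, 1), 0.0)
    return pi


def windowed_pi(
    gm: GenotypeMatrix,
    window: int = 50_000,
    step: int = 20_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity.

    Windows of ``window`` bp advance by ``step`` bp along each chromosome
    (1-based inclusive coordinates) and never span chromosome boundaries;
    window pi is the sum of per-site pi over the full window length.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    pi = site_pi(gm)
    pos = gm.sites["pos"].to_numpy()
    chroms = gm.sites["chrom"].to_numpy()
    rows = []
    for c in dict.fromkeys(chroms):
        sel = chroms == c
        cpos, cpi = pos[sel], pi[sel]
        length = (chrom_lengths or {}).get(c, int(cpos.max()) if len(cpos) else 0)
        start = 1
        while start <= length:
            end = start + window - 1
            lo, hi = np.searchsorted(cpos, [start, end + 1])
            rows.append((c, start, end, int(hi - lo), cpi[lo:hi].sum() / window))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def fst_wc(gm: GenotypeMatrix, pop_labels: dict | None = None, pops=None):
    """Per-site Weir & Cockerham (1984) theta-hat plus (mean, SD).

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are estimated per site from
    sample sizes, allele frequencies and observed heterozygosity;
    theta-hat = a / (a + b + c). Sites where fewer than two populations have
    two or more genotyped individuals, or where the denominator is zero
    (monomorphic), are NaN and excluded from the summary. Negative per-site
    values are retained in the mean.

    Returns ``(theta_site, mean, sd)``.
    """
    labels = pop_labels or gm.populations
    if pops is None:
        pops = sorted({labels[s] for s in gm.samples if labels.get(s)})
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    cols = {p: [i for i, s in enumerate(gm.samples) if labels.get(s) == p] for p in pops}
    g = gm.genotypes
    n_i, p_i, h_i = [], [], []
    for p in pops:
        sub = g[:, cols[p]]
        called = sub != MISSING
        n = called.sum(axis=1).astype(float)  # genotyped individuals
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
            hobs = np.where(n > 0, (sub == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
        n_i.append(n)
        p_i.append(freq)
        h_i.append(hobs)
    n_i = np.stack(n_i)  # (r, sites)
    p_i = np.nan_to_num(np.stack(p_i))
    h_i = np.nan_to_num(np.stack(h_i))
    ok = (n_i >= 2).sum(axis=0) >= 2
    use = n_i >= 2
    n_i = np.where(use, n_i, 0.0)
    r = use.sum(axis=0).astype(float)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = np.where(use, n_i * p_i, 0.0).sum(axis=0) / nsum
        s2 = np.where(use, n_i * (p_i - pbar) ** 2, 0.0).sum(axis=0) / ((r - 1) * nbar)
        hbar = np.where(use, n_i * h_i, 0.0).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(ok & (denom != 0), a / denom, np.nan)
    vals = theta[~np.isnan(theta)]
    mean = float(vals.mean()) if len(vals) else np.nan
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
    return theta, mean, sd


def fst_hudson(gm: GenotypeMatrix, pop_labels: dict | None = None, pops=None):
    """Hudson-style per-site F_ST (1 - Hw/Hb) for two populations."""
    labels = pop_labels or gm.populations
    if pops is None:
        pops = sorted({labels[s] for s in gm.samples if labels.get(s)})
    if len(pops) != 2:
        raise ValueError("Hudson F_ST is defined for exactly two populations")
    g = gm.genotypes
    stats = []
    for p in pops:
        cols = [i for i, s in enumerate(gm.samples) if labels.get(s) == p]
        sub = g[:, cols]
        called = sub != MISSING
        m = 2 * called.sum(axis=1).astype(float)
        alt = np.where(called, sub, 0).sum(axis=1)
        stats.append((m, alt))
    (m1, d1), (m2, d2) = stats
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = d1 / m1, d2 / m2
        hw = (p1 * (1 - p1) * m1 / (m1 - 1) + p2 * (1 - p2) * m2 / (m2 - 1)) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        ok = (m1 >= 4) & (m2 >= 4) & (hb > 0)
        theta = np.where(ok, 1 - hw / hb, np.nan)
    vals = theta[~np.isnan(theta)]
    return theta, (float(vals.mean()) if len(vals) else np.nan)


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

def folded_sfs(
    gm: GenotypeMatrix,
    pop: str | None = None,
    projection_n: int | None = None,
):
    """Folded site-frequency spectrum with hypergeometric projection.

    Each segregating site's observed derived (= alt) count d of m called
    alleles is projected down to ``projection_n`` alleles: class j receives
    the hypergeometric probability of drawing j derived alleles in
    ``projection_n`` draws without replacement, then classes j and
    ``projection_n - j`` are folded together. Sites with fewer called
    alleles than the projection are skipped and counted.

    Returns ``(sfs, n_skipped)`` where ``sfs`` has length
    ``projection_n // 2 + 1`` and sums to the number of sites used.
    """
    if pop is not None:
        idx = gm.sample_indices(pop)
        if len(idx) == 0:
            raise ValueError(f"no samples in population {pop!r}")
        g = gm.genotypes[:, idx]
    else:
        g = gm.genotypes
    n_alleles = 2 * g.shape[1]
    if projection_n is None:
        projection_n = n_alleles
    if projection_n < 2 or projection_n % 2:
        raise ValueError("projection_n must be an even number >= 2")
    if projection_n > n_alleles:
        raise ValueError("projection_n exceeds available alleles")
    called = g != MISSING
    m = 2 * called.sum(axis=1)
    d = np.where(called, g, 0).sum(axis=1)
    seg = (d > 0) & (d < m)
    usable = seg & (m >= projection_n)
    n_skipped = int((seg & ~usable).sum())
    half = projection_n // 2
    sfs = np.zeros(half + 1)
    j = np.arange(projection_n + 1)
    ks = np.arange(half + 1)
    for mi, di in zip(m[usable], d[usable]):
        w = hypergeom.pmf(j, mi, di, projection_n)
        folded = w[ks] + np.where(projection_n - ks != ks, w[projection_n - ks], 0.0)
        sfs += folded
    return sfs, n_skipped


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 200_000,
    bin_width: int = 10_000,
    max_snps_per_chrom: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean genotype r2 in physical-distance bins.

    All within-chromosome site pairs at distance <= ``max_dist`` contribute;
    ``max_snps_per_chrom`` optionally thins sites (deterministically per
    ``seed``) to bound the pair count. Returns a frame with bin edges, mean
    r2 and pair counts.
    """
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    rng = np.random.default_rng(seed)
    chroms = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    g_all = gm.genotypes
    for c in dict.fromkeys(chroms):
        sel = np.nonzero(chroms == c)[0]
        if max_snps_per_chrom is not None and len(sel) > max_snps_per_chrom:
            sel = np.sort(rng.choice(sel, size=max_snps_per_chrom, replace=False))
        pos = pos_all[sel]
        g = g_all[sel]
        complete = not (g == MISSING).any()
        gf = g.astype(float)
        if complete:
            mu = gf.mean(axis=1, keepdims=True)
            sd = gf.std(axis=1)
            z = gf - mu
        for i in range(len(sel)):
            hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            if hi <= i + 1:
                continue
            dist = pos[i + 1 : hi] - pos[i]
            if complete:
                if sd[i] == 0:
                    continue
                denom = sd[i] * sd[i + 1 : hi]
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = (z[i + 1 : hi] @ z[i]) / (g.shape[1] * denom)
                r2 = r * r
                ok = denom > 0
            else:
                r2 = np.array([genotype_r2(g[i], g[j]) for j in range(i + 1, hi)])
                ok = ~np.isnan(r2)
            b = np.minimum((dist - 1) // bin_width, n_bins - 1)
            np.add.at(sums, b[ok], r2[ok])
            np.add.at(counts, b[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins) * bin_width
    return pd.DataFrame(
        {
            "dist_lo": edges + 1,
            "dist_hi": edges + bin_width,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def ld_decay_distance(decay: pd.DataFrame, level: float = 0.1) -> float:
    """First bin midpoint where mean r2 drops below ``level`` (NaN if never)."""
    mid = (decay["dist_lo"] + decay["dist_hi"]) / 2
    below = decay["mean_r2"] < level
    for m, b, n in zip(mid, below, decay["n_pairs"]):
        if n > 0 and b:
            return float(m)
    return float("nan")
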