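"""Pairwise relatedness, relative removal, LD pruning and genotype PCA.

Kinship uses the KING-robust within-pair estimator (Manichaikul et al. 2010):

    phi_hat(i,j) = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))

computed over sites genotyped in both samples. It is robust to population
allele-frequency misspecification and yields ~0.5 for duplicates, ~0.25 for
first-degree relatives, ~0 for unrelated pairs; >0.177 is the conventional
first-degree cutoff. LD pruning and PCA mirror PLINK conventions (sliding
window genotype-r2 pruning; Patterson-scaled eigendecomposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

FIRST_DEGREE_KINSHIP = 0.177


@dataclass
class KinshipMatrix:
    samples: list
    phi: np.ndarray  # (n, n) symmetric; NaN where no overlapping sites

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.samples)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.samples[i], self.samples[j], self.phi[i, j]))
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi"])

    def pairs_above(self, threshold: float):
        df = self.to_frame()
        return df[df["phi"] > threshold]


def king_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust pairwise kinship from a genotype matrix.

    Missing genotypes are excluded pairwise. Pairs with no overlapping
    informative sites (zero heterozygotes in both) get NaN rather than a
    silent zero.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = gm.genotypes
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    valid = (g != MISSING).astype(np.float64)
    n_hethet = het.T @ het
    n_opp = hom0.T @ hom2 + hom2.T @ hom0
    het_i = het.T @ valid  # het in i over sites called in both i and j
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(samples=list(gm.samples), phi=phi)


def drop_related(
    km: KinshipMatrix,
    threshold: float = FIRST_DEGREE_KINSHIP,
    call_rate: dict | None = None,
):
    """Greedy removal of close relatives.

    While any pair exceeds ``threshold``, remove the sample involved in the
    most over-threshold pairs; ties broken by lower call rate, then by
    lexicographically larger sample id. Returns ``(retained_ids, removed_log)``
    where the log lists ``(sample, n_conflicts)`` in removal order.
    """
    names = list(km.samples)
    phi = np.nan_to_num(km.phi, nan=0.0).copy()
    np.fill_diagonal(phi, 0.0)
    active = set(range(len(names)))
    removed = []
    while True:
        over = {
            i: sum(1 for j in active if j != i and phi[i, j] > threshold)
            for i in active
        }
        worst = max(over.values(), default=0)
        if worst == 0:
            break
        cands = [i for i, c in over.items() if c == worst]
        if call_rate and len(cands) > 1:
            lo = min(call_rate.get(names[i], 1.0) for i in cands)
            cands = [i for i in cands if call_rate.get(names[i], 1.0) == lo]
        pick = max(cands, key=lambda i: names[i])
        active.discard(pick)
        removed.append((names[pick], worst))
    retained = [names[i] for i in sorted(active)]
    return retained, removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype vectors.

    Missing entries are deleted pairwise (the composite genotype-correlation
    convention). Returns NaN when either vector is constant on the
    overlapping calls.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.2,
    window_snps: int = 50,
    step_snps: int = 5,
) -> GenotypeMatrix:
    """Sliding-window LD pruning.

    Within each window of ``window_snps`` sites (advanced by ``step_snps``),
    any retained pair with genotype r2 > ``r2_max`` loses the site with the
    lower minor-allele frequency (ties: the later position is removed).
    Windows are re-scanned until no retained within-window pair exceeds the
    threshold, so the output is a fixpoint (idempotent).
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    g = gm.genotypes
    maf = gm.maf()
    keep = np.ones(gm.n_sites, dtype=bool)
    chroms = gm.sites["chrom"].to_numpy()
    starts = {}
    for i, c in enumerate(chroms):
        starts.setdefault(c, [i, i])
        starts[c][1] = i + 1
    changed = True
    while changed:
        changed = False
        for lo, hi in starts.values():
            for w0 in range(lo, hi, step_snps):
                idx = [i for i in range(w0, min(w0 + window_snps, hi)) if keep[i]]
                if len(idx) < 2:
                    continue
                block = g[idx]
                r2mat = None
                if not (block == MISSING).any():  # fast path: complete data
                    with np.errstate(invalid="ignore", divide="ignore"):
                        r2mat = np.corrcoef(block.astype(float)) ** 2
                for a in range(len(idx)):
                    if not keep[idx[a]]:
                        continue
                    for b in range(a + 1, len(idx)):
                        i, j = idx[a], idx[b]
                        if not (keep[i] and keep[j]):
                            continue
                        r2 = r2mat[a, b] if r2mat is not None else genotype_r2(g[i], g[j])
                        if np.isnan(r2) or r2 <= r2_max:
                            continue
                        mi = -1.0 if np.isnan(maf[i]) else maf[i]
                        mj = -1.0 if np.isnan(maf[j]) else maf[j]
                        drop = j if (mj < mi or (mj == mi)) else i
                        keep[drop] = False
                        changed = True
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, n_components: int = 10):
    """Genotype principal components with Patterson scaling.

    Each site is centered by twice its allele frequency and scaled by
    ``sqrt(2 p (1-p))``; missing genotypes contribute zero after centering.
    Returns ``(coords, explained)``: an ``(n_samples, k)`` coordinate array
    (columns ordered by decreasing eigenvalue, sign fixed so the
    largest-magnitude loading is positive) and the explained-variance
    fractions of the k components.
    """
    g = gm.genotypes.astype(float)
    called = gm.genotypes != MISSING
    alt, tot = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    g = g[poly]
    called = called[poly]
    p = p[poly]
    x = np.where(called, g - 2 * p[:, None], 0.0) / np.sqrt(2 * p * (1 - p))[:, None]
    cov = x.T @ x / x.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    k = min(n_components, gm.n_samples)
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] *= -1
    explained = vals[:k] / vals.sum() if vals.sum() > 0 else np.zeros(k)
    return coords, explained
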