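"""Kinship, relative removal, LD pruning and PCA on a simulated panel.

KING-robust kinship is ~0.5 for duplicates, ~0.25 for parent-offspring and ~0
for unrelated pairs; >0.177 flags first-degree relationships. After dropping
relatives and pruning linked sites, PCA separates the two populations.
"""

import numpy as np

import deerload as dl

# pedigree panel: known relationships at 10k unlinked sites
gm, pairs = dl.simulate_pedigree_panel(n_founders=20, n_sites=10_000, seed=3)
km = dl.king_kinship(gm)
idx = {s: i for i, s in enumerate(km.samples)}
for rel in ("duplicate", "parent_offspring", "unrelated"):
    phis = [km.phi[idx[a], idx[b]] for a, b in pairs[rel]]
    print(f"mean kinship, {rel}: {np.mean(phis):.3f}  (n={len(phis)})")

retained, removed = dl.drop_related(km, threshold=0.177)
print(f"removed {len(removed)} of {len(km.samples)} samples as close relatives")

# structure: two diverged populations
ds = dl.simulate_scenario(dl.study_scenario(seed=3))
pruned = dl.ld_prune(ds.gm, r2_max=0.2)
print(f"LD pruning: {ds.gm.n_sites} -> {pruned.n_sites} SNPs (r2 > 0.2 removed)")
coords, explained = dl.pca(pruned, n_components=4)
print(f"PC1 explains {explained[0]:.1%} of genotype variance")
for pop in ("A", "B", "B1", "B2"):
    sel = [i for i, s in enumerate(pruned.samples) if pruned.populations[s] == pop]
    print(f"  {pop}: PC1 mean {coords[sel, 0].mean():+.2f}")
# Mainland (A) and the island group (B/B1/B2) take opposite signs on PC1:
# the leading axis of genotype covariance is the between-population split.
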