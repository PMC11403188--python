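"""Consequence annotation, Grantham classes and the R_A/B load statistic.

Annotates SNPs on a toy genome (codon-level consequences, Grantham distance
for missense), then computes the relative per-individual derived-allele load
of the island group versus the mainland with block-jackknife confidence
intervals.
"""

import numpy as np
import pandas as pd

import deerload as dl

# --- consequence annotation on a toy genome -------------------------------
genome = dl.generate_toy_genome(n_genes=4, cds_len=120, seed=2, n_exons=3)
chrom = genome.transcripts[0].chrom
seq = genome.sequences[chrom]
rng = np.random.default_rng(0)
rows = []
for pos in sorted(rng.choice(len(seq), 60, replace=False) + 1):
    ref = seq[pos - 1]
    rows.append((chrom, int(pos), ref, rng.choice([b for b in "ACGT" if b != ref])))
sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
anns = dl.annotate_consequences(sites, genome.sequences, genome.transcripts)
counts = pd.Series([a.consequence for a in anns]).value_counts()
print("consequences of 60 random SNPs on the toy genome:")
print(counts.to_string())
print(f"example Grantham distances: L->I = {dl.grantham('L','I')}, "
      f"W->C = {dl.grantham('W','C')} (class boundary at 150)")

# --- R_island/mainland load ------------------------------------------------
ds = dl.simulate_scenario(dl.study_scenario(seed=7))
gm = ds.gm
grp = {s: ("island" if p != "A" else "mainland") for s, p in gm.populations.items()}
gm2 = dl.GenotypeMatrix(gm.sites, gm.genotypes, gm.samples, grp)
derived = dl.polarize(gm2, ds.truth)  # truth ancestral states from the simulator
rep = dl.rab(gm2, ds.truth["class"].to_numpy(), derived,
             pops=("island", "mainland"), n_blocks=50)
cols = ["class", "zygosity", "mean_A", "mean_B", "r", "r_norm", "ci_low", "ci_high", "p"]
print("\nR_island/mainland per class and zygosity:")
print(rep.table[cols].round(3).to_string(index=False))
# r is the raw ratio of mean per-individual derived-allele counts
# (island / mainland); r_norm divides by the synonymous-class ratio, so
# values above 1 mean an excess relative to the neutral baseline. CIs come
# from a 50-block weighted jackknife on log r.
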