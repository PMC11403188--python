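# deerload

Conservation-genomics assessment of small, fragmented populations from
multi-sample VCFs — built around the situation of the Hainan Eld's deer
(*Rucervus eldii hainanus*): an island population that crashed to a few dozen
individuals, was split by translocations into founder herds, and now carries
the genomic signatures of that history. The package measures those signatures
and ships a forward simulator that reproduces the whole scenario at desk
scale, so every statistic can be validated against known truth.

## What it computes

* **Variant ingestion and filtering** — biallelic autosomal SNPs from VCF
  (`read_vcf`), with the standard resequencing filters: per-call depth
  masking, per-site missingness ≤ 10%, QUAL ≥ 20, hard INFO thresholds
  (FS/MQ/QD/…), an exact Hardy–Weinberg test (p ≥ 0.05) and MAF ≥ 0.05
  (`filter_sites`, `hwe_exact_pvalue`).
* **Relatedness and structure** — KING-robust pairwise kinship
  φ̂ = (N_Aa,Aa − 2N_AA,aa)/(N_Aa^(i) + N_Aa^(j)), greedy removal of pairs
  with φ̂ > 0.177, sliding-window LD pruning (r² > 0.2) and Patterson-scaled
  genotype PCA (`king_kinship`, `drop_related`, `ld_prune`, `pca`).
* **Diversity** — per-sample heterozygosity H = het sites / effective genome
  length; windowed π (50-kb windows, 20-kb steps); per-site Weir–Cockerham
  (1984) F_ST summarized as mean ± SD; folded SFS with hypergeometric
  projection; distance-binned LD decay (`heterozygosity`, `windowed_pi`,
  `fst_wc`, `folded_sfs`, `ld_decay`).
* **Inbreeding** — PLINK-style scanning-window ROH calling
  (`--homozyg`-equivalent parameters: 50-SNP windows, ≥ 50 SNPs and ≥ 100 kb
  per run), F_ROH = ΣROH / effective genome length, and >500-kb length-class
  fractions (`call_roh`, `froh`, `roh_length_classes`).
* **Mutation load** — codon-level consequence annotation against gene models
  (FASTA + GFF3), Grantham-distance classification of missense variants
  (> 150 deleterious, < 150 benign), LoF terms (splice donor/acceptor,
  start-lost, stop-lost, stop-gained, stop-retained), derived-allele
  polarization, and the R_A/B statistic — the ratio of mean per-individual
  derived-allele counts of a class, by zygosity, between two populations —
  with weighted block-jackknife CIs on log R (`annotate_consequences`,
  `grantham`, `classify`, `polarize`, `rab`).
* **Forward simulation** — a Wright–Fisher simulator with infinite-sites
  mutation, crossover recombination, class-specific selection, migration
  epochs, bottlenecks and founder splits (`simulate_scenario`,
  `study_scenario`, `generate_toy_genome`, `simulate_pedigree_panel`).

## Worked example

```python
import pandas as pd
import deerload as dl

ds = dl.simulate_scenario(dl.study_scenario(seed=7))
gm, eff = ds.gm, ds.effective_length
pops = pd.Series(gm.populations)

h = dl.heterozygosity(gm, eff)
print(h.groupby(pops).mean())          # island groups lower than mainland A

segs = dl.call_roh(gm)
print(dl.froh(segs, eff).groupby(pops[:len(eff)]).mean())  # island higher

_, fst, sd = dl.fst_wc(gm, pop_labels={s: ("A" if p == "A" else "I")
                                       for s, p in pops.items()}, pops=["A", "I"])
print(f"F_ST = {fst:.2f} +- {sd:.2f}")
```

With seed 7 this prints mainland (A) heterozygosity 8.5 × 10⁻⁵ per bp against
island-group means of 6.8–8.2 × 10⁻⁵ (the founder herds lowest), mainland
F_ROH 0.25 against island 0.32–0.48, and F_ST 0.11 ± 0.20 — the qualitative
pattern of a recently crashed, translocation-fragmented island population
against a larger mainland one, at desk-scale effect sizes.
The `examples/` scripts walk through each capability (filtering, kinship and
PCA, diversity and ROH, mutation load) and print commentary with the numbers.

There is also a thin CLI mirroring the library:

```bash
deerload simulate --seed 1 --out simdir
deerload filter --vcf simdir/sim.vcf --out filtered.vcf --report report.json
deerload roh --vcf simdir/sim.vcf --samples simdir/samples.tsv --out-prefix roh
```

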