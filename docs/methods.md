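# Methods

This note documents the models and estimators the package implements, the
design of the synthetic-data generator, the numerical conventions, and the
limits of what the desk-scale validation can show.

## The analysis pipeline

**Genotype model.** All statistics operate on a `GenotypeMatrix`: biallelic
SNPs × samples with alt-allele dosages 0/1/2 and explicit missingness.
Multiallelic records and indels are excluded at ingestion and counted; sites
on named sex chromosomes are dropped so downstream statistics are autosomal.

**Site filtering.** Filters are applied in a fixed order — per-call depth
masking (DP < 3 → missing), per-site missingness > 10%, QUAL < 20, hard INFO
thresholds (FS > 60, MQ < 40, QD < 2, MQRankSum < −12.5, |ReadPosRankSum| > 8;
applied only when the key is present, since simulator VCFs carry no caller
annotations), exact Hardy–Weinberg p < 0.05, MAF < 0.05 — and each removed
site is attributed to the first rule it fails, so reports reconcile exactly.
The order is a package convention; the filters themselves are the standard
resequencing set. Missingness is per-site; per-sample missingness is not
filtered. The HWE test conditions on the minor-allele count and sums the
probabilities of all heterozygote counts no more probable than the observed
one (the PLINK/vcftools construction, no mid-p correction), computed in log
space with exact normalization.

**Kinship.** The KING-robust within-pair estimator
φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa^(i) + N_Aa^(j)) over sites called in both
samples. It needs no allele-frequency estimates, so it is robust to structure;
pairs with no informative overlap are NaN rather than zero. Relative removal
is greedy: repeatedly remove the sample with the most over-threshold
(φ̂ > 0.177) partners, ties broken by lower call rate then lexicographically
larger ID — deterministic and close to a minimal vertex cover on the
conflict graph.

**Diversity.** Per-sample H divides heterozygous-site counts by the
per-sample effective (alignment-covered) genome length, the same denominator
used for F_ROH. Windowed π uses the full window length as denominator (the
vcftools convention; callable-length normalization would need per-window
coverage masks, which VCF-only input does not carry). Weir–Cockerham F_ST is
the 1984 per-site variance-component estimator a/(a+b+c) for any number of
populations; sites where fewer than two populations have ≥ 2 genotyped
individuals are skipped, negative per-site values are retained, and the
summary is mean ± SD across informative sites (a windowed mean and a Hudson
estimator are available for sensitivity checks). The folded SFS projects each
site hypergeometrically to a fixed allele count, skipping (and counting)
sites with fewer called alleles — the easySFS-style treatment of missingness.

**ROH.** The caller reproduces PLINK 1.9's scanning-window algorithm with the
printed parameter set (50-SNP windows, ≤ 1 heterozygote and ≤ 3 missing per
window, per-SNP hit fraction ≥ 0.05, runs of ≥ 50 SNPs and ≥ 100 kb, density
≤ 1000 kb/SNP, gap split at 1 Mb); length-equal-to-threshold runs pass
(≥, the PLINK convention). A property test holds it equal to an independent
literal transcription of these rules on hundreds of random instances.

**Mutation load.** Consequences are assigned by translating the codon
containing each CDS SNP for both alleles (strand-aware, standard code):
synonymous, missense, stop-gained/lost/retained, start-lost; SNPs in the
first/last two intron bases are splice donor/acceptor. The LoF class is
{splice donor, splice acceptor, start-lost, stop-lost, stop-gained,
stop-retained} — stop-retained is conventionally synonymous-like but is kept
in LoF here to match the classification this pipeline validates; a flag
reassigns it. Missense variants split at Grantham distance 150 (> 150
deleterious, < 150 benign; exactly 150 is assigned benign and flagged — the
definition leaves the boundary open). `grantham()` is the published 1974
matrix embedded as data; `grantham_from_properties()` recomputes it from the
composition/polarity/volume formula with the mean-100 normalization and
agrees within ±1 everywhere (the published table's own rounding).

R_A/B: for class C and zygosity z, each individual contributes the number of
class-C sites (known derived allele, genotype called) where it carries z
derived copies; R = mean_A / mean_B. Because a bottleneck depresses (het) or
inflates (hom) *every* class's counts, the comparable quantity is the
synonymous-normalized R′ = R(C, z) / R(synonymous, z), reported alongside raw
R. Uncertainty: delete-one weighted block jackknife over 50 contiguous
equal-SNP blocks, variance on log R (block-size-weighted pseudovalues), 95%
CI as R·exp(±1.96·SE), two-sided Z-test of log R = 0. Fewer than three
informative blocks, or a zero denominator, is flagged rather than silently
estimated. Polarization is a policy: simulator truth tables, the INFO AA tag,
or reference-equals-ancestral (the default for real data without an outgroup,
with the caveat that it mispolarizes exactly the sites where the reference
carries the derived allele).

## The simulator

Discrete-generation diploid Wright–Fisher with: infinite-sites mutation on an
integer coordinate grid (collisions redrawn); crossovers at a per-bp rate
converted from cM/Mb with independent assortment between chromosomes;
multiplicative fitness 1, 1+hs, (1+s) per site; migration as a per-generation
replacement fraction during a configurable epoch; bottlenecks as step changes
in N; founder splits sampling individuals without replacement. Fitness enters
twice: parents are sampled proportionally to fitness, and the final sampled
"study individuals" are drawn fitness-weighted too — samples represent living
adults, so strongly deleterious homozygotes are under-represented exactly as
in field data. Fixed or lost sites are pruned continuously; fixed-derived
sites leave the VCF (they are invisible to SNP calling). Runs are
bit-reproducible per seed.

Two initializations: `"empty"` (monomorphic, mutation-drift burn-in; used
where an equilibrium independent of the initial state must be demonstrated,
e.g. the neutral-SFS check, with a burn-in of ≥ 10–20·N generations) and
`"sfs"` (standing variation drawn from the neutral stationary frequency
spectrum at linkage equilibrium, then a burn-in of ~N generations to build
linkage structure; used by the heavier scenarios). The SFS start is exact for
neutral allele frequencies and approximate for LD and for selected classes —
the burn-in plus the pre-split epoch lets selected-class frequencies relax
toward their balance.

### Desk-scale rescaling

Real parameters (Ne ~ 10⁴, 18,192 generations, μ = 2.11 × 10⁻⁹, 1.04 cM/Mb)
are divided/multiplied by a factor λ = 256: sizes and epoch lengths ÷ λ,
per-generation rates (μ, s, m) × λ, preserving 4Neμ, Ne·s and 4Ne·m.
Recombination uses its own factor λ_r = 8 rather than λ: compressing the map
by the full λ would shrink every IBD segment ~256-fold in physical length,
destroying the 100-kb/500-kb thresholds the ROH analysis applies, while
λ_r = 8 keeps per-generation linkage breakup fast enough that the genome
behaves as many quasi-independent blocks (full map preservation, λ_r = 1–4,
was found to push the simulation into a pathological strong-linkage regime:
associative overdominance props up heterozygosity in the bottlenecked
population and r² saturates genome-wide). Where the compressed map meets a
physical-length threshold, map-equivalent values are used (e.g. the long-ROH
class cut 500 kb/λ_r, see below). Events inside the recent small-census epoch
(the 1976-equivalent crash to 26, recovery, translocations of 19 and 22) keep
their literal generation times and census sizes: those numbers are already
desk-scale, and the drift they cause is simulated directly rather than
rescaled. Scaled migration fractions m·λ would exceed 1 and are capped at
0.45 per generation — nominal 4Nm ≫ 1 means the early-contact epoch is
effectively panmictic either way.

### The study scenario (generator defaults)

One ancestral population (scaled N = 156, nominal 40,000) splits 71 scaled
generations ago (18,192 nominal; 27,288 years at 1.5 yr/generation) into
mainland A (N = 156, nominal 40,000) and island B (N = 58, nominal 15,000);
bidirectional migration (nominal 0.0129 A→B, 0.0200 B→A) through the first
quarter after divergence; B crashes to 26 at generation 33 (≈ 1976), recovers
to 90, and seeds founder groups of 19 (generation 27) and 22 (generation
20) that grow to 60. Sampling matches the study design: 8 mainland, 6 + 6 + 8
island. Genome: 8 × 1.5 Mb at μ·λ = 5.4 × 10⁻⁷ (≈ 10,000–15,000 sample SNPs —
about a tenth of the real panel, the main sacrifice of desk scale). The
ancestral/daughter Ne values are not published quantities; they were chosen
so that scaled drift since the split produces differentiation and diversity
loss of the reported order, with the recent sizes anchored to the study's own
recent-Ne inferences (island recent Ne ≈ 70).

Mutation classes: 70% non-coding neutral, 12% synonymous, 8% benign missense
(all s = 0), 6% deleterious missense (scaled s = −0.05, h = 0.5; nominal
s ≈ −2 × 10⁻⁴) and 4% LoF (strongly deleterious, nearly recessive). For LoF
dominance, h = 0.1 with scaled s = −0.8 keeps the heterozygous exposure
(h·s = −0.08) identical to a (−0.4, 0.2) parameterization while doubling
homozygote selection — severe LoF alleles in mammals are close to recessive
(h ≈ 0.02–0.2), and purging operates through the homozygous term.

### What the generator does and does not emulate

It produces the statistical structure the pipeline assumes — drift,
inbreeding, linkage, class-specific purifying selection, founder effects,
truth annotations for polarization — but not: sequencing error, depth
variation or genotype-caller artifacts (per-sample depth fields are absent;
depth masking is exercised on hand-built fixtures); real gene structures at
genome scale (the toy-genome module provides small FASTA+GFF3 models for the
annotator, decoupled from the simulator's class labels); variable
recombination or mutation landscapes; overlapping generations or non-random
mating beyond small-N drift. Passing the directional checks therefore shows
the estimators respond correctly to the population-genetic signal, not that
they are robust to sequencing artifacts.

## Validation experiments

* **Oracle equivalence** (exact): ROH caller vs a literal loop transcription
  on ≥ 200 random sample-chromosome instances; F_ST vs the WC-1984
  components on all two-population tables with ≤ 6 samples a side; HWE vs
  rational-arithmetic enumeration for every table with n ≤ 20; Grantham vs
  the committed table (190/190).
* **Kinship calibration**: simulated pedigrees at 10k unlinked sites; mean
  parent-offspring φ̂ within 0.02 of 0.25, unrelated within 0.02 of 0,
  duplicates exactly 0.5, and the 0.177 threshold classifies first-degree vs
  unrelated pairs without error.
* **R_A/B null calibration**: 100 panmictic replicates split into arbitrary
  halves (20 vs 20); the 95% jackknife CI covers R = 1 in 95 ± 5% of
  replicates. The null population is deliberately large and long burnt-in
  (N = 400, 300 generations): in small or freshly-initialized populations,
  identity disequilibrium gives sampled individuals genuinely different
  genome-wide load counts, and the resulting group-composition offset is
  uniform across genomic blocks — invisible to a block jackknife, which
  then under-covers. The calibration is therefore run in the regime the
  estimator is designed for (site-level noise dominant), which is also the
  regime of real between-population comparisons where individuals are not
  an arbitrary split of one panmictic pool.
* **Directional recovery**: 20 study-scenario seeds; the island group is
  checked for lower H, higher F_ROH, a larger long-ROH fraction
  (map-equivalent 500-kb cut = 500/λ_r kb, with the run-length filters scaled
  the same way), slower LD decay (mean r² at 10–100 kb, comparing the
  youngest founder subpopulation with the mainland at equal n = 8 — r² is
  biased by 1/n, so equal sample sizes are required), and for
  synonymous-normalized R′_island/mainland: homozygous LoF < 1 (purging) and
  heterozygous deleterious (missense-deleterious + LoF pooled) > 1
  (relaxed-selection excess). Diversity/ROH/LD directions are expected in
  ≥ 90% of seeds; the load directions, which are intrinsically
  heavier-tailed at ~10⁴ SNPs, in a majority.

Problem sizes throughout (panel sizes, replicate counts, genome lengths) are
chosen as the smallest that give the statistics stable Monte-Carlo behavior.

## Numerical conventions and degenerate inputs

Missing genotypes are excluded pairwise (kinship, r², F_ST, π, SFS); sites
left with no information are flagged or skipped, never imputed as zero.
All-missing-after-masking sites fall under the missingness filter. PCA
centers by 2p̂ and scales by sqrt(2p̂(1−p̂)) with missing→0 after centering;
component signs are fixed by making the largest-magnitude coordinate
positive. LD pruning removes the lower-MAF site of an offending pair (tie:
later position) and iterates windows to a fixpoint, so pruning is idempotent.
Empty segment lists yield absent (not zero) length-class fractions. R_A/B
with a zero denominator or < 3 informative jackknife blocks reports a flag
instead of a number.

## Known limitations

Forward simulation at λ = 256 compresses 18k generations into ~70; slow
processes (mutation-selection balance re-equilibration after events,
long-term purging) act over proportionally fewer generations than in the real
history, which limits how strongly selection-mediated signatures can emerge —
the homozygous-LoF purging deficit is the weakest of the directional signals
for exactly this reason. The annotator handles single-transcript,
fully-coding gene models (no UTRs, no alternative transcripts). The LD
pruner is O(window²) per window and meant for panels of ~10⁴–10⁵ SNPs, not
whole-genome arrays. VCF ingestion is eager (dense in-memory matrix), sized
for the ~10⁵-SNP panels this analysis targets.
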