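"""Simulate a two-population bottleneck scenario and apply SNP quality filters.

Generates a small island/mainland history (split, early gene flow, crash to 26
individuals, two translocated founder groups), writes a VCF, re-reads it, and
runs the standard site filters (missingness, QUAL, INFO, exact HWE, MAF).
"""

import tempfile
from pathlib import Path

import deerload as dl

out = Path(tempfile.mkdtemp(prefix="deerload_"))
cfg = dl.study_scenario(seed=1)
ds = dl.simulate_scenario(cfg, out_dir=out)
print(f"simulated {ds.gm.n_sites} SNPs for {ds.gm.n_samples} samples -> {ds.vcf_path}")
print(f"nominal history: split {cfg.nominal['split_gen']} generations "
      f"({cfg.nominal['split_years']} yr), rescale x{cfg.nominal['rescale']}")

gm, exclusions = dl.read_vcf(ds.vcf_path)
print(f"re-read VCF: {gm.n_sites} biallelic SNPs, exclusions {exclusions}")

filtered, report = dl.filter_sites(gm, min_maf=0.05)
print(f"filtering: {report.input_sites} -> {report.output_sites} sites")
for rule, n in report.removed.items():
    print(f"  removed by {rule}: {n}")
# The MAF rule dominates here: a 20-sample panel cannot show frequencies
# below 0.05 except as singletons/doubletons, which a real study would also
# lose. The HWE rule removes sites whose genotype proportions deviate from
# random mating, e.g. strong population mixture.
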