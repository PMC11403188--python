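"""VCF ingestion, the genotype data model, and site-level quality filtering.

The central container is :class:`GenotypeMatrix`: biallelic autosomal SNPs as a
``sites x samples`` matrix of alt-allele dosages (0/1/2, -1 for missing) with
per-site metadata. Filtering follows the standard resequencing recipe: per-call
depth masking, per-site missingness, QUAL, hard INFO thresholds, an exact
Hardy-Weinberg test and a minor-allele-frequency floor, with every removed site
attributed to the first rule it fails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = -1

#: default hard INFO-field thresholds (key -> (op, value)); applied only when
#: the key is present in a record's INFO.
DEFAULT_INFO_THRESHOLDS = {
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "QD": ("<", 2.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum_hi": (">", 8.0),
    "ReadPosRankSum": ("<", -8.0),
}


class VcfFormatError(ValueError):
    """Raised for structurally unusable VCF input (no GT, unsorted sites)."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a sample panel.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, qual`` and
        ``info`` (a dict per site). Positions are 1-based and strictly
        increasing within each chromosome.
    genotypes : numpy.ndarray
        ``(n_sites, n_samples)`` int8 array of alt-allele counts; -1 = missing.
    samples : list of str
    populations : dict
        sample id -> population label ('' when unknown).
    depth : numpy.ndarray or None
        Optional per-site, per-sample read depth (same shape as genotypes).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list
    populations: dict = field(default_factory=dict)
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites/samples")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        self._check_sorted()

    def _check_sorted(self):
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            i = int(np.nonzero(same & (pos[1:] <= pos[:-1]))[0][0]) + 1
            raise VcfFormatError(
                f"sites not strictly increasing at {chrom[i]}:{pos[i]}"
            )

    # -- basic views -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def pop_of(self, sample: str) -> str:
        return self.populations.get(sample, "")

    def sample_indices(self, pop: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.pop_of(s) == pop],
            dtype=int,
        )

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            populations=dict(self.populations),
            depth=None if self.depth is None else self.depth[index],
        )

    def take_samples(self, keep) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            sites=self.sites.reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
            samples=list(keep),
            populations={s: self.populations.get(s, "") for s in keep},
            depth=None if self.depth is None else self.depth[:, idx],
        )

    # -- per-site summaries ------------------------------------------------
    def allele_counts(self):
        """Return (alt allele count, called allele count) per site."""
        g = self.genotypes
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        return alt, 2 * called.sum(axis=1)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency from non-missing genotypes (NaN if none)."""
        alt, tot = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        return np.minimum(p, 1 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)


@dataclass
class FilterReport:
    """Per-rule removal accounting for :func:`filter_sites`."""

    rules: list
    removed: dict
    input_sites: int
    output_sites: int
    masked_calls: int = 0

    def __post_init__(self):
        if self.input_sites != self.output_sites + sum(self.removed.values()):
            raise ValueError("filter report does not reconcile")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "rules": self.rules,
                    "removed": self.removed,
                    "input_sites": self.input_sites,
                    "output_sites": self.output_sites,
                    "masked_calls": self.masked_calls,
                },
                fh,
                indent=2,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": self.rules, "removed": [self.removed[r] for r in self.rules]}
        )


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(
    path,
    autosomes_only: bool = True,
    sex_chrom_names=("X", "Y", "chrX", "chrY"),
    populations: dict | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Indels, multiallelic records and (optionally) sex-chromosome sites are
    excluded and counted. Returns ``(matrix, exclusions)`` where exclusions
    maps reason -> number of records dropped.

    Raises
    ------
    VcfFormatError
        If the VCF has no GT field or sites are not position-sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: no samples / no GT field")
    sex = set(sex_chrom_names)
    rows, gts, depths = [], [], []
    excl = {"indel": 0, "multiallelic": 0, "sex_chrom": 0, "other": 0}
    has_depth = False
    for v in vcf:
        if autosomes_only and v.CHROM in sex:
            excl["sex_chrom"] += 1
            continue
        if len(v.ALT) != 1:
            excl["multiallelic"] += 1
            continue
        if not v.is_snp:
            excl["indel"] += 1
            continue
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                v.ALT[0],
                v.QUAL if v.QUAL is not None else np.nan,
                dict(v.INFO),
            )
        )
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        gts.append(g)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_depth = True
            depths.append(dp.reshape(-1).astype(np.int32))
        else:
            depths.append(np.full(len(samples), -1, dtype=np.int32))
    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "qual", "info"]
    )
    gm = GenotypeMatrix(
        sites=sites,
        genotypes=np.array(gts, dtype=np.int8).reshape(len(rows), len(samples)),
        samples=samples,
        populations=populations or {},
        depth=np.array(depths).reshape(len(rows), len(samples)) if has_depth else None,
    )
    return gm, excl


def write_vcf(gm: GenotypeMatrix, path, extra_info_keys=()):
    """Write a GenotypeMatrix as a minimal VCFv4.2 text file."""
    chroms = list(dict.fromkeys(gm.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=deerload\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Mutation class">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            info = row.info or {}
            items = [f"{k}={info[k]}" for k in info]
            qual = "." if pd.isna(row.qual) else f"{row.qual:g}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{qual}\t.\t"
                + (";".join(items) if items else ".")
                + "\tGT\t"
                + "\t".join(code[int(g)] for g in gm.genotypes[i])
                + "\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic site.

    Conditions on the total genotype count and the minor-allele count; the
    p-value sums the conditional probabilities of every heterozygote count
    whose probability does not exceed that of the observed configuration
    (the PLINK/vcftools convention, without a mid-p correction).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(h) up to a constant: multinomial arrangements x 2^h
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    logp = (
        hs * np.log(2.0)
        - gammaln(hs + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.nonzero(hs == n_Aa)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def _info_fails(info: dict, thresholds) -> bool:
    for key, (op, val) in thresholds.items():
        k = key.removesuffix("_hi")
        if info is None or k not in info:
            continue
        try:
            x = float(info[k])
        except (TypeError, ValueError):
            continue
        if (op == ">" and x > val) or (op == "<" and x < val):
            return True
    return False


def filter_sites(
    gm: GenotypeMatrix,
    min_depth: int = 3,
    max_missing: float = 0.10,
    min_qual: float = 20.0,
    min_maf: float = 0.05,
    hwe_alpha: float = 0.05,
    info_thresholds: dict | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site-quality filters and report per-rule removals.

    Order: per-call depth masking, then per-site missingness > ``max_missing``,
    QUAL < ``min_qual``, hard INFO thresholds, exact HWE p < ``hwe_alpha``,
    MAF < ``min_maf``. Each removed site is attributed to the first rule it
    fails. Sites left with no called genotype after depth masking fall under
    the missingness rule.
    """
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf),
                    ("hwe_alpha", hwe_alpha)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    if info_thresholds is None:
        info_thresholds = DEFAULT_INFO_THRESHOLDS

    g = gm.genotypes.copy()
    masked = 0
    if gm.depth is not None:
        mask = (gm.depth >= 0) & (gm.depth < min_depth) & (g != MISSING)
        masked = int(mask.sum())
        g[mask] = MISSING
    elif min_depth > 0:
        warnings.warn("no per-sample depth available; depth masking skipped")

    work = GenotypeMatrix(
        sites=gm.sites.reset_index(drop=True),
        genotypes=g,
        samples=list(gm.samples),
        populations=dict(gm.populations),
        depth=gm.depth,
    )
    n = work.n_sites
    reason = np.full(n, "", dtype=object)

    miss = work.missing_rate()
    all_missing = (work.genotypes != MISSING).sum(axis=1) == 0
    fail = (miss > max_missing) | all_missing
    reason[fail & (reason == "")] = "missingness"

    qual = work.sites["qual"].to_numpy(dtype=float)
    fail = ~np.isnan(qual) & (qual < min_qual)
    reason[fail & (reason == "")] = "qual"

    fail = np.array(
        [_info_fails(info, info_thresholds) for info in work.sites["info"]]
    )
    reason[fail & (reason == "")] = "info"

    todo = reason == ""
    hwe_fail = np.zeros(n, dtype=bool)
    for i in np.nonzero(todo)[0]:
        gi = work.genotypes[i]
        gi = gi[gi != MISSING]
        counts = (int((gi == 0).sum()), int((gi == 1).sum()), int((gi == 2).sum()))
        if sum(counts) >= 1 and hwe_exact_pvalue(*counts) < hwe_alpha:
            hwe_fail[i] = True
    reason[hwe_fail & (reason == "")] = "hwe"

    maf = work.maf()
    fail = np.nan_to_num(maf, nan=0.0) < min_maf
    reason[fail & (reason == "")] = "maf"

    rules = ["missingness", "qual", "info", "hwe", "maf"]
    removed = {r: int((reason == r).sum()) for r in rules}
    keep = reason == ""
    out = work.take_sites(keep)
    report = FilterReport(
        rules=rules,
        removed=removed,
        input_sites=n,
        output_sites=int(keep.sum()),
        masked_calls=masked,
    )
    return out, report
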