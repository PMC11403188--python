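"""Variant consequences, Grantham-based deleteriousness classes, derived-allele
polarization and the R_A/B relative mutation-load statistic.

Mutation classes follow the resequencing-study convention: missense variants
are split into deleterious (Grantham distance > 150) and benign (< 150; the
boundary value 150 is assigned benign and flagged); splice donor/acceptor,
start-lost, stop-lost, stop-gained and stop-retained variants form the
loss-of-function (LoF) class. R_A/B compares the mean per-individual number of
derived alleles of a class carried in heterozygous (one copy) or homozygous
(two copies) form between two populations; uncertainty comes from a weighted
block jackknife over contiguous equal-SNP genomic blocks, with inference on
log R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from Bio.Seq import Seq

from .io import MISSING, GenotypeMatrix
from .toygenome import Transcript

LOF_TERMS = frozenset(
    {
        "splice_donor_variant",
        "splice_acceptor_variant",
        "start_lost",
        "stop_lost",
        "stop_gained",
        "stop_retained_variant",
    }
)
GRANTHAM_DELETERIOUS = 150

# ---------------------------------------------------------------------------
# Grantham distances
# ---------------------------------------------------------------------------

#: published amino-acid distance matrix (Grantham 1974), 190 unordered pairs.
_GRANTHAM_TABLE = """
S: R 110, L 145, P 74, T 58, A 99, V 124, G 56, I 142, F 155, Y 144, C 112, H 89, Q 68, N 46, K 121, D 65, E 80, M 135, W 177
R: L 102, P 103, T 71, A 112, V 96, G 125, I 97, F 97, Y 77, C 180, H 29, Q 43, N 86, K 26, D 96, E 54, M 91, W 101
L: P 98, T 92, A 96, V 32, G 138, I 5, F 22, Y 36, C 198, H 99, Q 113, N 153, K 107, D 172, E 138, M 15, W 61
P: T 38, A 27, V 68, G 42, I 95, F 114, Y 110, C 169, H 77, Q 76, N 91, K 103, D 108, E 93, M 87, W 147
T: A 58, V 69, G 59, I 89, F 103, Y 92, C 149, H 47, Q 42, N 65, K 78, D 85, E 65, M 81, W 128
A: V 64, G 60, I 94, F 113, Y 112, C 195, H 86, Q 91, N 111, K 106, D 126, E 107, M 84, W 148
V: G 109, I 29, F 50, Y 55, C 192, H 84, Q 96, N 133, K 97, D 152, E 121, M 21, W 88
G: I 135, F 153, Y 147, C 159, H 98, Q 87, N 80, K 127, D 94, E 98, M 127, W 184
I: F 21, Y 33, C 198, H 94, Q 109, N 149, K 102, D 168, E 134, M 10, W 61
F: Y 22, C 205, H 100, Q 116, N 158, K 102, D 177, E 140, M 28, W 40
Y: C 194, H 83, Q 99, N 143, K 85, D 160, E 122, M 36, W 37
C: H 174, Q 154, N 139, K 202, D 154, E 170, M 196, W 215
H: Q 24, N 68, K 32, D 81, E 40, M 87, W 115
Q: N 46, K 53, D 61, E 29, M 101, W 130
N: K 94, D 23, E 42, M 142, W 174
K: D 101, E 56, M 95, W 110
D: E 45, M 160, W 191
E: M 126, W 152
M: W 67
"""

#: Grantham's physicochemical properties: composition c, polarity p, volume v
GRANTHAM_PROPERTIES = {
    "A": (0.0, 8.1, 31.0), "R": (0.65, 10.5, 124.0), "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0), "C": (2.75, 5.5, 55.0), "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0), "G": (0.74, 9.0, 3.0), "H": (0.58, 10.4, 96.0),
    "I": (0.0, 5.2, 111.0), "L": (0.0, 4.9, 111.0), "K": (0.33, 11.3, 119.0),
    "M": (0.0, 5.7, 105.0), "F": (0.0, 5.2, 132.0), "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0), "V": (0.0, 5.9, 84.0),
}
_ALPHA, _BETA, _GAMMA = 1.833, 0.1018, 0.000399


def _build_matrix() -> dict:
    m = {}
    for line in _GRANTHAM_TABLE.strip().splitlines():
        row, rest = line.split(":")
        for tok in rest.split(","):
            aa, v = tok.split()
            m[frozenset((row.strip(), aa))] = int(v)
    assert len(m) == 190
    return m


_GRANTHAM = _build_matrix()


def grantham(aa1: str, aa2: str) -> int:
    """Grantham physicochemical distance between two amino acids (0..215)."""
    for a in (aa1, aa2):
        if a not in GRANTHAM_PROPERTIES:
            raise ValueError(f"unknown residue {a!r}")
    if aa1 == aa2:
        return 0
    return _GRANTHAM[frozenset((aa1, aa2))]


def grantham_from_properties(aa1: str, aa2: str) -> int:
    """Distance recomputed from composition/polarity/volume.

    D = rho * sqrt(alpha (c1-c2)^2 + beta (p1-p2)^2 + gamma (v1-v2)^2),
    with rho normalizing the mean pairwise distance to 100, rounded to the
    nearest integer. Agrees with the published matrix within +-1.
    """
    import itertools, math

    def raw(x, y):
        c1, p1, v1 = GRANTHAM_PROPERTIES[x]
        c2, p2, v2 = GRANTHAM_PROPERTIES[y]
        return math.sqrt(
            _ALPHA * (c1 - c2) ** 2 + _BETA * (p1 - p2) ** 2 + _GAMMA * (v1 - v2) ** 2
        )

    global _RHO
    try:
        rho = _RHO
    except NameError:
        pairs = list(itertools.combinations(GRANTHAM_PROPERTIES, 2))
        rho = _RHO = 100.0 / (sum(raw(*p) for p in pairs) / len(pairs))
    for a in (aa1, aa2):
        if a not in GRANTHAM_PROPERTIES:
            raise ValueError(f"unknown residue {a!r}")
    return int(math.floor(raw(aa1, aa2) * rho + 0.5))


# ---------------------------------------------------------------------------
# consequence annotation
# ---------------------------------------------------------------------------

@dataclass
class SiteAnnotation:
    chrom: str
    pos: int
    consequence: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    grantham: int | None = None
    boundary: bool = False  # Grantham score exactly at the threshold

    @property
    def klass(self) -> str:
        return classify(self)


def classify(ann: SiteAnnotation, stop_retained_is_lof: bool = True) -> str:
    """Map a consequence (+ Grantham score) to a mutation-load class."""
    c = ann.consequence
    if c == "stop_retained_variant" and not stop_retained_is_lof:
        return "synonymous"
    if c in LOF_TERMS:
        return "lof"
    if c == "synonymous_variant":
        return "synonymous"
    if c == "missense_variant":
        if ann.grantham is None:
            raise ValueError("missense annotation lacks a Grantham score")
        return (
            "missense_deleterious"
            if ann.grantham > GRANTHAM_DELETERIOUS
            else "missense_benign"
        )
    return "other"


def annotate_consequences(
    sites: pd.DataFrame,
    sequences: dict,
    transcripts: list[Transcript],
) -> list[SiteAnnotation]:
    """Codon-level consequence annotation of SNPs against toy gene models.

    ``sites`` needs columns chrom, pos, ref, alt. For each SNP inside a CDS
    the containing codon is translated for the reference and alternate
    alleles (standard genetic code, strand aware); SNPs in the first or last
    two bases of an intron become splice donor/acceptor variants; everything
    else is non_coding.

    Raises
    ------
    ValueError
        If the VCF reference allele disagrees with the reference sequence.
    """
    by_chrom: dict = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    cds_cache = {t.gene_id: t.cds_sequence(sequences) for t in transcripts}
    splice_cache = {t.gene_id: t.splice_sites() for t in transcripts}
    out = []
    for row in sites.itertuples(index=False):
        chrom, pos, ref, alt = row.chrom, int(row.pos), row.ref, row.alt
        seq = sequences.get(chrom)
        if seq is not None and pos <= len(seq) and seq[pos - 1] != ref:
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: VCF {ref} vs sequence {seq[pos - 1]}"
            )
        ann = SiteAnnotation(chrom, pos, "non_coding")
        for t in by_chrom.get(chrom, []):
            donors, acceptors = splice_cache[t.gene_id]
            if pos in donors:
                ann = SiteAnnotation(chrom, pos, "splice_donor_variant")
                break
            if pos in acceptors:
                ann = SiteAnnotation(chrom, pos, "splice_acceptor_variant")
                break
            ci = t.cds_index(pos)
            if ci is None:
                continue
            cds = cds_cache[t.gene_id]
            ref_t, alt_t = (ref, alt)
            if t.strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                ref_t, alt_t = comp[ref], comp[alt]
            if cds[ci] != ref_t:
                raise ValueError(
                    f"CDS/reference inconsistency at {chrom}:{pos} in {t.gene_id}"
                )
            codon_i = ci // 3
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            mut = codon[: ci % 3] + alt_t + codon[ci % 3 + 1 :]
            ref_aa = str(Seq(codon).translate())
            alt_aa = str(Seq(mut).translate())
            if codon_i == 0 and codon == "ATG" and mut != "ATG":
                ann = SiteAnnotation(chrom, pos, "start_lost", ref_aa, alt_aa)
            elif ref_aa == "*" and alt_aa == "*":
                ann = SiteAnnotation(chrom, pos, "stop_retained_variant", ref_aa, alt_aa)
            elif alt_aa == "*":
                ann = SiteAnnotation(chrom, pos, "stop_gained", ref_aa, alt_aa)
            elif ref_aa == "*":
                ann = SiteAnnotation(chrom, pos, "stop_lost", ref_aa, alt_aa)
            elif ref_aa == alt_aa:
                ann = SiteAnnotation(chrom, pos, "synonymous_variant", ref_aa, alt_aa)
            else:
                score = grantham(ref_aa, alt_aa)
                ann = SiteAnnotation(
                    chrom, pos, "missense_variant", ref_aa, alt_aa,
                    grantham=score, boundary=score == GRANTHAM_DELETERIOUS,
                )
            break
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def polarize(gm: GenotypeMatrix, ancestral_source="reference") -> np.ndarray:
    """Per-site index of the derived allele (0 = ref, 1 = alt, -1 = unknown).

    ``ancestral_source`` is ``"reference"`` (ancestral = REF, so derived =
    ALT), ``"aa"`` (the INFO AA tag names the ancestral allele) or a
    DataFrame with columns chrom, pos, ancestral (a truth table); sites whose
    ancestral state is absent or matches neither allele are flagged unknown.
    """
    n = gm.n_sites
    ref = gm.sites["ref"].to_numpy()
    alt = gm.sites["alt"].to_numpy()
    if isinstance(ancestral_source, str) and ancestral_source == "reference":
        return np.ones(n, dtype=np.int8)
    if isinstance(ancestral_source, str) and ancestral_source == "aa":
        anc = np.array(
            [str((info or {}).get("AA", "")) for info in gm.sites["info"]]
        )
    elif isinstance(ancestral_source, pd.DataFrame):
        key = pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]])
        truth = ancestral_source.set_index(["chrom", "pos"])["ancestral"]
        anc = truth.reindex(key).fillna("").to_numpy()
    else:
        raise ValueError(f"unknown ancestral source {ancestral_source!r}")
    out = np.full(n, -1, dtype=np.int8)
    out[anc == ref] = 1
    out[anc == alt] = 0
    return out


# ---------------------------------------------------------------------------
# R_A/B with block jackknife
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    """R_A/B estimates per (class, zygosity) plus per-individual counts."""

    table: pd.DataFrame
    per_individual: pd.DataFrame
    pops: tuple
    n_blocks: int
    n_unknown_derived: int
    flags: list = field(default_factory=list)


def _jackknife_log_ratio(tot_a, tot_b, block_a, block_b, m_b, n_a, n_b):
    """Weighted delete-one block jackknife of log(meanA/meanB).

    ``tot_*``: total count summed over individuals; ``block_*``: per-block
    totals; ``m_b``: SNPs per block. Returns (se, n_informative_blocks).
    """
    if tot_a <= 0 or tot_b <= 0:
        return np.nan, 0
    M = m_b.sum()
    theta = np.log((tot_a / n_a) / (tot_b / n_b))
    use = m_b > 0
    la, lb = tot_a - block_a, tot_b - block_b
    ok = use & (la > 0) & (lb > 0)
    if ok.sum() < 3:
        return np.nan, int(ok.sum())
    h = M / m_b[ok]
    theta_b = np.log((la[ok] / n_a) / (lb[ok] / n_b))
    B = int(ok.sum())
    theta_J = B * theta - ((1 - m_b[ok] / M) * theta_b).sum()
    tau = h * theta - (h - 1) * theta_b
    var = ((tau - theta_J) ** 2 / (h - 1)).sum() / B
    return float(np.sqrt(var)), B


def rab(
    gm: GenotypeMatrix,
    site_classes,
    derived_index,
    pops: tuple,
    classes=("synonymous", "missense_benign", "missense_deleterious", "lof"),
    n_blocks: int = 50,
) -> LoadReport:
    """Relative per-individual derived-allele load of population A vs B.

    For class C and zygosity z (het = exactly one derived copy, hom = two),
    each individual's count is the number of class-C sites, with known
    derived allele and a called genotype in that individual, where it carries
    z derived copies; R_A/B(z, C) = mean_A / mean_B. ``r_norm`` additionally
    divides by the synonymous-class ratio of the same zygosity. Standard
    errors, 95% CIs and two-sided Z-test p-values for log R = 0 come from a
    weighted block jackknife over ``n_blocks`` contiguous equal-SNP blocks.
    """
    site_classes = np.asarray(site_classes)
    derived_index = np.asarray(derived_index)
    pa, pb = pops
    ia = gm.sample_indices(pa)
    ib = gm.sample_indices(pb)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both populations need at least two individuals")
    known = derived_index >= 0
    n_unknown = int((~known).sum())
    g = gm.genotypes
    dc = np.where(derived_index[:, None] == 1, g, 2 - g).astype(np.int8)
    dc[g == MISSING] = MISSING
    blocks = np.array_split(np.nonzero(known)[0], n_blocks)
    flags = []
    rows = []
    per_ind = {}
    stats = {}
    for cl in classes:
        cmask = known & (site_classes == cl)
        idx = np.nonzero(cmask)[0]
        for zyg, copies in (("het", 1), ("hom", 2)):
            carrier = dc[idx] == copies
            cnt_a = carrier[:, ia].sum(axis=0)
            cnt_b = carrier[:, ib].sum(axis=0)
            per_ind[(cl, zyg, pa)] = cnt_a
            per_ind[(cl, zyg, pb)] = cnt_b
            block_a = np.zeros(len(blocks))
            block_b = np.zeros(len(blocks))
            m_b = np.zeros(len(blocks))
            in_class = np.zeros(g.shape[0], dtype=bool)
            in_class[idx] = True
            for bi, bidx in enumerate(blocks):
                sel = bidx[in_class[bidx]]
                m_b[bi] = len(bidx)
                if len(sel):
                    car = dc[sel] == copies
                    block_a[bi] = car[:, ia].sum()
                    block_b[bi] = car[:, ib].sum()
            tot_a, tot_b = cnt_a.sum(), cnt_b.sum()
            mean_a = tot_a / len(ia)
            mean_b = tot_b / len(ib)
            if tot_b == 0:
                flags.append(f"{cl}/{zyg}: mean_B = 0, R undefined")
                stats[(cl, zyg)] = (mean_a, mean_b, np.nan, np.nan)
                continue
            r = mean_a / mean_b
            se, n_ok = _jackknife_log_ratio(
                tot_a, tot_b, block_a, block_b, m_b, len(ia), len(ib)
            )
            if np.isnan(se):
                flags.append(f"{cl}/{zyg}: fewer than 3 informative blocks, no CI")
            stats[(cl, zyg)] = (mean_a, mean_b, r, se)
    for cl in classes:
        for zyg in ("het", "hom"):
            mean_a, mean_b, r, se = stats[(cl, zyg)]
            syn = stats.get(("synonymous", zyg), (np.nan,) * 4)[2]
            r_norm = r / syn if (syn and not np.isnan(syn) and syn > 0) else np.nan
            if not np.isnan(se) and not np.isnan(r):
                ci = (float(r * np.exp(-1.96 * se)), float(r * np.exp(1.96 * se)))
                z = np.log(r) / se if se > 0 else 0.0
                p = float(2 * norm.sf(abs(z)))
            else:
                ci, p = (np.nan, np.nan), np.nan
            rows.append(
                {
                    "class": cl,
                    "zygosity": zyg,
                    "mean_A": mean_a,
                    "mean_B": mean_b,
                    "r": r,
                    "r_norm": r_norm,
                    "se_log": se,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p": p,
                }
            )
    per_rows = []
    for (cl, zyg, pop), counts in per_ind.items():
        names = [gm.samples[i] for i in (ia if pop == pa else ib)]
        for s, c in zip(names, counts):
            per_rows.append({"class": cl, "zygosity": zyg, "population": pop,
                             "sample": s, "count": int(c)})
    return LoadReport(
        table=pd.DataFrame(rows),
        per_individual=pd.DataFrame(per_rows),
        pops=pops,
        n_blocks=n_blocks,
        n_unknown_derived=n_unknown,
        flags=flags,
    )
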