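"""Independent brute-force oracles used to validate the library.

Everything here is written as a literal, loop-based transcription of the
underlying definition, deliberately sharing no code with the package.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np

MISSING = -1


# -- Hardy-Weinberg exact test ----------------------------------------------

def hwe_enumerate(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p by full enumeration with rational arithmetic.

    Enumerates every genotype table with the same total and allele counts,
    weighting each by its multinomial arrangement count times 2^het.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    weights = {}
    for het in range(min(n_a, 2 * n - n_a) + 1):
        hom_a = n_a - het
        if hom_a < 0 or hom_a % 2:
            continue
        hom_a //= 2
        hom_A = n - het - hom_a
        if hom_A < 0:
            continue
        w = Fraction(
            comb(n, het) * comb(n - het, hom_a) * 2**het
        )
        weights[het] = w
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


# -- Weir & Cockerham 1984 ---------------------------------------------------

def wc_theta_oracle(pop_counts):
    """Literal WC84 variance-component transcription for one biallelic site.

    ``pop_counts``: list of (n_AA, n_Aa, n_aa) per population. Returns
    theta-hat or None when undefined (fewer than two populations with >= 2
    individuals, or zero denominator).
    """
    pops = [(a, h, b) for a, h, b in pop_counts if a + h + b >= 2]
    r = len(pops)
    if r < 2:
        return None
    n = [a + h + b for a, h, b in pops]
    p = [(2 * b + h) / (2 * ni) for (a, h, b), ni in zip(pops, n)]
    hbar_i = [h / ni for (a, h, b), ni in zip(pops, n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, hbar_i)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return None
    return a / (a + b + c)


# -- nucleotide diversity ----------------------------------------------------

def pi_brute(genotypes):
    """Sum over sites of mean pairwise allele differences (per-site pi).

    ``genotypes``: (sites, samples) array with -1 missing. Each diploid
    genotype contributes two alleles; pi_site averages differences over all
    allele pairs.
    """
    total = 0.0
    for row in genotypes:
        alleles = []
        for g in row:
            if g == MISSING:
                continue
            alleles += [1] * g + [0] * (2 - g)
        if len(alleles) < 2:
            continue
        diffs = sum(x != y for x, y in combinations(alleles, 2))
        total += diffs / comb(len(alleles), 2)
    return total


# -- SFS projection ----------------------------------------------------------

def project_site(m: int, d: int, k: int):
    """Probability of j derived in k draws without replacement from m alleles
    with d derived, by direct enumeration."""
    return [comb(d, j) * comb(m - d, k - j) / comb(m, k) for j in range(k + 1)]


# -- PLINK-style ROH ---------------------------------------------------------

def roh_brute(
    genos,
    positions,
    window_snp=50,
    min_snps=50,
    window_missing=3,
    min_kb=100.0,
    density_kb_per_snp=1000.0,
    window_het=1,
    hit_threshold=0.05,
    max_gap_kb=1000.0,
):
    """One sample, one chromosome: literal scanning-window transcription.

    Returns [(start_index, end_index)] of accepted runs (indices into the
    site list).
    """
    n = len(genos)
    windows = []
    for w0 in range(0, n - window_snp + 1):
        chunk = genos[w0 : w0 + window_snp]
        het = sum(1 for g in chunk if g == 1)
        mis = sum(1 for g in chunk if g == MISSING)
        windows.append(het <= window_het and mis <= window_missing)
    eligible = []
    for i in range(n):
        containing = [w for w in range(len(windows)) if w <= i <= w + window_snp - 1]
        if not containing:
            eligible.append(False)
            continue
        frac = sum(windows[w] for w in containing) / len(containing)
        eligible.append(frac >= hit_threshold)
    # maximal stretches, then gap split
    stretches = []
    start = None
    for i in range(n):
        if eligible[i] and start is None:
            start = i
        if not eligible[i] and start is not None:
            stretches.append((start, i - 1))
            start = None
    if start is not None:
        stretches.append((start, n - 1))
    split = []
    for a, b in stretches:
        s = a
        for i in range(a + 1, b + 1):
            if positions[i] - positions[i - 1] > max_gap_kb * 1000:
                split.append((s, i - 1))
                s = i
        split.append((s, b))
    out = []
    for a, b in split:
        n_snps = b - a + 1
        length = positions[b] - positions[a] + 1
        if n_snps < min_snps:
            continue
        if length < min_kb * 1000:
            continue
        if length / 1000 / n_snps > density_kb_per_snp:
            continue
        out.append((a, b))
    return out


# -- codon consequences ------------------------------------------------------

def consequence_oracle(transcript, sequences, pos, ref, alt):
    """Consequence by mutating the genome and re-translating the transcript.

    Independent of the annotator's codon bookkeeping: it rebuilds the CDS
    from a mutated copy of the chromosome and diffs the two peptides.
    """
    from Bio.Seq import Seq

    donors, acceptors = transcript.splice_sites()
    if pos in donors:
        return "splice_donor_variant"
    if pos in acceptors:
        return "splice_acceptor_variant"
    if transcript.cds_index(pos) is None:
        return "non_coding"
    seq = sequences[transcript.chrom]
    assert seq[pos - 1] == ref
    mutated = dict(sequences)
    mutated[transcript.chrom] = seq[: pos - 1] + alt + seq[pos:]
    cds_ref = transcript.cds_sequence(sequences)
    cds_alt = transcript.cds_sequence(mutated)
    pep_ref = str(Seq(cds_ref).translate())
    pep_alt = str(Seq(cds_alt).translate())
    i = transcript.cds_index(pos) // 3
    aa_ref, aa_alt = pep_ref[i], pep_alt[i]
    if i == 0 and cds_ref[:3] == "ATG" and cds_alt[:3] != "ATG":
        return "start_lost"
    if aa_ref == "*" and aa_alt == "*":
        return "stop_retained_variant"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    if aa_ref == aa_alt:
        return "synonymous_variant"
    return "missense_variant"
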