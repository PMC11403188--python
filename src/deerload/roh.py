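"""Run-of-homozygosity detection (PLINK scanning-window algorithm), the
F_ROH genomic inbreeding coefficient, and ROH length-class summaries.

The caller reproduces PLINK 1.9's ``--homozyg`` logic: a window of
``window_snp`` consecutive SNPs slides along each chromosome; a window is
"homozygous" if it contains at most ``window_het`` heterozygous and at most
``window_missing`` missing calls; each SNP's hit fraction is the proportion
of windows containing it that are homozygous; SNPs at or above
``hit_threshold`` are run-eligible; maximal eligible stretches are split at
physical gaps above ``max_gap_kb`` and then filtered by SNP count, physical
length and SNP density. F_ROH divides the summed ROH length by the sample's
alignment-covered (effective) genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # bp of first SNP in run (1-based)
    end: int  # bp of last SNP in run (inclusive)
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _eligible_snps(
    het: np.ndarray,
    miss: np.ndarray,
    window_snp: int,
    window_missing: int,
    window_het: int,
    hit_threshold: float,
) -> np.ndarray:
    """Per-SNP run eligibility from the scanning-window hit fraction."""
    n = len(het)
    if n < window_snp:
        return np.zeros(n, dtype=bool)
    w = window_snp
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(n - w + 1)
    hom_win = (
        (cs_het[starts + w] - cs_het[starts] <= window_het)
        & (cs_mis[starts + w] - cs_mis[starts] <= window_missing)
    ).astype(np.int64)
    cs_hom = np.concatenate([[0], np.cumsum(hom_win)])
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, n - w)
    n_windows = hi - lo + 1
    n_hom = cs_hom[hi + 1] - cs_hom[lo]
    return n_hom / n_windows >= hit_threshold


def call_roh(
    gm: GenotypeMatrix,
    window_snp: int = 50,
    min_snps: int = 50,
    window_missing: int = 3,
    min_kb: float = 100.0,
    density_kb_per_snp: float = 1000.0,
    window_het: int = 1,
    hit_threshold: float = 0.05,
    max_gap_kb: float = 1000.0,
) -> list[ROHSegment]:
    """Detect runs of homozygosity for every sample.

    Parameter defaults are the PLINK 1.9 defaults with the window/SNP-count/
    length/density settings used for low-coverage resequencing panels
    (window of 50 SNPs, >= 50 SNPs and >= 100 kb per run, <= 3 missing and
    <= 1 heterozygous call per window, density ceiling 1000 kb/SNP, runs
    split at gaps > 1000 kb). Returns segments sorted by (sample, chrom,
    start); per sample the segments are non-overlapping.
    """
    chroms = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    segments: list[ROHSegment] = []
    for si, sample in enumerate(gm.samples):
        g = gm.genotypes[:, si]
        for c in dict.fromkeys(chroms):
            sel = np.nonzero(chroms == c)[0]
            pos = pos_all[sel]
            gc = g[sel]
            elig = _eligible_snps(
                gc == 1,
                gc == MISSING,
                window_snp,
                window_missing,
                window_het,
                hit_threshold,
            )
            # maximal eligible stretches, split at large physical gaps
            runs = []
            start = None
            for k in range(len(sel)):
                if elig[k]:
                    if start is None:
                        start = k
                    elif pos[k] - pos[k - 1] > max_gap_kb * 1000:
                        runs.append((start, k - 1))
                        start = k
                else:
                    if start is not None:
                        runs.append((start, k - 1))
                        start = None
            if start is not None:
                runs.append((start, len(sel) - 1))
            for a, b in runs:
                n_snps = b - a + 1
                length = pos[b] - pos[a] + 1
                if n_snps < min_snps:
                    continue
                if length < min_kb * 1000:
                    continue
                if length / 1000 / n_snps > density_kb_per_snp:
                    continue
                segments.append(
                    ROHSegment(sample, c, int(pos[a]), int(pos[b]), n_snps)
                )
    return segments


def segments_frame(segments: list[ROHSegment], populations: dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start, s.end, s.n_snps, s.length) for s in segments],
        columns=["sample", "chrom", "start", "end", "n_snps", "length"],
    )
    if populations is not None and len(df):
        df["population"] = df["sample"].map(lambda s: populations.get(s, ""))
    return df


def froh(segments: list[ROHSegment], effective_length: dict) -> pd.Series:
    """Per-sample F_ROH = total ROH length / effective genome length.

    Samples present in ``effective_length`` but without segments get 0.
    """
    total = {s: 0 for s in effective_length}
    for seg in segments:
        if seg.sample not in effective_length:
            raise ValueError(f"no effective length for sample {seg.sample}")
        total[seg.sample] += seg.length
    out = {}
    for s, t in total.items():
        L = effective_length[s]
        if L <= 0:
            raise ValueError(f"effective length must be > 0 for {s}")
        if t > L:
            raise ValueError(f"ROH length {t} exceeds effective length {L} for {s}")
        out[s] = t / L
    return pd.Series(out, name="F_ROH")


def inbreeding_summary(
    segments: list[ROHSegment],
    effective_length: dict,
    populations: dict,
    cut_kb: float = 500.0,
) -> pd.DataFrame:
    """Population table of N_ROH, S_ROH, F_ROH (means +- SD) and the long-ROH fraction."""
    f = froh(segments, effective_length)
    per = pd.DataFrame(
        {
            "sample": list(effective_length),
            "population": [populations.get(s, "") for s in effective_length],
        }
    )
    n_roh = {s: 0 for s in effective_length}
    s_roh = {s: 0 for s in effective_length}
    for seg in segments:
        n_roh[seg.sample] += 1
        s_roh[seg.sample] += seg.length
    per["N_ROH"] = per["sample"].map(n_roh)
    per["S_ROH"] = per["sample"].map(s_roh)
    per["F_ROH"] = per["sample"].map(f)
    frac = roh_length_classes(segments, cut_kb=cut_kb, populations=populations)
    rows = []
    for pop, grp in per.groupby("population"):
        rows.append(
            {
                "population": pop,
                "n_samples": len(grp),
                "N_ROH_mean": grp["N_ROH"].mean(),
                "N_ROH_sd": grp["N_ROH"].std(),
                "S_ROH_mean": grp["S_ROH"].mean(),
                "F_ROH_mean": grp["F_ROH"].mean(),
                "F_ROH_sd": grp["F_ROH"].std(),
                "frac_long": frac.get(pop, (np.nan, 0, 0))[0],
            }
        )
    return pd.DataFrame(rows)


def roh_length_classes(
    segments: list[ROHSegment],
    cut_kb: float = 500.0,
    populations: dict | None = None,
) -> dict:
    """Per-population fraction of ROH segments longer than ``cut_kb``.

    Returns pop -> (fraction_above, n_above, n_total); populations without
    segments are absent from the result (the fraction is undefined, not 0).
    """
    counts: dict = {}
    for seg in segments:
        pop = (populations or {}).get(seg.sample, "all")
        above, total = counts.get(pop, (0, 0))
        counts[pop] = (above + (seg.length > cut_kb * 1000), total + 1)
    return {
        pop: (above / total, above, total) for pop, (above, total) in counts.items()
    }
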