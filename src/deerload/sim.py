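"""Forward-time Wright-Fisher simulator for two-population bottleneck scenarios.

Simulates diploid individuals on a multi-chromosome genome under infinite-sites
mutation, crossover recombination, multiplicative per-site selection, migration
during a configurable epoch, population bottlenecks and founder splits
(translocations). Mutations carry a functional class label (neutral,
synonymous, benign/deleterious missense, loss-of-function) with class-specific
selection coefficients, so downstream diversity, inbreeding and mutation-load
statistics can be validated against known truth.

Two initialization modes are supported: ``"empty"`` starts from a monomorphic
population and relies on a long mutation-drift burn-in to reach equilibrium;
``"sfs"`` seeds standing variation from the neutral stationary frequency
spectrum (at linkage equilibrium) and uses a shorter burn-in to build linkage
structure before any demographic event.

Large real-scale parameters are made desk-scale by rescaling: population sizes
and epoch lengths are divided by ``rescale``, while per-generation rates
(mutation, selection, migration) are multiplied by it, preserving the
population-scaled compounds 4*Ne*mu and Ne*s. Recombination has its own factor
``rescale_r`` so that the physical base-pair scale of homozygosity runs and LD
decay — which downstream analyses threshold in kb — can be preserved
independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

CLASSES = ("neutral", "synonymous", "missense_benign", "missense_deleterious", "lof")
_BASES = np.array(list("ACGT"))


class ExtinctionError(RuntimeError):
    """All individuals of a population have zero fitness."""


def _merge(old, old_to, new, new_to, dtype):
    out = np.empty(len(old) + len(new), dtype=dtype)
    out[old_to] = old
    out[new_to] = new
    return out


@dataclass
class ScenarioConfig:
    """Demographic + selection parameters for one simulation run.

    Times are generations before present (sampling time = 0); the simulator
    runs forward from ``split_gen + burn_in``. ``migration_epoch`` is
    ``(start_gen, end_gen, m_AtoB, m_BtoA)`` with start_gen > end_gen, both
    before present; ``m_AtoB`` is the fraction of population B newly drawn
    from A each generation. ``bottleneck`` entries ``(pop, gen, size)`` set a
    population's size from that generation onward; ``founder_splits`` entries
    ``(source_pop, gen, n_founders, new_pop_label)`` establish a new
    population from ``n_founders`` individuals sampled without replacement.
    """

    n_chrom: int = 5
    chrom_length_bp: int = 1_500_000
    mu: float = 5.4e-7  # per site per generation (after any rescaling)
    rec_rate: float = 8.32  # cM/Mb
    gen_time_years: float = 1.5
    ne_ancestral: int = 156
    split_gen: int = 71
    ne_pops: dict = field(default_factory=lambda: {"A": 156, "B": 78})
    migration_epoch: tuple = (71, 53, 0.45, 0.45)
    bottleneck: list = field(default_factory=list)
    founder_splits: list = field(default_factory=list)
    class_mix: dict = field(
        default_factory=lambda: {
            "neutral": 0.70,
            "synonymous": 0.12,
            "missense_benign": 0.08,
            "missense_deleterious": 0.06,
            "lof": 0.04,
        }
    )
    sel_coeff: dict = field(
        default_factory=lambda: {
            "neutral": (0.0, 0.5),
            "synonymous": (0.0, 0.5),
            "missense_benign": (0.0, 0.5),
            "missense_deleterious": (-0.05, 0.5),
            "lof": (-0.4, 0.2),
        }
    )
    sample_sizes: dict = field(default_factory=lambda: {"A": 8, "B": 8})
    seed: int = 0
    burn_in: int | None = None  # default: 10*2N ("empty") or N ("sfs")
    init: str = "sfs"  # "sfs" | "empty"
    nominal: dict = field(default_factory=dict)  # unscaled parameter record

    def __post_init__(self):
        mix = self.class_mix
        if any(v < 0 for v in mix.values()):
            raise ValueError("class_mix proportions must be >= 0")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for c, (s, h) in self.sel_coeff.items():
            if c in ("neutral", "synonymous") and s != 0:
                raise ValueError(f"{c} must have s = 0")
            if c in ("missense_deleterious", "lof") and s > 0:
                raise ValueError(f"{c} must have s <= 0")
        start, end, m_ab, m_ba = self.migration_epoch
        if not (0 <= m_ab <= 1 and 0 <= m_ba <= 1):
            raise ValueError("migration fractions must lie in [0, 1]")
        for pop, gen, size in self.bottleneck:
            if gen >= self.split_gen:
                raise ValueError("bottleneck generations must postdate the split")
            if size < 2:
                raise ValueError("population sizes must be >= 2")
        for pop, gen, k, label in self.founder_splits:
            if gen >= self.split_gen:
                raise ValueError("founder splits must postdate the split")
            if k < 2:
                raise ValueError("founder groups must be >= 2")
        if min([self.ne_ancestral, *self.ne_pops.values()]) < 2:
            raise ValueError("population sizes must be >= 2")

    @property
    def genome_length(self) -> int:
        return self.n_chrom * self.chrom_length_bp

    @property
    def rec_per_bp(self) -> float:
        # cM/Mb -> crossover probability per bp per meiosis
        return self.rec_rate / 100.0 / 1e6


@dataclass
class SimulatedDataset:
    """Simulator output: genotypes + truth, optionally mirrored to disk."""

    gm: GenotypeMatrix
    truth: pd.DataFrame  # chrom,pos,ancestral,derived,class,derived_index
    sample_table: pd.DataFrame  # sample, population, effective_length
    config: ScenarioConfig
    vcf_path: str | None = None

    @property
    def effective_length(self) -> dict:
        return dict(
            zip(self.sample_table["sample"], self.sample_table["effective_length"])
        )


# ---------------------------------------------------------------------------
# internal population state
# ---------------------------------------------------------------------------

class _State:
    """Shared segregating-site table + per-population haplotype matrices."""

    def __init__(self, cfg: ScenarioConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.pos = np.empty(0, dtype=np.int64)  # global coordinate (chrom-offset)
        self.cls = np.empty(0, dtype=np.int8)  # index into CLASSES
        self.haps: dict[str, np.ndarray] = {}  # pop -> (2N, S) uint8
        self.taken = set()  # occupied global positions (infinite sites)
        mix_classes = [c for c in CLASSES if cfg.class_mix.get(c, 0) > 0]
        self.mix_classes = np.array([CLASSES.index(c) for c in mix_classes], dtype=np.int8)
        self.mix_probs = np.array([cfg.class_mix[c] for c in mix_classes])
        self.s = np.array([cfg.sel_coeff.get(c, (0.0, 0.5))[0] for c in CLASSES])
        self.h = np.array([cfg.sel_coeff.get(c, (0.0, 0.5))[1] for c in CLASSES])
        self.chrom_bounds = np.arange(cfg.n_chrom + 1) * cfg.chrom_length_bp

    # -- site bookkeeping --------------------------------------------------
    def compact(self):
        """Drop sites lost or fixed in every population."""
        if len(self.pos) == 0:
            return
        total = np.zeros(len(self.pos), dtype=np.int64)
        n_haps = 0
        for H in self.haps.values():
            total += H.sum(axis=0, dtype=np.int64)
            n_haps += H.shape[0]
        keep = (total > 0) & (total < n_haps)
        if keep.all():
            return
        for lost in self.pos[~keep]:
            self.taken.discard(int(lost))
        self.pos = self.pos[keep]
        self.cls = self.cls[keep]
        for p in self.haps:
            self.haps[p] = np.ascontiguousarray(self.haps[p][:, keep])

    def add_sites(self, new_pos, new_cls, carrier_pop, carrier_rows):
        """Insert new singleton mutation columns, keeping positions sorted."""
        if len(new_pos) == 0:
            return
        order = np.argsort(new_pos, kind="stable")
        new_pos = np.asarray(new_pos)[order]
        new_cls = np.asarray(new_cls)[order]
        carrier_rows = np.asarray(carrier_rows)[order]
        k = len(new_pos)
        S = len(self.pos)
        insert_at = np.searchsorted(self.pos, new_pos)
        old_to = np.arange(S) + np.searchsorted(insert_at, np.arange(S), side="right")
        new_to = insert_at + np.arange(k)
        self.pos = _merge(self.pos, old_to, new_pos, new_to, np.int64)
        self.cls = _merge(self.cls, old_to, new_cls, new_to, np.int8)
        for p, H in self.haps.items():
            out = np.zeros((H.shape[0], S + k), dtype=np.uint8)
            out[:, old_to] = H
            if p == carrier_pop:
                out[carrier_rows, new_to[np.arange(k)]] = 1
            self.haps[p] = out
        self.taken.update(int(x) for x in new_pos)

    # -- one generation of one population ---------------------------------
    def fitness(self, pop: str) -> np.ndarray:
        H = self.haps[pop]
        n = H.shape[0] // 2
        sel = np.nonzero(self.s[self.cls] != 0)[0]
        if len(sel) == 0:
            return np.ones(n)
        g = H[0::2][:, sel].astype(np.int16) + H[1::2][:, sel]
        s = self.s[self.cls[sel]]
        h = self.h[self.cls[sel]]
        log_het = np.log1p(np.maximum(h * s, -1 + 1e-12))
        log_hom = np.log1p(np.maximum(s, -1 + 1e-12))
        logw = (g == 1) @ log_het + (g == 2) @ log_hom
        # lethal genotypes (s = -1 homozygous, or fully dominant lethals) are
        # inviable outright; everything else competes on relative fitness
        lethal_hom = s <= -1 + 1e-9
        lethal_het = h * s <= -1 + 1e-9
        inviable = ((g == 2) & lethal_hom).any(axis=1) | (
            (g >= 1) & lethal_het
        ).any(axis=1)
        w = np.exp(logw - logw.max())
        w[inviable] = 0.0
        return w

    def gametes(self, pop: str, parents: np.ndarray) -> np.ndarray:
        """One gamete per entry of ``parents`` (individual indices)."""
        H = self.haps[pop]
        cfg = self.cfg
        k = len(parents)
        S = len(self.pos)
        if S == 0:
            return H[2 * parents].copy()
        # which parental haplotype each chromosome starts from
        start = self.rng.integers(0, 2, size=(k, cfg.n_chrom), dtype=np.int8)
        chrom_of_site = np.searchsorted(self.chrom_bounds, self.pos, side="right") - 1
        choose = start[:, chrom_of_site]
        # crossovers within chromosomes
        n_x = self.rng.poisson(cfg.rec_per_bp * cfg.chrom_length_bp, size=(k, cfg.n_chrom))
        for gi, ci in zip(*np.nonzero(n_x)):
            lo, hi = self.chrom_bounds[ci], self.chrom_bounds[ci + 1]
            breaks = lo + self.rng.integers(1, cfg.chrom_length_bp, size=n_x[gi, ci])
            lim = np.searchsorted(self.pos, hi)
            for b in breaks:
                j = np.searchsorted(self.pos, b)
                choose[gi, j:lim] ^= 1
        return np.where(choose.astype(bool), H[2 * parents + 1], H[2 * parents])

    def mutate(self, pop: str):
        H = self.haps[pop]
        cfg = self.cfg
        n_new = self.rng.poisson(cfg.mu * cfg.genome_length * H.shape[0])
        if n_new == 0:
            return
        new_pos: list[int] = []
        need = n_new
        while need > 0:  # infinite sites: reject occupied/duplicate positions
            draw = self.rng.integers(0, cfg.genome_length, size=need)
            for p in draw:
                p = int(p)
                if p not in self.taken and p not in new_pos:
                    new_pos.append(p)
            need = n_new - len(new_pos)
        rows = self.rng.integers(0, H.shape[0], size=n_new)
        new_cls = self.mix_classes[
            self.rng.choice(len(self.mix_classes), size=n_new, p=self.mix_probs)
        ]
        self.add_sites(new_pos, new_cls, pop, rows)

    def step(self, sizes: dict, migration: dict | None, generation: int):
        """Advance every population one generation (sizes = next-gen sizes)."""
        fits = {p: self.fitness(p) for p in self.haps}
        for p, w in fits.items():
            if w.sum() == 0:
                raise ExtinctionError(
                    f"population {p} extinct (all-zero fitness) at generation {generation}"
                )
        probs = {p: w / w.sum() for p, w in fits.items()}
        new_haps = {}
        for p in self.haps:
            n_next = sizes[p]
            source = np.full(n_next, p, dtype=object)
            if migration and p in migration:
                for src, frac in migration[p].items():
                    mig = self.rng.random(n_next) < frac
                    source[mig] = src
            gam = np.empty((2 * n_next, len(self.pos)), dtype=np.uint8)
            for src in np.unique(source):
                rows = np.nonzero(source == src)[0]
                par = self.rng.choice(
                    len(probs[src]), size=(len(rows), 2), p=probs[src]
                )
                gam[2 * rows] = self.gametes(src, par[:, 0])
                gam[2 * rows + 1] = self.gametes(src, par[:, 1])
            new_haps[p] = gam
        self.haps = new_haps
        for p in self.haps:
            self.mutate(p)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_sfs(state: _State, n: int):
    """Seed standing variation from the neutral stationary SFS.

    Site count ~ Poisson(theta*L*sum 1/i); derived frequencies have density
    proportional to 1/i over allele counts i = 1..2n-1; alleles are assigned
    by sampling exactly i carriers per site (linkage equilibrium).
    """
    cfg, rng = state.cfg, state.rng
    theta_site = 4 * n * cfg.mu
    i = np.arange(1, 2 * n)
    weights = 1.0 / i
    n_sites = rng.poisson(theta_site * cfg.genome_length * weights.sum())
    pos = rng.choice(cfg.genome_length, size=min(n_sites, cfg.genome_length), replace=False)
    pos.sort()
    counts = i[rng.choice(len(i), size=len(pos), p=weights / weights.sum())]
    cls = state.mix_classes[
        rng.choice(len(state.mix_classes), size=len(pos), p=state.mix_probs)
    ]
    H = np.zeros((2 * n, len(pos)), dtype=np.uint8)
    for j, c in enumerate(counts):
        H[rng.choice(2 * n, size=c, replace=False), j] = 1
    state.pos = pos.astype(np.int64)
    state.cls = cls.astype(np.int8)
    state.taken = set(int(x) for x in pos)
    return H


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_scenario(config: ScenarioConfig, out_dir=None) -> SimulatedDataset:
    """Run the forward simulation described by ``config``.

    Returns an in-memory :class:`SimulatedDataset`; when ``out_dir`` is given,
    also writes ``sim.vcf`` (INFO: CLASS + AA), ``samples.tsv``,
    ``truth.tsv`` and ``scenario.json`` there. Bit-reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    state = _State(config, rng)

    n_anc = config.ne_ancestral
    if config.init == "sfs":
        state.haps["anc"] = _init_sfs(state, n_anc)
        burn = config.burn_in if config.burn_in is not None else n_anc
    elif config.init == "empty":
        state.haps["anc"] = np.zeros((2 * n_anc, 0), dtype=np.uint8)
        burn = config.burn_in if config.burn_in is not None else 20 * n_anc
    else:
        raise ValueError(f"unknown init mode {config.init!r}")

    for g in range(burn):
        state.step({"anc": n_anc}, None, generation=-(config.split_gen + burn - g))
        if g % 8 == 0:
            state.compact()
    state.compact()

    # split: daughters sample parents from the ancestral pool
    anc = state.haps.pop("anc")
    sizes = {}
    for pop, ne in config.ne_pops.items():
        picks = rng.choice(anc.shape[0] // 2, size=ne, replace=True)
        rows = np.empty(2 * ne, dtype=int)
        rows[0::2], rows[1::2] = 2 * picks, 2 * picks + 1
        state.haps[pop] = anc[rows].copy()
        sizes[pop] = ne
    del anc

    events = {}
    for pop, gen, size in config.bottleneck:
        events.setdefault(gen, []).append(("resize", pop, size))
    for pop, gen, k, label in config.founder_splits:
        events.setdefault(gen, []).append(("found", pop, k, label))

    m_start, m_end, m_ab, m_ba = config.migration_epoch
    pops = list(config.ne_pops)
    for gen in range(config.split_gen, 0, -1):  # gen = generations before present
        for ev in events.get(gen, []):
            if ev[0] == "resize":
                sizes[ev[1]] = ev[2]
            else:
                _, src, k, label = ev
                n_src = state.haps[src].shape[0] // 2
                if k > n_src:
                    raise ValueError(
                        f"founder split of {k} exceeds source size {n_src}"
                    )
                picks = rng.choice(n_src, size=k, replace=False)
                rows = np.empty(2 * k, dtype=int)
                rows[0::2], rows[1::2] = 2 * picks, 2 * picks + 1
                state.haps[label] = state.haps[src][rows].copy()
                sizes[label] = k
        migration = None
        if m_end <= gen <= m_start and len(pops) >= 2:
            a, b = pops[0], pops[1]
            migration = {b: {a: m_ab}, a: {b: m_ba}}
        state.step(sizes, migration, generation=gen)
        if gen % 8 == 0:
            state.compact()
    state.compact()

    return _collect(state, config, out_dir)


def _collect(state: _State, config: ScenarioConfig, out_dir) -> SimulatedDataset:
    """Sample individuals, build the VCF-shaped dataset and truth tables."""
    rng = state.rng
    samples, pops_of, geno_cols = [], {}, []
    for pop, n_want in config.sample_sizes.items():
        if pop not in state.haps:
            continue
        H = state.haps[pop]
        n_have = H.shape[0] // 2
        # sample living adults: survival to sampling age is fitness-weighted
        w = state.fitness(pop)
        p = w / w.sum() if w.sum() > 0 else None
        picks = rng.choice(n_have, size=min(n_want, n_have), replace=False, p=p)
        for j, ind in enumerate(sorted(picks)):
            name = f"{pop}_{j:02d}"
            samples.append(name)
            pops_of[name] = pop
            geno_cols.append(H[2 * ind].astype(np.int8) + H[2 * ind + 1])
    G = np.stack(geno_cols, axis=1) if geno_cols else np.empty((len(state.pos), 0), np.int8)
    seg = (G.sum(axis=1) > 0) & (G.sum(axis=1) < 2 * G.shape[1])
    G = G[seg]
    pos = state.pos[seg]
    cls = state.cls[seg]

    chrom_idx = np.searchsorted(state.chrom_bounds, pos, side="right") - 1
    bp = pos - state.chrom_bounds[chrom_idx] + 1
    chrom = np.array([f"chr{i + 1}" for i in chrom_idx])

    anc_idx = rng.integers(0, 4, size=len(pos))
    der_idx = (anc_idx + rng.integers(1, 4, size=len(pos))) % 4
    anc_base, der_base = _BASES[anc_idx], _BASES[der_idx]

    # a random "reference genome" haplotype may carry the derived allele:
    # flip REF/ALT with probability equal to the sample derived frequency
    freq = G.sum(axis=1) / (2 * max(G.shape[1], 1))
    flip = rng.random(len(pos)) < freq
    ref = np.where(flip, der_base, anc_base)
    alt = np.where(flip, anc_base, der_base)
    G = np.where(flip[:, None], 2 - G, G)
    derived_index = np.where(flip, 0, 1)  # which VCF allele is derived

    class_names = np.array(CLASSES)[cls]
    info = [
        {"CLASS": c, "AA": a} for c, a in zip(class_names, anc_base)
    ]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": bp,
            "ref": ref,
            "alt": alt,
            "qual": np.full(len(pos), 100.0),
            "info": info,
        }
    )
    gm = GenotypeMatrix(sites=sites, genotypes=G, samples=samples, populations=pops_of)
    truth = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": bp,
            "ancestral": anc_base,
            "derived": np.where(flip, ref, alt),
            "class": class_names,
            "derived_index": derived_index,
        }
    )
    sample_table = pd.DataFrame(
        {
            "sample": samples,
            "population": [pops_of[s] for s in samples],
            "effective_length": config.genome_length,
        }
    )
    ds = SimulatedDataset(gm=gm, truth=truth, sample_table=sample_table, config=config)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_vcf

        vcf = out / "sim.vcf"
        write_vcf(gm, vcf)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        sample_table.to_csv(out / "samples.tsv", sep="\t", index=False)
        cfg = asdict(config)
        with open(out / "scenario.json", "w") as fh:
            json.dump(cfg, fh, indent=2, default=str)
        ds.vcf_path = str(vcf)
    return ds


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def study_scenario(seed: int = 0, rescale: int = 256, rescale_r: float = 8.0) -> ScenarioConfig:
    """Desk-scale version of the two-population Eld's deer history.

    Nominal history: an ancestral population splits 18,192 generations ago
    (27,288 years at 1.5 yr/generation) into a mainland population A and an
    island population B; gene flow (0.0129 A->B, 0.0200 B->A per generation)
    persists through the first quarter after divergence; B crashes to 26
    individuals ~33 generations ago (1976), recovers, and seeds two founder
    groups of 19 and 22 translocated individuals. Mutation rate 2.11e-9 per
    site per generation, recombination 1.04 cM/Mb.

    Ne/time/mu/s/m are divided/multiplied by ``rescale``; recombination by
    ``rescale_r``. Events within the recent small-census epoch keep their
    literal generation times and census sizes (they are already desk-scale).
    """
    lam = rescale
    mu_nominal = 2.11e-9
    rec_nominal = 1.04
    ne_anc, ne_a, ne_b = 40_000, 40_000, 15_000
    split_nominal = 18_192
    split = max(int(round(split_nominal / lam)), 10)
    m_ab = min(0.0129 * lam, 0.45)
    m_ba = min(0.0200 * lam, 0.45)
    cfg = ScenarioConfig(
        n_chrom=8,
        chrom_length_bp=1_500_000,
        mu=mu_nominal * lam,
        rec_rate=rec_nominal * rescale_r,
        gen_time_years=1.5,
        ne_ancestral=max(ne_anc // lam, 10),
        split_gen=split,
        ne_pops={"A": max(ne_a // lam, 10), "B": max(ne_b // lam, 10)},
        migration_epoch=(split, split - max(split // 4, 1), m_ab, m_ba),
        bottleneck=[("B", 33, 26), ("B", 30, 90), ("B1", 24, 60), ("B2", 17, 60)],
        founder_splits=[("B", 27, 19, "B1"), ("B", 20, 22, "B2")],
        sel_coeff={
            "neutral": (0.0, 0.5),
            "synonymous": (0.0, 0.5),
            "missense_benign": (0.0, 0.5),
            "missense_deleterious": (-0.05, 0.5),
            "lof": (-0.4, 0.2),
        },
        sample_sizes={"A": 8, "B": 6, "B1": 6, "B2": 8},
        seed=seed,
        init="sfs",
        nominal={
            "mu": mu_nominal,
            "rec_rate_cM_per_Mb": rec_nominal,
            "ne_ancestral": ne_anc,
            "ne_pops": {"A": ne_a, "B": ne_b},
            "split_gen": split_nominal,
            "split_years": 27_288,
            "migration": {"A_to_B": 0.0129, "B_to_A": 0.0200},
            "sel_coeff": {"missense_deleterious": -0.05 / lam, "lof": -0.4 / lam},
            "rescale": lam,
            "rescale_r": rescale_r,
        },
    )
    return cfg


def simulate_pedigree_panel(
    n_founders: int = 30,
    n_sites: int = 10_000,
    seed: int = 0,
    maf_range=(0.1, 0.5),
):
    """Unlinked-site pedigree panel for relatedness calibration.

    Founders are drawn in Hardy-Weinberg proportions at independent sites;
    founder couples each produce one offspring by Mendelian transmission, and
    the first founder is duplicated. Returns ``(GenotypeMatrix, pairs)``
    where pairs maps relationship -> list of sample-id tuples.
    """
    rng = np.random.default_rng(seed)
    if n_founders % 2:
        raise ValueError("n_founders must be even (founders are paired)")
    p = rng.uniform(*maf_range, size=n_sites)
    fhap = rng.random((n_sites, n_founders, 2)) < p[:, None, None]
    names = [f"F{i:02d}" for i in range(n_founders)]
    cols = {n: fhap[:, i, :] for i, n in enumerate(names)}
    pairs = {"parent_offspring": [], "unrelated": [], "duplicate": []}
    for i in range(0, n_founders, 2):
        child = np.stack(
            [
                np.take_along_axis(
                    fhap[:, i, :], rng.integers(0, 2, n_sites)[:, None], axis=1
                )[:, 0],
                np.take_along_axis(
                    fhap[:, i + 1, :], rng.integers(0, 2, n_sites)[:, None], axis=1
                )[:, 0],
            ],
            axis=1,
        )
        cname = f"C{i // 2:02d}"
        cols[cname] = child
        pairs["parent_offspring"] += [(names[i], cname), (names[i + 1], cname)]
    cols["DUP00"] = cols[names[0]].copy()
    pairs["duplicate"].append((names[0], "DUP00"))
    for i in range(n_founders):
        for j in range(i + 1, n_founders):
            if j != i + 1 or i % 2 != 0:
                pairs["unrelated"].append((names[i], names[j]))
    samples = list(cols)
    G = np.stack([cols[s].sum(axis=1) for s in samples], axis=1).astype(np.int8)
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "qual": 100.0,
            "info": [{} for _ in range(n_sites)],
        }
    )
    gm = GenotypeMatrix(
        sites=sites, genotypes=G, samples=samples,
        populations={s: "PED" for s in samples},
    )
    return gm, pairs
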