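"""Synthetic GBS populations for testing the imputation pipeline.

The generator emulates the structure the analysis assumes: a founder
panel of diverse clones, a single generation of crosses producing large
full-sib and half-sib families, a site-frequency spectrum that
overrepresents low-frequency variants, and low heterogeneous read depth
where missing means zero reads.

Founder haplotypes are mosaics of ``k_ancestral`` base haplotypes with a
geometric segment-switch process, which induces distance-decaying LD
without a coalescent model.  Allele-B frequencies are Beta-distributed
(default Beta(0.3, 1.7), skewed low).  Gametes recombine with
Poisson(genetic_length) crossovers at uniform map positions.  Read
depths are Poisson with Gamma-distributed per-individual and per-site
rate multipliers, and reads carry allele B with the same ``p_B(g)`` the
inference likelihood assumes, so parameter-recovery tests are
well-posed.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .genolik import ErrorModel
from .io_vcf import AlleleDepthMatrix, Site

__all__ = [
    "FounderPool",
    "CrossPlan",
    "DepthModel",
    "SimConfig",
    "SyntheticDataset",
    "simulate_founders",
    "simulate_crosses",
    "simulate_reads",
    "generate_dataset",
    "breeding_program_preset",
]


@dataclasses.dataclass
class FounderPool:
    """Founder haplotypes (n_founders, 2, n_sites), positions, truth freqs."""

    haplotypes: np.ndarray
    positions: np.ndarray
    freqs: np.ndarray
    k_ancestral: int

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def genotypes(self) -> np.ndarray:
        """True founder genotypes, shape (n_sites, n_founders)."""
        return self.haplotypes.sum(axis=1).T.astype(np.int8)


@dataclasses.dataclass(frozen=True)
class Cross:
    parent1: int
    parent2: int
    n_offspring: int

    def __post_init__(self) -> None:
        if self.parent1 == self.parent2:
            raise ValueError("parents must be distinct")
        if self.n_offspring < 0:
            raise ValueError("n_offspring must be >= 0")


@dataclasses.dataclass
class CrossPlan:
    """List of (parent1, parent2, n_offspring) crosses."""

    crosses: list[Cross]

    @property
    def n_offspring(self) -> int:
        return sum(c.n_offspring for c in self.crosses)

    @property
    def parents(self) -> np.ndarray:
        return np.unique([(c.parent1, c.parent2) for c in self.crosses])


@dataclasses.dataclass(frozen=True)
class DepthModel:
    """Read-depth model: D ~ Poisson(lam * s_individual * r_site).

    Multipliers are Gamma with unit mean (shapes ``ind_shape`` and
    ``site_shape``); ``None`` disables that axis of heterogeneity.
    ``fixed=True`` makes every depth exactly ``lam`` (deep-genotyping
    configurations for calibration tests).
    """

    lam: float = 4.0
    ind_shape: float | None = 4.0
    site_shape: float | None = 2.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        for s in (self.ind_shape, self.site_shape):
            if s is not None and s <= 0:
                raise ValueError("Gamma shapes must be > 0")


def simulate_founders(n: int, n_sites: int, k_ancestral: int = 6,
                      freq_shape: tuple[float, float] = (0.3, 1.7),
                      switch_prob: float = 0.008,
                      chrom_length: int = 30_000_000,
                      seed=None) -> FounderPool:
    """Founder haplotypes as geometric mosaics of ancestral haplotypes.

    Allele-B frequencies come from Beta(``freq_shape``); ``k_ancestral``
    base haplotypes are drawn Bernoulli per frequency, and each founder
    haplotype switches its ancestral source with probability
    ``switch_prob`` per site (mean segment ``1/switch_prob`` sites),
    giving distance-decaying LD.  ``k_ancestral=1`` collapses all
    founders onto one haplotype.
    """
    if n < 1 or n_sites < 1 or k_ancestral < 1:
        raise ValueError("n, n_sites and k_ancestral must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(chrom_length, size=n_sites, replace=False)) + 1
    freqs = rng.beta(freq_shape[0], freq_shape[1], size=n_sites)
    ancestral = (rng.random((k_ancestral, n_sites)) < freqs).astype(np.int8)
    n_hap = 2 * n
    src = np.empty((n_hap, n_sites), dtype=np.intp)
    src[:, 0] = rng.integers(k_ancestral, size=n_hap)
    switch = rng.random((n_hap, n_sites)) < switch_prob
    fresh = rng.integers(k_ancestral, size=(n_hap, n_sites))
    for v in range(1, n_sites):
        src[:, v] = np.where(switch[:, v], fresh[:, v], src[:, v - 1])
    hap = ancestral[src, np.arange(n_sites)]
    return FounderPool(haplotypes=hap.reshape(n, 2, n_sites),
                       positions=positions, freqs=freqs,
                       k_ancestral=k_ancestral)


def _gamete(parent_haps: np.ndarray, map_frac: np.ndarray,
            genetic_length: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes."""
    n_cx = rng.poisson(genetic_length)
    start = rng.integers(2)
    if n_cx == 0:
        return parent_haps[start]
    breaks = np.sort(rng.random(n_cx))
    phase = (start + np.searchsorted(breaks, map_frac, side="left")) % 2
    return parent_haps[phase, np.arange(parent_haps.shape[1])]


def simulate_crosses(pool: FounderPool, plan: CrossPlan,
                     genetic_length: float = 1.0, seed=None) -> np.ndarray:
    """True offspring genotypes (n_sites, n_offspring) from a crossing plan.

    Each gamete carries Poisson(``genetic_length``) crossovers at
    positions uniform on the genetic map, taken proportional to physical
    position.  ``genetic_length=0`` transmits unrecombined parental
    haplotypes.
    """
    rng = np.random.default_rng(seed)
    pos = pool.positions.astype(float)
    span = pos[-1] - pos[0] if len(pos) > 1 else 1.0
    map_frac = (pos - pos[0]) / (span if span > 0 else 1.0)
    out = np.empty((pool.n_sites, plan.n_offspring), dtype=np.int8)
    j = 0
    for cross in plan.crosses:
        for p in (cross.parent1, cross.parent2):
            if not 0 <= p < pool.n_founders:
                raise ValueError(f"parent {p} not in the founder pool")
        for _ in range(cross.n_offspring):
            g1 = _gamete(pool.haplotypes[cross.parent1], map_frac,
                         genetic_length, rng)
            g2 = _gamete(pool.haplotypes[cross.parent2], map_frac,
                         genetic_length, rng)
            out[:, j] = g1 + g2
            j += 1
    return out


def simulate_reads(truth: np.ndarray, dm: DepthModel,
                   model: ErrorModel = ErrorModel(), seed=None,
                   sites: Sequence[Site] | None = None,
                   positions: np.ndarray | None = None,
                   samples: Sequence[str] | None = None,
                   chrom: str = "1") -> AlleleDepthMatrix:
    """Sample allelic read counts from true genotypes.

    Depth is Poisson(lam * s_d * r_v) (or exactly ``lam`` when the model
    is fixed); given depth D, ``N_B ~ Binomial(D, p_B(g))`` with the
    same ``p_B`` the genotype likelihood assumes, and ``N_A = D − N_B``.
    Zero-depth entries are the missing data.
    """
    truth = np.asarray(truth)
    n_sites, n_ind = truth.shape
    rng = np.random.default_rng(seed)
    if dm.fixed:
        depth = np.full(truth.shape, int(round(dm.lam)))
    else:
        s_d = rng.gamma(dm.ind_shape, 1.0 / dm.ind_shape, size=n_ind) \
            if dm.ind_shape is not None else np.ones(n_ind)
        r_v = rng.gamma(dm.site_shape, 1.0 / dm.site_shape, size=n_sites) \
            if dm.site_shape is not None else np.ones(n_sites)
        depth = rng.poisson(dm.lam * np.outer(r_v, s_d))
    p_b = model.p_b[truth.astype(np.intp)]
    n_b = rng.binomial(depth, p_b)
    depths = np.stack([depth - n_b, n_b], axis=-1).astype(np.int32)
    if sites is None:
        if positions is None:
            positions = np.arange(1, n_sites + 1) * 100
        sites = [Site(chrom, int(p), "A", "C") for p in positions]
    if samples is None:
        samples = [f"S{j + 1:04d}" for j in range(n_ind)]
    return AlleleDepthMatrix(sites=list(sites), samples=list(samples),
                             depths=depths)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic dataset.

    The default preset mimics a breeding-program study at desk scale: 200
    founders, 134 crosses among 82 parents with 8 offspring each (1072
    progeny), 2000 sites on one chromosome, mean read depth 4, error
    rate 0.01.
    """

    n_founders: int = 200
    n_parents: int = 82
    n_crosses: int = 134
    offspring_per_cross: int = 8
    n_sites: int = 2000
    k_ancestral: int = 6
    freq_shape: tuple[float, float] = (0.3, 1.7)
    switch_prob: float = 0.008
    genetic_length: float = 1.0
    chrom: str = "1"
    chrom_length: int = 30_000_000
    mean_depth: float = 4.0
    ind_depth_shape: float | None = 4.0
    site_depth_shape: float | None = 2.0
    fixed_depth: bool = False
    error_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_parents > self.n_founders:
            raise ValueError("n_parents cannot exceed n_founders")
        if self.n_crosses > self.n_parents * (self.n_parents - 1) // 2:
            raise ValueError("n_crosses exceeds the number of distinct pairs")
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["freq_shape"] = list(self.freq_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "freq_shape" in d:
            d["freq_shape"] = tuple(d["freq_shape"])
        return cls(**d)


def breeding_program_preset(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale preset shaped like a breeding-program GBS study
    (diverse founder panel plus one generation of crosses)."""
    return dataclasses.replace(SimConfig(seed=seed), **overrides)


@dataclasses.dataclass
class SyntheticDataset:
    """Generated population: truth, reads and the config that made them."""

    config: SimConfig
    pool: FounderPool
    plan: CrossPlan
    truth: np.ndarray  # (n_sites, n_founders + n_offspring)
    adm: AlleleDepthMatrix

    @property
    def founder_samples(self) -> list[str]:
        return self.adm.samples[: self.pool.n_founders]

    @property
    def offspring_samples(self) -> list[str]:
        return self.adm.samples[self.pool.n_founders:]

    @property
    def sib_pairs(self) -> list[tuple[int, int]]:
        """Full-sib pairs as column indices into the truth/adm matrices."""
        pairs = []
        j = self.pool.n_founders
        for cross in self.plan.crosses:
            for a in range(cross.n_offspring):
                for b in range(a + 1, cross.n_offspring):
                    pairs.append((j + a, j + b))
            j += cross.n_offspring
        return pairs


def _build_plan(cfg: SimConfig, rng: np.random.Generator) -> CrossPlan:
    parents = rng.choice(cfg.n_founders, size=cfg.n_parents, replace=False)
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < cfg.n_crosses:
        a, b = rng.choice(cfg.n_parents, size=2, replace=False)
        pair = (int(parents[min(a, b)]), int(parents[max(a, b)]))
        pairs.add(pair)
    crosses = [Cross(p1, p2, cfg.offspring_per_cross)
               for p1, p2 in sorted(pairs)]
    return CrossPlan(crosses=crosses)


def generate_dataset(config: SimConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset from a config.

    Independently seeded streams (founders, plan, meiosis, reads) are
    spawned from the config seed, so each stage is separately
    reproducible and two runs with one seed are identical.
    """
    cfg = config if config is not None else SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_found, s_plan, s_cross, s_reads = ss.spawn(4)

    pool = simulate_founders(cfg.n_founders, cfg.n_sites, cfg.k_ancestral,
                             cfg.freq_shape, cfg.switch_prob,
                             cfg.chrom_length, seed=s_found)
    plan = _build_plan(cfg, np.random.default_rng(s_plan))
    offspring = simulate_crosses(pool, plan, cfg.genetic_length, seed=s_cross)
    truth = np.hstack([pool.genotypes, offspring])

    samples = [f"GG{i + 1:04d}" for i in range(cfg.n_founders)] + \
              [f"C1-{j + 1:04d}" for j in range(plan.n_offspring)]
    dm = DepthModel(lam=cfg.mean_depth, ind_shape=cfg.ind_depth_shape,
                    site_shape=cfg.site_depth_shape, fixed=cfg.fixed_depth)
    adm = simulate_reads(truth, dm, ErrorModel(cfg.error_rate), seed=s_reads,
                         positions=pool.positions, samples=samples,
                         chrom=cfg.chrom)
    return SyntheticDataset(config=cfg, pool=pool, plan=plan, truth=truth,
                            adm=adm)


def write_dataset(ds: SyntheticDataset, out_dir,
                  reference_vcf: bool = True) -> dict[str, Path]:
    """Write study VCF, phased founder reference VCF, truth TSV, config echo."""
    from . import genolik, io_vcf  # deferred: io_vcf imports genolik

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["study_vcf"] = io_vcf.write_vcf(
        ds.adm, out / "study.vcf",
        error_model=ErrorModel(ds.config.error_rate))

    if reference_vcf:
        n_f = ds.pool.n_founders
        founder_adm = AlleleDepthMatrix(
            sites=list(ds.adm.sites), samples=ds.founder_samples,
            depths=ds.adm.depths[:, :n_f, :])
        haps = np.transpose(ds.pool.haplotypes, (2, 0, 1))  # sites x ind x 2
        ref_dos = genolik.DosageMatrix(
            ds.pool.genotypes.astype(float),
            sites=ds.adm.sites, samples=ds.founder_samples)
        paths["reference_vcf"] = io_vcf.write_vcf(
            founder_adm, out / "reference.vcf", dosages=ref_dos,
            phased=True, haplotypes=haps,
            error_model=ErrorModel(ds.config.error_rate))

    truth_dm = genolik.DosageMatrix(ds.truth.astype(float),
                                    sites=ds.adm.sites, samples=ds.adm.samples)
    paths["truth_tsv"] = io_vcf.write_dosage_tsv(truth_dm, out / "truth.tsv")

    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(ds.config.to_dict(), indent=2) + "\n")
    paths["config"] = cfg_path
    return paths
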