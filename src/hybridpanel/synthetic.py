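"""Synthetic data with the statistical structure of a diagnostic-panel study.

Emulates two long-diverged populations genotyped at ~50 biallelic markers
that are fixed or nearly fixed for alternative alleles (minor allele
frequencies 0-5%), sample sizes around 95-127 individuals per population,
and pooled resequencing with pools of 11-18 diploid individuals at ~11-12x
per-pool coverage.  Three frequency scenarios are supported:

* ``diagnostic``       - strictly fixed: pop A carries only allele_a,
                         pop B only allele_b;
* ``introgressing_maf``- fixed in pop A, while pop B carries the pop-A-type
                         allele at a small minor frequency (one-directional
                         leakage);
* ``symmetric_maf``    - both populations carry the other side's allele at a
                         small minor frequency.

Sampling assumes Hardy-Weinberg equilibrium and locus independence; every
stochastic operation takes an explicit integer seed (no hidden global RNG).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, Locus
from .selection import PoolCount, PooledSiteCounts

SCENARIOS = ("diagnostic", "introgressing_maf", "symmetric_maf")

#: realistic MAF envelope observed on validated panels (upper end 4.7%)
DEFAULT_MAF = 0.047
#: default study preset: marker and sample scale of the validated baseline
DEFAULT_N_LOCI = 50
DEFAULT_POP_SIZE = 95


@dataclass(frozen=True)
class FrequencyScenario:
    """Recipe for a two-population allele-frequency profile."""

    n_loci: int
    scenario: str = "diagnostic"
    m: float = 0.0
    maf_draw: str = "constant"  # "constant" or "uniform"

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario != "diagnostic" and not (0 <= self.m < 0.5):
            raise ValueError("MAF m must lie in [0, 0.5)")
        if self.maf_draw not in ("constant", "uniform"):
            raise ValueError("maf_draw must be 'constant' or 'uniform'")


@dataclass
class PopulationFrequencies:
    """Per-locus allele_b frequency for each population.

    This is the generative truth behind sampled genotype matrices and pooled
    count tables; the locus list is shared with anything sampled from it.
    """

    loci: list[Locus]
    pops: tuple[str, ...]
    freq_b: np.ndarray  # shape (n_pops, n_loci)

    def __post_init__(self) -> None:
        self.freq_b = np.asarray(self.freq_b, dtype=float)
        if self.freq_b.shape != (len(self.pops), len(self.loci)):
            raise ValueError("freq_b shape must be (n_pops, n_loci)")
        if ((self.freq_b < 0) | (self.freq_b > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def freq(self, pop: str) -> np.ndarray:
        try:
            return self.freq_b[self.pops.index(pop)]
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass(frozen=True)
class PoolSpec:
    """Layout of a pooled-resequencing experiment (per population)."""

    n_pools: int = 2
    individuals_per_pool: int = 18
    mean_depth: float = 12.0
    n_scaffolds: int = 50
    scaffold_lengths: tuple[int, ...] | None = None
    sites_per_scaffold: int = 1

    def __post_init__(self) -> None:
        if (self.n_pools <= 0 or self.individuals_per_pool <= 0
                or self.mean_depth <= 0 or self.n_scaffolds <= 0
                or self.sites_per_scaffold <= 0):
            raise ValueError("pool spec values must be positive")
        if (self.scaffold_lengths is not None
                and len(self.scaffold_lengths) != self.n_scaffolds):
            raise ValueError("scaffold_lengths must match n_scaffolds")


def default_loci(n_loci: int, sites_per_scaffold: int = 1,
                 scaffold_lengths: Sequence[int] | None = None) -> list[Locus]:
    """Deterministic locus layout: loci spread over scaffolds of strictly
    decreasing length (longest first), alleles A/C everywhere."""
    n_scaffolds = -(-n_loci // sites_per_scaffold)
    if scaffold_lengths is None:
        scaffold_lengths = [10_000_000 + (n_scaffolds - i) * 1_000
                            for i in range(n_scaffolds)]
    loci: list[Locus] = []
    for i in range(n_loci):
        scf = i // sites_per_scaffold
        site = i % sites_per_scaffold
        length = int(scaffold_lengths[scf])
        pos = (site + 1) * (length // (sites_per_scaffold + 1))
        loci.append(Locus(
            locus_id=f"L{i + 1:04d}",
            scaffold_id=f"scaffold{scf + 1:04d}",
            scaffold_length=length,
            position=max(1, pos),
        ))
    return loci


def site_layout(pool_spec: PoolSpec) -> list[Locus]:
    """Locus layout implied by a PoolSpec (n_scaffolds x sites_per_scaffold)."""
    return default_loci(
        pool_spec.n_scaffolds * pool_spec.sites_per_scaffold,
        sites_per_scaffold=pool_spec.sites_per_scaffold,
        scaffold_lengths=pool_spec.scaffold_lengths,
    )


def make_frequency_profile(spec: FrequencyScenario, seed: int,
                           pops: tuple[str, str] = ("A", "B"),
                           loci: Sequence[Locus] | None = None,
                           ) -> PopulationFrequencies:
    """Build a two-population frequency profile for a scenario.

    Deterministic given seed.  Diagnostic loci are strictly fixed
    (freq_b = 0 in pop A, 1 in pop B); MAF scenarios place minor alleles of
    frequency m (or Uniform(0, m) per locus) on the stated side(s).
    """
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = default_loci(spec.n_loci)
    elif len(loci) != spec.n_loci:
        raise ValueError("provided loci do not match n_loci")

    def draw_maf(size: int) -> np.ndarray:
        if spec.maf_draw == "constant":
            return np.full(size, spec.m)
        return rng.uniform(0.0, spec.m, size=size)

    fa = np.zeros(spec.n_loci)
    fb = np.ones(spec.n_loci)
    if spec.scenario == "introgressing_maf":
        fb = 1.0 - draw_maf(spec.n_loci)
    elif spec.scenario == "symmetric_maf":
        fa = draw_maf(spec.n_loci)
        fb = 1.0 - draw_maf(spec.n_loci)
    return PopulationFrequencies(list(loci), pops, np.vstack([fa, fb]))


def sample_population(freqs: PopulationFrequencies, pop: str, n: int,
                      missing_rate: float = 0.0, seed: int = 0,
                      id_prefix: str | None = None) -> GenotypeMatrix:
    """Sample n Hardy-Weinberg genotypes from one population's frequencies.

    Per locus the allele_b copy number is Binomial(2, freq_b); MISSING is
    applied i.i.d. at missing_rate.  Deterministic given seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    f = freqs.freq(pop)
    rng = np.random.default_rng(seed)
    calls = rng.binomial(2, f, size=(n, freqs.n_loci)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(size=calls.shape) < missing_rate] = MISSING
    prefix = id_prefix if id_prefix is not None else pop
    ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(freqs.loci, ids, [pop] * n, calls)


def generate_pooled_counts(
    freqs: PopulationFrequencies,
    pool_spec: PoolSpec,
    seed: int,
    pool_to_pop: Mapping[str, str] | None = None,
    two_stage: bool = True,
) -> list[PooledSiteCounts]:
    """Simulate pooled-sequencing allele counts at every locus of a profile.

    Default pool layout: ``n_pools`` pools per population, named e.g. "A1",
    "A2", "B1", "B2".  Per site and pool the model is two-stage: the pool's
    2 x individuals_per_pool allele copies are drawn from the population
    frequency, depth is Poisson(mean_depth), and each read draws an allele
    from the pool's copies -- so finite pool size inflates the read-frequency
    variance.  ``two_stage=False`` collapses this to a one-stage binomial on
    the population frequency.  Zero-depth sites are recorded, not dropped.
    """
    rng = np.random.default_rng(seed)
    if pool_to_pop is None:
        pool_to_pop = {f"{pop}{j + 1}": pop
                       for pop in freqs.pops
                       for j in range(pool_spec.n_pools)}
    m_copies = 2 * pool_spec.individuals_per_pool
    sites: list[PooledSiteCounts] = []
    for j, locus in enumerate(freqs.loci):
        pools: dict[str, PoolCount] = {}
        for pool_id, pop in pool_to_pop.items():
            f = float(freqs.freq(pop)[j])
            depth = int(rng.poisson(pool_spec.mean_depth))
            if two_stage:
                x = int(rng.binomial(m_copies, f))
                cb = int(rng.binomial(depth, x / m_copies)) if depth else 0
            else:
                cb = int(rng.binomial(depth, f)) if depth else 0
            pools[pool_id] = PoolCount(depth=depth, count_a=depth - cb, count_b=cb)
        sites.append(PooledSiteCounts(
            scaffold_id=locus.scaffold_id,
            scaffold_length=locus.scaffold_length,
            position=locus.position,
            pools=pools,
        ))
    return sites


def study_preset(seed: int, n_loci: int = DEFAULT_N_LOCI,
                 pop_size: int = DEFAULT_POP_SIZE,
                 m: float = DEFAULT_MAF,
                 scenario: str = "introgressing_maf",
                 missing_rate: float = 0.0,
                 ) -> tuple[PopulationFrequencies, GenotypeMatrix, GenotypeMatrix]:
    """Default study emulation: 50 loci, 95+95 individuals, one population
    fixed and the other carrying minor alleles uniform on (0, m].

    Returns (frequencies, pure_A_matrix, pure_B_matrix).
    """
    spec = FrequencyScenario(n_loci=n_loci, scenario=scenario, m=m,
                             maf_draw="uniform" if scenario != "diagnostic"
                             else "constant")
    rng = np.random.default_rng(seed)
    s_prof, s_a, s_b = rng.integers(0, 2**31 - 1, size=3)
    freqs = make_frequency_profile(spec, seed=int(s_prof))
    pure_a = sample_population(freqs, "A", pop_size, missing_rate, seed=int(s_a))
    pure_b = sample_population(freqs, "B", pop_size, missing_rate, seed=int(s_b))
    return freqs, pure_a, pure_b
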