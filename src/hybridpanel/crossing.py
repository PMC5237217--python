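"""In-silico Mendelian crossing: F1 hybrids, iterated reciprocal backcrosses,
and the labelled multi-category baseline.

Loci are treated as unlinked: a heterozygous parent transmits either allele
with probability 1/2 independently across loci; homozygotes transmit their
allele deterministically.  There is no mutation, so every offspring allele
exists in some parent.  A parent MISSING at a transmitting locus propagates
MISSING to the offspring (no imputation).

The backcross chain follows the standard design: F1 = pure A x pure B;
FgA = F(g-1)A x pure A (backcross *into* population A), and symmetrically
FgB.  Over fully diagnostic loci the heterozygous-marker count of an Fg
individual is Binomial(n, 2**(1-g)) -- the bridge to the binomial
generation classifier.
"""
from __future__ import annotations

import numpy as np

from .genotypes import (MISSING, GenotypeMatrix, PedigreeCategory,
                        PanelMismatchError, PURE_A, PURE_B)


def sample_gamete(genotype_row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete (per-locus allele_b copy, 0/1; -1 for missing).

    Homozygotes transmit their allele; heterozygotes transmit either allele
    with probability 1/2 independently per locus.
    """
    row = np.asarray(genotype_row, dtype=np.int8)
    gamete = np.where(row == 1,
                      rng.integers(0, 2, size=row.shape).astype(np.int8),
                      (row // 2).astype(np.int8))
    gamete[row == MISSING] = MISSING
    return gamete


def cross(parents_1: GenotypeMatrix, parents_2: GenotypeMatrix,
          n_offspring: int, seed: int, label: str = "CROSS") -> GenotypeMatrix:
    """Cross two parent pools: each offspring draws one uniformly random
    parent (with replacement) from each pool and one gamete from each."""
    if parents_1.n_individuals == 0 or parents_2.n_individuals == 0:
        raise ValueError("parent pools must be non-empty")
    if parents_1.locus_ids != parents_2.locus_ids:
        raise PanelMismatchError("parent pools must share the same locus panel")
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    rng = np.random.default_rng(seed)
    idx1 = rng.integers(0, parents_1.n_individuals, size=n_offspring)
    idx2 = rng.integers(0, parents_2.n_individuals, size=n_offspring)
    rows1 = parents_1.calls[idx1]
    rows2 = parents_2.calls[idx2]
    coin = lambda shape: rng.integers(0, 2, size=shape).astype(np.int8)
    g1 = np.where(rows1 == 1, coin(rows1.shape), rows1 // 2).astype(np.int8)
    g2 = np.where(rows2 == 1, coin(rows2.shape), rows2 // 2).astype(np.int8)
    calls = (g1 + g2).astype(np.int8)
    calls[(rows1 == MISSING) | (rows2 == MISSING)] = MISSING
    ids = [f"{label}_{i + 1:05d}" for i in range(n_offspring)]
    return GenotypeMatrix(parents_1.loci, ids, [label] * n_offspring, calls)


def simulate_category(pure_a: GenotypeMatrix, pure_b: GenotypeMatrix,
                      category: PedigreeCategory | str, n: int, seed: int,
                      chain_pool_size: int | None = None) -> GenotypeMatrix:
    """Simulate n individuals of a pedigree category, regenerating the
    intermediate generations of the backcross chain internally.

    ``chain_pool_size`` is the size of intermediate parent pools (defaults
    to n).  Offspring are labelled with the category name.
    """
    if isinstance(category, str):
        category = PedigreeCategory.from_name(category)
    if category.name == PURE_A:
        return pure_a.with_labels(PURE_A)
    if category.name == PURE_B:
        return pure_b.with_labels(PURE_B)
    if category.generation is None or category.generation < 1:
        raise ValueError(f"cannot simulate category {category.name!r}")
    pool = chain_pool_size or n
    seeds = np.random.SeedSequence(seed).generate_state(category.generation)
    current = cross(pure_a, pure_b,
                    pool if category.generation > 1 else n,
                    seed=int(seeds[0]) % 2**31, label="F1")
    recurrent = pure_a if category.direction == "A" else pure_b
    for g in range(2, (category.generation or 1) + 1):
        size = n if g == category.generation else pool
        current = cross(current, recurrent, size,
                        seed=int(seeds[g - 1]) % 2**31,
                        label=f"F{g}{category.direction}")
    return current


def baseline_categories(max_generation: int) -> list[str]:
    """Category names of the baseline: pures, F1, and reciprocal backcrosses
    up to max_generation (11 categories for max_generation=5)."""
    if max_generation < 2:
        raise ValueError("max_generation must be >= 2")
    cats = [PURE_A, PURE_B, "F1"]
    cats += [f"F{g}A" for g in range(2, max_generation + 1)]
    cats += [f"F{g}B" for g in range(2, max_generation + 1)]
    return cats


def build_baseline(pure_a: GenotypeMatrix, pure_b: GenotypeMatrix,
                   n_per_category: int = 100, max_generation: int = 5,
                   seed: int = 0) -> GenotypeMatrix:
    """Build the labelled baseline: the pure samples as given plus
    n_per_category simulated individuals for F1 and every backcross.

    The chain is built once per direction and reused (F3A offspring descend
    from the simulated F2A pool), mirroring the iterative design.
    """
    cats = baseline_categories(max_generation)
    seeds = np.random.SeedSequence(seed).generate_state(len(cats))
    parts = [pure_a.with_labels(PURE_A), pure_b.with_labels(PURE_B)]
    f1 = cross(pure_a, pure_b, n_per_category, seed=int(seeds[0]) % 2**31,
               label="F1")
    parts.append(f1)
    k = 1
    for direction, recurrent in (("A", pure_a), ("B", pure_b)):
        current = f1
        for g in range(2, max_generation + 1):
            current = cross(current, recurrent, n_per_category,
                            seed=int(seeds[k]) % 2**31, label=f"F{g}{direction}")
            parts.append(current)
            k += 1
    return GenotypeMatrix.concat(parts)
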