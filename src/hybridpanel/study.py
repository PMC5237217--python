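"""End-to-end simulated assignment study.

Reproduces the evaluation design of a diagnostic-panel validation: sample
two pure populations, build the reciprocal backcross baseline to F5 (11
categories), simulate fresh test cohorts for chosen categories, assign them
against the baseline, and summarise accuracy per category plus the
adjacency of misassignments along the backcross chain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import chain_distance, confusion_matrix
from .crossing import build_baseline, simulate_category
from .genotypes import GenotypeMatrix
from .synthetic import study_preset


@dataclass
class StudyResult:
    baseline: GenotypeMatrix
    test: GenotypeMatrix
    confusion: pd.DataFrame

    def percent_correct(self, categories: str | list[str]) -> float:
        """Percent of test individuals of the given true categories assigned
        to exactly their own category."""
        if isinstance(categories, str):
            categories = [categories]
        sub = self.confusion.loc[categories]
        total = int(sub.to_numpy().sum())
        correct = sum(int(self.confusion.loc[c, c]) for c in categories)
        if total == 0:
            raise ValueError(f"no test individuals in {categories}")
        return 100.0 * correct / total

    def adjacency_percent(self) -> float:
        """Percent of misassigned individuals whose assigned category is one
        step from the true one along the backcross chain."""
        mis = adjacent = 0
        for true_cat in self.confusion.index:
            for assigned in self.confusion.columns:
                if assigned == true_cat:
                    continue
                k = int(self.confusion.loc[true_cat, assigned])
                if k == 0:
                    continue
                mis += k
                if chain_distance(true_cat, assigned) == 1:
                    adjacent += k
        if mis == 0:
            return 100.0
        return 100.0 * adjacent / mis


def simulate_assignment_study(
    seed: int,
    n_loci: int = 50,
    pop_size: int = 95,
    m: float = 0.05,
    scenario: str = "introgressing_maf",
    n_per_category: int = 100,
    max_generation: int = 5,
    test_cohorts: dict[str, int] | None = None,
    method: str = "rannala_mountain",
) -> StudyResult:
    """Run the full synthetic assignment study.

    Defaults mirror the validated-panel regime: 50 markers, 95 individuals
    per pure population, one population fixed and the other carrying minor
    alleles uniform on (0, m], an 11-category baseline with 100 simulated
    individuals per hybrid category, and fresh test cohorts of F1/F2/F3
    backcrosses in both directions.
    """
    if test_cohorts is None:
        test_cohorts = {"F1": 200, "F2A": 250, "F2B": 250,
                        "F3A": 250, "F3B": 250}
    rng = np.random.default_rng(seed)
    preset_seed, baseline_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    freqs, pure_a, pure_b = study_preset(preset_seed, n_loci=n_loci,
                                         pop_size=pop_size, m=m,
                                         scenario=scenario)
    baseline = build_baseline(pure_a, pure_b, n_per_category=n_per_category,
                              max_generation=max_generation, seed=baseline_seed)
    parts = []
    for cat, n in test_cohorts.items():
        cat_seed = int(rng.integers(0, 2**31 - 1))
        sim = simulate_category(pure_a, pure_b, cat, n, seed=cat_seed)
        # keep ids globally unique across cohorts
        sim = GenotypeMatrix(sim.loci,
                             [f"test_{cat}_{i:05d}" for i in range(n)],
                             sim.labels, sim.calls)
        parts.append(sim)
    test = GenotypeMatrix.concat(parts)
    conf = confusion_matrix(test, baseline, method=method, leave_one_out=True)
    return StudyResult(baseline=baseline, test=test, confusion=conf)
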