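"""Per-locus diagnosticity assessment and per-individual marker scoring.

A marker panel separates two populations when each population is (nearly)
fixed for a different allele.  ``diagnose_panel`` orients every locus by the
majority allele in each population, estimates the minor allele frequency
(frequency of the *other* population's diagnostic allele) with an
Agresti-Coull confidence interval on allele copies, and flags loci as
"fully diagnostic" in the observed-data sense: no copy of the alternative
population's allele seen in the sample.  ``score_individual`` reduces a
genotype row to the heterozygote / local-homozygote / foreign-homozygote
counts that drive generation classification.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .genotypes import MISSING, GenotypeMatrix, Locus


def agresti_coull_ci(minor_count: int, n_trials: int,
                     confidence: float = 0.95) -> tuple[float, float, float]:
    """Agresti-Coull adjusted binomial estimate and confidence interval.

    p~ = (x + z^2/2) / (n + z^2), interval p~ +/- z*sqrt(p~(1-p~)/(n+z^2)),
    clamped to [0, 1].  Returns (point, lower, upper) where point is the
    adjusted estimate p~.
    """
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0 <= minor_count <= n_trials):
        raise ValueError("minor_count must lie in [0, n_trials]")
    z = norm.ppf(1 - (1 - confidence) / 2)
    n_adj = n_trials + z * z
    p = (minor_count + z * z / 2) / n_adj
    half = z * math.sqrt(p * (1 - p) / n_adj)
    return p, max(0.0, p - half), min(1.0, p + half)


@dataclass
class LocusDiagnosis:
    """Diagnosticity summary of one locus for a population pair."""

    locus_id: str
    #: allele each population is (nearly) fixed for
    diagnostic_allele_per_pop: dict[str, str]
    #: frequency of the opposite population's diagnostic allele
    observed_maf_per_pop: dict[str, float]
    maf_ci_per_pop: dict[str, tuple[float, float]]
    n_called_per_pop: dict[str, int]
    fully_diagnostic: bool
    flags: list[str] = field(default_factory=list)

    @property
    def orientable(self) -> bool:
        """True when the two populations favour different alleles."""
        a, b = self.diagnostic_allele_per_pop.values()
        return a != b and "all_missing" not in self.flags


@dataclass
class HetCounts:
    """Marker-class counts for one individual against an oriented panel."""

    individual_id: str
    n_obs: int
    k_het: int
    k_hom_local: int
    k_hom_foreign: int

    def __post_init__(self) -> None:
        if self.k_het + self.k_hom_local + self.k_hom_foreign != self.n_obs:
            raise ValueError("marker class counts must sum to n_obs")


def _allele_copies(matrix: GenotypeMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (copies of allele_b, total called copies) over given rows."""
    calls = matrix.calls[rows]
    called = calls != MISSING
    copies_b = np.where(called, calls, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return copies_b.astype(int), total.astype(int)


def diagnose_panel(matrix: GenotypeMatrix, pop_a: str, pop_b: str,
                   confidence: float = 0.95) -> list[LocusDiagnosis]:
    """Assess every locus of a two-population genotype matrix.

    The diagnostic allele of each population is its majority allele (ties
    broken toward allele_a, deterministically); the observed MAF in a
    population is the frequency of the other population's diagnostic allele;
    its CI is Agresti-Coull on allele copies (2 x called individuals).
    Loci with an uncallable population are flagged, never silently dropped.
    """
    labels = np.asarray(matrix.labels)
    rows = {pop: np.flatnonzero(labels == pop) for pop in (pop_a, pop_b)}
    for pop, r in rows.items():
        if r.size == 0:
            raise ValueError(f"population label {pop!r} absent from matrix")
    copies = {pop: _allele_copies(matrix, r) for pop, r in rows.items()}

    out: list[LocusDiagnosis] = []
    for j, locus in enumerate(matrix.loci):
        diag: dict[str, str] = {}
        flags: list[str] = []
        for pop in (pop_a, pop_b):
            b_copies, total = copies[pop][0][j], copies[pop][1][j]
            if total == 0:
                flags.append("all_missing")
                diag[pop] = locus.allele_a
            else:
                # majority allele; exact ties fall to allele_a
                diag[pop] = locus.allele_b if b_copies * 2 > total else locus.allele_a
        maf: dict[str, float] = {}
        ci: dict[str, tuple[float, float]] = {}
        ncall: dict[str, int] = {}
        minor_seen = 0
        for pop, other in ((pop_a, pop_b), (pop_b, pop_a)):
            b_copies, total = copies[pop][0][j], copies[pop][1][j]
            ncall[pop] = total // 2
            if total == 0:
                maf[pop] = float("nan")
                ci[pop] = (0.0, 1.0)
                continue
            other_allele = diag[other]
            if other_allele == locus.allele_b:
                x = int(b_copies)
            else:
                x = int(total - b_copies)
            if diag[pop] == diag[other]:
                # no diagnostic contrast at this locus; MAF defined as the
                # overall minor-allele frequency instead
                x = min(x, total - x)
            maf[pop] = x / total
            _, lo, hi = agresti_coull_ci(x, total, confidence)
            ci[pop] = (lo, hi)
            minor_seen += x
        fully = (minor_seen == 0 and diag[pop_a] != diag[pop_b]
                 and "all_missing" not in flags)
        if diag[pop_a] == diag[pop_b] and "all_missing" not in flags:
            flags.append("not_orientable")
        out.append(LocusDiagnosis(
            locus_id=locus.locus_id,
            diagnostic_allele_per_pop=diag,
            observed_maf_per_pop=maf,
            maf_ci_per_pop=ci,
            n_called_per_pop=ncall,
            fully_diagnostic=fully,
            flags=flags,
        ))
    return out


def score_individual(calls: np.ndarray, loci: Sequence[Locus],
                     diagnosis: Sequence[LocusDiagnosis], local_pop: str,
                     individual_id: str = "") -> HetCounts:
    """Count heterozygous / local-homozygous / foreign-homozygous markers.

    MISSING calls are excluded from n_obs; loci lacking a diagnostic
    orientation are excluded with a warning.
    """
    by_id = {d.locus_id: d for d in diagnosis}
    n_obs = k_het = k_local = k_foreign = 0
    for j, locus in enumerate(loci):
        d = by_id.get(locus.locus_id)
        if d is None or not d.orientable:
            warnings.warn(f"locus {locus.locus_id}: no diagnostic orientation, "
                          "excluded from scoring")
            continue
        code = int(calls[j])
        if code == MISSING:
            continue
        n_obs += 1
        if code == 1:
            k_het += 1
            continue
        allele = locus.allele_a if code == 0 else locus.allele_b
        if allele == d.diagnostic_allele_per_pop[local_pop]:
            k_local += 1
        else:
            k_foreign += 1
    return HetCounts(individual_id=individual_id, n_obs=n_obs, k_het=k_het,
                     k_hom_local=k_local, k_hom_foreign=k_foreign)


def score_matrix(matrix: GenotypeMatrix, diagnosis: Sequence[LocusDiagnosis],
                 local_pop: str) -> list[HetCounts]:
    """Score every individual of a matrix against an oriented panel."""
    return [
        score_individual(matrix.calls[i], matrix.loci, diagnosis, local_pop,
                         individual_id=iid)
        for i, iid in enumerate(matrix.individual_ids)
    ]
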