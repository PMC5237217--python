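"""Likelihood-based assignment of individuals to baseline categories.

Two likelihood computations are provided, both operating on a labelled
baseline genotype matrix whose categories (pure species plus hybrid and
backcross classes) define empirical allele frequencies per locus:

* ``empirical_ml_assign`` -- conditional maximum likelihood: the genotype
  probability under Hardy-Weinberg at the category's empirical allele
  frequencies, with zero frequencies floored at 1/(2N+1);
* ``rannala_mountain_assign`` -- the Bayesian predictive computation of
  Rannala & Mountain: the individual's two allele copies are drawn
  sequentially from the Dirichlet-multinomial posterior with prior 1/K per
  allele (K = 2) added to the observed category counts.

Scores are reported as the best category's likelihood as a percentage of
the summed likelihoods over all candidate categories.  Leave-one-out
removes the tested individual's own allele copies from its category before
computing frequencies, for unbiased self-assignment of baseline members.

``estimate_hybrid_index`` is a deterministic maximum-likelihood admixture
proportion (q) estimator -- an explicitly labelled stand-in for MCMC
admixture clustering, which this package does not reimplement.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

_CHAIN_ORDER = ["PUREA", "F5A", "F4A", "F3A", "F2A", "F1",
                "F2B", "F3B", "F4B", "F5B", "PUREB"]


@dataclass
class AssignmentResult:
    individual_id: str
    best_category: str
    score_percent: float
    log_likelihoods: dict[str, float]

    def score_percentages(self) -> dict[str, float]:
        """Per-category likelihood percentages (sum to 100)."""
        lls = np.array(list(self.log_likelihoods.values()), dtype=float)
        finite = lls[np.isfinite(lls)]
        if finite.size == 0:
            raise ValueError("no finite likelihood in any category")
        shifted = np.exp(lls - finite.max())
        pct = 100.0 * shifted / shifted.sum()
        return dict(zip(self.log_likelihoods.keys(), pct))


@dataclass
class _BaselineCounts:
    """Per-category allele_b copies and total called copies per locus."""

    categories: list[str]
    copies_b: dict[str, np.ndarray]
    copies_total: dict[str, np.ndarray]
    member_category: dict[str, str]  # individual id -> category

    @classmethod
    def from_matrix(cls, baseline: GenotypeMatrix) -> "_BaselineCounts":
        labels = np.asarray(baseline.labels)
        categories: list[str] = []
        for lab in baseline.labels:
            if lab not in categories:
                categories.append(lab)
        copies_b: dict[str, np.ndarray] = {}
        copies_total: dict[str, np.ndarray] = {}
        for cat in categories:
            calls = baseline.calls[labels == cat]
            called = calls != MISSING
            copies_b[cat] = np.where(called, calls, 0).sum(axis=0).astype(float)
            copies_total[cat] = 2.0 * called.sum(axis=0)
        member = dict(zip(baseline.individual_ids, baseline.labels))
        return cls(categories, copies_b, copies_total, member)

    def adjusted(self, cat: str, row: np.ndarray | None
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Counts for a category, optionally with one member's copies removed."""
        nb, nt = self.copies_b[cat], self.copies_total[cat]
        if row is None:
            return nb, nt
        called = row != MISSING
        nb = nb - np.where(called, row, 0)
        nt = nt - 2.0 * called
        if (nb < 0).any() or (nt < 0).any():  # pragma: no cover
            raise RuntimeError("leave-one-out produced negative counts")
        return nb, nt


def _genotype_loglik_hwe(row: np.ndarray, nb: np.ndarray, nt: np.ndarray) -> float:
    """HWE genotype log-likelihood at empirical frequencies, floored zeros."""
    called = row != MISSING
    if not called.any():
        raise ValueError("individual has no called loci")
    ll = 0.0
    skipped = 0
    for j in np.flatnonzero(called):
        if nt[j] == 0:
            skipped += 1
            continue
        n_ind = nt[j] / 2.0
        floor = 1.0 / (nt[j] + 1.0)
        p = min(max(nb[j] / nt[j], floor), 1.0 - floor)
        g = int(row[j])
        if g == 0:
            ll += 2 * math.log(1 - p)
        elif g == 1:
            ll += math.log(2 * p * (1 - p))
        else:
            ll += 2 * math.log(p)
    if skipped:
        warnings.warn(f"{skipped} loci skipped: category has no called alleles")
    return ll


def _genotype_loglik_rm(row: np.ndarray, nb: np.ndarray, nt: np.ndarray,
                        tau: float = 0.5) -> float:
    """Rannala-Mountain predictive genotype log-likelihood.

    Sequential draws from the Dirichlet(tau, tau) posterior updated with the
    category's allele counts: P(first=b) = (n_b+tau)/(n+2*tau), then the
    drawn copy is added before the second draw.
    """
    called = row != MISSING
    if not called.any():
        raise ValueError("individual has no called loci")
    ll = 0.0
    for j in np.flatnonzero(called):
        n_b, n = nb[j], nt[j]
        n_a = n - n_b
        denom = (n + 2 * tau) * (n + 1 + 2 * tau)
        g = int(row[j])
        if g == 0:
            like = (n_a + tau) * (n_a + 1 + tau) / denom
        elif g == 2:
            like = (n_b + tau) * (n_b + 1 + tau) / denom
        else:
            like = 2 * (n_a + tau) * (n_b + tau) / denom
        ll += math.log(like)
    return ll


def _assign(row: np.ndarray, individual_id: str, counts: _BaselineCounts,
            method: str, leave_one_out: bool) -> AssignmentResult:
    own_cat = counts.member_category.get(individual_id) if leave_one_out else None
    lls: dict[str, float] = {}
    for cat in counts.categories:
        nb, nt = counts.adjusted(cat, row if cat == own_cat else None)
        if method == "empirical":
            lls[cat] = _genotype_loglik_hwe(row, nb, nt)
        else:
            lls[cat] = _genotype_loglik_rm(row, nb, nt)
    best = max(lls, key=lambda c: lls[c])
    result = AssignmentResult(individual_id, best, 0.0, lls)
    result.score_percent = result.score_percentages()[best]
    return result


def empirical_ml_assign(individual: np.ndarray, baseline: GenotypeMatrix,
                        leave_one_out: bool = False,
                        individual_id: str = "") -> AssignmentResult:
    """Assign one genotype row by conditional ML at empirical frequencies."""
    counts = _BaselineCounts.from_matrix(baseline)
    return _assign(np.asarray(individual, dtype=np.int8), individual_id,
                   counts, "empirical", leave_one_out)


def rannala_mountain_assign(individual: np.ndarray, baseline: GenotypeMatrix,
                            leave_one_out: bool = False,
                            individual_id: str = "") -> AssignmentResult:
    """Assign one genotype row by the Rannala-Mountain Bayesian computation."""
    counts = _BaselineCounts.from_matrix(baseline)
    return _assign(np.asarray(individual, dtype=np.int8), individual_id,
                   counts, "rannala_mountain", leave_one_out)


def assign_matrix(test: GenotypeMatrix, baseline: GenotypeMatrix,
                  method: str = "rannala_mountain",
                  leave_one_out: bool = False) -> list[AssignmentResult]:
    """Assign every individual of a test matrix (shared baseline pass)."""
    if method not in ("empirical", "rannala_mountain"):
        raise ValueError(f"unknown method {method!r}")
    if test.locus_ids != baseline.locus_ids:
        test = test.subset_loci(baseline.locus_ids)
    counts = _BaselineCounts.from_matrix(baseline)
    return [
        _assign(test.calls[i], iid, counts, method, leave_one_out)
        for i, iid in enumerate(test.individual_ids)
    ]


def confusion_matrix(test: GenotypeMatrix, baseline: GenotypeMatrix,
                     method: str = "rannala_mountain",
                     leave_one_out: bool = False) -> pd.DataFrame:
    """True-category x assigned-category counts (correct on the diagonal)."""
    results = assign_matrix(test, baseline, method, leave_one_out)
    true_cats = [c for c in dict.fromkeys(test.labels)]
    base_cats: list[str] = list(dict.fromkeys(baseline.labels))
    missing = set(true_cats) - set(base_cats)
    if missing:
        raise ValueError(f"test categories absent from baseline: {sorted(missing)}")
    order = [c for c in _CHAIN_ORDER if c in base_cats]
    order += [c for c in base_cats if c not in order]
    table = pd.DataFrame(0, index=[c for c in order if c in true_cats],
                         columns=order, dtype=int)
    for lab, res in zip(test.labels, results):
        table.loc[lab, res.best_category] += 1
    return table


def chain_distance(cat_1: str, cat_2: str) -> int:
    """Steps between categories along the backcross chain ordering
    PUREA, F5A..F2A, F1, F2B..F5B, PUREB (misassignments one step away are
    'adjacent')."""
    try:
        return abs(_CHAIN_ORDER.index(cat_1) - _CHAIN_ORDER.index(cat_2))
    except ValueError:
        raise KeyError(f"category outside the F5 chain: {cat_1!r} or {cat_2!r}")


@dataclass
class AdmixtureEstimate:
    individual_id: str
    q: float
    ci: tuple[float, float]


def estimate_hybrid_index(individual: np.ndarray, freqs_a: np.ndarray,
                          freqs_b: np.ndarray, individual_id: str = "",
                          grid: int = 2001) -> AdmixtureEstimate:
    """Maximum-likelihood admixture proportion q (ancestry from population A).

    Deterministic stand-in for an MCMC admixture-proportion estimate: q
    maximises the product over called loci of HWE genotype probabilities at
    the per-locus mixture frequency q*p_A + (1-q)*p_B; the 95% CI is the
    profile-likelihood region within 1.92 log units of the maximum.
    """
    row = np.asarray(individual, dtype=np.int8)
    called = row != MISSING
    if not called.any():
        raise ValueError("individual has no called loci")
    pa = np.asarray(freqs_a, dtype=float)[called]
    pb = np.asarray(freqs_b, dtype=float)[called]
    g = row[called].astype(float)
    qs = np.linspace(0.0, 1.0, grid)
    eps = 1e-12
    p = np.clip(qs[:, None] * pa[None, :] + (1 - qs[:, None]) * pb[None, :],
                eps, 1 - eps)
    ll = (g[None, :] * np.log(p) + (2 - g[None, :]) * np.log(1 - p))
    ll += np.where(g[None, :] == 1, math.log(2), 0.0)
    ll = ll.sum(axis=1)
    best = int(np.argmax(ll))
    inside = np.flatnonzero(ll >= ll[best] - 1.92)
    return AdmixtureEstimate(
        individual_id=individual_id,
        q=float(qs[best]),
        ci=(float(qs[inside.min()]), float(qs[inside.max()])),
    )
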