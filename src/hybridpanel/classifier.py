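"""Binomial maximum-likelihood classification of hybrid generation from
heterozygous-marker counts.

On a panel of n diagnostic markers, an individual whose ancestry is a pure
backcross chain of generation g (F1: g=1) is heterozygous at each marker
independently with probability p_g; the heterozygote count k is therefore
Binomial(n, p_g) and generations can be compared by likelihood.  Per-marker
heterozygosity under the three allele-fixedness scenarios:

* diagnostic:        p_g = 2**(1-g)                       (f_g itself)
* introgressing MAF: p_g = 2**(1-g) * (1-m)               (the foreign
  chromosome may carry the local-type allele at frequency m)
* symmetric MAF:     p_g = f_g*(1-h) + (1-f_g)*h, h = 2m(1-m)  (either
  lineage may be heterozygous by residual polymorphism)

Native (unadmixed) individuals have p = 0 (diagnostic/introgressing) or
p = h (symmetric).  Classification intervals partition 0..n by pairwise
likelihood-ratio crossings; the F1 boundary uses an explicit convention
(see ``classification_table``) because p_1 = 1 collapses the F1 likelihood
to a point mass at k = n.

Dual-ancestry (hybrid x hybrid) detection rests on a different signal: the
offspring of two hybrids shows homozygote markers specific to *both*
ancestral populations, which no pure backcross chain can produce on a fully
diagnostic panel.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .panel import HetCounts

NATIVE = "Native"


@dataclass(frozen=True)
class HetModel:
    """Binomial heterozygote-count model over a diagnostic panel."""

    n: int
    scenario: str = "diagnostic"
    m: float = 0.0
    max_generation: int = 8

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("panel size n must be >= 1")
        if self.scenario not in ("diagnostic", "introgressing_maf", "symmetric_maf"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario != "diagnostic" and not (0 <= self.m < 0.5):
            raise ValueError("MAF m must lie in [0, 0.5)")
        if self.max_generation < 1:
            raise ValueError("max_generation must be >= 1")

    @property
    def p_native(self) -> float:
        if self.scenario == "symmetric_maf":
            return 2 * self.m * (1 - self.m)
        return 0.0

    def categories(self) -> list[str]:
        return [NATIVE] + [f"F{g}" for g in range(1, self.max_generation + 1)]


def het_probability(g: int, model: HetModel) -> float:
    """Per-marker heterozygosity probability of generation g under a model."""
    if g < 1:
        raise ValueError("generation must be >= 1")
    f_g = 2.0 ** (1 - g)
    if model.scenario == "diagnostic":
        return f_g
    if model.scenario == "introgressing_maf":
        return f_g * (1 - model.m)
    h = 2 * model.m * (1 - model.m)
    return f_g * (1 - h) + (1 - f_g) * h


def _category_probability(category: str, model: HetModel) -> float:
    if category == NATIVE:
        return model.p_native
    return het_probability(int(category[1:]), model)


def _pmf(k: int, n: int, p: float) -> float:
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    return float(binom.pmf(k, n, p))


@dataclass(frozen=True)
class ClassificationInterval:
    category: str
    k_lo: int | None  # None marks an empty interval ("never most likely")
    k_hi: int | None
    prob_correct: float

    @property
    def empty(self) -> bool:
        return self.k_lo is None


@dataclass
class ClassificationTable:
    """Partition of heterozygote counts 0..n into generation intervals."""

    model: HetModel
    intervals: list[ClassificationInterval]
    _owner: dict[int, str] = field(repr=False, default_factory=dict)

    def interval(self, category: str) -> ClassificationInterval:
        for iv in self.intervals:
            if iv.category == category:
                return iv
        raise KeyError(category)

    def category_for(self, k: int) -> str:
        if not (0 <= k <= self.model.n):
            raise ValueError(f"k={k} outside 0..{self.model.n}")
        return self._owner[k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv in self.intervals:
            rows.append({
                "category": iv.category,
                "from": iv.k_lo if not iv.empty else pd.NA,
                "to": iv.k_hi if not iv.empty else pd.NA,
                "prob_correct": iv.prob_correct,
                "note": "never most likely" if iv.empty else "",
            })
        return pd.DataFrame(rows)


def f1_lower_bound(n: int) -> int:
    """F1/F2 boundary convention: ceil(n / sqrt(2)).

    Pure maximum likelihood degenerates at F1 because p_1 = 1 makes
    L(F1, k) = 0 for every k < n; the geometric mean of the adjacent
    expected counts n and n/2 gives a boundary (36 for n = 50) applied in
    every scenario.  This is a convention, not a derivation.
    """
    return math.ceil(n / math.sqrt(2))


def classification_table(model: HetModel) -> ClassificationTable:
    """Build the classification-interval table for a model.

    For k below the F1 boundary the owner is the maximum-likelihood category
    among F2..Fmax and Native (pairwise binomial likelihood crossings); ties
    go to the lower (more recent) generation, with Native losing ties.
    prob_correct(c) = P(Binomial(n, p_c) in interval_c).
    """
    n = model.n
    f1_lo = min(f1_lower_bound(n), n)
    competitors = [f"F{g}" for g in range(2, model.max_generation + 1)] + [NATIVE]
    probs = {c: _category_probability(c, model) for c in competitors}
    probs["F1"] = het_probability(1, model)

    owner: dict[int, str] = {}
    for k in range(0, f1_lo):
        best, best_l = None, -1.0
        for c in competitors:  # ordered F2..Fmax, Native: ties keep first
            like = _pmf(k, n, probs[c])
            if like > best_l + 1e-15:
                best, best_l = c, like
        owner[k] = best
    for k in range(f1_lo, n + 1):
        owner[k] = "F1"

    intervals: list[ClassificationInterval] = []
    for c in model.categories():
        ks = [k for k in range(n + 1) if owner[k] == c]
        if not ks:
            intervals.append(ClassificationInterval(c, None, None, 0.0))
            continue
        lo, hi = min(ks), max(ks)
        if ks != list(range(lo, hi + 1)):
            raise RuntimeError(
                f"non-contiguous interval for {c}: {ks}")  # pragma: no cover
        p = probs[c] if c != "F1" else probs["F1"]
        if p in (0.0, 1.0):
            target = 0 if p == 0.0 else n
            pc = 1.0 if lo <= target <= hi else 0.0
        else:
            pc = float(binom.cdf(hi, n, p) - (binom.cdf(lo - 1, n, p) if lo else 0.0))
        intervals.append(ClassificationInterval(c, lo, hi, pc))
    return ClassificationTable(model=model, intervals=intervals, _owner=owner)


def log_likelihoods(k: int, model: HetModel) -> dict[str, float]:
    """Log-likelihood of heterozygote count k under every category."""
    out = {}
    for c in model.categories():
        p = _category_probability(c, model)
        like = _pmf(k, model.n, p)
        out[c] = math.log(like) if like > 0 else -math.inf
    return out


def classify(counts: HetCounts, model: HetModel) -> tuple[str, dict[str, float]]:
    """Classify an individual's heterozygote count by its interval owner.

    The table is computed at n = n_obs (missing markers shrink the panel
    rather than rescaling k).  Returns (category, per-category
    log-likelihoods).
    """
    if counts.n_obs < 1:
        raise ValueError("cannot classify an individual with no called markers")
    if counts.k_het > counts.n_obs:
        raise ValueError("k_het exceeds n_obs")
    m = model if model.n == counts.n_obs else replace(model, n=counts.n_obs)
    table = classification_table(m)
    return table.category_for(counts.k_het), log_likelihoods(counts.k_het, m)


# ---------------------------------------------------------------------------
# dual-ancestry (hybrid x hybrid) detection
# ---------------------------------------------------------------------------

def dual_ancestry_expected_fractions(g: int) -> tuple[float, float, float]:
    """Expected (hom-local, het, hom-foreign) marker fractions for the
    offspring of two independent generation-g hybrids (FgxFg cross) on a
    fully diagnostic panel.

    Computed by exact enumeration of parental marker states: along a pure
    backcross chain each parent is heterozygous with probability
    h = 2**(1-g) and homozygous local otherwise, and transmits each allele
    of a heterozygous marker with probability 1/2.
    """
    if g < 1:
        raise ValueError("generation must be >= 1")
    h = 2.0 ** (1 - g)
    parent_states = [(h, 0.5), (1 - h, 0.0)]  # (P(state), P(transmit foreign))
    hom_local = het = hom_foreign = 0.0
    for p1, t1 in parent_states:
        for p2, t2 in parent_states:
            w = p1 * p2
            hom_foreign += w * t1 * t2
            hom_local += w * (1 - t1) * (1 - t2)
            het += w * (t1 * (1 - t2) + (1 - t1) * t2)
    return hom_local, het, hom_foreign


@dataclass(frozen=True)
class DualAncestryResult:
    flagged: bool
    #: expected (hom-local, het, hom-foreign) fractions for named crosses
    expected_fractions: dict[str, tuple[float, float, float]]
    #: P(a pure backcross shows >= k_hom_foreign foreign homozygotes)
    tail_probability: float


def dual_ancestry_test(counts: HetCounts, model: HetModel) -> DualAncestryResult:
    """Flag mixed (hybrid x hybrid) ancestry from homozygote classes.

    On a fully diagnostic panel a pure backcross chain can never produce a
    foreign homozygote, so any individual showing homozygotes specific to
    both ancestral populations carries dual ancestry.
    """
    if model.scenario != "diagnostic":
        raise ValueError("dual-ancestry test is defined for diagnostic panels")
    flagged = counts.k_hom_foreign > 0 and counts.k_hom_local > 0
    expected = {f"F{g}xF{g}": dual_ancestry_expected_fractions(g) for g in (1, 2)}
    tail = 0.0 if counts.k_hom_foreign > 0 else 1.0
    return DualAncestryResult(flagged=flagged, expected_fractions=expected,
                              tail_probability=tail)


def dual_detection_probability(n: int, t: int, cross: str = "F1xF1") -> float:
    """P(both ancestral homozygote counts reach >= t) for an FgxFg offspring
    over n fully diagnostic markers, by exact trinomial summation.
    """
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    if t > n:
        return 0.0
    if t == 0:
        return 1.0
    g = int(cross.split("x")[0][1:])
    p_local, p_het, p_foreign = dual_ancestry_expected_fractions(g)
    total = 0.0
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    for k_local in range(t, n + 1):
        for k_foreign in range(t, n - k_local + 1):
            k_het = n - k_local - k_foreign
            logp = (log_fact[n] - log_fact[k_local] - log_fact[k_foreign]
                    - log_fact[k_het]
                    + k_local * math.log(p_local)
                    + k_foreign * math.log(p_foreign)
                    + (k_het * math.log(p_het) if k_het else 0.0))
            total += math.exp(logp)
    return total
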