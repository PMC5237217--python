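"""Candidate diagnostic-SNP selection from pooled-sequencing allele counts.

Pooled resequencing yields per-site allele read counts for each DNA pool,
not individual genotypes.  Selection proceeds in the order the screening
strategy prescribes: keep sites with unexceptional coverage, score the
between-group frequency contrast, restrict to the longest scaffolds (a proxy
for genomic spread, hence marker independence), and keep the top few sites
per scaffold.

The per-site score here is a declared SURROGATE for the expected SNP
information value (ESIV) of the original pooled-screening tool, whose
formula is not public: the lower 95% confidence bound (Agresti-Coull on
read counts) of the absolute between-group allele-frequency difference,
truncated at zero.  It is monotone in both the frequency contrast and the
sequencing depth, and is a plug-in point (`score_fn`) so a faithful ESIV
can replace it.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .panel import agresti_coull_ci


@dataclass(frozen=True)
class PoolCount:
    """Read tally for one sequencing pool at one site."""

    depth: int
    count_a: int
    count_b: int

    def __post_init__(self) -> None:
        if min(self.depth, self.count_a, self.count_b) < 0:
            raise ValueError("negative read counts")
        if self.count_a + self.count_b > self.depth:
            raise ValueError("allele counts exceed depth")


@dataclass
class PooledSiteCounts:
    """Per-site allele tallies across sequencing pools."""

    scaffold_id: str
    scaffold_length: int
    position: int
    pools: dict[str, PoolCount] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.position <= self.scaffold_length):
            raise ValueError(
                f"{self.scaffold_id}:{self.position}: position outside scaffold")

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold_id}:{self.position}"

    @property
    def total_depth(self) -> int:
        return sum(p.depth for p in self.pools.values())


@dataclass
class SelectionConfig:
    """Tuning knobs of the screening pipeline (defaults follow the
    two-per-scaffold, fifty-scaffold, two-sigma-coverage screening design)."""

    n_scaffolds: int = 50
    per_scaffold: int = 2
    coverage_sd_bound: float = 2.0
    min_pools_covered: int = 1

    def __post_init__(self) -> None:
        if (self.n_scaffolds <= 0 or self.per_scaffold <= 0
                or self.coverage_sd_bound < 0 or self.min_pools_covered <= 0):
            raise ValueError("selection config values must be positive")


@dataclass(frozen=True)
class Candidate:
    """A scored candidate SNP."""

    locus_id: str
    scaffold_id: str
    position: int
    score: float
    freq_a: float
    freq_b: float


# ---------------------------------------------------------------------------
# pooled-count TSV interface
# ---------------------------------------------------------------------------
_TSV_HEADER = ("scaffold_id", "scaffold_length", "position", "pool_id",
               "depth", "count_allele_a", "count_allele_b")


def write_pooled_tsv(sites: Iterable[PooledSiteCounts], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for site in sites:
            for pool_id, pc in site.pools.items():
                fh.write("\t".join(map(str, (
                    site.scaffold_id, site.scaffold_length, site.position,
                    pool_id, pc.depth, pc.count_a, pc.count_b))) + "\n")


def read_pooled_tsv(path: str | Path) -> list[PooledSiteCounts]:
    sites: dict[tuple[str, int], PooledSiteCounts] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_HEADER:
            raise ValueError(f"{path}: unexpected pooled-counts header {header}")
        for lineno, ln in enumerate(fh, start=2):
            ln = ln.rstrip("\n")
            if not ln:
                continue
            parts = ln.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields")
            scf, length, pos, pool_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            key = (scf, pos)
            if key not in sites:
                sites[key] = PooledSiteCounts(scf, length, pos)
            sites[key].pools[pool_id] = PoolCount(
                int(parts[4]), int(parts[5]), int(parts[6]))
    return list(sites.values())


def read_scaffold_catalogue(path: str | Path) -> dict[str, int]:
    """Read a `scaffold_id<TAB>length` catalogue."""
    out: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.startswith("scaffold_id"):
                continue
            scf, length = ln.split("\t")
            out[scf] = int(length)
    return out


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def coverage_filter(sites: Iterable[PooledSiteCounts],
                    config: SelectionConfig | None = None) -> list[PooledSiteCounts]:
    """Drop sites whose total depth lies outside mean +/- bound*SD.

    Extreme coverage flags repeats and collapsed regions (too high) or
    unreliable calls (too low).  Statistics are computed over the input pass
    itself.
    """
    config = config or SelectionConfig()
    sites = list(sites)
    if not sites:
        warnings.warn("coverage_filter: empty input")
        return []
    if len(sites) < 2:
        return sites
    depths = [s.total_depth for s in sites]
    mean = sum(depths) / len(depths)
    sd = math.sqrt(sum((d - mean) ** 2 for d in depths) / len(depths))
    lo = mean - config.coverage_sd_bound * sd
    hi = mean + config.coverage_sd_bound * sd
    return [s for s, d in zip(sites, depths) if lo <= d <= hi]


def _group_tally(site: PooledSiteCounts, pool_ids: Sequence[str]) -> tuple[int, int, int]:
    """(allele_b reads, allele reads total, pools with coverage) for a group."""
    xb = n = covered = 0
    for pid in pool_ids:
        pc = site.pools.get(pid)
        if pc is None or pc.depth == 0:
            continue
        xb += pc.count_b
        n += pc.count_a + pc.count_b
        covered += 1
    return xb, n, covered


def information_score(site: PooledSiteCounts,
                      group_a_pools: Sequence[str],
                      group_b_pools: Sequence[str],
                      confidence: float = 0.95) -> float:
    """SURROGATE information score: lower confidence bound of the absolute
    between-group allele-frequency difference (0 if a group is uncovered)."""
    xa, na, _ = _group_tally(site, group_a_pools)
    xb, nb, _ = _group_tally(site, group_b_pools)
    if na == 0 or nb == 0:
        return 0.0
    pa, la, ua = agresti_coull_ci(xa, na, confidence)
    pb, lb, ub = agresti_coull_ci(xb, nb, confidence)
    # shared z-scale SEs recovered from the AC interval half-widths
    se_a = (ua - la) / 2.0
    se_b = (ub - lb) / 2.0
    lower = abs(pa - pb) - math.sqrt(se_a ** 2 + se_b ** 2)
    return max(0.0, min(1.0, lower))


def group_frequencies(site: PooledSiteCounts,
                      group_a_pools: Sequence[str],
                      group_b_pools: Sequence[str]) -> tuple[float, float]:
    """Raw pooled allele_b read frequencies per group (nan if uncovered)."""
    out = []
    for pools in (group_a_pools, group_b_pools):
        x, n, _ = _group_tally(site, pools)
        out.append(x / n if n else float("nan"))
    return out[0], out[1]


def select_candidates(
    sites: Iterable[PooledSiteCounts],
    scaffold_catalogue: Mapping[str, int],
    config: SelectionConfig,
    group_a_pools: Sequence[str],
    group_b_pools: Sequence[str],
    score_fn: Callable[[PooledSiteCounts], float] | None = None,
) -> list[Candidate]:
    """Rank candidates: longest scaffolds only, top `per_scaffold` per
    scaffold, sorted by descending score."""
    if score_fn is None:
        def score_fn(s: PooledSiteCounts) -> float:
            return information_score(s, group_a_pools, group_b_pools)

    kept: dict[str, list[PooledSiteCounts]] = {}
    for site in sites:
        if site.scaffold_id not in scaffold_catalogue:
            warnings.warn(f"site {site.locus_id}: scaffold not in catalogue, skipped")
            continue
        kept.setdefault(site.scaffold_id, []).append(site)

    # longest scaffolds; ties broken lexicographically by id for determinism
    ranked = sorted(scaffold_catalogue, key=lambda s: (-scaffold_catalogue[s], s))
    if len(ranked) < config.n_scaffolds:
        warnings.warn(
            f"only {len(ranked)} scaffolds available, {config.n_scaffolds} requested")
    chosen_scaffolds = ranked[:config.n_scaffolds]

    candidates: list[Candidate] = []
    for scf in chosen_scaffolds:
        scored = []
        for site in kept.get(scf, []):
            _, _, cov_a = _group_tally(site, group_a_pools)
            _, _, cov_b = _group_tally(site, group_b_pools)
            if min(cov_a, cov_b) < config.min_pools_covered:
                continue
            scored.append((score_fn(site), site))
        scored.sort(key=lambda t: (-t[0], t[1].position))
        for score, site in scored[:config.per_scaffold]:
            fa, fb = group_frequencies(site, group_a_pools, group_b_pools)
            candidates.append(Candidate(site.locus_id, site.scaffold_id,
                                        site.position, score, fa, fb))
    candidates.sort(key=lambda c: (-c.score, c.scaffold_id, c.position))
    return candidates


def resolve_conflicts(
    candidates: Sequence[Candidate],
    assay_groups: Mapping[str, str] | None = None,
) -> list[Candidate]:
    """Within each assay group, keep only the top-scoring locus per scaffold.

    Loci that end up multiplexed together must not share a scaffold; the
    lower-scoring one is removed (applied transitively).  With no grouping
    everything is treated as a single assay.
    """
    best: dict[tuple[str, str], Candidate] = {}
    for cand in candidates:
        group = assay_groups.get(cand.locus_id, "assay0") if assay_groups else "assay0"
        key = (group, cand.scaffold_id)
        prev = best.get(key)
        if prev is None or cand.score > prev.score:
            best[key] = cand
    survivors = set(id(c) for c in best.values())
    return [c for c in candidates if id(c) in survivors]


def write_candidates_tsv(candidates: Sequence[Candidate], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("locus_id\tscaffold\tposition\tscore\tfreq_groupA\tfreq_groupB\n")
        for c in candidates:
            fh.write(f"{c.locus_id}\t{c.scaffold_id}\t{c.position}\t"
                     f"{c.score:.6f}\t{c.freq_a:.6f}\t{c.freq_b:.6f}\n")
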