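"""Genotype containers and file I/O for biallelic diagnostic SNP panels.

Genotypes are unphased, biallelic calls stored as the number of copies of
``allele_b`` (0 = AA, 1 = AB, 2 = BB) with ``-1`` marking a missing call.
Coordinates are 1-based.  Alleles are named nucleotides, not oriented to a
reference strand.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1
#: valid call codes: copies of allele_b, or MISSING
VALID_CODES = frozenset({-1, 0, 1, 2})

_NUCLEOTIDES = ("A", "C", "G", "T")


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the declared dialect."""


class PanelMismatchError(ValueError):
    """Raised when two matrices do not share the same locus panel."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP locus anchored on a genome scaffold.

    ``scaffold_length`` matters because marker independence is approximated
    by spreading loci across long scaffolds; selection ranks scaffolds by it.
    """

    locus_id: str
    scaffold_id: str = "unknown"
    scaffold_length: int = 1
    position: int = 1
    allele_a: str = "A"
    allele_b: str = "C"

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"locus {self.locus_id}: alleles must differ")
        if self.position < 1:
            raise ValueError(f"locus {self.locus_id}: position must be >= 1 (1-based)")
        if self.scaffold_length < self.position:
            raise ValueError(
                f"locus {self.locus_id}: scaffold_length {self.scaffold_length} "
                f"< position {self.position}"
            )

    def genotype_string(self, code: int) -> str:
        if code == MISSING:
            return "NA"
        if code == 0:
            return self.allele_a + self.allele_a
        if code == 1:
            return self.allele_a + self.allele_b
        if code == 2:
            return self.allele_b + self.allele_b
        raise ValueError(f"invalid call code {code}")


PURE_A = "PUREA"
PURE_B = "PUREB"

_CAT_RE = re.compile(r"^F(\d+)([AB])?$")


@dataclass(frozen=True)
class PedigreeCategory:
    """A pure/hybrid/backcross pedigree class.

    ``generation`` g follows the backcross-chain convention: F1 is the
    first-generation hybrid, FgA is the (g-1)-th backcross into population A
    (F2A = F1 x pure A).  The expected foreign-lineage genome fraction is
    f_g = 2**(1-g); pure classes carry no generation.
    """

    name: str
    generation: int | None
    direction: str | None  # "A", "B" or None

    @classmethod
    def pure(cls, pop: str) -> "PedigreeCategory":
        if pop not in ("A", "B"):
            raise ValueError("pure population must be 'A' or 'B'")
        return cls(name=f"PURE{pop}", generation=None, direction=None)

    @classmethod
    def f1(cls) -> "PedigreeCategory":
        return cls(name="F1", generation=1, direction=None)

    @classmethod
    def backcross(cls, generation: int, direction: str) -> "PedigreeCategory":
        if generation < 2:
            raise ValueError("backcross generation must be >= 2")
        if direction not in ("A", "B"):
            raise ValueError("backcross direction must be 'A' or 'B'")
        return cls(name=f"F{generation}{direction}", generation=generation,
                   direction=direction)

    @classmethod
    def from_name(cls, name: str) -> "PedigreeCategory":
        if name == PURE_A:
            return cls.pure("A")
        if name == PURE_B:
            return cls.pure("B")
        m = _CAT_RE.match(name)
        if m is None:
            raise ValueError(f"unrecognised pedigree category name {name!r}")
        g = int(m.group(1))
        direction = m.group(2)
        if g == 1:
            if direction is not None:
                raise ValueError("F1 carries no backcross direction")
            return cls.f1()
        if direction is None:
            raise ValueError(f"backcross category {name!r} needs a direction")
        return cls.backcross(g, direction)

    @property
    def foreign_fraction(self) -> float:
        """Expected genome fraction from the non-local lineage, 2**(1-g)."""
        if self.generation is None:
            return 0.0
        return 2.0 ** (1 - self.generation)


class GenotypeMatrix:
    """Rectangular individuals x loci table of biallelic genotype calls.

    Rectangularity and id uniqueness are enforced on construction and never
    silently repaired.  Calls are stored as an int8 array of allele_b copy
    numbers with -1 for missing.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        individual_ids: Sequence[str],
        labels: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.loci: list[Locus] = list(loci)
        self.individual_ids: list[str] = list(individual_ids)
        self.labels: list[str] = list(labels)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape != (len(self.individual_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.loci)} loci"
            )
        if len(self.labels) != len(self.individual_ids):
            raise ValueError("one label required per individual")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = sorted({i for i in self.individual_ids
                            if self.individual_ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        lids = [l.locus_id for l in self.loci]
        if len(set(lids)) != len(lids):
            dupes = sorted({i for i in lids if lids.count(i) > 1})
            raise ValueError(f"duplicate locus ids: {dupes}")
        bad = set(np.unique(calls)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid call codes present: {sorted(bad)}")
        self.calls: np.ndarray = calls

    # -- basic geometry -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def row(self, individual_id: str) -> np.ndarray:
        return self.calls[self.individual_ids.index(individual_id)]

    # -- manipulation -------------------------------------------------------
    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset/reorder; unknown ids raise listing every offender."""
        index = {l.locus_id: j for j, l in enumerate(self.loci)}
        unknown = [lid for lid in locus_ids if lid not in index]
        if unknown:
            raise KeyError(f"unknown locus ids: {unknown}")
        cols = [index[lid] for lid in locus_ids]
        return GenotypeMatrix(
            [self.loci[j] for j in cols],
            self.individual_ids,
            self.labels,
            self.calls[:, cols],
        )

    def subset_individuals(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        unknown = [iid for iid in individual_ids if iid not in index]
        if unknown:
            raise KeyError(f"unknown individual ids: {unknown}")
        rows = [index[iid] for iid in individual_ids]
        return GenotypeMatrix(
            self.loci,
            [self.individual_ids[i] for i in rows],
            [self.labels[i] for i in rows],
            self.calls[rows],
        )

    def with_labels(self, label: str) -> "GenotypeMatrix":
        return GenotypeMatrix(self.loci, self.individual_ids,
                              [label] * self.n_individuals, self.calls)

    @classmethod
    def concat(cls, matrices: Iterable["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack matrices sharing a locus panel (by locus id, same order)."""
        mats = list(matrices)
        if not mats:
            raise ValueError("nothing to concatenate")
        ref = mats[0].locus_ids
        for m in mats[1:]:
            if m.locus_ids != ref:
                raise PanelMismatchError("locus panels differ between matrices")
        return cls(
            mats[0].loci,
            [i for m in mats for i in m.individual_ids],
            [l for m in mats for l in m.labels],
            np.vstack([m.calls for m in mats]),
        )

    # -- equality -----------------------------------------------------------
    def _normalised_cell(self, i: int, j: int) -> str | None:
        c = self.calls[i, j]
        if c == MISSING:
            return None
        return "".join(sorted(self.loci[j].genotype_string(int(c))))

    def __eq__(self, other: object) -> bool:
        # Compared on ids, labels, locus ids and unordered genotype letter
        # pairs -- allele orientation (which letter is "a") is not meaningful
        # for unphased data, and files do not always preserve it.
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if (self.individual_ids != other.individual_ids
                or self.labels != other.labels
                or self.locus_ids != other.locus_ids):
            return False
        for i in range(self.n_individuals):
            for j in range(self.n_loci):
                if self._normalised_cell(i, j) != other._normalised_cell(i, j):
                    return False
        return True

    def __repr__(self) -> str:
        return (f"<GenotypeMatrix {self.n_individuals} individuals x "
                f"{self.n_loci} loci>")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------
# header: individual_id,label,<locus_id_1>,...
# cells: two allele letters (e.g. "AG"), "NA" for missing; UTF-8, comma
# separated, no quoting.

def _infer_alleles(letters: set[str], locus_id: str) -> tuple[str, str]:
    """Pick (allele_a, allele_b) from observed letters, alphabetically."""
    bad = letters - set(_NUCLEOTIDES)
    if bad:
        raise GenotypeParseError(
            f"locus {locus_id}: non-nucleotide allele symbols {sorted(bad)}")
    if len(letters) > 2:
        raise GenotypeParseError(
            f"locus {locus_id}: more than two alleles observed: {sorted(letters)}")
    if len(letters) == 2:
        a, b = sorted(letters)
        return a, b
    if len(letters) == 1:
        a = next(iter(letters))
        b = next(n for n in _NUCLEOTIDES if n != a)
        return a, b
    return "A", "C"


def _read_csv(path: Path) -> GenotypeMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    header = lines[0].split(",")
    if len(header) < 2 or header[0] != "individual_id" or header[1] != "label":
        raise GenotypeParseError(
            f"{path}:1: malformed header (expected 'individual_id,label,...')")
    locus_ids = header[2:]
    n_loci = len(locus_ids)
    ids: list[str] = []
    labels: list[str] = []
    raw_cells: list[list[str]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2 + n_loci:
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {2 + n_loci} fields, got {len(parts)}")
        if parts[0] in ids:
            raise GenotypeParseError(
                f"{path}:{lineno}: duplicate individual id {parts[0]!r}")
        ids.append(parts[0])
        labels.append(parts[1])
        for cell in parts[2:]:
            if cell != "NA" and (len(cell) != 2 or not cell.isalpha()):
                raise GenotypeParseError(
                    f"{path}:{lineno}: unrecognised genotype token {cell!r}")
        raw_cells.append(parts[2:])

    loci: list[Locus] = []
    calls = np.full((len(ids), n_loci), MISSING, dtype=np.int8)
    for j, lid in enumerate(locus_ids):
        letters = {ch for row in raw_cells for ch in row[j] if row[j] != "NA"}
        a, b = _infer_alleles(letters, lid)
        loci.append(Locus(locus_id=lid, allele_a=a, allele_b=b))
        for i, row in enumerate(raw_cells):
            cell = row[j]
            if cell == "NA":
                continue
            code = sum(1 for ch in cell if ch == b)
            if any(ch not in (a, b) for ch in cell):
                raise GenotypeParseError(
                    f"{path}: locus {lid}, individual {ids[i]}: "
                    f"allele outside {{{a},{b}}} in {cell!r}")
            calls[i, j] = code
    return GenotypeMatrix(loci, ids, labels, calls)


def _write_csv(matrix: GenotypeMatrix, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(["individual_id", "label"] + matrix.locus_ids) + "\n")
        for i, iid in enumerate(matrix.individual_ids):
            cells = [matrix.loci[j].genotype_string(int(matrix.calls[i, j]))
                     for j in range(matrix.n_loci)]
            fh.write(",".join([iid, matrix.labels[i]] + cells) + "\n")


# ---------------------------------------------------------------------------
# Genepop 4-digit diploid dialect
# ---------------------------------------------------------------------------
# allele_a -> 01, allele_b -> 02, missing genotype -> 0000.  The format has
# no slot for population label names or allele letters, so the writer records
# them in the free-text title line; files from other tools fall back to
# POP1..POPn labels and placeholder alleles.

_GENEPOP_MARK = "hybridpanel-genepop"


def _genepop_code(code: int) -> str:
    return {MISSING: "0000", 0: "0101", 1: "0102", 2: "0202"}[int(code)]


def _write_genepop(matrix: GenotypeMatrix, path: Path) -> None:
    # POP blocks force grouping by label; first-appearance order is kept.
    order: list[str] = []
    for lab in matrix.labels:
        if lab not in order:
            order.append(lab)
    alleles = ",".join(l.allele_a + l.allele_b for l in matrix.loci)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_GENEPOP_MARK}|pops={';'.join(order)}|alleles={alleles}\n")
        for lid in matrix.locus_ids:
            fh.write(lid + "\n")
        for lab in order:
            fh.write("POP\n")
            for i, iid in enumerate(matrix.individual_ids):
                if matrix.labels[i] != lab:
                    continue
                geno = " ".join(_genepop_code(matrix.calls[i, j])
                                for j in range(matrix.n_loci))
                fh.write(f"{iid} ,  {geno}\n")


def _read_genepop(path: Path) -> GenotypeMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    title = lines[0]
    pop_names: list[str] | None = None
    allele_pairs: list[str] | None = None
    if title.startswith(_GENEPOP_MARK):
        for field in title.split("|")[1:]:
            if field.startswith("pops="):
                pop_names = field[len("pops="):].split(";")
            elif field.startswith("alleles="):
                allele_pairs = field[len("alleles="):].split(",")
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        ln = lines[i].strip()
        if ln:
            # locus names may be one per line or comma separated
            locus_ids.extend(t.strip() for t in ln.split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no POP section found")
    n_loci = len(locus_ids)
    if allele_pairs is not None and len(allele_pairs) != n_loci:
        raise GenotypeParseError(f"{path}:1: allele annotation does not match loci")
    loci = []
    for j, lid in enumerate(locus_ids):
        if allele_pairs is not None:
            a, b = allele_pairs[j][0], allele_pairs[j][1]
        else:
            a, b = "A", "C"
        loci.append(Locus(locus_id=lid, allele_a=a, allele_b=b))

    ids: list[str] = []
    labels: list[str] = []
    rows: list[list[int]] = []
    pop_index = -1
    for lineno in range(i, len(lines)):
        ln = lines[lineno].strip()
        if not ln:
            continue
        if ln.upper() == "POP":
            pop_index += 1
            continue
        if "," not in ln:
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: expected 'id , genotypes' line")
        iid, geno_part = ln.split(",", 1)
        iid = iid.strip()
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: expected {n_loci} genotypes, "
                f"got {len(tokens)}")
        if iid in ids:
            raise GenotypeParseError(
                f"{path}:{lineno + 1}: duplicate individual id {iid!r}")
        row: list[int] = []
        for tok in tokens:
            if len(tok) != 4 or not tok.isdigit():
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: bad 4-digit genotype {tok!r}")
            if tok == "0000":
                row.append(MISSING)
                continue
            a1, a2 = tok[:2], tok[2:]
            if {a1, a2} - {"01", "02"}:
                raise GenotypeParseError(
                    f"{path}:{lineno + 1}: allele codes beyond biallelic "
                    f"01/02 in {tok!r}")
            row.append((a1 == "02") + (a2 == "02"))
        ids.append(iid)
        rows.append(row)
        if pop_names is not None and pop_index < len(pop_names):
            labels.append(pop_names[pop_index])
        else:
            labels.append(f"POP{pop_index + 1}")
    return GenotypeMatrix(loci, ids, labels,
                          np.array(rows, dtype=np.int8).reshape(len(ids), n_loci))


# ---------------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``csv`` or ``genepop`` format."""
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path,
                    format: str = "csv") -> None:
    """Write a genotype matrix; the emitted file re-reads to an equal matrix."""
    path = Path(path)
    if format == "csv":
        _write_csv(matrix, path)
    elif format == "genepop":
        _write_genepop(matrix, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def subset_panel(matrix: GenotypeMatrix, locus_ids: Sequence[str]) -> GenotypeMatrix:
    """Restrict/reorder a matrix to the requested marker panel."""
    return matrix.subset_loci(locus_ids)
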