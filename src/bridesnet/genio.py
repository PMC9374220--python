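"""Genotype and population-attribute input/output.

Reads multilocus codominant genotypes (GenePop dialect or the in-memory
:class:`GenotypeTable`), reads per-population attribute tables (sample size,
expected heterozygosity, estimated population size, element-occurrence rank),
and computes Nei's unbiased gene diversity per population.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "EO_RANKS",
    "GenotypeTable",
    "PopulationAttributes",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_population_attributes",
    "write_population_attributes",
    "expected_heterozygosity",
]

#: Sentinel allele code for a missing genotype. Real allele codes are
#: positive integers, so 0 can never collide with an observed allele.
MISSING = 0

#: Element-occurrence viability ranks, best (A) to worst (D), including the
#: composite ranks used when the estimate is uncertain.
EO_RANKS = ("A", "AB", "B", "BC", "C", "CD", "D")


class GenepopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed; names the offending line."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with population labels.

    ``calls[i, l]`` is the unordered pair of allele codes of individual *i*
    at locus *l*; a pair of :data:`MISSING` zeros marks an untyped genotype.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray  # shape (n_individuals, n_loci, 2), dtype int

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, m = len(self.individuals), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if (self.calls < 0).any():
            raise ValueError("allele codes must be positive (0 = missing)")

    @property
    def population_ids(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def population_mask(self, pop: str) -> np.ndarray:
        return np.array([p == pop for p in self.populations])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        # genotypes are unordered pairs: compare after per-call sorting
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(np.sort(self.calls, -1), np.sort(other.calls, -1))
        )


@dataclass(frozen=True)
class PopulationAttributes:
    """Per-population management attributes.

    ``n`` sampled individuals, expected heterozygosity ``he`` in [0, 1],
    estimated census size ``psize``, and element-occurrence rank ``eo``.
    """

    id: str
    n: int
    he: float
    psize: int
    eo: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.he <= 1.0:
            raise ValueError(f"{self.id}: H_E {self.he} outside [0, 1]")
        if self.n < 0 or self.psize < 0:
            raise ValueError(f"{self.id}: sizes must be non-negative")
        if self.eo not in EO_RANKS:
            raise ValueError(
                f"{self.id}: unknown EO rank {self.eo!r}; allowed: {EO_RANKS}"
            )


# ---------------------------------------------------------------------------
# GenePop format
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_alleles(token: str, width: int, lineno: int) -> tuple[int, int]:
    if len(token) != 2 * width or not token.isdigit():
        raise GenepopParseError(
            f"line {lineno}: genotype token {token!r} is not "
            f"{2 * width} digits"
        )
    return int(token[:width]), int(token[width:])


def read_genepop(path: str | Path, *, pop_label: str = "first") -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele coding).

    Parameters
    ----------
    path
        GenePop text file: title line, locus names (one per line or one
        comma-separated line), then ``POP`` blocks of
        ``name , 0101 0202 ...`` records.
    pop_label
        ``"first"`` labels each block by its first individual's name (the
        common convention); ``"index"`` labels blocks ``pop_1``, ``pop_2``…

    Notes
    -----
    All-zero genotype codes (``0000`` / ``000000``) become missing calls.
    The allele-code width is inferred from the first genotype token and must
    be consistent throughout the file.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short for a GenePop header")

    # locus block: everything between title and first POP line
    try:
        first_pop = next(i for i, l in enumerate(lines) if _POP_RE.match(l))
    except StopIteration:
        raise GenepopParseError("no POP line found") from None
    if first_pop < 2:
        raise GenepopParseError(f"line {first_pop + 1}: POP before any locus")
    loci: list[str] = []
    for raw in lines[1:first_pop]:
        parts = [p.strip() for p in raw.split(",") if p.strip()]
        loci.extend(parts)
    if not loci:
        raise GenepopParseError("no locus names between title and first POP")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    block = 0
    current_label: str | None = None

    for lineno, raw in enumerate(lines[first_pop:], start=first_pop + 1):
        if _POP_RE.match(raw):
            block += 1
            current_label = None
            continue
        if not raw.strip():
            continue
        if "," not in raw:
            raise GenepopParseError(
                f"line {lineno}: expected 'name , genotypes' record"
            )
        name, _, geno = raw.partition(",")
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        if width is None:
            if len(tokens[0]) not in (4, 6):
                raise GenepopParseError(
                    f"line {lineno}: cannot infer 2- or 3-digit coding "
                    f"from token {tokens[0]!r}"
                )
            width = len(tokens[0]) // 2
        if current_label is None:
            current_label = name if pop_label == "first" else f"pop_{block}"
        calls = [_split_alleles(t, width, lineno) for t in tokens]
        individuals.append(name)
        populations.append(current_label)
        rows.append(calls)

    if not rows:
        raise GenepopParseError("no individual records found")
    calls = np.array(rows, dtype=int)
    # half-missing genotypes (e.g. "0102" vs "0002") are treated as missing
    half = (calls == MISSING).any(-1)
    calls[half] = MISSING
    return GenotypeTable(individuals, populations, loci, calls)


def write_genepop(
    table: GenotypeTable, path: str | Path, *, width: int = 3, title: str = "bridesnet export"
) -> None:
    """Write a :class:`GenotypeTable` in GenePop format (3-digit default)."""
    if width not in (2, 3):
        raise ValueError("allele-code width must be 2 or 3")
    if int(table.calls.max(initial=0)) >= 10**width:
        raise ValueError(f"allele codes too large for {width}-digit coding")
    out = [title]
    out.extend(table.loci)
    last_pop = None
    for i, (ind, pop) in enumerate(zip(table.individuals, table.populations)):
        if pop != last_pop:
            out.append("POP")
            last_pop = pop
        genos = " ".join(
            f"{a:0{width}d}{b:0{width}d}" for a, b in table.calls[i]
        )
        out.append(f"{ind} , {genos}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Attribute tables
# ---------------------------------------------------------------------------

def read_population_attributes(path: str | Path) -> list[PopulationAttributes]:
    """Read a delimited attribute table with columns Id, N, HE, PSize, EO.

    Column order is free and header matching is case-insensitive. EO ranks
    are validated against the A…D vocabulary; duplicate ids are rejected.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    needed = ["id", "n", "he", "psize", "eo"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"attribute table missing columns: {missing}")
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[cols["id"]])
        if pid in seen:
            raise ValueError(f"duplicate population id {pid!r}")
        seen.add(pid)
        records.append(
            PopulationAttributes(
                id=pid,
                n=int(row[cols["n"]]),
                he=float(row[cols["he"]]),
                psize=int(row[cols["psize"]]),
                eo=str(row[cols["eo"]]).strip(),
            )
        )
    return records


def write_population_attributes(
    attrs: Sequence[PopulationAttributes], path: str | Path
) -> None:
    pd.DataFrame(
        [(a.id, a.n, a.he, a.psize, a.eo) for a in attrs],
        columns=["Id", "N", "HE", "PSize", "EO"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expected heterozygosity
# ---------------------------------------------------------------------------

def expected_heterozygosity(
    table: GenotypeTable, *, unbiased: bool = True
) -> dict[str, float]:
    """Per-population expected heterozygosity (Nei's gene diversity).

    For each population and locus, allele frequencies are taken over the
    non-missing diploid calls (n individuals → 2n gene copies) and the locus
    diversity is ``h = (2n/(2n-1)) * (1 - sum p_a^2)`` (the small-sample
    correction is dropped when ``unbiased=False``). H_E is the mean of h over
    loci typed in at least one individual; a population with no usable locus
    gets ``nan``.
    """
    result: dict[str, float] = {}
    calls = table.calls
    for pop in table.population_ids:
        mask = table.population_mask(pop)
        hs: list[float] = []
        for l in range(len(table.loci)):
            sub = calls[mask, l, :]  # (n_i, 2)
            typed = sub[(sub != MISSING).all(axis=1)]
            n = typed.shape[0]
            if n == 0:
                continue
            alleles, counts = np.unique(typed, return_counts=True)
            p = counts / (2 * n)
            h = 1.0 - float(np.sum(p**2))
            if unbiased:
                h *= (2 * n) / (2 * n - 1)
            hs.append(h)
        result[pop] = float(np.mean(hs)) if hs else float("nan")
    return result
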