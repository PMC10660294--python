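"""Residue seed tables and BLOSUM62-derived degeneracy levels.

Each hash level is defined by a table mapping the 20 standard amino acids to
64-bit seed words:

* level 1 — every residue gets its own word (ordinary exact hashing);
* level 2 — residues with positive BLOSUM62 scores to each other are grouped
  into degeneracy zones and share one word, so within-zone substitutions do
  not change the hash;
* level 3 — the grouping is widened to nonnegative scores, giving a coarser
  partition (level 3 always coarsens level 2, because every positive-score
  edge is also a nonnegative-score edge).

Zones require *mutual* similarity: every pair of residues inside a zone must
satisfy the level's score rule (a clique, not a connected component — mere
chains of similar intermediates, e.g. W-Y-H-N-S-A, do not merge a zone).
Level-2 zones are built greedily in lexicographic residue order; level-3
zones are built by merging level-2 zones whose cross-pairs are all
nonnegative, which makes the coarsening relation hold by construction. With
BLOSUM62 this yields the level-2 zones
``{A,S} {C} {D,E} {F,W,Y} {G} {H,N} {I,L,M,V} {K,Q,R} {P} {T}`` and the
level-3 zones merge ``{A,S}`` with ``{G}``.

The level-1 words are generated once from a fixed, documented PRNG seed
(:data:`CANONICAL_RNG_SEED`), rejecting candidates whose popcount falls
outside [30, 34] so every seed has a nearly equal number of 1s and 0s.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .bits import popcount, srol

#: The 20 standard one-letter amino-acid codes, in lexicographic order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue -> 0..19 index.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Fixed PRNG seed used to generate the canonical level-1 seed table.
CANONICAL_RNG_SEED = 0xAA

_POPCOUNT_RANGE = (30, 34)

# Standard public BLOSUM62 scores (20x20 core alphabet), row order AMINO_ACIDS.
_BLOSUM62_ROWS = """
 4  0 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1 -1  1  0  0 -3 -2
 0  9 -3 -4 -2 -3 -3 -1 -3 -1 -1 -3 -3 -3 -3 -1 -1 -1 -2 -2
-2 -3  6  2 -3 -1 -1 -3 -1 -4 -3  1 -1  0 -2  0 -1 -3 -4 -3
-1 -4  2  5 -3 -2  0 -3  1 -3 -2  0 -1  2  0  0 -1 -2 -3 -2
-2 -2 -3 -3  6 -3 -1  0 -3  0  0 -3 -4 -3 -3 -2 -2 -1  1  3
 0 -3 -1 -2 -3  6 -2 -4 -2 -4 -3  0 -2 -2 -2  0 -2 -3 -2 -3
-2 -3 -1  0 -1 -2  8 -3 -1 -3 -2  1 -2  0  0 -1 -2 -3 -2  2
-1 -1 -3 -3  0 -4 -3  4 -3  2  1 -3 -3 -3 -3 -2 -1  3 -3 -1
-1 -3 -1  1 -3 -2 -1 -3  5 -2 -1  0 -1  1  2  0 -1 -2 -3 -2
-1 -1 -4 -3  0 -4 -3  2 -2  4  2 -3 -3 -2 -2 -2 -1  1 -2 -1
-1 -1 -3 -2  0 -3 -2  1 -1  2  5 -2 -2  0 -1 -1 -1  1 -1 -1
-2 -3  1  0 -3  0  1 -3  0 -3 -2  6 -2  0  0  1  0 -3 -4 -2
-1 -3 -1 -1 -4 -2 -2 -3 -1 -3 -2 -2  7 -1 -2 -1 -1 -2 -4 -3
-1 -3  0  2 -3 -2  0 -3  1 -2  0  0 -1  5  1  0 -1 -2 -2 -1
-1 -3 -2  0 -3 -2  0 -3  2 -2 -1  0 -2  1  5 -1 -1 -3 -3 -2
 1 -1  0  0 -2  0 -1 -2  0 -2 -1  1 -1  0 -1  4  1 -2 -3 -2
 0 -1 -1 -1 -2 -2 -2 -1 -1 -1 -1  0 -1 -1 -1  1  5  0 -2 -2
 0 -1 -3 -2 -1 -3 -3  3 -2  1  1 -3 -2 -2 -3 -2  0  4 -3 -1
-3 -2 -4 -3  1 -2 -2 -3 -3 -2 -1 -4 -4 -2 -3 -3 -2 -3 11  2
-2 -2 -3 -2  3 -3  2 -1 -2 -1 -1 -2 -3 -1 -2 -2 -2 -1  2  7
"""


class PartitionError(ValueError):
    """Raised when a degeneracy rule fails to produce a valid partition."""


@dataclass(frozen=True)
class BlosumMatrix:
    """Symmetric residue-pair substitution scores."""

    scores: Mapping[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]


@dataclass(frozen=True)
class DegeneracyPartition:
    """Disjoint residue groups covering the alphabet, for levels 2 and 3."""

    level: int
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        members = [aa for g in self.groups for aa in g]
        if sorted(members) != sorted(AMINO_ACIDS):
            raise PartitionError(
                "groups are not a partition of the 20-residue alphabet"
            )

    def group_of(self, residue: str) -> frozenset[str]:
        for g in self.groups:
            if residue in g:
                return g
        raise KeyError(residue)

    def coarsens(self, other: "DegeneracyPartition") -> bool:
        """True if every group of ``other`` lies inside one of our groups."""
        return all(any(g <= mine for mine in self.groups) for g in other.groups)


@dataclass(frozen=True)
class SeedTable:
    """Per-level mapping from each residue to a 64-bit seed word."""

    level: int
    seeds: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.seeds)
        if missing:
            raise ValueError(f"seed table missing residues: {sorted(missing)}")

    def seed(self, residue: str) -> int:
        return self.seeds[residue]


@dataclass(frozen=True)
class NmerTables:
    """Precomputed dimer/trimer seeds used to bootstrap a window hash.

    ``dimer[ab] == srol(seed(a)) ^ seed(b)`` and
    ``trimer[abc] == srol(dimer[ab]) ^ seed(c)``; folding a k-mer three
    residues at a time through these tables is bit-identical to the scalar
    recurrence but needs a third of the lookups.
    """

    dimer: Mapping[str, int]
    trimer: Mapping[str, int]


def blosum62() -> BlosumMatrix:
    """The standard public BLOSUM62 matrix over the 20-residue core alphabet."""
    rows = [
        [int(v) for v in line.split()]
        for line in _BLOSUM62_ROWS.strip().splitlines()
    ]
    scores = {
        (a, b): rows[i][j]
        for i, a in enumerate(AMINO_ACIDS)
        for j, b in enumerate(AMINO_ACIDS)
    }
    return BlosumMatrix(scores=scores)


def load_matrix(path) -> BlosumMatrix:
    """Read an NCBI-format substitution matrix (header row of residues,
    one labelled row per residue); extra residues such as B/Z/X/* are ignored."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        a = parts[0].upper()
        if a not in AA_INDEX:
            continue
        for b, val in zip(header, parts[1:]):
            if b.upper() in AA_INDEX:
                scores[(a, b.upper())] = int(val)
    matrix = BlosumMatrix(scores=scores)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            if (a, b) not in scores:
                raise ValueError(f"matrix file lacks pair ({a},{b})")
            if scores[(a, b)] != scores[(b, a)]:
                raise ValueError(f"matrix not symmetric at ({a},{b})")
    return matrix


def generate_base_seeds(rng_seed: int = CANONICAL_RNG_SEED) -> SeedTable:
    """Generate the level-1 seed table: 20 distinct 64-bit words with
    popcount in [30, 34], deterministically from ``rng_seed``.

    Uses the stdlib Mersenne Twister, whose integer stream is stable across
    platforms and Python versions, so the canonical table is reproducible.
    """
    rng = random.Random(rng_seed)
    lo, hi = _POPCOUNT_RANGE
    seeds: dict[str, int] = {}
    seen: set[int] = set()
    for aa in AMINO_ACIDS:
        while True:
            candidate = rng.getrandbits(64)
            if lo <= popcount(candidate) <= hi and candidate not in seen:
                seeds[aa] = candidate
                seen.add(candidate)
                break
    return SeedTable(level=1, seeds=seeds)


def _check_symmetric(matrix: BlosumMatrix) -> None:
    for i, a in enumerate(AMINO_ACIDS):
        for b in AMINO_ACIDS[i + 1 :]:
            if matrix.score(a, b) != matrix.score(b, a):
                raise PartitionError(f"matrix not symmetric at ({a},{b})")


def _sorted_groups(groups: Iterable[set[str]]) -> tuple[frozenset[str], ...]:
    return tuple(frozenset(g) for g in sorted(groups, key=min))


def derive_partition(matrix: BlosumMatrix, rule: str) -> DegeneracyPartition:
    """Partition the alphabet into degeneracy zones under ``rule``.

    A zone is a set of residues that are *pairwise* similar under the rule
    (score > 0 for ``"positive"``, level 2; score >= 0 for ``"nonnegative"``,
    level 3), so every member genuinely resembles every other member — the
    requirement that justifies giving them one shared seed.

    Construction is deterministic: level 2 assigns each residue, in
    lexicographic order, to the first zone where it scores positively with
    all current members (else it opens a new zone). Level 3 starts from the
    level-2 zones and repeatedly merges the first pair of zones (ordered by
    smallest member) whose cross-zone pairs are all nonnegative; this makes
    level 3 a coarsening of level 2 by construction.
    """
    _check_symmetric(matrix)
    if rule == "positive":
        return _greedy_cliques(matrix, lambda s: s > 0, level=2)
    if rule == "nonnegative":
        level2 = _greedy_cliques(matrix, lambda s: s > 0, level=2)
        return _merge_zones(matrix, level2, lambda s: s >= 0, level=3)
    raise ValueError(f"unknown degeneracy rule: {rule!r}")


def _greedy_cliques(matrix: BlosumMatrix, linked, level: int) -> DegeneracyPartition:
    zones: list[set[str]] = []
    for aa in AMINO_ACIDS:
        for zone in zones:
            if all(linked(matrix.score(aa, member)) for member in zone):
                zone.add(aa)
                break
        else:
            zones.append({aa})
    return DegeneracyPartition(level=level, groups=_sorted_groups(zones))


def _merge_zones(
    matrix: BlosumMatrix, base: DegeneracyPartition, linked, level: int
) -> DegeneracyPartition:
    zones = [set(g) for g in base.groups]
    merged = True
    while merged:
        merged = False
        zones.sort(key=min)
        for i in range(len(zones)):
            for j in range(i + 1, len(zones)):
                if all(
                    linked(matrix.score(a, b))
                    for a in zones[i]
                    for b in zones[j]
                ):
                    zones[i] |= zones[j]
                    del zones[j]
                    merged = True
                    break
            if merged:
                break
    return DegeneracyPartition(level=level, groups=_sorted_groups(zones))


def build_level_table(base: SeedTable, partition: DegeneracyPartition) -> SeedTable:
    """Degenerate seed table: every residue in a zone gets the base seed of
    the zone's lexicographically smallest member."""
    if base.level != 1:
        raise ValueError("level tables are derived from a level-1 base table")
    seeds = {
        aa: base.seed(min(group)) for group in partition.groups for aa in group
    }
    return SeedTable(level=partition.level, seeds=seeds)


def build_nmer_tables(table: SeedTable) -> NmerTables:
    """Precompute all 400 dimer and 8000 trimer seed words for ``table``."""
    s = table.seeds
    dimer = {
        a + b: srol(s[a]) ^ s[b] for a in AMINO_ACIDS for b in AMINO_ACIDS
    }
    trimer = {
        ab + c: srol(h) ^ s[c]
        for ab, h in dimer.items()
        for c in AMINO_ACIDS
    }
    return NmerTables(dimer=dimer, trimer=trimer)


@dataclass(frozen=True)
class LevelTables:
    """The canonical three-level table set plus per-level n-mer tables."""

    tables: tuple[SeedTable, SeedTable, SeedTable]
    nmers: tuple[NmerTables, NmerTables, NmerTables]
    partitions: tuple[DegeneracyPartition, DegeneracyPartition] = field(repr=False)

    def table(self, level: int) -> SeedTable:
        return self.tables[level - 1]

    def nmer(self, level: int) -> NmerTables:
        return self.nmers[level - 1]

    def partition(self, level: int) -> DegeneracyPartition:
        if level not in (2, 3):
            raise ValueError("partitions exist for levels 2 and 3 only")
        return self.partitions[level - 2]


_DEFAULT: LevelTables | None = None


def default_tables() -> LevelTables:
    """The canonical seed tables for all three levels (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        base = generate_base_seeds()
        matrix = blosum62()
        p2 = derive_partition(matrix, "positive")
        p3 = derive_partition(matrix, "nonnegative")
        t2 = build_level_table(base, p2)
        t3 = build_level_table(base, p3)
        _DEFAULT = LevelTables(
            tables=(base, t2, t3),
            nmers=tuple(build_nmer_tables(t) for t in (base, t2, t3)),
            partitions=(p2, p3),
        )
    return _DEFAULT


def export_tsv(tables: Iterable[SeedTable], path) -> None:
    """Dump seed tables as TSV (residue, level, 16-digit hex seed) for audit."""
    with open(path, "w") as fh:
        fh.write("residue\tlevel\tseed\n")
        for table in tables:
            for aa in AMINO_ACIDS:
                fh.write(f"{aa}\t{table.level}\t{table.seed(aa):016x}\n")
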