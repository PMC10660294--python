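"""Core recursive hash: base formula, O(1) rolling, multi-hashing, patterns.

A k-mer ``s[0..k-1]`` hashes to

    H = srol^(k-1)(seed(s[0])) ^ srol^(k-2)(seed(s[1])) ^ ... ^ seed(s[k-1])

where ``seed`` is the residue's 64-bit word in the active level's table.
Sliding the window one residue right multiplies every retained term by one
more rotation, so the next hash follows in O(1):

    H' = srol(H) ^ srol^k(seed(outgoing)) ^ seed(incoming)

Multi-level patterns pick the seed table per position, turning the hash into
a graded analogue of a spaced seed: positions hashed at level 2 or 3 tolerate
substitutions within their BLOSUM62 degeneracy zone instead of being ignored
outright. Pattern hashes are recomputed per window — with mixed tables the
outgoing term no longer telescopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .bits import MASK64, srol, srol_n
from .seed_tables import AMINO_ACIDS, LevelTables, SeedTable, default_tables

__all__ = [
    "srol",
    "srol_n",
    "HashState",
    "HashRecord",
    "InvalidResidueError",
    "hash_base",
    "roll",
    "multi_hash",
    "multi_hash_array",
    "pattern_hash",
    "iterate_sequence",
    "hash_values",
    "parse_pattern",
]


class InvalidResidueError(ValueError):
    """A character outside the 20-letter amino-acid alphabet."""

    def __init__(self, char: str, offset: int):
        self.char = char
        self.offset = offset
        super().__init__(f"invalid residue {char!r} at offset {offset}")


@dataclass
class HashState:
    """Rolling-window state for uniform-level hashing."""

    k: int
    level: int
    value: int
    position: int
    valid: bool = True


@dataclass(frozen=True)
class HashRecord:
    """Hashes of one window: ``hashes[0]`` is the canonical value."""

    position: int
    hashes: tuple[int, ...]


def _validate_kmer(kmer: str) -> str:
    kmer = kmer.upper()
    for j, ch in enumerate(kmer):
        if ch not in AMINO_ACIDS:
            raise InvalidResidueError(ch, j)
    return kmer


def hash_base(kmer: str, table: SeedTable, nmers=None) -> int:
    """Hash a whole k-mer from scratch.

    With ``nmers`` the leading residues are folded three (then two) at a time
    through the precomputed trimer/dimer tables; the result is bit-identical
    to the one-residue-at-a-time recurrence.
    """
    if len(kmer) < 1:
        raise ValueError("k-mer must have length >= 1")
    kmer = _validate_kmer(kmer)
    seeds = table.seeds
    h = 0
    i = 0
    k = len(kmer)
    if nmers is not None:
        trimer = nmers.trimer
        while k - i >= 3:
            h = srol_n(h, 3) ^ trimer[kmer[i : i + 3]]
            i += 3
        if k - i == 2:
            h = srol_n(h, 2) ^ nmers.dimer[kmer[i : i + 2]]
            i = k
    while i < k:
        h = srol(h) ^ seeds[kmer[i]]
        i += 1
    return h


def roll(state: HashState, outgoing: str, incoming: str, table: SeedTable) -> HashState:
    """Advance the window one residue: O(1) update of the hash."""
    incoming = incoming.upper()
    outgoing = outgoing.upper()
    if incoming not in AMINO_ACIDS:
        return HashState(state.k, state.level, 0, state.position + 1, valid=False)
    value = (
        srol(state.value)
        ^ srol_n(table.seeds[outgoing], state.k)
        ^ table.seeds[incoming]
    )
    return HashState(state.k, state.level, value, state.position + 1, valid=True)


# splitmix64-style odd multipliers / finalizer for the extra hashes
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


def _mix_multiplier(index: int, k: int) -> int:
    return (((index * _MIX1) ^ (k * _MIX2)) | 1) & MASK64


def multi_hash(base: int, h: int, k: int) -> list[int]:
    """Derive ``h`` hash values from one canonical hash.

    Index 0 is ``base`` untouched; index ``i > 0`` multiplies ``base`` by an
    odd constant derived from ``(i, k)`` and applies a xor-shift finalizer,
    giving h pseudo-independent uniform values as a Bloom filter requires.
    """
    if h < 1:
        raise ValueError("number of hashes must be >= 1")
    out = [base]
    for i in range(1, h):
        x = (base * _mix_multiplier(i, k)) & MASK64
        x ^= x >> 30
        x = (x * _MIX1) & MASK64
        x ^= x >> 27
        x = (x * _MIX2) & MASK64
        x ^= x >> 31
        out.append(x)
    return out


def multi_hash_array(bases: np.ndarray, h: int, k: int) -> np.ndarray:
    """Vectorized :func:`multi_hash`: (n,) uint64 -> (n, h) uint64."""
    if h < 1:
        raise ValueError("number of hashes must be >= 1")
    bases = np.asarray(bases, dtype=np.uint64)
    out = np.empty((bases.size, h), dtype=np.uint64)
    out[:, 0] = bases
    for i in range(1, h):
        x = bases * np.uint64(_mix_multiplier(i, k))
        x ^= x >> np.uint64(30)
        x *= np.uint64(_MIX1)
        x ^= x >> np.uint64(27)
        x *= np.uint64(_MIX2)
        x ^= x >> np.uint64(31)
        out[:, i] = x
    return out


def parse_pattern(pattern: str) -> tuple[int, ...]:
    """Parse a multi-level pattern string like ``"1122331"``."""
    if not pattern or any(ch not in "123" for ch in pattern):
        raise ValueError(
            f"pattern must be a nonempty string over {{1,2,3}}, got {pattern!r}"
        )
    return tuple(int(ch) for ch in pattern)


def pattern_hash(
    kmer: str, pattern: Sequence[int], tables: LevelTables | None = None
) -> int:
    """Hash a k-mer with a per-position level assignment."""
    if tables is None:
        tables = default_tables()
    if len(pattern) != len(kmer):
        raise ValueError(
            f"pattern length {len(pattern)} != k-mer length {len(kmer)}"
        )
    kmer = _validate_kmer(kmer)
    h = 0
    for level, ch in zip(pattern, kmer):
        h = srol(h) ^ tables.table(level).seeds[ch]
    return h


def _base_stream(seq: str, k: int, table: SeedTable, nmers) -> Iterator[tuple[int, int]]:
    """Yield (position, canonical hash) for every fully valid window.

    Windows containing a non-alphabet character are skipped; rolling restarts
    at the next fully valid window. The rolling update is inlined for speed —
    this loop is the hot path of every experiment.
    """
    n = len(seq)
    seq = seq.upper()
    seeds = table.seeds
    # residue -> seed, residue -> srol^k(seed); None marks invalid characters
    code = [seeds.get(ch) for ch in seq]
    out_rot = {ch: srol_n(s, k) for ch, s in seeds.items()}
    out_code = [out_rot.get(ch) for ch in seq]

    low_mask = (1 << 33) - 1
    pos = 0
    h = None
    while pos + k <= n:
        if h is None:
            window = code[pos : pos + k]
            if any(c is None for c in window):
                # jump past the last invalid character in this window
                bad = max(j for j, c in enumerate(window) if c is None)
                pos += bad + 1
                continue
            h = hash_base(seq[pos : pos + k], table, nmers)
        yield pos, h
        incoming = pos + k
        if incoming >= n:
            break
        c_in = code[incoming]
        if c_in is None:
            pos = incoming + 1
            h = None
            continue
        # inlined srol(h) ^ srol^k(seed(out)) ^ seed(in)
        low = h & low_mask
        high = h >> 33
        h = (
            ((((high << 1) | (high >> 30)) & 0x7FFFFFFF) << 33)
            | (((low << 1) | (low >> 32)) & low_mask)
        ) ^ out_code[pos] ^ c_in
        pos += 1


def iterate_sequence(
    seq: str,
    k: int,
    level: int | Sequence[int] = 1,
    h: int = 1,
    tables: LevelTables | None = None,
) -> Iterator[HashRecord]:
    """Stream hash records over every valid k-mer window of ``seq``.

    ``level`` is either a uniform hash level (1, 2 or 3, rolled in O(1) per
    window) or a per-position level pattern of length ``k`` (recomputed per
    window). ``h`` hashes are emitted per window, the first being canonical.
    A ``k`` longer than the sequence yields an empty stream.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if h < 1:
        raise ValueError("number of hashes must be >= 1")
    if tables is None:
        tables = default_tables()

    if isinstance(level, int):
        if level not in (1, 2, 3):
            raise ValueError("hash level must be 1, 2 or 3")
        stream = _base_stream(seq, k, tables.table(level), tables.nmer(level))
    else:
        pattern = tuple(level)
        if len(pattern) != k:
            raise ValueError(f"pattern length {len(pattern)} != k ({k})")
        stream = _pattern_stream(seq, k, pattern, tables)

    for pos, value in stream:
        yield HashRecord(position=pos, hashes=tuple(multi_hash(value, h, k)))


def _pattern_stream(seq, k, pattern, tables) -> Iterator[tuple[int, int]]:
    seq = seq.upper()
    n = len(seq)
    level_seeds = [tables.table(lv).seeds for lv in pattern]
    for pos in range(n - k + 1):
        h = 0
        ok = True
        for j in range(k):
            ch = seq[pos + j]
            s = level_seeds[j].get(ch)
            if s is None:
                ok = False
                break
            low = h & ((1 << 33) - 1)
            high = h >> 33
            h = (
                ((((high << 1) | (high >> 30)) & 0x7FFFFFFF) << 33)
                | (((low << 1) | (low >> 32)) & ((1 << 33) - 1))
            ) ^ s
        if ok:
            yield pos, h


def hash_values(
    seq: str, k: int, level: int = 1, tables: LevelTables | None = None
) -> np.ndarray:
    """Canonical hashes of all valid windows as a uint64 array (fast path)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if tables is None:
        tables = default_tables()
    values = [
        h for _, h in _base_stream(seq, k, tables.table(level), tables.nmer(level))
    ]
    return np.array(values, dtype=np.uint64)
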