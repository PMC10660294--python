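"""Minimal Bloom filter for the false-positive-rate validation experiment.

An element is represented by ``h`` 64-bit hash values; bit addressing is
plain ``hash mod m``. The theoretical false-positive rate after ``n``
insertions is ``q**h`` with expected occupancy ``q = 1 - (1 - 1/m)**(h*n)``.
"""

from __future__ import annotations

import struct
from typing import Sequence

import numpy as np


class BloomFilter:
    """m-bit Bloom filter addressed by ``h`` hashes per element."""

    def __init__(self, m: int, h: int):
        if m < 1:
            raise ValueError("m must be >= 1")
        if h < 1:
            raise ValueError("h must be >= 1")
        self.m = int(m)
        self.h = int(h)
        self.bits = np.zeros(self.m, dtype=bool)
        self.n_inserted = 0

    def _positions(self, hashes: Sequence[int]) -> np.ndarray:
        hashes = np.asarray(hashes, dtype=np.uint64)
        if hashes.shape[-1] != self.h:
            raise ValueError(
                f"expected {self.h} hashes per element, got {hashes.shape[-1]}"
            )
        return hashes % np.uint64(self.m)

    def insert(self, hashes: Sequence[int]) -> "BloomFilter":
        """Insert one element given its ``h`` hash values."""
        self.bits[self._positions(hashes)] = True
        self.n_inserted += 1
        return self

    def contains(self, hashes: Sequence[int]) -> bool:
        """True iff all ``h`` addressed bits are set (never a false negative)."""
        return bool(self.bits[self._positions(hashes)].all())

    def insert_many(self, hash_matrix: np.ndarray) -> "BloomFilter":
        """Insert ``n`` elements from an (n, h) uint64 hash matrix."""
        pos = self._positions(np.atleast_2d(hash_matrix))
        self.bits[pos.ravel()] = True
        self.n_inserted += pos.shape[0]
        return self

    def contains_many(self, hash_matrix: np.ndarray) -> np.ndarray:
        """Vectorized membership query: (n, h) hashes -> (n,) booleans."""
        pos = self._positions(np.atleast_2d(hash_matrix))
        return self.bits[pos].all(axis=1)

    @property
    def occupancy(self) -> float:
        """Fraction of set bits."""
        return float(self.bits.sum()) / self.m

    # binary layout: magic, little-endian u64 m, u32 h, u64 n_inserted,
    # then ceil(m/8) bytes of bit-packed array (LSB-first within each byte)
    _MAGIC = b"AABF\x01"

    def save(self, path) -> None:
        packed = np.packbits(self.bits, bitorder="little")
        with open(path, "wb") as fh:
            fh.write(self._MAGIC)
            fh.write(struct.pack("<QIQ", self.m, self.h, self.n_inserted))
            fh.write(packed.tobytes())

    @classmethod
    def load(cls, path) -> "BloomFilter":
        with open(path, "rb") as fh:
            magic = fh.read(len(cls._MAGIC))
            if magic != cls._MAGIC:
                raise ValueError("not a Bloom filter file")
            m, h, n_inserted = struct.unpack("<QIQ", fh.read(20))
            packed = np.frombuffer(fh.read(), dtype=np.uint8)
        bf = cls(m, h)
        bf.bits = np.unpackbits(packed, count=m, bitorder="little").astype(bool)
        bf.n_inserted = n_inserted
        return bf


def theoretical_fpr(m: int, n: int, h: int) -> float:
    """Expected false-positive rate of an m-bit filter holding n elements."""
    if m < 1 or h < 1 or n < 0:
        raise ValueError("require m >= 1, h >= 1, n >= 0")
    q = 1.0 - (1.0 - 1.0 / m) ** (h * n)
    return q**h


def size_for_occupancy(n: int, occupancy: float) -> int:
    """Bits needed so that n single-hash insertions reach a target occupancy.

    Solves ``1 - (1 - 1/m)**n = occupancy`` for m.
    """
    if not 0 < occupancy < 1:
        raise ValueError("occupancy must be in (0, 1)")
    return max(1, round(-n / np.log1p(-occupancy)))
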