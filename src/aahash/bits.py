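"""64-bit split-register rotation primitive.

The hash recurrences are built from ``srol``, a "rotate-and-swap" that treats
a 64-bit word as two independent cyclic registers: a 33-bit low register
(bits 0..32) and a 31-bit high register (bits 33..63), each rotated left by
one. Because gcd(33, 31) = 1, a state with activity in both registers only
returns to itself after lcm(33, 31) = 1023 applications — far beyond any k-mer
length used in practice — whereas a plain 64-bit rotate has period 64.

``srol`` is a bit permutation, hence bijective and linear over XOR; both
properties are load-bearing (the n-mer tables and the rolling recurrence rely
on them).
"""

from __future__ import annotations

MASK64 = (1 << 64) - 1
_LOW_BITS = 33
_HIGH_BITS = 31
_LOW_MASK = (1 << _LOW_BITS) - 1
_HIGH_MASK = (1 << _HIGH_BITS) - 1

#: Number of srol applications after which every 64-bit word returns to
#: itself: lcm(33, 31).
SROL_PERIOD = _LOW_BITS * _HIGH_BITS  # 1023


def srol(x: int) -> int:
    """Rotate the low 33 bits and the high 31 bits of ``x`` left by one.

    Equivalent to a 64-bit rotate-left-by-one followed by swapping bit
    positions 0 and 33.
    """
    low = x & _LOW_MASK
    high = (x >> _LOW_BITS) & _HIGH_MASK
    low = ((low << 1) | (low >> (_LOW_BITS - 1))) & _LOW_MASK
    high = ((high << 1) | (high >> (_HIGH_BITS - 1))) & _HIGH_MASK
    return (high << _LOW_BITS) | low


def srol_n(x: int, n: int) -> int:
    """Apply :func:`srol` ``n`` times, in O(1).

    The two registers rotate independently, so the composition reduces to
    rotating the low register by ``n mod 33`` and the high register by
    ``n mod 31``. ``n`` may be any integer; negative values undo rotations.
    """
    rl = n % _LOW_BITS
    rh = n % _HIGH_BITS
    low = x & _LOW_MASK
    high = (x >> _LOW_BITS) & _HIGH_MASK
    low = ((low << rl) | (low >> (_LOW_BITS - rl))) & _LOW_MASK if rl else low
    high = ((high << rh) | (high >> (_HIGH_BITS - rh))) & _HIGH_MASK if rh else high
    return (high << _LOW_BITS) | low


def popcount(x: int) -> int:
    """Number of set bits in ``x``."""
    return int(x).bit_count()
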