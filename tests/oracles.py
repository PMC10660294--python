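"""Independent reference implementations used only as test oracles.

Everything here is written from the definitions, not from the package's
optimized code paths: the split rotation permutes an explicit list of bits,
and the reference k-mer hash iterates that rotation one application at a
time. Slow on purpose.
"""


def srol_oracle(x: int) -> int:
    """Split rotation as an explicit permutation of a 64-entry bit list.

    Bits 0..32 form one cycle, bits 33..63 another; each bit moves up one
    position within its cycle.
    """
    bits = [(x >> i) & 1 for i in range(64)]
    out = [0] * 64
    for i in range(33):
        out[(i + 1) % 33] = bits[i]
    for i in range(33, 64):
        out[33 + (i - 33 + 1) % 31] = bits[i]
    return sum(b << i for i, b in enumerate(out))


def srol_n_oracle(x: int, n: int) -> int:
    for _ in range(n):
        x = srol_oracle(x)
    return x


def hash_oracle(kmer: str, seeds: dict) -> int:
    """Reference k-mer hash: XOR of each residue's seed rotated k-1-j times."""
    k = len(kmer)
    h = 0
    for j, ch in enumerate(kmer):
        h ^= srol_n_oracle(seeds[ch], k - 1 - j)
    return h
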