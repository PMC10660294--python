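# aahash

Recursive multi-level hashing for amino-acid k-mers, with a statistical
validation harness.

K-mer hashing sits under many protein bioinformatics workflows — k-mer
counting, sketching, Bloom-filter membership, seed-and-extend homology
search. Generic string hashes recompute each window from scratch and know
nothing about amino-acid biochemistry. `aahash` provides a *rolling* hash
specialized to the 20-letter amino-acid alphabet: each residue maps to a
balanced 64-bit seed word, a k-mer hashes to

```
H(s) = srol^(k-1)(h(s₀)) ⊕ srol^(k-2)(h(s₁)) ⊕ … ⊕ h(s₍k-1₎)
```

and sliding the window costs O(1):

```
H(sᵢ) = srol(H(sᵢ₋₁)) ⊕ srol^k(h(outgoing)) ⊕ h(incoming)
```

`srol` is a split-register rotation (33-bit low / 31-bit high halves, each
rotated left by one) with period lcm(33, 31) = 1023 instead of a plain
rotation's 64, so residue contributions don't wrap for any practical k.

On top of the exact (level-1) hash, two degenerate levels derived from
BLOSUM62 make biochemically similar k-mers collide on purpose: level 2
shares one seed within each zone of mutually positive-scoring residues
(e.g. {I,L,M,V}, {F,W,Y}), level 3 widens the rule to nonnegative scores.
Per-position level patterns ("12231…") generalize spaced seeds with graded
similarity instead of don't-care positions. A minimal Bloom filter,
multi-hash derivation (h pseudo-independent hashes per k-mer), synthetic
peptide generation, and the full statistical validation pipeline
(uniformity histogram + Kolmogorov–Smirnov, Box–Muller normality and
independence, Bloom-filter false-positive rates with paired t-tests) are
included. See `docs/methods.md` for the model and design details.

## Worked example

Library use — hash a peptide at level 1 and level 2:

```python
>>> import aahash
>>> t = aahash.default_tables()
>>> hex(aahash.hash_base("MKTAYIAKQR", t.table(1), t.nmer(1)))
'0x6c5f94426c7e2803'
>>> hex(aahash.hash_base("MKTAYIAKQR", t.table(2), t.nmer(2)))
'0xd0c9c08e55b921a1'
>>> hex(aahash.hash_base("MKTAYLAKQR", t.table(2), t.nmer(2)))   # I -> L
'0xd0c9c08e55b921a1'
```

The level-1 values of the two variants differ, but at level 2 the I→L
substitution (BLOSUM62 score +2, same degeneracy zone) hashes identically —
the collision is the feature.

Command line — simulate a 250-residue peptide and hash its 25-mers with
three hashes per k-mer:

```sh
$ aahash simulate -n 1 -l 250 --seed 42 -o demo.fa
$ aahash hash demo.fa -k 25 -n 3 | head -4
# aahash 0.1.0 config: {"command": "hash", "hashes": 3, "input": "demo.fa", "k": 25, "level": 1, "pattern": null}
peptide_0	0	a2f596f41e66f17a	ab0029f1eb60b657	4bd25f68240d44a1
peptide_0	1	e9808d03dbb7b764	b070f4b3668585f0	3878571b26c806ba
peptide_0	2	51c0243ac7f34128	7c394a962c8a3c55	9803bb88ebf5a361
```

A 250-mer has 250 − 25 + 1 = 226 windows, so the command emits 226 rows;
column 2 is the 0-based window start and the remaining columns are the
hashes in hex (first = canonical, the rest derived for Bloom-filter use).

Evaluate hash quality on a scaled-down run (100,000 25-mer hashes, 100
bins):

```sh
$ aahash eval-uniformity --hashes 100000 --bins 100 -k 25 --seed 1
level	k	n_hashes	bins	mean	sd	ks_stat	ks_p
1	25	100000	100	1000.0000	30.6434	0.002009	0.8134
```

The mean bin count is exactly N/bins; the sd is near the multinomial
expectation sqrt(N·p(1−p)) ≈ 31.5, and the K-S p-value of 0.81 means the
normalized hashes are indistinguishable from Uniform(0,1). The companion
commands `eval-boxmuller` and `eval-bloom` run the independence and
false-positive experiments the same way.

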