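# Methods

## The hash function

`aahash` is a recursive (rolling) hash for k-mers over the 20-letter
amino-acid alphabet Σ = {A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y}. Each
residue maps to a fixed 64-bit seed word h(·); a k-mer s hashes to

    H(s) = srol^(k-1)(h(s[0])) ⊕ srol^(k-2)(h(s[1])) ⊕ … ⊕ h(s[k-1])

and sliding the window one residue right costs O(1):

    H(s') = srol(H(s)) ⊕ srol^k(h(outgoing)) ⊕ h(incoming).

`srol` treats the 64-bit word as two independent cyclic registers — bits
0–32 (33 bits) and bits 33–63 (31 bits) — each rotated left by one. A plain
64-bit rotation has period 64, so for k near or above 64 the leading
residue's contribution would wrap onto later ones; the split rotation raises
the period to lcm(33, 31) = 1023, far beyond practical k. The split is
pinned by that requirement: 33 + 31 is the unique two-register partition of
64 bits with lcm 1023. An equivalent formulation is rotate-left-by-one
followed by swapping bit positions 0 and 33. `srol` is a bit permutation,
hence bijective and linear over XOR; linearity is what lets precomputed
dimer/trimer tables (`srol(h(a)) ⊕ h(b)`, etc.) bootstrap the first window
hash bit-identically to the scalar recurrence, and bijectivity is what makes
the rolling update information-preserving.

### Seed words

The 20 level-1 seeds are generated once from a fixed PRNG seed
(`CANONICAL_RNG_SEED = 0xAA`, stdlib Mersenne Twister, whose 64-bit integer
stream is platform-stable), rejecting candidates whose popcount falls
outside [30, 34]. Balanced words keep each output bit near fair-coin
behaviour under XOR combination. The exact constants are therefore arbitrary
but frozen; only their statistical properties matter, and those are what the
test suite pins. `seed_tables.export_tsv` dumps them for audit.

## Degeneracy levels

Levels 2 and 3 make biochemically similar k-mers collide on purpose.
Residues are partitioned into zones; all members of a zone share one seed
(the level-1 seed of the zone's lexicographically smallest member, a
deterministic tie-break), so any within-zone substitution leaves the hash
unchanged.

Zone membership comes from BLOSUM62 (embedded as constants and cross-checked
against Biopython's copy in the tests): level 2 groups residues that score
positively with each other; level 3 widens the rule to nonnegative scores.
We require *mutual* similarity — every pair inside a zone must satisfy the
rule. The alternative reading, connected components of the similarity graph,
was implemented first and rejected by measurement: BLOSUM62's positive-score
graph is connected through chains such as W–Y–H–N–S–A, so components collapse
level 2 to five zones and level 3 to just two ({P} and the other 19
residues). With two seeds, a 100-mer window's hash depends only on its
proline positions; the ~0.6% of windows with no proline all hash to a single
value, and the level-3 uniformity histogram degenerates (measured bin-count
sd ≈ 410 against the multinomial expectation ≈ 31.6, K-S p ≈ 0). Mutual
similarity is also what justifies sharing a seed in the first place: a zone
member should resemble every sequence the zone makes it interchangeable
with.

The clique construction is deterministic: level 2 assigns each residue, in
lexicographic order, to the first zone where it scores positively with all
current members, else opens a new zone; level 3 starts from the level-2
zones and greedily merges zone pairs (ordered by smallest member) whose
cross-zone scores are all nonnegative. Level 3 therefore coarsens level 2 by
construction. The resulting zones are

    level 2: {A,S} {C} {D,E} {F,W,Y} {G} {H,N} {I,L,M,V} {K,Q,R} {P} {T}
    level 3: {A,G,S} {C} {D,E} {F,W,Y} {H,N} {I,L,M,V} {K,Q,R} {P} {T}

These match classic reduced amino-acid alphabets (aliphatic, aromatic,
acidic/amide, basic groups). Greedy assignment order is a genuine design
freedom; lexicographic order was fixed before any evaluation and is treated
as canonical for this package. Reference implementations of the same idea
may group differently; only within-zone hash equality, cross-zone hash
distinctness, and the uniformity statistics below are contractual.

Multi-level patterns assign a level per position ("1223…"), a graded
analogue of spaced seeds: a level-2/3 position tolerates substitutions
within its zone rather than being ignored outright. Pattern hashes are
recomputed in O(k) per window because with mixed per-position tables the
outgoing term no longer telescopes; a rolling formulation would need
per-level partial states and is noted as an optimization, not attempted.

### Multi-hashing

Bloom filters need h hash values per element. Index 0 is the canonical hash
untouched; index i > 0 multiplies it by an odd 64-bit constant derived from
(i, k) and applies the splitmix64 finalizer (xor-shift/multiply rounds).
This is constant-time per extra hash and empirically uniform (the derived
values pass a K-S uniformity test at α = 0.01 over 10^5 random bases; the
Bloom experiment below exercises joint behaviour at h = 3 and 5).

### Invalid residues

Ambiguity codes (B, J, O, U, X, Z, *) are not hashable. Streaming over a
sequence skips every window that covers such a character and re-initializes
rolling at the next fully valid window, mirroring how DNA k-mer tools treat
N. FASTA input is uppercased on read and never filtered at I/O time.
Single-k-mer hashing of an invalid residue raises an error naming the
character and offset.

## Validation pipeline

All experiments run on synthetic peptides: residues i.i.d. uniform over the
20 letters, from a seeded PCG64 integer stream (no float state, so streams
are platform-stable). Real proteomes have biased residue composition and
repeats; the synthetic model matches the randomized design of the validation
experiments, so passing tests demonstrate distributional quality of the hash
under random input, not performance on any particular proteome. The
evaluation drivers default to seed `0xAA`; every report records its seed.

1. **Uniformity.** Hash all 1,000,000 100-mers of one random sequence of
   length 1,000,099, normalize by 2^64 − 1, and bin into 1000 equal-width
   bins on [0, 1] (right edge inclusive). The mean count is exactly
   N/bins = 1000; under perfect uniformity counts are
   Multinomial(10^6, 1/1000), giving sd ≈ sqrt(N·p(1−p)) ≈ 31.6. Measured:
   sd ≈ 31.2 / 31.6 / 30.4 for levels 1 / 2 / 3 at the default seed, with
   one-sample two-sided K-S tests against Uniform(0,1) all non-significant
   at α = 0.05 (scipy implementation).
2. **Box–Muller.** Adjacent normalized hash pairs (U0, U1) map to
   Z0 = sqrt(−2 ln U0)·cos(2πU1), Z1 = sqrt(−2 ln U0)·sin(2πU1). Pairs are
   non-overlapping (positions 0&1, 2&3, …) by default so U0 and U1 come from
   disjoint windows; overlapping pairing is available as an option. Pairs
   with U0 = 0 (hash 0, probability 2^-64 per window) are dropped, not
   clamped. The first 1000 Z0 and Z1 values are tested with Shapiro–Wilk
   (1000 is comfortably below the implementation's n = 5000 ceiling) and
   their Pearson correlation is reported with standard error
   1/sqrt(n−3) ≈ 0.032. Because the transform is a bijection, normal and
   independent outputs imply uniform and independent inputs.
3. **Bloom-filter false positives.** A filter of m bits is sized so that
   10^6 single-hash insertions reach 11.8% occupancy
   (m = −n/ln(1−0.118) ≈ 7.96·10^6 bits). Parameterizing by this load
   factor rather than an absolute filter size keeps the experiment scale-free
   and makes the occupancy-model rates come out at 11.8% / 3.1% / 2.2% for
   h = 1 / 3 / 5. For each k ∈ {25, 50, 100} and h ∈ {1, 3, 5}, 10^6
   k-mers from seeded random peptides (250 residues each) are inserted and
   10^5 k-mers from an independently seeded set are queried; every hit is a
   false positive. Empirical rates carry the binomial standard error
   sqrt(p̂(1−p̂)/n_queries) and are compared with the occupancy model
   q^h, q = 1 − (1 − 1/m)^(h·n); a two-sided paired t-test per h across the
   k conditions flags systematic deviation (degenerate inputs — fewer than
   two conditions or zero-variance differences — yield NaN rather than a
   fabricated statistic). Insert/query overlap above 0.1% triggers a
   warning, since shared k-mers bias the rate upward; with random 25-mers
   over a 20-letter alphabet the expected overlap is effectively zero.

Problem sizes in the shipped tests are the study conditions themselves
(10^6 hashes per histogram, 10^6 Bloom insertions, n = 1000 for the
normality checks); the rolling hot loop makes a million windows in about a
second, so no scaling down was needed.

## Numerical and degenerate-input choices

* Hash values are Python ints masked to 64 bits in the scalar path and
  `uint64` in the vectorized paths; the two are tested bit-identical.
* Normalization divides by 2^64 − 1, so 0 → 0.0 and the all-ones hash → 1.0
  exactly.
* `k` greater than the sequence length yields an empty stream, not an error;
  `k < 1` and `h < 1` are parameter errors.
* Histogram bins are equal-width on [0, 1] with the right edge included in
  the last bin (numpy semantics); bin-count sd is the population sd (ddof 0).
* The Shapiro–Wilk range [3, 5000] is enforced; larger samples must be
  sliced by the caller, as the drivers do.

## Known limitations

* The hash is empirically uniform, not formally uniform — recursive cyclic
  hashing cannot be — and the split rotation only guarantees non-wrapping
  contributions for k < 1023.
* Zone memberships depend on the greedy assignment order and on BLOSUM62;
  other substitution matrices (e.g. PAM) and more than three levels are out
  of scope.
* Pattern-mode hashing is O(k) per window, not rolling.
* The Bloom filter is the minimal textbook variant (mod-m addressing, no
  blocking or counting), sufficient for the validation experiment it exists
  for.
* Throughput comparisons against general-purpose string hashes are
  hardware- and implementation-bound and are deliberately not part of this
  package; the property and distribution tests stand in for them.
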