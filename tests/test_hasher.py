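"""Base hash, rolling recurrence, multi-hashing, patterns, streaming."""

import random

import numpy as np
import pytest
from scipy import stats

from aahash.hasher import (
    HashState,
    InvalidResidueError,
    hash_base,
    hash_values,
    iterate_sequence,
    multi_hash,
    multi_hash_array,
    parse_pattern,
    pattern_hash,
    roll,
)
from aahash.seed_tables import AMINO_ACIDS
from aahash.simdata import random_sequence

from .oracles import hash_oracle


def random_kmer(rng, k):
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(k))


class TestHashBase:
    def test_single_residue_is_its_seed(self, tables):
        table = tables.table(1)
        assert hash_base("A", table) == table.seed("A")

    def test_two_residues(self, tables):
        from aahash.bits import srol

        table = tables.table(1)
        assert hash_base("AC", table) == srol(table.seed("A")) ^ table.seed("C")

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6, 7, 11, 25, 64, 100, 200])
    def test_matches_independent_oracle(self, tables, k):
        """n-mer-table fast path is bit-identical to the naive definition."""
        rng = random.Random(k)
        table = tables.table(1)
        nm = tables.nmer(1)
        for _ in range(5):
            kmer = random_kmer(rng, k)
            expected = hash_oracle(kmer, dict(table.seeds))
            assert hash_base(kmer, table, nm) == expected
            assert hash_base(kmer, table) == expected

    def test_lowercase_accepted(self, tables):
        table = tables.table(1)
        assert hash_base("acd", table) == hash_base("ACD", table)

    def test_invalid_residue_names_char_and_offset(self, tables):
        with pytest.raises(InvalidResidueError) as err:
            hash_base("ACXDE", tables.table(1))
        assert err.value.char == "X"
        assert err.value.offset == 2

    def test_empty_kmer_rejected(self, tables):
        with pytest.raises(ValueError):
            hash_base("", tables.table(1))


class TestRoll:
    def test_roll_equals_direct_hash_small(self, tables):
        table = tables.table(1)
        state = HashState(k=2, level=1, value=hash_base("AC", table), position=0)
        rolled = roll(state, "A", "D", table)
        assert rolled.value == hash_base("CD", table)
        assert rolled.position == 1

    def test_homopolymer_roll_is_fixed_point(self, tables):
        table = tables.table(1)
        h = hash_base("AA", table)
        state = HashState(k=2, level=1, value=h, position=0)
        assert roll(state, "A", "A", table).value == h

    def test_full_scan_matches_direct_hashes(self, tables):
        """All 226 rolled hashes of a 250-mer at k=25 equal direct hashes."""
        seq = random_sequence(250, 1234)
        table = tables.table(1)
        values = hash_values(seq, 25)
        assert len(values) == 226
        for i, v in enumerate(values):
            assert int(v) == hash_base(seq[i : i + 25], table, tables.nmer(1))

    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_rolling_direct_equivalence_random_instances(self, tables, level):
        rng = random.Random(level)
        table = tables.table(level)
        nm = tables.nmer(level)
        for _ in range(30):
            n = rng.randint(5, 120)
            k = rng.randint(1, n)
            seq = random_kmer(rng, n)
            for pos, value in zip(range(n - k + 1), hash_values(seq, k, level=level)):
                assert int(value) == hash_base(seq[pos : pos + k], table, nm)

    def test_invalid_incoming_invalidates_state(self, tables):
        table = tables.table(1)
        state = HashState(k=2, level=1, value=hash_base("AC", table), position=0)
        assert not roll(state, "A", "X", table).valid


class TestMultiHash:
    def test_single_hash_is_canonical(self):
        assert multi_hash(12345, 1, 25) == [12345]

    def test_deterministic_and_first_is_base(self):
        a = multi_hash(987654321, 5, 50)
        b = multi_hash(987654321, 5, 50)
        assert a == b
        assert a[0] == 987654321
        assert len(set(a)) == 5

    def test_h_below_one_rejected(self):
        with pytest.raises(ValueError):
            multi_hash(1, 0, 25)

    def test_array_path_matches_scalar(self):
        rng = random.Random(5)
        bases = np.array([rng.getrandbits(64) for _ in range(200)], dtype=np.uint64)
        arr = multi_hash_array(bases, 5, 25)
        for row, base in zip(arr, bases):
            assert list(map(int, row)) == multi_hash(int(base), 5, 25)

    def test_derived_hashes_uniform(self):
        """Index-1 values over 1e5 random bases pass K-S uniformity (a=0.01)."""
        rng = np.random.Generator(np.random.PCG64(77))
        bases = rng.integers(0, 2**64, size=100_000, dtype=np.uint64)
        derived = multi_hash_array(bases, 2, 25)[:, 1]
        u = derived.astype(np.float64) / float(2**64 - 1)
        assert stats.kstest(u, "uniform").pvalue >= 0.01


class TestPatternHash:
    def test_all_level1_pattern_equals_base_hash(self, tables):
        kmer = "ACDEFGHIK"
        assert pattern_hash(kmer, (1,) * 9, tables) == hash_base(
            kmer, tables.table(1), tables.nmer(1)
        )

    def test_degenerate_position_tolerates_in_group_substitution(self, tables):
        # I and L share a level-2 zone: a level-2 position cannot tell them apart
        assert pattern_hash("AI", (1, 2), tables) == pattern_hash("AL", (1, 2), tables)

    def test_levels_are_positional(self, tables):
        assert pattern_hash("IA", (2, 1), tables) == pattern_hash("LA", (2, 1), tables)
        assert pattern_hash("AI", (2, 1), tables) != pattern_hash("AL", (2, 1), tables)

    def test_length_mismatch_rejected(self, tables):
        with pytest.raises(ValueError):
            pattern_hash("ACD", (1, 2), tables)

    def test_parse_pattern(self):
        assert parse_pattern("1231") == (1, 2, 3, 1)
        with pytest.raises(ValueError):
            parse_pattern("1241")
        with pytest.raises(ValueError):
            parse_pattern("")


class TestIterateSequence:
    def test_250mer_yields_226_windows(self):
        seq = random_sequence(250, 42)
        records = list(iterate_sequence(seq, 25))
        assert len(records) == 226
        assert [r.position for r in records] == list(range(226))

    def test_invalid_residue_skips_covering_windows(self, tables):
        records = list(iterate_sequence("ACXDE", 2))
        assert [r.position for r in records] == [0, 3]
        assert records[0].hashes[0] == hash_base("AC", tables.table(1))
        assert records[1].hashes[0] == hash_base("DE", tables.table(1))

    def test_k_equal_to_length_single_window(self):
        assert len(list(iterate_sequence("ACDEF", 5))) == 1

    def test_k_longer_than_sequence_empty_stream(self):
        assert list(iterate_sequence("ACD", 4)) == []

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            list(iterate_sequence("ACD", 0))

    def test_multi_hash_records(self):
        records = list(iterate_sequence("ACDEF", 3, level=1, h=3))
        assert all(len(r.hashes) == 3 for r in records)
        assert records[0].hashes == tuple(multi_hash(records[0].hashes[0], 3, 3))

    def test_pattern_mode_matches_pattern_hash(self, tables):
        seq = random_sequence(40, 8)
        pattern = parse_pattern("12312")
        records = list(iterate_sequence(seq, 5, level=pattern))
        assert len(records) == 36
        for r in records:
            assert r.hashes[0] == pattern_hash(seq[r.position : r.position + 5], pattern, tables)

    def test_streams_are_reproducible(self):
        seq = random_sequence(100, 5)
        a = [r.hashes for r in iterate_sequence(seq, 10, h=3)]
        b = [r.hashes for r in iterate_sequence(seq, 10, h=3)]
        assert a == b


class TestLevelDegeneracy:
    def test_within_group_substitutions_preserve_hash(self, tables):
        """Any within-zone substitution at any position leaves the hash
        unchanged at that level."""
        rng = random.Random(11)
        for level in (2, 3):
            seq = random_kmer(rng, 30)
            base_hash = hash_base(seq, tables.table(level), tables.nmer(level))
            for pos in range(30):
                group = tables.partition(level).group_of(seq[pos])
                for sub in group:
                    mutated = seq[:pos] + sub + seq[pos + 1 :]
                    assert (
                        hash_base(mutated, tables.table(level), tables.nmer(level))
                        == base_hash
                    )

    def test_cross_group_substitutions_change_hash(self, tables):
        rng = random.Random(13)
        for level in (2, 3):
            partition = tables.partition(level)
            seq = random_kmer(rng, 30)
            for _ in range(40):
                pos = rng.randrange(30)
                sub = rng.choice(AMINO_ACIDS)
                if sub in partition.group_of(seq[pos]):
                    continue
                mutated = seq[:pos] + sub + seq[pos + 1 :]
                assert hash_base(mutated, tables.table(level), tables.nmer(level)) != hash_base(
                    seq, tables.table(level), tables.nmer(level)
                )
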