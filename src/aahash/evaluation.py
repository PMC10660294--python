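"""Statistical validation of the hash function.

Three complementary checks, all on seeded synthetic peptides:

1. **Uniformity** — hash every k-mer of a long random sequence, normalize by
   2^64 - 1, histogram into equal-width bins, and test the normalized values
   against Uniform(0, 1) with a one-sample Kolmogorov–Smirnov test. A good
   hash gives bin counts ~ Multinomial(N, 1/bins), i.e. mean N/bins and
   standard deviation near sqrt(N * p * (1-p)).

2. **Box–Muller independence** — pairs of uniform variates (U0, U1) map to
   independent standard normals Z0 = sqrt(-2 ln U0) cos(2 pi U1),
   Z1 = sqrt(-2 ln U0) sin(2 pi U1). Feeding adjacent normalized k-mer hashes
   through the transform and checking Z0/Z1 for normality (Shapiro–Wilk) and
   mutual correlation (Pearson) probes both uniformity and pairwise
   independence of the hash stream: the transform is a bijection, so normal
   and independent outputs imply uniform and independent inputs.

3. **Bloom-filter false positives** — load a filter with k-mers from random
   peptides, query k-mers from disjoint random peptides (every hit is a false
   positive), and compare the empirical rate with the occupancy-based
   prediction ``q**h``; a paired two-sided t-test across conditions flags a
   systematic deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

from . import bloom as bloom_mod
from .bloom import BloomFilter, size_for_occupancy, theoretical_fpr
from .hasher import hash_values, multi_hash_array
from .seed_tables import LevelTables, default_tables
from .simdata import random_peptides, random_sequence

MAX_HASH = float(2**64 - 1)

#: Default seed for the evaluation drivers; recorded in every report.
DEFAULT_SEED = 0xAA


class DegenerateInputError(ValueError):
    """Statistic undefined for this input (e.g. zero-variance differences)."""


# ---------------------------------------------------------------------------
# uniformity


@dataclass(frozen=True)
class UniformityReport:
    level: int
    k: int
    n_hashes: int
    bins: int
    bin_counts: np.ndarray = field(repr=False)
    mean: float
    sd: float
    ks_stat: float
    ks_p: float
    rng_seed: int


def normalize_hashes(values: Sequence[int] | np.ndarray) -> np.ndarray:
    """Map 64-bit hashes to [0, 1] by dividing by 2^64 - 1."""
    return np.asarray(values, dtype=np.uint64).astype(np.float64) / MAX_HASH


def uniformity_histogram(values: np.ndarray, bins: int) -> tuple[np.ndarray, float, float]:
    """Equal-width histogram on [0, 1]; returns (counts, mean, sd of counts)."""
    values = np.asarray(values, dtype=np.float64)
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("values must lie in [0, 1]")
    counts, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return counts, float(counts.mean()), float(counts.std())


def ks_uniform(values: np.ndarray) -> tuple[float, float]:
    """Two-sided one-sample K-S test against Uniform(0, 1)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("K-S test needs a nonempty sample")
    res = stats.kstest(values, "uniform")
    return float(res.statistic), float(res.pvalue)


def uniformity_experiment(
    level: int = 1,
    n_hashes: int = 1_000_000,
    k: int = 100,
    bins: int = 1000,
    rng_seed: int = DEFAULT_SEED,
    tables: LevelTables | None = None,
) -> UniformityReport:
    """Histogram + K-S uniformity check on the hashes of one long random
    sequence (length ``n_hashes + k - 1``, so exactly ``n_hashes`` windows)."""
    seq = random_sequence(n_hashes + k - 1, rng_seed)
    hashes = hash_values(seq, k, level=level, tables=tables)
    normalized = normalize_hashes(hashes)
    counts, mean, sd = uniformity_histogram(normalized, bins)
    ks_stat, ks_p = ks_uniform(normalized)
    return UniformityReport(
        level=level,
        k=k,
        n_hashes=len(hashes),
        bins=bins,
        bin_counts=counts,
        mean=mean,
        sd=sd,
        ks_stat=ks_stat,
        ks_p=ks_p,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Box-Muller


def adjacent_pairs(values: Iterable[float], overlapping: bool = False) -> Iterator[tuple[float, float]]:
    """Pair up consecutive normalized hashes.

    Non-overlapping pairing (positions 0&1, 2&3, ...) is the default so U0
    and U1 come from disjoint windows; ``overlapping=True`` pairs every
    consecutive position instead.
    """
    values = list(values)
    if overlapping:
        yield from zip(values, values[1:])
    else:
        it = iter(values)
        yield from zip(it, it)


def box_muller(u0: np.ndarray, u1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map uniform pairs to standard-normal pairs.

    Pairs with U0 == 0 (hash value 0, probability ~2^-64 per window) are
    dropped rather than clamped, to avoid an infinite radius.
    """
    u0 = np.asarray(u0, dtype=np.float64)
    u1 = np.asarray(u1, dtype=np.float64)
    keep = u0 > 0
    u0, u1 = u0[keep], u1[keep]
    r = np.sqrt(-2.0 * np.log(u0))
    return r * np.cos(2.0 * np.pi * u1), r * np.sin(2.0 * np.pi * u1)


def normality_check(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk test; sample size must be in [3, 5000]."""
    sample = np.asarray(sample, dtype=np.float64)
    if not 3 <= sample.size <= 5000:
        raise ValueError("Shapiro-Wilk sample size must be in [3, 5000]")
    res = stats.shapiro(sample)
    return float(res.statistic), float(res.pvalue)


def independence_check(z0: np.ndarray, z1: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between Z0 and Z1 with its standard error
    ~ 1/sqrt(n - 3)."""
    z0 = np.asarray(z0, dtype=np.float64)
    z1 = np.asarray(z1, dtype=np.float64)
    if z0.size != z1.size:
        raise ValueError("Z0 and Z1 must have equal length")
    if z0.size < 3:
        raise ValueError("need at least 3 pairs")
    r, _ = stats.pearsonr(z0, z1)
    return float(r), 1.0 / np.sqrt(z0.size - 3)


@dataclass(frozen=True)
class BoxMullerReport:
    level: int
    k: int
    n: int
    shapiro_w_z0: float
    shapiro_p_z0: float
    shapiro_w_z1: float
    shapiro_p_z1: float
    pearson_r: float
    pearson_se: float
    rng_seed: int


def box_muller_experiment(
    level: int = 1,
    k: int = 100,
    n: int = 1000,
    rng_seed: int = DEFAULT_SEED,
    tables: LevelTables | None = None,
    overlapping: bool = False,
) -> BoxMullerReport:
    """Transform adjacent normalized hash pairs and test the first ``n``
    Z0/Z1 values for normality and mutual independence."""
    n_windows = 2 * n + 2  # a little slack in case a pair is dropped
    seq = random_sequence(n_windows + k - 1, rng_seed)
    normalized = normalize_hashes(hash_values(seq, k, level=level, tables=tables))
    pairs = np.array(list(adjacent_pairs(normalized, overlapping=overlapping)))
    z0, z1 = box_muller(pairs[:, 0], pairs[:, 1])
    z0, z1 = z0[:n], z1[:n]
    w0, p0 = normality_check(z0)
    w1, p1 = normality_check(z1)
    r, se = independence_check(z0, z1)
    return BoxMullerReport(
        level=level,
        k=k,
        n=int(z0.size),
        shapiro_w_z0=w0,
        shapiro_p_z0=p0,
        shapiro_w_z1=w1,
        shapiro_p_z1=p1,
        pearson_r=r,
        pearson_se=se,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Bloom-filter false-positive experiment


@dataclass(frozen=True)
class FprCondition:
    k: int
    h: int
    n_inserted: int
    n_queries: int
    empirical_fpr: float
    empirical_se: float
    theoretical_fpr: float
    occupancy: float


@dataclass(frozen=True)
class FprReport:
    conditions: tuple[FprCondition, ...]
    # paired empirical-vs-theoretical t-test per h, across k conditions
    ttests: dict[int, tuple[float, float]]
    m_bits: int
    target_occupancy: float
    rng_seed: int


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student's t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.var(x - y) == 0:
        raise DegenerateInputError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def _kmer_hashes(
    n_kmers: int, k: int, level: int, seq_length: int, rng_seed: int, tables
) -> np.ndarray:
    """Base hashes of ``n_kmers`` k-mers taken from random peptides."""
    per_seq = seq_length - k + 1
    n_seqs = -(-n_kmers // per_seq)
    peptides = random_peptides(n_seqs, seq_length, rng_seed)
    chunks = [hash_values(seq, k, level=level, tables=tables) for seq in peptides.sequences()]
    return np.concatenate(chunks)[:n_kmers]


def fpr_experiment(
    k_values: Sequence[int] = (25, 50, 100),
    h_values: Sequence[int] = (1, 3, 5),
    n_insert: int = 1_000_000,
    n_query: int = 100_000,
    target_occupancy: float = 0.118,
    seq_length: int = 250,
    level: int = 1,
    rng_seed: int = DEFAULT_SEED,
    tables: LevelTables | None = None,
    overlap_warn_threshold: float = 0.001,
) -> FprReport:
    """False-positive-rate experiment across (k, h) conditions.

    One filter per condition, all of the same size ``m``, chosen so that
    ``n_insert`` single-hash insertions reach ``target_occupancy`` (0.118 by
    default, which puts the theoretical rates at 11.8% / 3.1% / 2.2% for
    h = 1 / 3 / 5). Insert and query k-mers come from independently seeded
    peptide sets; any overlap above ``overlap_warn_threshold`` is warned
    about since shared k-mers would bias the false-positive rate upward.
    """
    if tables is None:
        tables = default_tables()
    m = size_for_occupancy(n_insert, target_occupancy)
    conditions: list[FprCondition] = []
    for ki, k in enumerate(k_values):
        base_insert = _kmer_hashes(
            n_insert, k, level, seq_length, rng_seed + 2 * ki, tables
        )
        base_query = _kmer_hashes(
            n_query, k, level, seq_length, rng_seed + 2 * ki + 1, tables
        )
        shared = np.intersect1d(base_insert, base_query).size / n_query
        if shared > overlap_warn_threshold:
            import warnings

            warnings.warn(
                f"insert/query k-mer overlap {shared:.2%} at k={k} "
                "will bias the false-positive rate upward",
                stacklevel=2,
            )
        for h in h_values:
            bf = BloomFilter(m, h)
            bf.insert_many(multi_hash_array(base_insert, h, k))
            hits = bf.contains_many(multi_hash_array(base_query, h, k))
            p_hat = float(hits.mean())
            se = float(np.sqrt(p_hat * (1 - p_hat) / n_query))
            conditions.append(
                FprCondition(
                    k=k,
                    h=h,
                    n_inserted=n_insert,
                    n_queries=n_query,
                    empirical_fpr=p_hat,
                    empirical_se=se,
                    theoretical_fpr=theoretical_fpr(m, n_insert, h),
                    occupancy=bf.occupancy,
                )
            )
    ttests: dict[int, tuple[float, float]] = {}
    for h in h_values:
        emp = [c.empirical_fpr for c in conditions if c.h == h]
        theo = [c.theoretical_fpr for c in conditions if c.h == h]
        try:
            ttests[h] = paired_ttest(emp, theo)
        except ValueError:  # single condition or zero-variance differences
            ttests[h] = (float("nan"), float("nan"))
    return FprReport(
        conditions=tuple(conditions),
        ttests=ttests,
        m_bits=m,
        target_occupancy=target_occupancy,
        rng_seed=rng_seed,
    )


# re-exported for convenience of the CLI and scripts
__all__ = [
    "DEFAULT_SEED",
    "UniformityReport",
    "BoxMullerReport",
    "FprCondition",
    "FprReport",
    "DegenerateInputError",
    "normalize_hashes",
    "uniformity_histogram",
    "ks_uniform",
    "uniformity_experiment",
    "adjacent_pairs",
    "box_muller",
    "normality_check",
    "independence_check",
    "box_muller_experiment",
    "paired_ttest",
    "fpr_experiment",
    "theoretical_fpr",
    "bloom_mod",
]
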