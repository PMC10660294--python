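"""Synthetic peptide generation and FASTA I/O.

The validation experiments run entirely on simulated data: random peptide
sequences with residues drawn i.i.d. uniformly over the 20-letter alphabet,
reproducible from an integer seed (PCG64 integer stream, no float state).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seed_tables import AMINO_ACIDS


class FastaFormatError(ValueError):
    """Malformed or empty FASTA input."""


@dataclass(frozen=True)
class PeptideSet:
    """Named peptide sequences plus the seed that generated them (if any)."""

    records: tuple[tuple[str, str], ...]
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]


def random_peptides(n: int, length: int, rng_seed: int) -> PeptideSet:
    """``n`` random peptides of ``length`` residues, uniform over the alphabet."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    draws = rng.integers(0, len(AMINO_ACIDS), size=(n, length))
    records = tuple(
        (f"peptide_{i}", alphabet[row].tobytes().decode())
        for i, row in enumerate(draws)
    )
    return PeptideSet(records=records, rng_seed=rng_seed)


def random_sequence(length: int, rng_seed: int) -> str:
    """One random peptide sequence of ``length`` residues."""
    return random_peptides(1, length, rng_seed).records[0][1]


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> PeptideSet:
    """Read a FASTA file (gzip-transparent); residues are uppercased.

    Sequences are not filtered: ambiguity codes survive the read and are
    handled downstream by the hasher's window-invalidation rule.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise FastaFormatError(f"{path}: empty FASTA file (line 1)")
        if not first.startswith(">"):
            raise FastaFormatError(
                f"{path}: line 1 does not start with '>' — not FASTA"
            )
    with _open_text(path) as fh:
        records = tuple(
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")
        )
    return PeptideSet(records=records)


def write_fasta(peptides: PeptideSet, path, width: int = 60) -> None:
    """Write peptides as wrapped FASTA (gzip-transparent by extension)."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in peptides.records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)
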