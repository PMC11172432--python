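"""Sequence and pair-table input/output, tokenization and length normalization.

Proteins are carried as :class:`ProteinRecord` (id + uppercase amino-acid
string).  Labeled pairs come from 2- or 3-column TSV tables.  For the
embedding channel of the predictor, sequences are converted to fixed-length
integer token sequences: tokens 0-19 are the 20 standard residues in
alphabetical one-letter order, tokens 20-24 the five non-standard codes
(B, O, U, X, Z), and token 25 is right-padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Alphabetical one-letter codes of the 20 standard amino acids -> tokens 0..19.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Non-standard residue codes -> tokens 20..24; any other letter folds into X.
NONSTANDARD_RESIDUES = "BOUXZ"

#: Padding token appended on the right of short sequences.
PAD_TOKEN = 25

#: Total vocabulary size for the embedding layer (20 + 5 + padding).
VOCAB_SIZE = 26

_TOKEN_OF = {aa: i for i, aa in enumerate(STANDARD_RESIDUES)}
_TOKEN_OF.update({aa: 20 + i for i, aa in enumerate(NONSTANDARD_RESIDUES)})
_X_TOKEN = _TOKEN_OF["X"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty sequence, duplicate id)."""


class PairTableError(ValueError):
    """Raised for malformed pair tables (bad label, wrong column count)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier plus uppercase amino-acid string."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairExample:
    """A protein pair; ``label`` is 1 (interacting), 0, or None (unlabeled)."""

    id_a: str
    id_b: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise PairTableError(
                f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1, "
                f"got {self.label!r}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records; uppercase sequences, reject duplicate ids."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).strip()
        if not seq:
            raise FastaParseError(f"record {entry.id!r} in {path} has an empty sequence")
        records.append(ProteinRecord(entry.id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (one entry per record)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_pair_table(path: str | Path, header: bool = False) -> list[PairExample]:
    """Read a 2- or 3-column TSV of protein pairs.

    Columns are id_a, id_b and an optional {0,1} label.  Unknown ids are not
    checked here; they surface when pairs are joined with sequence records.
    """
    df = pd.read_csv(
        str(path), sep="\t", header=0 if header else None, dtype=str,
        keep_default_na=False,
    )
    if df.shape[1] not in (2, 3):
        raise PairTableError(
            f"{path}: expected 2 or 3 tab-separated columns, found {df.shape[1]}"
        )
    pairs: list[PairExample] = []
    for row in df.itertuples(index=False):
        label: Optional[int] = None
        if len(row) == 3:
            raw = row[2].strip()
            if raw not in ("0", "1"):
                raise PairTableError(
                    f"{path}: label must be 0 or 1, got {raw!r} for pair "
                    f"({row[0]}, {row[1]})"
                )
            label = int(raw)
        pairs.append(PairExample(str(row[0]), str(row[1]), label))
    return pairs


def write_pair_table(pairs: Iterable[PairExample], path: str | Path) -> None:
    """Write pairs as TSV; the label column is included when any pair has one."""
    pairs = list(pairs)
    with open(path, "w") as fh:
        for p in pairs:
            if p.label is None:
                fh.write(f"{p.id_a}\t{p.id_b}\n")
            else:
                fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")


def tokenize(sequence: str) -> list[int]:
    """Map residues to tokens 0..24 (unknown letters fold into the X token)."""
    return [_TOKEN_OF.get(aa, _X_TOKEN) for aa in sequence.upper()]


def tokenize_and_pad(record: ProteinRecord, n: int) -> list[int]:
    """Fixed-length token encoding: right-truncate to ``n`` or right-pad with 25."""
    if n < 1:
        raise ValueError(f"fixed length must be >= 1, got {n}")
    toks = tokenize(record.sequence)[:n]
    toks.extend([PAD_TOKEN] * (n - len(toks)))
    return toks


def detokenize(tokens: Sequence[int]) -> str:
    """Inverse of :func:`tokenize` for tokens 0..24; stops at the first pad."""
    letters = STANDARD_RESIDUES + NONSTANDARD_RESIDUES
    out = []
    for t in tokens:
        if t == PAD_TOKEN:
            break
        out.append(letters[t])
    return "".join(out)


def mean_sequence_length(records: Sequence[ProteinRecord]) -> int:
    """Floor of the mean sequence length; the default fixed length N."""
    if not records:
        raise ValueError("mean_sequence_length requires a non-empty collection")
    return math.floor(sum(len(r) for r in records) / len(records))


def records_by_id(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index records by id, rejecting duplicates."""
    index: dict[str, ProteinRecord] = {}
    for r in records:
        if r.id in index:
            raise FastaParseError(f"duplicate record id {r.id!r}")
        index[r.id] = r
    return index
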