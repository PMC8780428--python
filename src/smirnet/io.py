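"""Readers and writers for the pipeline's external formats.

Formats are deliberately plain: FASTA for miRNA sequences, a two-column
id/SMILES table (TSV or CSV), a two-column association TSV, and a labelled
similarity-matrix TSV.  All dialects are fixed and round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Nucleotide alphabet used for miRNA sequences.  Sequences are stored
#: DNA-style (U is mapped to T on read); N is the wildcard and '-' the gap.
MIRNA_ALPHABET = ("A", "C", "G", "T", "N", "-")


class EmptyCorpusError(ValueError):
    """Raised when a corpus file contains no records."""


class DuplicateIdentifierError(ValueError):
    """Raised when two records in one corpus share an identifier."""


class MalformedRowError(ValueError):
    """Raised for a table row with the wrong number of columns."""


class EmptyAssociationError(ValueError):
    """Raised when no association survives id filtering."""


@dataclass(frozen=True)
class SequenceRecord:
    """One identified biological string: a miRNA sequence or a SMILES.

    ``domain`` declares the alphabet the text lives in ("mirna" or
    "smiles"); miRNA text is normalised (uppercase, U->T, unknown
    nucleotides -> N) while SMILES text is kept verbatim because SMILES is
    case-significant.
    """

    id: str
    text: str
    domain: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.text:
            raise ValueError(f"record {self.id!r} has empty text")
        if self.domain not in ("mirna", "smiles"):
            raise ValueError(f"unknown domain {self.domain!r}")

    def __len__(self) -> int:
        return len(self.text)


@dataclass
class AssociationList:
    """Known small molecule-miRNA links plus the two entity orderings.

    ``pairs`` has set semantics: duplicates collapse, order is immaterial.
    Every pair references ids present in ``sm_ids`` / ``mirna_ids``.
    """

    pairs: set[tuple[str, str]]
    sm_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        sm_set, mi_set = set(self.sm_ids), set(self.mirna_ids)
        for s, m in self.pairs:
            if s not in sm_set or m not in mi_set:
                raise ValueError(f"pair ({s}, {m}) references unknown entity")

    def __len__(self) -> int:
        return len(self.pairs)

    def matrix(self) -> np.ndarray:
        """Binary |SM| x |miRNA| incidence matrix in entity-list order."""
        a = np.zeros((len(self.sm_ids), len(self.mirna_ids)), dtype=float)
        srow = {s: i for i, s in enumerate(self.sm_ids)}
        mcol = {m: j for j, m in enumerate(self.mirna_ids)}
        for s, m in self.pairs:
            a[srow[s], mcol[m]] = 1.0
        return a

    def partners_of_sm(self, sm_id: str) -> set[str]:
        return {m for s, m in self.pairs if s == sm_id}

    def partners_of_mirna(self, mirna_id: str) -> set[str]:
        return {s for s, m in self.pairs if m == mirna_id}


def normalize_mirna_text(text: str) -> str:
    """Uppercase, map U->T, and map unknown nucleotide letters to N.

    The gap character '-' is preserved; it is part of the declared
    miRNA alphabet.
    """
    out = []
    for ch in text.upper():
        if ch == "U":
            ch = "T"
        if ch not in MIRNA_ALPHABET:
            ch = "N"
        out.append(ch)
    return "".join(out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a miRNA FASTA corpus.

    The id is the header token up to the first whitespace.  Sequences are
    normalised via :func:`normalize_mirna_text`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdentifierError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, normalize_mirna_text(str(rec.seq)), "mirna")
        )
    if not records:
        raise EmptyCorpusError(f"no FASTA records in {path}")
    return records


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_smiles_table(path: str | Path) -> list[SequenceRecord]:
    """Read a two-column id/SMILES table (TSV or CSV).

    An optional header row is recognised by the token "smiles"
    (case-insensitive) in the second column.  SMILES text is kept verbatim.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(_sniff_delimiter(line))
            if len(fields) != 2:
                raise MalformedRowError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            ident, smiles = fields[0].strip(), fields[1].strip()
            if lineno == 1 and smiles.lower() == "smiles":
                continue
            if ident in seen:
                raise DuplicateIdentifierError(f"duplicate id {ident!r} in {path}")
            seen.add(ident)
            records.append(SequenceRecord(ident, smiles, "smiles"))
    if not records:
        raise EmptyCorpusError(f"no SMILES rows in {path}")
    return records


def read_associations(
    path: str | Path,
    sm_corpus: Sequence[SequenceRecord],
    mirna_corpus: Sequence[SequenceRecord],
) -> AssociationList:
    """Read a sm_id/mirna_id TSV, restricted to ids present in both corpora.

    Pairs referencing unknown ids are dropped with a logged count;
    duplicate rows collapse (set semantics).
    """
    path = Path(path)
    sm_ids = [r.id for r in sm_corpus]
    mirna_ids = [r.id for r in mirna_corpus]
    sm_set, mi_set = set(sm_ids), set(mirna_ids)
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise MalformedRowError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            s, m = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (s.lower(), m.lower()) == ("sm_id", "mirna_id"):
                continue
            if s in sm_set and m in mi_set:
                pairs.add((s, m))
            else:
                dropped += 1
    if dropped:
        logger.warning("dropped %d association rows with unknown ids", dropped)
    if not pairs:
        raise EmptyAssociationError(f"no valid associations in {path}")
    return AssociationList(pairs=pairs, sm_ids=sm_ids, mirna_ids=mirna_ids)


def write_associations(assoc: AssociationList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sm_id\tmirna_id\n")
        for s, m in sorted(assoc.pairs):
            fh.write(f"{s}\t{m}\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.text}\n")


def write_smiles_table(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsmiles\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.text}\n")


def write_matrix(ids: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    """Write a labelled square matrix as TSV with full float precision."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    if len(ids) != values.shape[0]:
        raise ValueError("label count does not match matrix size")
    df = pd.DataFrame(values, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labelled square matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"matrix file {path} is not square: {df.shape[0]} rows x {df.shape[1]} cols"
        )
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if ids != cols:
        raise ValueError(f"matrix file {path}: row labels differ from column labels")
    return ids, df.to_numpy(dtype=float)
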