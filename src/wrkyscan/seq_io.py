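"""Protein FASTA and tabular expression / Ct I/O.

All other modules consume the record types defined here.  Sequences are
upper-case strings over the 20 standard amino acids plus ``X`` for unknown
residues; coordinates throughout the package are 0-based, half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 standard residues plus X (unknown).  Degenerate codes (B, Z, U, J, O)
#: are rejected unless explicitly mapped to X by the caller.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_DEGENERATE = frozenset("BZUJO")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class ValidationError(ValueError):
    """A record violates the model invariants (alphabet, uniqueness...)."""


class TableParseError(ValueError):
    """Malformed delimited expression / Ct table."""


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein sequence.

    Parameters
    ----------
    id : str
        Unique, non-empty identifier (first whitespace-delimited header token).
    description : str
        Remainder of the FASTA header; may be empty.
    sequence : str
        Upper-case amino-acid string over :data:`AMINO_ALPHABET`, length >= 1.
    """

    id: str
    description: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)}; "
                "allowed are the 20 standard amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str, record_id: str, permissive: bool) -> str:
    seq = raw.upper().rstrip("*")
    if permissive:
        seq = "".join("X" if c in _DEGENERATE else c for c in seq)
    return seq


def read_fasta(path, *, permissive: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are upper-cased and trailing stop symbols (``*``) stripped.
    Duplicate ids raise :class:`ValidationError`.  With ``permissive=True``
    the degenerate codes B/Z/U/J/O are mapped to X instead of rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first = text.strip().splitlines()[0]
        raise FastaParseError(f"not FASTA: first non-blank line {first!r} lacks '>'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = _normalize_sequence(str(rec.seq), rec.id, permissive)
        records.append(ProteinRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, *, width: int = 60) -> None:
    """Write records as multi-line FASTA; round-trips through :func:`read_fasta`."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    with path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


@dataclass
class ExpressionMatrix:
    """Gene x condition grid of log2-scale expression values with a missing mask.

    ``values`` is a float DataFrame (genes as rows, condition labels as
    columns); ``mask`` is a congruent boolean DataFrame, True where the value
    was missing in the source (the paper's "black boxes": transcripts absent
    from a dataset).  Masked cells hold NaN in ``values``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.values.isna()
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate condition labels")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold table.

    One row per well: sample label, gene id, replicate Ct value, plus optional
    treatment and timepoint (hours) annotations.  Reactions are typically run
    in triplicate; every (sample, gene) group must have >= 1 finite, positive
    Ct.
    """

    data: pd.DataFrame

    REQUIRED = ("sample", "gene", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table missing column(s) {missing}")
        ct = pd.to_numeric(self.data["ct"], errors="coerce")
        if ct.isna().any() or not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValidationError("Ct values must be finite and positive")
        self.data = self.data.assign(ct=ct.astype(float))

    def replicate_means(self) -> pd.DataFrame:
        """Mean and sd of Ct per (sample, gene) group."""
        g = self.data.groupby(["sample", "gene"])["ct"]
        return g.agg(mean="mean", sd="std", n="size").reset_index()


def read_expression_table(
    path, *, missing_token: str = "NA", sep: str = "\t"
) -> ExpressionMatrix:
    """Read a delimited gene x condition table into an :class:`ExpressionMatrix`.

    Cells equal to ``missing_token`` become masked; any other non-numeric cell
    raises :class:`TableParseError` naming its row and column.
    """
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableParseError(str(exc)) from exc
    mask = df.eq(missing_token)
    numeric = df.mask(mask).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mask
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise TableParseError(
            f"non-numeric cell at gene {gene!r}, column {col!r}: "
            f"{df.loc[gene, col]!r}"
        )
    return ExpressionMatrix(values=numeric.astype(float), mask=mask)


def write_expression_table(
    expr: ExpressionMatrix, path, *, missing_token: str = "NA", sep: str = "\t"
) -> None:
    out = expr.values.where(~expr.mask, other=np.nan)
    out.to_csv(path, sep=sep, na_rep=missing_token)


def read_ct_table(path, *, sep: str = "\t") -> CtTable:
    """Read a long-format Ct table (columns sample, gene, ct[, treatment, timepoint])."""
    df = pd.read_csv(path, sep=sep)
    return CtTable(df)


def write_ct_table(ct: CtTable, path, *, sep: str = "\t") -> None:
    ct.data.to_csv(path, sep=sep, index=False)
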