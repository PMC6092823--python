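"""Alignment container, readers, trimming, and per-position result tables.

The central object is :class:`Alignment`, an immutable rectangular block of
aligned protein sequences.  Symbols are the 20 standard amino acids, the gap
``'-'`` and ``'X'`` for anything non-standard.  On ingest (``read_alignment``)
lowercase letters are uppercased, ``'.'`` gaps become ``'-'`` and ambiguous or
non-standard letters (B, Z, J, U, O, ``*`` ...) are mapped to ``'X'``;
``'X'`` is excluded from amino-acid counts everywhere downstream but still
counts toward column totals, like a gap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"


class AlignmentError(ValueError):
    """Invalid alignment input or operation."""


class RaggedAlignmentError(AlignmentError):
    """Rows of unequal length."""


@dataclass(frozen=True)
class Alignment:
    """Rectangular multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    rows
        Equal-length aligned sequences.
    column_index
        1-based provenance of each column in the original (untrimmed)
        alignment.  Defaults to ``1..n_col``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    column_index: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must have the same length")
        if len(self.ids) != len(set(self.ids)):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise AlignmentError(f"duplicate sequence id: {dup!r}")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise RaggedAlignmentError(
                        f"ragged alignment: sequence {sid!r} has length "
                        f"{len(row)}, expected {n}"
                    )
        if not self.column_index:
            object.__setattr__(
                self, "column_index", tuple(range(1, self.n_col + 1))
            )
        elif len(self.column_index) != self.n_col:
            raise AlignmentError("column_index length must equal n_col")

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def n_col(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise KeyError(f"unknown sequence id: {sid!r}") from None

    def column(self, col: int) -> str:
        """Column as a string; ``col`` is 1-based."""
        if not 1 <= col <= self.n_col:
            raise AlignmentError(f"column {col} out of range 1..{self.n_col}")
        return "".join(r[col - 1] for r in self.rows)

    def to_array(self) -> np.ndarray:
        """(n_seq, n_col) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")


_STANDARD = set(AA_ALPHABET) | {GAP, UNKNOWN}


def _normalize_row(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        elif ch not in _STANDARD:
            ch = UNKNOWN
        out.append(ch)
    return "".join(out)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    Raises
    ------
    RaggedAlignmentError
        If rows have unequal lengths (names the offending id).
    AlignmentError
        On duplicate ids or an empty file.
    """
    if format not in ("fasta", "clustal"):
        raise AlignmentError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "clustal"))
        except ValueError as exc:
            raise AlignmentError(f"cannot parse clustal file {path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"empty alignment file: {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(_normalize_row(str(r.seq)) for r in records)
    return Alignment(ids=ids, rows=rows)


def trim_alignment(
    a: Alignment,
    drop_ids: Iterable[str] = (),
    drop_cols: Iterable[int] = (),
) -> Alignment:
    """Return a copy without the named rows and 1-based columns.

    Column provenance (original 1-based indices) is carried in
    ``column_index`` so trimmed results still report original positions.
    """
    drop_ids = set(drop_ids)
    drop_cols = set(drop_cols)
    unknown = drop_ids - set(a.ids)
    if unknown:
        raise AlignmentError(f"unknown ids to drop: {sorted(unknown)}")
    bad = {c for c in drop_cols if not 1 <= c <= a.n_col}
    if bad:
        raise AlignmentError(f"columns out of range: {sorted(bad)}")
    keep_rows = [i for i, sid in enumerate(a.ids) if sid not in drop_ids]
    keep_cols = [j for j in range(a.n_col) if (j + 1) not in drop_cols]
    if len(keep_rows) < 2:
        raise AlignmentError("trimming would leave fewer than 2 sequences")
    if len(keep_cols) < 1:
        raise AlignmentError("trimming would leave no columns")
    return Alignment(
        ids=tuple(a.ids[i] for i in keep_rows),
        rows=tuple(
            "".join(a.rows[i][j] for j in keep_cols) for i in keep_rows
        ),
        column_index=tuple(a.column_index[j] for j in keep_cols),
    )


@dataclass
class ProfileTable:
    """Per-alignment-column result table.

    ``data`` holds one row per column with at least a ``column`` field
    (1-based alignment position); ``orientation`` maps each metric column to
    ``"variability"`` or ``"conservation"``.
    """

    data: pd.DataFrame
    orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "column" not in self.data.columns:
            raise AlignmentError("ProfileTable requires a 'column' field")


def write_profile_csv(table: ProfileTable, path: str | Path) -> None:
    """Write an RFC-4180 CSV; floats at 6 significant digits, missing cells
    empty (no sentinel text)."""
    table.data.to_csv(path, index=False, float_format="%.6g", na_rep="")


def read_profile_csv(path: str | Path,
                     orientation: Mapping[str, str] | None = None) -> ProfileTable:
    df = pd.read_csv(path)
    return ProfileTable(data=df, orientation=dict(orientation or {}))
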