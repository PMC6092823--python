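"""Structural compartments, PDB missing-residue correction, residue mapping.

A *compartment* is a named set of structure residues that are dispersed in
sequence but adjacent in the tertiary structure — tunnel linings, gates,
binding sites.  Compartment tables arrive as simple whitespace-delimited
text (residue number, residue name, optional numeric features).  Structure
software often numbers residues sequentially over the residues it actually
observes, while sequences use author numbering; the REMARK 465 section of a
PDB file lists the unobserved residues, which is all that is needed to
convert between the two.  Only that header section is ever read —
coordinates are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio.SeqUtils import seq1

from .msa import GAP, Alignment, AlignmentError

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_AA1 = {seq1(x) for x in _AA3}


class StructureError(ValueError):
    """Invalid compartment table, PDB record, or residue mapping."""


@dataclass(frozen=True)
class CompartmentResidue:
    number: int
    name: str  # one-letter code
    features: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Compartment:
    """Named set of structure residues with optional numeric features."""

    name: str
    residues: tuple[CompartmentResidue, ...]
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if len(numbers) != len(set(numbers)):
            dup = next(n for n in numbers if numbers.count(n) > 1)
            raise StructureError(
                f"duplicate residue number {dup} in compartment {self.name!r}"
            )

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(r.number for r in self.residues)


def _one_letter(name: str, row: int) -> str:
    name = name.upper()
    if len(name) == 3:
        if name not in _AA3:
            raise StructureError(f"row {row}: unknown residue name {name!r}")
        return seq1(name)
    if len(name) == 1:
        if name not in _AA1:
            raise StructureError(f"row {row}: unknown residue code {name!r}")
        return name
    raise StructureError(f"row {row}: residue name must be 1 or 3 letters, got {name!r}")


def read_compartment_table(path: str | Path, name: str | None = None) -> Compartment:
    """Parse a compartment table.

    Whitespace- or tab-delimited with a header line: residue number,
    residue name (1- or 3-letter), then zero or more named numeric feature
    columns.  A missing trailing feature cell yields a record without that
    feature, with a warning.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise StructureError(f"empty compartment table: {path}")
    header = lines[0].split()
    if len(header) < 2:
        raise StructureError("header must name at least number and name columns")
    feature_names = tuple(header[2:])
    residues = []
    for rowno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        try:
            number = int(parts[0])
        except ValueError:
            raise StructureError(
                f"row {rowno}: residue number {parts[0]!r} is not an integer"
            ) from None
        code = _one_letter(parts[1], rowno)
        cells = parts[2:]
        if len(cells) < len(feature_names):
            warnings.warn(
                f"row {rowno}: {len(feature_names) - len(cells)} missing "
                "feature cell(s)"
            )
        features = {}
        for fname, cell in zip(feature_names, cells):
            try:
                features[fname] = float(cell)
            except ValueError:
                raise StructureError(
                    f"row {rowno}: feature {fname!r} value {cell!r} is not numeric"
                ) from None
        residues.append(CompartmentResidue(number, code, features))
    return Compartment(
        name=name or path.stem,
        residues=tuple(residues),
        feature_names=feature_names,
    )


def read_missing_residues(pdb_path: str | Path) -> dict[str, list[int]]:
    """Author residue numbers listed in REMARK 465, per chain.

    Records are parsed from the fixed columns of ``REMARK 465`` lines
    (residue name, chain id, author sequence number, insertion code);
    header/preamble lines without a residue name are skipped.  Insertion
    codes are rejected — sequential renumbering is undefined with them.
    """
    missing: dict[str, list[int]] = {}
    for line in Path(pdb_path).read_text().splitlines():
        if not line.startswith("REMARK 465"):
            continue
        resname = line[15:18].strip()
        if resname not in _AA3:
            continue  # preamble / column-header lines
        chain = line[19:20].strip()
        seqnum = line[21:26].strip()
        icode = line[26:27].strip()
        if icode:
            raise StructureError(
                f"REMARK 465 insertion code {icode!r} at {chain}{seqnum} "
                "is not supported"
            )
        if not chain or not seqnum:
            raise StructureError(f"malformed REMARK 465 record: {line!r}")
        missing.setdefault(chain, []).append(int(seqnum))
    for chain in missing:
        missing[chain].sort()
    return missing


def sequential_to_author(index: int, missing: set[int], n_res: int | None = None) -> int:
    """Author number of the ``index``-th observed residue (1-based), with
    author numbering assumed contiguous from 1 except for ``missing``."""
    if index < 1:
        raise StructureError(f"sequential index must be >= 1, got {index}")
    if n_res is not None:
        n_observed = n_res - len([m for m in missing if 1 <= m <= n_res])
        if index > n_observed:
            raise StructureError(
                f"sequential index {index} exceeds observed residue count "
                f"{n_observed}"
            )
    author, seen = 0, 0
    while seen < index:
        author += 1
        if author not in missing:
            seen += 1
    return author


def author_to_sequential(author: int, missing: set[int]) -> int:
    """Inverse of :func:`sequential_to_author`."""
    if author in missing:
        raise StructureError(f"author residue {author} is missing from the structure")
    return author - len([m for m in missing if m < author])


def correct_numbering(
    c: Compartment,
    pdb_path: str | Path,
    chain: str,
    n_res: int | None = None,
) -> Compartment:
    """Convert a compartment from sequential (observed-residue) numbering to
    author numbering using REMARK 465.

    A chain with no missing residues — or absent from REMARK 465 entirely —
    yields the identity mapping (with a notice in the latter case).
    ``n_res`` (total author residues), when known, bounds the observed
    count so out-of-range indices fail loudly.
    """
    all_missing = read_missing_residues(pdb_path)
    if chain not in all_missing:
        warnings.warn(
            f"chain {chain!r} has no REMARK 465 entries; numbering unchanged"
        )
        missing: set[int] = set()
    else:
        missing = set(all_missing[chain])
    new = tuple(
        replace(r, number=sequential_to_author(r.number, missing, n_res))
        for r in c.residues
    )
    return Compartment(name=c.name, residues=new, feature_names=c.feature_names)


@dataclass(frozen=True)
class ResidueMap:
    """Mapping from reference residue numbers (1-based over the ungapped
    reference row) to 1-based alignment columns; strictly increasing."""

    ref_id: str
    columns: tuple[int, ...]  # columns[r-1] = column of residue r

    def column_of(self, residue: int) -> int:
        if not 1 <= residue <= len(self.columns):
            raise StructureError(
                f"residue {residue} outside 1..{len(self.columns)} for "
                f"reference {self.ref_id!r}"
            )
        return self.columns[residue - 1]

    def columns_for(self, c: Compartment) -> set[int]:
        bad = [r.number for r in c.residues if not 1 <= r.number <= len(self.columns)]
        if bad:
            raise StructureError(
                f"compartment {c.name!r} residues beyond reference length "
                f"{len(self.columns)}: {bad}"
            )
        return {self.column_of(r.number) for r in c.residues}

    def complement_columns(self, c: Compartment, n_col: int) -> set[int]:
        return set(range(1, n_col + 1)) - self.columns_for(c)


def build_residue_map(a: Alignment, ref_id: str) -> ResidueMap:
    """Map each residue of the reference row to its alignment column."""
    row = a.row(ref_id)
    cols = tuple(j + 1 for j, ch in enumerate(row) if ch != GAP)
    if not cols:
        raise AlignmentError(f"reference row {ref_id!r} is all gaps")
    return ResidueMap(ref_id=ref_id, columns=cols)
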