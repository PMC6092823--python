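"""Seedable synthetic fixtures: alignments with tunable per-column
conservation, and toy structure bundles with known missing residues.

The MSA generator emulates the features that matter for validating
conservation analysis — a per-column conservation knob, gap blocks that
mimic extra domains or large insertions, and duplicate-sequence clusters
that mimic taxonomic bias.  It does not simulate a phylogeny or a
substitution process; columns are independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.SeqUtils import seq3

from .msa import AA_ALPHABET, GAP, Alignment, AlignmentError
from .structure import sequential_to_author

_AA = np.array(list(AA_ALPHABET))


@dataclass(frozen=True)
class GapBlock:
    """Columns ``start..end`` (1-based, inclusive) gapped in a random
    ``fraction`` of the sequences."""

    start: int
    end: int
    fraction: float


@dataclass(frozen=True)
class DuplicateCluster:
    """``copies`` rows immediately after row ``source`` (0-based) are
    replaced by copies of it, each with ``substitutions`` random point
    substitutions."""

    source: int
    copies: int
    substitutions: int = 0


@dataclass(frozen=True)
class MsaSpec:
    """Recipe for a synthetic alignment.

    ``conservation`` is either one level for all columns or one per column;
    level 1 forces an invariant column, level 0 is near-uniform.
    """

    n_seq: int
    n_col: int
    conservation: float | tuple[float, ...] = 0.5
    gap_blocks: tuple[GapBlock, ...] = ()
    duplicate_clusters: tuple[DuplicateCluster, ...] = ()
    seed: int = 0

    def conservation_levels(self) -> np.ndarray:
        c = np.asarray(
            self.conservation
            if not np.isscalar(self.conservation)
            else [self.conservation] * self.n_col,
            dtype=float,
        )
        if c.shape != (self.n_col,):
            raise AlignmentError("conservation must be scalar or length n_col")
        if (c < 0).any() or (c > 1).any():
            raise AlignmentError("conservation levels must lie in [0, 1]")
        return c

    def validate(self) -> None:
        if self.n_seq < 2 or self.n_col < 1:
            raise AlignmentError("need n_seq >= 2 and n_col >= 1")
        self.conservation_levels()
        for b in self.gap_blocks:
            if not (1 <= b.start <= b.end <= self.n_col):
                raise AlignmentError(f"gap block {b} outside 1..{self.n_col}")
            if not 0 <= b.fraction <= 1:
                raise AlignmentError("gap fraction must lie in [0, 1]")
        for d in self.duplicate_clusters:
            if not (0 <= d.source < self.n_seq):
                raise AlignmentError(f"duplicate source {d.source} out of range")
            if d.source + d.copies >= self.n_seq:
                raise AlignmentError("duplicate cluster extends past last row")


def generate_msa(spec: MsaSpec) -> Alignment:
    """Deterministic synthetic alignment from (spec, seed).

    Column residue distributions are Dirichlet draws whose concentration
    piles onto a random focal residue as the conservation level rises;
    level 1 short-circuits to an exactly invariant column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    levels = spec.conservation_levels()
    mat = np.empty((spec.n_seq, spec.n_col), dtype="U1")
    for j in range(spec.n_col):
        focal = rng.integers(20)
        c = levels[j]
        if c >= 1.0:
            mat[:, j] = _AA[focal]
            continue
        alpha = np.full(20, 0.05 + 2.0 * (1.0 - c))
        alpha[focal] += 30.0 * c
        p = rng.dirichlet(alpha)
        mat[:, j] = rng.choice(_AA, size=spec.n_seq, p=p)
    for d in spec.duplicate_clusters:
        for i in range(d.source + 1, d.source + 1 + d.copies):
            mat[i] = mat[d.source]
            for _ in range(d.substitutions):
                col = rng.integers(spec.n_col)
                mat[i, col] = _AA[rng.integers(20)]
    for b in spec.gap_blocks:
        n_gapped = int(round(b.fraction * spec.n_seq))
        rows = rng.choice(spec.n_seq, size=n_gapped, replace=False)
        mat[np.ix_(rows, range(b.start - 1, b.end))] = GAP
    ids = tuple(f"seq{i + 1:03d}" for i in range(spec.n_seq))
    return Alignment(ids=ids, rows=tuple("".join(r) for r in mat))


@dataclass(frozen=True)
class StructureFixture:
    """A mutually consistent toy bundle: reference protein, alignment
    containing it, compartment table in sequential numbering, and a PDB
    fragment whose REMARK 465 lists exactly the missing residues."""

    alignment: Alignment
    ref_id: str
    reference: str  # ungapped reference sequence, author numbering 1..n_res
    chain: str
    missing: tuple[int, ...]
    compartment_table: str
    pdb_text: str
    compartment_indices: tuple[int, ...]  # sequential (observed) numbering
    feature_name: str = "depth"


def generate_structure_fixture(
    n_res: int,
    missing: Sequence[int] = (),
    compartment_indices: Sequence[int] | None = None,
    seed: int = 0,
    n_seq: int = 6,
    chain: str = "A",
) -> StructureFixture:
    """Toy structure bundle for exercising the numbering-correction and
    residue-mapping round trip.

    The compartment table uses sequential numbering over *observed*
    residues; applying the REMARK 465 correction and then the residue map
    must land every record on an alignment column whose reference symbol
    equals the record's residue name.
    """
    missing = tuple(sorted(set(missing)))
    if any(not 1 <= m <= n_res for m in missing):
        raise AlignmentError("missing residues must lie in 1..n_res")
    n_observed = n_res - len(missing)
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(_AA, size=n_res))
    if compartment_indices is None:
        k = min(3, n_observed)
        compartment_indices = tuple(
            sorted(rng.choice(n_observed, size=k, replace=False) + 1)
        )
    else:
        compartment_indices = tuple(compartment_indices)
        if any(not 1 <= i <= n_observed for i in compartment_indices):
            raise AlignmentError(
                f"compartment indices must lie in 1..{n_observed} (observed)"
            )

    # Alignment: reference plus mutated homologs, with an inserted block
    # where the reference is gapped (so columns != residue numbers).
    homologs = []
    for _ in range(n_seq - 1):
        row = list(reference)
        for _ in range(max(1, n_res // 10)):
            pos = rng.integers(n_res)
            row[pos] = _AA[rng.integers(20)]
        homologs.append(row)
    insert_at = int(rng.integers(1, n_res))
    insert_len = 3
    rows = []
    ref_row = reference[:insert_at] + GAP * insert_len + reference[insert_at:]
    rows.append(ref_row)
    for h in homologs:
        ins = "".join(rng.choice(_AA, size=insert_len))
        rows.append("".join(h[:insert_at]) + ins + "".join(h[insert_at:]))
    ids = ("ref",) + tuple(f"hom{i + 1:02d}" for i in range(n_seq - 1))
    alignment = Alignment(ids=ids, rows=tuple(rows))

    feature_name = "depth"
    lines = [f"number name {feature_name}"]
    for idx in compartment_indices:
        author = sequential_to_author(idx, set(missing), n_res)
        name3 = seq3(reference[author - 1]).upper()
        lines.append(f"{idx} {name3} {rng.uniform(0, 1):.3f}")
    compartment_table = "\n".join(lines) + "\n"

    pdb_lines = [
        "REMARK 465",
        "REMARK 465 MISSING RESIDUES",
        "REMARK 465 THE FOLLOWING RESIDUES WERE NOT LOCATED IN THE",
        "REMARK 465 EXPERIMENT. (M=MODEL NUMBER; RES=RESIDUE NAME;",
        "REMARK 465 C=CHAIN IDENTIFIER; SSSEQ=SEQUENCE NUMBER;)",
        "REMARK 465   M RES C SSSEQI",
    ]
    for m in missing:
        name3 = seq3(reference[m - 1]).upper()
        pdb_lines.append(f"REMARK 465     {name3} {chain}{m:>6}")
    pdb_text = "\n".join(pdb_lines) + "\n"

    return StructureFixture(
        alignment=alignment,
        ref_id="ref",
        reference=reference,
        chain=chain,
        missing=missing,
        compartment_table=compartment_table,
        pdb_text=pdb_text,
        compartment_indices=compartment_indices,
        feature_name=feature_name,
    )


def write_fixture_bundle(fix: StructureFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA + compartment TSV + minimal PDB text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "msa": outdir / "msa.fasta",
        "compartment": outdir / "compartment.tsv",
        "pdb": outdir / "structure.pdb",
    }
    with open(paths["msa"], "w") as fh:
        for sid, row in zip(fix.alignment.ids, fix.alignment.rows):
            fh.write(f">{sid}\n{row}\n")
    paths["compartment"].write_text(fix.compartment_table)
    paths["pdb"].write_text(fix.pdb_text)
    return paths
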