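"""Per-column conservation/variability metrics.

Seven metrics are implemented, all reported with a declared orientation
(here: higher = more variable):

* **Shannon** — entropy of the gap-excluded residue frequencies, in nats.
* **Schneider** — Shannon normalised by ln 20, so values lie in [0, 1].
* **Kabat** — k*N/n1: distinct residue types times non-gap depth over the
  majority-residue count; 1 iff the column is invariant.
* **E-score** — a min-max normalised variability built from the dominant
  amino-acid frequency *with gaps in the denominator* divided by the count
  of distinct residue types: P_i = max(p_i)/n_i, P_norm = P_i / max(P),
  E = -ln(P_norm) / max(-ln(P_norm)).  Gaps act as an extra letter that
  dilutes frequencies without entering the entropy itself, so gap-heavy
  columns remain distinguishable.
* **Landgraf** — weighted asymmetric substitution distances, by default
  from the Gonnet matrix: L = sum over ordered residue pairs j != k of
  w_j * (S(a_j,a_j) - S(a_j,a_k)), divided by N(N-1).
* **RET** (real-valued Evolutionary Trace) — 1 plus a sum over successive
  partitions of a UPGMA guide tree of the mean within-group column
  entropies; conserved columns stay at 1.
* **CRE** (cumulative relative entropy) — size-weighted Kullback–Leibler
  divergence of subgroup column distributions from the pooled distribution.

Shannon, Schneider, Kabat and the E-score accept Henikoff weights and
pseudo-count correction; Landgraf accepts weights; RET derives its own
weighting from the guide tree; CRE takes an explicit (or tree-derived)
grouping.  All-gap columns score NaN for every metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .consensus import DistanceMatrix, pairwise_distance_matrix
from .msa import AA_ALPHABET, GAP, UNKNOWN, Alignment, AlignmentError
from .weights import PseudocountSettings, pseudocount_frequencies

WEIGHTABLE_METRICS = ("kabat", "shannon", "schneider", "escore")
ALL_METRICS = WEIGHTABLE_METRICS + ("landgraf", "ret", "cre")


@dataclass(frozen=True)
class ColumnProfile:
    """Symbol bookkeeping for one alignment column.

    ``p`` holds amino-acid frequencies with gaps included in the
    denominator; ``n_types`` counts distinct amino acids with gaps
    excluded.  'X' is excluded from amino-acid counts but contributes to
    ``n_total`` like a gap.
    """

    column: int
    counts: dict[str, float]
    n_total: float
    n_aa: float
    p: dict[str, float]
    n_types: int

    @property
    def is_all_gap(self) -> bool:
        return self.n_aa <= 0


@dataclass(frozen=True)
class ConservationProfile:
    """Named per-column score vector with an orientation contract."""

    metric: str
    values: np.ndarray
    orientation: str = "variability"  # higher = more variable

    def __post_init__(self) -> None:
        if self.orientation not in ("variability", "conservation"):
            raise AlignmentError("orientation must be variability|conservation")
        # +0.0 normalises IEEE negative zeros from -ln(1) etc.
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float) + 0.0
        )


def _residue_symbols(col: str) -> set[str]:
    return {c for c in col if c not in (GAP, UNKNOWN)}


def _column_masses(col: str, weights: np.ndarray | None, n_seq: int) -> dict[str, float]:
    """Per-symbol mass: raw counts, or weight sums scaled to n_seq so that
    pseudo-count arithmetic sees a sample-size-like N."""
    masses: dict[str, float] = {}
    for i, ch in enumerate(col):
        m = weights[i] * n_seq if weights is not None else 1.0
        masses[ch] = masses.get(ch, 0.0) + m
    return masses


def column_profile(
    a: Alignment, col: int, weights: Sequence[float] | None = None
) -> ColumnProfile:
    """Counts and frequencies for 1-based column ``col``."""
    column = a.column(col)
    w = _check_weights(a, weights)
    masses = _column_masses(column, w, a.n_seq)
    n_total = sum(masses.values())
    aa_masses = {s: m for s, m in masses.items() if s not in (GAP, UNKNOWN)}
    n_aa = sum(aa_masses.values())
    p = {s: m / n_total for s, m in aa_masses.items()}
    return ColumnProfile(
        column=col,
        counts=masses,
        n_total=n_total,
        n_aa=n_aa,
        p=p,
        n_types=len(aa_masses),
    )


def _check_weights(a: Alignment, weights: Sequence[float] | None) -> np.ndarray | None:
    if weights is None:
        return None
    w = np.asarray(weights, dtype=float)
    if w.shape != (a.n_seq,):
        raise AlignmentError("weights length must equal n_seq")
    if (w < 0).any():
        raise AlignmentError("weights must be nonnegative")
    return w / w.sum()


def _shannon(freqs: Iterable[float]) -> float:
    return -sum(q * math.log(q) for q in freqs if q > 0)


def _adjusted_frequencies(
    prof: ColumnProfile, pseudocounts: PseudocountSettings | None
) -> tuple[dict[str, float], dict[str, float]]:
    """(gap-excluded frequencies q, gap-in-denominator frequencies p),
    pseudo-corrected when requested."""
    if prof.is_all_gap:
        return {}, {}
    if pseudocounts is None:
        q = {s: m / prof.n_aa for s, m in prof.counts.items()
             if s not in (GAP, UNKNOWN)}
        return q, dict(prof.p)
    aa_counts = {s: m for s, m in prof.counts.items()
                 if s not in (GAP, UNKNOWN)}
    B = pseudocounts.mass(prof.n_types)
    q = pseudocount_frequencies(aa_counts, B, pseudocounts.background)
    scale = prof.n_aa / prof.n_total  # reinstate the gap share of the denominator
    p = {s: v * scale for s, v in q.items()}
    return q, p


def score_alignment(
    a: Alignment,
    metric: str,
    weights: Sequence[float] | None = None,
    pseudocounts: PseudocountSettings | None = None,
) -> ConservationProfile:
    """Score every column with one of kabat/shannon/schneider/escore."""
    if metric not in WEIGHTABLE_METRICS:
        raise AlignmentError(
            f"unknown metric {metric!r}; expected one of {WEIGHTABLE_METRICS}"
        )
    if a.n_seq < 2:
        raise AlignmentError("need at least 2 sequences to score")
    profs = [column_profile(a, j + 1, weights) for j in range(a.n_col)]
    if metric == "escore":
        values = _escore(profs, pseudocounts)
    else:
        values = np.empty(a.n_col)
        for j, prof in enumerate(profs):
            if prof.is_all_gap:
                warnings.warn(f"column {j + 1} is all gaps; score is NaN")
                values[j] = np.nan
                continue
            q, _ = _adjusted_frequencies(prof, pseudocounts)
            if metric == "shannon":
                values[j] = _shannon(q.values())
            elif metric == "schneider":
                values[j] = _shannon(q.values()) / math.log(20)
            else:  # kabat: k*N/n1 == k / max gap-excluded frequency
                values[j] = prof.n_types / max(q.values())
    return ConservationProfile(metric=metric, values=values)


def _escore(
    profs: list[ColumnProfile], pseudocounts: PseudocountSettings | None
) -> np.ndarray:
    P = np.full(len(profs), np.nan)
    for j, prof in enumerate(profs):
        if prof.is_all_gap:
            warnings.warn(f"column {j + 1} is all gaps; score is NaN")
            continue
        _, p = _adjusted_frequencies(prof, pseudocounts)
        P[j] = max(p.values()) / prof.n_types
    finite = np.isfinite(P)
    if not finite.any():
        return P
    Pnorm = P / np.nanmax(P)
    with np.errstate(invalid="ignore"):
        L = -np.log(Pnorm)
    Lmax = np.nanmax(L)
    if Lmax <= 0:
        out = np.where(finite, 0.0, np.nan)
        return out
    return L / Lmax


def load_substitution_matrix(source: str | Path):
    """A substitution matrix by bundled name (e.g. ``GONNET1992``,
    ``BLOSUM62``) or from an NCBI square plain-text file."""
    source = str(source)
    if source in substitution_matrices.load():
        return substitution_matrices.load(source)
    return substitution_matrices.read(source)


def score_landgraf(
    a: Alignment,
    weights: Sequence[float] | None = None,
    matrix=None,
) -> ConservationProfile:
    """Landgraf conservation: weighted asymmetric substitution distances
    d(a->b) = S(a,a) - S(a,b) summed over ordered residue pairs in the
    column and divided by N(N-1); gapped (and 'X') rows are excluded from
    the pair set.  0 iff the column is invariant."""
    if matrix is None:
        matrix = substitution_matrices.load("GONNET1992")
    w = _check_weights(a, weights)
    if w is None:
        w = np.full(a.n_seq, 1.0 / a.n_seq)
    alphabet = set(matrix.alphabet)
    values = np.empty(a.n_col)
    for j in range(a.n_col):
        col = a.column(j + 1)
        idx = [i for i, ch in enumerate(col) if ch not in (GAP, UNKNOWN)]
        if not idx:
            warnings.warn(f"column {j + 1} is all gaps; score is NaN")
            values[j] = np.nan
            continue
        missing = {col[i] for i in idx} - alphabet
        if missing:
            raise AlignmentError(
                f"symbols absent from substitution matrix: {sorted(missing)}"
            )
        n = len(idx)
        if n < 2:
            values[j] = 0.0
            continue
        total = 0.0
        for i in idx:
            ai = col[i]
            sii = matrix[ai, ai]
            for k in idx:
                if k == i:
                    continue
                total += w[i] * (sii - matrix[ai, col[k]])
        values[j] = total / (n * (n - 1))
    return ConservationProfile(metric="landgraf", values=values)


# ---------------------------------------------------------------------------
# UPGMA guide tree, RET and CRE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeNode:
    """Node of an ultrametric guide tree; ``height`` is half the merge
    distance (leaves sit at height 0)."""

    height: float
    children: tuple["TreeNode", ...] = ()
    leaf: str | None = None
    leaves: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.leaf is not None:
            object.__setattr__(self, "leaves", (self.leaf,))
        elif not self.leaves:
            lv: list[str] = []
            for c in self.children:
                lv.extend(c.leaves)
            object.__setattr__(self, "leaves", tuple(sorted(lv)))

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves)

    def cut_top(self, n_groups: int) -> list[tuple[str, ...]]:
        """Partition the leaves into ``n_groups`` groups by successively
        splitting the highest remaining internal node (ties broken by
        lexicographically smallest leaf id)."""
        groups: list[TreeNode] = [self.root]
        while len(groups) < n_groups:
            internal = [g for g in groups if not g.is_leaf]
            if not internal:
                raise AlignmentError(
                    f"cannot cut into {n_groups} groups: only "
                    f"{len(groups)} subtrees available"
                )
            best = max(internal, key=lambda g: (g.height, _neg_key(g.leaves[0])))
            groups.remove(best)
            groups.extend(best.children)
        return [g.leaves for g in groups]

    def cut_at_height(self, h: float) -> list[tuple[str, ...]]:
        """Maximal subtrees whose root height is <= ``h``."""
        groups: list[tuple[str, ...]] = []

        def descend(node: TreeNode) -> None:
            if node.height <= h or node.is_leaf:
                groups.append(node.leaves)
            else:
                for c in node.children:
                    descend(c)

        descend(self.root)
        return groups


class _neg_key:
    """Inverts string ordering so max() picks the lexicographically
    smallest leaf id among equal heights."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_key") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_key) and self.s == other.s


def upgma_tree(d: DistanceMatrix) -> GuideTree:
    """UPGMA agglomeration with arithmetic-mean linkage.

    Node heights are half the merge distance; equal-distance ties are
    broken by the lexicographically smallest pair of cluster labels (each
    cluster labelled by its smallest member id), so the result is
    deterministic.
    """
    n = len(d.ids)
    if n < 2:
        raise AlignmentError("need at least 2 sequences for UPGMA")
    nodes: dict[str, TreeNode] = {
        sid: TreeNode(height=0.0, leaf=sid) for sid in d.ids
    }
    sizes: dict[str, int] = {sid: 1 for sid in d.ids}
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((d.ids[i], d.ids[j]))] = float(d.values[i, j])
    while len(nodes) > 1:
        labels = sorted(nodes)
        best_pair, best_d = None, math.inf
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                dij = dist[frozenset((labels[i], labels[j]))]
                if dij < best_d - 1e-12:
                    best_pair, best_d = (labels[i], labels[j]), dij
                # equal distances: labels are scanned in sorted order, so
                # the first minimal pair is already the lexicographic winner
        x, y = best_pair
        merged = TreeNode(
            height=best_d / 2.0,
            children=tuple(
                sorted((nodes[x], nodes[y]), key=lambda t: t.leaves[0])
            ),
        )
        new_label = min(x, y)
        sx, sy = sizes[x], sizes[y]
        for other in labels:
            if other in (x, y):
                continue
            dxz = dist.pop(frozenset((x, other)))
            dyz = dist.pop(frozenset((y, other)))
            dist[frozenset((new_label, other))] = (sx * dxz + sy * dyz) / (sx + sy)
        dist.pop(frozenset((x, y)))
        for lbl in (x, y):
            del nodes[lbl], sizes[lbl]
        nodes[new_label] = merged
        sizes[new_label] = sx + sy
    return GuideTree(root=next(iter(nodes.values())))


def _group_entropy(a: Alignment, ids: Sequence[str], col: int) -> float:
    """Gap-excluded Shannon entropy of one column within a sequence group;
    0 when the group has no residues at the column."""
    counts: dict[str, int] = {}
    for sid in ids:
        ch = a.row(sid)[col - 1]
        if ch not in (GAP, UNKNOWN):
            counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return _shannon(c / total for c in counts.values())


def score_ret(a: Alignment, tree: GuideTree | None = None) -> ConservationProfile:
    """Real-valued Evolutionary Trace.

    rho_i = 1 + sum over partition levels n = 1..N-1 of (1/n) times the sum
    of gap-excluded Shannon entropies of column i within each of the n
    groups obtained by splitting the guide tree's n-1 highest internal
    nodes.  rho = 1 iff every group at every level is column-invariant.
    """
    if tree is None:
        tree = upgma_tree(pairwise_distance_matrix(a))
    if set(tree.root.leaves) != set(a.ids):
        raise AlignmentError("guide tree leaves must match alignment ids")
    N = a.n_seq
    partitions = [tree.cut_top(n) for n in range(1, N)]
    values = np.empty(a.n_col)
    arr_all_gap = [
        all(ch in (GAP, UNKNOWN) for ch in a.column(j + 1))
        for j in range(a.n_col)
    ]
    for j in range(a.n_col):
        if arr_all_gap[j]:
            warnings.warn(f"column {j + 1} is all gaps; score is NaN")
            values[j] = np.nan
            continue
        rho = 1.0
        for n, groups in enumerate(partitions, start=1):
            rho += sum(_group_entropy(a, g, j + 1) for g in groups) / n
        values[j] = rho
    return ConservationProfile(metric="ret", values=values)


def default_cre_groups(a: Alignment) -> list[tuple[str, ...]]:
    """Default CRE partition: UPGMA tree cut at half its root height."""
    tree = upgma_tree(pairwise_distance_matrix(a))
    return tree.cut_at_height(tree.root.height / 2.0)


def score_cre(
    a: Alignment, groups: Sequence[Sequence[str]] | None = None
) -> ConservationProfile:
    """Cumulative relative entropy.

    CRE_i = sum_g (N_g/N) * KL(p_g || q) with p_g the group's gap-excluded
    column frequencies and q the pooled gap-excluded frequencies; >= 0,
    and 0 exactly when every group matches the pooled distribution.
    """
    if groups is None:
        groups = default_cre_groups(a)
    else:
        groups = [tuple(g) for g in groups]
        flat = [sid for g in groups for sid in g]
        if sorted(flat) != sorted(a.ids):
            raise AlignmentError("groups must partition the alignment ids")
        if len(groups) < 2:
            raise AlignmentError("need at least 2 groups for CRE")
    N = a.n_seq
    values = np.empty(a.n_col)
    for j in range(a.n_col):
        col = j + 1
        pooled: dict[str, int] = {}
        for sid in a.ids:
            ch = a.row(sid)[col - 1]
            if ch not in (GAP, UNKNOWN):
                pooled[ch] = pooled.get(ch, 0) + 1
        tot = sum(pooled.values())
        if tot == 0:
            warnings.warn(f"column {col} is all gaps; score is NaN")
            values[j] = np.nan
            continue
        q = {s: c / tot for s, c in pooled.items()}
        cre = 0.0
        for g in groups:
            counts: dict[str, int] = {}
            for sid in g:
                ch = a.row(sid)[col - 1]
                if ch not in (GAP, UNKNOWN):
                    counts[ch] = counts.get(ch, 0) + 1
            gt = sum(counts.values())
            if gt == 0:
                warnings.warn(
                    f"group {g[0]!r}.. has no residues at column {col}; skipped"
                )
                continue
            kl = sum(
                (c / gt) * math.log((c / gt) / q[s]) for s, c in counts.items()
            )
            cre += (len(g) / N) * kl
        values[j] = cre
    return ConservationProfile(metric="cre", values=values)


# ---------------------------------------------------------------------------
# Grouping mode
# ---------------------------------------------------------------------------

def read_grouping_scheme(path: str | Path) -> dict[str, str]:
    """Two-column text (residue, group); '#' comments allowed."""
    scheme: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 2:
            raise AlignmentError(f"bad grouping-scheme line: {ln!r}")
        scheme[parts[0].upper()] = parts[1]
    return scheme


def apply_grouping(a: Alignment, scheme: Mapping[str, str]) -> Alignment:
    """Re-express the alignment over a reduced property alphabet.

    The scheme must map all 20 amino acids; gaps and 'X' pass through.
    Scoring functions accept the result unchanged (group symbols are
    treated exactly like residue letters).
    """
    missing = set(AA_ALPHABET) - set(scheme)
    if missing:
        raise AlignmentError(
            f"grouping scheme does not cover: {''.join(sorted(missing))}"
        )
    if any(v in (GAP, UNKNOWN) for v in scheme.values()):
        raise AlignmentError("group symbols may not be '-' or 'X'")
    table = dict(scheme)
    table[GAP] = GAP
    table[UNKNOWN] = UNKNOWN
    try:
        rows = tuple("".join(table[ch] for ch in row) for row in a.rows)
    except KeyError as exc:
        raise AlignmentError(f"unmapped symbol: {exc.args[0]!r}") from None
    return Alignment(ids=a.ids, rows=rows, column_index=a.column_index)
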