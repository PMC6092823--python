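"""Consensus sequence and outlier detection for alignment validation.

Two complementary routes flag suspect sequences before scoring: similarity
of each sequence to a thresholded consensus (catches extra domains / large
insertions, which depress similarity), and mean pairwise distance to the
rest of the set.  Flagging is advisory — removal is the caller's decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .msa import AA_ALPHABET, GAP, UNKNOWN, Alignment, AlignmentError


@dataclass(frozen=True)
class ConsensusResult:
    """Thresholded consensus: per column the winning amino acid if its
    frequency (gaps in the denominator) strictly exceeds ``threshold``,
    else ``'X'``.  ``tie_columns`` lists 1-based columns where the winner
    was decided alphabetically among equally frequent residues."""

    symbols: str
    threshold: float
    winning_frequency: tuple[float, ...]
    tie_columns: tuple[int, ...] = ()


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix over sequence ids, entries in [0,1]."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise AlignmentError("distance matrix shape must match ids")
        if not np.allclose(v, v.T):
            raise AlignmentError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise AlignmentError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise AlignmentError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])


def consensus_sequence(
    a: Alignment,
    threshold: float = 0.3,
    weights: Sequence[float] | None = None,
) -> ConsensusResult:
    """Majority consensus with a minimum-frequency threshold.

    The winning amino acid must have (weighted) frequency strictly greater
    than ``threshold`` among *all* rows — gaps and 'X' sit in the
    denominator but can never win.  Ties are broken alphabetically and the
    column recorded in ``tie_columns``.
    """
    if not 0 < threshold <= 1:
        raise AlignmentError("threshold must be in (0, 1]")
    w = _norm_weights(a, weights)
    arr = a.to_array()
    symbols, freqs, ties = [], [], []
    for j in range(a.n_col):
        col = arr[:, j]
        best_sym, best_f = UNKNOWN, 0.0
        tied = False
        for aa in AA_ALPHABET:  # alphabetical order makes ties break low
            f = float(w[col == aa].sum())
            if f > best_f + 1e-12:
                best_sym, best_f, tied = aa, f, False
            elif f > 0 and abs(f - best_f) <= 1e-12:
                tied = True
        if best_f > threshold:
            symbols.append(best_sym)
            if tied:
                ties.append(j + 1)
        else:
            symbols.append(UNKNOWN)
        freqs.append(best_f)
    return ConsensusResult(
        symbols="".join(symbols),
        threshold=threshold,
        winning_frequency=tuple(freqs),
        tie_columns=tuple(ties),
    )


def similarity_to_consensus(a: Alignment, c: ConsensusResult) -> dict[str, float]:
    """Fraction of informative consensus columns (consensus != 'X') where
    each sequence matches the consensus symbol."""
    if len(c.symbols) != a.n_col:
        raise AlignmentError("consensus length must equal n_col")
    informative = [j for j, s in enumerate(c.symbols) if s != UNKNOWN]
    if not informative:
        raise AlignmentError("consensus uninformative: every column is 'X'")
    out = {}
    for sid, row in zip(a.ids, a.rows):
        matches = sum(1 for j in informative if row[j] == c.symbols[j])
        out[sid] = matches / len(informative)
    return out


def pairwise_distance_matrix(a: Alignment) -> DistanceMatrix:
    """p-distance: d(i,j) = 1 - matches / comparable, where comparable
    columns are those where the two rows are not both gaps (a gap against a
    residue is a comparable mismatch).  A pair with no comparable columns
    gets d = 1 with a warning."""
    if a.n_seq < 2:
        raise AlignmentError("need at least 2 sequences")
    arr = a.to_array()
    gaps = arr == GAP
    n = a.n_seq
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(gaps[i] & gaps[j])
            nc = int(comparable.sum())
            if nc == 0:
                warnings.warn(
                    f"sequences {a.ids[i]!r} and {a.ids[j]!r} share no "
                    "comparable columns; distance set to 1"
                )
                d[i, j] = d[j, i] = 1.0
            else:
                matches = int((comparable & (arr[i] == arr[j])).sum())
                d[i, j] = d[j, i] = 1.0 - matches / nc
    return DistanceMatrix(ids=a.ids, values=d)


def mean_pairwise_distance(d: DistanceMatrix) -> dict[str, float]:
    n = len(d.ids)
    return {
        sid: float(d.values[i].sum() / (n - 1)) for i, sid in enumerate(d.ids)
    }


def detect_outliers(
    values: Mapping[str, float],
    direction: str = "low",
    rule: str = "iqr",
) -> set[str]:
    """Tukey-fence outliers on a per-sequence statistic.

    ``direction="low"`` flags values below Q1 - 1.5*IQR (use for consensus
    similarity); ``"high"`` flags values above Q3 + 1.5*IQR (use for mean
    pairwise distance).  Quartiles are order statistics (nearest-rank); a
    zero IQR (effectively constant data) flags nothing.
    """
    if rule != "iqr":
        raise AlignmentError(f"unknown outlier rule: {rule!r}")
    if direction not in ("low", "high"):
        raise AlignmentError("direction must be 'low' or 'high'")
    if len(values) < 4:
        raise AlignmentError("need at least 4 values for the IQR rule")
    vals = np.array(list(values.values()), dtype=float)
    q1, q3 = np.quantile(vals, [0.25, 0.75], method="nearest")
    iqr = q3 - q1
    if iqr <= 0:
        return set()
    if direction == "low":
        fence = q1 - 1.5 * iqr
        return {k for k, v in values.items() if v < fence}
    fence = q3 + 1.5 * iqr
    return {k for k, v in values.items() if v > fence}


def outlier_report(a: Alignment, threshold: float = 0.3) -> pd.DataFrame:
    """Combined validation report: per-sequence consensus similarity, mean
    pairwise distance, and outlier flags from both routes."""
    cons = consensus_sequence(a, threshold)
    sim = similarity_to_consensus(a, cons)
    dmat = pairwise_distance_matrix(a)
    mdist = mean_pairwise_distance(dmat)
    low = detect_outliers(sim, "low") if a.n_seq >= 4 else set()
    high = detect_outliers(mdist, "high") if a.n_seq >= 4 else set()
    return pd.DataFrame(
        {
            "id": list(a.ids),
            "consensus_similarity": [sim[s] for s in a.ids],
            "mean_pairwise_distance": [mdist[s] for s in a.ids],
            "low_similarity_outlier": [s in low for s in a.ids],
            "high_distance_outlier": [s in high for s in a.ids],
        }
    )


def _norm_weights(a: Alignment, weights: Sequence[float] | None) -> np.ndarray:
    if weights is None:
        return np.full(a.n_seq, 1.0 / a.n_seq)
    w = np.asarray(weights, dtype=float)
    if w.shape != (a.n_seq,):
        raise AlignmentError("weights length must equal n_seq")
    if (w < 0).any() or w.sum() <= 0:
        raise AlignmentError("weights must be nonnegative with positive sum")
    return w / w.sum()
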