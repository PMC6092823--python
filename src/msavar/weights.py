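"""Sequence weighting and pseudo-count frequency correction.

Position-based (Henikoff & Henikoff) weights counteract taxonomic bias:
each column contributes 1/(k*n) to every sequence, where k is the number of
distinct symbols in the column (gap counted as its own symbol type) and n
the count of the sequence's own symbol there; redundant sequences split the
credit for their shared symbols.

Pseudo-counts stabilise column frequencies for small alignments by mixing
in substitution-background expectations: the pseudo-count for residue a is
b_a = B * sum_b f_b * g(a|b), with f the observed amino-acid frequencies
and g(a|b) the background probability of seeing a given b; the adjusted
frequency is p'_a = (n_a + b_a) / (N + B).  Gaps never receive pseudo-mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .msa import AA_ALPHABET, Alignment, AlignmentError

# BLOSUM62 amino-acid background frequencies (Henikoff & Henikoff 1992),
# ordered as AA_ALPHABET.
_BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


def henikoff_weights(a: Alignment) -> np.ndarray:
    """Position-based sequence weights, normalised to sum to 1.

    Gap and 'X' are counted as symbol types of their own when determining a
    column's k, so gap-block sequences are weighted consistently.
    """
    if a.n_seq < 2:
        raise AlignmentError("need at least 2 sequences to weight")
    arr = a.to_array()
    raw = np.zeros(a.n_seq)
    for j in range(a.n_col):
        col = arr[:, j]
        syms, counts = np.unique(col, return_counts=True)
        k = len(syms)
        count_of = dict(zip(syms.tolist(), counts.tolist()))
        for i in range(a.n_seq):
            raw[i] += 1.0 / (k * count_of[col[i]])
    return raw / raw.sum()


@lru_cache(maxsize=1)
def blosum62_background() -> tuple[str, np.ndarray]:
    """Background conditionals g(a|b) derived from BLOSUM62.

    Target frequencies are reconstructed from the log-odds scores,
    q_ab ∝ p_a * p_b * 2^(S_ab/2), then each row b is normalised so that
    sum_a g(a|b) = 1.  Returns (alphabet, 20x20 matrix with G[b, a] = g(a|b)).
    """
    S = substitution_matrices.load("BLOSUM62")
    p = np.array([_BLOSUM62_BACKGROUND[a] for a in AA_ALPHABET])
    n = len(AA_ALPHABET)
    q = np.empty((n, n))
    for i, b in enumerate(AA_ALPHABET):
        for j, a in enumerate(AA_ALPHABET):
            q[i, j] = p[i] * p[j] * 2.0 ** (S[b, a] / 2.0)
    G = q / q.sum(axis=1, keepdims=True)
    return AA_ALPHABET, G


def read_background_conditionals(path: str | Path) -> tuple[str, np.ndarray]:
    """Load a 20x20 conditional-probability table from plain text.

    Format: header row of amino-acid letters, then one row per letter
    (label followed by 20 numbers); rows must sum to 1.
    """
    lines = [ln.split() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = "".join(lines[0])
    if sorted(header) != sorted(AA_ALPHABET):
        raise AlignmentError("background table must cover the 20 amino acids")
    n = len(header)
    G = np.zeros((n, n))
    row_order = []
    for parts in lines[1:]:
        row_order.append(parts[0])
        G[len(row_order) - 1] = [float(x) for x in parts[1:]]
    if sorted(row_order) != sorted(AA_ALPHABET):
        raise AlignmentError("background table rows must cover the 20 amino acids")
    # reorder to AA_ALPHABET on both axes
    ridx = [row_order.index(a) for a in AA_ALPHABET]
    cidx = [header.index(a) for a in AA_ALPHABET]
    G = G[np.ix_(ridx, cidx)]
    if not np.allclose(G.sum(axis=1), 1.0, atol=1e-6):
        raise AlignmentError("background table rows must sum to 1")
    return AA_ALPHABET, G


def pseudocount_frequencies(
    counts: Mapping[str, float],
    B: float,
    background: tuple[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Pseudo-count-adjusted amino-acid frequencies.

    ``counts`` maps amino acids to observed (possibly weighted) counts; any
    symbol outside the background alphabet is rejected.  With B = 0 the
    observed frequencies are returned exactly; with B > 0 every adjusted
    frequency is strictly positive and the vector sums to 1.
    """
    if B < 0:
        raise AlignmentError("pseudo-count mass B must be nonnegative")
    alphabet, G = background if background is not None else blosum62_background()
    bad = set(counts) - set(alphabet)
    if bad:
        raise AlignmentError(f"symbols not in background alphabet: {sorted(bad)}")
    n = np.array([float(counts.get(a, 0.0)) for a in alphabet])
    if (n < 0).any():
        raise AlignmentError("counts must be nonnegative")
    N = n.sum()
    if N <= 0:
        raise AlignmentError("no amino-acid observations in column")
    f = n / N
    b = B * (f @ G)  # b_a = B * sum_b f_b g(a|b)
    p = (n + b) / (N + B)
    return dict(zip(alphabet, p.tolist()))


@dataclass(frozen=True)
class PseudocountSettings:
    """How to pseudo-correct column frequencies inside a score.

    ``B`` is the total pseudo-count mass; ``None`` selects the default
    5 * (number of distinct amino acids in the column).  ``background`` is a
    (alphabet, 20x20 conditional matrix) pair; ``None`` selects the
    BLOSUM62-derived default.
    """

    B: float | None = None
    background: tuple[str, np.ndarray] | None = None

    def mass(self, n_types: int) -> float:
        return float(self.B) if self.B is not None else 5.0 * n_types
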