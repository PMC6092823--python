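"""Compartment-versus-rest statistics and per-position result assembly.

The question asked of a compartment (tunnel, gate, binding site) is whether
its residues evolve at a different rate than the rest of the protein.  The
two-sample Kolmogorov–Smirnov test compares the empirical distribution of a
conservation metric over the compartment's alignment columns against the
complement; the asymptotic p-value (effective size n1*n2/(n1+n2)) is used,
appropriate for the hundreds of columns typical of such comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consensus import ConsensusResult
from .msa import Alignment, AlignmentError, ProfileTable
from .scores import ConservationProfile
from .structure import Compartment, ResidueMap, StructureError


@dataclass(frozen=True)
class KSResult:
    statistic: float  # sup |ECDF_comp - ECDF_rest|, in [0, 1]
    pvalue: float
    n1: int
    n2: int


def ks_compare(
    profile: ConservationProfile, compartment_cols: Iterable[int]
) -> KSResult:
    """Two-sample KS test of compartment columns against the complement.

    NaN columns (all-gap) are excluded from both samples; each sample must
    retain at least 2 finite scores.
    """
    cols = set(compartment_cols)
    n_col = len(profile.values)
    bad = {c for c in cols if not 1 <= c <= n_col}
    if bad:
        raise AlignmentError(f"compartment columns out of range: {sorted(bad)}")
    comp = np.array([profile.values[c - 1] for c in sorted(cols)])
    rest = np.array(
        [profile.values[j] for j in range(n_col) if (j + 1) not in cols]
    )
    comp = comp[np.isfinite(comp)]
    rest = rest[np.isfinite(rest)]
    if rest.size == 0:
        raise AlignmentError("complement is empty: compartment covers every column")
    if comp.size < 2 or rest.size < 2:
        raise AlignmentError(
            "need at least 2 finite scores in compartment and complement "
            f"(got {comp.size} and {rest.size})"
        )
    res = sps.ks_2samp(comp, rest, alternative="two-sided", method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n1=int(comp.size),
        n2=int(rest.size),
    )


def extreme_positions(
    profile: ConservationProfile, cols: Iterable[int], k: int = 1
) -> tuple[list[int], list[int]]:
    """(least variable, most variable) columns within ``cols``.

    Respects the profile's orientation: for a conservation-oriented metric
    the largest scores are the *least* variable.  Ties break toward the
    lower column index; if fewer than ``k`` finite columns exist the lists
    are truncated with a warning.
    """
    if k < 1:
        raise AlignmentError("k must be >= 1")
    cols = sorted(set(cols))
    if not cols:
        raise AlignmentError("empty column set")
    n_col = len(profile.values)
    scored = [
        (float(profile.values[c - 1]), c)
        for c in cols
        if 1 <= c <= n_col and math.isfinite(profile.values[c - 1])
    ]
    if k > len(scored):
        import warnings

        warnings.warn(
            f"k={k} exceeds {len(scored)} scorable columns; truncating"
        )
        k = len(scored)
    ascending = sorted(scored, key=lambda t: (t[0], t[1]))
    descending = sorted(scored, key=lambda t: (-t[0], t[1]))
    low = [c for _, c in ascending[:k]]
    high = [c for _, c in descending[:k]]
    if profile.orientation == "variability":
        return low, high
    return high, low


def ks_summary_table(results: Mapping[tuple[str, str], KSResult]) -> pd.DataFrame:
    """Flatten {(metric, compartment): KSResult} into a report table."""
    rows = [
        {
            "metric": metric,
            "compartment": comp,
            "D": r.statistic,
            "p_value": r.pvalue,
            "n_compartment": r.n1,
            "n_rest": r.n2,
        }
        for (metric, comp), r in results.items()
    ]
    return pd.DataFrame(rows)


def assemble_profile_table(
    a: Alignment,
    profiles: Sequence[ConservationProfile],
    residue_map: ResidueMap | None = None,
    compartments: Sequence[Compartment] = (),
    consensus: ConsensusResult | None = None,
) -> ProfileTable:
    """One record per alignment column: original position, reference residue
    number, consensus symbol, every metric, compartment membership flags and
    compartment features on mapped columns."""
    for p in profiles:
        if len(p.values) != a.n_col:
            raise AlignmentError(
                f"profile {p.metric!r} length {len(p.values)} != n_col {a.n_col}"
            )
    if compartments and residue_map is None:
        raise StructureError("compartments require a residue map")
    data: dict[str, list] = {"column": list(a.column_index)}
    if residue_map is not None:
        col_to_res = {c: r + 1 for r, c in enumerate(residue_map.columns)}
        data["ref_residue"] = [
            col_to_res.get(j + 1, np.nan) for j in range(a.n_col)
        ]
    if consensus is not None:
        data["consensus"] = list(consensus.symbols)
    orientation = {}
    for p in profiles:
        data[p.metric] = list(p.values)
        orientation[p.metric] = p.orientation
    for comp in compartments:
        mapped = residue_map.columns_for(comp)
        data[f"in_{comp.name}"] = [(j + 1) in mapped for j in range(a.n_col)]
        for fname in comp.feature_names:
            feat = [np.nan] * a.n_col
            for r in comp.residues:
                if fname in r.features:
                    feat[residue_map.column_of(r.number) - 1] = r.features[fname]
            data[f"{comp.name}_{fname}"] = feat
    return ProfileTable(data=pd.DataFrame(data), orientation=orientation)
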