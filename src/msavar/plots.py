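"""Plot rendering for conservation profiles.

Every plotting function returns the plotted numbers as a DataFrame so the
figures are testable without image comparison; the CLI writes that table
next to the image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .msa import AA_ALPHABET, Alignment
from .scores import ConservationProfile, column_profile
from .stats import extreme_positions

_MARKERS = "ovs^DP*Xd"


def profile_plot(
    profile: ConservationProfile,
    out_path: str | Path,
    compartment_cols: Mapping[str, set[int]] | None = None,
    columns: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Bar chart of the per-column score; compartment residues marked with
    one symbol per compartment."""
    n = len(profile.values)
    cols = np.asarray(columns if columns is not None else range(1, n + 1))
    vals = profile.values
    fig, ax = plt.subplots(figsize=(max(6, n / 12), 3.2))
    ax.bar(cols, vals, width=1.0, color="0.6", linewidth=0)
    data = {"column": cols, profile.metric: vals}
    for i, (name, cset) in enumerate((compartment_cols or {}).items()):
        mask = np.array([c in cset for c in cols])
        ymark = np.nanmax(vals) * 1.05 if np.isfinite(vals).any() else 1.0
        ax.plot(
            cols[mask],
            np.full(mask.sum(), ymark),
            _MARKERS[i % len(_MARKERS)],
            label=name,
            markersize=4,
        )
        data[f"in_{name}"] = mask
    if compartment_cols:
        ax.legend(fontsize=7)
    ax.set_xlabel("alignment position")
    ax.set_ylabel(f"{profile.metric} ({profile.orientation})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return pd.DataFrame(data)


def composition_plot(
    a: Alignment, out_path: str | Path, columns: Sequence[int] | None = None
) -> pd.DataFrame:
    """Stacked per-column residue composition bars."""
    cols = list(columns) if columns is not None else list(range(1, a.n_col + 1))
    freq = {aa: [] for aa in AA_ALPHABET}
    for c in cols:
        prof = column_profile(a, c)
        for aa in AA_ALPHABET:
            freq[aa].append(prof.p.get(aa, 0.0))
    fig, ax = plt.subplots(figsize=(max(6, len(cols) / 8), 3.2))
    bottom = np.zeros(len(cols))
    cmap = plt.get_cmap("tab20")
    for i, aa in enumerate(AA_ALPHABET):
        f = np.array(freq[aa])
        ax.bar(cols, f, bottom=bottom, width=1.0, color=cmap(i % 20), label=aa)
        bottom += f
    ax.set_xlabel("alignment position")
    ax.set_ylabel("residue frequency (gaps in denominator)")
    ax.legend(fontsize=5, ncol=2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return pd.DataFrame({"column": cols, **freq})


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def cdf_plot(
    profile: ConservationProfile,
    compartment_cols: set[int],
    out_path: str | Path,
    compartment_name: str = "compartment",
    annotate_extremes: int = 1,
) -> pd.DataFrame:
    """ECDF overlay of compartment vs rest-of-protein scores, with the
    least/most variable compartment positions annotated."""
    n = len(profile.values)
    comp = np.array(
        [profile.values[c - 1] for c in sorted(compartment_cols)]
    )
    rest = np.array(
        [profile.values[j] for j in range(n) if (j + 1) not in compartment_cols]
    )
    comp, rest = comp[np.isfinite(comp)], rest[np.isfinite(rest)]
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    records = []
    for name, sample, color in (
        (compartment_name, comp, "tab:green"),
        ("rest", rest, "0.5"),
    ):
        xs, ys = _ecdf(sample)
        ax.step(xs, ys, where="post", color=color, label=name)
        records.extend(
            {"sample": name, "score": float(x), "ecdf": float(y)}
            for x, y in zip(xs, ys)
        )
    if annotate_extremes and comp.size:
        least, most = extreme_positions(
            profile, compartment_cols, annotate_extremes
        )
        for c in least:
            ax.annotate(
                f"{c}", (profile.values[c - 1], 0.02), color="red", fontsize=7
            )
        for c in most:
            ax.annotate(
                f"{c}", (profile.values[c - 1], 0.95), color="blue", fontsize=7
            )
    ax.set_xlabel(f"{profile.metric} ({profile.orientation})")
    ax.set_ylabel("ECDF")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return pd.DataFrame(records)


def scatter_plot(
    p1: ConservationProfile, p2: ConservationProfile, out_path: str | Path
) -> pd.DataFrame:
    """Score–score scatter for comparing two metrics' behaviour."""
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.plot(p1.values, p2.values, ".", markersize=3, alpha=0.6)
    ax.set_xlabel(p1.metric)
    ax.set_ylabel(p2.metric)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return pd.DataFrame(
        {
            "column": range(1, len(p1.values) + 1),
            p1.metric: p1.values,
            p2.metric: p2.values,
        }
    )
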