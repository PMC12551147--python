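"""Positional sequence logos, dipeptide adjacency, and property regression.

These are the descriptive analyses run on peptide sets (screening positives,
top-100 predictions per round): position frequency matrices with information
content in bits for logo rendering, ordered adjacent-residue-pair counts (the
Sankey-diagram data), and ordinary least squares of per-variant activity on a
per-residue physicochemical property (the fourth-residue analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_space import AMINO_ACIDS


@dataclass
class PositionFrequencyMatrix:
    """Relative residue frequencies per variable position (Met excluded).

    ``freqs`` is a (20, L) DataFrame indexed by residue with 1-based position
    columns; every column sums to 1.  ``n`` is the number of peptides.
    """

    freqs: pd.DataFrame
    n: int


def position_frequency_matrix(peptides: Sequence[str]) -> PositionFrequencyMatrix:
    peptides = list(peptides)
    if not peptides:
        raise ValueError("need at least one peptide")
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise ValueError("peptides must have equal length")
    counts = np.zeros((len(AMINO_ACIDS), length))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for p in peptides:
        for j, aa in enumerate(p):
            counts[aa_index[aa], j] += 1
    freqs = counts / len(peptides)
    df = pd.DataFrame(freqs, index=list(AMINO_ACIDS), columns=range(1, length + 1))
    return PositionFrequencyMatrix(freqs=df, n=len(peptides))


def information_content(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> np.ndarray:
    """Logo column heights: IC_j = log2(20) + sum_a f_aj log2 f_aj (bits).

    Zero frequencies contribute nothing (0 log 0 = 0).  The optional
    small-sample correction subtracts (|A|-1) / (2 ln2 * n).
    """
    f = pfm.freqs.to_numpy()
    logf = np.zeros_like(f)
    np.log2(f, out=logf, where=f > 0)
    plogp = f * logf
    ic = np.log2(len(AMINO_ACIDS)) + plogp.sum(axis=0)
    if small_sample_correction:
        ic = ic - (len(AMINO_ACIDS) - 1) / (2 * np.log(2) * pfm.n)
    return np.maximum(ic, 0.0)


def dipeptide_adjacency(peptides: Sequence[str]) -> pd.DataFrame:
    """Ordered adjacent-pair counts over positions (1,2), (2,3), (3,4).

    Returns a (20, 20) DataFrame, rows = first residue, columns = second;
    total count is 3x the number of peptides (for tetrapeptides).
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("need at least one peptide")
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((len(AMINO_ACIDS), len(AMINO_ACIDS)), dtype=int)
    for p in peptides:
        for a, b in zip(p, p[1:]):
            counts[aa_index[a], aa_index[b]] += 1
    return pd.DataFrame(counts, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


def top_dipeptides(adjacency: pd.DataFrame, n: int = 5) -> list[tuple[str, int]]:
    """The n most frequent ordered residue pairs, ties lexicographic."""
    pairs = [
        (a + b, int(adjacency.loc[a, b]))
        for a in adjacency.index
        for b in adjacency.columns
    ]
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))[:n]


@dataclass(frozen=True)
class PropertyRegression:
    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool = False


def residue_property_regression(
    activity_by_variant: Mapping[str, float],
    property_by_residue: Mapping[str, float],
) -> PropertyRegression:
    """OLS of per-variant activity on a per-residue property value.

    Used for the fourth-residue analysis: each variant differs only in one
    residue, and its activity is regressed on a physicochemical parameter of
    that residue.  Requires >= 3 residues shared by both mappings with finite
    values; a property with zero variance yields a degenerate-fit flag rather
    than an estimate.  R^2 is invariant to affine rescaling of the property.
    """
    shared = sorted(
        r
        for r in activity_by_variant
        if r in property_by_residue
        and np.isfinite(activity_by_variant[r])
        and np.isfinite(property_by_residue[r])
    )
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues with finite values")
    x = np.array([property_by_residue[r] for r in shared], dtype=float)
    y = np.array([activity_by_variant[r] for r in shared], dtype=float)
    if np.ptp(x) == 0:
        return PropertyRegression(
            slope=float("nan"),
            intercept=float("nan"),
            r_squared=float("nan"),
            n=len(shared),
            degenerate=True,
        )
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else 1.0
    return PropertyRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n=len(shared),
    )


#: Generic Kyte-Doolittle hydropathy, bundled as a demo property table only —
#: NOT the side-chain parameter set used in the original fourth-residue
#: analysis, which is not reproduced here.
KD_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


def write_pfm(pfm: PositionFrequencyMatrix, path) -> None:
    pfm.freqs.to_csv(path, sep="\t", index_label="residue")


def write_adjacency(adjacency: pd.DataFrame, path) -> None:
    adjacency.to_csv(path, sep="\t", index_label="first")


def plot_logo(pfm: PositionFrequencyMatrix, path=None, ax=None):
    """Render a simple information-content-scaled sequence logo.

    Letters are stacked per position, heights proportional to f * IC; this is
    a plain matplotlib rendering, not a typography-faithful logo.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ic = information_content(pfm)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * pfm.freqs.shape[1], 3))
    cmap = plt.get_cmap("tab20")
    colors = {aa: cmap(i % 20) for i, aa in enumerate(AMINO_ACIDS)}
    for j, pos in enumerate(pfm.freqs.columns):
        bottom = 0.0
        column = pfm.freqs[pos].sort_values()
        for aa, f in column.items():
            h = f * ic[j]
            if h <= 0:
                continue
            ax.bar(pos, h, bottom=bottom, width=0.8, color=colors[aa], edgecolor="none")
            if h > 0.15:
                ax.text(pos, bottom + h / 2, aa, ha="center", va="center", fontsize=8)
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_xticks(list(pfm.freqs.columns))
    ax.set_ylim(0, np.log2(len(AMINO_ACIDS)))
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
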