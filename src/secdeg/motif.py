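"""Positional amino-acid occurrence matrices for cleavage windows.

The ten Schechter–Berger positions (P5..P1 on the non-prime side, P1'..P5' on
the prime side of the scissile bond) are tallied over the cleavage windows of
significantly enriched semi-tryptic peptides; the result is a 10-position x
20-residue count matrix (the heatmap-style summary).  Padding characters "-"
from windows truncated at a protein terminus are counted separately and never
enter the residue tallies, so for every position

    sum over residues + padding = n_windows.

Counting is per unique cleavage site (accession + position), not per peptide
or spectrum, to avoid charge-state inflation; a flag restores per-peptide
counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SecdegError

POSITIONS: tuple[str, ...] = (
    "P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'", "P5'",
)
RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
PADDING = "-"


@dataclass
class MotifMatrix:
    """Counts of residues per cleavage-window position."""

    counts: pd.DataFrame  # index POSITIONS x columns RESIDUES, integers
    padding: pd.Series  # per-position count of terminus padding
    n_windows: int

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["padding"] = self.padding
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_windows: int) -> "MotifMatrix":
        counts = frame[list(RESIDUES)].astype(int)
        padding = frame["padding"].astype(int)
        return cls(counts=counts, padding=padding, n_windows=n_windows)


def build_positional_matrix(windows: Iterable[str]) -> MotifMatrix:
    """Tally residues per position over 10-character cleavage windows.

    Padding ("-") is ignored in the residue counts but tracked so the
    conservation invariant holds.  Wrong-length windows or unknown characters
    raise :class:`SecdegError`.
    """
    counts = np.zeros((len(POSITIONS), len(RESIDUES)), dtype=int)
    padding = np.zeros(len(POSITIONS), dtype=int)
    res_index = {aa: j for j, aa in enumerate(RESIDUES)}
    n = 0
    for window in windows:
        if len(window) != len(POSITIONS):
            raise SecdegError(
                f"cleavage window must have length {len(POSITIONS)}, "
                f"got {window!r}"
            )
        for i, ch in enumerate(window):
            if ch == PADDING:
                padding[i] += 1
            elif ch in res_index:
                counts[i, res_index[ch]] += 1
            else:
                raise SecdegError(f"unknown residue {ch!r} in window {window!r}")
        n += 1
    return MotifMatrix(
        counts=pd.DataFrame(counts, index=list(POSITIONS), columns=list(RESIDUES)),
        padding=pd.Series(padding, index=list(POSITIONS), name="padding"),
        n_windows=n,
    )


def dominant_residues(matrix: MotifMatrix, position: str) -> list[tuple[str, int]]:
    """Residues at one position ranked by count (descending, ties broken
    alphabetically)."""
    if position not in POSITIONS:
        raise SecdegError(
            f"unknown position {position!r}; expected one of {POSITIONS}"
        )
    row = matrix.counts.loc[position]
    ranked = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(aa, int(c)) for aa, c in ranked]


def significant_windows(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    fraction: int | None = None,
    contrast: str | None = None,
    alpha: float = 0.05,
    unique_sites: bool = True,
) -> list[str]:
    """Cleavage windows of significantly enriched semi-tryptic peptides.

    Selects rows of a :func:`~secdeg.differential.per_fraction_contrasts`
    result with adj_p < alpha and positive log2FC (optionally restricted to
    one fraction and/or contrast), joins the P5-P5' windows from the
    annotation table, and de-duplicates to unique cleavage sites.
    """
    sel = results.loc[(results["adj_p"] < alpha) & (results["log2fc"] > 0)]
    if fraction is not None:
        sel = sel.loc[sel["fraction_id"] == fraction]
    if contrast is not None:
        sel = sel.loc[sel["contrast"] == contrast]
    if sel.empty:
        return []
    joined = sel.join(
        annotations[["cleavage_pos", "window"]],
        on=["peptide", "accession"],
        how="inner",
    )
    joined = joined.dropna(subset=["window"])
    if unique_sites:
        joined = joined.drop_duplicates(subset=["accession", "cleavage_pos"])
    else:
        joined = joined.drop_duplicates(subset=["peptide", "accession"])
    return joined["window"].tolist()


def motif_report(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    fraction: int | None = None,
    contrast: str | None = None,
    alpha: float = 0.05,
    unique_sites: bool = True,
) -> MotifMatrix:
    """Positional matrix of the significant cleavage windows; warns (does not
    fail) when no window passes the threshold."""
    windows = significant_windows(
        results,
        annotations,
        fraction=fraction,
        contrast=contrast,
        alpha=alpha,
        unique_sites=unique_sites,
    )
    if not windows:
        warnings.warn(
            f"no significant cleavage windows "
            f"(fraction={fraction}, contrast={contrast}, alpha={alpha})"
        )
    return build_positional_matrix(windows)


def plot_motif_heatmap(matrix: MotifMatrix, path) -> None:
    """Plain position x residue count heatmap (fixed row/column order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(matrix.counts.to_numpy().T, aspect="auto", cmap="Reds")
    ax.set_xticks(range(len(POSITIONS)), POSITIONS)
    ax.set_yticks(range(len(RESIDUES)), RESIDUES, fontsize=6)
    ax.set_xlabel("cleavage-window position")
    fig.colorbar(im, ax=ax, label="occurrences")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
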