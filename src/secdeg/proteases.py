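"""Protease SEC profiling: subset percentage matrices to annotated proteases
and order rows by hierarchical clustering.

Protease membership and family labels come from a static annotation table
(accession -> family), the in-repo stand-in for a MEROPS-derived list.
Subsetting never alters values, only row membership; the clustered leaf order
is deterministic given the matrix, distance, linkage and the label tie-break
(rows are sorted by label before clustering).
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import SecdegError


def annotate_proteases(
    matrix: pd.DataFrame,
    merops: pd.DataFrame,
    *,
    gene_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict a feature x fraction matrix to annotated proteases.

    Rows are relabelled ``gene_accession``; returns the subset and the
    aligned family labels.  Accessions absent from the annotation are
    excluded; an empty annotation table is an error.
    """
    if merops.empty:
        raise SecdegError("protease annotation table is empty")
    proteases = merops.loc[merops["is_protease"]]
    keep = [acc for acc in matrix.index if acc in proteases.index]
    subset = matrix.loc[keep]
    labels = []
    families = []
    for acc in keep:
        gene = proteases.at[acc, "gene"] or (gene_map or {}).get(acc, "")
        labels.append(f"{gene}_{acc}" if gene else str(acc))
        families.append(proteases.at[acc, "family"])
    subset = subset.copy()
    subset.index = pd.Index(labels, name="protease")
    return subset, pd.Series(families, index=subset.index, name="family")


def cluster_rows(
    matrix: pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
) -> list:
    """Leaf order of agglomerative hierarchical clustering on the rows.

    Missing values become 0 before clustering; rows are pre-sorted by label
    so equal-distance ties resolve deterministically.  A single row needs no
    clustering.
    """
    if len(matrix) == 0:
        raise SecdegError("cannot cluster an empty matrix")
    matrix = matrix.sort_index(kind="mergesort")
    if len(matrix) == 1:
        return list(matrix.index)
    values = matrix.fillna(0.0).to_numpy(dtype=float)
    link = hierarchy.linkage(pdist(values, metric=metric), method=method)
    order = hierarchy.leaves_list(link)
    return [matrix.index[i] for i in order]


def protease_report(
    pct_matrix: pd.DataFrame,
    merops: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    *,
    gene_map: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Clustered percentage sub-matrices per protease family group.

    ``pct_matrix`` is a protein x fraction percentage distribution; ``groups``
    maps a report name to the families it pools (default: one group per
    family present).  Groups with no member are skipped with a warning.
    """
    subset, families = annotate_proteases(pct_matrix, merops, gene_map=gene_map)
    if groups is None:
        groups = {fam: [fam] for fam in sorted(families.dropna().unique())}
    out: dict[str, pd.DataFrame] = {}
    for name, members in groups.items():
        rows = subset.loc[families.isin(members)]
        if rows.empty:
            warnings.warn(f"protease group {name!r} has no members; skipped")
            continue
        out[name] = rows.loc[cluster_rows(rows)]
    return out


def plot_protease_heatmap(pct: pd.DataFrame, path, title: str = "") -> None:
    """Percentage-per-fraction heatmap (0-100, red gradient) in leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.4 * len(pct) + 1.5))
    im = ax.imshow(pct.to_numpy(), aspect="auto", cmap="Reds", vmin=0, vmax=100)
    ax.set_yticks(range(len(pct)), pct.index, fontsize=7)
    ax.set_xticks(range(len(pct.columns)), pct.columns, fontsize=6)
    ax.set_xlabel("SEC fraction")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="% of summed intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
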