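"""SEC elution profiles, condition differences, percentage distributions and
retention/release classification of cleavage products.

Fraction ids increase with elution volume: later fractions hold smaller
(lower-MW) species.  A cleavage product whose elution peak sits at least
``min_shift`` fractions *later* than its parent protein's peak has separated
from the parent complex ("released"); products co-eluting with the parent are
"retained".  Shifts toward earlier fractions never count as release.  Calls
are "ambiguous" when either profile is observed in too few fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import REPLICATES, sample_id
from .errors import SecdegError
from .terminomics import SEMI_CLASSES, SPECIFICITY_TRYPTIC


def condition_profile(
    matrix: pd.DataFrame,
    feature,
    condition: str,
    n_fractions: int = 21,
) -> pd.Series:
    """Replicate-averaged log2 elution profile of one feature.

    ``matrix`` is a quantification matrix whose last index level is
    ``fraction_id`` (protein level: (accession, fraction_id); peptide level:
    (peptide, accession, fraction_id)); ``feature`` is the index prefix
    identifying the feature.  Per fraction the mean of the condition's
    replicate log2 values is taken, ignoring missing; a fraction with no
    observed replicate is missing.  Unknown features raise ``KeyError``.
    """
    cols = [
        sample_id(condition, r)
        for r in REPLICATES
        if sample_id(condition, r) in matrix.columns
    ]
    if not cols:
        raise KeyError(f"no sample columns for condition {condition!r}")
    block = matrix.loc[feature]  # remaining index level: fraction_id
    values = block[cols].mean(axis=1, skipna=True)
    values.index = values.index.astype(int)
    profile = values.reindex(range(1, n_fractions + 1))
    profile.index.name = "fraction_id"
    profile.name = str(feature)
    return profile


def profile_difference(
    profile_treatment: pd.Series, profile_control: pd.Series
) -> pd.Series:
    """Element-wise treatment minus control; missing in either stays missing."""
    if len(profile_treatment) != len(profile_control):
        raise SecdegError(
            f"profile length mismatch: {len(profile_treatment)} vs "
            f"{len(profile_control)}"
        )
    return profile_treatment - profile_control.to_numpy()


def percentage_distribution(
    rows: pd.DataFrame, input_scale: str = "linear"
) -> pd.DataFrame:
    """Row-percentage matrix: each feature's intensity summed over fractions,
    per-fraction contribution expressed in percent (rows sum to 100).

    ``input_scale='log2'`` reconstructs linear intensities as ``2 ** value``
    (log2 ratios back-transformed) with missing -> 0 before normalising.
    All-zero rows are excluded with a warning (their distribution is
    undefined).
    """
    if input_scale == "log2":
        linear = np.exp2(rows.to_numpy(dtype=float))
        linear[~np.isfinite(linear)] = 0.0
    elif input_scale == "linear":
        linear = rows.to_numpy(dtype=float)
        linear = np.where(np.isfinite(linear), linear, 0.0)
        if (linear < 0).any():
            raise SecdegError("linear intensities must be non-negative")
    else:
        raise SecdegError(f"unknown input_scale {input_scale!r}")
    totals = linear.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} all-zero row(s) from the percentage "
            "distribution"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * linear / totals[:, None]
    out = pd.DataFrame(pct, index=rows.index, columns=rows.columns)
    return out.loc[~zero]


def peak_fraction(row: pd.Series) -> int:
    """Fraction holding the maximum value; ties resolve to the lowest
    fraction id.  Invariant under strictly monotone transforms of the row."""
    values = row.dropna()
    values = values[np.isfinite(values.to_numpy(dtype=float))]
    if values.empty:
        raise SecdegError("peak_fraction of an all-missing profile is undefined")
    values = values.sort_index()
    return int(values.index[int(np.argmax(values.to_numpy()))])


@dataclass(frozen=True)
class ReleaseCall:
    """Retention-vs-release classification of one cleavage product."""

    feature_id: str
    parent: str
    peptide_peak: int | None
    protein_peak: int | None
    shift: int | None  # peptide peak - protein peak, in fractions
    call: str  # "retained" | "released" | "ambiguous"


def classify_release(
    peptide_row: pd.Series | None,
    protein_row: pd.Series | None,
    *,
    min_shift: int = 3,
    min_fractions: int = 3,
    feature_id: str = "",
    parent: str = "",
) -> ReleaseCall:
    """Classify a cleavage product against its parent protein's elution.

    Both rows are (percentage or raw linear) intensity vectors over the same
    fractions.  ``released`` when the peptide peak lies >= ``min_shift``
    fractions later than the protein peak (toward lower MW); shifts toward
    earlier fractions never count as release and map to ``retained``;
    ``ambiguous`` when either row has fewer than ``min_fractions`` non-zero
    fractions or the protein row is absent.
    """

    def _n_observed(row: pd.Series | None) -> int:
        if row is None:
            return 0
        vals = row.to_numpy(dtype=float)
        return int(np.sum(np.isfinite(vals) & (vals > 0)))

    if (
        protein_row is None
        or peptide_row is None
        or _n_observed(protein_row) < min_fractions
        or _n_observed(peptide_row) < min_fractions
    ):
        return ReleaseCall(feature_id, parent, None, None, None, "ambiguous")
    pep_peak = peak_fraction(peptide_row)
    prot_peak = peak_fraction(protein_row)
    shift = pep_peak - prot_peak
    call = "released" if shift >= min_shift else "retained"
    return ReleaseCall(feature_id, parent, pep_peak, prot_peak, shift, call)


def protein_fraction_matrix(
    matrix: pd.DataFrame, condition: str, n_fractions: int = 21
) -> pd.DataFrame:
    """Wide feature x fraction matrix of replicate-averaged log2 values for
    one condition (rows: first index levels; columns: fraction 1..n)."""
    cols = [
        sample_id(condition, r)
        for r in REPLICATES
        if sample_id(condition, r) in matrix.columns
    ]
    mean = matrix[cols].mean(axis=1, skipna=True)
    wide = mean.unstack("fraction_id")
    wide.columns = wide.columns.astype(int)
    return wide.reindex(columns=range(1, n_fractions + 1))


def release_calls(
    peptide_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    condition: str,
    *,
    min_shift: int = 3,
    min_fractions: int = 3,
    n_fractions: int = 21,
) -> pd.DataFrame:
    """Release classification for every annotated semi-tryptic peptide.

    Elution rows are linear reconstructions (``2 ** log2``) of the
    replicate-averaged condition profiles.
    """
    semi = annotations.loc[annotations["specificity"].isin(SEMI_CLASSES)]
    pep_wide = protein_fraction_matrix(peptide_matrix, condition, n_fractions)
    prot_wide = protein_fraction_matrix(protein_matrix, condition, n_fractions)
    rows = []
    for (peptide, accession), ann in semi.iterrows():
        key = (peptide, accession)
        pep_row = (
            np.exp2(pep_wide.loc[key]) if key in pep_wide.index else None
        )
        prot_row = (
            np.exp2(prot_wide.loc[accession])
            if accession in prot_wide.index
            else None
        )
        call = classify_release(
            pep_row,
            prot_row,
            min_shift=min_shift,
            min_fractions=min_fractions,
            feature_id=peptide,
            parent=accession,
        )
        rows.append(
            {
                "peptide": peptide,
                "accession": accession,
                "condition": condition,
                "specificity": ann["specificity"],
                "cleavage_pos": ann["cleavage_pos"],
                "p1": ann["p1"],
                "peptide_peak": call.peptide_peak,
                "protein_peak": call.protein_peak,
                "shift": call.shift,
                "call": call.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide", "accession", "condition", "specificity", "cleavage_pos",
            "p1", "peptide_peak", "protein_peak", "shift", "call",
        ],
    )


def feature_distribution_report(
    accession: str,
    annotations: pd.DataFrame,
    peptide_matrix: pd.DataFrame,
    condition: str,
    n_fractions: int = 21,
) -> pd.DataFrame:
    """Percentage rows for one protein: the fully-tryptic aggregate plus one
    row per semi-tryptic peptide, each normalised independently.

    The tryptic row sums the linear (``2 ** log2``) intensities of the
    protein's fully tryptic peptides per fraction; semi rows carry cleavage
    metadata (P1 residue, position) in their label.  Raises ``KeyError`` for
    an unknown protein and :class:`SecdegError` when the protein has no
    tryptic peptide.
    """
    ann = annotations.xs(accession, level="accession", drop_level=False)
    if ann.empty:
        raise KeyError(f"protein {accession!r} has no annotated peptides")
    tryptic = ann.loc[ann["specificity"] == SPECIFICITY_TRYPTIC]
    if tryptic.empty:
        raise SecdegError(f"protein {accession!r} has no fully tryptic peptide")
    wide = protein_fraction_matrix(peptide_matrix, condition, n_fractions)
    rows: dict[str, np.ndarray] = {}
    tryp_keys = [k for k in tryptic.index if k in wide.index]
    if tryp_keys:
        lin = np.exp2(wide.loc[tryp_keys].to_numpy(dtype=float))
        lin[~np.isfinite(lin)] = 0.0
        rows["tryptic_protein"] = lin.sum(axis=0)
    for key, meta in ann.loc[ann["specificity"].isin(SEMI_CLASSES)].iterrows():
        if key not in wide.index:
            continue
        lin = np.exp2(wide.loc[key].to_numpy(dtype=float))
        lin[~np.isfinite(lin)] = 0.0
        label = (
            f"{key[0]}|{meta['specificity']}|P1={meta['p1']}|"
            f"pos={meta['cleavage_pos']}"
        )
        rows[label] = lin
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = list(range(1, n_fractions + 1))
    frame.index.name = "row"
    return percentage_distribution(frame, input_scale="linear")


def plot_profiles(profiles: dict[str, pd.Series], path, title: str = "") -> None:
    """Basic line plot of log2 elution profiles (one line per condition)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for label, profile in profiles.items():
        ax.plot(profile.index, profile.to_numpy(), marker="o", label=label)
    ax.set_xlabel("SEC fraction")
    ax.set_ylabel("log2 normalized abundance")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
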