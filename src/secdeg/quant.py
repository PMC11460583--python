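"""PSM filtering, reference-channel normalization and aggregation.

Mirrors a TMT-Integrator-style workflow: PSMs are filtered (isolation purity
strictly > 50% by default, no decoys/contaminants, non-zero total reporter
signal), each sample channel is expressed as a log2 ratio to the reference
channel (a pooled pre-SEC mix present in every plex, which makes ratios
comparable across fractions by construction — no additional between-fraction
renormalization is applied), and ratios are aggregated by the median: PSMs ->
peptides, and fully tryptic peptides -> proteins.  Spiked iRT standards are
routed to a QC stream that validates the channel assignment of each plex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SAMPLES, PlexDesign
from .errors import DesignMismatchError, MappingError
from .io import intensity_columns
from .terminomics import SPECIFICITY_TRYPTIC

NORM_META = ("spectrum", "peptide", "accession", "start_pos", "fraction_id")


def split_irt(psms: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate spiked iRT standards (QC stream) from quantifiable PSMs."""
    is_irt = psms["is_irt"].to_numpy(dtype=bool)
    return psms.loc[~is_irt].copy(), psms.loc[is_irt].copy()


def filter_psms(psms: pd.DataFrame, purity_threshold: float = 0.5) -> pd.DataFrame:
    """Retain PSMs with purity strictly above the threshold, no decoy or
    contaminant flag, and positive total reporter intensity; iRT records are
    excluded here (use :func:`split_irt` for the QC stream).  Idempotent."""
    if not 0 <= purity_threshold <= 1:
        raise ValueError(f"purity_threshold must lie in [0, 1], got {purity_threshold}")
    if psms.empty:
        return psms.copy()
    channels = intensity_columns(psms)
    total = psms[channels].to_numpy(dtype=float).sum(axis=1)
    keep = (
        (psms["purity"].to_numpy(dtype=float) > purity_threshold)
        & ~psms["is_decoy"].to_numpy(dtype=bool)
        & ~psms["is_contaminant"].to_numpy(dtype=bool)
        & ~psms["is_irt"].to_numpy(dtype=bool)
        & (total > 0)
    )
    return psms.loc[keep].copy()


def normalize_to_reference(
    psms: pd.DataFrame, designs: dict[int, PlexDesign]
) -> pd.DataFrame:
    """Per-PSM log2(sample / reference) ratios.

    The empty channel is dropped.  A non-positive reference intensity makes
    the whole row missing; a non-positive sample intensity makes that cell
    missing.  Multiplying all channels of a PSM by a constant leaves the
    ratios unchanged (shift-free normalization).
    """
    out_blocks = []
    for fraction, block in psms.groupby("fraction_id", sort=True):
        design = designs.get(int(fraction))
        if design is None:
            raise DesignMismatchError(
                f"fraction {fraction} present in PSMs but absent from the design"
            )
        ref = block[design.reference_channel].to_numpy(dtype=float)
        ref_ok = ref > 0
        data = {meta: block[meta].to_numpy() for meta in NORM_META}
        with np.errstate(divide="ignore", invalid="ignore"):
            for channel, sample in design.sample_channels.items():
                inten = block[channel].to_numpy(dtype=float)
                ratio = np.log2(inten / ref)
                ratio[~ref_ok | (inten <= 0)] = np.nan
                data[sample] = ratio
        out_blocks.append(pd.DataFrame(data, index=block.index))
    if not out_blocks:
        return pd.DataFrame(columns=[*NORM_META, *SAMPLES])
    out = pd.concat(out_blocks)
    return out[[*NORM_META, *SAMPLES]]


def aggregate_peptides(normalized: pd.DataFrame) -> pd.DataFrame:
    """Peptide-level quantification matrix.

    Median of the PSM log2 ratios per (peptide, accession, fraction, sample),
    ignoring missing values; a cell is missing when every contributing PSM is
    missing.  Rows: MultiIndex (peptide, accession, fraction_id); columns:
    the nine samples.
    """
    if normalized.empty:
        return pd.DataFrame(
            columns=list(SAMPLES),
            index=pd.MultiIndex.from_arrays(
                [[], [], []], names=("peptide", "accession", "fraction_id")
            ),
        )
    return (
        normalized.groupby(["peptide", "accession", "fraction_id"], sort=True)[
            list(SAMPLES)
        ].median()
    )


def peptide_index(psms: pd.DataFrame) -> pd.DataFrame:
    """Unique (peptide, accession, start_pos) triples of a PSM frame."""
    return (
        psms[["peptide", "accession", "start_pos"]]
        .drop_duplicates(subset=["peptide", "accession"])
        .sort_values(["accession", "start_pos", "peptide"])
        .reset_index(drop=True)
    )


def aggregate_proteins(
    peptide_matrix: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Protein-level matrix from fully tryptic peptides only.

    Semi-tryptic peptides never contribute to protein abundance; a protein
    with no tryptic peptide in a fraction is absent from that fraction.
    Every peptide row must carry a specificity annotation.
    """
    key = peptide_matrix.index.droplevel("fraction_id")
    missing = ~key.isin(annotations.index)
    if missing.any():
        offender = key[missing][0]
        raise MappingError(f"peptide without specificity annotation: {offender}")
    spec = annotations["specificity"].reindex(key).to_numpy()
    tryptic = peptide_matrix.loc[spec == SPECIFICITY_TRYPTIC]
    if tryptic.empty:
        return pd.DataFrame(
            columns=list(peptide_matrix.columns),
            index=pd.MultiIndex.from_arrays(
                [[], []], names=("accession", "fraction_id")
            ),
        )
    return tryptic.groupby(level=["accession", "fraction_id"], sort=True).median()


def validate_channel_assignment(
    irt_psms: pd.DataFrame,
    designs: dict[int, PlexDesign],
    *,
    empty_max_ratio: float = 0.10,
    channel_floor_ratio: float = 0.10,
) -> pd.DataFrame:
    """Per-fraction labelling-control check using spiked iRT standards.

    The iRT standards are added to every labelled channel, so their median
    intensity should be comparable in all sample/reference channels and near
    zero in the empty channel.  A fraction fails when the empty channel's
    median iRT intensity exceeds ``empty_max_ratio`` of the across-channel
    median, or when any labelled channel falls below ``channel_floor_ratio``
    of it; with no iRT records the fraction is "not_evaluable".
    """
    rows = []
    for fraction, design in sorted(designs.items()):
        block = irt_psms.loc[irt_psms["fraction_id"] == fraction]
        if block.empty:
            rows.append(
                {
                    "fraction_id": fraction,
                    "status": "not_evaluable",
                    "empty_ratio": np.nan,
                    "min_channel_ratio": np.nan,
                }
            )
            continue
        labelled = [design.reference_channel, *design.sample_channels]
        medians = block[labelled].median()
        across = float(medians.median())
        empty_med = float(block[design.empty_channel].median())
        empty_ratio = empty_med / across if across > 0 else np.inf
        min_ratio = float(medians.min()) / across if across > 0 else 0.0
        status = (
            "fail"
            if empty_ratio > empty_max_ratio or min_ratio < channel_floor_ratio
            else "pass"
        )
        rows.append(
            {
                "fraction_id": fraction,
                "status": status,
                "empty_ratio": empty_ratio,
                "min_channel_ratio": min_ratio,
            }
        )
    return pd.DataFrame(
        rows, columns=["fraction_id", "status", "empty_ratio", "min_channel_ratio"]
    ).set_index("fraction_id")
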