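"""Cleavage-site annotation of identified peptides.

A peptide from a semi-specific tryptic search has zero or one non-tryptic
terminus.  A terminus generated by trypsin (preceded by K/R, or a native
protein terminus) is "specific"; a peptide with both termini specific is fully
tryptic, otherwise it is semi-tryptic and witnesses an endogenous cleavage
event.  The cleavage position is the protein coordinate of the P1 residue —
the residue immediately N-terminal of the scissile bond — and the surrounding
sequence is summarised as the ten-residue Schechter–Berger window
P5..P1 | P1'..P5', padded with "-" beyond the protein termini.

Conventions (documented, configurable where noted):

* A peptide starting at position 2 of a Met-initiated protein counts as a
  native N-terminus (initiator-methionine excision), not a cleavage event.
* Cleavage after K/R counts as tryptic-specific even when the next residue is
  proline (strict-trypsin rule); set ``cleave_before_pro=False`` for the
  ExPASy behaviour.
* N-terminal modification state (TMT vs. acetyl) is metadata only and does
  not change the specificity class.
"""

from __future__ import annotations

import pandas as pd

from .errors import (
    CoordinateError,
    MappingError,
    MissingProteinError,
    NonSpecificPeptideError,
)
from .io import ProteomeDb

TRYPTIC_RESIDUES = frozenset("KR")

SPECIFICITY_TRYPTIC = "tryptic"
SPECIFICITY_SEMI_N = "semi_N"  # non-tryptic N-terminus: cleavage before the peptide
SPECIFICITY_SEMI_C = "semi_C"  # non-tryptic C-terminus: cleavage after the peptide
SEMI_CLASSES = (SPECIFICITY_SEMI_N, SPECIFICITY_SEMI_C)


def terminal_position(prev_residue_pos: int, peptide: str) -> int:
    """Position of a peptide's last residue given the position of the residue
    immediately preceding it (0 for a peptide at the protein N-terminus).

    >>> terminal_position(1093, "LLDLSDSTSVASFPSADETD")
    1113
    """
    if prev_residue_pos < 0:
        raise CoordinateError(f"prev_residue_pos must be >= 0, got {prev_residue_pos}")
    return prev_residue_pos + len(peptide)


def classify_specificity(
    peptide: str,
    prev_aa: str,
    next_aa: str,
    start_pos: int,
    protein_length: int | None = None,
    initiator_met: bool = False,
    cleave_before_pro: bool = True,
) -> str:
    """Classify a peptide as tryptic, semi_N or semi_C.

    ``prev_aa``/``next_aa`` are single residues or "-" for a protein terminus.
    Raises :class:`NonSpecificPeptideError` when neither terminus is specific
    (such peptides cannot come from a semi-specific search).
    """
    if not peptide:
        raise MappingError("empty peptide")
    n_specific = (
        prev_aa in TRYPTIC_RESIDUES
        or prev_aa == "-"
        or start_pos == 1
        or (start_pos == 2 and initiator_met)
    )
    if (
        not cleave_before_pro
        and prev_aa in TRYPTIC_RESIDUES
        and peptide[0] == "P"
        and start_pos > 2
    ):
        n_specific = False
    c_specific = peptide[-1] in TRYPTIC_RESIDUES or next_aa == "-"
    if not cleave_before_pro and peptide[-1] in TRYPTIC_RESIDUES and next_aa == "P":
        c_specific = next_aa == "-"
    if n_specific and c_specific:
        return SPECIFICITY_TRYPTIC
    if c_specific:
        return SPECIFICITY_SEMI_N
    if n_specific:
        return SPECIFICITY_SEMI_C
    raise NonSpecificPeptideError(
        f"peptide {peptide!r} (prev={prev_aa}, next={next_aa}) has no "
        "tryptic-specific terminus"
    )


def extract_cleavage_window(sequence: str, cleavage_pos: int, flank: int = 5) -> str:
    """Schechter–Berger window around a cleavage site.

    ``cleavage_pos`` is the 1-based position of the P1 residue; the scissile
    bond lies between ``cleavage_pos`` and ``cleavage_pos + 1``.  Returns the
    ``2 * flank``-character string P<flank>..P1 P1'..P<flank>', padded with
    "-" where positions fall outside the protein.
    """
    n = len(sequence)
    if not 1 <= cleavage_pos < n:
        raise CoordinateError(
            f"cleavage_pos {cleavage_pos} outside valid range [1, {n - 1}]"
        )
    chars = []
    for pos in range(cleavage_pos - flank + 1, cleavage_pos + flank + 1):
        chars.append(sequence[pos - 1] if 1 <= pos <= n else "-")
    return "".join(chars)


def annotate_peptides(
    peptides: pd.DataFrame,
    proteome: ProteomeDb,
    *,
    cleave_before_pro: bool = True,
) -> pd.DataFrame:
    """Annotate unique (peptide, accession) pairs with specificity, cleavage
    position, P1 residue and the P5–P5' window.

    ``peptides`` needs columns ``peptide``, ``accession`` and ``start_pos``
    (1-based).  Every accession must be present in the proteome and every
    peptide must occur verbatim at its stated position; violations raise
    :class:`MissingProteinError` / :class:`MappingError` naming the offender.

    Returns a frame indexed by (peptide, accession) with columns
    ``start_pos, end_pos, specificity, cleavage_pos, p1, window``; fully
    tryptic peptides carry no cleavage position or window.
    """
    unique = peptides.drop_duplicates(subset=["peptide", "accession"])
    rows = []
    for tup in unique.itertuples(index=False):
        pep, acc, start = tup.peptide, tup.accession, int(tup.start_pos)
        if acc not in proteome:
            raise MissingProteinError(f"accession {acc!r} absent from proteome")
        seq = proteome[acc]
        end = start + len(pep) - 1
        if seq[start - 1:end] != pep:
            raise MappingError(
                f"peptide {pep!r} not found in {acc} at position {start} "
                f"(found {seq[start - 1:end]!r})"
            )
        prev_aa = seq[start - 2] if start > 1 else "-"
        next_aa = seq[end] if end < len(seq) else "-"
        spec = classify_specificity(
            pep,
            prev_aa,
            next_aa,
            start,
            protein_length=len(seq),
            initiator_met=seq.startswith("M"),
            cleave_before_pro=cleave_before_pro,
        )
        if spec == SPECIFICITY_SEMI_N:
            cpos: int | None = start - 1
        elif spec == SPECIFICITY_SEMI_C:
            cpos = end
        else:
            cpos = None
        rows.append(
            {
                "peptide": pep,
                "accession": acc,
                "start_pos": start,
                "end_pos": end,
                "specificity": spec,
                "cleavage_pos": cpos,
                "p1": seq[cpos - 1] if cpos else None,
                "window": extract_cleavage_window(seq, cpos) if cpos else None,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "peptide", "accession", "start_pos", "end_pos", "specificity",
            "cleavage_pos", "p1", "window",
        ],
    )
    out["cleavage_pos"] = out["cleavage_pos"].astype("Int64")
    return out.set_index(["peptide", "accession"])
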