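"""Readers and writers for the tables every other module consumes.

The PSM dialect is a minimal, documented subset of FragPipe's ``psm.tsv``:
tab-separated, one row per peptide-spectrum match, with reporter-intensity
columns named by TMT channel label.  Decoys and contaminants are indicated by
configurable accession prefixes and carried as flags (they are removed during
filtering, not at parse time).  Coordinates are 1-based inclusive; "-" marks
a protein terminus in the prev/next residue columns.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import PlexDesign
from .errors import DesignMismatchError, FormatError, RowParseError

#: metadata columns of the internal PSM frame; the remaining columns are
#: reporter intensities in the plex design's channel order.
PSM_META: tuple[str, ...] = (
    "spectrum", "peptide", "accession", "prev_aa", "next_aa", "start_pos",
    "purity", "is_decoy", "is_contaminant", "is_irt", "has_nterm_label",
    "fraction_id",
)

_REQUIRED_COLUMNS = (
    "Peptide", "Protein", "Prev AA", "Next AA", "Protein Start", "Purity",
)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match (typed view of a PSM-frame row)."""

    peptide: str
    accession: str
    prev_aa: str
    next_aa: str
    start_pos: int
    purity: float
    is_decoy: bool
    is_contaminant: bool
    fraction_id: int
    reporter_intensities: tuple[float, ...]
    has_nterm_label: bool = True
    is_irt: bool = False
    spectrum: str = ""


def intensity_columns(psms: pd.DataFrame) -> list[str]:
    """Reporter-intensity columns of a PSM frame (everything non-meta)."""
    return [c for c in psms.columns if c not in PSM_META]


def _numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.str.strip().ne("")
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowParseError(
            f"unparseable value {series.iloc[idx]!r} in column {column!r}",
            line=idx + 2,  # 1-based, after the header row
        )
    return out


def read_psm_table(
    path,
    design: PlexDesign,
    *,
    decoy_prefix: str = "rev_",
    contaminant_prefix: str = "contam_",
    irt_prefix: str = "iRT_",
) -> pd.DataFrame:
    """Parse one per-fraction PSM table into the internal PSM frame.

    Reporter columns are re-ordered to the design's channel order and missing
    reporter values become zero intensities.  Raises :class:`FormatError` for a
    missing required column, :class:`DesignMismatchError` when the reporter
    columns do not match the design, and :class:`RowParseError` (with the file
    line) for an unparseable numeric cell.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"PSM table {path} missing required column(s): {', '.join(missing)}"
        )
    absent = [c for c in design.channels if c not in raw.columns]
    if absent:
        raise DesignMismatchError(
            f"PSM table {path} lacks reporter column(s) {absent} required by "
            f"the design of fraction {design.fraction_id}"
        )

    out = pd.DataFrame(index=raw.index)
    if "Spectrum" in raw.columns:
        out["spectrum"] = raw["Spectrum"]
    else:
        out["spectrum"] = [f"psm_{i}" for i in range(len(raw))]
    out["peptide"] = raw["Peptide"].str.strip()
    if (out["peptide"] == "").any():
        idx = int(np.flatnonzero((out["peptide"] == "").to_numpy())[0])
        raise RowParseError("empty peptide", line=idx + 2)
    out["accession"] = raw["Protein"].str.strip()
    out["prev_aa"] = raw["Prev AA"].replace("", "-")
    out["next_aa"] = raw["Next AA"].replace("", "-")
    start = _numeric(raw["Protein Start"], "Protein Start")
    if start.isna().any() or (start < 1).any():
        idx = int(np.flatnonzero((start.isna() | (start < 1)).to_numpy())[0])
        raise RowParseError("Protein Start must be a 1-based position", line=idx + 2)
    out["start_pos"] = start.astype(int)
    purity = _numeric(raw["Purity"], "Purity")
    if purity.isna().any() or (purity < 0).any() or (purity > 1).any():
        idx = int(
            np.flatnonzero((purity.isna() | (purity < 0) | (purity > 1)).to_numpy())[0]
        )
        raise RowParseError("Purity must lie in [0, 1]", line=idx + 2)
    out["purity"] = purity
    out["is_decoy"] = out["accession"].str.startswith(decoy_prefix)
    out["is_contaminant"] = out["accession"].str.startswith(contaminant_prefix)
    out["is_irt"] = out["accession"].str.startswith(irt_prefix)
    if "Assigned Modifications" in raw.columns:
        out["has_nterm_label"] = raw["Assigned Modifications"].str.contains(
            "N-term", regex=False
        )
    else:
        out["has_nterm_label"] = True
    out["fraction_id"] = design.fraction_id
    for channel in design.channels:
        out[channel] = _numeric(raw[channel], channel).fillna(0.0)
    return out


def write_psm_table(psms: pd.DataFrame, design: PlexDesign, path) -> None:
    """Write a PSM frame back to the ``psm.tsv`` dialect (one fraction)."""
    out = pd.DataFrame(
        {
            "Spectrum": psms["spectrum"],
            "Peptide": psms["peptide"],
            "Protein": psms["accession"],
            "Prev AA": psms["prev_aa"],
            "Next AA": psms["next_aa"],
            "Protein Start": psms["start_pos"],
            "Purity": psms["purity"],
            "Assigned Modifications": np.where(
                psms["has_nterm_label"], "N-term(229.1629)", ""
            ),
        }
    )
    for channel in design.channels:
        out[channel] = psms[channel]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic matrix round-tripping


def write_matrix(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a feature x sample/fraction table as TSV.

    The (possibly hierarchical) index is written as leading columns and
    recorded in an ``#index:`` header so :func:`read_matrix` restores it.
    Missing values become empty cells.  Provenance key/value pairs are written
    as ``# key: value`` comment lines.  Duplicate row identifiers are refused.
    """
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:3]
        raise FormatError(f"duplicate row identifiers: {dupes}")
    names = [n if n is not None else "index" for n in df.index.names]
    buf = _io.StringIO()
    for key, value in (provenance or {}).items():
        buf.write(f"# {key}: {value}\n")
    buf.write("#index:\t" + "\t".join(names) + "\n")
    body = df.copy()
    body.index.names = names
    body.reset_index().to_csv(buf, sep="\t", index=False, na_rep="")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_matrix`, restoring the index.

    Index levels named ``fraction_id`` are coerced back to integers.
    Provenance comments are exposed on ``df.attrs['provenance']``.
    """
    provenance: dict[str, str] = {}
    names: list[str] | None = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("#index:"):
                names = line[len("#index:"):].strip("\n").strip("\t").split("\t")
            else:
                key, _, value = line[1:].partition(":")
                provenance[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    if names:
        df = df.set_index(names)
        if "fraction_id" in names:
            if isinstance(df.index, pd.MultiIndex):
                lvl = names.index("fraction_id")
                df.index = df.index.set_levels(
                    df.index.levels[lvl].astype(int), level=lvl
                )
            else:
                df.index = df.index.astype(int)
    df.attrs["provenance"] = provenance
    return df


# ---------------------------------------------------------------------------
# proteome and protease annotation


@dataclass
class ProteomeDb:
    """Accession -> amino-acid sequence (one-letter code), with optional gene symbols."""

    sequences: dict[str, str] = field(default_factory=dict)
    genes: dict[str, str] = field(default_factory=dict)

    def add(self, accession: str, sequence: str, gene: str | None = None) -> None:
        sequence = sequence.upper()
        if not sequence:
            raise FormatError(f"empty sequence for {accession}")
        bad = set(sequence) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{accession}: invalid residue(s) {sorted(bad)} "
                "(allowed: 20 standard residues + X)"
            )
        self.sequences[accession] = sequence
        if gene:
            self.genes[accession] = gene

    def __contains__(self, accession: str) -> bool:
        return accession in self.sequences

    def __getitem__(self, accession: str) -> str:
        return self.sequences[accession]

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


def read_fasta(path) -> ProteomeDb:
    """Load a proteome FASTA; gene symbols are parsed from ``GN=`` tags."""
    db = ProteomeDb()
    for record in SeqIO.parse(str(path), "fasta"):
        gene = None
        for token in record.description.split():
            if token.startswith("GN="):
                gene = token[3:]
        db.add(record.id, str(record.seq), gene)
    if not db.sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return db


def write_fasta(db: ProteomeDb, path) -> None:
    records = []
    for accession, seq in db.items():
        gene = db.genes.get(accession)
        desc = f"GN={gene}" if gene else ""
        records.append(SeqRecord(Seq(seq), id=accession, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_merops(path) -> pd.DataFrame:
    """Read a protease annotation TSV (accession, family[, gene[, is_protease]]).

    Accessions listed without an ``is_protease`` column are all proteases.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "family"):
        if col not in df.columns:
            raise FormatError(f"protease annotation missing column {col!r}")
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise FormatError(f"duplicate accession(s) in protease annotation: {dupes}")
    if "gene" not in df.columns:
        df["gene"] = ""
    if "is_protease" in df.columns:
        df["is_protease"] = df["is_protease"].str.lower().isin(("true", "1", "yes"))
    else:
        df["is_protease"] = True
    return df.set_index("accession")[["family", "gene", "is_protease"]]


def write_merops(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)
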