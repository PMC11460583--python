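"""End-to-end orchestration over intermediate TSVs.

Every stage reads and writes plain TSV files through :mod:`secdeg.io`, so the
pipeline is resumable from any intermediate and `run-all` is a thin chain of
the same stage functions the CLI exposes.  Outputs carry a provenance header
(config hash, seed, package version — deliberately nothing time- or
path-dependent) so a fixed seed reproduces byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .design import CONDITIONS, read_design
from .differential import per_fraction_contrasts
from .errors import StageError
from .io import (
    read_fasta,
    read_matrix,
    read_merops,
    read_psm_table,
    write_matrix,
)
from .motif import motif_report
from .profiles import (
    percentage_distribution,
    protein_fraction_matrix,
    release_calls,
)
from .proteases import protease_report
from .quant import (
    aggregate_peptides,
    aggregate_proteins,
    filter_psms,
    normalize_to_reference,
    peptide_index,
    split_irt,
    validate_channel_assignment,
)
from .simulate import (
    SimConfig,
    generate_ground_truth,
    simulate_psm_tables,
    write_simulation,
)
from .terminomics import annotate_peptides

DEFAULT_THRESHOLDS = {
    "purity_threshold": 0.5,
    "adj_p": 0.05,
    "min_shift": 3,
    "min_fractions": 3,
}


def _provenance(config: dict, seed: int) -> dict:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {"config_sha256": digest, "seed": seed, "secdeg_version": __version__}


def _slug(text: str) -> str:
    return (
        text.replace("+", "")
        .replace(" ", "_")
        .replace("/", "-")
    )


def stage_simulate(out_dir, seed: int, sim_overrides: dict | None = None) -> Path:
    """Generate and write the synthetic study (PSM tables, design, FASTA,
    protease annotation, ground-truth labels)."""
    from .design import rotated_design

    cfg = SimConfig.from_dict(sim_overrides or {})
    truth = generate_ground_truth(cfg, seed)
    designs = rotated_design(cfg.n_fractions)
    sim = simulate_psm_tables(truth, designs, seed + 1)
    out = Path(out_dir)
    write_simulation(sim, truth, designs, out)
    return out


def stage_quantify(
    input_dir, out_dir, *, purity_threshold: float = 0.5, provenance: dict
) -> None:
    """PSM tables + design -> filtered, normalized peptide matrix + iRT QC."""
    inp, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    designs = read_design(inp / "design.tsv")
    frames = []
    for f, design in designs.items():
        path = inp / f"psm_fraction{f:02d}.tsv"
        if path.exists():
            frames.append(read_psm_table(path, design))
    psms = pd.concat(frames, ignore_index=True)
    quant, irt = split_irt(psms)
    kept = filter_psms(quant, purity_threshold)
    normalized = normalize_to_reference(kept, designs)
    pep_matrix = aggregate_peptides(normalized)
    write_matrix(pep_matrix, out / "peptide_matrix.tsv", provenance)
    idx = peptide_index(kept)
    idx.to_csv(out / "peptide_index.tsv", sep="\t", index=False)
    qc = validate_channel_assignment(irt, designs)
    write_matrix(qc, out / "qc_irt.tsv", provenance)
    log = [
        f"psms_in={len(psms)}",
        f"irt={len(irt)}",
        f"kept_after_filter={len(kept)}",
        f"peptide_rows={len(pep_matrix)}",
    ]
    (out / "quantify_log.txt").write_text("\n".join(log) + "\n")


def stage_annotate(input_dir, out_dir, *, provenance: dict) -> None:
    """Peptide index + proteome FASTA -> cleavage annotations + protein matrix."""
    inp, out = Path(input_dir), Path(out_dir)
    fasta = inp / "proteome.fasta"
    if not fasta.exists():
        raise FileNotFoundError(f"proteome FASTA not found: {fasta}")
    proteome = read_fasta(fasta)
    peptides = pd.read_csv(out / "peptide_index.tsv", sep="\t")
    annotations = annotate_peptides(peptides, proteome)
    write_matrix(annotations, out / "annotations.tsv", provenance)
    pep_matrix = read_matrix(out / "peptide_matrix.tsv")
    prot_matrix = aggregate_proteins(pep_matrix, annotations)
    write_matrix(prot_matrix, out / "protein_matrix.tsv", provenance)


def stage_contrast(out_dir, *, alpha: float, provenance: dict) -> None:
    """Semi-tryptic per-fraction moderated contrasts with BH correction."""
    out = Path(out_dir)
    pep_matrix = read_matrix(out / "peptide_matrix.tsv")
    annotations = read_matrix(out / "annotations.tsv")
    results = per_fraction_contrasts(pep_matrix, annotations, alpha=alpha)
    results.to_csv(out / "contrasts.tsv", sep="\t", index=False)


def stage_motif(out_dir, *, alpha: float, provenance: dict) -> None:
    """Positional cleavage-window matrices per contrast (pooled fractions)."""
    import warnings as _warnings

    out = Path(out_dir)
    results = pd.read_csv(out / "contrasts.tsv", sep="\t")
    annotations = read_matrix(out / "annotations.tsv")
    for contrast in sorted(results["contrast"].dropna().unique()):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            mm = motif_report(
                results, annotations, contrast=contrast, alpha=alpha
            )
        write_matrix(
            mm.to_frame(),
            out / f"motif_{_slug(contrast)}.tsv",
            {**provenance, "n_windows": mm.n_windows},
        )


def stage_profiles(
    out_dir,
    *,
    min_shift: int,
    min_fractions: int,
    n_fractions: int,
    provenance: dict,
) -> None:
    """Condition percentage distributions, profile differences and release calls."""
    out = Path(out_dir)
    pep_matrix = read_matrix(out / "peptide_matrix.tsv")
    prot_matrix = read_matrix(out / "protein_matrix.tsv")
    annotations = read_matrix(out / "annotations.tsv")
    wides = {
        c: protein_fraction_matrix(prot_matrix, c, n_fractions) for c in CONDITIONS
    }
    import warnings as _warnings

    for cond, wide in wides.items():
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            pct = percentage_distribution(wide, input_scale="log2")
        write_matrix(pct, out / f"percentages_{_slug(cond)}.tsv", provenance)
    for treated in CONDITIONS[1:]:
        diff = wides[treated] - wides[CONDITIONS[0]]
        write_matrix(
            diff, out / f"profile_diff_{_slug(treated)}_vs_L.tsv", provenance
        )
    calls = []
    for cond in CONDITIONS:
        calls.append(
            release_calls(
                pep_matrix,
                prot_matrix,
                annotations,
                cond,
                min_shift=min_shift,
                min_fractions=min_fractions,
                n_fractions=n_fractions,
            )
        )
    pd.concat(calls, ignore_index=True).to_csv(
        out / "release_calls.tsv", sep="\t", index=False
    )


def stage_proteases(
    input_dir, out_dir, *, n_fractions: int, condition: str, provenance: dict
) -> None:
    """Clustered percentage distributions of annotated proteases."""
    import warnings as _warnings

    inp, out = Path(input_dir), Path(out_dir)
    merops = read_merops(inp / "merops.tsv")
    prot_matrix = read_matrix(out / "protein_matrix.tsv")
    wide = protein_fraction_matrix(prot_matrix, condition, n_fractions)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        pct = percentage_distribution(wide, input_scale="log2")
        reports = protease_report(pct, merops)
    for name, frame in reports.items():
        write_matrix(frame, out / f"proteases_{_slug(name)}.tsv", provenance)


def run_pipeline(
    out_dir,
    *,
    seed: int = 0,
    simulate: bool = True,
    input_dir=None,
    config: dict | None = None,
) -> Path:
    """Run every stage end-to-end; deterministic given inputs + seed.

    ``config`` may override the thresholds in :data:`DEFAULT_THRESHOLDS` and,
    under the key ``"sim"``, any :class:`~secdeg.simulate.SimConfig` field.
    Any stage error aborts with the stage name attached.
    """
    config = config or {}
    thresholds = {**DEFAULT_THRESHOLDS, **{
        k: v for k, v in config.items() if k in DEFAULT_THRESHOLDS
    }}
    sim_overrides = dict(config.get("sim", {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance({**thresholds, "sim": sim_overrides}, seed)
    n_fractions = int(sim_overrides.get("n_fractions", 21))

    def _run(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise StageError(name, exc) from exc

    if simulate:
        input_dir = _run("simulate", stage_simulate, out / "sim", seed, sim_overrides)
    elif input_dir is None:
        raise StageError("setup", ValueError("need input_dir when simulate=False"))
    input_dir = Path(input_dir)
    _run(
        "quantify", stage_quantify, input_dir, out,
        purity_threshold=thresholds["purity_threshold"], provenance=prov,
    )
    _run("annotate", stage_annotate, input_dir, out, provenance=prov)
    _run("contrast", stage_contrast, out, alpha=thresholds["adj_p"], provenance=prov)
    _run("motif", stage_motif, out, alpha=thresholds["adj_p"], provenance=prov)
    _run(
        "profiles", stage_profiles, out,
        min_shift=thresholds["min_shift"],
        min_fractions=thresholds["min_fractions"],
        n_fractions=n_fractions, provenance=prov,
    )
    _run(
        "proteases", stage_proteases, input_dir, out,
        n_fractions=n_fractions, condition=CONDITIONS[1], provenance=prov,
    )
    (out / "run_log.txt").write_text(
        "\n".join(
            [
                f"seed={seed}",
                f"config_sha256={prov['config_sha256']}",
                f"secdeg_version={__version__}",
                "stages=simulate,quantify,annotate,contrast,motif,profiles,proteases"
                if simulate
                else "stages=quantify,annotate,contrast,motif,profiles,proteases",
            ]
        )
        + "\n"
    )
    return out
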