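"""Per-fraction moderated differential abundance and the cleavage motif.

Plants 60 cleavage events (80% with Asp at P1) at a log2 effect of 2 under
both treatments, tests every semi-tryptic peptide per SEC fraction with the
moderated t-statistic, BH-adjusts within each fraction x contrast family and
tallies the significant cleavage windows into a positional matrix.
"""

import pandas as pd

from secdeg import (
    SimConfig,
    aggregate_peptides,
    annotate_peptides,
    dominant_residues,
    filter_psms,
    generate_ground_truth,
    motif_report,
    normalize_to_reference,
    per_fraction_contrasts,
    rotated_design,
    simulate_psm_tables,
)
from secdeg.quant import split_irt

cfg = SimConfig(n_proteins=40, n_cleavage_events=60, frac_p1_asp=0.8,
                delta_log2=2.0, sigma_noise=0.3, n_proteases_per_family=0)
truth = generate_ground_truth(cfg, seed=5)
designs = rotated_design(cfg.n_fractions)
sim = simulate_psm_tables(truth, designs, seed=6)
psms = pd.concat(sim.tables.values(), ignore_index=True)
quant, _ = split_irt(psms)
kept = filter_psms(quant)
matrix = aggregate_peptides(normalize_to_reference(kept, designs))
idx = kept[["peptide", "accession", "start_pos"]].drop_duplicates(
    subset=["peptide", "accession"])
ann = annotate_peptides(idx, truth.proteome())

results = per_fraction_contrasts(matrix, ann, alpha=0.05)
sig = results[results.significant]
print(f"{len(sig)} significant (peptide, fraction, contrast) hits of "
      f"{int(results.tested.sum())} tests")
print("moderated-t prior pooled per fraction; families:",
      results.groupby(['fraction_id', 'contrast']).size().shape[0])

mm = motif_report(results, ann, contrast="L+N vs L", alpha=0.05)
print(f"motif matrix over {mm.n_windows} unique cleavage sites")
print("P1 ranking:", dominant_residues(mm, "P1")[:4])
# Asp dominates P1: the planted caspase-like specificity is recovered from
# the differential results alone.
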