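"""Annotate semi-tryptic peptides with cleavage sites and P5-P5' windows.

A peptide with exactly one tryptic terminus witnesses an endogenous cleavage;
its cleavage position (the P1 residue) and the surrounding ten-residue
Schechter-Berger window are derived from the protein sequence.
"""

import pandas as pd

from secdeg import (
    ProteomeDb,
    annotate_peptides,
    classify_specificity,
    extract_cleavage_window,
    terminal_position,
)

# Worked example: the caspase-3 site DETD|G at position 1113 of Rock1.
# The fragment downstream of the preceding tryptic K (position 1093) is the
# printed 20-residue peptide, so its C-terminal Asp sits at 1093 + 20 = 1113.
peptide = "LLDLSDSTSVASFPSADETD"
print("Rock1 fragment ends at residue", terminal_position(1093, peptide))
print("its specificity:", classify_specificity(peptide, "K", "G", 1094))
print("the released counterpart:", classify_specificity("GNLPESR", "D", "A", 1114))

# Window extraction around a gelsolin-like DQTD|G site in a toy sequence.
seq = "MKTAYDQTDGPGLGK"
window = extract_cleavage_window(seq, 9)
print("cleavage window P5..P1|P1'..P5':", window[:5], "|", window[5:])

# Bulk annotation against a proteome
db = ProteomeDb()
db.add("P1", seq, gene="Gsn")
rows = pd.DataFrame(
    [("TAYDQTD", "P1", 3), ("GPGLGK", "P1", 10), ("TAYDQTDGPGLGK", "P1", 3)],
    columns=["peptide", "accession", "start_pos"],
)
print(annotate_peptides(rows, db)[["specificity", "cleavage_pos", "p1", "window"]])
# semi_C / semi_N share the same site (position 9, P1 = D); the fully
# tryptic peptide carries no window.
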