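"""Reference sequences used throughout the analysis.

The four G2-rich RNA aptamers (RF000, RF001, RF002, RF004) selected
against FOXL2, the scrambled control unable to fold into a G-quadruplex
(scr50), the G-doublet-disrupted mutant of RF001 with identical base
composition (mutRF001), the fixed primer flanks of the two SELEX
library designs, and the relaxed G2-rich consensus motif.
"""

from __future__ import annotations

from .reads import Chemistry, LibraryDesign

RF000 = "GAGGUAUUAAGAGGCGGAGGCGGAAGGAUGGCGGAGGACCGACAGAGAAG"
RF001 = "CGUCAUUUGGUGGAUGGCGGAAGGAGGCGGAGGACGGGAAAUUCUGGAAA"
RF002 = "UCGGACUUUGGUGGUUGGAGGACGGAUGGACGGAGGUUUAUUAGGCUCGC"
RF004 = "AUCUGCGACUGGCUGGAGGUGGACGGAUGGCUGGAGGCGAAAUUGGCUUA"
SCR50 = "GGGACACUCGCUGUUUUCGAAAUUACCCUUUAUGCGCGGGUAUUGAACCA"
MUTRF001 = "CGUCAUUUGAGUGAGUGAGCGAGAGAGAGUGCGUGAGAGACGAGAGCGUG"

G4_APTAMERS = {"RF000": RF000, "RF001": RF001, "RF002": RF002, "RF004": RF004}
CONTROL_ID = "scr50"
ALL_APTAMERS = {**G4_APTAMERS, CONTROL_ID: SCR50, "mutRF001": MUTRF001}

# 28-nt G2-rich consensus motif distilled from the most enriched
# families (8 G doublets; N = any non-G-extending base).
G2_CONSENSUS = "GGNNGGNNGGNGGANGGANGGNNGGAGG"

# Library designs: a 26-nt random core for the double-stranded DNA
# screen and a 50-nt random core for the RNA screen (flanks as on the
# cDNA strand that is sequenced).
DNA_DESIGN = LibraryDesign(
    flank5="CAGATCAGTTCAGCGGATCGTGTCT",
    flank3="GATGCGGAATTCAGTGCAACTGCAGC",
    var_len=26,
    chemistry=Chemistry.DNA,
)
RNA_DESIGN = LibraryDesign(
    flank5="GGGAGAGUAUCCGUUGAGGCUGA",
    flank3="AGAUCGGAAGAGCGUCGUGUAGG",
    var_len=50,
    chemistry=Chemistry.RNA,
)
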