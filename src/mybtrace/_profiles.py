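"""Shipped repeat consensus profiles.

A MYB repeat is a ~50-54 aa three-helix bundle with three regularly spaced
tryptophans buried in the hydrophobic core.  The package ships one consensus
per repeat class: the R2 and R3 repeats of typical plant R2R3-MYBs
(c-MYB-like) and the two MYB-like repeats of CDC5 proteins, which carry the
same W spacing but an otherwise divergent sequence.  All four are 53 columns
wide with the W anchors at columns 6, 26 and 45 (1-based), approximating
c-Myb spacing.

These consensi are synthetic profiles designed for the packaged simulator and
scanner; they are not curated database entries.
"""

REPEAT_LENGTH = 53

# 0-based offsets of the three conserved Trp anchors within a repeat.
ANCHOR_OFFSETS = (5, 25, 44)

# Approximate helix spans within a repeat (0-based, half-open), helices 2-3
# forming the helix-turn-helix.
HELIX_SPANS = ((2, 15), (20, 32), (37, 50))

MYB_R2 = "LKKGA" "W" "TAEEDQLLVNYIQKHGEGN" "W" "RSLPKAAGLQRCGKSCRL" "W" "LNYLKPNI"
MYB_R3 = "VKRGN" "W" "TEEEDRIIVEAHQILGNRK" "W" "AEIAKRLPGRTDNEIKNH" "W" "NSTLRRKL"

CDC5_R1 = "PRIMI" "W" "SEEEDEKLRALVKEYGKNN" "W" "SKIASHLPNRTDVQCQHR" "W" "HRLDPAIN"
CDC5_R2 = "GEIDI" "W" "NPEKDAQLLELVEKHGAKK" "W" "TLIAKHLEGRIGKQCRER" "W" "HNELNPAL"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Structurally constrained (slowly evolving) repeat columns, 0-based: a
#: fixed 40% of non-anchor positions standing in for the helix-packing
#: residues that real MYB repeats conserve across deep time.
SLOW_COLUMNS = tuple(
    i for i in range(REPEAT_LENGTH) if i not in ANCHOR_OFFSETS and i % 5 < 2
)

#: Profile weights by column class: conservation-aware scoring, as in any
#: position-specific scanner — conserved columns are informative, fast
#: columns nearly neutral, the Trp anchors most diagnostic.
ANCHOR_WEIGHT = 3.0
SLOW_WEIGHT = 2.0
FAST_WEIGHT = 0.5

for _c in (MYB_R2, MYB_R3, CDC5_R1, CDC5_R2):
    assert len(_c) == REPEAT_LENGTH, _c
    assert all(_c[_o] == "W" for _o in ANCHOR_OFFSETS), _c
del _c
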