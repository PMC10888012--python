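"""Independent hand-written residue-property lookup used as a test oracle.

Written residue by residue (three-letter mnemonics, one dict entry each) so
it cannot share a transcription error with the set-based definitions in the
package.  Entries: (hydropathy, size, ring or None, charge or None).
"""

RESIDUE_PROPERTIES = {
    "A": ("hydrophobic", "small", "aliphatic", None),        # Ala
    "R": ("polar", "large", None, "positive"),               # Arg
    "N": ("polar", "small", None, None),                     # Asn
    "D": ("polar", "small", None, "negative"),               # Asp
    "C": ("hydrophobic", "small", None, None),               # Cys
    "Q": ("polar", "large", None, None),                     # Gln
    "E": ("polar", "large", None, "negative"),               # Glu
    "G": ("hydrophobic", "small", None, None),               # Gly
    "H": ("polar", "large", "aromatic", "positive"),         # His
    "I": ("hydrophobic", "large", "aliphatic", None),        # Ile
    "L": ("hydrophobic", "large", "aliphatic", None),        # Leu
    "K": ("polar", "large", "aliphatic", "positive"),        # Lys (aliphatic here)
    "M": ("hydrophobic", "large", "aliphatic", None),        # Met
    "F": ("hydrophobic", "large", "aromatic", None),         # Phe
    "P": ("hydrophobic", "small", "aliphatic", None),        # Pro
    "S": ("polar", "small", None, None),                     # Ser
    "T": ("polar", "small", None, None),                     # Thr
    "W": ("hydrophobic", "large", "aromatic", None),         # Trp
    "Y": ("polar", "large", "aromatic", None),               # Tyr
    "V": ("hydrophobic", "small", "aliphatic", None),        # Val
}

AXIS_INDEX = {"hydropathy": 0, "size": 1, "ring": 2, "charge": 3}


def expected_categories(wt: str, mut: str) -> set[tuple[str, str, str]]:
    """(axis, from_group, to_group) triples both residues have groups for."""
    out = set()
    for axis, i in AXIS_INDEX.items():
        fg = RESIDUE_PROPERTIES[wt][i]
        tg = RESIDUE_PROPERTIES[mut][i]
        if fg is not None and tg is not None:
            out.add((axis, fg, tg))
    return out
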