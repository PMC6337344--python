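"""Canonical amino-acid alphabet shared across the package.

Twenty standard amino acids in alphabetical one-letter order, plus a single
gap character.  All symbol-to-integer conversions in the package use this
ordering; the gap is assigned the sentinel index 20.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
GAP_INDEX: int = 20

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Ambiguity / non-standard codes mapped to gap: B (Asx), Z (Glx), X (any),
# J (Leu/Ile), O (pyrrolysine), U (selenocysteine).  The gap encodes as the
# zero vector downstream, so this keeps every encoding exact.
AMBIGUOUS_CODES: frozenset[str] = frozenset("BZXJOU")
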