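"""Amino-acid alphabet, integer encoding, and biochemical classes.

The toolkit works over the 20 standard amino acids plus a gap state ('-')
and an ambiguity state ('X'). Integer codes: 0..19 amino acids (alphabetical
one-letter order), 20 gap, 21 ambiguity. Ambiguity never contributes mass to
residue frequencies; in Potts encodings it is folded into the gap state.
"""

from __future__ import annotations

import numpy as np

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"
ALPHABET: str = AA20 + GAP + UNKNOWN

GAP_CODE: int = 20
UNKNOWN_CODE: int = 21
N_AA: int = 20
Q: int = 21  # Potts states: 20 amino acids + gap

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

# Biochemical classes used for residue-set search and for coloring:
# the eight classes partition the 20 amino acids exactly.
RESIDUE_CLASSES: dict[str, str] = {
    "nonpolar": "AVILMWFY",
    "cysteine": "C",
    "acidic": "DE",
    "basic": "KR",
    "polar": "STNQ",
    "glycine": "G",
    "histidine": "H",
    "proline": "P",
}

CLASS_OF: dict[str, str] = {
    aa: name for name, members in RESIDUE_CLASSES.items() for aa in members
}

_ENCODE_LUT = np.full(128, UNKNOWN_CODE, dtype=np.int8)
for _ch, _i in AA_INDEX.items():
    _ENCODE_LUT[ord(_ch)] = _i


def encode(row: str) -> np.ndarray:
    """Encode an aligned row into integer codes (0..19 aa, 20 gap, 21 'X')."""
    raw = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw].astype(np.int8)


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)
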