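"""21-token design alphabet: the 20 standard amino acids plus one unknown token.

Tokens 0..19 are the standard residues sorted by one-letter code; token 20 is
the unknown/nonstandard placeholder ``X``.
"""

from __future__ import annotations

import numpy as np

ONE_LETTER = "ACDEFGHIKLMNPQRSTVWYX"
ALPHABET_SIZE = 21
UNKNOWN_TOKEN = 20

_THREE_LETTER = [
    "ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS", "LEU",
    "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL", "TRP", "TYR",
    "UNK",
]

TOKEN_TO_THREE = dict(enumerate(_THREE_LETTER))
THREE_TO_TOKEN = {three: tok for tok, three in TOKEN_TO_THREE.items()}
TOKEN_TO_ONE = dict(enumerate(ONE_LETTER))
ONE_TO_TOKEN = {one: tok for tok, one in TOKEN_TO_ONE.items()}


def encode_sequence(seq: str) -> np.ndarray:
    """Map a one-letter sequence string to integer tokens (unknown -> 20)."""
    return np.array([ONE_TO_TOKEN.get(c.upper(), UNKNOWN_TOKEN) for c in seq],
                    dtype=np.int64)


def decode_sequence(tokens: np.ndarray) -> str:
    """Map integer tokens back to a one-letter sequence string."""
    return "".join(TOKEN_TO_ONE[int(t)] for t in np.asarray(tokens).ravel())


def token_from_three(name: str) -> int:
    """Three-letter residue name to token; nonstandard names map to unknown."""
    return THREE_TO_TOKEN.get(name.upper(), UNKNOWN_TOKEN)
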