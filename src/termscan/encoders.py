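"""Sequence encodings for the two model input formats.

One-hot: an L x 4 indicator matrix (column order A, C, G, U). Pairing
matrix: an L x L symmetric matrix scoring the self-pairing potential of
every position pair — G-C 1.0, A-U 0.66, G-U 0.33, non-pairing 0 — so the
network sees every possible stem of the input as an (anti-)diagonal stripe.
The ambiguous base N encodes to zeros in both formats, which lets genome
scans tolerate assembly gaps. No minimum-distance masking is applied near
the diagonal (models must learn loop constraints); the diagonal itself is 0.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PAIRING_WEIGHTS",
    "one_hot_encode",
    "pairing_matrix_encode",
    "batch_one_hot",
    "batch_pairing_matrix",
]

_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

_ONE_HOT_ROWS = np.vstack([np.eye(4, dtype=np.float32), np.zeros(4, np.float32)])

#: unordered pair weights: {G,C} -> 1, {A,U} -> 0.66, {G,U} -> 0.33
PAIRING_WEIGHTS = {
    frozenset("GC"): 1.0,
    frozenset("AU"): 0.66,
    frozenset("GU"): 0.33,
}

_PAIR_LUT = np.zeros((5, 5), dtype=np.float32)
for _bases, _w in PAIRING_WEIGHTS.items():
    _a, _b = sorted(_bases)
    _PAIR_LUT[_INDEX[_a], _INDEX[_b]] = _PAIR_LUT[_INDEX[_b], _INDEX[_a]] = _w


def _encode_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def one_hot_encode(seq: str) -> np.ndarray:
    """L x 4 one-hot matrix over {A,C,G,U}; N rows are all-zero."""
    return _ONE_HOT_ROWS[_encode_indices(seq)]


def pairing_matrix_encode(seq: str) -> np.ndarray:
    """L x L self-pairing potential matrix (symmetric, zero diagonal)."""
    idx = _encode_indices(seq)
    m = _PAIR_LUT[idx[:, None], idx[None, :]].copy()
    np.fill_diagonal(m, 0.0)
    return m


def batch_one_hot(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into a (B, L, 4) tensor."""
    return np.stack([one_hot_encode(s) for s in seqs])


def batch_pairing_matrix(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into a (B, L, L, 1) single-channel tensor."""
    return np.stack([pairing_matrix_encode(s) for s in seqs])[..., None]
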