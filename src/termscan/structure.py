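"""RNA secondary-structure core: dot-bracket parsing, a weighted maximum-pairing
folder, base-pair distance, and inverse folding.

The folder is a Nussinov-style dynamic program that maximises total pair weight
(G-C = 3, A-U = 2, G-U = 1) over pseudoknot-free structures with a minimum
hairpin loop of ``min_loop`` unpaired nucleotides. It deliberately uses a
maximum-pairing model rather than a thermodynamic energy model: the simple
weights make the optimum enumerable by brute force on short sequences, so the
folder (and everything built on it, notably inverse folding) is testable
against an independent oracle. A thermodynamic backend (ViennaRNA) can be
selected for inverse folding where it is installed.

Inverse folding searches sequence space for a sequence whose folded structure
equals a dot-bracket target. The internal backend runs an adaptive stochastic
local search: single-base moves concentrated on positions that currently
disagree with the target, and pair-compensatory moves that rewrite both sides
of a target base pair, accepting any move that does not increase the base-pair
distance between the candidate's fold and the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "PAIR_WEIGHTS",
    "PAIRING_DINUCLEOTIDES",
    "parse_dotbracket",
    "pairs_to_dotbracket",
    "fold_nussinov",
    "basepair_distance",
    "structure_weight",
    "InverseFoldResult",
    "InverseFoldError",
    "inverse_fold",
    "PretrainRecord",
    "PretrainingSet",
    "generate_pretraining_set",
    "gc_content",
]

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4
_BASE_INDEX["T"] = 3  # DNA input tolerated; T read as U

#: canonical + wobble pair weights on base indices (A,C,G,U,N)
PAIR_WEIGHTS = np.zeros((5, 5), dtype=np.int32)
PAIR_WEIGHTS[2, 1] = PAIR_WEIGHTS[1, 2] = 3  # G-C
PAIR_WEIGHTS[0, 3] = PAIR_WEIGHTS[3, 0] = 2  # A-U
PAIR_WEIGHTS[2, 3] = PAIR_WEIGHTS[3, 2] = 1  # G-U

#: the six pairing dinucleotides (canonical + wobble), as base strings
PAIRING_DINUCLEOTIDES = ("GC", "CG", "AU", "UA", "GU", "UG")


def encode_sequence(seq: str) -> np.ndarray:
    """Map an RNA string over {A,C,G,U,N} to base indices (int8)."""
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def decode_sequence(enc: np.ndarray) -> str:
    return "".join("ACGUN"[i] for i in enc)


def parse_dotbracket(db: str) -> set[tuple[int, int]]:
    """Parse a dot-bracket string into a set of (i, j) pairs with i < j.

    Raises ``ValueError`` on unbalanced strings or foreign characters.
    """
    pairs: set[tuple[int, int]] = set()
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], length: int) -> str:
    chars = ["."] * length
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def _pairs_to_partner(pairs: Iterable[tuple[int, int]], length: int) -> np.ndarray:
    partner = np.full(length, -1, dtype=np.int32)
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    return partner


@njit(cache=True)
def _nussinov_fill(enc, weights, min_loop):  # pragma: no cover - jitted
    n = enc.shape[0]
    W = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(0, n - d):
            j = i + d
            best = W[i, j - 1]
            for k in range(i, j - min_loop):
                w = weights[enc[k], enc[j]]
                if w > 0:
                    left = W[i, k - 1] if k > i else 0
                    inner = W[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    s = left + inner + w
                    if s > best:
                        best = s
                W[i, j] = best
    return W


@njit(cache=True)
def _nussinov_traceback(W, enc, weights, min_loop):  # pragma: no cover - jitted
    n = enc.shape[0]
    partner = np.full(n, -1, dtype=np.int32)
    # explicit stack of (i, j) intervals
    stack_i = np.empty(n + 1, dtype=np.int32)
    stack_j = np.empty(n + 1, dtype=np.int32)
    top = 0
    stack_i[0] = 0
    stack_j[0] = n - 1
    top = 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j or j - i <= min_loop:
            continue
        # prefer pairing (leftmost partner k of j) over leaving j unpaired
        paired = False
        for k in range(i, j - min_loop):
            w = weights[enc[k], enc[j]]
            if w > 0:
                left = W[i, k - 1] if k > i else 0
                inner = W[k + 1, j - 1] if k + 1 <= j - 1 else 0
                if left + inner + w == W[i, j]:
                    partner[k] = j
                    partner[j] = k
                    stack_i[top] = i
                    stack_j[top] = k - 1
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j - 1
                    top += 1
                    paired = True
                    break
        if not paired:
            stack_i[top] = i
            stack_j[top] = j - 1
            top += 1
    return partner


def _fold_partner(enc: np.ndarray, min_loop: int) -> np.ndarray:
    if enc.shape[0] == 0:
        return np.empty(0, dtype=np.int32)
    W = _nussinov_fill(enc, PAIR_WEIGHTS, min_loop)
    return _nussinov_traceback(W, enc, PAIR_WEIGHTS, min_loop)


def fold_nussinov(seq: str, min_loop: int = 3) -> set[tuple[int, int]]:
    """Fold ``seq`` under the weighted maximum-pairing model.

    Returns the set of base pairs of a maximum-weight nested structure.
    Traceback is deterministic (leftmost pairing partner preferred, pairing
    preferred over leaving a base unpaired at equal score).
    """
    enc = encode_sequence(seq)
    if np.any(enc == 4):
        raise ValueError("fold_nussinov does not accept ambiguous bases (N)")
    partner = _fold_partner(enc, min_loop)
    return {(i, int(j)) for i, j in enumerate(partner) if j > i}


def structure_weight(seq: str, pairs: Iterable[tuple[int, int]]) -> int:
    """Total pair weight of ``pairs`` on ``seq`` (G-C 3, A-U 2, G-U 1)."""
    enc = encode_sequence(seq)
    return int(sum(PAIR_WEIGHTS[enc[i], enc[j]] for i, j in pairs))


def basepair_distance(
    a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]
) -> int:
    """Number of base pairs in the symmetric difference of two structures."""
    return len(set(a) ^ set(b))


class InverseFoldError(RuntimeError):
    """Raised when an inverse-folding search cannot reach the target."""


@dataclass(frozen=True)
class InverseFoldResult:
    """Outcome of an inverse-folding search.

    ``achieved_distance`` is the base-pair distance between the fold of
    ``sequence`` and ``target`` under the backend's folding model; 0 means the
    target was hit exactly. A nonzero distance is reported honestly rather
    than raised.
    """

    sequence: str
    target: str
    achieved_distance: int
    iterations: int
    backend: str


def _partner_distance(a: np.ndarray, b: np.ndarray) -> int:
    na = int(np.count_nonzero(a >= 0)) // 2
    nb = int(np.count_nonzero(b >= 0)) // 2
    common = int(np.count_nonzero((a == b) & (a > np.arange(a.shape[0]))))
    return na + nb - 2 * common

# pair-compensatory move: pairing dinucleotides as index tuples, GC-weighted
# because strong pairs make the maximum-weight optimum unique more often
_PAIR_CHOICES = np.array([[2, 1], [1, 2], [0, 3], [3, 0]], dtype=np.int8)
_PAIR_PROBS = np.array([0.42, 0.42, 0.08, 0.08])


def _random_init(
    rng: np.random.Generator, n: int, tpairs: set[tuple[int, int]]
) -> np.ndarray:
    # unpaired positions biased to A (A pairs with nothing but U, so it rarely
    # creates spurious pairs); target pairs seeded complementary
    s = rng.choice(4, size=n, p=[0.55, 0.15, 0.15, 0.15]).astype(np.int8)
    for i, j in tpairs:
        choice = _PAIR_CHOICES[rng.choice(4, p=_PAIR_PROBS)]
        s[i], s[j] = choice[0], choice[1]
    return s


def _inverse_fold_internal(
    target: str,
    rng: np.random.Generator,
    max_iter: int,
    min_loop: int,
    stall_limit: int = 1200,
) -> InverseFoldResult:
    """Adaptive stochastic local search over sequences.

    Moves are concentrated on defect positions (where the candidate's fold
    disagrees with the target): target-paired defects get a pair-compensatory
    redraw, target-unpaired defects are quieted (usually to A). A move is
    accepted when the base-pair distance to the target does not increase.
    A restart from a fresh random initialisation is triggered after
    ``stall_limit`` iterations without improvement; the total iteration budget
    is shared across restarts and the best candidate seen is returned.
    """
    tpairs = parse_dotbracket(target)
    n = len(target)
    tpartner = _pairs_to_partner(tpairs, n)
    tpair_list = np.array(sorted(tpairs), dtype=np.int32).reshape(-1, 2)

    s = _random_init(rng, n, tpairs)
    fpartner = _fold_partner(s, min_loop)
    d = _partner_distance(fpartner, tpartner)
    best_s, best_d = s.copy(), d
    it = 0
    stall = 0
    while best_d > 0 and it < max_iter:
        it += 1
        stall += 1
        if stall > stall_limit:
            s = _random_init(rng, n, tpairs)
            fpartner = _fold_partner(s, min_loop)
            d = _partner_distance(fpartner, tpartner)
            stall = 0
            if d < best_d:
                best_s, best_d = s.copy(), d
            continue
        s_new = s.copy()
        defects = np.flatnonzero(fpartner != tpartner)
        if defects.size == 0 or rng.random() < 0.2:
            # exploratory move
            if len(tpair_list) > 0 and rng.random() < 0.5:
                i, j = tpair_list[rng.integers(len(tpair_list))]
                choice = _PAIR_CHOICES[rng.choice(4, p=_PAIR_PROBS)]
                s_new[i], s_new[j] = choice[0], choice[1]
            else:
                pos = int(rng.integers(n))
                if tpartner[pos] < 0 and s_new[pos] != 0 and rng.random() < 0.7:
                    s_new[pos] = 0
                else:
                    options = [b for b in range(4) if b != s_new[pos]]
                    s_new[pos] = options[rng.integers(3)]
        else:
            pos = int(defects[rng.integers(defects.size)])
            if tpartner[pos] >= 0:
                i, j = (pos, int(tpartner[pos]))
                if j < i:
                    i, j = j, i
                choice = _PAIR_CHOICES[rng.choice(4, p=_PAIR_PROBS)]
                s_new[i], s_new[j] = choice[0], choice[1]
            elif s_new[pos] != 0:
                s_new[pos] = 0
            else:
                options = [1, 2, 3]
                s_new[pos] = options[rng.integers(3)]
        f_new = _fold_partner(s_new, min_loop)
        d_new = _partner_distance(f_new, tpartner)
        if d_new < d:
            stall = 0
        if d_new <= d:
            s, fpartner, d = s_new, f_new, d_new
            if d < best_d:
                best_s, best_d = s.copy(), d
    return InverseFoldResult(
        sequence=decode_sequence(best_s),
        target=target,
        achieved_distance=int(best_d),
        iterations=it,
        backend="internal",
    )


def _inverse_fold_vienna(
    target: str, rng: np.random.Generator, max_iter: int
) -> InverseFoldResult:
    try:
        import RNA  # ViennaRNA python bindings
    except ImportError as exc:
        raise InverseFoldError(
            "external backend requires the ViennaRNA python bindings (RNAlib)"
        ) from exc
    parse_dotbracket(target)  # validate
    start = "".join(BASES[i] for i in rng.integers(0, 4, size=len(target)))
    seq, _ = RNA.inverse_fold(start, target)
    mfe_structure, _ = RNA.fold(seq)
    dist = basepair_distance(parse_dotbracket(mfe_structure), parse_dotbracket(target))
    return InverseFoldResult(
        sequence=seq,
        target=target,
        achieved_distance=int(dist),
        iterations=1,
        backend="vienna",
    )


def inverse_fold(
    target: str,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 20000,
    backend: str = "internal",
    min_loop: int = 3,
) -> InverseFoldResult:
    """Search for a sequence whose fold equals the dot-bracket ``target``.

    backend "internal" uses the weighted maximum-pairing folder and a seeded
    stochastic local search; backend "vienna" delegates to RNAinverse through
    the ViennaRNA bindings (thermodynamic model). The result reports the
    achieved base-pair distance; callers decide whether nonzero is fatal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if backend == "internal":
        return _inverse_fold_internal(target, rng, max_iter, min_loop)
    if backend == "vienna":
        return _inverse_fold_vienna(target, rng, max_iter)
    raise InverseFoldError(f"unknown inverse-folding backend {backend!r}")


@dataclass(frozen=True)
class PretrainRecord:
    id: str
    sequence: str
    label: int
    #: dot-bracket target of the inverse-folded element (positives only)
    target: str | None = None
    #: start of the inverse-folded element within ``sequence``
    core_start: int = 0


@dataclass
class PretrainingSet:
    """Structure-only pre-training data: inverse-folded positives plus
    length-matched uniform-random negatives, split into a pre-training
    partition and a held-out early-stopping partition."""

    records: list[PretrainRecord]
    pretrain_idx: np.ndarray
    earlystop_idx: np.ndarray

    def _subset(self, idx: np.ndarray) -> tuple[list[str], np.ndarray]:
        seqs = [self.records[i].sequence for i in idx]
        labels = np.array([self.records[i].label for i in idx], dtype=np.float32)
        return seqs, labels

    def pretrain(self) -> tuple[list[str], np.ndarray]:
        return self._subset(self.pretrain_idx)

    def earlystop(self) -> tuple[list[str], np.ndarray]:
        return self._subset(self.earlystop_idx)


def generate_pretraining_set(
    structures: Sequence[str],
    n_positive: int,
    seed: int | None = None,
    backend: str = "internal",
    max_iter: int = 20000,
    split: tuple[float, float] = (0.85, 0.15),
    max_restarts: int = 5,
    pad_to: int | None = None,
) -> PretrainingSet:
    """Build a structure-pretraining dataset from dot-bracket targets.

    ``n_positive`` sequences are inverse-folded, drawing targets round-robin
    from ``structures``; an equal number of uniform-random negatives is drawn
    with the same length multiset. Each class is split 85%/15% into
    pre-training and early-stopping partitions (fractions configurable).

    With ``pad_to`` set, each inverse-folded element is embedded in
    uniform-random context padding up to that length (symmetric, extra
    nucleotide 3') — mirroring how real terminator records are padded with
    genomic context. Pass the *element* structures (e.g. A-tail through
    U-tail) in that case: padding the structural element with unconstrained
    random context keeps the positives' overall composition indistinguishable
    from the negatives', so the classifier can only use structure. Each
    positive records its target and element offset for verification.
    """
    if n_positive < 1:
        raise ValueError("n_positive must be >= 1")
    for s in structures:
        parse_dotbracket(s)
        if pad_to is not None and len(s) > pad_to:
            raise ValueError(f"structure longer than pad_to={pad_to}")
    rng = np.random.default_rng(seed)
    records: list[PretrainRecord] = []
    for k in range(n_positive):
        target = structures[k % len(structures)]
        result = None
        for _ in range(max_restarts):
            result = inverse_fold(target, seed=rng, max_iter=max_iter, backend=backend)
            if result.achieved_distance == 0:
                break
        if result is None or result.achieved_distance > 0:
            raise InverseFoldError(
                f"inverse folding failed for target {k % len(structures)} "
                f"after {max_restarts} restarts (distance {result.achieved_distance})"
            )
        seq = result.sequence
        core_start = 0
        if pad_to is not None:
            pad_total = pad_to - len(seq)
            left = pad_total // 2
            right = pad_total - left
            seq = (
                "".join(BASES[i] for i in rng.integers(0, 4, size=left))
                + seq
                + "".join(BASES[i] for i in rng.integers(0, 4, size=right))
            )
            core_start = left
        records.append(PretrainRecord(f"pos_{k}", seq, 1, target, core_start))
    for k in range(n_positive):
        length = len(records[k].sequence)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        records.append(PretrainRecord(f"neg_{k}", seq, 0))

    # per-class split so both partitions keep the 1:1 balance
    pre_idx: list[int] = []
    stop_idx: list[int] = []
    for offset in (0, n_positive):
        idx = offset + rng.permutation(n_positive)
        n_pre = int(round(split[0] * n_positive))
        pre_idx.extend(idx[:n_pre])
        stop_idx.extend(idx[n_pre:])
    return PretrainingSet(
        records=records,
        pretrain_idx=np.array(pre_idx, dtype=np.int64),
        earlystop_idx=np.array(stop_idx, dtype=np.int64),
    )


def gc_content(
    records: Iterable[PretrainRecord] | Iterable[tuple[str, int]],
) -> dict[int, dict[str, object]]:
    """Per-class G+C fraction summary of a labeled sequence collection.

    Accepts PretrainRecord-like objects (``.sequence``/``.label``) or
    ``(sequence, label)`` tuples. Returns ``{label: {"mean": float,
    "values": ndarray}}``; raises on an empty input or empty class.
    """
    per_label: dict[int, list[float]] = {}
    for rec in records:
        if hasattr(rec, "sequence"):
            seq, label = rec.sequence, rec.label
        else:
            seq, label = rec
        if len(seq) == 0:
            raise ValueError("empty sequence in gc_content input")
        frac = sum(1 for c in seq.upper() if c in "GC") / len(seq)
        per_label.setdefault(int(label), []).append(frac)
    if not per_label:
        raise ValueError("empty dataset in gc_content")
    return {
        label: {"mean": float(np.mean(vals)), "values": np.array(vals)}
        for label, vals in per_label.items()
    }
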