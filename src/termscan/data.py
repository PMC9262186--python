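"""Dataset I/O and assembly: FASTA read/write, genomic-context padding,
origin/strand-balanced negative sampling, and Monte Carlo cross-validation
splits.

All coordinates are 0-based, half-open. Sequences are handled as RNA
(T is transliterated to U on read).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import reverse_complement

__all__ = [
    "LabeledRecord",
    "LabeledDataset",
    "SplitSet",
    "RecordTooLong",
    "read_fasta",
    "write_fasta",
    "pad_with_context",
    "sample_negatives",
    "monte_carlo_split",
]


@dataclass(frozen=True)
class LabeledRecord:
    id: str
    sequence: str
    label: int
    genome_id: str = "."
    strand: str = "+"
    start: int = -1  # genomic interval, 0-based half-open (-1: unknown)
    end: int = -1


@dataclass
class LabeledDataset:
    """Fixed-length labeled sequences (terminators vs background)."""

    records: list[LabeledRecord]
    target_length: int

    def __post_init__(self) -> None:
        for rec in self.records:
            if len(rec.sequence) != self.target_length:
                raise ValueError(
                    f"record {rec.id} has length {len(rec.sequence)}, "
                    f"expected {self.target_length}"
                )
            if rec.label not in (0, 1):
                raise ValueError(f"record {rec.id} has non-binary label")

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.float32)

    def subset(self, idx: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in idx], self.target_length)


class RecordTooLong(ValueError):
    """Record exceeds the padding target length and is to be discarded."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) tuples; T -> U, uppercased."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    return out


def write_fasta(records, path: str | Path) -> None:
    """Write records to FASTA. Accepts (id, seq) tuples or objects with
    ``.id``/``.sequence`` (a ``label`` attribute is encoded into the header
    as ``|label=<x>``)."""
    seq_records = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec
        else:
            rid, seq = rec.id, rec.sequence
            label = getattr(rec, "label", None)
            if label is not None:
                rid = f"{rid}|label={label}"
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def pad_with_context(
    interval: tuple[int, int],
    genome_sequence: str,
    target_length: int,
    strand: str = "+",
) -> tuple[str, tuple[int, int]]:
    """Pad a genomic interval to ``target_length`` with its true flanking
    genome bases, split symmetrically with the extra base on the 3' side.

    Returns (sequence on the requested strand, padded genome interval).
    Raises ``RecordTooLong`` if the interval exceeds the target (such
    records are discarded by callers) and ``ValueError`` if the padding
    would run off the contig.
    """
    start, end = interval
    length = end - start
    if length > target_length:
        raise RecordTooLong(
            f"interval of {length} nt exceeds target {target_length} nt"
        )
    pad_total = target_length - length
    pad5 = pad_total // 2
    pad3 = pad_total - pad5  # extra base 3'
    if strand == "+":
        new_start, new_end = start - pad5, end + pad3
    else:
        new_start, new_end = start - pad3, end + pad5
    if new_start < 0 or new_end > len(genome_sequence):
        raise ValueError("padding runs off the contig end")
    seq = genome_sequence[new_start:new_end]
    if strand == "-":
        seq = reverse_complement(seq)
    return seq, (new_start, new_end)


def _proportional_counts(counts: Mapping, total: int) -> dict:
    """Largest-remainder apportionment of ``total`` following ``counts``."""
    keys = sorted(counts, key=str)
    weights = np.array([counts[k] for k in keys], dtype=float)
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    remainder = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in order[:remainder]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


def sample_negatives(
    genomes: Mapping[str, str],
    positives: Sequence,
    ratio: int = 3,
    length: int = 75,
    seed: int | None = None,
    max_tries: int = 10000,
) -> list[LabeledRecord]:
    """Draw ``ratio`` x len(positives) background windows, matching the
    positives' genome-origin and strand proportions, avoiding any overlap
    with positive intervals.

    ``positives`` carry ``genome_id``, ``strand`` and a genomic interval as
    ``.start``/``.end`` attributes. Negative windows have fixed ``length``
    and may overlap each other but never a positive interval.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], int] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for p in positives:
        key = (p.genome_id, p.strand)
        groups[key] = groups.get(key, 0) + 1
        occupied.setdefault(p.genome_id, []).append((p.start, p.end))
    for gid in occupied:
        if gid not in genomes:
            raise ValueError(f"genome {gid!r} not provided for its positives")
    n_total = ratio * len(positives)
    per_group = _proportional_counts(groups, n_total)

    negatives: list[LabeledRecord] = []
    k = 0
    for (gid, strand), count in per_group.items():
        genome = genomes[gid]
        if len(genome) < length:
            raise ValueError(f"genome {gid!r} shorter than window length")
        blocked = occupied.get(gid, [])
        for _ in range(count):
            for _attempt in range(max_tries):
                start = int(rng.integers(0, len(genome) - length + 1))
                end = start + length
                if all(end <= s or start >= e for s, e in blocked):
                    break
            else:
                raise RuntimeError(
                    f"could not sample a non-overlapping window in {gid!r}"
                )
            seq = genome[start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            negatives.append(
                LabeledRecord(
                    f"neg_{k}", seq, 0, genome_id=gid, strand=strand,
                    start=start, end=end,
                )
            )
            k += 1
    return negatives


@dataclass
class SplitSet:
    """One Monte Carlo cross-validation replicate: disjoint, exhaustive
    train/test/validation index lists."""

    replicate: int
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def manifest(self) -> dict:
        return {
            "replicate": self.replicate,
            "fractions": list(self.fractions),
            "train": self.train.tolist(),
            "test": self.test.tolist(),
            "validation": self.validation.tolist(),
        }


def monte_carlo_split(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    n_replicates: int = 10,
    seed: int | None = None,
    labels: np.ndarray | None = None,
    stratify: bool = False,
) -> list[SplitSet]:
    """Repeated random train/test/validation splitting.

    Each replicate is an independent shuffle of ``range(n)`` cut at the
    cumulative fractions (any rounding remainder goes to the training part).
    With ``stratify`` the shuffle-and-cut happens per class of ``labels``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if stratify and labels is None:
        raise ValueError("stratify requires labels")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    splits = []
    for r, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        if stratify:
            train, test, val = [], [], []
            for cls in np.unique(labels):
                idx = np.flatnonzero(labels == cls)
                t, te, v = _cut(rng.permutation(idx), fractions)
                train.append(t)
                test.append(te)
                val.append(v)
            parts = tuple(np.concatenate(p) for p in (train, test, val))
        else:
            parts = _cut(rng.permutation(n), fractions)
        splits.append(SplitSet(r, *parts, fractions=fractions))
    return splits


def _cut(
    perm: np.ndarray, fractions: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = perm.size
    n_test = int(round(fractions[1] * n))
    n_val = int(round(fractions[2] * n))
    n_train = n - n_test - n_val
    return (
        perm[:n_train],
        perm[n_train : n_train + n_test],
        perm[n_train + n_test :],
    )
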