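"""In-silico mutagenesis: quantifying how much a trained model relies on
each terminator section and on stem base pairing.

Two experiment families:

*Section mutations* — for each of the 7 sections (left pad, A-tail, 5' stem,
loop, 3' stem, U-tail, right pad), half of the section's nucleotides are
randomly mutated; the relative activation impact of the section is
``1 - (mean mutated output / mean original output)``.

*Structure mutations* — k stem base pairs are picked at random and both
partners are rewritten, either *retaining* the pairing (a different pairing
dinucleotide) or *disrupting* it (a non-pairing dinucleotide, both positions
changed); the relative activation impact of pairing is
``1 - (mean disrupted output / mean retained output)`` per k.

For binary detectors (hit counts instead of activations) the same formulas
are applied to detection rates (fraction of sequences with at least one
hit), giving a relative detection impact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .structure import PAIRING_DINUCLEOTIDES
from .synthetic import SECTION_ORDER, AnnotatedTerminator

__all__ = [
    "MutationSpec",
    "SectionImpactResult",
    "StructureImpactResult",
    "mutate_section",
    "mutate_stem_pairs",
    "section_impact",
    "structure_impact",
    "detection_impact",
    "impacts_to_frame",
]

_BASES = "ACGU"
_PAIR_SET = set(PAIRING_DINUCLEOTIDES)
_ALL_DINUC = [a + b for a in _BASES for b in _BASES]
_NONPAIR_SET = [d for d in _ALL_DINUC if d not in _PAIR_SET]


@dataclass(frozen=True)
class MutationSpec:
    """Parameters of a mutagenesis experiment."""

    mode: str = "section"  # "section" | "structure"
    section: str | None = None
    k: int = 1
    pairing_fate: str = "disrupt"  # "retain" | "disrupt"
    n_repeats: int = 15
    seed: int | None = None

    def validate(self) -> None:
        if self.mode not in ("section", "structure"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "section" and self.section not in SECTION_ORDER:
            raise ValueError(f"unknown section {self.section!r}")
        if self.mode == "structure":
            if self.k < 1:
                raise ValueError("k must be >= 1")
            if self.pairing_fate not in ("retain", "disrupt"):
                raise ValueError(f"unknown pairing fate {self.pairing_fate!r}")


def mutate_section(
    record: AnnotatedTerminator,
    section: str,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Mutate half of the nucleotides of one section (floor, at least 1).

    Positions are drawn uniformly without replacement within the section;
    each is replaced by a uniformly chosen *different* nucleotide. All
    positions outside the section are untouched.
    """
    if section not in SECTION_ORDER:
        raise ValueError(f"unknown section {section!r}")
    start, end = record.sections[section]
    length = end - start
    if length == 0:
        raise ValueError(f"section {section!r} is empty in {record.id}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_mut = max(1, length // 2)
    positions = start + rng.choice(length, size=n_mut, replace=False)
    seq = list(record.sequence)
    for pos in positions:
        options = [b for b in _BASES if b != seq[pos]]
        seq[pos] = options[rng.integers(3)]
    return "".join(seq)


def mutate_stem_pairs(
    record: AnnotatedTerminator,
    k: int,
    pairing_fate: str,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Rewrite ``k`` randomly chosen stem pairs, retaining or disrupting
    the base pairing; both partner positions always change.

    retain: new dinucleotide uniform over the canonical+wobble pairing set
    excluding any option that keeps either original base. disrupt: uniform
    over the 10 non-pairing dinucleotides under the same both-changed
    constraint.
    """
    if pairing_fate not in ("retain", "disrupt"):
        raise ValueError(f"unknown pairing fate {pairing_fate!r}")
    pairs = record.stem_pairs()
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds stem size {len(pairs)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=k, replace=False)
    pool = PAIRING_DINUCLEOTIDES if pairing_fate == "retain" else _NONPAIR_SET
    seq = list(record.sequence)
    for idx in chosen:
        i, j = pairs[idx]
        feasible = [d for d in pool if d[0] != seq[i] and d[1] != seq[j]]
        # both-changed options exist for every original dinucleotide
        # (>= 4 pairing and >= 5 non-pairing choices by enumeration)
        choice = feasible[rng.integers(len(feasible))]
        seq[i], seq[j] = choice[0], choice[1]
    return "".join(seq)


Scorer = Callable[[list[str]], np.ndarray]


def _as_scorer(model) -> Scorer:
    if hasattr(model, "predict_scores"):
        return model.predict_scores
    if callable(model):
        return lambda seqs: np.asarray(model(seqs), dtype=float)
    raise TypeError("model must be a TermModel or a callable scorer")


@dataclass
class SectionImpactResult:
    """Per-section relative activation impact: 1 - (x̄_S / x̄_0)."""

    x0: float
    section_means: dict[str, float]
    impacts: dict[str, float]
    n: int
    n_repeats: int


@dataclass
class StructureImpactResult:
    """Per-k relative activation impact of pairing: 1 - (x̄_d / x̄_r)."""

    retain_means: dict[int, float]
    disrupt_means: dict[int, float]
    impacts: dict[int, float]
    n: dict[int, int] = field(default_factory=dict)
    n_repeats: int = 15


def section_impact(
    model,
    records: Sequence[AnnotatedTerminator],
    n_repeats: int = 15,
    seed: int | None = None,
    sections: Iterable[str] = SECTION_ORDER,
) -> SectionImpactResult:
    """Relative activation impact of every section.

    For each section, every record contributes ``n_repeats`` independent
    mutants; x̄_S is the mean model output over all mutants and x̄_0 the mean
    over the original records (scored once each).
    """
    if not records:
        raise ValueError("no records given")
    scorer = _as_scorer(model)
    rng = np.random.default_rng(seed)
    x0 = float(np.mean(scorer([r.sequence for r in records])))
    if x0 <= 0:
        raise ZeroDivisionError("mean original output is zero; impact undefined")
    means: dict[str, float] = {}
    impacts: dict[str, float] = {}
    for section in sections:
        mutants = [
            mutate_section(rec, section, rng)
            for rec in records
            for _ in range(n_repeats)
        ]
        xs = float(np.mean(scorer(mutants)))
        means[section] = xs
        impacts[section] = 1.0 - xs / x0
    return SectionImpactResult(x0, means, impacts, len(records), n_repeats)


def structure_impact(
    model,
    records: Sequence[AnnotatedTerminator],
    k_range: Iterable[int] = range(1, 11),
    n_repeats: int = 15,
    seed: int | None = None,
) -> StructureImpactResult:
    """Relative activation impact of stem pairing for a growing number of
    mutated pairs ``k``; at each k only records with a stem of at least k
    pairs participate (their count is recorded)."""
    if not records:
        raise ValueError("no records given")
    scorer = _as_scorer(model)
    rng = np.random.default_rng(seed)
    result = StructureImpactResult({}, {}, {}, {}, n_repeats)
    for k in k_range:
        usable = [r for r in records if len(r.stem_pairs()) >= k]
        if not usable:
            raise ValueError(f"no record has a stem of >= {k} pairs")
        retained = [
            mutate_stem_pairs(rec, k, "retain", rng)
            for rec in usable
            for _ in range(n_repeats)
        ]
        disrupted = [
            mutate_stem_pairs(rec, k, "disrupt", rng)
            for rec in usable
            for _ in range(n_repeats)
        ]
        xr = float(np.mean(scorer(retained)))
        xd = float(np.mean(scorer(disrupted)))
        if xr <= 0:
            raise ZeroDivisionError(
                f"mean retained output is zero at k={k}; impact undefined"
            )
        result.retain_means[k] = xr
        result.disrupt_means[k] = xd
        result.impacts[k] = 1.0 - xd / xr
        result.n[k] = len(usable)
    return result


def detection_impact(
    detector: Callable[[list[str]], Sequence[int]],
    records: Sequence[AnnotatedTerminator],
    spec: MutationSpec,
) -> dict:
    """Relative detection impact for a binary detector (e.g. an external
    terminator finder returning per-sequence hit counts).

    The detection rate — fraction of sequences with at least one hit —
    stands in for the mean activation in the impact formulas.
    """
    spec.validate()
    if not records:
        raise ValueError("no records given")
    rng = np.random.default_rng(spec.seed)

    def rate(seqs: list[str]) -> float:
        hits = detector(seqs)
        if len(hits) != len(seqs):
            raise RuntimeError("detector returned wrong number of hit counts")
        return float(np.mean([h >= 1 for h in hits]))

    if spec.mode == "section":
        r0 = rate([r.sequence for r in records])
        if r0 <= 0:
            raise ZeroDivisionError("baseline detection rate is zero")
        mutants = [
            mutate_section(rec, spec.section, rng)
            for rec in records
            for _ in range(spec.n_repeats)
        ]
        rs = rate(mutants)
        return {
            "mode": "section",
            "section": spec.section,
            "rate_original": r0,
            "rate_mutated": rs,
            "impact": 1.0 - rs / r0,
            "n": len(records),
        }
    usable = [r for r in records if len(r.stem_pairs()) >= spec.k]
    if not usable:
        raise ValueError(f"no record has a stem of >= {spec.k} pairs")
    retained = [
        mutate_stem_pairs(rec, spec.k, "retain", rng)
        for rec in usable
        for _ in range(spec.n_repeats)
    ]
    disrupted = [
        mutate_stem_pairs(rec, spec.k, "disrupt", rng)
        for rec in usable
        for _ in range(spec.n_repeats)
    ]
    rr = rate(retained)
    rd = rate(disrupted)
    if rr <= 0:
        raise ZeroDivisionError("retained detection rate is zero")
    return {
        "mode": "structure",
        "k": spec.k,
        "rate_retain": rr,
        "rate_disrupt": rd,
        "impact": 1.0 - rd / rr,
        "n": len(usable),
    }


def impacts_to_frame(
    result: SectionImpactResult | StructureImpactResult,
    model_name: str = "model",
    replicate: int = 1,
) -> pd.DataFrame:
    """Tidy rows (model, replicate, section-or-k, mode, means, impact)."""
    rows = []
    if isinstance(result, SectionImpactResult):
        for section, xs in result.section_means.items():
            rows.append(
                {
                    "model": model_name,
                    "replicate": replicate,
                    "mode": "section",
                    "unit": section,
                    "x_original": result.x0,
                    "x_mutated": xs,
                    "impact": result.impacts[section],
                    "n": result.n,
                }
            )
    else:
        for k, xr in result.retain_means.items():
            rows.append(
                {
                    "model": model_name,
                    "replicate": replicate,
                    "mode": "structure",
                    "unit": k,
                    "x_retain": xr,
                    "x_disrupt": result.disrupt_means[k],
                    "impact": result.impacts[k],
                    "n": result.n[k],
                }
            )
    return pd.DataFrame(rows)
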