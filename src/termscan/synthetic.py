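"""Synthetic fixtures with known ground truth: annotated hairpin terminators,
cloverleaf tRNA-like records, genomes with implanted elements, transcript
tables and termination-site lists.

The generator emulates the anatomy of intrinsic (rho-independent)
transcription terminators: an A-rich tract (A-tail) 5' of a GC-rich
stem-loop hairpin, followed by a U-rich tract (U-tail), embedded in flanking
genomic context (left/right pads). Section coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import (
    BASES,
    fold_nussinov,
    inverse_fold,
    InverseFoldError,
    parse_dotbracket,
)

__all__ = [
    "SECTION_ORDER",
    "GeneratorParams",
    "AnnotatedTerminator",
    "StructuredRecord",
    "SyntheticGenome",
    "ImplantedElement",
    "Transcript",
    "CLOVERLEAF",
    "make_terminator",
    "make_trna_like",
    "make_genome",
    "make_transcripts",
    "write_bed",
    "write_sites",
    "write_manifest",
]

#: the seven sections of an annotated terminator record, 5' to 3'
SECTION_ORDER = (
    "left_pad",
    "a_tail",
    "stem5",
    "loop",
    "stem3",
    "u_tail",
    "right_pad",
)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N", "T": "A"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class GeneratorParams:
    """Sampling ranges for terminator anatomy. Ranges are inclusive, in nt
    (stem length in bp). Defaults describe a plausible GC-rich terminator;
    they are deliberately generic, not fitted to any one species."""

    a_tail_len: tuple[int, int] = (6, 10)
    stem_len: tuple[int, int] = (7, 12)
    stem_gc: float = 0.8
    loop_len: tuple[int, int] = (3, 7)
    u_tail_len: tuple[int, int] = (6, 10)
    a_fraction: float = 0.8
    u_fraction: float = 0.8
    target_length: int = 75
    seed: int | None = None

    def validate(self) -> None:
        for name in ("a_tail_len", "stem_len", "loop_len", "u_tail_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        for name in ("stem_gc", "a_fraction", "u_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        max_core = (
            self.a_tail_len[1]
            + 2 * self.stem_len[1]
            + self.loop_len[1]
            + self.u_tail_len[1]
        )
        min_core = (
            self.a_tail_len[0]
            + 2 * self.stem_len[0]
            + self.loop_len[0]
            + self.u_tail_len[0]
        )
        if min_core > self.target_length:
            raise ValueError(
                f"minimum component lengths ({min_core} nt) exceed "
                f"target_length ({self.target_length} nt)"
            )
        if max_core > self.target_length:
            raise ValueError(
                f"maximum component lengths ({max_core} nt) exceed "
                f"target_length ({self.target_length} nt); shrink ranges"
            )


@dataclass(frozen=True)
class AnnotatedTerminator:
    """A terminator-like sequence with per-section coordinates and its
    annotated dot-bracket structure (stem paired, everything else unpaired)."""

    id: str
    sequence: str
    sections: dict[str, tuple[int, int]]
    structure: str

    def __len__(self) -> int:
        return len(self.sequence)

    def section_seq(self, name: str) -> str:
        start, end = self.sections[name]
        return self.sequence[start:end]

    def stem_pairs(self) -> list[tuple[int, int]]:
        """Annotated stem pairs, outermost first: stem5 position i pairs with
        the mirror position of stem3."""
        s5_start, s5_end = self.sections["stem5"]
        s3_start, s3_end = self.sections["stem3"]
        return [
            (s5_start + k, s3_end - 1 - k) for k in range(s5_end - s5_start)
        ]

    def core_interval(self) -> tuple[int, int]:
        """[start, end) of the biological element: A-tail through U-tail."""
        return self.sections["a_tail"][0], self.sections["u_tail"][1]

    def core_structure(self) -> str:
        """Dot-bracket of the biological element (pads stripped) — the
        natural inverse-folding target for pre-training data."""
        start, end = self.core_interval()
        return self.structure[start:end]

    def validate(self) -> None:
        pos = 0
        for name in SECTION_ORDER:
            start, end = self.sections[name]
            if start != pos or end < start:
                raise ValueError(f"sections not contiguous at {name}")
            pos = end
        if pos != len(self.sequence) or len(self.structure) != len(self.sequence):
            raise ValueError("sections/structure do not cover the sequence")
        pairs = parse_dotbracket(self.structure)
        if pairs != set(self.stem_pairs()):
            raise ValueError("structure pairs do not match the annotated stem")


@dataclass(frozen=True)
class StructuredRecord:
    """A sequence with a known dot-bracket structure (e.g. tRNA-like)."""

    id: str
    sequence: str
    structure: str

    def __len__(self) -> int:
        return len(self.sequence)


def _sample_biased(
    rng: np.random.Generator, n: int, main_base: str, fraction: float
) -> str:
    others = [b for b in BASES if b != main_base]
    out = []
    for _ in range(n):
        if rng.random() < fraction:
            out.append(main_base)
        else:
            out.append(others[rng.integers(3)])
    return "".join(out)


def _sample_uniform(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def make_terminator(
    params: GeneratorParams | None = None,
    seed: int | np.random.Generator | None = None,
    record_id: str = "term_0",
    max_tries: int = 100,
) -> AnnotatedTerminator:
    """Sample one annotated terminator of ``params.target_length`` nt.

    The stem halves are complementary (Watson-Crick; GC with probability
    ``stem_gc``); pads fill the record symmetrically with the extra
    nucleotide on the 3' side. Draws are rejection-sampled until the folded
    maximum-pairing optimum of the record contains every annotated stem pair,
    so the annotation is guaranteed self-consistent: occasionally a random
    pad is accidentally complementary to the stem and would displace a stem
    pair in the fold; such draws are discarded.
    """
    params = params or GeneratorParams()
    params.validate()
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    for _ in range(max_tries):
        record = _draw_terminator(params, rng, record_id)
        if set(record.stem_pairs()) <= fold_nussinov(record.sequence):
            return record
    raise RuntimeError(
        f"no self-consistent terminator draw in {max_tries} tries; "
        "parameters may make the hairpin too weak (low stem_gc/short stem)"
    )


def _draw_terminator(
    params: GeneratorParams, rng: np.random.Generator, record_id: str
) -> AnnotatedTerminator:

    a_len = int(rng.integers(params.a_tail_len[0], params.a_tail_len[1] + 1))
    stem_len = int(rng.integers(params.stem_len[0], params.stem_len[1] + 1))
    loop_len = int(rng.integers(params.loop_len[0], params.loop_len[1] + 1))
    u_len = int(rng.integers(params.u_tail_len[0], params.u_tail_len[1] + 1))

    a_tail = _sample_biased(rng, a_len, "A", params.a_fraction)
    stem5 = "".join(
        ("G" if rng.random() < 0.5 else "C")
        if rng.random() < params.stem_gc
        else ("A" if rng.random() < 0.5 else "U")
        for _ in range(stem_len)
    )
    stem3 = reverse_complement(stem5)
    loop = _sample_uniform(rng, loop_len)
    u_tail = _sample_biased(rng, u_len, "U", params.u_fraction)

    core_len = a_len + 2 * stem_len + loop_len + u_len
    pad_total = params.target_length - core_len
    left_len = pad_total // 2
    right_len = pad_total - left_len  # extra nucleotide 3'
    left_pad = _sample_uniform(rng, left_len)
    right_pad = _sample_uniform(rng, right_len)

    parts = [left_pad, a_tail, stem5, loop, stem3, u_tail, right_pad]
    sections: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, part in zip(SECTION_ORDER, parts):
        sections[name] = (pos, pos + len(part))
        pos += len(part)
    sequence = "".join(parts)
    structure = (
        "." * (left_len + a_len)
        + "(" * stem_len
        + "." * loop_len
        + ")" * stem_len
        + "." * u_len
        + "." * right_len
    )
    record = AnnotatedTerminator(record_id, sequence, sections, structure)
    record.validate()
    return record


#: a compact cloverleaf template (76 nt): acceptor stem (7 bp), D-arm (4 bp),
#: anticodon arm (5 bp), T-arm (5 bp), in standard tRNA arrangement
CLOVERLEAF = (
    "((((((("
    + ".."
    + "((((.....))))"
    + "."
    + "(((((.......)))))"
    + ".."
    + "(((((.......)))))"
    + ")))))))"
    + "...."
)


def make_trna_like(
    template_structure: str = CLOVERLEAF,
    params: GeneratorParams | None = None,
    seed: int | np.random.Generator | None = None,
    target_length: int = 95,
    max_iter: int = 40000,
    max_restarts: int = 5,
) -> StructuredRecord:
    """Inverse-fold a cloverleaf-like dot-bracket template and pad it to
    ``target_length`` nt (symmetric padding, extra nucleotide 3').

    The returned sequence folds (internal folder) to base-pair distance 0
    from the padded template; raises ``InverseFoldError`` if the search
    exhausts its iteration budget on every restart.
    """
    parse_dotbracket(template_structure)
    if len(template_structure) > target_length:
        raise ValueError(
            f"template ({len(template_structure)} nt) longer than "
            f"target_length ({target_length} nt)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else (params.seed if params else None)
    )
    pad_total = target_length - len(template_structure)
    left = pad_total // 2
    right = pad_total - left
    padded = "." * left + template_structure + "." * right
    last = None
    for _ in range(max_restarts):
        last = inverse_fold(padded, seed=rng, max_iter=max_iter)
        if last.achieved_distance == 0:
            break
    if last is None or last.achieved_distance > 0:
        raise InverseFoldError(
            f"cloverleaf inverse folding did not reach distance 0 "
            f"(best {last.achieved_distance})"
        )
    return StructuredRecord("trna_0", last.sequence, padded)


@dataclass(frozen=True)
class ImplantedElement:
    id: str
    strand: str
    start: int
    end: int
    site: int  # termination site: 3' end of the element on its strand


@dataclass(frozen=True)
class Transcript:
    id: str
    start: int
    end: int
    strand: str


@dataclass
class SyntheticGenome:
    id: str
    sequence: str
    implanted: list[ImplantedElement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def make_genome(
    n_elements: int,
    genome_length: int,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    minus_strand: bool = False,
    min_gap: int = 75,
    max_tries: int = 10000,
    genome_id: str = "synth_chr",
) -> SyntheticGenome:
    """Uniform-random genome with ``n_elements`` implanted terminator cores.

    The implanted interval covers A-tail through U-tail (the pads of the
    generated record are discarded; the random genome supplies context).
    Elements are placed non-overlapping with at least ``min_gap`` nt between
    them so that no scan window spans two elements. With ``minus_strand``,
    each element lands on + or - with equal probability (reverse-complemented
    in the genome).
    """
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(seed)
    genome = list(_sample_uniform(rng, genome_length))
    if n_elements * (params.target_length + min_gap) > genome_length:
        raise ValueError("genome too short for the requested element count")

    placed: list[tuple[int, int]] = []
    elements: list[ImplantedElement] = []
    for k in range(n_elements):
        record = make_terminator(params, seed=rng, record_id=f"elem_{k}")
        c_start, c_end = record.core_interval()
        core = record.sequence[c_start:c_end]
        for attempt in range(max_tries):
            start = int(rng.integers(0, genome_length - len(core)))
            end = start + len(core)
            if all(
                end + min_gap <= s or start >= e + min_gap for s, e in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place element {k} without overlap after "
                f"{max_tries} tries"
            )
        strand = "+"
        if minus_strand and rng.random() < 0.5:
            strand = "-"
        insert = core if strand == "+" else reverse_complement(core)
        genome[start:end] = list(insert)
        placed.append((start, end))
        site = end - 1 if strand == "+" else start
        elements.append(ImplantedElement(record.id, strand, start, end, site))
    elements.sort(key=lambda e: e.start)
    return SyntheticGenome(genome_id, "".join(genome), elements)


def make_transcripts(
    genome: SyntheticGenome,
    seed: int | None = None,
    flank_range: tuple[int, int] = (100, 400),
) -> tuple[list[Transcript], list[int]]:
    """Wrap each implanted element in a transcript interval.

    Transcripts are truncated at midpoints between neighbouring elements so
    that every element lies inside exactly one transcript. Returns the
    transcript table and the ground-truth termination-site list (genome
    coordinates, one site per element).
    """
    if not genome.implanted:
        raise ValueError("genome has no implanted elements")
    rng = np.random.default_rng(seed)
    elements = sorted(genome.implanted, key=lambda e: e.start)
    transcripts: list[Transcript] = []
    sites: list[int] = []
    for k, elem in enumerate(elements):
        left_flank = int(rng.integers(flank_range[0], flank_range[1] + 1))
        right_flank = int(rng.integers(flank_range[0], flank_range[1] + 1))
        lo = 0 if k == 0 else (elements[k - 1].end + elem.start) // 2
        hi = len(genome) if k == len(elements) - 1 else (
            (elem.end + elements[k + 1].start) // 2
        )
        start = max(lo, elem.start - left_flank)
        end = min(hi, elem.end + right_flank)
        transcripts.append(Transcript(f"tx_{elem.id}", start, end, elem.strand))
        sites.append(elem.site)
    return transcripts, sites


# ---------------------------------------------------------------------------
# table writers (0-based, half-open coordinates)

def write_bed(intervals, path: str | Path, chrom: str = "synth_chr") -> None:
    """Write 6-column BED-like TSV (chrom, start, end, name, score, strand);
    coordinates 0-based, half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "id", ".")
            score = getattr(iv, "score", 0)
            fh.write(
                f"{chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def write_sites(sites, path: str | Path, chrom: str = "synth_chr") -> None:
    """Termination sites as single-nucleotide BED-like rows (0-based)."""
    with open(path, "w") as fh:
        for k, pos in enumerate(sites):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsite_{k}\t0\t+\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
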