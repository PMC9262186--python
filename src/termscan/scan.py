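"""Transcriptome-wide sliding-window terminator scan and distance-threshold
precision-recall evaluation against termination-site lists.

Transcribed regions are extended by 150 nt on each end (so terminators at
transcript boundaries fall fully inside a window), scanned with a 75-nt
window at a 3-nt step, and neighbouring above-threshold windows are fused
into hits carrying their center position and maximum model output. A hit
counts as a true positive when its center lies within a distance threshold
of the nearest termination site; sites with no hit within the threshold are
false negatives. The PR curve sweeps a secondary cutoff over fused-hit
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import SyntheticGenome, Transcript, reverse_complement

__all__ = [
    "Region",
    "WindowScores",
    "ScanHit",
    "ScanEvaluation",
    "DISTANCE_THRESHOLDS",
    "prepare_regions",
    "scan",
    "call_hits",
    "scan_regions",
    "evaluate_scan",
    "positional_profile",
    "hits_to_bed",
    "evaluation_to_frame",
]

#: distance thresholds (nt) at which predicted terminators are matched to sites
DISTANCE_THRESHOLDS = (10, 15, 35, 50, 100, 150, 250)


@dataclass(frozen=True)
class Region:
    """An elongated transcribed region with its sense-strand sequence."""

    id: str
    start: int
    end: int
    strand: str
    sequence: str


@dataclass
class WindowScores:
    region_id: str
    starts: np.ndarray  # window starts in region coordinates
    scores: np.ndarray
    window: int
    step: int


@dataclass(frozen=True)
class ScanHit:
    """A fused run of above-threshold windows (region coordinates)."""

    region_id: str
    start: int
    end: int
    center: int
    score: float
    genome_center: int = -1  # center mapped to genome coordinates


def _genome_lookup(genome) -> Mapping[str, str]:
    if isinstance(genome, SyntheticGenome):
        return {genome.id: genome.sequence}
    return genome


def prepare_regions(
    transcripts: Sequence[Transcript],
    genome,
    elongation: int = 150,
    chrom: str | None = None,
) -> list[Region]:
    """Extend each transcript by ``elongation`` nt on both ends (clamped at
    contig boundaries) and extract the sense-strand sequence.

    ``genome`` is a SyntheticGenome or a mapping of contig id to sequence;
    single-contig genomes need no per-transcript contig column.
    """
    contigs = _genome_lookup(genome)
    regions = []
    for tx in transcripts:
        key = chrom or getattr(tx, "chrom", None) or next(iter(contigs))
        if key not in contigs:
            raise KeyError(f"contig {key!r} not found in genome")
        contig = contigs[key]
        start = max(0, tx.start - elongation)
        end = min(len(contig), tx.end + elongation)
        seq = contig[start:end]
        if tx.strand == "-":
            seq = reverse_complement(seq)
        regions.append(Region(tx.id, start, end, tx.strand, seq))
    return regions


def scan(
    model,
    region: Region | str,
    window: int = 75,
    step: int = 3,
    batch_size: int = 512,
) -> WindowScores:
    """Score every sliding window of a region; starts at 0, step nt apart."""
    seq = region.sequence if isinstance(region, Region) else region
    region_id = region.id if isinstance(region, Region) else "."
    L = len(seq)
    if L < window:
        return WindowScores(
            region_id, np.empty(0, dtype=int), np.empty(0), window, step
        )
    starts = np.arange(0, L - window + 1, step)
    scorer = model.predict_scores if hasattr(model, "predict_scores") else model
    scores = []
    for lo in range(0, len(starts), batch_size):
        chunk = starts[lo : lo + batch_size]
        scores.append(
            np.asarray(scorer([seq[s : s + window] for s in chunk]), dtype=float)
        )
    return WindowScores(region_id, starts, np.concatenate(scores), window, step)


def call_hits(ws: WindowScores, threshold: float = 0.5) -> list[ScanHit]:
    """Fuse maximal runs of adjacent above-threshold windows into hits.

    Adjacent means consecutive step positions; a single sub-threshold window
    breaks a run. The hit spans the union of its windows, scores the run
    maximum, and centers at floor((start + end - 1) / 2).
    """
    hits: list[ScanHit] = []
    above = ws.scores > threshold
    i = 0
    n = len(ws.starts)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and ws.starts[j + 1] - ws.starts[j] == ws.step:
            j += 1
        start = int(ws.starts[i])
        end = int(ws.starts[j]) + ws.window
        hits.append(
            ScanHit(
                region_id=ws.region_id,
                start=start,
                end=end,
                center=(start + end - 1) // 2,
                score=float(ws.scores[i : j + 1].max()),
            )
        )
        i = j + 1
    return hits


def scan_regions(
    model,
    regions: Sequence[Region],
    window: int = 75,
    step: int = 3,
    threshold: float = 0.5,
    batch_size: int = 512,
) -> list[ScanHit]:
    """Scan every region and map hit centers to genome coordinates
    (strand-aware: region coordinates run 5'->3' on the sense strand)."""
    all_hits = []
    for region in regions:
        for hit in call_hits(scan(model, region, window, step, batch_size), threshold):
            if region.strand == "+":
                genome_center = region.start + hit.center
            else:
                genome_center = region.end - 1 - hit.center
            all_hits.append(
                ScanHit(
                    hit.region_id,
                    hit.start,
                    hit.end,
                    hit.center,
                    hit.score,
                    genome_center,
                )
            )
    return all_hits


@dataclass
class ScanEvaluation:
    distance_threshold: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    pr_curve: tuple[np.ndarray, np.ndarray]  # (recall, precision) points
    auprc: float


def _match_counts(
    centers: np.ndarray, sites: np.ndarray, threshold: int
) -> tuple[int, int, int]:
    if centers.size == 0:
        return 0, 0, len(sites)
    dist = np.abs(centers[:, None] - sites[None, :])
    hit_is_tp = (dist <= threshold).any(axis=1)
    detected = (dist <= threshold).any(axis=0)
    tp = int(hit_is_tp.sum())
    fp = int(centers.size - tp)
    fn = int(len(sites) - detected.sum())
    return tp, fp, fn


def evaluate_scan(
    hits: Sequence[ScanHit],
    sites: Sequence[int],
    distance_thresholds: Iterable[int] = DISTANCE_THRESHOLDS,
) -> dict[int, ScanEvaluation]:
    """Distance-threshold precision/recall of scan hits against termination
    sites (genome coordinates).

    A hit is a true positive iff its center lies within the threshold of the
    nearest site, otherwise a false positive; a site with no hit within the
    threshold is a false negative. Matching is not one-to-one: several hits
    may credit one site, and recall counts distinct detected sites. The PR
    curve sweeps cutoffs over the fused-hit scores (descending); AUPRC is
    the step-wise average precision over that sweep.
    """
    sites_arr = np.asarray(sorted(sites), dtype=int)
    if sites_arr.size == 0:
        raise ValueError("empty termination-site list")
    centers = np.array([h.genome_center for h in hits], dtype=int)
    scores = np.array([h.score for h in hits], dtype=float)
    out: dict[int, ScanEvaluation] = {}
    for threshold in distance_thresholds:
        tp, fp, fn = _match_counts(centers, sites_arr, threshold)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = (len(sites_arr) - fn) / len(sites_arr)
        rec_pts, prec_pts = [], []
        auprc = 0.0
        prev_recall = 0.0
        for cutoff in np.sort(np.unique(scores))[::-1]:
            keep = centers[scores >= cutoff]
            tpc, fpc, fnc = _match_counts(keep, sites_arr, threshold)
            p = tpc / (tpc + fpc) if tpc + fpc else 0.0
            r = (len(sites_arr) - fnc) / len(sites_arr)
            rec_pts.append(r)
            prec_pts.append(p)
            auprc += (r - prev_recall) * p
            prev_recall = r
        out[threshold] = ScanEvaluation(
            threshold,
            tp,
            fp,
            fn,
            precision,
            recall,
            (np.array(rec_pts), np.array(prec_pts)),
            auprc,
        )
    return out


def positional_profile(
    model,
    regions: Sequence[Region],
    sites: Sequence[int],
    flank: int = 150,
    window: int = 75,
    step: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean model output by window-center offset from the termination site.

    Offsets are strand-aware (negative = upstream of the site). Returns
    (offsets in [-flank, flank], mean scores; NaN where no window center
    fell on an offset).
    """
    sites_arr = np.asarray(sorted(sites), dtype=int)
    offsets = np.arange(-flank, flank + 1)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size)
    for region in regions:
        ws = scan(model, region, window, step)
        if ws.starts.size == 0:
            continue
        centers_region = ws.starts + (window - 1) // 2
        if region.strand == "+":
            genome_centers = region.start + centers_region
        else:
            genome_centers = region.end - 1 - centers_region
        for gc, score in zip(genome_centers, ws.scores):
            nearest = sites_arr[np.argmin(np.abs(sites_arr - gc))]
            off = gc - nearest
            if region.strand == "-":
                off = -off
            if -flank <= off <= flank:
                sums[off + flank] += score
                counts[off + flank] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return offsets, means


def hits_to_bed(
    hits: Sequence[ScanHit], path, chrom: str = "synth_chr"
) -> None:
    """Write hits as 6-column BED-like rows, one nucleotide around the
    genome-mapped hit center (0-based half-open); the region id and the
    region-local span go into the name column."""
    with open(path, "w") as fh:
        for k, h in enumerate(hits):
            center = h.genome_center if h.genome_center >= 0 else h.center
            name = f"hit_{k}|{h.region_id}:{h.start}-{h.end}"
            fh.write(
                f"{chrom}\t{center}\t{center + 1}\t{name}\t{h.score:.4f}\t+\n"
            )


def evaluation_to_frame(evaluations: dict[int, ScanEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "distance_threshold": t,
                "tp": e.tp,
                "fp": e.fp,
                "fn": e.fn,
                "precision": e.precision,
                "recall": e.recall,
                "auprc": e.auprc,
            }
            for t, e in sorted(evaluations.items())
        ]
    )
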