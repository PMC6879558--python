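"""QTL interval calling on the smoothed -log10 P track.

A QTL is seeded at a local maximum of the smoothed -log10 P track whose
P-value passes the FDR-derived critical threshold, and extended outward
marker by marker while the score stays *strictly above* ``peak - 1.0``
(the 1-log-drop support interval: the first marker at or below the drop
line lies outside the QTL).  Two adjacent significant peaks are separate
QTLs when the valley between them drops at least 1.0 below the lower
peak; otherwise they are one QTL whose peak is the higher maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "QTLInterval", "call_qtls", "call_qtls_genome", "split_adjacent_peaks",
    "overlap_qtls", "summarize_qtls", "read_gene_annotation", "qtls_to_bed",
]


@dataclass
class QTLInterval:
    """One called QTL: 1-based inclusive bounds at member-marker positions."""

    trait: str
    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_score: float
    member_idx: np.ndarray = field(repr=False)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "QTLInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


def _local_maxima(score: np.ndarray) -> list[int]:
    """Indices of local maxima; a flat run flanked by lower values is one
    peak at its central marker (ties to the left)."""
    n = score.size
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and score[j + 1] == score[i]:
            j += 1
        left_lower = i == 0 or score[i - 1] < score[i]
        right_lower = j == n - 1 or score[j + 1] < score[i]
        if left_lower and right_lower:
            peaks.append((i + j) // 2)
        i = j + 1
    return peaks


def _log_drop_interval(score: np.ndarray, peak: int) -> tuple[int, int]:
    """Inclusive index bounds of markers strictly above score[peak] - 1."""
    drop = score[peak] - 1.0
    lo = peak
    while lo > 0 and score[lo - 1] > drop:
        lo -= 1
    hi = peak
    while hi + 1 < score.size and score[hi + 1] > drop:
        hi += 1
    return lo, hi


def split_adjacent_peaks(score: np.ndarray, peaks: list[int]) -> list[int]:
    """Resolve adjacent significant peaks into distinct QTL seeds.

    For each neighbouring pair, the peaks stay separate iff the minimum
    between them is at least 1.0 below the *lower* peak; otherwise the
    lower peak is absorbed into the higher one.  Repeats until stable.
    """
    peaks = sorted(peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for a, b in zip(peaks, peaks[1:]):
            valley = score[a:b + 1].min()
            lower = min(score[a], score[b])
            if valley > lower - 1.0:
                # merge: keep the higher peak (ties: keep the left one)
                drop_idx = b if score[b] < score[a] else (
                    a if score[a] < score[b] else b)
                peaks.remove(drop_idx)
                changed = True
                break
    return peaks


def call_qtls(positions: np.ndarray, neglogp: np.ndarray, critical_P: float,
              trait: str = "", chrom: str = "",
              index: np.ndarray | None = None) -> list[QTLInterval]:
    """Call QTL intervals on one chromosome's -log10 P track.

    ``positions`` must be sorted ascending; ``neglogp`` is the smoothed
    -log10 P per marker; ``critical_P`` the FDR critical P-value (0 means
    nothing is significant).  Markers with NaN scores break the track
    into independent segments.  ``index`` optionally supplies the member
    labels recorded in the intervals (defaults to 0..n-1 positions on
    this track).
    """
    positions = np.asarray(positions)
    neglogp = np.asarray(neglogp, dtype=float)
    if index is None:
        index = np.arange(positions.size)
    else:
        index = np.asarray(index)
    if positions.size == 0 or critical_P <= 0:
        return []
    threshold = -np.log10(critical_P)

    qtls: list[QTLInterval] = []
    # split on NaN so a masked marker never joins two QTLs
    ok = np.isfinite(neglogp)
    seg_starts = np.flatnonzero(ok & ~np.r_[False, ok[:-1]])
    seg_ends = np.flatnonzero(ok & ~np.r_[ok[1:], False])
    for s, e in zip(seg_starts, seg_ends):
        score = neglogp[s:e + 1]
        seeds = [i for i in _local_maxima(score) if score[i] >= threshold]
        if not seeds:
            continue
        seeds = split_adjacent_peaks(score, seeds)
        for peak in seeds:
            lo, hi = _log_drop_interval(score, peak)
            members = index[s + lo:s + hi + 1]
            qtls.append(QTLInterval(
                trait=trait, chrom=chrom,
                start=int(positions[s + lo]), end=int(positions[s + hi]),
                peak_pos=int(positions[s + peak]),
                peak_score=float(score[peak]),
                member_idx=members,
            ))
    qtls.sort(key=lambda q: q.start)
    return qtls


def call_qtls_genome(assoc: pd.DataFrame, critical_P: float,
                     trait: str = "") -> list[QTLInterval]:
    """Call QTLs on every chromosome of an association table (chrom pos P)."""
    out: list[QTLInterval] = []
    for chrom, sub in assoc.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        with np.errstate(divide="ignore"):
            track = -np.log10(sub["P"].to_numpy(float))
        out.extend(call_qtls(sub["pos"].to_numpy(), track, critical_P,
                             trait=trait, chrom=str(chrom),
                             index=sub.index.to_numpy()))
    return out


def overlap_qtls(qtls_a: list[QTLInterval], qtls_b: list[QTLInterval]
                 ) -> list[tuple[QTLInterval, QTLInterval]]:
    """Pairs of intervals (one per trait) sharing >= 1 bp on a chromosome."""
    return [(a, b) for a in qtls_a for b in qtls_b if a.overlaps(b)]


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene intervals from a GFF3 file: columns chrom, start, end, gene_id.

    Keeps feature type ``gene`` (or every feature if no ``gene`` rows
    exist); coordinates stay 1-based inclusive as in GFF3.
    """
    gff = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end",
               "score", "strand", "frame", "attributes"],
        dtype={"chrom": str},
    )
    genes = gff[gff["type"] == "gene"]
    if genes.empty:
        genes = gff
    ids = genes["attributes"].str.extract(r"ID=([^;]+)", expand=False)
    out = genes[["chrom", "start", "end"]].copy()
    out["gene_id"] = ids.fillna(
        pd.Series((f"feature_{i}" for i in range(len(genes))), index=genes.index))
    return out.reset_index(drop=True)


def summarize_qtls(qtls: list[QTLInterval],
                   genes: pd.DataFrame | None = None) -> dict:
    """Descriptive summary of a trait's QTL set.

    Lengths in bp; inter-QTL distance on a chromosome is the gap from the
    end of one interval to the start of the next (exclusive of both).
    With a gene annotation (chrom/start/end/gene_id, 1-based inclusive),
    genes overlapping each QTL by >= 1 bp are counted, along with QTLs
    holding exactly one gene and QTLs holding none.
    """
    summary: dict = {"n_qtls": len(qtls)}
    if not qtls:
        return summary
    lengths = np.array([q.length_bp for q in qtls])
    summary["mean_length_bp"] = float(lengths.mean())
    summary["min_length_bp"] = int(lengths.min())
    summary["max_length_bp"] = int(lengths.max())

    gaps = []
    by_chrom: dict[str, list[QTLInterval]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for chrom_qtls in by_chrom.values():
        chrom_qtls.sort(key=lambda q: q.start)
        for left, right in zip(chrom_qtls, chrom_qtls[1:]):
            gaps.append(right.start - left.end)
    summary["inter_qtl_distances_bp"] = gaps
    summary["mean_inter_qtl_distance_bp"] = (
        float(np.mean(gaps)) if gaps else float("nan"))

    if genes is not None:
        counts = []
        for q in qtls:
            g = genes[(genes["chrom"] == q.chrom)
                      & (genes["start"] <= q.end) & (genes["end"] >= q.start)]
            counts.append(int(len(g)))
        summary["genes_per_qtl"] = counts
        summary["single_gene_qtls"] = int(sum(c == 1 for c in counts))
        summary["no_orf_qtls"] = int(sum(c == 0 for c in counts))
    return summary


def qtls_to_bed(qtls: list[QTLInterval]) -> pd.DataFrame:
    """0-based half-open BED representation of the 1-based inclusive calls."""
    return pd.DataFrame({
        "chrom": [q.chrom for q in qtls],
        "start": [q.start - 1 for q in qtls],
        "end": [q.end for q in qtls],
        "name": [f"{q.trait}_qtl_{i + 1}" for i, q in enumerate(qtls)],
        "score": [round(q.peak_score, 4) for q in qtls],
    })
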