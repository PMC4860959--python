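"""Occupancy–expression correlation and peak/track comparisons.

Promoter occupancy is the dyad count in a strand-oriented window around the
TSS (default −50..+500 bp in transcript orientation); its Pearson
correlation with per-gene expression quantifies the coupling between
factor-bound nucleosomes at promoters and transcriptional output.  Peak
sets are compared with a length-fraction overlap rule (a mark peak
qualifies when at least a minimum fraction of its length overlaps the
reference peaks), and signal tracks with binned Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dyads import DyadTrack
from .io_formats import AnnotationSet, PeakSet

__all__ = [
    "CorrelationResult",
    "OverlapResult",
    "promoter_occupancy",
    "pearson_correlation",
    "peak_overlap_fraction",
    "binned_track_correlation",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class OverlapResult:
    """Per-mark-peak qualification flags and the set-level fraction.

    Note this statistic is asymmetric: the overlap fraction is measured
    relative to each *mark* peak's length, so swapping the arguments can
    change the result.
    """

    qualifies: np.ndarray
    fraction: float


def promoter_occupancy(track: DyadTrack, ann: AnnotationSet,
                       window: Tuple[int, int] = (-50, 500),
                       anchor: str = "tss") -> pd.DataFrame:
    """Per-gene dyad counts in a strand-oriented window around the TSS (or TTE).

    ``window`` offsets are in transcript orientation and inclusive on both
    ends: a "+" gene with TSS t and window (−50, 500) sums counts over
    reference positions [t−50, t+500]; for a "−" gene the window is
    reflected to [t−500, t+50].  Windows are clipped at contig bounds;
    genes on contigs absent from the track are skipped with a warning.
    """
    frm, to = window
    if frm >= to:
        raise ValueError("window must satisfy from < to")
    if anchor not in ("tss", "tte"):
        raise ValueError("anchor must be 'tss' or 'tte'")
    rows = []
    skipped = 0
    for g in ann.genes:
        arr = track.counts.get(g.contig)
        if arr is None:
            skipped += 1
            continue
        pos = g.tss if anchor == "tss" else g.tte
        if g.strand == "-":
            lo, hi = pos - to, pos - frm
        else:
            lo, hi = pos + frm, pos + to
        lo = max(0, lo)
        hi = min(arr.size - 1, hi)
        value = float(arr[lo:hi + 1].sum()) if hi >= lo else 0.0
        rows.append({"gene_id": g.gene_id, "occupancy": value})
    if skipped:
        warnings.warn(f"{skipped} genes on contigs absent from the track; skipped")
    return pd.DataFrame(rows)


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=int(x.size))


def _merged_intervals(peaks: PeakSet) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Union of peaks per contig as sorted disjoint (starts, ends) arrays."""
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    by_contig: Dict[str, list] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    for contig, spans in by_contig.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged)
        out[contig] = (arr[:, 0], arr[:, 1])
    return out


def _overlap_with_union(contig_union, start: int, end: int) -> int:
    starts, ends = contig_union
    i = np.searchsorted(ends, start, side="right")
    j = np.searchsorted(starts, end, side="left")
    if i >= j:
        return 0
    s = np.maximum(starts[i:j], start)
    e = np.minimum(ends[i:j], end)
    return int(np.sum(e - s))


def peak_overlap_fraction(marks: PeakSet, reference: PeakSet,
                          min_fraction: float = 0.10) -> OverlapResult:
    """Flag each mark peak overlapping the reference by >= a length fraction.

    A mark peak qualifies iff its overlap (in bp, against the union of
    reference peaks) divided by its own length is at least
    ``min_fraction``; the set-level fraction is qualifying/total.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    flags = np.zeros(len(marks), dtype=bool)
    if len(reference) > 0:
        union = _merged_intervals(reference)
        for i, p in enumerate(marks):
            contig_union = union.get(p.contig)
            if contig_union is None:
                continue
            ov = _overlap_with_union(contig_union, p.start, p.end)
            flags[i] = ov / len(p) >= min_fraction
    fraction = float(flags.mean()) if flags.size else 0.0
    return OverlapResult(qualifies=flags, fraction=fraction)


def binned_track_correlation(track_a: DyadTrack, track_b: DyadTrack,
                             bin_size: int = 500) -> CorrelationResult:
    """Pearson correlation of two tracks' per-bin summed counts."""
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    if set(track_a.counts) != set(track_b.counts):
        raise ValueError("tracks cover different contigs")
    binned_a, binned_b = [], []
    for contig in sorted(track_a.counts):
        a = track_a.counts[contig]
        b = track_b.counts[contig]
        size = min(a.size, b.size)
        n_bins = size // bin_size
        if n_bins == 0:
            continue
        binned_a.append(a[:n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1))
        binned_b.append(b[:n_bins * bin_size].reshape(n_bins, bin_size).sum(axis=1))
    if not binned_a:
        raise ValueError("fewer than 3 bins")
    xa = np.concatenate(binned_a)
    xb = np.concatenate(binned_b)
    if xa.size < 3:
        raise ValueError("fewer than 3 bins")
    return pearson_correlation(xa, xb)
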