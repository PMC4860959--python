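"""Fragment-length estimation and nucleosome dyad-center tracks.

For a single-end nucleosome library the average DNA insert length ``d`` is
estimated from the cross-correlation of Watson- and Crick-strand tag 5'
starts: the two strands' tag starts flank each fragment from opposite ends,
so the correlation peaks at a lag of ``d − 1`` (the inclusive span between
the two 5' ends of one fragment).  Tags are then shifted by ``d/2`` toward
the fragment midpoint — Watson starts forward, Crick starts backward — so
that the per-base tag frequency approximates the probability of each
position being a nucleosome center (dyad).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .io_formats import TagSet

__all__ = [
    "CorrelationCurve",
    "FragmentEstimate",
    "DyadTrack",
    "strand_cross_correlation",
    "estimate_fragment_length",
    "tags_to_dyads",
    "normalize_by_genome_mean",
    "coverage_track",
]


@dataclass
class CorrelationCurve:
    lags: np.ndarray       # strictly increasing integer lags, bp
    values: np.ndarray     # one correlation score per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.size != self.values.size:
            raise ValueError("lags and values must have equal length")
        if self.lags.size > 1 and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation values must be finite")


@dataclass
class FragmentEstimate:
    d: int                 # average DNA insert length, bp
    peak_lag: int          # argmax lag of the correlation curve
    curve: CorrelationCurve


@dataclass
class DyadTrack:
    """Per-base dyad-center counts, optionally normalized to genome mean 1."""

    counts: Dict[str, np.ndarray]
    total_mapped: int
    normalized: bool = False
    dropped: int = 0

    @property
    def genome_mean(self) -> float:
        span = sum(a.size for a in self.counts.values())
        if span == 0:
            return float("nan")
        return float(sum(a.sum() for a in self.counts.values()) / span)

    def contigs(self):
        return sorted(self.counts)

    @property
    def span(self) -> int:
        return int(sum(a.size for a in self.counts.values()))


def strand_cross_correlation(tags: TagSet, max_lag: int) -> CorrelationCurve:
    """Cross-correlate Watson and Crick tag-start counts over lags 0..max_lag.

    ``value(k) = Σ_x W(x)·C(x+k)`` summed over contigs, with W and C the
    per-base tag-start count vectors.  Computed by exact dot products on
    integer-valued counts, so the result matches a brute-force
    pairwise-distance histogram bit for bit.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    n_w = sum(len(a) for a in tags.watson.values())
    n_c = sum(len(a) for a in tags.crick.values())
    if n_w == 0 or n_c == 0:
        raise ValueError("cannot estimate fragment length: one strand is empty")
    values = np.zeros(max_lag + 1, dtype=float)
    for contig in tags.contigs():
        w = tags.watson.get(contig)
        c = tags.crick.get(contig)
        if w is None or c is None or len(w) == 0 or len(c) == 0:
            continue
        length = int(max(w[-1], c[-1])) + 1
        wv = np.bincount(w, minlength=length).astype(float)
        cv = np.bincount(c, minlength=length).astype(float)
        for k in range(min(max_lag, length - 1) + 1):
            values[k] += wv[: length - k] @ cv[k:]
    return CorrelationCurve(np.arange(max_lag + 1), values)


def estimate_fragment_length(curve: CorrelationCurve,
                             search: Optional[Tuple[int, int]] = None
                             ) -> FragmentEstimate:
    """Locate the cross-correlation peak and return ``d = peak_lag + 1``.

    ``search`` is an inclusive lag window; it defaults to the full curve.
    Restricting the window to lags above the read length avoids the phantom
    peak that tag-start correlation shows at the read length.  Ties are
    broken toward the smallest lag.
    """
    lags, values = curve.lags, curve.values
    if search is not None:
        lo, hi = search
        if lo < lags[0] or hi > lags[-1] or lo > hi:
            raise ValueError(
                f"search window [{lo}, {hi}] outside curve lag range "
                f"[{lags[0]}, {lags[-1]}]"
            )
        mask = (lags >= lo) & (lags <= hi)
        lags, values = lags[mask], values[mask]
    if np.all(values == values[0]):
        raise ValueError("no peak: correlation curve is flat in the search window")
    peak_lag = int(lags[int(np.argmax(values))])  # argmax takes first on ties
    return FragmentEstimate(d=peak_lag + 1, peak_lag=peak_lag, curve=curve)


def tags_to_dyads(tags: TagSet, d: int,
                  contig_lengths: Optional[Mapping[str, int]] = None
                  ) -> DyadTrack:
    """Shift tag starts by ``floor(d/2)`` toward the fragment midpoint.

    Watson dyad = start + floor(d/2); Crick dyad = start − floor(d/2)
    (the Crick start is already the read's 5' end in reference
    coordinates).  Dyads falling outside contig bounds are dropped and
    tallied.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    shift = d // 2
    counts: Dict[str, np.ndarray] = {}
    total = 0
    dropped = 0
    for contig in tags.contigs():
        w = tags.watson.get(contig, np.empty(0, dtype=np.int64))
        c = tags.crick.get(contig, np.empty(0, dtype=np.int64))
        dyads = np.concatenate([w + shift, c - shift])
        if contig_lengths is not None:
            length = int(contig_lengths[contig])
        else:
            length = int(max(w[-1] if len(w) else 0, c[-1] if len(c) else 0)) + 1
        keep = (dyads >= 0) & (dyads < length)
        dropped += int((~keep).sum())
        dyads = dyads[keep]
        counts[contig] = np.bincount(dyads, minlength=length).astype(float)
        total += len(dyads)
    if total == 0:
        warnings.warn("all dyads fell outside contig bounds; track is empty")
    return DyadTrack(counts=counts, total_mapped=total, dropped=dropped)


def normalize_by_genome_mean(track: DyadTrack,
                             mappable_span: Optional[int] = None) -> DyadTrack:
    """Divide per-base counts by the genome-average density.

    The average density is ``total_mapped / mappable_span``;
    ``mappable_span`` defaults to the sum of contig lengths.  After
    normalization the genome-wide mean over the mappable span is 1.
    """
    if track.normalized:
        raise ValueError("track is already normalized")
    if track.total_mapped == 0:
        raise ValueError("cannot normalize an empty track")
    if mappable_span is None:
        mappable_span = track.span
    if mappable_span <= 0:
        raise ValueError("mappable_span must be > 0")
    rate = track.total_mapped / mappable_span
    counts = {c: a / rate for c, a in track.counts.items()}
    return DyadTrack(counts=counts, total_mapped=track.total_mapped,
                     normalized=True, dropped=track.dropped)


def coverage_track(tags: TagSet, d: int, scale: bool = False,
                   contig_lengths: Optional[Mapping[str, int]] = None
                   ) -> Dict[str, np.ndarray]:
    """Extend each tag to length ``d`` in its strand direction and pile up.

    This is the browser-track construction: per-base overlap counts of the
    extended reads, optionally scaled to one million (``1e6/total_tags``).
    Extensions running off a contig are clipped, not dropped.
    """
    if d < tags.read_length:
        raise ValueError("extension length d must be >= read length")
    total = tags.total_tags
    out: Dict[str, np.ndarray] = {}
    for contig in tags.contigs():
        w = tags.watson.get(contig, np.empty(0, dtype=np.int64))
        c = tags.crick.get(contig, np.empty(0, dtype=np.int64))
        if contig_lengths is not None:
            length = int(contig_lengths[contig])
        else:
            length = int(max(w[-1] if len(w) else 0, c[-1] if len(c) else 0)) + 1
        diff = np.zeros(length + 1, dtype=float)
        # Watson covers [s, s+d); Crick 5' end at s covers (s-d, s] = [s-d+1, s+1)
        starts = np.concatenate([w, c - d + 1]).clip(0, length)
        ends = np.concatenate([w + d, c + 1]).clip(0, length)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        cov = np.cumsum(diff[:-1])
        if scale and total > 0:
            cov *= 1e6 / total
        out[contig] = cov
    return out
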