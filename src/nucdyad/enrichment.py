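"""GC-content enrichment of factor-bound nucleosomes and per-region abundance.

The GC-percentile curve asks whether factor-bound nucleosome dyads sit on
GC-richer DNA than bulk nucleosomes: every dyad position contributes the GC
fraction of the nucleosome-sized window centered on it, positions are
binned by percentile of the *total*-nucleosome GC distribution, and the
curve is the ratio of the factor dyad fraction to the total dyad fraction
per bin, optionally loess-smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dyads import DyadTrack
from .io_formats import GenomicInterval

__all__ = [
    "GCEnrichmentCurve",
    "gc_window_content",
    "gc_percentile_curve",
    "region_relative_abundance",
]

# Default GC window = nucleosomal DNA length (147 bp wrapped around the octamer).
DEFAULT_GC_WINDOW = 147


@dataclass
class GCEnrichmentCurve:
    bin_index: np.ndarray
    mean_gc: np.ndarray           # total-dyad-weighted mean GC per bin
    relative_density: np.ndarray  # (factor fraction)/(total fraction), NaN if empty
    smoothed: Optional[np.ndarray] = None
    edges: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.bin_index, "mean_gc": self.mean_gc,
                           "relative_density": self.relative_density})
        if self.smoothed is not None:
            df["loess"] = self.smoothed
        return df


def _fetch_seq(genome, contig: str, start: int, end: int) -> str:
    """Sequence slice from a pyfaidx.Fasta or a plain {contig: str} mapping."""
    return str(genome[contig][start:end]).upper()


def _contig_length(genome, contig: str) -> int:
    return len(genome[contig])


def gc_window_content(genome, contig: str, center: int, window: int,
                      oob: str = "error") -> Optional[float]:
    """GC fraction of the odd-length window centered on ``center``.

    Computed as (#G + #C)/(window − #N); an all-N window is undefined and
    returns None.  ``oob`` controls windows that do not fit in the contig:
    "error" raises, "skip" returns None.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    length = _contig_length(genome, contig)
    if not (0 <= center < length):
        raise ValueError(f"center {center} outside contig {contig} (len {length})")
    half = window // 2
    start, end = center - half, center + half + 1
    if start < 0 or end > length:
        if oob == "skip":
            return None
        raise ValueError(f"window at {contig}:{center} does not fit in contig")
    seq = _fetch_seq(genome, contig, start, end)
    n_n = seq.count("N")
    denom = window - n_n
    if denom == 0:
        return None
    return (seq.count("G") + seq.count("C")) / denom


def _window_gc_profile(seq: str, window: int) -> np.ndarray:
    """Per-position GC fraction of the centered window; NaN where undefined."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((codes == ord("G")) | (codes == ord("C"))).astype(np.int64)
    is_n = (codes == ord("N")).astype(np.int64)
    half = window // 2
    csum_gc = np.concatenate(([0], np.cumsum(is_gc)))
    csum_n = np.concatenate(([0], np.cumsum(is_n)))
    n = codes.size
    out = np.full(n, np.nan)
    if n < window:
        return out
    centers = np.arange(half, n - half)
    gc = csum_gc[centers + half + 1] - csum_gc[centers - half]
    nn = csum_n[centers + half + 1] - csum_n[centers - half]
    denom = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, gc / denom, np.nan)
    out[centers] = vals
    return out


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       probs: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    idx = np.searchsorted(cw, probs, side="left").clip(0, v.size - 1)
    return v[idx]


def gc_percentile_curve(factor: DyadTrack, total: DyadTrack, genome,
                        window: int = DEFAULT_GC_WINDOW, n_bins: int = 20,
                        loess_frac: float = 0.3) -> GCEnrichmentCurve:
    """Factor/total dyad density ratio as a function of GC percentile.

    Percentile bin edges are computed from the GC distribution of
    total-nucleosome dyad windows (dyad-count weighted); the ratio in each
    bin is (factor dyads in bin / all factor dyads) ÷ (total dyads in bin /
    all total dyads), which is invariant to uniform scaling of either
    track.  A degree-1 loess fit with span ``loess_frac`` is attached.
    """
    if factor.normalized or total.normalized:
        raise ValueError("gc_percentile_curve requires unnormalized count tracks")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    gc_vals: List[np.ndarray] = []
    w_fac: List[np.ndarray] = []
    w_tot: List[np.ndarray] = []
    for contig in sorted(set(factor.counts) | set(total.counts)):
        fa = factor.counts.get(contig)
        to = total.counts.get(contig)
        length = _contig_length(genome, contig)
        gc = _window_gc_profile(_fetch_seq(genome, contig, 0, length), window)
        size = min(length, max(fa.size if fa is not None else 0,
                               to.size if to is not None else 0))
        fa_c = fa[:size] if fa is not None else np.zeros(size)
        to_c = to[:size] if to is not None else np.zeros(size)
        pos = np.flatnonzero((fa_c > 0) | (to_c > 0))
        if pos.size == 0:
            continue
        g = gc[pos]
        ok = ~np.isnan(g)  # windows off contig ends or all-N are skipped
        gc_vals.append(g[ok])
        w_fac.append(fa_c[pos][ok])
        w_tot.append(to_c[pos][ok])
    if not gc_vals:
        raise ValueError("no dyads with defined GC windows")
    gc_all = np.concatenate(gc_vals)
    fac_all = np.concatenate(w_fac)
    tot_all = np.concatenate(w_tot)
    if tot_all.sum() == 0 or fac_all.sum() == 0:
        raise ValueError("a track has no dyads with defined GC windows")

    probs = np.arange(1, n_bins) / n_bins
    inner = _weighted_quantile(gc_all[tot_all > 0], tot_all[tot_all > 0], probs)
    bins = np.searchsorted(inner, gc_all, side="right")

    fac_frac = np.bincount(bins, weights=fac_all, minlength=n_bins) / fac_all.sum()
    tot_frac = np.bincount(bins, weights=tot_all, minlength=n_bins) / tot_all.sum()
    tot_gc_sum = np.bincount(bins, weights=tot_all * gc_all, minlength=n_bins)
    tot_w_sum = np.bincount(bins, weights=tot_all, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(tot_frac > 0, fac_frac / tot_frac, np.nan)
        mean_gc = np.where(tot_w_sum > 0, tot_gc_sum / tot_w_sum, np.nan)

    smoothed = np.full(n_bins, np.nan)
    ok = ~np.isnan(rel) & ~np.isnan(mean_gc)
    if ok.sum() >= 3:
        fit = lowess(rel[ok], mean_gc[ok], frac=loess_frac, it=1,
                     return_sorted=False)
        smoothed[ok] = fit
    return GCEnrichmentCurve(np.arange(n_bins), mean_gc, rel, smoothed, inner)


def region_relative_abundance(track: DyadTrack,
                              regions: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Per-region dyad-center count divided by the total mapped count.

    This is the relative-abundance score: the fraction of all mapped
    nucleosome centers that fall in each region.
    """
    if track.normalized:
        raise ValueError("region_relative_abundance requires raw counts")
    if track.total_mapped <= 0:
        raise ValueError("track has no mapped dyads")
    rows = []
    for r in regions:
        arr = track.counts.get(r.contig)
        if arr is None:
            raise KeyError(f"region on unknown contig {r.contig!r}")
        count = float(arr[r.start:min(r.end, arr.size)].sum())
        rows.append({"contig": r.contig, "start": r.start, "end": r.end,
                     "dyads": count, "score": count / track.total_mapped})
    return pd.DataFrame(rows)
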