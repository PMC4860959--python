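"""Anchor sets and anchor-relative mean dyad-density (metagene) profiles.

Anchors are single strand-oriented positions — TSSs, transcription
termination ends, or exon 5'/3' sites — and a metagene profile is the mean
normalized dyad density at each offset in a symmetric flank around them,
with offsets measured in transcript orientation (negated for minus-strand
anchors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .dyads import DyadTrack
from .io_formats import AnnotationSet, Gene

__all__ = [
    "Anchor",
    "AnchorSet",
    "MetageneProfile",
    "build_anchors",
    "metagene_profile",
    "subtract_background",
]

ANCHOR_LABELS = ("TSS", "TTE", "exon_start", "exon_end")


@dataclass(frozen=True)
class Anchor:
    contig: str
    position: int
    strand: str


@dataclass
class AnchorSet:
    anchors: List[Anchor]
    label: str
    exon_class: str = "all"       # all | first | internal
    expression_class: str = "all"  # all | active | silent

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self):
        return iter(self.anchors)


@dataclass
class MetageneProfile:
    offsets: np.ndarray       # -flank .. +flank, transcript orientation
    mean_density: np.ndarray
    n_anchors: int

    def peak(self, window: Optional[tuple] = None) -> tuple:
        """(offset, value) of the profile maximum, optionally within a window."""
        off, dens = self.offsets, self.mean_density
        if window is not None:
            mask = (off >= window[0]) & (off <= window[1])
            off, dens = off[mask], dens[mask]
        i = int(np.argmax(dens))
        return int(off[i]), float(dens[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets,
                             "mean_density": self.mean_density,
                             "n_anchors": self.n_anchors})


def _exon_five_prime(gene: Gene, exon_index: int) -> int:
    """Reference coordinate of the 5' site of exon ``exon_index`` (transcript order)."""
    e = gene.exons[exon_index]
    return e.start if gene.strand == "+" else e.end - 1


def _exon_three_prime(gene: Gene, exon_index: int) -> int:
    e = gene.exons[exon_index]
    return e.end - 1 if gene.strand == "+" else e.start


def _active_threshold(expression: pd.DataFrame) -> float:
    nonzero = expression.loc[expression["expression"] > 0, "expression"]
    if nonzero.empty:
        return 0.0
    return float(nonzero.median())


def build_anchors(ann: AnnotationSet, label: str,
                  expression: Optional[pd.DataFrame] = None,
                  expression_class: str = "all",
                  exon_class: str = "all",
                  tss_exclusion: int = 0,
                  exclude_last: bool = False,
                  active_threshold: Optional[float] = None) -> AnchorSet:
    """Build a strand-oriented anchor set from gene models.

    Parameters
    ----------
    label : one of TSS, TTE, exon_start, exon_end.
    expression, expression_class : optional active/silent split; "active"
        keeps genes with expression above ``active_threshold`` (default: the
        median of nonzero expression values).
    exon_class : "all", "first", or "internal".  Internal excludes the first
        exon in transcript order; set ``exclude_last`` to also drop the last
        exon.  Exon anchors are drawn only from intron-containing genes.
    tss_exclusion : drop anchors within this many bp of any annotated TSS
        (0 disables the filter).
    """
    if label not in ANCHOR_LABELS:
        raise ValueError(f"unknown anchor label {label!r}")
    if exon_class not in ("all", "first", "internal"):
        raise ValueError(f"unknown exon_class {exon_class!r}")
    if expression_class not in ("all", "active", "silent"):
        raise ValueError(f"unknown expression_class {expression_class!r}")

    genes = list(ann.genes)
    if expression_class != "all":
        if expression is None:
            raise ValueError("expression table required for active/silent split")
        expr = expression.set_index("gene_id")["expression"]
        missing = [g.gene_id for g in genes if g.gene_id not in expr.index]
        if missing:
            raise KeyError(f"expression table missing genes: {missing[:5]}...")
        thr = (active_threshold if active_threshold is not None
               else _active_threshold(expression))
        if expression_class == "active":
            genes = [g for g in genes if expr[g.gene_id] > thr]
        else:
            genes = [g for g in genes if expr[g.gene_id] <= thr]

    anchors: List[Anchor] = []
    if label == "TSS":
        anchors = [Anchor(g.contig, g.tss, g.strand) for g in genes]
    elif label == "TTE":
        anchors = [Anchor(g.contig, g.tte, g.strand) for g in genes]
    else:
        site = _exon_five_prime if label == "exon_start" else _exon_three_prime
        for g in genes:
            if not g.intron_containing:
                continue  # single-exon genes have no intron/exon boundaries
            idx = range(g.n_exons)
            if exon_class == "first":
                idx = [0]
            elif exon_class == "internal":
                last = g.n_exons - 1
                idx = [i for i in idx if i != 0 and not (exclude_last and i == last)]
            anchors.extend(Anchor(g.contig, site(g, i), g.strand) for i in idx)

    if tss_exclusion > 0:
        tss_by_contig: Dict[str, np.ndarray] = {}
        for g in ann.genes:
            tss_by_contig.setdefault(g.contig, []).append(g.tss)  # type: ignore
        tss_by_contig = {c: np.sort(np.asarray(v)) for c, v in tss_by_contig.items()}
        kept = []
        for a in anchors:
            tss = tss_by_contig.get(a.contig)
            if tss is not None and tss.size:
                i = np.searchsorted(tss, a.position)
                near = min(
                    abs(a.position - tss[max(i - 1, 0)]),
                    abs(a.position - tss[min(i, tss.size - 1)]),
                )
                if near <= tss_exclusion:
                    continue
            kept.append(a)
        anchors = kept

    if not anchors:
        warnings.warn(f"anchor set {label}/{exon_class}/{expression_class} is empty")
    return AnchorSet(anchors, label, exon_class, expression_class)


def metagene_profile(track: DyadTrack, anchors: AnchorSet, flank: int,
                     smooth: int = 0) -> MetageneProfile:
    """Mean normalized dyad density at offsets −flank..+flank around anchors.

    Offsets run in transcript orientation (negated for minus-strand
    anchors).  Offsets that fall outside a contig are skipped per anchor,
    with the per-offset denominator adjusted accordingly.  ``smooth``
    applies a centered moving average of that window (0 = off).
    """
    if not track.normalized:
        raise ValueError("metagene_profile requires a normalized track")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if len(anchors) == 0:
        raise ValueError("no anchors")
    width = 2 * flank + 1
    sums = np.zeros(width)
    denom = np.zeros(width)
    for a in anchors:
        arr = track.counts.get(a.contig)
        if arr is None:
            continue
        length = arr.size
        lo = max(0, a.position - flank)
        hi = min(length, a.position + flank + 1)
        if lo >= hi:
            continue
        window = arr[lo:hi]
        if a.strand == "-":
            window = window[::-1]
            i0 = (a.position - (hi - 1)) + flank
        else:
            i0 = (lo - a.position) + flank
        sums[i0:i0 + window.size] += window
        denom[i0:i0 + window.size] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(denom > 0, sums / denom, 0.0)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        mean = np.convolve(mean, kernel, mode="same")
    return MetageneProfile(np.arange(-flank, flank + 1), mean, len(anchors))


def subtract_background(signal: MetageneProfile,
                        background: MetageneProfile) -> MetageneProfile:
    """Pointwise signal − background (e.g. factor minus total nucleosomes)."""
    if (signal.offsets.size != background.offsets.size
            or np.any(signal.offsets != background.offsets)):
        raise ValueError("profiles have mismatched offsets")
    return MetageneProfile(signal.offsets.copy(),
                           signal.mean_density - background.mean_density,
                           signal.n_anchors)
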