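"""Alternative-splicing event filtering, peak intersection and Venn partitions.

Event tables come from isoform-inference tools in two flavours: MISO-style
rows carry inclusion/exclusion read counts, a ΔΨ and a Bayes factor;
MATS-style rows carry a p-value, a splicing difference and a gene-level
expression fold change.  This module implements only the event-level
filtering and set arithmetic downstream of those tools — their internal
inference is consumed, not reimplemented.

MISO-mode retention criteria (all must hold):
  inclusion reads >= 1, exclusion reads >= 1, inclusion+exclusion >= 10,
  |ΔΨ| >= 0.20, Bayes factor >= 10.

MATS-mode retention criteria: p <= p cutoff, |splicing difference| >=
0.0001, and a gene-expression fold-change guard keeping events with
max(FC, 1/FC) <= threshold (default 10000, i.e. effectively permissive —
the guard exists to discard events explainable by expression change alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .io_formats import PeakSet

__all__ = [
    "EVENT_CLASSES",
    "FilterPolicy",
    "FilterResult",
    "filter_events",
    "peak_event_overlap",
    "venn_partition",
    "naive_psi",
]

EVENT_CLASSES = ("SE", "MXE", "A3SS", "A5SS", "RI")

MISO_COLUMNS = ("inc_reads", "exc_reads", "delta_psi", "bayes_factor")
MATS_COLUMNS = ("p_value", "splice_difference", "expression_fold_change")
SPAN_COLUMNS = ("contig", "start", "end")


@dataclass(frozen=True)
class FilterPolicy:
    """Event-retention thresholds for both table flavours."""

    min_inc: int = 1
    min_exc: int = 1
    min_sum: int = 10
    min_abs_delta_psi: float = 0.20
    min_bayes_factor: float = 10.0
    mats_p: float = 0.05
    mats_min_splice_diff: float = 0.0001
    max_expression_fold_change: float = 10000.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be >= 0")


@dataclass
class FilterResult:
    table: pd.DataFrame          # input rows + boolean "retained" column
    audit: Dict[str, int]        # criterion -> number of rows failing it

    @property
    def flags(self) -> pd.Series:
        return self.table["retained"]

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]].drop(columns="retained")


def _require_columns(events: pd.DataFrame, required: Iterable[str]) -> None:
    for col in required:
        if col not in events.columns:
            raise ValueError(f"missing required column {col!r}")


def filter_events(events: pd.DataFrame, policy: Optional[FilterPolicy] = None,
                  mode: str = "miso") -> FilterResult:
    """Apply the event-retention criteria for the given table flavour.

    Row order is preserved; the returned table adds a boolean ``retained``
    column and the audit maps each criterion to the number of rows that
    fail it (independently of the other criteria).
    """
    policy = policy or FilterPolicy()
    if mode not in ("miso", "mats"):
        raise ValueError(f"unknown mode {mode!r}")
    events = events.reset_index(drop=True)
    if mode == "miso":
        _require_columns(events, MISO_COLUMNS)
        inc = events["inc_reads"].to_numpy()
        exc = events["exc_reads"].to_numpy()
        criteria = {
            "min_inc": inc >= policy.min_inc,
            "min_exc": exc >= policy.min_exc,
            "min_sum": inc + exc >= policy.min_sum,
            "min_abs_delta_psi":
                np.abs(events["delta_psi"].to_numpy()) >= policy.min_abs_delta_psi,
            "min_bayes_factor":
                events["bayes_factor"].to_numpy() >= policy.min_bayes_factor,
        }
    else:
        _require_columns(events, MATS_COLUMNS)
        fc = events["expression_fold_change"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            sym_fc = np.where(fc > 0, np.maximum(fc, 1.0 / fc), np.inf)
        criteria = {
            "mats_p": events["p_value"].to_numpy() <= policy.mats_p,
            "mats_min_splice_diff":
                np.abs(events["splice_difference"].to_numpy())
                >= policy.mats_min_splice_diff,
            "max_expression_fold_change":
                sym_fc <= policy.max_expression_fold_change,
        }
    keep = np.ones(len(events), dtype=bool)
    audit: Dict[str, int] = {}
    for name, mask in criteria.items():
        audit[name] = int((~mask).sum())
        keep &= mask
    table = events.copy()
    table["retained"] = keep
    return FilterResult(table=table, audit=audit)


def peak_event_overlap(peaks: PeakSet, events: pd.DataFrame,
                       min_overlap: int = 1):
    """Flag events whose genomic span overlaps any peak by >= ``min_overlap`` bp.

    Returns (flags: boolean Series aligned to ``events``, class_counts:
    per-event-class flagged counts, fraction flagged overall).
    """
    _require_columns(events, SPAN_COLUMNS)
    from .association import _merged_intervals, _overlap_with_union

    union = _merged_intervals(peaks) if len(peaks) else {}
    flags = np.zeros(len(events), dtype=bool)
    unknown = 0
    for i, row in enumerate(events.itertuples(index=False)):
        contig_union = union.get(row.contig)
        if contig_union is None:
            if row.contig not in union and len(peaks) and not any(
                    p.contig == row.contig for p in peaks):
                unknown += 1
            continue
        ov = _overlap_with_union(contig_union, int(row.start), int(row.end))
        flags[i] = ov >= min_overlap
    if unknown:
        warnings.warn(f"{unknown} events on contigs without any peak")
    flag_series = pd.Series(flags, index=events.index, name="peak_overlap")
    if "event_class" in events.columns:
        class_counts = (events.loc[flags, "event_class"].value_counts()
                        .reindex(EVENT_CLASSES, fill_value=0).to_dict())
    else:
        class_counts = {}
    fraction = float(flags.mean()) if flags.size else 0.0
    return flag_series, class_counts, fraction


def venn_partition(sets: Mapping[str, Iterable]) -> Dict[str, int]:
    """Exclusive-region counts for 2–4 named sets.

    Keys are the member names joined by "&" in the order given (e.g. "A",
    "A&B", "A&B&C"); every one of the 2^k − 1 nonempty membership patterns
    is reported, and the counts sum to the size of the union.
    """
    names = list(sets)
    k = len(names)
    if not 2 <= k <= 4:
        raise ValueError("venn_partition requires between 2 and 4 sets")
    as_sets: List[Set] = [set(sets[n]) for n in names]
    union = set().union(*as_sets)
    counts: Dict[str, int] = {}
    for pattern in range(1, 2 ** k):
        members = [i for i in range(k) if pattern >> i & 1]
        key = "&".join(names[i] for i in members)
        counts[key] = 0
    for item in union:
        pattern = sum(1 << i for i, s in enumerate(as_sets) if item in s)
        members = [i for i in range(k) if pattern >> i & 1]
        key = "&".join(names[i] for i in members)
        counts[key] += 1
    return counts


def naive_psi(inc_reads: int, exc_reads: int, inc_len_norm: float = 1.0,
              exc_len_norm: float = 1.0) -> float:
    """Length-normalized percent-spliced-in point estimate.

    Ψ = (inc/inc_len_norm) / (inc/inc_len_norm + exc/exc_len_norm); with no
    reads at all the estimate is undefined (NaN).  This is a point estimate
    for validating synthetic tables, not a posterior.
    """
    if inc_len_norm <= 0 or exc_len_norm <= 0:
        raise ValueError("length normalizers must be > 0")
    if inc_reads < 0 or exc_reads < 0:
        raise ValueError("read counts must be >= 0")
    if inc_reads + exc_reads == 0:
        return float("nan")
    inc = inc_reads / inc_len_norm
    exc = exc_reads / exc_len_norm
    return inc / (inc + exc)
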