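"""Readers and writers for the genomic file formats the pipeline touches.

Coordinate conventions
----------------------
Every coordinate inside this package is 0-based, half-open — the BED
convention.  GTF input (1-based, inclusive on both ends) is converted on
read.  A single convention everywhere eliminates off-by-one drift between
the tag, annotation, peak and track layers.

Tag coordinates are the 5' ends of single-end reads in reference
coordinates: for a Watson (+) read that is the BED start, for a Crick (−)
read it is ``BED end − 1``.  This is the geometry the strand
cross-correlation in :mod:`nucdyad.dyads` relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TagSet",
    "Gene",
    "AnnotationSet",
    "PeakSet",
    "read_tags",
    "read_annotation",
    "read_peaks",
    "write_peaks",
    "write_bedgraph",
    "read_bedgraph",
    "read_expression",
    "read_events",
    "write_tsv",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``contig``."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 if different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TagSet:
    """Stranded single-end tag 5'-start positions, per contig.

    ``watson[contig]`` and ``crick[contig]`` are sorted int64 arrays of
    5'-end reference coordinates.
    """

    watson: Dict[str, np.ndarray] = field(default_factory=dict)
    crick: Dict[str, np.ndarray] = field(default_factory=dict)
    read_length: int = 0

    @property
    def total_tags(self) -> int:
        return int(
            sum(len(a) for a in self.watson.values())
            + sum(len(a) for a in self.crick.values())
        )

    def contigs(self) -> List[str]:
        return sorted(set(self.watson) | set(self.crick))


@dataclass
class Gene:
    """A gene with its exon structure in transcript (5'→3') order."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    tte: int
    exons: List[GenomicInterval]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def intron_containing(self) -> bool:
        return len(self.exons) >= 2

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.contig, lo, hi, self.strand, self.gene_id)


@dataclass
class AnnotationSet:
    genes: List[Gene]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> Dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class PeakSet:
    """A named set of peak intervals, sorted by (contig, start).

    ``aux`` preserves any extra narrowPeak columns (7–10) so that a
    read→write round trip is lossless.
    """

    name: str
    peaks: List[GenomicInterval]
    aux: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        order = sorted(
            range(len(self.peaks)),
            key=lambda i: (self.peaks[i].contig, self.peaks[i].start, self.peaks[i].end),
        )
        self.peaks = [self.peaks[i] for i in order]
        if self.aux is not None:
            self.aux = self.aux.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


# ---------------------------------------------------------------------------
# tags (BED6)
# ---------------------------------------------------------------------------

def read_tags(path: str | Path, read_length: Optional[int] = None,
              dedup: bool = False) -> TagSet:
    """Read stranded single-end tags from a BED6 file.

    The Watson tag start is the BED start; the Crick tag start is
    ``BED end − 1`` (the 5' end of a minus-strand read in reference
    coordinates).  Whether duplicate tags should be collapsed is not a
    settled question for this assay, so ``dedup`` defaults to off.
    """
    watson: Dict[str, list] = {}
    crick: Dict[str, list] = {}
    inferred_len = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            strand = fields[5]
            if strand == "+":
                watson.setdefault(contig, []).append(start)
            elif strand == "-":
                crick.setdefault(contig, []).append(end - 1)
            else:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            inferred_len = max(inferred_len, end - start)
    out = TagSet(read_length=read_length if read_length is not None else inferred_len)
    for src, dst in ((watson, out.watson), (crick, out.crick)):
        for contig, starts in src.items():
            arr = np.sort(np.asarray(starts, dtype=np.int64))
            if dedup:
                arr = np.unique(arr)
            dst[contig] = arr
    return out


def write_tags(tags: TagSet, path: str | Path, name_prefix: str = "tag") -> None:
    """Write a TagSet back to BED6 (read spans reconstructed from read_length)."""
    rl = max(tags.read_length, 1)
    rows = []
    for contig in tags.contigs():
        for s in tags.watson.get(contig, ()):
            rows.append((contig, int(s), int(s) + rl, "+"))
        for s in tags.crick.get(contig, ()):
            rows.append((contig, int(s) - rl + 1, int(s) + 1, "-"))
    rows.sort()
    with open(path, "w") as fh:
        for i, (contig, start, end, strand) in enumerate(rows):
            fh.write(f"{contig}\t{start}\t{end}\t{name_prefix}{i}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# annotation (GTF / BED12)
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_annotation(path: str | Path, dialect: Optional[str] = None) -> AnnotationSet:
    """Read gene models from a GTF or BED12 file.

    The dialect is taken from the file extension unless given explicitly.
    TSS is the strand-aware 5' end of the gene span, TTE the 3' end; exons
    are returned in transcript (5'→3') order.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in (".gtf", ".gff"):
            dialect = "gtf"
        elif suffix in (".bed", ".bed12"):
            dialect = "bed12"
        else:
            raise ValueError(f"cannot infer annotation dialect from {path.name!r}")
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _finalize_gene(gene_id: str, contig: str, strand: str,
                   exons: List[GenomicInterval]) -> Gene:
    exons = sorted(exons, key=lambda e: e.start)
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValueError(f"gene {gene_id}: overlapping exons")
    lo = exons[0].start
    hi = exons[-1].end
    if strand == "-":
        exons = exons[::-1]
        tss, tte = hi - 1, lo
    else:
        tss, tte = lo, hi - 1
    return Gene(gene_id, contig, strand, tss, tte, exons)


def _read_gtf(path: Path) -> AnnotationSet:
    by_gene: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            m = _GTF_GENE_ID.search(fields[8])
            if m is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            contig, strand = fields[0], fields[6]
            # GTF is 1-based inclusive; convert to 0-based half-open.
            start, end = int(fields[3]) - 1, int(fields[4])
            rec = by_gene.setdefault(gid, {"contig": contig, "strand": strand,
                                           "exons": []})
            if rec["contig"] != contig:
                raise ValueError(f"gene {gid}: exons on multiple contigs")
            rec["exons"].append(GenomicInterval(contig, start, end, strand))
    genes = [_finalize_gene(gid, rec["contig"], rec["strand"], rec["exons"])
             for gid, rec in by_gene.items()]
    return AnnotationSet(genes)


def _read_bed12(path: Path) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns")
            contig = fields[0]
            chrom_start = int(fields[1])
            gid, strand = fields[3], fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if not (len(sizes) == len(starts) == n_blocks):
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            exons = [
                GenomicInterval(contig, chrom_start + off, chrom_start + off + size,
                                strand)
                for off, size in zip(starts, sizes)
            ]
            genes.append(_finalize_gene(gid, contig, strand, exons))
    return AnnotationSet(genes)


def write_gtf(ann: AnnotationSet, path: str | Path, source: str = "nucdyad") -> None:
    with open(path, "w") as fh:
        for g in ann.genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.contig}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for e in sorted(g.exons, key=lambda e: e.start):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def write_bed12(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ann.genes:
            span = g.span
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(len(e)) for e in exons)
            offs = ",".join(str(e.start - span.start) for e in exons)
            fh.write(
                f"{g.contig}\t{span.start}\t{span.end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{span.start}\t{span.end}\t0\t{len(exons)}\t"
                f"{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# peaks (BED / narrowPeak)
# ---------------------------------------------------------------------------

_NARROWPEAK_AUX = ["signalValue", "pValue", "qValue", "peak"]


def read_peaks(path: str | Path, name: Optional[str] = None) -> PeakSet:
    """Read a BED (≥3 columns) or narrowPeak (10 columns) peak file."""
    intervals: List[GenomicInterval] = []
    aux_rows: List[list] = []
    n_aux = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            pk_name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in _STRANDS else "."
            intervals.append(
                GenomicInterval(contig, start, end, strand, pk_name, score)
            )
            if len(fields) >= 10:  # narrowPeak
                aux_rows.append([float(fields[6]), float(fields[7]),
                                 float(fields[8]), int(fields[9])])
                n_aux += 1
            else:
                aux_rows.append(None)
    aux = None
    if n_aux and n_aux == len(intervals):
        aux = pd.DataFrame(aux_rows, columns=_NARROWPEAK_AUX)
    return PeakSet(name or Path(path).stem, intervals, aux)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED6, or narrowPeak when aux columns are present."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks.peaks):
            name = p.name if p.name is not None else f"{peaks.name}_{i}"
            score = p.score if p.score is not None else 0
            score_s = f"{score:g}"
            row = f"{p.contig}\t{p.start}\t{p.end}\t{name}\t{score_s}\t{p.strand}"
            if peaks.aux is not None:
                a = peaks.aux.iloc[i]
                row += (f"\t{a.signalValue:g}\t{a.pValue:g}\t{a.qValue:g}"
                        f"\t{int(a.peak)}")
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write a per-base value map as a run-length-merged bedGraph.

    Adjacent equal values are merged into a single line; values are printed
    with 6 significant digits.  NaN or infinite values are rejected.
    """
    with open(path, "w") as fh:
        for contig in sorted(track):
            values = np.asarray(track[contig], dtype=float)
            if values.size == 0:
                continue
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite value in track for {contig}")
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{values[s]:.6g}\n")


def read_bedgraph(path: str | Path,
                  contig_lengths: Optional[Mapping[str, int]] = None
                  ) -> Dict[str, np.ndarray]:
    """Read a bedGraph into per-base value arrays (0-filled gaps)."""
    spans: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            spans.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    out: Dict[str, np.ndarray] = {}
    for contig, rows in spans.items():
        length = (contig_lengths[contig] if contig_lengths is not None
                  else max(e for _, e, _ in rows))
        arr = np.zeros(length, dtype=float)
        for s, e, v in rows:
            arr[s:e] = v
        out[contig] = arr
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a per-gene expression TSV with columns gene_id, expression."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "expression"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_ids")
    if (df["expression"] < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an alternative-splicing event table (TSV, header row)."""
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
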