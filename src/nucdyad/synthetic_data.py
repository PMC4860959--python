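"""Synthetic genomes, nucleosome tag libraries and splicing-event tables.

The generator produces toy data with the statistical structure every
pipeline stage assumes, together with the ground truth needed to test it:

* a genome whose exons are GC-elevated relative to background;
* nucleosome placements: a phased array downstream of each TSS (the +1/+2
  nucleosomes, with gene-specific promoter occupancy), a nucleosome
  positioned at each internal exon 5' site (the exon-demarcating
  nucleosome), and a Poisson-like background elsewhere;
* two stranded single-end tag libraries drawn from fragments of length
  ``round(N(d0, σ))`` centered on sampled dyads — a "total" library
  sampling placements as-is, and a "factor" library whose dyad weights are
  multiplied up near internal exon boundaries and by window GC raised to
  an affinity exponent;
* an expression table coupled to realized promoter dyad occupancy at a
  target Pearson correlation;
* MISO- and MATS-style alternative-splicing event tables whose rows carry
  known pass/fail status under the retention filters.

All randomness flows from a single integer seed through
``numpy.random.default_rng([seed, stage])``; a fixed seed reproduces every
output file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .enrichment import _window_gc_profile
from .io_formats import (AnnotationSet, Gene, GenomicInterval, write_bed12,
                         write_gtf, write_tsv)
from .splicing_events import EVENT_CLASSES

__all__ = ["SimulationSpec", "GroundTruth", "generate_reference",
           "simulate_tags", "simulate_expression_and_events", "simulate"]

_BASES = np.array([b"A", b"T", b"C", b"G"], dtype="S1")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study; defaults define the study conditions."""

    # genome and annotation
    n_contigs: int = 4
    contig_length: int = 1_200_000
    n_genes: int = 2000
    exons_per_gene: int = 4
    exon_length: int = 150
    intron_length: int = 300
    gene_spacing: int = 500
    edge_margin: int = 2000
    background_gc: float = 0.40
    exon_gc_delta: float = 0.12
    # fragments and tags
    d0_factor: int = 156
    d0_total: int = 150
    fragment_sigma: float = 10.0
    n_tags: int = 100_000
    read_length: int = 50
    # nucleosome placement
    nucleosome_spacing: int = 175
    plus_one_offset: int = 100
    n_promoter_nucs: int = 2
    background_nuc_spacing: int = 200
    background_nuc_weight: float = 0.5
    promoter_boost: float = 3.0
    promoter_log_sd: float = 0.8
    # factor binding preferences
    boundary_enrichment: float = 5.0
    boundary_halfwidth: int = 50
    gc_affinity_beta: float = 2.0
    gc_window: int = 147
    # expression coupling
    expression_rho: float = 0.4
    expression_log2_mean: float = 5.0
    expression_log2_sd: float = 1.0
    promoter_window: Tuple[int, int] = (-50, 500)
    # splicing-event tables
    n_ase_events: int = 300
    ase_pass_rate: float = 0.7
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        positive = ("n_contigs", "contig_length", "n_genes", "exons_per_gene",
                    "exon_length", "intron_length", "n_tags", "read_length",
                    "nucleosome_spacing", "background_nuc_spacing",
                    "n_ase_events", "gc_window")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.exons_per_gene < 2:
            raise ValueError("exons_per_gene must be >= 2: downstream exon-"
                             "boundary analyses require intron-containing genes")
        if not 0 <= self.expression_rho < 1:
            raise ValueError("expression_rho must be in [0, 1)")
        if self.fragment_sigma < 0:
            raise ValueError("fragment_sigma must be >= 0")
        if not 0 <= self.ase_pass_rate <= 1:
            raise ValueError("ase_pass_rate must be in [0, 1]")
        if min(self.d0_factor, self.d0_total) < self.read_length:
            raise ValueError("fragment length must be >= read length")

    @property
    def gene_span(self) -> int:
        return (self.exons_per_gene * self.exon_length
                + (self.exons_per_gene - 1) * self.intron_length)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spec: SimulationSpec
    contig_lengths: Dict[str, int]
    annotation: AnnotationSet
    sequences: Dict[str, str]
    boundary_sites: Dict[str, np.ndarray]     # internal exon 5' sites
    cand_contig: np.ndarray = field(default=None)  # candidate dyad placements
    cand_pos: np.ndarray = field(default=None)
    cand_weight_total: np.ndarray = field(default=None)
    cand_weight_factor: np.ndarray = field(default=None)
    factor_dyads: Optional[Dict[str, np.ndarray]] = None  # realized, sorted
    total_dyads: Optional[Dict[str, np.ndarray]] = None
    promoter_occupancy: Optional[pd.Series] = None  # realized factor dyads/gene
    expression: Optional[pd.DataFrame] = None
    miso_labels: Optional[np.ndarray] = None
    mats_labels: Optional[np.ndarray] = None
    paths: Dict[str, Path] = field(default_factory=dict)

    @property
    def d0_factor(self) -> int:
        return self.spec.d0_factor

    @property
    def d0_total(self) -> int:
        return self.spec.d0_total


def _rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stage])


def _write_fasta(sequences: Dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in sorted(sequences):
            fh.write(f">{contig}\n")
            seq = sequences[contig]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def generate_reference(spec: SimulationSpec, out_dir: str | Path) -> GroundTruth:
    """Emit genome FASTA + annotation (GTF and BED12) and place nucleosomes."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 0)

    slot = spec.gene_span + spec.gene_spacing
    usable = spec.contig_length - 2 * spec.edge_margin
    per_contig = usable // slot
    if per_contig * spec.n_contigs < spec.n_genes:
        raise ValueError(
            f"{spec.n_genes} genes do not fit: capacity is "
            f"{per_contig * spec.n_contigs} at these contig sizes"
        )
    contig_lengths = {f"chr{i + 1}": spec.contig_length
                      for i in range(spec.n_contigs)}
    contigs = sorted(contig_lengths)

    strands = np.where(rng.random(spec.n_genes) < 0.5, "+", "-")
    genes: List[Gene] = []
    exon_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contigs}
    for gi in range(spec.n_genes):
        contig = contigs[gi // per_contig]
        slot_i = gi % per_contig
        g0 = spec.edge_margin + slot_i * slot
        exons_coord = [
            GenomicInterval(
                contig,
                g0 + k * (spec.exon_length + spec.intron_length),
                g0 + k * (spec.exon_length + spec.intron_length) + spec.exon_length,
                str(strands[gi]),
            )
            for k in range(spec.exons_per_gene)
        ]
        for e in exons_coord:
            exon_spans[contig].append((e.start, e.end))
        strand = str(strands[gi])
        if strand == "-":
            exons = exons_coord[::-1]
            tss = exons_coord[-1].end - 1
            tte = exons_coord[0].start
        else:
            exons = exons_coord
            tss = exons_coord[0].start
            tte = exons_coord[-1].end - 1
        genes.append(Gene(f"g{gi:05d}", contig, strand, tss, tte, exons))
    ann = AnnotationSet(genes)

    # sequence: exonic GC elevated over background in expectation
    sequences: Dict[str, str] = {}
    for contig in contigs:
        length = contig_lengths[contig]
        p_gc = np.full(length, spec.background_gc)
        for s, e in exon_spans[contig]:
            p_gc[s:e] = spec.background_gc + spec.exon_gc_delta
        is_gc = rng.random(length) < p_gc
        which = rng.integers(0, 2, length)
        seq = _BASES[is_gc.astype(np.int64) * 2 + which]
        sequences[contig] = seq.tobytes().decode("ascii")

    # internal exon 5' sites (non-first in transcript order)
    boundary_sites: Dict[str, np.ndarray] = {}
    for g in genes:
        for e in g.exons[1:]:
            pos = e.start if g.strand == "+" else e.end - 1
            boundary_sites.setdefault(g.contig, []).append(pos)  # type: ignore
    boundary_sites = {c: np.sort(np.asarray(v, dtype=np.int64))
                      for c, v in boundary_sites.items()}

    truth = GroundTruth(spec=spec, contig_lengths=contig_lengths,
                        annotation=ann, sequences=sequences,
                        boundary_sites=boundary_sites)
    _place_nucleosomes(truth, rng)

    fasta = out_dir / "genome.fa"
    gtf = out_dir / "annotation.gtf"
    bed12 = out_dir / "annotation.bed12"
    _write_fasta(sequences, fasta)
    write_gtf(ann, gtf)
    write_bed12(ann, bed12)
    truth.paths.update({"genome": fasta, "gtf": gtf, "bed12": bed12})
    return truth


def _place_nucleosomes(truth: GroundTruth, rng: np.random.Generator) -> None:
    """Candidate dyad positions with total- and factor-track weights."""
    spec = truth.spec
    contigs = sorted(truth.contig_lengths)
    contig_idx = {c: i for i, c in enumerate(contigs)}
    pos_l: List[int] = []
    ctg_l: List[int] = []
    w_l: List[float] = []

    margin = max(spec.d0_factor, spec.d0_total) + 20  # keep fragments on-contig
    # phased arrays downstream of each TSS; +1/+2 carry promoter occupancy
    for g in truth.annotation.genes:
        strength = float(rng.lognormal(0.0, spec.promoter_log_sd))
        direction = 1 if g.strand == "+" else -1
        span = g.span
        k = 0
        while True:
            p = g.tss + direction * (spec.plus_one_offset
                                     + k * spec.nucleosome_spacing)
            if not (span.start <= p < span.end):
                break
            pos_l.append(p)
            ctg_l.append(contig_idx[g.contig])
            w_l.append(strength * spec.promoter_boost
                       if k < spec.n_promoter_nucs else 1.0)
            k += 1
    # nucleosomes positioned at internal exon boundaries (both tracks)
    for contig, sites in truth.boundary_sites.items():
        for p in sites:
            pos_l.append(int(p))
            ctg_l.append(contig_idx[contig])
            w_l.append(1.0)
    # jittered background grid
    for contig in contigs:
        length = truth.contig_lengths[contig]
        grid = np.arange(margin, length - margin, spec.background_nuc_spacing)
        jitter = rng.integers(-50, 51, grid.size)
        for p in grid + jitter:
            pos_l.append(int(p))
            ctg_l.append(contig_idx[contig])
            w_l.append(spec.background_nuc_weight)

    pos = np.asarray(pos_l, dtype=np.int64)
    ctg = np.asarray(ctg_l, dtype=np.int64)
    w_total = np.asarray(w_l, dtype=float)
    keep = np.ones(pos.size, dtype=bool)
    for i, contig in enumerate(contigs):
        length = truth.contig_lengths[contig]
        sel = ctg == i
        keep[sel] &= (pos[sel] >= margin) & (pos[sel] < length - margin)
    pos, ctg, w_total = pos[keep], ctg[keep], w_total[keep]

    # factor weights: boundary proximity and GC affinity on top of placement
    w_factor = w_total.copy()
    for i, contig in enumerate(contigs):
        sel = np.flatnonzero(ctg == i)
        if sel.size == 0:
            continue
        p = pos[sel]
        gc = _window_gc_profile(truth.sequences[contig], spec.gc_window)[p]
        gc = np.where(np.isnan(gc), spec.background_gc, gc)
        mult = (gc / 0.5) ** spec.gc_affinity_beta
        sites = truth.boundary_sites.get(contig)
        if sites is not None and sites.size and spec.boundary_enrichment > 0:
            j = np.searchsorted(sites, p)
            left = np.abs(p - sites[np.clip(j - 1, 0, sites.size - 1)])
            right = np.abs(p - sites[np.clip(j, 0, sites.size - 1)])
            near = np.minimum(left, right) <= spec.boundary_halfwidth
            mult = mult * (1.0 + spec.boundary_enrichment * near)
        w_factor[sel] = w_total[sel] * mult

    truth.cand_contig = ctg
    truth.cand_pos = pos
    truth.cand_weight_total = w_total
    truth.cand_weight_factor = w_factor


def _sample_track(truth: GroundTruth, rng: np.random.Generator, d0: int,
                  weights: np.ndarray, path: Path, name_prefix: str
                  ) -> Dict[str, np.ndarray]:
    """Sample fragments from candidate dyads and write one BED6 tag per fragment."""
    spec = truth.spec
    contigs = sorted(truth.contig_lengths)
    p = weights / weights.sum()
    idx = rng.choice(truth.cand_pos.size, size=spec.n_tags, p=p)
    dyads = truth.cand_pos[idx]
    ctg = truth.cand_contig[idx]
    if spec.fragment_sigma > 0:
        lens = np.rint(rng.normal(d0, spec.fragment_sigma, spec.n_tags))
    else:
        lens = np.full(spec.n_tags, d0, dtype=float)
    lens = lens.astype(np.int64).clip(min=spec.read_length)
    starts = dyads - lens // 2
    ends = starts + lens
    watson = rng.random(spec.n_tags) < 0.5

    lengths = np.asarray([truth.contig_lengths[contigs[i]] for i in range(len(contigs))])
    ok = (starts >= 0) & (ends <= lengths[ctg])
    dyads, ctg, starts, ends, watson = (dyads[ok], ctg[ok], starts[ok],
                                        ends[ok], watson[ok])

    rl = spec.read_length
    read_start = np.where(watson, starts, ends - rl)
    read_end = read_start + rl
    order = np.lexsort((read_start, ctg))
    with open(path, "w") as fh:
        for n, i in enumerate(order):
            strand = "+" if watson[i] else "-"
            fh.write(f"{contigs[ctg[i]]}\t{read_start[i]}\t{read_end[i]}\t"
                     f"{name_prefix}{n}\t0\t{strand}\n")
    realized = {c: np.sort(dyads[ctg == i])
                for i, c in enumerate(contigs) if np.any(ctg == i)}
    return realized


def simulate_tags(truth: GroundTruth, out_dir: str | Path
                  ) -> Dict[str, Path]:
    """Emit the factor and total stranded tag libraries as BED6 files."""
    if truth.cand_pos is None:
        raise ValueError("generate_reference must run first")
    spec = truth.spec
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 1)
    factor_path = out_dir / "factor_tags.bed"
    total_path = out_dir / "total_tags.bed"
    truth.factor_dyads = _sample_track(truth, rng, spec.d0_factor,
                                       truth.cand_weight_factor, factor_path, "f")
    truth.total_dyads = _sample_track(truth, rng, spec.d0_total,
                                      truth.cand_weight_total, total_path, "t")
    truth.promoter_occupancy = _true_promoter_occupancy(truth)
    truth.paths.update({"factor_tags": factor_path, "total_tags": total_path})
    return {"factor_tags": factor_path, "total_tags": total_path}


def _true_promoter_occupancy(truth: GroundTruth) -> pd.Series:
    """Realized factor dyad counts in the promoter window, per gene."""
    frm, to = truth.spec.promoter_window
    values = {}
    for g in truth.annotation.genes:
        dyads = truth.factor_dyads.get(g.contig, np.empty(0, dtype=np.int64))
        if g.strand == "-":
            lo, hi = g.tss - to, g.tss - frm
        else:
            lo, hi = g.tss + frm, g.tss + to
        values[g.gene_id] = int(np.searchsorted(dyads, hi, side="right")
                                - np.searchsorted(dyads, lo, side="left"))
    return pd.Series(values, name="occupancy")


def simulate_expression_and_events(truth: GroundTruth, out_dir: str | Path
                                   ) -> Dict[str, Path]:
    """Emit the expression table, event tables and peak files."""
    if truth.promoter_occupancy is None:
        raise ValueError("simulate_tags must run first")
    spec = truth.spec
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(spec, 2)

    occ = truth.promoter_occupancy.to_numpy(dtype=float)
    sd = occ.std()
    if sd == 0:
        raise ValueError("promoter occupancy has zero variance")
    z = (occ - occ.mean()) / sd
    rho = spec.expression_rho
    noise = rng.standard_normal(occ.size)
    log2e = (spec.expression_log2_mean
             + spec.expression_log2_sd * (rho * z + np.sqrt(1 - rho ** 2) * noise))
    expression = np.maximum(np.exp2(log2e) - 1.0, 0.0)
    expr_df = pd.DataFrame({"gene_id": truth.promoter_occupancy.index,
                            "expression": expression})
    expr_path = out_dir / "expression.tsv"
    write_tsv(expr_df, expr_path)
    truth.expression = expr_df

    miso_df, miso_labels = _miso_table(truth, rng)
    mats_df, mats_labels = _mats_table(truth, rng)
    miso_path = out_dir / "miso_events.tsv"
    mats_path = out_dir / "mats_events.tsv"
    write_tsv(miso_df, miso_path)
    write_tsv(mats_df, mats_path)
    truth.miso_labels = miso_labels
    truth.mats_labels = mats_labels

    peaks_path = out_dir / "factor_peaks.bed"
    decoys_path = out_dir / "decoy_peaks.bed"
    _write_boundary_peaks(truth, peaks_path)
    _write_decoy_peaks(truth, rng, decoys_path)

    manifest = {
        "seed": spec.seed,
        "d0_factor": spec.d0_factor,
        "d0_total": spec.d0_total,
        "expression_rho": spec.expression_rho,
        "n_genes": spec.n_genes,
        "n_ase_events": spec.n_ase_events,
        "files": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    truth.paths.update({"expression": expr_path, "miso_events": miso_path,
                        "mats_events": mats_path, "factor_peaks": peaks_path,
                        "decoy_peaks": decoys_path, "manifest": manifest_path})
    return dict(truth.paths)


def _event_spans(truth: GroundTruth, rng: np.random.Generator, n: int):
    """Random internal-exon spans (padded) for n events, with their genes."""
    genes = truth.annotation.genes
    gi = rng.choice(len(genes), size=n, replace=n > len(genes))
    rows = []
    for i in gi:
        g = genes[int(i)]
        e = g.exons[int(rng.integers(1, g.n_exons))]
        rows.append((g.gene_id, g.contig, max(0, e.start - 50), e.end + 50))
    return rows


def _miso_table(truth: GroundTruth, rng: np.random.Generator):
    spec = truth.spec
    n = spec.n_ase_events
    p = spec.ase_pass_rate
    l_inc, l_exc, l_sum, l_dpsi, l_bf = (rng.random((5, n)) < p)
    inc = np.where(l_inc, rng.integers(1, 9, n), 0)
    exc = np.where(l_exc, rng.integers(1, 9, n), 0)
    # realize the read-sum criterion where the marginal draws allow it
    for i in range(n):
        if l_sum[i]:
            short = 10 - (inc[i] + exc[i])
            if short > 0:
                if inc[i] > 0:
                    inc[i] += short
                elif exc[i] > 0:
                    exc[i] += short
                # both zero: the sum criterion cannot be realized
        else:
            if inc[i] + exc[i] > 9:
                exc[i] = max(1 if l_exc[i] else 0, 9 - inc[i])
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    mag = np.where(l_dpsi, rng.uniform(0.20, 0.80, n), rng.uniform(0.0, 0.19, n))
    delta_psi = sign * mag
    bayes = np.where(l_bf, 10.0 * 10 ** rng.uniform(0, 2, n),
                     rng.uniform(0.0, 9.5, n))
    lo = np.where(delta_psi >= 0, 0.0, -delta_psi)
    hi = np.where(delta_psi >= 0, 1.0 - delta_psi, 1.0)
    psi1 = lo + rng.random(n) * (hi - lo)
    psi2 = psi1 + delta_psi
    spans = _event_spans(truth, rng, n)
    df = pd.DataFrame({
        "event_id": [f"miso_ev{i}" for i in range(n)],
        "gene_id": [s[0] for s in spans],
        "event_class": rng.choice(EVENT_CLASSES, n),
        "contig": [s[1] for s in spans],
        "start": [s[2] for s in spans],
        "end": [s[3] for s in spans],
        "psi_1": np.round(psi1, 4),
        "psi_2": np.round(psi2, 4),
        "delta_psi": np.round(delta_psi, 4),
        "inc_reads": inc,
        "exc_reads": exc,
        "bayes_factor": np.round(bayes, 3),
    })
    labels = ((df["inc_reads"] >= 1) & (df["exc_reads"] >= 1)
              & (df["inc_reads"] + df["exc_reads"] >= 10)
              & (df["delta_psi"].abs() >= 0.20)
              & (df["bayes_factor"] >= 10)).to_numpy()
    return df, labels


def _mats_table(truth: GroundTruth, rng: np.random.Generator):
    spec = truth.spec
    n = spec.n_ase_events
    p = spec.ase_pass_rate
    l_p, l_diff, l_fc = (rng.random((3, n)) < p)
    pval = np.where(l_p, rng.uniform(0.0, 0.05, n), rng.uniform(0.06, 1.0, n))
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    diff = sign * np.where(l_diff, rng.uniform(0.01, 0.5, n),
                           rng.uniform(0.0, 0.00009, n))
    thr = 10000.0
    fc = np.where(l_fc, np.exp(rng.normal(0.0, 0.3, n)),
                  thr * rng.uniform(1.5, 5.0, n))
    spans = _event_spans(truth, rng, n)
    df = pd.DataFrame({
        "event_id": [f"mats_ev{i}" for i in range(n)],
        "gene_id": [s[0] for s in spans],
        "event_class": rng.choice(EVENT_CLASSES, n),
        "contig": [s[1] for s in spans],
        "start": [s[2] for s in spans],
        "end": [s[3] for s in spans],
        "p_value": np.round(pval, 6),
        "splice_difference": np.round(diff, 6),
        "expression_fold_change": np.round(fc, 4),
    })
    sym = np.maximum(df["expression_fold_change"],
                     1.0 / df["expression_fold_change"])
    labels = ((df["p_value"] <= 0.05)
              & (df["splice_difference"].abs() >= 0.0001)
              & (sym <= thr)).to_numpy()
    return df, labels


def _write_boundary_peaks(truth: GroundTruth, path: Path,
                          halfwidth: int = 73) -> None:
    with open(path, "w") as fh:
        n = 0
        for contig in sorted(truth.boundary_sites):
            merged: List[List[int]] = []
            for p in truth.boundary_sites[contig]:
                s, e = int(p) - halfwidth, int(p) + halfwidth + 1
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                fh.write(f"{contig}\t{s}\t{e}\tpeak{n}\t0\t.\n")
                n += 1


def _write_decoy_peaks(truth: GroundTruth, rng: np.random.Generator,
                       path: Path, n_peaks: int = 200) -> None:
    contigs = sorted(truth.contig_lengths)
    rows = []
    for i in range(n_peaks):
        contig = contigs[int(rng.integers(0, len(contigs)))]
        length = int(rng.integers(150, 501))
        start = int(rng.integers(0, truth.contig_lengths[contig] - length))
        rows.append((contig, start, start + length))
    rows.sort()
    with open(path, "w") as fh:
        for i, (contig, s, e) in enumerate(rows):
            fh.write(f"{contig}\t{s}\t{e}\tdecoy{i}\t0\t.\n")


def simulate(spec: SimulationSpec, out_dir: str | Path) -> GroundTruth:
    """Run all three generation stages and return the ground truth."""
    truth = generate_reference(spec, out_dir)
    simulate_tags(truth, out_dir)
    simulate_expression_and_events(truth, out_dir)
    return truth
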