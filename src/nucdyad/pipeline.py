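"""End-to-end orchestration of the occupancy and splicing analysis stages.

``run_pipeline`` runs: fragment-length estimation → dyad tracks → metagene
profiles → GC enrichment → occupancy/expression association → splicing-event
filtering and intersection, persisting every intermediate under the output
directory and returning a machine-readable report.  Stages are pure reads
of their input files; re-running with the same config reproduces identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import pyfaidx

from . import association, dyads, enrichment, io_formats, metagene, splicing_events
from .splicing_events import FilterPolicy

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("nucdyad")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Defaults follow the analysis parameters stated for the method: a
    −50..+500 bp promoter window, ±250 bp TSS exclusion for exon-boundary
    anchors, a 10% peak-overlap rule, and event filters 1/1/10/0.20/10.
    """

    factor_tags: Path = None
    total_tags: Path = None
    genome: Path = None
    annotation: Path = None
    expression: Optional[Path] = None
    miso_events: Optional[Path] = None
    mats_events: Optional[Path] = None
    factor_peaks: Optional[Path] = None
    mark_peaks: Optional[Path] = None
    out_dir: Path = Path("nucdyad_out")

    max_lag: int = 300
    search_window: Optional[Tuple[int, int]] = None  # default: (read_len+1, max_lag)
    flank_tss: int = 2000
    flank_exon: int = 1000
    promoter_window: Tuple[int, int] = (-50, 500)
    tss_exclusion: int = 250
    gc_window: int = 147
    gc_bins: int = 20
    loess_frac: float = 0.3
    min_overlap_fraction: float = 0.10
    bin_size: int = 500
    log_expression: bool = True
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    seed: int = 0

    def validate(self) -> None:
        for name in ("factor_tags", "total_tags", "genome", "annotation"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config is missing required input {name!r}")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")


def _round(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage and write a deterministic report.json to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"stages": {}}
    stage_name = "setup"

    def timed(name):
        nonlocal stage_name
        stage_name = name
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = timed("load")
        genome = pyfaidx.Fasta(str(config.genome))
        contig_lengths = {c: len(genome[c]) for c in genome.keys()}
        ann = io_formats.read_annotation(config.annotation)
        factor = io_formats.read_tags(config.factor_tags)
        total = io_formats.read_tags(config.total_tags)
        report["stages"]["load"] = {
            "n_contigs": len(contig_lengths),
            "n_genes": len(ann),
            "factor_tags": factor.total_tags,
            "total_tags": total.total_tags,
        }

        timed("estimate_d")
        search = config.search_window
        estimates = {}
        for name, tags in (("factor", factor), ("total", total)):
            curve = dyads.strand_cross_correlation(tags, config.max_lag)
            win = search or (tags.read_length + 1, config.max_lag)
            est = dyads.estimate_fragment_length(curve, win)
            estimates[name] = est
            io_formats.write_tsv(
                pd.DataFrame({"lag": curve.lags, "value": curve.values}),
                out / f"{name}_crosscorr.tsv")
        report["stages"]["estimate_d"] = {
            "d_factor": estimates["factor"].d,
            "d_total": estimates["total"].d,
        }

        timed("dyads")
        track_f = dyads.tags_to_dyads(factor, estimates["factor"].d, contig_lengths)
        track_t = dyads.tags_to_dyads(total, estimates["total"].d, contig_lengths)
        norm_f = dyads.normalize_by_genome_mean(track_f)
        norm_t = dyads.normalize_by_genome_mean(track_t)
        io_formats.write_bedgraph(track_f.counts, out / "factor_dyads.bedgraph")
        io_formats.write_bedgraph(track_t.counts, out / "total_dyads.bedgraph")
        report["stages"]["dyads"] = {
            "factor_mapped": track_f.total_mapped,
            "factor_dropped": track_f.dropped,
            "total_mapped": track_t.total_mapped,
            "total_dropped": track_t.dropped,
            "normalized_mean_factor": norm_f.genome_mean,
            "normalized_mean_total": norm_t.genome_mean,
        }

        timed("metagene")
        expr_df = (io_formats.read_expression(config.expression)
                   if config.expression else None)
        profiles = {}
        for label, flank in (("TSS", config.flank_tss), ("TTE", config.flank_tss)):
            anchors = metagene.build_anchors(ann, label)
            for tname, track in (("factor", norm_f), ("total", norm_t)):
                prof = metagene.metagene_profile(track, anchors, flank)
                profiles[f"{label}_{tname}"] = prof
        for exon_class in ("first", "internal"):
            excl = config.tss_exclusion if exon_class == "internal" else 0
            anchors = metagene.build_anchors(ann, "exon_start",
                                             exon_class=exon_class,
                                             tss_exclusion=excl)
            for tname, track in (("factor", norm_f), ("total", norm_t)):
                prof = metagene.metagene_profile(track, anchors, config.flank_exon)
                profiles[f"exon_start_{exon_class}_{tname}"] = prof
        for key, prof in profiles.items():
            io_formats.write_tsv(prof.to_frame(), out / f"profile_{key}.tsv")
        residual = metagene.subtract_background(
            profiles["exon_start_internal_factor"],
            profiles["exon_start_internal_total"])
        io_formats.write_tsv(residual.to_frame(),
                             out / "profile_exon_start_internal_residual.tsv")
        report["stages"]["metagene"] = {
            "tss_peak_offset": profiles["TSS_factor"].peak()[0],
            "internal_exon_peak": profiles["exon_start_internal_factor"].peak(
                (-50, 50))[1],
            "first_exon_peak": profiles["exon_start_first_factor"].peak(
                (-50, 50))[1],
            "residual_peak_offset": residual.peak((-config.flank_exon,
                                                   config.flank_exon))[0],
        }

        timed("gc_enrichment")
        curve = enrichment.gc_percentile_curve(
            track_f, track_t, genome, window=config.gc_window,
            n_bins=config.gc_bins, loess_frac=config.loess_frac)
        io_formats.write_tsv(curve.to_frame(), out / "gc_curve.tsv")
        ok = ~np.isnan(curve.relative_density)
        report["stages"]["gc_enrichment"] = {
            "n_bins": int(ok.sum()),
            "low_bin_density": float(curve.relative_density[ok][0]),
            "high_bin_density": float(curve.relative_density[ok][-1]),
        }

        timed("association")
        assoc: Dict = {}
        occ = association.promoter_occupancy(track_f, ann,
                                             config.promoter_window, "tss")
        io_formats.write_tsv(occ, out / "promoter_occupancy.tsv")
        if expr_df is not None:
            merged = occ.merge(expr_df, on="gene_id")
            y = merged["expression"].to_numpy()
            if config.log_expression:
                y = np.log2(y + 1.0)
            res = association.pearson_correlation(merged["occupancy"], y)
            assoc["promoter_expression_r"] = res.r
            assoc["promoter_expression_p"] = res.p
            occ_tte = association.promoter_occupancy(
                track_f, ann, config.promoter_window, "tte")
            merged_t = occ_tte.merge(expr_df, on="gene_id")
            yt = merged_t["expression"].to_numpy()
            if config.log_expression:
                yt = np.log2(yt + 1.0)
            res_t = association.pearson_correlation(merged_t["occupancy"], yt)
            assoc["tte_expression_r"] = res_t.r
        res_bins = association.binned_track_correlation(track_f, track_t,
                                                        config.bin_size)
        assoc["factor_total_binned_r"] = res_bins.r
        if config.mark_peaks and config.factor_peaks:
            marks = io_formats.read_peaks(config.mark_peaks)
            reference = io_formats.read_peaks(config.factor_peaks)
            ov = association.peak_overlap_fraction(marks, reference,
                                                   config.min_overlap_fraction)
            assoc["mark_overlap_fraction"] = ov.fraction
        report["stages"]["association"] = assoc

        timed("splicing")
        spl: Dict = {}
        gene_sets: Dict[str, set] = {}
        peakset = (io_formats.read_peaks(config.factor_peaks)
                   if config.factor_peaks else None)
        for mode, path in (("miso", config.miso_events),
                           ("mats", config.mats_events)):
            if path is None:
                continue
            events = io_formats.read_events(path)
            result = splicing_events.filter_events(events, config.filter_policy,
                                                   mode=mode)
            io_formats.write_tsv(result.table, out / f"{mode}_filtered.tsv")
            spl[mode] = {"n_events": len(events),
                         "n_retained": int(result.flags.sum()),
                         "audit": result.audit}
            gene_sets[mode] = set(result.retained["gene_id"])
            if peakset is not None:
                flags, class_counts, frac = splicing_events.peak_event_overlap(
                    peakset, events)
                spl[mode]["peak_overlap_fraction"] = frac
                spl[mode]["peak_overlap_by_class"] = class_counts
                gene_sets[f"{mode}_peak"] = set(
                    events.loc[flags.to_numpy(), "gene_id"])
        if len(gene_sets) >= 2:
            venn = splicing_events.venn_partition(
                {k: gene_sets[k] for k in sorted(gene_sets)[:4]})
            (out / "venn.json").write_text(
                json.dumps(venn, indent=2, sort_keys=True) + "\n")
            spl["venn"] = venn
        report["stages"]["splicing"] = spl
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc

    report = _round(report)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
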