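import filecmp
import json

import numpy as np
import pytest

from nucdyad import (SimulationSpec, build_anchors, estimate_fragment_length,
                     filter_events, generate_reference, metagene_profile,
                     normalize_by_genome_mean, pearson_correlation,
                     promoter_occupancy, read_annotation, read_events,
                     read_expression, read_peaks, read_tags, simulate,
                     strand_cross_correlation, tags_to_dyads)
from conftest import small_spec


class TestSpecValidation:
    def test_zero_intron_request_rejected(self):
        with pytest.raises(ValueError, match="intron"):
            SimulationSpec(exons_per_gene=1).validate()

    def test_rho_bounds(self):
        with pytest.raises(ValueError, match="rho"):
            SimulationSpec(expression_rho=1.0).validate()

    def test_genes_must_fit(self, tmp_path):
        spec = SimulationSpec(n_genes=10_000, n_contigs=1, contig_length=100_000)
        with pytest.raises(ValueError, match="do not fit"):
            generate_reference(spec, tmp_path)


class TestDeterminism:
    def test_fixed_seed_byte_identical(self, tmp_path):
        spec = small_spec(seed=3, n_tags=5_000, n_ase_events=50)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate(spec, a)
        simulate(small_spec(seed=3, n_tags=5_000, n_ase_events=50), b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert not mismatch and not errors


class TestReference:
    def test_exonic_gc_elevated(self, tmp_path):
        spec = small_spec(seed=21, exon_gc_delta=0.2, n_tags=1000,
                          exon_length=300)  # >=50 kb exonic sequence
        truth = generate_reference(spec, tmp_path)
        exonic = []
        for g in truth.annotation.genes:
            for e in g.exons:
                exonic.append(truth.sequences[g.contig][e.start:e.end])
        exonic = "".join(exonic)
        assert len(exonic) >= 50_000
        gc = (exonic.count("G") + exonic.count("C")) / len(exonic)
        assert 0.57 <= gc <= 0.63

    def test_emitted_files_readable_by_io_layer(self, small_truth):
        paths = small_truth.paths
        tags = read_tags(paths["factor_tags"])
        assert tags.total_tags > 0
        gtf = read_annotation(paths["gtf"])
        bed12 = read_annotation(paths["bed12"])
        assert len(gtf) == len(bed12) == small_truth.spec.n_genes
        ga, gb = gtf.by_id()["g00000"], bed12.by_id()["g00000"]
        assert (ga.tss, ga.tte) == (gb.tss, gb.tte)
        assert [(e.start, e.end) for e in ga.exons] == \
               [(e.start, e.end) for e in gb.exons]
        assert len(read_peaks(paths["factor_peaks"])) > 0
        assert len(read_expression(paths["expression"])) == \
            small_truth.spec.n_genes
        assert len(read_events(paths["miso_events"])) == \
            small_truth.spec.n_ase_events


class TestTags:
    def test_sigma_zero_exact_fragment_geometry(self, tmp_path):
        spec = small_spec(seed=31, fragment_sigma=0.0, d0_factor=150,
                          d0_total=150, n_tags=5_000)
        truth = simulate(spec, tmp_path)
        tags = read_tags(truth.paths["factor_tags"])
        curve = strand_cross_correlation(tags, 300)
        # every tag 5' end sits exactly floor(d/2) / d-1-floor(d/2) from its
        # dyad, so the cross-correlation spikes at lag d0-1 exactly
        assert int(np.argmax(curve.values)) == 149
        assert estimate_fragment_length(curve, (51, 300)).d == 150
        for contig, dyads in truth.factor_dyads.items():
            w = tags.watson.get(contig)
            if w is not None:
                assert set(w + 75) <= set(dyads.tolist())

    def test_fragment_length_recovery(self, tmp_path):
        truth = simulate(small_spec(seed=41), tmp_path)
        for key, d0 in (("factor_tags", truth.d0_factor),
                        ("total_tags", truth.d0_total)):
            tags = read_tags(truth.paths[key])
            est = estimate_fragment_length(
                strand_cross_correlation(tags, 300), (51, 300))
            assert abs(est.d - d0) <= 2

    def test_null_generator_factor_matches_total(self, tmp_path):
        """With no boundary enrichment and no GC affinity the factor and total
        metagene profiles at internal exon boundaries are indistinguishable."""
        spec = small_spec(seed=51, boundary_enrichment=0.0, gc_affinity_beta=0.0)
        truth = simulate(spec, tmp_path)
        ann = read_annotation(truth.paths["gtf"])
        anchors = build_anchors(ann, "exon_start", exon_class="internal",
                                tss_exclusion=250)
        profiles, raws = {}, {}
        for key, d0 in (("factor_tags", truth.d0_factor),
                        ("total_tags", truth.d0_total)):
            tags = read_tags(truth.paths[key])
            raw = tags_to_dyads(tags, d0, truth.contig_lengths)
            raws[key] = raw
            profiles[key] = metagene_profile(normalize_by_genome_mean(raw),
                                             anchors, 500)
        # z-score the profile difference on 50-bp bins under Poisson counting
        bin_bp = 50
        n = len(anchors)

        def binned(key):
            prof = profiles[key]
            scale = raws[key].span / raws[key].total_mapped  # norm factor
            raw_sum = prof.mean_density * n / scale          # total dyads/offset
            usable = (prof.offsets.size // bin_bp) * bin_bp
            return raw_sum[:usable].reshape(-1, bin_bp).sum(axis=1), scale

        f_counts, f_scale = binned("factor_tags")
        t_counts, t_scale = binned("total_tags")
        diff = f_counts * f_scale - t_counts * t_scale
        se = np.sqrt(np.maximum(f_counts, 1) * f_scale ** 2
                     + np.maximum(t_counts, 1) * t_scale ** 2)
        assert np.max(np.abs(diff) / se) < 4.0


class TestExpressionAndEvents:
    def recovered_r(self, truth):
        tags = read_tags(truth.paths["factor_tags"])
        track = tags_to_dyads(tags, truth.d0_factor, truth.contig_lengths)
        ann = truth.annotation
        occ = promoter_occupancy(track, ann, (-50, 500))
        expr = read_expression(truth.paths["expression"])
        merged = occ.merge(expr, on="gene_id")
        return pearson_correlation(merged["occupancy"],
                                   np.log2(merged["expression"] + 1)).r

    def test_null_coupling(self, tmp_path):
        truth = simulate(SimulationSpec(seed=61, expression_rho=0.0), tmp_path)
        assert abs(self.recovered_r(truth)) < 2 / np.sqrt(truth.spec.n_genes)

    def test_target_coupling_recovered(self, tmp_path):
        truth = simulate(SimulationSpec(seed=62), tmp_path)
        assert 0.35 <= self.recovered_r(truth) <= 0.45

    def test_all_pass_rates_one_retains_everything(self, tmp_path):
        spec = small_spec(seed=71, ase_pass_rate=1.0, n_tags=2_000)
        truth = simulate(spec, tmp_path)
        for mode in ("miso", "mats"):
            events = read_events(truth.paths[f"{mode}_events"])
            assert filter_events(events, mode=mode).flags.all()

    def test_known_labels_reproduced(self, small_truth):
        for mode, labels in (("miso", small_truth.miso_labels),
                             ("mats", small_truth.mats_labels)):
            events = read_events(small_truth.paths[f"{mode}_events"])
            flags = filter_events(events, mode=mode).flags.to_numpy()
            np.testing.assert_array_equal(flags, labels)


class TestEndToEndStructure:
    def test_promoter_phasing_and_boundary_contrast(self, full_truth):
        """The default study reproduces the expected occupancy structure:
        a downstream (+1/+2) TSS peak, internal > first exon boundary
        enrichment, and a rising GC curve."""
        import pyfaidx

        from nucdyad import gc_percentile_curve, subtract_background
        tags_f = read_tags(full_truth.paths["factor_tags"])
        tags_t = read_tags(full_truth.paths["total_tags"])
        tf = tags_to_dyads(tags_f, full_truth.d0_factor, full_truth.contig_lengths)
        tt = tags_to_dyads(tags_t, full_truth.d0_total, full_truth.contig_lengths)
        nf, nt = normalize_by_genome_mean(tf), normalize_by_genome_mean(tt)
        ann = read_annotation(full_truth.paths["gtf"])

        tss = build_anchors(ann, "TSS")
        prof_tss = metagene_profile(nf, tss, 2000)
        peak_offset, peak_value = prof_tss.peak()
        assert peak_offset > 0  # nucleosomes phased downstream of the TSS
        upstream = prof_tss.mean_density[prof_tss.offsets < 0].mean()
        assert peak_value > 2 * upstream

        internal = build_anchors(ann, "exon_start", exon_class="internal",
                                 tss_exclusion=250)
        first = build_anchors(ann, "exon_start", exon_class="first")
        p_int = metagene_profile(nf, internal, 1000)
        p_first = metagene_profile(nf, first, 1000)
        assert p_int.peak((-50, 50))[1] > p_first.peak((-50, 50))[1]
        residual = subtract_background(p_int, metagene_profile(nt, internal, 1000))
        assert abs(residual.peak()[0]) <= 10

        genome = pyfaidx.Fasta(str(full_truth.paths["genome"]))
        curve = gc_percentile_curve(tf, tt, genome)
        ok = ~np.isnan(curve.relative_density)
        rel = curve.relative_density[ok]
        assert rel[-1] > rel[0]  # factor shifted toward GC-rich nucleosomes
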