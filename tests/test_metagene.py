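import numpy as np
import pandas as pd
import pytest

from nucdyad import (AnchorSet, DyadTrack, build_anchors, metagene_profile,
                     normalize_by_genome_mean, subtract_background)
from nucdyad.io_formats import AnnotationSet, Gene, GenomicInterval
from nucdyad.metagene import Anchor


def two_exon_gene(strand="+", gene_id="g1", contig="chr1"):
    exons = [GenomicInterval(contig, 100, 200, strand),
             GenomicInterval(contig, 300, 400, strand)]
    if strand == "-":
        return Gene(gene_id, contig, strand, 399, 100, exons[::-1])
    return Gene(gene_id, contig, strand, 100, 399, exons)


def single_exon_gene(gene_id="s1"):
    return Gene(gene_id, "chr1", "+", 1000, 1199,
                [GenomicInterval("chr1", 1000, 1200, "+")])


def uniform_track(length=2000, contig="chr1"):
    return normalize_by_genome_mean(
        DyadTrack({contig: np.ones(length)}, total_mapped=length))


class TestBuildAnchors:
    def test_plus_gene_exon_starts(self):
        ann = AnnotationSet([two_exon_gene("+")])
        assert {a.position for a in build_anchors(ann, "exon_start")} == {100, 300}
        internal = build_anchors(ann, "exon_start", exon_class="internal")
        assert {a.position for a in internal} == {300}

    def test_minus_gene_exon_five_prime_sites(self):
        ann = AnnotationSet([two_exon_gene("-")])
        # 5' sites in transcript orientation are the high-coordinate edges
        assert {a.position for a in build_anchors(ann, "exon_start")} == {399, 199}
        internal = build_anchors(ann, "exon_start", exon_class="internal")
        assert {a.position for a in internal} == {199}

    def test_single_exon_gene_contributes_no_exon_anchors(self):
        ann = AnnotationSet([single_exon_gene()])
        with pytest.warns(UserWarning, match="empty"):
            anchors = build_anchors(ann, "exon_start")
        assert len(anchors) == 0

    def test_first_class_and_exclude_last(self):
        exons = [GenomicInterval("chr1", s, s + 100, "+")
                 for s in (100, 300, 500)]
        g = Gene("g3", "chr1", "+", 100, 599, exons)
        ann = AnnotationSet([g])
        first = build_anchors(ann, "exon_start", exon_class="first")
        assert {a.position for a in first} == {100}
        internal = build_anchors(ann, "exon_start", exon_class="internal")
        assert {a.position for a in internal} == {300, 500}
        trimmed = build_anchors(ann, "exon_start", exon_class="internal",
                                exclude_last=True)
        assert {a.position for a in trimmed} == {300}

    def test_tss_exclusion_removes_nearby_anchors(self):
        ann = AnnotationSet([two_exon_gene("+")])
        kept = build_anchors(ann, "exon_start", tss_exclusion=250)
        # both 100 (at the TSS) and 300 (200 bp away) fall inside +-250
        assert len(kept) == 0
        kept = build_anchors(ann, "exon_start", tss_exclusion=150)
        assert {a.position for a in kept} == {300}

    def test_tss_and_tte_labels(self):
        ann = AnnotationSet([two_exon_gene("+"), two_exon_gene("-", "g2", "chr2")])
        tss = build_anchors(ann, "TSS")
        assert {(a.contig, a.position) for a in tss} == {("chr1", 100),
                                                         ("chr2", 399)}
        tte = build_anchors(ann, "TTE")
        assert {(a.contig, a.position) for a in tte} == {("chr1", 399),
                                                         ("chr2", 100)}

    def test_active_silent_split(self):
        genes = [two_exon_gene("+", f"g{i}") for i in range(4)]
        ann = AnnotationSet(genes)
        expr = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                             "expression": [0.0, 1.0, 10.0, 100.0]})
        active = build_anchors(ann, "TSS", expression=expr,
                               expression_class="active")
        silent = build_anchors(ann, "TSS", expression=expr,
                               expression_class="silent")
        # median of nonzero = 10 -> active keeps strictly greater
        assert len(active) == 1 and len(silent) == 3

    def test_missing_expression_gene_rejected(self):
        ann = AnnotationSet([two_exon_gene("+")])
        expr = pd.DataFrame({"gene_id": ["other"], "expression": [1.0]})
        with pytest.raises(KeyError):
            build_anchors(ann, "TSS", expression=expr, expression_class="active")


class TestMetageneProfile:
    def test_dyads_at_anchors_peak_at_zero(self):
        counts = np.zeros(2000)
        counts[[500, 1200]] = 50
        track = normalize_by_genome_mean(DyadTrack({"chr1": counts}, 100))
        anchors = AnchorSet([Anchor("chr1", 500, "+"), Anchor("chr1", 1200, "+")],
                            "TSS")
        prof = metagene_profile(track, anchors, 100)
        assert prof.peak()[0] == 0

    def test_uniform_track_flat_profile(self):
        anchors = AnchorSet([Anchor("chr1", 1000, "+")], "TSS")
        prof = metagene_profile(uniform_track(), anchors, 200)
        np.testing.assert_allclose(prof.mean_density, 1.0)

    def test_minus_strand_orientation(self):
        counts = np.zeros(2000)
        counts[550] = 10
        track = normalize_by_genome_mean(DyadTrack({"chr1": counts}, 10))
        prof = metagene_profile(track, AnchorSet([Anchor("chr1", 500, "-")],
                                                 "TSS"), 100)
        assert prof.mean_density[prof.offsets == -50] > 0
        assert prof.mean_density[prof.offsets == 50] == 0

    def test_edge_anchor_uses_partial_window(self):
        anchors = AnchorSet([Anchor("chr1", 10, "+")], "TSS")
        prof = metagene_profile(uniform_track(100), anchors, 50)
        # offsets reaching below position 0 have no data; others stay 1.0
        assert prof.mean_density[prof.offsets == -20] == 0.0
        assert prof.mean_density[prof.offsets == 0] == pytest.approx(1.0)

    def test_anchor_permutation_invariance(self, rng):
        counts = rng.poisson(2, 4000).astype(float)
        track = normalize_by_genome_mean(DyadTrack({"chr1": counts},
                                                   int(counts.sum())))
        positions = rng.integers(200, 3800, 20)
        strands = np.where(rng.random(20) < 0.5, "+", "-")
        anchors = [Anchor("chr1", int(p), s) for p, s in zip(positions, strands)]
        p1 = metagene_profile(track, AnchorSet(anchors, "TSS"), 100)
        p2 = metagene_profile(track, AnchorSet(anchors[::-1], "TSS"), 100)
        np.testing.assert_allclose(p1.mean_density, p2.mean_density)

    def test_genome_mirror_invariance(self, rng):
        """Reflecting coordinates and flipping strands leaves profiles unchanged."""
        length = 3000
        counts = rng.poisson(2, length).astype(float)
        track = normalize_by_genome_mean(DyadTrack({"chr1": counts},
                                                   int(counts.sum())))
        mirrored = normalize_by_genome_mean(
            DyadTrack({"chr1": counts[::-1].copy()}, int(counts.sum())))
        positions = rng.integers(200, length - 200, 15)
        fwd = [Anchor("chr1", int(p), "+") for p in positions]
        rev = [Anchor("chr1", length - 1 - int(p), "-") for p in positions]
        p1 = metagene_profile(track, AnchorSet(fwd, "TSS"), 150)
        p2 = metagene_profile(mirrored, AnchorSet(rev, "TSS"), 150)
        np.testing.assert_allclose(p1.mean_density, p2.mean_density)

    def test_requires_normalized_track_and_anchors(self):
        track = DyadTrack({"chr1": np.ones(100)}, 100)
        with pytest.raises(ValueError, match="normalized"):
            metagene_profile(track, AnchorSet([Anchor("chr1", 50, "+")], "TSS"), 10)
        with pytest.raises(ValueError, match="anchors"):
            metagene_profile(uniform_track(), AnchorSet([], "TSS"), 10)


class TestSubtractBackground:
    def test_identical_profiles_zero(self):
        prof = metagene_profile(uniform_track(),
                                AnchorSet([Anchor("chr1", 1000, "+")], "TSS"), 50)
        diff = subtract_background(prof, prof)
        np.testing.assert_allclose(diff.mean_density, 0.0)

    def test_mismatched_offsets_rejected(self):
        a = metagene_profile(uniform_track(),
                             AnchorSet([Anchor("chr1", 1000, "+")], "TSS"), 50)
        b = metagene_profile(uniform_track(),
                             AnchorSet([Anchor("chr1", 1000, "+")], "TSS"), 60)
        with pytest.raises(ValueError, match="offsets"):
            subtract_background(a, b)


class TestBoundaryEnrichmentQualitative:
    def test_internal_exceeds_first_exon_profile(self, full_truth):
        """Factor enrichment injected at internal exon 5' sites shows up as an
        internal-exon boundary peak absent from first-exon profiles."""
        from nucdyad import read_annotation, read_tags, tags_to_dyads
        tags = read_tags(full_truth.paths["factor_tags"])
        track = normalize_by_genome_mean(
            tags_to_dyads(tags, full_truth.d0_factor, full_truth.contig_lengths))
        ann = read_annotation(full_truth.paths["gtf"])
        internal = build_anchors(ann, "exon_start", exon_class="internal",
                                 tss_exclusion=250)
        first = build_anchors(ann, "exon_start", exon_class="first")
        p_int = metagene_profile(track, internal, 1000)
        p_first = metagene_profile(track, first, 1000)
        assert p_int.peak((-50, 50))[1] > p_first.peak((-50, 50))[1]
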