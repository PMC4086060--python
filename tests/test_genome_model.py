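"""Neighbor search, orientation classes, filters and anchor resolution."""

import numpy as np
import pytest

from vapro import genome_model as gm
from vapro.io_formats import Annotation, AnnotationSet, CoordinateRecord, ReferenceGroup


def ann(name, start, end, strand="+", chrom="chrI", exons=None):
    return Annotation(name, chrom, strand, start, end,
                      tuple(exons) if exons else ((start, end),))


def make_set(*annotations):
    return AnnotationSet(annotations)


THREE = (ann("left", 0, 500), ann("mid", 1000, 2000), ann("right", 2500, 3000))


class TestNeighbors:
    def test_plus_strand_geometry(self):
        idx = gm.build_index(make_set(*THREE))
        up, down = gm.find_neighbors(THREE[1], idx)
        assert up.annotation.name == "left" and not up.overlaps
        assert down.annotation.name == "right" and not down.overlaps

    def test_minus_strand_swaps_roles(self):
        annotations = make_set(ann("left", 0, 500), ann("mid", 1000, 2000, "-"),
                               ann("right", 2500, 3000))
        idx = gm.build_index(annotations)
        up, down = gm.find_neighbors(annotations["mid"], idx)
        assert up.annotation.name == "right"
        assert down.annotation.name == "left"

    def test_single_gene_has_no_neighbors(self):
        idx = gm.build_index(make_set(ann("only", 100, 200)))
        assert gm.find_neighbors(ann("only", 100, 200), idx) == (None, None)

    def test_overlapping_neighbor_is_flagged(self):
        annotations = make_set(ann("a", 0, 1100), ann("b", 1000, 2000))
        idx = gm.build_index(annotations)
        up, down = gm.find_neighbors(annotations["b"], idx)
        assert up.annotation.name == "a" and up.overlaps

    def test_random_layout_matches_linear_scan(self):
        rng = np.random.default_rng(42)
        genes = []
        pos = 0
        for i in range(100):
            pos += int(rng.integers(0, 300))
            length = int(rng.integers(100, 1200))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(ann(f"g{i:03d}", pos, pos + length, strand))
            pos += length
        aset = make_set(*genes)
        idx = gm.build_index(aset)
        for g in genes:
            lefts = [o for o in genes if o.name != g.name and o.start < g.start]
            rights = [o for o in genes if o.name != g.name and o.end > g.end]
            exp_left = max(lefts, key=lambda o: (o.end, o.start, o.name)) if lefts else None
            exp_right = min(rights, key=lambda o: (o.start, o.end, o.name)) if rights else None
            up, down = gm.find_neighbors(g, idx)
            got_left, got_right = (up, down) if g.strand == "+" else (down, up)
            assert (got_left.annotation if got_left else None) == exp_left
            assert (got_right.annotation if got_right else None) == exp_right


class TestOrientation:
    @pytest.mark.parametrize("up_strand,down_strand,exp_up,exp_down", [
        ("+", "+", "tandem", "tandem"),
        ("-", "-", "divergent", "convergent"),
        ("+", "-", "tandem", "convergent"),
        ("-", "+", "divergent", "tandem"),
    ])
    def test_plus_feature_labels(self, up_strand, down_strand, exp_up, exp_down):
        f = ann("f", 1000, 2000, "+")
        up = gm.NeighborInfo(ann("u", 0, 500, up_strand), overlaps=False)
        down = gm.NeighborInfo(ann("d", 2500, 3000, down_strand), overlaps=False)
        lab = gm.classify_orientation(f, up, down)
        assert (lab.upstream, lab.downstream) == (exp_up, exp_down)

    def test_missing_and_overlap_labels(self):
        f = ann("f", 1000, 2000, "+")
        over = gm.NeighborInfo(ann("u", 0, 1200, "+"), overlaps=True)
        lab = gm.classify_orientation(f, over, None)
        assert (lab.upstream, lab.downstream) == ("overlap", "none")

    def test_partition_of_fully_neighbored_group(self):
        # interior genes with non-overlapping neighbors fall in exactly one
        # of the four up/down combinations
        rng = np.random.default_rng(7)
        genes, pos = [], 0
        for i in range(60):
            pos += int(rng.integers(200, 500))
            genes.append(ann(f"g{i:02d}", pos, pos + int(rng.integers(300, 900)),
                             "+" if rng.random() < 0.5 else "-"))
            pos = genes[-1].end
        aset = make_set(*genes)
        idx = gm.build_index(aset)
        counts = {c: 0 for c in
                  [("tandem", "tandem"), ("tandem", "convergent"),
                   ("divergent", "tandem"), ("divergent", "convergent")]}
        full = 0
        for g in genes:
            up, down = gm.find_neighbors(g, idx)
            if up is None or down is None or up.overlaps or down.overlaps:
                continue
            full += 1
            lab = gm.classify_orientation(g, up, down)
            counts[(lab.upstream, lab.downstream)] += 1
        assert full == 58  # all but the two chromosome-end genes
        assert sum(counts.values()) == full

    def test_strand_flip_swaps_sides_and_divergent_convergent(self):
        # flipping every strand exchanges upstream/downstream roles and maps
        # divergent <-> convergent while tandem stays tandem
        swap = {"tandem": "tandem", "divergent": "convergent",
                "convergent": "divergent", "none": "none", "overlap": "overlap"}
        rng = np.random.default_rng(5)
        genes, pos = [], 0
        for i in range(30):
            pos += int(rng.integers(200, 500))
            genes.append(ann(f"g{i:02d}", pos, pos + int(rng.integers(300, 900)),
                             "+" if rng.random() < 0.5 else "-"))
            pos = genes[-1].end
        flipped = [ann(g.name, g.start, g.end, "-" if g.strand == "+" else "+")
                   for g in genes]
        idx = gm.build_index(make_set(*genes))
        idx_f = gm.build_index(make_set(*flipped))
        for g, gf in zip(genes, flipped):
            lab = gm.classify_orientation(g, *gm.find_neighbors(g, idx))
            lab_f = gm.classify_orientation(gf, *gm.find_neighbors(gf, idx_f))
            assert lab_f.upstream == swap[lab.downstream]
            assert lab_f.downstream == swap[lab.upstream]


class TestFilters:
    def group(self, *names):
        return ReferenceGroup("g", "annotation", list(names))

    def test_length_filter(self):
        aset = make_set(ann("s", 0, 500), ann("m", 1000, 2500), ann("l", 3000, 6000))
        out = gm.apply_filters(self.group("s", "m", "l"), aset, None,
                               gm.FilterSpec(min_length=1000))
        assert out.members == ["m", "l"]

    def test_chrom_exclude(self):
        aset = make_set(ann("a", 0, 500), ann("mito", 0, 500, chrom="chrM"))
        out = gm.apply_filters(self.group("a", "mito"), aset, None,
                               gm.FilterSpec(chrom_exclude=["chrM"]))
        assert out.members == ["a"]

    def test_exclude_overlapping_drops_flagged_and_nested(self):
        aset = make_set(ann("a", 0, 1100), ann("b", 1000, 3000),
                        ann("inner", 1500, 1600), ann("c", 4000, 5000))
        idx = gm.build_index(aset)
        out = gm.apply_filters(self.group("a", "b", "c"), aset, idx,
                               gm.FilterSpec(exclude_overlapping=True))
        # a and b overlap each other; b also contains 'inner'; c is clean
        assert out.members == ["c"]

    def test_all_removed_is_an_error(self):
        aset = make_set(ann("s", 0, 100))
        with pytest.raises(ValueError, match="all members"):
            gm.apply_filters(self.group("s"), aset, None,
                             gm.FilterSpec(min_length=1000))

    def test_absent_names_dropped_not_fatal(self):
        aset = make_set(ann("a", 0, 500))
        out = gm.apply_filters(self.group("a", "phantom"), aset, None, gm.FilterSpec())
        assert out.members == ["a"]


class TestResolveAnchors:
    def neighbors(self):
        aset = make_set(*THREE)
        idx = gm.build_index(aset)
        return aset, gm.find_neighbors(aset["mid"], idx)

    def test_two_and_one_point(self):
        aset, (up, down) = self.neighbors()
        a2 = gm.resolve_anchors(aset["mid"], up, down, 2)
        assert a2.anchors == (1000, 2000)
        a1 = gm.resolve_anchors(aset["mid"], up, down, 1)
        assert a1.anchors == (1000,)

    def test_minus_strand_tss_is_genomic_end(self):
        f = ann("m", 1000, 2000, "-")
        a1 = gm.resolve_anchors(f, None, None, 1)
        assert a1.anchors == (2000,)

    def test_four_and_six_points(self):
        aset, (up, down) = self.neighbors()
        a4 = gm.resolve_anchors(aset["mid"], up, down, 4)
        assert a4.anchors == (500, 1000, 2000, 2500)
        a6 = gm.resolve_anchors(aset["mid"], up, down, 6)
        assert a6.anchors == (0, 500, 1000, 2000, 2500, 3000)

    def test_minus_strand_mirrors_plus(self):
        L = 3000
        mirrored = make_set(ann("right", 0, 500), ann("mid", 1000, 2000, "-"),
                            ann("left", 2500, 3000))
        idx = gm.build_index(mirrored)
        up, down = gm.find_neighbors(mirrored["mid"], idx)
        a6 = gm.resolve_anchors(mirrored["mid"], up, down, 6)
        plus = (0, 500, 1000, 2000, 2500, 3000)
        assert a6.anchors == tuple(sorted(L - np.array(plus)))

    def test_missing_neighbor_collapses_with_extent(self):
        f = ann("solo", 5000, 6000)
        a4 = gm.resolve_anchors(f, None, None, 4, intergenic_extent=500)
        assert a4.anchors == (4500, 5000, 6000, 6500)
        near_edge = ann("edge", 200, 900)
        a4 = gm.resolve_anchors(near_edge, None, None, 4, intergenic_extent=500)
        assert a4.anchors == (0, 200, 900, 1400)

    def test_overlapping_neighbor_gives_zero_length_intergenic(self):
        aset = make_set(ann("a", 0, 1100), ann("b", 1000, 2000))
        idx = gm.build_index(aset)
        up, down = gm.find_neighbors(aset["b"], idx)
        a4 = gm.resolve_anchors(aset["b"], up, down, 4, intergenic_extent=500)
        assert a4.anchors == (1000, 1000, 2000, 2500)


class TestCoordinateAnchors:
    def test_two_points(self):
        a = gm.resolve_coordinate_anchor(CoordinateRecord("chr1", 100, 200, "-"), 2)
        assert a.anchors == (100, 200) and a.strand == "-"

    def test_midpoint_and_single_base_summit(self):
        assert gm.resolve_coordinate_anchor(
            CoordinateRecord("chr1", 100, 200), 1).anchors == (150,)
        assert gm.resolve_coordinate_anchor(
            CoordinateRecord("chr1", 100, 101), 1).anchors == (100,)


class TestExonAnchors:
    def test_three_exons_plus(self):
        f = ann("e3", 0, 500, exons=[(0, 100), (200, 300), (400, 500)])
        a = gm.select_exon_anchors(f)
        assert a.anchors == (0, 100, 200, 300, 400, 500)

    def test_minus_strand_first_exon_is_genomically_last(self):
        f = ann("e3m", 0, 500, "-", exons=[(0, 100), (200, 300), (400, 500)])
        a = gm.select_exon_anchors(f)
        # anchors stay in genomic order; transcription order is handled later
        assert a.anchors == (0, 100, 200, 300, 400, 500) and a.strand == "-"

    @pytest.mark.parametrize("k,expected_middle", [(3, 2), (4, 2), (5, 3), (6, 3), (7, 4)])
    def test_middle_exon_is_ceil_k_over_2(self, k, expected_middle):
        exons = [(i * 200, i * 200 + 100) for i in range(k)]
        f = ann("ek", 0, exons[-1][1], exons=exons)
        a = gm.select_exon_anchors(f)
        mid = exons[expected_middle - 1]
        assert mid[0] in a.anchors and mid[1] in a.anchors

    def test_too_few_exons_excluded(self):
        assert gm.select_exon_anchors(ann("e1", 0, 500)) is None
        f2 = ann("e2", 0, 500, exons=[(0, 100), (300, 500)])
        assert gm.select_exon_anchors(f2) is None
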