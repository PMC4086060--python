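"""Neighbor lookup, orientation classification, filters and anchor resolution.

A profiled feature is aligned at 1-6 reference points (anchors).  With one
or two points the anchors come from the feature itself (TSS, or start and
end); with four or six points the proximal and distal boundaries of the
nearest upstream and downstream annotations are added so the flanking
intergenic regions and flanking annotations occupy their own blocks.

Orientation of the flanking annotations (tandem = tail-head, divergent =
head-head, convergent = tail-tail) is classified strand-relatively and is
the basis for subgrouping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_formats import Annotation, AnnotationSet, CoordinateRecord, ReferenceGroup

logger = logging.getLogger(__name__)

N_REFPOINTS_ALLOWED = (1, 2, 4, 6)


@dataclass(frozen=True)
class AnchorSet:
    """Ordered genomic reference points for one feature.

    Anchors are emitted in ascending genomic order regardless of strand;
    the strand determines how blocks between them are traversed (5'->3').
    Adjacent anchors may coincide (zero-length block) when an overlapping
    or missing neighbor collapses an intergenic region.
    """

    name: str
    chrom: str
    strand: str
    anchors: tuple[int, ...]

    def __post_init__(self):
        if len(self.anchors) not in N_REFPOINTS_ALLOWED:
            raise ValueError(f"{self.name}: {len(self.anchors)} anchors not in {N_REFPOINTS_ALLOWED}")
        if any(b < a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError(f"{self.name}: anchors must be non-decreasing")


@dataclass(frozen=True)
class NeighborInfo:
    annotation: Annotation
    overlaps: bool


@dataclass(frozen=True)
class OrientationLabel:
    """Strand-relative orientation of the two flanking annotations."""

    upstream: str     # tandem | divergent | none | overlap
    downstream: str   # tandem | convergent | none | overlap


@dataclass
class FilterSpec:
    """Selection/exclusion filters applied to a reference group."""

    min_length: int | None = None
    max_length: int | None = None
    chrom_include: list[str] | None = None
    chrom_exclude: list[str] | None = None
    exclude_overlapping: bool = False
    name_exclude: list[str] | None = None

    def __post_init__(self):
        if (self.min_length is not None and self.max_length is not None
                and self.min_length > self.max_length):
            raise ValueError("min_length must be <= max_length")


class NeighborIndex:
    """Per-chromosome sorted annotation lists for neighbor/overlap queries."""

    def __init__(self, annotations: AnnotationSet):
        if len(annotations) == 0:
            raise ValueError("cannot index an empty annotation set")
        self._by_chrom = annotations.by_chrom()
        # parallel sorted arrays per chromosome
        self._starts = {c: [a.start for a in lst] for c, lst in self._by_chrom.items()}

    def _candidates(self, chrom: str) -> list[Annotation]:
        return self._by_chrom.get(chrom, [])

    def left_neighbor(self, feature: Annotation) -> NeighborInfo | None:
        """Annotation left of the feature whose right boundary is nearest.

        Candidates start strictly before the feature; the one with the
        largest end wins (ties broken by start then name, for determinism).
        The overlap flag is set when it reaches into the feature.
        """
        best = None
        for a in self._candidates(feature.chrom):
            if a.name == feature.name:
                continue
            if a.start >= feature.start:
                break  # list sorted by start; no further candidates
            if best is None or (a.end, a.start, a.name) > (best.end, best.start, best.name):
                best = a
        if best is None:
            return None
        return NeighborInfo(best, overlaps=best.end > feature.start)

    def right_neighbor(self, feature: Annotation) -> NeighborInfo | None:
        """Mirror of :meth:`left_neighbor` on the right side (smallest start
        among annotations ending strictly after the feature)."""
        best = None
        for a in self._candidates(feature.chrom):
            if a.name == feature.name or a.end <= feature.end:
                continue
            if best is None or (a.start, a.end, a.name) < (best.start, best.end, best.name):
                best = a
            if a.start >= feature.end:
                break  # sorted by start; later candidates cannot be nearer
        if best is None:
            return None
        return NeighborInfo(best, overlaps=best.start < feature.end)

    def has_nested(self, feature: Annotation) -> bool:
        """True when some other annotation lies fully within the feature."""
        for a in self._candidates(feature.chrom):
            if a.name == feature.name:
                continue
            if a.start >= feature.end:
                break
            if a.start >= feature.start and a.end <= feature.end:
                return True
        return False


def build_index(annotations: AnnotationSet) -> NeighborIndex:
    """Build the per-chromosome neighbor/overlap index."""
    return NeighborIndex(annotations)


def find_neighbors(feature: Annotation, index: NeighborIndex
                   ) -> tuple[NeighborInfo | None, NeighborInfo | None]:
    """Nearest annotations on the feature's 5' and 3' sides.

    Upstream/downstream are strand-relative: for a minus-strand feature the
    upstream neighbor lies to its genomic right.  A neighbor that overlaps
    the feature is still reported, flagged ``overlaps``.
    """
    left = index.left_neighbor(feature)
    right = index.right_neighbor(feature)
    if feature.strand == "+":
        return left, right
    return right, left


def classify_orientation(feature: Annotation,
                         upstream: NeighborInfo | None,
                         downstream: NeighborInfo | None) -> OrientationLabel:
    """Tandem / divergent / convergent labels for the flanking annotations.

    Upstream neighbor on the same strand reads into the feature tail-first
    (tandem); on the opposite strand the two 5' ends face each other
    (divergent).  Downstream: same strand is tandem, opposite strand puts
    the two 3' ends face to face (convergent).
    """
    def up_label(n: NeighborInfo | None) -> str:
        if n is None:
            return "none"
        if n.overlaps:
            return "overlap"
        return "tandem" if n.annotation.strand == feature.strand else "divergent"

    def down_label(n: NeighborInfo | None) -> str:
        if n is None:
            return "none"
        if n.overlaps:
            return "overlap"
        return "tandem" if n.annotation.strand == feature.strand else "convergent"

    return OrientationLabel(up_label(upstream), down_label(downstream))


def apply_filters(group: ReferenceGroup, annotations: AnnotationSet,
                  index: NeighborIndex | None, filters: FilterSpec) -> ReferenceGroup:
    """Return the group with members failing any filter removed.

    ``exclude_overlapping`` drops features with an overlapping neighbor on
    either side or another annotation nested inside them.  Names absent
    from the annotation set are dropped here with a logged count.
    """
    if group.mode == "coordinate":
        raise ValueError("filters apply to annotation/exon mode groups only")
    kept: list[str] = []
    absent = 0
    excl = set(filters.name_exclude or ())
    for name in group.members:
        if name not in annotations:
            absent += 1
            continue
        a = annotations[name]
        if name in excl:
            continue
        if filters.min_length is not None and a.length < filters.min_length:
            continue
        if filters.max_length is not None and a.length > filters.max_length:
            continue
        if filters.chrom_include is not None and a.chrom not in filters.chrom_include:
            continue
        if filters.chrom_exclude is not None and a.chrom in filters.chrom_exclude:
            continue
        if filters.exclude_overlapping:
            if index is None:
                raise ValueError("exclude_overlapping requires a neighbor index")
            up, down = find_neighbors(a, index)
            if (up is not None and up.overlaps) or (down is not None and down.overlaps):
                continue
            if index.has_nested(a):
                continue
        kept.append(name)
    if absent:
        logger.warning("group %s: %d names absent from the annotation set",
                       group.label, absent)
    logger.info("group %s: %d of %d members pass filters",
                group.label, len(kept), len(group.members))
    if not kept:
        raise ValueError(f"group {group.label!r}: all members removed by filters")
    return ReferenceGroup(label=group.label, mode=group.mode, members=kept)


# ---------------------------------------------------------------------------
# anchor resolution
# ---------------------------------------------------------------------------

def resolve_anchors(feature: Annotation,
                    upstream: NeighborInfo | None,
                    downstream: NeighborInfo | None,
                    n_refpoints: int,
                    *,
                    intergenic_extent: float | None = None,
                    annotation_extent: float | None = None,
                    chrom_size: int | None = None) -> AnchorSet:
    """Resolve the anchor positions for one feature in annotation mode.

    n=1: the TSS.  n=2: start and end.  n=4: plus the proximal boundaries
    of the two neighbors.  n=6: plus their distal boundaries.  An
    overlapping neighbor's proximal boundary is clamped to the feature
    boundary (zero-length intergenic block).  A missing neighbor collapses
    the corresponding anchors to the chromosome boundary, truncated at the
    block's maximum represented extent (``intergenic_extent`` /
    ``annotation_extent``, bp) so the feature still contributes to every
    other block.
    """
    if n_refpoints not in N_REFPOINTS_ALLOWED:
        raise ValueError(f"n_refpoints must be one of {N_REFPOINTS_ALLOWED}")
    if n_refpoints == 1:
        return AnchorSet(feature.name, feature.chrom, feature.strand, (feature.tss,))
    if n_refpoints == 2:
        return AnchorSet(feature.name, feature.chrom, feature.strand,
                         (feature.start, feature.end))

    lim_left = 0.0
    lim_right = float(chrom_size) if chrom_size is not None else math.inf
    ig = math.inf if intergenic_extent is None else float(intergenic_extent)
    ann = math.inf if annotation_extent is None else float(annotation_extent)

    # genomic-left side
    left = upstream if feature.strand == "+" else downstream
    if left is not None:
        l_prox = min(left.annotation.end, feature.start)
        l_dist = min(left.annotation.start, l_prox)
    else:
        l_prox = max(lim_left, feature.start - ig)
        if not math.isfinite(l_prox):
            l_prox = feature.start
        l_dist = max(lim_left, l_prox - ann)
        if not math.isfinite(l_dist):
            l_dist = l_prox
    # genomic-right side
    right = downstream if feature.strand == "+" else upstream
    if right is not None:
        r_prox = max(right.annotation.start, feature.end)
        r_dist = max(right.annotation.end, r_prox)
    else:
        r_prox = min(lim_right, feature.end + ig)
        if not math.isfinite(r_prox):
            r_prox = feature.end
        r_dist = min(lim_right, r_prox + ann)
        if not math.isfinite(r_dist):
            r_dist = r_prox

    if (left is None or right is None):
        logger.info("%s: missing neighbor; anchors collapsed to boundary/extent",
                    feature.name)
    if n_refpoints == 4:
        anchors = (int(l_prox), feature.start, feature.end, int(r_prox))
    else:
        anchors = (int(l_dist), int(l_prox), feature.start, feature.end,
                   int(r_prox), int(r_dist))
    return AnchorSet(feature.name, feature.chrom, feature.strand, anchors)


def resolve_coordinate_anchor(record: CoordinateRecord, n_refpoints: int) -> AnchorSet:
    """Anchors for a coordinate-mode record: the interval boundaries (n=2)
    or the interval midpoint, floor((start+end)/2) (n=1; exact for 1 bp
    summit records)."""
    if n_refpoints not in (1, 2):
        raise ValueError("coordinate mode supports 1 or 2 reference points")
    strand = record.strand if record.strand in ("+", "-") else "+"
    name = record.name or f"{record.chrom}:{record.start}-{record.end}"
    if n_refpoints == 2:
        return AnchorSet(name, record.chrom, strand, (record.start, record.end))
    mid = (record.start + record.end) // 2
    return AnchorSet(name, record.chrom, strand, (mid,))


def select_exon_anchors(feature: Annotation) -> AnchorSet | None:
    """Six anchors at the boundaries of the first, middle and last exons.

    Exons are counted 5'->3' in the transcribed direction; of k exons the
    middle one is exon ceil(k/2).  Features with fewer than three exons are
    excluded from exon mode (returns None, logged).
    """
    k = len(feature.exons)
    if k < 3:
        logger.info("%s: %d exon(s), excluded from exon mode", feature.name, k)
        return None
    tx = feature.exons_transcribed()
    first, last = tx[0], tx[-1]
    middle = tx[math.ceil(k / 2) - 1]
    bounds = sorted([first[0], first[1], middle[0], middle[1], last[0], last[1]])
    return AnchorSet(feature.name, feature.chrom, feature.strand, tuple(bounds))
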