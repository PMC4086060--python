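"""Window layout, signal extraction, per-feature profiles and aggregation.

Two binning methods are supported.  The *absolute* method tiles each block
with windows of constant size (bp); features shorter than the represented
extent realize only some layout windows, according to the block's alignment
(left, right, or split around the middle).  The *relative* method divides
each block into a constant number of equal-width windows, so window size
scales with feature length.

Layouts are expressed in the transcribed (5'->3') direction: block 1 is the
5' flank, aligned right against the first anchor, and the last block is the
3' flank, aligned left.  Minus-strand features are handled by mapping
transcribed offsets onto the genome right-to-left, which makes every
operation mirror-symmetric by construction.

The within-window estimator is the coverage-weighted mean of the signal
intervals over the bases each window covers; bases without data are
excluded from the weighting, and a window with no covered bases is missing
(tracked by the proportion profile rather than zero-filled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .genome_model import AnchorSet
from .io_formats import SignalTrack

ALIGNMENTS = ("left", "right", "split")
STATISTICS = ("mean", "median", "min", "max")

Window = "tuple[float, float] | None"


# ---------------------------------------------------------------------------
# layout types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One block of the layout.

    ``window_count`` is the number of layout windows (absolute) or bins
    (relative).  ``window_size`` (bp) applies to the absolute method only.
    ``extent`` fixes the genomic span of flank blocks; for absolute flanks
    it defaults to window_count * window_size.
    """

    window_count: int
    window_size: float | None = None
    alignment: str = "split"
    split_fraction: float = 0.5
    extent: float | None = None

    def __post_init__(self):
        if self.window_count < 0:
            raise ValueError("window_count must be >= 0")
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"alignment must be one of {ALIGNMENTS}")
        if self.window_size is not None and self.window_size < 1:
            raise ValueError("window_size must be >= 1 bp")
        if not (0.0 <= self.split_fraction <= 1.0):
            raise ValueError("split_fraction must be in [0, 1]")


@dataclass(frozen=True)
class BlockLayout:
    """Ordered blocks (transcribed direction); n anchors give n+1 blocks."""

    method: str                     # 'absolute' | 'relative'
    blocks: tuple[BlockSpec, ...]
    smoothing: int = 1              # sliding-window span applied to aggregates

    def __post_init__(self):
        if self.method not in ("absolute", "relative"):
            raise ValueError("method must be 'absolute' or 'relative'")
        if len(self.blocks) < 2:
            raise ValueError("a layout needs at least two blocks (one anchor)")
        if self.blocks[0].alignment != "right" or self.blocks[-1].alignment != "left":
            raise ValueError("first block must be right-aligned and last left-aligned")
        if self.method == "absolute" and any(b.window_size is None for b in self.blocks):
            raise ValueError("absolute method requires window_size on every block")
        if self.smoothing < 1:
            raise ValueError("smoothing span must be >= 1")

    @property
    def n_anchors(self) -> int:
        return len(self.blocks) - 1

    @property
    def total_windows(self) -> int:
        return sum(b.window_count for b in self.blocks)

    @property
    def block_of_window(self) -> np.ndarray:
        """0-based block id of each layout window."""
        return np.repeat(np.arange(len(self.blocks)),
                         [b.window_count for b in self.blocks])

    def block_slices(self) -> list[slice]:
        out, off = [], 0
        for b in self.blocks:
            out.append(slice(off, off + b.window_count))
            off += b.window_count
        return out

    def flank_extent(self, which: int) -> float:
        """Represented genomic span of the first (0) or last (-1) block."""
        b = self.blocks[which]
        if b.extent is not None:
            return b.extent
        if self.method == "absolute":
            return b.window_count * b.window_size
        raise ValueError("relative-method flank blocks need an explicit extent")

    def signature(self) -> tuple:
        return (self.method, self.blocks, self.smoothing)


def make_layout(method: str,
                window_counts: Sequence[int],
                window_size: float | None = None,
                alignments: Sequence[str] | None = None,
                split_fraction: float = 0.5,
                flank_extent: float | None = None,
                smoothing: int = 1) -> BlockLayout:
    """Build a layout with the conventional alignments.

    The first block is right-aligned, the last left-aligned; interior
    blocks default to split.  ``flank_extent`` (bp) fixes the span of the
    two flank blocks (required for the relative method).
    """
    n = len(window_counts)
    if alignments is None:
        alignments = ["right"] + ["split"] * (n - 2) + ["left"]
    if len(alignments) != n:
        raise ValueError("alignments must match window_counts in length")
    blocks = []
    for i, (wc, al) in enumerate(zip(window_counts, alignments)):
        ext = flank_extent if i in (0, n - 1) else None
        blocks.append(BlockSpec(window_count=int(wc),
                                window_size=window_size if method == "absolute" else None,
                                alignment=al, split_fraction=split_fraction,
                                extent=ext))
    return BlockLayout(method=method, blocks=tuple(blocks), smoothing=smoothing)


# ---------------------------------------------------------------------------
# per-block window placement
# ---------------------------------------------------------------------------

def relative_layout(block_length: float, n_bins: int) -> list:
    """Equal-width bins over a block; width = block_length / n_bins.

    Fractional widths are permitted (extraction weights by base overlap).
    A non-positive block length makes every bin unrealized (None).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if block_length <= 0:
        return [None] * n_bins
    w = block_length / n_bins
    return [(i * w, min((i + 1) * w, block_length)) for i in range(n_bins)]


def relative_bin_index(offset: float, block_length: float, n_bins: int) -> int:
    """1-based bin holding a position ``offset`` bp from the block 5' edge.

    index = ceil(offset * n_bins / block_length); offsets are in
    (0, block_length].
    """
    if not (0 < offset <= block_length):
        raise ValueError(f"offset {offset} outside (0, {block_length}]")
    return int(math.ceil(offset * n_bins / block_length))


def _ceil_div(a: float, b: float) -> int:
    return int(math.ceil(round(a / b, 9)))


def absolute_layout(block_length: float, window_size: float, window_count: int,
                    alignment: str = "split", split_fraction: float = 0.5) -> list:
    """Map constant-size feature windows onto the block's layout positions.

    The feature side of the block is tiled 5'->3' with Wf =
    ceil(block_length / window_size) windows (the last possibly partial).
    With Wl = window_count layout positions and c = min(Wf, Wl):

    - left:  feature windows 1..c occupy layout 1..c;
    - right: the last c feature windows occupy the layout tail;
    - split: the feature's first ceil(c * split_fraction) windows occupy
      the layout head and its last c - ceil(c * split_fraction) occupy the
      layout tail (middle layout positions stay unrealized when the
      feature is short; the feature's own middle is ignored when it is
      long).  With the default fraction 0.5 and odd c the extra window
      goes to the 5' side.

    Returns one entry per layout position: an (offset_start, offset_end)
    pair in bp from the block's 5' edge, or None.
    """
    if alignment not in ALIGNMENTS:
        raise ValueError(f"alignment must be one of {ALIGNMENTS}")
    if window_count == 0:
        return []
    out: list = [None] * window_count
    if block_length <= 0:
        return out
    wf = _ceil_div(block_length, window_size)
    fw = [(k * window_size, min((k + 1) * window_size, block_length))
          for k in range(wf)]
    c = min(wf, window_count)
    if alignment == "left":
        for k in range(c):
            out[k] = fw[k]
    elif alignment == "right":
        for j in range(c):
            out[window_count - c + j] = fw[wf - c + j]
    else:
        l5 = int(math.ceil(round(c * split_fraction, 9)))
        l3 = c - l5
        for k in range(l5):
            out[k] = fw[k]
        for j in range(l3):
            out[window_count - l3 + j] = fw[wf - l3 + j]
    return out


# ---------------------------------------------------------------------------
# feature geometry
# ---------------------------------------------------------------------------

def block_bounds(anchors: AnchorSet, layout: BlockLayout,
                 chrom_size: int | None = None) -> list:
    """Genomic (start, end) of every block, in transcribed order.

    Flank blocks extend outward by the layout's flank extent, truncated at
    the chromosome limits (position 0 and, when known, ``chrom_size``).
    """
    a = anchors.anchors
    if len(a) != layout.n_anchors:
        raise ValueError(f"{anchors.name}: {len(a)} anchors but layout expects "
                         f"{layout.n_anchors}")
    lim_l, lim_r = 0.0, float(chrom_size) if chrom_size is not None else math.inf
    ext5, ext3 = layout.flank_extent(0), layout.flank_extent(-1)
    bounds = []
    if anchors.strand == "+":
        bounds.append((max(lim_l, a[0] - ext5), float(a[0])))
        for i in range(len(a) - 1):
            bounds.append((float(a[i]), float(a[i + 1])))
        bounds.append((float(a[-1]), min(lim_r, a[-1] + ext3)))
    else:
        bounds.append((float(a[-1]), min(lim_r, a[-1] + ext5)))
        for i in range(len(a) - 1, 0, -1):
            bounds.append((float(a[i - 1]), float(a[i])))
        bounds.append((max(lim_l, a[0] - ext3), float(a[0])))
    return bounds


def feature_windows(anchors: AnchorSet, layout: BlockLayout,
                    chrom_size: int | None = None) -> list:
    """Genomic sub-interval (or None) of every layout window for a feature.

    Windows are listed in transcribed order.  Offsets within each block are
    measured from the block's 5' edge, which for minus-strand features is
    its genomic right edge.
    """
    windows: list = []
    for (gs, ge), spec in zip(block_bounds(anchors, layout, chrom_size),
                              layout.blocks):
        length = ge - gs
        if layout.method == "relative":
            offs = relative_layout(length, spec.window_count) \
                if spec.window_count else []
        else:
            offs = absolute_layout(length, spec.window_size, spec.window_count,
                                   spec.alignment, spec.split_fraction)
        for o in offs:
            if o is None:
                windows.append(None)
            elif anchors.strand == "+":
                windows.append((gs + o[0], gs + o[1]))
            else:
                windows.append((ge - o[1], ge - o[0]))
    return windows


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_window_values(track: SignalTrack, chrom: str, windows: Sequence,
                          strand: str = "+", uncovered_zero: bool = False
                          ) -> np.ndarray:
    """Coverage-weighted mean of the signal over each genomic window.

    ``windows`` are genomic (start, end) pairs or None, listed in genomic
    order; for minus-strand features the output is reversed so profiles
    read 5'->3'.  Bases without data are excluded from the weighting
    (or treated as signal 0 under ``uncovered_zero``); a window with no
    covered bases is NaN.
    """
    starts, ends, values = track.arrays(chrom)
    out = np.full(len(windows), np.nan)
    for i, w in enumerate(windows):
        if w is None:
            continue
        a, b = w
        if b <= a:
            continue
        j0 = int(np.searchsorted(ends, a, side="right"))
        j1 = int(np.searchsorted(starts, b, side="left"))
        if j1 > j0:
            ov = np.minimum(ends[j0:j1], b) - np.maximum(starts[j0:j1], a)
            ov = np.clip(ov, 0.0, None)
            den = float(ov.sum())
            num = float(np.dot(values[j0:j1], ov))
        else:
            den, num = 0.0, 0.0
        if uncovered_zero:
            out[i] = num / (b - a)
        elif den > 0:
            out[i] = num / den
    if strand == "-":
        out = out[::-1].copy()
    return out


@dataclass
class FeatureProfile:
    """Per-window values (NaN = missing) for one feature, 5'->3'."""

    name: str
    values: np.ndarray
    length: int = 0

    @property
    def contributes(self) -> np.ndarray:
        return ~np.isnan(self.values)


def build_feature_profile(anchors: AnchorSet, layout: BlockLayout,
                          track: SignalTrack, chrom_size: int | None = None,
                          uncovered_zero: bool = False,
                          length: int | None = None) -> FeatureProfile:
    """Lay out a feature's windows and extract its signal profile."""
    wins = feature_windows(anchors, layout, chrom_size)
    # feature_windows is already in transcribed order; hand the extraction
    # genomic-ordered windows so its strand flip restores transcribed order.
    genomic = wins[::-1] if anchors.strand == "-" else wins
    vals = extract_window_values(track, anchors.chrom, genomic,
                                 anchors.strand, uncovered_zero)
    if length is None:
        length = (max(anchors.anchors) - min(anchors.anchors)) or 1
    return FeatureProfile(anchors.name, vals, length=length)


@dataclass
class ProfileMatrix:
    """Per-feature per-window values for one reference group.

    ``group_size`` is the aggregation denominator: the number of group
    members after filtering and resolution, including members that
    contribute no data anywhere (all-NaN rows are retained here and
    excluded window-wise from aggregation).
    """

    names: list
    lengths: list
    values: np.ndarray            # (n_features, n_windows) with NaN missing
    layout: BlockLayout
    group_size: int | None = None

    def __post_init__(self):
        if self.group_size is None:
            self.group_size = len(self.names)

    def select(self, keep: Sequence[int]) -> "ProfileMatrix":
        keep = list(keep)
        return ProfileMatrix([self.names[i] for i in keep],
                             [self.lengths[i] for i in keep],
                             self.values[keep], self.layout,
                             group_size=len(keep))


@dataclass
class AggregateProfile:
    """Per-window statistic with dispersion and contribution tracking."""

    statistic: str
    values: np.ndarray            # statistic per window (possibly smoothed)
    sd: np.ndarray
    sem: np.ndarray
    n_contrib: np.ndarray
    proportion: np.ndarray
    layout: BlockLayout


def aggregate_profiles(matrix: ProfileMatrix, statistic: str = "mean"
                       ) -> AggregateProfile:
    """Aggregate a profile matrix window by window.

    The statistic is taken over contributing (non-missing) features only;
    sd is the sample standard deviation (n-1 denominator) and sem =
    sd / sqrt(n), both missing below two contributors.  The proportion is
    n_contrib divided by the full group size, so members whose windows are
    unrealized or uncovered pull the proportion below one.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    v = matrix.values
    if v.size == 0:
        raise ValueError("empty profile matrix")
    n = np.sum(~np.isnan(v), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        fn = {"mean": np.nanmean, "median": np.nanmedian,
              "min": np.nanmin, "max": np.nanmax}[statistic]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat = fn(v, axis=0)
            sd = np.nanstd(v, axis=0, ddof=1)
    stat = np.where(n >= 1, stat, np.nan)
    sd = np.where(n >= 2, sd, np.nan)
    with np.errstate(invalid="ignore"):
        sem = sd / np.sqrt(n)
    group = float(matrix.group_size)
    prop = n / group if group > 0 else np.zeros_like(n)
    return AggregateProfile(statistic=statistic, values=stat, sd=sd, sem=sem,
                            n_contrib=n.astype(int), proportion=prop,
                            layout=matrix.layout)


def smooth_profile(values: np.ndarray, span: int,
                   layout: BlockLayout | None = None) -> np.ndarray:
    """Sliding mean of ``span`` consecutive windows, centered.

    For even spans the window is left-biased: floor(span/2) positions to
    the left and span-1-floor(span/2) to the right.  Edges average over
    whatever positions are in range; missing inputs are excluded from each
    mean.  When a layout is given, smoothing is applied within each block
    independently (blocks are genomically discontinuous).
    """
    if span < 1:
        raise ValueError("smoothing span must be >= 1")
    values = np.asarray(values, dtype=float)
    if span == 1:
        return values.copy()

    def smooth_block(x: np.ndarray) -> np.ndarray:
        out = np.full_like(x, np.nan)
        left = span // 2
        for i in range(len(x)):
            lo = max(0, i - left)
            hi = min(len(x), i - left + span)
            seg = x[lo:hi]
            good = ~np.isnan(seg)
            if good.any():
                out[i] = seg[good].mean()
        return out

    if layout is None:
        return smooth_block(values)
    out = np.empty_like(values)
    for sl in layout.block_slices():
        out[sl] = smooth_block(values[sl])
    return out


def smooth_aggregate(profile: AggregateProfile) -> AggregateProfile:
    """Apply the layout's smoothing span to the aggregate statistic only."""
    span = profile.layout.smoothing
    if span == 1:
        return profile
    return replace(profile,
                   values=smooth_profile(profile.values, span, profile.layout))
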