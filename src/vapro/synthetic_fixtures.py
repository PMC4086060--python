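"""Deterministic toy genomes with closed-form expected profiles.

Generates annotation tables with controlled neighbor orientations, lengths
and exon counts, plus signal tracks realizing simple analytic patterns:

- ``uniform(c)``       constant signal everywhere;
- ``tss_peak(h, w)``   triangular peak of height h and half-width w bp
                       centered on each feature's TSS;
- ``body_ramp(s)``     signal increasing linearly with distance from the
                       TSS inside the feature body (slope s per bp), zero
                       elsewhere — the shape of co-transcriptional marks
                       that accumulate toward the 3' end;
- ``exon_enriched(f)`` baseline 1 everywhere, f over exons.

Each pattern is defined per base as a function of position, so noise-free
fixtures admit exact expected window values (``expected_profile``), which
serve as analytic oracles for the extraction and aggregation pipeline.
The same values are emitted as BedGraph and as WIG so format invariance
can be checked bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import AnchorSet
from .io_formats import Annotation, AnnotationSet
from .profile_engine import BlockLayout, feature_windows

PATTERNS = ("uniform", "tss_peak", "body_ramp", "exon_enriched")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture; same spec + seed = same bytes."""

    seed: int = 0
    n_genes: int = 8
    gene_length: tuple[int, int] = (800, 2400)   # uniform range, bp (lo, hi)
    gap: tuple[int, int] = (400, 900)            # intergenic gaps, bp
    strand_rule: str = "alternating"             # alternating|plus|minus|random
    strand_p: float = 0.5                        # P(+) under 'random'
    exon_count: int = 1                          # exons per gene
    pattern: tuple = ("uniform", 1.0)
    noise_sd: float = 0.0                        # i.i.d. Gaussian per interval
    missing_fraction: float = 0.0                # fraction of genes with a gap
    overlap_fraction: float = 0.0                # fraction of genes paired overlapping
    chrom: str = "chrI"
    n_chroms: int = 1
    margin: int = 1500                           # bp clear of the first/last gene

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _strand_for(spec: FixtureSpec, i: int, rng) -> str:
    if spec.strand_rule == "alternating":
        return "+" if i % 2 == 0 else "-"
    if spec.strand_rule == "plus":
        return "+"
    if spec.strand_rule == "minus":
        return "-"
    if spec.strand_rule == "random":
        return "+" if rng.random() < spec.strand_p else "-"
    raise ValueError(f"unknown strand rule {spec.strand_rule!r}")


def _make_exons(start: int, end: int, k: int) -> tuple:
    """k exons separated by introns, tiled evenly over [start, end)."""
    if k <= 1:
        return ((start, end),)
    length = end - start
    # 2k-1 alternating exon/intron segments; exons get the rounding slack
    seg = length // (2 * k - 1)
    exons = []
    pos = start
    for j in range(k):
        e_start = pos
        e_end = pos + seg if j < k - 1 else end
        exons.append((e_start, e_end))
        pos = e_end + seg
    return tuple(exons)


def make_annotations(spec: FixtureSpec, out_dir) -> tuple[Path, pd.DataFrame]:
    """Write the annotation table; return its path and a ground-truth table.

    The sidecar table records, per gene, its true length, neighbors and
    orientation labels (computed by direct linear inspection of the placed
    genes, independently of the package's neighbor index).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = spec.rng()
    genes: list[Annotation] = []
    n_pairs = int(round(spec.overlap_fraction * spec.n_genes))
    overlap_tail = set()
    for c in range(spec.n_chroms):
        chrom = spec.chrom if spec.n_chroms == 1 else f"{spec.chrom}{c + 1}"
        pos = spec.margin
        for i in range(spec.n_genes):
            glen = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            strand = _strand_for(spec, i, rng)
            name = f"gene{c}_{i:03d}"
            start = pos
            if c == 0 and n_pairs > 0 and i % 2 == 1 and (i - 1) // 2 < n_pairs:
                # slide this gene back into its predecessor by ~30% of its length
                prev = genes[-1]
                shift = min(prev.length, glen) // 3 or 1
                start = prev.end - shift
                overlap_tail.add(name)
                overlap_tail.add(prev.name)
            end = start + glen
            exons = _make_exons(start, end, spec.exon_count)
            genes.append(Annotation(name, chrom, strand, start, end, exons))
            gap = int(rng.integers(spec.gap[0], spec.gap[1] + 1))
            pos = end + gap

    path = out_dir / "annotations.tsv"
    with open(path, "w") as fh:
        fh.write("#assembly=synthetic\n")
        fh.write("#name\tchrom\tstrand\tstart\tend\texonStarts\texonEnds\n")
        for g in genes:
            es = ",".join(str(s) for s, _ in g.exons)
            ee = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{es}\t{ee}\n")

    truth = _truth_table(genes)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return path, truth


def _truth_table(genes: list[Annotation]) -> pd.DataFrame:
    """Neighbor/orientation ground truth by direct linear inspection."""
    rows = []
    by_chrom: dict[str, list[Annotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda g: (g.start, g.end, g.name))
        for g in lst:
            lefts = [o for o in lst if o.name != g.name and o.start < g.start]
            rights = [o for o in lst if o.name != g.name and o.end > g.end]
            left = max(lefts, key=lambda o: (o.end, o.start, o.name)) if lefts else None
            right = min(rights, key=lambda o: (o.start, o.end, o.name)) if rights else None
            if g.strand == "+":
                up, down = left, right
                up_olap = left is not None and left.end > g.start
                down_olap = right is not None and right.start < g.end
            else:
                up, down = right, left
                up_olap = right is not None and right.start < g.end
                down_olap = left is not None and left.end > g.start

            def _olabel(n, olap, side):
                if n is None:
                    return "none"
                if olap:
                    return "overlap"
                if n.strand == g.strand:
                    return "tandem"
                return "divergent" if side == "up" else "convergent"

            rows.append({
                "name": g.name, "chrom": chrom, "strand": g.strand,
                "start": g.start, "end": g.end, "length": g.length,
                "n_exons": len(g.exons),
                "upstream": up.name if up else "",
                "downstream": down.name if down else "",
                "up_orientation": _olabel(up, up_olap, "up"),
                "down_orientation": _olabel(down, down_olap, "down"),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _pattern_array(spec: FixtureSpec, genes: list[Annotation], length: int
                   ) -> np.ndarray:
    """Per-base pattern values over one chromosome (noise-free)."""
    kind, *params = spec.pattern
    base = np.zeros(length)
    if kind == "uniform":
        base[:] = params[0]
        return base
    if kind == "exon_enriched":
        base[:] = 1.0
        for g in genes:
            for (s, e) in g.exons:
                base[s:e] = params[0]
        return base
    if kind == "body_ramp":
        slope = params[0]
        for g in genes:
            d = np.arange(g.length) + 0.5       # base-center distance from TSS
            if g.strand == "+":
                base[g.start:g.end] = slope * d
            else:
                base[g.start:g.end] = (slope * d)[::-1]
        return base
    if kind == "tss_peak":
        h, w = params
        for g in genes:
            lo, hi = max(0, int(g.tss - w)), min(length, int(g.tss + w))
            centers = np.arange(lo, hi) + 0.5
            tri = h * np.clip(1.0 - np.abs(centers - g.tss) / w, 0.0, None)
            base[lo:hi] = np.maximum(base[lo:hi], tri)
        return base
    raise ValueError(f"unknown pattern {kind!r}")


def _compress_runs(values: np.ndarray, covered: np.ndarray):
    """(start, end, value) runs of equal value over covered bases."""
    runs = []
    n = len(values)
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i + 1
        while j < n and covered[j] and values[j] == values[i]:
            j += 1
        runs.append((i, j, float(values[i])))
        i = j
    return runs


def make_signal(spec: FixtureSpec, annotations: AnnotationSet, out_dir
                ) -> tuple[Path, Path]:
    """Write the fixture's signal as BedGraph and WIG; return both paths.

    Noise (per emitted interval) and missing-data gaps are applied after
    the pattern; BedGraph and WIG encode the identical interval
    decomposition so either parser yields the same stream.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    by_chrom = annotations.by_chrom()
    all_runs: list[tuple[str, int, int, float]] = []
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        length = max(g.end for g in genes) + spec.margin
        values = _pattern_array(spec, genes, length)
        covered = np.ones(length, dtype=bool)
        if spec.missing_fraction > 0:
            for g in genes:
                if rng.random() < spec.missing_fraction:
                    gap = max(50, g.length // 4)
                    lo = int(rng.integers(g.start, max(g.start + 1, g.end - gap)))
                    covered[lo:lo + gap] = False
        runs = _compress_runs(values, covered)
        for (s, e, v) in runs:
            if spec.noise_sd > 0:
                v += float(rng.normal(0.0, spec.noise_sd))
            all_runs.append((chrom, s, e, v))

    bg_path = out_dir / "signal.bedgraph"
    wig_path = out_dir / "signal.wig"
    with open(bg_path, "w") as fh:
        fh.write("track type=bedGraph name=synthetic\n")
        for chrom, s, e, v in all_runs:
            fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")
    with open(wig_path, "w") as fh:
        fh.write("track type=wiggle_0 name=synthetic\n")
        for chrom, s, e, v in all_runs:
            span = e - s
            fh.write(f"fixedStep chrom={chrom} start={s + 1} step={span} span={span}\n")
            fh.write(f"{v!r}\n")
    return bg_path, wig_path


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

def _window_value(values: np.ndarray, window) -> float:
    """Overlap-weighted per-base mean of an array over one (fractional) window."""
    if window is None:
        return float("nan")
    a, b = window
    if b <= a:
        return float("nan")
    lo, hi = int(np.floor(a)), min(int(np.ceil(b)), len(values))
    if hi <= lo:
        return float("nan")
    idx = np.arange(lo, hi)
    w = np.clip(np.minimum(idx + 1, b) - np.maximum(idx, a), 0.0, None)
    if w.sum() <= 0:
        return float("nan")
    return float(np.dot(values[lo:hi], w) / w.sum())


def expected_window_value(spec: FixtureSpec, genes: list[Annotation],
                          chrom_length: int, window) -> float:
    """Exact expected value of one genomic window under a noise-free pattern.

    Evaluates the per-base pattern directly and weights each base by its
    overlap with the (possibly fractional) window — independent of the
    file formats and of the extraction pipeline.
    """
    return _window_value(_pattern_array(spec, genes, chrom_length), window)


def expected_profile(spec: FixtureSpec, annotations: AnnotationSet,
                     anchor_sets: list[AnchorSet], layout: BlockLayout
                     ) -> np.ndarray:
    """Expected aggregate mean profile for noise-free, gap-free fixtures.

    Returns the per-window mean over features of the analytic window
    values; raises for specs whose expectation is not exact (noise or
    missing data).
    """
    if spec.noise_sd > 0 or spec.missing_fraction > 0:
        raise ValueError("closed-form expectation requires a noise-free, "
                         "gap-free fixture")
    by_chrom = annotations.by_chrom()
    arrays = {c: _pattern_array(spec, gl, max(g.end for g in gl) + spec.margin)
              for c, gl in by_chrom.items()}
    rows = []
    for aset in anchor_sets:
        wins = feature_windows(aset, layout)
        vals = [_window_value(arrays[aset.chrom], w) for w in wins]
        rows.append(vals)
    mat = np.array(rows, dtype=float)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=0)
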