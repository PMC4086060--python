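"""Run configuration, orchestration of datasets x groups x subgroups, and plots.

A run is described by a plain-text ``key = value`` parameter file (schema in
``docs/parameters.md``).  The orchestrator resolves anchors for every group
member, lays out their windows, then streams each dataset once — intervals
are read in chunks of at most ``chunk_limit`` data lines and accumulated
into per-(feature, window) coverage-weighted sums through an interval tree,
so results are identical for any chunk limit and memory stays bounded by
the window geometry, not the dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from . import genome_model as gm
from . import io_formats as iof
from . import profile_engine as pe

logger = logging.getLogger(__name__)

ORIENT_COMBOS = (
    ("tandem", "tandem"),
    ("tandem", "convergent"),
    ("divergent", "tandem"),
    ("divergent", "convergent"),
)

_MANDATORY = ("analysis_mode", "method", "dataset", "group")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated parameters of one profiling run."""

    analysis_mode: str                      # annotation | exon | coordinate
    method: str                             # absolute | relative
    dataset: list[str] = field(default_factory=list)
    group: list[str] = field(default_factory=list)
    annotations: str | None = None
    assembly: str | None = None
    n_refpoints: int = 2
    window_size: float | None = 50.0        # bp (absolute method)
    block_windows: list[int] | None = None
    block_extents: list[float] | None = None  # bp, alternative to block_windows
    block_aligns: list[str] | None = None
    split_fraction: float = 0.5
    flank_extent: float | None = None       # bp span of the two flank blocks
    statistic: str = "mean"
    smoothing: int = 1
    orientation_subgroups: list[str] = field(default_factory=list)
    min_length: int | None = None
    max_length: int | None = None
    chrom_include: list[str] | None = None
    chrom_exclude: list[str] | None = None
    name_exclude: list[str] | None = None
    exclude_overlapping: bool = False
    chunk_limit: int | None = None
    output_dir: str = "."
    prefix: str = ""
    individual: bool = False
    sort_key: str = "input"
    sort_descending: bool = True
    missing_as_zero: bool = False
    y_min: float | None = None
    y_max: float | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.analysis_mode not in ("annotation", "exon", "coordinate"):
            raise ConfigError(f"unknown analysis_mode {self.analysis_mode!r}")
        if self.method not in ("absolute", "relative"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.analysis_mode == "exon":
            if self.n_refpoints not in (6,):
                raise ConfigError("exon mode requires n_refpoints = 6")
        elif self.analysis_mode == "coordinate":
            if self.n_refpoints not in (1, 2):
                raise ConfigError("coordinate mode supports 1 or 2 reference points")
        elif self.n_refpoints not in gm.N_REFPOINTS_ALLOWED:
            raise ConfigError(f"n_refpoints must be one of {gm.N_REFPOINTS_ALLOWED}")
        if self.analysis_mode in ("annotation", "exon") and not self.annotations:
            raise ConfigError(f"{self.analysis_mode} mode requires an annotations file")
        if self.statistic not in pe.STATISTICS:
            raise ConfigError(f"statistic must be one of {pe.STATISTICS}")
        if self.smoothing < 1:
            raise ConfigError("smoothing must be >= 1")
        if self.sort_key not in iof.SORT_KEYS:
            raise ConfigError(f"sort_key must be one of {iof.SORT_KEYS}")
        if self.chunk_limit is not None and self.chunk_limit < 1:
            raise ConfigError("chunk_limit must be >= 1")
        n_blocks = self.n_refpoints + 1
        if self.block_windows is None and self.block_extents is None:
            raise ConfigError("either block_windows or block_extents is required")
        if self.method == "absolute":
            if self.window_size is None or self.window_size < 1:
                raise ConfigError("absolute method requires window_size >= 1")
            if self.block_windows is None:
                bw = []
                for ext in self.block_extents:
                    q = ext / self.window_size
                    if abs(q - round(q)) > 1e-9:
                        raise ConfigError(
                            f"block extent {ext:g} bp is not a multiple of "
                            f"window_size {self.window_size:g}")
                    bw.append(int(round(q)))
                self.block_windows = bw
        else:
            if self.block_windows is None:
                raise ConfigError("relative method requires block_windows (bin counts)")
            if self.flank_extent is None:
                raise ConfigError("relative method requires flank_extent (bp)")
        if len(self.block_windows) != n_blocks:
            raise ConfigError(
                f"{self.n_refpoints} reference points create {n_blocks} blocks; "
                f"got {len(self.block_windows)} block window counts")
        for sub in self.orientation_subgroups:
            if sub != "all" and tuple(sub.split("-")) not in ORIENT_COMBOS:
                raise ConfigError(
                    f"unknown orientation subgroup {sub!r}; use up-down pairs "
                    f"like 'tandem-convergent' or 'all'")
        if self.orientation_subgroups and self.analysis_mode == "coordinate":
            raise ConfigError("orientation subgroups need annotated neighbors")

    def layout(self) -> pe.BlockLayout:
        return pe.make_layout(self.method, self.block_windows,
                              window_size=self.window_size,
                              alignments=self.block_aligns,
                              split_fraction=self.split_fraction,
                              flank_extent=self.flank_extent,
                              smoothing=self.smoothing)

    def filters(self) -> gm.FilterSpec:
        return gm.FilterSpec(min_length=self.min_length, max_length=self.max_length,
                             chrom_include=self.chrom_include,
                             chrom_exclude=self.chrom_exclude,
                             exclude_overlapping=self.exclude_overlapping,
                             name_exclude=self.name_exclude)

    def subgroup_combos(self) -> list[tuple[str, str]]:
        combos: list[tuple[str, str]] = []
        for sub in self.orientation_subgroups:
            if sub == "all":
                for c in ORIENT_COMBOS:
                    if c not in combos:
                        combos.append(c)
            else:
                c = tuple(sub.split("-"))
                if c not in combos:
                    combos.append(c)
        return combos


_LIST_KEYS = {"dataset", "group", "block_windows", "block_extents", "block_aligns",
              "chrom_include", "chrom_exclude", "name_exclude",
              "orientation_subgroups"}
_INT_KEYS = {"n_refpoints", "smoothing", "min_length", "max_length", "chunk_limit"}
_FLOAT_KEYS = {"window_size", "split_fraction", "flank_extent", "y_min", "y_max"}
_BOOL_KEYS = {"exclude_overlapping", "individual", "sort_descending",
              "missing_as_zero"}


def parse_parameter_file(path) -> RunConfig:
    """Parse a ``key = value`` parameter file into a validated RunConfig.

    Repeatable keys (``dataset``, ``group``) accumulate; list values may
    also be comma-separated.  Unknown keys warn; missing mandatory keys
    raise one error naming all of them.
    """
    path = Path(path)
    known = {f.name for f in fields(RunConfig)}
    raw: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if "=" not in s:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, val = (x.strip() for x in s.split("=", 1))
            if key not in known:
                logger.warning("%s:%d: unknown parameter %r ignored", path, lineno, key)
                continue
            raw.setdefault(key, []).append(val)

    missing = [k for k in _MANDATORY if k not in raw]
    if "annotations" not in raw and raw.get("analysis_mode", ["?"])[0] in ("annotation", "exon"):
        missing.append("annotations")
    if missing:
        raise ConfigError(f"{path}: missing mandatory parameter(s): {', '.join(missing)}")

    kwargs: dict = {}
    for key, vals in raw.items():
        if key in _LIST_KEYS:
            items: list[str] = []
            for v in vals:
                items.extend(x.strip() for x in v.split(",") if x.strip())
            if key == "block_windows":
                kwargs[key] = [int(x) for x in items]
            elif key == "block_extents":
                kwargs[key] = [float(x) for x in items]
            else:
                kwargs[key] = items
        else:
            v = vals[-1]
            if len(vals) > 1:
                logger.warning("%s: parameter %r given %d times; last wins",
                               path, key, len(vals))
            if key in _INT_KEYS:
                kwargs[key] = None if v.lower() in ("none", "") else int(v)
            elif key in _FLOAT_KEYS:
                kwargs[key] = None if v.lower() in ("none", "") else float(v)
            elif key in _BOOL_KEYS:
                if v.lower() not in ("true", "false", "yes", "no", "1", "0"):
                    raise ConfigError(f"{path}: boolean parameter {key}={v!r}")
                kwargs[key] = v.lower() in ("true", "yes", "1")
            else:
                kwargs[key] = v
    return RunConfig(**kwargs)


def serialize_config(config: RunConfig, path) -> None:
    """Write a RunConfig back to the parameter-file format (round-trips)."""
    lines = []
    for f in fields(RunConfig):
        v = getattr(config, f.name)
        if v is None or v == [] or v == "":
            continue
        if isinstance(v, bool):
            lines.append(f"{f.name} = {'true' if v else 'false'}")
        elif isinstance(v, list):
            if f.name in ("dataset", "group"):
                lines.extend(f"{f.name} = {x}" for x in v)
            else:
                lines.append(f"{f.name} = {','.join(str(x) for x in v)}")
        else:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# streaming accumulation
# ---------------------------------------------------------------------------

class WindowAccumulator:
    """Accumulates coverage-weighted sums per (feature, window) from a stream.

    Window geometry is indexed once in per-chromosome interval trees; each
    signal interval then deposits value*overlap into the cells it touches.
    Per cell, deposits arrive in file order for any chunk limit, so sums
    are bit-identical regardless of chunking.
    """

    def __init__(self, window_lists: list[list], chroms: list[str]):
        self.n_features = len(window_lists)
        self.n_windows = len(window_lists[0]) if window_lists else 0
        self.num = np.zeros((self.n_features, self.n_windows))
        self.den = np.zeros((self.n_features, self.n_windows))
        self.widths = np.full((self.n_features, self.n_windows), np.nan)
        self.trees: dict[str, IntervalTree] = {}
        for fi, (wins, chrom) in enumerate(zip(window_lists, chroms)):
            tree = self.trees.setdefault(chrom, IntervalTree())
            for wi, w in enumerate(wins):
                if w is None:
                    continue
                a, b = w
                if b <= a:
                    continue
                self.widths[fi, wi] = b - a
                tree.addi(a, b, (fi, wi))

    def add(self, si: iof.SignalInterval) -> None:
        tree = self.trees.get(si.chrom)
        if tree is None:
            return
        for iv in sorted(tree.overlap(si.start, si.end), key=lambda x: x.data):
            ov = min(iv.end, si.end) - max(iv.begin, si.start)
            if ov > 0:
                fi, wi = iv.data
                self.num[fi, wi] += si.value * ov
                self.den[fi, wi] += ov

    def consume(self, stream) -> None:
        for si in stream:
            self.add(si)

    def values(self, uncovered_zero: bool = False) -> np.ndarray:
        """Per-cell coverage-weighted means; NaN where nothing was realized."""
        with np.errstate(invalid="ignore", divide="ignore"):
            if uncovered_zero:
                out = self.num / self.widths
            else:
                out = np.where(self.den > 0, self.num / np.where(self.den > 0, self.den, 1.0), np.nan)
        out[np.isnan(self.widths)] = np.nan
        return out


# ---------------------------------------------------------------------------
# run orchestration
# ---------------------------------------------------------------------------

@dataclass
class ComboResult:
    dataset: str
    group: str
    subgroup: str                   # 'all' or 'up-down'
    matrix: pe.ProfileMatrix
    aggregate: pe.AggregateProfile

    @property
    def label(self) -> str:
        return f"{self.dataset}|{self.group}|{self.subgroup}"


@dataclass
class RunResult:
    layout: pe.BlockLayout
    combos: list[ComboResult]
    feature_windows: dict[str, list]
    feature_chroms: dict[str, str]
    log_lines: list[str]


def _resolve_group(config: RunConfig, group: iof.ReferenceGroup,
                   annotations: iof.AnnotationSet | None,
                   index: gm.NeighborIndex | None,
                   layout: pe.BlockLayout, log: list[str]):
    """Filters + anchor resolution + orientation labels for one group.

    Returns (ordered member keys, anchors by key, lengths by key,
    orientation label by key or None).
    """
    anchors: dict[str, gm.AnchorSet] = {}
    lengths: dict[str, int] = {}
    orients: dict[str, gm.OrientationLabel] = {}
    keys: list[str] = []

    if config.analysis_mode == "coordinate":
        for rec in group.members:
            aset = gm.resolve_coordinate_anchor(rec, config.n_refpoints)
            keys.append(aset.name)
            anchors[aset.name] = aset
            lengths[aset.name] = rec.end - rec.start
        log.append(f"group {group.label}: {len(keys)} coordinate records")
        return keys, anchors, lengths, None

    before = len(group.members)
    filtered = gm.apply_filters(group, annotations, index, config.filters())
    log.append(f"group {group.label}: {before} members, "
               f"{len(filtered.members)} after filters")
    ig_ext = ann_ext = None
    if config.n_refpoints >= 4:
        ig_block = layout.blocks[1] if config.n_refpoints == 4 else layout.blocks[2]
        ig_ext = (ig_block.window_count * ig_block.window_size
                  if layout.method == "absolute" else None)
        if config.n_refpoints == 6 and layout.method == "absolute":
            ann_ext = layout.blocks[1].window_count * layout.blocks[1].window_size
    dropped_exon = 0
    for name in filtered.members:
        a = annotations[name]
        up, down = gm.find_neighbors(a, index)
        orients[name] = gm.classify_orientation(a, up, down)
        if config.analysis_mode == "exon":
            aset = gm.select_exon_anchors(a)
            if aset is None:
                dropped_exon += 1
                continue
        else:
            aset = gm.resolve_anchors(a, up, down, config.n_refpoints,
                                      intergenic_extent=ig_ext,
                                      annotation_extent=ann_ext)
        keys.append(name)
        anchors[name] = aset
        lengths[name] = a.length
    if dropped_exon:
        log.append(f"group {group.label}: {dropped_exon} members excluded "
                   f"from exon mode (<3 exons)")
    if not keys:
        raise ConfigError(f"group {group.label}: no resolvable members")
    return keys, anchors, lengths, orients


def compute_run(config: RunConfig) -> RunResult:
    """Execute a run in memory and return matrices and aggregates."""
    layout = config.layout()
    log: list[str] = []
    annotations = index = None
    if config.analysis_mode in ("annotation", "exon"):
        annotations = iof.read_annotations(config.annotations)
        if (config.assembly and annotations.assembly
                and config.assembly != annotations.assembly):
            logger.warning("declared assembly %r differs from annotation file %r",
                           config.assembly, annotations.assembly)
            log.append(f"WARNING: assembly mismatch ({config.assembly} vs "
                       f"{annotations.assembly})")
        index = gm.build_index(annotations)

    groups = [iof.read_group(p, "coordinate" if config.analysis_mode == "coordinate"
                             else "annotation") for p in config.group]

    resolved = {}
    union_keys: list[str] = []
    union_anchors: dict[str, gm.AnchorSet] = {}
    union_lengths: dict[str, int] = {}
    for g in groups:
        keys, anchors, lengths, orients = _resolve_group(
            config, g, annotations, index, layout, log)
        resolved[g.label] = (keys, orients)
        for k in keys:
            if k not in union_anchors:
                union_keys.append(k)
                union_anchors[k] = anchors[k]
                union_lengths[k] = lengths[k]

    window_lists = [pe.feature_windows(union_anchors[k], layout) for k in union_keys]
    chroms = [union_anchors[k].chrom for k in union_keys]
    row_of = {k: i for i, k in enumerate(union_keys)}

    combos: list[ComboResult] = []
    subgroup_combos = config.subgroup_combos()
    ds_labels = _unique_labels(config.dataset)
    for ds_path, ds_label in zip(config.dataset, ds_labels):
        acc = WindowAccumulator(window_lists, chroms)
        acc.consume(iof.open_signal(ds_path, config.chunk_limit))
        values = acc.values(uncovered_zero=config.missing_as_zero)
        for g in groups:
            keys, orients = resolved[g.label]
            rows = [row_of[k] for k in keys]
            # feature_windows emits windows 5'->3' already; rows select only
            base = pe.ProfileMatrix(
                names=list(keys), lengths=[union_lengths[k] for k in keys],
                values=values[rows].copy(), layout=layout)
            selections = [("all", list(range(len(keys))))]
            for (u, d) in subgroup_combos:
                sel = [i for i, k in enumerate(keys)
                       if orients and orients[k].upstream == u
                       and orients[k].downstream == d]
                label = f"{u}-{d}"
                log.append(f"subgroup {g.label}/{label}: {len(sel)} members")
                if sel:
                    selections.append((label, sel))
            for sub_label, sel in selections:
                m = base.select(sel) if sub_label != "all" else base
                agg = pe.smooth_aggregate(pe.aggregate_profiles(m, config.statistic))
                combos.append(ComboResult(ds_label, g.label, sub_label, m, agg))

    fw = {k: w for k, w in zip(union_keys, window_lists)}
    fc = dict(zip(union_keys, chroms))
    return RunResult(layout=layout, combos=combos, feature_windows=fw,
                     feature_chroms=fc, log_lines=log)


def _unique_labels(paths: list[str]) -> list[str]:
    """Short per-dataset labels: file stem, disambiguated by full name or
    position when stems collide."""
    stems = [Path(p).stem for p in paths]
    labels = []
    for i, (p, stem) in enumerate(zip(paths, stems)):
        label = stem
        if stems.count(stem) > 1:
            label = Path(p).name
        if label in labels:
            label = f"{label}#{i + 1}"
        labels.append(label)
    return labels


def run_analysis(config: RunConfig) -> list[Path]:
    """Run end to end and write aggregate/individual TSVs and the run log."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = compute_run(config)
    prefix = config.prefix
    written: list[Path] = []

    agg_path = out_dir / f"{prefix}aggregate.tsv"
    iof.write_aggregate_tsv({c.label: c.aggregate for c in result.combos}, agg_path)
    written.append(agg_path)

    if config.individual:
        for c in result.combos:
            if c.subgroup != "all":
                continue
            p = out_dir / f"{prefix}individual.{c.dataset}.{c.group}.tsv"
            iof.write_individual_tsv(c.matrix, p, sort_key=config.sort_key,
                                     descending=config.sort_descending)
            written.append(p)

    log_path = out_dir / f"{prefix}run.log"
    with open(log_path, "w") as fh:
        fh.write(f"mode={config.analysis_mode} method={config.method} "
                 f"refpoints={config.n_refpoints} statistic={config.statistic} "
                 f"smoothing={config.smoothing}\n")
        for line in result.log_lines:
            fh.write(line + "\n")
        for p in written:
            fh.write(f"wrote {p}\n")
    written.append(log_path)
    return written


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def render_plot(aggregate_tsvs: list, out_path, *, show_sem: bool = True,
                show_proportion: bool = True, y_min: float | None = None,
                y_max: float | None = None, title: str | None = None) -> Path:
    """Line plot of aggregate profiles with anchor marks and proportion panel.

    All input TSVs must share one block layout; anchors (block boundaries)
    are drawn as vertical marks on the x axis.  The output format follows
    the file extension (svg / pdf / png).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frames = []
    layout_lines = None
    for p in aggregate_tsvs:
        with open(p) as fh:
            header = [l for l in fh if l.startswith("#")]
        if layout_lines is None:
            layout_lines = header
        elif header != layout_lines:
            raise ValueError(f"{p}: block layout differs from the first input")
        frames.append((Path(p).stem, iof.read_aggregate_tsv(p)))

    n_rows = 2 if show_proportion else 1
    fig, axes = plt.subplots(n_rows, 1, sharex=True,
                             figsize=(8, 3.2 * n_rows), squeeze=False)
    ax = axes[0][0]
    boundaries = None
    for stem, df in frames:
        blocks = df["block"].to_numpy()
        boundaries = np.flatnonzero(np.diff(blocks)) + 1.5
        x = df["window"].to_numpy()
        stat_cols = [c for c in df.columns
                     if c.endswith((".mean", ".median", ".min", ".max"))]
        for col in stat_cols:
            label = col.rsplit(".", 1)[0]
            (line,) = ax.plot(x, df[col], label=f"{stem}:{label}" if len(frames) > 1 else label)
            sem_col = label + ".sem"
            if show_sem and sem_col in df.columns:
                ax.fill_between(x, df[col] - df[sem_col], df[col] + df[sem_col],
                                alpha=0.25, color=line.get_color(), linewidth=0)
        if show_proportion:
            axp = axes[1][0]
            for col in [c for c in df.columns if c.endswith(".proportion")]:
                axp.plot(x, df[col], label=col.rsplit(".", 1)[0])
            axp.set_ylim(0, 1.05)
            axp.set_ylabel("proportion")
    for a in axes.ravel():
        if boundaries is not None:
            for b in boundaries:
                a.axvline(b, color="black", linewidth=1.2, ymax=0.04)
        a.set_xlabel("window")
    ax.set_ylabel("aggregate signal")
    if y_min is not None or y_max is not None:
        ax.set_ylim(y_min, y_max)
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
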