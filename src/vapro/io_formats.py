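"""Readers and writers for the text formats the profiler consumes and emits.

Input side: BedGraph and WIG (fixedStep / variableStep) signal tracks, a
genePred-like tab-delimited annotation table, and reference-group files
(name lists or BED-style coordinate records).  Output side: tab-delimited
aggregate and individual-profile tables with ``NA`` missing markers.

All coordinates are held internally as 0-based half-open intervals.
BedGraph is native 0-based half-open; WIG positions are 1-based and are
converted on read; the annotation table is declared 0-based half-open
(see ``docs/formats.md``).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "NA"


class ParseError(ValueError):
    """Raised for malformed input, carrying file path and line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalInterval:
    """One scored interval of a signal track (0-based half-open)."""

    chrom: str
    start: int
    end: int
    value: float


@dataclass(frozen=True)
class Annotation:
    """A named stranded genomic feature with optional exon structure."""

    name: str
    chrom: str
    strand: str          # '+' or '-'
    start: int           # 0-based inclusive
    end: int             # 0-based exclusive
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        prev = self.start
        for (s, e) in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"{self.name}: bad exon ({s},{e})")
            prev = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Strand-aware start position (transcription start site)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Strand-aware end position (transcription end site)."""
        return self.end if self.strand == "+" else self.start

    def exons_transcribed(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered 5'->3' in the transcribed direction."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


@dataclass(frozen=True)
class CoordinateRecord:
    """A BED-style user-supplied region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("coordinate record: start must be < end")


@dataclass
class ReferenceGroup:
    """An ordered group of features to profile, by name or by coordinate."""

    label: str
    mode: str                       # 'annotation' | 'exon' | 'coordinate'
    members: list                   # list[str] or list[CoordinateRecord]

    def __post_init__(self):
        if self.mode not in ("annotation", "exon", "coordinate"):
            raise ValueError(f"unknown group mode {self.mode!r}")
        if not self.members:
            raise ValueError(f"reference group {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


class AnnotationSet:
    """Annotations keyed by unique name, with per-chromosome access."""

    def __init__(self, annotations: Iterable[Annotation], assembly: str | None = None):
        self.assembly = assembly
        self._by_name: dict[str, Annotation] = {}
        for a in annotations:
            if a.name in self._by_name:
                raise ValueError(f"duplicate annotation name {a.name!r}")
            self._by_name[a.name] = a

    def __getitem__(self, name: str) -> Annotation:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def by_chrom(self) -> dict[str, list[Annotation]]:
        out: dict[str, list[Annotation]] = {}
        for a in self:
            out.setdefault(a.chrom, []).append(a)
        for lst in out.values():
            lst.sort(key=lambda x: (x.start, x.end, x.name))
        return out


# ---------------------------------------------------------------------------
# signal readers
# ---------------------------------------------------------------------------

class _OverlapChecker:
    """Detects overlapping intervals within one signal file.

    Keeps a per-chromosome list of disjoint covered runs (merged when
    adjacent), so memory stays proportional to the number of gaps in the
    coverage rather than the number of data lines.
    """

    def __init__(self, path):
        self.path = path
        self._runs: dict[str, tuple[list, list]] = {}  # chrom -> (starts, ends)

    def add(self, chrom: str, start: int, end: int, lineno: int) -> None:
        starts, ends = self._runs.setdefault(chrom, ([], []))
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            raise ParseError(self.path, lineno,
                             f"interval {chrom}:{start}-{end} overlaps an earlier interval")
        if i < len(starts) and starts[i] < end:
            raise ParseError(self.path, lineno,
                             f"interval {chrom}:{start}-{end} overlaps an earlier interval")
        # insert, merging with touching neighbours to keep the list short
        lo, hi = start, end
        if i > 0 and ends[i - 1] == start:
            lo = starts[i - 1]
            del starts[i - 1]
            del ends[i - 1]
            i -= 1
        if i < len(starts) and starts[i] == hi:
            hi = ends[i]
            del starts[i]
            del ends[i]
        starts.insert(i, lo)
        ends.insert(i, hi)


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s or s.startswith("#") or s.startswith("track")
            or s.startswith("browser"))


def read_bedgraph(path, chunk_limit: int | None = None) -> Iterator[SignalInterval]:
    """Stream a BedGraph file as SignalInterval records, in file order.

    ``chunk_limit`` bounds how many data lines are materialized at once;
    ``None`` means the whole file may be buffered.  Results are independent
    of the chunk limit.
    """
    path = Path(path)
    checker = _OverlapChecker(path)

    def parse(line: str, lineno: int) -> SignalInterval:
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(path, lineno,
                             f"expected 4 fields (chrom start end value), got {len(parts)}")
        chrom, s, e, v = parts
        try:
            start, end = int(s), int(e)
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinate in {line.strip()!r}") from None
        if start >= end:
            raise ParseError(path, lineno, f"start {start} must be < end {end}")
        try:
            value = float(v)
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric value {v!r}") from None
        checker.add(chrom, start, end, lineno)
        return SignalInterval(chrom, start, end, value)

    yield from _chunked_lines(path, chunk_limit, parse)


def _chunked_lines(path, chunk_limit, parse) -> Iterator[SignalInterval]:
    buf: list[SignalInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            buf.append(parse(line, lineno))
            if chunk_limit is not None and len(buf) >= chunk_limit:
                yield from buf
                buf = []
    yield from buf


def read_wig(path, chunk_limit: int | None = None) -> Iterator[SignalInterval]:
    """Stream a WIG file (fixedStep / variableStep) as 0-based intervals.

    WIG positions are 1-based; a fixedStep block with start s, step p and
    span v places its k-th value on [s-1+(k-1)p, s-1+(k-1)p+v).
    """
    path = Path(path)
    checker = _OverlapChecker(path)
    state: dict = {"mode": None}

    def parse_decl(line: str, lineno: int) -> None:
        parts = line.split()
        kind = parts[0]
        kv = {}
        for p in parts[1:]:
            if "=" not in p:
                raise ParseError(path, lineno, f"malformed declaration field {p!r}")
            k, v = p.split("=", 1)
            kv[k] = v
        try:
            if kind == "fixedStep":
                state.update(mode="fixed", chrom=kv["chrom"], pos=int(kv["start"]) - 1,
                             step=int(kv.get("step", 1)), span=int(kv.get("span", 1)))
                if state["span"] > state["step"]:
                    raise ParseError(path, lineno,
                                     f"span {state['span']} > step {state['step']} would overlap")
            else:
                state.update(mode="variable", chrom=kv["chrom"], span=int(kv.get("span", 1)))
        except KeyError as exc:
            raise ParseError(path, lineno, f"declaration missing {exc.args[0]}") from None
        except ValueError:
            raise ParseError(path, lineno, f"non-integer declaration value in {line.strip()!r}") from None

    def parse(line: str, lineno: int) -> SignalInterval | None:
        stripped = line.strip()
        if stripped.startswith(("fixedStep", "variableStep")):
            parse_decl(stripped, lineno)
            return None
        if state["mode"] is None:
            raise ParseError(path, lineno, "data line before any step declaration")
        if state["mode"] == "fixed":
            try:
                value = float(stripped)
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric value {stripped!r}") from None
            start = state["pos"]
            state["pos"] += state["step"]
            end = start + state["span"]
        else:
            parts = stripped.split()
            if len(parts) != 2:
                raise ParseError(path, lineno, "variableStep line needs 'position value'")
            try:
                start = int(parts[0]) - 1
                value = float(parts[1])
            except ValueError:
                raise ParseError(path, lineno, f"malformed variableStep line {stripped!r}") from None
            end = start + state["span"]
        if start < 0:
            raise ParseError(path, lineno, "position must be >= 1")
        checker.add(state["chrom"], start, end, lineno)
        return SignalInterval(state["chrom"], start, end, value)

    buf: list[SignalInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            si = parse(line, lineno)
            if si is None:
                continue
            buf.append(si)
            if chunk_limit is not None and len(buf) >= chunk_limit:
                yield from buf
                buf = []
    yield from buf


def open_signal(path, chunk_limit: int | None = None) -> Iterator[SignalInterval]:
    """Dispatch on file extension: .wig -> WIG, anything else -> BedGraph."""
    if str(path).endswith(".wig"):
        return read_wig(path, chunk_limit)
    return read_bedgraph(path, chunk_limit)


class SignalTrack:
    """In-memory signal: per chromosome, sorted non-overlapping intervals."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = data

    @classmethod
    def from_intervals(cls, intervals: Iterable[SignalInterval]) -> "SignalTrack":
        acc: dict[str, list[tuple[int, int, float]]] = {}
        for si in intervals:
            acc.setdefault(si.chrom, []).append((si.start, si.end, si.value))
        data = {}
        for chrom, rows in acc.items():
            rows.sort(key=lambda r: r[0])
            starts = np.array([r[0] for r in rows], dtype=float)
            ends = np.array([r[1] for r in rows], dtype=float)
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping signal intervals on {chrom}")
            data[chrom] = (starts, ends, np.array([r[2] for r in rows]))
        return cls(data)

    @classmethod
    def from_file(cls, path, chunk_limit: int | None = None) -> "SignalTrack":
        return cls.from_intervals(open_signal(path, chunk_limit))

    def chroms(self) -> list[str]:
        return list(self._data)

    def arrays(self, chrom: str):
        """(starts, ends, values) float arrays for one chromosome (may be empty)."""
        if chrom not in self._data:
            z = np.empty(0)
            return z, z, z
        return self._data[chrom]


# ---------------------------------------------------------------------------
# annotations and reference groups
# ---------------------------------------------------------------------------

def _parse_exon_list(text: str):
    return [int(x) for x in text.strip().rstrip(",").split(",") if x.strip()]


def read_annotations(path) -> AnnotationSet:
    """Read the genePred-like annotation table.

    Tab-delimited columns: name, chrom, strand, start, end and optionally
    comma-separated exonStarts / exonEnds (UCSC-style trailing commas are
    tolerated).  Coordinates are 0-based half-open.  A header comment of the
    form ``#assembly=NAME`` is retained for cross-checking against the
    assembly declared in the run configuration.  Empty exon columns denote a
    single exon spanning the feature.
    """
    path = Path(path)
    assembly = None
    annotations = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip():
                continue
            if s.startswith("#"):
                if s.startswith("#assembly="):
                    assembly = s.split("=", 1)[1].strip()
                continue
            parts = s.split("\t")
            if len(parts) < 5:
                raise ParseError(path, lineno, f"expected >=5 tab-delimited columns, got {len(parts)}")
            name, chrom, strand = parts[0], parts[1], parts[2]
            if name in names:
                raise ParseError(path, lineno, f"duplicate annotation name {name!r}")
            names.add(name)
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            exons: tuple[tuple[int, int], ...]
            if len(parts) >= 7 and (parts[5].strip() or parts[6].strip()):
                try:
                    es = _parse_exon_list(parts[5])
                    ee = _parse_exon_list(parts[6])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer exon coordinate") from None
                if len(es) != len(ee):
                    raise ParseError(path, lineno,
                                     f"exon count mismatch: {len(es)} starts vs {len(ee)} ends")
                exons = tuple(zip(es, ee))
            else:
                exons = ((start, end),)
            try:
                annotations.append(Annotation(name, chrom, strand, start, end, exons))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
    return AnnotationSet(annotations, assembly=assembly)


def read_group(path, mode: str) -> ReferenceGroup:
    """Read a reference-group file.

    In annotation/exon mode the file lists one feature name per line; in
    coordinate mode it holds BED-style records
    ``chrom start end [name] [score] [strand]``.  Duplicates are removed
    with a warning; names absent from the annotation set are dealt with at
    resolution time, not here.
    """
    path = Path(path)
    label = path.stem
    members: list = []
    seen: set = set()
    dups = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("track") or s.startswith("browser"):
                continue
            if mode in ("annotation", "exon"):
                name = s.split()[0]
                if name in seen:
                    dups += 1
                    continue
                seen.add(name)
                members.append(name)
            elif mode == "coordinate":
                parts = s.split()
                if len(parts) < 3:
                    raise ParseError(path, lineno, "BED record needs at least chrom start end")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer BED coordinates") from None
                name = parts[3] if len(parts) >= 4 else None
                strand = parts[5] if len(parts) >= 6 else "."
                if strand not in ("+", "-", "."):
                    raise ParseError(path, lineno, f"bad strand {strand!r}")
                if start >= end:
                    raise ParseError(path, lineno, f"start {start} must be < end {end}")
                rec = CoordinateRecord(parts[0], start, end, strand, name)
                key = (rec.chrom, rec.start, rec.end, rec.strand, rec.name)
                if key in seen:
                    dups += 1
                    continue
                seen.add(key)
                members.append(rec)
            else:
                raise ValueError(f"unknown group mode {mode!r}")
    if dups:
        logger.warning("%s: removed %d duplicate entries", path, dups)
    if not members:
        raise ParseError(path, 0, "reference group file is empty")
    return ReferenceGroup(label=label, mode=mode, members=members)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _layout_header_lines(layout) -> list[str]:
    lines = [f"# layout\tmethod={layout.method}\tsmoothing={layout.smoothing}"]
    for i, b in enumerate(layout.blocks, start=1):
        ws = "" if b.window_size is None else f"\twindow_size={b.window_size:g}"
        ext = "" if b.extent is None else f"\textent={b.extent:g}"
        lines.append(f"# block {i}\twindows={b.window_count}{ws}"
                     f"\talignment={b.alignment}\tsplit_fraction={b.split_fraction:g}{ext}")
    return lines


def write_aggregate_tsv(profiles: dict, path) -> None:
    """Write aggregate profiles sharing one layout, side by side.

    ``profiles`` maps a column-label to an AggregateProfile.  Columns per
    label: statistic, sd, sem, n, proportion; missing values are ``NA``.
    Header comment lines document the block layout.
    """
    profiles = dict(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    first = next(iter(profiles.values()))
    for p in profiles.values():
        if p.layout.signature() != first.layout.signature():
            raise ValueError("aggregate profiles do not share one layout")
    layout = first.layout
    n = layout.total_windows
    cols: dict[str, np.ndarray] = {
        "window": np.arange(1, n + 1),
        "block": np.asarray(layout.block_of_window) + 1,
    }
    for label, p in profiles.items():
        cols[f"{label}.{p.statistic}"] = p.values
        cols[f"{label}.sd"] = p.sd
        cols[f"{label}.sem"] = p.sem
        cols[f"{label}.n"] = p.n_contrib
        cols[f"{label}.proportion"] = p.proportion
    df = pd.DataFrame(cols)
    path = Path(path)
    with open(path, "w") as fh:
        for line in _layout_header_lines(layout):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def read_aggregate_tsv(path) -> pd.DataFrame:
    """Re-read an aggregate TSV (header comments skipped) as a DataFrame."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])


SORT_KEYS = ("input", "length", "name")


def write_individual_tsv(matrix, path, sort_key: str = "input",
                         descending: bool = True) -> None:
    """Write per-feature profile rows (heatmap input).

    One row per feature, one column per layout window, ``NA`` for missing.
    ``sort_key`` is one of input / length / name; ties (and the input key)
    preserve input order.  All-missing features are retained so the row set
    matches the reference group.
    """
    if sort_key not in SORT_KEYS:
        raise ValueError(f"unknown sort key {sort_key!r}; expected one of {SORT_KEYS}")
    if matrix.values.shape[0] == 0:
        raise ValueError("empty profile matrix")
    order = np.arange(len(matrix.names))
    if sort_key == "length":
        order = np.argsort(np.asarray(matrix.lengths), kind="stable")
        if descending:
            order = order[::-1]
    elif sort_key == "name":
        order = np.argsort(np.asarray(matrix.names), kind="stable")
        if descending:
            order = order[::-1]
    df = pd.DataFrame(matrix.values[order],
                      index=np.asarray(matrix.names)[order],
                      columns=[f"w{i}" for i in range(1, matrix.values.shape[1] + 1)])
    df.index.name = "feature"
    with open(path, "w") as fh:
        for line in _layout_header_lines(matrix.layout):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=MISSING)


def read_individual_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING], index_col=0)
    return df
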