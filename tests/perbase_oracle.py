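"""Independent per-base reference implementation used as a test oracle.

Expands a BedGraph file into base-resolution value/coverage arrays and
computes window means and group statistics naively, without touching the
package's interval machinery, streaming accumulator or aggregation code.
"""

from __future__ import annotations

import math

import numpy as np


def load_perbase(bedgraph_path):
    """chrom -> (values, covered) base-resolution arrays."""
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(bedgraph_path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s[0] == "#" or s.startswith(("track", "browser")):
                continue
            chrom, a, b, v = s.split()
            raw.setdefault(chrom, []).append((int(a), int(b), float(v)))
    out = {}
    for chrom, rows in raw.items():
        size = max(b for _, b, _ in rows)
        vals = np.zeros(size)
        cov = np.zeros(size, dtype=bool)
        for a, b, v in rows:
            assert not cov[a:b].any(), "oracle input has overlapping intervals"
            vals[a:b] = v
            cov[a:b] = True
        out[chrom] = (vals, cov)
    return out


def window_mean(perbase, chrom, window, uncovered_zero=False):
    """Coverage-weighted mean over one (possibly fractional) genomic window."""
    if window is None:
        return math.nan
    a, b = window
    if b <= a:
        return math.nan
    if chrom not in perbase:
        return 0.0 if uncovered_zero else math.nan
    vals, cov = perbase[chrom]
    lo, hi = int(math.floor(a)), int(math.ceil(b))
    num = den = 0.0
    for i in range(lo, min(hi, len(vals))):
        w = min(i + 1, b) - max(i, a)
        if w <= 0:
            continue
        if cov[i]:
            num += vals[i] * w
            den += w
    if uncovered_zero:
        return num / (b - a)
    return num / den if den > 0 else math.nan


def oracle_matrix(bedgraph_path, window_lists, chroms, uncovered_zero=False):
    """Per-feature per-window means (rows follow window_lists order)."""
    perbase = load_perbase(bedgraph_path)
    rows = []
    for wins, chrom in zip(window_lists, chroms):
        rows.append([window_mean(perbase, chrom, w, uncovered_zero) for w in wins])
    return np.array(rows, dtype=float)


def oracle_aggregate(matrix, group_size, statistic="mean"):
    """Naive per-window statistics: stat, sd (n-1), sem, n, proportion."""
    n_windows = matrix.shape[1]
    stat = np.full(n_windows, np.nan)
    sd = np.full(n_windows, np.nan)
    sem = np.full(n_windows, np.nan)
    n = np.zeros(n_windows)
    fn = {"mean": np.mean, "median": np.median, "min": np.min, "max": np.max}[statistic]
    for j in range(n_windows):
        col = matrix[:, j]
        vals = col[~np.isnan(col)]
        n[j] = len(vals)
        if len(vals) >= 1:
            stat[j] = fn(vals)
        if len(vals) >= 2:
            sd[j] = np.std(vals, ddof=1)
            sem[j] = sd[j] / math.sqrt(len(vals))
    return stat, sd, sem, n, n / group_size
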