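# File formats

All coordinates in all files are 0-based half-open unless stated
otherwise.  Missing values in outputs are written as `NA`.

## Signal tracks (input)

- **BedGraph** (UCSC): `chrom  start  end  value`, tab- or
  space-separated; `track`, `browser` and `#` lines are permitted
  anywhere.  Intervals within one file must not overlap (hard error).
- **WIG** (UCSC): `fixedStep chrom=.. start=.. [step=..] [span=..]` and
  `variableStep chrom=.. [span=..]` declarations followed by value lines.
  WIG positions are 1-based and converted on read; `span > step` is
  rejected (it would create overlaps).

Files ending in `.wig` are parsed as WIG, everything else as BedGraph.

## Annotation table (input)

Tab-delimited, one feature per row:

```
name  chrom  strand  start  end  [exonStarts  exonEnds]
```

- `name` must be unique; `strand` is `+` or `-`.
- `exonStarts`/`exonEnds` are comma-separated lists of equal length
  (UCSC-style trailing commas tolerated).  Empty exon columns denote a
  single exon spanning the feature.
- `#`-prefixed header lines are skipped; an optional `#assembly=NAME`
  line is kept and cross-checked (warning only) against the `assembly`
  declared in the run configuration — annotations and datasets must come
  from the same assembly for profiles to make sense.

## Reference groups (input)

- Annotation/exon mode: one feature name per line.  Duplicates are
  removed with a warning; names absent from the annotation table are
  dropped at resolution time with a logged count.
- Coordinate mode: BED-style `chrom start end [name] [score] [strand]`
  records; strand `.` is treated as `+` for orientation purposes.

## Aggregate TSV (output)

`#`-prefixed header lines document the block layout (method, smoothing,
per-block window count, window size, alignment, split fraction).  Then a
tab-delimited table with columns `window` (1-based, global), `block`
(1-based) and, per dataset×group×subgroup label: `<label>.<statistic>`
(the smoothed aggregate), `<label>.sd`, `<label>.sem`, `<label>.n`,
`<label>.proportion`.

## Individual-profile TSV (output)

Same header lines; one row per feature (row label = feature name), one
column per layout window (`w1..wN`), `NA` for missing windows.  Rows are
ordered by the configured sort key (input order, length or name);
all-missing features are retained so the row set matches the group.
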