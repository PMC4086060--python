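# Parameter file

Plain text, `key = value` per line; `#` starts a comment.  `dataset` and
`group` may be repeated (or comma-separated); other repeated keys warn
and keep the last value.  Unknown keys warn and are ignored; missing
mandatory keys produce one error naming all of them.
See `examples/four_point_run.params` for a complete file.

| key | meaning | default |
| --- | --- | --- |
| `analysis_mode` | `annotation` \| `exon` \| `coordinate` | (mandatory) |
| `method` | `absolute` (constant window size) \| `relative` (constant bin count) | (mandatory) |
| `dataset` | signal track path (BedGraph, or WIG if `.wig`); repeatable | (mandatory) |
| `group` | reference-group file path; repeatable | (mandatory) |
| `annotations` | annotation table; required unless coordinate mode | — |
| `assembly` | declared assembly, cross-checked against the annotation header | — |
| `n_refpoints` | 1, 2, 4 or 6 (annotation), 1 or 2 (coordinate), 6 (exon) | 2 |
| `window_size` | bp per window, absolute method | 50 |
| `block_windows` | comma list of window/bin counts, one per block (n_refpoints+1) | — |
| `block_extents` | alternative to `block_windows`: block spans in bp, each a multiple of `window_size` | — |
| `block_aligns` | per-block alignment override; first must be `right`, last `left`, interior default `split` | derived |
| `split_fraction` | fraction of a split block aligned to its 5' anchor | 0.5 |
| `flank_extent` | bp span of the two flank blocks (required for relative method) | derived |
| `statistic` | `mean` \| `median` \| `min` \| `max` | mean |
| `smoothing` | sliding-window span on the aggregate (1 = off) | 1 |
| `orientation_subgroups` | comma list of `up-down` pairs (`tandem-convergent`, `divergent-tandem`, ...) or `all` | none |
| `min_length` / `max_length` | feature length filter, bp | — |
| `chrom_include` / `chrom_exclude` | chromosome whitelist / blacklist | — |
| `name_exclude` | feature names to drop | — |
| `exclude_overlapping` | drop features with overlapping or nested neighbors | false |
| `chunk_limit` | max data lines buffered while reading (results are identical for any value) | unlimited |
| `missing_as_zero` | treat uncovered bases as signal 0 instead of missing | false |
| `output_dir` / `prefix` | output directory and filename prefix | `.` / empty |
| `individual` | also write per-feature profile TSVs | false |
| `sort_key` / `sort_descending` | individual-profile row order: `input` \| `length` \| `name` | input / true |
| `y_min` / `y_max` | fixed y-axis range for plots | auto |
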