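# Four-reference-point absolute-method run over a compact genome:
# five blocks (upstream annotations, upstream intergenic, reference
# features, downstream intergenic, downstream annotations) at 50 bp
# resolution covering up to 1 kb / 500 bp / 1.5 kb / 500 bp / 1 kb,
# mean aggregate with SEM, smoothing of six sliding windows, keeping
# non-mitochondrial, non-overlapping genes and splitting by the
# orientation of the flanking annotations.
analysis_mode = annotation
method = absolute
n_refpoints = 4
window_size = 50
block_windows = 20,10,30,10,20
statistic = mean
smoothing = 6
chrom_exclude = chrM
exclude_overlapping = true
orientation_subgroups = tandem-convergent,divergent-tandem
dataset = fixtures/signal.bedgraph
group = fixtures/all_genes.txt
annotations = fixtures/annotations.tsv
output_dir = results
prefix = demo_
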