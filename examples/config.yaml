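# Demo pipeline configuration: simulate a Chr19-like triploid population and
# run the full analysis. Generate the input files first:
#     python examples/make_inputs.py
# then:
#     hdnacap run --config examples/config.yaml --seed 42 --out results/demo
markers: examples/markers.tsv
chromosomes: examples/chromosomes.yaml
chrom: Chr19
genotype_label: demo
tracks:
  methylation: examples/methylation.bedgraph
  ltr_gypsy: examples/ltr_gypsy.bedgraph
  low_complexity: examples/low_complexity.bedgraph
  gene_density: examples/gene_density.bedgraph
  recomb_rate: examples/recomb_rate.bedgraph
simulate:
  n_individuals: 83        # the larger of the two study population sizes
  missing_rate: 0.02
  # params / weights blocks are optional; defaults are the package's
  # illustrative study conditions
subsample_sizes: [14, 24, 41, 60, 79]
subsample_reps: 25
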