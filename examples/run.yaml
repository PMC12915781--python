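# Full-pipeline configuration for `tamscan run --config examples/run.yaml`.
# Paths are relative to where you invoke tamscan.
fasta: demo/data/genome.fa
mask_bed: demo/data/mask.bed
gff3: demo/data/genes.gff3
coverage:
  - {path: demo/data/coverage_adult_control.bedgraph, stage: adult, condition: control}
  - {path: demo/data/coverage_neonate_control.bedgraph, stage: neonate, condition: control}
mutations:
  - {path: demo/data/mutations_G1.vcf, genotype: G1}
  - {path: demo/data/mutations_G2.vcf, genotype: G2}
  - {path: demo/data/mutations_G3.vcf, genotype: G3}
outdir: demo/out
window_configs: [[10000, 1000], [1000, 100]]
metrics: [depth_tpm, breadth_pct]
n_permutations: 10000
tie_rule: strict_greater
gc_band: [0.30, 0.50]
seed: 7
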