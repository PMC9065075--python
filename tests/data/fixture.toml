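[run]
outdir = "fixture_run"
seed = 7

[simulate]
line_names = ["CTL", "SEL", "CMP"]
control = "CTL"
focal = "SEL"
x_contigs = ["chrX"]
planted_regions = [["chr1", 100001, 150000]]
effective_size = 50
generations = 20
selection_coefficient = 0.5
samples_per_line = 10
seed = 7

[simulate.contig_lengths]
chr1 = 500000
chrX = 300000

[simulate.sites_per_contig]
chr1 = 500
chrX = 300
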