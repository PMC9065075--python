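# Methods

## The scan

**Per-site estimator.** Differentiation between a selected line and the
unselected control is measured per biallelic SNP with the Weir–Cockerham
(1984) moment estimator for two populations. From each population's called
diploid sample size `n_i`, alt-allele frequency `p_i` and observed
heterozygote frequency `h_i`, with `r` populations (here r = 2):

```
n̄  = Σ n_i / r
n_c = (Σ n_i − Σ n_i² / Σ n_i) / (r − 1)
p̄  = Σ n_i p_i / Σ n_i
s²  = Σ n_i (p_i − p̄)² / ((r − 1) n̄)
h̄  = Σ n_i h_i / Σ n_i

a = (n̄/n_c) [ s² − ( p̄(1−p̄) − ((r−1)/r) s² − h̄/4 ) / (n̄ − 1) ]
b = (n̄/(n̄−1)) [ p̄(1−p̄) − ((r−1)/r) s² − ((2n̄−1)/(4n̄)) h̄ ]
c = h̄ / 2
θ̂ = a / (a + b + c)
```

A site is uncomputable when a population has no called individuals, when
n̄ = 1 (the within-population term divides by n̄ − 1), or when
a + b + c = 0 (monomorphic across the pair); such sites are excluded and
counted, never silently zeroed. Negative θ̂ (sampling noise around zero) is
kept, because the window statistic averages raw per-site values — this
matches what vcftools prints and keeps the null mean unbiased (measured
null mean ≈ 1e-4 at n = 50, 20,000 sites). A clamp-to-zero flag exists but
is off by default.

**Windows.** Windows of 50 kbp advance by 25 kbp from position 1 of each
contig; trailing truncated windows are kept. Membership is 1-based
inclusive, so each interior site contributes to exactly two windows.
Windows with fewer than 10 scored SNPs are dropped. The window statistic is
the unweighted arithmetic mean of per-site θ̂; a `weighted` switch computes
the ratio of sums Σa / Σ(a+b+c) instead, which down-weights low-information
sites, but the mean is the default because it is what the windowed z-scores
downstream are defined on.

**Standardization.** Within one contrast, window means are converted to
z-scores with the class mean and sample standard deviation (ddof = 1),
computed separately for the pooled autosomes and for X-class contigs. The X
is standardized apart because its smaller effective population size gives
it a different drift scale; pooling it with autosomes would shift both
distributions. A class with fewer than two windows or zero variance is a
hard error — there is no deviation scale to standardize against.

**Calling rule.** Only windows that survived the min-SNP filter in the
focal table *and* every retained comparison table are eligible; this
prevents a window that was never scored in some line from passing by
absence. Per table, thresholds are quantiles of z-Fst over the eligible
windows — the (1 − 0.15) quantile for the focal high flag, the 0.25
quantile for each comparison low flag — using linear-interpolation
(type 7) quantiles with inclusive comparisons (≥ high, ≤ low), so ties at
the threshold are called. Thresholds pool both chromosome classes after
their separate standardization. A window passes when the focal flag and all
low flags hold; passing windows that overlap or abut merge into maximal
regions (1-based inclusive internally, exported as 0-based half-open BED).

**Genes and enrichment.** Genes are `gene`-type GFF3 features; biotype
comes from `gene_biotype`/`biotype`, defaulting to "unknown" (counted as
non-coding). A gene is reported when it overlaps any called region by at
least 1 bp under inclusive coordinates. Over-representation of gene-set
terms in the overlapping gene list uses the one-sided hypergeometric upper
tail P[X ≥ k] and the enrichment ratio (k/n)/(K/N); the universe is all
genes of the supplied annotation, the reference-set choice of
WebGestaltR-style "genome" analyses. No term-size filter or FDR cutoff is
applied when writing results; filtering is the caller's decision. BH
adjustment is the standard step-up procedure across the tested terms.

## The simulator

The generator emulates the structure of a multi-line selection experiment:
all lines descend from one founder population whose per-site alt-allele
frequencies are i.i.d. Beta(α, β) (default α = β = 1), then evolve
independently for G discrete Wright–Fisher generations of 2N gene copies.
Inside the planted regions of the focal line (only), frequencies are first
updated deterministically by genic selection `p' = p(1+s)/(1+sp)` each
generation. An optional correlated line reuses the focal mask at s/2,
emulating two lines selected for overlapping traits. Genotypes are
Hardy–Weinberg draws (dosage ~ Binomial(2, p)) for `samples_per_line`
individuals; optional missingness is injected uniformly at random.

Reference settings (`default_config`): six lines named after the
Dummerstorf design (FZTDU control, DU6 focal, DU6P/DUK/DUC/DUhLB
comparisons), two 2-Mbp autosomes plus a 1-Mbp X-class contig at one
segregating site per kbp (5,000 sites, 200 windows), three planted 100-kbp
regions aligned to the 25-kbp window step, N = 50, G = 40, s = 0.5, 10
genotyped individuals per line. N and G are set so that neutral
line-to-control differentiation is substantial (window mean θ̂ ≈ 0.3–0.4,
as expected for long-term closed lines) while s = 0.5 over 40 generations
drives planted alleles close to fixation in the focal line; 10 samples per
line reflects a typical re-sequencing cohort for such experiments. These
problem sizes keep a full simulated run under a second while giving every
window ≥ 10 scored SNPs.

What the generator does **not** emulate: linkage and recombination (sites
are independent; window-scale signal exists only because planted sites are
clustered), mutation (0 and 1 are absorbing), sex-specific inheritance (the
X-class contig exists purely to exercise separate standardization),
pedigree structure, and variable sequencing depth or genotyping error
beyond uniform missingness. Passing tests on this cohort therefore
demonstrate the correctness of the counting, estimation and calling
machinery — not the demographic realism of any particular experiment.

## Behaviour of the intersection rule

The calling rule is an *intersection* filter: it is designed for
specificity (a region must look exceptional in the focal line and
unremarkable everywhere else), not for sensitivity. In the simulated
cohort the focal top-15 % flag recovers planted windows essentially
perfectly (measured high-flag sensitivity 1.0 on the reference run). But in
a comparison line's contrast the planted windows are statistically ordinary
— selection acted only in the focal line — so each low flag holds with
probability equal to its quantile mass (25 %), and the conjunction over
four comparison lines retains only a small, seed-dependent fraction of true
sweep windows (0–25 %). This is a property of the rule itself, not of the
implementation: with k comparison lines the expected full-rule sensitivity
is bounded by the bottom-quantile mass, however strong the sweep. The
corresponding strength is a very low false-call rate: under the s = 0
control the called-window fraction is ≈ 0 (≤ 15 % × 25 %ᵏ in expectation).
Users scanning for *candidate discovery* rather than line-specific
certification should inspect the focal high flag (`HIGH_FOCAL` in
`rdd_windows.tsv`) alongside the full `PASS` column.

## Numerical and design choices

- Quantiles: numpy's default linear interpolation (type 7); deterministic
  and the most widely used convention. Recorded in the audit table via the
  flags themselves.
- Thresholds are computed over the eligible-window intersection (after the
  min-SNP filter in all tables), then flags are evaluated on the same set.
- Standardization is per contrast: each line-vs-control table is scaled on
  its own genomic distribution, so a globally more-drifted line is not
  penalized.
- VCF ingestion keeps biallelic SNPs only; indels and multi-allelic records
  are skipped and counted. FILTER is ignored by default (a PASS-only flag
  exists). Phased separators equal unphased; half-missing genotypes count
  as missing. No MAF or missingness thresholds are imposed.
- TSV floats are written with `%.17g`, so staged CLI runs that re-read
  intermediate tables are byte-identical to the monolithic run; reruns of
  the same config are byte-identical (the log format carries no
  timestamps, and all randomness derives from the config seed through
  named, order-fixed substreams).
- The fixture regression (committed reference manifest) uses a 3-line,
  800-site cohort; at that scale the intersection rule typically calls no
  windows, which the regression asserts byte-exactly rather than
  cosmetically inflating the fixture.

## Limitations

- Diploid GT-only VCFs; no genotype likelihoods, no BCF.
- Two-population θ̂ per contrast (the r-population components are
  implemented and tested, but the pipeline only uses pairwise contrasts).
- No permutation significance for z-Fst outliers and no haplotype
  statistics; the quantile rule is a ranking, not a test.
- GO-graph propagation, ortholog mapping and ID conversion are out of
  scope; the enrichment universe is whatever annotation is supplied.
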