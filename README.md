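# quartetscan

Windowed four-taxon introgression scans for population resequencing
data, with truth-labeled coalescent simulation for validation.

## The problem

Given genotypes for a quartet of populations `(P1, P2, P3, O)` — two
sister taxa P1 and P2, a more distant taxon P3 suspected of exchanging
genes with P2, and an outgroup O — the package locates genomic windows
where allele sharing between P2 and P3 exceeds what incomplete lineage
sorting can explain, grades those candidate loci through a cascade of
corroborating filters, and classifies per-locus gene trees to infer the
timing and direction of the gene flow. It is aimed at population
geneticists working from a multi-sample VCF, a sample→taxon map, and
(optionally) a scaffold→chromosome placement map and per-locus gene
trees.

## The statistics

With `p̂_ij` the derived-allele frequency of site *i* in population *j*
(polarized so the outgroup majority allele is ancestral), the per-site
ABBA and BABA weights are

    ABBA_i = (1 − p̂_i1) p̂_i2 p̂_i3 (1 − p̂_i4)
    BABA_i = p̂_i1 (1 − p̂_i2) p̂_i3 (1 − p̂_i4)

and Patterson's **D** = Σ(ABBA−BABA) / Σ(ABBA+BABA), zero under pure
lineage sorting and positive when P2 and P3 share an excess of derived
alleles. The windowed admixture-proportion estimator **f_d** divides
the same numerator by its value with the per-site donor frequency
`p_D = max(p̂_2, p̂_3)` substituted for both P2 and P3. Absolute
divergence **d_xy** = (1/n) Σ [p̂_x(1−p̂_y) + p̂_y(1−p̂_x)] distinguishes
true introgression (reduced P2–P3 d_xy) from shared ancestral
variation, and windowed **F_ST** uses the Weir–Cockerham (1984)
variance-components estimator as a ratio of summed components.

Uncertainty comes from a 50-kb delete-one block jackknife (chromosome
scale) and a moving-block bootstrap with block length ⌈n^(1/3)⌉
(window scale), followed by two-tailed z-tests and Benjamini–Hochberg
FDR control (q = 0.01) applied separately to the D, f_d and d_xy test
families. Candidate windows must clear a reference-locus-calibrated D
threshold, carry more than five valid SNPs per 5 kb, show P2–P3 d_xy
below the chromosome (Mann–Whitney U on 100-bp blocks) and below both
other pairs, and fall inside the 5–40× read-depth band; loci passing
every filter are tiered "well-supported".

## Worked example

Simulate a 500-kb chromosome where a 50-kb tract received a strong
(f = 0.8) pulse from P3 into P2, then scan it, calibrating the D
threshold on that tract:

```python
from quartetscan import (DemographyConfig, IntrogressionEvent, ScanConfig,
                         ResamplingConfig, simulate_quartet_genotypes, run_scan)

demog = DemographyConfig(chromosomes={"chr1": 500_000})
pulse = IntrogressionEvent(donor="P3", recipient="P2", time=2_000,
                           proportion=0.8, windows=[("chr1", 200_000, 250_000)])
matrix, truth, quartet = simulate_quartet_genotypes(demog, [pulse], seed=5)

result = run_scan(matrix, quartet,
                  ScanConfig(reference_region=("chr1", 200_000, 250_000),
                             chromosome_lengths={"chr1": 500_000}),
                  ResamplingConfig(seed=0))
print(result["counts"])
```

prints (seed 5):

```
{'n_candidates': 3, 'n_significant_D': 3, 'n_significant_fd': 2,
 'n_significant_D_and_fd': 2, 'n_dxy_below_chromosome': 2,
 'n_dxy_lowest_pair': 2, 'n_depth_ok': 3, 'n_well_supported': 2, ...}
```

Three windows clear the calibrated D threshold and SNP-count rule; the
two that fall inside the planted tract also show significant f_d and
reduced P2–P3 d_xy and are tiered well-supported, while a third
high-D window elsewhere (lineage sorting) fails the d_xy comparisons
and is filtered — exactly the false-positive class the cascade exists
to remove. `result["candidates"]` holds the full per-locus table with
pass flags, and `write_outputs(result, outdir)` writes
`windows.tsv` / `chromosomes.tsv` / `candidates.tsv` / `candidates.bed`.

The same pipeline runs from the shell on real files:

```bash
quartetscan scan --vcf calls.vcf --pops populations.tsv \
    --scaffold-map placements.tsv --reference-region chr18:1150000-1250000 \
    --q 0.01 --seed 1 --out scan_out/
```

Gene-tree classification takes newick trees with bootstrap supports
plus a clade map and reports one of six categories (concordant, focal
nested in donor, donor taxon nested in focal clade, focal sister to the
donor clade, other in-clade species involved, uninterpretable) with the
rule that fired, the inferred direction and timing, and the decisive
branch support:

```python
from quartetscan import CladeMap, classify_gene_tree
call = classify_gene_tree(newick_text, CladeMap.from_tsv("clades.tsv"))
print(call.category, call.direction, call.timing, call.support)
```

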