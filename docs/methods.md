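# Methods

## Model and procedure

The pipeline treats introgression detection as a four-taxon problem on
the species topology `((P1, P2), P3), O`. Under incomplete lineage
sorting alone, derived alleles shared by (P2, P3) and by (P1, P3) arise
at equal rates, so the frequency-weighted ABBA/BABA contrast
(Patterson's D) is centered at zero; gene flow between P2 and P3
shifts it positive. Because D saturates and is noisy in small windows,
three corroborating measures are attached to every candidate region:
f_d (an admixture-proportion estimate bounded by the per-site donor
frequency), absolute divergence d_xy (which drops in truly
introgressed regions but not in regions of shared ancestral
polymorphism), and read depth (which flags reference-mapping artifacts
that can mimic allele sharing).

The scan proceeds in the order the modules are laid out:

1. **genotype_io** — biallelic SNPs with QUAL > 30 are read from VCF;
   scaffolds are lifted onto chromosomes via a placement map
   (reverse-oriented scaffolds flipped, unplaced scaffolds kept under
   their own names and excluded from chromosome summaries); fixed
   windows of 5/10/50 kb are tiled from coordinate zero, terminal
   partial windows retained but flagged.
2. **popgen** — sites are polarized against the outgroup majority
   allele; windows get D, f_d, three pairwise d_xy values,
   Weir–Cockerham F_ST, a valid-SNP count and per-taxon mean depth.
3. **resampling** — chromosome-level D uses a 50-kb delete-one block
   jackknife; window-level D and f_d use a moving-block bootstrap
   (block length ⌈n^(1/3)⌉, 1000 replicates by default); both feed
   two-tailed z-tests and per-family Benjamini–Hochberg control.
4. **pipeline** — the filter cascade: per-size D thresholds calibrated
   as the maximum window D over a reference locus with an a-priori
   introgression signal; a strict valid-SNP minimum (> 5 per 5 kb,
   scaled proportionally to window size); merging of nested multi-scale
   windows into unique loci (smallest significant interval wins, all
   supporting sizes recorded); the d_xy-versus-chromosome Mann–Whitney
   comparison on 100-bp blocks; the lowest-pair d_xy rule; the 5–40×
   depth band; and tiering, with "well-supported" reserved for loci
   passing all five flags.
5. **topology** — per-locus gene trees are rooted on the outgroup and
   classified by ordered rules R0–R5 (see the module docstring) into
   direction/timing categories; calls below the decisive-branch support
   threshold (default 80) are demoted to uninterpretable, and
   original/extended-window disagreements are reported rather than
   resolved.
6. **simulate** — msprime coalescent simulation of the quartet with
   optional admixture pulses, used both as the test bed and as a
   user-facing generator of truth-labeled data.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| min QUAL | 30 | phred | conventional good-quality call floor |
| window sizes | 5, 10, 50 kb | bp | small enough to isolate single loci, large enough for tens–hundreds of SNPs |
| jackknife block | 50 000 | bp | exceeds typical insect LD, so blocks are ~independent |
| bootstrap blocks | ⌈n^(1/3)⌉ | sites | standard optimal moving-block length |
| bootstrap B | 1000 | replicates | SE Monte-Carlo error ≈ 2% |
| FDR q | 0.01 | — | one expected false candidate per hundred |
| valid SNPs | > 5 per 5 kb | count | guards against single-site windows (strict inequality) |
| depth band | [5, 40] | × coverage | below: mapping dropout; above: collapsed repeats |
| support threshold | 80 | bootstrap % | only well-resolved decisive branches polarize gene flow |

## What the generator emulates — and what it does not

`DemographyConfig` defaults encode the sampling design the statistics
assume: 4 diploids per ingroup taxon and a single diploid outgroup
(which exercises the outgroup-heterozygote exclusion rule), split times
of 20 k / 60 k / 200 k generations with N_e = 10⁴ (one coalescent unit
between the ingroup splits, hence substantial lineage sorting), and
coalescent-scaled rates chosen so nucleotide diversity is
θ = 4N_e μ ≈ 0.01/bp — the magnitude seen in highly polymorphic
butterfly genomes, giving a 5-kb window on the order of a hundred SNPs.
Only the products 4N_e μ, 4N_e r and the split times in units of 2N_e
enter the statistics, not absolute N_e.

Introgression pulses are mass-migration events with stated donor,
recipient, time and proportion f. Window-confined pulses are realized
by simulating affected and background segments independently, so
linkage does not cross segment boundaries — adequate for windowed
statistics, wrong for anything that needs genome-scale LD (which the
package does not compute). The realized donor-ancestry fraction
recorded in the truth table is measured from a census layer placed just
above the pulse time; with 8 recipient lineages per segment it is
binomially dispersed around f, which is real coalescent behavior, not
noise to be removed. Read depths are i.i.d. Poisson: no GC bias, no
mapping-quality structure. Mutations follow msprime's default model
with multi-hit sites dropped; there is no selection, no gene
conversion, and no genotyping error, so passing tests demonstrate
statistical correctness of the pipeline, not robustness to upstream
calling artifacts.

## Numerical choices

- Frequencies are computed over non-missing alleles per population; a
  site is "valid" only when all four populations have at least one
  called allele after polarization. Sites where the outgroup is at
  exactly 0.5 are excluded by default (`"ref-ancestral"` keeps them).
- f_d is reported only where window D > 0; otherwise it is stored as
  NaN (the estimator is not meaningful for BABA excess).
- d_xy is normalized by contributing SNP sites by default (the input
  VCF carries no invariant sites); per-bp normalization is available
  where a sequence-length denominator is wanted.
- F_ST is the ratio of summed Weir–Cockerham components (weighted
  multi-site form), reported unclamped; monomorphic and
  single-individual sites contribute zeros.
- Jackknife of ratio statistics recomputes the ratio from summed block
  numerators/denominators rather than averaging per-block ratios;
  blocks with zero denominator are dropped.
- Bootstrap replicates with an all-zero denominator are discarded from
  the SE; the estimate itself always comes from the full data.
- BH step-up: NaN p-values are excluded from m and never rejected;
  ties are rejected together; adjusted p-values use the monotone
  cummin transform.
- The Mann–Whitney comparison uses the exact null below 20 locus
  blocks and the tie-corrected normal approximation otherwise.
- Windows with fewer than 8 usable sites get no bootstrap (SE/z/p NaN)
  and are naturally removed by the SNP-count rule.

## Design decisions that were genuinely open

- **Polarization rule.** Derived-allele labeling needs an ancestral
  state; the outgroup-majority rule with exclusion of outgroup
  heterozygotes was chosen because a single diploid outgroup otherwise
  contributes sites with undefined polarity.
- **"Neighboring regions" for the d_xy comparison** are implemented as
  the chromosome-wide 100-bp block population; a flanking-window
  variant was considered and rejected as less stable for short loci.
- **FDR families.** D, f_d and d_xy p-values are adjusted as three
  separate families over the candidate set, matching the three separate
  significance thresholds the cascade applies.
- **Multi-scale merging** reports the smallest selected interval and
  records every window size supporting it; the alternative (union of
  overlapping windows) inflates locus length with low-resolution ends.
- **Gene-tree rules.** Visual genealogy inspection was formalized as
  the ordered rule set R0–R5 with an explicit decisive branch (the
  smallest clade whose composition triggers the rule), so every call is
  reproducible and auditable; rule order puts the focal-species
  rearrangements before donor-taxon nesting because the focal species
  is the hypothesis under test.
- **Validation problem sizes.** The simulation-backed tests use 0.2–2.6
  Mb chromosomes, 200 null replicates for z-test calibration and 50
  replicates for the d_xy direction check; these sizes give the
  binomial/Monte-Carlo resolution the assertions need while keeping the
  default suite practical to run routinely.

## Known limitations

- The jackknife z-test is asymptotic in the number of blocks; on very
  short chromosomes (≲ 20 blocks of 50 kb) it is anticonservative, and
  chromosome-level p-values there should be read with care.
- f_d underestimates the pulse proportion when the pulse is old or the
  donor is diverged; recovery tests therefore target the median over
  many windows, not per-window accuracy.
- The d_xy-reduction filter assumes the comparison chromosome is mostly
  non-introgressed; genome-wide gene flow would mute the contrast.
- Gene trees are consumed, not inferred; classification quality is
  bounded by the tree-building step upstream.
- One leaf per sample: within-individual haplotype conflicts
  (heterozygous introgressed tracts) are out of scope.
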