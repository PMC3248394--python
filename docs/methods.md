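# Methods

This note documents the statistical models implemented in `famassoc`, the
assumptions behind them, the synthetic data the package validates itself
against, and the numerical and design choices made where more than one
reasonable option existed.

## Single-marker tests

### Pedigree disequilibrium test (PDT)

The PDT extends the transmission disequilibrium test to general pedigrees
and remains valid as a test of association in the presence of linkage. Two
kinds of informative units contribute:

* **triads** — an affected child with both parents genotyped and at least
  one parent heterozygous; the contribution is (#target alleles
  transmitted) − (#target untransmitted), which for dosage-coded genotypes
  is 2·child − father − mother (triads with two homozygous parents
  contribute zero automatically);
* **discordant sib pairs (DSPs)** — one affected, one unaffected full sib,
  both genotyped; the contribution is the difference in target-allele
  counts.

Family scores D_i sum these units; Z = ΣD_i / √(ΣD_i²) with Z² ~ χ²(1)
under the null. We implement the *sum*-PDT (unweighted per-family sums) as
the default; the averaged variant (per-family mean over units) is available
via `variant="avg"`. The default follows the classical formulation; no
claim is made about the internal weighting of any particular historical
implementation.

Triads with an ungenotyped parent are dropped rather than reconstructed:
no EM over uncertain haplotypes or missing parental genotypes is attempted,
so only DSP information is used for such offspring. This is a deliberate
divergence from likelihood-based packages that model genotype uncertainty;
it costs some information but keeps the statistic exact and the permutation
null straightforward.

Estimability: a SNP needs at least `min_families` (default 2) families with
an informative unit and a positive denominator; otherwise the result is
flagged not-estimable (p set to 1, never NaN). Two-sided p-values come from
the χ²(1) upper tail throughout. Reported Z values are signed with respect
to the minor allele internally; tables print |Z| together with the
associated (positively scoring) allele.

### Quantitative PDT

For a trait t observed on offspring, each family contributes

S_i = Σ_offspring (t_j − t̄)(x_j − E[x_j|parents]) + Σ_DSPs (t_a − t_u)(x_a − x_u)

where x is minor-allele dosage and E[x|parents] is half the parents' summed
dosage. Centering uses the grand mean over all scored offspring by default
(`centering="family"` centres within family). DSP terms require both sibs
scored; in samples where only affected individuals carry factor scores the
DSP pathway contributes nothing, which matches the design of symptom-factor
analyses restricted to cases. Both pathways are implemented and
config-selectable because conventional gamete accounting reports
discordant-pair gametes without resolving whether unscored sibs entered.
The association direction is reported as the allele whose carriers have the
higher trait mean; the statistic itself is invariant to positive affine
trait transforms.

## Gene-dropping permutation null

Replicate genotype sets preserve founder allele/haplotype frequencies,
marker order, the exact missingness pattern, the pedigree structures and
all phenotypes, while randomising founder alleles and within-family
transmissions. Consequences: (i) single-marker statistics are
null-distributed on replicates even at truly associated SNPs (association
is broken, linkage machinery preserved); (ii) between-marker LD is
conserved through cluster dropping.

Choices:

* **Clustering** — markers join a cluster by adjacent-pair r² ≥ 0.1
  (single linkage on consecutive markers, never across chromosomes);
  complete linkage against all open-cluster members is available.
  Adjacency chaining was chosen as the default because tag-SNP panels have
  short, contiguous blocks; the alternative is one config flag away.
* **r² estimator** — squared Pearson correlation of founder 0/1/2 dosages
  with pairwise-complete observations (composite LD; no phasing).
  Monomorphic markers have undefined r² and become singletons with a
  warning.
* **Frequency estimation** — singleton frequencies are founder allele
  counts; cluster haplotype frequencies come from an EM over unphased
  founder genotypes (all 2^k haplotypes enumerated per cluster; founders
  whose het/missing ambiguity exceeds 4096 expansions are skipped).
  Pedigrees above 70 bits of complexity (bits = 2·non-founders − founders)
  are excluded from estimation but still receive simulated genotypes.
* **Dropping** — founders draw cluster haplotypes i.i.d. from the model;
  children inherit one haplotype per cluster from each parent uniformly,
  with no recombination inside a cluster and free recombination between
  clusters. Clusters are short tag-SNP runs, so intra-cluster recombination
  is negligible at pedigree depth; no recombination map is modelled.
* **Reproducibility** — one named seed per run; replicate i uses a
  substream keyed by (seed, i), so any single replicate can be regenerated
  in isolation. Fully missing founders still receive (then masked)
  genotypes, preserving downstream informativeness patterns.

## Gene-based tests and adaptive staging

Min-P is the smallest single-SNP p in the gene. The truncated product is
Σ log p over p ≤ α_trunc (default 0.01), kept on the log scale to avoid
underflow; an empty selection scores 0 (product 1, least significant).
Not-estimable SNPs contribute p = 1 in replicates, so estimability changes
across drops cannot bias the null.

Empirical significance is p_emp = (r_obs + 1)/(n_perm + 1). Stages run at
100/1,000/10,000/100,000 replicates; a gene continues only while fewer than
ten replicate statistics are at least as significant as the observed one.
Ties count as exceedances (conservative; keeps p_emp ≥ 1/(n+1)); strict
counting is a config flag. Replicates are cumulative across stages — early
replicates are retained and recounted, which minimises compute and does not
bias the count. One whole-dataset drop serves every gene at a given
replicate index, preserving cross-gene correlation for any future
experiment-wide extension.

For independent uniform p-values the truncated-product tail has a closed
form (`zaykin_analytic_p`), used purely as an oracle in validation; real
genes are calibrated by permutation because LD invalidates independence.

## Effective number of tests and LD preservation

M_eff = 1 + (M−1)(1 − Var(λ)/M) with the (M−1)-denominator sample variance
of the correlation-matrix eigenvalues; thresholds are α/M_eff. Correlation
is computed on founders only by default — including relatives inflates
apparent LD — with a flagged full-sample option. Small negative eigenvalues
from pairwise-complete estimation are clipped at zero and logged.

The LD-preservation diagnostic computes M_eff on each gene-drop replicate
and locates the observed M_eff in that distribution with a two-sided
add-one empirical p (2·min of the tail fractions, capped at 1). Two-sided
was chosen as the conservative reading since either direction of LD
distortion (under- or over-stated correlation) would bias the truncated
product. A Wilson 95% interval for the tail fraction is attached as a
clearly-labelled descriptive extra; no claim is made that any external
interval used this method.

## Synthetic data generator

The generator emulates a family study ascertained for multiplex psychotic
illness. What it models:

* **Structure** — nuclear families of 2 + (2 + Poisson(1.5), capped at 6
  children); with probability 0.25 paternal grandparents are added (three
  generations). These sizes give ≈5–6 members per family, matching
  high-density samples of ~1,400 subjects in ~270 families.
* **Diagnosis** — liability L = A + E with polygenic A (founders N(0, h²),
  offspring mid-parent mean plus segregation variance h²/2; h² = 0.8) and
  E ~ N(0, 1−h²). Nested tiers (narrow ⊂ intermediate ⊂ broad ⊂
  very_broad) are normal quantiles of population prevalences
  0.01/0.017/0.025/0.10 — chosen so tier sample counts scale like the
  concentric diagnostic schemes used in family studies of psychosis.
* **Ascertainment** — rejection sampling until a family contains two
  affected first-degree relatives at the narrow tier (parent–child or full
  sibs), mirroring "two or more affected first-degree relatives" study
  entry criteria. Rejection rather than importance weighting keeps the
  semantics of the study design exact.
* **Genotypes** — per-gene haplotype blocks (default 3 SNPs per block,
  within-block r² target 0.4, common block MAF drawn U(0.1, 0.5) per the
  tag-SNP MAF floor); founder haplotypes from a two-component mixture
  (perfect-LD component with weight θ = √r², independent component with
  weight 1−θ), which hits the target haplotype-level r² exactly and is
  infeasible only at r² = 1. Genotypes drop through the pedigree
  Mendelian-ly; missingness is i.i.d. at rate 3×10⁻⁴ (≈99.97% completion).
* **Factor scores** — five correlated latent Gaussians (exchangeable
  correlation 0.3: the symptom dimensions are moderately positively
  correlated) observed only for individuals affected at the broad tier
  (psychosis history), emitted as integer item sums: ten Bernoulli items
  with graded thresholds over the latent plus item noise, mimicking
  checklist summation. Scores are integers in [0, 10], not raw Gaussians.
* **Modifier locus** — an optional SNP adds β per minor allele to one
  factor among affected individuals and nothing to liability. β is stated
  in population score-SD units; the generator converts it to the latent
  coefficient through an analytic item-sum calibration (numeric integration
  of the score's slope and SD against the latent), so the planted condition
  refers to the trait the analysis actually sees. Residual attenuation from
  item-sum saturation at extreme latents is a few percent and is part of
  what the generator deliberately emulates.

What it does **not** model: recombination maps and mutation, genotyping
error, population stratification or immigration, assortative mating,
diagnosis–genotype association (by construction the null for diagnosis is
exact), and missingness that is informative of genotype. Passing tests on
this generator therefore demonstrate correctness of the statistics and the
permutation machinery under the stated model, not robustness to those
real-data complications.

## Validation design and problem sizes

* Worked-example arithmetic (χ² tails, Z², count ratios, threshold
  divisions) is checked to the printed precision of the reference worked
  tables.
* The PDT is checked for exact (1e-12) agreement against an independent
  brute-force enumeration over Mendelian-consistent random families of ≤6
  members; the Nyholt M_eff against symbolic eigendecomposition for M ≤ 5;
  the truncated-product permutation tail against the closed form at 10⁵
  independent-uniform replicates within 3 Monte Carlo SEs.
* Null calibration runs 500 two-SNP genes in 60 families at 1,000
  permutations: gene-wise empirical p-values are tested for uniformity
  (Kolmogorov–Smirnov), and null single-marker Z must have mean within
  3·SE of 0 and variance in [0.8, 1.2].
* Parameter recovery runs 50 independent studies of 200 families with a
  planted 0.5-SD depressive-factor modifier, requiring gene-wise detection
  (min-P empirical p < 0.05 at 200 permutations) in at least 80% of runs
  while the same SNP's diagnosis PDT stays null (median p > 0.1).
* Structural guarantees: every gene-drop replicate is Mendelian-consistent
  with bit-identical missingness; adaptive stage counts are non-increasing.

These sizes were chosen as the smallest that make the statistical
assertions sharp; the engines scale to the full staged 100k-replicate runs
via the same code paths.

## Known limitations

* Haplotype uncertainty is not modelled: ungenotyped parents remove triad
  information instead of being integrated over, so single-marker power is
  slightly conservative relative to likelihood-based implementations.
* The EM enumerates all haplotypes per cluster, capping practical cluster
  size near 12 SNPs; extremely long LD runs should be clustered with a
  higher threshold.
* X-chromosome markers, multi-allelic variants and binary genotype formats
  are out of scope; input is text PED/MAP with a separate tiered phenotype
  table, since a single PED affection column cannot carry four concentric
  diagnostic definitions.
* The empirical p floor is 1/(n_perm+1); findings at the floor are bounds,
  not point estimates, and pushing beyond 10⁵ replicates is a compute
  decision left to the caller.
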