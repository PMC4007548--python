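# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `balsel`. It is written for a maintainer or reviewer
who wants to know *why* the code does what it does; user-facing usage is
in the README.

## Data model and missing data

A region is an `n_hap × n_site` phased 0/1 matrix over biallelic SNVs
with 1-based inclusive coordinates. Gaps and Ns follow an **all-or-none
column rule**: an alignment column with a gap/N in any ingroup sequence
is removed from both the site set and the effective length
`L_effective`, so every per-site statistic is normalised by sequence
screened in *all* chromosomes. This is the simplest convention that is
consistent with per-site θ normalisation; alternatives (per-site sample
sizes) change third-decimal values on realistic gap fractions but
complicate every downstream variance formula. Columns with more than two
ingroup alleles are excluded from the site set (with a warning) but kept
in `L_effective` — they are screened sequence, just not usable as
biallelic markers.

Polarization assigns the outgroup-matching allele as ancestral; sites
where the outgroup is missing or carries a third state stay unpolarized
and feed only folded statistics. Fixed differences are counted at
read time over ingroup-monomorphic callable columns.

## Diversity and neutrality statistics

- π is the mean pairwise Hamming distance over all C(n,2) chromosome
  pairs, computed from per-site allele counts as
  Σ_j 2c_j(n−c_j)/(n(n−1)), divided by `L_effective`.
- θ_W = S/(a_{n−1}·L), a_m = Σ_{i≤m} 1/i.
- Tajima's D uses the original 1989 variance constants. At n=3 both
  variance constants are exactly zero and the statistic is reported as
  undefined rather than ±∞.
- Fu & Li's D* and F* use the folded singleton count (minor-allele count
  of one) and the **corrected variance constants of the
  Simonsen–Churchill–Aquadro follow-up literature**, the set used by the
  common C++ summary-statistics library. The original 1993 printing
  contains typos; which constant set any given published table used is
  often unknowable, so the choice here is documented and verified against
  an independent direct-formula transcription (tests/oracles.py) rather
  than tuned to any published table.
- Undefined statistics (S=0, or the n=3 degeneracy) propagate as
  explicit `None`/exceptions, never as 0.

Significance is reported two ways, mirroring common practice for
candidate regions: an **empirical percentile rank** (midrank convention:
fraction strictly below plus half the ties) against a reference panel of
same-length windows, and a **Monte-Carlo p-value** (r+1)/(m+1) against a
simulated null panel, two-sided as twice the smaller tail capped at 1.

A calibration note: the finite-sample neutral mean of Tajima's D is not
zero — at n=40 and θ=10 per locus it is ≈ −0.11 (confirmed against an
independent coalescent simulator). Tests that check the simulated null
should centre on the simulated distribution, not on 0.

## Coalescent simulator

A Hudson-style ancestral-recombination-graph simulator written in plain
Python, with time in generations throughout; conversion to years happens
only in reporting (generation time g, default 25 years).

- Lineages carry lists of ancestral segments; recombination splits a
  lineage at a uniform point of its span, coalescence merges segment
  lists, creating marginal-tree edges where material overlaps and
  retiring intervals once all n samples have coalesced.
- Demography: piecewise-constant sizes with optional exponential growth
  (closed-form hazard inversion for coalescence waiting times), splits
  (backward mass moves), migration (per-lineage per-generation rates),
  and instantaneous bottlenecks parameterised by the pair-coalescence
  probability F (a Kingman burst of scaled duration −ln(1−F)).
- Mutations are **conditioned on the mutation rate** (fixed-θ Poisson on
  branch lengths, rate θ/(4N_ref) per locus per generation), not on S —
  this keeps the likelihood interpretation of downstream estimators
  clean. Infinite sites with continuous positions, then mapped to
  strictly increasing integer coordinates.
- `theta` and `rho` are per-locus population-scaled parameters relative
  to the first population's present-day size (N_ref).
- Seeding: one config seed; each replicate uses `default_rng([seed, rep])`,
  so any replicate is reproducible in isolation and identical seeds give
  byte-identical ms output.
- The `calibrated_human_3pop` preset (African/European/Asian with
  out-of-Africa and per-population bottlenecks, recent expansions, low
  migration switched off before the Eurasian split) stores its constants
  as program data in `data/calibrated_human_3pop.json`, reproducing the
  best-fit calibrated model commonly used for human-demography nulls.

**Balanced mode** is a structured coalescent with two allelic classes at
a focal site: within-class coalescence at rate scaled by the class
frequency, symmetric class switching at a configurable rate (weighted by
the opposite class frequency), and a forced class merger at the allele
age T_b. The sample is split across classes deterministically at the
equilibrium frequency (conditioning on the polymorphism being observed),
so whenever both classes are sampled the root necessarily predates T_b —
the deep-two-clade genealogy that long-term balancing selection
produces. Balanced mode models a non-recombining LD block (rho must be
0), matching how genealogy-based analyses select a high-LD subregion.

Validation: E(T2)=2N, E(TMRCA)=4N(1−1/n), E(S)=θa_{n−1}, E(π)=θ, KS
uniformity of positions, and a distributional cross-check of S against
msprime (note msprime's ploidy=1 timescale is N, not 2N; the cross-check
uses ploidy=2 with n/2 individuals).

## F_ST

Weir–Cockerham (1984) variance components with haploid samples (the
within-individual heterozygosity terms vanish), θ = a/(a+b); negative
estimates are reported as computed. Windows advance in SNP-index space
(20 SNPs, step 3 by default) and combine sites by ratio-of-sums of the
per-site components, the standard multi-site weighting; the final
partial window is reported but flagged. Full hierarchical (region ×
population) F_ST is out of scope; multi-population WC is the documented
substitute.

Percentiles everywhere use the **classic nearest-rank** definition (the
ceil(p·N)-th smallest value), applied identically to the MAF-class
thresholds (50 quantile classes over the pooled-panel MAF, empty classes
merged leftward) and to reference-window thresholds. Outlier flags are
*strictly above* the class threshold. Note an intrinsic capacity limit:
a class-conditional 95th-percentile rule can flag at most ~5% of each
class, so planted-signal fractions at or above 5% cannot be fully
recovered regardless of implementation.

## ML-HKA

Counts are modelled as independent Poissons: E[S_i]=k_i·θ_i·L_i·a_{n_i−1}
and E[D_i]=θ_i·L_i·(T+k_i); the k inside the divergence expectation is
the ancestral-polymorphism correction, scaled by selection because
balancing selection deepens the ancestral coalescent too. For fixed
(T, k) the θ_i maximising the likelihood are closed-form,
(S_i+D_i)/(L_i(k_i·a_i+T+k_i)), so the fit profiles θ out and optimises
only log T and log k by multi-start L-BFGS-B — deterministic given the
start seed, in place of the original method's MCMC, with the same
inference target. The LRT uses 2ΔlnL against χ² with df = number of free
k parameters; the selection fit is seeded from the neutral solution so
nesting holds numerically.

Calibration caveat, by design: the χ² LRT is calibrated under the
Poisson sampling model (the parametric bootstrap in
`simulate_hka_counts`). Genuine coalescent polymorphism counts are
overdispersed (Var(S)=θa₁+θ²a₂ ≫ E(S)), which makes the test
anticonservative on fully coalescent data — a known property of the
method, not of this implementation. Point estimation is unaffected:
median k̂ on coalescent-simulated neutral data sits slightly below 1
(≈0.85; the median of right-skewed S lies below its mean) with mean ≈1.

## LD, blocks, network

Phased input makes two-locus gamete counts exact; D, D′ and r² are
direct counting, no EM. The D′ confidence interval is the 5th–95th
cumulative of the multinomial gamete-count likelihood over a 101-point
|D′| grid with allele frequencies fixed at sample values. Blocks follow
the confidence-interval ("strong LD") definition: strong pairs have CI
lower bound > 0.70 and upper bound ≥ 0.98, strong recombination means
upper bound < 0.90; a candidate span needs its outermost pair strong and
≥95% of informative pairs strong; longest spans win without overlap;
MAF < 0.05 sites are ignored. Small samples (n≈6) produce CIs too wide
for any block — the expected behaviour, reported as an empty set.

The median-joining network iterates minimum-spanning-network
construction (Kruskal by distance classes over components) with median
(majority-of-triplet) vectors for every neighbour pair of every node,
then prunes unsampled nodes of degree ≤2; ε defaults to 0 (sparsest
network) and candidate ordering is lexicographic for determinism. On
recombination-free infinite-sites data the result is the mutation tree:
each segregating site labels exactly one edge. The MRCA node is the
all-ancestral haplotype (requires polarization). The clade split removes
the heaviest **bridge** (ties broken toward the smallest leftmost site
index); a split is flagged weak when the cut carries ≤1 mutation or
strands a single chromosome.

## TMRCA and N_e

μ_year = F/(2·L·t_split) from F fixed differences to the outgroup
(default split 6 Myr, g=25 yr). The estimator is the mean derived-allele
load per chromosome divided by μ_year·L: because coalescent trees are
ultrametric in real time, every chromosome's distance to the
all-ancestral MRCA estimates μ·TMRCA, making the estimator unbiased
under neutrality (verified: mean within 10% of 4N_e(1−1/n)·g over 500
replicates at N_e=18,000, n=40). Sites violating four-gamete
compatibility are removed first by greedy maximal-violation deletion
(sites only, never chromosomes; leftmost on ties), and the result is
audited against a full pairwise four-gamete check in tests.

The SD is a **parametric bootstrap**: constant-size coalescent
replicates at the N_e implied by the data's per-locus Watterson θ and
the calibrated μ, estimator applied to each, SD across replicates;
seed-reproducible, method-tagged in output. N_e = θ/(4·μ_locus); the θ
feeding it defaults to Watterson's estimate (a genealogy-ML θ would be
an alternative; the substitution is tagged in the output).

## Synthetic data: what it does and does not emulate

The simulator generates the study conditions the pipeline targets:
~40 chromosomes per population, ~5-kb regions, tens of segregating
sites, three-population human demography, and an optional ~4-Myr-old
balanced polymorphism producing two deep clades. It does **not** emulate
sequencing error, alignment gaps (beyond the mask machinery), recurrent
mutation, gene conversion, or SNP ascertainment bias; passing tests
therefore demonstrate correctness of the estimators and the qualitative
detectability of the balancing signature under the model, not robustness
to those artefacts on real data.

## Problem sizes

Test-suite and acceptance-script replication counts are chosen so the
Monte-Carlo standard error is several times smaller than each assertion
band: 10,000 replicates for the closed-form simulator checks, 2×2,000
for neutrality-test size (thresholds from one batch, rejection measured
on a fresh batch), 500 for TMRCA recovery, 300 per arm for the
balanced/neutral contrast (clade concordance on 100), 40 datasets for
median k̂, 500/200 for LRT size/power. The whole suite runs in about a
minute on one CPU.
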