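# Methods

## Model

### Haplotype-copying HMM

A study haplotype over S biallelic SNPs is modelled as an imperfect
mosaic of K template haplotypes (the Li & Stephens conditional
likelihood). The hidden state z_j ∈ {1..K} is the template copied at SNP
j. Transitions between adjacent SNPs use a single switch rate:

    p_switch(j) = 1 − exp(−ρ_j / K),        ρ_j = 4 · Ne · d_j,

with d_j the genetic distance in Morgans between SNPs j and j+1 and Ne
the effective population size. Conditional on a switch the new state is
uniform on all K templates, so the transition matrix is
(1−p)·I + (p/K)·J. Genetic distances are linearly interpolated from the
cumulative-cM map; positions beyond the map ends use constant
extrapolation, and when no map is supplied a constant 1 cM/Mb map is
substituted (and logged).

Emission allows a per-site copying error: the observed allele equals the
template allele with probability 1−λ. By default

    λ = θ / (2(θ + K)),   θ = ( Σ_{i=1}^{K−1} 1/i )^{−1},

recomputed for whichever template count is active (k for phasing, k_hap
for imputation), so the assumed error rate shrinks as templates
accumulate; λ can be overridden in `ModelParams`. For K = 1 the harmonic
sum is empty and θ is taken as 1.

Untyped SNPs are included in the HMM's site grid as missing-observation
columns (emission 1 for every state). The forward–backward pass therefore
produces exact state marginals γ at every position, and

    P(allele 1 at untyped SNP) = Σ_z γ_z · [ (1−λ)·1{template_z = 1} + λ·1{template_z = 0} ].

This choice (rather than interpolating γ between flanking typed SNPs) is
exact within the model and is verified against brute-force path
enumeration in the tests. The cost remains linear, O((S_typed +
S_untyped)·K) per haplotype.

### Diploid phasing updates

Phase is sampled by forward filtering / backward sampling over the
template-*pair* chain. We run the ordered pair chain with K² states: by
exchangeability of the two chains it induces exactly the same
distribution over unordered configurations as the unordered k²/2
formulation, and the factorized transition (each chain switches
independently) keeps the update at O(S·K²) using row/column sums rather
than a K²×K² matrix. The diploid emission at a typed SNP sums the two
haploid emissions over the allele assignments consistent with the
genotype (both orderings at heterozygous sites); missing genotypes emit 1.
After a state path is sampled, per-site alleles are drawn from the
emission-consistent assignment posterior, so the returned haplotype pair
is genotype-consistent at every non-missing site; at missing sites the
two alleles are drawn independently given the states.

### Surrogate-family selection

Within the active (buffered) chunk, candidate templates are ranked by
Hamming distance to the query haplotype at the typed SNPs. All haplotypes
strictly below the count-th order statistic are kept; remaining slots are
filled by a uniform draw from the haplotypes exactly at the boundary
distance, so exactly the requested number of states is used. For phasing
updates the candidate pool is all reference haplotypes plus the other
study individuals' current haplotypes (never the pair being updated);
k/2 templates are taken per haplotype of the pair, the union deduplicated
and topped up from the pooled ranking. For imputation updates the pool is
reference-only and the k_hap nearest are taken per sampled haplotype.
Selections are recomputed at every sweep; caching them after early sweeps
is a possible future optimisation. Requests larger than the pool are
clamped with a logged warning.

### MCMC schedule and output

Defaults: 30 sweeps, 10 burn-in, k = 80, k_hap = 500, Ne = 20 000.
Phase is initialized genotype-consistently (fair coin at heterozygous
sites; missing sites drawn from the reference allele frequency), and the
first sweep ranks distances against this initialization. Genotype
triples from post-burn-in sweeps are averaged with equal weight. Typed
SNPs at which an individual's input genotype is missing are masked for
that individual in the imputation step (treated as untyped) and reported
separately. The two haplotypes of an individual are combined under
conditional independence given the reference: P(G=g) sums the products of
the two haploid allele probabilities over allele pairs summing to g.

Long regions are tiled by non-overlapping 5-Mb core chunks with 250-kb
buffers on each side; each chunk is analysed independently (one RNG
stream per chunk, spawned from the run seed, so results are reproducible
and chunk-parallelizable) and only core-interval results are kept when
stitching. Buffers absorb HMM edge effects: state information decays like
exp(−ρ/K) across the buffer, which is negligible at default settings.

## Evaluation harness

Accuracy at a masked SNP is the squared Pearson correlation between true
genotypes {0,1,2} and imputed dosages [0,2], with R² = 0 when either
vector is constant (no association power) or fewer than two complete
pairs remain; SNPs degenerate in both truth and dosage are counted as 0
and flagged separately. Mean R² is reported overall and within half-open
MAF bins (lo, hi] covering (0, 0.5], with an option to drop MAF < 1%
SNPs whose estimates are unreliable; the count-weighted bin means
recombine exactly to the overall mean. MAF is always computed in the
validation (target) individuals. Two masking protocols are provided:
leave-one-out over the individuals of a phased panel, and every-n-th-SNP
masking repeated in a sliding window so each SNP is masked exactly once.

Panels are ordered by divergence using Hudson's F_ST estimator with
finite-sample correction, averaged as a ratio of sums across shared
polymorphic SNPs. The corrected estimator is slightly negative for
identical panels, so the final ratio is clamped to [0,1]; only the
ordering it induces is consumed downstream, which limits sensitivity to
this choice.

## Synthetic data generator

The generator produces the structure the method exploits without a
coalescent or forward simulation:

* ancestral allele frequencies ~ Beta(0.3, 0.3) (U-shaped, mimicking a
  low-frequency-rich site frequency spectrum), positions uniform on the
  region;
* a shared pool of 20 ancestral founder haplotypes drawn Bernoulli from
  those frequencies;
* per population: a Balding–Nichols frequency draw
  p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with split depth F, and a founder
  pool in which each ancestral founder allele is resampled from p_pop
  with probability F. F_ST between populations therefore grows with the
  split depths while haplotype backbones stay shared in proportion to
  1−F — the cross-population allele sharing that makes cosmopolitan
  panels useful at low-frequency variants;
* within-population haplotypes as imperfect mosaics of the founder pool
  (switch probability 1−exp(−r·gap) with r = 10⁻⁵/bp, i.e. ~100-kb
  segments; per-site mismatch 0.002), giving local haplotype sharing and
  LD decay with distance.

Defaults describe a desk-scale panel: 3 populations × 200 haplotypes,
2 Mb, ~5 SNPs/kb before ascertainment, split depths (0.01, 0.05, 0.15),
1 cM/Mb. Typed-SNP sets are produced either by array-like thinning
(sampling without replacement with weight ∝ MAF above a floor, to a
target density) or by low-coverage discovery ascertainment: each SNP is
discovered independently in each population with a user-supplied
probability curve over variant-allele counts (non-decreasing, zero at
count 0; no default values are claimed), and the retained set is the
union over populations with genotypes kept everywhere.

What the generator does **not** emulate: recurrent mutation, gene
conversion, selection, genotyping error in the study data, realistic
variation in recombination rate, or deep demographic structure
(admixture, bottlenecks). Passing tests on this generator show that the
engine recovers haplotype-sharing signal of the kind it models — they do
not certify accuracy levels on real human data.

## Numerical choices

* Forward/backward messages are rescaled per site; with λ > 0 total
  likelihoods cannot vanish, so log-domain arithmetic is unnecessary.
* All selection and sampling randomness flows from a single numpy
  Generator per chunk; the compiled kernels receive pre-drawn uniforms,
  so results are independent of the compiler's RNG and bit-reproducible
  for equal seeds.
* Boundary ties in template selection are the only stochastic element of
  selection; the below-boundary set is deterministic.
* Site matching between study and reference requires identical position
  and allele pair (in either order, flipping genotypes when swapped);
  conflicting sites are dropped with a warning.
* Genetic maps with duplicate positions keep the first entry; decreasing
  cumulative cM is a format error.
* Monomorphic reference sites are retained; the HMM simply emits the
  fixed allele.

## Problem sizes used in tests and the acceptance script

HMM exactness uses instances with ≤ 5 sites and ≤ 4 templates (path
enumeration is exponential); sampler calibration uses a 3-site,
3-template instance with 20 000–50 000 draws. The accuracy experiments
use a 600-haplotype, 3-population panel over 2 Mb at 1 SNP/kb with 25
study individuals and 30 MCMC sweeps — the full default panel density is
exercised once in the end-to-end smoke run. Mean R² in these experiments
is evaluated at untyped SNPs polymorphic in the validation individuals,
mirroring cross-validation on genotyping-array SNPs (which are
polymorphic by construction); low frequency means MAF < 5% in the
validation set. Chunking consistency uses a deterministic fixture
(homozygous study genotypes force the phase; k_hap equal to the panel
removes selection ties) so chunked and unchunked runs are comparable to
floating-point accuracy.

## Known limitations

* Scenario-A only: reference haplotypes must share one SNP set;
  multi-panel references typed on different SNP sets are out of scope.
* No pre-phasing mode; phase is re-sampled every sweep.
* Biallelic SNPs only; no indels, multiallelic sites, or chromosome-X
  ploidy handling.
* The candidate pool for phasing mixes study and reference haplotypes
  purely by distance rank, with no fixed mixing proportion.
* k_hap selections are recomputed every sweep; no divergent-haplotype
  caching.
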