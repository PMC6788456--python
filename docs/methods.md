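# Methods

## The model

`heatnorm` analyses dairy test-day records under a multi-trait
repeatability reaction-norm model in which each of the first three
lactations (parities) is treated as a separate trait.  A record of cow *n*
in parity *l* taken on herd-test-day *k* at days-in-milk class *m* is

    y_klmn = HTD_kl + DIM_m + a_nl + pe_nl + (v_nl + q_nl) * f(THI) + e_klmn

where `a` and `v` are the general (intercept) and thermotolerance (slope)
additive genetic effects, `pe` and `q` the analogous permanent-environment
effects, and `f(THI) = max(0, THI - 68)` is the broken-stick heat load of
the test day.  The (co)variance structure is

    Var[a; pe; e] = blockdiag( A ⊗ Φ,  I ⊗ Ψ,  I ⊗ R )

with A the pedigree numerator relationship matrix, Φ and Ψ 2p×2p
(co)variance matrices over the (intercept, slope) pairs of the p modelled
parities, and R diagonal with one residual variance per parity.  The
implementation is generic in p: the standard run uses parities (1,2,3) and
6×6 Φ/Ψ; single-parity runs (p=1, 2×2 matrices) are used for
desk-scale recovery experiments.

Derived parameters follow from the reaction-norm algebra: the additive
variance at heat load f is `σa² + f²σv² + 2fσav`, heritability divides that
by the total of genetic, permanent-environment and residual variance at f,
and the general-by-thermotolerance correlation `fσav / √(σa²·f²σv²)`
reduces to `σav/√(σa²σv²)` for any f > 0.

## Heat-load covariates

Hourly THI is `(1.8·temp + 32) − (0.55 − 0.55·rh)(1.8·temp − 26)` with
temperature in °C and relative humidity as a proportion in [0, 1].
Humidity is deliberately taken as a proportion — the coefficient 0.55·rh
only produces sensible indices on that scale — and percent-scale input is
rejected at ingest unless explicitly converted (`rh_percent`).  Hourly
values are averaged per calendar day without diurnal weighting (hours may
be missing; available hours are averaged), and each test day receives the
mean daily THI of the three preceding calendar days, reflecting the lag
between heat exposure and milk-yield response.  The threshold defaults to
THI 68 and is configurable.

## Relationship matrices

* **A⁻¹** is assembled sparsely by Henderson's rules with
  Mendelian-sampling variances from the Meuwissen–Luo inbreeding
  recursion.  Ignoring inbreeding biases A⁻¹ on deep pedigrees, so it is
  always accounted for.
* **A₂₂** (pedigree relationships among genotyped animals) comes from the
  tabular recursion, quadratic in pedigree size and adequate at the scales
  this package targets (thousands of animals).
* **G** is the centred cross-product `ZZ'/(2Σp(1−p))` with observed allele
  frequencies, blended as `0.95·G + 0.05·A₂₂` to guarantee invertibility.
  No further scaling/tuning of G to the A₂₂ means is applied (configurable).
* **H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹]** adds the genomic correction into the
  genotyped block.  Genomic information enters only the gene-mapping
  solve; variance components are estimated from pedigree alone.

SNP quality control removes, in order, sex-chromosome SNPs, monomorphic
SNPs, and SNPs with minor allele frequency strictly below 1%, counting
each SNP under the first filter it fails.  Missing genotype calls are
rejected rather than imputed (the generator never emits them).

## Gibbs sampler

Variance components are estimated in a Bayesian framework.  Location
effects are sampled blockwise — scalars for fixed effects, contiguous
(intercept, slope) pairs per animal×parity and cow×parity — from their
conditional normals using a numba kernel over the fixed CSR sparsity
pattern of the mixed-model coefficient matrix; only the data array is
refreshed each iteration (per-parity residual weights, Φ⁻¹ and Ψ⁻¹ blocks)
through precomputed index maps.  Φ is then drawn from an inverse-Wishart
whose scale accumulates `U'A⁻¹U` over the additive coefficient matrix U, Ψ
from the analogous cow-level cross-product, and each parity's residual
variance from a scaled inverse chi-square of that parity's residuals.

Priors are proper but weak: inverse-Wishart with ν = dim + 2 and scale
equal to the prior-mean matrix (so the prior expectation is the supplied
starting value), and scaled inverse chi-square with ν = 5 for residuals.
Fixed effects carry flat priors; identifiability is handled at design time
by dropping the first DIM class within each parity (HTD and DIM classes
are confounded with a per-parity intercept).  DIM classes are 20 d wide
anchored at DIM 5 ([5,24], [25,44], …, the last class absorbing the
remainder to 305).

Chain-length presets: the desk-scale default is 20 000 iterations with
5 000 burn-in and thinning 10; `ChainSpec.reference_protocol()` provides
the long production protocol (500 000 / 100 000 / 100, retaining 4 000
draws).  All randomness flows from a single seeded generator, so chains
are bitwise reproducible.  A Geweke-style z-score is reported per
component as an advisory convergence diagnostic alongside the trace plots.

Posterior summaries of derived parameters (h², correlations) are computed
per retained draw and then summarised with shortest empirical HPD
intervals — never by plugging posterior-mean components into the formulas,
which is biased for nonlinear functionals.

## Genome scan

GEBVs from the single-step solve are backsolved to SNP effects via
`ŝ = DZ'(ZDZ')⁻ â` with equal SNP weights (D = I) and a spectral
pseudo-inverse (relative eigenvalue cutoff 1e−10): with more SNPs than
animals ZDZ' is singular by construction and ŝ is the minimum-norm
preimage.  Because Z is column-centred, adding a constant to the GEBVs
leaves ŝ unchanged.

Windows of adjacent SNPs spanning `[anchor, anchor + 2 Mb)` are anchored at
every SNP (per-SNP sliding; distinct tiling available by config).  The
window share is 100 × the variance across genotyped individuals of the
window's summed SNP contributions divided by σu², taken as the variance of
the total genomic value Zŝ per component (general vs thermotolerance) and
parity; using the GEBV variance instead is exposed as an option since the
operational definition of σu² is a genuine modelling choice.

## Gene-set analysis

SNPs are assigned to every gene whose interval, extended 15 kb on both
sides (strand-agnostic, 1-based inclusive coordinates), contains them.
Per parity, "relevant" SNPs are those at or above the 95th percentile of
absolute thermotolerance SNP effects (ties at the cutoff are kept rather
than silently dropped); a gene is a candidate when it contains a relevant
SNP in at least two parities.  Enrichment per gene set is the upper-tail
hypergeometric probability (Fisher's exact test), reported at p ≤ 0.05
with an auxiliary Benjamini–Hochberg FDR column that is not used for the
headline call.  The default gene universe is the set of genes with at
least one assigned SNP (configurable), since enrichment against
never-assayed genes is not meaningful.

## Synthetic data

The generator produces data with exactly the structure the model assumes:

* **Pedigree** — discrete generations, random mating; founders (default
  200) and intermediate generations of constant size; a final generation of
  phenotyped females (default 1 500).
* **Genotypes** — founder alleles Bernoulli at frequencies uniform on
  [0.05, 0.5]; gene-drop of unlinked loci through the pedigree (no
  LD-realistic coalescent structure, so linkage-based fine-mapping claims
  cannot be tested on these data — planted QTLs are themselves genotyped
  SNPs).
* **Weather** — sinusoidal annual THI cycle (mean 72, amplitude 9, noise
  SD 2.5), spending ≈65% of days above the THI-68 threshold, emulating a
  subtropical climate with roughly 250 heat-stress days per year.
* **Phenotypes** — breeding-value pairs by the pedigree-recursive rule
  (child = parent average + Mendelian deviation scaled by the
  inbreeding-adjusted variance share), which realises Var = A⊗Φ in linear
  time; permanent-environment pairs i.i.d. with Ψ; herd-wide monthly test
  days, DIM ∈ [5, 305], lactations of ≥ 6 tests by construction;
  herd-test-day and DIM-class fixed effects drawn once per level
  (class-constant, so the generating model matches the fitted model
  exactly).  Optional QTL allele effects are added on top of the polygenic
  draw without re-normalising Φ; the resulting variance inflation is
  reported in the truth object.

Default variance components are published Holstein estimates for milk
(σa² = 9.26/10.03/10.55, 100σv² = 0.94/1.56/1.62, 10σav =
−1.21/−1.17/−2.31, σe² = 7.31/12.97/15.65 across parities 1–3; analogous
tables for fat and protein).  Across-parity intercept and slope covariances
use the published correlations; two quantities are not published and are
filled in by documented conventions: (i) cross-parity intercept-by-slope
covariances by the path rule corr(aᵢ, vⱼ) = cor_gen(i,j)·r_av(j), which
keeps Φ positive definite at the published values, and (ii)
permanent-environment components at half the corresponding genetic ones
(σpe² = 0.5σa², σq² = 0.5σv², σpq = 0.5σav), uncorrelated across parities.
The planted-QTL default picks a common variant (allele frequency near 0.4)
close to the middle of chromosome 1, so that a "large-effect" QTL is
actually expressed in the sample.

## Problem sizes and numerical choices

Recovery experiments in the test suite use single-parity runs of 1 500
cows (≈15 000 records, ≈1 900 pedigree animals) with 20 000-iteration
chains, and genome-scan experiments of 500 cows × 600 SNPs on 3
chromosomes — sizes at which the full pipeline is exercised end to end
while a ten-replicate experiment remains a desk-scale computation.  The
mixed-model solve uses sparse LU and raises if the relative residual
exceeds 1e−8.  The null-calibration experiment for enrichment uses a
2 000-gene universe with 600 candidates, a configuration where the exact
null rejection probability of the discrete hypergeometric test is close to
the nominal 5% for all tested set sizes (10, 50, 200); with very small
universes or candidate sets the test's discreteness makes it conservative,
which is a property of Fisher's exact test, not of the implementation.

## Known limitations

* The tabular A₂₂ and dense G⁻¹/A₂₂⁻¹ inversions are quadratic/cubic in the
  number of genotyped animals; no APY-style approximations are provided.
* Residual variances are homogeneous across THI within parity; no
  heterogeneous-residual bands.
* The lactation curve is modelled only through 20-d DIM classes; no
  splines.
* Gene-dropped genotypes carry no LD beyond pedigree co-segregation.
* The Geweke diagnostic is advisory; no automatic convergence gating.
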