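# Methods

## Overview

`mtphewas` implements a two-stage framework for relating mitochondrial DNA
variation to many phenotypes at once. Stage one is polygenic: for each
trait, a mixed linear model with two random genetic effects — one
structured by a nuclear additive GRM, one by a mitochondrial
allelic-sharing GRM — is fitted by restricted maximum likelihood, and the
mitochondrial component is tested by a likelihood-ratio test against the
nuclear-only model. Stage two is a single-variant scan of the
mitochondrial panel for every trait, so the implied relationship between
per-trait mitochondrial PVE and the number of significantly associated
mtSNPs can be checked rather than assumed.

## Relationship matrices

**Nuclear (additive).** For diploid dosages `x_ij ∈ {0,1,2}` with sample
A1 frequency `p_i`,
`A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))`.
Missing calls are mean-imputed to `2p_i` (zero after centering), the GCTA
convention. Monomorphic sites are excluded with a warning since the
denominator vanishes. Diagonal values average ~1 for unrelated samples
(`1 + F` in general).

**Mitochondrial (allelic sharing).** Additivity has no meaning for a
haploid locus, so relatedness is mean identity-by-state:
`S_jk = (1/m_jk) Σ_i 1[x_ij = x_ik]` over the `m_jk` sites observed in
both samples. Pairwise-complete denominators are used because sharing can
only be assessed where both genomes are observed; a pair with no jointly
observed site is an error. Without missingness
`S = (X Xᵀ + (1−X)(1−X)ᵀ)/m`, hence `S` is positive semidefinite with
unit diagonal and entries in `[0,1]`. A standardized-haploid variant
(`(x−p)/√(p(1−p))` cross-products) is available behind a flag for
sensitivity analysis; the raw sharing matrix is the default and is what
all reported results use. The sharing matrix is deliberately *not*
centered before REML: its large constant component is absorbed by the
fixed-effect intercept and cannot masquerade as signal.

**Principal components.** Nuclear PCs follow the Eigenstrat recipe:
column-standardize genotypes (center `2p`, scale `√(2p(1−p))`,
missing → 0), eigendecompose the sample-by-sample covariance, and take the
top-k unit-norm eigenvectors as scores (k = 2 by default, matching the
covariate set). Sign is fixed by making each component's
largest-magnitude entry positive. No LD pruning is applied before the PCA.

## EM-REML

The restricted log-likelihood used throughout is
`logL = −½(log|V| + log|XᵀV⁻¹X| + yᵀPy)` with
`V = Σ_i σ²_i A_i + σ²_e I` and
`P = V⁻¹ − V⁻¹X(XᵀV⁻¹X)⁻¹XᵀV⁻¹`. The additive constant
`−½(n−p)log 2π` (and the `|XᵀX|` REML-invariance term) is dropped; only
likelihood *differences* enter the LRT, which makes the convention
immaterial there.

Maximization iterates the EM update
`σ²_i ← σ²_i + (σ⁴_i/n)(yᵀPA_iPy − tr(A_iP))` (with `A_e = I`), starting
from an equal split of the phenotypic variance across components.
The update keeps every component non-negative and never decreases the
restricted likelihood, but it crawls near the optimum, so pairs of EM
steps are extrapolated with the SQUAREM scheme; an extrapolated candidate
is accepted only when its likelihood is at least that of the second EM
step, so the recorded iterate trajectory is monotone and the EM map
remains the primitive. Convergence is declared when successive accepted
iterates change the likelihood by less than `tol` (default `1e−6`; the
heavier simulation studies use `1e−5`), within a budget of 200 EM steps;
an unconverged fit is returned flagged, never silently. Components are
floored at `1e−6 × var(y)` to guard underflow. Models with at most one GRM
are evaluated in the GRM eigenbasis, where each iteration costs `O(np²)`
instead of `O(n³)`; the two code paths agree because all quadratic forms
are rotation-invariant.

Standard errors come from the inverse average-information matrix
`AI_ij = ½ yᵀPA_iPA_jPy` at the solution (EM itself provides none). PVE is
`σ²_g / Vp` with `Vp = Σ σ̂²` (fixed-effect variance excluded), and PVE
standard errors use the delta method. Binary traits are analyzed on the
observed 0/1 scale with the same linear mixed model; no liability-scale
or prevalence adjustment is applied, so binary PVE values are
observed-scale quantities.

## Likelihood-ratio test and prioritization

The mitochondrial component is tested with
`LRT = max(0, 2(logL_full − logL_reduced))`. The null value `σ²_mt = 0`
lies on the boundary of the parameter space, so the primary p-value uses
the mixture `½χ²₀ + ½χ²₁` (p = 0.5 at a statistic of 0); the plain `χ²₁`
p-value is reported alongside because conventions differ between tools.
Traits are ranked by p-value; `p ≤ 0.05` flags a trait prioritized and
`p ≤ 0.055` suggestive (both thresholds configurable). The scan stage
still covers all traits by default — prioritization is reported, not
enforced — because the PVE-versus-count correlation that justifies the
filtering step is only observable if unprioritized traits are scanned too.

**Finite-sample calibration.** The `½χ²₀ + ½χ²₁` mixture is an asymptotic
result that additionally assumes the information about `σ²_mt` grows
large. A mitochondrial sharing matrix is dominated by haplogroup blocks,
so the effective number of independent contrasts informing `σ²_mt` is
roughly the number of haplogroup lineages — a small number that does not
grow with sample size. Under null simulations with the default generator
(eight founder haplotypes) the test is therefore *conservative*: the
point mass at zero exceeds ½ (0.60–0.67 across our null studies) and
rejection at mixture-p < 0.05 runs at roughly 1.5–2.5% rather than 5% —
at or just inside the lower edge of the exact binomial band the
calibration test asserts. This is the familiar finite-sample behavior of
variance-component LRTs (conservatism, never anti-conservatism), and it
matches how the same convention behaves in standard GREML tools.
Prioritization decisions based on the mixture p-value are
therefore cautious: a trait that passes is trustworthy, while genuinely
weak mitochondrial signals may need the plain `χ²₁` p-value or larger
haplogroup diversity to surface.

## Single-mtSNP scan

Haploid genotypes are coded 0/1 (single allele dose); effect sizes are
per-allele on that coding (tools that code haploids 0/2 will report
halved betas). Continuous traits use OLS with a Wald t test on the SNP
term; binary traits use maximum-likelihood logistic regression with a
Wald z test, both adjusted for age, sex and the first two nuclear PCs
(statsmodels supplies the fitters). Sites monomorphic within a trait's
complete cases, and logistic fits showing (quasi-)separation, are flagged
untestable rather than dropped silently, and a failing SNP never aborts
the scan. SNPs below 1% MAF are excluded before scanning. Significance is
judged at uncorrected `p < 0.05` by design — the framework is
hypothesis-generating — with per-trait counts compared to the `m × α`
chance line and to per-trait mitochondrial PVE via Spearman rank
correlation (robust to the PVE scale).

A caution about count statistics: mitochondrial SNPs are in near-complete
linkage within haplogroup blocks, so the `m` per-trait tests behave like
a much smaller number of independent contrasts. Individual tests stay
calibrated (permutation nulls average `m × α`), but the per-trait
*count* of significant SNPs is strongly over-dispersed relative to
`Binomial(m, α)`: a chance alignment between a trait and one large
haplogroup can push dozens of SNPs past the threshold at once. Counts
above the chance line should therefore be read together with the LRT
p-value, not as independent evidence.

## Synthetic data generator

The generator provides ground truth for every inference stage. Nuclear
SNPs are unlinked `Binomial(2, p)` draws with `p ~ U(0.05, 0.5)`.
Mitochondrial haplotypes are copies of one of `h = 8` founder haplotypes
(frequencies `Dirichlet(5·1)`) with per-site copy error 0.002, which
induces the block-structured sharing matrix haplogroups produce in real
cohorts; i.i.d. haploid sites would make `S` nearly constant and `σ²_mt`
unidentifiable at a ~100-site panel. A configurable count of designed-rare
sites (carrier rate 0.003) reproduces the sub-1%-MAF tail of real
mitochondrial array content.

Phenotypes realize the variance-component model exactly:
`y = Xβ + g_nuc + g_mt + ε` with each genetic value drawn from the
corresponding GRM's eigendecomposition (tiny negative eigenvalues clipped
to zero and logged). Each component is rescaled so its centered in-sample
variance equals `σ²·E[centered variance under Cov = σ²A]`, i.e.
`σ²(tr(A) − 1ᵀA1/n)/(n−1)`. The correction matters for the sharing
matrix: its constant component is absorbed by the intercept, so naively
rescaling to `σ²` itself would inflate the REML-normalized signal by
~2–3× and bias recovery tests. Binary traits threshold the latent
liability at the empirical prevalence quantile, making case counts exact.
Ages are `N(46.1, 16.8²)` (clipped at 18) and sex is Bernoulli(0.654
female), mirroring a large EMR biobank's demographics. All draws flow
from one seed; every stage is bit-reproducible.

Two ready-made cohorts are provided. `make_biobank_fixture` mirrors the
*structure* of the motivating study at desk scale (default n = 2000,
5000 nuclear SNPs, 130 mito sites of which ~44 fall below 1% MAF, eight
traits — six continuous, two binary — with nuclear PVE ≤ 3% and mito PVE
≤ 0.4%). `make_planted_fixture` (default n = 1500, 2000 nuclear SNPs)
instead plants a single detectable mitochondrial signal
(`pve_mt = 0.05`, the value used throughout the recovery benchmarks) on
one trait and zeroes the rest, giving end-to-end prioritization an
unambiguous right answer; a 0.3% mito PVE — realistic for real cohorts —
is far below what any method can rank reliably at desk-scale n, which is
itself a faithful statement about the power of the design.

What the generator does *not* emulate: linkage disequilibrium among
nuclear SNPs, realistic mtDNA mutation processes or heteroplasmy,
nested haplogroup phylogenies, genotyping error, and EMR missingness
patterns correlated with health status. Passing tests therefore
demonstrate correctness of the estimators under the assumed model, not
robustness to those real-data complications.

## Numerical choices and defaults

| Parameter | Default | Rationale |
|---|---|---|
| REML tolerance on ΔlogL | 1e−6 (1e−5 in simulation studies) | GREML-tool convention; LRT needs ~1e−3 accuracy |
| EM-step budget | 200 | with SQUAREM, fits converge in 40–100 steps |
| Variance floor | 1e−6 × var(y) | keeps V positive definite; EM is non-negative anyway |
| MAF filter (mito scan) | 0.01 | sub-1% sites are untestable at desk-scale n |
| Prioritization α / suggestive | 0.05 / 0.055 | conventional; both reported |
| Scan α | 0.05, uncorrected | hypothesis-generating design |
| PCs | 2 | matches the covariate set |
| BMI plausibility bounds | [10, 100] kg/m² | unit-conversion artefacts are orders of magnitude off |
| Founder haplotypes / mutation rate | 8 / 0.002 | haplogroup-scale clustering with mild within-block diversity |

Simulation sizes in the test and acceptance suites (recovery: 30
replicates at n = 1200, 2000 nuclear / 100 mito SNPs; calibration: 200
replicates at n = 1000 scaled to n = 400; end-to-end: n = 1500) are the
package's desk-scale defaults: large enough for the asymptotics being
tested to bite, small enough to run routinely on a single core.

Degenerate inputs are handled explicitly: all-missing SNPs are flagged and
excluded by the MAF filter; monomorphic SNPs are excluded from GRMs (with
a warning) and flagged untestable in scans; a non-positive-definite V or
singular `XᵀV⁻¹X` raises with a condition-number report; ties in the
prioritization table break by trait name for determinism.

## Known limitations

- Binary traits use the observed-scale linear mixed model; estimates are
  not comparable across prevalences without a liability transformation.
- The boundary LRT is conservative when mitochondrial diversity collapses
  to few haplogroup lineages (see above); power statements should be read
  accordingly.
- The PLINK reader supports the v1.0 SNP-major binary dialect only, and
  treats any heterozygous-coded haploid call as missing — heteroplasmy is
  not modeled.
- Sample-relatedness pruning, LD pruning, and haplogroup inference are out
  of scope; the nuclear GRM assumes the input cohort is nominally
  unrelated.
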