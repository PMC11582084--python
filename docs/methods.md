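# Methods

This note documents the models, the numerical choices and the
synthetic-data conditions behind `karyoevol`, in the order the pipeline
runs them. Nothing here reports an empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Karyotype traits

A karyotype record is a diploid formula over the four Levan morphology
classes — metacentric (m), submetacentric (sm), subtelocentric (st),
telocentric (t); acrocentric is treated as telocentric. Classes are
assigned from the arm ratio r = long/short with bands m [1, 1.7),
sm [1.7, 3), st [3, 7), t [7, ∞), and a missing short arm is
telocentric. Six traits are derived: haploid chromosome number
n = 2n/2, haploid per-class counts, and the fundamental number
fn = 2(m + sm + st) + t (arm count).

Two conventions required a decision:

* **fn scale.** The assembled table prints haploid class counts but a
  *diploid* fn (e.g. *Amoimyrmex striatus*: nm = 10, fn = 44). We store
  fn diploid to match the table and expose `fn_haploid`.
* **fn convention.** Counting m/sm/st as two-armed reproduces most
  published rows exactly (*Ac. balzani* 74, *Ac. heyeri* 62,
  *Ac. ameliae* 66). Five rows disagree (four *Atta* rows printing 40
  where the convention gives 44, and the Brazilian *Ac. ambiguus*
  record printing 68 vs 72); the loader flags these rather than
  adopting either number silently, and analyses use the convention's
  value.

Species with multiple published karyotypes carry one *preferred*
record (the first listed, matching the measurement-based baseline
rule); the per-species analysis table uses preferred records only. The
optional trait transform is log(x + 1), because several traits contain
structural zeros (e.g. nt = 0 in all *Atta*).

## Trees

Trees are rooted, with branch lengths in time units; Newick I/O runs
through dendropy, tip labels are normalized (whitespace trimmed,
underscores read as spaces). Pruning to the taxa with karyotype data
sums branch lengths through suppressed degree-2 nodes, so patristic
distances and ultrametricity are preserved. Polytomies are resolved
deterministically (children ordered by smallest descendant tip) with
zero-length branches; this leaves all likelihoods unchanged.
Ultrametricity is checked at relative tolerance 1e-6; only the OU
transform strictly requires it.

## Phylogenetic signal

* **Moran's I** uses weights w_ij = 1/d_ij (patristic), zero diagonal,
  unnormalized rows, I = (n/S0)·zᵀWz/zᵀz. The weighting is a
  convention choice (the source analysis names the statistic but not
  its weights); it is the standard phylogenetic-proximity default.
  Note that on a perfectly balanced four-tip tree with unit branches
  and a clade-aligned ±1 trait, I is exactly 0 under these weights —
  positive autocorrelation needs the between-clade separation to
  exceed the within-clade distances.
* **Abouheif's C_mean** is the same Moran form with the topology-only
  proximity a_ij = Π 1/(number of children) over the interior nodes on
  the nodal path between i and j, MRCA included. Several published
  dialects of this product exist; ours is fixed by a hand-computed
  three-tip oracle (a_AB = 1/2, a_AC = 1/4 on ((A,B),C)).
* **Blomberg's K** divides the observed MSE0/MSE ratio (GLS mean under
  C; MSE C-weighted) by its Brownian expectation
  (tr C − n/(1ᵀC⁻¹1))/(n − 1), so K ≈ 1 under BM. The test suite
  verifies the calibration (mean K within 0.1 of 1 over 500 BM
  replicates on a 100-tip tree).
* **Pagel's λ** is the ML λ ∈ [0, 1] of the λ-transformed GLS
  likelihood, tested against λ = 0 by a χ²₁ LRT without boundary
  correction (matching the named test in the source table).

Permutation tests (999 reps by default, mandatory seed) are one-sided
greater with p = (1 + #{perm ≥ obs})/(1 + reps); ties count as
exceedances, so p is never 0.

## Trait-evolution models

The trait is multivariate normal with mean root·1 and covariance σ²C
under BM, where C is the shared-path-length matrix. Transforms:
λ scales off-diagonals; δ raises C elementwise to δ (no height
renormalization — the simplest reading; a rescaling would only be
absorbed by σ²); κ raises branch lengths to κ before rebuilding C; OU
uses V_ij = (1 − e^{−2α t_ij})/(2α) · e^{−2α(T − t_ij)} with t_ij =
C_ij, which recovers C as α → 0.

Root state and σ² have closed-form GLS/ML profiles, so each fit is a
1-D bounded search (Brent on five spread sub-brackets, tolerance 1e-8,
bounds re-checked at both ends so boundary optima like λ = 1 are
exact). Bounds: λ ∈ [0, 1], δ ∈ (0, 5], κ ∈ [0, 3], α ∈ [0, 2]; the δ
and α ceilings are deliberately attainable values, since real model
tables report fits pinned at δ = 5 and α = 2. Parameter counts k = 2
(BM) / 3 (transforms); model choice by AICc with n = number of tips.
ML, not REML, throughout. Model tables print −lnL, matching the
convention of published comparative-model tables whose "likelihood"
column stores the negative log-likelihood.

A calibration caveat the test suite documents: the δ estimator on
birth–death trees is noisy and right-skewed (boundary pile-up at 5).
At n = 200 its median for δ = 0.3 data sits around 0.4–0.6, so the
tests assert the discriminative property (medians on either side of 1
for early- vs late-burst data) rather than a tight band around the
truth.

## Rate shifts

Greedy forward trait-MEDUSA-style search. Every internal non-root node
defines a candidate: all branches of its clade, stem included, get a
multiplicative rate scalar (searched in [1e-4, 1e4] on the log scale).
Covariances are assembled as C(w) = Uᵀdiag(w∘len)U over branch
indicators, so a candidate evaluation is one Cholesky, and accepted
shift scalars are re-optimized jointly (Nelder–Mead) after each
acceptance. A branch always takes the rate of its nearest enclosing
shift, so nested shifts refine rather than overwrite. The best
candidate is accepted when AICc improves by more than the cut-off
(defaults 4; 9 as the conservative option). Each shift adds two
parameters (scalar + location, the MEDUSA convention; configurable to
one).

**Minimum clade size.** Candidates are restricted to clades with at
least 5 tips by default. Without this, a near-zero rate fitted to a
cherry or triplet of similar tips collapses the clade variance and
clears any fixed AICc cut-off far too often (measured false-shift rate
~27% at cut-off 4 on 50-tip null data, vs ≤10% with the guard). Set
`min_clade_tips=1` for an exhaustive scan.

## Chromosome-number CTMC

States are haploid numbers on [n_min, n_max]; defaults n_min = 1,
n_max = 2·max(observed) + 2 so one duplication from the largest
observed count is representable. Events from state i: gain i→i+1 at
g (+ g1·(i − n_min) if linear, floored at 0), loss i→i−1 at l (+ l1·…),
duplication i→2i at ρ, demi-duplication i→1.5i at d (equal split to
⌊1.5i⌋/⌈1.5i⌉ for odd i). Transitions leaving the bounds are dropped,
not absorbed — absorbing would inflate the top state. Root prior is
uniform by default (stationary optional). Likelihood is Felsenstein
pruning; ancestral states are standard up–down marginal posteriors.

Model families compared by AIC (k = number of free rates):
gain/loss only, +demi, +duplication, +both, and linear-rate variants.
Fitting is Nelder–Mead on log base rates (linear coefficients on the
natural scale) from spread random starts.

**Matrix exponentials.** exp(Q·b) is computed from a spectral
decomposition of Q validated against Q itself (reconstruction error
≤ 1e-9 relative and eigenbasis condition < 1e10); per-branch
propagation then costs O(k²) matvecs. Whenever the decomposition fails
validation, the implementation falls back to scipy's
scaling-and-squaring `expm`, and any full transition matrix is
row-clipped to [0, ∞) and renormalized (checked to 1e-6). The pruning
likelihood is verified against brute-force enumeration over ancestral
states to 1e-10.

## Karyograph SSE model

State (y, x): haploid chromosome number and haploid arm number, valid
iff y ≤ x ≤ 2y (2y − x uni-armed, x − y bi-armed chromosomes). Moves
and rate laws:

| event | move | rate |
|---|---|---|
| Robertsonian fusion | (y, x) → (y−1, x) | k1·(2y − x), needs ≥ 2 uni-armed |
| centric fission | (y, x) → (y+1, x) | k2·(x − y) |
| telo→meta (arm gain) | (y, x) → (y, x+1) | k3·(2y − x) |
| meta→telo (arm loss) | (y, x) → (y, x−1) | k4·(x − y) |
| polyploidy (M2 only) | (y, x) → (2y, 2x) | k5 |

The per-eligible-chromosome multipliers are the cited karyograph
method's convention; the source analysis does not print them, so they
sit behind a `multiplier` switch (`"constant"` gives per-karyotype
rates). States are haploid; diploid tables are halved on ingestion
(x = fn/2). y_max defaults to 2·max(observed y) + 2.

The chain is embedded in a multi-state speciation–extinction
likelihood with *state-independent* speciation λ and extinction μ
(state-dependent diversification is out of scope). That restriction
has an exact consequence: the extinction function E(t) is the scalar
birth–death extinction probability, and the FitzJohn D-equations
factorize into `exp(Q·t)·D` times the scalar
exp(∫ 2λE − (λ+μ) ds), which has a closed form (stable variants are
used on both sides of λ = μ and for λ = 0 or μ = 0). The default
likelihood engine (`method="exact"`) uses this factorization — it is
exact, not an approximation — while `method="ode"` integrates the full
FitzJohn E/D system per branch with adaptive RK45 (rtol 1e-8, E
constrained to [0, 1] and D to [0, ∞)); the two agree to ~1e-9 in the
tests and the ODE route remains the general-purpose reference.

Internal nodes contribute the usual λ·D_left∘D_right; at λ = 0 the λ
factor is skipped so the model degrades exactly to CTMC pruning (the
λ = μ = 0 equivalence the tests assert). The root uses FitzJohn
weighting (w_i ∝ D_i) by default, flat weighting as an option, and no
survival conditioning. M1 (k5 structurally absent, 6 parameters) and
M2 (7) are fitted by multi-start Nelder–Mead on log parameters, with
M2 additionally seeded from the M1 optimum plus a tiny k5 so the
nesting lnL(M2) ≥ lnL(M1) holds; a violation beyond 1e-6 marks the M2
fit unconverged. The LRT uses plain χ²₁ (matching the named test); the
boundary-corrected halved p is printed alongside. Ancestral (y, x)
marginals are computed on the embedded CTMC — exact under
state-independent λ, μ because every scalar factor cancels in the
normalized posteriors — with the root prior matching the chosen root
weighting.

## Synthetic data

Every generator is a pure function of its arguments and one seed.

* **Trees:** forward birth–death simulation from two root lineages,
  retry on extinction, stopped one exponential waiting time after the
  n-th tip so pure-birth root heights match the Yule expectation
  Σ_{k=2..n} 1/(b·k); extinct lineages pruned. The stop rule has the
  usual mild conditioning bias with extinction, accepted for test
  purposes.
* **Continuous traits:** BM and OU by exact per-branch transition
  sampling; λ/δ/κ by multivariate-normal draws from the transformed
  covariance (equivalent to simulating on the transformed tree).
* **Discrete histories:** Gillespie simulation along branches under an
  arbitrary generator, returning internal-node truth for coverage and
  recovery tests.
* **Karyotype tables:** bi-armed chromosomes spread over m/sm/st by a
  seeded multinomial, uni-armed become t, doubled to diploid and
  formatted so tables round-trip through the formula parser.

What the generators deliberately do not emulate: measurement error in
published karyotypes, intraspecific polymorphism (beyond the duplicate
records carried in the data table), fossil sampling, and
state-dependent diversification. Passing recovery tests therefore
show estimator correctness under each model's own assumptions, not
robustness to their violation.

## Problem sizes used in the tests

The calibration suites run at sizes chosen to make each property
measurable while keeping the default suite practical: Pagel-λ recovery
on 50-tip trees (200 replicates BM and star each), Blomberg-K
calibration on one 100-tip tree (500 replicates), gain/loss recovery
on 200-tip trees (50 replicates, medians within ±50%), rate-shift
type-I on 50-tip trees and 20× detection on 100-tip trees (100
replicates each), and the M1/M2 LRT null calibration on 12-tip trees
with y_max = 7 (50 replicates, rejection ≤ 15% at nominal 5%,
boundary-tolerant). Oracle equivalences (GLS vs dense MVN density at
1e-8, pruning vs enumeration at 1e-10, SSE vs CTMC at 1e-8,
factorized marginals at 1e-6) run on small trees where brute force is
exact.

## Known limitations

* The published headline numbers of the motivating analysis depend on
  an unpublished 26-tip calibrated tree; without it they are structure
  references, not reproducible targets. The package reproduces all
  printed arithmetic identities (AIC/AICc/LRT) and the full karyotype
  table instead.
* δ estimation is imprecise at these tree sizes (see above).
* The greedy shift scan is order-dependent by construction; it returns
  a good nested sequence, not a global optimum.
* ChromEvol-style base-number transitions, MCMC posteriors, and
  state-dependent λ/μ are not implemented.
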