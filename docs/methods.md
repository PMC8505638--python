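# Methods

## The emulated MHE layer

The package expresses every federated algorithm in the operation set of a
multiparty CKKS-style homomorphic cryptosystem without implementing
lattice cryptography. A `CipherVector` is a fixed-width vector of
`num_slots` real slots (default 4096, power of two) under a named key; the
public operations are slot-wise addition, slot-wise multiplication,
negation, and cyclic rotation. The payload is held in a private attribute
with no public accessor: the only path to cleartext is `decrypt()` with
valid credentials (every site's key share for the collective key, or
possession of the querier's key object). Interactive protocols —
`collective_refresh`, `collective_key_switch`, collective decryption —
verify that *all* shares are presented, which is the property that makes
one honest site sufficient to block any disclosure.

Two arithmetic modes:

* **exact** (default) — double-precision arithmetic; isolates algorithmic
  correctness from approximation noise.
* **noisy** — each encryption and each multiplication perturbs every slot
  by an independent zero-mean Gaussian *relative* error of scale
  `2**-precision_bits` (default 40, valid range 20–60). This is the
  simplest model that reproduces the qualitative precision-loss behaviour
  of approximate HE; it does not model the exact CKKS noise growth (which
  depends on moduli and rescaling strategy that are deliberately not
  claimed here). Integer aggregates (the Kaplan–Meier counts) survive the
  noisy mode exactly after rounding for counts up to 1e6 summed over 128
  sites at `precision_bits >= 30`.

Multiplicative depth is accounted per ciphertext (`depth_used`, budget
default 5); an operation that would exceed the budget raises instead of
producing a result. Pipelines route multiplications through a
`RefreshPolicy` that inserts collective refreshes automatically and logs
each as an interactive round in the transcript. Rotation is fixed as a
cyclic *left* shift (negative = right); rotation by `num_slots` is the
identity.

## Transcript and audit

Every inter-party transfer appends one event
`(sender, receiver, step, payload_class, digest)` with payload class
`ciphertext`, `public_query`, or `final_result`. `audit_check` passes iff
every payload between data providers is ciphertext, the only cleartext
messages are the querier's query and the final result delivered to the
querier, and at most one decryption event occurred. A pipeline whose
final result spans several ciphertexts (Kaplan–Meier chunks, the GWAS
`{u, s, yᵀy, q0}` family) logs one logical decryption event for the run.

## Encrypted numerical kernels

**Chebyshev reciprocal.** `1/x` is interpolated at Chebyshev nodes on an
interval `[a, b]` with `0 < a < b` (default `[0.01, 2]`, degree 63).
Interpolation at Chebyshev points is within a small factor of the minimax
polynomial, so the *worst-case* error over the pivot range is controlled —
the reason for preferring it over a least-squares fit, which can diverge
near interval edges.

**Polynomial evaluation** on ciphertexts uses a baby-step/giant-step
(Paterson–Stockmeyer) scheme in the Chebyshev basis: baby steps
T_1..T_m (m = 2^⌈log2(d+1)/2⌉) and power-of-two giant steps built by the
duplication identities, with the series split by Chebyshev division
against T_q. Multiplicative depth is at most ⌈log2 d⌉ + 2 (8 for degree
63) instead of the linear depth of a Clenshaw recurrence; multiplication
by integer 2 is realized as an addition and costs no depth.

**Trace preconditioning.** For an SPD Gram matrix A the scaling
s = 2/trace(A) places all eigenvalues — hence all Gauss–Jordan pivots, by
eigenvalue interlacing — in (0, 2]. The trace is a sum of per-site
scalars, so it is aggregated in cleartext without touching patient-level
data; the inverse is recovered as A⁻¹ = s·(sA)⁻¹.

**Gauss–Jordan inversion** works on `[A | I]` with one ciphertext per row,
so each elimination is one SIMD multiply-subtract. The pivot is broadcast
to all slots by a mask multiplication plus log2(num_slots)
rotate-and-add doublings, its reciprocal evaluated through the Chebyshev
surrogate, and then sharpened by `newton_steps` (default 2) iterations of
r ← r(2 − xr) — pure add/mul, each step squaring the relative error.
Measured on trace-preconditioned 13×13 Gram matrices: max entry error
≈ 3e-7 from the degree-63 polynomial alone, ≈ 4e-18 with two Newton
steps. A validation mode (synthetic runs only) decrypts each pivot and
errors if it leaves the approximation interval. No division other than
the pivot reciprocal is ever performed under encryption; everything else
is deferred to the querier. Dimension is capped at 32 (the covariate
block of a GWAS, not the variant count, sets the dimension).

## Exact GWAS: bordered inverse, minimal decrypted payload

With A = X̃ᵀX̃ inverted once, each variant's OLS on [X̃, g] reduces via
the partitioned-regression (Schur complement) identity to
u = gᵀy − bᵀA⁻¹X̃ᵀy and s = c − bᵀA⁻¹b, computed variant-major so one
ciphertext carries one scalar family for a whole batch of variants
(default batch = `num_slots`). The querier decrypts exactly
{u_i, s_i, yᵀy, q0 = X̃ᵀy·A⁻¹·X̃ᵀy} and finishes in cleartext:

    beta = u/s,  RSS = yᵀy − q0 − u²/s,  MSE = RSS/df,  se = sqrt(MSE/s).

Every decrypted scalar is recoverable from the published (beta, se, MSE)
set, so the protocol releases no statistic class beyond the results
themselves. `df = p − (f+2)` by default (`df_mode="n"` gives `p`);
the reference distribution is the standard normal by default, with a
t-distribution option. P values are clamped at 1e-320 before the log.
A variant is flagged `collinear` (NA statistics) when s ≤ 1e-8·max(s);
the tolerance is scale-relative to the decrypted s family because the
per-variant gᵀg is deliberately *not* part of the decrypted payload.
Negative RSS beyond 1e-6·|yᵀy| raises a numerical-consistency error;
small negatives are clipped to zero.

## Fast GWAS: gradient descent + residualized univariate models

Covariates are standardized against global means/variances computed from
per-site sums (p_i, Σx, Σx²) — additively aggregable scalars handled like
the Gram trace — so the standardized X̃ᵀX̃/p is close to the identity and
a unit learning rate is stable: the full-batch update
w ← w − (lr/p)(X̃ᵀX̃w − X̃ᵀy) contracts linearly for lr < 2/λ_max(X̃ᵀX̃/p).
Defaults: lr 1.0, 50 iterations, refresh every 2 iterations. The
iteration count is fixed rather than adaptive because an encrypted loss
cannot be inspected mid-run without violating the no-intermediate-
decryption contract. Each site computes its gradient as a cleartext
matrix × encrypted vector product; the weight vector is never decrypted.

Residuals y″ = y − X̃w′ are formed homomorphically and stay encrypted at
their site. The univariate stage aggregates, per variant, Σg, Σg², Σg·y″
plus shared Σy″, Σ(y″)², and the querier fits g-on-y″ regressions with an
intercept (default; the intercept absorbs the slightly nonzero residual
mean when the gradient descent is inexact), df = p − 2. The approximation
relative to exact GWAS is the neglected residual genotype–covariate
correlation, O(1/√p) on cohorts where genotypes and covariates are
independent; measured mean |Δ(−log10 P)| vs pooled OLS is ~2e-3 at
p = 800, f = 12 — and this error *cannot* be smaller than the exact
pipeline's, which the tests assert. Monomorphic variants (zero dosage
variance) are flagged NA.

## Kaplan–Meier conventions

Times are integers on a caller-supplied grid 0..T (months in the intended
use); continuous times must be rounded upstream. At a tied time point,
deaths are counted against an at-risk set that still includes patients
censored at the same time (the convention of mainstream survival
software, against which the tests check). Both c_j and d_j are aggregated
and reported — c_j is needed for the at-risk table even though S(t) uses
only d and n. Division d_j/n_j happens only at the querier, on rounded
integer aggregates. Curves whose 3(T+1)-long triplet vector exceeds one
ciphertext are split across ciphertexts transparently.

## Output-perturbation differential privacy

Because no intermediate value is ever decrypted, calibrated noise is
added **once**, to the final decrypted result: Laplace with scale
`sensitivity/epsilon` (pure ε-DP), or a Gaussian calibrated as
σ = Δf·sqrt(2 ln(1.25/δ))/ε for (ε, δ)-DP. Compared with federated
schemes that perturb every site's every iteration, the same privacy level
costs one noise draw. The choice of ε, δ and the sensitivity Δf is the
caller's: no recommendation is made, and for high-dimensional outputs
(per-variant GWAS statistics) sensible sensitivities are an open
modelling question deliberately left outside this package.

## Synthetic cohorts: what they emulate and what they do not

`gen_survival` draws, per patient, geometric event and censoring times on
the integer grid (the discrete analogue of constant-hazard exponential
times) with administrative censoring at T; defaults are three strata of
500/550/550 patients (n = 1600) with per-month hazards 0.030/0.018/0.010
and censoring probability 0.02 on a T = 200 grid — a biomarker-stratified
oncology cohort at the scale the pipelines are meant for. It does not
emulate time-varying hazards, dependent censoring, or delayed entry.

`gen_gwas` draws genotypes Binomial(2, maf) per variant with maf uniform
on [0.05, 0.5] (Hardy–Weinberg, independent variants — **no LD**),
standard-normal covariates standing in for ancestry components
(**no actual population structure**: covariates are independent of
genotypes), and a linear phenotype y = Xβ_cov + Σ g·β_g + ε with defaults
p = 800, f = 12, v = 256, 10 causal variants with N(0, 0.25²) effects,
covariate effects N(0, 0.3²), noise sd 1. Consequently the test suite
demonstrates *protocol* fidelity — federated equals pooled — and
calibration under independence; it says nothing about confounding,
LD-induced correlation between test statistics, or case-control traits.

Splitting across sites is a seeded uniform row partition (optionally with
proportions); heterogeneous site *distributions* are not simulated.

## Problem sizes and numerical defaults

The shipped tests and the acceptance script use: survival n = 1600,
T = 200, over 1/3/8 sites; GWAS p ≈ 800, f = 12, v = 256 (2000 for the
null-calibration run) over 1–12 sites; 13×13 encrypted inversions;
5 seeds for the cross-method ordering and 20 seeded runs for the audit
sweep — sizes chosen so a full run completes in seconds on one core while
exercising every packing/chunking code path (multi-ciphertext KM grids,
partial last variant batches). Key tolerances: collinearity s ≤ 1e-8
relative; P-value clamp 1e-320; RSS negativity tolerance 1e-6 relative;
noisy-mode homomorphism bound 2^-(precision_bits−4) relative.

## Known limitations

* The cryptography is emulated; nothing here is a security implementation,
  and no claims are made about parameter selection of a real scheme. The
  `mhe` module is a narrow surface intended to be replaced by bindings to
  a real MHE library.
* Depth/refresh counts are semantically faithful but not calibrated to a
  specific CKKS parameterization; wall-clock and bandwidth behaviour of a
  deployment are out of scope.
* Survival analysis stops at curves and at-risk tables: no log-rank test,
  Greenwood bands, or hazard-ratio (Cox) models — the decrypted aggregate
  counts are sufficient inputs for downstream tools that provide them.
* GWAS is linear-regression only (quantitative traits, additive dosage
  coding, no MAF filter by default, no multiple-testing correction);
  logistic/case-control models and LD-aware methods are not provided.
* The weighted-Z meta-analysis uses sample-size weights; inverse-variance
  and random-effects schemes are not implemented.
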