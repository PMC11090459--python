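# Methods

## The encryption scheme

`hegp` implements homomorphic encryption of genotypes and phenotypes (HEGP)
by high-dimensional random orthogonal rotation. A data owner holding
phenotypes `y` (length n), a fixed-effect incidence matrix `X` (n × q), and
genotype dosages `M` (n × p, coded 0/1/2 then column-centered) samples a
private n × n orthogonal matrix `P` and shares only

    y* = P y,    X* = P X,    M* = P M.

Because `P'P = I`, every cross product used by mixed-model inference is
preserved exactly in real arithmetic:

    M*'M* = M'M,   M*'y* = M'y,   M*'X* = M'X,   y*'y* = y'y.

Consequences, each verified by the test suite:

* the Gaussian mixed-model likelihood is invariant
  (`|P V P'| = |V|` and the quadratic form is preserved), so variance
  components, heritability and fixed effects estimated from cyphertext equal
  those from plaintext;
* the full conditional distributions of a single-site Gibbs sampler depend on
  the data only through `m_j'm_j`, `m_j'e`, `x_l'e`, so SNP-BLUP and BayesCπ
  chains are unchanged;
* linkage disequilibrium between markers is preserved, while the genomic
  relationship matrix between individuals is conjugated to `P G P'` —
  individual identity is destroyed (rows of the cyphertext are random linear
  combinations of individuals);
* marker-effect estimates are plaintext-interpretable without decryption; EBV
  `M α̂` require plaintext genotypes and can only be formed by the data owner.

### Key sampling

Keys are drawn from the Haar measure on the orthogonal group via the
eigendecomposition route: `B` with i.i.d. N(0,1) entries, `B'B = Q Λ Q'`,
`P = B Q Λ^{-1/2} Q'`. Haar sampling yields det ±1 with equal probability;
the first row is negated when det = −1, which preserves orthogonality and
gives the Haar measure on SO(n). The `det_corrected` flag records the flip.

Numerical behaviour: for a well-conditioned draw the off-diagonal entries of
`P'P` sit at the ~1e-13 scale (n ≈ 3,500), which is the rounding error the
scheme injects into downstream cross products. A rare draw with a very small
singular value of `B` can degrade this by orders of magnitude; when
`max|P'P − I| > 1e-10` the implementation applies Newton–Schulz polar
refinement (`P ← 1.5 P − 0.5 P P'P`), which converges to the same orthogonal
factor `B(B'B)^{-1/2}` and restores machine-level orthogonality. Eigenvalues
are clamped at 1e-300 before the inverse square root, and a condition warning
is emitted if `min(Λ)/max(Λ) < 1e-12`.

For large n or multi-party data, keys are assembled block-diagonally;
blocks are sampled from independent `SeedSequence` substreams so parallel
generation is reproducible. Keys persist to a checksummed, versioned HDF5
container (float64 row-major payload — decryption requires a bit-exact round
trip); loading verifies the checksum and re-checks orthogonality at 1e-8.

### Centering and normalization

Column centering is a plaintext-side operation: the column means (≡ allele
frequencies) are confidential and never enter the cyphertext. The VanRaden
normalization `H_ij = (M_ij − 2p_j)/√(2p_j(1−p_j))` contains a location
shift that does **not** commute with rotation, so the protocol is: center on
the plaintext side, encrypt, and normalize cyphertext with
`normalize(..., centered=True)` (rescale only), passing the owner-supplied
frequencies. Using the same constants on both paths is what makes plaintext
and cyphertext LD matrices equal element by element.

Missing data are a hard error everywhere (`impute_mean` exists as an
explicit, separate step). `X` must contain its intercept explicitly — an
all-ones column becomes non-constant after rotation, which is correct and
required. All cyphertext is float64; the rounding analysis presumes double
precision.

### Security diagnostics

Under a Haar key the per-marker correlation between plaintext and cyphertext
columns behaves like the correlation of two independent random vectors,
approximately N(0, 1/n): at n = 3,534 about 93% of correlations fall inside
[−0.03, 0.03] (2Φ(0.03√n) − 1 ≈ 0.925). The one known leakage channel is a
variant private to few individuals — its column approximates an indicator
vector and its cyphertext approximates a column of `P` itself.
`risky_variant_screen` flags markers with frequency < 0.01 or fewer than 10
carriers for removal before encryption.

## The Gibbs sampler

`wgr.fit` runs single-site Gibbs for two models on one code path:

* **SNP-BLUP** (`model="snp_blup"`): `α_j ~ N(0, σ_α²)` for all markers
  (π fixed at 0, every marker always included);
* **BayesCπ** (`model="bayes_cpi"`): each `α_j` is a point-mass-at-zero /
  N(0, σ_α²) mixture; π is the prior probability of a **zero** effect and is
  sampled as Beta(p − k + 1, k + 1) with k = Σδ_j included effects
  (uniform prior on π).

Update order per iteration: fixed effects (flat prior), markers in column
order, σ_α² and σ_e² (scaled-inverse-χ² conditionals), then π. The residual
vector is updated incrementally after every effect change. The inclusion
indicator uses the marginal-likelihood ratio with `α_j` integrated out:

    log odds(δ_j = 1) = log((1−π)/π) + ½ log(σ_e² / (σ_α² l_j)) + r_j² / (2 σ_e² l_j),

with `r_j = m_j'(e + m_j α_j)` and `l_j = m_j'm_j + σ_e²/σ_α²`.

Hyperpriors: ν_α = ν_e = 4; scales are set so the prior means equal the
requested variance partition (default: half of var(y) genetic, half
residual), with the per-marker variance dividing the genetic variance by
`(1 − π₀) Σ_j m_j'm_j / n`. The variance and π conditionals follow the
standard BayesCπ construction. `fix_variances=(σ_α², σ_e²)` freezes both
components, turning SNP-BLUP into exact Bayesian ridge regression with the
closed form `(M'M + I σ_e²/σ_α²) α̂ = M'(y − Xβ̂)` — the oracle used in
testing.

The inner loop is compiled with numba and draws from numba's own seeded
`np.random` stream. Because plaintext and cyphertext runs execute the same
instruction sequence on cross products that agree to ~1e-13, a shared seed
produces chains that agree to ~1e-9 relative after hundreds of iterations —
the mechanism behind the chain-identity tests.

Degenerate inputs: markers with `m_j'm_j = 0` (monomorphic after centering)
are permanently excluded with a warning; rank-deficient `X` is an error (no
identifiability constraint is imposed); a non-finite chain state aborts with
the iteration number. Convergence reporting: split-chain potential scale
reduction on σ_e², σ_α², h² (`PosteriorSamples.split_rhat`); no automatic
stopping.

Per-draw genetic variance is the quadratic form `u'u/(n−1)` with `u = Mα`
(see below) and `h² = σ_g²/(σ_g² + σ_e²)`.

Default chain lengths (20,000 iterations, half burn-in, thin 10 in the CLI)
suit the desk-scale problems in this package (n ≤ a few thousand,
p ≤ a few thousand); reference analyses of 50k-marker panels use chains an
order of magnitude longer.

## Windows and WPPA

Markers are partitioned into consecutive index-based windows of 20 SNPs
(the convention that makes 50,436 markers → 2,522 windows; the last window
holds the remainder). The local genetic variance of window w in draw s is
the quadratic form

    v_ws = g'g/(n−1),   g = M_w α_w^(s),

deliberately **not** the mean-centered sample variance: the quadratic form
is exactly invariant under rotation, and for column-centered `M` the two
statistics are nearly identical anyway. WPPA_w is the fraction of draws in
which window w explains more than a threshold share of the total genetic
variance (sum over windows) in that draw; the default threshold 1/n_windows
(an equal share) is configurable, and WPPA is monotone nonincreasing in it.
Quadratic forms are additive within windows only; the cross-window
covariance term accounts exactly for the difference from the genome-wide
variance (asserted on fixtures in the tests).

## Joint analysis

Each contributor centers its genotypes within its own cohort, samples its
own key, and shares cyphertext only. Row-stacking the contributions equals
encrypting the stacked plaintexts with the block-diagonal key
`diag(P_1, …, P_T)`, so a single fit of the merged cyphertext reproduces the
joint plaintext analysis. Assumptions made explicit: variance components are
shared across parties (heterogeneous variances are refused, not silently
absorbed); marker panels must match in identity and order (allele/strand
harmonization is a pre-encryption responsibility); per-contributor centering
means the merged model absorbs per-cohort means — a contributor-indicator
block in `X` is possible but off by default. Only each contributor can
compute interpretable EBV, for its own individuals, using the jointly
estimated marker effects.

## Synthetic data generator

The generator reproduces the statistical structure of the validation study:

* **Genotypes**: two haplotypes per individual; per-marker allele frequency
  uniform on `maf_range` (default 0.05–0.5). LD comes from a first-order
  copying process — within a block of `ld_block_len` markers each haplotype
  copies the previous allele with probability ρ = 0.9, else draws fresh;
  blocks are independent; `ld_block_len=1` gives independent markers. This
  produces enough local correlation to exercise window and LD logic but is
  not a coalescent model: it has no recombination-distance decay, no allele
  ages, no population structure or relatedness between individuals.
* **Phenotypes**: `y = Xβ + u + e`. A fraction `qtl_prop` of markers are
  QTL with i.i.d. standard-normal effects; `u = M_qtl α_qtl` is rescaled so
  the sample variance of `u` equals h² **exactly** per replicate (residuals
  are N(0, 1 − h²), phenotypic variance ≈ 1). Exact rescaling sharpens
  parameter-recovery tests relative to expected-variance scaling.
  Contemporary-group effects: individuals are split into `n_groups` (default
  4) equal groups; group effects are N(0, 0.5) on the phenotypic scale (a
  package convention — reference magnitudes are not published), carried by
  an intercept + treatment-coded indicators, so `X` is full rank.
* **Design grid**: the 4 × 4 factorial h² ∈ {0.1, 0.3, 0.5, 0.7} ×
  QTL fraction ∈ {1, 10, 50, 100}%, 16 scenarios, with 10 replicate seeds
  per scenario when requested.

Because the generator has no cryptographic content, passing tests demonstrate
the *algebraic* invariances and the sampler's statistical calibration on
well-specified Gaussian architectures; they do not measure robustness to
model misspecification (non-Gaussian residuals, dominance/epistasis,
population stratification) or the cryptographic hardness of the scheme.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` regenerate everything they
measure. The main sizes, chosen as the package's desk-scale defaults: LD
invariance on 200 × 500; the correlation-distribution and key-rounding
diagnostics at the reference cohort size n = 3,534 with 2,000 markers (one
~3,500² eigendecomposition); ridge-oracle agreement at n = 200, p = 100 with
30k iterations; chain-state identity at n = 100, p = 50; full BayesCπ
plaintext-vs-cyphertext agreement at n = 500, p = 1,000 with 20k iterations;
joint-vs-solo accuracy over 10 replicates of a 200 + 300 split with p = 500.

## Known limitations

* The scheme addresses confidentiality of identities and individual-level
  records under the analyses above; it is not proven cryptographically
  secure, and rare variants must be screened out before encryption.
* Only complete data are supported; imputation is an explicit prior step.
* BayesA/B/R-style priors, REML estimation, multi-trait models, and
  map-distance (bp-based) windows are out of scope.
* Decryption restores values, not identifiers — identifiers never leave the
  plaintext owner.
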