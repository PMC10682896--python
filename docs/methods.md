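# Methods

## Model

Each species s contributes an n_s × d matrix of per-individual isotope values
(‰), assumed iid multivariate normal, X_i ~ N(μ_s, Σ_s), independently across
species. The default dimensionality is d = 3 with the fixed column ordering
(δ¹³C, δ¹⁵N, δ³⁴S). Records with any missing isotope value are dropped before
fitting: the model is jointly d-variate and partial records cannot enter the
covariance estimate.

Inference uses the noninformative (Jeffreys-type) limit of the
Normal-Inverse-Wishart family, under which the posterior is closed-form:

    Σ | X  ~  Inverse-Wishart(df = n − 1, scale = S),   S = Σ_i (x_i − x̄)(x_i − x̄)ᵀ
    μ | Σ, X  ~  N(x̄, Σ / n)

Because the posterior is exactly samplable, the sampler returns independent
joint draws — there is no Markov chain, burn-in or thinning; the conventional
"10,000 iterations" setting is simply 10,000 iid draws. A proper posterior
with finite covariance mean requires n ≥ d + 2, enforced as a hard
precondition. In d = 1 the implied marginal for the mean is Student-t:
(μ − x̄) / √(S / (n(n − 1))) ~ t_{n−1}; the test suite verifies the sampler
against a brute-force t-sampler by two-sample Kolmogorov–Smirnov.

## Niche quantities

**Region.** The α-probability niche region of a species is the ellipsoid
{x : (x − μ)ᵀ Σ⁻¹ (x − μ) ≤ χ²_{d,α}} containing a fraction α of its assumed
normal distribution. Default α = 0.95; the 40% standard-ellipse convention is
deliberately not implemented. Region membership is boundary-inclusive (≤).

**Size.** The hypervolume of that ellipsoid is
V = π^{d/2}/Γ(d/2+1) · (χ²_{d,α})^{d/2} · √det Σ, in ‰^d. Computed per
posterior draw of Σ (via log-determinant for numerical stability), giving a
posterior size distribution; the point estimate is the posterior mean and the
interval the equal-tailed 2.5th–97.5th percentile. Tests validate the formula
against brute-force Monte-Carlo integration (uniform rejection sampling in
the ellipsoid's tight axis-aligned bounding box, 10⁷ points, <1% relative
error over random 2-D and 3-D covariances).

**Exceedance.** P(V_A > V_B) is the fraction of paired posterior draws
(draw i of A against draw i of B; the species posteriors are independent)
with V_A,i > V_B,i, in percent. Ties — a measure-zero event — count 0.5 so
that P(A>B) + P(B>A) = 100 exactly. The statistic is invariant under any
common monotone transform of both volume samples.

**Overlap.** The directional overlap of A onto B is the probability that a
random individual of A falls in B's α-region. Per paired posterior draw i,
m_points individuals are simulated from N(μ_A,i, Σ_A,i) and scored against
the region built from (μ_B,i, Σ_B,i, α); the posterior distribution of the
per-draw percentages is summarised by its mean and equal-tailed 95% credible
interval. Overlap is asymmetric (a narrow niche nested in a broad one overlaps
it almost fully, not conversely) and invariant under a common invertible
affine transform of both species. The 1-D closed form
Φ((u−μ_A)/σ_A) − Φ((l−μ_A)/σ_A) serves as an independent oracle in tests.
A generalized-chi-square analytic route would avoid the inner Monte Carlo but
is out of scope; m_points defaults to 1,000 per draw (binomial SE ≈ 0.7
percentage points per draw, which averages out over draws).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.95 | probability mass of the niche region; sizes grow monotonically with it |
| `n_draws` | 10,000 | joint posterior draws per species |
| `m_points` | 1,000 | Monte-Carlo individuals per draw for overlap |
| `random_state` / `seed` | — | master seed; all sub-streams derive from it |

Seeds fan out deterministically: `subseed(master, *keys)` hashes each key
with CRC-32 into a `numpy.random.SeedSequence`, so per-species streams depend
on the species *label*, not its position — adding or removing a species never
perturbs another species' draws. Every emitted manifest records the master
seed; re-running from a manifest reproduces the report tables byte-for-byte.

## Synthetic data generator

`table1_defaults()` encodes the three-species turtle study design: labels
Cc/Cm/Lk, n = 104/95/49, per-species trivariate means (−14.7, 7.7, 9.5),
(−14.2, 6.2, 7.1), (−14.5, 7.1, 7.4) ‰ and SDs (1.32, 1.52, 4.35),
(2.10, 1.31, 4.27), (0.98, 1.62, 4.00) ‰. The published summary table prints
no inter-isotope covariances, so the default correlation is the identity and
a full correlation matrix R can be supplied (Σ = D R D with D the SD
diagonal) — an unbiased stand-in, not an estimate. Consequences: synthetic
niche volumes are larger than those from the real deposited data (any real
correlation shrinks det Σ), and synthetic overlaps/exceedances differ
accordingly; tests against the generator check the machinery and its
calibration, not the study's field-data values. An optional outlier mechanism
adds a fixed shift on one isotope to k randomly chosen individuals (default
use: 8 green-turtle recruits at −6 ‰ δ¹³C), emulating depleted recent
recruits without inventing a mixture model. Not emulated: seasonal/temporal
structure, tissue-turnover kinetics, body-size trends, inter-laboratory
offsets (reported as < 0.5 ‰ and treated as negligible).

## Numerical choices

- Positive-definiteness is checked by Cholesky factorization everywhere; a
  scatter matrix with non-finite or > 1e12 condition number raises rather
  than being silently regularized.
- Volumes use `slogdet`/log-Gamma to avoid overflow for large draws.
- Overlap Monte Carlo is vectorised over posterior draws in chunks (default
  256 draws) to bound memory; chunking changes the random stream allotment
  but not the estimator.
- Sampling order per posterior draw is Σ first, then μ | Σ, from a single
  generator stream, giving bit-reproducible draws for a fixed seed.
- With a single record the sample SD is reported as NaN (undefined), never 0.
- Report tables are written at full precision; rounding to the two decimals
  used for display (one decimal for size ratios) happens only at the surface.

## Problem sizes used in checks

The acceptance script runs the full pipeline at the study settings
(10,000 draws, m_points = 1,000). The test suite uses reduced but statistically
adequate sizes chosen for tight oracles: 10⁷-point Monte-Carlo volume
integration, 20,000 draws for the Student-t conjugacy check, 200 simulation
replicates for credible-interval coverage (≥ 90% observed coverage allowed
around the nominal 95%, binomial slack), and n = 5,000 individuals for the
self-overlap calibration check (mean self-overlap within [94, 96]%).

## Limitations

- Normality per species is assumed, not tested; heavy tails or mixtures
  (e.g. recruit clusters) inflate covariance and hence niche size — the
  outlier-sensitivity comparison (`compare_runs`) quantifies this but no
  robust estimator is provided.
- The noninformative-limit prior is one defensible choice within the NIW
  family; other noninformative limits shift posterior volumes slightly
  (order 1/n), which matters when comparing to published point values.
- Isotopic overlap is a proxy: it does not by itself establish dietary or
  spatial overlap.
- Ellipse panel figures draw a few random posterior ellipses per species pair
  and are illustrative only.
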