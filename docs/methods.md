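# Methods

This note documents the statistical machinery in `forestdiv`: the
estimators, the numerical choices behind them, what the synthetic survey
generator does and does not emulate, and the known limitations.

## Survey model and data flow

The unit of observation is a stem: a tree with DBH ≥ 5 cm (the inclusion
threshold is inclusive and configurable) in a 30 × 30 m plot belonging to
one of ten stand types, five per altitudinal belt. `plot_data` validates
stem records (positive DBH, stand code drawn from the fixed design, belt
derived from the stand code), and aggregates them into a species × unit
abundance matrix (unit = plot, stand or belt) or an incidence table
(Y_i = number of plots occupied, T plots). Basal area is π(DBH/2)²;
per-hectare quantities are scaled by the summed plot area of the stand, not
by a hard-coded constant. Taxonomy (species → genus → family) comes from a
packaged lookup of ~95 montane-China tree species; species missing from it
fall into an "unknown" bucket with a warning rather than an error.

## Importance values

IV_i = (RD_i + RF_i + Rd_i)/3 with RD_i = 100·n_i/N,
RF_i = 100·F_i/ΣF_j, Rd_i = 100·d_i/Σd_j. Each component is a share of a
whole, so each column and the IVs sum to 100 exactly (before any rounding;
rounding happens only at report time). A legacy variant that divides the
relative frequency by the number of species instead of the summed
frequencies is available behind `rf_denominator="species_count"`; it does
not produce percentages that sum to 100 and exists only for comparison with
older reports that printed that form. Family/genus overall relative
importance is ORI = R.Ab + R.Fr on the same frequency denominator as the
species-level RF.

## Hill-number rarefaction and extrapolation

Let x_1..x_S be pooled counts, n = Σx_i, f_1/f_2 the singleton/doubleton
counts. The standardized diversity at size m is:

- **q = 0.** m ≤ n: S_obs − Σ_i C(n−x_i, m)/C(n, m) (exact hypergeometric
  expectation). m = n + m*: S_obs + f̂_0·[1 − (1 − f_1/(n f̂_0 + f_1))^{m*}]
  with f̂_0 the Chao1 unseen-species estimate
  ((n−1)/n · f_1²/(2f_2), bias-corrected to f_1(f_1−1)/2 when f_2 = 0 —
  never a division by zero).
- **q = 1.** m ≤ n: exp of the exact expected plug-in entropy of a size-m
  subsample, Σ_k −(k/m)ln(k/m)·E[f_k(m)] with
  E[f_k(m)] = Σ_i C(x_i,k)C(n−x_i,m−k)/C(n,m). m = n + m*: exp of the
  size-weighted mixture (n/(n+m*))·H_obs + (m*/(n+m*))·Ĥ_∞, where Ĥ_∞ is
  the Chao–Jost asymptotic entropy estimator (digamma form with the
  f_1-tail correction, floored at H_obs so extrapolation never decreases).
- **q = 2.** One closed form valid on both sides:
  1/(1/m + (1 − 1/m)·Σ x_i(x_i−1)/(n(n−1))); at m = n it reduces exactly to
  the plug-in inverse Simpson.

All binomial coefficients are evaluated as log-gamma differences, so
reference samples in the thousands are unproblematic. The three estimators
are continuous at m = n by construction (the interpolation expectations
reduce to the observed sample, the extrapolations to the m* = 0 limit), and
extrapolation is restricted to m ≤ 2n — the short range over which these
estimators are considered reliable; when two assemblages are compared the
common limit is twice the smaller reference size (the doubling rule).

Incidence-based curves replace (x_i, n) by (Y_i, T) with U = ΣY_i and
diversity defined on Y_i/U: hypergeometric interpolation and Chao2-anchored
extrapolation for q = 0, the same closed form for q = 2 with U(t) = tU/T,
and for q = 1 the analogous mixture whose asymptote applies the Chao–Jost
estimator to the incidence frequencies on the Y_i/T scale and shifts by
ln(U/T) (entropy on Y_i/U decomposes exactly that way at the reference
point). This incidence q = 1 extrapolation is the package's own
reconstruction of the framework's estimator and is documented as such.

**Coverage.** At the reference size, the Good–Turing estimate
Ĉ = 1 − (f_1/n)·(n−1)f_1/((n−1)f_1 + 2f_2); below it the unbiased
subsample form 1 − Σ(x_i/n)·C(n−x_i,m)/C(n−1,m); above it the geometric
extension with exponent m* + 1. The C(n−1, m) denominator makes the
estimate target the *community's* coverage (and keeps the curve
nondecreasing through the reference point), rather than the
finite-population coverage of the observed sample.

**Bootstrap.** The observed community is augmented by ⌈f̂_0⌉ unseen species
carrying probability (1 − Ĉ)/⌈f̂_0⌉ each, while observed probabilities are
shrunk to x_i/n·(1 − λ(1 − x_i/n)^n) with λ chosen so the observed part
sums to Ĉ. Replicates are multinomial (abundance) or per-unit Bernoulli
(incidence) redraws of the same size; the 95% band is
estimate ± 1.96·SD(replicates) around the analytic point estimate — a
normal approximation, not percentile. Every bootstrap path takes an
explicit seed; default 200 replicates, 40-knot grid from 1 to 2n with the
reference size always included.

## SAD models and fitting

Expected abundance of the rank-r species (rank 1 most abundant):

| model | â_r | free parameters k |
|---|---|---|
| broken-stick | (N/S) Σ_{k=r..S} 1/k | 0 |
| niche preemption | N α (1−α)^{r−1} | 1 (α) |
| log-normal | exp(ln μ + ln σ · Φ_r) | 2 (μ, σ) |
| Zipf | N p̂₁ r^γ | 1 (γ; p̂₁ tied to the observed rank-1 share, `free_p1=True` makes it 2) |
| Zipf–Mandelbrot | N c (r+β)^γ | 3 |
| neutral | rank curve from φ_n(θ, m) | 2 |

Φ_r is the standard normal quantile at the mid-rank plotting position
(S − r + 0.5)/S, with the σ > 1 convention so ranks decay. The
Zipf–Mandelbrot reduces exactly to the Zipf at β = 0, c = p̂₁.

All models are scored by the same Poisson likelihood of the observed ranked
abundances given â_r (the convention of standard rank-abundance fitters),
so log L and AIC = −2 log L + 2k are directly comparable across models.
Optimization is deterministic: bounded 1-D golden-section for single
parameters, Nelder–Mead (tolerances 1e-8) from a fixed list of starting
points for the log-normal and Zipf–Mandelbrot (the latter in the
(ln c, ln(1+β), ln(−γ)) parametrization with four restarts — this bounded
multi-start is how "failed to fit" is operationalized: non-convergence is
flagged on the result and failed fits sort last in the comparison table,
never a silent wrong answer). Goodness of fit is additionally summarized by
the two-sample Kolmogorov–Smirnov statistic between the observed and
expected abundance distributions (zero iff identical); its p-value is the
asymptotic one and is conservative under the heavy ties of discrete counts.

**Neutral model.** φ_n — the expected number of species with n individuals
in a local community of J individuals receiving migrants at rate m from a
metacommunity with fundamental biodiversity number θ — is the classical
sampling-formula integral over y ∈ [0, γ], γ = m(J−1)/(1−m). It is
evaluated entirely in the log domain (log-gamma arithmetic, 240-point
Gauss–Legendre quadrature with log-sum-exp accumulation), which is stable
for J in the thousands; non-finite intermediate results raise with
diagnostics rather than returning garbage. For J > 400 the n-grid is
log-spaced (dense for n ≤ 32, 140 geometric knots above) and log φ is
interpolated in log n, which agrees with the dense evaluation to well
within the fitting noise. The expected rank curve inverts the cumulative
expected species count F(a) = Σ_{n≥a} φ_n at the mid-rank levels r − ½;
ranks beyond the expected richness receive a vanishing expectation, which
correctly penalizes θ values too small for the observed S. The (θ, m) fit
is a coarse log-grid search (θ seeded by solving the Ewens relation
S = θ ln(1 + J/θ)) followed by Nelder–Mead in (ln θ, logit m).

Two properties worth knowing: Σ n φ_n = J holds to within 1% under the
default quadrature (checked in tests at J = 200), and the m → 1 limit
approaches — but does not exactly equal — the finite-J Ewens expectation:
at J = 2 the integral evaluates analytically to
φ_1 = 2(θ − 1 + e^{−θ})/θ versus the Ewens 2θ/(θ+1), a ~1.5% gap at θ = 8
that grows to a few percent for mid-range abundance classes at J = 100.
The formula is a mean-field expectation, and the package treats it as such.

Because the fit objective compares each *realization* to the model's
*expected* rank curve, the neutral model is at a structural disadvantage in
AIC comparisons on its own data: the identity of the dominant species'
share fluctuates strongly between neutral realizations (the variance comes
from the Ewens metacommunity draw and does not shrink with J), and
three-parameter shape models absorb that fluctuation while the neutral
expectation cannot. Model-recovery simulations show the generating neutral
model is usually *not* ranked in the top two by AIC under this objective.
A species-level probability likelihood (Etienne's exact sampling formula)
would remove the disadvantage but is deliberately out of scope; the
expectation-based likelihood is documented as an approximation and the code
is structured so an exact likelihood could be swapped in later.

## Clustering and ordination

Stand dissimilarity defaults to Bray–Curtis on raw abundances (range
[0, 1], 1 for disjoint species sets); a chi-square-distance option matches
the metric implicit in correspondence analysis. No abundance transformation
is applied by default — the original protocol does not state one — but the
matrix can be transformed upstream. Agglomeration is group-average (UPGMA)
via scipy's average linkage (verified against brute-force all-cross-pairs
agglomeration on small trees); merge heights are monotone for this
criterion, and the dendrogram serializes to Newick with ultrametric branch
lengths (tip depth = half the merge height). The two-group classification
is the k = 2 maxclust cut.

Correspondence analysis is the SVD of D_r^{−1/2}(P − rc^T)D_c^{−1/2} for
the relative-frequency matrix P with margins r, c. Eigenvalues are squared
singular values, total inertia = Σλ = χ²/N exactly; rank-deficient tables
yield fewer axes rather than failing. Scores are reported in symmetric
scaling (D^{−1/2}·singular vectors·√singular value), under which row scores
are the row-profile weighted averages of column scores shrunk by the axis
singular value, and all scores have zero weighted mean.

## Synthetic surveys

`synthetic_data` generates the full reference design: 2 belts × 5 stands ×
5 plots of 900 m², with belt-level communities drawn once from a chosen SAD
model and individuals scattered multinomially over the belt's 25 plots, so
plot totals fluctuate realistically around the target (116 stems/plot
birch, 110 pine–oak ≈ 2,900/2,750 stems per belt). Defaults emulate the
study system's contrast: the birch belt draws 43 species from a flat
niche-preemption SAD (α = 0.10, top species ~10% of stems), the pine–oak
belt 41 species from a steep Zipf SAD (γ = −1.3, top-3 share ~55%, all 41
species typically observed). The Zipf was chosen over a preemption of
matching steepness because a geometric tail at that dominance truncates the
observable richness far below the pool size. Pools share 80% of the
smaller pool by default — the shared species form the common tail while
each belt keeps its own exclusive dominants, so the belts are floristically
similar but structurally different. DBH is 5 cm plus a guild-specific
log-normal (conifer median 13 cm, broadleaf 9 cm, σ_log = 0.45); height
and crown follow simple allometries with noise. A neutral-community option
assembles individuals by a sequential urn (immigrate from an Ewens(θ)
metacommunity urn with probability m, otherwise copy a resident).

Everything flows from one `numpy` generator, so a fixed seed reproduces the
survey byte for byte. What the generator does **not** emulate: spatial
aggregation within and among plots (individuals are scattered
independently), environmental gradients between stands of a belt (stands
are exchangeable draws, so within-belt clustering structure is noise),
species-specific detection error, and DBH–abundance correlations. Passing
tests on these surveys therefore demonstrate the estimators' sampling
properties, not robustness to spatial or observational artifacts of real
inventories.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to be comparable to the study
design while keeping the suite quick: bootstrap-CI coverage on 200
preemption communities (S = 30, α = 0.12, n = 2,000; q = 1, 200 bootstrap
replicates each); extrapolated-richness coverage on 100 log-normal
communities (S = 40, n = 500); AIC model recovery over 50 replicates each
for the broken-stick (S = 40, N = 3,000) and neutral (θ = 30, m = 0.2,
J = 1,000) generators; belt recovery and the diversity contrast over 100
full synthetic surveys; enumeration oracles on ≤ 12-individual toys where
exhaustive subsampling is exact.

## Known limitations

- The neutral fit is expectation-based (see above); AIC comparisons
  involving it should be read with that asymmetry in mind.
- K-S p-values are asymptotic and anti-conservative claims should not be
  based on them for small S; the statistic itself is the primary summary.
- Incidence-based q = 1 extrapolation uses the package's reconstruction of
  the framework's estimator (mixture form); q = 0 and q = 2 follow the
  standard published forms.
- Coverage-based (as opposed to size-based) standardization is available
  implicitly through the coverage column of every curve, but the package
  does not invert coverage to size.
- Extrapolation beyond 2× the reference sample raises by design.
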