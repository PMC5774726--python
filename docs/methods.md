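# Methods

## Model

A single "lead" ribosome occupies one of `d` codon sites of an mRNA and hops
unidirectionally, site `i → i+1`, with first-order rate constant `ε_i`
(units 1/time).  Reaching the termination site `d` releases a completed
protein; the ribosome then reinitiates on the same template with probability
`λ` (the circular, closed-loop configuration of eukaryotic templates) or
leaves for the free ribosome pool with probability `1 − λ`.  Population
effects enter entirely through randomness of the rates: each template in an
ensemble draws its own vector `ε` from a named distribution family,
independently per site unless a correlation structure is requested.

The discrete-step picture uses step probabilities `p_i = ε_i/α` with a scale
`α` (1/time) satisfying `α p_i = ε_i`; the transition matrix `U` has diagonal
`1 − p_i`, subdiagonal `p_i` and corner `(1, d) = λ p_d`.  Continuous time is
generated by `T = α(U − I)` (diagonal `−ε_i`, subdiagonal `ε_i`, corner
`λ ε_d`), and every continuous-time quantity is independent of `α`.  The
default `α = 1.2 · max ε` simply keeps all `p_i < 1`.  The "codon 0"/free
ribosome pool is represented implicitly: for `λ < 1` the occupancy mass
`1 − Σ V_i` is the probability the ribosome has left the template, which
keeps the matrices exactly bidiagonal-plus-corner.

Assumptions worth keeping in mind: only the lead ribosome is tracked (no
explicit excluded-volume interaction between ribosomes; collisions and
spacing enter only through slow sites and the spacing parameter `R`), rates
are constant in time within a template, and initiation is not rate-limiting.

## Propagators

Four routes to `Q(t) = e^{tT}` are implemented and cross-validated; scipy's
general `expm` is the arbiter.

* **Open-chain pole sum** (`λ = 0`): `Q(t)[i,j]` for `i ≥ j` is an
  alternating-sign sum of `e^{−tε_k}` over `k = j..i` with product
  denominators `Π(ε_k − ε_l)`.  The denominators are singular at ties, so
  rates within relative distance 1e−6 raise a confluent-rates condition and
  the caller re-routes.
* **Divided differences**: the same entries equal
  `Π_{m=j..i−1} ε_m · dd(e^{t·}; −ε_j … −ε_i)`.  Divided differences are
  symmetric in their nodes, so nodes are sorted, exact ties grouped, and the
  confluent rule `g^{(n)}(x)/n!` applied.  An order-`n` difference of an
  exponential cancels catastrophically in double precision, and the loss
  grows with the order, so the table is evaluated in mpmath with working
  precision `max(50, 25 + 2d)` digits.  When all rates coincide this
  reproduces the Poisson step law `e^{−tε}(tε)^{i−j}/(i−j)!` exactly.
* **Spectral (residue) sum** (`0 < λ ≤ 1`): the contour-integral entries for
  the circular chain are rational in the Laplace variable, so the contour
  integral equals the sum of residues at the roots of
  `P(s) = Π(s+ε_k) − λΠε_m`.  Roots come from companion-matrix eigenvalues
  of the mean-scaled expanded polynomial, polished by Newton on the product
  form (the roots lie near `s = −ε_k`, so the companion eigenvalues are good
  starting points).  Root residuals above 1e−7 (relative) or root pairs
  closer than 1e−6 raise an error; `propagate(..., method="spectral")` then
  falls back to `expm`.  For `λ = 1` the root at `s = 0` contributes the
  stationary law.  Literal contour quadrature over a circle enclosing the
  poles is kept as a test-only oracle.
* **Laplace-domain operator**: `∫ c e^{−ct} Q(t) dt` has closed-form entries
  (products of `ε` and `c + ε` over the appropriate index ranges divided by
  `P(c)`), including the leading factor `c`; the variant of the formula that
  appears without the leading `c` in one printed form is dimensionally the
  expected count over an `Exp(c)` lifetime and is exposed as the
  `include_decay_prefactor=False` flag of `polypeptides_per_template`.

All products of rates are computed as exponentials of sums of logarithms:
`Πε` overflows double precision already at `d = 30` with rates near 50.

Numerical conventions: occupancy vectors are clipped to `[0, 1]` on output;
matrices from the analytic routes are clipped the same way; tie-breaking in
the codon optimizer takes the lowest site index among equal minima.

## Per-template statistics

* Stationary occupancy (`λ = 1`): `π_i = (1/ε_i)/Σ_k(1/ε_k)`; the steady
  circulation flux is `1/Σ_k(1/ε_k)`.
* Polypeptides per template under first-order transcript decay `c`:
  `c Πε / (Π(c+ε) − λΠε)`.
* Mean ribosomes per template: decay-weighted mean lead-ribosome position
  divided by the inter-ribosome spacing `R` (default 10 residues);
  reinitiation neglected, as appropriate for the elongation-limited regime
  this estimate targets.
* Greedy codon optimization: repeatedly lift the smallest `ε_i` to its
  achievable maximum and record the new circulation flux; stops when the
  limiting codon cannot be improved.  The flux sequence is non-decreasing
  because each step raises a term of the harmonic sum.

## Ensemble protocol

The population experiment draws `n` templates (default conditions follow the
reference experiments: `d = 30`, gamma rates with shape 10 and scale 5, and
`n = 25,000` for full runs; the test suite uses `n = 5,000` and smaller, with
tolerances widened to the replicate spread measured at that size), starts
each at `V(0) = (1, 0, …, 0)`, and evolves on a shared time grid.  Time is
conveniently measured in units of one mean traversal `T = d/mean(ε)`; the
steady state is reached by `3T` in the sense that the protein distribution
is invariant under further evolution (KS distance between consecutive late
times < 0.01).

The protein readout per template is the terminal-site occupancy `V_d(t)`
(default).  Alternatives: the completion flux `ε_d V_d`, the cumulative
count `∫ ε_d V_d dτ` (optionally drained at a protein decay rate), and the
literal instantaneous termination-minus-initiation flux difference
`ε_d V_d − ε_1 V_1`.  The last is provided for completeness but is not a
sensible population histogram at steady state (it converges to 0 on the
circular chain), which is why terminal occupancy is the default.

A completed protein is counted once per arrival at site `d` at rate
`ε_d V_d`, regardless of whether the ribosome then reinitiates — release
happens before the recycling branch.

Protein decay is configurable; the default rate `0.02·mean(ε)/d` is the
package's own choice (a slow drain relative to production) since no value is
prescribed by the underlying model.  Transcript decay `c` and protein decay
are both first order.

Sampling details: normal-family draws are resampled until positive, which
keeps the support correct and the marginal equal to the conditional law
given positivity; parameter sets whose truncated mass exceeds one third are
rejected as no longer resembling the named family.  Correlated rates use a
Gaussian copula — a latent field mixing an iid component with a shared
circular moving-average component (window `length_scale`, variance fraction
`strength`) — so marginals are preserved exactly while the realized lag-1
autocorrelation is reported.  Templates whose propagation produces
non-finite values are dropped and counted (`n_in = n_out + n_dropped`); the
run aborts if more than 1% drop.

## Transient statistics

The expected chain extension is `L(t) = Σ_i i·V_i(t)`, averaged over the
ensemble.  On open chains the mass released at termination would silently
leave this sum, so `L` adds `d · P(t)` where `P` is the completed-protein
pool fed by `ε_d V_d` and drained at the protein decay rate; with zero decay
`P` is the cumulative completion count.  This is the package's construction
for "chain extension including finished product"; it makes the effect of
protein decay on `L` a well-defined computed quantity (decay lowers the
late-time curve below both the no-decay curve and the early linear
extrapolation).

`L(t)` is linear at early times.  The early window is genuinely short for
heavy-tailed rate families: with exponential rates the ensemble's
instantaneous mean velocity declines as walkers accumulate behind slow
codons (the harmonic mean of an exponential is zero), so linearity at
`R² > 0.99` holds for roughly the first 1/15 of a mean traversal and the
tests use that window.

The across-template variance of `log V_i(t)` is reported per site and time,
excluding (and counting) non-positive entries.  On the circular chain this
variance converges across sites and decreases at late times, as each
`V_i → π_i`; on the open chain it grows without bound as sites drain, which
is why the convergence check uses `λ = 1`.

## Fitting layer

Single-family fits are exact or 1-d-solver MLEs: log-normal and normal by
closed-form moments (of logs), gamma by solving
`log a − ψ(a) = log mean − mean log` with Brent, log-logistic by BFGS with
analytic gradient on the log scale.  The log-logistic is parameterised so
that `log X` is logistic with location `loc` and scale `scale` — stated
explicitly to avoid the shape/scale dialect confusion around this family.
Log-likelihoods are always reported on the original data scale (log-domain
families carry the Jacobian), so information criteria are comparable across
families.

Two-component mixtures are fit by EM with responsibilities initialized from
a quantile split (the median first, then random quantiles per restart, 10
restarts by default, seed-controlled; best final log-likelihood wins;
components sorted by descending weight).  EM stops when the absolute
log-likelihood change falls below 1e−8, with a 20,000-iteration cap for
pairs whose M-steps are closed-form and a 1,000-iteration/1e−6 budget when a
component's M-step is itself an inner optimisation (log-logistic).  The
tight tolerance matters: near-log-normal samples put the two-log-normal
mixture on an almost flat likelihood ridge, and a loose stopping rule
strands the fit mid-ridge at an arbitrary weight, whereas runs from opposite
initialisations converge to the same maximiser when allowed to finish.
Solutions with a component weight below 0.01 are flagged as weight-collapsed
but still returned.

"Unbiased" model selection is operationalized as BIC over a fixed candidate
library (four singles and three two-component mixtures over log-normal,
log-logistic and gamma): no target family is pre-specified, so the winner is
determined by the data.  Which information criterion the original
black-box fitter used is unknown; BIC is this package's documented choice.
Near-ties go to the model with fewer parameters.

Q-Q tables pair empirical and theoretical quantiles at plotting positions
`(k − ½)/n`, log-transformed when the reference is log-domain so that a
perfect fit lies on `y = x` either way; mixture quantiles are obtained by
bracketed root-finding on the mixture CDF.  Tail diagnostics report the mean
signed Q-Q residual over the outer 5% on each side plus the inner-90%
residual RMS as a central-fit score.

## What the synthetic data does and does not show

The generator emulates template-to-template and site-to-site rate
variability, slow codons, rate correlations, and first-order transcript and
protein decay.  It does not emulate explicit multi-ribosome traffic
(TASEP-style exclusion), initiation-limited regimes, time-varying rates
within a template, or measurement noise of any real assay.  Passing tests
therefore demonstrate the internal consistency of the model and its
numerics — e.g. that multiplicative rate noise produces near-log-normal
protein distributions whose central fit is excellent and whose tails
deviate — not that any particular organism's protein abundances follow
these laws.

## Known limitations

* The two-log-normal mixture on a near-log-normal sample is weakly
  identified; the dominant weight is reproducible under a fixed seed but
  moves within roughly ±0.05 across ensemble random streams at
  `n = 25,000` (more at smaller `n`).  This is a property of the statistic,
  not of the optimizer — EM converges to the same maximiser from opposite
  starts.
* The standardized log steady-state protein samples of different rate
  families are close but not indistinguishable: the truncated-normal family
  is separated from the gamma and log-normal families by a two-sample KS
  distance of about 0.05–0.07 at `n = 5,000` (the single-site `1/ε_d`
  factor in the terminal occupancy inherits the family's left tail).  The
  family-robustness claim holds qualitatively, and exactly at the 0.05
  level for the other four family pairs.
* The spectral route assumes simple, well-separated denominator roots; for
  nearly confluent spectra it declines and the caller falls back to `expm`.
* The divided-difference route is exact but slow at large `d` (mpmath); it
  is the fallback path, not the default.
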