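# ribowalk

Stochastic modelling of translational elongation: why protein abundance
distributions across a cell population look log-normal.

## The problem

For moderately to highly expressed proteins, elongation — the codon-by-codon
addition of residues by the ribosome — is the rate-limiting stage of
translation, and its per-codon rate constants fluctuate from cell to cell and
template to template (tRNA availability, mRNA structure, pausing).
`ribowalk` models the lead ribosome on an mRNA of `d` codons as a
unidirectional continuous-time random walk with site-specific first-order
rates `ε₁ … ε_d` and an optional reinitiation probability `λ` (the
circularised eukaryotic template; `λ = 0` is the open, prokaryotic/short-lived
chain).  The occupancy vector evolves under the compound-Poisson semigroup

```
V(t) = e^{tT} V(0),    T = α(U − I),   α p_i = ε_i
```

where `T` has diagonal `−ε_i`, subdiagonal `ε_i` and corner entry `λ ε_d`.
Because the entries of `e^{tT}` are sums of high-order *products* of the
random rates, the protein output across a population of templates with random
rate vectors is approximately log-normally distributed — a natural
generalisation of the Poisson to processes with multiplicative noise.

The package is aimed at people studying stochastic gene expression and
translation kinetics who want a small, well-tested reference implementation
of this model: its closed-form propagators, its steady-state and per-template
statistics, the ensemble simulation protocol, and the distribution-fitting
layer used to characterise the resulting protein distributions.

## What is inside

| module        | contents |
| ------------- | -------- |
| `kinetics`    | `RateProfile`, transition matrix `U`, generator `T`, stationary law `π_i ∝ 1/ε_i`, polypeptides and ribosomes per template, expected chain length, greedy codon optimization |
| `propagators` | four independent routes to `Q(t) = e^{tT}`: scipy `expm` (reference), the open-chain pole-sum closed form, extended-precision divided differences (robust at tied rates), and the circular-chain residue/spectral sum; plus the transcript-lifetime (Laplace) operator |
| `ensemble`    | sampling rate-profile populations (gamma/normal/exponential/lognormal families, per-site means, slow codons, copula correlation), occupancy simulation, protein-output samples, stalling profiles, transient statistics |
| `distfit`     | maximum-likelihood fits of log-normal / log-logistic / gamma / normal, two-component mixtures by EM, BIC model selection, Q-Q tables and tail diagnostics |
| `config`, `fixtures`, `results`, `cli` | JSON run configs (schema-validated), deterministic test fixtures, CSV/manifest output, `ribowalk` command-line interface |

## Worked example

```python
import numpy as np
from ribowalk import (RateProfile, steady_state_distribution,
                      polypeptides_per_template, DecayModel,
                      RateEnsembleSpec, sample_rate_profiles,
                      simulate_occupancy, protein_output_distribution,
                      fit_mixture)

# one circular template: stationary occupancy is inversely
# proportional to the local rate
profile = RateProfile(epsilons=np.array([1.0, 2.0, 4.0]), reinit_prob=1.0)
print(steady_state_distribution(profile).probs)
# [0.57142857 0.28571429 0.14285714]

# proteins produced per transcript with decay rate c = 1
print(polypeptides_per_template(
    RateProfile(np.array([2.0, 3.0]), reinit_prob=1.0), DecayModel(1.0)))
# 0.9999999999999999

# a population: 5,000 templates, 30 codons, gamma(10, 5) rates,
# propagated to three mean traversals (steady state)
spec = RateEnsembleSpec("gamma", {"shape": 10.0, "scale": 5.0},
                        d=30, n_templates=5000, seed=1)
occ = simulate_occupancy(sample_rate_profiles(spec), [1.8])
sample = protein_output_distribution(occ, "terminal_occupancy", time=1.8).values

# the protein sample is ~log-normal: a two-component log-normal
# mixture fit is dominated by a single component
fit = fit_mixture(sample, ("lognormal", "lognormal"), restarts=4, seed=0)
print(round(fit.dominant_weight, 4))
# 0.9893
```

The stationary occupancy `(4/7, 2/7, 1/7)` says the ribosome spends time at
each codon in proportion to `1/ε_i`; the mixture fit says the across-template
protein distribution is a log-normal up to a small secondary component
carrying ~1% of the mass (the not-yet-relaxed tail of the population).

The same operations are available from the shell:

```
ribowalk fixtures --kind fig6_slow_codon --seed 1 --outdir work
ribowalk simulate --spec work/fig6_slow_codon.json --out work/run
ribowalk fit --sample work/run_samples.csv --model lognormal+lognormal --seed 0
```

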