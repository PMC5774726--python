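"""Single-template elongation kinetics.

The lead ribosome on an mRNA of ``d`` codons performs a unidirectional
continuous-time random walk: the residue at site ``i`` is added with
first-order rate constant ``eps_i`` (units 1/time).  At the termination
site ``d`` a completed protein is released; the ribosome then reinitiates
on the same (circularised) template with probability ``lam`` or returns to
the free ribosome pool with probability ``1 - lam``.

The discrete-step picture works with transition probabilities
``p_i = eps_i / alpha`` where ``alpha`` (1/time) is the scale that turns
step probabilities into rates.  All continuous-time quantities are
independent of ``alpha``; it only matters for the discrete transition
matrix ``U``.

Sites are reported 1-based at every interface (site 1 = initiation,
site ``d`` = termination); arrays are stored 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RateProfile",
    "OccupancyVector",
    "DecayModel",
    "OptimizationStep",
    "build_transition_matrix",
    "build_generator",
    "steady_state_distribution",
    "steady_state_flux",
    "polypeptides_per_template",
    "mean_ribosomes_per_template",
    "mean_chain_length",
    "optimize_limiting_codons",
]

_TOL = 1e-8


@dataclass(frozen=True)
class RateProfile:
    """Per-codon rate constants of one mRNA template.

    Parameters
    ----------
    epsilons:
        Vector of ``d`` positive per-codon rate constants (1/time).
    reinit_prob:
        Reinitiation probability ``lam`` in [0, 1].  ``lam = 1`` is the
        circular (closed-loop) template; ``lam = 0`` the open chain.
    alpha:
        Scale relating step probabilities to rates (``alpha * p_i = eps_i``).
        Defaults to ``1.2 * max(eps)`` so that every ``p_i < 1``.
    """

    epsilons: np.ndarray
    reinit_prob: float = 0.0
    alpha: float | None = None

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilons, dtype=float)
        if eps.ndim != 1 or eps.size < 2:
            raise ValueError("epsilons must be a 1-d vector with d >= 2")
        if not np.all(np.isfinite(eps)) or np.any(eps <= 0):
            raise ValueError("all rate constants eps_i must be positive and finite")
        if not 0.0 <= self.reinit_prob <= 1.0:
            raise ValueError(
                f"reinit_prob (lambda) must lie in [0, 1], got {self.reinit_prob}"
            )
        alpha = self.alpha
        if alpha is None:
            alpha = 1.2 * float(eps.max())
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        bad = np.nonzero(eps / alpha > 1.0 + 1e-15)[0]
        if bad.size:
            raise ValueError(
                f"step probability p_{bad[0] + 1} = eps/alpha > 1 at site "
                f"{bad[0] + 1}; increase alpha (alpha={alpha}, eps={eps[bad[0]]})"
            )
        eps.setflags(write=False)
        object.__setattr__(self, "epsilons", eps)
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "reinit_prob", float(self.reinit_prob))

    @property
    def d(self) -> int:
        """Number of codons in the open reading frame."""
        return int(self.epsilons.size)

    @property
    def step_probs(self) -> np.ndarray:
        """Per-site step probabilities ``p_i = eps_i / alpha``."""
        return self.epsilons / self.alpha

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "epsilons": self.epsilons.tolist(),
            "lambda": self.reinit_prob,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "RateProfile":
        return cls(
            epsilons=np.asarray(obj["epsilons"], dtype=float),
            reinit_prob=float(obj.get("lambda", 0.0)),
            alpha=obj.get("alpha"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RateProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_csv(self, path: str | Path) -> None:
        lines = ["epsilon"] + [repr(float(e)) for e in self.epsilons]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        reinit_prob: float = 0.0,
        alpha: float | None = None,
    ) -> "RateProfile":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        if not lines or lines[0].lower() != "epsilon":
            raise ValueError(f"{path}: expected a one-column CSV with header 'epsilon'")
        eps = np.array([float(x) for x in lines[1:]])
        return cls(epsilons=eps, reinit_prob=reinit_prob, alpha=alpha)


@dataclass(frozen=True)
class OccupancyVector:
    """Probability ``V_i(t)`` that the lead ribosome sits at codon ``i``.

    Mass may be below 1 when ``lam < 1``: the deficit is the probability the
    ribosome has left the template for the free pool.
    """

    probs: np.ndarray
    time: float

    def __post_init__(self) -> None:
        v = np.asarray(self.probs, dtype=float)
        if v.ndim != 1:
            raise ValueError("probs must be a 1-d vector")
        if np.any(v < -_TOL):
            raise ValueError(f"negative occupancy beyond tolerance: min {v.min()}")
        if v.sum() > 1.0 + _TOL:
            raise ValueError(f"occupancy mass {v.sum()} exceeds 1")
        if self.time < 0:
            raise ValueError("time must be nonnegative")
        v = np.clip(v, 0.0, None)
        v.setflags(write=False)
        object.__setattr__(self, "probs", v)
        object.__setattr__(self, "time", float(self.time))

    @property
    def d(self) -> int:
        return int(self.probs.size)


@dataclass(frozen=True)
class DecayModel:
    """First-order decay rates and ribosome spacing.

    ``mrna_decay_rate`` is the transcript decay constant ``c`` (1/time);
    ``protein_decay_rate`` optionally drains the completed-protein pool;
    ``ribosome_spacing`` is ``R``, the average number of residues between
    successive ribosomes on a polysome.
    """

    mrna_decay_rate: float
    protein_decay_rate: float = 0.0
    ribosome_spacing: float = 10.0

    def __post_init__(self) -> None:
        if self.mrna_decay_rate < 0 or self.protein_decay_rate < 0:
            raise ValueError("decay rates must be nonnegative")
        if self.ribosome_spacing < 1:
            raise ValueError("ribosome_spacing R must be >= 1")


@dataclass(frozen=True)
class OptimizationStep:
    """One codon substitution in the greedy optimization walk."""

    site: int  # 1-based
    new_epsilon: float
    flux: float


def build_transition_matrix(profile: RateProfile) -> np.ndarray:
    """Discrete one-step transition matrix ``U`` (columns are source sites).

    Diagonal ``1 - p_i``, subdiagonal ``p_i`` (step ``i -> i+1``), corner
    ``(1, d) = lam * p_d`` (reinitiation).  Columns sum to 1 when
    ``lam = 1``; otherwise column ``d`` leaks mass ``(1 - lam) p_d`` to the
    free-ribosome pool, which is tracked implicitly as ``1 - sum(V)``.
    """
    p = profile.step_probs
    d = profile.d
    U = np.diag(1.0 - p)
    U[np.arange(1, d), np.arange(0, d - 1)] = p[:-1]
    U[0, d - 1] += profile.reinit_prob * p[-1]
    return U


def build_generator(profile: RateProfile) -> np.ndarray:
    """Continuous-time generator ``T = alpha (U - I)``.

    Diagonal ``-eps_i``, subdiagonal ``eps_i``, corner ``(1, d) =
    lam * eps_d``.  Columns sum to zero when ``lam = 1`` (conservative
    chain).  Built directly from the rates, which is algebraically
    identical to ``alpha (U - I)`` and free of the intermediate rounding.
    """
    eps = profile.epsilons
    d = profile.d
    T = np.diag(-eps)
    T[np.arange(1, d), np.arange(0, d - 1)] = eps[:-1]
    T[0, d - 1] += profile.reinit_prob * eps[-1]
    return T


def steady_state_distribution(profile: RateProfile) -> OccupancyVector:
    """Stationary ribosome-position distribution ``pi_i ∝ 1/eps_i``.

    Only the conservative circular chain (``lam = 1``) has a stationary
    distribution; for ``lam < 1`` the walk is absorbing (the ribosome
    eventually leaves for the free pool) and an error is raised.
    """
    if profile.reinit_prob != 1.0:
        raise ValueError(
            "steady state requires reinit_prob (lambda) = 1; for lambda < 1 "
            "the chain is absorbing and all template mass eventually leaks "
            "to the free ribosome pool"
        )
    w = 1.0 / profile.epsilons
    return OccupancyVector(probs=w / w.sum(), time=np.inf)


def steady_state_flux(epsilons: np.ndarray) -> float:
    """Steady circulation flux ``1 / sum_k (1/eps_k)`` on the circular template."""
    eps = np.asarray(epsilons, dtype=float)
    return 1.0 / float(np.sum(1.0 / eps))


def polypeptides_per_template(
    profile: RateProfile,
    decay: DecayModel,
    include_decay_prefactor: bool = True,
) -> float:
    """Average number of polypeptides produced per mRNA template.

    For a transcript decaying with first-order rate ``c`` the completion
    flux ``eps_d V_d(t)`` integrated against the transcript survival gives

        c * prod(eps) / (prod(c + eps) - lam * prod(eps))

    With ``include_decay_prefactor=False`` the leading ``c`` is dropped,
    which is the expected completion count over an Exp(c) lifetime
    (``E int_0^tau f dt = int e^{-ct} f dt``); this form diverges like
    ``1/(c sum 1/eps)`` as ``c -> 0`` with ``lam = 1`` (a template that
    never decays produces unboundedly many proteins), whereas the
    prefactored form tends to the steady flux ``1/sum(1/eps)``.

    Products are evaluated as exponentials of log sums; naive products
    overflow already at ``d = 30`` with rates around 50.
    """
    c = decay.mrna_decay_rate
    lam = profile.reinit_prob
    if c <= 0:
        raise ValueError(
            "mrna_decay_rate c must be positive (c = 0 with lambda = 1 makes "
            "the denominator vanish: an immortal circular template)"
        )
    eps = profile.epsilons
    log_ratio = float(np.sum(np.log(eps)) - np.sum(np.log(c + eps)))
    ratio = np.exp(log_ratio)  # prod(eps)/prod(c+eps) in (0, 1)
    denom = 1.0 - lam * ratio
    value = ratio / denom
    if include_decay_prefactor:
        value *= c
    return float(value)


def mean_ribosomes_per_template(profile: RateProfile, decay: DecayModel) -> float:
    """Mean number of ribosomes per template over the template's life.

    Estimated as the decay-weighted mean position of the lead ribosome
    divided by the ribosome spacing ``R``:

        sum_i (i / R) * c * prod_{m<i} eps_m / prod_{k<=i} (c + eps_k)

    Reinitiation is neglected (the open-chain form): the quantity targets
    the elongation-limited regime where the template decays before many
    recycling rounds occur.
    """
    c = decay.mrna_decay_rate
    R = decay.ribosome_spacing
    if c <= 0:
        raise ValueError("mrna_decay_rate c must be positive")
    eps = profile.epsilons
    d = profile.d
    # log term_i = log c + sum_{m<i} log eps_m - sum_{k<=i} log(c+eps_k)
    cum_log_eps = np.concatenate(([0.0], np.cumsum(np.log(eps))[:-1]))
    cum_log_ce = np.cumsum(np.log(c + eps))
    log_terms = np.log(c) + cum_log_eps - cum_log_ce
    i = np.arange(1, d + 1)
    return float(np.sum(i / R * np.exp(log_terms)))


def mean_chain_length(V: OccupancyVector) -> float:
    """Expected chain extension ``L = sum_i i * V_i(t)`` (1-based sites)."""
    i = np.arange(1, V.d + 1)
    return float(np.dot(i, V.probs))


def optimize_limiting_codons(
    profile: RateProfile,
    achievable_max: Sequence[float],
    steps: int | None = None,
) -> list[OptimizationStep]:
    """Greedy codon optimization: repeatedly lift the rate-limiting site.

    At each step the slowest site (smallest ``eps_i``, lowest index on
    ties) is raised to its achievable maximum and the new steady
    circulation flux ``1/sum(1/eps)`` recorded.  The walk stops when the
    slowest site is already at its maximum — the rate-limiting codon can
    no longer be substituted — or when ``steps`` are exhausted.  The flux
    sequence is non-decreasing by construction.
    """
    if profile.reinit_prob != 1.0:
        raise ValueError(
            "codon optimization evaluates the steady circulation flux, which "
            "requires the circular template (reinit_prob = 1)"
        )
    amax = np.asarray(achievable_max, dtype=float)
    eps = profile.epsilons.copy()
    if amax.shape != eps.shape:
        raise ValueError("achievable_max must have one entry per site")
    low = np.nonzero(amax < eps)[0]
    if low.size:
        raise ValueError(
            f"achievable_max at site {low[0] + 1} is below the current rate"
        )
    out: list[OptimizationStep] = []
    budget = np.inf if steps is None else int(steps)
    while len(out) < budget:
        i = int(np.argmin(eps))
        if eps[i] >= amax[i]:
            break  # rate-limiting codon cannot be improved
        eps[i] = amax[i]
        out.append(
            OptimizationStep(site=i + 1, new_epsilon=float(eps[i]),
                             flux=steady_state_flux(eps))
        )
    return out
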