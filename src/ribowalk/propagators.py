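"""Propagators ``Q(t) = exp(t T)`` for the elongation random walk.

Four independent routes to the same semigroup, cross-validated against one
another:

``expm_propagate``
    General matrix exponential (scipy); the reference oracle.
``closed_form_open_chain``
    The open-chain (``lam = 0``) partial-fraction closed form — a sum of
    exponentials over the pole set ``eps_j .. eps_i`` with alternating-sign
    product denominators.  Numerically fragile near tied rates.
``divided_difference_propagator``
    The same entries written as ``prod(eps) x`` divided differences of
    ``exp(t x)`` over the nodes ``-eps_j .. -eps_i``, evaluated in
    extended precision with the confluent rule for repeated nodes.  This
    is the robust fallback where the closed form cancels catastrophically.
``spectral_propagator_circular``
    The circular-template (``lam > 0``) contour-integral entries realized
    as residue sums over the roots of ``prod(s + eps_k) - lam prod(eps)``.

Plus the Laplace-domain operator ``int c e^{-ct} Q(t) dt`` in closed form,
used for per-template polypeptide statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as _scipy_expm
from scipy.stats import poisson as _poisson

import mpmath as mp

from .kinetics import OccupancyVector, RateProfile, build_generator

__all__ = [
    "ConfluentRatesError",
    "SpectralError",
    "expm_propagate",
    "closed_form_open_chain",
    "poisson_propagator",
    "divided_difference_propagator",
    "spectral_propagator_circular",
    "laplace_propagator",
    "propagate",
]

#: relative distance under which two rates are treated as confluent (tied)
CONFLUENCE_RTOL = 1e-6


class ConfluentRatesError(ValueError):
    """Raised when the naive pole-sum form hits (near-)tied rates."""


class SpectralError(RuntimeError):
    """Raised when denominator root-finding is not trustworthy."""


def _clip_matrix(Q: np.ndarray) -> np.ndarray:
    return np.clip(Q, 0.0, 1.0)


def expm_propagate(T: np.ndarray, t: float, v0: OccupancyVector) -> OccupancyVector:
    """Evolve an occupancy vector by ``exp(t T)`` (reference route)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return OccupancyVector(probs=v0.probs.copy(), time=0.0)
    v = _scipy_expm(t * np.asarray(T, dtype=float)) @ v0.probs
    return OccupancyVector(probs=np.clip(v, 0.0, 1.0), time=t)


def expm_matrix(profile: RateProfile, t: float) -> np.ndarray:
    """Full propagator matrix via the general matrix exponential."""
    return _clip_matrix(_scipy_expm(t * build_generator(profile)))


def closed_form_open_chain(profile: RateProfile, t: float) -> np.ndarray:
    """Open-chain propagator by the explicit pole-sum closed form.

    ``Q(t)[i, j] = (-1)^(i-j) prod_{m=j..i-1} eps_m *
    sum_{k=j..i} exp(-t eps_k) / prod_{l != k} (eps_k - eps_l)`` for
    ``i >= j`` (lower triangular).  Requires ``lam = 0`` and pairwise
    distinct rates; raises :class:`ConfluentRatesError` when any two rates
    in a needed block are within relative distance ``CONFLUENCE_RTOL`` so
    the caller can reroute to the divided-difference path.
    """
    if profile.reinit_prob != 0.0:
        raise ValueError("closed_form_open_chain requires reinit_prob = 0")
    eps = profile.epsilons
    d = profile.d
    scale = float(eps.max())
    diffs = np.abs(eps[:, None] - eps[None, :])
    np.fill_diagonal(diffs, np.inf)
    tied = np.nonzero(diffs < CONFLUENCE_RTOL * scale)
    if tied[0].size:
        a, b = int(tied[0][0]) + 1, int(tied[1][0]) + 1
        raise ConfluentRatesError(
            f"rates at sites {a} and {b} are confluent (relative distance "
            f"< {CONFLUENCE_RTOL}); use the divided-difference propagator"
        )
    e = np.exp(-t * eps)
    log_eps = np.log(eps)
    Q = np.zeros((d, d))
    for j in range(d):
        cum = 0.0  # log prod_{m=j..i-1} eps_m
        for i in range(j, d):
            if i > j:
                cum += log_eps[i - 1]
            nodes = eps[j : i + 1]
            acc = 0.0
            for k in range(j, i + 1):
                den = np.prod(eps[k] - np.delete(nodes, k - j))
                acc += e[k] / den
            Q[i, j] = (-1.0) ** (i - j) * np.exp(cum) * acc
    return Q


def poisson_propagator(epsilon: float, d: int, t: float) -> np.ndarray:
    """Equal-rate open-chain propagator: the Poisson step distribution.

    ``Q(t)[i, j] = exp(-t eps) (t eps)^(i-j) / (i-j)!`` for ``i >= j``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = np.arange(d)
    steps = n[:, None] - n[None, :]
    Q = np.where(steps >= 0, _poisson.pmf(np.clip(steps, 0, None), t * epsilon), 0.0)
    return Q


def _dd_exp_table(nodes: list, t) -> list[list]:
    """Divided-difference table of g(x) = exp(t x) over sorted mpmath nodes.

    Equal nodes (grouped adjacent by sorting) use the confluent rule
    ``g^(n)(x)/n! = t^n exp(t x)/n!``.  Divided differences are symmetric
    in their nodes, so sorting is legitimate.
    """
    n = len(nodes)
    tab = [[None] * n for _ in range(n)]
    for a in range(n):
        tab[a][a] = mp.e ** (t * nodes[a])
    for width in range(1, n):
        for a in range(n - width):
            b = a + width
            if nodes[a] == nodes[b]:
                tab[a][b] = t**width * mp.e ** (t * nodes[a]) / mp.factorial(width)
            else:
                tab[a][b] = (tab[a + 1][b] - tab[a][b - 1]) / (nodes[b] - nodes[a])
    return tab


def divided_difference_propagator(profile: RateProfile, t: float) -> np.ndarray:
    """Open-chain propagator via extended-precision divided differences.

    ``Q(t)[i, j] = prod_{m=j..i-1} eps_m * dd(exp(t .); -eps_j .. -eps_i)``.
    Working precision grows with ``d`` (order-``d`` differences cancel
    catastrophically in double precision); repeated nodes take the
    confluent derivative rule, which reproduces the Poisson limit exactly
    when all rates coincide.
    """
    if profile.reinit_prob != 0.0:
        raise ValueError("divided_difference_propagator requires reinit_prob = 0")
    eps = profile.epsilons
    d = profile.d
    Q = np.zeros((d, d))
    with mp.workdps(max(50, 25 + 2 * d)):
        tmp_t = mp.mpf(repr(float(t)))
        nodes_all = [-mp.mpf(repr(float(x))) for x in eps]
        has_ties = len(set(nodes_all)) < d
        log_eps = np.log(eps)
        if not has_ties:
            # one table per column over the natural node order
            for j in range(d):
                tab = _dd_exp_table(nodes_all[j:], tmp_t)
                cum = 0.0
                for i in range(j, d):
                    if i > j:
                        cum += log_eps[i - 1]
                    Q[i, j] = float(mp.e**cum * tab[0][i - j])
        else:
            for j in range(d):
                cum = 0.0
                for i in range(j, d):
                    if i > j:
                        cum += log_eps[i - 1]
                    block = sorted(nodes_all[j : i + 1])
                    tab = _dd_exp_table(block, tmp_t)
                    Q[i, j] = float(mp.e**cum * tab[0][i - j])
    return _clip_matrix(Q)


def _denominator_roots(profile: RateProfile) -> np.ndarray:
    """Roots of ``P(s) = prod(s + eps_k) - lam prod(eps_m)``.

    Companion-matrix eigenvalues of the scaled expanded polynomial,
    polished by one round of Newton on the product form.  The roots lie
    near ``s = -eps_k`` (the perturbation ``lam prod(eps)`` is small
    relative to the spread of the poles for heterogeneous rates).
    """
    eps = profile.epsilons
    lam = profile.reinit_prob
    sigma = float(eps.mean())
    scaled = eps / sigma
    coeffs = np.poly(-scaled)  # prod(u + eps_k/sigma)
    coeffs[-1] -= lam * np.prod(scaled)
    roots = np.roots(coeffs) * sigma

    def P(s):
        return np.prod(s + eps) - lam * np.prod(eps)

    def dP(s):
        prod = np.prod(s + eps)
        return prod * np.sum(1.0 / (s + eps))

    polished = []
    for r in roots:
        s = complex(r)
        for _ in range(3):
            ds = dP(s)
            if ds == 0:
                break
            step = P(s) / ds
            s -= step
            if abs(step) < 1e-14 * (abs(s) + sigma):
                break
        polished.append(s)
    return np.asarray(polished)


def spectral_propagator_circular(profile: RateProfile, t: float) -> np.ndarray:
    """Circular-template propagator as a residue (partial-fraction) sum.

    Each entry is the contour integral of ``exp(t s) N_ij(s) / P(s)`` over
    a contour enclosing every root of the denominator
    ``P(s) = prod(s + eps_k) - lam prod(eps)``; for a rational integrand
    this equals the sum of residues ``exp(t s_r) N_ij(s_r) / P'(s_r)``
    over the (simple) roots ``s_r``.  For ``lam = 1`` the root at
    ``s = 0`` contributes the stationary distribution.
    """
    lam = profile.reinit_prob
    if not 0.0 < lam <= 1.0:
        raise ValueError("spectral_propagator_circular requires 0 < lambda <= 1")
    eps = profile.epsilons
    d = profile.d
    sigma = float(eps.mean())
    roots = _denominator_roots(profile)

    # validate: residual and separation
    prod_eps = np.prod(eps)
    for s in roots:
        res = abs(np.prod(s + eps) - lam * prod_eps)
        scale = max(np.prod(np.abs(s + eps)), lam * prod_eps)
        if res > 1e-7 * scale:
            raise SpectralError(
                f"root residual {res / scale:.2e} above tolerance; "
                "fall back to expm_propagate"
            )
    dist = np.abs(roots[:, None] - roots[None, :])
    np.fill_diagonal(dist, np.inf)
    if dist.min() < CONFLUENCE_RTOL * sigma:
        raise SpectralError(
            "repeated denominator roots beyond confluence tolerance; "
            "fall back to expm_propagate"
        )

    dP = np.array([np.prod(s + eps) * np.sum(1.0 / (s + eps)) for s in roots])
    ets = np.exp(t * roots)

    # suffix/prefix products of (s + eps_k) per root, and of eps
    Q = np.zeros((d, d))
    for r, s in enumerate(roots):
        f = s + eps
        pre = np.concatenate(([1.0 + 0j], np.cumprod(f)))  # pre[k] = prod_{<k}
        suf = np.concatenate((np.cumprod(f[::-1])[::-1], [1.0 + 0j]))
        eps_pre = np.concatenate(([1.0], np.cumprod(eps)))
        eps_suf = np.concatenate((np.cumprod(eps[::-1])[::-1], [1.0]))
        w = ets[r] / dP[r]
        for j in range(d):
            for i in range(d):
                if i < j:
                    # lam * prod_{k=i+1..j-1}(s+eps) * prod_{m=j..d} eps * prod_{m<i} eps
                    num = lam * (pre[j] / pre[i + 1]) * eps_suf[j] * eps_pre[i]
                else:
                    # prod_{k<j}(s+eps) * prod_{k>i}(s+eps) * prod_{m=j..i-1} eps
                    num = pre[j] * suf[i + 1] * (eps_pre[i] / eps_pre[j])
                Q[i, j] += (w * num).real
    return _clip_matrix(Q)


def laplace_propagator(profile: RateProfile, decay) -> np.ndarray:
    """Closed-form ``int_0^inf c e^{-ct} Q(t) dt`` (transcript-lifetime average).

    Entries (log-space products over the positive factors):

    * ``i < j``:  ``c lam prod_{k=i+1..j-1}(c+eps_k) prod_{m=j..d} eps_m
      prod_{m<i} eps_m / D``
    * ``i >= j``: ``c prod_{k<j}(c+eps_k) prod_{k>i}(c+eps_k)
      prod_{m=j..i-1} eps_m / D``

    with ``D = prod(c+eps_k) - lam prod(eps_m)``.  Columns sum to exactly
    1 for ``lam = 1`` (the conservative chain); for ``lam < 1`` the
    deficit is the probability of termination before transcript decay.
    """
    c = decay.mrna_decay_rate
    lam = profile.reinit_prob
    if c <= 0:
        raise ValueError(
            "mrna_decay_rate c must be positive (c = 0 with lambda = 1 has a "
            "vanishing denominator)"
        )
    eps = profile.epsilons
    d = profile.d
    log_ce = np.log(c + eps)
    log_eps = np.log(eps)
    A = float(log_ce.sum())  # log prod(c+eps)
    B = float(log_eps.sum())  # log prod(eps)
    denom = 1.0 - lam * np.exp(B - A)  # D / prod(c+eps)

    cum_ce = np.concatenate(([0.0], np.cumsum(log_ce)))  # cum_ce[k] = sum_{<k}
    cum_eps = np.concatenate(([0.0], np.cumsum(log_eps)))

    Q = np.zeros((d, d))
    logc = np.log(c)
    for j in range(d):
        for i in range(d):
            if i < j:
                if lam == 0.0:
                    continue
                # log num = log c + sum_{k=i+1..j-1} log(c+eps) +
                #           sum_{m=j..d} log eps + sum_{m<i} log eps
                ln = (
                    logc
                    + (cum_ce[j] - cum_ce[i + 1])
                    + (cum_eps[d] - cum_eps[j - 1 + 1])
                    + cum_eps[i]
                )
                Q[i, j] = lam * np.exp(ln - A) / denom
            else:
                ln = (
                    logc
                    + cum_ce[j]
                    + (cum_ce[d] - cum_ce[i + 1])
                    + (cum_eps[i] - cum_eps[j])
                )
                Q[i, j] = np.exp(ln - A) / denom
    return Q


def propagate(
    profile: RateProfile,
    t: float,
    v0: OccupancyVector | None = None,
    method: str = "auto",
) -> OccupancyVector:
    """Evolve ``v0`` to time ``t`` by the requested propagator.

    ``method``: ``expm`` (default for ``auto``), ``closed`` (open chain;
    reroutes to the divided-difference path on confluent rates),
    ``divdiff``, or ``spectral`` (circular chain; falls back to ``expm``
    if root-finding fails).
    """
    if v0 is None:
        p0 = np.zeros(profile.d)
        p0[0] = 1.0
        v0 = OccupancyVector(probs=p0, time=0.0)
    if method in ("auto", "expm"):
        return expm_propagate(build_generator(profile), t, v0)
    if method == "closed":
        try:
            Q = closed_form_open_chain(profile, t)
        except ConfluentRatesError:
            Q = divided_difference_propagator(profile, t)
        return OccupancyVector(probs=np.clip(Q @ v0.probs, 0.0, 1.0), time=t)
    if method == "divdiff":
        Q = divided_difference_propagator(profile, t)
        return OccupancyVector(probs=np.clip(Q @ v0.probs, 0.0, 1.0), time=t)
    if method == "spectral":
        try:
            Q = spectral_propagator_circular(profile, t)
        except SpectralError:
            return expm_propagate(build_generator(profile), t, v0)
        return OccupancyVector(probs=np.clip(Q @ v0.probs, 0.0, 1.0), time=t)
    raise ValueError(f"unknown method {method!r}")
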