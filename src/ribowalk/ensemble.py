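"""Ensemble simulation: populations of templates with random rate constants.

Each template in a population carries its own vector of per-codon rate
constants, drawn site-by-site from a named distribution family.  Evolving
the lead-ribosome occupancy on every template and reading out a protein
metric at the terminal site yields the across-population protein
distribution, which is approximately log-normal: the propagator entries are
sums of high-order *products* of the random rates, and products of random
variables with finite log-variance tend to log-normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as st
from scipy.ndimage import uniform_filter1d

from .kinetics import DecayModel, OccupancyVector, RateProfile, steady_state_distribution
from .propagators import propagate

__all__ = [
    "CorrelationSpec",
    "RateEnsembleSpec",
    "EnsembleOccupancy",
    "ProteinSample",
    "SlowCodonSummary",
    "TransientStats",
    "sample_rate_profiles",
    "apply_spatial_correlation",
    "simulate_occupancy",
    "protein_output_distribution",
    "steady_state_protein_sample",
    "slow_codon_profile",
    "transient_statistics",
    "characteristic_time",
]

_FAMILIES = ("gamma", "normal", "exponential", "lognormal", "fixed")
_METRICS = (
    "terminal_occupancy",
    "completion_flux",
    "cumulative_count",
    "flux_difference",
)


@dataclass(frozen=True)
class CorrelationSpec:
    """Correlation structure imposed on the sampled rates.

    ``along_sites`` correlates rates at neighbouring codons of the same
    template; ``across_templates`` correlates the same codon position
    across neighbouring templates.  ``strength`` in [0, 1) is the variance
    fraction carried by a shared moving-average component of window
    ``length_scale``; marginals are preserved through a Gaussian copula.
    """

    mode: Literal["along_sites", "across_templates"] = "along_sites"
    length_scale: int = 10
    strength: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength < 1.0:
            raise ValueError("correlation strength must lie in [0, 1)")
        if self.length_scale < 1:
            raise ValueError("length_scale must be >= 1")
        if self.mode not in ("along_sites", "across_templates"):
            raise ValueError(f"unknown correlation mode {self.mode!r}")


@dataclass(frozen=True)
class RateEnsembleSpec:
    """Recipe for sampling a population of rate profiles.

    ``params`` per family: gamma ``{shape, scale}``, normal ``{mean, sd}``,
    exponential ``{mean}``, lognormal ``{mu, sigma}`` (of the underlying
    normal), fixed ``{value}``.  ``per_site_means`` overrides the global
    mean site-by-site (keeping the family's shape/sd/sigma); ``slow_sites``
    overrides individual sites, e.g. ``[(20, 1.0)]`` for a near-stalled
    codon.  ``truncation`` is the positivity rule for families with
    negative support (``resample`` rejects and redraws; ``error`` raises).
    """

    family: str
    params: dict
    d: int
    n_templates: int
    seed: int
    reinit_prob: float = 1.0
    per_site_means: Sequence[float] | None = None
    slow_sites: Sequence[tuple[int, float]] | None = None
    correlation: CorrelationSpec | None = None
    truncation: Literal["resample", "error"] = "resample"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if not 0.0 <= self.reinit_prob <= 1.0:
            raise ValueError("reinit_prob (lambda) must lie in [0, 1]")
        if self.per_site_means is not None and len(self.per_site_means) != self.d:
            raise ValueError("per_site_means must have one entry per site")
        if self.slow_sites:
            for site, _ in self.slow_sites:
                if not 1 <= site <= self.d:
                    raise ValueError(f"slow site {site} outside 1..{self.d}")

    def site_means(self) -> np.ndarray:
        """Per-site mean rate after per-site and slow-site overrides."""
        base = _family_mean(self.family, self.params)
        means = (
            np.full(self.d, base)
            if self.per_site_means is None
            else np.asarray(self.per_site_means, dtype=float).copy()
        )
        for site, m in self.slow_sites or []:
            means[site - 1] = m
        if np.any(means <= 0):
            raise ValueError("site means must be positive")
        return means


def _family_mean(family: str, params: dict) -> float:
    if family == "gamma":
        return params["shape"] * params["scale"]
    if family == "normal":
        return params["mean"]
    if family == "exponential":
        return params["mean"]
    if family == "lognormal":
        return float(np.exp(params["mu"] + 0.5 * params["sigma"] ** 2))
    if family == "fixed":
        return params["value"]
    raise ValueError(family)


def _site_dists(spec: RateEnsembleSpec) -> list:
    """Frozen scipy distribution per site, mean-matched to the site means."""
    means = spec.site_means()
    out = []
    for m in means:
        if spec.family == "gamma":
            a = spec.params["shape"]
            out.append(st.gamma(a, scale=m / a))
        elif spec.family == "normal":
            sd = spec.params["sd"]
            out.append(st.norm(loc=m, scale=sd))
        elif spec.family == "exponential":
            out.append(st.expon(scale=m))
        elif spec.family == "lognormal":
            sigma = spec.params["sigma"]
            mu = np.log(m) - 0.5 * sigma**2
            out.append(st.lognorm(sigma, scale=np.exp(mu)))
        elif spec.family == "fixed":
            out.append(None)  # degenerate at m
    return out


def _check_truncation_mass(spec: RateEnsembleSpec) -> None:
    if spec.family != "normal":
        return
    means = spec.site_means()
    sd = spec.params["sd"]
    frac_neg = st.norm.cdf(0.0, loc=means, scale=sd)
    worst = float(frac_neg.max())
    # discarding more than a third of the mass leaves a law that no longer
    # resembles the requested family
    if worst > 1.0 / 3.0:
        raise ValueError(
            f"positivity truncation would discard {worst:.0%} of the mass at "
            "some site; the truncated law no longer resembles the requested "
            "normal family"
        )


def sample_rate_profiles(spec: RateEnsembleSpec) -> list[RateProfile]:
    """Draw ``n_templates`` rate profiles, iid per site and template.

    Deterministic under ``spec.seed``.  Normal-family draws that land at or
    below zero are redrawn (rejection keeps the support correct) under the
    default ``truncation='resample'`` rule.  When a correlation spec is
    present, sampling is delegated to :func:`apply_spatial_correlation`.
    """
    if spec.correlation is not None:
        profiles, _ = apply_spatial_correlation(spec)
        return profiles
    _check_truncation_mass(spec)
    rng = np.random.default_rng(spec.seed)
    means = spec.site_means()
    n, d = spec.n_templates, spec.d
    if spec.family == "fixed":
        eps = np.tile(means, (n, 1))
    elif spec.family == "gamma":
        a = spec.params["shape"]
        eps = rng.gamma(a, means / a, size=(n, d))
    elif spec.family == "exponential":
        eps = rng.exponential(means, size=(n, d))
    elif spec.family == "lognormal":
        sigma = spec.params["sigma"]
        mu = np.log(means) - 0.5 * sigma**2
        eps = rng.lognormal(mu, sigma, size=(n, d))
    elif spec.family == "normal":
        sd = spec.params["sd"]
        eps = rng.normal(means, sd, size=(n, d))
        for _ in range(1000):
            bad = eps <= 0
            if not bad.any():
                break
            if spec.truncation == "error":
                raise ValueError("normal draw produced a non-positive rate")
            idx = np.nonzero(bad)
            eps[idx] = rng.normal(means[idx[1]], sd)
        else:
            raise RuntimeError("positivity resampling failed to converge")
    alpha = 1.2 * float(eps.max())
    return [
        RateProfile(epsilons=row, reinit_prob=spec.reinit_prob, alpha=alpha)
        for row in eps
    ]


def apply_spatial_correlation(
    spec: RateEnsembleSpec,
) -> tuple[list[RateProfile], dict]:
    """Sample rates with the requested correlation via a Gaussian copula.

    A latent standard-normal field mixes an iid component with a shared
    moving-average component (window ``length_scale``, circular so the
    variance is exact), with variance fraction ``strength`` on the shared
    part; mapping through each site's marginal quantile function preserves
    the marginal family exactly.  Returns the profiles and a diagnostics
    dict with the realized lag-1 autocorrelation of the rates.
    """
    corr = spec.correlation
    if corr is None:
        raise ValueError("spec has no correlation block")
    _check_truncation_mass(spec)
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_templates, spec.d
    axis = 1 if corr.mode == "along_sites" else 0
    e = rng.standard_normal((n, d))
    g = rng.standard_normal((n, d))
    w = int(corr.length_scale)
    m = uniform_filter1d(g, size=w, axis=axis, mode="wrap") * np.sqrt(w)
    z = np.sqrt(corr.strength) * m + np.sqrt(1.0 - corr.strength) * e
    u = st.norm.cdf(z)

    dists = _site_dists(spec)
    means = spec.site_means()
    eps = np.empty((n, d))
    for i, dist in enumerate(dists):
        if dist is None:  # fixed family
            eps[:, i] = means[i]
        elif spec.family == "normal":
            # truncated-normal quantile: condition the marginal on positivity
            f0 = dist.cdf(0.0)
            eps[:, i] = dist.ppf(f0 + u[:, i] * (1.0 - f0))
        else:
            eps[:, i] = dist.ppf(u[:, i])
    eps = np.clip(eps, np.finfo(float).tiny, None)

    a = eps[:, :-1] if axis == 1 else eps[:-1, :]
    b = eps[:, 1:] if axis == 1 else eps[1:, :]
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    lag1 = float(np.mean(az * bz))

    alpha = 1.2 * float(eps.max())
    profiles = [
        RateProfile(epsilons=row, reinit_prob=spec.reinit_prob, alpha=alpha)
        for row in eps
    ]
    return profiles, {"lag1_autocorrelation": lag1, "mode": corr.mode}


@dataclass
class EnsembleOccupancy:
    """Occupancy trajectories ``V(t)`` for every retained template.

    ``occupancy`` has shape ``(n_templates, n_times, d)``.  Templates whose
    propagation produced out-of-bound values are dropped and counted
    (``n_in = n_out + n_dropped`` always holds).
    """

    times: np.ndarray
    occupancy: np.ndarray
    profiles: list[RateProfile]
    n_dropped: int = 0
    dropped_indices: list[int] = field(default_factory=list)

    @property
    def n_templates(self) -> int:
        return len(self.profiles)

    @property
    def d(self) -> int:
        return self.occupancy.shape[2]

    def time_index(self, time: float) -> int:
        k = np.nonzero(np.isclose(self.times, time))[0]
        if not k.size:
            raise ValueError(f"time {time} not on the simulated grid {self.times}")
        return int(k[0])


@dataclass(frozen=True)
class ProteinSample:
    """Across-template sample of a protein-output metric at one time."""

    values: np.ndarray
    metric: str
    time: float
    summary: dict


@dataclass(frozen=True)
class SlowCodonSummary:
    times: np.ndarray
    mean_occupancy: np.ndarray  # (n_times, d)
    argmax_site: int  # 1-based, at the latest time


@dataclass(frozen=True)
class TransientStats:
    times: np.ndarray
    chain_length: np.ndarray  # ensemble-mean L(t)
    log_variance: np.ndarray  # (n_times, d) across-template var of log V_i
    n_excluded: np.ndarray  # (n_times, d) zero-probability entries skipped


def simulate_occupancy(
    profiles: Sequence[RateProfile],
    time_grid: Sequence[float],
    v0: np.ndarray | None = None,
    method: str = "auto",
    max_drop_fraction: float = 0.01,
) -> EnsembleOccupancy:
    """Evolve every template over the time grid with the chosen propagator.

    The default initial condition places the ribosome at the initiation
    site, ``V(0) = (1, 0, ..., 0)``.  Templates raising numeric
    out-of-bound conditions are discarded and counted; the run aborts if
    more than ``max_drop_fraction`` of templates are dropped.
    """
    times = np.asarray(time_grid, dtype=float)
    if times.size == 0 or np.any(np.diff(times) < 0):
        raise ValueError("time grid must be non-empty and monotone increasing")
    d = profiles[0].d
    if v0 is None:
        v0 = np.zeros(d)
        v0[0] = 1.0
    kept: list[RateProfile] = []
    rows: list[np.ndarray] = []
    dropped: list[int] = []
    for idx, prof in enumerate(profiles):
        vec = OccupancyVector(probs=v0, time=0.0)
        traj = np.empty((times.size, d))
        ok = True
        for k, t in enumerate(times):
            try:
                out = propagate(prof, t, vec, method=method)
            except (FloatingPointError, OverflowError, ValueError):
                ok = False
                break
            if not np.all(np.isfinite(out.probs)):
                ok = False
                break
            traj[k] = out.probs
        if ok:
            kept.append(prof)
            rows.append(traj)
        else:
            dropped.append(idx)
    n_in = len(profiles)
    if len(dropped) > max_drop_fraction * n_in:
        raise RuntimeError(
            f"{len(dropped)}/{n_in} templates dropped (> {max_drop_fraction:.0%})"
        )
    return EnsembleOccupancy(
        times=times,
        occupancy=np.stack(rows) if rows else np.empty((0, times.size, d)),
        profiles=kept,
        n_dropped=len(dropped),
        dropped_indices=dropped,
    )


def _terminal_rates(occ: EnsembleOccupancy) -> np.ndarray:
    return np.array([p.epsilons[-1] for p in occ.profiles])


def _initial_rates(occ: EnsembleOccupancy) -> np.ndarray:
    return np.array([p.epsilons[0] for p in occ.profiles])


def _decayed_cumulative(
    times: np.ndarray, flux: np.ndarray, k_decay: float, upto: int
) -> np.ndarray:
    """``int_0^t exp(-k (t - tau)) f(tau) dtau`` by trapezoid on the grid."""
    t = times[: upto + 1]
    f = flux[:, : upto + 1]
    if k_decay == 0.0:
        return np.trapezoid(f, t, axis=1)
    kern = np.exp(-k_decay * (t[-1] - t))
    return np.trapezoid(f * kern, t, axis=1)


def protein_output_distribution(
    occ: EnsembleOccupancy,
    metric: str = "terminal_occupancy",
    time: float | None = None,
    decay: DecayModel | None = None,
) -> ProteinSample:
    """Across-template sample of a protein-output metric.

    Metrics: ``terminal_occupancy`` (``V_d(t)``, the default population
    readout), ``completion_flux`` (``eps_d V_d``), ``cumulative_count``
    (``int_0^t eps_d V_d dtau``, drained at ``decay.protein_decay_rate``
    when given), and ``flux_difference`` (``eps_d V_d - eps_1 V_1``, the
    instantaneous termination-minus-initiation flux).
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    k = occ.time_index(time) if time is not None else occ.occupancy.shape[1] - 1
    t = float(occ.times[k])
    vd = occ.occupancy[:, :, -1]
    if metric == "terminal_occupancy":
        values = vd[:, k]
    elif metric == "completion_flux":
        values = _terminal_rates(occ) * vd[:, k]
    elif metric == "cumulative_count":
        flux = _terminal_rates(occ)[:, None] * vd
        kd = decay.protein_decay_rate if decay is not None else 0.0
        values = _decayed_cumulative(occ.times, flux, kd, k)
    else:  # flux_difference
        values = _terminal_rates(occ) * vd[:, k] - _initial_rates(occ) * occ.occupancy[
            :, k, 0
        ]
    values = np.asarray(values, dtype=float)
    summary = {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
        "n_dropped": occ.n_dropped,
    }
    return ProteinSample(values=values, metric=metric, time=t, summary=summary)


def steady_state_protein_sample(
    profiles: Sequence[RateProfile], metric: str = "terminal_occupancy"
) -> np.ndarray:
    """Exact long-time protein sample on circular templates (``lam = 1``).

    The stationary occupancy is ``pi_i ∝ 1/eps_i``, so the terminal
    occupancy is ``(1/eps_d) / sum_k (1/eps_k)`` and the completion flux
    is the circulation flux ``1 / sum_k (1/eps_k)`` per template.
    """
    vals = np.empty(len(profiles))
    for j, p in enumerate(profiles):
        pi_d = steady_state_distribution(p).probs[-1]
        if metric == "terminal_occupancy":
            vals[j] = pi_d
        elif metric == "completion_flux":
            vals[j] = p.epsilons[-1] * pi_d
        else:
            raise ValueError(
                "steady-state sample supports terminal_occupancy or completion_flux"
            )
    return vals


def slow_codon_profile(occ: EnsembleOccupancy) -> SlowCodonSummary:
    """Mean occupancy per site over time, and the late-time stalling site.

    A near-zero rate at one codon makes the walk pile up there: the
    argmax of the late-time mean occupancy localises the stall.
    """
    mean_occ = occ.occupancy.mean(axis=0)  # (n_times, d)
    return SlowCodonSummary(
        times=occ.times,
        mean_occupancy=mean_occ,
        argmax_site=int(np.argmax(mean_occ[-1])) + 1,
    )


def transient_statistics(
    occ: EnsembleOccupancy,
    decay: DecayModel | None = None,
    floor: float = 1e-300,
) -> TransientStats:
    """Ensemble-mean chain length ``L(t)`` and per-site log-variance.

    ``L(t) = mean_j sum_i i V_i(t)`` plus, on open chains
    (``lam = 0``), ``d`` times the completed-protein pool fed by the
    completion flux ``eps_d V_d`` and drained at
    ``decay.protein_decay_rate`` — without this term mass released at
    termination would silently vanish from the expected length.  The
    log-variance is the across-template variance of ``log V_i(t)``;
    entries at or below ``floor`` are excluded and counted.
    """
    if occ.n_templates < 2:
        raise ValueError("transient statistics need at least 2 templates")
    n, nt, d = occ.occupancy.shape
    i = np.arange(1, d + 1)
    ell = occ.occupancy @ i  # (n, nt)
    lam0 = all(p.reinit_prob == 0.0 for p in occ.profiles)
    if lam0:
        kd = decay.protein_decay_rate if decay is not None else 0.0
        flux = _terminal_rates(occ)[:, None] * occ.occupancy[:, :, -1]
        pool = np.stack(
            [_decayed_cumulative(occ.times, flux, kd, k) for k in range(nt)], axis=1
        )
        ell = ell + d * pool
    L = ell.mean(axis=0)

    logv = np.full((nt, d), np.nan)
    nexcl = np.zeros((nt, d), dtype=int)
    for k in range(nt):
        V = occ.occupancy[:, k, :]
        for s in range(d):
            col = V[:, s]
            good = col > floor
            nexcl[k, s] = int(np.sum(~good))
            if good.sum() >= 2:
                logv[k, s] = float(np.var(np.log(col[good]), ddof=1))
    return TransientStats(times=occ.times, chain_length=L, log_variance=logv,
                          n_excluded=nexcl)


def characteristic_time(spec: RateEnsembleSpec) -> float:
    """One mean traversal of the template: ``T = d / mean(eps)``."""
    return spec.d / float(spec.site_means().mean())


def default_protein_decay_rate(spec: RateEnsembleSpec) -> float:
    """Default completed-protein decay: ``0.02 * mean(eps) / d``."""
    return 0.02 * float(spec.site_means().mean()) / spec.d
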