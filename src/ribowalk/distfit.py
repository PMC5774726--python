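"""Distribution fitting for protein-output samples.

Maximum-likelihood fits of log-normal, log-logistic, gamma and normal
families, two-component mixtures by EM, model selection by an information
criterion over a fixed candidate library, and Q-Q / tail diagnostics.

All log-likelihoods are reported on the *original* data scale (log-domain
families carry the Jacobian term), so criteria are comparable across
families that live on different scales.

The log-logistic family is parameterised on the log scale: if ``X`` is
log-logistic then ``log X`` is logistic with location ``loc`` and scale
``scale`` — stated explicitly to avoid the shape/scale dialect confusion
around this family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as st

__all__ = [
    "FitResult",
    "DegenerateDataError",
    "fit_single",
    "fit_mixture",
    "select_best_model",
    "qq_points",
    "tail_deviation_metric",
    "mixture_logpdf",
    "mixture_cdf",
    "mixture_ppf",
]

_MIN_N = 50
# EM stops on an absolute log-likelihood change below _EM_TOL.  Near-lognormal
# samples put the two-lognormal mixture on a long, almost flat likelihood
# ridge: a loose (relative) tolerance or a small iteration cap strands the fit
# mid-ridge at an arbitrary weight, whereas runs from opposite initialisations
# converge to the same maximiser when allowed to finish.
_EM_TOL = 1e-8
_EM_MAX_ITER = 20_000
# mixtures containing a component whose M-step is itself an inner numerical
# optimisation (log-logistic) get a bounded budget: full ridge convergence is
# only required for the closed-form M-step pairs
_EM_TOL_SLOW = 1e-6
_EM_MAX_ITER_SLOW = 1_000


class DegenerateDataError(ValueError):
    """Sample admits no MLE (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# component families
# ---------------------------------------------------------------------------


class _Family:
    name: str
    n_params: int
    log_domain: bool

    def logpdf(self, x: np.ndarray, params: tuple) -> np.ndarray:
        raise NotImplementedError

    def fit_weighted(self, x: np.ndarray, w: np.ndarray, x0: tuple | None = None) -> tuple:
        raise NotImplementedError

    def ppf(self, q: np.ndarray, params: tuple) -> np.ndarray:
        raise NotImplementedError

    def ppf_log(self, q: np.ndarray, params: tuple) -> np.ndarray:
        """Quantiles of log X (log-domain families only)."""
        raise NotImplementedError


_LOG_2PI = float(np.log(2.0 * np.pi))


class _LogNormal(_Family):
    name = "lognormal"
    n_params = 2
    log_domain = True

    def logpdf(self, x, params):
        mu, sigma = params
        y = np.log(x)
        z = (y - mu) / sigma
        return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI - y

    def fit_weighted(self, x, w, x0=None):
        y = np.log(x)
        wsum = w.sum()
        mu = float(np.dot(w, y) / wsum)
        var = float(np.dot(w, (y - mu) ** 2) / wsum)
        if var < 1e-24:
            raise DegenerateDataError("zero variance on the log scale")
        return (mu, float(np.sqrt(var)))

    def ppf(self, q, params):
        mu, sigma = params
        return np.exp(st.norm.ppf(q, mu, sigma))

    def ppf_log(self, q, params):
        mu, sigma = params
        return st.norm.ppf(q, mu, sigma)


class _LogLogistic(_Family):
    name = "loglogistic"
    n_params = 2
    log_domain = True

    def logpdf(self, x, params):
        loc, scale = params
        y = np.log(x)
        z = (y - loc) / scale
        return -z - 2.0 * np.log1p(np.exp(-z)) - np.log(scale) - y

    def fit_weighted(self, x, w, x0=None):
        y = np.log(x)
        wsum = w.sum()
        mu0 = float(np.dot(w, y) / wsum)
        sd0 = float(np.sqrt(np.dot(w, (y - mu0) ** 2) / wsum))
        if sd0 < 1e-12:
            raise DegenerateDataError("zero variance on the log scale")
        if x0 is not None:
            start = [x0[0], np.log(x0[1])]
        else:
            start = [mu0, np.log(sd0 * np.sqrt(3.0) / np.pi)]  # logistic sd = s*pi/sqrt(3)

        def nll_grad(theta):
            loc, logs = theta
            s = np.exp(logs)
            z = (y - loc) / s
            val = float(np.dot(w, z + 2.0 * np.log1p(np.exp(-z)) + logs))
            th = np.tanh(0.5 * z)
            g_loc = -float(np.dot(w, th)) / s
            g_logs = float(np.dot(w, 1.0 - z * th))
            return val, np.array([g_loc, g_logs])

        res = optimize.minimize(nll_grad, x0=start, jac=True, method="BFGS",
                                options={"gtol": 1e-8})
        loc, logs = res.x
        return (float(loc), float(np.exp(logs)))

    def ppf(self, q, params):
        loc, scale = params
        return np.exp(st.logistic.ppf(q, loc, scale))

    def ppf_log(self, q, params):
        loc, scale = params
        return st.logistic.ppf(q, loc, scale)


class _Gamma(_Family):
    name = "gamma"
    n_params = 2
    log_domain = False

    def logpdf(self, x, params):
        shape, scale = params
        return (
            (shape - 1.0) * np.log(x)
            - x / scale
            - shape * np.log(scale)
            - special.gammaln(shape)
        )

    def fit_weighted(self, x, w, x0=None):
        # weighted MLE: solve log(a) - psi(a) = log(mean_w x) - mean_w log x
        wsum = w.sum()
        mx = float(np.dot(w, x) / wsum)
        mlx = float(np.dot(w, np.log(x)) / wsum)
        s = np.log(mx) - mlx
        if s <= 0:
            raise DegenerateDataError("zero variance")

        def g(a):
            return np.log(a) - special.digamma(a) - s

        a = optimize.brentq(g, 1e-6, 1e8)
        return (float(a), mx / a)

    def ppf(self, q, params):
        shape, scale = params
        return st.gamma.ppf(q, shape, scale=scale)


class _Normal(_Family):
    name = "normal"
    n_params = 2
    log_domain = False

    def logpdf(self, x, params):
        mu, sigma = params
        z = (x - mu) / sigma
        return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI

    def fit_weighted(self, x, w, x0=None):
        wsum = w.sum()
        mu = float(np.dot(w, x) / wsum)
        var = float(np.dot(w, (x - mu) ** 2) / wsum)
        if var < 1e-24:
            raise DegenerateDataError("zero variance")
        return (mu, float(np.sqrt(var)))

    def ppf(self, q, params):
        return st.norm.ppf(q, *params)


FAMILIES: dict[str, _Family] = {
    f.name: f for f in (_LogNormal(), _LogLogistic(), _Gamma(), _Normal())
}


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """A fitted distribution or mixture.

    ``components`` is a list of ``(family, params, weight)`` sorted by
    descending weight; weights are positive and sum to 1.  ``criterion``
    is the BIC on the original data scale.
    """

    components: list[tuple[str, tuple, float]]
    loglik: float
    n: int
    criterion: float
    converged: bool
    n_restarts_used: int = 0
    degenerate: bool = False
    leaderboard: list[tuple[str, float, int]] = field(default_factory=list)

    @property
    def dominant_weight(self) -> float:
        return self.components[0][2]

    @property
    def label(self) -> str:
        return "+".join(c[0] for c in self.components)

    @property
    def n_free_params(self) -> int:
        return sum(FAMILIES[c[0]].n_params for c in self.components) + (
            len(self.components) - 1
        )

    @property
    def log_domain(self) -> bool:
        return all(FAMILIES[c[0]].log_domain for c in self.components)

    def to_dict(self) -> dict:
        return {
            "components": [
                {"family": f, "params": list(p), "weight": w}
                for f, p, w in self.components
            ],
            "loglik": self.loglik,
            "n": self.n,
            "criterion": self.criterion,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "degenerate": self.degenerate,
        }


def mixture_logpdf(x: np.ndarray, components) -> np.ndarray:
    parts = np.stack(
        [np.log(w) + FAMILIES[f].logpdf(x, p) for f, p, w in components]
    )
    return special.logsumexp(parts, axis=0)


def mixture_cdf(x: np.ndarray, components, log_scale: bool = False) -> np.ndarray:
    out = np.zeros_like(np.asarray(x, dtype=float))
    for f, p, w in components:
        fam = FAMILIES[f]
        if log_scale:
            if f == "lognormal":
                out += w * st.norm.cdf(x, *p)
            elif f == "loglogistic":
                out += w * st.logistic.cdf(x, *p)
            else:
                raise ValueError(f"{f} has no log-scale cdf")
        else:
            if f == "lognormal":
                out += w * st.norm.cdf(np.log(x), *p)
            elif f == "loglogistic":
                out += w * st.logistic.cdf(np.log(x), *p)
            else:
                out += w * st.gamma.cdf(x, p[0], scale=p[1]) if f == "gamma" else (
                    w * st.norm.cdf(x, *p)
                )
    return out


def mixture_ppf(q: np.ndarray, components, log_scale: bool = False) -> np.ndarray:
    """Quantiles of a mixture by bracketed root-finding on the cdf."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if len(components) == 1:
        f, p, _ = components[0]
        fam = FAMILIES[f]
        return fam.ppf_log(q, p) if log_scale else fam.ppf(q, p)
    # bracket with the extreme component quantiles
    los, his = [], []
    for f, p, _ in components:
        fam = FAMILIES[f]
        pf = fam.ppf_log if log_scale else fam.ppf
        los.append(pf(q, p))
        his.append(pf(q, p))
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    out = np.empty_like(q)
    for k, (qq, a, b) in enumerate(zip(q, lo, hi)):
        if b - a < 1e-13:
            out[k] = a
            continue
        a -= 1e-9 + 1e-9 * abs(a)
        b += 1e-9 + 1e-9 * abs(b)
        out[k] = optimize.brentq(
            lambda x: mixture_cdf(np.array([x]), components, log_scale)[0] - qq,
            a, b, xtol=1e-13, rtol=8.9e-16,
        )
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _validate_sample(x: np.ndarray, families: Sequence[str]) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < _MIN_N:
        raise ValueError(f"need at least {_MIN_N} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if any(FAMILIES[f].log_domain for f in families) and np.any(x <= 0):
        raise ValueError("log-domain families require strictly positive data")
    return x


def _bic(loglik: float, k: int, n: int) -> float:
    return k * np.log(n) - 2.0 * loglik


def fit_single(sample: np.ndarray, family: str = "lognormal") -> FitResult:
    """Maximum-likelihood fit of one family.  Deterministic given the sample."""
    fam = FAMILIES[family]
    x = _validate_sample(sample, [family])
    params = fam.fit_weighted(x, np.ones_like(x))
    ll = float(np.sum(fam.logpdf(x, params)))
    return FitResult(
        components=[(family, params, 1.0)],
        loglik=ll,
        n=x.size,
        criterion=_bic(ll, fam.n_params, x.size),
        converged=True,
    )


def _em_once(
    x: np.ndarray, fams: Sequence[str], resp0: np.ndarray
) -> tuple[list, float, bool, int]:
    """One EM run from initial responsibilities; returns components, loglik."""
    slow = "loglogistic" in fams
    tol = _EM_TOL_SLOW if slow else _EM_TOL
    max_iter = _EM_MAX_ITER_SLOW if slow else _EM_MAX_ITER
    resp = resp0
    ll_old = -np.inf
    components: list = []
    converged = False
    it = 0
    prev_params: list = [None, None]
    for it in range(1, max_iter + 1):
        # M-step
        weights = np.clip(resp.mean(axis=1), 1e-8, None)
        weights = weights / weights.sum()
        components = []
        for c, fname in enumerate(fams):
            params = FAMILIES[fname].fit_weighted(x, resp[c], x0=prev_params[c])
            prev_params[c] = params
            components.append((fname, params, float(weights[c])))
        # E-step (two components: manual logsumexp)
        a = np.log(components[0][2]) + FAMILIES[fams[0]].logpdf(x, components[0][1])
        b = np.log(components[1][2]) + FAMILIES[fams[1]].logpdf(x, components[1][1])
        hi = np.maximum(a, b)
        norm = hi + np.log(np.exp(a - hi) + np.exp(b - hi))
        ll = float(norm.sum())
        resp = np.stack([np.exp(a - norm), np.exp(b - norm)])
        if abs(ll - ll_old) <= tol:
            converged = True
            break
        ll_old = ll
    return components, ll, converged, it


def fit_mixture(
    sample: np.ndarray,
    families: Sequence[str] = ("lognormal", "lognormal"),
    restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Two-component mixture MLE by EM with random restarts.

    Initial responsibilities split the sample at a random quantile (the
    first restart uses the median), hardened to 0.9/0.1.  The best
    final log-likelihood across restarts wins; components are sorted by
    descending weight.  A solution with a component weight below 0.01 is
    flagged ``degenerate`` (weight-collapsed) but still returned.
    """
    if len(families) != 2:
        raise ValueError("families must name exactly two components")
    x = _validate_sample(sample, families)
    x = np.sort(x)
    n = x.size
    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    for r in range(max(1, restarts)):
        q = 0.5 if r == 0 else float(rng.uniform(0.15, 0.85))
        cut = np.quantile(x, q)
        hard = (x <= cut).astype(float)
        resp0 = np.stack([0.9 * hard + 0.1 * (1 - hard),
                          0.1 * hard + 0.9 * (1 - hard)])
        try:
            comps, ll, conv, _ = _em_once(x, families, resp0)
        except DegenerateDataError:
            continue
        n_used = r + 1
        if best is None or ll > best[1]:
            best = (comps, ll, conv)
    if best is None:
        raise DegenerateDataError("all EM restarts failed on this sample")
    comps, ll, conv = best
    comps = sorted(comps, key=lambda c: -c[2])
    k = sum(FAMILIES[f].n_params for f, _, _ in comps) + 1
    return FitResult(
        components=comps,
        loglik=ll,
        n=n,
        criterion=_bic(ll, k, n),
        converged=conv,
        n_restarts_used=n_used,
        degenerate=min(c[2] for c in comps) < 0.01,
    )


DEFAULT_CANDIDATES: list = [
    "lognormal",
    "loglogistic",
    "gamma",
    "normal",
    ("lognormal", "lognormal"),
    ("lognormal", "loglogistic"),
    ("lognormal", "gamma"),
]


def select_best_model(
    sample: np.ndarray,
    candidates: Sequence | None = None,
    restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit every candidate and return the lowest-BIC model.

    The candidate library is fixed in advance — no target family is
    pre-specified, so the winner is determined by the data alone.  Failed
    candidates are excluded; near-ties (BIC within 1e-6) go to the model
    with fewer parameters.  The full leaderboard (label, BIC, k) is kept
    on the returned result.
    """
    if candidates is None:
        candidates = DEFAULT_CANDIDATES
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    fits: list[FitResult] = []
    for cand in candidates:
        try:
            if isinstance(cand, str):
                fits.append(fit_single(sample, cand))
            else:
                fits.append(fit_mixture(sample, cand, restarts=restarts, seed=seed))
        except (DegenerateDataError, ValueError):
            continue
    if not fits:
        raise DegenerateDataError("no candidate could be fitted")
    fits.sort(key=lambda f: (round(f.criterion, 6), f.n_free_params))
    board = [(f.label, f.criterion, f.n_free_params) for f in fits]
    winner = fits[0]
    return FitResult(
        components=winner.components,
        loglik=winner.loglik,
        n=winner.n,
        criterion=winner.criterion,
        converged=winner.converged,
        n_restarts_used=winner.n_restarts_used,
        degenerate=winner.degenerate,
        leaderboard=board,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _as_fit(sample: np.ndarray, reference) -> FitResult:
    if isinstance(reference, FitResult):
        return reference
    if isinstance(reference, str):
        return fit_single(sample, reference)
    raise TypeError("reference must be a FitResult or a family name")


def qq_points(sample: np.ndarray, reference) -> "pd.DataFrame":
    """Paired (theoretical, empirical) quantiles at positions ``(k-1/2)/n``.

    When the reference is log-domain both axes are log-transformed, so a
    perfect fit lies on ``y = x`` either way.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    if x.size < 10:
        raise ValueError("need at least 10 observations for a Q-Q table")
    fit = _as_fit(sample, reference)
    q = (np.arange(1, x.size + 1) - 0.5) / x.size
    if fit.log_domain:
        theo = mixture_ppf(q, fit.components, log_scale=True)
        emp = np.log(x)
    else:
        theo = mixture_ppf(q, fit.components, log_scale=False)
        emp = x
    return pd.DataFrame({"theoretical": theo, "empirical": emp})


def tail_deviation_metric(sample: np.ndarray, fit) -> dict:
    """Signed mean Q-Q residual in each 5% tail, plus inner-90% RMS.

    Positive upper-tail values mean the sample is heavier to the right
    than the fitted law; the inner RMS scores the central fit.
    """
    table = qq_points(sample, fit)
    resid = (table["empirical"] - table["theoretical"]).to_numpy()
    n = resid.size
    m = max(1, int(np.ceil(0.05 * n)))
    inner = resid[m:-m] if n > 2 * m else resid
    return {
        "lower": float(resid[:m].mean()),
        "upper": float(resid[-m:].mean()),
        "inner_rms": float(np.sqrt(np.mean(inner**2))),
    }
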