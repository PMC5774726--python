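"""Deterministic fixture generator.

Produces the small inputs every other module is tested against, without
any external data: a tiny rate profile, reduced-size ensemble configs for
the steady-state and slow-codon experiments, and a known two-lognormal
sample for the fitting layer.  Output is bit-identical for a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("tiny_profile", "fig2_small", "fig6_slow_codon", "mixture_sample")


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def generate_fixtures(kind: str, seed: int, outdir: str | Path = ".") -> list[Path]:
    """Write the named fixture into ``outdir`` and return the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if kind == "tiny_profile":
        eps = rng.gamma(10.0, 5.0, size=5)
        path = out / "tiny_profile.csv"
        lines = ["epsilon"] + [repr(float(e)) for e in eps]
        path.write_text("\n".join(lines) + "\n")
        return [path]

    if kind == "fig2_small":
        # steady-state protein-distribution experiment at reduced size:
        # d=30 gamma(10, 5) rates, circular boundary, time grid in units of
        # one mean traversal T = d/mean(eps) = 0.6
        cfg = {
            "family": "gamma",
            "params": {"shape": 10.0, "scale": 5.0},
            "d": 30,
            "n": 500,
            "seed": seed,
            "reinit_prob": 1.0,
            "times": [0.3, 0.6, 1.2, 1.8],
            "metric": "terminal_occupancy",
        }
        path = out / "fig2_small.json"
        _write_json(path, cfg)
        return [path]

    if kind == "fig6_slow_codon":
        means = rng.uniform(50.0, 150.0, size=30)
        means[19] = 1.0  # site 20 near zero relative to 50-150 elsewhere
        cfg = {
            "family": "gamma",
            "params": {"shape": 10.0, "scale": 5.0},
            "d": 30,
            "n": 500,
            "seed": seed,
            "reinit_prob": 1.0,
            "per_site_means": [float(m) for m in means],
            "times": [0.05, 0.2, 1.0, 5.0],
        }
        path = out / "fig6_slow_codon.json"
        _write_json(path, cfg)
        return [path]

    if kind == "mixture_sample":
        n = 2000
        labels = rng.random(n) < 0.7
        y = np.where(
            labels,
            rng.normal(3.0, 0.4, size=n),
            rng.normal(4.5, 0.3, size=n),
        )
        sample = np.exp(y)
        path = out / "mixture_sample.csv"
        lines = ["value"] + [repr(float(v)) for v in sample]
        path.write_text("\n".join(lines) + "\n")
        return [path]

    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
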