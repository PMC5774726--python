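"""Result tables and run manifests.

Every CLI run writes its tables as CSV with a fixed column order plus a
JSON manifest (config hash, seed, library versions, drop counts) from
which the run is reproducible.  No timestamps: identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

__all__ = ["write_results"]


def write_results(
    tables: dict[str, pd.DataFrame],
    prefix: str | Path,
    manifest: dict | None = None,
) -> list[Path]:
    """Write ``<prefix>_<name>.csv`` per table and ``<prefix>_manifest.json``.

    Empty tables still produce a header-only CSV, and the manifest is
    always written.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for name, df in tables.items():
        p = prefix.parent / f"{prefix.name}_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    from . import __version__

    man = {
        "versions": {
            "ribowalk": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    man.update(manifest or {})
    mp = prefix.parent / f"{prefix.name}_manifest.json"
    mp.write_text(json.dumps(man, indent=2, sort_keys=True) + "\n")
    paths.append(mp)
    return paths
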