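"""Run manifests: enough metadata to reproduce any simulation bit-exactly."""

from __future__ import annotations

import json
import platform
import warnings
from importlib import metadata as _ilmd

import numpy as np

from .params import SimParams


def _versions() -> dict:
    out = {"python": platform.python_version(), "numpy": np.__version__}
    for pkg in ("igcsim", "numba", "scipy"):
        try:
            out[pkg] = _ilmd.version(pkg)
        except _ilmd.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


def run_manifest(params: SimParams, seed: int | None = None,
                 thin: int = 10, extra: dict | None = None) -> dict:
    """Build a JSON-serializable manifest for one run.  A missing seed is
    generated (and recorded) so the run stays reproducible."""
    if seed is None:
        seed = int(np.random.default_rng().integers(0, 2**31 - 1))
    p = params.replace(seed=int(seed))
    man = {"params": p.to_dict(), "seed": int(seed), "thin": int(thin),
           "versions": _versions()}
    if extra:
        man["extra"] = extra
    return man


def write_manifest(man: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def replay(man: dict):
    """Re-run the simulation a manifest describes.  Version drift between
    the recording and replaying environments is warned about (bit-exact
    replay is only guaranteed on matching versions)."""
    from .sim_core import run_simulation

    current = _versions()
    drift = {k: (v, current.get(k)) for k, v in man["versions"].items()
             if current.get(k) != v}
    if drift:
        warnings.warn(f"replaying under different versions: {drift}",
                      stacklevel=2)
    params = SimParams.from_dict(man["params"]).replace(seed=man["seed"])
    return run_simulation(params, thin=man.get("thin", 10))
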