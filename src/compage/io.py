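"""Reading and writing system configurations, tables and trajectories.

A system is described by a JSON config that either names a built-in
fixture, gives constant ``B`` and ``s`` inline, points at sampled CSV
tables (columns ``t, b_1_1, ..., b_d_d`` row-major and
``t, s_1, ..., s_d``; omit ``t`` for a constant system), requests the
CASA model with parameter overrides, or requests a generated random
system.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import CompartmentalSystem

__all__ = ["load_system", "save_generated_system"]


def load_system(config) -> CompartmentalSystem:
    """Build a system from a JSON config path, file object or dict."""
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        with open(config) as fh:
            cfg = json.load(fh)
    else:
        cfg = dict(config)
        base = Path(".")

    if "fixture" in cfg:
        from .synthetic import fixture
        return fixture(cfg["fixture"])

    if "casa" in cfg:
        from .casa import CasaParameters, build_casa_system
        return build_casa_system(CasaParameters(**cfg["casa"]))

    if "generator" in cfg:
        from .synthetic import GeneratorSpec, generate_system
        return generate_system(GeneratorSpec(**cfg["generator"]))

    labels = cfg.get("labels")
    if "B" in cfg and "s" in cfg:
        interval = tuple(cfg.get("interval", (0.0, np.inf)))
        return CompartmentalSystem.from_constant(
            np.asarray(cfg["B"], dtype=float), np.asarray(cfg["s"], dtype=float),
            interval=interval, labels=labels)

    if "B_csv" in cfg and "s_csv" in cfg:
        Bt = pd.read_csv(base / cfg["B_csv"])
        st = pd.read_csv(base / cfg["s_csv"])
        return CompartmentalSystem.from_tables(Bt, st, labels=labels)

    raise ValueError(
        "config must contain one of: 'fixture', 'casa', 'generator', "
        "inline 'B'+'s', or 'B_csv'+'s_csv'")


def save_generated_system(system: CompartmentalSystem, out_json,
                          n_knots: int = 101) -> None:
    """Write a system as a JSON config plus sampled CSV coefficient tables.

    The tables sample B and s on ``n_knots`` evenly spaced times across
    the practical interval; reloading interpolates linearly between the
    knots, so a reloaded time-varying system is an approximation of the
    original at the knot resolution.
    """
    out_json = Path(out_json)
    stem = out_json.with_suffix("")
    lo, hi = system.interval
    hi = min(hi, lo + 100.0)
    ts = np.linspace(lo, hi, n_knots)

    Brows = {"t": ts}
    for i in range(system.d):
        for j in range(system.d):
            Brows[f"b_{i+1}_{j+1}"] = [system.B_at(t)[i, j] for t in ts]
    srows = {"t": ts}
    for i in range(system.d):
        srows[f"s_{i+1}"] = [system.s_at(t)[i] for t in ts]

    b_path = stem.parent / (stem.name + "_B.csv")
    s_path = stem.parent / (stem.name + "_s.csv")
    pd.DataFrame(Brows).to_csv(b_path, index=False)
    pd.DataFrame(srows).to_csv(s_path, index=False)
    cfg = {
        "d": system.d,
        "labels": list(system.labels) if system.labels else None,
        "interval": [float(lo), float(hi)],
        "B_csv": b_path.name,
        "s_csv": s_path.name,
    }
    with open(out_json, "w") as fh:
        json.dump(cfg, fh, indent=2)
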