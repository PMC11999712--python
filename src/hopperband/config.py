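"""Flat TOML configuration files for the model parameter set.

The on-disk dialect is a flat key = value file whose keys are exactly
the ten tunable constants (``D, gamma, A, r, k, kappa, delta, nu,
eta_l, eta_f``).  Missing keys take their calibrated defaults; unknown
keys are rejected so typos cannot silently fall back to a default.
Round-tripping is bit-exact because values are written with ``repr``.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .model import PARAM_KEYS, ModelParams

__all__ = ["load_params", "save_params"]


def load_params(path) -> ModelParams:
    """Read a parameter file; an empty file yields the full defaults."""
    text = Path(path).read_text()
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    unknown = set(data) - set(PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter key(s): {', '.join(sorted(unknown))}")
    bad = [k for k, v in data.items() if not isinstance(v, (int, float)) or isinstance(v, bool)]
    if bad:
        raise ValueError(f"parameter(s) {', '.join(sorted(bad))} must be numbers")
    try:
        return ModelParams(**{k: float(v) for k, v in data.items()})
    except ValueError as exc:
        raise ValueError(f"invalid parameter file {path}: {exc}") from exc


def save_params(params: ModelParams, path) -> None:
    """Write the ten constants as flat TOML, full float precision."""
    lines = [f"{k} = {getattr(params, k)!r}" for k in PARAM_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")
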