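"""Flat key = value run configuration for the command-line pipeline.

One option per line, ``key = value``; blank lines and ``#`` comments are
ignored. Unknown keys are rejected so typos fail loudly. Defaults match the
analysis conventions: top 500 peaks, ±250 bp summit windows, 50 bp merge
gap, similarity background n = 100,000 and l = 100.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from motifbench.errors import ConfigError
from motifbench.pipeline import CompareParams
from motifbench.reference_selection import Thresholds
from motifbench.synthetic_data import SimConfig

_SIM_FIELDS = {f.name: f for f in dataclasses.fields(SimConfig)}
_PARAM_KEYS = {
    "n_top": int,
    "flank": int,
    "merge_gap": int,
    "similarity_n": int,
    "similarity_l": int,
    "seed": int,
}
_THRESHOLD_KEYS = {
    "class_a_margin": float,
    "class_b_gap": float,
    "auc_quality_bar": float,
    "similarity_same": float,
    "similarity_related": float,
    "ere_disagreement": float,
    "motif_disagreement": float,
}
_PATH_KEYS = {"input_dir", "compare_dir", "outdir"}


def parse_config(text: str) -> dict[str, str]:
    """Parse flat key = value text into a string dict."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ConfigError(f"line {lineno}: empty key")
        out[key] = value
    return out


def _coerce(key: str, value: str, typ):
    try:
        if typ is bool:
            if value.lower() in ("true", "1", "yes"):
                return True
            if value.lower() in ("false", "0", "no"):
                return False
            raise ValueError(value)
        return typ(value)
    except ValueError as exc:
        raise ConfigError(f"config key {key!r}: cannot parse {value!r}") from exc


def sim_config_from(raw: dict[str, str]) -> SimConfig:
    """Build a SimConfig, rejecting unknown keys."""
    kwargs = {}
    for key, value in raw.items():
        if key in _PATH_KEYS:
            continue
        if key not in _SIM_FIELDS:
            raise ConfigError(f"unknown config key {key!r}")
        type_str = str(_SIM_FIELDS[key].type)
        if "bool" in type_str:
            typ = bool
        elif "float" in type_str:
            typ = float
        else:
            typ = int
        kwargs[key] = _coerce(key, value, typ)
    return SimConfig(**kwargs)


def compare_params_from(raw: dict[str, str]) -> CompareParams:
    """Build CompareParams (+ Thresholds), rejecting unknown keys."""
    kwargs = {}
    th_kwargs = {}
    for key, value in raw.items():
        if key in _PATH_KEYS:
            continue
        if key in _PARAM_KEYS:
            kwargs[key] = _coerce(key, value, _PARAM_KEYS[key])
        elif key in _THRESHOLD_KEYS:
            th_kwargs[key] = _coerce(key, value, _THRESHOLD_KEYS[key])
        else:
            raise ConfigError(f"unknown config key {key!r}")
    if th_kwargs:
        kwargs["thresholds"] = Thresholds(**th_kwargs)
    return CompareParams(**kwargs)


def load_config(path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    return parse_config(path.read_text())
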