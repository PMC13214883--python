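"""YAML run-configuration loader.

A config file mirrors the pipeline dataclasses, e.g.::

    anticipation:
      window_h: 5.0
      start_h: 20.0
      pc1_fit: linear
      pc2_fit: linear
    detrend:
      window_points: 15
      poly_order: 3

Top-level flat keys are also accepted for the anticipation block.
"""

from __future__ import annotations

import yaml

from .anticipate import AnticipationConfig
from .errors import ConfigError
from .preprocess import DetrendConfig

__all__ = ["load_config"]

_ANTICIPATION_KEYS = {
    "window_h", "start_h", "n_components", "pc1_fit", "pc2_fit",
    "ridge_lambda", "min_window_spectra",
}
_DETREND_KEYS = {"window_points", "poly_order"}


def load_config(path) -> tuple[AnticipationConfig, DetrendConfig | None]:
    """Read a YAML config; returns the anticipation settings and, when a
    ``detrend`` block is present, the d2-detrending settings."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")

    block = raw.get("anticipation", {})
    flat = {k: v for k, v in raw.items() if k in _ANTICIPATION_KEYS}
    block = {**flat, **block}
    unknown = set(block) - _ANTICIPATION_KEYS
    if unknown:
        raise ConfigError(f"unknown anticipation keys {sorted(unknown)}")
    try:
        anticipation = AnticipationConfig(**block)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc

    detrend = None
    if "detrend" in raw and raw["detrend"] is not None:
        dblock = raw["detrend"]
        unknown = set(dblock) - _DETREND_KEYS
        if unknown:
            raise ConfigError(f"unknown detrend keys {sorted(unknown)}")
        detrend = DetrendConfig(**dblock)
    return anticipation, detrend
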