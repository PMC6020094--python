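"""Run configuration resolution, seed sub-streams, and versioned model
serialization."""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

FORMAT_VERSION = 1

# named sub-streams so component seeds are independent but reproducible
_STREAMS = ("split", "cv", "grid", "sampling", "simulate")


class IntegrityError(RuntimeError):
    """Raised when a serialized model fails its integrity check."""


@dataclass
class RunConfig:
    subcommand: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    version: int = FORMAT_VERSION

    def substream_seed(self, name: str) -> int:
        if name not in _STREAMS:
            raise ValueError(f"unknown seed stream {name!r}")
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def header(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "params": dict(self.params),
            "seed": self.seed,
            "log_level": self.log_level,
            "version": self.version,
        }


def resolve_config(
    defaults: dict, config_file: str | Path | None, cli_args: dict, subcommand: str = ""
) -> RunConfig:
    """Merge parameters with precedence command line > file > defaults.

    Unknown keys (not present in *defaults*) are rejected by name; values
    must be coercible to the default's type.
    """
    merged = dict(defaults)
    layers = []
    if config_file:
        with open(config_file) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold key-value pairs")
        layers.append(loaded)
    layers.append({k: v for k, v in cli_args.items() if v is not None})
    for layer in layers:
        for key, value in layer.items():
            if key not in defaults and key not in {"seed", "log_level"}:
                raise ValueError(f"unknown configuration key {key!r}")
            ref = defaults.get(key)
            if ref is not None and value is not None and not isinstance(value, type(ref)):
                try:
                    value = type(ref)(value)
                except (TypeError, ValueError):
                    raise ValueError(f"configuration key {key!r} expects {type(ref).__name__}")
            merged[key] = value
    seed = int(merged.pop("seed", 0) or 0)
    log_level = str(merged.pop("log_level", "INFO") or "INFO")
    return RunConfig(subcommand=subcommand, params=merged, seed=seed, log_level=log_level)


def save_model(model, path: str | Path) -> None:
    """Serialize a trained or consensus model with a format-version tag and
    an embedded payload digest."""
    payload = pickle.dumps(model, protocol=4)
    wrapper = {
        "format_version": FORMAT_VERSION,
        "sha256": hashlib.sha256(payload).hexdigest(),
        "payload": payload,
    }
    joblib.dump(wrapper, path)


def load_model(path: str | Path):
    """Load a serialized model, verifying version and payload integrity."""
    try:
        wrapper = joblib.load(path)
    except Exception as exc:
        raise IntegrityError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(wrapper, dict) or "payload" not in wrapper:
        raise IntegrityError(f"{path} is not an admetkit model file")
    if wrapper.get("format_version", 0) > FORMAT_VERSION:
        raise IntegrityError(
            f"{path} was written by a newer format (v{wrapper['format_version']})"
        )
    payload = wrapper["payload"]
    if hashlib.sha256(payload).hexdigest() != wrapper.get("sha256"):
        raise IntegrityError(f"{path} failed its integrity check")
    return pickle.loads(payload)
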