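"""Flat key=value configuration files for physiology and MCMC settings."""

from __future__ import annotations

import dataclasses

from .calibration import CalibSettings
from .crop_model import PhysioConstants

__all__ = ["read_config", "physio_from_config", "settings_from_config"]


def read_config(path) -> dict:
    """Parse ``key = value`` lines; '#' starts a comment; values are numbers."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            try:
                out[key] = float(value)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value {value!r}") from exc
    return out


def _fill(cls, values: dict, prefix: str = ""):
    fields = {f.name: f.type for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in values.items():
        name = key[len(prefix):] if prefix and key.startswith(prefix) else key
        if name in fields:
            kwargs[name] = int(val) if float(val).is_integer() and isinstance(
                getattr(cls(), name), int
            ) else val
    return cls(**kwargs)


def physio_from_config(path) -> PhysioConstants:
    """PhysioConstants with any defaults overridden by the config file."""
    return _fill(PhysioConstants, read_config(path))


def settings_from_config(path) -> CalibSettings:
    """MCMC budgets (n_steps, n_chains, seed, burn_in, face_*) from a config file."""
    return _fill(CalibSettings, read_config(path))
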