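"""YAML round-tripping for the simulation and correction parameter sets."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .correction import CorrectionFactors
from .simulate import CameraParams, PhotophysicsParams

__all__ = ["save_params", "load_params"]

_SECTIONS = {
    "camera": CameraParams,
    "photophysics": PhotophysicsParams,
    "correction": CorrectionFactors,
}


def _plain(obj):
    out = {}
    for k, v in dataclasses.asdict(obj).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def save_params(
    path: str | Path,
    camera: CameraParams = CameraParams(),
    photophysics: PhotophysicsParams = PhotophysicsParams(),
    correction: CorrectionFactors = CorrectionFactors(),
) -> None:
    data = {
        "camera": _plain(camera),
        "photophysics": _plain(photophysics),
        "correction": _plain(correction),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_params(path: str | Path) -> dict:
    """Load a parameter YAML; returns dict of dataclass instances by section."""
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw[section].items()
            }
            out[section] = cls(**kwargs)
    return out
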