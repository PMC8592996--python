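"""Access to the packaged default configuration (parameters, geometry, tasks, EMG).

All defaults live in YAML files under :mod:`spineload.data`; every loader
accepts an explicit path or pre-parsed mapping so that studies can override
any table or constant without touching the package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

_DATA_PACKAGE = "spineload.data"


def _read_packaged(name: str) -> dict[str, Any]:
    text = resources.files(_DATA_PACKAGE).joinpath(name).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_config(source: str | Path | Mapping[str, Any] | None, default: str) -> dict[str, Any]:
    """Resolve a config argument: None -> packaged default, path -> YAML file,
    mapping -> used as-is (shallow copy)."""
    if source is None:
        return _read_packaged(default)
    if isinstance(source, Mapping):
        return dict(source)
    return yaml.safe_load(Path(source).read_text(encoding="utf-8"))


def default_parameters() -> dict[str, Any]:
    return _read_packaged("parameters.yaml")


def default_geometry() -> dict[str, Any]:
    return _read_packaged("geometry.yaml")


def default_tasks() -> dict[str, Any]:
    return _read_packaged("tasks.yaml")


def default_emg() -> dict[str, Any]:
    return _read_packaged("emg.yaml")
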