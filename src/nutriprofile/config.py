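"""Loaders for the packaged YAML configuration shipped with nutriprofile.

Every threshold, band table, term list and rule set the models use is plain
editable YAML so that regulatory revisions never require code changes.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

_DATA_PACKAGE = "nutriprofile.data"


class ConfigError(ValueError):
    """A configuration file is missing or structurally invalid."""


def data_path(name: str) -> Path:
    """Filesystem path of a packaged config file (for copying/editing)."""
    return Path(str(resources.files(_DATA_PACKAGE).joinpath(name)))


@lru_cache(maxsize=None)
def load_packaged(name: str) -> dict[str, Any]:
    """Load a YAML file shipped in ``nutriprofile/data``."""
    ref = resources.files(_DATA_PACKAGE).joinpath(name)
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise ConfigError(f"no packaged config named {name!r}") from exc
    return yaml.safe_load(text)


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Load a user-supplied YAML (or JSON, a YAML subset) config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with p.open("r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError(f"config file {p} must contain a mapping")
    return loaded


def supply_stats() -> dict[str, Any]:
    """Published 2018 SA supply statistics (category means, NSS counts,
    regulated counts) used for generator defaults and worked computations."""
    return load_packaged("sa_supply_2018.yaml")
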