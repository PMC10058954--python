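"""Access to the versioned default configuration.

All numeric defaults of the simulator — phenotype geometries, calcium
transients, crossbridge kinetics, circulation parameters and the drug
registry — live in one YAML file shipped with the package
(``data/defaults.yaml``). Each entry there is annotated as either
``calibrated`` (fitted once against a published headline effect and then
frozen) or ``chosen`` (implementer default with no published number).
Code never hard-codes a calibrated value.
"""

from __future__ import annotations

import copy
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@lru_cache(maxsize=1)
def _raw_defaults() -> dict:
    text = resources.files("myoloop").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_defaults() -> dict[str, Any]:
    """Return a deep copy of the package default configuration."""
    return copy.deepcopy(_raw_defaults())


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ConfigError(f"expected a mapping at top level of {path}")
    return out


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
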