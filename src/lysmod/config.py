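"""Loading of the shipped editable YAML configs (lexicons, catalogue)."""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

import yaml

PathLike = Union[str, Path]


def _load_packaged(name: str) -> dict[str, Any]:
    text = resources.files("lysmod.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_yaml(path: Optional[PathLike], default_name: str) -> dict[str, Any]:
    """Load ``path`` if given, else the packaged default ``default_name``."""
    if path is None:
        return _load_packaged(default_name)
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_role_lexicon_dict() -> dict[str, Any]:
    return _load_packaged("role_lexicon.yaml")


def default_domain_lexicon_dict() -> dict[str, Any]:
    return _load_packaged("domain_lexicon.yaml")


def default_catalogue_dict() -> dict[str, Any]:
    return _load_packaged("catalogue.yaml")


def reference_architectures() -> dict[str, list[str]]:
    """The shipped 25-layout reference architecture table (label -> domains)."""
    return _load_packaged("architectures.yaml")["architectures"]
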