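"""Registry of literature-derived TEF/TDF presets (shipped as YAML)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .records import TEF, AminoAcidTDF


@lru_cache(maxsize=1)
def load_presets() -> dict:
    text = resources.files(__package__).joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def get_tef(name: str) -> TEF:
    """Look up a bulk TEF preset by name (e.g. 'madigan-muscle')."""
    reg = load_presets()["tef"]
    if name not in reg:
        raise KeyError(f"unknown TEF preset {name!r}; have {sorted(reg)}")
    return TEF(**reg[name])


def get_tdf(name: str) -> AminoAcidTDF:
    """Look up an amino-acid TDF preset by name (e.g. 'bradley-tuna')."""
    reg = load_presets()["tdf"]
    if name not in reg:
        raise KeyError(f"unknown TDF preset {name!r}; have {sorted(reg)}")
    return AminoAcidTDF(**reg[name])
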