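"""Packaged fixture configurations.

Two simulation presets ship with the package, mirroring the two archetypal
relapse narratives the pipeline is built to resolve:

* ``73m-like`` — a duplicated mutant driver (multiplicity 2 inside
  chromosome-scale copy-neutral LOH) depleted at relapse by the outgrowth of
  a pre-existing resistant subclone carrying its own CN-LOH, with driver
  heterozygosity re-acquired;
* ``jw81-like`` — a de novo resistance mutation, undetectable in the primary
  tumor, emerging at relapse at the cost of the ancestral clone.
"""
from __future__ import annotations

from importlib import resources

from .errors import ConfigurationError
from .simulate import SimConfig

_FILES = {
    "73m-like": "m73_like.yaml",
    "jw81-like": "jw81_like.yaml",
}

PRESET_NAMES = tuple(sorted(_FILES))


def preset_config(name: str, seed: int | None = None) -> SimConfig:
    """Load a packaged preset by name, optionally overriding its seed."""
    key = name.lower()
    if key not in _FILES:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    text = (resources.files("f1loh") / "configs" / _FILES[key]).read_text()
    config = SimConfig.from_yaml(text)
    if seed is not None:
        config.seed = int(seed)
    return config
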