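"""Packaged default configuration (climate parameters, BAU calibration, SCC)."""

from __future__ import annotations

from importlib import resources

import yaml

from .scc import ClimateParams


def load_config(path=None) -> dict:
    """Load a YAML config; defaults to the packaged one."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    text = resources.files("agscc").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def default_climate_params(config: dict | None = None) -> ClimateParams:
    cfg = (config or load_config())["climate"]
    return ClimateParams(**cfg)
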