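"""Shipped default parameter files and their loaders.

The YAML files under ``angiosched/data/`` are *synthetic, representative*
defaults: they reproduce the qualitative behavior of the bevacizumab +
paclitaxel system (growth to a few-hundred-fold burden over seven weeks,
a vascular normalization window of a couple of days) but were not fitted
to any animal data.  Replace them with values calibrated to your own
experiment before drawing quantitative conclusions.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import yaml

from .dynamics import ModelParams
from .pk import ANTIANGIOGENIC, CYTOTOXIC, PKParams

__all__ = ["default_pk", "default_model_params", "load_packaged_yaml"]

_PK_FILE = "pk_params.synthetic.yaml"
_MODEL_FILE = "model_params.synthetic.yaml"


def load_packaged_yaml(name: str) -> dict[str, Any]:
    with resources.files("angiosched.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_pk() -> dict[str, PKParams]:
    """Default kinetic constants for both drugs (see the data file notes)."""
    raw = load_packaged_yaml(_PK_FILE)
    out = {}
    for drug in (CYTOTOXIC, ANTIANGIOGENIC):
        entry = raw[drug]
        out[drug] = PKParams(
            ka=float(entry["ka_per_day"]),
            ke=float(entry["ke_per_day"]),
            scale=float(entry["scale"]),
        )
    return out


def default_model_params(model_id: int) -> ModelParams:
    """Representative pharmacodynamic parameters for model 1 or 2."""
    if model_id not in (1, 2):
        raise ValueError("model_id must be 1 or 2")
    raw = load_packaged_yaml(_MODEL_FILE)
    merged = dict(raw.get("shared", {}))
    merged.update(raw.get(f"model{model_id}", {}))
    return ModelParams(**{k: float(v) for k, v in merged.items()})
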