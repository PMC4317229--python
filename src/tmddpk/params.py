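"""Packaged parameter sets.

Loads the shipped YAML fixtures: the cynomolgus-monkey population
estimates (typical values, IIV, residual error) and the human parameter
set obtained by allometric scaling with the species-specific Kd.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .models import PKParameters
from .synthetic import IIVSpec, ResidualErrorSpec

__all__ = [
    "load_params_yaml",
    "monkey_parameters",
    "monkey_iiv",
    "monkey_residual_error",
    "human_parameters",
    "MONKEY_BW_KG",
    "HUMAN_BW_KG",
]

MONKEY_BW_KG = 2.8
HUMAN_BW_KG = 70.0


def _read_packaged(name: str) -> dict:
    with resources.files("tmddpk.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_params_yaml(source) -> dict:
    """Load a parameter YAML (path or file-like) and validate its schema."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not str(doc.get("schema", "")).startswith(
        "tmddpk-params/"
    ):
        raise ValueError("not a tmddpk parameter file (missing schema tag)")
    return doc


def params_from_dict(doc: dict) -> PKParameters:
    return PKParameters(**doc["parameters"])


def monkey_parameters() -> PKParameters:
    """Typical cynomolgus QE-TMDD parameters (population estimates)."""
    return params_from_dict(_read_packaged("monkey_qe.yaml"))


def monkey_iiv() -> IIVSpec:
    doc = _read_packaged("monkey_qe.yaml")["iiv"]
    return IIVSpec(**doc)


def monkey_residual_error() -> ResidualErrorSpec:
    doc = _read_packaged("monkey_qe.yaml")["residual_error"]
    return ResidualErrorSpec(**doc)


def human_parameters(kd: float | None = None) -> PKParameters:
    """Human QE-TMDD parameters from allometric scaling.

    By default Kd is the in vitro binding EC50 against human primary
    T cells (0.031 nmol/L).  Pass ``kd=0.013`` to use the monkey value
    instead (the two are compared in the low-dose sensitivity analysis),
    or any other override.
    """
    doc = _read_packaged("human_qe.yaml")
    p = params_from_dict(doc)
    if kd is not None:
        p = p.replace(kd=kd)
    return p


def human_kd_alternative() -> float:
    """The alternative (monkey in vitro) Kd retained for sensitivity."""
    return float(_read_packaged("human_qe.yaml")["kd_alternative"])
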