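"""Dataset and configuration I/O.

Datasets are serialized as NONMEM-style rectangular CSV (one row per dose
event or observation) with missing numeric cells written as ".".  A short
comment header records the schema, the DV unit and a hash of the
generating configuration so that outputs are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .synthetic import DATASET_COLUMNS, StudyDataset
from .units import DEFAULT_DRUG, DrugProperties, ngml_to_molar

__all__ = ["read_dataset", "write_dataset", "config_hash", "load_config"]

log = logging.getLogger("tmddpk")

MANDATORY = ["ID", "TIME", "AMT", "DV", "EVID"]
_SCHEMA = "tmddpk-dataset/1"


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_dataset(
    dataset: StudyDataset,
    path,
    dv_unit: str = "nmol/L",
    config: Optional[dict] = None,
) -> None:
    """Write a dataset as CSV with '.' for missing cells and a comment
    header carrying the schema, DV unit and config hash."""
    tab = dataset.table.copy()
    with open(path, "w") as fh:
        fh.write(f"# schema: {_SCHEMA}\n")
        fh.write(f"# dv_unit: {dv_unit}\n")
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        tab.to_csv(fh, index=False, na_rep=".", float_format="%.10g")


def read_dataset(
    path, dv_unit: Optional[str] = None, drug: DrugProperties = DEFAULT_DRUG
) -> StudyDataset:
    """Read a NONMEM-style CSV into a typed dataset.

    '.' cells are parsed as missing.  The DV unit is taken from the
    ``# dv_unit:`` header (override with ``dv_unit``); ng/mL and µg/mL
    values are converted to the internal nmol/L on load.  Raises a schema
    error naming any missing mandatory column and a validation error on
    non-monotone times within an individual.
    """
    header_meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("#").partition(":")
                header_meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        tab = pd.read_csv(fh, na_values=["."], keep_default_na=True)

    missing = [c for c in MANDATORY if c not in tab.columns]
    if missing:
        raise ValueError(f"dataset schema error: missing mandatory column(s) {missing}")
    for col, default in (
        ("MDV", None), ("ROUTE", "IV"), ("BW", np.nan), ("STUDY", "X"),
        ("GROUP", 0), ("DOSE_MGKG", np.nan), ("LLOQ", 1e-12),
        ("BLQ", 0), ("ADA", 0), ("EXCL", 0), ("EXPECTED", np.nan),
    ):
        if col not in tab.columns:
            if col == "MDV":
                tab["MDV"] = np.where(tab["EVID"] == 1, 1, tab["DV"].isna().astype(int))
            else:
                tab[col] = default

    unit = dv_unit or header_meta.get("dv_unit", "nmol/L")
    unit_norm = unit.replace("µ", "u").replace(" ", "").lower()
    if unit_norm in ("nmol/l", "nm"):
        factor = 1.0
    elif unit_norm in ("ng/ml",):
        factor = ngml_to_molar(1.0, drug)
    elif unit_norm in ("ug/ml",):
        factor = ngml_to_molar(1.0, drug) * 1e3
    else:
        raise ValueError(f"unsupported DV unit {unit!r}")
    if factor != 1.0:
        tab["DV"] = tab["DV"] * factor
        tab["EXPECTED"] = tab["EXPECTED"] * factor

    for aid, sub in tab.groupby("ID"):
        t = sub["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"non-monotone times within ID {aid}")

    if (tab["EVID"] == 0).sum() == 0:
        log.warning("dataset %s contains no observation rows", path)

    tab = tab[[c for c in DATASET_COLUMNS if c in tab.columns]]
    return StudyDataset(tab)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping")
    return doc
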