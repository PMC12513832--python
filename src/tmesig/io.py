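"""Readers, writers and run configuration.

Artifacts are plain text: cell-fraction and clinical tables as CSV, count
matrices as genes x patients TSV, gene-set libraries as GMT, signature
models as JSON, spatial cell tables as CSV, run configuration as YAML.
Every schema check names the offending columns; round trips are identities
on the in-memory objects.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .celltype import SignatureModel
from .genes import GeneSetLibrary
from .survival import SurvivalData
from .synthetic import FeatureMatrix, SpatialCellTable

__all__ = [
    "ENDPOINT_HORIZONS",
    "RunConfig",
    "apply_endpoint",
    "read_clinical", "write_clinical",
    "read_fractions", "write_fractions",
    "read_counts", "write_counts",
    "read_gmt", "write_gmt",
    "read_model", "write_model",
    "read_spatial", "write_spatial",
    "read_config", "write_config",
]

#: endpoint label -> administrative horizon in months
ENDPOINT_HORIZONS = {"PFS-2y": 24.0, "PFS-5y": 60.0, "OS-2y": 24.0,
                     "OS-5y": 60.0}

CLINICAL_REQUIRED = ("patient_id", "time", "event")


@dataclass
class RunConfig:
    """Top-level run settings; the master seed feeds every stage."""

    endpoint: str = "PFS-2y"
    compartment: str = "tumor"
    direction: str = "resistance"
    seed: int = 0
    output_dir: str = "results"
    celltype: Dict = field(default_factory=dict)
    genes: Dict = field(default_factory=dict)
    synthetic: Dict = field(default_factory=dict)
    spatial: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.endpoint not in ENDPOINT_HORIZONS and not str(self.endpoint).replace(
                ".", "", 1).isdigit():
            raise ValueError(f"unknown endpoint {self.endpoint!r}")

    @property
    def horizon_months(self) -> float:
        if self.endpoint in ENDPOINT_HORIZONS:
            return ENDPOINT_HORIZONS[self.endpoint]
        return float(self.endpoint)

    def config_hash(self) -> str:
        blob = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def apply_endpoint(clinical: pd.DataFrame, endpoint) -> SurvivalData:
    """Administrative censoring at the endpoint horizon: observations beyond
    the horizon become (horizon, event=0); others are unchanged.  Idempotent.
    """
    missing = [c for c in CLINICAL_REQUIRED if c not in clinical.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    horizon = (ENDPOINT_HORIZONS[endpoint] if isinstance(endpoint, str)
               else float(endpoint))
    if horizon <= 0:
        raise ValueError("endpoint horizon must be positive")
    t = clinical["time"].to_numpy(dtype=float)
    e = clinical["event"].to_numpy(dtype=int)
    if np.any(t <= 0):
        raise ValueError("nonpositive times")
    over = t > horizon
    t = np.where(over, horizon, t)
    e = np.where(over, 0, e)
    return SurvivalData(t, e, clinical["patient_id"].to_numpy())


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df.to_csv(path, index=False)


def read_fractions(path, compartment: str = "tumor") -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    return FeatureMatrix(df, compartment=compartment, kind="fractions")


def write_fractions(fm: FeatureMatrix, path) -> None:
    fm.data.to_csv(path, index_label="patient_id")


def read_counts(path, compartment: str = "tumor") -> FeatureMatrix:
    """Counts stored genes x patients (TSV); loaded patients x genes."""
    df = pd.read_csv(path, sep="\t", index_col=0).T
    df.index.name = None
    df.columns.name = None
    return FeatureMatrix(df, compartment=compartment, kind="counts")


def write_counts(fm: FeatureMatrix, path) -> None:
    fm.data.T.to_csv(path, sep="\t", index_label="gene")


def read_spatial(path) -> SpatialCellTable:
    df = pd.read_csv(path)
    missing = [c for c in SpatialCellTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"spatial table missing columns: {missing}")
    return SpatialCellTable(df)


def write_spatial(table: SpatialCellTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetLibrary:
    """GMT: one set per line, tab-separated ``name <tab> description <tab>
    gene...``.  Duplicate genes within a set are dropped with a warning."""
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, genes = parts[0], parts[2:]
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            warnings.warn(f"duplicate genes in set {name!r} deduplicated",
                          stacklevel=2)
        sets[name] = deduped
    return GeneSetLibrary(sets, provenance=str(path))


def write_gmt(library: GeneSetLibrary, path) -> None:
    lines = []
    for name, genes in library.sets.items():
        lines.append("\t".join([name, library.provenance, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# models & config
# ---------------------------------------------------------------------------


def write_model(model: SignatureModel, path) -> None:
    Path(path).write_text(model.to_json() + "\n")


def read_model(path) -> SignatureModel:
    return SignatureModel.from_json(Path(path).read_text())


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(vars(cfg), sort_keys=True))


def read_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)
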