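"""Formats, configuration and the run manifest.

External interfaces:

* point tables — delimited text with header ``x_nm,y_nm[,z_nm][,tip_id]``,
  one point per row;
* networks — structured JSON (anchors, polylines, contacts, termini,
  params, seed), schema-checked on read;
* volumes — MRC2014 (see :mod:`glycomesh.mrc`);
* config — a single YAML file mirroring GeneratorParams field names plus
  analysis/stage sections;
* results — JSON documents embedding the run-manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import GlycocalyxNetwork, TerminiPattern, as_extent
from .exceptions import ParameterError, PointTableError
from .generate import GeneratorParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_points",
    "write_points",
    "read_network",
    "write_network",
    "load_config",
    "params_from_config",
    "RunManifest",
    "write_result",
    "validate_document",
]

_COORD_COLS = ("x_nm", "y_nm", "z_nm")


def read_points(path, dialect: str = ",", extent=None) -> TerminiPattern:
    """Read a point table into a pattern.

    Dimensionality is inferred from the columns present; malformed rows
    (non-numeric cells) are rejected with their line numbers logged.  The
    extent defaults to the points' bounding box padded by half a typical
    spacing.
    """
    path = Path(path)
    if not path.exists():
        raise PointTableError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, sep=dialect, skipinitialspace=True)
    except Exception as e:  # noqa: BLE001 - surface parse errors uniformly
        raise PointTableError(f"{path}: unparseable table ({e})") from e
    df.columns = [c.strip().lower() for c in df.columns]
    cols = [c for c in _COORD_COLS if c in df.columns]
    if "x_nm" not in cols or "y_nm" not in cols:
        raise PointTableError(
            f"{path}: missing coordinate columns (need x_nm,y_nm[,z_nm])"
        )
    coerced = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        logger.warning("%s: rejected %d malformed rows at lines %s", path, bad.sum(), lines)
    pts = coerced[~bad].to_numpy(dtype=float)
    if len(pts) == 0:
        raise PointTableError(f"{path}: no valid rows")
    tip_ids = None
    if "tip_id" in df.columns:
        tid = pd.to_numeric(df["tip_id"], errors="coerce")[~bad]
        tip_ids = tid.fillna(-1).to_numpy(dtype=int)
    if extent is None:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        pad = np.maximum(0.5 * (hi - lo) / max(np.sqrt(len(pts)), 1.0), 1.0)
        extent = np.column_stack([lo - pad, hi + pad])
    return TerminiPattern(
        points=pts, extent=as_extent(extent, pts.shape[1]), tip_ids=tip_ids
    )


def write_points(path, pattern: TerminiPattern, dialect: str = ",") -> None:
    pattern.to_dataframe().to_csv(path, sep=dialect, index=False, float_format="%.6g")


def write_network(path, network: GlycocalyxNetwork) -> None:
    with open(path, "w") as fh:
        json.dump(network.to_dict(), fh)


def read_network(path) -> GlycocalyxNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    validate_document(doc, "network")
    return GlycocalyxNetwork.from_dict(doc)


# ---------------------------------------------------------------------------
# Lightweight schema checking
# ---------------------------------------------------------------------------


def _schema(kind: str) -> dict:
    import importlib.resources as res

    with res.files("glycomesh.schemas").joinpath(f"{kind}.schema.json").open() as fh:
        return json.load(fh)


def validate_document(doc: dict, kind: str) -> None:
    """Check required keys and basic types against the shipped schema."""
    schema = _schema(kind)
    for key, typename in schema.get("required", {}).items():
        if key not in doc:
            raise ParameterError(f"{kind} document missing required key '{key}'")
        pytype = {"object": dict, "array": list, "string": str, "number": (int, float)}[
            typename
        ]
        if doc[key] is not None and not isinstance(doc[key], pytype):
            raise ParameterError(
                f"{kind} document key '{key}' must be {typename}"
            )
    expect = schema.get("const", {})
    for key, val in expect.items():
        if doc.get(key) != val:
            raise ParameterError(f"{kind} document: {key} must equal {val!r}")


# ---------------------------------------------------------------------------
# Config and manifest
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParameterError("config must be a mapping")
    return cfg


def params_from_config(cfg: dict) -> GeneratorParams:
    gen = dict(cfg.get("generator", {}))
    if "extent" in gen:
        gen["extent"] = tuple(tuple(row) for row in gen["extent"])
    return GeneratorParams(**gen)


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


@dataclass
class RunManifest:
    """Reproducibility record: identical config + master seed give an
    identical manifest hash (timestamps are excluded from the hash)."""

    version: str
    config: dict
    master_seed: int
    stages: list = field(default_factory=list)  # [{stage, child_label, outputs}]
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    started: Optional[str] = None
    finished: Optional[str] = None

    @classmethod
    def create(cls, config: dict, master_seed: int) -> "RunManifest":
        return cls(
            version=__version__,
            config=config,
            master_seed=int(master_seed),
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    @property
    def hash(self) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "master_seed": self.master_seed,
            "stages": self.stages,
        }
        return hashlib.sha256(_canonical_json(payload).encode()).hexdigest()[:16]

    def record_stage(self, stage: str, child_label: str, outputs=()):
        self.stages.append(
            {"stage": stage, "child_label": child_label, "outputs": list(outputs)}
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hash"] = self.hash
        return d

    def write(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def write_result(path, result, manifest: Optional[RunManifest] = None) -> None:
    """Write an analysis result document as JSON, embedding the manifest hash."""
    doc = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    doc["schema"] = doc.get("schema", "glycomesh.result/1")
    if manifest is not None:
        doc["manifest_hash"] = manifest.hash
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
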