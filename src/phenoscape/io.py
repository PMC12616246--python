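"""Reading and writing event tables and channel manifests.

Event tables travel as CSV (one row per cell, one column per channel,
reserved metadata columns ``condition``/``batch``/``replicate``) next to a
YAML manifest of the form::

    channels:
      pSTAT3: PTM
      PanCK: lineage
    gates:
      - population: epithelial
        positive: {PanCK: 1.0, EpCAM: 1.0}
        negative: {CD45: 1.0}
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .celltable import CellTable, ManifestError, METADATA_COLUMNS, RAW
from .gating import GateSpec


class FormatError(ValueError):
    """Malformed input file."""


def load_manifest(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "channels" not in manifest:
        raise ManifestError(f"{path}: manifest must contain a 'channels' mapping")
    if not isinstance(manifest["channels"], dict):
        raise ManifestError(f"{path}: 'channels' must map channel name -> role")
    return manifest


def manifest_gates(manifest: dict[str, Any]) -> list[GateSpec]:
    gates = []
    for entry in manifest.get("gates", []) or []:
        gates.append(
            GateSpec(
                population=entry["population"],
                positive=dict(entry.get("positive", {}) or {}),
                negative=dict(entry.get("negative", {}) or {}),
            )
        )
    return gates


def read_cell_table(
    path: str | Path,
    manifest: str | Path | dict[str, Any],
    transform: str = RAW,
) -> CellTable:
    """Read a CSV event table under a channel-role manifest.

    Channels present in the file but not in the manifest are retained with
    role ``"other"``.  Channels named in the manifest must exist in the file.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a readable CSV event table ({exc})") from exc
    roles = dict(manifest["channels"])
    missing = [ch for ch in roles if ch not in df.columns]
    if missing:
        raise ManifestError(f"{path}: manifest channels missing from file: {missing}")
    return CellTable(data=df, channel_roles=roles, transform=transform)


def write_cell_table(table: CellTable, path: str | Path, include_metadata: bool = True) -> None:
    df = table.data
    if not include_metadata:
        df = df[[c for c in df.columns if c not in METADATA_COLUMNS]]
    df.to_csv(path, index=False)


def write_manifest(
    table: CellTable, path: str | Path, gates: list[GateSpec] | None = None
) -> None:
    doc: dict[str, Any] = {"channels": {c: table.channel_roles[c] for c in table.channels}}
    if gates:
        doc["gates"] = [
            {"population": g.population, "positive": dict(g.positive), "negative": dict(g.negative)}
            for g in gates
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
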