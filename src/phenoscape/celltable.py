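"""Single-cell event table with channel roles and per-cell labels.

The central cytometry container: one row per cell, one column per measured
channel, plus reserved metadata columns (``condition``, ``batch``,
``replicate``, ``population``, ``barcode``).  Channel values are either on
the raw ion-count scale (non-negative) or arcsinh-transformed; the transform
state is tracked explicitly so a transform is never applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: metadata columns recognised next to channel columns
METADATA_COLUMNS = ("condition", "batch", "replicate", "population", "barcode")

#: channel roles understood by the pipeline
CHANNEL_ROLES = frozenset(
    {"PTM", "state", "immunophenotype", "lineage", "DNA", "viability", "barcode", "other"}
)

RAW = "raw"
ARCSINH = "arcsinh"


class ManifestError(ValueError):
    """A channel referenced by the analysis has no role in the manifest."""


class TransformStateError(RuntimeError):
    """A transform was requested in an incompatible transform state."""


@dataclass
class CellTable:
    """Cells x channels event table.

    Parameters
    ----------
    data:
        DataFrame holding one column per channel plus any of the reserved
        metadata columns.  Cells are rows, channels are columns, everywhere.
    channel_roles:
        Mapping channel name -> role (one of :data:`CHANNEL_ROLES`).
        Channels present in ``data`` but absent here are assigned ``"other"``.
    transform:
        ``"raw"`` or ``"arcsinh"``.
    centered:
        Whether per-batch mean-centering has been applied (only meaningful
        on the arcsinh scale).
    """

    data: pd.DataFrame
    channel_roles: dict[str, str] = field(default_factory=dict)
    transform: str = RAW
    centered: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        roles = dict(self.channel_roles)
        for ch in self.channels:
            roles.setdefault(ch, "other")
        bad = {r for r in roles.values() if r not in CHANNEL_ROLES}
        if bad:
            raise ManifestError(f"unknown channel roles: {sorted(bad)}")
        missing = [ch for ch in roles if ch not in self.data.columns]
        if missing:
            raise ManifestError(f"manifest channels absent from data: {missing}")
        self.channel_roles = roles
        if self.transform == RAW:
            vals = self.values
            if vals.size and np.nanmin(vals) < 0:
                raise ValueError("raw-scale channel values must be non-negative")

    # ------------------------------------------------------------------ views
    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c not in METADATA_COLUMNS]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data[self.channels].to_numpy(dtype=float)

    def channels_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.channels if self.channel_roles[c] in roles]

    def marker_channels(self) -> list[str]:
        """Analysis markers: everything except barcode, DNA and viability."""
        return self.channels_with_role("PTM", "state", "immunophenotype", "lineage", "other")

    def __getitem__(self, channel: str) -> np.ndarray:
        if channel not in self.data.columns:
            raise KeyError(channel)
        return self.data[channel].to_numpy(dtype=float)

    def copy(self) -> "CellTable":
        return replace(self, data=self.data.copy(), channel_roles=dict(self.channel_roles))

    # -------------------------------------------------------------- selection
    def subset(self, mask: np.ndarray | pd.Series) -> "CellTable":
        """Row subset preserving cell order and all labels."""
        sub = self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return replace(self, data=sub, channel_roles=dict(self.channel_roles))

    def where_population(self, population: str) -> "CellTable":
        if "population" not in self.data.columns:
            raise KeyError("no population labels assigned; run gating first")
        return self.subset((self.data["population"] == population).to_numpy())

    def where_condition(self, condition: str) -> "CellTable":
        if "condition" not in self.data.columns:
            raise KeyError("no condition labels assigned")
        return self.subset((self.data["condition"].astype(str) == str(condition)).to_numpy())

    def conditions(self) -> list[str]:
        if "condition" not in self.data.columns:
            return []
        return sorted(self.data["condition"].astype(str).unique())


def concat_tables(tables: Iterable[CellTable]) -> CellTable:
    """Row-concatenate tables sharing channels, roles and transform state."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.channels != first.channels:
            raise ValueError("tables have differing channel sets")
        if (t.transform, t.centered) != (first.transform, first.centered):
            raise TransformStateError("tables have differing transform states")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return CellTable(
        data=data,
        channel_roles=dict(first.channel_roles),
        transform=first.transform,
        centered=first.centered,
    )


def make_channel_roles(panel: Iterable[tuple[str, str]]) -> dict[str, str]:
    roles: dict[str, str] = {}
    for name, role in panel:
        if name in roles:
            raise ManifestError(f"duplicate channel name {name!r}")
        roles[name] = role
    return roles
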