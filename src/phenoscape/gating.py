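"""Threshold gating of cell populations.

Gates are explicit, manually chosen thresholds (the screening workflow this
package supports sets them interactively per dataset); an optional
density-valley helper is provided but never applied implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmin
from scipy.stats import gaussian_kde

from .celltable import CellTable


@dataclass(frozen=True)
class GateSpec:
    """A population gate: all positive channels above, all negative at/below.

    A cell is assigned iff ``value > t`` for every positive channel and
    ``value <= t`` for every negative channel.
    """

    population: str
    positive: dict[str, float] = field(default_factory=dict)
    negative: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"channels in both positive and negative sets: {sorted(overlap)}")
        for ch, t in {**self.positive, **self.negative}.items():
            if not np.isfinite(t):
                raise ValueError(f"non-finite threshold for channel {ch!r}")

    def mask(self, table: CellTable) -> np.ndarray:
        m = np.ones(table.n_cells, dtype=bool)
        for ch, t in self.positive.items():
            m &= table[ch] > t
        for ch, t in self.negative.items():
            m &= table[ch] <= t
        return m


def gate_population(table: CellTable, gate: GateSpec) -> CellTable:
    """Label cells matching ``gate`` with its population name.

    Returns a new table with the ``population`` column set for matching
    cells; non-matching cells keep any existing label (``unassigned`` if
    none).  Cell order is preserved.  Idempotent.
    """
    for ch in list(gate.positive) + list(gate.negative):
        if ch not in table.data.columns:
            raise KeyError(f"gate channel {ch!r} not in table")
    out = table.copy()
    if "population" not in out.data.columns:
        out.data["population"] = "unassigned"
    out.data.loc[gate.mask(table), "population"] = gate.population
    return out


def apply_gates(table: CellTable, gates: list[GateSpec]) -> CellTable:
    for gate in gates:
        table = gate_population(table, gate)
    return table


def density_valley_threshold(values: np.ndarray, grid: int = 512) -> float:
    """Optional helper: deepest KDE valley between the two main modes.

    Never used as a default; gates in this package are explicit config.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10 or np.ptp(values) == 0:
        raise ValueError("need >=10 non-constant values to locate a valley")
    kde = gaussian_kde(values)
    xs = np.linspace(values.min(), values.max(), grid)
    dens = kde(xs)
    minima = argrelmin(dens)[0]
    if minima.size == 0:
        raise ValueError("no density valley found")
    return float(xs[minima[np.argmin(dens[minima])]])
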