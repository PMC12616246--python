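"""Signed EMD shift statistics and cytotoxicity / cell-state metrics.

For every marker, the shift between a condition and its matched control is
the exact 1-D Wasserstein-1 (earth mover's) distance between the two
empirical distributions, signed by the direction of the median difference.
Averaging the unsigned per-marker EMDs gives the condition summary x̄EMD —
a coordinate sliced Wasserstein distance quantifying total phenotypic
modulation irrespective of direction.

All distances are computed on the transformed (arcsinh, batch-centered)
scale; the magnitude for unequal sample sizes is the exact empirical
quantile-function integral (no subsampling), so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .celltable import CellTable


# --------------------------------------------------------------------- EMD
def signed_emd(test, reference) -> float:
    """Signed 1-D earth mover's distance of ``test`` relative to ``reference``.

    Magnitude is the exact Wasserstein-1 distance between the empirical
    distributions; the sign is ``sign(median(test) - median(reference))``
    (ties keep ``+``).  Symmetric in magnitude, antisymmetric in sign.
    """
    test = np.asarray(test, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    if test.size == 0 or reference.size == 0:
        raise ValueError("signed_emd requires non-empty samples")
    magnitude = float(stats.wasserstein_distance(test, reference))
    direction = 1.0 if np.median(test) >= np.median(reference) else -1.0
    return direction * magnitude


@dataclass
class ShiftResult:
    """Per-marker signed EMDs of one condition against its reference."""

    condition: str
    reference: str
    signed_emd: dict[str, float] = field(default_factory=dict)

    @property
    def included_markers(self) -> list[str]:
        return list(self.signed_emd)

    @property
    def abs_emd(self) -> dict[str, float]:
        return {m: abs(v) for m, v in self.signed_emd.items()}

    @property
    def xbar_emd(self) -> float:
        return xbar_emd(self)


def xbar_emd(shifts: "ShiftResult | dict[str, float]") -> float:
    """Mean of the absolute per-marker EMDs (x̄EMD); always >= 0."""
    values = shifts.signed_emd if isinstance(shifts, ShiftResult) else shifts
    if not values:
        raise ValueError("xbar_emd needs at least one included marker")
    return float(np.mean([abs(v) for v in values.values()]))


def compute_shift(
    test: CellTable, reference: CellTable, markers: list[str] | None = None
) -> ShiftResult:
    """Signed EMD per marker between two single-population tables.

    ``markers`` defaults to every non-barcode, non-DNA, non-viability
    channel ("all measured markers").
    """
    if (test.transform, test.centered) != (reference.transform, reference.centered):
        raise ValueError("test and reference tables differ in transform state")
    if markers is None:
        markers = test.marker_channels()
    cond = str(test.data["condition"].iloc[0]) if "condition" in test.data.columns and test.n_cells else "test"
    ref = (
        str(reference.data["condition"].iloc[0])
        if "condition" in reference.data.columns and reference.n_cells
        else "reference"
    )
    emds = {m: signed_emd(test[m], reference[m]) for m in markers}
    return ShiftResult(condition=cond, reference=ref, signed_emd=emds)


def shift_table(results: list[ShiftResult]) -> pd.DataFrame:
    """Long-format (condition, reference, marker, signed_emd) table."""
    rows = [
        {"condition": r.condition, "reference": r.reference, "marker": m, "signed_emd": v}
        for r in results
        for m, v in r.signed_emd.items()
    ]
    return pd.DataFrame(rows, columns=["condition", "reference", "marker", "signed_emd"])


# ----------------------------------------------------- positivity fractions
def fraction_positive(values, threshold: float) -> float:
    """Proportion of values strictly above ``threshold``."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("fraction_positive requires a non-empty sample")
    return float(np.mean(values > threshold))


def therapeutic_apoptosis(
    coculture: CellTable,
    monoculture_baseline: CellTable,
    apoptosis_channel: str = "cPARP",
    threshold: float = 0.0,
) -> float:
    """Apoptosis induced over the matched monoculture baseline, in points.

    ``100 * (cPARP+ fraction in coculture - cPARP+ fraction in monoculture)``;
    may be negative.  Both tables must already be gated to the epithelial
    (target) population.
    """
    if coculture.n_cells == 0:
        raise ValueError("empty epithelial gate in coculture sample")
    if monoculture_baseline.n_cells == 0:
        raise ValueError("empty epithelial gate in monoculture baseline sample")
    f_co = fraction_positive(coculture[apoptosis_channel], threshold)
    f_mono = fraction_positive(monoculture_baseline[apoptosis_channel], threshold)
    return 100.0 * (f_co - f_mono)


def percent_change_positive(
    test: CellTable, control: CellTable, channel: str, threshold: float = 0.0
) -> float:
    """Percent change of the positive fraction relative to control.

    ``100 * (f_test - f_control) / f_control``; returns NaN (reported as
    missing) when the control fraction is 0.
    """
    f_test = fraction_positive(test[channel], threshold)
    f_control = fraction_positive(control[channel], threshold)
    if f_control == 0:
        return float("nan")
    return 100.0 * (f_test - f_control) / f_control


# ----------------------------------------------------------- cell states
CELL_STATES = ("apoptotic", "S", "G0", "other")


@dataclass(frozen=True)
class StateThresholds:
    """Positivity thresholds for the cell-state hierarchy channels."""

    cparp: float = 0.0
    idu: float = 0.0
    prb: float = 0.0
    cparp_channel: str = "cPARP"
    idu_channel: str = "IdU"
    prb_channel: str = "pRB"


def classify_cell_state(table: CellTable, thresholds: StateThresholds | None = None) -> np.ndarray:
    """Assign each cell exactly one state by a fixed priority hierarchy.

    apoptotic if cPARP+; else S if IdU+; else G0 if pRB-; else other.
    """
    t = thresholds or StateThresholds()
    for ch in (t.cparp_channel, t.idu_channel, t.prb_channel):
        if ch not in table.data.columns:
            raise KeyError(f"cell-state channel {ch!r} missing from table")
    cparp = table[t.cparp_channel] > t.cparp
    idu = table[t.idu_channel] > t.idu
    prb_neg = table[t.prb_channel] <= t.prb
    states = np.full(table.n_cells, "other", dtype=object)
    states[prb_neg] = "G0"
    states[idu & ~cparp] = "S"
    states[cparp] = "apoptotic"
    return states


def cell_state_counts(table: CellTable, thresholds: StateThresholds | None = None) -> dict[str, int]:
    states = classify_cell_state(table, thresholds)
    return {s: int(np.sum(states == s)) for s in CELL_STATES}


@dataclass
class CytotoxicityResult:
    """Therapeutic-apoptosis and cell-state summary for one condition."""

    condition: str
    apoptotic_fraction: float
    baseline_fraction: float
    s_phase_fraction: float
    cell_state_counts: dict[str, int]

    @property
    def therapeutic_apoptosis(self) -> float:
        return 100.0 * (self.apoptotic_fraction - self.baseline_fraction)


def cytotoxicity_summary(
    coculture: CellTable,
    monoculture_baseline: CellTable,
    thresholds: StateThresholds | None = None,
) -> CytotoxicityResult:
    t = thresholds or StateThresholds()
    counts = cell_state_counts(coculture, t)
    n = max(coculture.n_cells, 1)
    cond = (
        str(coculture.data["condition"].iloc[0])
        if "condition" in coculture.data.columns and coculture.n_cells
        else "test"
    )
    return CytotoxicityResult(
        condition=cond,
        apoptotic_fraction=fraction_positive(coculture[t.cparp_channel], t.cparp),
        baseline_fraction=fraction_positive(monoculture_baseline[t.cparp_channel], t.cparp),
        s_phase_fraction=counts["S"] / n,
        cell_state_counts=counts,
    )


# --------------------------------------------------------------- rank stats
def kendall_tau(x, y) -> float:
    """Kendall rank correlation (tau-b, tie-adjusted), in [-1, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("kendall_tau requires equal-length vectors")
    if x.size < 2:
        raise ValueError("kendall_tau requires length >= 2")
    return float(stats.kendalltau(x, y).statistic)
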