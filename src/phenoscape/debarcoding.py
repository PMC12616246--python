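"""Combinatorial k-of-n barcode debarcoding.

Pooled cultures are labelled with combinatorial metal barcodes: each sample
receives a unique subset of ``k_hot`` out of ``n_channels`` barcode metals
(9-choose-4 gives the 126-plex scheme used for large organoid screens).
After pooling, every cell is assigned back to its sample by ranking its
rescaled barcode-channel intensities: a singlet shows ``k`` clearly high
channels matching one code; doublets and ambiguous events show a small gap
between the k-th and (k+1)-th ranked channels ("separation") and are
rejected rather than mis-assigned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .celltable import ARCSINH, CellTable, TransformStateError

DEFAULT_SEPARATION_THRESHOLD = 0.3

Code = tuple[int, ...]


class SchemeError(ValueError):
    """Invalid barcode scheme configuration."""


def enumerate_codes(n_channels: int, k_hot: int) -> list[Code]:
    """All k-subsets of ``range(n_channels)`` in lexicographic order."""
    if not 0 < k_hot < n_channels:
        raise SchemeError(f"need 0 < k_hot < n_channels, got k={k_hot}, n={n_channels}")
    return [tuple(c) for c in itertools.combinations(range(n_channels), k_hot)]


@dataclass(frozen=True)
class BarcodeScheme:
    """A combinatorial barcode scheme plus an optional code->condition map."""

    n_channels: int
    k_hot: int
    condition_map: dict[Code, str] = field(default_factory=dict)
    codes: tuple[Code, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(enumerate_codes(self.n_channels, self.k_hot)))
        valid = set(self.codes)
        bad = [c for c in self.condition_map if tuple(sorted(c)) not in valid]
        if bad:
            raise SchemeError(f"condition_map codes not in scheme: {bad}")

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    def code_index(self, code: Code) -> int:
        return self.codes.index(tuple(sorted(code)))

    def condition_for(self, code: Code) -> str | None:
        return self.condition_map.get(tuple(sorted(code)))

    @classmethod
    def from_conditions(cls, n_channels: int, k_hot: int, conditions: list[str]) -> "BarcodeScheme":
        """Deterministically map conditions onto evenly strided codes.

        Striding through the lexicographic enumeration balances how often
        each barcode channel is hot across the pool, which the per-channel
        percentile rescaling presumes (as holds for real full-plex runs).
        """
        codes = spread_codes(n_channels, k_hot, len(conditions))
        return cls(n_channels, k_hot, dict(zip(codes, conditions)))


def enumerate_scheme(n_channels: int, k_hot: int) -> BarcodeScheme:
    """Bare scheme (no condition map); e.g. (9, 4) -> 126 codes."""
    return BarcodeScheme(n_channels=n_channels, k_hot=k_hot)


def spread_codes(n_channels: int, k_hot: int, n_conditions: int) -> list[Code]:
    """``n_conditions`` codes strided evenly through the lexicographic list."""
    codes = enumerate_codes(n_channels, k_hot)
    if n_conditions > len(codes):
        raise SchemeError(f"{n_conditions} conditions exceed the {len(codes)} available codes")
    stride = max(len(codes) // max(n_conditions, 1), 1)
    return [codes[(i * stride) % len(codes)] for i in range(n_conditions)]


class CombinatorialDebarcoder(BaseEstimator):
    """Rank-based single-pass debarcoder (sklearn estimator shape).

    ``fit`` learns per-channel robust rescaling windows (1st-99th
    percentile); ``predict`` returns the lexicographic code index per cell
    (-1 for unassigned).  A cell is assigned iff its top-``k_hot`` rescaled
    channels form a scheme code and the separation (gap between the k-th and
    (k+1)-th ranked rescaled intensity) is at least ``separation_threshold``.
    Exact ties across the rank boundary give separation 0 and are always
    rejected — conservative doublet handling.
    """

    def __init__(
        self,
        scheme: BarcodeScheme | None = None,
        separation_threshold: float = DEFAULT_SEPARATION_THRESHOLD,
        percentile_window: tuple[float, float] = (1.0, 99.0),
    ):
        self.scheme = scheme
        self.separation_threshold = separation_threshold
        self.percentile_window = percentile_window

    def _scheme(self) -> BarcodeScheme:
        return self.scheme if self.scheme is not None else enumerate_scheme(9, 4)

    def fit(self, X, y=None):
        scheme = self._scheme()
        X = check_array(X)
        if X.shape[1] != scheme.n_channels:
            raise ValueError(
                f"expected {scheme.n_channels} barcode channels, got {X.shape[1]}"
            )
        lo, hi = self.percentile_window
        self.scale_low_ = np.percentile(X, lo, axis=0)
        self.scale_high_ = np.percentile(X, hi, axis=0)
        self.n_features_in_ = X.shape[1]
        self._code_lookup_ = {code: i for i, code in enumerate(scheme.codes)}
        return self

    def _rescale(self, X: np.ndarray) -> np.ndarray:
        span = self.scale_high_ - self.scale_low_
        span = np.where(span > 0, span, 1.0)
        return np.clip((X - self.scale_low_) / span, 0.0, 1.0)

    def debarcode(self, X) -> pd.DataFrame:
        """Per-cell calls: ``code_index``, ``separation``, ``assigned``."""
        check_is_fitted(self)
        X = check_array(X)
        scheme = self._scheme()
        k = scheme.k_hot
        R = self._rescale(X)
        order = np.argsort(-R, axis=1, kind="stable")
        sorted_desc = -np.sort(-R, axis=1)
        separation = sorted_desc[:, k - 1] - sorted_desc[:, k]
        top_sets = np.sort(order[:, :k], axis=1)
        code_index = np.fromiter(
            (self._code_lookup_.get(tuple(row), -1) for row in top_sets),
            dtype=int,
            count=len(top_sets),
        )
        assigned = (
            (code_index >= 0)
            & (separation >= self.separation_threshold)
            & (separation > 0.0)
        )
        return pd.DataFrame(
            {
                "code_index": np.where(assigned, code_index, -1),
                "separation": separation,
                "assigned": assigned,
            }
        )

    def predict(self, X) -> np.ndarray:
        return self.debarcode(X)["code_index"].to_numpy()


def debarcode(
    table: CellTable,
    scheme: BarcodeScheme,
    separation_threshold: float = DEFAULT_SEPARATION_THRESHOLD,
) -> pd.DataFrame:
    """Debarcode an arcsinh-transformed pooled table on its barcode channels."""
    if table.transform != ARCSINH:
        raise TransformStateError("debarcoding expects an arcsinh-transformed table")
    bc_channels = table.channels_with_role("barcode")
    if len(bc_channels) != scheme.n_channels:
        raise SchemeError(
            f"table has {len(bc_channels)} barcode channels; scheme needs {scheme.n_channels}"
        )
    caller = CombinatorialDebarcoder(scheme, separation_threshold)
    X = table.data[bc_channels].to_numpy(dtype=float)
    calls = caller.fit(X).debarcode(X)
    calls.insert(0, "cell", np.arange(table.n_cells))
    return calls


def split_by_condition(
    table: CellTable, calls: pd.DataFrame, scheme: BarcodeScheme
) -> tuple[dict[str, CellTable], pd.DataFrame]:
    """Partition assigned cells into per-condition tables.

    Returns ``(tables, qc)`` where ``qc`` is a per-code summary
    (code, condition, n_assigned, median_separation) with an extra
    ``unassigned`` row.  Codes without a condition mapping route to
    ``"unmapped"``.  Conservation: assigned cells across outputs plus
    unassigned equals the input cell count.
    """
    if len(calls) != table.n_cells:
        raise ValueError("calls do not match table")
    out: dict[str, CellTable] = {}
    qc_rows = []
    assigned = calls[calls["assigned"]]
    for code_idx, group in assigned.groupby("code_index"):
        code = scheme.codes[int(code_idx)]
        condition = scheme.condition_for(code)
        if condition is None:
            condition = "unmapped"
        sub = table.subset(np.isin(np.arange(table.n_cells), group["cell"].to_numpy()))
        sub.data["condition"] = condition
        sub.data["barcode"] = "-".join(map(str, code))
        if condition in out:
            from .celltable import concat_tables

            sub = concat_tables([out[condition], sub])
        out[condition] = sub
        qc_rows.append(
            {
                "code": "-".join(map(str, code)),
                "condition": condition,
                "n_assigned": len(group),
                "median_separation": float(group["separation"].median()),
            }
        )
    n_unassigned = int((~calls["assigned"]).sum())
    qc_rows.append(
        {
            "code": "unassigned",
            "condition": "",
            "n_assigned": n_unassigned,
            "median_separation": float(
                calls.loc[~calls["assigned"], "separation"].median()
            )
            if n_unassigned
            else float("nan"),
        }
    )
    return out, pd.DataFrame(qc_rows)
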