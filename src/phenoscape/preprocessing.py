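"""Scale transforms and batch centering.

Mass-cytometry ion counts are variance-stabilised with the inverse
hyperbolic sine, ``asinh(x / cofactor)`` (cofactor 5 by convention for
metal-tag data), then mean-centered per channel within each acquisition
batch so that between-run intensity drift does not masquerade as a
biological shift.

Both steps are exposed as sklearn-style transformers on plain arrays and as
functions on :class:`~phenoscape.celltable.CellTable` that additionally
track the transform state.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .celltable import ARCSINH, RAW, CellTable, TransformStateError

DEFAULT_COFACTOR = 5.0


class ArcsinhScaler(TransformerMixin, BaseEstimator):
    """Element-wise ``asinh(x / cofactor)``.

    Stateless; ``fit`` only validates. ``inverse_transform`` returns
    ``cofactor * sinh(x)``.
    """

    def __init__(self, cofactor: float = DEFAULT_COFACTOR):
        self.cofactor = cofactor

    def fit(self, X, y=None):
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        X = check_array(X, ensure_2d=False, allow_nd=False, ensure_min_samples=0)
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=False, ensure_min_samples=0)
        return np.arcsinh(X / self.cofactor)

    def inverse_transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=False, ensure_min_samples=0)
        return np.sinh(X) * self.cofactor


class BatchCenterer(TransformerMixin, BaseEstimator):
    """Per-batch, per-feature mean centering.

    ``fit(X, batch=labels)`` learns one mean vector per batch
    (``batch_means_``); ``transform`` subtracts the matching batch mean.
    """

    def __init__(self):
        pass

    def fit(self, X, y=None, *, batch=None):
        X = check_array(X, ensure_min_samples=0)
        if batch is None:
            batch = np.zeros(X.shape[0], dtype=int)
        batch = np.asarray(batch)
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch labels must match number of rows")
        self.n_features_in_ = X.shape[1]
        self.batch_means_ = {}
        for b in pd.unique(batch):
            mask = batch == b
            if not mask.any():  # pragma: no cover - pd.unique guarantees presence
                continue
            self.batch_means_[b] = X[mask].mean(axis=0)
        return self

    def transform(self, X, *, batch=None):
        check_is_fitted(self)
        X = check_array(X, ensure_min_samples=0).copy()
        if batch is None:
            batch = np.zeros(X.shape[0], dtype=int)
        batch = np.asarray(batch)
        for b in pd.unique(batch):
            mask = batch == b
            if b not in self.batch_means_:
                warnings.warn(f"batch {b!r} unseen at fit time; left uncentered")
                continue
            X[mask] -= self.batch_means_[b]
        return X

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X, batch=fit_params.get("batch"))


def arcsinh_transform(table: CellTable, cofactor: float = DEFAULT_COFACTOR) -> CellTable:
    """arcsinh-transform every channel of a raw-scale table."""
    if table.transform != RAW:
        raise TransformStateError("table is already arcsinh-transformed")
    scaler = ArcsinhScaler(cofactor=cofactor).fit(table.values)
    out = table.copy()
    channels = out.channels
    if channels and out.n_cells:
        out.data[channels] = scaler.transform(out.data[channels].to_numpy(dtype=float))
    out.transform = ARCSINH
    return out


def batch_mean_center(
    table: CellTable, batch_column: str = "batch", channels: list[str] | None = None
) -> CellTable:
    """Subtract the per-batch mean of each channel (transformed scale).

    Post-condition: within every batch, each centered channel's mean is 0
    (to 1e-9).  Empty batches are skipped with a warning.
    """
    if table.transform != ARCSINH:
        raise TransformStateError("batch centering requires an arcsinh-transformed table")
    if batch_column not in table.data.columns:
        raise KeyError(f"no {batch_column!r} column on table")
    channels = list(channels) if channels is not None else table.channels
    out = table.copy()
    batches = out.data[batch_column].to_numpy()
    if table.n_cells == 0:
        warnings.warn("batch with 0 cells skipped")
        out.centered = True
        return out
    centerer = BatchCenterer().fit(out.data[channels].to_numpy(dtype=float), batch=batches)
    out.data[channels] = centerer.transform(
        out.data[channels].to_numpy(dtype=float), batch=batches
    )
    out.centered = True
    return out
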