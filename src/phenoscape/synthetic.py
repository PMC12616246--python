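"""Synthetic cytometry and scRNA-seq data with planted, recoverable truth.

The cytometry generator emulates the statistical structure of a pooled
organoid / γδ T-cell screen: arcsinh-scale marker distributions with
condition-specific location shifts, sigmoidal PTM→PTM dependencies of
tunable strength, k-of-n combinatorial barcode intensity patterns with
summed-channel doublets, planted apoptosis / S-phase fractions, and
per-batch channel offsets.  Raw-scale intensities are lognormal-like
(``raw = cofactor * sinh(z)`` for Gaussian ``z``), so a planted shift δ is
*exactly* the arcsinh-scale translation the downstream EMD statistics
should recover — the ground truth is analytic.

The scRNA-seq generator emulates a gene-count matrix with proCSC/revCSC
gene programs blended per cell by a planted ``program_mix``, mitochondrial
fractions ("MT-"-prefixed genes) and UMI/read ratios, sized so that the
default QC bounds pass the bulk of cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .celltable import CellTable, make_channel_roles
from .debarcoding import Code, spread_codes
from .stem import MITO_PREFIX, OBS_GENES, OBS_MITO, OBS_RATIO, OBS_TOTAL


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


# --------------------------------------------------------------- panels
PTM_MARKERS = (
    "pSTAT3", "pSTAT5", "pZAP70", "pSLP76", "pERK", "pAKT",
    "pS6", "pNFkB", "pP38", "pJNK", "pCREB",
)

def default_marker_panel() -> list[tuple[str, str]]:
    """Name/role panel mirroring a γδ T-cell / organoid screening panel."""
    panel: list[tuple[str, str]] = []
    panel += [(m, "lineage") for m in ("PanCK", "EpCAM", "CD45", "CD3", "TCRgd")]
    panel += [(m, "PTM") for m in PTM_MARKERS]
    panel += [(m, "state") for m in ("cPARP", "IdU", "pRB")]
    panel += [(m, "immunophenotype") for m in ("CD16", "CD69", "GranzymeB", "Perforin")]
    panel += [("DNA1", "DNA"), ("DNA2", "DNA"), ("cisplatin", "viability")]
    panel += [(f"BC{i+1}", "barcode") for i in range(9)]
    return panel


# arcsinh-scale baseline (mu, sigma) per role; lineage split by population
_BASELINES = {
    "PTM": (2.2, 0.35),
    "immunophenotype": (2.0, 0.40),
    "DNA": (4.0, 0.20),
    "viability": (0.5, 0.30),
    "other": (1.5, 0.40),
}
_LINEAGE_HIGH = (3.2, 0.30)
_LINEAGE_LOW = (0.3, 0.25)
_STATE_HIGH = (3.0, 0.30)
_STATE_LOW = (0.25, 0.25)
_EPITHELIAL_LINEAGE = {"PanCK", "EpCAM"}
_GDT_LINEAGE = {"CD45", "CD3", "TCRgd"}

# raw-scale barcode intensities (lognormal)
_BARCODE_HOT = (np.log(600.0), 0.30)
_BARCODE_COLD = (np.log(3.0), 0.50)

_SIGMOID_SLOPE = 4.0
_DEPENDENCY_SPAN = 3.0
_DEPENDENCY_NOISE_SD = 0.12


@dataclass
class CytometrySimConfig:
    """Planted parameters of a simulated pooled cytometry screen."""

    conditions: list[str]
    cells_per_condition: int = 1000
    marker_panel: list[tuple[str, str]] = field(default_factory=default_marker_panel)
    shift_map: dict[tuple[str, str], float] = field(default_factory=dict)
    dependency_map: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    apoptosis_fraction: dict[str, float] = field(default_factory=dict)
    s_phase_fraction: dict[str, float] = field(default_factory=dict)
    population_mix: dict[str, dict[str, float]] = field(default_factory=dict)
    doublet_rate: float = 0.0
    barcode_n: int = 9
    barcode_k: int = 4
    batch_of_condition: dict[str, str] = field(default_factory=dict)
    batch_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_condition < 1:
            raise ConfigurationError("cells_per_condition must be >= 1")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ConfigurationError("doublet_rate must be in [0, 1]")
        roles = {role for _, role in self.marker_panel}
        if "DNA" not in roles or "viability" not in roles:
            raise ConfigurationError("panel must contain a DNA and a viability channel")
        names = [n for n, _ in self.marker_panel]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate channel names in panel")
        conds = set(self.conditions)
        for (c, m) in self.shift_map:
            if c not in conds:
                raise ConfigurationError(f"shift_map condition {c!r} not in design")
            if m not in names:
                raise ConfigurationError(f"shift_map marker {m!r} not in panel")
        for (c, pair) in self.dependency_map:
            if c not in conds:
                raise ConfigurationError(f"dependency_map condition {c!r} not in design")
            for m in pair:
                if m not in names:
                    raise ConfigurationError(f"dependency_map marker {m!r} not in panel")
        for fracs in (self.apoptosis_fraction, self.s_phase_fraction):
            for c, f in fracs.items():
                if c not in conds:
                    raise ConfigurationError(f"fraction for unknown condition {c!r}")
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError("state fractions must be in [0, 1]")
        for s in self.dependency_map.values():
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError("dependency strengths must be in [0, 1]")
        n_codes = 1
        for i in range(self.barcode_k):  # C(n, k) without importing math.comb twice
            n_codes = n_codes * (self.barcode_n - i) // (i + 1)
        if len(self.conditions) > n_codes:
            raise ConfigurationError(
                f"{len(self.conditions)} conditions exceed {n_codes} barcode codes"
            )


@dataclass
class CytometryGroundTruth:
    """Everything that was planted, per condition and per cell."""

    config: CytometrySimConfig
    condition_codes: dict[str, Code]
    cell_condition: list[str]
    cell_code: list[Code | None]
    cell_state: list[str]
    cell_population: list[str]
    is_doublet: np.ndarray

    def to_json(self, path: str | Path) -> None:
        doc = {
            "conditions": self.config.conditions,
            "cells_per_condition": self.config.cells_per_condition,
            "seed": self.config.seed,
            "doublet_rate": self.config.doublet_rate,
            "shift_map": {f"{c}|{m}": v for (c, m), v in self.config.shift_map.items()},
            "dependency_map": {
                f"{c}|{x}->{y}": s for (c, (x, y)), s in self.config.dependency_map.items()
            },
            "apoptosis_fraction": self.config.apoptosis_fraction,
            "s_phase_fraction": self.config.s_phase_fraction,
            "condition_codes": {c: list(code) for c, code in self.condition_codes.items()},
            "cell_condition": self.cell_condition,
            "cell_code": [list(c) if c is not None else None for c in self.cell_code],
            "cell_state": self.cell_state,
            "cell_population": self.cell_population,
            "is_doublet": self.is_doublet.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def generate_cytometry_experiment(
    config: CytometrySimConfig,
) -> tuple[CellTable, CytometryGroundTruth]:
    """Simulate a pooled, barcoded screen; returns a raw-scale table + truth.

    Deterministic for a fixed config and seed (bit-identical re-runs).
    """
    rng = np.random.default_rng(config.seed)
    roles = make_channel_roles(config.marker_panel)
    channels = [n for n, _ in config.marker_panel]
    non_barcode = [c for c in channels if roles[c] != "barcode"]
    barcode_channels = [c for c in channels if roles[c] == "barcode"]
    if len(barcode_channels) != config.barcode_n:
        raise ConfigurationError(
            f"panel has {len(barcode_channels)} barcode channels, scheme needs {config.barcode_n}"
        )
    codes = spread_codes(config.barcode_n, config.barcode_k, len(config.conditions))
    condition_codes = dict(zip(config.conditions, codes))

    blocks: list[np.ndarray] = []
    cell_condition: list[str] = []
    cell_state: list[str] = []
    cell_population: list[str] = []
    cell_code: list[Code | None] = []
    batches: list[str] = []

    for cond in config.conditions:
        n = config.cells_per_condition
        p_apop = config.apoptosis_fraction.get(cond, 0.05)
        p_s = config.s_phase_fraction.get(cond, 0.20)
        if p_apop + p_s > 1.0:
            raise ConfigurationError(f"apoptosis + S-phase fractions exceed 1 for {cond!r}")
        mix = config.population_mix.get(cond, {"gd_t": 1.0})
        pops = rng.choice(list(mix), size=n, p=np.array(list(mix.values())) / sum(mix.values()))
        states = rng.choice(
            ["apoptotic", "S", "other"], size=n, p=[p_apop, p_s, 1.0 - p_apop - p_s]
        )
        batch = config.batch_of_condition.get(cond, "batch1")
        offsets = config.batch_effects.get(batch, {})

        z = np.zeros((n, len(non_barcode)))
        for j, m in enumerate(non_barcode):
            role = roles[m]
            if role == "lineage":
                hi_for = _EPITHELIAL_LINEAGE if m in _EPITHELIAL_LINEAGE else _GDT_LINEAGE
                is_hi = (
                    np.isin(pops, ["epithelial"])
                    if hi_for is _EPITHELIAL_LINEAGE
                    else np.isin(pops, ["gd_t"])
                )
                mu = np.where(is_hi, _LINEAGE_HIGH[0], _LINEAGE_LOW[0])
                sd = np.where(is_hi, _LINEAGE_HIGH[1], _LINEAGE_LOW[1])
            elif role == "state":
                if m == "cPARP":
                    hi = states == "apoptotic"
                elif m == "IdU":
                    hi = states == "S"
                else:  # pRB: high in cycling/other cells, low in apoptotic
                    hi = states != "apoptotic"
                mu = np.where(hi, _STATE_HIGH[0], _STATE_LOW[0])
                sd = np.where(hi, _STATE_HIGH[1], _STATE_LOW[1])
            else:
                mu0, sd0 = _BASELINES.get(role, _BASELINES["other"])
                mu = np.full(n, mu0)
                sd = np.full(n, sd0)
            z[:, j] = rng.normal(mu, sd)
            delta = config.shift_map.get((cond, m), 0.0)
            if delta:
                z[:, j] += delta

        # planted sigmoidal PTM->PTM dependencies (response of y to x)
        idx = {m: j for j, m in enumerate(non_barcode)}
        for (c, (mx, my)), s in config.dependency_map.items():
            if c != cond:
                continue
            x = z[:, idx[mx]]
            x0 = float(np.mean(x))
            base_mu = _BASELINES.get(roles[my], _BASELINES["other"])[0]
            base_mu += config.shift_map.get((cond, my), 0.0)
            response = _sigmoid(_SIGMOID_SLOPE * (x - x0))
            noise = response[rng.permutation(len(response))]  # marginal-preserving
            blend = s * response + (1.0 - s) * noise
            z[:, idx[my]] = (
                base_mu - _DEPENDENCY_SPAN / 2.0
                + _DEPENDENCY_SPAN * blend
                + rng.normal(0.0, _DEPENDENCY_NOISE_SD, size=n)
            )

        for m, off in offsets.items():
            if m in idx:
                z[:, idx[m]] += off

        raw = config.cofactor * np.sinh(np.clip(z, 0.0, None))

        # barcode channels: k hot lognormal, rest cold
        code = condition_codes[cond]
        bc = rng.lognormal(_BARCODE_COLD[0], _BARCODE_COLD[1], size=(n, config.barcode_n))
        hot = rng.lognormal(_BARCODE_HOT[0], _BARCODE_HOT[1], size=(n, config.barcode_k))
        bc[:, list(code)] = hot
        blocks.append(np.hstack([raw, bc]))
        cell_condition += [cond] * n
        cell_state += list(states)
        cell_population += list(pops)
        cell_code += [code] * n
        batches += [batch] * n

    X = np.vstack(blocks) if blocks else np.empty((0, len(channels)))
    n_singlets = X.shape[0]
    is_doublet = np.zeros(n_singlets, dtype=bool)

    n_doublets = int(round(config.doublet_rate * n_singlets))
    if n_doublets:
        first = rng.integers(0, n_singlets, size=n_doublets)
        second = rng.integers(0, n_singlets, size=n_doublets)
        same = first == second
        second[same] = (second[same] + 1) % n_singlets
        # coincident events sum channel-wise (ion-count physics)
        X = np.vstack([X, X[first] + X[second]])
        cell_condition += ["doublet"] * n_doublets
        cell_state += ["doublet"] * n_doublets
        cell_population += ["doublet"] * n_doublets
        cell_code += [None] * n_doublets
        batches += [batches[i] for i in first]
        is_doublet = np.concatenate([is_doublet, np.ones(n_doublets, dtype=bool)])

    order = rng.permutation(X.shape[0])
    X = X[order]
    reorder = lambda lst: [lst[i] for i in order]  # noqa: E731
    cell_condition = reorder(cell_condition)
    cell_state = reorder(cell_state)
    cell_population = reorder(cell_population)
    cell_code = reorder(cell_code)
    batches = reorder(batches)
    is_doublet = is_doublet[order]

    ordered_channels = non_barcode + barcode_channels
    data = pd.DataFrame(X, columns=ordered_channels)
    data["condition"] = cell_condition
    data["batch"] = batches
    data["replicate"] = 1
    table = CellTable(data=data, channel_roles=roles, transform="raw")
    truth = CytometryGroundTruth(
        config=config,
        condition_codes=condition_codes,
        cell_condition=cell_condition,
        cell_code=cell_code,
        cell_state=cell_state,
        cell_population=cell_population,
        is_doublet=is_doublet,
    )
    return table, truth


# ------------------------------------------------------------- scRNA-seq
@dataclass
class ScrnaSimConfig:
    """Planted parameters of a simulated gene-count matrix."""

    n_cells: int = 2000
    n_genes: int = 400
    n_mito_genes: int = 10
    n_program_genes: int = 20
    median_library_size: float = 4000.0
    library_sigma: float = 0.35
    mito_fraction_dist: tuple[float, float] = (4.0, 45.0)  # Beta(a, b)
    umi_read_ratio_dist: tuple[float, float] = (5.0, 15.0)  # Beta(a, b)
    program_mix: np.ndarray | None = None  # default Uniform(0,1) per cell
    pro_gene_names: list[str] | None = None
    rev_gene_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_genes < 1:
            raise ConfigurationError("need n_cells >= 0 and n_genes >= 1")
        if len(self.pro_genes) + len(self.rev_genes) + self.n_mito_genes >= self.n_genes:
            raise ConfigurationError("gene universe too small for programs + mito genes")
        if set(self.pro_genes) & set(self.rev_genes):
            raise ConfigurationError("proCSC and revCSC gene sets must be disjoint")

    @property
    def pro_genes(self) -> list[str]:
        if self.pro_gene_names is not None:
            return list(self.pro_gene_names)
        return [f"PROCSC{i+1}" for i in range(self.n_program_genes)]

    @property
    def rev_genes(self) -> list[str]:
        if self.rev_gene_names is not None:
            return list(self.rev_gene_names)
        return [f"REVCSC{i+1}" for i in range(self.n_program_genes)]

    @property
    def gene_names(self) -> list[str]:
        n_other = self.n_genes - len(self.pro_genes) - len(self.rev_genes) - self.n_mito_genes
        return (
            self.pro_genes
            + self.rev_genes
            + [f"{MITO_PREFIX}{i+1}" for i in range(self.n_mito_genes)]
            + [f"GENE{i+1}" for i in range(n_other)]
        )


@dataclass
class ScrnaGroundTruth:
    config: ScrnaSimConfig
    program_mix: np.ndarray

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.config.seed,
                    "n_cells": self.config.n_cells,
                    "n_genes": self.config.n_genes,
                    "program_mix": self.program_mix.tolist(),
                },
                fh,
            )


def generate_scrna_counts(config: ScrnaSimConfig):
    """Simulate a counts AnnData with planted proCSC/revCSC program mixing.

    ``program_mix`` w near 1 elevates revCSC genes and depresses proCSC
    genes (and vice versa); truth records w per cell.
    """
    import anndata as adlib

    if set(config.pro_genes) & set(config.rev_genes):  # defensive; names disjoint by design
        raise ConfigurationError("program gene sets overlap")
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    n_cells, n_genes = config.n_cells, len(genes)

    w = (
        np.asarray(config.program_mix, dtype=float)
        if config.program_mix is not None
        else rng.uniform(0.0, 1.0, size=n_cells)
    )
    if w.shape != (n_cells,):
        raise ConfigurationError("program_mix must have one weight per cell")
    if n_cells and (w.min() < 0 or w.max() > 1):
        raise ConfigurationError("program_mix weights must be in [0, 1]")

    base = rng.gamma(2.0, 1.0, size=n_genes) + 0.05
    is_pro = np.array([g in set(config.pro_genes) for g in genes])
    is_rev = np.array([g in set(config.rev_genes) for g in genes])
    is_mito = np.array([g.startswith(MITO_PREFIX) for g in genes])

    L = rng.lognormal(np.log(config.median_library_size), config.library_sigma, size=n_cells)
    f_mito = rng.beta(*config.mito_fraction_dist, size=n_cells)
    ratio = rng.beta(*config.umi_read_ratio_dist, size=n_cells)

    weights = np.tile(base, (n_cells, 1))
    weights[:, is_rev] *= (0.2 + 1.8 * w)[:, None]
    weights[:, is_pro] *= (2.0 - 1.8 * w)[:, None]

    lam = np.zeros((n_cells, n_genes))
    non_mito = ~is_mito
    nm_w = weights[:, non_mito]
    nm_sum = nm_w.sum(axis=1, keepdims=True)
    lam[:, non_mito] = (L * (1 - f_mito))[:, None] * nm_w / np.maximum(nm_sum, 1e-12)
    m_w = weights[:, is_mito]
    m_sum = m_w.sum(axis=1, keepdims=True)
    lam[:, is_mito] = (L * f_mito)[:, None] * m_w / np.maximum(m_sum, 1e-12)

    counts = rng.poisson(lam).astype(np.int64)

    obs = pd.DataFrame(index=[f"CELL{i+1}" for i in range(n_cells)])
    totals = counts.sum(axis=1)
    obs[OBS_TOTAL] = totals
    obs[OBS_GENES] = (counts > 0).sum(axis=1)
    obs[OBS_MITO] = counts[:, is_mito].sum(axis=1) / np.maximum(totals, 1)
    obs[OBS_RATIO] = ratio
    adata = adlib.AnnData(
        X=sparse.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=genes)
    )
    adata.uns["programs"] = {"proCSC": config.pro_genes, "revCSC": config.rev_genes}
    return adata, ScrnaGroundTruth(config=config, program_mix=w)


# ----------------------------------------------------------------- writers
def write_scrna_experiment(adata, truth: ScrnaGroundTruth, out_dir: str | Path) -> None:
    """MatrixMarket MTX + genes.tsv + barcodes.tsv + metadata.tsv + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), sparse.coo_matrix(adata.X))
    pd.Series(list(adata.var_names)).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(list(adata.obs_names)).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(out / "metadata.tsv", sep="\t")
    truth.to_json(out / "ground_truth.json")
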