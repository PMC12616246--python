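"""End-to-end orchestration: debarcode → gate → center → shift → DREMI → embed.

A single YAML config drives the run; every stage writes a plain TSV into
the run directory, together with a machine-readable provenance manifest
(settings hash, package version, seeds) and a log.  All randomness flows
from config seeds, so re-running an identical config reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .celltable import CellTable
from .debarcoding import BarcodeScheme, debarcode, split_by_condition
from .dremi import DremiSettings, PtmPanel, delta_dremi, delta_dremi_matrix, dremi_long_table, dremi_table
from .embedding import embed_conditions
from .gating import GateSpec
from .io import load_manifest, manifest_gates, read_cell_table, write_cell_table, write_manifest
from .preprocessing import arcsinh_transform, batch_mean_center
from .shift import StateThresholds, compute_shift, cytotoxicity_summary, shift_table, xbar_emd
from .synthetic import PTM_MARKERS, CytometrySimConfig, generate_cytometry_experiment

logger = logging.getLogger("phenoscape.pipeline")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (raised before any stage executes)."""


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    data_csv: str
    manifest: str
    design: str
    out_dir: str
    barcode_n: int = 9
    barcode_k: int = 4
    separation_threshold: float = 0.3
    cofactor: float = 5.0
    dremi_panel: list[str] = field(default_factory=lambda: list(PTM_MARKERS))
    dremi_k: int = 10
    dremi_bins: int = 20
    dremi_mesh: int = 3
    embed_k: int = 5
    embed_alpha: float = 10.0
    embed_t: int = 10
    state_threshold: float = 1.5
    seed: int = 42

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def settings_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"condition": str}).fillna("")
    required = {"condition", "batch", "population", "control"}
    missing = required - set(design.columns)
    if missing:
        raise PipelineConfigError(f"design table lacks columns: {sorted(missing)}")
    if design["condition"].duplicated().any():
        raise PipelineConfigError("duplicate condition ids in design")
    known = set(design["condition"])
    for _, row in design.iterrows():
        if row["control"] and row["control"] not in known:
            raise PipelineConfigError(
                f"condition {row['condition']!r} references unknown control {row['control']!r}"
            )
        if "baseline" in design.columns and row["baseline"] and row["baseline"] not in known:
            raise PipelineConfigError(
                f"condition {row['condition']!r} references unknown baseline {row['baseline']!r}"
            )
    return design


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with the stage name and offending sample id in
    the raised error's message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        design = _load_design(config.design)
        manifest = load_manifest(config.manifest)
        gates = manifest_gates(manifest)
        scheme = BarcodeScheme.from_conditions(
            config.barcode_n, config.barcode_k, list(design["condition"])
        )

        logger.info("stage=read file=%s", config.data_csv)
        table = read_cell_table(config.data_csv, manifest)
        table = arcsinh_transform(table, cofactor=config.cofactor)

        logger.info("stage=debarcode n_cells=%d", table.n_cells)
        calls = debarcode(table, scheme, config.separation_threshold)
        per_condition, qc = split_by_condition(table, calls, scheme)
        qc.to_csv(out / "debarcode_qc.tsv", sep="\t", index=False)

        design_ix = design.set_index("condition")
        pops: dict[str, CellTable] = {}
        for cond, sub in per_condition.items():
            if cond == "unmapped":
                continue
            row = design_ix.loc[cond]
            sub.data["batch"] = row["batch"]
            sub.data["replicate"] = row.get("replicate", 1)
            gated = sub
            for gate in gates:
                from .gating import gate_population

                gated = gate_population(gated, gate)
            pops[cond] = gated

        # batch centering across the pooled, debarcoded, gated cells
        from .celltable import concat_tables

        if not pops:
            raise RuntimeError("stage=debarcode: no condition received any assigned cells")
        pooled = concat_tables(list(pops.values()))
        marker_channels = pooled.marker_channels()
        centered = batch_mean_center(pooled, channels=marker_channels)

        def _sel(cond: str, population: str, table_: CellTable) -> CellTable:
            t = table_.where_condition(cond)
            return t.where_population(population)

        # ------------------------------------------------------ shift stage
        logger.info("stage=shift")
        shift_results, summary_rows = [], []
        thresholds = StateThresholds(
            cparp=config.state_threshold,
            idu=config.state_threshold,
            prb=config.state_threshold,
        )
        for _, row in design.iterrows():
            cond, ctrl = row["condition"], row["control"]
            if not ctrl or cond not in pops or ctrl not in pops:
                continue
            population = row["population"] or "gd_t"
            try:
                test_c = _sel(cond, population, centered)
                ref_c = _sel(ctrl, population, centered)
                if test_c.n_cells == 0 or ref_c.n_cells == 0:
                    logger.warning("stage=shift sample=%s: empty gate, skipped", cond)
                    continue
                res = compute_shift(test_c, ref_c)
                res.condition, res.reference = cond, ctrl
                shift_results.append(res)
                summary = {"condition": cond, "reference": ctrl, "xbar_emd": xbar_emd(res)}
                baseline = row.get("baseline", "")
                if baseline and baseline in pops:
                    co_epi = _sel(cond, "epithelial", pooled)
                    base_epi = _sel(baseline, "epithelial", pooled)
                    if co_epi.n_cells and base_epi.n_cells:
                        cyto = cytotoxicity_summary(co_epi, base_epi, thresholds)
                        summary["therapeutic_apoptosis"] = cyto.therapeutic_apoptosis
                        summary["epithelial_apoptotic_fraction"] = cyto.apoptotic_fraction
                gd = _sel(cond, population, pooled)
                if gd.n_cells:
                    from .shift import cell_state_counts

                    counts = cell_state_counts(gd, thresholds)
                    total = max(sum(counts.values()), 1)
                    summary.update({f"frac_{k}": v / total for k, v in counts.items()})
                summary_rows.append(summary)
            except Exception as exc:
                raise RuntimeError(f"stage=shift sample={cond}: {exc}") from exc
        shift_table(shift_results).to_csv(out / "shifts.tsv", sep="\t", index=False)
        pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)

        # ------------------------------------------------------ DREMI stage
        logger.info("stage=dremi")
        panel = PtmPanel(tuple(config.dremi_panel))
        settings = DremiSettings(k=config.dremi_k, n_bins=config.dremi_bins, n_mesh=config.dremi_mesh)
        dremi_by_cond = {}
        for _, row in design.iterrows():
            cond = row["condition"]
            population = row["population"] or "gd_t"
            if population != "gd_t" or cond not in pops:
                continue
            cells = _sel(cond, population, centered)
            if cells.n_cells < settings.k + 1:
                logger.warning("stage=dremi sample=%s: too few cells, skipped", cond)
                continue
            try:
                dremi_by_cond[cond] = dremi_table(cells, panel, settings, condition=cond)
            except Exception as exc:
                raise RuntimeError(f"stage=dremi sample={cond}: {exc}") from exc
        dremi_long_table(list(dremi_by_cond.values())).to_csv(
            out / "dremi.tsv", sep="\t", index=False
        )
        deltas = []
        for _, row in design.iterrows():
            cond, ctrl = row["condition"], row["control"]
            if cond in dremi_by_cond and ctrl in dremi_by_cond:
                deltas.append(delta_dremi(dremi_by_cond[cond], dremi_by_cond[ctrl]))
        ddremi = delta_dremi_matrix(deltas)
        ddremi.to_csv(out / "delta_dremi.tsv", sep="\t", index_label="condition")

        # ------------------------------------------------------ embed stage
        logger.info("stage=embed")
        emd_matrix = (
            shift_table(shift_results)
            .pivot(index="condition", columns="marker", values="signed_emd")
            .fillna(0.0)
        )
        coords = []
        for name, matrix in (("emd", emd_matrix), ("delta_dremi", ddremi)):
            if len(matrix) >= max(3, config.embed_k + 1):
                for method in ("pca", "diffusion"):
                    kwargs = (
                        dict(k=config.embed_k, alpha=config.embed_alpha, t=config.embed_t,
                             random_state=config.seed)
                        if method == "diffusion"
                        else {}
                    )
                    c = embed_conditions(matrix, method=method, **kwargs)
                    c["features"] = name
                    coords.append(c)
        if coords:
            pd.concat(coords, ignore_index=True).to_csv(
                out / "embedding.tsv", sep="\t", index=False
            )

        run_manifest = {
            "package": "phenoscape",
            "version": __version__,
            "settings_hash": config.settings_hash(),
            "seed": config.seed,
            "config": asdict(config),
            "n_cells_input": int(table.n_cells),
            "n_assigned": int(calls["assigned"].sum()),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2, sort_keys=True)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


# ------------------------------------------------------------------- demo
DEMO_SHIFT_MARKERS = {
    "pSTAT3": 1.0, "pSTAT5": 0.9, "pZAP70": 0.8, "pSLP76": 0.8,
    "pERK": 1.1, "pS6": 0.9, "CD69": 1.0, "GranzymeB": 1.2,
}
ANTIBODY_RESCUE = 0.35  # mAb shrinks PDO-induced shifts to 35%


def make_demo(
    out_dir: str | Path, seed: int = 42, cells_per_condition: int = 500
) -> PipelineConfig:
    """Write a small synthetic screen plus a ready-to-run config.

    Scenario: 2 donors x 2 engineering states x 3 organoids ± B7-H3 mAb.
    Cocultures plant PTM / immunophenotype shifts on the γδ cells and a
    rewired pSTAT3→pSTAT5 dependency; the antibody shrinks the planted
    shifts (rescued immunomodulation), so x̄EMD(coculture + mAb) <
    x̄EMD(coculture) is the expected demo read-out.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    donors, engs, orgs = ["D1", "D2"], ["unmod", "stIL15"], ["PDO1", "PDO2", "PDO3"]

    rows, conditions = [], []
    shift_map, dependency_map = {}, {}
    apoptosis, s_phase, popmix = {}, {}, {}

    def add(cond, population, control="", baseline="", batch="batch1"):
        conditions.append(cond)
        rows.append(
            {
                "condition": cond, "donor": cond.split("_")[0],
                "engineering": "", "organoid": "", "antibody": "mAb" in cond,
                "replicate": 1, "batch": batch,
                "population": population, "control": control, "baseline": baseline,
            }
        )

    for org in orgs:
        cond = f"{org}_mono"
        add(cond, "epithelial")
        apoptosis[cond], s_phase[cond] = 0.10, 0.25
        popmix[cond] = {"epithelial": 1.0}

    for i, (d, e) in enumerate([(d, e) for d in donors for e in engs]):
        mono = f"{d}_{e}_mono"
        add(mono, "gd_t", batch=f"batch{i % 2 + 1}")
        apoptosis[mono], s_phase[mono] = 0.05, 0.30 if e == "stIL15" else 0.10
        popmix[mono] = {"gd_t": 1.0}
        dependency_map[(mono, ("pSTAT3", "pSTAT5"))] = 0.2
        for org in orgs:
            for mab in (False, True):
                cond = f"{d}_{e}_{org}" + ("_mAb" if mab else "")
                add(cond, "gd_t", control=mono, baseline=f"{org}_mono",
                    batch=f"batch{i % 2 + 1}")
                strength = 1.0 if e == "stIL15" else 0.7
                scale = ANTIBODY_RESCUE if mab else 1.0
                for m, delta in DEMO_SHIFT_MARKERS.items():
                    shift_map[(cond, m)] = delta * strength * scale
                dependency_map[(cond, ("pSTAT3", "pSTAT5"))] = 0.4 if mab else 0.8
                apoptosis[cond] = 0.35 if e == "stIL15" else 0.18
                s_phase[cond] = 0.20
                popmix[cond] = {"epithelial": 0.5, "gd_t": 0.5}

    sim = CytometrySimConfig(
        conditions=conditions,
        cells_per_condition=cells_per_condition,
        shift_map=shift_map,
        dependency_map=dependency_map,
        apoptosis_fraction=apoptosis,
        s_phase_fraction=s_phase,
        population_mix=popmix,
        doublet_rate=0.03,
        batch_effects={"batch2": {"pERK": 0.15, "pAKT": -0.1}},
        batch_of_condition={
            r["condition"]: r["batch"] for r in rows
        },
        seed=seed,
    )
    table, truth = generate_cytometry_experiment(sim)
    truth.to_json(out / "ground_truth.json")

    pooled = table.copy()
    pooled.data = pooled.data.drop(columns=["condition", "batch", "replicate"])
    write_cell_table(pooled, out / "pooled.csv")

    gates = [
        GateSpec("epithelial", positive={"PanCK": 1.5, "EpCAM": 1.5}, negative={"CD45": 1.5}),
        GateSpec("gd_t", positive={"CD45": 1.5, "CD3": 1.5, "TCRgd": 1.5}),
    ]
    write_manifest(table, out / "manifest.yaml", gates=gates)
    pd.DataFrame(rows).to_csv(out / "design.tsv", sep="\t", index=False)

    config = PipelineConfig(
        data_csv=str(out / "pooled.csv"),
        manifest=str(out / "manifest.yaml"),
        design=str(out / "design.tsv"),
        out_dir=str(out / "run"),
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
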