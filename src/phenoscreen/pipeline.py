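"""Configured, logged, reproducible end-to-end runs over flat CSV files.

Stages run in dependency order — ``simulate -> growth -> bliss -> cells
-> screen -> model`` — each reading the previous stage's CSV outputs
from the run directory, so any stage is also runnable standalone on
existing files.  Every stochastic stage derives its randomness from the
config seed, and the run manifest (config snapshot, package version,
dataset-wide min(DIP), test-family size m, per-file SHA-256 checksums)
is sufficient to re-run bit-identically.

All tables are flat CSV with a versioned header comment line
(``# phenoscreen-table-v1``); truth columns from the generator carry a
``truth_`` prefix and are never read by the analysis stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bliss import DEFAULT_ADDITIVITY_TOL, global_min_dip, score_combination_table
from .embedding import embed_single_cells
from .growth import dip_table, growth_rate_table
from .heterogeneity import (
    apply_gate,
    fit_gate,
    heterogeneity_table,
    log_zscore,
    subsample_cells,
)
from .regression import (
    MultiLinearRegression,
    PLSRegressionVIP,
    rank_marker_correlations,
    split_train_validation,
)
from .screen import (
    build_response_matrix,
    call_hits,
    compound_hits,
    hierarchical_cluster,
    normalize_to_control,
    well_growth_rates,
)
from .simulate import (
    DEFAULT_MARKERS,
    SimulationConfig,
    simulate_regression_dataset,
    simulate_screen_plate,
    simulate_screen_proteins,
    simulate_single_cells,
)

__all__ = ["AnalysisConfig", "RunManifest", "run_pipeline", "validate_tables",
           "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "growth", "bliss", "cells", "screen", "model")
_TABLE_VERSION = "# phenoscreen-table-v1"


def _demo_simulation() -> SimulationConfig:
    """Desk-scale screen: 48 compounds of the full library (12 strong +
    12 moderate planted hits + 24 inert), a 24-replicate control pool,
    and a 21-sample regression dataset (14 train / 7 validation under
    the sorted 2:1 split)."""
    full = SimulationConfig()
    compounds = full.compounds[:12] + full.compounds[20:32] + full.compounds[58:82]
    return dataclasses.replace(
        full,
        compounds=compounds,
        control_replicates=24,
        regression=dataclasses.replace(full.regression, n_samples=21),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a run needs; fully serialized into the manifest."""

    seed: int = 0
    outdir: str = "phenoscreen_run"
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 0.05
    effect_threshold: float = 0.5  # day^-1 on the net-rate delta
    effect_on: str = "net"
    additivity_tol: float = DEFAULT_ADDITIVITY_TOL
    cells_per_condition_simulated: int = 300
    subsample_per_condition: int = 60
    tsne_perplexity: float = 480.0
    gate_overrides: Mapping[str, float] = field(default_factory=dict)
    simulation: SimulationConfig = field(default_factory=_demo_simulation)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from YAML or JSON; the ``simulation`` key maps onto
        :class:`SimulationConfig` fields."""
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        kwargs = dict(raw)
        if sim is not None:
            for key in ("timepoints", "compounds", "doses", "cell_lines",
                        "mapk_conditions"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config: dict
    version: str
    min_dip: float | None = None
    test_family_m: int | None = None
    pca_variance_explained: list[float] | None = None
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def _write_csv(df: pd.DataFrame, path: Path, *, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_TABLE_VERSION + "\n")
        df.to_csv(fh, index=index)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    # planted_effects etc. may be arbitrary mappings; make them JSON-safe
    return json.loads(json.dumps(d, default=str))


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: AnalysisConfig, out: Path) -> None:
    sim = config.simulation.with_seed(config.seed)
    counts, truth = simulate_screen_plate(sim)
    _write_csv(counts, out / "screen_counts.csv")
    _write_csv(truth, out / "screen_truth.csv")
    proteins = simulate_screen_proteins(sim)
    _write_csv(proteins, out / "screen_proteins.csv")

    rng = sim.stage_rng("cells")
    cell_frames = []
    for line in sim.cell_lines:
        for mapk in sim.mapk_conditions:
            cell_frames.append(
                simulate_single_cells(
                    sim,
                    config.cells_per_condition_simulated,
                    cell_line=line,
                    treatment=mapk,
                    rng=rng,
                )
            )
    cells = pd.concat(cell_frames, ignore_index=True)
    cells["cell_id"] = [f"cell_{i}" for i in range(len(cells))]
    _write_csv(cells, out / "single_cells.csv")

    X, y, beta = simulate_regression_dataset(sim)
    _write_csv(X.rename_axis("sample"), out / "regression_features.csv", index=True)
    _write_csv(
        y.rename_axis("sample").reset_index(), out / "regression_response.csv"
    )
    _write_csv(
        pd.DataFrame({"feature": X.columns, "truth_coefficient": beta}),
        out / "regression_truth.csv",
    )
    logger.info("simulate: %d count rows, %d cells", len(counts), len(cells))


def _stage_growth(config: AnalysisConfig, out: Path) -> None:
    counts = _read_csv(out / "screen_counts.csv")
    rates = well_growth_rates(counts)
    _write_csv(rates, out / "well_rates.csv")

    by = ["cell_line", "mapk_condition", "compound", "dose"]
    cond = growth_rate_table(counts, by=by)
    control_label = config.simulation.control_label
    ctrl_mask = (cond["mapk_condition"] == "DMSO") & (
        cond["compound"] == control_label
    )
    cond = dip_table(cond, control_mask=ctrl_mask, by=["cell_line"])
    _write_csv(cond, out / "condition_growth.csv")
    logger.info("growth: %d wells in, %d conditions out", len(counts), len(cond))


def _stage_bliss(config: AnalysisConfig, out: Path) -> None:
    cond = _read_csv(out / "condition_growth.csv")
    control_label = config.simulation.control_label
    key = ["cell_line", "compound", "dose", "mapk_condition"]
    dip = cond.set_index(key)["dip"]

    rows = []
    mapk_combos = [m for m in cond["mapk_condition"].unique() if m != "DMSO"]
    treated = cond[
        (cond["compound"] != control_label) & (cond["mapk_condition"] == "DMSO")
    ]
    for _, row in treated.iterrows():
        for mapk in mapk_combos:
            try:
                dip_b = dip[(row["cell_line"], control_label, 0.0, mapk)]
                dip_ab = dip[(row["cell_line"], row["compound"], row["dose"], mapk)]
            except KeyError:
                continue
            rows.append(
                {
                    "cell_line": row["cell_line"],
                    "drug_a": row["compound"],
                    "dose_a": row["dose"],
                    "drug_b": mapk,
                    "dip_a": row["dip"],
                    "dip_b": dip_b,
                    "dip_ab": dip_ab,
                }
            )
    pairs = pd.DataFrame(rows)
    min_dip = global_min_dip(cond["dip"])
    scored = score_combination_table(
        pairs, min_dip=min_dip, additivity_tol=config.additivity_tol
    )
    _write_csv(scored, out / "bliss_scores.csv")
    (out / "min_dip.json").write_text(json.dumps({"min_dip": min_dip}))
    logger.info("bliss: %d pairs scored, min_dip=%.4g", len(scored), min_dip)


def _stage_cells(config: AnalysisConfig, out: Path) -> None:
    cells = _read_csv(out / "single_cells.csv")
    markers = [m for m in DEFAULT_MARKERS if m in cells.columns]
    pooled = subsample_cells(
        cells, config.subsample_per_condition, config.seed
    )
    het = heterogeneity_table(cells, markers, seed=config.seed)
    _write_csv(het, out / "heterogeneity.csv")

    gates = {}
    for m in markers:
        gates[m] = fit_gate(
            cells[m],
            marker=m,
            threshold=config.gate_overrides.get(m),
            random_state=config.seed,
        )
    fractions = apply_gate(cells, gates)
    _write_csv(fractions, out / "high_fractions.csv")
    (out / "gates.json").write_text(
        json.dumps({m: dataclasses.asdict(g) for m, g in gates.items()}, indent=2)
    )

    result = embed_single_cells(
        pooled, markers, seed=config.seed, perplexity=config.tsne_perplexity
    )
    emb = pd.concat(
        [
            pooled[["cell_id", "cell_line", "treatment"]].reset_index(drop=True),
            result.pc_scores.reset_index(drop=True).iloc[:, :2],
            result.tsne_xy.reset_index(drop=True),
        ],
        axis=1,
    )
    _write_csv(emb, out / "embedding.csv")
    (out / "pca_variance.json").write_text(
        json.dumps({"variance_explained": result.variance_explained.tolist()})
    )
    logger.info("cells: %d cells in, %d pooled for embedding", len(cells), len(pooled))


def _stage_screen(config: AnalysisConfig, out: Path) -> None:
    rates = _read_csv(out / "well_rates.csv")
    control_label = config.simulation.control_label
    calls = call_hits(
        rates,
        alpha=config.alpha,
        effect_threshold=config.effect_threshold,
        control_label=control_label,
        effect_on=config.effect_on,
    )
    _write_csv(calls, out / "hit_calls.csv")
    hits = compound_hits(calls).rename("hit").reset_index()
    _write_csv(hits, out / "compound_hits.csv")
    (out / "test_family.json").write_text(
        json.dumps({k: calls.attrs[k] for k in ("m", "alpha", "p_threshold")})
    )

    growth_delta = normalize_to_control(rates, control_label=control_label)
    growth_delta["readout"] = "growth_rate"
    proteins = _read_csv(out / "screen_proteins.csv")
    protein_delta = normalize_to_control(
        proteins,
        value_col="log_intensity",
        control_label=control_label,
        group_cols=["cell_line", "mapk_condition", "timepoint", "readout"],
    )
    long = pd.concat(
        [
            growth_delta[
                ["compound", "readout", "cell_line", "mapk_condition", "dose",
                 "timepoint", "delta"]
            ],
            protein_delta[
                ["compound", "readout", "cell_line", "mapk_condition", "dose",
                 "timepoint", "delta"]
            ],
        ],
        ignore_index=True,
    )
    hit_names = set(hits.loc[hits["hit"], "compound"])
    long = long[long["compound"].isin(hit_names)]
    if len(hit_names) >= 2:
        matrix, incomplete = build_response_matrix(long)
        flat = matrix.copy()
        flat.columns = ["|".join(map(str, c)) for c in matrix.columns]
        _write_csv(flat.rename_axis("compound"), out / "response_matrix.csv",
                   index=True)
        result = hierarchical_cluster(matrix.loc[~incomplete])
        (out / "dendrogram.nwk").write_text(result.newick + "\n")
        (out / "row_order.txt").write_text("\n".join(result.leaf_order) + "\n")
    else:
        logger.warning("screen: <2 hit compounds; clustering skipped")
    logger.info("screen: %d conditions tested, %d hit compounds",
                calls.attrs["m"], int(hits["hit"].sum()))


def _zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def _stage_model(config: AnalysisConfig, out: Path) -> None:
    X = _read_csv(out / "regression_features.csv").set_index("sample")
    y = _read_csv(out / "regression_response.csv").set_index("sample")["response"]
    Xz = _zscore_columns(X)
    yz = (y - y.mean()) / y.std(ddof=1)

    pls = PLSRegressionVIP().fit(Xz.to_numpy(), yz.to_numpy())
    vip = pd.DataFrame({"feature": X.columns, "vip": pls.vip_})
    _write_csv(vip, out / "plsr_vip.csv")

    ids = list(X.index)
    train_ids, val_ids = split_train_validation(ids, y.loc[ids].to_numpy())
    n_feat = min(4, X.shape[1])
    mlr_cols = list(X.columns[:n_feat])
    mlr = MultiLinearRegression().fit(
        X.loc[train_ids, mlr_cols].to_numpy(), y.loc[train_ids].to_numpy()
    )
    preds = pd.DataFrame(
        {
            "sample": ids,
            "split": ["train" if s in set(train_ids) else "validation" for s in ids],
            "measured": y.loc[ids].to_numpy(),
            "predicted": mlr.predict(X.loc[ids, mlr_cols].to_numpy()),
        }
    )
    _write_csv(preds, out / "mlr_predictions.csv")
    _write_csv(
        pd.DataFrame(
            {"feature": ["intercept"] + mlr_cols,
             "coefficient": [mlr.intercept_, *mlr.coef_]}
        ),
        out / "mlr_coefficients.csv",
    )
    if len(val_ids) >= 3:
        val_r, val_p = mlr.validate(
            X.loc[val_ids, mlr_cols].to_numpy(), y.loc[val_ids].to_numpy()
        )
    else:
        val_r, val_p = np.nan, np.nan
    summary = pd.DataFrame(
        [
            {"model": "PLSR", "n_components": pls.n_components_, "r2": pls.r2_,
             "q2": pls.q2_, "pearson_r": pls.loocv_r_, "pearson_p": pls.loocv_p_},
            {"model": "MLR", "n_components": np.nan, "r2": mlr.r2_, "q2": np.nan,
             "pearson_r": val_r, "pearson_p": val_p},
        ]
    )
    _write_csv(summary, out / "model_summary.csv")

    corr = rank_marker_correlations(
        Xz, Xz.columns[0], Xz.columns[1], named=list(Xz.columns[2:4])
    )
    _write_csv(corr, out / "marker_correlations.csv")
    logger.info("model: PLSR R2=%.3f Q2=%.3f; MLR validation r=%.3f",
                pls.r2_, pls.q2_, val_r)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "growth": _stage_growth,
    "bliss": _stage_bliss,
    "cells": _stage_cells,
    "screen": _stage_screen,
    "model": _stage_model,
}


def run_pipeline(
    config: AnalysisConfig,
    *,
    stages: Sequence[str] | None = None,
) -> RunManifest:
    """Execute the requested stages in dependency order and write the
    run manifest.  Returns the manifest object."""
    stages = list(config.stages if stages is None else stages)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in ALL_STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, out)

    manifest = RunManifest(config=_config_dict(config), version=__version__)
    min_dip_file = out / "min_dip.json"
    if min_dip_file.exists():
        manifest.min_dip = json.loads(min_dip_file.read_text())["min_dip"]
    family_file = out / "test_family.json"
    if family_file.exists():
        manifest.test_family_m = json.loads(family_file.read_text())["m"]
    pca_file = out / "pca_variance.json"
    if pca_file.exists():
        manifest.pca_variance_explained = json.loads(pca_file.read_text())[
            "variance_explained"
        ]
    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest.checksums[path.name] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# validation

_COUNT_COLUMNS = ["cell_line", "replicate", "time_days", "live_count"]
_TREATMENT_COLUMNS = ({"treatment"}, {"compound", "mapk_condition"})
_CELL_META = ["cell_id", "cell_line", "treatment", "timepoint", "replicate"]


def validate_tables(paths: Sequence[str | Path]) -> pd.DataFrame:
    """Schema/positivity/completeness checks over input CSVs.

    Table kind is inferred from the columns: a ``live_count`` column
    marks a count time-course, a ``cell_id`` column a single-cell table.
    Returns a report frame (path, row, column, message); empty when all
    files are well formed.
    """
    violations: list[dict] = []

    def flag(path, row, column, message):
        violations.append(
            {"path": str(path), "row": row, "column": column, "message": message}
        )

    for path in paths:
        path = Path(path)
        try:
            df = _read_csv(path)
        except Exception as exc:  # unreadable/binary file
            flag(path, None, None, f"unreadable: {exc}")
            continue
        if "live_count" in df.columns:
            for col in _COUNT_COLUMNS:
                if col not in df.columns:
                    flag(path, None, col, "missing required column")
            cols = set(df.columns)
            if not any(req <= cols for req in _TREATMENT_COLUMNS):
                flag(path, None, "treatment",
                     "missing treatment (or compound+mapk_condition) column")
            bad = df.index[pd.to_numeric(df["live_count"], errors="coerce")
                           .fillna(-1) <= 0]
            for i in bad:
                flag(path, int(i), "live_count", "nonpositive or non-numeric")
        elif "cell_id" in df.columns:
            for col in _CELL_META:
                if col not in df.columns:
                    flag(path, None, col, "missing required column")
                elif df[col].isna().any():
                    for i in df.index[df[col].isna()]:
                        flag(path, int(i), col, "missing metadata value")
            dupes = df.index[df["cell_id"].duplicated()]
            for i in dupes:
                flag(path, int(i), "cell_id", "duplicated cell_id")
            marker_cols = [c for c in df.columns
                           if c not in _CELL_META + ["compartment"]
                           and not c.startswith("truth_")]
            for col in marker_cols:
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[vals.isna() | (vals <= 0)]
                for i in bad:
                    flag(path, int(i), col, "nonpositive or non-numeric intensity")
        else:
            if df.isna().any().any():
                cols = df.columns[df.isna().any()]
                for col in cols:
                    for i in df.index[df[col].isna()]:
                        flag(path, int(i), col, "missing value")
    return pd.DataFrame(violations, columns=["path", "row", "column", "message"])
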