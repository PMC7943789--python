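"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline (growth metrics, Bliss scoring,
single-cell statistics, screen hit calling, regression modeling) is
exercised on tables produced here, so the whole analysis is testable
without any experimental data.  Four generators cover the four input
shapes:

* :func:`simulate_timecourse` — per-well live-cell counts following
  exponential growth ``N(t) = N0 * exp(mu * t)`` with multiplicative
  log-normal count noise of a stated coefficient of variation (CV).
* :func:`simulate_screen_plate` — a full compound screen: compounds x
  doses x replicates across cell lines and MAPK-inhibitor backgrounds,
  with a large shared no-compound control pool and a ground-truth table
  of planted growth-rate effects.
* :func:`simulate_single_cells` — log-normal mixtures of marker
  intensities over High/Low subpopulations, with the true subpopulation
  label retained for gate validation.
* :func:`simulate_regression_dataset` — a low-rank-plus-noise feature
  matrix with a linear response and planted coefficients, the substrate
  of the PLSR/MLR stage.

Seed policy
-----------
One global seed expands into per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn(...)`` in the fixed order
``timecourse, screen, screen_proteins, cells, regression``; each stage is
therefore reproducible in isolation and an identical
:class:`SimulationConfig` yields bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

__all__ = [
    "SubpopulationSpec",
    "RegressionSpec",
    "SimulationConfig",
    "simulate_timecourse",
    "simulate_screen_plate",
    "simulate_screen_proteins",
    "simulate_single_cells",
    "simulate_regression_dataset",
]

_STAGES = ("timecourse", "screen", "screen_proteins", "cells", "regression")

#: Marker panel measured per cell (immunofluorescence-style intensities).
DEFAULT_MARKERS = ("Mitf", "Ngfr", "Axl")


@dataclass(frozen=True)
class SubpopulationSpec:
    """One log-normal component of the single-cell marker mixture.

    ``log_means`` maps marker name -> mean of ln(intensity); ``log_sd`` is
    the common standard deviation on the ln scale; ``fraction`` is the
    mixing proportion of the component.
    """

    fraction: float
    log_means: Mapping[str, float]
    log_sd: float
    label: str = ""


@dataclass(frozen=True)
class RegressionSpec:
    """Low-rank linear-response dataset: X = T P + E, y = X beta + eps.

    ``coefficients`` (length ``n_features``) defaults to a sparse vector
    with four informative features; ``noise_sd`` is the response noise,
    ``feature_noise_sd`` the entrywise noise on the low-rank features.
    """

    n_samples: int = 8
    n_features: int = 24
    rank: int = 2
    coefficients: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    feature_noise_sd: float = 0.05

    def beta(self) -> np.ndarray:
        if self.coefficients is not None:
            b = np.asarray(self.coefficients, dtype=float)
            if b.size != self.n_features:
                raise ValueError(
                    f"coefficients has length {b.size}, expected {self.n_features}"
                )
            return b
        b = np.zeros(self.n_features)
        planted = (1.5, -1.0, 0.75, 0.5)
        b[: min(4, self.n_features)] = planted[: min(4, self.n_features)]
        return b


def _default_subpopulations() -> tuple[SubpopulationSpec, ...]:
    # Two well-separated differentiation states: a 70% Mitf-high
    # (melanocytic) mode and a 30% Axl-high (undifferentiated) mode.
    return (
        SubpopulationSpec(
            fraction=0.7,
            log_means={"Mitf": 7.0, "Ngfr": 5.0, "Axl": 4.5},
            log_sd=0.35,
            label="Mitf_high",
        ),
        SubpopulationSpec(
            fraction=0.3,
            log_means={"Mitf": 5.0, "Ngfr": 5.5, "Axl": 6.5},
            log_sd=0.35,
            label="Axl_high",
        ),
    )


def _default_planted_effects() -> dict[str, float]:
    """Growth-rate deltas (day^-1) for the default 276-compound library.

    20 strongly cytotoxic compounds (-1.0/day), 38 moderate ones
    (-0.6/day) — 58 true hits at the 0.5/day effect threshold — and the
    remaining 218 inert.
    """
    effects: dict[str, float] = {}
    for i in range(20):
        effects[f"EPI-{i + 1:03d}"] = -1.0
    for i in range(20, 58):
        effects[f"EPI-{i + 1:03d}"] = -0.6
    return effects


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for all synthetic generators.

    Defaults mirror the screen design the pipeline targets: counts at 0,
    3 and 5 days of MAPK-inhibitor exposure (compounds added 24 h before
    t=0); a 276-compound library at 0.2 and 1 uM in two replicates; a
    shared 276-replicate no-compound control pool; two cell lines under
    three MAPK backgrounds.  Count noise (``noise_cv``, the CV of the
    multiplicative log-normal noise) is not reported by any upstream
    source; the 10% default is a typical well-to-well CV for imaging-based
    cell counts and is stated here as this package's own choice.
    """

    seed: int = 0
    timepoints: tuple[float, ...] = (0.0, 3.0, 5.0)
    noise_cv: float = 0.1
    n0: int = 2000
    compounds: tuple[str, ...] = tuple(f"EPI-{i + 1:03d}" for i in range(276))
    doses: tuple[float, ...] = (0.2, 1.0)
    replicates: int = 2
    control_replicates: int = 276
    control_label: str = "DMSO"
    cell_lines: tuple[str, ...] = ("COLO858", "MMACSF")
    mapk_conditions: tuple[str, ...] = ("DMSO", "vem", "vem+tram")
    baseline_mu: Mapping[str, float] = field(
        default_factory=lambda: {"COLO858": 0.65, "MMACSF": 0.5}
    )
    mapk_mu_delta: Mapping[str, float] = field(
        default_factory=lambda: {"DMSO": 0.0, "vem": -0.25, "vem+tram": -0.4}
    )
    planted_effects: Mapping[str, float] = field(
        default_factory=_default_planted_effects
    )
    truth_effect_threshold: float = 0.5
    subpopulations: tuple[SubpopulationSpec, ...] = field(
        default_factory=_default_subpopulations
    )
    regression: RegressionSpec = field(default_factory=RegressionSpec)

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise DomainError("timepoints must be strictly increasing, >= 2 points")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if self.subpopulations:
            total = sum(s.fraction for s in self.subpopulations)
            if not np.isclose(total, 1.0):
                raise DomainError(f"mixing fractions sum to {total}, expected 1")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Child RNG for one pipeline stage (documented splitting rule)."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return np.random.default_rng(children[_STAGES.index(stage)])

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def _noisy_counts(
    rng: np.random.Generator,
    n0: np.ndarray,
    mu: np.ndarray,
    t: np.ndarray,
    cv: float,
) -> np.ndarray:
    """N(t) = N0 exp(mu t) times noise, rounded to integers, floored at 1.

    The floor makes a downstream log of zero impossible by construction.
    """
    expected = n0 * np.exp(mu * t)
    noisy = expected * _lognormal_noise(rng, cv, expected.shape)
    return np.maximum(np.rint(noisy), 1.0).astype(np.int64)


def simulate_timecourse(
    config: SimulationConfig,
    mu_true: Mapping[str, float],
    *,
    n_replicates: int | None = None,
    cell_line: str = "simulated",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-condition live-cell-count time courses.

    ``mu_true`` maps condition labels to net growth rates (day^-1).
    Counts at every timepoint (including t0) carry multiplicative noise
    of CV ``config.noise_cv``.  Returns the long-format table consumed by
    the growth-metrics stage, with columns ``condition_id, cell_line,
    treatment, replicate, time_days, live_count``.
    """
    t = np.asarray(config.timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DomainError("timepoints must be strictly increasing")
    if config.n0 <= 0:
        raise DomainError("initial count must be positive")
    mus = {str(k): float(v) for k, v in mu_true.items()}
    if not all(np.isfinite(list(mus.values()))):
        raise DomainError("growth rates must be finite")
    reps = config.replicates if n_replicates is None else int(n_replicates)
    rng = config.stage_rng("timecourse") if rng is None else rng

    conds = list(mus)
    n_rows = len(conds) * reps * t.size
    cond_col = np.repeat(conds, reps * t.size)
    mu_col = np.repeat([mus[c] for c in conds], reps * t.size)
    rep_col = np.tile(np.repeat(np.arange(1, reps + 1), t.size), len(conds))
    t_col = np.tile(t, len(conds) * reps)
    counts = _noisy_counts(
        rng, np.full(n_rows, float(config.n0)), mu_col, t_col, config.noise_cv
    )
    return pd.DataFrame(
        {
            "condition_id": cond_col,
            "cell_line": cell_line,
            "treatment": cond_col,
            "replicate": rep_col,
            "time_days": t_col,
            "live_count": counts,
        }
    )


def _screen_design(config: SimulationConfig) -> pd.DataFrame:
    """Well-level design table: one row per (line, MAPK, compound, dose, rep)."""
    rows = []
    for line in config.cell_lines:
        for mapk in config.mapk_conditions:
            for comp in config.compounds:
                for dose in config.doses:
                    for rep in range(1, config.replicates + 1):
                        rows.append((line, mapk, comp, dose, rep))
            for rep in range(1, config.control_replicates + 1):
                rows.append((line, mapk, config.control_label, 0.0, rep))
    return pd.DataFrame(
        rows, columns=["cell_line", "mapk_condition", "compound", "dose", "replicate"]
    )


def simulate_screen_plate(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Well-level screen time courses plus the ground-truth hit table.

    The true rate of a well is ``baseline_mu[line] + mapk_mu_delta[mapk]
    + planted_effects.get(compound, 0)``; the planted delta applies at
    both doses.  The truth table has one row per compound with
    ``truth_delta_mu`` and ``truth_hit`` (|delta| >= the configured
    effect threshold), the reference the hit caller's empirical error
    rates are measured against.
    """
    if config.replicates < 2:
        raise InsufficientDataError(
            "screen simulation needs >= 2 replicates per compound condition"
        )
    if config.control_label in config.compounds:
        raise DomainError("control label collides with a compound name")
    no_rate = [l for l in config.cell_lines if l not in config.baseline_mu]
    if no_rate:
        raise DomainError(f"baseline_mu missing for cell line(s) {no_rate}")
    no_delta = [m for m in config.mapk_conditions if m not in config.mapk_mu_delta]
    if no_delta:
        raise DomainError(f"mapk_mu_delta missing for condition(s) {no_delta}")
    rng = config.stage_rng("screen")
    design = _screen_design(config)
    mu = (
        design["cell_line"].map(config.baseline_mu).to_numpy(float)
        + design["mapk_condition"].map(config.mapk_mu_delta).to_numpy(float)
        + design["compound"].map(config.planted_effects).fillna(0.0).to_numpy(float)
    )
    t = np.asarray(config.timepoints, dtype=float)
    n = len(design)
    wide = design.loc[design.index.repeat(t.size)].reset_index(drop=True)
    wide["time_days"] = np.tile(t, n)
    mu_col = np.repeat(mu, t.size)
    wide["live_count"] = _noisy_counts(
        rng,
        np.full(len(wide), float(config.n0)),
        mu_col,
        wide["time_days"].to_numpy(),
        config.noise_cv,
    )
    wide["condition_id"] = (
        wide["cell_line"]
        + "|"
        + wide["mapk_condition"]
        + "|"
        + wide["compound"]
        + "|"
        + wide["dose"].astype(str)
    )

    deltas = pd.Series(
        [float(config.planted_effects.get(c, 0.0)) for c in config.compounds],
        index=list(config.compounds),
    )
    truth = pd.DataFrame(
        {
            "compound": deltas.index,
            "truth_delta_mu": deltas.to_numpy(),
            "truth_hit": np.abs(deltas.to_numpy())
            >= config.truth_effect_threshold,
        }
    ).reset_index(drop=True)
    cols = [
        "condition_id",
        "cell_line",
        "mapk_condition",
        "compound",
        "dose",
        "replicate",
        "time_days",
        "live_count",
    ]
    return wide[cols], truth


#: Screen co-staining readouts and their baseline ln-intensities.
SCREEN_PROTEIN_BASELINE = {"p-Erk": 7.5, "p-Rb": 7.0, "Mitf": 6.5}


def simulate_screen_proteins(
    config: SimulationConfig,
    *,
    protein_effects: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Per-well log-intensities of the screen co-staining readouts.

    Emulates the p-Erk/p-Rb/Mitf immunofluorescence that accompanies the
    growth readout in the mechanism-clustering stage.  ``protein_effects``
    maps compound -> readout -> additive ln-intensity shift; by default
    the strongly cytotoxic planted compounds reduce p-Rb by 0.5 (cell
    cycle exit) and the moderate ones by 0.25.
    """
    if protein_effects is None:
        protein_effects = {
            comp: {"p-Rb": 0.5 * delta, "p-Erk": 0.2 * delta, "Mitf": 0.1 * delta}
            for comp, delta in config.planted_effects.items()
        }
    rng = config.stage_rng("screen_proteins")
    design = _screen_design(config)
    t_post = [tp for tp in config.timepoints if tp > 0]
    rows = []
    for readout, base in SCREEN_PROTEIN_BASELINE.items():
        shift = np.array(
            [
                float(protein_effects.get(c, {}).get(readout, 0.0))
                for c in design["compound"]
            ]
        )
        for tp in t_post:
            block = design.copy()
            block["timepoint"] = tp
            block["readout"] = readout
            block["log_intensity"] = (
                base + shift + rng.normal(0.0, noise_sd, len(design))
            )
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


def _allocate_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment so label fractions are exact."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def simulate_single_cells(
    config: SimulationConfig,
    n_cells: int,
    *,
    cell_line: str = "simulated",
    treatment: str = "DMSO",
    timepoint: float = 3.0,
    replicate: int = 1,
    compartment: str = "whole-cell",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-cell marker intensities from a log-normal mixture.

    Subpopulation sizes follow the mixing fractions exactly (largest-
    remainder apportionment), so the ``truth_subpopulation`` column's
    label fractions equal the specified fractions; intensities within a
    component are log-normal with the component's ln-means and ln-sd.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    if not config.subpopulations:
        raise DomainError("subpopulation_specs must be nonempty")
    rng = config.stage_rng("cells") if rng is None else rng
    markers = sorted({m for s in config.subpopulations for m in s.log_means})
    counts = _allocate_counts([s.fraction for s in config.subpopulations], n_cells)
    frames = []
    for i, (spec, k) in enumerate(zip(config.subpopulations, counts)):
        if k == 0:
            continue
        data = {
            m: np.exp(rng.normal(spec.log_means[m], spec.log_sd, k)) for m in markers
        }
        frame = pd.DataFrame(data)
        frame["truth_subpopulation"] = spec.label or f"pop{i}"
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "cell_id", [f"{cell_line}.{treatment}.{i}" for i in range(len(table))])
    table.insert(1, "cell_line", cell_line)
    table.insert(2, "treatment", treatment)
    table.insert(3, "timepoint", timepoint)
    table.insert(4, "replicate", replicate)
    table.insert(5, "compartment", compartment)
    return table


def simulate_regression_dataset(
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Low-rank feature matrix, linear response, and the planted beta.

    X = T P + E with T (n x r), P (r x p) standard normal and E entrywise
    Gaussian of sd ``feature_noise_sd``; y = X beta + eps with eps of sd
    ``noise_sd``.  Returned as a (samples x features) DataFrame, a
    response Series, and the coefficient vector.
    """
    spec = config.regression
    if spec.rank > spec.n_features:
        raise DomainError("latent rank must be <= n_features")
    if spec.noise_sd < 0 or spec.feature_noise_sd < 0:
        raise DomainError("noise sd must be >= 0")
    rng = config.stage_rng("regression") if rng is None else rng
    scores = rng.standard_normal((spec.n_samples, spec.rank))
    load = rng.standard_normal((spec.rank, spec.n_features))
    X = scores @ load
    if spec.feature_noise_sd > 0:
        X = X + rng.normal(0.0, spec.feature_noise_sd, X.shape)
    beta = spec.beta()
    y = X @ beta
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    cols = [f"feature_{j + 1}" for j in range(spec.n_features)]
    idx = [f"sample_{i + 1}" for i in range(spec.n_samples)]
    return (
        pd.DataFrame(X, columns=cols, index=idx),
        pd.Series(y, index=idx, name="response"),
        beta,
    )
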