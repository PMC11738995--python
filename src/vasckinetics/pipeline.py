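"""Run configuration, end-to-end orchestration and the report schema.

A :class:`RunConfig` is validated before any stage runs; units are declared
(µm / hours / degrees) and never inferred. :func:`run_pipeline` executes
simulate → classify → count / cell-cycle / polarity and emits a single JSON
report stamped with the config hash and seed; with fixed config the report
is byte-identical across runs (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import cellcycle, morphometry, polarity, synthetic_data
from .synthetic_data import CycleSimParams, PulseSchedule, SceneParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "run_pipeline", "config_hash"]

UNITS = {"length": "um", "time": "hours", "angle": "degrees"}


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    edu_window: tuple[float, float] = (0.0, 6.0)
    brdu_window: tuple[float, float] = (6.0, 8.0)
    t_i: float = 6.0


class CycleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_cycle: float = 26.6
    t_s: float = 10.0
    growth_fraction: float = 0.8
    n_cells: int = 20000
    s_phase_start: float | None = None


class SceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    volume_shape: tuple[int, int, int] = (40, 192, 192)
    voxel_spacing: tuple[float, float, float] = (2.0, 0.5, 0.5)
    vessel_radius: float = 20.0
    n_inside: int = 10
    n_outside: int = 10
    golgi_offset: float = 6.0
    mu_deg: float = 0.0
    kappa: float = 2.0
    nucleus_radius: float = 3.0
    golgi_radius: float = 1.5
    min_separation: float = 16.0


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_dist_um: float = 5.0
    tolerance_um: float = 0.0


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run. ``seed`` is required."""

    model_config = ConfigDict(extra="forbid")
    seed: int
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    cycle: CycleConfig = Field(default_factory=CycleConfig)
    scene: SceneConfig = Field(default_factory=SceneConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    n_bins: int = 24
    n_boot: int = 500
    units: dict[str, str] = Field(default_factory=lambda: dict(UNITS))

    @field_validator("units")
    @classmethod
    def _check_units(cls, v):
        if v != UNITS:
            raise ValueError(f"units must declare {UNITS}, got {v}")
        return v


class CellCycleReport(BaseModel):
    t_s_hours: float
    t_c_hours: float
    growth_fraction: float
    ci_95: dict[str, list[float]]
    n_boot: int
    n_failed_replicates: int
    counts: dict[str, float]
    ground_truth: dict[str, float]


class MorphometryReport(BaseModel):
    n_inside: int
    n_outside: int
    n_unassigned: int
    n_total: int
    classification_accuracy: float


class PolarityReport(BaseModel):
    bin_edges_deg: list[float]
    counts: list[int]
    n_included: int
    n_excluded: int
    n_unmatched_nuclei: int
    n_unmatched_golgi: int
    circular_mean_deg: float
    resultant_length: float
    rayleigh_p: float
    mu_deg_truth: float


class Report(BaseModel):
    """Schema every pipeline report JSON validates against."""

    config_hash: str
    seed: int
    units: dict[str, str]
    cellcycle: CellCycleReport
    morphometry: MorphometryReport
    polarity: PolarityReport


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig, out_path: str | Path | None = None) -> Report:
    """Execute every stage on synthetic inputs defined by ``config``.

    Stage errors propagate with their typed exception; on success the report
    aggregates cell-cycle estimates (with ground truth for comparison),
    compartment counts with classification accuracy, and the polarity
    summary. If ``out_path`` is given, the validated report is written as
    deterministic (sorted-keys) JSON.
    """
    seeds = _sub_seeds(config.seed, 3)

    # --- cell cycle: simulate a dual-pulse experiment and invert it
    params = CycleSimParams(
        t_cycle=config.cycle.t_cycle,
        t_s=config.cycle.t_s,
        growth_fraction=config.cycle.growth_fraction,
        n_cells=config.cycle.n_cells,
        s_phase_start=config.cycle.s_phase_start,
        seed=seeds[0],
    )
    schedule = PulseSchedule(**config.schedule.model_dump())
    table, counts, truth = synthetic_data.simulate_pulse_labeling(params, schedule)
    est = cellcycle.bootstrap_estimates(
        table, t_i=schedule.t_i, n_boot=config.n_boot, seed=seeds[1]
    )
    cc_report = CellCycleReport(
        t_s_hours=est.t_s,
        t_c_hours=est.t_c,
        growth_fraction=est.gf,
        ci_95={k: list(v) for k, v in est.ci.items()},
        n_boot=est.n_boot,
        n_failed_replicates=est.n_failed_replicates,
        counts={
            "p_cells": counts.p_cells,
            "s_cells": counts.s_cells,
            "l_cells": counts.l_cells,
            "ki67_pos": counts.ki67_pos,
            "t_i": counts.t_i,
        },
        ground_truth={
            "t_cycle": params.t_cycle,
            "t_s": params.t_s,
            "growth_fraction": params.growth_fraction,
        },
    )

    # --- scene: classify compartments and count
    scene_params = SceneParams(**config.scene.model_dump(), seed=seeds[2])
    nuclei_mask, golgi_mask, vessel_mask, scene_truth = synthetic_data.generate_vessel_scene(
        scene_params
    )
    cells = scene_truth.cells.rename(columns={"compartment": "compartment_truth"})
    classified = morphometry.classify_compartment(
        cells, vessel_mask, tolerance_um=config.thresholds.tolerance_um
    )
    pop = morphometry.count_population(classified)
    accuracy = float(
        np.mean(classified["compartment"].to_numpy() == cells["compartment_truth"].to_numpy())
    )
    morph_report = MorphometryReport(
        n_inside=pop.n_inside,
        n_outside=pop.n_outside,
        n_unassigned=pop.n_unassigned,
        n_total=pop.n_total,
        classification_accuracy=accuracy,
    )

    # --- polarity: masks -> angular distribution
    pairing, dist = polarity.polarity_pipeline(
        nuclei_mask,
        golgi_mask,
        max_dist=config.thresholds.max_dist_um,
        n_bins=config.n_bins,
    )
    pol_report = PolarityReport(
        **dist.to_dict(),
        n_unmatched_nuclei=len(pairing.unmatched_nuclei),
        n_unmatched_golgi=len(pairing.unmatched_golgi),
        mu_deg_truth=scene_params.mu_deg,
    )

    report = Report(
        config_hash=config_hash(config),
        seed=config.seed,
        units=dict(UNITS),
        cellcycle=cc_report,
        morphometry=morph_report,
        polarity=pol_report,
    )
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(report.model_dump(), sort_keys=True, indent=2) + "\n"
        )
    return report
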