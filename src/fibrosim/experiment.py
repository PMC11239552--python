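"""Experiment planning and orchestration.

The full study crosses 20 GRF samples x 4 length scales (1.25, 2.5, 5.0,
10.0 mm) x 6 coupling models = 480 simulations, plus one uniform-diffusion
baseline run used to reference activation delay and APD differences.  The 80
structural samples (GRF seeds) are shared across the six models, so model
effects can be compared sample by sample; removal seeds additionally depend
on the model name so the three ``-random`` variants draw independent masks.

Seeds derive from a master seed through ``numpy.random.SeedSequence``, which
makes every run reproducible in isolation and collision-free across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import MODEL_NAMES, NodeClass, TissueModel, build_smooth_d, build_tissue_model
from .grf import CirculantEmbedding
from .grid import DEFAULT_SHEET, GridSpec
from .pacing import PacingProtocol
from .postprocess import (
    beat_windows_from_events,
    classify_reentry,
    compute_lat_apd,
    dispersion_stats,
)
from .scar import D_MAX_DEFAULT, DiffusionField, ScarGeometry, make_scar_diffusion_field
from .solver import NumericsConfig, simulate

__all__ = [
    "LENGTH_SCALES_MM",
    "ExperimentPlan",
    "RunConfig",
    "enumerate_runs",
    "build_run_model",
    "make_strip_fixture",
    "run_experiment",
]

LENGTH_SCALES_MM = (1.25, 2.5, 5.0, 10.0)


@dataclass(frozen=True)
class RunConfig:
    """One simulation of the experiment grid (or the uniform baseline)."""

    run_id: str
    length_scale: float | None
    sample_index: int | None  # 0-based within a length scale
    model_name: str | None
    grf_seed: int | None
    removal_seed: int | None
    baseline: bool = False


@dataclass(frozen=True)
class ExperimentPlan:
    """The sample/scale/model grid and its master seed."""

    n_samples_per_scale: int = 20
    length_scales: tuple[float, ...] = LENGTH_SCALES_MM
    models: tuple[str, ...] = MODEL_NAMES
    master_seed: int = 20240628
    grid: GridSpec = DEFAULT_SHEET

    @property
    def n_runs(self) -> int:
        return self.n_samples_per_scale * len(self.length_scales) * len(self.models)

    def grf_seed(self, scale_index: int, sample_index: int) -> int:
        """GRF seed shared by all six models of one structural sample."""
        ss = np.random.SeedSequence(
            [self.master_seed, 101, scale_index, sample_index]
        )
        return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)

    def removal_seed(self, scale_index: int, sample_index: int, model_name: str) -> int:
        ss = np.random.SeedSequence(
            [self.master_seed, 202, scale_index, sample_index, MODEL_NAMES.index(model_name)]
        )
        return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def enumerate_runs(plan: ExperimentPlan, include_baseline: bool = True) -> list[RunConfig]:
    """Ordered run configurations; 480 for the default plan plus a baseline."""
    runs: list[RunConfig] = []
    if include_baseline:
        runs.append(
            RunConfig(
                run_id="baseline-uniform",
                length_scale=None, sample_index=None, model_name=None,
                grf_seed=None, removal_seed=None, baseline=True,
            )
        )
    for (si, scale), sample, model in itertools.product(
        enumerate(plan.length_scales), range(plan.n_samples_per_scale), plan.models
    ):
        grf_seed = plan.grf_seed(si, sample)
        removal = (
            plan.removal_seed(si, sample, model) if model.endswith("-random") else None
        )
        runs.append(
            RunConfig(
                run_id=f"l{scale:g}-s{sample:02d}-{model}",
                length_scale=scale,
                sample_index=sample,
                model_name=model,
                grf_seed=grf_seed,
                removal_seed=removal,
            )
        )
    seeds = [(r.grf_seed, r.removal_seed, r.model_name) for r in runs if not r.baseline]
    if len(set(seeds)) != len(seeds):
        raise RuntimeError("seed derivation produced colliding run configurations")
    return runs


def build_run_model(
    cfg: RunConfig,
    plan: ExperimentPlan,
    geometry: ScarGeometry | None = None,
    embedding: CirculantEmbedding | None = None,
) -> TissueModel:
    """Construct the tissue model for one run configuration."""
    grid = plan.grid
    if cfg.baseline:
        uniform = DiffusionField(np.full(grid.shape, D_MAX_DEFAULT), grid)
        return build_smooth_d(uniform)
    emb = embedding or CirculantEmbedding(grid, cfg.length_scale)
    sample = emb.sample(cfg.grf_seed)
    smooth = make_scar_diffusion_field(sample, geometry)
    return build_tissue_model(smooth, cfg.model_name, cfg.removal_seed)


def default_strip_profile(x: float) -> float:
    """Thin-strip diffusion profile: 0.1 at the paced end, smooth logistic
    descent through the 0.025 excitability threshold (at ~18.5 mm) onto a
    0.024 mm^2/ms plateau at the far end.  The sub-threshold tail is where
    the coupling models diverge: ThresholdD and SmoothD seal it off
    (inexcitable, uncoupled), while ContinuousD keeps it diffusively coupled
    as a passive current sink that can block premature beats."""
    return 0.024 + 0.076 / (1.0 + np.exp((x - 15.0) / 0.8))


def make_strip_fixture(
    profile,
    model_name: str = "SmoothD",
    length: float = 25.0,
    width: float = 4.0,
    dx: float = 0.25,
    removal_seed: int | None = None,
) -> TissueModel:
    """Thin tissue strip with D varying along its length only.

    ``profile`` is either a callable D(x_mm) or an array of per-column values
    in [0, 0.1]; the same profile fills every row, and any of the coupling
    models can then be applied to it.
    """
    grid = GridSpec.from_extent(length, width, dx)
    if callable(profile):
        d_line = np.asarray([profile(x) for x in grid.x_coords()], dtype=float)
    else:
        d_line = np.asarray(profile, dtype=float)
        if d_line.shape != (grid.nx,):
            raise ValueError(f"profile must have {grid.nx} values")
    if d_line.min() < 0 or d_line.max() > D_MAX_DEFAULT + 1e-12:
        raise ValueError("profile values must lie in [0, 0.1]")
    smooth = DiffusionField(np.tile(d_line, (grid.ny, 1)), grid)
    return build_tissue_model(smooth, model_name, removal_seed)


def _summary_row(cfg: RunConfig, rec, controller_events, geometry, grid) -> dict:
    from .pacing import PacingProtocol  # noqa: F401  (doc cross-ref)

    outcome, n_early, n_late = (None, None, None)
    end = float(rec.times[-1])
    if end >= 3000.0 - 1e-6:
        outcome, n_early, n_late = classify_reentry(rec)
    s2 = [t for t, lbl in rec.stim_events if lbl == "S2"]
    all_times = [t for t, _ in rec.stim_events]
    couplings = [b - a for a, b in zip(all_times, all_times[1:])][
        max(0, len(all_times) - len(s2) - 1):
    ]
    row = {
        "run_id": cfg.run_id,
        "length_scale_mm": cfg.length_scale,
        "sample_index": cfg.sample_index,
        "model_name": cfg.model_name or "uniform",
        "grf_seed": cfg.grf_seed,
        "removal_seed": cfg.removal_seed,
        "n_stimuli": len(rec.stim_events),
        "coupling_intervals_ms": ";".join(f"{c:.2f}" for c in couplings),
        "outcome": outcome.value if outcome is not None else "",
        "wavefronts_2600ms": n_early,
        "wavefronts_3000ms": n_late,
    }
    return row


def run_experiment(
    plan: ExperimentPlan,
    numerics: NumericsConfig,
    protocol: PacingProtocol,
    output_dir,
    geometry: ScarGeometry | None = None,
    length_scales: tuple[float, ...] | None = None,
    models: tuple[str, ...] | None = None,
    samples: tuple[int, ...] | None = None,
    include_baseline: bool = True,
    save_recordings: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute (a filtered subset of) the experiment grid; resumable.

    One summary CSV row per executed run is appended to ``summary.csv`` in
    ``output_dir``; runs whose id already appears there are skipped, so an
    interrupted experiment can simply be restarted.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    summary_path = output_dir / "summary.csv"
    done: set[str] = set()
    if summary_path.exists():
        done = set(pd.read_csv(summary_path)["run_id"].astype(str))

    runs = enumerate_runs(plan, include_baseline=include_baseline)
    selected = []
    for cfg in runs:
        if cfg.baseline:
            selected.append(cfg)
            continue
        if length_scales is not None and cfg.length_scale not in length_scales:
            continue
        if models is not None and cfg.model_name not in models:
            continue
        if samples is not None and cfg.sample_index not in samples:
            continue
        selected.append(cfg)

    embeddings: dict[float, CirculantEmbedding] = {}
    rows = []
    for cfg in selected:
        if cfg.run_id in done:
            continue
        if not cfg.baseline and cfg.length_scale not in embeddings:
            embeddings[cfg.length_scale] = CirculantEmbedding(
                plan.grid, cfg.length_scale
            )
        if progress:
            print(f"running {cfg.run_id}", flush=True)
        model = build_run_model(
            cfg, plan, geometry, embeddings.get(cfg.length_scale)
        )
        rec = simulate(
            model,
            protocol,
            numerics,
            metadata={"run_id": cfg.run_id, "master_seed": plan.master_seed},
        )
        if save_recordings:
            from .io import save_recording

            save_recording(output_dir / f"{cfg.run_id}.h5", rec)
        row = _summary_row(cfg, rec, rec.stim_events, geometry, plan.grid)
        rows.append(row)
        df_one = pd.DataFrame([row])
        header = not summary_path.exists()
        df_one.to_csv(summary_path, mode="a", header=header, index=False)
        done.add(cfg.run_id)

    return pd.read_csv(summary_path) if summary_path.exists() else pd.DataFrame(rows)
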