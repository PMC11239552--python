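"""HDF5 and CSV persistence for fields, tissue models, and recordings."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .coupling import TissueModel
from .grid import GridSpec
from .scar import DiffusionField
from .solver import VoltageRecording

__all__ = [
    "save_field",
    "load_field",
    "save_tissue_model",
    "load_tissue_model",
    "save_recording",
    "load_recording",
    "field_to_csv",
]


def _write_grid(g: h5py.Group, grid: GridSpec) -> None:
    g.attrs["nx"] = grid.nx
    g.attrs["ny"] = grid.ny
    g.attrs["dx"] = grid.dx


def _read_grid(g: h5py.Group) -> GridSpec:
    return GridSpec(nx=int(g.attrs["nx"]), ny=int(g.attrs["ny"]), dx=float(g.attrs["dx"]))


def save_field(path, field: DiffusionField, **attrs) -> None:
    """Write a 2D field with grid metadata and free-form scalar attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=field.values, compression="gzip")
        _write_grid(f, field.grid)
        for k, v in attrs.items():
            f.attrs[k] = v


def load_field(path) -> tuple[DiffusionField, dict]:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        values = f["values"][...]
        attrs = {k: f.attrs[k] for k in f.attrs if k not in ("nx", "ny", "dx")}
    return DiffusionField(values, grid), attrs


def save_tissue_model(path, model: TissueModel, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("diffusion", data=model.diffusion.values, compression="gzip")
        f.create_dataset("classes", data=model.classes, compression="gzip")
        f.create_dataset(
            "smooth_source", data=model.smooth_source.values, compression="gzip"
        )
        _write_grid(f, model.grid)
        f.attrs["model_name"] = model.model_name
        if model.removal_seed is not None:
            f.attrs["removal_seed"] = model.removal_seed
        for k, v in attrs.items():
            f.attrs[k] = v


def load_tissue_model(path) -> TissueModel:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        model = TissueModel(
            model_name=str(f.attrs["model_name"]),
            diffusion=DiffusionField(f["diffusion"][...], grid),
            classes=f["classes"][...].astype(np.int8),
            smooth_source=DiffusionField(f["smooth_source"][...], grid),
            removal_seed=(
                int(f.attrs["removal_seed"]) if "removal_seed" in f.attrs else None
            ),
        )
    return model


def save_recording(path, rec: VoltageRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=rec.times)
        f.create_dataset("frames", data=rec.frames, compression="gzip", shuffle=True)
        if rec.stim_events:
            f.create_dataset(
                "stim_times", data=np.array([t for t, _ in rec.stim_events])
            )
            f.create_dataset(
                "stim_labels",
                data=np.array([lbl for _, lbl in rec.stim_events], dtype="S4"),
            )
        _write_grid(f, rec.grid)
        f.attrs["metadata_json"] = json.dumps(rec.metadata)


def load_recording(path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        events = []
        if "stim_times" in f:
            events = [
                (float(t), lbl.decode())
                for t, lbl in zip(f["stim_times"][...], f["stim_labels"][...])
            ]
        rec = VoltageRecording(
            times=f["times"][...],
            frames=f["frames"][...],
            stim_events=events,
            grid=grid,
            metadata=json.loads(f.attrs["metadata_json"]),
        )
    return rec


def field_to_csv(path, field: DiffusionField | np.ndarray, grid: GridSpec | None = None) -> None:
    """Export a small field as (x_mm, y_mm, value) rows."""
    if isinstance(field, DiffusionField):
        values, grid = field.values, field.grid
    else:
        values = np.asarray(field)
        if grid is None:
            raise ValueError("grid required for a bare array")
    x, y = grid.meshgrid()
    table = np.column_stack([x.ravel(), y.ravel(), values.ravel()])
    np.savetxt(path, table, delimiter=",", header="x_mm,y_mm,value", comments="")
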