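"""Explicit finite-difference monodomain solver on heterogeneous 2D tissue.

The transmembrane voltage obeys

    dV/dt = div( D(x, y) grad V ) - I_ion / C_m,

discretised with a conservative five-point flux-form stencil (arithmetic mean
face diffusivities), forward Euler for the diffusion term (0.05 ms step at
0.25 mm spacing; stable up to dx^2 / (4 D_max) = 0.156 ms), and the adaptive
Rush-Larsen reaction integrator of :mod:`fibrosim.cell`.  The sheet edges are
no-flux; faces touching an uncoupled node carry no flux either, so uncoupled
scar islands are electrically silent.  Coupled-but-inexcitable nodes have
I_ion fixed to zero: their voltage evolves by diffusion (and stimulus) alone
from a resting value of -86.2 mV.

Operator splitting runs the reaction substeps first, then one diffusion step
per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import kernel as _kernel
from .cell import tables as _tables
from .cell.tnnp2006 import (
    DT_REACTION_MAX,
    DT_REACTION_MIN,
    initial_state,
)
from .coupling import RESTING_POTENTIAL_MV, NodeClass, TissueModel
from .grid import GridSpec
from .pacing import PacingController, PacingProtocol

__all__ = [
    "NumericsConfig",
    "VoltageRecording",
    "Simulation",
    "face_diffusivity",
    "diffusion_operator",
    "simulate",
]


@dataclass(frozen=True)
class NumericsConfig:
    """Space/time discretisation parameters.

    ``dx`` must match the tissue model grid.  The explicit diffusion step is
    stable for ``dt_diffusion <= dx^2 / (4 D_max)``.
    """

    dx: float = 0.25  # mm
    dt_diffusion: float = 0.05  # ms
    dt_reaction_min: float = DT_REACTION_MIN  # ms
    dt_reaction_max: float = DT_REACTION_MAX  # ms
    duration: float = 3000.0  # ms
    record_interval: float = 1.0  # ms

    def validate(self, d_max: float = 0.1) -> None:
        if self.dt_diffusion > self.dx**2 / (4.0 * d_max) + 1e-12:
            raise ValueError(
                f"unstable diffusion step: dt={self.dt_diffusion} > "
                f"dx^2/(4 D_max)={self.dx ** 2 / (4 * d_max):.5f}"
            )
        if not 0 < self.dt_reaction_min <= self.dt_reaction_max:
            raise ValueError("need 0 < dt_reaction_min <= dt_reaction_max")
        if self.record_interval < self.dt_diffusion:
            raise ValueError("record_interval must be >= dt_diffusion")


@dataclass
class VoltageRecording:
    """Time-stamped voltage snapshots plus the stimulus-event log."""

    times: np.ndarray  # (n_frames,), ms
    frames: np.ndarray  # (n_frames, ny, nx), mV, float32
    stim_events: list[tuple[float, str]]
    grid: GridSpec
    metadata: dict = field(default_factory=dict)

    def frame_at(self, t: float) -> np.ndarray:
        """Frame nearest to time ``t`` (must be within half a frame step)."""
        i = int(np.argmin(np.abs(self.times - t)))
        dt_frame = self.times[1] - self.times[0] if len(self.times) > 1 else 0.0
        if abs(self.times[i] - t) > dt_frame / 2 + 1e-9:
            raise ValueError(f"recording does not cover t = {t} ms")
        return self.frames[i]

    def trace(self, iy: int, ix: int) -> tuple[np.ndarray, np.ndarray]:
        """(t, V) series at one node."""
        return self.times, self.frames[:, iy, ix].astype(float)


def face_diffusivity(d_i: float, d_j: float, class_i: int, class_j: int) -> float:
    """Diffusivity assigned to the face between two neighbouring nodes.

    Zero if either node is uncoupled (internal no-flux boundary); otherwise
    the arithmetic mean.  Coupled-but-inexcitable nodes participate fully.
    """
    if class_i == NodeClass.UNCOUPLED or class_j == NodeClass.UNCOUPLED:
        return 0.0
    return 0.5 * (d_i + d_j)


def _face_arrays(model: TissueModel) -> tuple[np.ndarray, np.ndarray]:
    """Face diffusivities: Gx (ny, nx-1) for vertical faces, Gy (ny-1, nx)."""
    d = model.diffusion.values
    unc = model.classes == NodeClass.UNCOUPLED
    gx = 0.5 * (d[:, :-1] + d[:, 1:])
    gx[unc[:, :-1] | unc[:, 1:]] = 0.0
    gy = 0.5 * (d[:-1, :] + d[1:, :])
    gy[unc[:-1, :] | unc[1:, :]] = 0.0
    return gx, gy


def diffusion_operator(
    v: np.ndarray, model: TissueModel, dx: float | None = None
) -> np.ndarray:
    """Flux-form five-point stencil: dV/dt contribution of diffusion (mV/ms).

    External boundary faces and faces of uncoupled nodes carry no flux, so
    the sheet total of the returned field telescopes to zero.
    """
    if v.shape != model.grid.shape:
        raise ValueError("voltage field shape does not match the tissue grid")
    dx = dx if dx is not None else model.grid.dx
    gx, gy = _face_arrays(model)
    out = np.zeros_like(v, dtype=float)
    flux = gx * (v[:, 1:] - v[:, :-1])
    out[:, :-1] += flux
    out[:, 1:] -= flux
    flux = gy * (v[1:, :] - v[:-1, :])
    out[:-1, :] += flux
    out[1:, :] -= flux
    out /= dx * dx
    return out


class Simulation:
    """Mutable simulation state for one tissue model.

    Splits the work per 0.05 ms cycle into (i) reaction substeps at every
    normal node (lookup-table TNNP06 kernel), (ii) stimulus on inexcitable
    coupled nodes if the pacing disc overlaps them, and (iii) one explicit
    diffusion step over all coupled nodes.
    """

    def __init__(self, model: TissueModel, numerics: NumericsConfig):
        model.validate()
        numerics.validate(d_max=max(model.diffusion.values.max(), 1e-12))
        if abs(numerics.dx - model.grid.dx) > 1e-12:
            raise ValueError("numerics.dx does not match the model grid")
        self.model = model
        self.numerics = numerics
        self.grid = model.grid
        self.t = 0.0

        rest = initial_state()
        self.v = np.full(self.grid.shape, RESTING_POTENTIAL_MV)
        # normal nodes start at the cell model's own quiescent voltage
        normal = model.classes == NodeClass.NORMAL
        self.v[normal] = rest[0]
        self._normal_ids = np.flatnonzero(normal.ravel()).astype(np.int64)
        self._states = _kernel.make_states(self._normal_ids.size, rest)
        self._coupled_inexcitable = model.classes == NodeClass.COUPLED_INEXCITABLE

        self._gx, self._gy = _face_arrays(model)
        self._dt_slow = min(numerics.dt_reaction_max, numerics.dt_diffusion)
        self._tab = _tables.build_rate_tables(numerics.dt_reaction_min, self._dt_slow)
        self._istim = np.zeros(self.grid.n_nodes)

    def advance(self, stim_amp: float = 0.0, stim_mask: np.ndarray | None = None) -> None:
        """One full cycle: reaction substeps, stimulus, one diffusion step."""
        dt = self.numerics.dt_diffusion
        v_flat = self.v.ravel()

        self._istim[:] = 0.0
        if stim_amp != 0.0 and stim_mask is not None:
            self._istim[stim_mask.ravel()] = stim_amp

        tab = self._tab
        bad = _kernel.reaction_step(
            v_flat,
            self._states,
            self._normal_ids,
            self._istim,
            dt,
            self.numerics.dt_reaction_max,
            tab.table,
            tab.v_min,
            tab.inv_dv,
            tab.k1_table,
            tab.uk_min,
            tab.inv_duk,
            self.numerics.dt_reaction_min,
            self._dt_slow,
        )
        if bad >= 0:
            iy, ix = divmod(int(bad), self.grid.nx)
            raise FloatingPointError(
                f"voltage diverged at node (ix={ix}, iy={iy}) near t={self.t:.2f} ms"
            )

        if stim_amp != 0.0 and stim_mask is not None:
            # inexcitable coupled nodes still receive the stimulus current
            ci_stim = stim_mask & self._coupled_inexcitable
            if ci_stim.any():
                self.v[ci_stim] += dt * (-stim_amp)

        # explicit diffusion step (uncoupled nodes see only zero-flux faces)
        flux = self._gx * (self.v[:, 1:] - self.v[:, :-1])
        lap = np.zeros_like(self.v)
        lap[:, :-1] += flux
        lap[:, 1:] -= flux
        flux = self._gy * (self.v[1:, :] - self.v[:-1, :])
        lap[:-1, :] += flux
        lap[1:, :] -= flux
        self.v += (dt / self.grid.dx**2) * lap
        self.t += dt

    def run(
        self,
        protocol: PacingProtocol | None,
        metadata: dict | None = None,
        progress: bool = False,
    ) -> VoltageRecording:
        """Run the pacing protocol for the configured duration and record."""
        num = self.numerics
        controller = (
            PacingController(protocol, self.grid) if protocol is not None else None
        )
        n_steps = int(round(num.duration / num.dt_diffusion))
        rec_stride = int(round(num.record_interval / num.dt_diffusion))
        n_frames = n_steps // rec_stride + 1
        frames = np.empty((n_frames, *self.grid.shape), dtype=np.float32)
        times = np.empty(n_frames)
        frames[0] = self.v
        times[0] = self.t

        for i in range(n_steps):
            if controller is not None:
                amp = controller.update(self.t, self.v)
                self.advance(amp, controller.mask)
            else:
                self.advance()
            if (i + 1) % rec_stride == 0:
                k = (i + 1) // rec_stride
                frames[k] = self.v
                times[k] = self.t
            if progress and (i + 1) % (n_steps // 20 or 1) == 0:
                print(f"  t = {self.t:8.1f} ms", flush=True)

        meta = {
            "model_name": self.model.model_name,
            "duration_ms": num.duration,
            "dx_mm": num.dx,
            "dt_diffusion_ms": num.dt_diffusion,
            "record_interval_ms": num.record_interval,
        }
        if metadata:
            meta.update(metadata)
        events = controller.events if controller is not None else []
        return VoltageRecording(
            times=times, frames=frames, stim_events=list(events),
            grid=self.grid, metadata=meta,
        )


def simulate(
    model: TissueModel,
    protocol: PacingProtocol | None,
    numerics: NumericsConfig,
    metadata: dict | None = None,
    progress: bool = False,
) -> VoltageRecording:
    """Run one complete simulation; deterministic for a given configuration."""
    return Simulation(model, numerics).run(protocol, metadata, progress)
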