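"""Functional models of coupling between normal tissue, border zone, and scar.

Six tissue models turn the smooth, clipped scar diffusion field D(x, y) into a
simulation-ready substrate.  Each node gets a diffusion value and one of three
classes:

* ``NORMAL`` — excitable, coupled myocardium.
* ``UNCOUPLED`` — inexcitable and electrically isolated (no-flux island); its
  voltage never changes.
* ``COUPLED_INEXCITABLE`` — the membrane current is fixed to zero but diffusion
  is retained, so the node loads its neighbours electrotonically.  Such nodes
  rest at -86.2 mV, matching the resting potential of surrounding tissue.

Base models (threshold at 0.025 mm^2/ms applied with the printed inequalities):

* ``ThresholdD`` — binary: D > 0.025 becomes fully coupled at 0.1; the rest is
  uncoupled with D = 0.
* ``SmoothD`` — D kept where >= 0.025, zeroed (and uncoupled) below.
* ``ContinuousD`` — D kept everywhere; nodes with D < 0.025 become coupled but
  inexcitable.

The ``-random`` variants additionally remove grid points around the edge of
the excitable region (a percolation-style model of diffuse fibrosis): a node
is removed when a uniform draw exceeds 20 * D, i.e. with probability
``max(0, 1 - 20 D)`` — zero at D >= 0.05 and rising to 0.5 at the 0.025 edge.
The probability is evaluated on the smooth pre-model field for every variant,
because the binary ThresholdD field would make it degenerate.  Removed nodes
become uncoupled (Threshold/Smooth) or coupled-inexcitable (Continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

from .grid import GridSpec
from .scar import D_MAX_DEFAULT, DiffusionField

__all__ = [
    "NodeClass",
    "TissueModel",
    "MODEL_NAMES",
    "D_THRESHOLD",
    "RESTING_POTENTIAL_MV",
    "build_threshold_d",
    "build_smooth_d",
    "build_continuous_d",
    "removal_probability",
    "apply_random_removal",
    "build_tissue_model",
]

D_THRESHOLD = 0.025  # mm^2/ms, excitability / coupling threshold
REMOVAL_SLOPE = 20.0  # 1/(mm^2/ms): P(remove) = max(0, 1 - 20 D)
RESTING_POTENTIAL_MV = -86.2

MODEL_NAMES = (
    "ThresholdD",
    "SmoothD",
    "ContinuousD",
    "ThresholdD-random",
    "SmoothD-random",
    "ContinuousD-random",
)


class NodeClass(IntEnum):
    NORMAL = 0
    UNCOUPLED = 1
    COUPLED_INEXCITABLE = 2


@dataclass(frozen=True)
class TissueModel:
    """A diffusion field plus per-node classes, ready to simulate."""

    model_name: str
    diffusion: DiffusionField
    classes: np.ndarray  # int8 array of NodeClass codes, shape (ny, nx)
    smooth_source: DiffusionField  # pre-model smooth field (removal probabilities)
    removal_seed: int | None = None

    def __post_init__(self) -> None:
        if self.classes.shape != self.grid.shape:
            raise ValueError("classes shape does not match grid")
        if self.diffusion.values.shape != self.grid.shape:
            raise ValueError("diffusion shape does not match grid")

    @property
    def grid(self) -> GridSpec:
        return self.diffusion.grid

    def validate(self) -> None:
        """Check the class/diffusion consistency invariants."""
        d = self.diffusion.values
        c = self.classes
        if np.any(d[c == NodeClass.UNCOUPLED] != 0.0):
            raise AssertionError("UNCOUPLED node with nonzero diffusion")
        if d.min() < 0 or d.max() > D_MAX_DEFAULT + 1e-12:
            raise AssertionError("diffusion outside [0, D_max]")


def _require_smooth(smooth: DiffusionField) -> np.ndarray:
    d = smooth.values
    if d.min() < 0 or d.max() > D_MAX_DEFAULT + 1e-12:
        raise ValueError("expected a clipped smooth field in [0, 0.1]")
    return d


def build_threshold_d(smooth: DiffusionField) -> TissueModel:
    """Binary model: D > 0.025 -> fully coupled at 0.1, else uncoupled."""
    d = _require_smooth(smooth)
    excitable = d > D_THRESHOLD  # strict: D == 0.025 is removed
    diffusion = np.where(excitable, D_MAX_DEFAULT, 0.0)
    classes = np.where(excitable, NodeClass.NORMAL, NodeClass.UNCOUPLED).astype(np.int8)
    return TissueModel(
        model_name="ThresholdD",
        diffusion=DiffusionField(diffusion, smooth.grid),
        classes=classes,
        smooth_source=smooth,
    )


def build_smooth_d(smooth: DiffusionField) -> TissueModel:
    """Smoothly varying D where >= 0.025; below that, uncoupled with D = 0."""
    d = _require_smooth(smooth)
    excitable = d >= D_THRESHOLD  # strict "<" zeroes only below 0.025
    diffusion = np.where(excitable, d, 0.0)
    classes = np.where(excitable, NodeClass.NORMAL, NodeClass.UNCOUPLED).astype(np.int8)
    return TissueModel(
        model_name="SmoothD",
        diffusion=DiffusionField(diffusion, smooth.grid),
        classes=classes,
        smooth_source=smooth,
    )


def build_continuous_d(smooth: DiffusionField) -> TissueModel:
    """Diffusion retained everywhere; D < 0.025 is coupled but inexcitable."""
    d = _require_smooth(smooth)
    inexcitable = d < D_THRESHOLD
    classes = np.where(
        inexcitable, NodeClass.COUPLED_INEXCITABLE, NodeClass.NORMAL
    ).astype(np.int8)
    return TissueModel(
        model_name="ContinuousD",
        diffusion=DiffusionField(d.copy(), smooth.grid),
        classes=classes,
        smooth_source=smooth,
    )


def removal_probability(smooth_value):
    """P(remove) = max(0, 1 - 20 D): 0.5 at D = 0.025, zero at D >= 0.05."""
    d = np.asarray(smooth_value, dtype=float)
    if np.any(d < 0):
        raise ValueError("diffusion value must be non-negative")
    p = np.clip(1.0 - REMOVAL_SLOPE * d, 0.0, 1.0)
    return p if p.ndim else float(p)


def apply_random_removal(model: TissueModel, seed: int) -> TissueModel:
    """Percolation-style removal of nodes near the edge of the excitable region.

    Each node draws an independent uniform number; it is removed when the draw
    exceeds 20 times the smooth pre-model diffusion value.  For Threshold/
    Smooth variants removed nodes become uncoupled with D = 0; for the
    Continuous variant they become coupled-inexcitable and keep their D.
    Deterministic for a given seed.
    """
    if model.model_name.endswith("-random"):
        raise ValueError("random removal already applied")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=model.grid.shape)
    removed = u > REMOVAL_SLOPE * model.smooth_source.values

    diffusion = model.diffusion.values.copy()
    classes = model.classes.copy()
    if model.model_name == "ContinuousD":
        classes[removed] = NodeClass.COUPLED_INEXCITABLE
    else:
        diffusion[removed] = 0.0
        classes[removed] = NodeClass.UNCOUPLED
    return replace(
        model,
        model_name=model.model_name + "-random",
        diffusion=DiffusionField(diffusion, model.grid),
        classes=classes,
        removal_seed=int(seed),
    )


_BASE_BUILDERS = {
    "ThresholdD": build_threshold_d,
    "SmoothD": build_smooth_d,
    "ContinuousD": build_continuous_d,
}


def build_tissue_model(
    smooth: DiffusionField, model_name: str, removal_seed: int | None = None
) -> TissueModel:
    """Build any of the six named tissue models from the smooth scar field."""
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    base_name = model_name.removesuffix("-random")
    model = _BASE_BUILDERS[base_name](smooth)
    if model_name.endswith("-random"):
        if removal_seed is None:
            raise ValueError(f"{model_name} requires a removal_seed")
        model = apply_random_removal(model, removal_seed)
    return model
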