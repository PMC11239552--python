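"""Two-lobe scar diffusion fields.

The raw GRF is mapped affinely onto a diffusion coefficient field

    D_GRF(x, y) = D_max * (GRF(x, y) + 2) / 4,

which predominantly spans [0, D_max] because the GRF has mean 0 and unit
standard deviation.  Two circular scar lobes on the sheet diagonal (centres at
one-third and two-thirds of the sheet width) are then superposed with logistic
(sigmoid) radial weightings: inside the infarct radius both the uniform D_max
term and the GRF term are suppressed; between infarct and border radius the
GRF term fades in, producing a patchy border zone; far from both lobes the
field tends to D_max + D_GRF before clipping.  The final field is clipped once
to [0, D_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec
from .grf import GRFSample

__all__ = [
    "DiffusionField",
    "ScarGeometry",
    "grf_to_diffusion",
    "scar_weighting",
    "apply_scar_weighting",
    "make_scar_diffusion_field",
    "D_MAX_DEFAULT",
]

D_MAX_DEFAULT = 0.1  # mm^2/ms, upper limit of the diffusion coefficient


@dataclass(frozen=True)
class DiffusionField:
    """Per-node isotropic diffusion coefficient D(x, y) in mm^2/ms."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")


def default_centers(grid: GridSpec) -> tuple[tuple[float, float], tuple[float, float]]:
    """Scar lobe centres on the diagonal at 1/3 and 2/3 of the sheet width."""
    return (
        (grid.width / 3.0, grid.height / 3.0),
        (2.0 * grid.width / 3.0, 2.0 * grid.height / 3.0),
    )


@dataclass(frozen=True)
class ScarGeometry:
    """Geometry and scales of the two-lobe scar.

    Parameters
    ----------
    center1, center2 : (x, y) in mm
        Centres of the two scar lobes.
    r_infarct : float
        Radius of the inexcitable infarct core, mm (default 12.5).
    r_border : float
        Radius of the partially fibrotic border zone, mm (default 30).
    sigmoid_slope : float
        Steepness of the logistic radial transitions, 1/mm (default 0.075).
    d_max : float
        Upper diffusion limit, mm^2/ms (default 0.1).
    """

    center1: tuple[float, float]
    center2: tuple[float, float]
    r_infarct: float = 12.5
    r_border: float = 30.0
    sigmoid_slope: float = 0.075
    d_max: float = D_MAX_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.r_infarct < self.r_border:
            raise ValueError("need 0 < r_infarct < r_border")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")

    @classmethod
    def default_for(cls, grid: GridSpec, **kwargs) -> "ScarGeometry":
        c1, c2 = default_centers(grid)
        return cls(center1=c1, center2=c2, **kwargs)


def grf_to_diffusion(sample: GRFSample, d_max: float = D_MAX_DEFAULT) -> DiffusionField:
    """Affine map of a GRF onto diffusion: ``D = d_max (GRF + 2) / 4``.

    No clipping happens here; values outside [0, d_max] survive until the scar
    superposition has been applied.
    """
    values = d_max * (sample.values + 2.0) / 4.0
    return DiffusionField(values=values, grid=sample.grid)


def scar_weighting(r1, r2, d_grf, geom: ScarGeometry):
    """Scalar/broadcast evaluation of the two-sigmoid scar superposition.

    ``r1``/``r2`` are distances (mm) to the two lobe centres, ``d_grf`` the
    GRF-derived diffusion value.  Returns the unclipped field value.
    """
    s = geom.sigmoid_slope

    def lobe_pair(radius):
        return (1.0 + np.exp(-s * (r1 - radius))) * (1.0 + np.exp(-s * (r2 - radius)))

    return geom.d_max / lobe_pair(geom.r_infarct) + d_grf / lobe_pair(geom.r_border)


def apply_scar_weighting(
    d_grf: DiffusionField, geom: ScarGeometry, grid: GridSpec | None = None
) -> DiffusionField:
    """Superpose the two scar lobes on a GRF diffusion field and clip.

    The result is clipped once, at the end, to [0, d_max]; this is the only
    clipping step in the field construction.
    """
    grid = grid or d_grf.grid
    if d_grf.values.shape != grid.shape:
        raise ValueError("d_grf field does not match grid")
    for c in (geom.center1, geom.center2):
        if not (0 <= c[0] <= grid.width and 0 <= c[1] <= grid.height):
            raise ValueError(f"scar centre {c} lies outside the grid")
    r1 = grid.distance_to(geom.center1)
    r2 = grid.distance_to(geom.center2)
    values = scar_weighting(r1, r2, d_grf.values, geom)
    np.clip(values, 0.0, geom.d_max, out=values)
    return DiffusionField(values=values, grid=grid)


def make_scar_diffusion_field(
    sample: GRFSample, geom: ScarGeometry | None = None
) -> DiffusionField:
    """GRF sample -> clipped two-lobe scar diffusion field (the smooth D)."""
    geom = geom or ScarGeometry.default_for(sample.grid)
    return apply_scar_weighting(grf_to_diffusion(sample, geom.d_max), geom)
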