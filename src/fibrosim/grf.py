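"""Stationary Gaussian random fields by circulant embedding.

The fibrosis texture is a zero-mean, unit-variance Gaussian random field (GRF)
with a squared-exponential covariance

    k(r) = exp(-r^2 / (2 l^2)),

where ``l`` is the characteristic length scale in mm.  Sampling is exact on a
regular grid: the covariance of the grid (restricted to a torus large enough to
kill wrap-around correlation) is diagonalised by the 2D FFT, and a sample is
the real part of the FFT of white complex Gaussian noise scaled by the square
root of the (non-negative) eigenvalue field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2, next_fast_len

from .grid import GridSpec

__all__ = ["GRFSample", "CirculantEmbedding", "squared_exponential_cov", "sample_grf"]

#: Relative tolerance for negative eigenvalues of the embedded circulant.
#: Minimum eigenvalues above ``-EIG_CLAMP_RTOL * max`` are clamped to zero;
#: anything more negative raises, because clamping would distort the covariance.
#: Round-off noise in the FFT of a smooth (near-singular) Gaussian covariance
#: grows with grid size and reaches ~1e-8 of the largest eigenvalue for the
#: longest length scales used here, so the cut sits two decades above that.
EIG_CLAMP_RTOL = 1e-6


def squared_exponential_cov(r, length_scale: float):
    """Squared-exponential covariance ``k(r) = exp(-r^2 / (2 l^2))``.

    Parameters
    ----------
    r : array_like
        Separation distance(s), mm.  Must be non-negative.
    length_scale : float
        Characteristic length scale ``l`` in mm, > 0.
    """
    if length_scale <= 0:
        raise ValueError(f"length_scale must be positive, got {length_scale}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation distance must be non-negative")
    out = np.exp(-(r**2) / (2.0 * length_scale**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GRFSample:
    """One sample of the Gaussian random field on a grid.

    ``values`` has population mean 0 and variance 1 by construction; any one
    sample's empirical mean/std fluctuate around those values because nearby
    nodes are correlated over the length scale.
    """

    values: np.ndarray
    grid: GridSpec
    length_scale: float
    seed: int

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")


class CirculantEmbedding:
    """Factorised sampler for a fixed (grid, length scale) pair.

    The embedding torus is at least twice the grid extent plus five length
    scales per axis, rounded up to an FFT-friendly size, which makes the
    squared-exponential circulant numerically positive semidefinite and
    suppresses wrap-around correlation.  Building the eigenvalue field once
    amortises the setup over repeated draws.
    """

    def __init__(self, grid: GridSpec, length_scale: float):
        if length_scale <= 0:
            raise ValueError(f"length_scale must be positive, got {length_scale}")
        self.grid = grid
        self.length_scale = float(length_scale)

        pad = int(np.ceil(5.0 * length_scale / grid.dx))
        self._mx = next_fast_len(2 * grid.nx + pad)
        self._my = next_fast_len(2 * grid.ny + pad)

        # covariance of the circulant: distances on the embedding torus
        ix = np.minimum(np.arange(self._mx), self._mx - np.arange(self._mx))
        iy = np.minimum(np.arange(self._my), self._my - np.arange(self._my))
        r = np.hypot(iy[:, None] * grid.dx, ix[None, :] * grid.dx)
        cov = squared_exponential_cov(r, length_scale)

        eig = fft2(cov).real
        emin, emax = eig.min(), eig.max()
        if emin < -EIG_CLAMP_RTOL * emax:
            raise ValueError(
                f"embedded circulant is not positive semidefinite "
                f"(min eigenvalue {emin:.3e} vs max {emax:.3e}); enlarge the padding"
            )
        np.clip(eig, 0.0, None, out=eig)
        self._sqrt_eig = np.sqrt(eig)

    @property
    def embedding_shape(self) -> tuple[int, int]:
        return (self._my, self._mx)

    def sample(self, seed: int) -> GRFSample:
        """Draw one field; bit-reproducible for a given seed."""
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((self._my, self._mx)) + 1j * rng.standard_normal(
            (self._my, self._mx)
        )
        spectral = fft2(self._sqrt_eig * noise, norm="ortho")
        values = np.ascontiguousarray(spectral.real[: self.grid.ny, : self.grid.nx])
        return GRFSample(
            values=values, grid=self.grid, length_scale=self.length_scale, seed=int(seed)
        )


def sample_grf(grid: GridSpec, length_scale: float, seed: int) -> GRFSample:
    """Sample one zero-mean, unit-variance GRF with the given length scale."""
    return CirculantEmbedding(grid, length_scale).sample(seed)
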