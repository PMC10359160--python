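"""Diffeomorphic displacement construction and folding diagnostics.

The network's raw 3-channel output is treated as a stationary velocity field
``v`` (mm); its exponential ``exp(v)`` is computed by scaling and squaring:
``u_0 = v / 2^n`` followed by ``n`` self-compositions
``u_{k+1}(p) = u_k(p) + u_k(p + u_k(p))``. For smooth velocities of moderate
magnitude this yields a displacement whose map ``p -> p + u(p)`` has strictly
positive Jacobian determinant everywhere, i.e. no folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import FormatError
from .volumes import BinaryMask, DisplacementField, ScalarVolume, VolumeGrid

__all__ = [
    "VelocityField",
    "integrate_velocity",
    "jacobian_determinant",
    "folding_fraction",
]


@dataclass
class VelocityField:
    """Stationary velocity field (mm) whose exponential is a diffeomorphism."""

    grid: VolumeGrid
    vectors: np.ndarray  # (*grid.shape, 3)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        expected = self.grid.shape + (3,)
        if self.vectors.shape != expected:
            raise FormatError(
                f"vector shape {self.vectors.shape} != expected {expected}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise FormatError("velocity field contains non-finite values")

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "VelocityField":
        return cls(grid, np.zeros(grid.shape + (3,)))


def _compose_step(u: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """One squaring step: u'(p) = u(p) + u(p + u(p)), linear interpolation."""
    idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid.shape],
                      indexing="ij")
    coords = np.stack(
        [idx[a] + u[..., a] / grid.spacing[a] for a in range(3)]
    )
    sampled = np.empty_like(u)
    for c in range(3):
        sampled[..., c] = map_coordinates(u[..., c], coords, order=1,
                                          mode="nearest")
    return u + sampled


def integrate_velocity(v: VelocityField, n_steps: int = 7) -> DisplacementField:
    """Exponentiate a stationary velocity by scaling and squaring."""
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    u = v.vectors / float(2**n_steps)
    for _ in range(n_steps):
        u = _compose_step(u, v.grid)
    return DisplacementField(v.grid, u)


def _displacement_gradient(dvf: DisplacementField) -> np.ndarray:
    """∂u_i/∂x_j (mm/mm) by central differences (one-sided at borders).

    Returns an array of shape (*grid.shape, 3, 3) with [..., i, j] = du_i/dx_j.
    """
    grid = dvf.grid
    if any(n < 3 for n in grid.shape):
        raise ValueError("jacobian requires >= 3 voxels per axis")
    grad = np.empty(grid.shape + (3, 3))
    for i in range(3):
        gx, gy, gz = np.gradient(dvf.vectors[..., i], *grid.spacing)
        grad[..., i, 0] = gx
        grad[..., i, 1] = gy
        grad[..., i, 2] = gz
    return grad


def jacobian_determinant(dvf: DisplacementField) -> ScalarVolume:
    """det(I + ∇u) per voxel; 1 everywhere for the identity mapping."""
    g = _displacement_gradient(dvf)
    g[..., 0, 0] += 1.0
    g[..., 1, 1] += 1.0
    g[..., 2, 2] += 1.0
    a, b, c = g[..., 0, 0], g[..., 0, 1], g[..., 0, 2]
    d, e, f = g[..., 1, 0], g[..., 1, 1], g[..., 1, 2]
    h, i, j = g[..., 2, 0], g[..., 2, 1], g[..., 2, 2]
    det = a * (e * j - f * i) - b * (d * j - f * h) + c * (d * i - e * h)
    return ScalarVolume(dvf.grid, det)


def folding_fraction(dvf: DisplacementField, region: BinaryMask | None = None
                     ) -> float:
    """Fraction of interior voxels with non-positive Jacobian determinant.

    The one-voxel border (one-sided differences) is excluded; an optional
    region mask further restricts the tally.
    """
    det = jacobian_determinant(dvf).values
    interior = np.zeros(dvf.grid.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    if region is not None:
        if not region.grid.matches(dvf.grid):
            raise ValueError("region mask must match the displacement grid")
        interior &= region.values
    n = int(interior.sum())
    if n == 0:
        return 0.0
    return float((det[interior] <= 0).sum()) / n
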