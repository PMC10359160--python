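"""Generator and discriminator loss terms as standalone scalar functionals.

The total generator objective is

    adversarial + lambda1 * image_similarity + lambda2 * contrast_fidelity
                + lambda3 * curvature_smoothness

where image similarity is a voxelwise L1 between the warped source and the
target, contrast fidelity is the same L1 after a differentiable sigmoid
window ("soft contrast") that emphasizes a chosen display window, and the
smoothness term penalizes the squared discrete Laplacian of each field
component. These numpy implementations are the reference definitions; the
training loop re-expresses them on the autodiff graph and is tested for
agreement with these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .diffeo import VelocityField
from .errors import GridMismatchError
from .volumes import BinaryMask, DisplacementField, ScalarVolume

__all__ = [
    "LossWeights",
    "ContrastWindow",
    "soft_contrast",
    "image_similarity_loss",
    "contrast_fidelity_loss",
    "curvature_regularizer",
    "adversarial_losses",
    "generator_total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the reconstruction terms relative to the adversarial term."""

    lambda1: float = 100.0  # image similarity (L1)
    lambda2: float = 100.0  # contrast fidelity
    lambda3: float = 1.0  # curvature smoothness

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ContrastWindow:
    """Sigmoid window I_out = c / (1 + exp(-(I_in - a)/b)).

    Defaults (a=500, b=500, c=3000, on the stored intensity scale) mimic a
    lung display window.
    """

    a: float = 500.0
    b: float = 500.0
    c: float = 3000.0

    def __post_init__(self):
        if self.b <= 0 or self.c <= 0:
            raise ValueError("contrast window requires b > 0 and c > 0")


def soft_contrast(volume: ScalarVolume, w: ContrastWindow = ContrastWindow()
                  ) -> ScalarVolume:
    """Differentiable window/level mapping; monotone, range (0, c)."""
    return ScalarVolume(volume.grid, w.c * expit((volume.values - w.a) / w.b))


def _masked_mean_abs(a: ScalarVolume, b: ScalarVolume,
                     region: BinaryMask | None) -> float:
    if not a.grid.matches(b.grid):
        raise GridMismatchError("loss operands must share a grid")
    diff = np.abs(a.values - b.values)
    if region is None:
        return float(diff.mean())
    if not region.grid.matches(a.grid):
        raise GridMismatchError("region mask must share the operand grid")
    if not region.values.any():
        return 0.0
    return float(diff[region.values].mean())


def image_similarity_loss(warped: ScalarVolume, target: ScalarVolume,
                          region: BinaryMask | None = None) -> float:
    """Mean absolute voxelwise difference (L1) over the region."""
    return _masked_mean_abs(warped, target, region)


def contrast_fidelity_loss(warped: ScalarVolume, target: ScalarVolume,
                           w: ContrastWindow = ContrastWindow(),
                           region: BinaryMask | None = None) -> float:
    """L1 between soft-contrast-windowed volumes."""
    return image_similarity_loss(soft_contrast(warped, w),
                                 soft_contrast(target, w), region)


def _laplacian_interior(comp: np.ndarray, spacing) -> np.ndarray:
    """6-neighbor discrete Laplacian (1/mm) on the interior of one component."""
    core = comp[1:-1, 1:-1, 1:-1]
    lap = np.zeros_like(core)
    sl = [slice(1, -1)] * 3
    for ax in range(3):
        lo = list(sl)
        hi = list(sl)
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        lap += (comp[tuple(hi)] - 2.0 * core + comp[tuple(lo)]) / spacing[ax] ** 2
    return lap


def curvature_regularizer(field: DisplacementField | VelocityField) -> float:
    """Mean over interior voxels of sum_j (Laplacian of component j)^2.

    Annihilates affine fields exactly; any positive scale is absorbed into
    lambda3.
    """
    grid = field.grid
    if any(n < 3 for n in grid.shape):
        raise ValueError("curvature regularizer requires >= 3 voxels per axis")
    total = None
    for j in range(3):
        lap = _laplacian_interior(field.vectors[..., j], grid.spacing)
        total = lap**2 if total is None else total + lap**2
    return float(total.mean())


_EPS = 1e-7


def adversarial_losses(disc_real_score, disc_fake_score):
    """Binary cross-entropy terms from post-sigmoid score maps in (0, 1).

    Returns ``(generator_term, discriminator_term)``: the discriminator is
    pushed to classify real pairs as 1 and fake pairs as 0; the generator is
    rewarded when fakes score 1. Means are taken over the score maps.
    """
    real = np.clip(np.asarray(disc_real_score, dtype=np.float64), _EPS, 1 - _EPS)
    fake = np.clip(np.asarray(disc_fake_score, dtype=np.float64), _EPS, 1 - _EPS)
    discriminator_term = float(-np.log(real).mean() - np.log(1.0 - fake).mean())
    generator_term = float(-np.log(fake).mean())
    return generator_term, discriminator_term


def generator_total_loss(adv: float, sim: float, fid: float, smooth: float,
                         weights: LossWeights = LossWeights()) -> float:
    """adv + lambda1*sim + lambda2*fid + lambda3*smooth."""
    for name, v in (("adv", adv), ("sim", sim), ("fid", fid), ("smooth", smooth)):
        if not np.isfinite(v):
            raise ValueError(f"loss term {name} is not finite: {v}")
    return float(adv + weights.lambda1 * sim + weights.lambda2 * fid
                 + weights.lambda3 * smooth)
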