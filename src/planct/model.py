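"""Generator/discriminator construction, augmentation, training, inference.

The generator is a 3D U-Net that maps a normalized single-channel CT patch
to a 3-channel stationary velocity field (mm). Inside the training loss the
velocity is exponentiated by differentiable scaling-and-squaring and applied
to the source patch by trilinear warping, so the full objective

    adversarial + lambda1*L1 + lambda2*contrast-fidelity-L1 + lambda3*curvature

is optimized end to end through the integrate-then-warp path. Because the
model outputs a deformation rather than intensities, every synthesized voxel
is an interpolated value of the input scan — HU calibration is preserved by
construction.

Full-volume inference assembles the velocity from overlapping patch
predictions blended by a cosine window, integrates once globally, and warps
the original-intensity input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from . import nn
from .diffeo import VelocityField, integrate_velocity
from .errors import TrainingDivergedError
from .losses import ContrastWindow, LossWeights
from .nn import autograd as ag
from .phantom import PhantomCase
from .preprocess import DEFAULT_WINDOW_HU, remove_couch, segment_body
from .volumes import DisplacementField, ScalarVolume, VolumeGrid, warp

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TrainConfig",
    "desk_train_config",
    "build_generator",
    "build_discriminator",
    "sample_training_patch",
    "generator_forward",
    "train",
    "synthesize",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorConfig:
    levels: int = 7
    base_channels: int = 16
    max_channels: int = 64
    velocity_scale_mm: float = 10.0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass(frozen=True)
class DiscriminatorConfig:
    layers: int = 4
    base_channels: int = 32
    max_channels: int = 64

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("layers must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    patch_size: int = 128
    shift_range_mm: tuple[float, float] = (-20.0, 20.0)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    weights: LossWeights = field(default_factory=LossWeights)
    contrast: ContrastWindow = field(default_factory=ContrastWindow)
    n_integration_steps: int = 7
    epochs: int = 30
    batch_size: int = 1
    learning_rate_g: float = 2e-4
    learning_rate_d: float = 2e-4
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    normalization_window: tuple[float, float] = DEFAULT_WINDOW_HU

    def __post_init__(self):
        if self.shift_range_mm[0] > self.shift_range_mm[1]:
            raise ValueError("shift range must be ordered")
        if self.rotation_range_deg[0] > self.rotation_range_deg[1]:
            raise ValueError("rotation range must be ordered")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_integration_steps < 1:
            raise ValueError("n_integration_steps must be >= 1")
        div = 2 ** (self.generator.levels - 1)
        if self.patch_size % div:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^(levels-1)={div}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key, sub in (("weights", LossWeights), ("contrast", ContrastWindow),
                         ("generator", GeneratorConfig),
                         ("discriminator", DiscriminatorConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("shift_range_mm", "rotation_range_deg",
                    "normalization_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def desk_train_config(epochs: int = 30, seed: int = 0,
                      n_integration_steps: int = 5, **overrides) -> TrainConfig:
    """Reduced profile (48^3 patches, 5 levels, narrow nets) for CPU runs."""
    params = dict(
        patch_size=48,
        shift_range_mm=(0.0, 0.0),
        rotation_range_deg=(0.0, 0.0),
        epochs=epochs,
        seed=seed,
        n_integration_steps=n_integration_steps,
        learning_rate_g=2e-3,
        learning_rate_d=2e-4,
        generator=GeneratorConfig(levels=5, base_channels=4, max_channels=32),
        discriminator=DiscriminatorConfig(layers=3, base_channels=4,
                                          max_channels=16),
    )
    params.update(overrides)
    return TrainConfig(**params)


def build_generator(cfg: GeneratorConfig, rng: np.random.Generator
                    ) -> nn.UNetGenerator:
    return nn.UNetGenerator(levels=cfg.levels, base_channels=cfg.base_channels,
                            velocity_scale=cfg.velocity_scale_mm,
                            max_channels=cfg.max_channels, rng=rng)


def build_discriminator(cfg: DiscriminatorConfig, rng: np.random.Generator
                        ) -> nn.PatchDiscriminator:
    return nn.PatchDiscriminator(layers=cfg.layers,
                                 base_channels=cfg.base_channels,
                                 max_channels=cfg.max_channels, rng=rng)


# ---------------------------------------------------------------------------
# data access and augmentation


def couchless_pair(case) -> tuple[ScalarVolume, ScalarVolume]:
    """(source, target) HU volumes with the couch removed.

    Accepts a :class:`PhantomCase` or an already-prepared ``(dct, pct)``
    tuple of :class:`ScalarVolume`.
    """
    if isinstance(case, PhantomCase):
        dct = remove_couch(case.dct, segment_body(case.dct))
        pct = remove_couch(case.pct, segment_body(case.pct))
        return dct, pct
    src, tgt = case
    return src, tgt


def sample_training_patch(case, cfg: TrainConfig, rng: np.random.Generator):
    """Extract one augmented (source, target) patch pair.

    The same random shift (mm) and rotation about the superior-inferior axis
    are applied to both volumes; the transform is returned for
    reproducibility. With zero-width ranges the patch is a deterministic
    centered crop (exact voxel values).
    """
    src, tgt = couchless_pair(case)
    grid = src.grid
    p = cfg.patch_size
    if any(n < p for n in grid.shape):
        raise ValueError(f"volume shape {grid.shape} smaller than patch {p}")
    shift = np.array([rng.uniform(*cfg.shift_range_mm) for _ in range(3)])
    theta = np.deg2rad(rng.uniform(*cfg.rotation_range_deg))

    base = [(n - p) // 2 for n in grid.shape]
    idx = list(np.meshgrid(*[np.arange(p, dtype=np.float64) + b for b in base],
                           indexing="ij"))
    if theta != 0.0:
        cx = base[0] + (p - 1) / 2.0
        cy = base[1] + (p - 1) / 2.0
        # rotate sampling positions about z through the patch center (mm-true
        # for isotropic in-plane spacing)
        dx = (idx[0] - cx) * grid.spacing[0]
        dy = (idx[1] - cy) * grid.spacing[1]
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        idx[0] = cx + (cos_t * dx - sin_t * dy) / grid.spacing[0]
        idx[1] = cy + (sin_t * dx + cos_t * dy) / grid.spacing[1]
    coords = np.stack(
        [idx[a] + shift[a] / grid.spacing[a] for a in range(3)]
    )
    patch_grid = VolumeGrid(
        (p, p, p), grid.spacing,
        tuple(grid.origin[a] + base[a] * grid.spacing[a] for a in range(3)),
    )
    out = []
    for vol in (src, tgt):
        vals = map_coordinates(vol.values, coords, order=1, mode="nearest")
        out.append(ScalarVolume(patch_grid, vals))
    record = {"shift_mm": shift.tolist(), "rotation_deg": float(np.rad2deg(theta)),
              "base_index": base}
    return out[0], out[1], record


def generator_forward(gen: nn.UNetGenerator, patch: ScalarVolume
                      ) -> VelocityField:
    """Run the generator on a normalized patch; returns a velocity in mm."""
    x = ag.constant(patch.values[np.newaxis].astype(np.float32))
    v = gen(x)
    return VelocityField(patch.grid,
                         np.moveaxis(v.data.astype(np.float64), 0, -1))


# ---------------------------------------------------------------------------
# differentiable loss path


def _integrate_diff(v: ag.Tensor, spacing, n_steps: int) -> ag.Tensor:
    """Scaling-and-squaring on the graph; v and result in mm, (3, X, Y, Z)."""
    inv_spacing = ag.constant(
        (1.0 / np.asarray(spacing, dtype=v.data.dtype)).reshape(3, 1, 1, 1))
    u = ag.mul(v, ag.constant(np.asarray(0.5**n_steps, dtype=v.data.dtype)))
    for _ in range(n_steps):
        u = ag.add(u, ag.grid_sample(u, ag.mul(u, inv_spacing)))
    return u


def _warp_diff(img: ag.Tensor, u: ag.Tensor, spacing) -> ag.Tensor:
    inv_spacing = ag.constant(
        (1.0 / np.asarray(spacing, dtype=img.data.dtype)).reshape(3, 1, 1, 1))
    return ag.grid_sample(img, ag.mul(u, inv_spacing))


def _soft_contrast_diff(x: ag.Tensor, w: ContrastWindow) -> ag.Tensor:
    dt = x.data.dtype
    shifted = ag.mul(ag.add(x, ag.constant(np.asarray(-w.a, dtype=dt))),
                     ag.constant(np.asarray(1.0 / w.b, dtype=dt)))
    return ag.mul(ag.sigmoid(shifted), ag.constant(np.asarray(w.c, dtype=dt)))


def _l1_diff(a: ag.Tensor, b: ag.Tensor) -> ag.Tensor:
    return ag.mean(ag.abs_(ag.sub(a, b)))


def _curvature_diff(v: ag.Tensor, spacing) -> ag.Tensor:
    """Mean over interior voxels of the summed squared per-component
    Laplacian; matches :func:`planct.losses.curvature_regularizer`."""
    interior = (slice(None), slice(1, -1), slice(1, -1), slice(1, -1))
    core = ag.crop(v, interior)
    lap = None
    for ax in range(3):
        lo = [slice(None)] + [slice(1, -1)] * 3
        hi = [slice(None)] + [slice(1, -1)] * 3
        lo[ax + 1] = slice(0, -2)
        hi[ax + 1] = slice(2, None)
        h2 = ag.constant(np.asarray(1.0 / spacing[ax] ** 2, dtype=v.data.dtype))
        term = ag.mul(
            ag.add(ag.add(ag.crop(v, tuple(hi)), ag.crop(v, tuple(lo))),
                   ag.mul(core, ag.constant(np.asarray(-2.0,
                                                       dtype=v.data.dtype)))),
            h2,
        )
        lap = term if lap is None else ag.add(lap, term)
    sq = ag.mul(lap, lap)
    # mean over components and interior voxels x 3 = mean over voxels of sum_j
    return ag.mul(ag.mean(sq), ag.constant(np.asarray(3.0, dtype=v.data.dtype)))


def _bce_real(logits: ag.Tensor) -> ag.Tensor:
    return ag.neg(ag.mean(ag.log(ag.sigmoid(logits))))


def _bce_fake(logits: ag.Tensor) -> ag.Tensor:
    one = ag.constant(np.asarray(1.0, dtype=logits.data.dtype))
    return ag.neg(ag.mean(ag.log(ag.sub(one, ag.sigmoid(logits)))))


def _normalize_array(hu: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (2.0 * (np.clip(hu, lo, hi) - lo) / (hi - lo) - 1.0)


# ---------------------------------------------------------------------------
# training


def train(dataset, cfg: TrainConfig, init=None):
    """Adversarially train the generator/discriminator pair.

    ``dataset`` is a list of :class:`PhantomCase` or ``(source, target)``
    volume pairs. Updates alternate one discriminator and one generator step
    per optimization step; each step averages gradients over ``batch_size``
    sampled patches. ``init`` may carry a ``(generator, discriminator)`` pair
    to resume from. Returns ``(generator, discriminator, history)`` where
    history holds every (batch-mean) loss component per step.
    """
    if not dataset:
        raise ValueError("train requires a nonempty dataset")
    if cfg.batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(cfg.generator, np.random.default_rng(rng.integers(2**31)))
    disc = build_discriminator(cfg.discriminator,
                               np.random.default_rng(rng.integers(2**31)))
    if init is not None:
        init_gen, init_disc = init
        gen.load_state_arrays(init_gen.state_arrays())
        disc.load_state_arrays(init_disc.state_arrays())
    opt_g = nn.Adam(gen.parameters(), lr=cfg.learning_rate_g)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.learning_rate_d)
    pairs = [couchless_pair(case) for case in dataset]
    w = cfg.weights
    history: list[dict] = []
    step = 0
    lo_w, hi_w = cfg.normalization_window
    half_window = (hi_w - lo_w) / 2.0
    center_window = (hi_w + lo_w) / 2.0

    dt = np.float32
    seed_frac = np.asarray(1.0 / cfg.batch_size, dtype=dt)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        for case_idx in order:
            # forward passes for every patch of the batch
            batch = []
            for _ in range(cfg.batch_size):
                src_p, tgt_p, _record = sample_training_patch(
                    pairs[case_idx], cfg, rng)
                spacing = src_p.grid.spacing
                src_hu = ag.constant(src_p.values[np.newaxis].astype(dt))
                tgt_hu = ag.constant(tgt_p.values[np.newaxis].astype(dt))
                src_n = ag.constant(_normalize_array(
                    src_p.values, cfg.normalization_window)[np.newaxis]
                    .astype(dt))
                tgt_n = ag.constant(_normalize_array(
                    tgt_p.values, cfg.normalization_window)[np.newaxis]
                    .astype(dt))
                v = gen(src_n)
                u = _integrate_diff(v, spacing, cfg.n_integration_steps)
                warped_hu = _warp_diff(src_hu, u, spacing)
                warped_n = ag.mul(
                    ag.add(warped_hu,
                           ag.constant(np.asarray(-center_window, dtype=dt))),
                    ag.constant(np.asarray(1.0 / half_window, dtype=dt)),
                )
                batch.append((spacing, src_n, tgt_n, tgt_hu, v, warped_hu,
                              warped_n))

            # discriminator update on (real pair) vs (fake pair, detached)
            opt_d.zero_grad()
            d_losses = []
            for spacing, src_n, tgt_n, _tgt_hu, _v, _w_hu, warped_n in batch:
                d_real = disc(ag.concat([src_n, tgt_n], axis=0))
                d_fake = disc(ag.concat([src_n, warped_n.detach()], axis=0))
                d_loss = ag.add(_bce_real(d_real), _bce_fake(d_fake))
                d_loss.backward(seed_frac)
                d_losses.append(d_loss.item())
            opt_d.step()

            # generator update through the full loss path
            opt_g.zero_grad()
            terms = {"adv": [], "sim": [], "fid": [], "smooth": [],
                     "total": []}
            for spacing, src_n, _tgt_n, tgt_hu, v, warped_hu, warped_n in batch:
                d_fake_g = disc(ag.concat([src_n, warped_n], axis=0))
                adv = _bce_real(d_fake_g)
                sim = _l1_diff(warped_hu, tgt_hu)
                fid = _l1_diff(_soft_contrast_diff(warped_hu, cfg.contrast),
                               _soft_contrast_diff(tgt_hu, cfg.contrast))
                smooth = _curvature_diff(v, spacing)
                total = ag.add(
                    adv,
                    ag.add(
                        ag.mul(sim,
                               ag.constant(np.asarray(w.lambda1, dtype=dt))),
                        ag.add(
                            ag.mul(fid, ag.constant(
                                np.asarray(w.lambda2, dtype=dt))),
                            ag.mul(smooth, ag.constant(
                                np.asarray(w.lambda3, dtype=dt))),
                        ),
                    ),
                )
                total.backward(seed_frac)
                for key, t in (("adv", adv), ("sim", sim), ("fid", fid),
                               ("smooth", smooth), ("total", total)):
                    terms[key].append(t.item())
            opt_g.step()

            row = {
                "step": step,
                "epoch": epoch,
                "case": int(case_idx),
                "d_loss": float(np.mean(d_losses)),
                **{k: float(np.mean(vals)) for k, vals in terms.items()},
            }
            if not all(np.isfinite(v_) for k, v_ in row.items()
                       if k not in ("step", "epoch", "case")):
                raise TrainingDivergedError(
                    f"non-finite loss at step {step}",
                    state={"step": step, "epoch": epoch, "row": row,
                           "history": history},
                )
            history.append(row)
            step += 1
    return gen, disc, history


# ---------------------------------------------------------------------------
# inference


def _tile_offsets(n: int, p: int) -> list[int]:
    if n == p:
        return [0]
    stride = max(1, p // 2)
    offs = list(range(0, n - p, stride))
    offs.append(n - p)
    return offs


def _cosine_window(p: int) -> np.ndarray:
    i = np.arange(p)
    w1 = 0.5 - 0.5 * np.cos(2.0 * np.pi * (i + 0.5) / p) + 1e-2
    return w1[:, None, None] * w1[None, :, None] * w1[None, None, :]


def synthesize(gen: nn.UNetGenerator, dct: ScalarVolume, cfg: TrainConfig
               ) -> tuple[ScalarVolume, DisplacementField]:
    """Predict the planning-state volume for a preprocessed diagnostic CT.

    The input must be couch-free (HU). The full-volume velocity is blended
    from overlapping patch predictions, integrated once into a diffeomorphic
    displacement, and applied to the original-intensity input; output voxels
    are interpolated input values only.
    """
    grid = dct.grid
    p = cfg.patch_size
    div = gen.required_divisor()
    if p % div:
        raise ValueError(f"patch_size {p} incompatible with generator "
                         f"divisor {div}")
    if any(n < p for n in grid.shape):
        raise ValueError(f"volume shape {grid.shape} smaller than patch {p}")
    norm = _normalize_array(dct.values, cfg.normalization_window)
    v_acc = np.zeros(grid.shape + (3,))
    w_acc = np.zeros(grid.shape)
    win = _cosine_window(p)
    for ox in _tile_offsets(grid.shape[0], p):
        for oy in _tile_offsets(grid.shape[1], p):
            for oz in _tile_offsets(grid.shape[2], p):
                sl = (slice(ox, ox + p), slice(oy, oy + p), slice(oz, oz + p))
                x = ag.constant(norm[sl][np.newaxis].astype(np.float32))
                v = np.moveaxis(gen(x).data.astype(np.float64), 0, -1)
                v_acc[sl] += v * win[..., None]
                w_acc[sl] += win
    v_full = v_acc / w_acc[..., None]
    dvf = integrate_velocity(VelocityField(grid, v_full),
                             cfg.n_integration_steps)
    sct = warp(dct, dvf, interpolation="linear")
    return sct, dvf


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, gen: nn.UNetGenerator, disc: nn.PatchDiscriminator,
                    cfg: TrainConfig, extra: dict | None = None) -> None:
    """Write generator+discriminator arrays (npz) and a JSON sidecar."""
    path = str(path)
    g_arrays = gen.state_arrays()
    d_arrays = disc.state_arrays()
    arrays = {f"g_{i}": a for i, a in enumerate(g_arrays)}
    arrays.update({f"d_{i}": a for i, a in enumerate(d_arrays)})
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    import hashlib

    from . import __version__

    cfg_dict = cfg.to_dict()
    sidecar = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "version": __version__,
        "n_generator_arrays": len(g_arrays),
        "n_discriminator_arrays": len(d_arrays),
    }
    if extra:
        sidecar.update(extra)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path):
    """Load ``(generator, discriminator, config, sidecar)`` from disk."""
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        sidecar = json.load(fh)
    cfg = TrainConfig.from_dict(sidecar["config"])
    data = np.load(base + ".npz")
    gen = build_generator(cfg.generator, np.random.default_rng(0))
    disc = build_discriminator(cfg.discriminator, np.random.default_rng(0))
    gen.load_state_arrays(
        [data[f"g_{i}"] for i in range(sidecar["n_generator_arrays"])])
    disc.load_state_arrays(
        [data[f"d_{i}"] for i in range(sidecar["n_discriminator_arrays"])])
    return gen, disc, cfg, sidecar
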