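"""Synthetic carotid-ultrasound phantoms.

Generates image / plaque-mask / vessel-mask triplets with the gross
statistical structure of longitudinal B-mode carotid scans: a dark lumen
band between bright adventitia/wall layers, echogenic plaques protruding
into the lumen from the near or far wall, multiplicative speckle,
optional acoustic-shadow columns and bright artifact streaks.  The
phantoms stand in for clinical data, which is private; they are not a
wave-propagation simulation (see docs/methods.md for what they do and do
not emulate).

Geometry is a horizontal vessel, matching the longitudinal view in which
carotid plaque is read clinically.  Plaque masks are constructed inside
the vessel mask by design — plaques only exist in the inner of the
artery — and every generated sample satisfies ``plaque_mask ⊆
vessel_mask`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PhantomParams", "PhantomSample", "speckle_field",
           "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, echogenicity and noise settings for one phantom.

    Defaults describe a 128 x 128 desk-scale phantom; pass explicit pixel
    values for other sizes (e.g. the 512-wide working size of a clinical
    scan).  ``scaled_to`` rescales the pixel-denominated fields.
    """

    height: int = 128
    width: int = 128
    lumen_center_frac: float = 0.5      # vessel axis position, fraction of height
    lumen_half_thickness: int = 20      # px, lumen half-height
    wall_brightness: float = 0.85       # adventitia/wall echo intensity
    lumen_brightness: float = 0.05      # anechoic lumen intensity
    n_plaques: int = 2
    plaque_axis_range: tuple[int, int] = (6, 16)   # px, semi-axis min/max
    speckle_shape: float = 4.0          # gamma shape; variance = 1/shape
    shadow_prob: float = 0.3
    artifact_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError(f"phantom size too small: {self.height}x{self.width}")
        if not (0 < self.lumen_half_thickness < self.height / 2):
            raise ValueError("lumen_half_thickness must lie in (0, height/2)")
        lo, hi = self.plaque_axis_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid plaque_axis_range {self.plaque_axis_range}")
        if hi > self.lumen_half_thickness:
            raise ValueError("plaque semi-axes must not exceed lumen_half_thickness "
                             "(plaques never exit the vessel)")
        for name in ("wall_brightness", "lumen_brightness"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        for name in ("shadow_prob", "artifact_prob", "lumen_center_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_plaques < 0:
            raise ValueError("n_plaques must be >= 0")

    def scaled_to(self, height: int, width: int) -> "PhantomParams":
        """Same phantom recipe at another grid size."""
        s = height / self.height
        lo, hi = self.plaque_axis_range
        return replace(
            self, height=height, width=width,
            lumen_half_thickness=max(2, round(self.lumen_half_thickness * s)),
            plaque_axis_range=(max(1, round(lo * s)), max(2, round(hi * s))),
        )


@dataclass(frozen=True)
class PhantomSample:
    """One image with its plaque label and vessel (adventitia) mask."""

    image: np.ndarray        # float32 in [0,1], (H, W)
    plaque_mask: np.ndarray  # uint8 {0,1}, (H, W)
    vessel_mask: np.ndarray  # uint8 {0,1}, (H, W)

    def __post_init__(self):
        if not (self.image.shape == self.plaque_mask.shape == self.vessel_mask.shape):
            raise ValueError("image and masks must share dimensions")


def _wall_thickness(params: PhantomParams) -> int:
    return max(3, params.lumen_half_thickness // 2)


def speckle_field(shape_param: float, size, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative speckle: gamma(shape, 1/shape) noise.

    The gamma surrogate is the classic model for fully developed,
    incoherently averaged ultrasound speckle; variance is 1/shape.
    """
    if shape_param <= 0:
        raise ValueError("speckle shape must be positive")
    return rng.gamma(shape_param, 1.0 / shape_param, size=size).astype(np.float32)


def generate_phantom(params: PhantomParams) -> PhantomSample:
    """Render one phantom; bit-identical for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    H, W = params.height, params.width
    rows = np.arange(H, dtype=np.float32)[:, None]
    cols = np.arange(W, dtype=np.float32)[None, :]

    # vessel axis with a gentle seeded undulation
    center = params.lumen_center_frac * H
    amp = rng.uniform(0.0, 0.03) * H
    phase = rng.uniform(0, 2 * np.pi)
    axis = center + amp * np.sin(2 * np.pi * cols / W + phase)   # (1, W)

    half = float(params.lumen_half_thickness)
    wall = float(_wall_thickness(params))
    dist = rows - axis                                            # signed distance to axis

    lumen = np.abs(dist) <= half
    vessel = np.abs(dist) <= half + wall
    wall_band = vessel & ~lumen

    # clean scene: echogenic tissue background, bright walls, dark lumen
    tissue = 0.35 + 0.05 * rng.standard_normal()
    scene = np.full((H, W), np.clip(tissue, 0.1, 0.6), dtype=np.float32)
    scene[wall_band] = params.wall_brightness
    scene[lumen] = params.lumen_brightness

    # plaques: ellipse blobs attached to the near (top) or far (bottom) wall,
    # protruding into the lumen; echo between lumen and wall
    plaque = np.zeros((H, W), dtype=bool)
    lo, hi = params.plaque_axis_range
    for _ in range(params.n_plaques):
        a = rng.uniform(lo, hi)          # semi-axis along the vessel
        b = rng.uniform(lo, hi)          # semi-axis across
        cx = rng.uniform(0.1 * W, 0.9 * W)
        side = rng.choice([-1.0, 1.0])   # near or far wall
        # anchor the ellipse center at the lumen-wall interface
        cy_off = side * half
        ell = (((cols - cx) / (1.8 * a)) ** 2 + ((dist - cy_off) / b) ** 2) <= 1.0
        plaque |= ell & lumen
    plaque &= lumen                      # strictly inside the vessel lumen
    scene[plaque] = np.clip(
        0.5 * params.wall_brightness + 0.1 * rng.standard_normal(), 0.2, 0.9)

    # multiplicative speckle: unit-mean gamma
    img = scene * speckle_field(params.speckle_shape, (H, W), rng)

    # acoustic shadow: attenuated vertical column with soft edges
    if rng.random() < params.shadow_prob:
        sc = rng.uniform(0.15 * W, 0.85 * W)
        sw = rng.uniform(0.04, 0.10) * W
        profile = 1.0 - 0.7 * np.exp(-0.5 * ((cols - sc) / sw) ** 2)
        img = img * profile

    # artifact: bright horizontal streak (reverberation-like), inside the frame
    if rng.random() < params.artifact_prob:
        ar = rng.uniform(0.1 * H, 0.9 * H)
        ah = rng.uniform(1.0, 2.5)
        streak = 0.5 * np.exp(-0.5 * ((rows - ar) / ah) ** 2)
        img = img + streak.astype(np.float32)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return PhantomSample(
        image=img,
        plaque_mask=plaque.astype(np.uint8),
        vessel_mask=vessel.astype(np.uint8),
    )


def generate_dataset(n: int, params: PhantomParams, seed: int | None = None) -> list[PhantomSample]:
    """Generate ``n`` phantoms with per-sample seeds spawned from a master seed.

    ``seed`` defaults to ``params.seed``; sample i uses an independent
    child seed, so datasets are reproducible and order-stable.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    master = params.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    return [generate_phantom(replace(params, seed=s)) for s in child_seeds]
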