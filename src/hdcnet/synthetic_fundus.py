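"""Seeded generator of fundus-like phantoms with exact vessel masks.

Real fundus photographs show dark curvilinear vessel trees, 1-8 px wide,
branching from thick trunks to fragile one-pixel twigs, on an orange,
unevenly illuminated, noisy background. The phantom generator reproduces
those properties — the ones a segmentation network's inductive biases are
aimed at — while returning a pixel-exact binary mask, so every stage of the
pipeline can be exercised and scored without downloading a dataset.

Vessel trees are grown as random branching walks (a Galton–Watson style
cascade: each branch point splits off a thinner child). Width tapers from
the root towards the tips. The mask is exactly the set of stamped vessel
pixels; anti-aliasing and noise are applied to the image only, never to the
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk

from .data_pipeline import DatasetSpec, ImagePair, save_pair

__all__ = ["PhantomSpec", "generate", "make_dataset", "rasterize_segment"]


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    Defaults emulate a small fundus patch: three vessel trees with widths
    tapering from 7 px trunks to 1 px twigs, moderate curvature, an
    orange background with a radial illumination falloff of 25% and pixel
    noise sigma 0.02 (on a [0,1] scale).
    """

    size: tuple[int, int] = (128, 128)
    n_trees: int = 3
    branch_prob: float = 0.04
    width_range: tuple[float, float] = (1.0, 7.0)
    tortuosity: float = 0.25
    base_color: tuple[float, float, float] = (0.62, 0.32, 0.12)
    illumination: float = 0.25
    noise_sigma: float = 0.02
    vessel_contrast: float = 0.35
    fov_radius_fraction: float | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.size) < 8:
            raise ValueError(f"degenerate phantom size {self.size}")
        if self.width_range[0] < 1:
            raise ValueError("minimum vessel width is 1 px")
        for name in ("branch_prob", "tortuosity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")


def rasterize_segment(mask: np.ndarray, p0, p1, width: float) -> None:
    """Stamp a straight vessel segment of the given width onto ``mask``.

    Disks of radius width/2 are stamped at half-pixel steps along the
    segment, producing a digital stroke of the nominal width.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.hypot(*(p1 - p0))
    steps = max(int(length * 2) + 1, 2)
    for t in np.linspace(0.0, 1.0, steps):
        c = p0 + t * (p1 - p0)
        rr, cc = disk(c, max(width / 2.0, 0.5), shape=mask.shape)
        mask[rr, cc] = 1


def _grow_tree(mask: np.ndarray, rng: np.random.Generator, spec: PhantomSpec,
               inside) -> None:
    h, w = mask.shape
    wmin, wmax = spec.width_range
    # root on a random border, heading inwards
    side = rng.integers(4)
    if side == 0:
        pos = np.array([0.0, rng.uniform(0, w)]); ang = np.pi / 2
    elif side == 1:
        pos = np.array([h - 1.0, rng.uniform(0, w)]); ang = -np.pi / 2
    elif side == 2:
        pos = np.array([rng.uniform(0, h), 0.0]); ang = 0.0
    else:
        pos = np.array([rng.uniform(0, h), w - 1.0]); ang = np.pi
    ang += rng.uniform(-0.5, 0.5)
    total = 0.9 * min(h, w)
    stack = [(pos, ang, wmax * rng.uniform(0.8, 1.0), total)]
    while stack:
        pos, ang, width, remaining = stack.pop()
        n_steps = max(int(remaining / 2.0), 1)
        w0 = width
        for i in range(n_steps):
            # taper linearly towards the minimum width at the tip
            cur = w0 + (wmin - w0) * (i / n_steps)
            step = 2.0
            ang += rng.normal(0.0, spec.tortuosity)
            nxt = pos + step * np.array([np.sin(ang), np.cos(ang)])
            if not inside(nxt):
                return
            rasterize_segment(mask, pos, nxt, cur)
            pos = nxt
            if cur > wmin and rng.random() < spec.branch_prob:
                child_w = max(cur * 0.6, wmin)
                child_a = ang + rng.choice((-1, 1)) * rng.uniform(0.4, 1.1)
                stack.append((pos.copy(), child_a, child_w, remaining * 0.6))


def generate(spec: PhantomSpec) -> ImagePair:
    """Render one phantom image/mask pair, deterministically for a seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    mask = np.zeros((h, w), dtype=np.uint8)

    if spec.fov_radius_fraction is not None:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r_fov = spec.fov_radius_fraction * min(h, w) / 2.0
        inside = lambda p: 0 <= p[0] < h and 0 <= p[1] < w and (p[0] - cy) ** 2 + (p[1] - cx) ** 2 <= r_fov**2  # noqa: E731
    else:
        inside = lambda p: 0 <= p[0] < h and 0 <= p[1] < w  # noqa: E731

    for _ in range(spec.n_trees):
        _grow_tree(mask, rng, spec, inside)

    # background: base colour, radial illumination falloff, low-frequency texture
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / ((h / 2.0) ** 2 + (w / 2.0) ** 2)
    shading = 1.0 - spec.illumination * r2
    texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=8.0)
    texture = 1.0 + 0.15 * texture / max(np.abs(texture).max(), 1e-12)
    image = np.empty((h, w, 3))
    for c, base in enumerate(spec.base_color):
        image[..., c] = base * shading * texture

    # vessels darker than background, anti-aliased on the image only
    soft = gaussian_filter(mask.astype(float), sigma=0.6)
    soft = np.clip(soft / max(soft.max(), 1e-12), 0.0, 1.0) if mask.any() else soft
    image *= 1.0 - spec.vessel_contrast * soft[..., None]

    if spec.fov_radius_fraction is not None:
        r_fov = spec.fov_radius_fraction * min(h, w) / 2.0
        out_fov = (yy - cy) ** 2 + (xx - cx) ** 2 > r_fov**2
        image[out_fov] *= 0.08

    image += rng.normal(0.0, spec.noise_sigma, image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return ImagePair(image, mask, source_id=f"phantom_{spec.seed:05d}")


def make_dataset(spec: PhantomSpec, n_images: int, out_dir: str | Path,
                 train_fraction: float = 0.5) -> DatasetSpec:
    """Write ``n_images`` phantom PNG pairs plus a plain-text partition file.

    Consecutive seeds starting at ``spec.seed`` are used; the first
    ``train_fraction`` of the images form the training partition.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    stems = []
    for i in range(n_images):
        pair = generate(replace(spec, seed=spec.seed + i))
        stem = pair.source_id
        save_pair(pair, out_dir / "images" / f"{stem}.png", out_dir / "masks" / f"{stem}.png")
        stems.append(stem)
    n_train = max(int(round(train_fraction * n_images)), 1) if n_images > 1 else 1
    train_ids, test_ids = stems[:n_train], stems[n_train:]
    # pad target: next multiple of 16 covers depths up to 4
    th = -(-spec.size[0] // 16) * 16
    tw = -(-spec.size[1] // 16) * 16
    with open(out_dir / "partition.txt", "w") as fh:
        for s in train_ids:
            fh.write(f"train {s}\n")
        for s in test_ids:
            fh.write(f"test {s}\n")
    return DatasetSpec(
        name="phantom", native_size=spec.size, target_size=(th, tw),
        train_ids=train_ids, test_ids=test_ids,
    )
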