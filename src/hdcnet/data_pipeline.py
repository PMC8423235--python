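"""Dataset I/O, resolution adjustment and augmentation for fundus images.

Fundus benchmarks come at odd native resolutions (DRIVE 584x565, CHASE-DB1
960x999, STARE 605x700) that a U-shaped network with 2^depth down-samplings
cannot ingest directly. Images are therefore zero-padded symmetrically to a
divisible target (592x592, 1008x1008, 704x704), and probability maps are
cropped back to the native size before scoring, so evaluation always happens
at the original resolution. The padding offsets are carried on the pair,
making pad -> restore an exact inverse on masks.

Four augmentation operators match the usual fundus training recipe: random
rotation (0-360 deg), additive Gaussian noise, hue/contrast/brightness
jitter, and horizontal/vertical/diagonal flips. Geometric operators are
applied identically to image and mask (nearest-neighbour for the mask so it
stays strictly binary); photometric operators touch the image only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "DatasetSpec",
    "ImagePair",
    "add_gaussian_noise",
    "augment",
    "color_jitter",
    "corner_crops",
    "flip_pair",
    "load_dataset",
    "pad_to_target",
    "restore_original",
    "rotate_pair",
    "save_pair",
]


@dataclass
class ImagePair:
    """A fundus image with its aligned binary vessel mask."""

    image: np.ndarray  # H x W x 3, float in [0, 1]
    mask: np.ndarray  # H x W, uint8 in {0, 1}
    original_size: tuple[int, int] | None = None
    pad_offsets: tuple[int, int] | None = None
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"mask {self.mask.shape} not aligned with image {self.image.shape[:2]}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary 0/1, found values {vals[:5]}")
        self.mask = self.mask.astype(np.uint8)
        if self.original_size is None:
            self.original_size = self.mask.shape


@dataclass
class DatasetSpec:
    """Declares a dataset's layout: native size, padded target, partition."""

    name: str
    native_size: tuple[int, int]
    target_size: tuple[int, int]
    crop_size: int | None = None
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        th, tw = self.target_size
        nh, nw = self.native_size
        if th < nh or tw < nw:
            raise ValueError("target size must be >= native size")


#: the three benchmark datasets' published resolution adjustments
STANDARD_SPECS = {
    "drive": DatasetSpec("drive", (584, 565), (592, 592)),
    "chase_db1": DatasetSpec("chase_db1", (960, 999), (1008, 1008), crop_size=512),
    "stare": DatasetSpec("stare", (605, 700), (704, 704)),
}


# ---------------------------------------------------------------------------
# resolution adjustment
# ---------------------------------------------------------------------------

def pad_to_target(p: ImagePair, target: tuple[int, int]) -> ImagePair:
    """Zero-pad symmetrically to ``target``; odd remainders go bottom/right."""
    h, w = p.mask.shape
    th, tw = target
    if th < h or tw < w:
        raise ValueError(f"target {target} smaller than input {(h, w)}")
    top = (th - h) // 2
    left = (tw - w) // 2
    image = np.pad(p.image, ((top, th - h - top), (left, tw - w - left), (0, 0)))
    mask = np.pad(p.mask, ((top, th - h - top), (left, tw - w - left)))
    return ImagePair(image, mask, original_size=(h, w), pad_offsets=(top, left),
                     source_id=p.source_id)


def restore_original(prob_map: np.ndarray, p: ImagePair) -> np.ndarray:
    """Crop a padded-resolution map back to the pair's native resolution."""
    if p.pad_offsets is None:
        raise ValueError("pair has no recorded pad offsets; was it padded?")
    top, left = p.pad_offsets
    h, w = p.original_size
    prob_map = np.asarray(prob_map)
    return prob_map[top : top + h, left : left + w]


def corner_crops(p: ImagePair, crop: int) -> list[ImagePair]:
    """Four ``crop`` x ``crop`` crops anchored at the corners.

    Crops overlap whenever 2*crop exceeds a dimension; together they cover
    every pixel as long as 2*crop >= each dimension (the published 512 crops
    of a 1008x1008 image satisfy this).
    """
    h, w = p.mask.shape
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} larger than image {(h, w)}")
    anchors = [(0, 0), (0, w - crop), (h - crop, 0), (h - crop, w - crop)]
    out = []
    for i, (top, left) in enumerate(anchors):
        out.append(
            ImagePair(
                p.image[top : top + crop, left : left + crop],
                p.mask[top : top + crop, left : left + crop],
                original_size=(crop, crop),
                pad_offsets=(top, left),
                source_id=f"{p.source_id}#crop{i}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# augmentation primitives
# ---------------------------------------------------------------------------

def rotate_pair(p: ImagePair, angle: float) -> ImagePair:
    """Rotate counter-clockwise by ``angle`` degrees; bilinear image,
    nearest-neighbour mask, zero fill outside."""
    if angle % 360 == 0:
        return replace(p, image=p.image.copy(), mask=p.mask.copy())
    image = _sk_rotate(p.image, angle, order=1, mode="constant", cval=0.0, preserve_range=True)
    mask = _sk_rotate(p.mask.astype(float), angle, order=0, mode="constant", cval=0.0,
                      preserve_range=True)
    return replace(p, image=image, mask=mask.astype(np.uint8))


def flip_pair(p: ImagePair, mode: str) -> ImagePair:
    """Flip both image and mask: 'horizontal', 'vertical' or 'diagonal'
    (main-diagonal transpose; square images only)."""
    if mode == "horizontal":
        return replace(p, image=p.image[:, ::-1].copy(), mask=p.mask[:, ::-1].copy())
    if mode == "vertical":
        return replace(p, image=p.image[::-1].copy(), mask=p.mask[::-1].copy())
    if mode == "diagonal":
        if p.mask.shape[0] != p.mask.shape[1]:
            raise ValueError("diagonal flip requires a square image (pad first)")
        return replace(
            p, image=p.image.transpose(1, 0, 2).copy(), mask=p.mask.T.copy()
        )
    raise ValueError(f"unknown flip mode {mode!r}")


def add_gaussian_noise(p: ImagePair, sigma: float, rng: np.random.Generator) -> ImagePair:
    noisy = np.clip(p.image + rng.normal(0.0, sigma, p.image.shape), 0.0, 1.0)
    return replace(p, image=noisy, mask=p.mask.copy())


def color_jitter(
    p: ImagePair,
    rng: np.random.Generator,
    hue: float = 0.05,
    brightness: float = 0.2,
    contrast: float = 0.2,
) -> ImagePair:
    """Random hue shift and brightness/contrast scaling of the image only."""
    dh = rng.uniform(-hue, hue)
    db = rng.uniform(-brightness, brightness)
    dc = 1.0 + rng.uniform(-contrast, contrast)
    hsv = rgb2hsv(p.image)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    img = hsv2rgb(hsv)
    img = np.clip((img - 0.5) * dc + 0.5 + db, 0.0, 1.0)
    return replace(p, image=img, mask=p.mask.copy())


DEFAULT_OPS = frozenset({"rotation", "noise", "jitter", "flip"})


def augment(p: ImagePair, ops: frozenset | set = DEFAULT_OPS, rng_seed: int = 0,
            noise_sigma: float = 0.02) -> ImagePair:
    """Apply the selected random augmentations, reproducibly for a seed."""
    rng = np.random.default_rng(rng_seed)
    out = p
    if "rotation" in ops:
        out = rotate_pair(out, rng.uniform(0.0, 360.0))
    if "flip" in ops:
        modes = ["horizontal", "vertical"]
        if out.mask.shape[0] == out.mask.shape[1]:
            modes.append("diagonal")
        out = flip_pair(out, modes[rng.integers(len(modes))])
    if "jitter" in ops:
        out = color_jitter(out, rng)
    if "noise" in ops:
        out = add_gaussian_noise(out, noise_sigma, rng)
    return out


def expand_dataset(pairs: list[ImagePair], multiplier: int, ops: frozenset | set = DEFAULT_OPS,
                   seed: int = 0) -> list[ImagePair]:
    """Offline expansion: the originals plus ``multiplier`` augmented copies each."""
    out = list(pairs)
    for k in range(multiplier):
        for i, p in enumerate(pairs):
            aug = augment(p, ops, rng_seed=seed + 7919 * k + i)
            aug.source_id = f"{p.source_id}#aug{k}"
            out.append(aug)
    return out


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def _read_image(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64)
    return arr / 255.0


def _read_mask(path: Path, stem: str) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    binary = (arr > 127).astype(np.uint8)
    leftovers = np.unique(arr[(arr != 0) & (arr != 255)])
    if leftovers.size:
        warnings.warn(
            f"mask {stem!r} has non-binary values {leftovers[:5]}; thresholded at 127",
            stacklevel=3,
        )
    return binary


def load_dataset(spec: DatasetSpec, root: str | Path) -> list[ImagePair]:
    """Load image/mask pairs from ``root/images`` and ``root/masks``.

    Pairs are matched by filename stem and returned in lexical order; masks
    are binarized at 127/255. Unmatched stems raise with their names.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(f"expected {img_dir} and {mask_dir}")
    images = {f.stem: f for f in sorted(img_dir.iterdir()) if f.is_file()}
    masks = {f.stem: f for f in sorted(mask_dir.iterdir()) if f.is_file()}
    wanted = sorted(spec.train_ids + spec.test_ids) or sorted(images)
    missing_img = [s for s in wanted if s not in images]
    missing_mask = [s for s in wanted if s not in masks]
    if missing_img or missing_mask:
        raise FileNotFoundError(
            f"unmatched stems — missing images: {missing_img}, missing masks: {missing_mask}"
        )
    pairs = []
    for stem in wanted:
        pairs.append(
            ImagePair(_read_image(images[stem]), _read_mask(masks[stem], stem), source_id=stem)
        )
    return pairs


def spec_from_dir(root: str | Path, name: str | None = None) -> DatasetSpec:
    """Build a DatasetSpec from a dataset directory.

    Reads ``partition.txt`` (lines ``train <stem>`` / ``test <stem>``) when
    present, infers the native size from the first image, and pads the
    target up to the next multiple of 16. A known benchmark name (drive,
    chase_db1, stare) selects the published target size instead.
    """
    root = Path(root)
    name = name or root.name
    train_ids: list[str] = []
    test_ids: list[str] = []
    part = root / "partition.txt"
    if part.exists():
        for line in part.read_text().splitlines():
            fields = line.split()
            if len(fields) != 2 or fields[0] not in ("train", "test"):
                raise ValueError(f"malformed partition line: {line!r}")
            (train_ids if fields[0] == "train" else test_ids).append(fields[1])
    img_dir = root / "images"
    first = next(iter(sorted(img_dir.iterdir())), None)
    if first is None:
        raise FileNotFoundError(f"no images under {img_dir}")
    with Image.open(first) as im:
        nw, nh = im.size
    if name in STANDARD_SPECS:
        std = STANDARD_SPECS[name]
        target = std.target_size
        crop = std.crop_size
    else:
        target = (-(-nh // 16) * 16, -(-nw // 16) * 16)
        crop = None
    return DatasetSpec(name=name, native_size=(nh, nw), target_size=target,
                       crop_size=crop, train_ids=train_ids, test_ids=test_ids)


def save_pair(p: ImagePair, img_path: str | Path, mask_path: str | Path) -> None:
    Image.fromarray((np.clip(p.image, 0, 1) * 255).round().astype(np.uint8)).save(img_path)
    Image.fromarray((p.mask * 255).astype(np.uint8)).save(mask_path)
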