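"""Synthetic image/mask pairs in three medical-segmentation morphologies.

Real 2-D medical segmentation benchmarks fall into a few characteristic mask
morphologies, and the generator emulates one of each:

* ``lesion`` — several overlapping mid-sized blobs with fuzzy intensity, the
  diffuse multi-focal appearance of infected lung regions in axial CT;
* ``polyp``  — a single large smooth region with a perturbed boundary, as in
  colonoscopy polyp frames;
* ``nuclei`` — many small, well-separated round objects, as in stained
  nucleus microscopy tiles.

Objects are random ellipses (with a radially perturbed boundary for the polyp
style).  The image is formed as ``bg + (fg - bg) * mask``, Gaussian-blurred,
corrupted with additive Gaussian noise and clipped to [0, 1]; the stored mask
is the exact pre-corruption object union.  Generation is a pure function of
``(spec.seed, index)``.

On disk a dataset is ``<root>/images/<id>.png``, ``<root>/masks/<id>.png``
(8-bit grayscale; masks use {0, 255}) plus a ``manifest.tsv``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

STYLES = ("lesion", "polyp", "nuclei")


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one style of synthetic sample."""

    style: str
    image_size: int = 128
    n_objects: tuple[int, int] = (1, 1)
    intensity_fg: float = 0.75
    intensity_bg: float = 0.25
    noise_sd: float = 0.05
    blur_sd: float = 1.0
    seed: int = 0

    def validate(self):
        if self.style not in STYLES:
            raise ConfigurationError(f"unknown style {self.style!r}")
        if self.image_size < 16 or self.image_size % 8:
            raise ConfigurationError(
                f"image_size must be >= 16 and divisible by 8, got {self.image_size}")
        lo, hi = self.n_objects
        if lo > hi or lo < 1:
            raise ConfigurationError(f"empty n_objects range {self.n_objects}")
        if self.style == "polyp" and self.n_objects != (1, 1):
            raise ConfigurationError("polyp style requires n_objects == (1, 1)")
        for name in ("intensity_fg", "intensity_bg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.blur_sd < 0:
            raise ConfigurationError("noise_sd and blur_sd must be non-negative")


def default_spec(style: str, image_size: int = 128, seed: int = 0) -> ShapeSpec:
    """The reference recipe for each style."""
    n_objects = {"lesion": (3, 8), "polyp": (1, 1), "nuclei": (8, 20)}[style]
    spec = ShapeSpec(style=style, image_size=image_size, n_objects=n_objects,
                     seed=seed)
    spec.validate()
    return spec


@dataclass(frozen=True)
class SegSample:
    """A paired grayscale image and binary mask."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def validate(self):
        if self.image.shape != self.mask.shape:
            raise DataError(f"{self.id}: image/mask shape mismatch")
        if not np.isin(self.mask, (0, 1)).all():
            raise DataError(f"{self.id}: mask is not binary")


# ---------------------------------------------------------------------------
# object placement
# ---------------------------------------------------------------------------

def _radius_range(style: str, size: int) -> tuple[float, float]:
    if style == "lesion":
        return 0.06 * size, 0.16 * size
    if style == "polyp":
        return 0.22 * size, 0.34 * size
    return 0.02 * size, 0.045 * size  # nuclei


def _one_ellipse(rng, style, size) -> np.ndarray:
    r_lo, r_hi = _radius_range(style, size)
    ry, rx = rng.uniform(r_lo, r_hi, size=2)
    margin = max(ry, rx) + 2
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    rot = rng.uniform(0, np.pi)
    mask = np.zeros((size, size), dtype=bool)
    if style == "polyp":
        # radially perturbed boundary: r(theta) with a low-order sinusoid
        theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        k = rng.integers(3, 7)
        amp = rng.uniform(0.05, 0.15)
        phase = rng.uniform(0, 2 * np.pi)
        wobble = 1.0 + amp * np.sin(k * theta + phase)
        rows = cy + ry * wobble * np.sin(theta)
        cols = cx + rx * wobble * np.cos(theta)
        rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    else:
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=mask.shape, rotation=rot)
    mask[rr, cc] = True
    return mask


def object_union(spec: ShapeSpec, index: int) -> np.ndarray:
    """The exact union of placed objects for (spec, index) — the mask source."""
    spec.validate()
    if index < 0:
        raise ConfigurationError("index must be non-negative")
    rng = np.random.default_rng((spec.seed & 0x7FFFFFFF, index))
    size = spec.image_size
    for _attempt in range(64):
        n = int(rng.integers(spec.n_objects[0], spec.n_objects[1] + 1))
        mask = np.zeros((size, size), dtype=bool)
        placed = 0
        tries = 0
        while placed < n and tries < 400:
            tries += 1
            obj = _one_ellipse(rng, spec.style, size)
            if not obj.any():
                continue
            if spec.style == "nuclei":
                # keep objects disjoint with a >=2 px gap so components count
                grown = ndimage.binary_dilation(obj, iterations=2)
                if (grown & mask).any():
                    continue
            mask |= obj
            placed += 1
        frac = mask.mean()
        if placed == n and 0.0 < frac < 0.6:
            return mask
    raise ConfigurationError(
        f"could not place objects for spec {spec} (foreground fraction/overlap "
        f"constraints unsatisfiable)")


def generate_sample(spec: ShapeSpec, index: int) -> SegSample:
    """Deterministic image/mask pair for (spec.seed, index)."""
    mask = object_union(spec, index)
    rng = np.random.default_rng((spec.seed & 0x7FFFFFFF, index, 1))
    image = spec.intensity_bg + (spec.intensity_fg - spec.intensity_bg) * mask
    if spec.blur_sd > 0:
        image = ndimage.gaussian_filter(image, spec.blur_sd)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    sample = SegSample(image=image, mask=mask.astype(np.uint8),
                       id=f"{spec.style}-{spec.seed}-{index:04d}")
    sample.validate()
    return sample


# ---------------------------------------------------------------------------
# on-disk format
# ---------------------------------------------------------------------------

def _write_png(path: Path, grid: np.ndarray):
    Image.fromarray(grid.astype(np.uint8), mode="L").save(path)


def write_sample(sample: SegSample, root: Path):
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    _write_png(root / "images" / f"{sample.id}.png",
               np.round(sample.image * 255.0))
    _write_png(root / "masks" / f"{sample.id}.png", sample.mask * 255)


def generate_dataset(spec: ShapeSpec, n: int, out_dir) -> list[str]:
    """Write n samples plus a manifest; returns the sample ids."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    spec.validate()
    out_dir = Path(out_dir)
    ids = []
    try:
        for index in range(n):
            sample = generate_sample(spec, index)
            write_sample(sample, out_dir)
            ids.append((sample.id, index))
        with open(out_dir / "manifest.tsv", "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["id", "style", "seed", "index"])
            for sample_id, index in ids:
                writer.writerow([sample_id, spec.style, spec.seed, index])
    except OSError as err:
        raise OSError(f"failed writing dataset under {out_dir}: {err}") from err
    return [sample_id for sample_id, _ in ids]


def read_manifest(root) -> list[str]:
    root = Path(root)
    path = root / "manifest.tsv"
    if not path.exists():
        raise DataError(f"no manifest.tsv under {root}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [row["id"] for row in reader]


def read_sample(image_path, mask_path, target_size: int) -> SegSample:
    """Load a PNG pair, rescale to [0,1] and resize to ``target_size``.

    The image is resized bilinearly; the mask with nearest-neighbour and then
    re-binarised at 0.5 so no interpolated grey levels survive.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise DataError(f"missing file: {p}")
    img = Image.open(image_path).convert("L")
    msk = Image.open(mask_path).convert("L")
    levels = np.unique(np.asarray(msk))
    if len(levels) > 2:
        raise DataError(f"mask {mask_path} has more than two levels: {levels[:5]}")
    if img.size != (target_size, target_size):
        img = img.resize((target_size, target_size), Image.BILINEAR)
    if msk.size != (target_size, target_size):
        msk = msk.resize((target_size, target_size), Image.NEAREST)
    image = np.asarray(img, dtype=np.float64) / 255.0
    mask = (np.asarray(msk, dtype=np.float64) / 255.0 >= 0.5).astype(np.uint8)
    sample = SegSample(image=image, mask=mask, id=image_path.stem)
    sample.validate()
    return sample


def load_dataset(root, target_size: int) -> list[SegSample]:
    """Read every manifest entry as a SegSample at ``target_size``."""
    root = Path(root)
    samples = []
    for sample_id in read_manifest(root):
        samples.append(read_sample(root / "images" / f"{sample_id}.png",
                                   root / "masks" / f"{sample_id}.png",
                                   target_size))
    return samples
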