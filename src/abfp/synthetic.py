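"""Deterministic synthetic inputs: random feature pyramids and lesion scenes.

The image generator emulates the qualitative regime of abdominal CT slices
containing stromal-tumour-like lesions: a smooth random-field background,
one or more low-contrast elliptical lesions with blurred edges and random
orientation/eccentricity, and additive Gaussian noise.  Boxes are tight to
the ellipse extents.  Everything is a pure function of the seed, so
datasets regenerate bit-identically.

It deliberately does not model several properties of real CT: Hounsfield
calibration, organ anatomy and confusable neighbouring structures,
multi-phase contrast enhancement, inter-slice 3-d context, or scanner
artefacts.  Passing detection tests here demonstrates that the pipeline is
wired correctly and can learn low-contrast blobs, not clinical performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pyramid import FeaturePyramid

__all__ = ["LesionSceneSpec", "make_pyramid", "make_lesion_scene", "make_lesion_dataset"]


def make_pyramid(n_levels: int, channels: int, base_hw: tuple[int, int],
                 seed: int | np.random.Generator = 0) -> FeaturePyramid:
    """Standard-normal feature pyramid with ceil-halving spatial shapes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = base_hw
    levels = []
    for _ in range(n_levels):
        levels.append(rng.standard_normal((channels, h, w)).astype(np.float32))
        h, w = -(-h // 2), -(-w // 2)
    return FeaturePyramid(levels=levels)


@dataclass
class LesionSceneSpec:
    """Generation parameters for one family of lesion scenes.

    ``contrast`` is the intensity gap between lesion interior and local
    background on the [0, 1] grey scale; the default 0.15 keeps lesions
    low-contrast, mimicking tumours whose grey values sit close to the
    surrounding tissue.  ``background_sigma``/``background_amplitude``
    shape the smooth random field standing in for soft-tissue texture.
    """

    image_size: int = 128
    n_lesions: int = 2
    contrast: float = 0.15
    noise_sigma: float = 0.02
    background_sigma: float = 8.0
    background_amplitude: float = 0.08
    background_level: float = 0.45
    edge_sigma: float = 1.0
    min_semi_axis: float = 6.0
    max_semi_axis: float = 16.0
    seed: int = 0

    def __post_init__(self):
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if 2 * self.max_semi_axis >= self.image_size:
            raise ValueError("lesion larger than image")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _mask_extent_box(mask: np.ndarray) -> list[float]:
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    y1, y2 = int(rows[0]), int(rows[-1]) + 1
    x1, x2 = int(cols[0]), int(cols[-1]) + 1
    return [float(x1), float(y1), float(x2 - x1), float(y2 - y1)]  # COCO [x, y, w, h]


def make_lesion_scene(spec: LesionSceneSpec, rng: np.random.Generator):
    """One image (float [0,1]) plus per-lesion COCO [x,y,w,h] boxes and masks."""
    s = spec.image_size
    background = ndimage.gaussian_filter(
        rng.standard_normal((s, s)), spec.background_sigma, mode="reflect"
    )
    std = background.std()
    if std > 0:
        background = background / std * spec.background_amplitude
    image = spec.background_level + background
    lesion_field = np.zeros((s, s), dtype=np.float64)
    boxes, masks = [], []
    for _ in range(spec.n_lesions):
        a = rng.uniform(spec.min_semi_axis, spec.max_semi_axis)
        b = rng.uniform(spec.min_semi_axis, spec.max_semi_axis)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 1.0
        cy = rng.uniform(margin, s - margin)
        cx = rng.uniform(margin, s - margin)
        mask = _ellipse_mask(s, cy, cx, a, b, theta)
        lesion_field = np.maximum(lesion_field, mask.astype(np.float64))
        boxes.append(_mask_extent_box(mask))
        masks.append(mask)
    if spec.edge_sigma > 0 and spec.n_lesions:
        lesion_field = ndimage.gaussian_filter(lesion_field, spec.edge_sigma, mode="constant")
    image = image + spec.contrast * lesion_field
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(s, s))
    return np.clip(image, 0.0, 1.0).astype(np.float32), boxes, masks


def make_lesion_dataset(spec: LesionSceneSpec, n_images: int,
                        out_dir: str | Path | None = None):
    """Generate ``n_images`` scenes and a COCO-dialect annotation dict.

    Returns ``(images, coco)`` where ``images`` is a list of float32 arrays
    and ``coco`` has ``images``, ``annotations`` (bbox ``[x, y, w, h]``,
    one per lesion) and ``categories``.  With ``out_dir`` set, images are
    also written as 8-bit grayscale PNGs next to ``annotations.json``.
    """
    rng = np.random.default_rng(spec.seed)
    images, image_records, annotations = [], [], []
    ann_id = 1
    for i in range(n_images):
        img, boxes, _ = make_lesion_scene(spec, rng)
        images.append(img)
        image_records.append({
            "id": i,
            "file_name": f"slice_{i:05d}.png",
            "width": spec.image_size,
            "height": spec.image_size,
        })
        for box in boxes:
            annotations.append({
                "id": ann_id,
                "image_id": i,
                "category_id": 1,
                "bbox": box,
                "area": box[2] * box[3],
                "iscrowd": 0,
            })
            ann_id += 1
    coco = {
        "images": image_records,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "lesion"}],
        "info": {"generator": asdict(spec), "n_images": n_images},
    }
    if out_dir is not None:
        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, img in zip(image_records, images):
            arr = np.round(img * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out_dir / rec["file_name"])
        with open(out_dir / "annotations.json", "w") as fh:
            json.dump(coco, fh)
    return images, coco


def load_lesion_dataset(data_dir: str | Path):
    """Read back a dataset written by :func:`make_lesion_dataset`."""
    from PIL import Image

    data_dir = Path(data_dir)
    with open(data_dir / "annotations.json") as fh:
        coco = json.load(fh)
    images = []
    for rec in coco["images"]:
        arr = np.asarray(Image.open(data_dir / rec["file_name"]), dtype=np.float32) / 255.0
        images.append(arr)
    return images, coco


def split_dataset(coco: dict, train_fraction: float = 0.8):
    """Deterministic train/validation split by image index."""
    ids = [rec["id"] for rec in coco["images"]]
    n_train = int(round(train_fraction * len(ids)))
    return ids[:n_train], ids[n_train:]
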