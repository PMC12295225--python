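"""Dataset handling: image-folder I/O, the training augmentation protocol,
Gaussian-noise perturbation, and a synthetic cell-image generator.

The generator produces four procedurally drawn morphology classes that
mimic cultured retinal-pigment-epithelium imagery: *fusiform* (elongated
spindle cells), *epithelioid* (rounded blobs with nuclei), *cobblestone*
(a dense polygonal monolayer tessellation) and *mixed* (a blend of the
first two).  It exists so every training / robustness harness runs with
zero downloads; the real datasets remain optional image folders.

Training images are randomly rotated within ±15°, passed through the
standard IMAGENET AutoAugment policy, resized to the model input size
and standardized with the usual ImageNet channel statistics
(mean [0.485, 0.456, 0.406], std [0.229, 0.224, 0.225]).  Evaluation uses
resize + normalize only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageEnhance, ImageOps
from skimage.draw import ellipse as _sk_ellipse
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "IMAGENET_MEAN", "IMAGENET_STD",
    "LabeledImageSet", "SyntheticDatasetSpec",
    "train_transform", "eval_transform", "normalize", "denormalize",
    "split_dataset", "add_gaussian_noise", "generate_synthetic",
    "save_image_folder", "load_image_folder",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

CLASS_NAMES = ("fusiform", "epithelioid", "cobblestone", "mixed")


@dataclass
class LabeledImageSet:
    """Images (uint8 RGB, HWC) with integer labels and class names."""

    images: list
    labels: list
    class_names: tuple
    split: str = "all"

    def __post_init__(self):
        n_cls = len(self.class_names)
        if any(not (0 <= int(l) < n_cls) for l in self.labels):
            raise ValueError("labels must lie in [0, num_classes)")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must align")

    def __len__(self):
        return len(self.images)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(np.asarray(self.labels), minlength=self.num_classes)


@dataclass
class SyntheticDatasetSpec:
    num_classes: int = 4
    per_class_count: int = 16
    image_size: int = 224
    elongation: float = 6.0          # fusiform major/minor axis ratio
    blob_count: int = 12             # epithelioid blobs per image
    tessellation_density: int = 8    # cobblestone cells per image side
    background_noise: float = 0.03   # background intensity sd on [0,1]
    seed: int = 0


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------

def _to_pil(image) -> Image.Image:
    if isinstance(image, Image.Image):
        img = image
    else:
        arr = np.asarray(image)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected an RGB (H, W, 3) image, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0, 1) * 255.0 if arr.max() <= 1.5 else arr
            arr = arr.astype(np.uint8)
        img = Image.fromarray(arr)
    if img.mode != "RGB":
        raise ValueError(f"expected an RGB image, got mode {img.mode!r}")
    return img


def normalize(x01: np.ndarray) -> np.ndarray:
    """Standardize a CHW [0,1] array with the ImageNet channel statistics."""
    return (x01 - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]


def denormalize(x: np.ndarray) -> np.ndarray:
    return x * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]


def eval_transform(image, size: int = 224) -> np.ndarray:
    """Bilinear resize + standardization (no augmentation); CHW float64."""
    img = _to_pil(image).resize((size, size), Image.BILINEAR)
    x01 = np.asarray(img, dtype=np.float64) / 255.0
    return normalize(x01.transpose(2, 0, 1))


def train_transform(image, size: int = 224, seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    rotation: float | None = None) -> np.ndarray:
    """Random ±15° rotation → IMAGENET AutoAugment → resize → standardize.

    Deterministic for a fixed ``seed`` (or caller-supplied generator);
    ``rotation`` overrides the sampled angle (used by closed-form tests).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    img = _to_pil(image)
    angle = rotation if rotation is not None else float(rng.uniform(-15.0, 15.0))
    img = img.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    img = _auto_augment(img, rng)
    img = img.resize((size, size), Image.BILINEAR)
    x01 = np.asarray(img, dtype=np.float64) / 255.0
    return normalize(x01.transpose(2, 0, 1))


def add_gaussian_noise(image01: np.ndarray, sigma: float = 0.05,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Additive zero-mean Gaussian noise (sd ``sigma`` on the [0,1] scale),
    clipped back to [0, 1].  Applied after resize, before standardization."""
    if rng is None:
        rng = np.random.default_rng(seed)
    image01 = np.asarray(image01, dtype=np.float64)
    if sigma == 0:
        return image01.copy()
    return np.clip(image01 + rng.normal(0.0, sigma, size=image01.shape), 0.0, 1.0)


def split_dataset(ds: LabeledImageSet, ratio: float = 0.8, seed: int = 0):
    """Stratified train/test split: per class, shuffled, sizes within one
    image of the requested ratio; disjoint and exhaustive."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(ds.labels)
    train_idx, test_idx = [], []
    for c in range(ds.num_classes):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(round(len(idx) * ratio))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])

    def subset(indices, split):
        return LabeledImageSet([ds.images[i] for i in indices],
                               [ds.labels[i] for i in indices],
                               ds.class_names, split=split)

    return subset(sorted(train_idx), "train"), subset(sorted(test_idx), "test")


# --------------------------------------------------------------------------
# AutoAugment (IMAGENET policy) on PIL primitives
# --------------------------------------------------------------------------

def _shear_x(img, m):
    return img.transform(img.size, Image.AFFINE, (1, m, 0, 0, 1, 0), Image.BILINEAR)


def _shear_y(img, m):
    return img.transform(img.size, Image.AFFINE, (1, 0, 0, m, 1, 0), Image.BILINEAR)


def _translate_x(img, m):
    return img.transform(img.size, Image.AFFINE, (1, 0, m * img.size[0], 0, 1, 0),
                         Image.BILINEAR)


def _translate_y(img, m):
    return img.transform(img.size, Image.AFFINE, (1, 0, 0, 0, 1, m * img.size[1]),
                         Image.BILINEAR)


_AA_OPS = {
    "ShearX": (_shear_x, 0.3, True),
    "ShearY": (_shear_y, 0.3, True),
    "TranslateX": (_translate_x, 0.45, True),
    "TranslateY": (_translate_y, 0.45, True),
    "Rotate": (lambda img, m: img.rotate(m, resample=Image.BILINEAR), 30.0, True),
    "Color": (lambda img, m: ImageEnhance.Color(img).enhance(1.0 + m), 0.9, True),
    "Contrast": (lambda img, m: ImageEnhance.Contrast(img).enhance(1.0 + m), 0.9, True),
    "Brightness": (lambda img, m: ImageEnhance.Brightness(img).enhance(1.0 + m), 0.9, True),
    "Sharpness": (lambda img, m: ImageEnhance.Sharpness(img).enhance(1.0 + m), 0.9, True),
    "Posterize": (lambda img, m: ImageOps.posterize(img, int(m)), None, False),
    "Solarize": (lambda img, m: ImageOps.solarize(img, int(m)), None, False),
    "AutoContrast": (lambda img, m: ImageOps.autocontrast(img), None, False),
    "Equalize": (lambda img, m: ImageOps.equalize(img), None, False),
    "Invert": (lambda img, m: ImageOps.invert(img), None, False),
}

# the standard 25 sub-policy IMAGENET table: (op, probability, magnitude bin 0–9)
_IMAGENET_POLICY = [
    (("Posterize", 0.4, 8), ("Rotate", 0.6, 9)),
    (("Solarize", 0.6, 5), ("AutoContrast", 0.6, None)),
    (("Equalize", 0.8, None), ("Equalize", 0.6, None)),
    (("Posterize", 0.6, 7), ("Posterize", 0.6, 6)),
    (("Equalize", 0.4, None), ("Solarize", 0.2, 4)),
    (("Equalize", 0.4, None), ("Rotate", 0.8, 8)),
    (("Solarize", 0.6, 3), ("Equalize", 0.6, None)),
    (("Posterize", 0.8, 5), ("Equalize", 1.0, None)),
    (("Rotate", 0.2, 3), ("Solarize", 0.6, 8)),
    (("Equalize", 0.6, None), ("Posterize", 0.4, 6)),
    (("Rotate", 0.8, 8), ("Color", 0.4, 0)),
    (("Rotate", 0.4, 9), ("Equalize", 0.6, None)),
    (("Equalize", 0.0, None), ("Equalize", 0.8, None)),
    (("Invert", 0.6, None), ("Equalize", 1.0, None)),
    (("Color", 0.6, 4), ("Contrast", 1.0, 8)),
    (("Rotate", 0.8, 8), ("Color", 1.0, 2)),
    (("Color", 0.8, 8), ("Solarize", 0.8, 7)),
    (("Sharpness", 0.4, 7), ("Invert", 0.6, None)),
    (("ShearX", 0.6, 5), ("Equalize", 1.0, None)),
    (("Color", 0.4, 0), ("Equalize", 0.6, None)),
    (("Equalize", 0.4, None), ("Solarize", 0.2, 4)),
    (("Solarize", 0.6, 5), ("AutoContrast", 0.6, None)),
    (("Invert", 0.6, None), ("Equalize", 1.0, None)),
    (("Color", 0.6, 4), ("Contrast", 1.0, 8)),
    (("Equalize", 0.8, None), ("Equalize", 0.6, None)),
]


def _aa_magnitude(op: str, bin_idx):
    if op == "Posterize":
        return 8 - int(bin_idx * 4 / 9)          # 8 → 4 bits
    if op == "Solarize":
        return 255 - int(bin_idx * 255 / 9)      # 255 → 0 threshold
    _, max_m, _signed = _AA_OPS[op]
    return max_m * bin_idx / 9.0


def _auto_augment(img: Image.Image, rng: np.random.Generator) -> Image.Image:
    sub = _IMAGENET_POLICY[int(rng.integers(len(_IMAGENET_POLICY)))]
    for op, prob, bin_idx in sub:
        apply = rng.random() < prob
        fn, _max_m, signed = _AA_OPS[op]
        m = 0.0 if bin_idx is None else _aa_magnitude(op, bin_idx)
        if signed and rng.random() < 0.5:
            m = -m
        if apply:
            img = fn(img, m)
    return img


# --------------------------------------------------------------------------
# synthetic cell-image generator
# --------------------------------------------------------------------------

def _blank(size: int, rng, noise_sd: float) -> np.ndarray:
    base = rng.uniform(0.10, 0.20)
    img = np.full((size, size, 3), base)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return img


def _paint(img, rr, cc, color, rng, jitter=0.04):
    c = np.clip(np.asarray(color) + rng.normal(0, jitter, 3), 0, 1)
    img[rr, cc] = 0.2 * img[rr, cc] + 0.8 * c


def _draw_fusiform(img, rng, spec, count=None):
    """Sparse, strongly elongated spindle cells at random orientations."""
    s = spec.image_size
    for _ in range(count if count is not None else rng.integers(10, 13)):
        r, c = rng.uniform(0.1 * s, 0.9 * s, 2)
        major = rng.uniform(0.11, 0.15) * s
        minor = max(1.5, major / (spec.elongation * rng.uniform(0.9, 1.15)))
        rr, cc = _sk_ellipse(r, c, major, minor, shape=(s, s),
                             rotation=rng.uniform(0, np.pi))
        _paint(img, rr, cc, (0.80, 0.40, 0.55), rng)


def _draw_epithelioid(img, rng, spec, count=None):
    """Rounded blobs with a darker nucleus dot."""
    s = spec.image_size
    if count is None:
        count = rng.integers(spec.blob_count - 2, spec.blob_count + 3)
    for _ in range(count):
        r, c = rng.uniform(0.08 * s, 0.92 * s, 2)
        rad = rng.uniform(0.055, 0.075) * s
        rr, cc = _sk_ellipse(r, c, rad, rad * rng.uniform(0.85, 1.15), shape=(s, s),
                             rotation=rng.uniform(0, np.pi))
        _paint(img, rr, cc, (0.45, 0.75, 0.55), rng)
        nr, nc = _sk_ellipse(r, c, rad * 0.3, rad * 0.3, shape=(s, s))
        _paint(img, nr, nc, (0.25, 0.30, 0.45), rng, jitter=0.03)


def _draw_cobblestone(img, rng, spec):
    """Dense jittered polygonal tessellation with bright cell borders."""
    s = spec.image_size
    n = spec.tessellation_density
    cell = s / n
    for i in range(n):
        for j in range(n):
            cy, cx = (i + 0.5) * cell, (j + 0.5) * cell
            k = rng.integers(5, 8)
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            rad = cell * rng.uniform(0.38, 0.52, k)
            rows = np.clip(cy + rad * np.sin(ang) + rng.normal(0, 0.06 * cell), 0, s - 1)
            cols = np.clip(cx + rad * np.cos(ang) + rng.normal(0, 0.06 * cell), 0, s - 1)
            rr, cc = _sk_polygon(rows, cols, shape=(s, s))
            _paint(img, rr, cc, (0.80, 0.75, 0.55), rng, jitter=0.08)


def _draw_mixed(img, rng, spec):
    """Balanced co-occurrence of both morphologies in one field."""
    _draw_fusiform(img, rng, spec, count=int(rng.integers(5, 7)))
    _draw_epithelioid(img, rng, spec, count=max(3, spec.blob_count // 2))


_PAINTERS = (_draw_fusiform, _draw_epithelioid, _draw_cobblestone, _draw_mixed)


def generate_synthetic(spec: SyntheticDatasetSpec) -> LabeledImageSet:
    """Deterministic class-conditional procedural images (uint8 RGB)."""
    if not 1 <= spec.num_classes <= 4:
        raise ValueError("generator supports 1–4 morphology classes")
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for cls in range(spec.num_classes):
        for _ in range(spec.per_class_count):
            img = _blank(spec.image_size, rng, spec.background_noise)
            _PAINTERS[cls](img, rng, spec)
            images.append((np.clip(img, 0, 1) * 255).astype(np.uint8))
            labels.append(cls)
    return LabeledImageSet(images, labels, CLASS_NAMES[: spec.num_classes])


# --------------------------------------------------------------------------
# image-folder I/O (one directory per class)
# --------------------------------------------------------------------------

_IMG_EXT = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def save_image_folder(ds: LabeledImageSet, root: str):
    for name in ds.class_names:
        os.makedirs(os.path.join(root, name), exist_ok=True)
    counters = {}
    for img, label in zip(ds.images, ds.labels):
        name = ds.class_names[label]
        i = counters.get(name, 0)
        counters[name] = i + 1
        Image.fromarray(img).save(os.path.join(root, name, f"{name}_{i:05d}.png"))


def load_image_folder(root: str) -> LabeledImageSet:
    class_names = tuple(sorted(
        d for d in os.listdir(root) if os.path.isdir(os.path.join(root, d))))
    if not class_names:
        raise ValueError(f"no class directories under {root}")
    images, labels = [], []
    for label, name in enumerate(class_names):
        cdir = os.path.join(root, name)
        for fname in sorted(os.listdir(cdir)):
            if fname.lower().endswith(_IMG_EXT):
                img = Image.open(os.path.join(cdir, fname)).convert("RGB")
                images.append(np.asarray(img))
                labels.append(label)
    return LabeledImageSet(images, labels, class_names)
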