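"""Synthetic brain-slice phantoms with ground-truth tumor masks.

Real brain-tumor MRI collections (T1-weighted contrast-enhanced axial
slices with expert tumor masks and one of three diagnoses: meningioma,
glioma, pituitary) require external downloads.  This module generates
desk-scale stand-ins: an elliptical "brain" on a dark background with a
smooth multiplicative intensity-inhomogeneity (bias) field, additive
noise, and a single bright lesion whose location prior, boundary
regularity and internal texture depend on the class label:

* ``pituitary`` — small, compact, near the inferior midline (the sellar
  region sits low and central in an axial/coronal view);
* ``meningioma`` — smooth and attached to the brain periphery (these
  tumors arise from the meninges);
* ``glioma`` — larger, with an irregular infiltrative boundary and
  internal texture.

The class-conditional geometry is deliberately overlapping in raw
intensity, so a trivial brightness threshold cannot separate the
classes, while shape and location remain informative for the full
pipeline.  Everything is deterministic under a seed.

The module also hosts the dataset-level preprocessing used by the
pipeline: min–max intensity normalization to [0, 1] and the 4x
rotation/flip augmentation scheme (original + one rotation + horizontal
flip + vertical flip), which maps a 3,064-image dataset to exactly
12,256 images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

CLASS_NAMES = ("meningioma", "glioma", "pituitary")
#: Two-class mode used for benign/malignant style datasets.
CLASS_NAMES_BINARY = ("benign", "malignant", "none")

#: Minimum contrast between tumor mean and surrounding brain mean that the
#: generator is designed to guarantee (on the [0, 1] intensity scale).
MIN_TUMOR_CONTRAST = 0.10

_MIN_IMAGE_SIZE = 32


class PhantomError(ValueError):
    """Raised for invalid phantom specifications (e.g. image too small)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic brain-slice phantom.

    Parameters
    ----------
    image_size:
        Pixels per side of the square grid; must be >= 32 so that the
        smallest (pituitary) lesion still covers several pixels.
    class_label:
        One of :data:`CLASS_NAMES` (or any label in a custom class set).
    noise_sd:
        Standard deviation of additive Gaussian noise on the [0, 1]
        intensity scale.
    inhomogeneity_strength:
        Amplitude of the smooth multiplicative bias field (0 disables).
    seed:
        Integer RNG seed; the same (spec, seed) pair is bit-reproducible.
    """

    image_size: int = 64
    class_label: str = "glioma"
    noise_sd: float = 0.02
    inhomogeneity_strength: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < _MIN_IMAGE_SIZE:
            raise PhantomError(
                f"image_size={self.image_size} is too small to place a tumor; "
                f"need at least {_MIN_IMAGE_SIZE} pixels per side"
            )
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")


@dataclass
class LabeledImage:
    """A grayscale image in [0, 1] with a class label and optional mask."""

    pixels: np.ndarray
    label: str
    mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must match pixels shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean smooth random field, max-abs-normalized to [-1, 1]."""
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal((size, size))
    sm = gaussian_filter(raw, sigma, mode="reflect")
    sm -= sm.mean()
    peak = np.max(np.abs(sm))
    return sm / peak if peak > 0 else sm


def _ellipse_mask(size: int, cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    rr, cc_grid = np.mgrid[0:size, 0:size]
    return ((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2 <= 1.0


def _sample_tumor_center(
    rng: np.random.Generator,
    label: str,
    cr: float,
    cc: float,
    ar: float,
    ac: float,
) -> tuple[float, float, float]:
    """Class-conditional tumor center (row, col) and a size scale in [0,1].

    The same sampler backs the placement property tests, so the location
    priors live in one place.
    """
    if label == "pituitary":
        # Inferior (high row) midline: lower-central part of the ellipse.
        row = cr + ar * rng.uniform(0.38, 0.55)
        col = cc + ac * rng.uniform(-0.12, 0.12)
        scale = rng.uniform(0.16, 0.24)
    elif label == "meningioma":
        # Attached to the periphery: center at ~82% of the boundary radius.
        phi = rng.uniform(0, 2 * np.pi)
        frac = rng.uniform(0.72, 0.85)
        row = cr + ar * frac * np.sin(phi)
        col = cc + ac * frac * np.cos(phi)
        scale = rng.uniform(0.22, 0.32)
    elif label == "glioma":
        # Anywhere in the interior, biased away from the rim.
        phi = rng.uniform(0, 2 * np.pi)
        frac = np.sqrt(rng.uniform(0.0, 0.35))
        row = cr + ar * frac * np.sin(phi)
        col = cc + ac * frac * np.cos(phi)
        scale = rng.uniform(0.32, 0.46)
    else:
        # Unknown labels (two-class mode etc.) behave like gliomas.
        phi = rng.uniform(0, 2 * np.pi)
        frac = np.sqrt(rng.uniform(0.0, 0.35))
        row = cr + ar * frac * np.sin(phi)
        col = cc + ac * frac * np.cos(phi)
        scale = rng.uniform(0.28, 0.42)
    return row, col, scale


def _tumor_mask(
    rng: np.random.Generator,
    label: str,
    size: int,
    center: tuple[float, float],
    radius: float,
) -> np.ndarray:
    """Binary lesion footprint; glioma boundaries are perturbed radially."""
    rr, cc = np.mgrid[0:size, 0:size]
    dr = rr - center[0]
    dc = cc - center[1]
    dist = np.hypot(dr, dc)
    psi = np.arctan2(dr, dc)

    if label == "glioma":
        # Irregular boundary: low-order random radial harmonics.
        r_eff = np.full_like(dist, radius)
        for m in range(2, 6):
            amp = rng.uniform(0.04, 0.10) * radius
            phase = rng.uniform(0, 2 * np.pi)
            r_eff = r_eff + amp * np.cos(m * psi + phase)
        return dist <= r_eff
    # Smooth ellipse for meningioma / compact near-circle for pituitary.
    elong = rng.uniform(1.0, 1.25) if label == "meningioma" else rng.uniform(1.0, 1.1)
    theta = rng.uniform(0, np.pi)
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / (radius * elong)) ** 2 + (v / (radius / elong)) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Generate one synthetic brain slice with its ground-truth mask.

    Deterministic: the same spec (including its seed) always yields the
    same pixel grid, bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size

    # Brain ellipse with mild jitter; kept axis-aligned (upright head).
    cr = size / 2 + rng.uniform(-0.02, 0.02) * size
    cc = size / 2 + rng.uniform(-0.02, 0.02) * size
    ar = 0.42 * size * rng.uniform(0.95, 1.05)
    ac = 0.35 * size * rng.uniform(0.95, 1.05)
    brain = _ellipse_mask(size, cr, cc, ar, ac)

    img = np.full((size, size), 0.05)
    brain_base = rng.uniform(0.38, 0.48)
    texture = 0.03 * _smooth_field(rng, size, sigma=1.5)
    img[brain] = brain_base + texture[brain]

    row, col, scale = _sample_tumor_center(rng, spec.class_label, cr, cc, ar, ac)
    radius = scale * min(ar, ac)
    tumor = _tumor_mask(rng, spec.class_label, size, (row, col), radius) & brain
    if not tumor.any():  # pragma: no cover - geometry makes this unreachable
        raise PhantomError("tumor placement produced an empty mask")

    # Bright lesion; brightness ranges overlap across classes on purpose.
    tumor_base = rng.uniform(0.72, 0.90)
    img[tumor] = tumor_base + texture[tumor]
    if spec.class_label == "glioma":
        # Internal heterogeneity characteristic of infiltrative tumors.
        tex = 0.08 * _smooth_field(rng, size, sigma=1.0)
        img[tumor] += tex[tumor]

    if spec.inhomogeneity_strength > 0:
        bias = _smooth_field(rng, size, sigma=size / 4)
        img = img * (1.0 + spec.inhomogeneity_strength * bias)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(
        pixels=img,
        label=spec.class_label,
        mask=tumor,
        provenance={
            "generator": "phantom",
            "spec": {
                "image_size": spec.image_size,
                "class_label": spec.class_label,
                "noise_sd": spec.noise_sd,
                "inhomogeneity_strength": spec.inhomogeneity_strength,
                "seed": spec.seed,
            },
        },
    )


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """n distinct per-image seeds (< 2^31), deterministic in master_seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n, dtype=np.uint32) % np.uint32(2**31)


def generate_dataset(
    n_per_class: int | None = None,
    image_size: int = 64,
    seed: int = 0,
    *,
    class_counts: Mapping[str, int] | None = None,
    class_names: Sequence[str] = CLASS_NAMES,
    noise_sd: float = 0.02,
    inhomogeneity_strength: float = 0.15,
) -> list[LabeledImage]:
    """Generate a labeled phantom dataset.

    Either ``n_per_class`` (class-balanced) or ``class_counts`` (explicit
    per-class counts, e.g. the 708/1426/930 imbalance of the public
    three-class T1-CE collection) must be given.  Per-image seeds are
    derived deterministically from the master seed, so two calls with
    the same arguments produce identical images and label sequences.
    """
    if class_counts is None:
        if n_per_class is None or n_per_class < 1:
            raise ValueError("n_per_class must be >= 1 when class_counts is not given")
        class_counts = {name: n_per_class for name in class_names}
    total = sum(class_counts.values())
    seeds = _derive_seeds(seed, total)

    images: list[LabeledImage] = []
    i = 0
    for name, count in class_counts.items():
        for _ in range(count):
            spec = PhantomSpec(
                image_size=image_size,
                class_label=name,
                noise_sd=noise_sd,
                inhomogeneity_strength=inhomogeneity_strength,
                seed=int(seeds[i]),
            )
            images.append(generate_phantom(spec))
            i += 1
    return images


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def min_max_normalize(image: np.ndarray) -> np.ndarray:
    """Rescale intensities to [0, 1] by (x - min) / (max - min).

    A constant image has a degenerate range; it is mapped to all zeros
    and a warning is emitted rather than dividing by zero.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        warnings.warn(
            "min_max_normalize: constant image (degenerate range); returning zeros",
            stacklevel=2,
        )
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def _rotate(arr: np.ndarray, angle: float, *, is_mask: bool) -> np.ndarray:
    """Rotate; right-angle rotations are exact (no interpolation)."""
    angle = float(angle) % 360.0
    if angle in (0.0, 90.0, 180.0, 270.0):
        return np.rot90(arr, k=int(angle // 90))
    from skimage.transform import rotate as sk_rotate

    order = 0 if is_mask else 1  # nearest-neighbour keeps masks binary
    out = sk_rotate(arr.astype(float), angle, order=order, mode="constant", cval=0.0)
    return out > 0.5 if is_mask else out


def _transformed(image: LabeledImage, pixels, mask, transform: str) -> LabeledImage:
    prov = dict(image.provenance)
    prov["augmentation"] = transform
    return LabeledImage(pixels=pixels, label=image.label, mask=mask, provenance=prov)


def augment(
    image: LabeledImage,
    angles: Sequence[float] = (90.0, 180.0, 270.0),
    seed: int = 0,
) -> list[LabeledImage]:
    """Expand one image into exactly four: original, one random rotation,
    horizontal flip, vertical flip.

    The rotation angle is drawn from ``angles`` (defaults to the
    grid-aligned set {90, 180, 270}, which avoids interpolation).  Labels
    are preserved and masks undergo the identical transform.
    """
    if len(angles) == 0:
        raise ValueError("angles must be non-empty")
    rng = np.random.default_rng(seed)
    angle = float(angles[int(rng.integers(len(angles)))])

    has_mask = image.mask is not None
    out = [_transformed(image, image.pixels.copy(),
                        image.mask.copy() if has_mask else None, "original")]
    out.append(_transformed(
        image,
        _rotate(image.pixels, angle, is_mask=False),
        _rotate(image.mask, angle, is_mask=True) if has_mask else None,
        f"rotate:{angle:g}",
    ))
    out.append(_transformed(
        image, image.pixels[:, ::-1].copy(),
        image.mask[:, ::-1].copy() if has_mask else None, "hflip"))
    out.append(_transformed(
        image, image.pixels[::-1, :].copy(),
        image.mask[::-1, :].copy() if has_mask else None, "vflip"))
    return out


def augment_dataset(
    images: Iterable[LabeledImage],
    angles: Sequence[float] = (90.0, 180.0, 270.0),
    seed: int = 0,
) -> list[LabeledImage]:
    """Apply :func:`augment` to every image; output size is exactly 4x.

    Each augmented copy records the index of its source image in
    ``provenance["source_index"]`` so cross-validation can keep all
    variants of one source in the same fold.
    """
    images = list(images)
    seeds = _derive_seeds(seed, max(len(images), 1))
    out: list[LabeledImage] = []
    for idx, (img, s) in enumerate(zip(images, seeds)):
        for aug in augment(img, angles=angles, seed=int(s)):
            aug.provenance["source_index"] = idx
            out.append(aug)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_image(image: LabeledImage, path: str | Path, *, bit_depth: int = 8) -> None:
    """Write pixels as grayscale PNG/TIFF (8- or 16-bit) and, when a mask
    is present, a companion ``<stem>_mask.png`` with values {0, 255}."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.round(np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(np.clip(image.pixels, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
    if image.mask is not None:
        mask_arr = (image.mask.astype(np.uint8)) * 255
        iio.imwrite(path.with_name(path.stem + "_mask.png"), mask_arr)


def load_image(path: str | Path, label: str = "", mask_path: str | Path | None = None) -> LabeledImage:
    """Read a grayscale PNG/TIFF into a [0, 1] :class:`LabeledImage`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    scale = 65535.0 if arr.max() > 255 else 255.0
    mask = None
    if mask_path is not None:
        mask = np.asarray(iio.imread(mask_path)) > 127
    return LabeledImage(pixels=arr / scale, label=label, mask=mask,
                        provenance={"path": str(path)})


def load_mat_record(path: str | Path) -> LabeledImage:
    """Read one record of the public brain-tumor ``.mat`` layout.

    Each record is a struct ``cjdata`` with fields ``image``, ``label``
    (1 = meningioma, 2 = glioma, 3 = pituitary) and ``tumorMask``.  Both
    the legacy MAT dialect and the HDF5-backed dialect are handled.
    """
    path = Path(path)
    label_map = {1: "meningioma", 2: "glioma", 3: "pituitary"}
    try:
        from scipy.io import loadmat
        from scipy.io.matlab import MatReadError

        data = loadmat(path)["cjdata"]
        image = np.asarray(data["image"][0, 0], dtype=float)
        label_num = int(np.asarray(data["label"][0, 0]).ravel()[0])
        mask = np.asarray(data["tumorMask"][0, 0]) > 0
    except (NotImplementedError, MatReadError):
        # MATLAB v7.3 files are HDF5 under the hood
        import h5py

        with h5py.File(path, "r") as f:
            grp = f["cjdata"]
            image = np.asarray(grp["image"], dtype=float)
            label_num = int(np.asarray(grp["label"]).ravel()[0])
            mask = np.asarray(grp["tumorMask"]) > 0
    return LabeledImage(
        pixels=min_max_normalize(image),
        label=label_map.get(label_num, str(label_num)),
        mask=mask,
        provenance={"path": str(path), "format": "mat/cjdata"},
    )


def load_nifti_slice(path: str | Path, label: str = "",
                     slice_index: int | None = None,
                     axis: int = 2) -> LabeledImage:
    """Read one axial slice of a NIfTI volume as a [0, 1] image.

    ``slice_index`` defaults to the middle slice along ``axis``.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if vol.ndim == 2:
        sl = vol
    else:
        if slice_index is None:
            slice_index = vol.shape[axis] // 2
        sl = np.take(vol, slice_index, axis=axis)
    return LabeledImage(pixels=min_max_normalize(sl), label=label,
                        provenance={"path": str(path),
                                    "slice_index": slice_index,
                                    "format": "nifti"})


def write_manifest(
    records: Sequence[Mapping[str, object]], path: str | Path
) -> pd.DataFrame:
    """Write a dataset manifest CSV (path, label, split, provenance)."""
    df = pd.DataFrame(records, columns=["path", "label", "split", "provenance"])
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
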