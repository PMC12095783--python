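"""Edge-preserving MRI enhancement: guided filtering with anisotropic
Gaussian side windows (AGSW), plus morphological non-brain cleanup.

The guided filter assumes the output ``Z`` is locally a linear transform
of a guidance image ``Y`` within a window centred at ``k``::

    Z_i = a_k * Y_i + b_k

The coefficients minimise a weighted square-error loss against the input
``p`` with a ridge penalty on the gain::

    E(a_k, b_k) = sum_i w_i (a_k Y_i + b_k - p_i)^2 + eps * a_k^2

whose closed-form minimiser (``loss_form="standard"``) is::

    a_k = Cov_w(Y, p) / (Var_w(Y) + eps)
    b_k = E_w[p] - a_k E_w[Y]

where the expectations are taken under the window weights ``w``.  A
``loss_form="literal"`` variant shifts the guidance by one unit inside
the residual (``a_k Y_i + b_k + a_k - p_i``); it shares the same gain
and differs from the standard form only by ``-a_k`` in the bias.

What makes the filter edge-preserving here is the *weight bank*: for
each orientation theta, an anisotropic Gaussian (scales ``sigma_major``
along theta and ``sigma_minor`` across it) is restricted to nine side
windows — the full window plus four half windows and four quadrant
windows.  Near an edge, one of the one-sided windows fits the local
signal with much lower reconstruction error than a window straddling
the edge, so per pixel the side window with minimal weighted
reconstruction error is selected.  The per-window coefficients are then
aggregated into per-pixel fields by a weighted mean over every selected
window covering the pixel::

    a_bar_i = (1/xi) * sum_k w_k(i - k) a_k      (xi = sum of weights)

and the output is ``Z_i = a_bar_i Y_i + b_bar_i``.

The guidance image is gradient-derived: a blend of the (normalized)
image with its (normalized) gradient magnitude, so local structure
steers the filter.  After enhancement, a morphological pipeline
(threshold, binary opening, hole filling, largest connected component)
removes non-brain structures before segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import min_max_normalize

#: Fixed side-window ordering; ties in the selection go to the earliest.
SIDE_WINDOWS = ("full", "left", "right", "up", "down", "nw", "ne", "sw", "se")


@dataclass(frozen=True)
class AGSWParams:
    """Parameters of the AGSW-weighted guided filter.

    radius        window half-width r (window is (2r+1) x (2r+1))
    orientations  Gaussian orientations theta, degrees
    sigma_major   Gaussian scale along theta, pixels
    sigma_minor   Gaussian scale across theta, pixels
    epsilon       ridge regularizer on the gain, >= 0
    side_windows  subset of :data:`SIDE_WINDOWS` to consider
    loss_form     "standard" (default) or "literal"
    guidance_lambda  blend weight of the gradient magnitude in the guidance
    """

    radius: int = 4
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    sigma_major: float = 2.0
    sigma_minor: float = 0.8
    epsilon: float = 1e-3
    side_windows: tuple[str, ...] = SIDE_WINDOWS
    loss_form: str = "standard"
    guidance_lambda: float = 0.3

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValueError("need sigma_major >= sigma_minor > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.loss_form not in ("standard", "literal"):
            raise ValueError("loss_form must be 'standard' or 'literal'")
        unknown = set(self.side_windows) - set(SIDE_WINDOWS)
        if unknown:
            raise ValueError(f"unknown side windows: {sorted(unknown)}")


@dataclass
class GuidanceImage:
    """Gradient-derived guidance grid, same shape as the input."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("guidance must be finite")


@dataclass
class FilterCoeffs:
    """Per-pixel gain/bias fields of the aggregated guided filter."""

    a: np.ndarray
    b: np.ndarray


@dataclass(frozen=True)
class StructuringElement:
    shape: str = "disk"
    radius: int = 3

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.shape not in ("disk", "square"):
            raise ValueError("shape must be 'disk' or 'square'")

    def footprint(self) -> np.ndarray:
        from skimage.morphology import disk, square

        return disk(self.radius) if self.shape == "disk" else square(2 * self.radius + 1)


# ---------------------------------------------------------------------------
# guidance
# ---------------------------------------------------------------------------

def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude (replicated borders)."""
    gr, gc = np.gradient(np.asarray(image, dtype=float))
    return np.hypot(gr, gc)


def compute_gradient_guidance(
    image: np.ndarray, lam: float = 0.3
) -> GuidanceImage:
    """Build the guidance image from the input and its gradients.

    ``Y = (1 - lam) * norm(image) + lam * norm(|grad image|)`` with both
    terms min-max normalized.  A constant image (zero gradient
    everywhere) has no structure to inject and is returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    grad = gradient_magnitude(image)
    if not grad.any():
        return GuidanceImage(image.copy())
    return GuidanceImage(
        (1.0 - lam) * min_max_normalize(image) + lam * min_max_normalize(grad)
    )


# ---------------------------------------------------------------------------
# weight bank
# ---------------------------------------------------------------------------

def _side_window_indicator(name: str, du: np.ndarray, dv: np.ndarray) -> np.ndarray:
    if name == "full":
        return np.ones_like(du, dtype=bool)
    table = {
        "left": dv <= 0,
        "right": dv >= 0,
        "up": du <= 0,
        "down": du >= 0,
        "nw": (du <= 0) & (dv <= 0),
        "ne": (du <= 0) & (dv >= 0),
        "sw": (du >= 0) & (dv <= 0),
        "se": (du >= 0) & (dv >= 0),
    }
    return table[name]


def agsw_weight_bank(params: AGSWParams) -> dict[tuple[float, str], np.ndarray]:
    """Anisotropic Gaussian side-window masks.

    Returns one (2r+1) x (2r+1) mask per (orientation, side window):
    ``exp(-(u'^2 / 2 sigma_major^2 + v'^2 / 2 sigma_minor^2))`` in
    coordinates rotated by theta, times the side-window indicator, then
    normalized to unit sum.
    """
    r = params.radius
    du, dv = np.mgrid[-r : r + 1, -r : r + 1]
    bank: dict[tuple[float, str], np.ndarray] = {}
    for theta in params.orientations:
        t = np.deg2rad(theta)
        u = dv * np.cos(t) + du * np.sin(t)  # along theta
        v = -dv * np.sin(t) + du * np.cos(t)  # across theta
        gauss = np.exp(
            -(u**2 / (2 * params.sigma_major**2) + v**2 / (2 * params.sigma_minor**2))
        )
        for name in params.side_windows:
            mask = gauss * _side_window_indicator(name, du, dv)
            bank[(theta, name)] = mask / mask.sum()
    return bank


# ---------------------------------------------------------------------------
# coefficient fitting
# ---------------------------------------------------------------------------

def _check_finite(*arrays: np.ndarray) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in filter input")


def fit_window_coeffs(
    p: np.ndarray,
    Y: GuidanceImage | np.ndarray,
    w: np.ndarray,
    epsilon: float,
    loss_form: str = "standard",
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (a_k, b_k) at every window centre for one weight mask.

    Windowed weighted moments are computed by correlation with replicated
    borders, so centres near the edge use the same closed form on the
    padded signal.  A zero-variance window with ``epsilon == 0`` yields
    a gain of 0 (pure mean smoothing) rather than 0/0.
    """
    p = np.asarray(p, dtype=float)
    Y = Y.pixels if isinstance(Y, GuidanceImage) else np.asarray(Y, dtype=float)
    _check_finite(p, Y, w)

    def wmean(x: np.ndarray) -> np.ndarray:
        return ndimage.correlate(x, w, mode="nearest")

    mY = wmean(Y)
    mp = wmean(p)
    var = wmean(Y * Y) - mY**2
    cov = wmean(Y * p) - mY * mp
    denom = var + epsilon
    a = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
    if loss_form == "standard":
        b = mp - a * mY
    elif loss_form == "literal":
        b = mp - a * (mY + 1.0)
    else:
        raise ValueError("loss_form must be 'standard' or 'literal'")
    return a, b


def _reconstruction_error(
    p: np.ndarray, Y: np.ndarray, w: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Weighted residual E_w[(a Y + b - p)^2] at every window centre."""

    def wmean(x: np.ndarray) -> np.ndarray:
        return ndimage.correlate(x, w, mode="nearest")

    mY, mp = wmean(Y), wmean(p)
    mYY, mpp, mYp = wmean(Y * Y), wmean(p * p), wmean(Y * p)
    return (
        a**2 * mYY + b**2 + mpp + 2 * a * b * mY - 2 * a * mYp - 2 * b * mp
    )


def select_side_window(
    p: np.ndarray,
    Y: GuidanceImage | np.ndarray,
    coeffs: dict[str, tuple[np.ndarray, np.ndarray]],
    masks: dict[str, np.ndarray],
) -> np.ndarray:
    """Per-pixel index (into :data:`SIDE_WINDOWS` order) of the side
    window whose fit reconstructs the input with minimal weighted error.

    Ties break to the earliest window in the fixed ordering (so a
    uniform region selects "full" everywhere).
    """
    p = np.asarray(p, dtype=float)
    Y = Y.pixels if isinstance(Y, GuidanceImage) else np.asarray(Y, dtype=float)
    names = [n for n in SIDE_WINDOWS if n in coeffs]
    errs = np.stack(
        [_reconstruction_error(p, Y, masks[n], *coeffs[n]) for n in names]
    )
    # round-off guard: treat errors equal within 1e-12 as ties
    best = np.min(errs, axis=0)
    tie = errs <= best + 1e-12
    sel_local = np.argmax(tie, axis=0)  # first True along the stack
    order = np.array([SIDE_WINDOWS.index(n) for n in names])
    return order[sel_local]


def aggregate_coeffs(
    a_sel: np.ndarray,
    b_sel: np.ndarray,
    selection: np.ndarray,
    masks: dict[str, np.ndarray],
) -> FilterCoeffs:
    """Weighted mean of the selected per-window coefficients over every
    window covering each pixel (border handled by replicate padding, so
    the normalizer xi is never zero).

    ``a_sel``/``b_sel`` hold, at each window centre k, the coefficients
    of the side window selected there; ``selection`` holds its index.
    """
    some_mask = next(iter(masks.values()))
    r = some_mask.shape[0] // 2
    pad = lambda x: np.pad(x, r, mode="edge")  # noqa: E731
    a_p, b_p, sel_p = pad(a_sel), pad(b_sel), pad(selection)

    num_a = np.zeros_like(a_p)
    num_b = np.zeros_like(b_p)
    xi = np.zeros_like(a_p)
    for name, mask in masks.items():
        idx = SIDE_WINDOWS.index(name)
        ind = (sel_p == idx).astype(float)
        if not ind.any():
            continue
        num_a += ndimage.convolve(a_p * ind, mask, mode="constant")
        num_b += ndimage.convolve(b_p * ind, mask, mode="constant")
        xi += ndimage.convolve(ind, mask, mode="constant")
    sl = (slice(r, -r), slice(r, -r))
    return FilterCoeffs(a=num_a[sl] / xi[sl], b=num_b[sl] / xi[sl])


def apply_guided_filter(
    Y: GuidanceImage | np.ndarray, coeffs: FilterCoeffs
) -> np.ndarray:
    """``Z_i = a_bar_i * Y_i + b_bar_i`` (unclipped; clip for display)."""
    Y = Y.pixels if isinstance(Y, GuidanceImage) else np.asarray(Y, dtype=float)
    if Y.shape != coeffs.a.shape:
        raise ValueError("shape mismatch between guidance and coefficients")
    return coeffs.a * Y + coeffs.b


def agsw_filter(
    image: np.ndarray,
    params: AGSWParams | None = None,
    guidance: GuidanceImage | None = None,
) -> tuple[np.ndarray, FilterCoeffs]:
    """Full AGSW-guided enhancement of one image.

    Per orientation, coefficients are fitted for every side window, the
    minimum-error window is selected per pixel, and the selections are
    aggregated (within and across orientations) into per-pixel (a, b)
    fields; the output is their linear transform of the guidance.

    Returns the unclipped output and the aggregated coefficients.
    """
    params = params or AGSWParams()
    image = np.asarray(image, dtype=float)
    _check_finite(image)
    if guidance is None:
        guidance = compute_gradient_guidance(image, params.guidance_lambda)
    Y = guidance.pixels

    bank = agsw_weight_bank(params)
    names = [n for n in SIDE_WINDOWS if n in params.side_windows]
    r = params.radius
    pad = lambda x: np.pad(x, r, mode="edge")  # noqa: E731
    sl = (slice(r, -r), slice(r, -r))

    num_a = np.zeros((image.shape[0] + 2 * r, image.shape[1] + 2 * r))
    num_b = np.zeros_like(num_a)
    xi = np.zeros_like(num_a)
    glob = np.array([SIDE_WINDOWS.index(n) for n in names])  # ascending
    for theta in params.orientations:
        masks = {n: bank[(theta, n)] for n in names}
        coeffs = {
            n: fit_window_coeffs(image, Y, m, params.epsilon, params.loss_form)
            for n, m in masks.items()
        }
        selection = select_side_window(image, Y, coeffs, masks)
        local = np.searchsorted(glob, selection)
        a_sel = np.take_along_axis(
            np.stack([coeffs[n][0] for n in names]), local[None], 0
        )[0]
        b_sel = np.take_along_axis(
            np.stack([coeffs[n][1] for n in names]), local[None], 0
        )[0]
        a_p, b_p, sel_p = pad(a_sel), pad(b_sel), pad(selection)
        for name, mask in masks.items():
            ind = (sel_p == SIDE_WINDOWS.index(name)).astype(float)
            if not ind.any():
                continue
            num_a += ndimage.convolve(a_p * ind, mask, mode="constant")
            num_b += ndimage.convolve(b_p * ind, mask, mode="constant")
            xi += ndimage.convolve(ind, mask, mode="constant")
    coeffs_bar = FilterCoeffs(a=num_a[sl] / xi[sl], b=num_b[sl] / xi[sl])
    return apply_guided_filter(Y, coeffs_bar), coeffs_bar


def enhance_image(image: np.ndarray, params: AGSWParams | None = None) -> np.ndarray:
    """Convenience wrapper: AGSW filter, clipped to [0, 1] for display."""
    z, _ = agsw_filter(image, params)
    return np.clip(z, 0.0, 1.0)


# ---------------------------------------------------------------------------
# morphological cleanup
# ---------------------------------------------------------------------------

def morphological_cleanup(
    enhanced: np.ndarray,
    se: StructuringElement | None = None,
    threshold: float | str = "otsu",
) -> tuple[np.ndarray, np.ndarray]:
    """Remove non-brain structures from an enhanced slice.

    Pipeline: global threshold (Otsu by default) -> binary opening with
    the structuring element -> hole filling -> keep the largest
    connected component -> multiply the image by the resulting mask.
    Output shapes equal the input shape.  If the threshold leaves no
    foreground, the full-image mask is returned with a warning.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    se = se or StructuringElement()
    enhanced = np.asarray(enhanced, dtype=float)
    if threshold == "otsu":
        if enhanced.min() == enhanced.max():
            warnings.warn(
                "morphological_cleanup: constant image; returning full mask",
                stacklevel=2,
            )
            mask = np.ones_like(enhanced, dtype=bool)
            return mask, enhanced * mask
        thr = threshold_otsu(enhanced)
    else:
        thr = float(threshold)
    fg = enhanced > thr
    if not fg.any():
        warnings.warn(
            "morphological_cleanup: empty foreground after threshold; "
            "returning full mask",
            stacklevel=2,
        )
        mask = np.ones_like(enhanced, dtype=bool)
        return mask, enhanced * mask

    opened = ndimage.binary_opening(fg, structure=se.footprint())
    if not opened.any():
        opened = fg  # opening removed everything; fall back to raw threshold
    filled = ndimage.binary_fill_holes(opened)
    labels = label(filled)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    mask = labels == counts.argmax()
    return mask, enhanced * mask
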