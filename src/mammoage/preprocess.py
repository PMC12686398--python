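"""Image IO and preprocessing: loading, breast segmentation, aspect-
preserving resize+pad, and the training augmentation policy.

The pipeline mirrors standard mammography preprocessing: 16-bit grayscale
PNGs are scaled into [0, 1], the breast is segmented as the largest
connected component above an automatic (Otsu) threshold, and images are
isotropically rescaled and zero-padded to a fixed frame with the chest
wall anchored at the frame edge (left edge for right breasts, right edge
for left breasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import filters, transform

__all__ = [
    "PreprocessConfig",
    "DegenerateInputError",
    "load_image",
    "segment_breast",
    "resize_pad",
    "augment",
    "default_augmentation_policy",
    "preprocess_view",
    "preprocess_exam",
]


class DegenerateInputError(ValueError):
    """Raised when an image has no usable foreground."""


#: transforms the augmentation policy may enable
KNOWN_TRANSFORMS = ("flip", "brightness", "contrast", "gaussian_blur",
                    "gaussian_noise", "coarse_dropout")


def default_augmentation_policy() -> dict[str, dict]:
    """Default magnitudes: brightness +-0.1, contrast +-10%, blur sigma <= 1 px,
    noise sd <= 0.02, dropout <= 4 holes each <= 1/16 of the image area."""
    return {
        "flip": {"prob": 0.5},
        "brightness": {"prob": 0.3, "low": -0.1, "high": 0.1},
        "contrast": {"prob": 0.3, "low": 0.9, "high": 1.1},
        "gaussian_blur": {"prob": 0.2, "sigma_max": 1.0},
        "gaussian_noise": {"prob": 0.2, "sd_max": 0.02},
        "coarse_dropout": {"prob": 0.2, "max_holes": 4, "max_area_frac": 1.0 / 16},
    }


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    ``target_shape`` defaults to the desk-scale 256x128 frame; the
    full-scale frame for full-resolution mammograms is 1536x768.
    """

    target_shape: tuple[int, int] = (256, 128)
    segmentation_threshold_method: str = "otsu"   # or "fixed"
    fixed_threshold: float = 0.05
    augmentation_policy: dict[str, dict] = field(default_factory=default_augmentation_policy)

    def __post_init__(self):
        if min(self.target_shape) <= 0:
            raise ValueError("target_shape must be positive")
        for name, params in self.augmentation_policy.items():
            if name not in KNOWN_TRANSFORMS:
                raise ValueError(f"unknown augmentation transform {name!r}")
            p = params.get("prob", 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} must be in [0, 1]")


def load_image(path: str) -> np.ndarray:
    """Load an 8- or 16-bit grayscale PNG as float64 in [0, 1]."""
    with Image.open(path) as im:
        mode = im.mode
        arr = np.asarray(im)
    if mode in ("I;16", "I;16B"):
        scale = 65535.0
    elif mode == "L":
        scale = 255.0
    elif mode == "I" and arr.max(initial=0) <= 65535:
        scale = 65535.0
    else:
        raise ValueError(f"unsupported image mode {mode!r} for {path}; "
                         "expected 8- or 16-bit grayscale")
    return arr.astype(np.float64) / scale


def segment_breast(image: np.ndarray, method: str = "otsu",
                   fixed_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Segment the breast as the largest bright connected component.

    Returns (cropped image, full-size boolean mask).  The mask is the
    largest connected component above the threshold after morphological
    closing; the crop is its tight bounding box with the background zeroed.
    """
    if method == "otsu":
        if np.ptp(image) == 0:
            raise DegenerateInputError("constant image: no foreground to segment")
        thr = filters.threshold_otsu(image)
    elif method == "fixed":
        thr = fixed_threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    fg = image > thr
    if not fg.any():
        raise DegenerateInputError("no pixels above the segmentation threshold")
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)))
    labels, n = ndimage.label(fg, structure=np.ones((3, 3)))  # 8-connected
    if n == 0:
        raise DegenerateInputError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.where(rows)[0][[0, -1]]
    c0, c1 = np.where(cols)[0][[0, -1]]
    cropped = np.where(mask, image, 0.0)[r0:r1 + 1, c0:c1 + 1]
    return cropped, mask


def resize_pad(image: np.ndarray, target_shape: tuple[int, int],
               laterality: str = "R") -> tuple[np.ndarray, dict]:
    """Isotropically rescale into ``target_shape`` and zero-pad the rest.

    The scale preserves the aspect ratio exactly; horizontal anchoring is
    laterality-aware so the chest wall touches the frame (right breast at
    the left edge, left breast at the right edge); vertical padding is
    centred (extra row at the bottom).  Returns the framed image and a
    transform record {scale, row_offset, col_offset, content_shape}
    sufficient to recover the content region.
    """
    if min(target_shape) <= 0 or min(image.shape) <= 0:
        raise ValueError("shapes must be positive")
    if laterality not in ("R", "L"):
        raise ValueError("laterality must be 'R' or 'L'")
    H, W = image.shape
    Ht, Wt = target_shape
    scale = min(Ht / H, Wt / W)
    h2 = min(int(round(H * scale)), Ht)
    w2 = min(int(round(W * scale)), Wt)
    if (h2, w2) == (H, W):
        content = image.copy()
    else:
        content = transform.resize(image, (h2, w2), order=1, mode="edge",
                                   anti_aliasing=scale < 1.0, preserve_range=True)
    out = np.zeros(target_shape, dtype=np.float64)
    row_off = (Ht - h2) // 2
    col_off = 0 if laterality == "R" else Wt - w2
    out[row_off:row_off + h2, col_off:col_off + w2] = content
    info = {"scale": scale, "row_offset": row_off, "col_offset": col_off,
            "content_shape": (h2, w2)}
    return out, info


def augment(image: np.ndarray, policy: dict[str, dict],
            rng: np.random.Generator) -> np.ndarray:
    """Apply the enabled stochastic transforms, clipping to [0, 1].

    Deterministic under a fixed generator state.  Transforms are applied in
    the fixed order of ``KNOWN_TRANSFORMS``.
    """
    for name in policy:
        if name not in KNOWN_TRANSFORMS:
            raise ValueError(f"unknown augmentation transform {name!r}")
    out = image.astype(np.float64, copy=True)
    for name in KNOWN_TRANSFORMS:
        if name not in policy:
            continue
        params = policy[name]
        if rng.random() >= params.get("prob", 0.0):
            continue
        if name == "flip":
            out = out[:, ::-1].copy()
        elif name == "brightness":
            out = out + rng.uniform(params["low"], params["high"])
        elif name == "contrast":
            factor = rng.uniform(params["low"], params["high"])
            out = (out - 0.5) * factor + 0.5
        elif name == "gaussian_blur":
            sigma = rng.uniform(0.0, params["sigma_max"])
            if sigma > 0:
                out = ndimage.gaussian_filter(out, sigma)
        elif name == "gaussian_noise":
            sd = rng.uniform(0.0, params["sd_max"])
            out = out + rng.normal(0.0, sd, size=out.shape) if sd > 0 else out
        elif name == "coarse_dropout":
            n_holes = int(rng.integers(1, params["max_holes"] + 1))
            H, W = out.shape
            max_area = params["max_area_frac"] * H * W
            side = max(1, int(np.sqrt(max_area)))
            for _ in range(n_holes):
                hh = int(rng.integers(1, side + 1))
                ww = int(rng.integers(1, side + 1))
                r0 = int(rng.integers(0, max(1, H - hh + 1)))
                c0 = int(rng.integers(0, max(1, W - ww + 1)))
                out[r0:r0 + hh, c0:c0 + ww] = 0.0
    return np.clip(out, 0.0, 1.0)


def preprocess_view(path: str, view_key: str, config: PreprocessConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Full deterministic pipeline for one view: load, segment, frame.

    With ``rng`` given, the augmentation policy is applied after framing
    (training mode); without it the pipeline is a pure function of the
    input file.
    """
    laterality = view_key.split("-")[0]
    img = load_image(path)
    cropped, _ = segment_breast(img, config.segmentation_threshold_method,
                                config.fixed_threshold)
    framed, _ = resize_pad(cropped, config.target_shape, laterality)
    if rng is not None:
        framed = augment(framed, config.augmentation_policy, rng)
    return framed


def preprocess_exam(views: dict[str, str], config: PreprocessConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Stack the four preprocessed views as (4, H, W) in the canonical
    order R-CC, R-MLO, L-CC, L-MLO."""
    from .synthetic import VIEW_KEYS
    return np.stack([preprocess_view(views[k], k, config, rng) for k in VIEW_KEYS])
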