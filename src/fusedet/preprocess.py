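"""Deterministic X-ray normalization.

Pipeline: detect the dominant background polarity with a binary k-means on
the intensity histogram, invert light-background images so every radiograph
has a dark background and bright anatomy, apply contrast-limited adaptive
histogram equalization (CLAHE, default 11x11 tile grid, clip limit 7.0),
then resize to the detector input size (default 800x800) and replicate the
single channel three times.

CLAHE is implemented here with the OpenCV clip-limit convention (the clip
limit is a multiple of the average tile histogram count), since that is the
convention in which a clip limit of 7.0 is meaningful.  Tile mappings are
blended with bilinear interpolation between tile centres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("fusedet")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the normalization recipe.

    ``clahe_grid`` is (rows, cols) of the tile grid; ``clahe_clip`` is the
    OpenCV-style clip limit (multiple of the uniform histogram height);
    ``target_size`` is (height, width) of the model input.
    """

    clahe_grid: tuple[int, int] = (11, 11)
    clahe_clip: float = 7.0
    target_size: tuple[int, int] = (800, 800)
    kmeans_seed: int = 0
    clahe_bins: int = 256

    def __post_init__(self) -> None:
        if min(self.clahe_grid) < 1 or min(self.target_size) < 1:
            raise ValueError("grid and target dimensions must be >= 1")
        if self.clahe_clip <= 0:
            raise ValueError("clip limit must be positive")


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    return img.astype(np.uint8, copy=False)


def _histogram_kmeans(hist: np.ndarray, init: tuple[float, float] = (64.0, 192.0),
                      max_iter: int = 100) -> tuple[float, float, np.ndarray]:
    """Weighted 2-means (Lloyd) on the 256-bin intensity histogram.

    Returns (low centroid, high centroid, boolean mask of bins assigned to
    the high cluster).  Deterministic: initialization at fixed centroids.
    """
    levels = np.arange(256, dtype=np.float64)
    c_lo, c_hi = float(init[0]), float(init[1])
    hi_mask = levels > (c_lo + c_hi) / 2.0
    for _ in range(max_iter):
        w_lo, w_hi = hist[~hi_mask].sum(), hist[hi_mask].sum()
        new_lo = (levels[~hi_mask] * hist[~hi_mask]).sum() / w_lo if w_lo else c_lo
        new_hi = (levels[hi_mask] * hist[hi_mask]).sum() / w_hi if w_hi else c_hi
        new_mask = levels > (new_lo + new_hi) / 2.0
        if new_lo == c_lo and new_hi == c_hi and np.array_equal(new_mask, hi_mask):
            break
        c_lo, c_hi, hi_mask = new_lo, new_hi, new_mask
    return c_lo, c_hi, hi_mask


def dominant_background(img: np.ndarray, seed: int = 0) -> str:
    """Classify the image background as ``"dark"`` or ``"light"``.

    Binary k-means over the intensity histogram; the cluster holding more
    pixels is taken to be the background.  The label is ``"light"`` iff the
    background cluster's centroid exceeds the other centroid.  A constant
    image is degenerate for 2-means and returns ``"dark"`` with a warning.
    """
    img = _as_gray(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        logger.warning("constant image: background polarity defaults to 'dark'")
        return "dark"
    _, _, hi_mask = _histogram_kmeans(hist)
    n_hi = hist[hi_mask].sum()
    n_lo = hist[~hi_mask].sum()
    # background = majority cluster; centroid order is lo < hi by construction
    return "light" if n_hi > n_lo else "dark"


def invert_if_light(img: np.ndarray, seed: int = 0) -> np.ndarray:
    """Map p -> 255 - p when the dominant background is light; idempotent."""
    img = _as_gray(img)
    if dominant_background(img, seed) == "light":
        return (255 - img.astype(np.int16)).astype(np.uint8)
    return img.copy()


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _tile_mapping(tile: np.ndarray, clip: float, nbins: int) -> np.ndarray:
    """Clipped, redistributed histogram -> 0..255 lookup table for one tile."""
    n = tile.size
    hist = np.bincount(tile.ravel(), minlength=nbins).astype(np.float64)
    limit = max(clip * n / nbins, 1.0)
    excess = np.maximum(hist - limit, 0.0).sum()
    hist = np.minimum(hist, limit)
    # redistribute clipped mass uniformly; deterministic, no residual loop
    hist += excess / nbins
    cdf = np.cumsum(hist)
    return np.rint(cdf * 255.0 / n).clip(0, 255)


def apply_clahe(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is padded by edge reflection to a multiple of the tile size,
    per-tile histograms are clipped at ``clahe_clip`` times the uniform
    height with the excess redistributed uniformly, and each output pixel
    bilinearly interpolates the mappings of its four nearest tile centres.
    """
    cfg = cfg or PreprocessConfig()
    img = _as_gray(img)
    gh, gw = cfg.clahe_grid
    h, w = img.shape
    if gh > h or gw > w:
        raise ValueError(
            f"CLAHE grid {gh}x{gw} larger than image {h}x{w}"
        )
    th, tw = math.ceil(h / gh), math.ceil(w / gw)
    pad_b, pad_r = th * gh - h, tw * gw - w
    padded = np.pad(img, ((0, pad_b), (0, pad_r)), mode="reflect")

    luts = np.empty((gh, gw, cfg.clahe_bins))
    for i in range(gh):
        for j in range(gw):
            tile = padded[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            luts[i, j] = _tile_mapping(tile, cfg.clahe_clip, cfg.clahe_bins)

    ph, pw = padded.shape
    ys = np.arange(ph, dtype=np.float64)
    xs = np.arange(pw, dtype=np.float64)
    # position in tile-centre coordinates; clamp to the centre lattice
    ty = np.clip((ys - (th - 1) / 2.0) / th, 0.0, gh - 1.0)
    tx = np.clip((xs - (tw - 1) / 2.0) / tw, 0.0, gw - 1.0)
    y0 = np.minimum(ty.astype(np.intp), gh - 2) if gh > 1 else np.zeros(ph, np.intp)
    x0 = np.minimum(tx.astype(np.intp), gw - 2) if gw > 1 else np.zeros(pw, np.intp)
    fy = (ty - y0) if gh > 1 else np.zeros(ph)
    fx = (tx - x0) if gw > 1 else np.zeros(pw)
    y1 = np.minimum(y0 + 1, gh - 1)
    x1 = np.minimum(x0 + 1, gw - 1)

    pix = padded.astype(np.intp)
    Y0 = y0[:, None]
    Y1 = y1[:, None]
    FY = fy[:, None]
    v00 = luts[Y0, x0[None, :], pix]
    v01 = luts[Y0, x1[None, :], pix]
    v10 = luts[Y1, x0[None, :], pix]
    v11 = luts[Y1, x1[None, :], pix]
    top = v00 * (1 - fx)[None, :] + v01 * fx[None, :]
    bot = v10 * (1 - fx)[None, :] + v11 * fx[None, :]
    out = top * (1 - FY) + bot * FY
    return np.rint(out[:h, :w]).clip(0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Resize and channel replication
# ---------------------------------------------------------------------------

def to_model_input(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Bilinear resize to ``target_size`` and replicate to three channels."""
    from skimage.transform import resize

    cfg = cfg or PreprocessConfig()
    img = _as_gray(img)
    if img.shape == tuple(cfg.target_size):
        resized = img.copy()
    else:
        resized = resize(
            img.astype(np.float64),
            cfg.target_size,
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        resized = np.rint(resized).clip(0, 255).astype(np.uint8)
    return np.repeat(resized[:, :, None], 3, axis=2)


def preprocess_image(
    img: np.ndarray,
    cfg: PreprocessConfig | None = None,
    crop: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Full normalization: (optional crop) -> polarity fix -> CLAHE -> resize.

    ``crop`` is an optional (y0, y1, x0, x1) rectangle standing in for the
    manual region-of-interest crop used when curating radiographs.
    Deterministic given the config.
    """
    cfg = cfg or PreprocessConfig()
    img = _as_gray(img)
    if crop is not None:
        y0, y1, x0, x1 = crop
        img = img[y0:y1, x0:x1]
    img = invert_if_light(img, cfg.kmeans_seed)
    img = apply_clahe(img, cfg)
    return to_model_input(img, cfg)


# ---------------------------------------------------------------------------
# File I/O helpers
# ---------------------------------------------------------------------------

def read_gray_png(path: str) -> np.ndarray:
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    return np.rint(img).clip(0, 255).astype(np.uint8)


def write_png(path: str, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def read_dicom_gray(path: str) -> np.ndarray:
    """Extract DICOM pixel data and window it to 8 bits by min-max scaling.

    Min-max windowing is a documented placeholder: clinical conversions may
    use modality-specific window centre/width instead.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    pix = ds.pixel_array.astype(np.float64)
    lo, hi = pix.min(), pix.max()
    if hi == lo:
        return np.zeros(pix.shape, dtype=np.uint8)
    return np.rint((pix - lo) * 255.0 / (hi - lo)).astype(np.uint8)
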