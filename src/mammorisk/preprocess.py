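"""Mammogram preprocessing: breast segmentation, aspect-preserving resize,
min-max normalisation.

The pipeline mirrors standard screening-image preparation: threshold the
image (Otsu), keep the largest connected foreground component as the breast
mask, crop to its bounding box, zero-pad to a 1:2 width:height aspect ratio
without distorting scale, resize to the model input size and min-max scale to
[0, 1].  Degenerate (constant) images come back as all zeros.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import resize


def _mask_and_threshold(img: np.ndarray) -> tuple[np.ndarray, float]:
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=bool), float(hi)
    # cap the Otsu threshold at 5% of the dynamic range: the background of a
    # mammogram is near-black, and an uncapped Otsu split can land *inside*
    # dense tissue and truncate the breast
    thr = min(threshold_otsu(img), lo + 0.05 * (hi - lo))
    fg = img > thr
    if not fg.any():
        return np.zeros(img.shape, dtype=bool), float(thr)
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return binary_fill_holes(labels == counts.argmax()), float(thr)


def breast_mask(img: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest connected foreground component."""
    return _mask_and_threshold(np.asarray(img, dtype=np.float64))[0]


def load_image(path) -> np.ndarray:
    """Read a grayscale mammogram from 16-bit PNG or DICOM.

    PNG is the native fixture format; DICOM is a read-only adapter (pixel
    data only — no de-identification or vendor calibration).
    """
    import os
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".dcm", ".dicom"):
        import pydicom
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
            arr = arr.max() - arr  # invert: in MONOCHROME1 low values are bright
        return arr
    import imageio.v3 as iio
    return iio.imread(str(path)).astype(np.float64)


def preprocess_image(raw: np.ndarray, out_shape: tuple[int, int] = (1024, 512),
                     mirror: bool = False) -> np.ndarray:
    """Normalise one grayscale image to ``out_shape`` (H, W) in [0, 1].

    ``mirror`` flips horizontally first (used for right-side views so every
    breast faces the same direction before the weight-shared encoder).
    """
    img = np.asarray(raw, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    oh, ow = out_shape
    if 2 * ow != oh:
        raise ValueError("output shape must have a 1:2 width:height aspect")
    if mirror:
        img = img[:, ::-1]
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(out_shape)
    mask, thr = _mask_and_threshold(img)
    if mask.any():
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        img = img[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
        m = mask[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
        # erase bright non-breast structures (labels, markers) but leave the
        # dark background as-is, so re-running the pipeline is a no-op
        img = np.where(~m & (img > thr), 0.0, img)
    h, w = img.shape
    # zero-pad to a 1:2 width:height canvas, keeping relative scale;
    # extra columns go to the right (away from the chest wall)
    target_h = max(h, 2 * w)
    target_h += target_h % 2
    target_w = target_h // 2
    pad_h = target_h - h
    img = np.pad(img, ((pad_h // 2, pad_h - pad_h // 2), (0, target_w - w)))
    out = resize(img, out_shape, order=1, mode="constant", anti_aliasing=True,
                 preserve_range=True)
    lo2, hi2 = out.min(), out.max()
    if hi2 <= lo2:
        return np.zeros(out_shape)
    return (out - lo2) / (hi2 - lo2)
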