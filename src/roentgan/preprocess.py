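"""Radiograph preparation: orientation, negative inversion, histogram
equalization, rescaling and Laplacian-variance focus filtering.

Focus scoring uses the sum-of-squared-deviations statistic
``S(I)_var = Σ (|S(I)| − S(I)_μ)²`` computed on the absolute Laplacian
response, which is what the default rejection threshold of 350 refers to.
By default the Laplacian is taken in "valid" mode, so border effects never
enter the statistic; a "same" mode (reflect padding, full m×n response) is
available for comparison.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import signal
from skimage.transform import resize

__all__ = [
    "FocusScore",
    "PreprocessConfig",
    "PreprocessResult",
    "equalize_histogram",
    "laplace_focus",
    "grid_search_threshold",
    "normalize_orientation",
    "detect_and_invert_negative",
    "run_preprocess",
    "LAPLACE_KERNEL",
]

LAPLACE_KERNEL = np.array([[0, -1, 0],
                           [-1, 4, -1],
                           [0, -1, 0]], dtype=np.float64)


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    return img


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """Contrast-equalize an 8-bit grayscale image.

    Each value v maps to ``round(255 * (cdf(v) - cdf_min) / (m*n - cdf_min))``
    where cdf is the cumulative pixel count over the 256 integer bins and
    cdf_min its smallest non-zero value. Rounding is half-up for bit
    reproducibility. A constant image has a zero denominator and is returned
    unchanged with a warning.
    """
    img = _check_gray(img)
    if img.min() < 0 or img.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    flat = img.astype(np.int64).ravel()
    counts = np.bincount(flat, minlength=256)
    cdf = counts.cumsum()
    nonzero = cdf[cdf > 0]
    cdf_min = int(nonzero[0])
    total = img.size
    if total - cdf_min == 0:
        warnings.warn("constant image: histogram equalization is undefined; "
                      "returning input unchanged", RuntimeWarning, stacklevel=2)
        return img.astype(np.uint8)
    lut = np.floor(255.0 * (cdf - cdf_min) / (total - cdf_min) + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[img.astype(np.int64)]


@dataclass(frozen=True)
class FocusScore:
    """Laplacian focus statistics for one image."""

    variance: float
    mean_abs: float
    is_focused: bool
    threshold: float


def laplace_focus(img: np.ndarray, threshold: float = 350.0,
                  mode: str = "valid") -> FocusScore:
    """Score image focus from the absolute Laplacian response.

    ``mode="valid"`` (default) evaluates the statistic on the un-padded
    (m−2)×(n−2) response; ``mode="same"`` reflect-pads to the full m×n.
    The variance is a SUM of squared deviations from the mean absolute
    response, not a mean.
    """
    img = _check_gray(img).astype(np.float64)
    m, n = img.shape
    if m < 3 or n < 3:
        raise ValueError("image must be at least 3x3 for the Laplacian kernel")
    if mode == "valid":
        resp = signal.convolve2d(img, LAPLACE_KERNEL, mode="valid")
    elif mode == "same":
        resp = signal.convolve2d(np.pad(img, 1, mode="reflect"),
                                 LAPLACE_KERNEL, mode="valid")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    abs_resp = np.abs(resp)
    mean_abs = float(abs_resp.mean())
    variance = float(((abs_resp - mean_abs) ** 2).sum())
    return FocusScore(variance=variance, mean_abs=mean_abs,
                      is_focused=variance >= threshold, threshold=threshold)


def grid_search_threshold(variances, grid: tuple[float, float, float] = (0.0, 525.0, 175.0)):
    """Partition counts for each candidate threshold in an inclusive grid.

    A score is blurry when ``variance < t`` (strict). Returns a list of
    ``(threshold, n_below, n_above)``; the choice among candidates is left to
    inspection, as the partition quality is qualitative.
    """
    variances = np.asarray(list(variances), dtype=float)
    if variances.size == 0:
        raise ValueError("empty score list")
    lo, hi, step = grid
    if lo > hi:
        raise ValueError("grid lo must be <= hi")
    if step <= 0:
        raise ValueError("grid step must be > 0")
    candidates = np.arange(lo, hi + step / 2, step)
    out = []
    for t in candidates:
        n_below = int((variances < t).sum())
        out.append((float(t), n_below, int(variances.size - n_below)))
    return out


def normalize_orientation(img: np.ndarray, laterality: str,
                          target: str = "left") -> np.ndarray:
    """Mirror horizontally iff the image's laterality differs from target."""
    img = _check_gray(img)
    if laterality not in ("left", "right") or target not in ("left", "right"):
        raise ValueError("laterality and target must be 'left' or 'right'")
    if laterality == target:
        return img
    return img[:, ::-1]


def detect_and_invert_negative(img: np.ndarray, frame_frac: float = 0.05
                               ) -> tuple[np.ndarray, bool]:
    """Detect an intensity-negative radiograph and restore its polarity.

    Heuristic: radiographs have dark (air) borders and bright (bone) centres,
    so a border-frame mean exceeding the centre mean flags a negative, which
    is returned as ``255 - pixels``.
    """
    img = _check_gray(img)
    m, n = img.shape
    f = max(1, int(round(frame_frac * min(m, n))))
    border_mask = np.zeros((m, n), dtype=bool)
    border_mask[:f, :] = border_mask[-f:, :] = True
    border_mask[:, :f] = border_mask[:, -f:] = True
    cm, cn = m // 4, n // 4
    center = img[cm:m - cm, cn:n - cn]
    is_negative = float(img[border_mask].mean()) > float(center.mean())
    if is_negative:
        return (255 - img.astype(np.int64)).astype(img.dtype), True
    return img, False


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 210
    focus_threshold: float = 350.0
    grid: tuple[float, float, float] = (0.0, 525.0, 175.0)
    flip_to: str = "left"
    equalize: bool = True
    laplace_mode: str = "valid"


@dataclass
class PreprocessResult:
    accepted: pd.DataFrame
    rejected: pd.DataFrame
    dropped: pd.DataFrame
    images: dict[str, np.ndarray]

    def conserves(self, n_input: int) -> bool:
        return len(self.accepted) + len(self.rejected) + len(self.dropped) == n_input


def _rescale(img: np.ndarray, size: int) -> np.ndarray:
    out = resize(img.astype(np.float64) / 255.0, (size, size), order=1,
                 anti_aliasing=True, mode="reflect")
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def run_preprocess(manifest: pd.DataFrame, config: PreprocessConfig | None = None,
                   images: dict[str, np.ndarray] | None = None,
                   out_dir: str | os.PathLike | None = None) -> PreprocessResult:
    """Run the full preparation pipeline over a manifest.

    Order: orientation normalization → negative inversion → histogram
    equalization → rescale to ``target_size`` (bilinear, anti-aliased) →
    focus split. Rows flagged ``artifact`` (or ``excluded``) are dropped
    before the focus split; blurry rows are kept in a separate rejected
    manifest because they remain useful downstream (e.g. as the scarce real
    pool of the augmentation experiment).

    ``images`` maps manifest paths to arrays; when absent, paths are read
    from disk. Missing files raise an IOError naming the offending rows.
    """
    config = config or PreprocessConfig()
    if config.target_size < 3:
        raise ValueError("target_size too small")

    if images is None:
        missing = [p for p in manifest["path"] if not os.path.exists(p)]
        if missing:
            raise IOError(f"missing image files for rows: {missing[:10]}"
                          + ("..." if len(missing) > 10 else ""))
        images = {p: iio.imread(p) for p in manifest["path"]}

    flagged = manifest["artifact"].astype(bool)
    if "excluded" in manifest.columns:
        flagged = flagged | manifest["excluded"].astype(bool)
    dropped = manifest[flagged].copy()
    dropped["status"] = "dropped_artifact"
    kept = manifest[~flagged]

    out_images: dict[str, np.ndarray] = {}
    records = []
    for _, row in kept.iterrows():
        img = np.asarray(images[row["path"]])
        img = normalize_orientation(img, row["laterality"], config.flip_to)
        img, was_neg = detect_and_invert_negative(img)
        if config.equalize:
            img = equalize_histogram(img)
        img = _rescale(img, config.target_size)
        score = laplace_focus(img, threshold=config.focus_threshold,
                              mode=config.laplace_mode)
        rec = row.to_dict()
        rec["focus_variance"] = score.variance
        rec["detected_negative"] = was_neg
        rec["status"] = "accepted" if score.is_focused else "rejected_blur"
        records.append(rec)
        out_images[row["path"]] = img

    frame = pd.DataFrame(records) if records else kept.assign(
        focus_variance=[], detected_negative=[], status=[])
    accepted = frame[frame["status"] == "accepted"].copy() if len(frame) else frame
    rejected = frame[frame["status"] == "rejected_blur"].copy() if len(frame) else frame

    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for path, img in out_images.items():
            iio.imwrite(os.path.join(out_dir, os.path.basename(path)), img)
        accepted.to_csv(os.path.join(out_dir, "accepted.csv"), index=False)
        rejected.to_csv(os.path.join(out_dir, "rejected.csv"), index=False)
        dropped.to_csv(os.path.join(out_dir, "dropped.csv"), index=False)
    return PreprocessResult(accepted=accepted, rejected=rejected, dropped=dropped,
                            images=out_images)
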