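"""Cheap per-image focus features for stream triage.

The central feature is the Power Log-Log Slope (PLLS): the slope of an
ordinary least-squares line fitted to log10(radially averaged periodogram
power) against log10(radial spatial frequency).  Natural images have power
spectra that fall off roughly as a power law; defocus blur suppresses high
spatial frequencies and makes the fall-off steeper, so more blur gives a
more negative slope.  PLLS is therefore a robust, reference-free focus
score: sharp images score high (slope near the image's intrinsic spectral
exponent), blurred images score low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FeatureVector",
    "SpectrumProfile",
    "DegenerateSpectrumError",
    "InsufficientBinsError",
    "ImageTooSmallError",
    "DEFAULT_FIT_RANGE",
    "DEFAULT_N_BINS",
    "radial_power_spectrum",
    "compute_plls",
    "extract_features",
    "load_grayscale",
]

#: Fraction of the sampling frequency over which the log-log line is fitted.
#: The lower edge avoids DC leakage into the coarsest radial bins.  The upper
#: edge stays inside the signal-dominated band of quantized detector images:
#: under strong defocus the spectrum bottoms out on the quantization/read-noise
#: floor above ~0.1 cycles/px, and fitting across that floor makes the slope
#: non-monotone in blur.  Pass a wider range explicitly (e.g. (0.02, 0.45))
#: for broadband spectra where floor effects are irrelevant.
DEFAULT_FIT_RANGE: tuple[float, float] = (0.02, 0.12)

#: Number of log-spaced radial frequency bins for the averaged periodogram.
DEFAULT_N_BINS: int = 64


class ImageTooSmallError(ValueError):
    """Image smaller than the 16x16 minimum needed for a usable spectrum."""


class DegenerateSpectrumError(ValueError):
    """No non-zero periodogram power in the fit range (e.g. constant image)."""


class InsufficientBinsError(ValueError):
    """Fewer than 3 usable radial bins inside the fit range."""


@dataclass(frozen=True)
class FeatureVector:
    """Named scalar features for one image.

    ``plls`` is NaN when the slope could not be computed (constant image,
    degenerate spectrum); ``plls_ok`` flags validity so downstream code can
    quarantine rather than crash.
    """

    plls: float
    mean_intensity: float
    std_intensity: float
    plls_ok: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "plls": self.plls,
            "mean_intensity": self.mean_intensity,
            "std_intensity": self.std_intensity,
        }


@dataclass(frozen=True)
class SpectrumProfile:
    """Radially averaged periodogram: mean power per radial-frequency bin.

    Frequencies are in cycles/pixel, normalized per axis so non-square
    images are handled symmetrically; only bins with at least one
    contributing frequency sample are kept.
    """

    radial_freqs: np.ndarray  # ascending, in (0, 0.5]
    mean_power: np.ndarray  # >= 0, same length
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE

    def __post_init__(self) -> None:
        f = np.asarray(self.radial_freqs, dtype=float)
        p = np.asarray(self.mean_power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("radial_freqs and mean_power must have equal length")
        if f.size and (np.any(f <= 0) or np.any(f > 0.5 + 1e-12)):
            raise ValueError("radial frequencies must lie in (0, 0.5]")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("radial frequencies must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("mean power must be non-negative")


def _as_grayscale_array(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        # Deterministic ITU-R BT.601 luminance; alpha ignored.
        arr = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def radial_power_spectrum(image: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> SpectrumProfile:
    """Radially averaged periodogram of a mean-subtracted image.

    The raw (untapered) periodogram ``|FFT(x - mean)|^2 / N`` is averaged in
    ``n_bins`` log-spaced radial frequency bins over (0, 0.5] cycles/pixel;
    the DC component is excluded by construction.  Empty bins are dropped.
    """
    arr = _as_grayscale_array(image)
    ny, nx = arr.shape
    if ny < 16 or nx < 16:
        raise ImageTooSmallError(f"image must be at least 16x16, got {ny}x{nx}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")

    power = np.abs(np.fft.fft2(arr - arr.mean())) ** 2 / arr.size
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    radius = np.hypot(fy, fx)

    sel = (radius > 0) & (radius <= 0.5)
    r = radius[sel]
    p = power[sel]

    f_min = min(1.0 / ny, 1.0 / nx)
    edges = np.geomspace(f_min * (1.0 - 1e-9), 0.5, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=p, minlength=n_bins)
    nonempty = counts > 0
    centers = np.sqrt(edges[:-1] * edges[1:])  # geometric bin centers
    return SpectrumProfile(
        radial_freqs=centers[nonempty],
        mean_power=sums[nonempty] / counts[nonempty],
    )


def compute_plls(
    image: np.ndarray,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Power Log-Log Slope of an image.

    OLS slope of log10(mean bin power) on log10(bin frequency) over the
    radial bins whose center falls inside ``fit_range`` (fractions of the
    sampling frequency) and whose power is strictly positive.
    """
    f_lo, f_hi = fit_range
    if not (0.0 < f_lo < f_hi <= 0.5):
        raise ValueError(f"fit_range must satisfy 0 < f_lo < f_hi <= 0.5, got {fit_range}")
    profile = radial_power_spectrum(image, n_bins=n_bins)
    f = profile.radial_freqs
    p = profile.mean_power
    in_range = (f >= f_lo) & (f <= f_hi)
    usable = in_range & (p > 0)
    if not np.any(usable):
        raise DegenerateSpectrumError(
            "no non-zero periodogram power inside the fit range (constant image?)"
        )
    if np.count_nonzero(usable) < 3:
        raise InsufficientBinsError(
            f"only {np.count_nonzero(usable)} usable bins in fit range; need >= 3"
        )
    slope = np.polyfit(np.log10(f[usable]), np.log10(p[usable]), 1)[0]
    if not math.isfinite(slope):  # pragma: no cover - guarded by checks above
        raise DegenerateSpectrumError("non-finite slope")
    return float(slope)


def extract_features(
    image: np.ndarray,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    n_bins: int = DEFAULT_N_BINS,
) -> FeatureVector:
    """Compute the full feature vector, flagging PLLS failure instead of raising.

    A constant or degenerate image still yields mean/std; ``plls`` is NaN
    with ``plls_ok=False`` so the pipeline can route the object to
    quarantine rather than abort the stream.
    """
    arr = _as_grayscale_array(image)
    mean = float(arr.mean())
    std = float(arr.std())
    try:
        plls = compute_plls(arr, fit_range=fit_range, n_bins=n_bins)
        return FeatureVector(plls=plls, mean_intensity=mean, std_intensity=std)
    except (DegenerateSpectrumError, InsufficientBinsError):
        return FeatureVector(
            plls=float("nan"), mean_intensity=mean, std_intensity=std, plls_ok=False
        )


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a PNG or TIFF (8- or 16-bit) image as a float64 grayscale array.

    RGB(A) inputs are converted with BT.601 luminance weights so the
    conversion is deterministic across runs and platforms.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im)
    return _as_grayscale_array(arr)
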