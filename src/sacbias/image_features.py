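"""Per-image orientation-anisotropy features.

Three features describe how strongly an image's content is organized along
particular orientations:

1. ``spectral_orientation_profile`` -- the Fourier amplitude spectrum
   averaged over log-spaced spatial-frequency annuli within orientation
   wedges (180 wedges at 1-degree steps, each 10 degrees wide).
2. ``saliency_direction_samples`` -- saccade vectors simulated by sampling
   fixations independently from an externally produced saliency probability
   map (the saliency model itself is an input to this package, not a
   dependency).
3. ``structural_orientation_likelihood`` -- a 360-element likelihood over
   the rotation angle of the image.  The default is a gradient-orientation
   histogram proxy; a trained orientation classifier can be plugged in
   through the same 360-vector contract.

Each feature is reduced to the scalar horizontal-bias metric by smoothing
with the same 0.1 rad circular KDE used for the saccade data and averaging
the density at 0 and 180 degrees.

Orientation convention: wedge angles are reported as CONTOUR orientation
(90 degrees from the Fourier energy axis), so an image of horizontal
stripes peaks at 0 degrees -- "horizontal" means the same thing in every
feature and in the saccade data.  The raw Fourier-axis convention is
available via ``contour_convention=False``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .circular_stats import DirectionDistribution, GRID_RAD, KdeConfig, circular_kde, horizontal_bias
from .grids import direction_deg, positions_from_pixels

__all__ = [
    "GreyImage",
    "SpectralConfig",
    "OrientationProfile",
    "SaliencyMap",
    "load_grey_image",
    "preprocess_image",
    "spectral_orientation_profile",
    "saliency_direction_samples",
    "structural_orientation_likelihood",
    "feature_horizontal_bias",
    "feature_distribution",
    "proxy_saliency_map",
    "read_saliency_text",
    "write_saliency_text",
]


@dataclass
class GreyImage:
    """Greyscale luminance image scaled to [0, 1] with a degree scale."""

    pixels: np.ndarray
    deg_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")


def load_grey_image(path, deg_per_px: float) -> GreyImage:
    """Read a PNG/PGM/TIFF image, convert to greyscale, scale to [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # luminance from RGB(A)
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return GreyImage(arr, deg_per_px)


@dataclass(frozen=True)
class SpectralConfig:
    """Ring/wedge spectral analysis settings.

    ``f_lo``/``f_hi`` bound the ``n_bands`` log-spaced frequency annuli in
    cycles per degree.  The two dataset presets reflect the pixel densities
    of the source corpora (0.3-12.1 c/deg at 40 px/deg; 0.5-18.1 c/deg at
    60 px/deg).  Wedges are 1 degree apart and 10 degrees wide, double-sided
    through the origin.
    """

    n_bands: int = 10
    f_lo: float = 0.3
    f_hi: float = 12.1
    wedge_width_deg: float = 10.0
    wedge_step_deg: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if 180.0 % self.wedge_step_deg != 0:
            raise ValueError("wedge_step_deg must divide 180")

    @classmethod
    def preset(cls, name: str) -> "SpectralConfig":
        name = name.lower()
        if name == "fvtilt":
            return cls(f_lo=0.3, f_hi=12.1)
        if name == "doves":
            return cls(f_lo=0.5, f_hi=18.1)
        raise ValueError(f"unknown preset {name!r}; expected 'doves' or 'fvtilt'")


@dataclass
class OrientationProfile:
    """Mean spectral amplitude per orientation wedge (contour orientation)."""

    angle_deg: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.angle_deg.shape != self.amplitude.shape:
            raise ValueError("angle/amplitude length mismatch")
        if np.any(self.amplitude < 0) or not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite and nonnegative")


@dataclass
class SaliencyMap:
    """Nonnegative fixation-probability grid summing to 1."""

    prob: np.ndarray
    deg_per_px: float

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.ndim != 2:
            raise ValueError("prob must be 2D")
        if np.any(self.prob < 0) or not np.all(np.isfinite(self.prob)):
            raise ValueError("probabilities must be finite and nonnegative")
        if abs(self.prob.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {self.prob.sum():.12f}, expected 1")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")

    @classmethod
    def from_unnormalized(cls, arr: np.ndarray, deg_per_px: float) -> "SaliencyMap":
        arr = np.asarray(arr, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("map has no mass")
        p = arr / total
        p = p / p.sum()
        return cls(p, deg_per_px)


def preprocess_image(img: GreyImage) -> GreyImage:
    """Hann-window the image and remove the mean (DC component).

    The luminance mean is removed before windowing -- so a constant image
    maps to exactly zero and the window does not imprint its own shape as a
    low-frequency pedestal -- and the small residual mean of the windowed
    result is subtracted afterwards, leaving an exactly zero-mean output.
    """
    h, w = img.pixels.shape
    if min(h, w) <= 2:
        raise ValueError(f"image dimension {img.pixels.shape} too small to window")
    win = np.outer(np.hanning(h), np.hanning(w))
    out = (img.pixels - img.pixels.mean()) * win
    out = out - out.mean()
    return GreyImage(out, img.deg_per_px)


@lru_cache(maxsize=16)
def _wedge_band_masks(shape, deg_per_px, cfg: SpectralConfig, contour: bool):
    """Precompute the wedge membership matrix and band membership masks.

    Returns (wedge_matrix (180/step, Npix) float, band_masks list of (Npix,)
    bool, centers_deg).  Frequencies outside [f_lo, f_hi] and the DC bin are
    excluded from every mask.
    """
    h, w = shape
    fy = np.fft.fftfreq(h, d=deg_per_px)  # cycles/deg along rows
    fx = np.fft.fftfreq(w, d=deg_per_px)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    freq = np.hypot(FX, FY)
    # Fourier-axis angle; rows increase downward so the y-up angle is
    # atan2(-FY, FX).  Orientation is defined modulo 180.
    axis_deg = np.mod(np.degrees(np.arctan2(-FY, FX)), 180.0)
    ori = np.mod(axis_deg + 90.0, 180.0) if contour else axis_deg

    freq = freq.ravel()
    ori = ori.ravel()
    nyq = min(np.abs(fy).max(), np.abs(fx).max())
    edges = np.geomspace(cfg.f_lo, cfg.f_hi, cfg.n_bands + 1)
    band_masks = []
    for b in range(cfg.n_bands):
        hi_edge = edges[b + 1]
        mask = (freq >= edges[b]) & (freq < hi_edge if b < cfg.n_bands - 1 else freq <= hi_edge)
        if not mask.any():
            raise ValueError(
                f"frequency band {b} ({edges[b]:.3g}-{edges[b+1]:.3g} c/deg) contains no "
                f"spectrum pixels (Nyquist {nyq:.3g} c/deg)"
            )
        band_masks.append(mask)

    centers = np.arange(0.0, 180.0, cfg.wedge_step_deg)
    half = cfg.wedge_width_deg / 2.0
    d = np.abs(ori[None, :] - centers[:, None])
    d = np.minimum(d, 180.0 - d)
    wedge = (d <= half).astype(float)
    return wedge, band_masks, centers


def spectral_orientation_profile(
    img: GreyImage,
    cfg: SpectralConfig = SpectralConfig(),
    contour_convention: bool = True,
) -> OrientationProfile:
    """Ring-and-wedge amplitude spectrum averaged over frequency bands.

    The image is Hann-windowed and mean-subtracted, its FFT amplitude is
    averaged inside each (orientation wedge x frequency annulus) mask, and
    the profile is the mean over the ``n_bands`` annuli.  With the default
    contour convention an image of horizontal stripes peaks at 0 degrees.
    """
    pre = preprocess_image(img)
    amp = np.abs(np.fft.fft2(pre.pixels)).ravel()
    wedge, band_masks, centers = _wedge_band_masks(
        pre.pixels.shape, img.deg_per_px, cfg, contour_convention
    )
    # Mean amplitude per (wedge, band); a low-frequency annulus can miss some
    # wedges entirely on a small DFT grid, so the band average is taken over
    # the populated cells of each wedge.
    sums = np.zeros(len(centers))
    n_pop = np.zeros(len(centers))
    for mask in band_masks:
        band_sums = wedge @ (amp * mask)
        counts = wedge @ mask.astype(float)
        pop = counts > 0
        sums[pop] += band_sums[pop] / counts[pop]
        n_pop += pop
    if np.any(n_pop == 0):
        empty = centers[n_pop == 0]
        raise ValueError(
            f"orientation wedge(s) at {empty[:5]} deg contain no spectrum pixels in any band"
        )
    return OrientationProfile(centers, sums / n_pop)


def saliency_direction_samples(
    sal: SaliencyMap,
    n_saccades: int = 2000,
    rng: np.random.Generator | int | None = None,
):
    """Simulate saccades by i.i.d. fixation sampling from a saliency map.

    ``n_saccades + 1`` fixations are drawn independently from the map
    (pixel by inverse CDF, uniform sub-pixel jitter); saccade ``k`` is the
    vector from fixation ``k`` to ``k+1``.  Returns ``(amplitudes_deg,
    directions_deg)`` in the y-up convention.
    """
    if n_saccades < 1:
        raise ValueError("n_saccades must be >= 1")
    rng = np.random.default_rng(rng)
    flat = sal.prob.ravel()
    if np.count_nonzero(flat) < 2:
        raise ValueError("saliency map has fewer than two nonzero pixels; all saccades would be zero-length")
    cdf = np.cumsum(flat)
    cdf /= cdf[-1]
    idx = np.searchsorted(cdf, rng.random(n_saccades + 1), side="right")
    rows, cols = np.unravel_index(idx, sal.prob.shape)
    jit = rng.random((2, n_saccades + 1))
    x, y = positions_from_pixels(rows, cols, sal.prob.shape, sal.deg_per_px, jitter_rc=jit)
    dx = np.diff(x)
    dy = np.diff(y)
    return np.hypot(dx, dy), direction_deg(dx, dy)


def structural_orientation_likelihood(img: GreyImage, classifier=None) -> np.ndarray:
    """360-element likelihood over the rotation angle of the image.

    With ``classifier=None`` a proxy is used: the histogram of
    gradient-magnitude-weighted Sobel gradient orientations, folded to 180
    degrees and duplicated to 360 bins.  Under this gradient convention a
    horizontal-stripe image peaks at bins 90/270 (gradients point vertically).
    An external orientation classifier is accepted through the same
    contract: a callable returning 360 nonnegative values, normalized here.
    """
    if classifier is not None:
        vec = np.asarray(classifier(img), dtype=float)
        if vec.shape != (360,) or np.any(vec < 0) or not np.all(np.isfinite(vec)):
            raise ValueError("classifier must return 360 finite nonnegative values")
        total = vec.sum()
        if total <= 0:
            raise ValueError("classifier output has no mass")
        return vec / total
    gx = ndimage.sobel(img.pixels, axis=1, mode="reflect")
    gy_down = ndimage.sobel(img.pixels, axis=0, mode="reflect")
    gy = -gy_down  # y-up
    mag = np.hypot(gx, gy)
    if mag.sum() <= 0:
        warnings.warn("constant image: structural orientation likelihood is uniform")
        return np.full(360, 1.0 / 360.0)
    ori = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    hist, _ = np.histogram(ori.ravel(), bins=180, range=(0.0, 180.0), weights=mag.ravel())
    vec = np.concatenate([hist, hist])
    return vec / vec.sum()


def proxy_saliency_map(img: GreyImage, blur_sigma_deg: float = 0.5) -> SaliencyMap:
    """Crude isotropic saliency stand-in: local RMS luminance contrast.

    Local contrast (Gaussian-windowed variance of luminance) is a classic
    low-level salience cue and is orientation-neutral by construction, which
    is what the white-noise control needs.  Any externally produced map can
    be supplied instead wherever a :class:`SaliencyMap` is accepted.
    """
    sigma_px = max(blur_sigma_deg / img.deg_per_px, 1.0)
    m = ndimage.gaussian_filter(img.pixels, sigma_px)
    m2 = ndimage.gaussian_filter(img.pixels**2, sigma_px)
    var = np.clip(m2 - m**2, 0.0, None)
    if var.sum() <= 0:
        var = np.ones_like(var)
    return SaliencyMap.from_unnormalized(var, img.deg_per_px)


def feature_horizontal_bias(
    samples_deg: np.ndarray | None = None,
    profile: OrientationProfile | None = None,
    likelihood: np.ndarray | None = None,
    cfg: KdeConfig = KdeConfig(),
) -> float:
    """Horizontal-bias metric of a feature, via the shared circular KDE.

    Exactly one of the three inputs must be given:

    - ``samples_deg``: raw direction samples in degrees (saliency feature);
    - ``profile``: an :class:`OrientationProfile`, whose 180 amplitudes are
      duplicated to 360 degrees and used as KDE weights;
    - ``likelihood``: a 360-element orientation-likelihood vector used as
      KDE weights.

    The same bandwidth (default 0.1 rad) is used for every feature, so the
    resulting metrics are directly comparable with the saccade-data metric.
    """
    given = [x is not None for x in (samples_deg, profile, likelihood)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of samples_deg, profile, likelihood")
    if samples_deg is not None:
        dist = circular_kde(np.deg2rad(np.asarray(samples_deg, float)), cfg=cfg)
    elif profile is not None:
        if profile.angle_deg.size != 180:
            raise ValueError("profile must cover 180 one-degree wedges")
        w = np.concatenate([profile.amplitude, profile.amplitude])
        dist = circular_kde(GRID_RAD, weights=w, cfg=cfg)
    else:
        vec = np.asarray(likelihood, dtype=float)
        if vec.shape != (360,):
            raise ValueError("likelihood must have 360 elements")
        dist = circular_kde(GRID_RAD, weights=vec, cfg=cfg)
    return horizontal_bias(dist)


def feature_distribution(
    samples_deg=None, profile=None, likelihood=None, cfg: KdeConfig = KdeConfig()
) -> DirectionDistribution:
    """KDE-smoothed :class:`DirectionDistribution` of a feature (same dispatch
    rules as :func:`feature_horizontal_bias`)."""
    given = [x is not None for x in (samples_deg, profile, likelihood)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of samples_deg, profile, likelihood")
    if samples_deg is not None:
        return circular_kde(np.deg2rad(np.asarray(samples_deg, float)), cfg=cfg)
    if profile is not None:
        w = np.concatenate([profile.amplitude, profile.amplitude])
        return circular_kde(GRID_RAD, weights=w, cfg=cfg)
    return circular_kde(GRID_RAD, weights=np.asarray(likelihood, float), cfg=cfg)


# ---------------------------------------------------------------------------
# plain-text saliency I/O


def write_saliency_text(sal: SaliencyMap, path) -> None:
    np.savetxt(path, sal.prob, header=f"deg_per_px={sal.deg_per_px}")


def read_saliency_text(path, deg_per_px: float | None = None) -> SaliencyMap:
    if deg_per_px is None:
        with open(path) as fh:
            first = fh.readline()
        if "deg_per_px=" not in first:
            raise ValueError("deg_per_px not given and not found in header")
        deg_per_px = float(first.split("deg_per_px=")[1])
    return SaliencyMap.from_unnormalized(np.loadtxt(path), deg_per_px)
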