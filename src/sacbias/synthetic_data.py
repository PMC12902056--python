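"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the study conditions of the analysis:

- ``gen_oriented_noise_image``: 1/f-amplitude noise images whose Fourier
  amplitude carries a controllable cos(2 phi) orientation envelope, standing
  in for natural scenes with cardinal orientation anisotropy;
- ``gen_saliency_map``: anisotropic Gaussian blobs arranged along a line,
  times an isotropic center-bias Gaussian -- the horizontally arranged
  salient regions plus center prior that an external saliency model would
  produce for such scenes;
- ``gen_eye_trace``: piecewise-stationary fixations joined by minimum-jerk
  saccades obeying a main-sequence amplitude/peak-velocity relation, with
  white position noise and injected blinks, plus ground-truth saccades;
- ``gen_model_corpus``: scanpaths simulated from known targeting-model
  parameters over upright and +-30 degree tilted maps, for parameter
  recovery and the tilt-reorientation analysis.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .eye_preprocess import EyeTrace, Saccade
from .grids import direction_deg
from .image_features import GreyImage, SaliencyMap
from .target_model import CombinationWeights, EgocentricParams, simulate_scanpath

__all__ = [
    "CorpusSpec",
    "default_truth_params",
    "gen_oriented_noise_image",
    "gen_saliency_map",
    "gen_white_noise_image",
    "rotate_saliency",
    "FixationPlan",
    "gen_eye_trace",
    "gen_model_corpus",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Specification of a synthetic image/saliency corpus.

    Defaults describe a 64 x 64 pixel grid at 0.35 deg/px (a 22.4 degree
    square field, comparable to the free-viewing displays the analysis was
    designed for), with three elongated salient blobs arranged horizontally
    and a center-bias sigma of a quarter of the field.
    """

    n_images: int = 12
    size_px: int = 64
    deg_per_px: float = 0.35
    anisotropy_strength: float = 0.8
    anisotropy_orientation_deg: float = 0.0
    blob_count: int = 3
    blob_sigma_deg: float = 1.2
    blob_elongation: float = 2.5
    arrangement_orientation_deg: float = 0.0
    arrangement_spread_deg: float = 6.0
    center_bias_sigma_deg: float = 5.5
    amplitude_ramp: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1 or self.size_px < 8:
            raise ValueError("sizes must be positive (size_px >= 8)")
        if not 0.0 <= self.anisotropy_strength <= 1.0:
            raise ValueError("anisotropy_strength must lie in [0, 1]")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")


def default_truth_params() -> EgocentricParams:
    """Canonical ground-truth egocentric parameters for synthetic corpora.

    Horizontal lobes dominate (as in human free viewing) and the four lobe
    weights are deliberately unequal: a perfectly symmetric direction
    profile would leave the reorientation cross-correlation ambiguous up to
    180 degrees, a degeneracy real oculomotor data does not have (rightward
    saccades outnumber leftward, and up/down are asymmetric).  The
    concentrations (kappa 8 horizontal, 5 vertical; angular SDs of roughly
    20 and 27 degrees) keep the four cardinal lobes clearly separated, which
    both resembles the sharp cardinal peaks of free-viewing direction
    histograms and keeps every mixture parameter identifiable.
    """
    from .target_model import VonMisesLobe

    return EgocentricParams(
        a=1.5,
        lobes=(
            VonMisesLobe(0.0, 8.0, 0.35),
            VonMisesLobe(90.0, 5.0, 0.15),
            VonMisesLobe(180.0, 8.0, 0.30),
            VonMisesLobe(270.0, 5.0, 0.20),
        ),
    )


def gen_white_noise_image(size_px: int, deg_per_px: float, rng) -> GreyImage:
    """Uniform white-noise image (the orientation-free control stimulus)."""
    rng = np.random.default_rng(rng)
    return GreyImage(rng.random((size_px, size_px)), deg_per_px)


def gen_oriented_noise_image(
    size_px: int,
    deg_per_px: float,
    strength: float,
    orientation_deg: float = 0.0,
    rng=None,
) -> GreyImage:
    """1/f noise with an orientation-anisotropic amplitude envelope.

    The Fourier amplitude of white noise is multiplied by ``1/f`` and by
    ``1 + strength * cos(2 (phi - phi0))`` where ``phi`` is the Fourier-axis
    angle.  ``orientation_deg`` is the CONTOUR orientation of the dominant
    structure (0 = horizontal contours), converted internally to the
    perpendicular Fourier axis; the cos(2 phi) form preserves the point
    symmetry of a real image's spectrum.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    n = size_px
    noise = rng.standard_normal((n, n))
    F = np.fft.fft2(noise)
    fy = np.fft.fftfreq(n, d=deg_per_px)
    fx = np.fft.fftfreq(n, d=deg_per_px)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    freq = np.hypot(FX, FY)
    freq[0, 0] = np.inf  # kill DC
    phi = np.arctan2(-FY, FX)  # y-up Fourier-axis angle
    phi0 = math.radians(orientation_deg + 90.0)  # contour -> Fourier axis
    env = (1.0 + strength * np.cos(2.0 * (phi - phi0))) / freq
    img = np.fft.ifft2(F * env).real
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return GreyImage(img, deg_per_px)


def gen_saliency_map(
    size_px: int,
    deg_per_px: float,
    blob_count: int = 3,
    blob_sigma_deg: float = 1.2,
    blob_elongation: float = 2.5,
    arrangement_orientation_deg: float = 0.0,
    arrangement_spread_deg: float = 6.0,
    center_bias_sigma_deg: float = 5.5,
    amplitude_ramp: float = 0.8,
    rng=None,
) -> SaliencyMap:
    """Salient blobs along a line through the image center, times center bias.

    Blob centers are spaced evenly (with small random jitter) along a line
    at ``arrangement_orientation_deg`` (y-up); each blob is a Gaussian
    elongated along that line by ``blob_elongation``.  Blob peak heights
    ramp linearly by ``+-amplitude_ramp/2`` along the arrangement, because
    real scenes are not point-symmetric; a perfectly symmetric map would
    make the circular cross-correlation of its direction distribution
    ambiguous up to 180 degrees.  A single centered isotropic blob is
    obtained with ``blob_count=1, blob_elongation=1``.
    """
    rng = np.random.default_rng(rng)
    extent = size_px * deg_per_px
    cx = cy = extent / 2.0
    xs = (np.arange(size_px) + 0.5) * deg_per_px
    ys = (size_px - np.arange(size_px) - 0.5) * deg_per_px
    X, Y = np.meshgrid(xs, ys)
    th = math.radians(arrangement_orientation_deg)
    ux, uy = math.cos(th), math.sin(th)  # along-arrangement unit vector
    dens = np.zeros((size_px, size_px))
    if blob_count == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-arrangement_spread_deg, arrangement_spread_deg, blob_count)
        offsets = offsets + rng.normal(0, 0.05 * arrangement_spread_deg, blob_count)
    sig_along = blob_sigma_deg * blob_elongation
    sig_across = blob_sigma_deg
    if blob_count == 1:
        heights = np.array([1.0])
    else:
        heights = 1.0 + amplitude_ramp * np.linspace(-0.5, 0.5, blob_count)
    for off, height in zip(offsets, heights):
        bx, by = cx + off * ux, cy + off * uy
        d_along = (X - bx) * ux + (Y - by) * uy
        d_across = -(X - bx) * uy + (Y - by) * ux
        dens += height * np.exp(
            -0.5 * ((d_along / sig_along) ** 2 + (d_across / sig_across) ** 2)
        )
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    dens *= np.exp(-0.5 * r2 / center_bias_sigma_deg**2)
    return SaliencyMap.from_unnormalized(dens, deg_per_px)


def rotate_saliency(sal: SaliencyMap, tilt_deg: float) -> SaliencyMap:
    """Saliency map rotated about its center by ``tilt_deg`` (counterclockwise
    in the y-up convention, i.e. a feature at direction phi moves to
    phi + tilt), zero-padded and renormalized."""
    if tilt_deg == 0:
        return SaliencyMap(sal.prob.copy(), sal.deg_per_px)
    # ndimage.rotate with its axes=(0, 1) default and a positive angle moves a
    # feature at y-up direction phi to phi + angle (verified against an
    # off-center blob), i.e. it is already counterclockwise in the y-up frame.
    rot = ndimage.rotate(sal.prob, tilt_deg, reshape=False, order=1, mode="constant", cval=0.0)
    rot = np.clip(rot, 0.0, None)
    return SaliencyMap.from_unnormalized(rot, sal.deg_per_px)


# ---------------------------------------------------------------------------
# eye traces


@dataclass
class FixationPlan:
    """Sequence of fixation positions (deg) and their durations (s)."""

    positions: np.ndarray  # (n, 2)
    durations_s: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.durations_s = np.atleast_1d(np.asarray(self.durations_s, dtype=float))
        if len(self.positions) != len(self.durations_s) or len(self.positions) == 0:
            raise ValueError("positions and durations must be nonempty and equal length")
        if np.any(self.durations_s <= 0):
            raise ValueError("durations must be positive")


def _main_sequence_peak_velocity(amplitude_deg: float) -> float:
    """Nominal main-sequence peak velocity (deg/s)."""
    return 550.0 * (1.0 - math.exp(-amplitude_deg / 5.0))


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def gen_eye_trace(
    plan: FixationPlan,
    rate_hz: float = 250.0,
    noise_sd_deg: float = 0.01,
    blinks: list[tuple[float, float]] | None = None,
    rng=None,
) -> tuple[EyeTrace, list[Saccade]]:
    """Synthesize an eye trace from a fixation plan, with ground truth.

    Consecutive fixations are joined by minimum-jerk saccade profiles whose
    duration is set so the peak velocity follows the main sequence
    (``Vp = 1.875 * A / T``).  White position noise is added everywhere and
    blinks (``(start_s, duration_s)`` pairs) become non-finite runs.
    Returns the trace and the list of injected saccades.
    """
    rng = np.random.default_rng(rng)
    dt = 1.0 / rate_hz
    segs_t: list[np.ndarray] = []  # per-sample positions
    truth: list[Saccade] = []
    t = 0.0
    xs: list[float] = []
    ys: list[float] = []
    pos = plan.positions
    for k in range(len(pos)):
        n_fix = max(1, int(round(plan.durations_s[k] * rate_hz)))
        xs.extend([pos[k, 0]] * n_fix)
        ys.extend([pos[k, 1]] * n_fix)
        if k + 1 < len(pos):
            amp = float(np.hypot(*(pos[k + 1] - pos[k])))
            if amp > 0:
                vp = _main_sequence_peak_velocity(amp)
                dur = 1.875 * amp / vp
                n_sac = max(2, int(round(dur * rate_hz)))
                tau = np.arange(1, n_sac + 1) / n_sac
                prof = _min_jerk(tau)
                onset_s = len(xs) * dt
                xs.extend(pos[k, 0] + prof * (pos[k + 1, 0] - pos[k, 0]))
                ys.extend(pos[k, 1] + prof * (pos[k + 1, 1] - pos[k, 1]))
                truth.append(
                    Saccade.from_endpoints(
                        onset_s,
                        onset_s + n_sac * dt,
                        pos[k, 0],
                        pos[k, 1],
                        pos[k + 1, 0],
                        pos[k + 1, 1],
                        peak_velocity=vp,
                    )
                )
    x = np.asarray(xs) + rng.normal(0, noise_sd_deg, len(xs))
    y = np.asarray(ys) + rng.normal(0, noise_sd_deg, len(ys))
    time = np.arange(len(x)) * dt
    if blinks:
        for start_s, dur_s in blinks:
            i0 = int(round(start_s * rate_hz))
            i1 = i0 + max(1, int(round(dur_s * rate_hz)))
            if i0 >= len(x):
                raise ValueError(f"blink at {start_s}s falls outside the trace")
            x[i0:i1] = np.nan
            y[i0:i1] = np.nan
    return EyeTrace(time, x, y, rate_hz), truth


# ---------------------------------------------------------------------------
# model-generated corpora


def gen_model_corpus(
    params: EgocentricParams,
    weights: CombinationWeights,
    spec: CorpusSpec,
    tilts: tuple[float, ...] = (-30.0, 0.0, 30.0),
    n_saccades: int = 400,
    rng_seed: int | None = None,
):
    """Scanpaths from known model parameters over a tilted-map corpus.

    For every image in the corpus a saliency map is generated, rotated to
    each tilt, and a scanpath of ``n_saccades`` is simulated.  Returns
    ``(tables, truth)`` where ``tables[(image_id, tilt)]`` is a list of
    Saccade records and ``truth`` holds the maps, parameters and seed.
    """
    seed = spec.rng_seed if rng_seed is None else rng_seed
    root = np.random.default_rng(seed)
    tables: dict[tuple[int, float], list[Saccade]] = {}
    maps: dict[int, SaliencyMap] = {}
    for i in range(spec.n_images):
        map_rng = np.random.default_rng(root.integers(2**31))
        sal = gen_saliency_map(
            spec.size_px,
            spec.deg_per_px,
            blob_count=spec.blob_count,
            blob_sigma_deg=spec.blob_sigma_deg,
            blob_elongation=spec.blob_elongation,
            arrangement_orientation_deg=spec.arrangement_orientation_deg,
            arrangement_spread_deg=spec.arrangement_spread_deg,
            center_bias_sigma_deg=spec.center_bias_sigma_deg,
            amplitude_ramp=spec.amplitude_ramp,
            rng=map_rng,
        )
        maps[i] = sal
        for tilt in tilts:
            path_rng = np.random.default_rng(root.integers(2**31))
            sp = simulate_scanpath(
                rotate_saliency(sal, tilt),
                params,
                weights,
                n_saccades=n_saccades,
                rng=path_rng,
            )
            tables[(i, tilt)] = sp.to_saccades()
    truth = {"maps": maps, "params": params, "weights": weights, "seed": seed, "spec": spec}
    return tables, truth
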