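"""Generative saccade-targeting model and its maximum-likelihood fit.

Each candidate target pixel (x, y) of an image receives a likelihood

    l(x, y) = l_ego(x - x_n, y - y_n)^alpha * l_allo(x, y)^beta

where (x_n, y_n) is the current fixation, ``l_allo`` is an allocentric
saliency map (an input produced by an external saliency model), and the
egocentric likelihood is a separable product of three known oculomotor
biases evaluated at the offset (x', y') from fixation:

    l_ego(x', y') = f(x', y') * v(theta) * s(x', y')

- ``f``: a radial Cauchy distribution with scale ``a`` (degrees) favouring
  small saccade amplitudes over large ones;
- ``v``: a four-lobe von Mises mixture over the saccade direction
  ``theta = atan2(y', x')`` capturing the cardinal/horizontal direction
  bias (weights constrained to sum to 1);
- ``s``: a small-saccade penalty ``1 - exp(-r^2 / (2 * 0.9^2))`` that
  suppresses targets closer than about a degree (tiny landing errors do
  not trigger new saccades).

Because the planar Cauchy is not integrable on the infinite plane, every
likelihood map is normalized over the finite pixel grid; scanpaths are then
simulated by repeatedly sampling the next fixation from the combined map.
The 13 free egocentric parameters (a; mu_i, kappa_i, w_i for four lobes)
are estimated by maximizing the likelihood of observed saccade vectors,
with the per-fixation grid normalization computed exactly through a
summed-area table over an extended offset grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .eye_preprocess import Saccade
from .grids import pixel_center_coords, positions_from_pixels, pixels_from_positions
from .image_features import SaliencyMap

__all__ = [
    "VonMisesLobe",
    "EgocentricParams",
    "CombinationWeights",
    "LikelihoodMap",
    "Scanpath",
    "cauchy_radial",
    "vonmises_mixture",
    "small_saccade_penalty",
    "egocentric_map",
    "combined_map",
    "simulate_scanpath",
    "fit_egocentric_params",
    "FitResult",
    "mixture_direction_distribution",
    "match_lobes",
]

PENALTY_SIGMA_DEG = 0.9  # fixed, not fitted


@dataclass(frozen=True)
class VonMisesLobe:
    mu_deg: float
    kappa: float
    weight: float


@dataclass
class EgocentricParams:
    """The 13 free parameters of the egocentric likelihood.

    ``a`` is the Cauchy amplitude scale in degrees; each of the four lobes
    has a circular mean ``mu_deg``, concentration ``kappa`` and ``weight``
    (weights sum to 1).  ``penalty_sigma_deg`` is fixed at 0.9 deg.
    """

    a: float
    lobes: tuple[VonMisesLobe, ...]
    penalty_sigma_deg: float = PENALTY_SIGMA_DEG

    def __post_init__(self) -> None:
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValueError("Cauchy scale a must be positive")
        if len(self.lobes) != 4:
            raise ValueError("exactly four von Mises lobes are required")
        for lb in self.lobes:
            if lb.kappa < 0 or lb.weight < 0:
                raise ValueError("kappa and weights must be nonnegative")
        wsum = sum(lb.weight for lb in self.lobes)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"lobe weights sum to {wsum}, expected 1")

    @classmethod
    def cardinal(cls, a=2.0, kappas=(2.0, 2.0, 2.0, 2.0), weights=(0.25, 0.25, 0.25, 0.25)):
        """Four lobes at the cardinal directions (the standard initialization)."""
        mus = (0.0, 90.0, 180.0, 270.0)
        return cls(a, tuple(VonMisesLobe(m, k, w) for m, k, w in zip(mus, kappas, weights)))

    # -- flat key-value serialization ---------------------------------------

    def to_dict(self) -> dict:
        d = {"a": self.a, "penalty_sigma_deg": self.penalty_sigma_deg}
        for i, lb in enumerate(self.lobes, start=1):
            d[f"mu{i}_deg"] = lb.mu_deg
            d[f"kappa{i}"] = lb.kappa
            d[f"w{i}"] = lb.weight
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EgocentricParams":
        lobes = tuple(
            VonMisesLobe(float(d[f"mu{i}_deg"]), float(d[f"kappa{i}"]), float(d[f"w{i}"]))
            for i in range(1, 5)
        )
        return cls(float(d["a"]), lobes, float(d.get("penalty_sigma_deg", PENALTY_SIGMA_DEG)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "EgocentricParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CombinationWeights:
    """Exponents of the egocentric (alpha) and allocentric (beta) maps.

    The defaults 0.7 / 1.3 are the compromise between upright horizontal
    bias and tilt response found by grid search over {0.1, ..., 2.0}^2.
    """

    alpha: float = 0.7
    beta: float = 1.3

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("exponents must be nonnegative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


@dataclass
class LikelihoodMap:
    """Normalized target-probability grid, optionally anchored to a fixation."""

    prob: np.ndarray
    deg_per_px: float
    fixation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if np.any(self.prob < 0) or not np.all(np.isfinite(self.prob)):
            raise ValueError("probabilities must be finite and nonnegative")
        if abs(self.prob.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


@dataclass
class Scanpath:
    """An ordered fixation sequence and the saccades connecting them."""

    fixations: np.ndarray  # (n+1, 2) x, y in degrees

    @property
    def amplitudes(self) -> np.ndarray:
        d = np.diff(self.fixations, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def directions_deg(self) -> np.ndarray:
        from .grids import direction_deg

        d = np.diff(self.fixations, axis=0)
        return direction_deg(d[:, 0], d[:, 1])

    def to_saccades(self, fixation_duration_s: float = 0.25) -> list[Saccade]:
        """Saccade records with nominal timing (for downstream tabular code)."""
        out = []
        for k in range(len(self.fixations) - 1):
            x0, y0 = self.fixations[k]
            x1, y1 = self.fixations[k + 1]
            t = k * fixation_duration_s
            amp = math.hypot(x1 - x0, y1 - y0)
            # nominal main-sequence peak velocity for bookkeeping
            pv = 550.0 * (1.0 - math.exp(-amp / 5.0))
            out.append(Saccade.from_endpoints(t, t + 0.02 + 0.002 * amp, x0, y0, x1, y1, pv))
        return out


# ---------------------------------------------------------------------------
# the three egocentric factors


def cauchy_radial(x_off, y_off, a: float):
    """Planar Cauchy amplitude bias: 1 / (pi a (1 + r^2 / a^2))."""
    if a <= 0:
        raise ValueError("Cauchy scale a must be positive")
    r2 = np.asarray(x_off, float) ** 2 + np.asarray(y_off, float) ** 2
    return 1.0 / (math.pi * a * (1.0 + r2 / a**2))


def vonmises_mixture(theta_rad, lobes) -> np.ndarray:
    """Four-lobe von Mises mixture density over direction.

    ``sum_i w_i exp(kappa_i cos(theta - mu_i)) / (2 pi I0(kappa_i))``,
    computed with exponentially scaled Bessel functions so large kappa is
    numerically safe.
    """
    theta = np.asarray(theta_rad, dtype=float)
    out = np.zeros_like(theta, dtype=float)
    for lb in lobes:
        mu = math.radians(lb.mu_deg)
        # exp(k cos d)/I0(k) = exp(k (cos d - 1)) / i0e(k)
        out = out + lb.weight * np.exp(lb.kappa * (np.cos(theta - mu) - 1.0)) / (
            2.0 * math.pi * special.i0e(lb.kappa)
        )
    return out


def small_saccade_penalty(x_off, y_off, sigma_deg: float = PENALTY_SIGMA_DEG):
    """Penalty 1 - exp(-r^2 / (2 sigma^2)) suppressing near-zero saccades."""
    r2 = np.asarray(x_off, float) ** 2 + np.asarray(y_off, float) ** 2
    return 1.0 - np.exp(-r2 / (2.0 * sigma_deg**2))


def _ego_density(dx, dy, params: EgocentricParams) -> np.ndarray:
    """Unnormalized egocentric density f*v*s at offsets (deg, y-up)."""
    theta = np.arctan2(dy, dx)
    return (
        cauchy_radial(dx, dy, params.a)
        * vonmises_mixture(theta, params.lobes)
        * small_saccade_penalty(dx, dy, params.penalty_sigma_deg)
    )


def egocentric_map(
    fixation: tuple[float, float],
    grid_shape: tuple[int, int],
    deg_per_px: float,
    params: EgocentricParams,
) -> LikelihoodMap:
    """Egocentric likelihood f*v*s evaluated over the pixel grid, normalized."""
    x, y = pixel_center_coords(grid_shape, deg_per_px)
    dx = x[None, :] - fixation[0]
    dy = y[:, None] - fixation[1]
    dens = _ego_density(dx + np.zeros_like(dy), dy + np.zeros_like(dx), params)
    total = dens.sum()
    if total <= 0:
        raise ValueError("egocentric map has no mass on this grid")
    return LikelihoodMap(dens / total, deg_per_px, fixation=tuple(fixation))


def combined_map(
    allo: LikelihoodMap | SaliencyMap,
    ego: LikelihoodMap,
    w: CombinationWeights = CombinationWeights(),
) -> LikelihoodMap:
    """Pointwise allo^beta * ego^alpha, renormalized (0^0 treated as 1)."""
    if allo.prob.shape != ego.prob.shape:
        raise ValueError("allocentric and egocentric grids differ in shape")
    with np.errstate(divide="ignore"):
        prob = np.power(allo.prob, w.beta) * np.power(ego.prob, w.alpha)
    total = prob.sum()
    if total <= 0:
        raise ValueError("combined map has no mass")
    return LikelihoodMap(prob / total, ego.deg_per_px, fixation=ego.fixation)


def _sample_pixel(prob: np.ndarray, rng: np.random.Generator):
    flat = prob.ravel()
    cdf = np.cumsum(flat)
    idx = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    idx = min(idx, flat.size - 1)
    return np.unravel_index(idx, prob.shape)


def simulate_scanpath(
    allo: SaliencyMap,
    params: EgocentricParams,
    weights: CombinationWeights = CombinationWeights(),
    n_saccades: int = 100,
    start_fixation: tuple[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> Scanpath:
    """Simulate a scanpath by sequential sampling from combined maps.

    At each step the egocentric map is rebuilt at the current fixation,
    combined with the allocentric map, and the next fixation is drawn from
    the combined map (pixel by inverse CDF plus uniform sub-pixel jitter).
    With ``alpha = 0`` the process reduces exactly to i.i.d. allocentric
    sampling and the (fixation-independent) map is built only once.
    """
    rng = np.random.default_rng(rng)
    shape = allo.prob.shape
    dpp = allo.deg_per_px
    h, w_px = shape
    if start_fixation is None:
        start_fixation = (w_px * dpp / 2.0, h * dpp / 2.0)
    fx = [tuple(map(float, start_fixation))]
    static = None
    if weights.alpha == 0.0:
        static = combined_map(
            allo, LikelihoodMap(np.full(shape, 1.0 / (h * w_px)), dpp), weights
        )
    for _ in range(n_saccades):
        if static is not None:
            cm = static
        else:
            ego = egocentric_map(fx[-1], shape, dpp, params)
            cm = combined_map(allo, ego, weights)
        r, c = _sample_pixel(cm.prob, rng)
        jr, jc = rng.random(2)
        x, y = positions_from_pixels(r, c, shape, dpp, jitter_rc=(jr, jc))
        fx.append((float(x), float(y)))
    return Scanpath(np.asarray(fx))


def match_lobes(fitted: EgocentricParams, reference: EgocentricParams):
    """Reorder fitted lobes to best match reference lobe means.

    Mixture components carry no intrinsic order; comparisons against known
    generating parameters must first resolve the label permutation.  Returns
    the fitted lobes permuted to minimize the total circular distance
    between matched means.
    """
    import itertools

    best = None
    for perm in itertools.permutations(range(4)):
        d = sum(
            abs((fitted.lobes[p].mu_deg - reference.lobes[i].mu_deg + 180.0) % 360.0 - 180.0)
            for i, p in enumerate(perm)
        )
        if best is None or d < best[0]:
            best = (d, perm)
    return tuple(fitted.lobes[p] for p in best[1])


def mixture_direction_distribution(params: EgocentricParams):
    """The fitted direction mixture v(theta) as a DirectionDistribution."""
    from .circular_stats import GRID_RAD, DirectionDistribution, _DEG_STEP_RAD

    dens = vonmises_mixture(GRID_RAD, params.lobes)
    dens = dens / (dens.sum() * _DEG_STEP_RAD)
    return DirectionDistribution(dens)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class FitResult:
    params: EgocentricParams
    log_likelihood: float
    n_saccades: int
    converged: bool
    n_starts: int


def _decode(vec: np.ndarray) -> EgocentricParams:
    a = math.exp(vec[0])
    mus = np.degrees(vec[1:5]) % 360.0
    kappas = np.exp(vec[5:9])
    logits = vec[9:13] - vec[9:13].max()
    w = np.exp(logits)
    w = w / w.sum()
    # exact simplex normalization for the dataclass invariant
    w[-1] = 1.0 - w[:-1].sum()
    lobes = tuple(VonMisesLobe(float(m), float(k), float(wi)) for m, k, wi in zip(mus, kappas, w))
    return EgocentricParams(a, lobes)


def _encode(params: EgocentricParams) -> np.ndarray:
    vec = np.empty(13)
    vec[0] = math.log(params.a)
    vec[1:5] = [math.radians(lb.mu_deg) for lb in params.lobes]
    vec[5:9] = [math.log(max(lb.kappa, 1e-6)) for lb in params.lobes]
    vec[9:13] = [math.log(max(lb.weight, 1e-9)) for lb in params.lobes]
    return vec


class _EgoObjective:
    """Negative log-likelihood of saccade offsets under the grid-normalized model.

    The egocentric density is evaluated once per parameter vector on an
    extended offset grid covering every possible pixel offset; the
    per-fixation normalization constant is then an axis-aligned box sum of
    that grid, obtained in O(1) per saccade from a summed-area table.  This
    makes the objective exact (at pixel resolution) for scanpaths generated
    by :func:`simulate_scanpath` with a uniform allocentric map.
    """

    def __init__(self, saccades, grid_shape, deg_per_px):
        h, w = grid_shape
        self.shape = grid_shape
        self.dpp = deg_per_px
        # extended offset grid in pixel units: dr in [-(h-1), h-1], dc likewise
        dr = np.arange(-(h - 1), h)
        dc = np.arange(-(w - 1), w)
        self.dx = dc[None, :] * deg_per_px + np.zeros((dr.size, 1))
        self.dy = -dr[:, None] * deg_per_px + np.zeros((1, dc.size))
        r0 = np.empty(len(saccades), dtype=int)
        c0 = np.empty(len(saccades), dtype=int)
        drr = np.empty(len(saccades), dtype=int)
        dcc = np.empty(len(saccades), dtype=int)
        for k, s in enumerate(saccades):
            rr, cc = pixels_from_positions(s.x0, s.y0, grid_shape, deg_per_px)
            r0[k], c0[k] = rr, cc
            dcc[k] = int(round((s.x1 - s.x0) / deg_per_px))
            drr[k] = -int(round((s.y1 - s.y0) / deg_per_px))
        self.obs_idx = (drr + (h - 1), dcc + (w - 1))
        # valid offset window for a fixation at (r0, c0):
        # rows [h-1-r0, 2h-2-r0], cols [w-1-c0, 2w-2-c0] (inclusive)
        self.win = (h - 1 - r0, 2 * h - 2 - r0, w - 1 - c0, 2 * w - 2 - c0)

    def __call__(self, vec: np.ndarray) -> float:
        try:
            params = _decode(vec)
        except (OverflowError, ValueError):
            return 1e12
        dens = _ego_density(self.dx, self.dy, params)
        sat = dens.cumsum(axis=0).cumsum(axis=1)
        r1, r2, c1, c2 = self.win
        z = sat[r2, c2]
        z -= np.where(r1 > 0, sat[r1 - 1, c2], 0.0)
        z -= np.where(c1 > 0, sat[r2, c1 - 1], 0.0)
        z += np.where((r1 > 0) & (c1 > 0), sat[r1 - 1, c1 - 1], 0.0)
        # An observed offset can round onto the zero-density center pixel when
        # the sub-pixel jitters of its two fixations differ by almost one
        # pixel; floor rather than reject so such rare events do not flatten
        # the objective.
        obs = np.maximum(dens[self.obs_idx], 1e-300)
        if np.any(z <= 0):
            return 1e12
        ll = np.log(obs).sum() - np.log(z).sum()
        if not math.isfinite(ll):
            return 1e12
        return -ll


def fit_egocentric_params(
    saccades,
    grid_shape: tuple[int, int],
    deg_per_px: float,
    n_starts: int = 8,
    seed: int | None = 0,
    maxiter: int = 400,
) -> FitResult:
    """Maximum-likelihood estimate of the egocentric parameters.

    Parameters are optimized in an unconstrained encoding (log a, raw lobe
    angles, log kappa, softmax weights) with L-BFGS-B from ``n_starts``
    initializations: the first at the cardinal directions (mu = 0, 90, 180,
    270 deg, equal weights), the rest randomly perturbed around it.  The
    best start is returned; if no start converges the error carries the
    best objective value seen.
    """
    saccades = list(saccades)
    if len(saccades) < 10:
        raise ValueError("too few saccades to fit (need at least 10; >= 100 recommended)")
    obj = _EgoObjective(saccades, grid_shape, deg_per_px)
    rng = np.random.default_rng(seed)
    base = _encode(EgocentricParams.cardinal(a=2.0, kappas=(1.0,) * 4))
    best = None
    any_ok = False
    for s in range(n_starts):
        x0 = base.copy()
        if s > 0:
            x0[0] += rng.normal(0, 0.5)  # log a
            x0[1:5] += rng.normal(0, math.radians(10.0), 4)
            x0[5:9] += rng.normal(0, 0.5, 4)
            x0[9:13] += rng.normal(0, 0.5, 4)
        res = optimize.minimize(obj, x0, method="L-BFGS-B", options={"maxiter": maxiter})
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_ok and best.fun >= 1e12:
        raise RuntimeError(
            f"egocentric fit failed to converge from any of {n_starts} starts "
            f"(best objective {best.fun:.6g})"
        )
    return FitResult(
        params=_decode(best.x),
        log_likelihood=-float(best.fun),
        n_saccades=len(saccades),
        converged=any_ok,
        n_starts=n_starts,
    )
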