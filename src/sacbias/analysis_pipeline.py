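"""Study-level statistics over a corpus of images and saccades.

Covers the per-image bias table, the shuffle-based chance comparison of
bias variance (F test), ordinary least squares of the saccade bias on the
three image-feature biases with a PLSR/VIP collinearity follow-up, the
tilt-reorientation experiment comparing model variants against a reference
(human or human-proxy) source, and the amplitude-quartile breakdown of
reorientation.

Every statistic here is a pure function of its input tables plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .circular_stats import (
    KdeConfig,
    circular_cross_correlation,
    circular_kde,
    horizontal_bias,
    reorientation_index,
)
from .image_features import SaliencyMap
from .synthetic_data import rotate_saliency
from .target_model import CombinationWeights, EgocentricParams, simulate_scanpath

__all__ = [
    "bias_table",
    "shuffle_chance_bias",
    "ShuffleChanceResult",
    "regress_bias_on_features",
    "plsr_vip",
    "tilt_reorientation_experiment",
    "amplitude_bin_reorientation",
]

FEATURE_COLS = ["spectral_bias", "saliency_bias", "structural_bias"]


def _direction_bias(directions_deg, cfg: KdeConfig) -> float:
    return horizontal_bias(circular_kde(np.deg2rad(np.asarray(directions_deg, float)), cfg=cfg))


def bias_table(
    saccade_dirs_by_image: dict,
    spectral: dict,
    saliency: dict,
    structural: dict,
    cfg: KdeConfig = KdeConfig(),
) -> pd.DataFrame:
    """Assemble the per-image bias table (one row per image).

    ``saccade_dirs_by_image`` maps image id to direction samples (deg); the
    three feature dicts map image id to an already computed bias metric.
    """
    rows = []
    for img, dirs in saccade_dirs_by_image.items():
        rows.append(
            {
                "image_id": img,
                "saccade_bias": _direction_bias(dirs, cfg),
                "spectral_bias": spectral[img],
                "saliency_bias": saliency[img],
                "structural_bias": structural[img],
            }
        )
    df = pd.DataFrame(rows)
    if (df[["saccade_bias"] + FEATURE_COLS] <= 0).any().any():
        raise ValueError("bias metrics must be positive")
    return df


@dataclass
class ShuffleChanceResult:
    real_bias: pd.Series
    chance_bias: np.ndarray  # (n_shuffles, n_images)
    f_statistic: float  # var(real) / var(chance)
    f_inverted: float  # var(chance) / var(real)
    p_two_sided: float
    df: tuple[int, int]


def shuffle_chance_bias(
    saccade_dirs_by_image: dict,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = None,
    cfg: KdeConfig = KdeConfig(),
    _identity: bool = False,
) -> ShuffleChanceResult:
    """Compare the across-image variance of the bias metric with chance.

    Chance is obtained by permuting the correspondence between images and
    saccades (preserving per-image counts) and recomputing the per-image
    bias.  ``F = var(real) / var(chance)`` with the two-sided p-value from
    the F distribution at ``(n_images - 1, n_shuffles * n_images - 1)``
    degrees of freedom (the pooled chance values supply the denominator
    variance).  Both ratio orientations are reported, since a variance
    ratio far below 1 is as significant as one far above.

    ``_identity`` forces the identity permutation (test hook: F becomes
    exactly 1 for a single shuffle).
    """
    ids = list(saccade_dirs_by_image)
    if len(ids) < 2:
        raise ValueError("need at least two images")
    rng = np.random.default_rng(rng)
    real = pd.Series(
        {img: _direction_bias(d, cfg) for img, d in saccade_dirs_by_image.items()}
    )
    pool = np.concatenate([np.asarray(saccade_dirs_by_image[i], float) for i in ids])
    counts = [len(saccade_dirs_by_image[i]) for i in ids]
    edges = np.cumsum([0] + counts)
    chance = np.empty((n_shuffles, len(ids)))
    for s in range(n_shuffles):
        perm = pool if _identity else rng.permutation(pool)
        for j in range(len(ids)):
            chance[s, j] = _direction_bias(perm[edges[j] : edges[j + 1]], cfg)
    var_real = float(np.var(real.to_numpy(), ddof=1))
    var_chance = float(np.var(chance.ravel(), ddof=1))
    f = var_real / var_chance
    df1 = len(ids) - 1
    df2 = n_shuffles * len(ids) - 1
    cdf = stats.f.cdf(f, df1, df2)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return ShuffleChanceResult(real, chance, f, 1.0 / f, p, (df1, df2))


def regress_bias_on_features(table: pd.DataFrame):
    """OLS of the saccade bias on the three feature biases (with intercept).

    Returns ``(summary_frame, r_squared)`` where the frame has one row per
    term with Estimate, SE, tStat and P columns.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 images for the regression")
    X = table[FEATURE_COLS].to_numpy(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("a predictor is constant")
    Xd = sm.add_constant(X)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(table["saccade_bias"].to_numpy(float), Xd).fit()
    out = pd.DataFrame(
        {
            "Estimate": fit.params,
            "SE": fit.bse,
            "tStat": fit.tvalues,
            "P": fit.pvalues,
        },
        index=["Intercept", "Spatial frequency", "Saliency", "Structural"],
    )
    return out, float(fit.rsquared)


def plsr_vip(predictors: np.ndarray, outcome: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Variable-Importance-in-Projection scores from a PLS regression.

    Predictors are standardized; VIP_j = sqrt(p * sum_a SSY_a (w_ja/|w_a|)^2
    / sum_a SSY_a) with w_a the PLS weight vectors and SSY_a the outcome
    variance explained by component a.  The mean of squared VIPs is 1 by
    construction.
    """
    X = np.asarray(predictors, float)
    y = np.asarray(outcome, float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance")
    if n_components > p:
        raise ValueError("n_components cannot exceed the number of predictors")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y)
    W = pls.x_weights_  # (p, A)
    T = pls.x_scores_  # (n, A)
    q = pls.y_loadings_.ravel()  # (A,)
    ssy = np.sum(T**2, axis=0) * q**2
    wnorm2 = np.sum(W**2, axis=0)
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ssy) / ssy.sum())
    return vip


# ---------------------------------------------------------------------------
# tilt reorientation


def _source_distribution(dirs_deg, cfg: KdeConfig):
    return circular_kde(np.deg2rad(np.asarray(dirs_deg, float)), cfg=cfg)


def _records_from_dirs(dirs_by_tilt: dict, cfg: KdeConfig):
    """Displacements of the +-30 deg distributions vs upright, and the index."""
    for tilt in (-30.0, 0.0, 30.0):
        if tilt not in dirs_by_tilt:
            raise ValueError(f"missing tilt condition {tilt}")
    upright = _source_distribution(dirs_by_tilt[0.0], cfg)
    d_minus = circular_cross_correlation(upright, _source_distribution(dirs_by_tilt[-30.0], cfg))
    d_plus = circular_cross_correlation(upright, _source_distribution(dirs_by_tilt[30.0], cfg))
    return d_minus, d_plus, reorientation_index(d_minus, d_plus)


def tilt_reorientation_experiment(
    saliency_maps: dict,
    reference_dirs: dict,
    params: EgocentricParams,
    weights: CombinationWeights = CombinationWeights(),
    sources: tuple[str, ...] = ("full", "allo", "ego"),
    n_saccades: int = 500,
    rng: np.random.Generator | int | None = None,
    cfg: KdeConfig = KdeConfig(),
):
    """Reorientation of simulated saccade distributions under image tilt.

    ``saliency_maps`` maps image id to the upright :class:`SaliencyMap`
    (tilted versions are produced by rotating it by +-30 degrees);
    ``reference_dirs[(image_id, tilt)]`` holds the reference (human or
    human-proxy) direction samples in degrees for tilts -30, 0 and +30.

    For every image, the model is simulated on the upright and tilted maps
    in up to three variants: the full combined model, allocentric-only
    (``alpha = 0``) and egocentric-only (``beta = 0``).  Each tilted
    distribution is cross-correlated against its upright partner and the
    displacements reduced to the reorientation index.  Returns a records
    DataFrame (one row per image x source) and a dict of Spearman rank
    correlations between each model source and the reference across images.
    """
    rng = np.random.default_rng(rng)
    variant_weights = {
        "full": weights,
        "allo": CombinationWeights(alpha=0.0, beta=weights.beta),
        "ego": CombinationWeights(alpha=weights.alpha, beta=0.0),
    }
    rows = []
    for img, sal in saliency_maps.items():
        missing = [t for t in (-30.0, 0.0, 30.0) if (img, t) not in reference_dirs]
        if missing:
            raise ValueError(f"image {img!r} is missing tilt condition(s) {missing}")
        ref = {t: reference_dirs[(img, t)] for t in (-30.0, 0.0, 30.0)}
        dm, dp, idx = _records_from_dirs(ref, cfg)
        rows.append(
            {"image_id": img, "source": "reference", "disp_minus30": dm, "disp_plus30": dp, "index": idx}
        )
        tilted = {t: rotate_saliency(sal, t) for t in (-30.0, 0.0, 30.0)}
        for src in sources:
            w = variant_weights[src]
            dirs_by_tilt = {}
            for t in (-30.0, 0.0, 30.0):
                sub = np.random.default_rng(rng.integers(2**31))
                ego_only = src == "ego"
                # egocentric-only ignores the map content but still runs on the
                # grid; use the upright map's grid for all tilts.
                sp = simulate_scanpath(
                    tilted[0.0] if ego_only else tilted[t],
                    params,
                    w,
                    n_saccades=n_saccades,
                    rng=sub,
                )
                dirs_by_tilt[t] = sp.directions_deg
            dm, dp, idx = _records_from_dirs(dirs_by_tilt, cfg)
            rows.append(
                {"image_id": img, "source": src, "disp_minus30": dm, "disp_plus30": dp, "index": idx}
            )
    records = pd.DataFrame(rows)
    ref_idx = records.query("source == 'reference'").set_index("image_id")["index"]
    correlations = {}
    for src in sources:
        src_idx = records.query("source == @src").set_index("image_id")["index"]
        aligned = pd.concat([ref_idx, src_idx], axis=1, keys=["ref", "src"]).dropna()
        if len(aligned) >= 3 and aligned["ref"].nunique() > 1 and aligned["src"].nunique() > 1:
            rho, p = stats.spearmanr(aligned["ref"], aligned["src"])
        else:
            rho, p = math.nan, math.nan
        correlations[src] = {"rho": float(rho), "p": float(p)}
    return records, correlations


def amplitude_bin_reorientation(
    saccades: pd.DataFrame,
    n_bins: int = 4,
    min_cell: int = 50,
    cfg: KdeConfig = KdeConfig(),
):
    """Reorientation indices by saccade-amplitude quartile, with linear trend.

    ``saccades`` needs columns ``image_id``, ``tilt`` (-30/0/30),
    ``amplitude`` and ``direction_deg``.  Bin edges are quartiles of the
    pooled amplitude distribution, so each bin holds the same number of
    saccades.  Per (image, bin) the reorientation pipeline runs on the
    saccades in that bin; the trend is the least-squares slope of the index
    on the bin rank over per-image values (a fixed-effects approximation on
    per-image means).

    Returns ``(per_bin_frame, per_image_frame, trend_slope, trend_p)``.
    """
    req = {"image_id", "tilt", "amplitude", "direction_deg"}
    if not req.issubset(saccades.columns):
        raise ValueError(f"saccade table must have columns {sorted(req)}")
    amp = saccades["amplitude"].to_numpy(float)
    edges = np.quantile(amp, np.linspace(0, 1, n_bins + 1))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("amplitude quartile edges are degenerate (tied amplitudes)")
    ranks = np.clip(np.searchsorted(edges, amp, side="right") - 1, 0, n_bins - 1)
    df = saccades.assign(amp_bin=ranks)
    # every bin x tilt cell must be populated
    for b in range(n_bins):
        for t in (-30.0, 0.0, 30.0):
            n = len(df.query("amp_bin == @b and tilt == @t"))
            if n < min_cell:
                raise ValueError(f"amplitude bin {b} x tilt {t} has only {n} saccades (< {min_cell})")
    rows = []
    for (img, b), grp in df.groupby(["image_id", "amp_bin"]):
        dirs_by_tilt = {t: grp.query("tilt == @t")["direction_deg"].to_numpy() for t in (-30.0, 0.0, 30.0)}
        if min(len(v) for v in dirs_by_tilt.values()) < 2:
            continue
        _, _, idx = _records_from_dirs(dirs_by_tilt, cfg)
        rows.append({"image_id": img, "amp_bin": int(b), "index": idx})
    per_image = pd.DataFrame(rows)
    per_bin = per_image.groupby("amp_bin")["index"].agg(["mean", "std", "count"]).reset_index()
    slope, _, _, p, _ = stats.linregress(per_image["amp_bin"], per_image["index"])
    return per_bin, per_image, float(slope), float(p)
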