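"""Eye-trace preprocessing: blink removal and velocity-threshold saccade detection.

Raw gaze recordings (uniformly sampled horizontal/vertical position in
degrees of visual angle) are cleaned of blinks and artifacts and then
segmented into saccades with the Engbert & Kliegl velocity-threshold
algorithm: velocities from a centered moving-window differentiator, a
per-axis robust (median-based) standard deviation, and an elliptic
threshold at ``lambda`` robust SDs.  The thresholds used for the two eye
trackers in the study conditions are lambda = 8 (250 Hz video tracker) and
lambda = 15 (200 Hz dual-Purkinje tracker); both are presets here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular_stats import DirectionDistribution, KdeConfig, circular_kde
from .grids import direction_deg

__all__ = [
    "EyeTrace",
    "Saccade",
    "DetectorConfig",
    "clean_trace",
    "detect_saccades",
    "saccade_summary",
    "SaccadeSummary",
    "read_trace",
    "write_trace",
    "saccades_to_frame",
    "read_saccades",
    "write_saccades",
]


@dataclass
class EyeTrace:
    """Uniformly sampled gaze positions in degrees with a validity mask."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate_hz: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.time.size
        if not (self.x.size == self.y.size == n):
            raise ValueError("time, x, y must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - 1.0 / self.rate_hz) > 1e-9):
                raise ValueError("time must advance in uniform steps of 1/rate_hz")
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.size != n:
                raise ValueError("valid mask length mismatch")
            self.valid &= np.isfinite(self.x) & np.isfinite(self.y)

    def __len__(self) -> int:
        return self.time.size


@dataclass
class Saccade:
    """A detected (or simulated) saccade.

    Direction follows the y-up screen convention: 0 deg = rightward,
    90 deg = upward.  Amplitude is the Euclidean start-to-end distance.
    """

    onset_s: float
    offset_s: float
    x0: float
    y0: float
    x1: float
    y1: float
    amplitude: float
    direction_deg: float
    peak_velocity: float

    @classmethod
    def from_endpoints(
        cls, onset_s, offset_s, x0, y0, x1, y1, peak_velocity=math.nan
    ) -> "Saccade":
        dx, dy = x1 - x0, y1 - y0
        return cls(
            onset_s=float(onset_s),
            offset_s=float(offset_s),
            x0=float(x0),
            y0=float(y0),
            x1=float(x1),
            y1=float(y1),
            amplitude=float(math.hypot(dx, dy)),
            direction_deg=float(direction_deg(dx, dy)),
            peak_velocity=float(peak_velocity),
        )


@dataclass(frozen=True)
class DetectorConfig:
    """Engbert-Kliegl detector settings.

    ``lam`` multiplies the per-axis robust SD of velocity to set the elliptic
    threshold.  Minimum duration, merge gap and blink padding are not fixed
    by the velocity-threshold method itself; the defaults follow its common
    practice and are exposed for adjustment.
    """

    lam: float = 8.0
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 20.0
    smooth_window_samples: int = 5
    blink_pad_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if min(self.min_duration_ms, self.merge_gap_ms, self.blink_pad_ms) < 0:
            raise ValueError("durations must be nonnegative")
        w = self.smooth_window_samples
        if w < 3 or w % 2 == 0:
            raise ValueError("smooth_window_samples must be an odd integer >= 3")


DOVES_PRESET = DetectorConfig(lam=15.0)
FVTILT_PRESET = DetectorConfig(lam=8.0)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def clean_trace(trace: EyeTrace, blink_pad_ms: float = 50.0) -> EyeTrace:
    """Mark blink/artifact samples (and a padding margin around them) invalid.

    Non-finite samples are treated as blink/artifact; every sample within
    ``blink_pad_ms`` of a non-finite run is also invalidated, removing the
    lid-closure transients that flank blinks.  Positions are untouched.
    """
    bad = ~(np.isfinite(trace.x) & np.isfinite(trace.y)) | ~trace.valid
    pad = int(round(blink_pad_ms / 1000.0 * trace.rate_hz))
    mask = bad.copy()
    if pad > 0 and bad.any():
        for s, e in _runs(bad):
            mask[max(0, s - pad) : min(len(mask), e + pad)] = True
    valid = ~mask
    if not valid.any():
        raise ValueError("trace is entirely invalid after cleaning")
    return EyeTrace(trace.time, trace.x, trace.y, trace.rate_hz, valid)


def _velocity(pos: np.ndarray, rate_hz: float, window: int) -> np.ndarray:
    """Centered moving-window differentiator (Engbert-Kliegl style).

    For window 2m+1: v[n] = sum_{j=1..m} (pos[n+j] - pos[n-j]) / (m(m+1) dt),
    which for m=2 is the classic 5-sample estimator
    (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (6 dt).
    """
    m = (window - 1) // 2
    n = pos.size
    v = np.full(n, np.nan)
    acc = np.zeros(n - 2 * m)
    for j in range(1, m + 1):
        acc += pos[m + j : n - m + j] - pos[m - j : n - m - j]
    v[m : n - m] = acc / (m * (m + 1)) * rate_hz
    return v


def _robust_sd(v: np.ndarray) -> float:
    v = v[np.isfinite(v)]
    med = np.median(v)
    sd = math.sqrt(max(np.median(v**2) - med**2, 0.0))
    return sd


def detect_saccades(trace: EyeTrace, cfg: DetectorConfig = DetectorConfig()):
    """Detect saccades with the elliptic velocity-threshold criterion.

    A sample is saccadic when ``(vx/(lam*sx))^2 + (vy/(lam*sy))^2 > 1`` with
    per-axis robust SDs ``sx, sy``.  Runs shorter than ``min_duration_ms``
    are discarded, runs separated by less than ``merge_gap_ms`` merged, and
    runs touching invalid samples dropped.  Returns saccades sorted by onset.
    """
    n = len(trace)
    if n < cfg.smooth_window_samples:
        raise ValueError(
            f"trace of {n} samples is shorter than the {cfg.smooth_window_samples}-sample "
            "smoothing window"
        )
    x = np.where(trace.valid, trace.x, np.nan)
    y = np.where(trace.valid, trace.y, np.nan)
    vx = _velocity(x, trace.rate_hz, cfg.smooth_window_samples)
    vy = _velocity(y, trace.rate_hz, cfg.smooth_window_samples)
    sx = _robust_sd(vx)
    sy = _robust_sd(vy)
    if sx <= 0 or sy <= 0:
        return []
    with np.errstate(invalid="ignore"):
        crit = (vx / (cfg.lam * sx)) ** 2 + (vy / (cfg.lam * sy)) ** 2 > 1.0
    crit &= np.isfinite(vx) & np.isfinite(vy)

    dt = 1.0 / trace.rate_hz
    min_len = max(1, int(round(cfg.min_duration_ms / 1000.0 / dt)))
    gap_len = int(round(cfg.merge_gap_ms / 1000.0 / dt))

    runs = [(s, e) for s, e in _runs(crit) if e - s >= min_len]
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_len:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    speed = np.hypot(vx, vy)
    out = []
    for s, e in merged:
        if not trace.valid[s:e].all():
            continue
        out.append(
            Saccade.from_endpoints(
                trace.time[s],
                trace.time[e - 1],
                trace.x[s],
                trace.y[s],
                trace.x[e - 1],
                trace.y[e - 1],
                peak_velocity=float(np.nanmax(speed[s:e])),
            )
        )
    out.sort(key=lambda sc: sc.onset_s)
    return out


@dataclass
class SaccadeSummary:
    """Main-sequence pairs, log-spaced amplitude histogram, direction density."""

    main_sequence: np.ndarray  # (n, 2): amplitude, peak velocity
    amp_bin_edges: np.ndarray
    amp_counts: np.ndarray
    direction_distribution: DirectionDistribution


def saccade_summary(
    saccades,
    kde_cfg: KdeConfig = KdeConfig(),
    n_amp_bins: int = 20,
) -> SaccadeSummary:
    """Summary statistics of a saccade table."""
    if not saccades:
        raise ValueError("saccade list is empty")
    amp = np.array([s.amplitude for s in saccades])
    pv = np.array([s.peak_velocity for s in saccades])
    dirs = np.deg2rad([s.direction_deg for s in saccades])
    lo = max(amp.min(), 1e-3)
    hi = max(amp.max(), lo * (1 + 1e-9))
    edges = np.geomspace(lo * (1 - 1e-12), hi * (1 + 1e-12), n_amp_bins + 1)
    counts, _ = np.histogram(amp, bins=edges)
    return SaccadeSummary(
        main_sequence=np.column_stack([amp, pv]),
        amp_bin_edges=edges,
        amp_counts=counts,
        direction_distribution=circular_kde(dirs, cfg=kde_cfg),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O


def write_trace(trace: EyeTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "x_deg": trace.x,
            "y_deg": trace.y,
            "valid": trace.valid.astype(int),
        }
    ).to_csv(path, index=False)


def read_trace(path, rate_hz: float | None = None) -> EyeTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    valid = df["valid"].to_numpy(bool) if "valid" in df else None
    return EyeTrace(t, df["x_deg"].to_numpy(float), df["y_deg"].to_numpy(float), rate_hz, valid)


def saccades_to_frame(saccades) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in saccades])


def write_saccades(saccades, path) -> None:
    saccades_to_frame(saccades).to_csv(path, index=False)


def read_saccades(path) -> list[Saccade]:
    df = pd.read_csv(path)
    return [Saccade(**row) for row in df.to_dict("records")]
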