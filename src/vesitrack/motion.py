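"""Per-track motion statistics for vesicle trajectories.

Classification follows the MSD-exponent convention: the slope alpha of
log MSD vs. log time lag is ~2 for directed (ballistic) motion, ~1 for
free diffusion, and <1 for confinement.  Tracks are called confined
below ``alpha_confined``, linear above ``alpha_linear``, and left
unclassified in between (free diffusion lands there by design).  The
default thresholds (0.7 / 1.3) are symmetric about the diffusive value
and were fixed against the labelled synthetic suite.

Confinement is summarised by the area of the minimal enclosing circle
of the track's positions — the circle one would draw around the
trajectory.  Pauses are steps whose instantaneous speed is strictly
below a threshold (0.1 µm/s by default).  Direction changes are sign
flips of successive step projections onto the track's first principal
axis, with paused steps excluded from the tabulation (but not from the
axis estimate, which uses all positions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import minimal_enclosing_circle
from .tracks import Track

DEFAULT_PAUSE_SPEED_THRESHOLD = 0.1   # µm/s, strict "less than"
DEFAULT_ALPHA_CONFINED = 0.7
DEFAULT_ALPHA_LINEAR = 1.3
DEFAULT_MIN_POINTS = 20


@dataclass
class MotionReport:
    """Per-track classification and derived statistics.

    ``confinement_area`` is populated only for confined tracks and
    ``direction_changes_per_s`` only for linear ones; the other holds
    NaN, so a column of reports can be aggregated per class directly.
    """

    track_id: str
    track_class: str          # confined | linear | unclassified
    msd_exponent: float
    confinement_area: float   # µm², NaN unless confined
    mean_speed: float         # µm/s
    pause_rate: float         # pauses/s
    direction_changes_per_s: float  # /s, NaN unless linear
    duration: float           # s
    total_path_length: float  # µm


def msd(track: Track, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean squared displacement.

    Averages squared displacements over all ordered pairs of
    observations separated by each integer frame lag 1..max_lag;
    returns (lag times in s, MSD in µm²).  Lags with no observation
    pair (possible for gappy tracks) are NaN.
    """
    if max_lag >= len(track):
        raise ValueError("max_lag must be smaller than the track length")
    frames = track.frames
    pos = track.positions
    index = {int(f): i for i, f in enumerate(frames)}
    lags = np.arange(1, max_lag + 1)
    out = np.full(max_lag, np.nan)
    for k, lag in enumerate(lags):
        d2 = [np.sum((pos[index[f + lag]] - pos[i]) ** 2)
              for i, f in enumerate(frames) if int(f) + lag in index]
        if d2:
            out[k] = float(np.mean(d2))
    return lags * track.frame_interval, out


def classify_track(track: Track,
                   alpha_confined: float = DEFAULT_ALPHA_CONFINED,
                   alpha_linear: float = DEFAULT_ALPHA_LINEAR,
                   min_points: int = DEFAULT_MIN_POINTS) -> tuple[str, float]:
    """Classify a track as confined / linear / unclassified.

    The MSD exponent is the least-squares slope of log MSD vs. log lag
    over frame lags 1..min(10, n//3).  A zero-variance (stationary)
    track is confined by convention with exponent 0.
    """
    if not 0 < alpha_confined < alpha_linear:
        raise ValueError("thresholds must satisfy 0 < alpha_confined < alpha_linear")
    if len(track) < min_points:
        return "unclassified", float("nan")
    max_lag = max(2, min(10, len(track) // 3))
    lag_t, m = msd(track, max_lag)
    valid = np.isfinite(m) & (m > 0)
    if valid.sum() < 2:
        # stationary or degenerate: no measurable displacement
        return "confined", 0.0
    slope = np.polyfit(np.log(lag_t[valid]), np.log(m[valid]), 1)[0]
    if slope < alpha_confined:
        return "confined", float(slope)
    if slope > alpha_linear:
        return "linear", float(slope)
    return "unclassified", float(slope)


def confinement_area(track: Track) -> float:
    """Area (µm²) of the minimal enclosing circle of the positions."""
    return minimal_enclosing_circle(track.positions).area


def mean_speed(track: Track) -> float:
    """Mean over consecutive observed pairs of displacement / elapsed time."""
    return float(np.mean(track.step_speeds()))


@dataclass
class PauseResult:
    segments: list          # (start_step, end_step) inclusive step indices
    n_pauses: int
    pause_rate: float       # onsets per second of track duration
    paused_steps: np.ndarray  # boolean per step


def detect_pauses(track: Track,
                  pause_speed_threshold: float = DEFAULT_PAUSE_SPEED_THRESHOLD
                  ) -> PauseResult:
    """Find pauses: maximal runs of steps with speed strictly below threshold.

    The rate denominator is the full track duration (first to last
    observation); a step at exactly the threshold speed is not paused.
    """
    if pause_speed_threshold <= 0:
        raise ValueError("pause_speed_threshold must be > 0")
    speeds = track.step_speeds()
    paused = speeds < pause_speed_threshold
    segments = []
    start = None
    for i, p in enumerate(paused):
        if p and start is None:
            start = i
        elif not p and start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, len(paused) - 1))
    rate = len(segments) / track.duration
    return PauseResult(segments=segments, n_pauses=len(segments),
                       pause_rate=rate, paused_steps=paused)


@dataclass
class DirectionChangeResult:
    count: int
    rate: float | None       # /s; None when no steps survive the pause filter
    projections: np.ndarray  # retained signed projections


def direction_changes(track: Track,
                      pause_speed_threshold: float = DEFAULT_PAUSE_SPEED_THRESHOLD
                      ) -> DirectionChangeResult:
    """Count principal-axis direction reversals, excluding paused steps.

    The first principal axis is estimated from all positions (paused
    ones included — they carry information about where the track
    lives); each consecutive displacement is projected onto it, paused
    steps and exactly-zero projections are discarded, and sign changes
    between successive retained projections are counted.  The count is
    invariant under the sign ambiguity of the axis.
    """
    if len(track) < 3:
        raise ValueError("direction_changes needs at least 3 points")
    centered = track.positions - track.positions.mean(axis=0)
    # first right singular vector = first principal axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    disp = np.diff(track.positions, axis=0)
    proj = disp @ axis
    paused = detect_pauses(track, pause_speed_threshold).paused_steps
    retained = proj[~paused]
    retained = retained[retained != 0.0]
    if len(retained) == 0:
        return DirectionChangeResult(count=0, rate=None,
                                     projections=retained)
    signs = np.sign(retained)
    count = int(np.sum(signs[1:] != signs[:-1]))
    return DirectionChangeResult(count=count, rate=count / track.duration,
                                 projections=retained)


def analyze_track(track: Track, *,
                  alpha_confined: float = DEFAULT_ALPHA_CONFINED,
                  alpha_linear: float = DEFAULT_ALPHA_LINEAR,
                  min_points: int = DEFAULT_MIN_POINTS,
                  pause_speed_threshold: float = DEFAULT_PAUSE_SPEED_THRESHOLD
                  ) -> MotionReport:
    """Full per-track report: class plus the class-appropriate statistics."""
    cls, alpha = classify_track(track, alpha_confined, alpha_linear, min_points)
    area = confinement_area(track) if cls == "confined" else float("nan")
    dc = float("nan")
    if cls == "linear":
        res = direction_changes(track, pause_speed_threshold)
        dc = res.rate if res.rate is not None else float("nan")
    pauses = detect_pauses(track, pause_speed_threshold)
    return MotionReport(
        track_id=track.track_id,
        track_class=cls,
        msd_exponent=alpha,
        confinement_area=area,
        mean_speed=mean_speed(track),
        pause_rate=pauses.pause_rate,
        direction_changes_per_s=dc,
        duration=track.duration,
        total_path_length=float(track.step_displacements().sum()),
    )


def analyze_tracks(tracks: list[Track], **kwargs) -> pd.DataFrame:
    """Reports for many tracks as a DataFrame (one row per track)."""
    reports = [analyze_track(t, **kwargs) for t in tracks]
    return pd.DataFrame([r.__dict__ for r in reports])


@dataclass
class GroupComparison:
    metric: str
    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    fold_change: float    # mean_b / mean_a
    n_a: int
    n_b: int


def compare_groups(reports_a: pd.DataFrame, reports_b: pd.DataFrame,
                   metric: str) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of a per-track metric.

    Track metrics are typically far from normal, hence the rank-based
    test; group means, standard errors, and the fold change are
    reported alongside for effect-size context.
    """
    for name, rep in (("a", reports_a), ("b", reports_b)):
        if metric not in rep.columns:
            raise ValueError(f"metric '{metric}' absent from group {name}")
    a = reports_a[metric].dropna().to_numpy()
    b = reports_b[metric].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"metric '{metric}' has no finite values in one group")
    stat, p = stats.ranksums(a, b)
    return GroupComparison(
        metric=metric, statistic=float(stat), pvalue=float(p),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        se_a=float(np.std(a, ddof=1) / math.sqrt(len(a))) if len(a) > 1 else float("nan"),
        se_b=float(np.std(b, ddof=1) / math.sqrt(len(b))) if len(b) > 1 else float("nan"),
        fold_change=float(np.mean(b) / np.mean(a)) if np.mean(a) != 0 else float("nan"),
        n_a=len(a), n_b=len(b),
    )
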