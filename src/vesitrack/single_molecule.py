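"""Single-molecule TIRF assay metrics.

Quantifies motor behaviour on surface-immobilised microtubules:
density of motor spots per µm of microtubule, the percentage of motors
that move (under joint speed / net-distance / duration criteria), and
lifespan statistics of the microtubule-bound pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import skeletonize

from .images import LabelImage
from .motion import mean_speed
from .tracks import SpotTable, Track

# Moving-motor criteria: strict inequalities on all three.
DEFAULT_SPEED_MIN = 0.12     # µm/s
DEFAULT_DISTANCE_MIN = 0.2   # µm net start-to-end displacement
DEFAULT_DURATION_MIN = 0.9   # s
DEFAULT_FRAME_INTERVAL = 0.041  # s, streaming TIRF cadence

_SQRT2 = np.sqrt(2.0)


@dataclass
class MotorAssayReport:
    motors_per_um: float
    percent_moving: float
    median_lifespan: float      # s
    n_motors: int               # tracks analysed
    mt_total_length: float      # µm
    per_track: "np.recarray | None" = None


def _skeleton_length_px(skel: np.ndarray) -> float:
    """Skeleton length in pixel units: adjacent pairs at 1 or sqrt(2)."""
    s = skel.astype(bool)
    horiz = np.count_nonzero(s[:, 1:] & s[:, :-1])
    vert = np.count_nonzero(s[1:, :] & s[:-1, :])
    diag1 = np.count_nonzero(s[1:, 1:] & s[:-1, :-1])
    diag2 = np.count_nonzero(s[1:, :-1] & s[:-1, 1:])
    return horiz + vert + _SQRT2 * (diag1 + diag2)


def microtubule_length(mt_mask: LabelImage,
                       pixel_size: float | None = None) -> tuple[np.ndarray, float]:
    """Per-filament and total microtubule length from a mask.

    Each labelled filament is skeletonized and its length taken as the
    sum over adjacent skeleton pixel pairs of the step length (1 px for
    axial, sqrt(2) px for diagonal neighbours) times the pixel size.
    """
    px = pixel_size if pixel_size is not None else mt_mask.pixel_size
    labels = mt_mask.labels
    n = mt_mask.n_objects
    if n == 0 or not np.any(labels):
        raise ValueError("microtubule mask is empty")
    lengths = np.zeros(n)
    for k in range(1, n + 1):
        m = labels == k
        if not m.any():
            continue
        lengths[k - 1] = _skeleton_length_px(skeletonize(m)) * px
    return lengths, float(lengths.sum())


def motor_density(spots: SpotTable, mt_mask: LabelImage, mt_length: float,
                  dilation_px: int = 1) -> float:
    """Motors per µm: mean per-frame on-microtubule spot count / length.

    The mask is dilated by ``dilation_px`` pixels before the on-mask
    test to absorb localization error.  Frames with no detections count
    as zero, so the average runs over every frame present in the table.
    """
    if mt_length <= 0:
        raise ValueError("mt_length must be > 0")
    px = mt_mask.pixel_size
    mask = mt_mask.mask()
    if dilation_px > 0:
        mask = binary_dilation(mask, iterations=dilation_px)
    df = spots.data
    if len(df) == 0:
        return 0.0
    h, w = mask.shape
    col = np.clip(np.round(df["x_um"].to_numpy() / px).astype(int), 0, w - 1)
    row = np.clip(np.round(df["y_um"].to_numpy() / px).astype(int), 0, h - 1)
    on = mask[row, col]
    frames = df["frame"].to_numpy()
    n_frames = int(frames.max()) + 1
    per_frame = np.bincount(frames[on].astype(int), minlength=n_frames)
    return float(per_frame.mean() / mt_length)


def classify_moving(track: Track,
                    speed_min: float = DEFAULT_SPEED_MIN,
                    distance_min: float = DEFAULT_DISTANCE_MIN,
                    duration_min: float = DEFAULT_DURATION_MIN,
                    use_path_length: bool = False) -> bool:
    """Is this motor moving?

    Moving means mean speed > ``speed_min``, net start-to-end
    displacement > ``distance_min`` (or total path length when
    ``use_path_length``), and tracked for > ``duration_min``; all
    strict.  Net displacement is the default so that diffusive jitter
    does not qualify as movement.
    """
    if speed_min <= 0 or distance_min <= 0 or duration_min <= 0:
        raise ValueError("thresholds must be > 0")
    if use_path_length:
        dist = float(track.step_displacements().sum())
    else:
        dist = float(np.hypot(*(track.positions[-1] - track.positions[0])))
    return (mean_speed(track) > speed_min
            and dist > distance_min
            and track.duration > duration_min)


def percent_moving(tracks: list[Track], **thresholds) -> float:
    """100 x moving / all tracks; short-lived tracks stay in the denominator."""
    if not tracks:
        raise ValueError("no tracks given")
    n_moving = sum(classify_moving(t, **thresholds) for t in tracks)
    return 100.0 * n_moving / len(tracks)


def lifespan_stats(tracks: list[Track],
                   cutoff: float | None = None) -> dict:
    """Median lifespan and the fraction of tracks outliving ``cutoff``.

    Lifespan is (last frame - first frame) x frame interval.
    """
    if not tracks:
        raise ValueError("no tracks given")
    spans = np.array([t.duration for t in tracks])
    out = {"median_lifespan": float(np.median(spans)), "n": len(spans)}
    if cutoff is not None:
        out["fraction_beyond_cutoff"] = float(np.mean(spans > cutoff))
        out["cutoff"] = float(cutoff)
    return out


def motor_assay_report(tracks: list[Track], spots: SpotTable,
                       mt_mask: LabelImage, *,
                       speed_min: float = DEFAULT_SPEED_MIN,
                       distance_min: float = DEFAULT_DISTANCE_MIN,
                       duration_min: float = DEFAULT_DURATION_MIN,
                       dilation_px: int = 1) -> MotorAssayReport:
    """Assemble the full TIRF report from tracks, detections, and mask."""
    _, total_length = microtubule_length(mt_mask)
    density = motor_density(spots, mt_mask, total_length, dilation_px=dilation_px)
    pm = percent_moving(tracks, speed_min=speed_min, distance_min=distance_min,
                        duration_min=duration_min) if tracks else float("nan")
    med = lifespan_stats(tracks)["median_lifespan"] if tracks else float("nan")
    return MotorAssayReport(motors_per_um=density, percent_moving=pm,
                            median_lifespan=med, n_motors=len(tracks),
                            mt_total_length=total_length)
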