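"""Track and spot-table data model, detection, linking, and CSV I/O.

A :class:`Track` stores time-ordered 2-D positions of one particle in
physical units (µm), with the frame interval in seconds; all downstream
motion statistics are computed in µm and seconds.  Positions converted
from pixel tables place the coordinate origin at the centre of pixel
(0, 0), i.e. ``x_um = x_px * pixel_size``.

Detection is a plain local-maximum finder with intensity-weighted 3x3
centroid refinement; linking is greedy nearest-neighbour with a hard
displacement gate and optional gap bridging.  Both are deliberately
simple, transparent stand-ins for the sophisticated detection/linking
suites used interactively in the field, and are validated against
ground truth from :mod:`vesitrack.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import label as ndimage_label
from scipy.ndimage import maximum_filter

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "intensity"]


@dataclass
class Track:
    track_id: str
    frames: np.ndarray          # strictly increasing integer frame indices
    positions: np.ndarray       # (n, 2) x, y in µm
    frame_interval: float       # s
    pixel_size: float | None = None  # µm/px provenance, if image-derived
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not (self.frame_interval > 0 and np.isfinite(self.frame_interval)):
            raise ValueError("frame_interval must be positive and finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Observation times in seconds, relative to frame 0."""
        return self.frames * self.frame_interval

    @property
    def duration(self) -> float:
        """Elapsed time from first to last observation, s."""
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)

    def step_displacements(self) -> np.ndarray:
        """Euclidean displacement per consecutive observed pair, µm."""
        return np.hypot(*np.diff(self.positions, axis=0).T)

    def step_dts(self) -> np.ndarray:
        """Elapsed time per consecutive observed pair, s (gaps included)."""
        return np.diff(self.frames) * self.frame_interval

    def step_speeds(self) -> np.ndarray:
        return self.step_displacements() / self.step_dts()


@dataclass
class SpotTable:
    """Per-frame point detections: columns frame, x_um, y_um, intensity."""

    data: pd.DataFrame
    pixel_size: float | None = None
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        required = {"frame", "x_um", "y_um", "intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"spot table missing column(s): {sorted(missing)}")
        if self.image_shape is not None and len(self.data) and self.pixel_size:
            h, w = self.image_shape
            x = self.data["x_um"].to_numpy() / self.pixel_size
            y = self.data["y_um"].to_numpy() / self.pixel_size
            if (x < -0.5).any() or (y < -0.5).any() or (x > w - 0.5).any() or (y > h - 0.5).any():
                raise ValueError("spot coordinates fall outside the attached image")

    def __len__(self) -> int:
        return len(self.data)

    def frame(self, f: int) -> pd.DataFrame:
        return self.data[self.data["frame"] == f]


@dataclass
class RejectionReport:
    n_read: int = 0
    n_kept: int = 0
    rejected: dict = field(default_factory=dict)  # track_id -> reason


def _refine_subpixel(v: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """Sub-pixel peak position from background-subtracted intensities.

    Three-point Gaussian (parabolic in log intensity) interpolation per
    axis — exact for a Gaussian spot, worst-case bias < 0.01 px for
    realistic widths.  Falls back to the 3x3 intensity-weighted
    centroid when the log-parabola is degenerate (non-positive or
    non-concave samples), whose known worst-case bias is ~0.2 px.
    """
    out = [float(py), float(px)]
    for axis, (c, a, b) in enumerate((
            (v[py, px], v[py - 1, px], v[py + 1, px]),
            (v[py, px], v[py, px - 1], v[py, px + 1]))):
        if min(c, a, b) > 0:
            la, lc, lb = np.log(a), np.log(c), np.log(b)
            den = la - 2 * lc + lb
            if den < 0 and c >= max(a, b):
                out[axis] += 0.5 * (la - lb) / den
                continue
        win = np.clip(v[py - 1:py + 2, px - 1:px + 2], 0, None)
        total = win.sum()
        if total > 0:
            g = np.mgrid[py - 1:py + 2, px - 1:px + 2][axis]
            out[axis] = float((win * g).sum() / total)
    return out[0], out[1]


def detect_spots(stack: np.ndarray, intensity_threshold: float,
                 min_separation: float, pixel_size: float = 1.0) -> SpotTable:
    """Detect bright spots in every frame of an image stack.

    A detection is a local maximum (8-neighbourhood) above
    ``intensity_threshold``; a connected plateau of equal maxima up to
    3x3 pixels counts as one peak, larger plateaus are treated as flat
    background.  Positions are refined to sub-pixel precision by
    three-point Gaussian interpolation on locally background-subtracted
    intensities (see :func:`_refine_subpixel`).  Maxima closer than
    ``min_separation`` pixels keep only the brighter one.  Coordinates
    are returned in µm; ``intensity`` is the background-subtracted 3x3
    sum.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("expected a non-empty 2-D frame or 3-D stack")
    if not np.isfinite(intensity_threshold):
        raise ValueError("intensity_threshold must be finite")
    rows = []
    h, w = stack.shape[1:]
    for f, img in enumerate(stack):
        # local maxima over the 8-neighbourhood; a connected run of
        # equal-valued maximum pixels (e.g. a spot centred exactly on a
        # pixel boundary) counts as one peak at its centroid, but a
        # plateau wider than a 3x3 core is flat background, not a spot
        mx = maximum_filter(img, size=3, mode="nearest")
        cand = (img == mx) & (img > intensity_threshold)
        lab, n_plateau = ndimage_label(cand, structure=np.ones((3, 3)))
        peaks = []
        for k in range(1, n_plateau + 1):
            ys, xs = np.nonzero(lab == k)
            if len(ys) > 9:
                continue
            peaks.append((int(round(ys.mean())), int(round(xs.mean()))))
        peaks = np.array(peaks, dtype=int).reshape(-1, 2)
        # keep away from the border so the 3x3 centroid window exists
        peaks = peaks[(peaks[:, 0] > 0) & (peaks[:, 0] < h - 1)
                      & (peaks[:, 1] > 0) & (peaks[:, 1] < w - 1)]
        if len(peaks) == 0:
            continue
        inten = img[peaks[:, 0], peaks[:, 1]]
        order = np.argsort(-inten, kind="stable")
        kept: list[tuple[int, int]] = []
        for idx in order:
            py, px = peaks[idx]
            if all((py - ky) ** 2 + (px - kx) ** 2 >= min_separation**2
                   for ky, kx in kept):
                kept.append((py, px))
        for py, px in kept:
            bg = img[max(py - 2, 0):py + 3, max(px - 2, 0):px + 3].min()
            v = img - bg
            cy, cx = _refine_subpixel(v, py, px)
            total = float(np.clip(v[py - 1:py + 2, px - 1:px + 2], 0, None).sum())
            rows.append((f, cx * pixel_size, cy * pixel_size, total))
    df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity"])
    return SpotTable(df, pixel_size=pixel_size, image_shape=(h, w))


def link_spots(spots: SpotTable, max_disp: float, max_gap: int = 0,
               frame_interval: float = 1.0) -> list[Track]:
    """Link detections into tracks by greedy nearest-neighbour assignment.

    Candidate links between open track ends and new-frame spots are
    sorted globally by distance and accepted greedily; a link is
    forbidden beyond ``max_disp`` µm per elapsed frame.  A track end
    stays open for up to ``max_gap`` missing frames.  Tracks with fewer
    than two points are dropped.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    df = spots.data.sort_values(["frame"], kind="stable").reset_index(drop=True)
    open_tracks: list[dict] = []   # {'frames': [...], 'xy': [...], 'I': [...]}
    closed: list[dict] = []
    for f in sorted(df["frame"].unique()):
        sub = df[df["frame"] == f]
        pts = sub[["x_um", "y_um"]].to_numpy()
        inten = sub["intensity"].to_numpy()
        # retire ends that can no longer be linked
        still_open = []
        for t in open_tracks:
            if f - t["frames"][-1] > max_gap + 1:
                closed.append(t)
            else:
                still_open.append(t)
        open_tracks = still_open
        # all candidate (distance, track, spot) pairs within the gate
        cands = []
        for ti, t in enumerate(open_tracks):
            elapsed = f - t["frames"][-1]
            last = t["xy"][-1]
            d = np.hypot(pts[:, 0] - last[0], pts[:, 1] - last[1])
            gate = max_disp * elapsed
            for si in np.nonzero(d <= gate)[0]:
                cands.append((d[si], ti, int(si)))
        cands.sort(key=lambda c: c[0])
        used_t: set[int] = set()
        used_s: set[int] = set()
        for d, ti, si in cands:
            if ti in used_t or si in used_s:
                continue
            used_t.add(ti)
            used_s.add(si)
            t = open_tracks[ti]
            t["frames"].append(int(f))
            t["xy"].append(tuple(pts[si]))
            t["I"].append(float(inten[si]))
        for si in range(len(pts)):
            if si not in used_s:
                open_tracks.append({"frames": [int(f)], "xy": [tuple(pts[si])],
                                    "I": [float(inten[si])]})
    closed.extend(open_tracks)
    tracks = []
    n = 0
    for t in closed:
        if len(t["frames"]) < 2:
            continue
        tracks.append(Track(track_id=f"t{n:05d}", frames=np.array(t["frames"]),
                            positions=np.array(t["xy"]),
                            frame_interval=frame_interval,
                            pixel_size=spots.pixel_size,
                            intensity=np.array(t["I"])))
        n += 1
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        inten = t.intensity if t.intensity is not None else np.full(len(t), np.nan)
        for f, (x, y), i in zip(t.frames, t.positions, inten):
            rows.append((t.track_id, int(f), float(x), float(y), float(i)))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks to CSV (columns track_id, frame, x_um, y_um, intensity)."""
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.6f")


def read_tracks(path: str | Path, frame_interval: float = 1.0,
                pixel_size: float | None = None) -> tuple[list[Track], RejectionReport]:
    """Read tracks from CSV; malformed tracks are rejected individually.

    Returns the valid tracks plus a :class:`RejectionReport` mapping
    rejected track ids to the reason (too few points, non-monotone
    frames, non-finite coordinates).  A missing required column raises.
    """
    df = pd.read_csv(path)
    for col in ("track_id", "frame", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"track CSV is missing required column '{col}'")
    report = RejectionReport()
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        report.n_read += 1
        sub = sub.sort_index()
        frames = sub["frame"].to_numpy()
        pos = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(sub) < 2:
            report.rejected[str(tid)] = "fewer than 2 points"
            continue
        if not np.all(np.diff(frames) > 0):
            report.rejected[str(tid)] = "frames not strictly increasing"
            continue
        if not np.all(np.isfinite(pos)):
            report.rejected[str(tid)] = "non-finite coordinates"
            continue
        inten = sub["intensity"].to_numpy(dtype=float) if "intensity" in sub else None
        tracks.append(Track(track_id=str(tid), frames=frames, positions=pos,
                            frame_interval=frame_interval, pixel_size=pixel_size,
                            intensity=inten))
        report.n_kept += 1
    return tracks, report
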