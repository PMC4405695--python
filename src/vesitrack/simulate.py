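"""Ground-truth generators for every analysis stage.

The generators emulate the statistical structure the downstream
analyses assume, with every relevant parameter known:

* :func:`simulate_track` — vesicle trajectories, either confined
  (Brownian motion with hard billiard reflection inside a disc, so the
  true occupied area is exactly pi R^2) or directed (constant speed
  along a heading that flips 180 degrees as a Poisson process).  Both
  modes support Poisson pause onsets with exponential pause durations;
  a pause suppresses true displacement but not localization noise.
  Event times are drawn in continuous time and sampled at frame
  boundaries, so an excursion shorter than one frame may be invisible
  to a frame-based estimator — that is a property of real sampled data
  and is deliberately not corrected here.

* :func:`simulate_motor_field` — straight microtubule filaments of
  known summed length decorated with motor spots at a stated linear
  density; spots are static or move along their filament, appear and
  disappear as a stationary birth-death process with exponential
  lifetimes, and carry ground-truth moving/static labels.

* :func:`render_cell_image` — two-channel still images: a Golgi
  channel with disc-shaped objects of prescribed area and intensity
  inside polygonal cells, and a diffuse per-cell marker channel.  The
  pixel-quantised achieved area, not the requested area, is recorded
  as ground truth.

* :func:`simulate_binding_table` — one-site saturation binding data
  with multiplicative Gaussian noise of stated coefficient of
  variation.

All generators are bit-reproducible from their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .images import LabelImage
from .tracks import SpotTable, Track


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid parameter '{name}': {msg}")


def _finite_nonneg(value: float, name: str) -> None:
    _require(np.isfinite(value) and value >= 0, name, f"must be finite and >= 0, got {value!r}")


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrackSimParams:
    """Parameters of a simulated vesicle trajectory.

    ``mode`` selects confined (reflected Brownian motion inside a disc
    of ``confinement_radius`` about the start point, diffusion
    coefficient ``diffusion_coefficient`` in µm²/s) or directed
    (constant ``speed`` µm/s along a heading that reverses at Poisson
    rate ``reversal_rate`` per second).  Pauses start as a Poisson
    process at ``pause_rate`` /s and last exponentially with mean
    ``pause_duration_mean`` s.  Independent Gaussian localization noise
    of ``localization_noise_sd`` µm per coordinate is added per frame.
    """

    mode: str = "confined"
    diffusion_coefficient: float = 0.05   # µm²/s, confined mode
    confinement_radius: float = 0.3       # µm, confined mode
    speed: float = 0.5                    # µm/s, directed mode
    reversal_rate: float = 0.05           # /s, directed mode
    pause_rate: float = 0.0               # /s
    pause_duration_mean: float = 4.0      # s
    frame_interval: float = 2.0           # s (live vesicle imaging cadence)
    n_frames: int = 71
    localization_noise_sd: float = 0.02   # µm
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.mode in ("confined", "directed"), "mode",
                 f"must be 'confined' or 'directed', got {self.mode!r}")
        for name in ("diffusion_coefficient", "confinement_radius", "speed",
                     "reversal_rate", "pause_rate", "pause_duration_mean",
                     "localization_noise_sd"):
            _finite_nonneg(getattr(self, name), name)
        _require(self.n_frames >= 2, "n_frames", "must be >= 2")
        _require(self.frame_interval > 0 and np.isfinite(self.frame_interval),
                 "frame_interval", "must be > 0")
        if self.mode == "confined":
            _require(self.confinement_radius > 0, "confinement_radius",
                     "must be > 0 in confined mode")


def _pause_intervals(rng: np.random.Generator, total_time: float,
                     pause_rate: float, pause_mean: float) -> list[tuple[float, float]]:
    """Alternating-renewal pause intervals on [0, total_time)."""
    if pause_rate <= 0:
        return []
    out = []
    t = 0.0
    while t < total_time:
        t += rng.exponential(1.0 / pause_rate)
        if t >= total_time:
            break
        dur = rng.exponential(pause_mean) if pause_mean > 0 else 0.0
        out.append((t, min(t + dur, total_time)))
        t += dur
    return out


def _event_times(rng: np.random.Generator, rate: float, total_time: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * total_time)
    return np.sort(rng.uniform(0.0, total_time, size=n))


def _moving_time(pauses: list[tuple[float, float]], a: float, b: float) -> float:
    """Non-paused time within [a, b)."""
    t = b - a
    for p0, p1 in pauses:
        t -= max(0.0, min(b, p1) - max(a, p0))
    return t


def _signed_moving_time(pauses, reversals, a: float, b: float, sign_at_a: float) -> float:
    """Integral of heading sign over non-paused time within [a, b)."""
    cuts = [a] + [t for t in reversals if a < t < b] + [b]
    s = sign_at_a
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        total += s * _moving_time(pauses, lo, hi)
        s = -s
    return total


def _reflect_into_disc(p: np.ndarray, step: np.ndarray, center: np.ndarray,
                       radius: float) -> np.ndarray:
    """Billiard (specular) reflection of a straight step inside a disc."""
    for _ in range(1000):
        q = p + step
        if np.hypot(*(q - center)) <= radius:
            return q
        # first crossing of the boundary: |p + t*step - c| = R, t in (0, 1]
        d = p - center
        a = step @ step
        b = 2.0 * (d @ step)
        c = d @ d - radius * radius
        disc = b * b - 4 * a * c
        if a == 0.0 or disc < 0:
            return p
        t = (-b + math.sqrt(disc)) / (2 * a)
        t = min(max(t, 0.0), 1.0)
        hit = p + t * step
        normal = (hit - center) / radius
        rest = (1.0 - t) * step
        step = rest - 2.0 * (rest @ normal) * normal
        p = hit
    # pathological step count: clamp radially
    q = p + step
    r = np.hypot(*(q - center))
    return center + (q - center) * (radius / r) if r > radius else q


def simulate_track(params: TrackSimParams) -> Track:
    """Simulate one vesicle trajectory; see :class:`TrackSimParams`."""
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    dt = params.frame_interval
    total_time = (n - 1) * dt
    pauses = _pause_intervals(rng, total_time, params.pause_rate,
                              params.pause_duration_mean)
    pos = np.zeros((n, 2))
    if params.mode == "directed":
        reversals = _event_times(rng, params.reversal_rate, total_time)
        theta = rng.uniform(0, 2 * math.pi)
        heading = np.array([math.cos(theta), math.sin(theta)])
        for i in range(1, n):
            a, b = (i - 1) * dt, i * dt
            sign_at_a = 1.0 if np.sum(reversals < a) % 2 == 0 else -1.0
            s = _signed_moving_time(pauses, reversals, a, b, sign_at_a)
            pos[i] = pos[i - 1] + params.speed * s * heading
    else:
        center = pos[0].copy()
        radius = params.confinement_radius
        for i in range(1, n):
            a, b = (i - 1) * dt, i * dt
            m = _moving_time(pauses, a, b)
            sd = math.sqrt(2.0 * params.diffusion_coefficient * m) if m > 0 else 0.0
            step = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
            pos[i] = _reflect_into_disc(pos[i - 1].copy(), step, center, radius)
    if params.localization_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.localization_noise_sd, size=pos.shape)
    return Track(track_id=f"sim-{params.mode}-{params.seed}",
                 frames=np.arange(n), positions=pos,
                 frame_interval=dt)


# ---------------------------------------------------------------------------
# single-molecule motor fields


@dataclass
class MotorField:
    """Output of :func:`simulate_motor_field`."""

    mask: LabelImage                 # one label per filament
    spots: SpotTable                 # observable: frame, x_um, y_um, intensity (+spot_id)
    truth: pd.DataFrame              # spot_id, moving, birth_s, death_s, filament
    filament_segments: list[tuple[np.ndarray, np.ndarray]]
    filament_lengths: np.ndarray     # µm, exact Euclidean
    total_length: float              # µm


def simulate_motor_field(mt_total_length: float, density: float,
                         moving_fraction: float, speed: float,
                         lifespan_mean: float, n_frames: int,
                         frame_interval: float = 0.041, seed: int = 0, *,
                         image_shape: tuple[int, int] = (256, 256),
                         pixel_size: float = 0.1, margin_um: float = 1.0,
                         intensity: float = 1000.0,
                         min_spot_separation: float = 0.0) -> MotorField:
    """Simulate motor spots on straight microtubule filaments.

    Filaments are straight segments of exact summed length
    ``mt_total_length`` placed inside the field of view.  The spot
    population is a stationary birth-death process: the initial count
    is Poisson with mean ``density * mt_total_length`` and births occur
    at the matching equilibrium rate, so the expected per-frame on-mask
    count equals ``density * mt_total_length`` at every frame.  Each
    spot is moving (probability ``moving_fraction``) at ``speed`` µm/s
    along its filament, or static; lifetimes are exponential with mean
    ``lifespan_mean`` s (moving spots additionally die on reaching a
    filament end).

    ``min_spot_separation`` (µm of arc length) switches the placement
    from Poisson to a hard-core process: new spots are rejected within
    that arc distance of an existing one.  Two emitters closer than the
    optical resolution are unresolvable by any detector, so recovery
    experiments that grade detection fidelity should place spots with
    an exclusion radius at least the resolution limit; 0 (default)
    gives pure Poisson placement.
    """
    _require(mt_total_length > 0, "mt_total_length", "must be > 0")
    _finite_nonneg(density, "density")
    _require(0 <= moving_fraction <= 1, "moving_fraction", "must be in [0, 1]")
    _finite_nonneg(speed, "speed")
    _require(lifespan_mean > 0, "lifespan_mean", "must be > 0")
    _require(n_frames >= 1, "n_frames", "must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    field_h = h * pixel_size
    field_w = w * pixel_size
    usable = min(field_h, field_w) - 2 * margin_um
    _require(usable > 1.0, "image_shape", "field too small for margin")

    # split total length into segments, then place each with both ends inside
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    lengths: list[float] = []
    remaining = mt_total_length
    while remaining > 1e-9:
        seg_len = min(remaining, float(rng.uniform(0.5, 0.9)) * usable)
        remaining -= seg_len
        for _ in range(10000):
            ang = rng.uniform(0, math.pi)
            u = np.array([math.cos(ang), math.sin(ang)])
            c = np.array([rng.uniform(margin_um, field_w - margin_um),
                          rng.uniform(margin_um, field_h - margin_um)])
            p0 = c - 0.5 * seg_len * u
            p1 = c + 0.5 * seg_len * u
            ok = all(margin_um / 2 <= p[0] <= field_w - margin_um / 2
                     and margin_um / 2 <= p[1] <= field_h - margin_um / 2
                     for p in (p0, p1))
            if ok:
                segments.append((p0, p1))
                lengths.append(seg_len)
                break
        else:
            raise RuntimeError("could not place a filament inside the field")
    lengths_arr = np.array(lengths)
    cum = np.concatenate([[0.0], np.cumsum(lengths_arr)])

    labels = np.zeros(image_shape, dtype=np.int64)
    for k, (p0, p1) in enumerate(segments, start=1):
        rr, cc = draw_line(int(round(p0[1] / pixel_size)), int(round(p0[0] / pixel_size)),
                           int(round(p1[1] / pixel_size)), int(round(p1[0] / pixel_size)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        labels[rr[keep], cc[keep]] = k
    mask = LabelImage(labels, pixel_size, channel="microtubule")

    # spot birth-death process
    total_time = max(n_frames - 1, 1) * frame_interval
    n0 = rng.poisson(density * mt_total_length)
    birth_rate = density * mt_total_length / lifespan_mean
    n_births = rng.poisson(birth_rate * total_time)
    births = np.concatenate([np.zeros(n0),
                             np.sort(rng.uniform(0, total_time, size=n_births))])
    rows = []
    truth_rows = []
    placed: list[tuple[float, float]] = []   # (arc at birth, death time)
    for sid, tb in enumerate(births):
        arc = rng.uniform(0.0, mt_total_length)
        if min_spot_separation > 0:
            for _ in range(100):
                clash = any(abs(arc - a) < min_spot_separation and d > tb
                            for a, d in placed)
                if not clash:
                    break
                arc = rng.uniform(0.0, mt_total_length)
        fil = int(np.searchsorted(cum, arc, side="right") - 1)
        fil = min(fil, len(lengths) - 1)
        s0 = arc - cum[fil]
        moving = bool(rng.uniform() < moving_fraction)
        direction = 1.0 if rng.uniform() < 0.5 else -1.0
        td = tb + rng.exponential(lifespan_mean)
        if moving and speed > 0:
            t_edge = (lengths_arr[fil] - s0) / speed if direction > 0 else s0 / speed
            td = min(td, tb + t_edge)
        p0, p1 = segments[fil]
        u = (p1 - p0) / lengths_arr[fil]
        placed.append((arc, td))
        truth_rows.append((sid, moving, tb, td, fil))
        for f in range(n_frames):
            t = f * frame_interval
            if not (tb <= t < td):
                continue
            s = s0 + direction * speed * (t - tb) if moving else s0
            xy = p0 + s * u
            rows.append((f, float(xy[0]), float(xy[1]), intensity, sid))
    spots_df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity",
                                           "spot_id"])
    truth = pd.DataFrame(truth_rows, columns=["spot_id", "moving", "birth_s",
                                              "death_s", "filament"])
    return MotorField(mask=mask,
                      spots=SpotTable(spots_df, pixel_size=pixel_size,
                                      image_shape=image_shape),
                      truth=truth, filament_segments=segments,
                      filament_lengths=lengths_arr,
                      total_length=float(lengths_arr.sum()))


def render_spot_stack(spots: SpotTable, image_shape: tuple[int, int],
                      pixel_size: float, n_frames: int | None = None, *,
                      psf_sigma: float = 1.2, amplitude: float = 200.0,
                      background: float = 10.0, noise_sd: float = 0.0,
                      seed: int = 0) -> np.ndarray:
    """Render a spot table into an image stack of Gaussian spots.

    Each detection becomes an isotropic Gaussian of peak ``amplitude``
    and width ``psf_sigma`` pixels at its sub-pixel position, on a
    constant ``background`` with additive Gaussian read noise.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    if n_frames is None:
        n_frames = int(spots.data["frame"].max()) + 1 if len(spots) else 1
    stack = np.full((n_frames, h, w), float(background))
    rad = max(1, int(math.ceil(4 * psf_sigma)))
    for row in spots.data.itertuples(index=False):
        f = int(row.frame)
        if f >= n_frames:
            continue
        cx = row.x_um / pixel_size
        cy = row.y_um / pixel_size
        x0, x1 = int(math.floor(cx)) - rad, int(math.floor(cx)) + rad + 1
        y0, y1 = int(math.floor(cy)) - rad, int(math.floor(cy)) + rad + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        gy, gx = np.mgrid[y0c:y1c, x0c:x1c]
        stack[f, y0c:y1c, x0c:x1c] += amplitude * np.exp(
            -((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * psf_sigma**2))
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack


# ---------------------------------------------------------------------------
# cell images


@dataclass
class GolgiObjectSpec:
    centroid_um: tuple[float, float]
    area_um2: float
    mean_intensity: float


@dataclass
class ImageSimParams:
    """Parameters of a rendered two-channel cell image.

    ``cell_polygons`` are vertex lists in µm; ``golgi_objects`` are
    rendered as filled discs of the nearest achievable pixel area
    (the achieved, pixel-quantised area is what the ground truth
    records).  The marker channel is uniform per cell, emulating a
    diffusely expressed protein used for expression normalisation.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.2                     # µm/px
    cell_polygons: list = field(default_factory=list)   # each (N, 2) in µm, (x, y)
    golgi_objects: list = field(default_factory=list)   # GolgiObjectSpec
    marker_mean_intensity: float | list = 100.0  # AU per cell
    background: float = 0.0                     # AU
    noise_sd: float = 0.0                       # AU
    psf_sigma: float = 0.0                      # px
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        for obj in self.golgi_objects:
            _require(obj.area_um2 > 0, "golgi_objects", "object areas must be > 0")
        _finite_nonneg(self.noise_sd, "noise_sd")
        _finite_nonneg(self.psf_sigma, "psf_sigma")


@dataclass
class CellImage:
    """Output of :func:`render_cell_image`."""

    golgi: np.ndarray
    marker: np.ndarray
    cell_labels: LabelImage
    object_labels: LabelImage
    truth: pd.DataFrame   # object_id, cell_id, area_um2 (achieved), ...


def render_cell_image(params: ImageSimParams) -> CellImage:
    """Render Golgi + marker channels with per-object ground truth."""
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    px = params.pixel_size
    cell_labels = np.zeros((h, w), dtype=np.int64)
    for k, poly in enumerate(params.cell_polygons, start=1):
        poly = np.asarray(poly, dtype=float)
        rr, cc = draw_polygon(poly[:, 1] / px, poly[:, 0] / px, shape=(h, w))
        cell_labels[rr, cc] = k
    n_cells = len(params.cell_polygons)
    marker_levels = params.marker_mean_intensity
    if np.isscalar(marker_levels):
        marker_levels = [float(marker_levels)] * n_cells

    golgi = np.zeros((h, w))
    obj_labels = np.zeros((h, w), dtype=np.int64)
    truth_rows = []
    for oid, obj in enumerate(params.golgi_objects, start=1):
        cx, cy = obj.centroid_um
        r_px = math.sqrt((obj.area_um2 / px**2) / math.pi)
        rr, cc = draw_disk((cy / px, cx / px), r_px, shape=(h, w))
        if len(rr) == 0:
            raise ValueError(f"golgi object {oid} rasterises to zero pixels")
        cell_id = int(cell_labels[int(round(cy / px)), int(round(cx / px))])
        if cell_id == 0:
            raise ValueError(f"golgi object {oid} lies outside all cell polygons")
        golgi[rr, cc] += obj.mean_intensity
        obj_labels[rr, cc] = oid
        achieved = len(rr) * px**2
        truth_rows.append((oid, cell_id, obj.area_um2, achieved,
                           obj.mean_intensity, len(rr) * obj.mean_intensity,
                           cx, cy))
    if params.psf_sigma > 0:
        from scipy.ndimage import gaussian_filter
        golgi = gaussian_filter(golgi, params.psf_sigma)
    marker = np.zeros((h, w))
    for k in range(1, n_cells + 1):
        marker[cell_labels == k] = marker_levels[k - 1]
    golgi = golgi + params.background
    marker = marker + params.background
    if params.noise_sd > 0:
        golgi = golgi + rng.normal(0, params.noise_sd, size=golgi.shape)
        marker = marker + rng.normal(0, params.noise_sd, size=marker.shape)
    truth = pd.DataFrame(truth_rows, columns=[
        "object_id", "cell_id", "requested_area_um2", "area_um2",
        "mean_intensity", "integrated_intensity", "centroid_x_um",
        "centroid_y_um"])
    return CellImage(golgi=golgi, marker=marker,
                     cell_labels=LabelImage(cell_labels, px, channel="cell"),
                     object_labels=LabelImage(obj_labels, px, channel="golgi"),
                     truth=truth)


# ---------------------------------------------------------------------------
# binding tables


def simulate_binding_table(kd: float, bmax: float, concentrations,
                           noise_cv: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """One-site saturation binding data with multiplicative noise.

    signal = bmax * L / (kd + L) * (1 + eps),  eps ~ N(0, noise_cv).
    """
    _require(kd > 0 and np.isfinite(kd), "kd", "must be > 0")
    _require(bmax > 0 and np.isfinite(bmax), "bmax", "must be > 0")
    conc = np.asarray(list(concentrations), dtype=float)
    _require(conc.size > 0, "concentrations", "must be non-empty")
    _require(np.all(conc >= 0), "concentrations", "must be >= 0")
    _finite_nonneg(noise_cv, "noise_cv")
    rng = np.random.default_rng(seed)
    signal = bmax * conc / (kd + conc)
    if noise_cv > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_cv, size=conc.shape))
    signal = np.clip(signal, 0.0, None)
    return pd.DataFrame({"concentration_um": conc, "signal": signal})
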