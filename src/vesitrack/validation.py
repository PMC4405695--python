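"""Parameter-recovery and oracle-equivalence experiments.

Each function here runs one self-contained experiment: generate inputs
with known ground truth via :mod:`vesitrack.simulate`, push them
through the analysis path under test, and report recovered vs. true
values.  The experiments are shared by the acceptance test suite, the
``vesitrack accept`` subcommand, and ``scripts/acceptance.py``; sizes
are arguments so callers choose their own compute budget.

Seeds: every experiment takes one integer seed and derives independent
child streams from it with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import hashlib
import itertools
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import binding, golgi, motion, simulate, single_molecule
from .geometry import minimal_enclosing_circle
from .simulate import (GolgiObjectSpec, ImageSimParams, TrackSimParams,
                       render_cell_image, render_spot_stack,
                       simulate_binding_table, simulate_motor_field,
                       simulate_track)
from .tracks import Track, detect_spots, link_spots


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# minimal enclosing circle vs. brute force


def brute_force_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Smallest enclosing circle by enumeration of all pair/triple circles.

    Independent oracle for :func:`vesitrack.geometry.minimal_enclosing_circle`:
    every minimal circle is determined by two diametral points or three
    boundary points, so enumerating all candidates and keeping the
    smallest one that contains every point is exact (O(n^4), fine for
    small n).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n == 1:
        return pts[0, 0], pts[0, 1], 0.0
    centers = []
    radii = []
    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2.0
        centers.append(c)
        radii.append(np.linalg.norm(pts[i] - c))
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if d == 0.0:
            continue
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        centers.append(np.array([ux, uy]))
        radii.append(np.hypot(ax - ux, ay - uy))
    centers = np.array(centers)
    radii = np.array(radii)
    dist = cdist(centers, pts)
    valid = dist.max(axis=1) <= radii * (1 + 1e-12) + 1e-12
    idx = np.flatnonzero(valid)
    best = idx[np.argmin(radii[idx])]
    return float(centers[best, 0]), float(centers[best, 1]), float(radii[best])


def mec_bruteforce_agreement(n_sets: int = 1000, max_points: int = 25,
                             seed: int = 0, tol: float = 1e-8) -> dict:
    """Fraction of random point sets where Welzl and brute force agree."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sets):
        n = int(rng.integers(1, max_points + 1))
        pts = rng.uniform(0, 10, size=(n, 2))
        c = minimal_enclosing_circle(pts)
        bx, by, br = brute_force_circle(pts)
        if (abs(c.r - br) <= tol * (1 + br)
                and abs(c.cx - bx) <= tol * (1 + abs(bx))
                and abs(c.cy - by) <= tol * (1 + abs(by))):
            agree += 1
    return {"agreement_fraction": agree / n_sets, "n": n_sets}


# ---------------------------------------------------------------------------
# confined-track area recovery


def confinement_area_recovery(radii=(0.2, 0.5, 1.0), n_seeds: int = 100,
                              n_frames: int = 500, seed: int = 0, *,
                              diffusion: float = 0.05, frame_interval: float = 2.0,
                              noise_sd: float = 0.0) -> dict:
    """Median minimal-enclosing-circle area vs. the true disc area pi R^2."""
    seeds = _child_seeds(seed, len(radii) * n_seeds)
    out = {}
    k = 0
    for r in radii:
        areas = []
        for _ in range(n_seeds):
            track = simulate_track(TrackSimParams(
                mode="confined", diffusion_coefficient=diffusion,
                confinement_radius=r, frame_interval=frame_interval,
                n_frames=n_frames, localization_noise_sd=noise_sd,
                pause_rate=0.0, seed=seeds[k]))
            k += 1
            areas.append(motion.confinement_area(track))
        true_area = np.pi * r * r
        out[r] = {"median_area": float(np.median(areas)),
                  "true_area": float(true_area),
                  "ratio": float(np.median(areas) / true_area),
                  "n": n_seeds}
    return out


# ---------------------------------------------------------------------------
# reversal-rate recovery


def reversal_rate_recovery(rates=(0.02, 0.05, 0.1), n_seeds: int = 200,
                           n_frames: int = 500, seed: int = 0, *,
                           frame_interval: float = 0.2, speed: float = 0.5,
                           noise_sd: float = 0.02) -> dict:
    """Mean recovered principal-axis direction-change rate vs. truth.

    Sampling runs at 5 Hz so that two reversals inside one frame (which
    cancel and are invisible to any frame-based estimator) are rare
    relative to the recovery precision.
    """
    seeds = _child_seeds(seed, len(rates) * n_seeds)
    out = {}
    k = 0
    for rho in rates:
        recovered = []
        for _ in range(n_seeds):
            track = simulate_track(TrackSimParams(
                mode="directed", speed=speed, reversal_rate=rho,
                pause_rate=0.0, frame_interval=frame_interval,
                n_frames=n_frames, localization_noise_sd=noise_sd,
                seed=seeds[k]))
            k += 1
            res = motion.direction_changes(track)
            recovered.append(res.rate if res.rate is not None else 0.0)
        recovered = np.array(recovered)
        se = float(recovered.std(ddof=1) / np.sqrt(n_seeds))
        out[rho] = {"mean_recovered": float(recovered.mean()), "true_rate": rho,
                    "se": se,
                    "z": float((recovered.mean() - rho) / se) if se > 0 else float("inf"),
                    "n": n_seeds}
    return out


# ---------------------------------------------------------------------------
# motion classification accuracy


def classification_accuracy(n_per_class: int = 200, n_frames: int = 200,
                            seed: int = 0) -> dict:
    """Confusion of the MSD-exponent classifier on labelled tracks."""
    seeds = _child_seeds(seed, 2 * n_per_class)
    correct = {"confined": 0, "linear": 0}
    for i in range(n_per_class):
        t = simulate_track(TrackSimParams(
            mode="confined", confinement_radius=0.3, diffusion_coefficient=0.05,
            n_frames=n_frames, seed=seeds[i]))
        cls, _ = motion.classify_track(t)
        correct["confined"] += cls == "confined"
        t = simulate_track(TrackSimParams(
            mode="directed", speed=0.5, reversal_rate=0.05,
            n_frames=n_frames, seed=seeds[n_per_class + i]))
        cls, _ = motion.classify_track(t)
        correct["linear"] += cls == "linear"
    return {"confined_accuracy": correct["confined"] / n_per_class,
            "directed_accuracy": correct["linear"] / n_per_class,
            "n_per_class": n_per_class}


# ---------------------------------------------------------------------------
# moving-motor classifier boundary table


def _straight_track(net_x: float, frame_interval: float, tid: str) -> Track:
    return Track(track_id=tid, frames=np.array([0, 1]),
                 positions=np.array([[0.0, 0.0], [net_x, 0.0]]),
                 frame_interval=frame_interval)


def moving_classifier_boundary_table() -> pd.DataFrame:
    """Constructed tracks straddling the moving-motor thresholds.

    Two-point tracks keep speed, net distance, and duration exactly at
    or around the thresholds (0.12 µm/s, 0.2 µm, 0.9 s; all strict
    inequalities), plus a zigzag with high speed but low net
    displacement.  ``expected`` is the hand-applied rule.
    """
    zig = Track(track_id="zigzag", frames=np.arange(6),
                positions=np.array([[0, 0], [0.1, 0], [0, 0], [0.1, 0],
                                    [0, 0], [0.1, 0]], dtype=float),
                frame_interval=0.2)
    cases = [
        # (track, expected, why)
        (_straight_track(0.5, 1.0, "clear-mover"), True,
         "speed 0.5, net 0.5, duration 1.0: all pass"),
        (_straight_track(0.12, 1.0, "speed-at-threshold"), False,
         "speed exactly 0.12 fails strict >"),
        (_straight_track(0.2, 1.0, "distance-at-threshold"), False,
         "net displacement exactly 0.2 fails strict >"),
        (_straight_track(0.45, 0.9, "duration-at-threshold"), False,
         "duration exactly 0.9 fails strict >"),
        (_straight_track(0.3, 0.5, "too-short"), False,
         "duration 0.5 < 0.9"),
        (zig, False,
         "mean speed 0.5 but net displacement 0.1 < 0.2"),
        (_straight_track(0.21, 1.0, "just-above"), True,
         "speed 0.21, net 0.21, duration 1.0: all pass"),
        (_straight_track(0.25, 2.0, "slow-but-far"), True,
         "speed 0.125 > 0.12, net 0.25, duration 2.0"),
        (_straight_track(0.23, 2.0, "below-speed"), False,
         "speed 0.115 < 0.12 despite net 0.23"),
    ]
    rows = []
    for track, expected, why in cases:
        observed = single_molecule.classify_moving(track)
        rows.append({"track_id": track.track_id, "expected": expected,
                     "observed": observed, "why": why})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motor-density recovery through the image pipeline


def motor_density_recovery(densities=(0.1, 0.3), n_seeds: int = 100,
                           seed: int = 0, *, noise_sd: float = 0.0,
                           mt_total_length: float = 60.0, n_frames: int = 10,
                           frame_interval: float = 0.041) -> dict:
    """simulate field -> render -> detect -> motors/µm vs. true density.

    Spots are placed with a 0.5 µm hard-core exclusion so that every
    emitter is optically resolvable: the experiment grades detection
    and counting fidelity, not the diffraction limit (two emitters
    inside one PSF merge into a single peak for any detector).
    """
    seeds = _child_seeds(seed, len(densities) * n_seeds)
    out = {}
    k = 0
    for d in densities:
        recovered = []
        for _ in range(n_seeds):
            fld = simulate_motor_field(
                mt_total_length=mt_total_length, density=d, moving_fraction=0.0,
                speed=0.0, lifespan_mean=50.0, n_frames=n_frames,
                frame_interval=frame_interval, seed=seeds[k],
                min_spot_separation=0.5)
            stack = render_spot_stack(fld.spots, fld.mask.labels.shape,
                                      fld.mask.pixel_size, n_frames=n_frames,
                                      psf_sigma=1.2, amplitude=200.0,
                                      background=10.0, noise_sd=noise_sd,
                                      seed=seeds[k] + 1)
            spots = detect_spots(stack, intensity_threshold=60.0,
                                 min_separation=3.0,
                                 pixel_size=fld.mask.pixel_size)
            _, total_len = single_molecule.microtubule_length(fld.mask)
            recovered.append(single_molecule.motor_density(
                spots, fld.mask, total_len))
            k += 1
        recovered = np.array(recovered)
        se = float(recovered.std(ddof=1) / np.sqrt(n_seeds))
        out[d] = {"mean_recovered": float(recovered.mean()), "true_density": d,
                  "se": se, "relative_error": float(recovered.mean() / d - 1),
                  "n": n_seeds}
    return out


# ---------------------------------------------------------------------------
# Golgi fragmentation score


def _square_cell(size_um: float, margin_um: float = 1.0) -> np.ndarray:
    lo, hi = margin_um, margin_um + size_um
    return np.array([[lo, lo], [hi, lo], [hi, hi], [lo, lo + size_um]])


def golgi_exact_score_check(area_thresholds=(4.11, 2.74)) -> dict:
    """Noise-free render -> segment -> score vs. hand-computed truth.

    One cell holds discs of requested areas 5, 3.4, and 1 µm² with
    equal mean intensity; the expected large-object fraction at each
    threshold follows by hand from the achieved (pixel-quantised) areas
    and integrated intensities in the render's ground truth.  The
    3.4 µm² object discriminates the two presets: large at 2.74 µm²,
    small at 4.11 µm².
    """
    cell = np.array([[1, 1], [39, 1], [39, 39], [1, 39]], dtype=float)
    params = ImageSimParams(
        image_shape=(220, 220), pixel_size=0.2,
        cell_polygons=[cell],
        golgi_objects=[GolgiObjectSpec((12.0, 12.0), 5.0, 100.0),
                       GolgiObjectSpec((28.0, 12.0), 3.4, 100.0),
                       GolgiObjectSpec((28.0, 28.0), 1.0, 100.0)],
        marker_mean_intensity=100.0, background=0.0, noise_sd=0.0,
        psf_sigma=0.0, seed=0)
    img = render_cell_image(params)
    labels = golgi.segment_channel(img.golgi, params.pixel_size,
                                   method="fixed", threshold=50.0)
    out = {}
    for thr in area_thresholds:
        scores, _ = golgi.golgi_fragmentation_score(
            img.golgi, labels, img.cell_labels, img.marker, thr)
        truth = img.truth
        large = truth[truth["area_um2"] > thr]["integrated_intensity"].sum()
        total = truth["integrated_intensity"].sum()
        out[thr] = {"observed": scores[0].large_fraction,
                    "expected": float(large / total),
                    "match": scores[0].large_fraction == float(large / total)}
    return out


def golgi_population_separation(n_cells: int = 30, seed: int = 0,
                                area_threshold: float = 4.11) -> dict:
    """Intact vs. fragmented synthetic cells must separate by Welch t.

    Intact cells carry one 20 µm² Golgi object; fragmented cells carry
    ten 1 µm² objects.  Marker expression varies cell to cell and mild
    Gaussian noise is added, so the per-cell normalised scores have
    realistic spread.
    """
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed, 2 * n_cells)

    def _score_cell(objects, s):
        marker_level = float(rng.normal(100.0, 10.0))
        params = ImageSimParams(
            image_shape=(128, 128), pixel_size=0.2,
            cell_polygons=[_square_cell(22.0)],
            golgi_objects=objects, marker_mean_intensity=marker_level,
            background=5.0, noise_sd=2.0, psf_sigma=0.0, seed=s)
        img = render_cell_image(params)
        labels = golgi.segment_channel(img.golgi, params.pixel_size,
                                       method="fixed", threshold=40.0,
                                       min_object_area=0.2)
        scores, _ = golgi.golgi_fragmentation_score(
            img.golgi, labels, img.cell_labels, img.marker, area_threshold)
        return scores[0]

    intact, fragmented = [], []
    grid = [(5.0 + 4.0 * (i % 4), 5.0 + 4.0 * (i // 4)) for i in range(10)]
    for i in range(n_cells):
        intact.append(_score_cell(
            [GolgiObjectSpec((12.0, 12.0), 20.0, 100.0)], seeds[i]))
        fragmented.append(_score_cell(
            [GolgiObjectSpec(c, 1.0, 100.0) for c in grid], seeds[n_cells + i]))
    cmp = golgi.compare_conditions(fragmented, intact)
    return {"pvalue": cmp.pvalue, "mean_fragmented": cmp.mean_a,
            "mean_intact": cmp.mean_b, "n_per_group": n_cells,
            "fragmented_lower": cmp.mean_a < cmp.mean_b}


# ---------------------------------------------------------------------------
# Pearson colocalization


def pearson_null_check(n_seeds: int = 100, n_pixels: int = 10000,
                       seed: int = 0) -> dict:
    """|r| on independent-noise channels should stay below 0.05."""
    from .images import LabelImage
    seeds = _child_seeds(seed, n_seeds)
    side = int(np.sqrt(n_pixels))
    mask = LabelImage(np.ones((side, side), dtype=np.int64), 1.0)
    small = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        a = rng.normal(size=(side, side))
        b = rng.normal(size=(side, side))
        r = golgi.pearson_colocalization(a, b, mask)["pooled_r"]
        small += abs(r) < 0.05
    return {"fraction_below_0.05": small / n_seeds, "n": n_seeds,
            "n_pixels": side * side}


# ---------------------------------------------------------------------------
# binding-curve recovery


def kd_recovery(seed: int = 0, n_seeds: int = 100, kd: float = 1.0,
                bmax: float = 1.0, noise_cv: float = 0.05) -> dict:
    """Noise-free exactness, noisy recovery, CI coverage, and Kd shift."""
    # exact recovery on noise-free hyperbolic data
    conc0 = [0.25, 0.5, 1, 2, 4, 8]
    table0 = simulate_binding_table(kd, bmax, conc0, noise_cv=0.0, seed=0)
    fit0 = binding.fit_one_site(table0["concentration_um"], table0["signal"])
    exact_rel_err = abs(fit0.kd - kd) / kd

    conc = [0.1, 0.3, 1, 3, 10, 30] * 2   # duplicates for honest dof
    seeds = _child_seeds(seed, 2 * n_seeds)
    kds = []
    covered = 0
    for s in seeds[:n_seeds]:
        table = simulate_binding_table(kd, bmax, conc, noise_cv=noise_cv, seed=s)
        fit = binding.fit_one_site(table["concentration_um"], table["signal"])
        kds.append(fit.kd)
        covered += abs(fit.kd - kd) <= 2 * fit.kd_se
    kds = np.array(kds)

    # 10-fold Kd shift between paired co-sedimentation curves
    mt_conc = [0.05, 0.1, 0.25, 0.5, 1, 2.5, 5, 10, 20]
    ratios = []
    for s in seeds[n_seeds:]:
        ta = simulate_binding_table(0.46, 0.9, mt_conc, noise_cv=noise_cv, seed=s)
        tb = simulate_binding_table(4.6, 0.9, mt_conc, noise_cv=noise_cv, seed=s + 7)
        fa = binding.fit_cosedimentation(ta["concentration_um"],
                                         np.clip(ta["signal"], 0, 1))
        fb = binding.fit_cosedimentation(tb["concentration_um"],
                                         np.clip(tb["signal"], 0, 1))
        ratio, _, ok = binding.kd_shift_ratio(fa, fb)
        if ok:
            ratios.append(ratio)
    return {"exact_relative_error": float(exact_rel_err),
            "noisy_mean_kd": float(kds.mean()), "true_kd": kd,
            "noisy_relative_error": float(kds.mean() / kd - 1),
            "coverage_2se": covered / n_seeds,
            "shift_ratio_mean": float(np.mean(ratios)), "true_shift": 10.0,
            "n": n_seeds}


# ---------------------------------------------------------------------------
# whole-pipeline determinism


def _hash_dir_csvs(outdir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(outdir.glob("*.csv")):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def determinism_check(workdir: str | Path, seed: int = 0) -> dict:
    """Run the simulate->motion pipeline twice; CSVs must be byte-identical."""
    from .config import RunConfig
    from .pipeline import run_pipeline
    workdir = Path(workdir)
    hashes = []
    for rep in ("a", "b"):
        out = workdir / f"run_{rep}"
        cfg = RunConfig({"seed": seed, "simulate": {"n_tracks": 20, "n_frames": 50}})
        run_pipeline(cfg, out)
        hashes.append(_hash_dir_csvs(out))
    return {"identical": hashes[0] == hashes[1],
            "n_files": len(hashes[0]), "hashes": hashes[0]}
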