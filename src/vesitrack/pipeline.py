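"""End-to-end orchestration: simulate -> analyse -> report, with manifest.

A pipeline run executes its configured stages in order, writes CSV
outputs, and records a machine-readable manifest (parameters, seeds,
package version, per-stage input/output counts, runtime) sufficient to
regenerate every output.  Identical config + seed gives byte-identical
CSV outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import motion, validation
from .config import RunConfig
from .simulate import TrackSimParams, simulate_track
from .tracks import read_tracks, write_tracks


def _simulate_stage(cfg: RunConfig, outdir: Path) -> dict:
    sim = cfg.section("simulate")
    n_tracks = sim.pop("n_tracks")
    base_seed = cfg["seed"]
    seeds = validation._child_seeds(base_seed, n_tracks)
    tracks = []
    for i in range(n_tracks):
        params = TrackSimParams(**{**sim, "seed": seeds[i]})
        t = simulate_track(params)
        t.track_id = f"sim{i:05d}"
        tracks.append(t)
    write_tracks(tracks, outdir / "tracks.csv")
    return {"n_tracks": n_tracks, "output": "tracks.csv"}


def _motion_stage(cfg: RunConfig, outdir: Path) -> dict:
    mo = cfg.section("motion")
    tracks, report = read_tracks(outdir / "tracks.csv",
                                 frame_interval=mo["frame_interval"])
    df = motion.analyze_tracks(
        tracks, alpha_confined=mo["alpha_confined"],
        alpha_linear=mo["alpha_linear"], min_points=mo["min_points"],
        pause_speed_threshold=mo["pause_speed_threshold"])
    df.to_csv(outdir / "motion_reports.csv", index=False, float_format="%.8g")
    summary = (df.groupby("track_class")
               .agg(n=("track_id", "size"),
                    mean_speed=("mean_speed", "mean"),
                    mean_confinement_area=("confinement_area", "mean"),
                    mean_pause_rate=("pause_rate", "mean"),
                    mean_direction_changes=("direction_changes_per_s", "mean"))
               .reset_index())
    summary.to_csv(outdir / "motion_summary.csv", index=False,
                   float_format="%.8g")
    return {"n_tracks_in": report.n_read, "n_tracks_kept": report.n_kept,
            "n_rejected": len(report.rejected),
            "outputs": ["motion_reports.csv", "motion_summary.csv"]}


_STAGES = {
    "simulate": _simulate_stage,
    "motion": _motion_stage,
}


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in order; returns the manifest.

    A stage failure aborts the run with the stage name; outputs of
    completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": _version, "config": cfg.data, "stages": {}}
    t_start = time.perf_counter()
    for stage in cfg["stages"]:
        if stage not in _STAGES:
            raise ValueError(f"unknown pipeline stage '{stage}'")
        t0 = time.perf_counter()
        try:
            counts = _STAGES[stage](cfg, outdir)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        counts["runtime_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = counts
    manifest["total_runtime_s"] = round(time.perf_counter() - t_start, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def acceptance_suite(seed: int = 0, scale: float = 0.2,
                     workdir: str | Path | None = None) -> pd.DataFrame:
    """Run every parameter-recovery / oracle-equivalence check.

    Returns a table of metric, expected, observed, tolerance, verdict.
    ``scale`` shrinks the replicate counts (1.0 = the full published
    check sizes) so the suite can double as a quick smoke test.
    """
    import tempfile

    def n(full: int, lo: int = 5) -> int:
        return max(lo, int(round(full * scale)))

    rows = []

    def add(metric, expected, observed, tolerance, ok, n_used):
        rows.append({"metric": metric, "expected": expected,
                     "observed": observed, "tolerance": tolerance,
                     "verdict": "pass" if ok else "FAIL", "n": n_used})

    t0 = time.perf_counter()
    res = validation.mec_bruteforce_agreement(n_sets=n(1000, 50), seed=seed)
    add("minimal_circle_vs_bruteforce", 1.0, res["agreement_fraction"],
        "exact", res["agreement_fraction"] == 1.0, res["n"])

    res = validation.confinement_area_recovery(
        n_seeds=n(100, 10), seed=seed + 1)
    for r, d in res.items():
        add(f"confinement_area_ratio_R{r}", 1.0, round(d["ratio"], 4),
            "within 15%", abs(d["ratio"] - 1) <= 0.15, d["n"])

    res = validation.reversal_rate_recovery(n_seeds=n(200, 20), seed=seed + 2)
    for rho, d in res.items():
        add(f"reversal_rate_{rho}", rho, round(d["mean_recovered"], 4),
            "3 SE", abs(d["z"]) <= 3.0, d["n"])

    res = validation.classification_accuracy(n_per_class=n(200, 20),
                                             seed=seed + 3)
    add("classification_confined", ">=0.9", res["confined_accuracy"],
        ">= 0.9", res["confined_accuracy"] >= 0.9, res["n_per_class"])
    add("classification_directed", ">=0.9", res["directed_accuracy"],
        ">= 0.9", res["directed_accuracy"] >= 0.9, res["n_per_class"])

    table = validation.moving_classifier_boundary_table()
    ok = bool((table["expected"] == table["observed"]).all())
    add("moving_classifier_boundaries", "all match", ok, "exact", ok, len(table))

    res = validation.motor_density_recovery(n_seeds=n(100, 10), seed=seed + 4)
    for d, r in res.items():
        add(f"motor_density_{d}", d, round(r["mean_recovered"], 4),
            "within 10%", abs(r["relative_error"]) <= 0.10, r["n"])

    res = validation.golgi_exact_score_check()
    for thr, r in res.items():
        add(f"golgi_large_fraction_thr{thr}", round(r["expected"], 6),
            round(r["observed"], 6), "exact", r["match"], 1)
    res = validation.golgi_population_separation(n_cells=n(30, 10),
                                                 seed=seed + 5)
    add("golgi_population_pvalue", "<0.001", f"{res['pvalue']:.2e}",
        "p < 0.001", res["pvalue"] < 0.001 and res["fragmented_lower"],
        res["n_per_group"])

    res = validation.pearson_null_check(n_seeds=n(100, 20), seed=seed + 6)
    add("pearson_null_fraction", ">=0.95", res["fraction_below_0.05"],
        ">= 0.95", res["fraction_below_0.05"] >= 0.95, res["n"])

    res = validation.kd_recovery(seed=seed + 7, n_seeds=n(100, 20))
    add("kd_exact_relative_error", 0.0, f"{res['exact_relative_error']:.2e}",
        "<= 1e-6", res["exact_relative_error"] <= 1e-6, 6)
    add("kd_noisy_mean", res["true_kd"], round(res["noisy_mean_kd"], 4),
        "within 10%", abs(res["noisy_relative_error"]) <= 0.10, res["n"])
    add("kd_ci_coverage", ">=0.9", res["coverage_2se"], ">= 0.9",
        res["coverage_2se"] >= 0.9, res["n"])
    add("kd_shift_ratio", 10.0, round(res["shift_ratio_mean"], 3),
        "within 15%", abs(res["shift_ratio_mean"] / 10.0 - 1) <= 0.15, res["n"])

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            res = validation.determinism_check(tmp, seed=seed)
    else:
        res = validation.determinism_check(workdir, seed=seed)
    add("pipeline_determinism", True, res["identical"], "byte-identical",
        res["identical"], res["n_files"])

    df = pd.DataFrame(rows)
    df.attrs["runtime_s"] = round(time.perf_counter() - t0, 2)
    df.attrs["seed"] = seed
    return df
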