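"""Run-level orchestration: batch fitting and the end-to-end demo.

These functions are the library face of the command-line interface; each
takes plain tables/paths, runs the relevant modules, and writes tabular
artifacts plus a JSON run report into an output directory.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemo_field import KSParameters, make_concentration
from .config import RunConfig, echo_config
from .geometry import DeviceGeometry
from .inference import (
    UnidentifiableParameterError,
    effective_drift_um_per_h,
    estimate_D,
    estimate_chi,
    migrating_percentage,
    pool_D,
)
from .migration_sim import (
    MigrationSnapshot,
    frame_to_snapshots,
    simulate_migration,
    snapshots_to_frame,
    write_snapshots_csv,
)
from .quantify import quantify_image, recruitment_timecourse
from .synthetic_images import generate_vessel_image, write_bundle

log = logging.getLogger("chiptaxis")

ARMS = ("control", "uniform", "gradient")


def setup_run_logging(out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("chiptaxis")
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        root.addHandler(logging.StreamHandler())
    root.setLevel(logging.INFO)
    log.info("chiptaxis %s on python %s", __version__, platform.python_version())


def _select_fit_snapshots(
    snapshots: list[MigrationSnapshot], fit_time_h: float | None
) -> list[MigrationSnapshot]:
    """Keep one timepoint per ROI: the requested one, else the latest common."""
    if not snapshots:
        return snapshots
    if fit_time_h is None:
        by_roi: dict[tuple, set] = {}
        for s in snapshots:
            by_roi.setdefault((s.device_id, s.roi_id), set()).add(s.time_h)
        common = set.intersection(*by_roi.values())
        fit_time_h = max(common) if common else max(s.time_h for s in snapshots)
    return [s for s in snapshots if s.time_h == fit_time_h]


def fit_conditions(
    positions: pd.DataFrame,
    manifest: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Fit D (controls, pooled) and chi (gradient arms) from a position table.

    ``positions`` is the long-format snapshot table; ``manifest`` maps
    (device_id, roi_id) to an arm in {control, uniform, gradient}. Writes
    ``estimates.csv`` and ``report.json`` to ``out_dir`` and returns the
    per-ROI estimates table. Per-ROI failures are flagged rows, not fatal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry
    model = config.model

    required = {"device_id", "roi_id", "arm"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad_arms = set(manifest["arm"]) - set(ARMS)
    if bad_arms:
        raise ValueError(f"unknown arms in manifest: {sorted(bad_arms)}")

    arm_of = {
        (str(r.device_id), str(r.roi_id)): r.arm for r in manifest.itertuples()
    }
    snapshots = _select_fit_snapshots(
        frame_to_snapshots(positions), model.fit_time_h
    )
    by_arm: dict[str, list[MigrationSnapshot]] = {arm: [] for arm in ARMS}
    for snap in snapshots:
        key = (snap.device_id, snap.roi_id)
        if key not in arm_of:
            raise ValueError(f"ROI {key} present in positions but not in manifest")
        by_arm[arm_of[key]].append(snap)

    rows = []
    control_fits = []
    for snap in by_arm["control"]:
        row = _base_row(snap, "control", geometry)
        try:
            fit = estimate_D(
                [snap], geometry, estimator=model.estimator,
                n_bins=model.n_bins, min_cells=model.min_cells,
            )
            control_fits.append(fit)
            row.update(D_hat=fit.estimate, objective=fit.objective,
                       converged=fit.converged, flags=";".join(fit.flags))
        except Exception as exc:  # noqa: BLE001 - batch isolation
            row["flags"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    D_pooled = pool_D([f for f in control_fits if f.converged]) if control_fits else None
    if D_pooled is not None:
        log.info("pooled control D = %.1f um^2/h from %d ROIs", D_pooled, len(control_fits))

    for snap in by_arm["uniform"]:
        row = _base_row(snap, "uniform", geometry)
        try:
            fit = estimate_D(
                [snap], geometry, estimator=model.estimator,
                n_bins=model.n_bins, min_cells=model.min_cells,
            )
            row.update(D_hat=fit.estimate, objective=fit.objective,
                       converged=fit.converged,
                       flags="chi unidentifiable (no gradient)")
        except Exception as exc:  # noqa: BLE001
            row["flags"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    conc = make_concentration(geometry, "linear_gradient")
    for snap in by_arm["gradient"]:
        row = _base_row(snap, "gradient", geometry)
        if D_pooled is None:
            row["flags"] = "no control arm: pooled D unavailable"
            rows.append(row)
            continue
        try:
            fit = estimate_chi(
                [snap], D_pooled, conc, geometry,
                n_bins=model.n_bins, min_cells=model.min_cells,
                chi_max=model.chi_max, bootstrap_reps=model.bootstrap_reps,
                seed=config.seed,
            )
            row.update(
                D_hat=D_pooled, chi_hat=fit.estimate,
                effective_drift_um_per_h=effective_drift_um_per_h(
                    fit.estimate, conc, geometry
                ),
                objective=fit.objective, converged=fit.converged,
                stderr=fit.stderr, flags="",
            )
        except UnidentifiableParameterError as exc:
            row["flags"] = str(exc)
        except Exception as exc:  # noqa: BLE001
            row["flags"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    estimates = pd.DataFrame(rows)
    estimates.to_csv(out_dir / "estimates.csv", index=False)
    report = {
        "version": __version__,
        "seed": config.seed,
        "n_rois": len(rows),
        "D_pooled_um2_per_h": D_pooled,
        "arms": {arm: len(by_arm[arm]) for arm in ARMS},
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    echo_config(config, out_dir)
    return estimates


def _base_row(snap: MigrationSnapshot, arm: str, geometry: DeviceGeometry) -> dict:
    return {
        "device_id": snap.device_id,
        "roi_id": snap.roi_id,
        "arm": arm,
        "condition_label": snap.condition_label,
        "time_h": snap.time_h,
        "n_cells": snap.n_cells,
        "migrating_pct": migrating_percentage(snap, geometry) if snap.n_cells else np.nan,
        "D_hat": np.nan,
        "chi_hat": np.nan,
        "effective_drift_um_per_h": np.nan,
        "objective": np.nan,
        "converged": False,
        "stderr": np.nan,
        "flags": "",
    }


def run_demo(config: RunConfig, out_dir: str | Path) -> dict:
    """Seeded end-to-end workflow on purely synthetic data.

    Generates a vascular-well image, quantifies it, simulates the three
    migration-assay arms, fits (D, chi), and writes every table. The whole
    run is a deterministic function of the configuration seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    seed = config.seed

    image_geometry = DeviceGeometry(
        roi_width_um=3000.0,
        roi_height_um=3000.0,
        well_diameter_um=config.geometry.well_diameter_um,
        vessel_diameter_um=config.geometry.vessel_diameter_um,
        pixel_size_um=config.geometry.pixel_size_um,
    )
    bundle = generate_vessel_image(
        image_geometry,
        n_luminal=sim.n_luminal,
        n_extravasated=sim.n_extravasated,
        n_recruited=sim.n_recruited,
        snr=sim.snr,
        seed=seed,
    )
    write_bundle(bundle, out_dir / "synthetic")
    counts_table = recruitment_timecourse(
        [("demo_device", 1, bundle.image)], bundle.pixel_size_um, config.image
    )
    counts_table.to_csv(out_dir / "counts.csv", index=False)

    geometry = config.geometry
    arm_params = {
        "control": (KSParameters(D_um2_per_h=sim.D_um2_per_h), "zero"),
        "uniform": (KSParameters(D_um2_per_h=sim.D_um2_per_h), "uniform"),
        "gradient": (
            KSParameters(D_um2_per_h=sim.D_um2_per_h, chi_um2_per_h=sim.chi_um2_per_h),
            "linear_gradient",
        ),
    }
    all_snaps = []
    manifest_rows = []
    for i, (arm, (params, kind)) in enumerate(arm_params.items()):
        conc = make_concentration(geometry, kind)
        snaps = simulate_migration(
            params, conc, geometry,
            n_cells=sim.n_cells, times_h=list(sim.times_h), dt_h=sim.dt_h,
            seed=seed + 101 * (i + 1),
            condition_label=arm, device_id="demo_device", roi_id=f"roi_{arm}",
        )
        all_snaps.extend(snaps)
        manifest_rows.append(
            {"device_id": "demo_device", "roi_id": f"roi_{arm}", "arm": arm}
        )
    positions = snapshots_to_frame(all_snaps)
    positions.to_csv(out_dir / "positions.csv", index=False)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)

    estimates = fit_conditions(positions, manifest, config, out_dir)
    summary = {
        "counts": counts_table.drop(columns=["flags"]).to_dict("records"),
        "estimates": estimates[
            ["roi_id", "arm", "migrating_pct", "D_hat", "chi_hat"]
        ].to_dict("records"),
    }
    (out_dir / "demo_summary.json").write_text(
        json.dumps(summary, indent=2, default=float)
    )
    return summary
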