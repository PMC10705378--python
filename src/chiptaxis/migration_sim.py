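"""Biased random-walk simulation of monocyte migration in the gel channel.

Each cell performs an overdamped drift-diffusion walk along the channel
axis: Euler-Maruyama steps with local drift ``chi * dc/dx`` and diffusion
``D``, reflected at the channel walls (x = 0 and x = L). This is the
microscopic counterpart of the Keller-Segel continuum model solved in
:mod:`chiptaxis.ks_model`, and the source of synthetic endpoint position
data with known ground-truth parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemo_field import ConcentrationField, KSParameters
from .geometry import DeviceGeometry

DEFAULT_DT_H = 0.01


@dataclass(frozen=True)
class MigrationSnapshot:
    """Cell x-positions in one ROI at a fixed time after seeding.

    The origin x = 0 is the monocyte-entry (endothelial) interface; the
    axis points toward the opposite media channel.
    """

    positions_um: np.ndarray
    time_h: float
    condition_label: str = ""
    roi_id: str = ""
    device_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        object.__setattr__(self, "positions_um", pos)
        if pos.ndim != 1:
            raise ValueError("positions_um must be a 1D array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions_um must be finite")
        if not (self.time_h > 0):
            raise ValueError(f"time_h must be > 0, got {self.time_h!r}")

    @property
    def n_cells(self) -> int:
        return int(self.positions_um.size)

    def validate_in_channel(self, geometry: DeviceGeometry) -> None:
        L = geometry.gel_channel_length_um
        if self.n_cells and (
            self.positions_um.min() < 0 or self.positions_um.max() > L
        ):
            raise ValueError(f"positions must lie in [0, {L}]")


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    # Fold positions back into [0, L]; a single step rarely overshoots by
    # more than one channel length, but the loop is exact regardless.
    out = x.copy()
    for _ in range(100):
        bad_low = out < 0
        bad_high = out > L
        if not (bad_low.any() or bad_high.any()):
            return out
        out[bad_low] = -out[bad_low]
        out[bad_high] = 2 * L - out[bad_high]
    raise RuntimeError("reflection did not converge; step size too large")


def simulate_migration(
    params: KSParameters,
    conc: ConcentrationField,
    geometry: DeviceGeometry,
    n_cells: int,
    times_h: list[float],
    dt_h: float = DEFAULT_DT_H,
    seed: int = 0,
    condition_label: str = "",
    device_id: str = "sim",
    roi_id: str = "roi0",
) -> list[MigrationSnapshot]:
    """Simulate ``n_cells`` walkers and record one snapshot per requested time.

    All cells start at x = 0 (the entry interface) at t = 0. Reflecting
    walls keep every position inside [0, L]. Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells!r}")
    if not times_h:
        raise ValueError("times_h must contain at least one time")
    times = sorted(float(t) for t in times_h)
    if times[0] <= 0:
        raise ValueError("snapshot times must be > 0")
    if not (dt_h > 0) or not math.isfinite(dt_h):
        raise ValueError(f"dt_h must be positive and finite, got {dt_h!r}")

    L = geometry.gel_channel_length_um
    step_scale = math.sqrt(2.0 * params.D_um2_per_h * dt_h)
    if step_scale >= L / 20:
        raise ValueError(
            f"dt_h={dt_h} too coarse: per-step displacement scale "
            f"sqrt(2 D dt) = {step_scale:.1f} um must stay below L/20 = {L / 20:.1f} um"
        )

    rng = np.random.default_rng(seed)
    x = np.zeros(n_cells, dtype=float)
    sigma = step_scale
    chi = params.chi_um2_per_h
    flat = not conc.has_gradient

    snapshots: list[MigrationSnapshot] = []
    t = 0.0
    for t_target in times:
        n_steps = int(round((t_target - t) / dt_h))
        for _ in range(n_steps):
            if flat:
                drift = 0.0
            else:
                drift = chi * conc.gradient_at(x)
            x = x + drift * dt_h
            if sigma > 0:
                x = x + sigma * rng.standard_normal(n_cells)
            x = _reflect(x, L)
        t = t_target
        snapshots.append(
            MigrationSnapshot(
                positions_um=x.copy(),
                time_h=t_target,
                condition_label=condition_label,
                roi_id=roi_id,
                device_id=device_id,
            )
        )
    return snapshots


def snapshots_to_frame(snapshots: list[MigrationSnapshot]) -> pd.DataFrame:
    """Long-format table of positions, one row per cell."""
    rows = []
    for snap in snapshots:
        rows.append(
            pd.DataFrame(
                {
                    "device_id": snap.device_id,
                    "roi_id": snap.roi_id,
                    "condition_label": snap.condition_label,
                    "time_h": snap.time_h,
                    "position_um": snap.positions_um,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["device_id", "roi_id", "condition_label", "time_h", "position_um"]
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_snapshots(frame: pd.DataFrame) -> list[MigrationSnapshot]:
    """Group a long-format position table back into snapshots."""
    required = {"device_id", "roi_id", "condition_label", "time_h", "position_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"position table missing columns: {sorted(missing)}")
    snapshots = []
    keys = ["device_id", "roi_id", "condition_label", "time_h"]
    for (device_id, roi_id, label, time_h), group in frame.groupby(keys, sort=True):
        snapshots.append(
            MigrationSnapshot(
                positions_um=group["position_um"].to_numpy(dtype=float),
                time_h=float(time_h),
                condition_label=str(label),
                roi_id=str(roi_id),
                device_id=str(device_id),
            )
        )
    return snapshots


def write_snapshots_csv(snapshots: list[MigrationSnapshot], path) -> None:
    snapshots_to_frame(snapshots).to_csv(path, index=False)


def read_snapshots_csv(path) -> list[MigrationSnapshot]:
    return frame_to_snapshots(pd.read_csv(path))
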