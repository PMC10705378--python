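"""Synthetic two-channel microscopy of a vascular bed with labelled monocytes.

Emulates a max-projected confocal field of a self-assembled microvascular
network surrounding a central spheroid well, plus point-like fluorescent
monocytes whose compartment (luminal / extravasated / recruited) is known
by construction. The generator makes the quantification pipeline testable
end-to-end without any real microscopy.

Vessel texture: a band-limited Gaussian random field is thresholded at its
median; the level-set boundaries (closed ribbons around ECM pockets) are
dilated to the target vessel width. This is procedural, seeded, and
statistically vessel-like: ~40 um ribbons enclosing gel pockets on a
~100 um scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import disk, medial_axis

from .geometry import DeviceGeometry

#: Full width at half maximum of one rendered cell, in micrometres.
SPOT_FWHM_UM = 12.0
#: Correlation length of the vessel-generating random field, in micrometres.
TEXTURE_SCALE_UM = 40.0

COMPARTMENTS = ("luminal", "extravasated", "recruited")


class PlacementError(RuntimeError):
    """Raised when requested cell counts cannot be placed with the
    minimum spot separation; names the limiting compartment."""

    def __init__(self, compartment: str, placed: int, requested: int):
        self.compartment = compartment
        super().__init__(
            f"could not place {requested} '{compartment}' cells with the minimum "
            f"spot separation (placed {placed}); reduce the count or the separation"
        )


@dataclass(frozen=True)
class SyntheticImageBundle:
    """A generated two-channel image with per-cell ground truth.

    ``image`` is channel-major (vasculature, monocytes). ``truth_cells``
    rows are (x_px, y_px, compartment) with x = column, y = row, 0-based.
    """

    image: np.ndarray
    pixel_size_um: float
    truth_vessel_mask: np.ndarray
    truth_well_mask: np.ndarray
    truth_cells: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[0] != 2:
            raise ValueError("image must be channel-major with 2 channels")
        if self.truth_vessel_mask.shape != self.image.shape[1:]:
            raise ValueError("truth_vessel_mask shape mismatch")
        if self.truth_well_mask.shape != self.image.shape[1:]:
            raise ValueError("truth_well_mask shape mismatch")
        if np.any(self.truth_vessel_mask & self.truth_well_mask):
            raise ValueError("vessel and well truth masks must be disjoint")
        for x, y, label in self.truth_cells:
            if label not in COMPARTMENTS:
                raise ValueError(f"unknown compartment label {label!r}")
            r, c = int(round(y)), int(round(x))
            in_well = bool(self.truth_well_mask[r, c])
            in_vessel = bool(self.truth_vessel_mask[r, c])
            if label == "recruited" and not in_well:
                raise ValueError("recruited truth cell outside the well mask")
            if label == "luminal" and not in_vessel:
                raise ValueError("luminal truth cell outside the vessel mask")
            if label == "extravasated" and (in_well or in_vessel):
                raise ValueError("extravasated truth cell inside a mask")

    @property
    def vasculature(self) -> np.ndarray:
        return self.image[0]

    @property
    def monocytes(self) -> np.ndarray:
        return self.image[1]

    def truth_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in COMPARTMENTS}
        for _, _, label in self.truth_cells:
            counts[label] += 1
        return counts


def _vessel_texture(
    shape: tuple[int, int], geometry: DeviceGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Binary ribbon network at the target vessel width."""
    px = geometry.pixel_size_um
    sigma_px = TEXTURE_SCALE_UM / px
    # Median level-set contours of two independent smooth fields: loops of
    # one field cross loops of the other, so the union percolates into a
    # single anastomosed network instead of disjoint rings.
    contours = np.zeros(shape, dtype=bool)
    for _ in range(2):
        field = ndi.gaussian_filter(rng.standard_normal(shape), sigma_px)
        blobs = field > np.median(field)
        contours |= blobs ^ ndi.binary_erosion(blobs)
    # One less than the nominal half-width: overlaps where the two loop
    # families run together push the realized median back to target.
    radius_px = max(1, int(round(geometry.vessel_diameter_um / (2 * px))) - 1)
    vessels = ndi.binary_dilation(contours, structure=disk(radius_px))
    return vessels


def _well_disk(shape: tuple[int, int], geometry: DeviceGeometry) -> np.ndarray:
    px = geometry.pixel_size_um
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius_px = geometry.well_diameter_um / (2 * px)
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius_px**2


def _place_spots(
    allowed: np.ndarray,
    count: int,
    min_sep_px: float,
    taken: list[tuple[float, float]],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Dart-throwing placement of ``count`` points inside ``allowed``
    keeping >= min_sep_px from every point in ``taken`` and each other.
    Returns (row, col) with subpixel jitter; empty candidates or crowding
    surface as a short return (caller raises PlacementError)."""
    candidates = np.flatnonzero(allowed)
    placed: list[tuple[float, float]] = []
    if count == 0 or candidates.size == 0:
        return placed
    ncols = allowed.shape[1]
    min_sep_sq = min_sep_px**2
    # Grid hash with cell size = separation radius: any conflicting point
    # lives in the 3x3 cell neighbourhood, making each attempt O(1).
    cell = max(1.0, min_sep_px)
    occupancy: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def conflicts(r: float, c: float) -> bool:
        kr, kc = int(r // cell), int(c // cell)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for pr, pc in occupancy.get((kr + dr, kc + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < min_sep_sq:
                        return True
        return False

    for pr, pc in taken:
        occupancy.setdefault((int(pr // cell), int(pc // cell)), []).append((pr, pc))

    failures = 0
    while len(placed) < count and failures < 5000:
        flat = candidates[int(rng.integers(candidates.size))]
        r = flat // ncols + rng.uniform(-0.5, 0.5)
        c = flat % ncols + rng.uniform(-0.5, 0.5)
        if conflicts(r, c):
            failures += 1
            continue
        failures = 0
        placed.append((r, c))
        occupancy.setdefault((int(r // cell), int(c // cell)), []).append((r, c))
    return placed


def _render_spots(
    shape: tuple[int, int], points: list[tuple[float, float]], sigma_px: float
) -> np.ndarray:
    """Sum of unit-amplitude isotropic Gaussians at subpixel centres."""
    img = np.zeros(shape, dtype=np.float64)
    half = int(math.ceil(4 * sigma_px))
    for r0, c0 in points:
        r_lo = max(0, int(math.floor(r0)) - half)
        r_hi = min(shape[0], int(math.floor(r0)) + half + 1)
        c_lo = max(0, int(math.floor(c0)) - half)
        c_hi = min(shape[1], int(math.floor(c0)) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        img[r_lo:r_hi, c_lo:c_hi] += np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma_px**2)
        )
    return img


def generate_vessel_image(
    geometry: DeviceGeometry | None = None,
    n_luminal: int = 30,
    n_extravasated: int = 40,
    n_recruited: int = 30,
    snr: float = 10.0,
    seed: int = 0,
) -> SyntheticImageBundle:
    """Generate one seeded two-channel field with known compartment labels.

    Luminal cells sit on vessel ribbons, recruited cells inside the central
    well, extravasated cells in the ECM pockets clear of both. Spots are
    rendered as unit-amplitude Gaussians (FWHM 12 um) with additive
    Gaussian noise of standard deviation 1/snr on both channels.
    """
    if geometry is None:
        geometry = DeviceGeometry(roi_width_um=3000.0, roi_height_um=3000.0)
    for name, n in (
        ("n_luminal", n_luminal),
        ("n_extravasated", n_extravasated),
        ("n_recruited", n_recruited),
    ):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n!r}")
    if not (snr > 0):
        raise ValueError(f"snr must be > 0, got {snr!r}")
    geometry.require_well_fits()

    px = geometry.pixel_size_um
    shape = geometry.shape_px
    rng = np.random.default_rng(seed)

    well = _well_disk(shape, geometry)
    vessels = _vessel_texture(shape, geometry, rng)
    # Vessels anastomose along the gel-well interface: add a ribbon hugging
    # the rim so the well is fully enclosed, as in the real devices.
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    r_well = geometry.well_diameter_um / (2 * px)
    r_vessel = geometry.vessel_diameter_um / (2 * px)
    vessels |= np.abs(dist - (r_well + r_vessel)) <= r_vessel
    vessels &= ~well

    sigma_px = SPOT_FWHM_UM / 2.355 / px
    min_sep_px = 2 * SPOT_FWHM_UM / px

    # Placement masks are eroded so spot centres sit unambiguously inside
    # their compartment even after subpixel jitter, and keep clear of the
    # 50 um well dilation the quantification pipeline applies at the rim.
    margin = disk(2)
    rim_exclusion = ndi.binary_dilation(well, structure=disk(int(round(70 / px))))
    luminal_zone = ndi.binary_erosion(vessels, structure=margin) & ~rim_exclusion
    recruited_zone = ndi.binary_erosion(well, structure=disk(int(round(40 / px))))
    clearance = ndi.binary_dilation(vessels, structure=disk(int(round(16 / px))))
    extravasated_zone = ~(clearance | rim_exclusion)
    extravasated_zone[: int(min_sep_px), :] = False
    extravasated_zone[-int(min_sep_px) :, :] = False
    extravasated_zone[:, : int(min_sep_px)] = False
    extravasated_zone[:, -int(min_sep_px) :] = False

    taken: list[tuple[float, float]] = []
    cells: list[tuple[float, float, str]] = []
    for label, zone, count in (
        ("luminal", luminal_zone, n_luminal),
        ("extravasated", extravasated_zone, n_extravasated),
        ("recruited", recruited_zone, n_recruited),
    ):
        placed = _place_spots(zone, count, min_sep_px, taken, rng)
        if len(placed) < count:
            raise PlacementError(label, len(placed), count)
        taken.extend(placed)
        cells.extend((c, r, label) for r, c in placed)

    vessel_channel = ndi.gaussian_filter(vessels.astype(np.float64), 0.8)
    cell_channel = _render_spots(shape, [(r, c) for c, r, _ in cells], sigma_px)
    noise_sd = 1.0 / snr
    image = np.stack(
        [
            vessel_channel + noise_sd * rng.standard_normal(shape),
            cell_channel + noise_sd * rng.standard_normal(shape),
        ]
    ).astype(np.float32)

    return SyntheticImageBundle(
        image=image,
        pixel_size_um=px,
        truth_vessel_mask=vessels,
        truth_well_mask=well,
        truth_cells=cells,
    )


def median_vessel_width_um(mask: np.ndarray, pixel_size_um: float) -> float:
    """Median ribbon width from the medial-axis distance transform."""
    skel, dist = medial_axis(mask, return_distance=True)
    if not skel.any():
        return 0.0
    return float(np.median(2 * dist[skel]) * pixel_size_um)


def truth_cells_frame(bundle: SyntheticImageBundle) -> pd.DataFrame:
    px = bundle.pixel_size_um
    return pd.DataFrame(
        [
            {
                "x_px": x,
                "y_px": y,
                "x_um": x * px,
                "y_um": y * px,
                "compartment": label,
            }
            for x, y, label in bundle.truth_cells
        ],
        columns=["x_px", "y_px", "x_um", "y_um", "compartment"],
    )


def write_bundle(bundle: SyntheticImageBundle, stem) -> dict[str, str]:
    """Write a bundle as TIFFs + a truth CSV next to ``stem``.

    Returns the mapping of artifact kind to path.
    """
    import os

    paths = {
        "image": f"{stem}_image.tif",
        "vessel_mask": f"{stem}_vessel_mask.tif",
        "well_mask": f"{stem}_well_mask.tif",
        "truth_cells": f"{stem}_truth_cells.csv",
    }
    os.makedirs(os.path.dirname(os.path.abspath(paths["image"])), exist_ok=True)
    tifffile.imwrite(
        paths["image"],
        bundle.image,
        metadata={"axes": "CYX", "pixel_size_um": bundle.pixel_size_um},
    )
    tifffile.imwrite(paths["vessel_mask"], bundle.truth_vessel_mask.astype(np.uint8))
    tifffile.imwrite(paths["well_mask"], bundle.truth_well_mask.astype(np.uint8))
    truth_cells_frame(bundle).to_csv(paths["truth_cells"], index=False)
    return paths
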