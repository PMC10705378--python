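"""Morphological quantification of monocyte recruitment.

Reproduces, step by step, an ImageJ-style analysis of a max-projected
two-channel field: threshold the vasculature, close the inter-vessel ECM
gaps with matched dilate/erode passes, invert to find the central spheroid
well, detect monocyte spots as prominence-filtered local maxima, and
classify each spot as luminal (inside a vessel lumen), extravasated (in
the gel) or recruited (inside the well).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, h_maxima

DEFAULT_MORPH_RADIUS_PX = 3
DEFAULT_N_ITERATIONS = 10
DEFAULT_MIN_HOLE_AREA_UM2 = 0.2e6  # 0.2 mm^2
DEFAULT_WELL_DILATION_UM = 50.0
DEFAULT_MIN_SEPARATION_UM = 15.0
DEFAULT_PROMINENCE = 0.25
DEFAULT_SMOOTH_SIGMA_UM = 3.0


class WellNotFoundError(RuntimeError):
    """No interior background component large enough to be the well:
    either morphological closing failed or the field has no well."""


@dataclass(frozen=True)
class VesselMask:
    binary: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.binary.ndim != 2 or self.binary.dtype != bool:
            raise ValueError("VesselMask.binary must be a 2D boolean array")


@dataclass(frozen=True)
class WellRegion:
    binary: np.ndarray
    area_um2: float
    centroid_px: tuple[float, float]


@dataclass(frozen=True)
class SpotSet:
    """Detected spots as (x_px, y_px, peak_intensity), x = column, y = row."""

    points: list[tuple[int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def coords_rc(self) -> np.ndarray:
        """(n, 2) array of (row, col) integer coordinates."""
        if not self.points:
            return np.empty((0, 2), dtype=int)
        return np.array([(y, x) for x, y, _ in self.points], dtype=int)


@dataclass(frozen=True)
class CompartmentCounts:
    luminal: int
    extravasated: int
    recruited: int

    @property
    def total(self) -> int:
        return self.luminal + self.extravasated + self.recruited

    @property
    def recruited_fraction(self) -> float:
        return self.recruited / self.total if self.total > 0 else 0.0

    def as_dict(self) -> dict:
        return {
            "luminal": self.luminal,
            "extravasated": self.extravasated,
            "recruited": self.recruited,
            "total": self.total,
            "recruited_fraction": self.recruited_fraction,
        }


def collapse_zstack(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum intensity projection over z."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be 2D or a 3D array with >= 1 z-plane")
    return stack.max(axis=0)


def segment_vasculature(
    channel: np.ndarray,
    pixel_size_um: float,
    method: str = "otsu",
    manual_threshold: float | None = None,
) -> VesselMask:
    """Threshold the vasculature channel into a binary mask.

    ``otsu`` picks the threshold maximizing between-class variance and is
    invariant to affine intensity shifts; ``manual`` keeps pixels at or
    above ``manual_threshold``.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("channel is empty")
    if method == "otsu":
        thr = threshold_otsu(channel)
        binary = channel > thr
    elif method == "manual":
        if manual_threshold is None:
            raise ValueError("manual thresholding requires manual_threshold")
        binary = channel >= manual_threshold
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return VesselMask(binary=binary, pixel_size_um=pixel_size_um)


def find_central_well(
    mask: VesselMask,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    min_hole_area_um2: float = DEFAULT_MIN_HOLE_AREA_UM2,
    well_dilation_um: float = DEFAULT_WELL_DILATION_UM,
    morph_radius_px: int = DEFAULT_MORPH_RADIUS_PX,
) -> tuple[WellRegion, VesselMask]:
    """Locate the central well by morphological closing and inversion.

    ``n_iterations`` dilations then the same number of erosions (disk
    structuring element) close the small dark ECM gaps between vessels
    while the much larger well survives; inverting then yields candidate
    holes. The largest interior (non-border-touching) background component
    with area >= ``min_hole_area_um2`` is the well; it is then dilated by
    ``well_dilation_um`` so that cells at its rim count as recruited.

    Returns the dilated well plus the *original* vessel mask with the
    dilated well punched out — the luminal test must use real lumens, not
    the closed mask whose filled gaps are gel, not lumen.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations!r}")
    px = mask.pixel_size_um
    selem = disk(morph_radius_px)
    closed = ndi.binary_dilation(mask.binary, structure=selem, iterations=n_iterations)
    closed = ndi.binary_erosion(
        closed, structure=selem, iterations=n_iterations, border_value=1
    )
    holes = ~closed

    labels, n_labels = ndi.label(holes)
    if n_labels == 0:
        raise WellNotFoundError(
            "no background component found after closing; no well present"
        )
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    areas = ndi.sum_labels(holes, labels, index=np.arange(1, n_labels + 1))
    min_area_px = min_hole_area_um2 / px**2
    best_label, best_area = 0, 0.0
    for lab, area in zip(range(1, n_labels + 1), areas):
        if lab in border_labels or area < min_area_px:
            continue
        if area > best_area:
            best_label, best_area = lab, area
    if best_label == 0:
        raise WellNotFoundError(
            f"no interior hole with area >= {min_hole_area_um2:g} um^2; "
            "closing failed or the field has no well"
        )

    well = labels == best_label
    dil_px = max(0, int(round(well_dilation_um / px)))
    if dil_px:
        well = ndi.binary_dilation(well, structure=disk(dil_px))
    cy, cx = ndi.center_of_mass(well)
    region = WellRegion(
        binary=well,
        area_um2=float(well.sum() * px**2),
        centroid_px=(float(cy), float(cx)),
    )
    lumens = VesselMask(binary=mask.binary & ~well, pixel_size_um=px)
    return region, lumens


def detect_spots(
    channel: np.ndarray,
    pixel_size_um: float,
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM,
    prominence: float = DEFAULT_PROMINENCE,
    smooth_sigma_um: float = DEFAULT_SMOOTH_SIGMA_UM,
) -> SpotSet:
    """Find-Maxima-style spot detection.

    The channel is lightly Gaussian-smoothed (a matched filter at roughly
    half the cell width, suppressing single-pixel noise maxima) and min-max
    normalized; regional maxima with normalized prominence >= ``prominence``
    are kept, then greedily thinned so that surviving peaks are >=
    ``min_separation_um`` apart (brightest first; ties broken by (row,
    column) order). A constant image yields no spots. Detection is
    invariant to affine intensity rescaling by construction.
    """
    if not (0 < prominence < 1):
        raise ValueError(f"prominence must be in (0, 1), got {prominence!r}")
    if not (min_separation_um > 0):
        raise ValueError(f"min_separation_um must be > 0, got {min_separation_um!r}")
    channel = np.asarray(channel, dtype=np.float64)
    if smooth_sigma_um > 0:
        channel = ndi.gaussian_filter(channel, smooth_sigma_um / pixel_size_um)
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return SpotSet(points=[])
    norm = (channel - lo) / (hi - lo)

    peaks_mask = h_maxima(norm, prominence) > 0
    labels, n_labels = ndi.label(peaks_mask)
    if n_labels == 0:
        return SpotSet(points=[])
    # One representative pixel per plateau: brightest, then lexicographic.
    candidates: list[tuple[float, int, int]] = []
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        region = labels[sl] == lab
        vals = np.where(region, norm[sl], -np.inf)
        r_off, c_off = sl[0].start, sl[1].start
        best = np.argwhere(vals == vals.max())
        r, c = best[np.lexsort((best[:, 1], best[:, 0]))][0]
        candidates.append((float(norm[r + r_off, c + c_off]), int(r + r_off), int(c + c_off)))

    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    min_sep_px = min_separation_um / pixel_size_um
    min_sep_sq = min_sep_px**2
    kept: list[tuple[float, int, int]] = []
    for val, r, c in candidates:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep_sq for _, kr, kc in kept):
            kept.append((val, r, c))
    kept.sort(key=lambda t: (t[1], t[2]))
    return SpotSet(points=[(c, r, val) for val, r, c in kept])


def classify_compartments(
    spots: SpotSet, vessels: VesselMask, well: WellRegion
) -> CompartmentCounts:
    """Assign each spot to a compartment and tally.

    Precedence: well > vessel — a spot inside both masks is recruited.
    """
    if vessels.binary.shape != well.binary.shape:
        raise ValueError("vessel and well masks must share a shape")
    luminal = extravasated = recruited = 0
    for x, y, _ in spots.points:
        if well.binary[y, x]:
            recruited += 1
        elif vessels.binary[y, x]:
            luminal += 1
        else:
            extravasated += 1
    return CompartmentCounts(
        luminal=luminal, extravasated=extravasated, recruited=recruited
    )


@dataclass(frozen=True)
class QuantConfig:
    """Tunable knobs of the image pipeline (defaults match a 4 um/px field)."""

    vasculature_channel: int = 0
    monocyte_channel: int = 1
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    n_iterations: int = DEFAULT_N_ITERATIONS
    morph_radius_px: int = DEFAULT_MORPH_RADIUS_PX
    min_hole_area_um2: float = DEFAULT_MIN_HOLE_AREA_UM2
    well_dilation_um: float = DEFAULT_WELL_DILATION_UM
    min_separation_um: float = DEFAULT_MIN_SEPARATION_UM
    prominence: float = DEFAULT_PROMINENCE
    smooth_sigma_um: float = DEFAULT_SMOOTH_SIGMA_UM


def quantify_image(
    image: np.ndarray, pixel_size_um: float, config: QuantConfig = QuantConfig()
) -> tuple[CompartmentCounts, SpotSet, VesselMask, WellRegion]:
    """Full pipeline on one channel-major image (or per-channel z-stacks)."""
    vasc = np.asarray(image[config.vasculature_channel])
    mono = np.asarray(image[config.monocyte_channel])
    vasc = collapse_zstack(vasc)
    mono = collapse_zstack(mono)
    mask = segment_vasculature(
        vasc, pixel_size_um, config.threshold_method, config.manual_threshold
    )
    well, lumens = find_central_well(
        mask,
        n_iterations=config.n_iterations,
        min_hole_area_um2=config.min_hole_area_um2,
        well_dilation_um=config.well_dilation_um,
        morph_radius_px=config.morph_radius_px,
    )
    spots = detect_spots(
        mono,
        pixel_size_um,
        config.min_separation_um,
        config.prominence,
        config.smooth_sigma_um,
    )
    counts = classify_compartments(spots, lumens, well)
    return counts, spots, lumens, well


def recruitment_timecourse(
    images: list[tuple[str, float, np.ndarray]],
    pixel_size_um: float,
    config: QuantConfig = QuantConfig(),
) -> pd.DataFrame:
    """Run the pipeline over a (device_id, day, image) batch.

    A failing image (e.g. no detectable well) produces a flagged row with
    NaN counts instead of aborting the batch.
    """
    if not images:
        raise ValueError("at least one timepoint is required")
    rows = []
    for device_id, day, image in images:
        row = {"device_id": device_id, "day": day}
        try:
            counts, _, _, _ = quantify_image(image, pixel_size_um, config)
            row.update(counts.as_dict())
            row["flags"] = ""
        except Exception as exc:  # noqa: BLE001 - isolation contract
            row.update(
                {
                    "luminal": np.nan,
                    "extravasated": np.nan,
                    "recruited": np.nan,
                    "total": np.nan,
                    "recruited_fraction": np.nan,
                    "flags": f"{type(exc).__name__}: {exc}",
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def spheroid_equivalent_diameter(
    spheroid_mask: np.ndarray, pixel_size_um: float
) -> float:
    """Circle-equivalent diameter 2*sqrt(area/pi) of a spheroid's projected mask."""
    mask = np.asarray(spheroid_mask, dtype=bool)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("spheroid mask is empty")
    _, n_components = ndi.label(mask)
    if n_components != 1:
        raise ValueError(
            f"spheroid mask must have one connected component, found {n_components}"
        )
    area_um2 = area_px * pixel_size_um**2
    return 2.0 * float(np.sqrt(area_um2 / np.pi))
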