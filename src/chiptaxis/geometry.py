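"""Physical geometry of the microfluidic devices.

Two device families are supported by the same dataclass:

* migration (chemotaxis) chips: a straight gel channel between two media
  channels; cells enter at ``x = 0`` and migrate along the channel axis
  toward ``x = gel_channel_length_um``.
* vascularized-well chips: a square gel region holding a self-assembled
  microvascular network around a central circular well into which a tumor
  spheroid is inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class DeviceGeometry:
    """Dimensions, in micrometres, of the gel region under analysis.

    Parameters
    ----------
    gel_channel_length_um:
        Extent of the gel along the migration axis. Cells enter at 0.
    roi_width_um, roi_height_um:
        Field of view of one imaged region of interest.
    well_diameter_um:
        Diameter of the central spheroid well (vascularized devices).
    vessel_diameter_um:
        Target microvessel width; self-assembled networks run ~40 um.
    pixel_size_um:
        Physical sampling of the images.
    """

    gel_channel_length_um: float = 1300.0
    roi_width_um: float = 2200.0
    roi_height_um: float = 1300.0
    well_diameter_um: float = 1500.0
    vessel_diameter_um: float = 40.0
    pixel_size_um: float = 4.0

    def __post_init__(self) -> None:
        lengths = {
            "gel_channel_length_um": self.gel_channel_length_um,
            "roi_width_um": self.roi_width_um,
            "roi_height_um": self.roi_height_um,
            "well_diameter_um": self.well_diameter_um,
            "vessel_diameter_um": self.vessel_diameter_um,
            "pixel_size_um": self.pixel_size_um,
        }
        for name, value in lengths.items():
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.vessel_diameter_um / self.pixel_size_um < 3:
            raise ValueError(
                "vessels are not resolvable: vessel_diameter_um / pixel_size_um "
                f"= {self.vessel_diameter_um / self.pixel_size_um:.2f} < 3"
            )

    def require_well_fits(self) -> None:
        """Raise unless the central well fits inside the ROI."""
        if self.well_diameter_um >= min(self.roi_width_um, self.roi_height_um):
            raise ValueError(
                "well_diameter_um must be smaller than the ROI: "
                f"{self.well_diameter_um} >= "
                f"min({self.roi_width_um}, {self.roi_height_um})"
            )

    @property
    def shape_px(self) -> tuple[int, int]:
        """Image shape (rows, columns) covering the ROI."""
        return (
            int(round(self.roi_height_um / self.pixel_size_um)),
            int(round(self.roi_width_um / self.pixel_size_um)),
        )

    def to_dict(self) -> dict:
        return asdict(self)


#: ROI used when imaging the vascularized-well devices (square field
#: centred on the well).
VASCULAR_WELL_IMAGING = DeviceGeometry(roi_width_um=3000.0, roi_height_um=3000.0)

#: ROI of one migration-assay field (channel runs along the height axis).
MIGRATION_ASSAY = DeviceGeometry()
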