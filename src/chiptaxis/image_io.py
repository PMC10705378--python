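"""Reading multi-channel TIFF / OME-TIFF fields with physical pixel size."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger("chiptaxis")


def read_pixel_size_um(path: str | Path) -> float | None:
    """Physical pixel size from OME metadata, if present (um/px)."""
    with tifffile.TiffFile(path) as tif:
        if tif.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tif.ome_metadata)
                for elem in root.iter():
                    if elem.tag.endswith("Pixels") and "PhysicalSizeX" in elem.attrib:
                        return float(elem.attrib["PhysicalSizeX"])
            except ET.ParseError:
                return None
    return None


def read_image(path: str | Path, config_pixel_size_um: float) -> tuple[np.ndarray, float]:
    """Load an image and resolve its pixel size.

    The configured pixel size wins over OME metadata; a conflict beyond 1%
    is logged as a warning rather than raised, since device configs are
    authoritative for a run.
    """
    image = tifffile.imread(path)
    meta = read_pixel_size_um(path)
    if meta is not None and abs(meta - config_pixel_size_um) > 0.01 * config_pixel_size_um:
        log.warning(
            "pixel size conflict for %s: OME metadata %.4g um vs config %.4g um; "
            "using the config value",
            path, meta, config_pixel_size_um,
        )
    return image, config_pixel_size_um
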