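"""TIFF and table I/O.

Images are single-channel 8/16-bit (or float) grayscale TIFFs read with
tifffile; tables are plain delimited text handled by pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ImageInputError
from .ratiometry import RatiometricResult
from .segmentation import FluorescenceField, Particle


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ImageInputError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return np.asarray(img, dtype=float)


def read_field(
    hoechst_path: str | Path,
    srb_path: str | Path,
    pixel_size: float,
    well_id: str = "",
    bit_depth: int | None = None,
) -> FluorescenceField:
    """Load a paired Hoechst/SRB well from two TIFF files."""
    hoechst = read_image(hoechst_path)
    srb = read_image(srb_path)
    if bit_depth is None:
        raw = tifffile.imread(hoechst_path)
        bit_depth = 8 if raw.dtype == np.uint8 else 16
    return FluorescenceField(
        hoechst=hoechst,
        srb=srb,
        pixel_size=pixel_size,
        well_id=well_id or Path(hoechst_path).stem,
        bit_depth=bit_depth,
    )


def write_field(field: FluorescenceField, hoechst_path: str | Path, srb_path: str | Path) -> None:
    tifffile.imwrite(Path(hoechst_path), field.hoechst.astype(np.float32))
    tifffile.imwrite(Path(srb_path), field.srb.astype(np.float32))


def particles_to_frame(particles: list[Particle], well_id: str = "") -> pd.DataFrame:
    """One row per particle: well, label, area, axes, circularity."""
    return pd.DataFrame(
        {
            "well_id": well_id,
            "label": [p.label for p in particles],
            "area": [p.area for p in particles],
            "centroid_x": [p.centroid[0] for p in particles],
            "centroid_y": [p.centroid[1] for p in particles],
            "long_axis": [p.long_axis for p in particles],
            "short_axis": [p.short_axis for p in particles],
            "circularity_ratio": [p.circularity_ratio for p in particles],
            "mean_hoechst": [p.mean_hoechst for p in particles],
        }
    )


def result_to_row(result: RatiometricResult) -> dict:
    census = result.census
    row = {
        "well_id": result.well_id,
        "esrb_total": result.esrb_total,
        "nsrb_mean": result.nsrb_mean,
        "n_cells": result.n_cells,
        "index": result.index,
    }
    if census is not None:
        f = census.fractions
        row.update(
            n_mono=census.n_mono,
            n_binucleate=census.n_binucleate,
            n_fibroblast=census.n_fibroblast,
            frac_mono=f[0],
            frac_binucleate=f[1],
            frac_fibroblast=f[2],
        )
    return row
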