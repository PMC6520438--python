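"""Nuclear segmentation and particle morphometry.

A Hoechst (or DAPI) image is background-corrected, thresholded with the
Ridler–Calvard intermeans (isodata) algorithm and labelled into connected
components ("particles").  Each particle is summarised by its area, centroid,
the major/minor axes of the moment-matched ellipse, and the circularity
ratio (long axis / short axis) used downstream to separate round fibroblast
nuclei from elongated binucleate-myocyte particles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border

from .errors import DegenerateImageError, ImageInputError, InternalConsistencyError

logger = logging.getLogger(__name__)

__all__ = [
    "FluorescenceField",
    "NuclearMask",
    "Particle",
    "estimate_background",
    "subtract_background",
    "ridler_calvard_threshold",
    "build_nuclear_mask",
    "measure_particles",
]


@dataclass(frozen=True)
class FluorescenceField:
    """Paired Hoechst/SRB images of one well (or one field of view).

    Parameters
    ----------
    hoechst, srb:
        Single-channel non-negative intensity arrays of identical shape.
    pixel_size:
        Micrometres per pixel (> 0).
    well_id:
        Free-text identifier used in outputs and error messages.
    bit_depth:
        Bit depth of the acquisition (8 or 16 for TIFF sources); intensities
        must not exceed ``2**bit_depth - 1``.
    """

    hoechst: np.ndarray
    srb: np.ndarray
    pixel_size: float
    well_id: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        hoechst = np.asarray(self.hoechst, dtype=float)
        srb = np.asarray(self.srb, dtype=float)
        if hoechst.ndim != 2 or srb.ndim != 2:
            raise ImageInputError("channel images must be 2-D")
        if hoechst.shape != srb.shape:
            raise ImageInputError(
                f"channel shapes differ: {hoechst.shape} vs {srb.shape}"
            )
        if self.pixel_size <= 0:
            raise ImageInputError("pixel_size must be > 0")
        if hoechst.size == 0:
            raise ImageInputError("empty image")
        if hoechst.min() < 0 or srb.min() < 0:
            raise ImageInputError("intensities must be non-negative")
        ceiling = 2.0**self.bit_depth - 1
        if hoechst.max() > ceiling or srb.max() > ceiling:
            raise ImageInputError(
                f"intensities exceed {self.bit_depth}-bit range (max {ceiling:g})"
            )
        object.__setattr__(self, "hoechst", hoechst)
        object.__setattr__(self, "srb", srb)


@dataclass(frozen=True)
class NuclearMask:
    """Labelled nuclear mask: 0 = extra-nuclear, 1..n_particles = particles."""

    labels: np.ndarray
    threshold: float
    n_particles: int
    background: float = 0.0
    degenerate: bool = False

    @property
    def nuclear(self) -> np.ndarray:
        """Boolean nuclear-region mask."""
        return self.labels > 0


@dataclass(frozen=True)
class Particle:
    """Geometry and Hoechst intensity of one connected nuclear component.

    ``area`` is in um^2; axes are the major/minor axis lengths (um) of the
    ellipse with the same normalised second central moments as the component;
    ``circularity_ratio = long_axis / short_axis >= 1``.
    """

    label: int
    area: float
    centroid: tuple[float, float]  # (x, y) = (column, row), 0-based
    long_axis: float
    short_axis: float
    circularity_ratio: float
    mean_hoechst: float
    n_pixels: int


def estimate_background(image: np.ndarray, bin_width: float = 1.0) -> float:
    """Modal intensity of the image histogram (bin width 1 by default).

    Cells are sparse relative to background, so the histogram mode is the
    dominant non-cell level; subtracting it (clipped at zero) gives the
    background-corrected image used everywhere downstream.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ImageInputError("cannot estimate background of an empty image")
    if image.min() < 0:
        raise ImageInputError("intensities must be non-negative")
    lo = np.floor(image.min() / bin_width) * bin_width
    hi = np.ceil(image.max() / bin_width) * bin_width
    if hi <= lo:  # constant image
        return float(image.flat[0])
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(image, bins=edges)
    mode_bin = int(np.argmax(counts))
    # report the mean intensity inside the modal bin (robust for float images,
    # exact for integer images with bin_width 1)
    in_bin = (image >= edges[mode_bin]) & (image < edges[mode_bin + 1])
    if mode_bin == len(counts) - 1:
        in_bin |= image == edges[-1]
    return float(image[in_bin].mean())


def subtract_background(image: np.ndarray, background: float | None = None) -> np.ndarray:
    """Constant background subtraction, clipped at zero."""
    image = np.asarray(image, dtype=float)
    if background is None:
        background = estimate_background(image)
    return np.clip(image - background, 0.0, None)


def ridler_calvard_threshold(
    image: np.ndarray, tol: float = 0.5, max_iter: int = 100
) -> float:
    """Ridler–Calvard intermeans (isodata) threshold.

    Iterates ``T_{k+1} = (mean(image <= T_k) + mean(image > T_k)) / 2`` from
    the global mean until the update is below ``tol`` (intensity units).  The
    returned threshold lies strictly between the two final class means.

    Raises
    ------
    DegenerateImageError
        If the image is constant (no threshold separates two classes).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ImageInputError("cannot threshold an empty image")
    flat = image.ravel()
    if flat.max() == flat.min():
        raise DegenerateImageError("constant image admits no threshold")
    t = float(flat.mean())
    for _ in range(max_iter):
        below = flat[flat <= t]
        above = flat[flat > t]
        if below.size == 0 or above.size == 0:
            # nudge inside the data range and retry
            t = float((flat.min() + flat.max()) / 2.0)
            below = flat[flat <= t]
            above = flat[flat > t]
            if below.size == 0 or above.size == 0:
                raise DegenerateImageError("intermeans iteration degenerated")
        t_new = 0.5 * (float(below.mean()) + float(above.mean()))
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    warnings.warn("intermeans threshold did not converge; returning last iterate")
    return t


def build_nuclear_mask(
    hoechst: np.ndarray,
    pixel_size: float,
    min_area: float = 20.0,
    background: float | None = None,
    exclude_border: bool = False,
    threshold_tol: float = 0.5,
) -> NuclearMask:
    """Segment a Hoechst image into a labelled nuclear mask.

    Background-subtracts, thresholds (Ridler–Calvard), labels 8-connected
    components and discards components smaller than ``min_area`` (um^2).
    Touching nuclei deliberately remain one particle: the resulting
    elongation is the signal used to recognise binucleate myocytes.

    A degenerate (constant) image yields an *empty* mask with a warning, not
    an exception — blank wells are legal on a plate.
    """
    hoechst = np.asarray(hoechst, dtype=float)
    if hoechst.ndim != 2 or hoechst.size == 0:
        raise ImageInputError("hoechst image must be a non-empty 2-D array")
    if background is None:
        background = estimate_background(hoechst)
    corrected = np.clip(hoechst - background, 0.0, None)
    try:
        threshold = ridler_calvard_threshold(corrected, tol=threshold_tol)
    except DegenerateImageError:
        logger.warning("degenerate Hoechst image: returning empty nuclear mask")
        return NuclearMask(
            labels=np.zeros(hoechst.shape, dtype=np.int32),
            threshold=float("nan"),
            n_particles=0,
            background=background,
            degenerate=True,
        )
    binary = corrected > threshold
    labels = sk_label(binary, connectivity=2)  # 8-connectivity
    if exclude_border:
        labels = clear_border(labels)
    min_pixels = min_area / pixel_size**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_pixels)
    keep = keep[keep != 0]
    relabel = np.zeros(counts.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    labels = relabel[labels]
    return NuclearMask(
        labels=labels,
        threshold=float(threshold),
        n_particles=int(keep.size),
        background=background,
    )


def measure_particles(
    mask: NuclearMask, hoechst: np.ndarray, pixel_size: float
) -> list[Particle]:
    """Per-particle geometry and mean Hoechst intensity.

    Axis lengths come from the ellipse with the same normalised second
    central moments as the pixel set (scikit-image ``regionprops``); the
    short axis is floored at one pixel so the circularity ratio stays finite
    for single-row components.
    """
    hoechst = np.asarray(hoechst, dtype=float)
    if mask.labels.shape != hoechst.shape:
        raise ImageInputError("mask and image shapes differ")
    props = regionprops(mask.labels, intensity_image=hoechst)
    if len(props) != mask.n_particles:
        raise InternalConsistencyError(
            f"mask claims {mask.n_particles} particles, found {len(props)}"
        )
    particles: list[Particle] = []
    for p in props:
        long_px = max(p.axis_major_length, 1.0)
        short_px = max(p.axis_minor_length, 1.0)
        row, col = p.centroid
        particles.append(
            Particle(
                label=int(p.label),
                area=float(p.num_pixels) * pixel_size**2,
                centroid=(float(col), float(row)),
                long_axis=long_px * pixel_size,
                short_axis=short_px * pixel_size,
                circularity_ratio=float(long_px / short_px),
                mean_hoechst=float(p.intensity_mean),
                n_pixels=int(p.num_pixels),
            )
        )
    return particles
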