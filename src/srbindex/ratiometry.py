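"""Ratiometric SRB index of hypertrophic growth.

The SRB (sulforhodamine B) channel reports protein biomass.  After
background subtraction its pixels are segregated by the nuclear mask into an
extra-nuclear sum (eSRB, tracking cytoplasmic protein and hence growth) and
a per-particle nuclear mean (nSRB, insensitive to cell size and to
acquisition settings).  The index

    index = eSRB_total / (mean nSRB x number of cells)

is dimensionless and invariant to multiplicative gain applied to both
channels, which is what makes results comparable across instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytometry import (
    AreaCutoff,
    CellCensus,
    CircularityMixture,
    census_cells,
    classify_particles,
    determine_area_cutoff,
    fit_circularity_mixture,
)
from .errors import (
    ImageInputError,
    InsufficientDataError,
    MissingControlError,
    UndefinedIndexError,
)
from .segmentation import (
    FluorescenceField,
    NuclearMask,
    Particle,
    build_nuclear_mask,
    estimate_background,
    measure_particles,
)

__all__ = [
    "SRBPartition",
    "RatiometricResult",
    "AnalysisConfig",
    "partition_srb",
    "ratiometric_index",
    "analyze_field",
    "normalize_to_control",
]


@dataclass(frozen=True)
class SRBPartition:
    """Background-corrected SRB signal split at the nuclear mask."""

    esrb_total: float  # summed corrected intensity over extra-nuclear pixels
    nsrb_mean: float  # unweighted mean over particles of per-particle mean SRB
    nsrb_per_particle: np.ndarray
    background: float
    n_nuclear_pixels: int
    nuclear_total: float  # summed corrected intensity over nuclear pixels
    flagged: bool = False  # True when no nuclear pixels exist


@dataclass(frozen=True)
class RatiometricResult:
    """One well's ratiometric index plus the intermediates that produced it."""

    index: float
    esrb_total: float
    nsrb_mean: float
    n_cells: int
    well_id: str = ""
    census: CellCensus | None = None
    partition: SRBPartition | None = None
    mask: NuclearMask | None = None
    particles: list[Particle] | None = None


@dataclass
class AnalysisConfig:
    """Tunable parameters of the per-field analysis chain.

    ``hoechst_background``/``srb_background`` override the automatic
    (histogram-mode) background estimate — mainly for calibration runs with
    known zero background.  ``cutoff``/``mixture`` inject classification
    models fitted at plate level (pooled control wells); when ``None`` the
    models are fitted from the field's own particles.
    """

    min_area: float = 20.0
    exclude_border: bool = False
    fallback_cutoff: float = 90.0
    include_fibroblasts: bool = True
    hoechst_background: float | None = None
    srb_background: float | None = None
    cutoff: AreaCutoff | None = None
    mixture: CircularityMixture | None = None
    seed: int | None = 0


def partition_srb(
    srb: np.ndarray,
    mask: NuclearMask,
    background: float | None = None,
) -> SRBPartition:
    """Segregate the background-corrected SRB image at the nuclear mask.

    The nuclear reference is the *unweighted* mean over particles of each
    particle's mean SRB, which de-weights the few large fibroblast nuclei.
    The extra-nuclear sum deliberately includes cell-free background pixels:
    with constant-background subtraction they contribute ~0 and the field
    total stays proportional to biomass.
    """
    srb = np.asarray(srb, dtype=float)
    if srb.shape != mask.labels.shape:
        raise ImageInputError(
            f"SRB image shape {srb.shape} != mask shape {mask.labels.shape}"
        )
    if background is None:
        background = estimate_background(srb)
    corrected = np.clip(srb - background, 0.0, None)
    nuclear = mask.labels > 0
    esrb_total = float(corrected[~nuclear].sum())
    n_nuclear = int(nuclear.sum())
    if n_nuclear == 0 or mask.n_particles == 0:
        return SRBPartition(
            esrb_total=esrb_total,
            nsrb_mean=float("nan"),
            nsrb_per_particle=np.empty(0),
            background=float(background),
            n_nuclear_pixels=n_nuclear,
            nuclear_total=float(corrected[nuclear].sum()),
            flagged=True,
        )
    sums = np.bincount(
        mask.labels.ravel(), weights=corrected.ravel(), minlength=mask.n_particles + 1
    )
    counts = np.bincount(mask.labels.ravel(), minlength=mask.n_particles + 1)
    per_particle = sums[1:] / counts[1:]
    return SRBPartition(
        esrb_total=esrb_total,
        nsrb_mean=float(per_particle.mean()),
        nsrb_per_particle=per_particle,
        background=float(background),
        n_nuclear_pixels=n_nuclear,
        nuclear_total=float(sums[1:].sum()),
    )


def ratiometric_index(
    partition: SRBPartition, census: CellCensus, well_id: str = ""
) -> RatiometricResult:
    """index = eSRB_total / (mean nSRB x n_cells)."""
    n_cells = census.n_cells
    if n_cells == 0:
        raise UndefinedIndexError("no cells: ratiometric index undefined")
    if not np.isfinite(partition.nsrb_mean) or partition.nsrb_mean <= 0:
        raise UndefinedIndexError("nuclear SRB reference is zero or undefined")
    return RatiometricResult(
        index=partition.esrb_total / (partition.nsrb_mean * n_cells),
        esrb_total=partition.esrb_total,
        nsrb_mean=partition.nsrb_mean,
        n_cells=n_cells,
        well_id=well_id,
        census=census,
        partition=partition,
    )


def analyze_field(
    field: FluorescenceField, config: AnalysisConfig | None = None
) -> RatiometricResult:
    """Full per-field chain: segmentation -> census -> ratiometric index.

    Deterministic for a given field and config; all intermediates (mask,
    particles, partition, census) are attached to the result for audit.
    """
    config = config or AnalysisConfig()
    try:
        mask = build_nuclear_mask(
            field.hoechst,
            pixel_size=field.pixel_size,
            min_area=config.min_area,
            background=config.hoechst_background,
            exclude_border=config.exclude_border,
        )
        if mask.n_particles == 0:
            raise UndefinedIndexError("blank field: no nuclear particles")
        particles = measure_particles(mask, field.hoechst, field.pixel_size)
        cutoff = config.cutoff
        if cutoff is None:
            cutoff = determine_area_cutoff(
                particles, fallback_cutoff=config.fallback_cutoff, seed=config.seed
            )
        mixture = config.mixture
        if mixture is None:
            large = [p for p in particles if p.area > cutoff.cutoff]
            mixture = fit_circularity_mixture(large, seed=config.seed)
        labels = classify_particles(particles, cutoff, mixture)
        census = census_cells(labels, include_fibroblasts=config.include_fibroblasts)
        partition = partition_srb(field.srb, mask, background=config.srb_background)
        result = ratiometric_index(partition, census, well_id=field.well_id)
    except (UndefinedIndexError, InsufficientDataError, ImageInputError) as exc:
        raise type(exc)(f"well {field.well_id!r}: {exc}") from exc
    return RatiometricResult(
        index=result.index,
        esrb_total=result.esrb_total,
        nsrb_mean=result.nsrb_mean,
        n_cells=result.n_cells,
        well_id=field.well_id,
        census=result.census,
        partition=result.partition,
        mask=mask,
        particles=particles,
    )


def normalize_to_control(
    results: pd.DataFrame, plate_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Percent-of-control responses, computed within (isolation, duration).

    ``results`` must carry columns ``well_id, index`` plus the design columns
    ``condition, dose, duration, isolation, is_control`` (either directly or
    merged in from ``plate_map`` on ``well_id``).  Within each isolation and
    time point the treated mean index is divided by the time-matched control
    mean and scaled to percent; isolation-level responses are then averaged
    so each biological isolation counts once.

    Returns a table with one row per (condition, dose, duration, isolation)
    plus the per-isolation ``response_percent``.
    """
    df = results.copy()
    if plate_map is not None:
        design_cols = [
            c
            for c in ("well_id", "condition", "dose", "duration", "isolation", "is_control")
            if c in plate_map.columns and c not in df.columns or c == "well_id"
        ]
        df = df.merge(plate_map[design_cols], on="well_id", how="left")
    required = {"index", "condition", "dose", "duration", "isolation", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    rows = []
    for (isolation, duration), stratum in df.groupby(["isolation", "duration"]):
        controls = stratum[stratum["is_control"].astype(bool)]
        if controls.empty:
            raise MissingControlError(
                f"stratum (isolation={isolation!r}, duration={duration!r}) has no control well"
            )
        control_mean = controls["index"].mean()
        for (condition, dose), grp in stratum.groupby(["condition", "dose"]):
            rows.append(
                {
                    "condition": condition,
                    "dose": dose,
                    "duration": duration,
                    "isolation": isolation,
                    "mean_index": grp["index"].mean(),
                    "control_mean_index": control_mean,
                    "response_percent": 100.0 * grp["index"].mean() / control_mean,
                    "n_wells": len(grp),
                }
            )
    return pd.DataFrame(rows)
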