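"""Synthetic data with known ground truth for every pipeline stage.

Three levels of realism, all seeded and bit-reproducible:

* **particle tables** — per-particle (area, circularity) draws from per-type
  log-normal distributions, for testing the census machinery alone;
* **image fields** — rendered Hoechst/SRB pairs: nuclei as bright ellipses
  (a binucleate cell = two overlapping ellipses forming one elongated
  particle), size-independent nuclear SRB, cytoplasmic Gaussian halos whose
  integrated intensity equals the per-cell biomass, additive background,
  Gaussian noise, multiplicative gain applied last, saturation at the bit
  ceiling;
* **plates** — wells crossed over conditions x doses x isolations x
  technical repeats, with isolation-level random effects (log-normal
  multipliers calibrated to a target intraclass correlation) and dose
  effects entering through a Hill model on the hypertrophy factor.

The control-culture defaults emulate neonatal rat ventricular myocyte
monolayers: ~77/16/7% mononucleate myocytes / binucleate myocytes /
fibroblasts, mononucleate nuclear area median 45 um^2 vs fibroblast
120 um^2, binucleate circularity median 2.2, 2000-3500 particles per field,
and a baseline ratiometric index near 0.3 x 10^3.  Nuclear SRB is
independent of cell biomass by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cytometry import BINUCLEATE, FIBROBLAST, MONONUCLEATE
from .errors import SRBIndexError
from .pharmacology import hill_response
from .segmentation import FluorescenceField

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PlateDesign",
    "generate_particle_table",
    "generate_control_wells",
    "generate_field_images",
    "generate_plate_dataset",
    "simulate_dose_response_data",
    "simulate_inhibition_data",
]

TYPES = (MONONUCLEATE, BINUCLEATE, FIBROBLAST)


class DensityError(SRBIndexError):
    """Nucleus placement failed: the requested density is infeasible."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults emulate a control NRVM culture field.

    Areas/circularities are log-normal with the given medians (um^2 /
    dimensionless) and log-scale SDs, per type in the order (mononucleate,
    binucleate, fibroblast).  ``biomass_per_cell`` is the integrated
    cytoplasmic SRB intensity per cell at hypertrophy_factor 1; the analytic
    ratiometric index of a field is
    ``biomass_per_cell * hypertrophy_factor / nuclear_srb_mean``.
    """

    field_size: tuple[int, int] = (1500, 1500)
    pixel_size: float = 1.0  # um per pixel
    n_cells_by_type: tuple[int, int, int] = (1925, 400, 175)
    area_median: tuple[float, float, float] = (45.0, 45.0, 120.0)
    area_logsd: tuple[float, float, float] = (0.12, 0.12, 0.12)
    circ_median: tuple[float, float, float] = (1.08, 2.2, 1.10)
    circ_logsd: tuple[float, float, float] = (0.12, 0.12, 0.12)
    nuclear_srb_mean: float = 200.0
    biomass_per_cell: float = 60000.0
    hypertrophy_factor: float = 1.0
    gain: float = 1.0
    background: tuple[float, float] = (10.0, 10.0)  # (hoechst, srb)
    noise_sd: float = 2.0
    hoechst_intensity: float = 150.0
    halo_sigma: float = 6.0  # um; spread of the cytoplasmic halo around each cell
    density_decay: float = 2.2e-4  # per particle/field; see spec_for_density
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_cells_by_type):
            raise ValueError("cell counts must be non-negative")
        for name in ("area_median", "area_logsd", "circ_median", "circ_logsd"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be positive")
        if min(self.nuclear_srb_mean, self.biomass_per_cell, self.gain, self.pixel_size) <= 0:
            raise ValueError("scales must be positive")
        if self.hypertrophy_factor <= 0:
            raise ValueError("hypertrophy_factor must be positive")

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_by_type))

    @property
    def analytic_index(self) -> float:
        """Expected ratiometric index, independent of cell number and gain."""
        return self.biomass_per_cell * self.hypertrophy_factor / self.nuclear_srb_mean


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows about the data it produced."""

    true_types: tuple[str, ...] = ()
    n_cells: int = 0
    n_by_type: tuple[int, int, int] = (0, 0, 0)
    biomass_per_cell: float = 0.0
    analytic_index: float = 0.0
    extras: dict = field(default_factory=dict)


def spec_for_density(base: SyntheticSpec, n_cells_total: int) -> SyntheticSpec:
    """Spec for a different seeding density on the same growth area.

    Cell counts are split by the base spec's type proportions; the per-cell
    biomass shrinks exponentially with density (cells at high density have
    less space to spread), ``biomass * exp(-density_decay * (n - n_base))``,
    normalised so the base density keeps the base biomass.  The default decay
    gives a >2-fold index span between ~1000 and ~4500 particles per field.
    """
    base_counts = np.asarray(base.n_cells_by_type, dtype=float)
    fractions = base_counts / base_counts.sum()
    counts = np.round(fractions * n_cells_total).astype(int)
    # density_decay is calibrated per particle on the reference 1500x1500 um
    # growth area; rescale so equal *density* changes give equal decay on any
    # field size
    area_um2 = base.field_size[0] * base.field_size[1] * base.pixel_size**2
    decay = base.density_decay * (1500.0 * 1500.0) / area_um2
    biomass = base.biomass_per_cell * math.exp(-decay * (n_cells_total - base.n_cells))
    return replace(
        base,
        n_cells_by_type=tuple(int(c) for c in counts),
        biomass_per_cell=float(biomass),
    )


def _lognormal(rng: np.random.Generator, median: float, logsd: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(math.log(median), logsd, size=n))


def generate_particle_table(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    well_id: str = "W01",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-particle (area, circularity) draws with true type labels.

    One row per particle; a binucleate *particle* carries roughly twice the
    mononucleate area (two fused nuclei) and the elongated circularity
    component.  Deterministic given (spec, seed).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    for t_idx, t_name in enumerate(TYPES):
        n = spec.n_cells_by_type[t_idx]
        area_median = spec.area_median[t_idx]
        if t_name == BINUCLEATE:
            area_median *= 1.85  # two fused nuclei minus overlap
        areas = _lognormal(rng, area_median, spec.area_logsd[t_idx], n)
        circs = _lognormal(rng, spec.circ_median[t_idx], spec.circ_logsd[t_idx], n)
        for a, c in zip(areas, circs):
            rows.append((well_id, t_name, float(a), float(max(c, 1.0))))
    df = pd.DataFrame(rows, columns=["well_id", "true_type", "area", "circularity_ratio"])
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(1, "particle", np.arange(1, len(df) + 1))
    gt = GroundTruth(
        true_types=tuple(df["true_type"]),
        n_cells=spec.n_cells,
        n_by_type=tuple(int(n) for n in spec.n_cells_by_type),
        biomass_per_cell=spec.biomass_per_cell * spec.hypertrophy_factor,
        analytic_index=spec.analytic_index,
    )
    return df, gt


def generate_control_wells(
    n_wells: int,
    particles_per_well: int,
    spec: SyntheticSpec | None = None,
    fraction_means: tuple[float, float, float] = (0.77, 0.16, 0.07),
    fraction_sds: tuple[float, float, float] = (0.12, 0.14, 0.03),
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Many control wells with per-well cell-type fraction scatter.

    Per-well fractions are drawn as independent truncated normals around the
    control-culture means (clipped at 1% and renormalised) — matching the
    observed well-to-well spread of the three sub-populations — then particle
    geometries are drawn per type as in :func:`generate_particle_table`.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    tables = []
    for w in range(n_wells):
        fractions = np.clip(rng.normal(fraction_means, fraction_sds), 0.01, None)
        fractions /= fractions.sum()
        counts = rng.multinomial(particles_per_well, fractions)
        well_spec = replace(spec, n_cells_by_type=tuple(int(c) for c in counts))
        table, _ = generate_particle_table(well_spec, rng=rng, well_id=f"W{w + 1:03d}")
        tables.append(table)
    df = pd.concat(tables, ignore_index=True)
    n_by_type = tuple(int((df["true_type"] == t).sum()) for t in TYPES)
    gt = GroundTruth(
        true_types=tuple(df["true_type"]),
        n_cells=len(df),
        n_by_type=n_by_type,
        biomass_per_cell=spec.biomass_per_cell,
        analytic_index=spec.analytic_index,
        extras={"n_wells": n_wells},
    )
    return df, gt


def _ellipse_pixels(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels inside the ellipse (semi-axes a >= b, px)."""
    half = int(math.ceil(a)) + 1
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, shape[0])
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, shape[1])
    if y0 >= y1 or x0 >= x1:
        return np.empty(0, int), np.empty(0, int)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def generate_field_images(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    well_id: str = "W01",
    max_retries: int = 200,
) -> tuple[FluorescenceField, GroundTruth]:
    """Render a paired Hoechst/SRB field with known ground truth.

    Each cell's cytoplasmic biomass is deposited as a Gaussian halo over
    *extra-nuclear* pixels only, renormalised over its in-field support, so
    the total extra-nuclear SRB equals ``n_cells * biomass_per_cell *
    hypertrophy_factor`` exactly and the analytic index is
    ``spec.analytic_index`` by construction.  Noise is added before the gain;
    saturation clips at the bit-depth ceiling after the gain.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    shape = spec.field_size
    px = spec.pixel_size
    nuclear = np.zeros(shape, dtype=bool)
    placement = np.zeros(shape, dtype=bool)  # dilated occupancy, keeps particles apart
    centers: list[tuple[float, float]] = []
    types: list[str] = []

    order = []  # interleave types so crowding penalises them evenly
    for t_idx, t_name in enumerate(TYPES):
        order += [(t_idx, t_name)] * spec.n_cells_by_type[t_idx]
    order = [order[i] for i in rng.permutation(len(order))]

    margin = 3
    for t_idx, t_name in order:
        area_px = (
            _lognormal(rng, spec.area_median[t_idx], spec.area_logsd[t_idx], 1)[0] / px**2
        )
        circ = max(_lognormal(rng, spec.circ_median[t_idx], spec.circ_logsd[t_idx], 1)[0], 1.0)
        theta = rng.uniform(0, math.pi)
        placed = False
        for _ in range(max_retries):
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            if t_name == BINUCLEATE:
                # two overlapping mono-sized nuclei along a shared axis
                b_ax = math.sqrt(area_px / math.pi)
                a_ax = b_ax
                off = 1.3 * b_ax
                lobes = [
                    (cy - 0.5 * off * math.sin(theta), cx - 0.5 * off * math.cos(theta)),
                    (cy + 0.5 * off * math.sin(theta), cx + 0.5 * off * math.cos(theta)),
                ]
            else:
                a_ax = math.sqrt(area_px * circ / math.pi)
                b_ax = math.sqrt(area_px / (circ * math.pi))
                lobes = [(cy, cx)]
            ys_all, xs_all = [], []
            for ly, lx in lobes:
                ys, xs = _ellipse_pixels(shape, ly, lx, a_ax, b_ax, theta)
                ys_all.append(ys)
                xs_all.append(xs)
            ys = np.concatenate(ys_all)
            xs = np.concatenate(xs_all)
            if ys.size == 0:
                continue
            # 2-px clearance so distinct cells never fuse into one particle
            y0, y1 = ys.min() - 2, ys.max() + 3
            x0, x1 = xs.min() - 2, xs.max() + 3
            if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
                continue
            if placement[y0:y1, x0:x1].any():
                continue
            nuclear[ys, xs] = True
            placement[y0:y1, x0:x1] = True
            centers.append((cy, cx))
            types.append(t_name)
            placed = True
            break
        if not placed:
            raise DensityError(
                f"could not place cell {len(centers) + 1}/{len(order)} after "
                f"{max_retries} retries; reduce density"
            )

    hoechst = np.zeros(shape, dtype=float)
    hoechst[nuclear] = spec.hoechst_intensity
    srb = np.zeros(shape, dtype=float)
    srb[nuclear] = spec.nuclear_srb_mean

    # cytoplasmic halos: per-cell Gaussian over extra-nuclear pixels only,
    # renormalised so each cell contributes exactly its biomass
    sigma_px = spec.halo_sigma / px
    half = int(math.ceil(3.5 * sigma_px))
    ax = np.arange(-half, half + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma_px**2))
    biomass = spec.biomass_per_cell * spec.hypertrophy_factor
    for cy, cx in centers:
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, shape[0])
        x0, x1 = max(ix - half, 0), min(ix + half + 1, shape[1])
        kpatch = kernel[y0 - (iy - half) : y1 - (iy - half), x0 - (ix - half) : x1 - (ix - half)]
        support = ~nuclear[y0:y1, x0:x1]
        weight = float(kpatch[support].sum())
        if weight <= 0:
            continue
        patch = np.where(support, kpatch, 0.0) * (biomass / weight)
        srb[y0:y1, x0:x1] += patch

    hoechst += spec.background[0]
    srb += spec.background[1]
    if spec.noise_sd > 0:
        hoechst += rng.normal(0.0, spec.noise_sd, size=shape)
        srb += rng.normal(0.0, spec.noise_sd, size=shape)
    ceiling = 2.0**spec.bit_depth - 1
    hoechst = np.clip(hoechst * spec.gain, 0.0, ceiling)
    srb = np.clip(srb * spec.gain, 0.0, ceiling)

    field_out = FluorescenceField(
        hoechst=hoechst,
        srb=srb,
        pixel_size=px,
        well_id=well_id,
        bit_depth=spec.bit_depth,
    )
    n_by_type = tuple(int(types.count(t)) for t in TYPES)
    gt = GroundTruth(
        true_types=tuple(types),
        n_cells=len(centers),
        n_by_type=n_by_type,
        biomass_per_cell=biomass,
        analytic_index=spec.analytic_index,
        extras={"centers": centers, "nuclear_fraction": float(nuclear.mean())},
    )
    return field_out, gt


@dataclass(frozen=True)
class PlateDesign:
    """Well layout: every condition row is replicated across isolations and
    technical repeats.  ``conditions`` rows are (condition, dose_uM,
    duration_h, is_control)."""

    conditions: tuple[tuple[str, float, float, bool], ...]
    n_isolations: int = 3
    n_technical: int = 4


def generate_plate_dataset(
    design: PlateDesign,
    spec: SyntheticSpec | None = None,
    hill_params: tuple[float, float, float, float] | None = None,
    target_icc: float = 0.0,
    well_cv: float = 0.05,
    seed: int = 0,
    images: bool = False,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a plate of wells with isolation random effects.

    The dose effect enters as a multiplier on the hypertrophy factor,
    ``1 + (Rhyp/R0) * d^n / (EC50^n + d^n)`` from ``hill_params`` (no effect
    when ``None``).  Isolation effects are log-normal multipliers on the
    baseline index with log-variance set so the intraclass correlation of
    control wells approximates ``target_icc`` given the well-level log-scale
    noise ``well_cv``.

    Returns ``(results, plate_map, ground_truth)``.  With ``images=True``
    each well is rendered via :func:`generate_field_images` and written as a
    pair of TIFFs under ``outdir`` (the results table then carries paths, not
    indices, and the well index noise enters through rendering).
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    sigma_w = max(well_cv, 1e-9)
    if not 0.0 <= target_icc < 1.0:
        raise ValueError("target_icc must be in [0, 1)")
    sigma_b = sigma_w * math.sqrt(target_icc / (1.0 - target_icc)) if target_icc > 0 else 0.0
    iso_effects = np.exp(rng.normal(0.0, sigma_b, size=design.n_isolations))
    baseline = spec.analytic_index

    if images and outdir is None:
        raise ValueError("images=True requires outdir")
    if images:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    map_rows, result_rows = [], []
    true_effect = {}
    widx = 0
    for condition, dose, duration, is_control in design.conditions:
        effect = 1.0
        if hill_params is not None and not is_control and dose > 0:
            r0, rhyp, n, ec50 = hill_params
            effect = 1.0 + (rhyp / r0) * dose**n / (ec50**n + dose**n)
        true_effect[(condition, dose, duration)] = effect
        for iso in range(design.n_isolations):
            for rep in range(design.n_technical):
                widx += 1
                well_id = f"{chr(ord('A') + iso)}{widx:03d}"
                row = {
                    "well_id": well_id,
                    "condition": condition,
                    "agonist": condition,
                    "dose": dose,
                    "duration": duration,
                    "isolation": f"iso{iso + 1}",
                    "is_control": is_control,
                }
                if images:
                    well_seed = int(rng.integers(2**31))
                    wspec = replace(
                        spec,
                        hypertrophy_factor=spec.hypertrophy_factor
                        * effect
                        * iso_effects[iso],
                        seed=well_seed,
                    )
                    fld, _ = generate_field_images(
                        wspec, rng=np.random.default_rng(well_seed), well_id=well_id
                    )
                    hpath = outdir / f"{well_id}_hoechst.tif"
                    spath = outdir / f"{well_id}_srb.tif"
                    tifffile.imwrite(hpath, fld.hoechst.astype(np.float32))
                    tifffile.imwrite(spath, fld.srb.astype(np.float32))
                    row["hoechst_path"] = str(hpath)
                    row["srb_path"] = str(spath)
                else:
                    noise = math.exp(rng.normal(0.0, sigma_w))
                    result_rows.append(
                        {
                            **row,
                            "index": baseline * effect * iso_effects[iso] * noise,
                        }
                    )
                map_rows.append(row)
    plate_map = pd.DataFrame(map_rows)
    results = pd.DataFrame(result_rows) if result_rows else plate_map.copy()
    gt = GroundTruth(
        n_cells=spec.n_cells,
        biomass_per_cell=spec.biomass_per_cell,
        analytic_index=baseline,
        extras={
            "iso_effects": iso_effects,
            "true_effect": true_effect,
            "sigma_between": sigma_b,
            "sigma_within": sigma_w,
        },
    )
    if images and outdir is not None:
        plate_map.to_csv(Path(outdir) / "plate_map.csv", index=False)
    return results, plate_map, gt


def simulate_dose_response_data(
    params: tuple[float, float, float, float],
    doses: np.ndarray | None = None,
    cv: float = 0.03,
    n_replicates: int = 16,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level Hill responses with multiplicative Gaussian noise.

    Default design: 8 log-spaced doses over 0.01-30 uM plus a zero-dose
    control, ``n_replicates`` wells per dose, noise SD = cv x true response.
    Returns flat (doses, responses) vectors.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if doses is None:
        doses = np.concatenate([[0.0], np.geomspace(0.01, 30.0, 8)])
    doses = np.asarray(doses, dtype=float)
    d_flat = np.repeat(doses, n_replicates)
    truth = hill_response(d_flat, params)
    responses = truth * (1.0 + rng.normal(0.0, cv, size=d_flat.size))
    return d_flat, responses


def simulate_inhibition_data(
    ki: float = 9.0,
    g0: float = 77.0,
    doses: np.ndarray | None = None,
    cv: float = 0.05,
    n_replicates: int = 25,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level one-site inhibition data (floor 0).

    Defaults follow the anti-hypertrophic screen design: inhibitor doses
    0/1/3/10/30 uM, 25 wells per dose, 5% multiplicative noise, growth
    component ``g0`` (percent above control) halved at I = Ki.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if doses is None:
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
    doses = np.asarray(doses, dtype=float)
    d_flat = np.repeat(doses, n_replicates)
    truth = g0 / (1.0 + d_flat / ki)
    responses = truth * (1.0 + rng.normal(0.0, cv, size=d_flat.size))
    return d_flat, responses
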