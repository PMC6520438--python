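"""Plate-scale orchestration: plate map in, tidy results out.

A plate map is a delimited table with one row per well: ``well_id``,
image paths per channel, ``condition``, ``agonist``, ``dose`` (uM),
``duration`` (h), ``isolation`` and an explicit ``is_control`` flag
(explicit rather than dose==0, so vehicle controls work).  Classification
models (area cutoff, circularity mixture) are fitted once on the pooled
control wells of the plate and applied plate-wide; per-well fitting is
available by flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cytometry import determine_area_cutoff, fit_circularity_mixture
from .errors import PlateMapError
from .hstats import ClusteredSample, hierarchical_anova
from .io import read_field, result_to_row
from .ratiometry import AnalysisConfig, RatiometricResult, analyze_field, normalize_to_control
from .segmentation import build_nuclear_mask, measure_particles

logger = logging.getLogger(__name__)

__all__ = ["PlateMap", "PlateRun", "run_well", "run_plate", "load_plate_map"]

_REQUIRED = ["well_id", "hoechst_path", "srb_path", "condition", "dose", "duration", "isolation", "is_control"]


@dataclass(frozen=True)
class PlateMap:
    """Validated plate map."""

    table: pd.DataFrame
    pixel_size: float = 1.0


@dataclass
class PlateRun:
    """Everything a plate run produced."""

    results: pd.DataFrame
    responses: pd.DataFrame | None
    anova: object | None
    manifest: dict
    well_results: dict[str, RatiometricResult]


def load_plate_map(path: str | Path, pixel_size: float = 1.0, check_files: bool = True) -> PlateMap:
    """Read and validate a delimited plate map (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    table = pd.read_csv(path, sep=sep)
    return validate_plate_map(table, pixel_size=pixel_size, check_files=check_files, base=path.parent)


def validate_plate_map(
    table: pd.DataFrame,
    pixel_size: float = 1.0,
    check_files: bool = True,
    base: Path | None = None,
) -> PlateMap:
    """Aggregate all validation failures before any analysis."""
    problems: list[str] = []
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise PlateMapError(f"plate map missing columns: {missing}")
    if table["well_id"].duplicated().any():
        dups = table.loc[table["well_id"].duplicated(), "well_id"].tolist()
        problems.append(f"duplicate well_ids: {dups}")
    if check_files:
        for col in ("hoechst_path", "srb_path"):
            for well, p in zip(table["well_id"], table[col]):
                fp = Path(p)
                if base is not None and not fp.is_absolute():
                    fp = base / fp
                if not fp.exists():
                    problems.append(f"well {well}: missing {col} {p}")
    treated = table[~table["is_control"].astype(bool)]
    controls = table[table["is_control"].astype(bool)]
    for (iso, dur), _ in treated.groupby(["isolation", "duration"]):
        ok = ((controls["isolation"] == iso) & (controls["duration"] == dur)).any()
        if not ok:
            problems.append(f"stratum (isolation={iso!r}, duration={dur!r}) has no control well")
    if problems:
        raise PlateMapError("plate map validation failed:\n  " + "\n  ".join(problems))
    return PlateMap(table=table.reset_index(drop=True), pixel_size=pixel_size)


def run_well(row: pd.Series | dict, config: AnalysisConfig, pixel_size: float = 1.0) -> RatiometricResult:
    """Segment -> census -> index for one plate-map row."""
    row = dict(row)
    for col in ("hoechst_path", "srb_path"):
        if col not in row or not row[col] or (isinstance(row[col], float) and np.isnan(row[col])):
            raise FileNotFoundError(f"well {row.get('well_id', '?')}: no {col} given")
    try:
        field = read_field(
            row["hoechst_path"], row["srb_path"], pixel_size=pixel_size, well_id=str(row["well_id"])
        )
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"well {row['well_id']}: {exc}") from exc
    return analyze_field(field, config)


def _fit_plate_models(plate: PlateMap, config: AnalysisConfig) -> AnalysisConfig:
    """Fit cutoff + circularity mixture on pooled control-well particles."""
    controls = plate.table[plate.table["is_control"].astype(bool)]
    pool = []
    for _, row in controls.iterrows():
        field = read_field(
            row["hoechst_path"], row["srb_path"], pixel_size=plate.pixel_size, well_id=str(row["well_id"])
        )
        mask = build_nuclear_mask(
            field.hoechst,
            pixel_size=plate.pixel_size,
            min_area=config.min_area,
            background=config.hoechst_background,
            exclude_border=config.exclude_border,
        )
        pool.extend(measure_particles(mask, field.hoechst, plate.pixel_size))
    cutoff = determine_area_cutoff(pool, fallback_cutoff=config.fallback_cutoff, seed=config.seed)
    large = [p for p in pool if p.area > cutoff.cutoff]
    mixture = fit_circularity_mixture(large, seed=config.seed)
    return replace(config, cutoff=cutoff, mixture=mixture)


def run_plate(
    plate: PlateMap,
    config: AnalysisConfig | None = None,
    pool_controls: bool = True,
    normalize: bool = True,
    anova: bool = False,
    seed: int | None = None,
) -> PlateRun:
    """Analyse every well of a plate.

    Results are independent of well order; the manifest records package
    version, configuration and seeds so every output row is traceable to its
    input files.
    """
    config = config or AnalysisConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    if pool_controls and (config.cutoff is None or config.mixture is None):
        config = _fit_plate_models(plate, config)
    rows, well_results = [], {}
    for _, map_row in plate.table.iterrows():
        result = run_well(map_row, config, pixel_size=plate.pixel_size)
        well_results[result.well_id] = result
        rows.append(
            {
                **result_to_row(result),
                "condition": map_row["condition"],
                "dose": map_row["dose"],
                "duration": map_row["duration"],
                "isolation": map_row["isolation"],
                "is_control": bool(map_row["is_control"]),
            }
        )
    results = pd.DataFrame(rows)
    responses = normalize_to_control(results) if normalize else None
    anova_result = None
    if anova:
        anova_result = hierarchical_anova(
            ClusteredSample(
                values=results["index"].to_numpy(),
                cluster_id=results["isolation"].to_numpy(),
                condition=results["condition"].to_numpy(),
            )
        )
    manifest = {
        "package": "srbindex",
        "version": __version__,
        "n_wells": int(len(plate.table)),
        "pixel_size": plate.pixel_size,
        "config": {
            k: v
            for k, v in asdict(config).items()
            if isinstance(v, (int, float, bool, str, type(None)))
        },
        "pooled_control_models": pool_controls,
        "wells": {
            str(r["well_id"]): {"hoechst": str(r["hoechst_path"]), "srb": str(r["srb_path"])}
            for _, r in plate.table.iterrows()
        },
    }
    return PlateRun(
        results=results,
        responses=responses,
        anova=anova_result,
        manifest=manifest,
        well_results=well_results,
    )


def write_run(run: PlateRun, outdir: str | Path) -> None:
    """Write results, responses and the manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run.results.to_csv(outdir / "well_results.csv", index=False)
    if run.responses is not None:
        run.responses.to_csv(outdir / "responses.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(run.manifest, indent=2))
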