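"""Tractparams-driven batch driver with full parameter provenance.

One run takes a whole-brain tractogram, a set of named ROIs and voxelwise
metric maps (supplied directly, or fitted from DWI data), plus a tract
parameter table, and produces per tract: the selected (and optionally
cleaned/clipped) streamlines as ``.tck``, the super fiber as ``_SF.tck``,
binary and fiber-count NIfTI masks, and per-metric profile CSVs with one
column per tract and one row per node.

Every run writes a manifest recording input digests, the fully resolved
parameter set, the package version and per-tract streamline counts, so that
a run can be audited and reproduced; identical inputs and parameters yield
byte-identical outputs apart from the manifest timestamp.  A failure in one
tract is recorded in the manifest and does not abort the others.

The execution path is single-threaded and deterministic by design.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bundle_ops import (
    clean_tract,
    select_by_rois,
    tract_to_binary_mask,
    tract_to_count_mask,
)
from .errors import TractoprofError, ValidationError
from .io_formats import (
    BinaryROI,
    ScalarMap,
    Tractogram,
    VolumeGrid,
    write_tck,
    write_volume,
)
from .profiling import (
    clip_to_roi,
    core_fiber,
    profiles_to_csv,
    tract_profile,
)
from .roi_ops import combine_rois, dilate_roi, validate_roi

__all__ = ["TractParams", "RunManifest", "parse_tractparams", "run_pipeline"]

logger = logging.getLogger("tractoprof")

_REQUIRED_COLUMNS = ("tract_name", "roi1", "roi2")
_KNOWN_COLUMNS = _REQUIRED_COLUMNS + (
    "dilate_roi1",
    "dilate_roi2",
    "combine_roi1",
    "combine_roi2",
    "clean",
    "max_len_sd",
    "max_dist_sd",
    "max_iter",
    "c2roi",
    "metrics",
)


@dataclass
class TractParams:
    """One row of the tract parameter table.

    ``combine_roi1``/``combine_roi2`` name extra ROIs unioned into the
    corresponding defining ROI before selection; ``dilate_roi*`` give the
    number of 26-connected dilation iterations applied afterwards.
    ``metrics`` lists the per-voxel maps to profile along the tract.
    """

    tract_name: str
    roi1: str
    roi2: str
    dilate_roi1: int = 0
    dilate_roi2: int = 0
    combine_roi1: tuple[str, ...] = ()
    combine_roi2: tuple[str, ...] = ()
    clean: bool = True
    max_len_sd: float = 4.0
    max_dist_sd: float = 4.0
    max_iter: int = 5
    c2roi: bool = False
    metrics: tuple[str, ...] = ("FA",)

    def __post_init__(self) -> None:
        if self.dilate_roi1 < 0 or self.dilate_roi2 < 0:
            raise ValidationError(
                f"tract {self.tract_name!r}: dilation iterations must be >= 0"
            )
        if self.max_len_sd <= 0 or self.max_dist_sd <= 0 or self.max_iter < 1:
            raise ValidationError(
                f"tract {self.tract_name!r}: cleaning thresholds must be positive"
            )

    def as_dict(self) -> dict:
        return {
            "tract_name": self.tract_name,
            "roi1": self.roi1,
            "roi2": self.roi2,
            "dilate_roi1": self.dilate_roi1,
            "dilate_roi2": self.dilate_roi2,
            "combine_roi1": list(self.combine_roi1),
            "combine_roi2": list(self.combine_roi2),
            "clean": self.clean,
            "max_len_sd": self.max_len_sd,
            "max_dist_sd": self.max_dist_sd,
            "max_iter": self.max_iter,
            "c2roi": self.c2roi,
            "metrics": list(self.metrics),
        }


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    timestamp: str
    input_digests: dict
    parameters: list[dict]
    tracts: dict = field(default_factory=dict)  # per-tract counts and status

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "timestamp": self.timestamp,
                "input_digests": self.input_digests,
                "parameters": self.parameters,
                "tracts": self.tracts,
            },
            indent=2,
            sort_keys=True,
        )


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n", ""):
        return False
    raise ValidationError(f"{context}: cannot parse boolean from {value!r}")


def _parse_number(value, kind, context: str):
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{context}: cannot parse number from {value!r}") from exc


def _split_names(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    return tuple(part.strip() for part in text.split(";") if part.strip())


def parse_tractparams(source) -> list[TractParams]:
    """Parse the tract parameter CSV (path, file object, or CSV text).

    Unknown columns produce a warning but are not fatal; duplicate tract
    names, missing required columns and unparseable numbers are errors with
    row/column context.
    """
    import io

    if isinstance(source, str) and "\n" in source:
        frame = pd.read_csv(io.StringIO(source), dtype=str)
    else:
        frame = pd.read_csv(source, dtype=str)
    for col in _REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise ValidationError(f"tractparams is missing required column {col!r}")
    unknown = [c for c in frame.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"tractparams has unknown columns (ignored): {unknown}", stacklevel=2)

    rows: list[TractParams] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        ctx = f"tractparams row {i + 1}"
        name = str(row["tract_name"]).strip()
        if not name or name.lower() == "nan":
            raise ValidationError(f"{ctx}: empty tract_name")
        if name in seen:
            raise ValidationError(f"duplicate tract_name {name!r}")
        seen.add(name)

        def get(col, default):
            if col not in frame.columns:
                return default
            value = row[col]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return default
            return value

        metrics = _split_names(get("metrics", None)) or ("FA",)
        rows.append(
            TractParams(
                tract_name=name,
                roi1=str(row["roi1"]).strip(),
                roi2=str(row["roi2"]).strip(),
                dilate_roi1=_parse_number(get("dilate_roi1", 0), int, f"{ctx} col dilate_roi1"),
                dilate_roi2=_parse_number(get("dilate_roi2", 0), int, f"{ctx} col dilate_roi2"),
                combine_roi1=_split_names(get("combine_roi1", None)),
                combine_roi2=_split_names(get("combine_roi2", None)),
                clean=_parse_bool(get("clean", True), f"{ctx} col clean"),
                max_len_sd=_parse_number(get("max_len_sd", 4.0), float, f"{ctx} col max_len_sd"),
                max_dist_sd=_parse_number(get("max_dist_sd", 4.0), float, f"{ctx} col max_dist_sd"),
                max_iter=_parse_number(get("max_iter", 5), int, f"{ctx} col max_iter"),
                c2roi=_parse_bool(get("c2roi", False), f"{ctx} col c2roi"),
                metrics=metrics,
            )
        )
    return rows


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_roi(
    name: str, rois: dict[str, BinaryROI], combine: tuple[str, ...], dilate: int, grid: VolumeGrid
) -> BinaryROI:
    if name not in rois:
        raise ValidationError(f"ROI {name!r} not found among inputs")
    roi = rois[name]
    if combine:
        missing = [c for c in combine if c not in rois]
        if missing:
            raise ValidationError(f"combine ROIs not found: {missing}")
        roi = combine_rois([roi] + [rois[c] for c in combine], mode="union")
    if dilate:
        roi = dilate_roi(roi, dilate)
    return validate_roi(roi, grid)


def run_pipeline(
    wbt: Tractogram,
    rois: dict[str, BinaryROI],
    tractparams: list[TractParams],
    metric_maps: dict[str, ScalarMap],
    out_dir: str | Path,
    grid: VolumeGrid | None = None,
    input_paths: dict[str, str | Path] | None = None,
) -> RunManifest:
    """Execute the full per-tract pipeline and write all outputs.

    Stage order per tract: resolve/validate ROIs (combine, dilate) ->
    select from the whole-brain tractogram -> clean -> optional clip-to-ROI
    -> core fiber -> per-metric profiles -> export tck / _SF.tck / binary
    mask / count mask.  Per-metric profile CSVs aggregate all tracts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if grid is None:
        if metric_maps:
            grid = next(iter(metric_maps.values())).grid
        elif rois:
            grid = next(iter(rois.values())).grid
        else:
            raise ValidationError("no grid available: supply metric maps, ROIs or a grid")

    digests = {}
    for label, p in (input_paths or {}).items():
        digests[label] = _digest_file(Path(p))

    manifest = RunManifest(
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        input_digests=digests,
        parameters=[tp.as_dict() for tp in tractparams],
    )

    profiles_by_metric: dict[str, list] = {}
    for tp in tractparams:
        record: dict = {"status": "ok"}
        manifest.tracts[tp.tract_name] = record
        try:
            roi1 = _resolve_roi(tp.roi1, rois, tp.combine_roi1, tp.dilate_roi1, grid)
            roi2 = _resolve_roi(tp.roi2, rois, tp.combine_roi2, tp.dilate_roi2, grid)
            logger.info("%s: ROIs validated (%s, %s)", tp.tract_name, roi1.name, roi2.name)

            tract = select_by_rois(wbt, [roi1, roi2], mode="all", name=tp.tract_name)
            record["n_candidates"] = tract.params["n_candidates"]
            record["n_selected"] = tract.n_streamlines
            logger.info(
                "%s: selected %d/%d streamlines",
                tp.tract_name,
                tract.n_streamlines,
                tract.params["n_candidates"],
            )
            if tract.n_streamlines == 0:
                record["status"] = "empty-selection"
                continue

            if tp.clean and tract.n_streamlines >= 3:
                tract, report = clean_tract(
                    tract,
                    max_len_sd=tp.max_len_sd,
                    max_dist_sd=tp.max_dist_sd,
                    max_iter=tp.max_iter,
                )
                record["n_after_cleaning"] = tract.n_streamlines
                record["cleaning_iterations"] = report.iterations_run
                logger.info(
                    "%s: cleaning kept %d streamlines in %d iteration(s)",
                    tp.tract_name,
                    tract.n_streamlines,
                    report.iterations_run,
                )

            profiled = tract
            if tp.c2roi:
                profiled = clip_to_roi(tract, roi1, roi2)
                record["n_after_clip"] = profiled.n_streamlines
                if profiled.n_streamlines == 0:
                    record["status"] = "empty-after-clip"
                    continue

            core = core_fiber(profiled)
            for metric in tp.metrics:
                if metric not in metric_maps:
                    raise ValidationError(f"metric map {metric!r} not available")
                prof = tract_profile(
                    profiled, metric_maps[metric], name=tp.tract_name, c2roi=tp.c2roi
                )
                profiles_by_metric.setdefault(metric, []).append(prof)

            write_tck(Tractogram(list(tract.streamlines)), out / f"{tp.tract_name}.tck")
            write_tck(
                Tractogram([core.nodes.astype(np.float32)]),
                out / f"{tp.tract_name}_SF.tck",
            )
            write_volume(tract_to_binary_mask(tract, grid), out / f"{tp.tract_name}_fa_bin.nii.gz")
            write_volume(tract_to_count_mask(tract, grid), out / f"{tp.tract_name}_fbcnt.nii.gz")
            logger.info("%s: exports written", tp.tract_name)
        except TractoprofError as exc:
            record["status"] = "failed"
            record["error"] = str(exc)
            logger.warning("%s: failed (%s)", tp.tract_name, exc)

    for metric, profs in profiles_by_metric.items():
        profiles_to_csv(profs, out / f"{metric}_profiles.csv")

    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest
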