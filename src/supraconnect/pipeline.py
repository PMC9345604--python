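"""End-to-end orchestration: configuration, point-file IO, staged runs.

A run goes load/generate -> assign -> count -> requested analyses, with
per-stage logging of points in/out so filter effects stay auditable.  The
same configuration and seed always produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, stats
from .atlas import PointSet, assign_points, count_by_region
from .spots import MatchParams, colabel_rate, dropout_curve, match_dual
from .synthetic_data import (
    CERVICAL,
    LUMBAR,
    UNINJURED,
    CohortDesign,
    build_toy_atlas,
    demo_design,
    simulate_cohort,
)

__all__ = ["ConfigError", "PipelineConfig", "RunReport", "read_points", "run"]

log = logging.getLogger("supraconnect")


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration, before any compute."""


@dataclass
class PipelineConfig:
    """Declarative description of a pipeline run.

    ``mode='synthetic'`` generates a cohort from ``design`` (or the demo
    design) on a toy atlas; ``mode='files'`` reads point CSVs and a
    metadata table from ``paths``.  ``analyses`` toggles the downstream
    stages; parameters carry the matching distance, screening alpha and
    thresholds, and the region exclusion list.
    """

    mode: str = "synthetic"
    seed: int | None = 0
    paths: dict = field(default_factory=dict)
    analyses: tuple[str, ...] = ("index", "coloc", "sparing", "screen")
    atlas_n_regions: int = 8
    atlas_shape: tuple[int, int, int] = (20, 22, 20)
    atlas_voxel_um: float = 25.0
    design: CohortDesign | None = None
    match: MatchParams = field(default_factory=MatchParams)
    alpha: float = 0.05
    high_threshold: float = 5.0
    impaired_threshold: float = 3.5
    exclude_regions: tuple = ()
    count_level: str = "region69"

    VALID_ANALYSES = ("index", "coloc", "sparing", "screen")

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        bad = set(self.analyses) - set(self.VALID_ANALYSES)
        if bad:
            raise ConfigError(f"unknown analyses {sorted(bad)}")
        if self.mode == "synthetic" and self.seed is None:
            raise ConfigError("synthetic mode requires a seed")
        if self.mode == "files":
            for key in ("points_dir", "metadata"):
                if key not in self.paths:
                    raise ConfigError(f"files mode requires paths.{key}")
                if not Path(self.paths[key]).exists():
                    raise ConfigError(f"paths.{key} does not exist: {self.paths[key]}")
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise ConfigError(f"paths.{key} does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        doc = yaml.safe_load(raw) if path.suffix in (".yml", ".yaml") else json.loads(raw)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "design" in doc and doc["design"] is not None:
            doc["design"] = CohortDesign.from_dict(doc["design"])
        if "match" in doc and isinstance(doc["match"], dict):
            doc["match"] = MatchParams(**doc["match"])
        for key in ("analyses", "exclude_regions", "atlas_shape"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"] = self.design.to_dict()
        d["match"] = dataclasses.asdict(self.match)
        return d


# ---------------------------------------------------------------------------
# Point-file IO
# ---------------------------------------------------------------------------


def read_points(
    path: str | Path,
    fmt: str = "csv",
    animal_id: str = "",
    channel: str = "",
    voxel_size_um: tuple[float, float, float] | None = None,
) -> PointSet:
    """Read a detected-nuclei point file.

    ``fmt='csv'`` expects a header with ``x_um,y_um,z_um`` and optional
    ``intensity`` ('.' decimal, UTF-8); coordinates are already in
    micrometres.  ``fmt='cellfinder-xml'`` reads CellCounter-style marker
    XML with voxel-indexed ``MarkerX/Y/Z`` entries, converted to
    micrometres via ``voxel_size_um``.  CSV round-trips losslessly
    through :meth:`PointSet.write_csv`.
    """
    path = Path(path)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"x_um", "y_um", "z_um"}
        if not required <= set(df.columns):
            raise ValueError(
                f"{path}: expected columns x_um,y_um,z_um; got {list(df.columns)}"
            )
        coords = df[["x_um", "y_um", "z_um"]]
        bad = coords.isna().any(axis=1) | ~coords.map(np.isreal).all(axis=1)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed row at line {line}")
        intensity = (
            df["intensity"].to_numpy(dtype=float)
            if "intensity" in df.columns
            else None
        )
        return PointSet(
            animal_id=animal_id,
            channel=channel,
            points=coords.to_numpy(dtype=float),
            intensity=intensity,
        )
    if fmt == "cellfinder-xml":
        if voxel_size_um is None:
            raise ValueError("cellfinder-xml input requires voxel_size_um")
        tree = ET.parse(path)
        pts = []
        for i, marker in enumerate(tree.getroot().iter("Marker")):
            try:
                x = float(marker.findtext("MarkerX"))
                y = float(marker.findtext("MarkerY"))
                z = float(marker.findtext("MarkerZ"))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed Marker #{i + 1}") from exc
            pts.append((x, y, z))
        arr = np.asarray(pts, dtype=float).reshape(-1, 3)
        arr = arr * np.asarray(voxel_size_um, dtype=float)
        return PointSet(animal_id=animal_id, channel=channel, points=arr)
    raise ValueError(f"unknown point format {fmt!r}")


def read_cohort_files(points_dir: str | Path, metadata_path: str | Path):
    """Load a serialized cohort: metadata CSV plus per-animal/channel CSVs."""
    meta = pd.read_csv(metadata_path)
    points_dir = Path(points_dir)
    pointsets = []
    for _, row in meta.iterrows():
        for ch in (LUMBAR, CERVICAL):
            f = points_dir / f"{row['animal_id']}_{ch}.csv"
            if f.exists():
                pointsets.append(
                    read_points(f, "csv", animal_id=str(row["animal_id"]), channel=ch)
                )
    return meta, pointsets


# ---------------------------------------------------------------------------
# Orchestrated run
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    config: dict
    tables: dict[str, pd.DataFrame]
    summary: dict
    outdir: Path | None = None

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.tables):
            self.tables[name].to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(
                {"config": self.config, "summary": self.summary},
                indent=2,
                sort_keys=True,
                default=_json_default,
            )
        )
        self.outdir = outdir
        return outdir


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute a full pipeline run.

    Stages: load or generate the cohort, assign points to atlas regions,
    count per region, then the requested analyses.  Stage failures
    propagate with the stage named; identical config and seed give
    byte-identical outputs.
    """
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    try:
        if config.mode == "synthetic":
            volume, ontology = build_toy_atlas(
                config.atlas_n_regions, config.atlas_shape, config.atlas_voxel_um
            )
            design = config.design or demo_design(seed=config.seed)
            if config.design is None and config.seed is not None:
                design = dataclasses.replace(design, seed=config.seed)
            cohort = simulate_cohort(design, volume, ontology)
            meta = cohort.metadata()
            pointsets = cohort.pointsets()
            log.info("stage simulate: %d animals, %d point sets", len(cohort.animals), len(pointsets))
        else:
            meta, pointsets = read_cohort_files(
                config.paths["points_dir"], config.paths["metadata"]
            )
            volume, ontology = build_toy_atlas(
                config.atlas_n_regions, config.atlas_shape, config.atlas_voxel_um
            )
            cohort = None
            log.info("stage load: %d animals, %d point sets", len(meta), len(pointsets))
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'load/generate' failed: {exc}") from exc

    try:
        assigned = [assign_points(ps, volume) for ps in pointsets]
        n_pts = sum(len(ps) for ps in assigned)
        n_un = sum(int(np.sum(ps.region == 0)) for ps in assigned)
        n_oob = sum(int(np.sum(ps.region < 0)) for ps in assigned)
        log.info("stage assign: %d points, %d unassigned, %d out of bounds", n_pts, n_un, n_oob)
        summary["n_points"] = n_pts
        summary["n_unassigned"] = n_un
        summary["n_out_of_bounds"] = n_oob
    except Exception as exc:
        raise RuntimeError(f"stage 'assign' failed: {exc}") from exc

    try:
        counts = count_by_region(assigned, ontology, level=config.count_level)
        tables["counts"] = counts.table
        log.info("stage count: %d rows at level %s", len(counts.table), counts.level)
    except Exception as exc:
        raise RuntimeError(f"stage 'count' failed: {exc}") from exc

    meta = meta.copy()
    meta["animal_id"] = meta["animal_id"].astype(str)
    uninjured_ids = set(meta.loc[meta["condition"] == UNINJURED, "animal_id"])
    injured_meta = meta[meta["condition"] != UNINJURED]

    from .atlas import RegionCounts

    def subset(ids) -> RegionCounts:
        t = counts.table[counts.table["animal"].astype(str).isin(ids)]
        return RegionCounts(table=t.reset_index(drop=True), level=counts.level)

    if "index" in config.analyses:
        try:
            baseline = subset(uninjured_ids) if uninjured_ids else counts
            idx = metrics.lumbar_projection_index(baseline)
            tables["lumbar_index_per_region"] = idx.per_region
            tables["lumbar_index_per_animal"] = idx.per_animal
            summary["brainwide_lumbar_index"] = idx.brainwide_mean
            summary["brainwide_lumbar_index_sem"] = idx.brainwide_sem
            log.info("stage index: brain-wide lumbar index %.3f", idx.brainwide_mean)
        except Exception as exc:
            raise RuntimeError(f"stage 'index' failed: {exc}") from exc

    if "coloc" in config.analyses:
        try:
            rows = []
            by_animal = {}
            for ps in assigned:
                by_animal.setdefault(ps.animal_id, {})[ps.channel] = ps
            for aid in sorted(by_animal):
                if aid not in uninjured_ids and uninjured_ids:
                    continue
                chans = by_animal[aid]
                if LUMBAR in chans and CERVICAL in chans:
                    m = match_dual(chans[LUMBAR], chans[CERVICAL], config.match)
                    cl = colabel_rate(m, chans[LUMBAR])
                    overall = cl[cl["region"] == "overall"].iloc[0]
                    rows.append(
                        {
                            "animal": aid,
                            "n_lumbar": overall["n_lumbar"],
                            "n_dual": overall["n_dual"],
                            "dual_rate": overall["rate"],
                        }
                    )
            coloc = pd.DataFrame(rows)
            tables["colabel_per_animal"] = coloc
            if len(coloc):
                summary["mean_dual_rate"] = float(coloc["dual_rate"].mean())
            log.info("stage coloc: %d animals matched", len(coloc))
        except Exception as exc:
            raise RuntimeError(f"stage 'coloc' failed: {exc}") from exc

    sparing_table = None
    if ("sparing" in config.analyses or "screen" in config.analyses) and len(injured_meta):
        try:
            if not uninjured_ids:
                raise ValueError("sparing analysis needs an uninjured reference arm")
            ref = subset(uninjured_ids)
            # restrict both cohorts to the lumbar channel: injured arms are
            # traced from a single lumbar injection
            ref_l = RegionCounts(
                table=ref.table[ref.table["channel"] == LUMBAR].reset_index(drop=True),
                level=ref.level,
            )
            inj = subset(set(injured_meta["animal_id"]))
            inj_l = RegionCounts(
                table=inj.table[inj.table["channel"] == LUMBAR].reset_index(drop=True),
                level=inj.level,
            )
            sparing_table = metrics.sparing_index(
                inj_l, ref_l, exclude_regions=config.exclude_regions
            )
            if "sparing" in config.analyses:
                tables["sparing_per_animal_region"] = sparing_table.per_animal_region
                tables["sparing_per_region"] = sparing_table.per_region
                tables["sparing_brainwide"] = sparing_table.brainwide
                summary["mean_brainwide_sparing_pct"] = float(
                    sparing_table.brainwide["sparing_pct"].mean()
                )
            log.info("stage sparing: %d injured animals", sparing_table.brainwide.shape[0])
        except Exception as exc:
            raise RuntimeError(f"stage 'sparing' failed: {exc}") from exc

    if "screen" in config.analyses and sparing_table is not None:
        try:
            split = stats.split_by_bms(
                injured_meta,
                high_threshold=config.high_threshold,
                impaired_threshold=config.impaired_threshold,
            )
            tables["bms_groups"] = split
            groups = dict(zip(split["animal_id"].astype(str), split["group"]))
            n_hi = sum(g == stats.HIGH for g in groups.values())
            n_lo = sum(g == stats.IMPAIRED for g in groups.values())
            if n_hi >= 2 and n_lo >= 2:
                comp = stats.screen_regions(sparing_table, groups, alpha=config.alpha)
                tables["screening"] = comp.table
                summary["screening_m"] = comp.m
                summary["screening_threshold"] = comp.adjusted_threshold
                summary["significant_regions"] = comp.significant_regions
                log.info(
                    "stage screen: m=%d, threshold %.5f, %d significant",
                    comp.m,
                    comp.adjusted_threshold,
                    len(comp.significant_regions),
                )
            else:
                log.info("stage screen: skipped (fewer than 2 animals per group)")
        except Exception as exc:
            raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    report = RunReport(config=config.to_dict(), tables=tables, summary=summary)
    if outdir is not None:
        report.write(outdir)
    return report
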