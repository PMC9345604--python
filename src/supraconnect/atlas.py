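"""Atlas-space bookkeeping: region ontologies, annotation volumes, and counts.

Detected nuclei arrive as point clouds registered to a common atlas space
(micrometre coordinates, origin at the array corner).  This module assigns
each point to the brain region of its containing voxel, splits counts by
hemisphere, and collapses leaf-level counts upward through the region
hierarchy: leaf regions -> reporting regions (the level at which results
are tabulated) -> a small set of summary categories used in figures.

Conventions
-----------
* Coordinates are micrometres in atlas space, zero-based voxels, and each
  voxel owns the half-open cube ``[v * s, (v + 1) * s)`` along every axis.
* Label 0 is reserved for outside-brain voxels; points landing there are
  flagged unassigned rather than dropped.
* Hemispheres are split by a midline voxel plane along a declared axis;
  points exactly on the midline are assigned to the left hemisphere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "OntologyError",
    "RegionRecord",
    "RegionOntology",
    "AnnotationVolume",
    "PointSet",
    "RegionCounts",
    "load_ontology",
    "assign_points",
    "count_by_region",
    "hemisphere_symmetry",
    "LEVELS",
]

#: Valid aggregation levels for region counts.
LEVELS = ("leaf", "region69", "summary25")

UNASSIGNED = "unassigned"
OUT_OF_BOUNDS = "out_of_bounds"


class OntologyError(ValueError):
    """Raised when a region ontology document is malformed."""


@dataclass(frozen=True)
class RegionRecord:
    """One node of the region hierarchy."""

    id: int
    acronym: str
    name: str
    parent_id: int | None
    level: int


@dataclass
class RegionOntology:
    """Hierarchical region graph plus the two collapse maps.

    Parameters
    ----------
    regions
        Mapping from integer region id to :class:`RegionRecord`.
    collapse_69
        Maps every countable leaf id to its reporting-region id.
    collapse_25
        Maps every reporting-region id to its summary-category id.
    """

    regions: dict[int, RegionRecord]
    collapse_69: dict[int, int]
    collapse_25: dict[int, int]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        for rid, rec in self.regions.items():
            if rec.parent_id is not None and rec.parent_id not in self.regions:
                raise OntologyError(
                    f"region {rid} ({rec.acronym!r}) has dangling parent "
                    f"{rec.parent_id}"
                )
        self._check_acyclic()
        for leaf, rep in self.collapse_69.items():
            if leaf not in self.regions:
                raise OntologyError(f"collapse_69 references unknown leaf {leaf}")
            if rep not in self.regions:
                raise OntologyError(
                    f"collapse_69 maps leaf {leaf} to unknown region {rep}"
                )
        for rep in set(self.collapse_69.values()):
            if rep not in self.collapse_25:
                raise OntologyError(
                    f"reporting region {rep} missing from collapse_25: "
                    "summary collapse must be total on reporting regions"
                )
        for rep, summ in self.collapse_25.items():
            if rep not in self.regions:
                raise OntologyError(f"collapse_25 references unknown region {rep}")
            if summ not in self.regions:
                raise OntologyError(
                    f"collapse_25 maps region {rep} to unknown summary {summ}"
                )

    def _check_acyclic(self) -> None:
        for rid in self.regions:
            seen = set()
            cur: int | None = rid
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"parent cycle through region {cur}")
                seen.add(cur)
                cur = self.regions[cur].parent_id

    # -- queries -------------------------------------------------------

    @property
    def leaves(self) -> list[int]:
        """Ids of regions that are nobody's parent."""
        parents = {r.parent_id for r in self.regions.values() if r.parent_id is not None}
        return sorted(set(self.regions) - parents)

    def ancestors(self, rid: int) -> list[int]:
        out = []
        cur = self.regions[rid].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.regions[cur].parent_id
        return out

    def collapse(self, leaf_id: int, level: str) -> int:
        """Map a leaf id to its id at ``level``."""
        if level == "leaf":
            return leaf_id
        rep = self.collapse_69.get(leaf_id, leaf_id)
        if level == "region69":
            return rep
        if level == "summary25":
            return self.collapse_25[rep]
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")

    def acronym(self, rid) -> str:
        rec = self.regions.get(rid)
        return rec.acronym if rec is not None else str(rid)


@dataclass
class AnnotationVolume:
    """3D integer label grid with voxel size and hemisphere metadata.

    ``labels`` is indexed ``[ix, iy, iz]`` so that a point ``(x, y, z)`` in
    micrometres falls in voxel ``floor(coord / voxel_size)`` per axis.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    midline: int
    midline_axis: int = 0
    orientation: str = "asr"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("annotation volume must be 3D")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not 0 <= self.midline <= self.labels.shape[self.midline_axis]:
            raise ValueError("midline plane outside array bounds")

    @property
    def midline_um(self) -> float:
        return self.midline * self.voxel_size_um[self.midline_axis]

    def region_voxel_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class PointSet:
    """Detected nuclei for one animal and channel.

    ``points`` is an (n, 3) float array of (x, y, z) in micrometres;
    ``intensity`` an (n,) array of nonnegative arbitrary units.  After
    :func:`assign_points`, ``region`` holds the leaf label per point (0 for
    unassigned, -1 for out of bounds) and ``hemisphere`` 'L'/'R'.
    """

    animal_id: str
    channel: str
    points: np.ndarray
    intensity: np.ndarray | None = None
    region: np.ndarray | None = None
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.intensity is None:
            self.intensity = np.ones(len(self.points))
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if len(self.intensity) != len(self.points):
            raise ValueError("intensity length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["x_um", "y_um", "z_um"])
        df["intensity"] = self.intensity
        if self.region is not None:
            df["region"] = self.region
        if self.hemisphere is not None:
            df["hemisphere"] = self.hemisphere
        return df

    def write_csv(self, path: str | Path) -> None:
        # %.17g keeps float64 coordinates exact through a CSV round trip
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class RegionCounts:
    """Long-format per-animal x region x channel x hemisphere counts.

    ``table`` has columns (animal, region, channel, hemisphere, count);
    ``level`` tags the aggregation level; ``flagged`` records unassigned /
    out-of-bounds tallies per (animal, channel) so that totals are
    auditable: sum over regions + flagged = points seen.
    """

    table: pd.DataFrame
    level: str
    flagged: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["animal", "channel", "kind", "count"]
        )
    )

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        required = {"animal", "region", "channel", "hemisphere", "count"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"counts table missing columns {sorted(missing)}")
        if (self.table["count"] < 0).any():
            raise ValueError("counts must be nonnegative")

    def totals(self, by: Sequence[str] = ("animal", "channel")) -> pd.Series:
        return self.table.groupby(list(by), sort=True)["count"].sum()

    def pivot(self, channel: str | None = None) -> pd.DataFrame:
        """animal x region matrix of counts (hemispheres pooled)."""
        t = self.table
        if channel is not None:
            t = t[t["channel"] == channel]
        return (
            t.groupby(["animal", "region"], sort=True)["count"]
            .sum()
            .unstack(fill_value=0)
        )

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ontology loading
# ---------------------------------------------------------------------------


def _flatten_structure_graph(doc) -> list[dict]:
    """Accept Allen-style documents: nested (``children``) or flat lists."""
    if isinstance(doc, dict) and "msg" in doc:
        doc = doc["msg"]
    if isinstance(doc, dict):
        doc = [doc]
    flat: list[dict] = []

    def walk(node: dict, parent: int | None) -> None:
        rec = dict(node)
        if "parent_structure_id" not in rec:
            rec["parent_structure_id"] = parent
        flat.append(rec)
        for child in node.get("children") or []:
            walk(child, node["id"])

    for root in doc:
        if "children" in root:
            walk(root, root.get("parent_structure_id"))
        else:
            flat.append(dict(root))
    return flat


def load_ontology(
    document,
    *,
    leaf_to_reporting: Mapping[int, int] | None = None,
    reporting_to_summary: Mapping[int, int] | None = None,
) -> RegionOntology:
    """Build a validated :class:`RegionOntology` from a structure-graph document.

    Parameters
    ----------
    document
        A path to a JSON file, or the parsed document itself: either a
        nested tree (each node carrying ``id``, ``acronym``, ``name`` and a
        ``children`` list) or a flat record list with
        ``parent_structure_id`` links, the dialect used by the Allen
        structure graph.
    leaf_to_reporting, reporting_to_summary
        Explicit collapse tables.  When omitted they are derived from the
        hierarchy itself: each leaf reports as itself, and its summary
        category is its ancestor one level below the root.  The derivation
        matches the shipped toy atlas; for a real Allen graph, pass the
        curated grouping tables (see ``data/allen_summary_template.json``
        for an editable starting point).

    Raises
    ------
    OntologyError
        On duplicate ids, dangling parents, cycles, or a non-total
        collapse, naming the offending id.
    """
    if isinstance(document, (str, Path)):
        document = json.loads(Path(document).read_text())
    flat = _flatten_structure_graph(document)

    regions: dict[int, RegionRecord] = {}
    for rec in flat:
        rid = int(rec["id"])
        if rid in regions:
            raise OntologyError(f"duplicate region id {rid}")
        parent = rec.get("parent_structure_id")
        regions[rid] = RegionRecord(
            id=rid,
            acronym=str(rec.get("acronym", rid)),
            name=str(rec.get("name", rec.get("acronym", rid))),
            parent_id=None if parent is None else int(parent),
            level=0,
        )
    # depth from root, for reporting only
    def depth(rid: int, _seen=None) -> int:
        _seen = _seen or set()
        d = 0
        cur = regions[rid].parent_id
        while cur is not None:
            if cur not in regions:
                raise OntologyError(
                    f"region {rid} ({regions[rid].acronym!r}) has dangling "
                    f"parent {cur}"
                )
            if cur in _seen:
                raise OntologyError(f"parent cycle through region {cur}")
            _seen.add(cur)
            d += 1
            cur = regions[cur].parent_id
        return d

    regions = {
        rid: replace(rec, level=depth(rid)) for rid, rec in regions.items()
    }

    parents = {r.parent_id for r in regions.values() if r.parent_id is not None}
    leaves = sorted(set(regions) - parents)

    if leaf_to_reporting is None:
        leaf_to_reporting = {leaf: leaf for leaf in leaves}
    if reporting_to_summary is None:
        reporting_to_summary = {}
        for rep in sorted(set(leaf_to_reporting.values())):
            if rep not in regions:
                raise OntologyError(f"collapse references unknown region {rep}")
            chain = [rep] + [a for a in _ancestors(regions, rep)]
            # ancestor one level below the root (or the node itself at a
            # 2-level hierarchy rooted directly above the leaves)
            non_root = [c for c in chain if regions[c].parent_id is not None]
            reporting_to_summary[rep] = non_root[-1] if non_root else rep

    return RegionOntology(
        regions=regions,
        collapse_69=dict(leaf_to_reporting),
        collapse_25=dict(reporting_to_summary),
    )


def _ancestors(regions: dict[int, RegionRecord], rid: int) -> list[int]:
    out = []
    cur = regions[rid].parent_id
    while cur is not None:
        out.append(cur)
        cur = regions[cur].parent_id
    return out


# ---------------------------------------------------------------------------
# Point assignment
# ---------------------------------------------------------------------------


def assign_points(points: PointSet, volume: AnnotationVolume) -> PointSet:
    """Assign every point to the label of its containing voxel.

    Voxel ownership is half-open: a coordinate ``c`` on axis ``a`` belongs
    to voxel ``floor(c / voxel_size[a])``.  Points in label-0 voxels keep
    region 0 (unassigned); points outside the array get region -1
    (out of bounds).  Neither is dropped.  Hemisphere is the side of the
    midline voxel plane along ``volume.midline_axis``; a point exactly on
    the midline goes to the left hemisphere.

    Returns a new :class:`PointSet`; the input is not modified.
    """
    coords = points.points
    vs = np.asarray(volume.voxel_size_um, dtype=float)
    idx = np.floor(coords / vs).astype(np.int64)
    shape = np.asarray(volume.labels.shape)
    in_bounds = np.all((idx >= 0) & (idx < shape), axis=1)

    region = np.full(len(coords), -1, dtype=np.int64)
    if in_bounds.any():
        ii = idx[in_bounds]
        region[in_bounds] = volume.labels[ii[:, 0], ii[:, 1], ii[:, 2]]

    ax = volume.midline_axis
    side = np.where(coords[:, ax] <= volume.midline_um, "L", "R")

    return PointSet(
        animal_id=points.animal_id,
        channel=points.channel,
        points=coords.copy(),
        intensity=np.asarray(points.intensity).copy(),
        region=region,
        hemisphere=side,
    )


# ---------------------------------------------------------------------------
# Counting and collapse
# ---------------------------------------------------------------------------


def count_by_region(
    assigned: PointSet | Iterable[PointSet],
    ontology: RegionOntology,
    level: str = "region69",
) -> RegionCounts:
    """Tally assigned points per (animal, region, channel, hemisphere).

    Counts are produced at the requested ``level`` by pushing each point's
    leaf label through the ontology collapse maps.  Unassigned (label 0)
    and out-of-bounds (-1) points are excluded from region rows but
    reported in the ``flagged`` table, so that for every animal/channel
    ``sum(region counts) + sum(flagged) == n points``.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if isinstance(assigned, PointSet):
        assigned = [assigned]

    rows = []
    flags = []
    for ps in assigned:
        if ps.region is None:
            raise ValueError(
                f"point set {ps.animal_id}/{ps.channel} has no region "
                "assignment; run assign_points first"
            )
        region = np.asarray(ps.region)
        hemi = np.asarray(ps.hemisphere)
        ok = region > 0
        n_unassigned = int(np.sum(region == 0))
        n_oob = int(np.sum(region < 0))
        if n_unassigned:
            flags.append((ps.animal_id, ps.channel, UNASSIGNED, n_unassigned))
        if n_oob:
            flags.append((ps.animal_id, ps.channel, OUT_OF_BOUNDS, n_oob))
        if ok.any():
            collapsed = np.array(
                [ontology.collapse(int(r), level) for r in region[ok]]
            )
            df = pd.DataFrame(
                {"region": collapsed, "hemisphere": hemi[ok]}
            )
            grouped = (
                df.groupby(["region", "hemisphere"], sort=True)
                .size()
                .reset_index(name="count")
            )
            grouped.insert(0, "animal", ps.animal_id)
            grouped.insert(2, "channel", ps.channel)
            rows.append(grouped)

    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["animal", "region", "channel", "hemisphere", "count"])
    )
    flagged = pd.DataFrame(flags, columns=["animal", "channel", "kind", "count"])
    return RegionCounts(table=table, level=level, flagged=flagged)


def collapse_counts(counts: RegionCounts, ontology: RegionOntology, level: str) -> RegionCounts:
    """Re-aggregate an existing counts table to a coarser level."""
    order = {lvl: i for i, lvl in enumerate(LEVELS)}
    if order[level] < order[counts.level]:
        raise ValueError(f"cannot refine {counts.level} counts to {level}")
    t = counts.table.copy()
    if counts.level == "leaf":
        t["region"] = [ontology.collapse(int(r), level) for r in t["region"]]
    elif counts.level == "region69" and level == "summary25":
        t["region"] = [ontology.collapse_25[int(r)] for r in t["region"]]
    t = (
        t.groupby(["animal", "region", "channel", "hemisphere"], sort=True)["count"]
        .sum()
        .reset_index()
    )
    return RegionCounts(table=t, level=level, flagged=counts.flagged.copy())


# ---------------------------------------------------------------------------
# Hemisphere symmetry
# ---------------------------------------------------------------------------


def hemisphere_symmetry(counts: RegionCounts, conf_level: float = 0.95) -> pd.DataFrame:
    """Left-fraction L/(L+R) per region with a binomial confidence interval.

    Returns one row per (region, channel) pooled over animals, with
    columns left, right, left_fraction, ci_low, ci_high, undefined.  Rows
    with ``L + R == 0`` are flagged undefined and carry NaN fractions;
    callers should exclude them from summaries.
    """
    t = counts.table
    wide = (
        t.groupby(["region", "channel", "hemisphere"], sort=True)["count"]
        .sum()
        .unstack(fill_value=0)
    )
    left = wide.get("L", pd.Series(0, index=wide.index)).to_numpy()
    right = wide.get("R", pd.Series(0, index=wide.index)).to_numpy()
    total = left + right
    frac = np.divide(left, total, out=np.full_like(left, np.nan, dtype=float), where=total > 0)
    lo = np.full_like(frac, np.nan)
    hi = np.full_like(frac, np.nan)
    nz = total > 0
    if nz.any():
        lo[nz], hi[nz] = proportion_confint(
            left[nz], total[nz], alpha=1 - conf_level, method="wilson"
        )
    out = wide.reset_index()[["region", "channel"]]
    out["left"] = left
    out["right"] = right
    out["left_fraction"] = frac
    out["ci_low"] = lo
    out["ci_high"] = hi
    out["undefined"] = ~nz
    return out
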