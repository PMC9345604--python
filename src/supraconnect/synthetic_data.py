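"""Synthetic cohorts with the statistical structure of retrograde tracing studies.

The generator stands in for the wet-lab side of a brain-wide supraspinal
tracing experiment: animals receive retrograde label from lumbar and/or
cervical spinal cord, nuclei are detected per brain region, injuries thin
the labeled populations, and a locomotor score (Basso Mouse Scale, 0-9)
tracks how much of the behavior-relevant projections survived.  Everything
downstream (region counting, colocalization, sparing indices, group
screening) can therefore be exercised against known ground truth.

Generative model
----------------
* Per-region nucleus counts are negative binomial with a shared size
  (overdispersion) parameter, capturing inter-animal spread beyond
  Poisson; ``dispersion=inf`` recovers Poisson.
* Each lumbar-projecting nucleus is independently dual-projecting
  (also labeled from cervical cord) with a region-specific probability.
* Intensities are lognormal per channel.  In dual nuclei the two
  channels' log-intensities are correlated, and the cervical intensity is
  multiplied by a dimming factor in (0, 1] — dual cells carry dimmer
  cervical label, which is what makes detection-threshold dropout bite.
* Injury arms thin every region binomially by a severity- and
  region-specific sparing fraction.
* The behavior score is a monotone map of the weighted realized sparing
  of designated regions plus Gaussian noise, clipped to [0, 9].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .atlas import AnnotationVolume, PointSet, RegionOntology, load_ontology

__all__ = [
    "LUMBAR",
    "CERVICAL",
    "UNINJURED",
    "RegionSpec",
    "IntensityModel",
    "BehaviorLink",
    "CohortDesign",
    "Animal",
    "GroundTruth",
    "Cohort",
    "ImageStack",
    "GfapSection",
    "build_toy_atlas",
    "demo_design",
    "simulate_cohort",
    "simulate_nuclei_stack",
    "simulate_gfap_section",
]

#: Channel names: the lumbar-injected green and cervical-injected red label.
LUMBAR = "lumbar"
CERVICAL = "cervical"
#: Condition name of the baseline arm.
UNINJURED = "uninjured"


# ---------------------------------------------------------------------------
# Toy atlas
# ---------------------------------------------------------------------------


def build_toy_atlas(
    n_leaf_regions: int,
    shape: tuple[int, int, int] = (20, 20, 20),
    voxel_size_um: float = 25.0,
) -> tuple[AnnotationVolume, RegionOntology]:
    """Build a small annotation volume plus matching two-level ontology.

    The volume has a one-voxel outside-brain border (label 0) and is split
    into ``n_leaf_regions`` contiguous slabs along y, mirrored across a
    midline plane on x so every region has a left and a right part.  The
    ontology groups consecutive leaf pairs under summary nodes, giving a
    root -> summary -> leaf hierarchy whose derived collapse maps are
    deterministic.

    Raises
    ------
    ValueError
        If the requested shape cannot give every region at least 8 voxels.
    """
    if n_leaf_regions < 2:
        raise ValueError("need at least 2 leaf regions")
    nx, ny, nz = shape
    if nx < 4 or ny < n_leaf_regions + 2 or nz < 3:
        raise ValueError(
            f"shape {shape} too small for {n_leaf_regions} regions: need "
            f"nx >= 4, ny >= n + 2, nz >= 3"
        )
    mid = nx // 2
    labels = np.zeros(shape, dtype=np.int32)
    interior_y = ny - 2
    edges = np.linspace(1, ny - 1, n_leaf_regions + 1).astype(int)
    half_width = mid - 1  # x in [1, mid)
    for i in range(n_leaf_regions):
        y0, y1 = edges[i], edges[i + 1]
        if y1 <= y0:
            raise ValueError(f"shape {shape} too small: empty slab for region {i + 1}")
        labels[1:mid, y0:y1, 1 : nz - 1] = i + 1
        # mirror: x -> nx - 1 - x
        labels[nx - mid : nx - 1, y0:y1, 1 : nz - 1] = i + 1
    voxels_per_region = 2 * half_width * (nz - 2)
    if voxels_per_region * interior_y // n_leaf_regions < 8:
        raise ValueError(f"shape {shape} too small: regions get < 8 voxels")

    n_summaries = math.ceil(n_leaf_regions / 2)
    doc = {
        "id": 1000,
        "acronym": "root",
        "name": "root",
        "parent_structure_id": None,
        "children": [
            {
                "id": 100 + s,
                "acronym": f"SUM{s + 1}",
                "name": f"summary category {s + 1}",
                "children": [
                    {
                        "id": leaf,
                        "acronym": f"R{leaf}",
                        "name": f"toy region {leaf}",
                        "children": [],
                    }
                    for leaf in range(1, n_leaf_regions + 1)
                    if (leaf - 1) // 2 == s
                ],
            }
            for s in range(n_summaries)
        ],
    }
    ontology = load_ontology(doc)
    volume = AnnotationVolume(
        labels=labels,
        voxel_size_um=(voxel_size_um,) * 3,
        midline=mid,
        midline_axis=0,
    )
    return volume, ontology


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """Ground-truth generative parameters for one brain region.

    ``mean_count`` is the expected number of lumbar-projecting nuclei in
    an uninjured animal; ``dual_probability`` the chance each of them is
    also labeled from cervical cord; ``cervical_mean_count`` the expected
    number of cervical-only nuclei (defaults to ``mean_count``, a balanced
    region).
    """

    region_id: int
    mean_count: float
    dual_probability: float
    cervical_mean_count: float | None = None

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ValueError(f"region {self.region_id}: mean_count must be >= 0")
        if not 0.0 <= self.dual_probability <= 1.0:
            raise ValueError(
                f"region {self.region_id}: dual_probability must be in [0, 1]"
            )
        if self.cervical_mean_count is not None and self.cervical_mean_count < 0:
            raise ValueError(
                f"region {self.region_id}: cervical_mean_count must be >= 0"
            )

    @property
    def cervical_mean(self) -> float:
        return (
            self.mean_count
            if self.cervical_mean_count is None
            else self.cervical_mean_count
        )

    @property
    def expected_lumbar_index(self) -> float:
        """E[lumbar] / (E[lumbar] + E[cervical detections]) under the model."""
        lum = self.mean_count
        cerv = self.cervical_mean + self.dual_probability * self.mean_count
        return lum / (lum + cerv) if lum + cerv > 0 else float("nan")


@dataclass(frozen=True)
class IntensityModel:
    """Correlated lognormal two-channel intensity model."""

    lumbar_location: float = 6.0
    lumbar_scale: float = 0.5
    cervical_location: float = 6.0
    cervical_scale: float = 0.5
    correlation: float = 0.6
    dual_cervical_dimming: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")
        if not 0.0 < self.dual_cervical_dimming <= 1.0:
            raise ValueError("dual_cervical_dimming must be in (0, 1]")
        if self.lumbar_scale <= 0 or self.cervical_scale <= 0:
            raise ValueError("lognormal scales must be positive")


@dataclass(frozen=True)
class BehaviorLink:
    """Which regions' sparing drives the locomotor score."""

    region_ids: tuple[int, ...]
    weights: tuple[float, ...]
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.weights):
            raise ValueError("behavior_link weights must match region_ids")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortDesign:
    """Full generative specification of a multi-arm tracing cohort.

    ``severity_sparing`` maps each injury-severity arm name to a
    per-region sparing fraction in [0, 1] (fraction of labeled neurons
    surviving the injury); an ``uninjured`` arm with sparing 1 everywhere
    is always generated in addition.  ``dispersion`` is the negative
    binomial size parameter shared across regions (``inf`` = Poisson).
    """

    regions: list[RegionSpec]
    dispersion: float = 8.0
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    severity_sparing: dict[str, dict[int, float]] = field(default_factory=dict)
    behavior_link: BehaviorLink | None = None
    n_animals: int = 4
    seed: int = 0
    jitter_sd_um: float = 0.5
    quantize_bms: bool = False

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (inf for Poisson)")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids in design")
        known = set(ids)
        for sev, table in self.severity_sparing.items():
            for rid, frac in table.items():
                if rid not in known:
                    raise ValueError(
                        f"severity {sev!r} references unknown region {rid}"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"severity {sev!r}, region {rid}: sparing fraction "
                        f"{frac} outside [0, 1]"
                    )
        if self.behavior_link is not None:
            missing = set(self.behavior_link.region_ids) - known
            if missing:
                raise ValueError(
                    f"behavior_link references unknown regions {sorted(missing)}"
                )

    def validate_against(self, ontology: RegionOntology, volume: AnnotationVolume) -> None:
        present = set(np.unique(volume.labels).tolist()) - {0}
        for spec in self.regions:
            if spec.region_id not in present:
                raise ValueError(
                    f"design region {spec.region_id} absent from annotation volume"
                )
            if spec.region_id not in ontology.regions:
                raise ValueError(
                    f"design region {spec.region_id} absent from ontology"
                )

    @property
    def arms(self) -> list[str]:
        return [UNINJURED] + sorted(self.severity_sparing)

    def sparing_fraction(self, condition: str, region_id: int) -> float:
        if condition == UNINJURED:
            return 1.0
        return self.severity_sparing[condition].get(region_id, 1.0)

    def to_dict(self) -> dict:
        return {
            "regions": [
                {
                    "region_id": r.region_id,
                    "mean_count": r.mean_count,
                    "dual_probability": r.dual_probability,
                    "cervical_mean_count": r.cervical_mean_count,
                }
                for r in self.regions
            ],
            "dispersion": self.dispersion,
            "intensity_model": vars(self.intensity_model).copy(),
            "severity_sparing": {
                s: {int(k): v for k, v in t.items()}
                for s, t in self.severity_sparing.items()
            },
            "behavior_link": None
            if self.behavior_link is None
            else {
                "region_ids": list(self.behavior_link.region_ids),
                "weights": list(self.behavior_link.weights),
                "noise_sd": self.behavior_link.noise_sd,
            },
            "n_animals": self.n_animals,
            "seed": self.seed,
            "jitter_sd_um": self.jitter_sd_um,
            "quantize_bms": self.quantize_bms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortDesign":
        bl = d.get("behavior_link")
        return cls(
            regions=[RegionSpec(**r) for r in d["regions"]],
            dispersion=d.get("dispersion", 8.0),
            intensity_model=IntensityModel(**d.get("intensity_model", {})),
            severity_sparing={
                s: {int(k): v for k, v in t.items()}
                for s, t in d.get("severity_sparing", {}).items()
            },
            behavior_link=None
            if bl is None
            else BehaviorLink(
                region_ids=tuple(bl["region_ids"]),
                weights=tuple(bl["weights"]),
                noise_sd=bl.get("noise_sd", 0.5),
            ),
            n_animals=d.get("n_animals", 4),
            seed=d.get("seed", 0),
            jitter_sd_um=d.get("jitter_sd_um", 0.5),
            quantize_bms=d.get("quantize_bms", False),
        )


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------


@dataclass
class Animal:
    animal_id: str
    condition: str
    severity: str
    bms_score: float
    pointsets: dict[str, PointSet]


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``per_region`` has one row per (animal, region) with the realized true
    lumbar count, cervical-only count, dual count, and realized sparing
    fraction.  ``dual_mask`` maps animal_id to a boolean array over that
    animal's lumbar points marking true dual-projecting nuclei.
    """

    design: CohortDesign
    per_region: pd.DataFrame
    dual_mask: dict[str, np.ndarray]


@dataclass
class Cohort:
    animals: list[Animal]
    ground_truth: GroundTruth

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "animal_id": a.animal_id,
                    "condition": a.condition,
                    "severity": a.severity,
                    "bms": a.bms_score,
                }
                for a in self.animals
            ]
        )

    def pointsets(self, channel: str | None = None) -> list[PointSet]:
        out = []
        for a in self.animals:
            for ch, ps in a.pointsets.items():
                if channel is None or ch == channel:
                    out.append(ps)
        return out

    def write(self, directory: str | Path) -> None:
        """Serialize: one CSV per animal/channel, a metadata CSV, design JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for a in self.animals:
            for ch, ps in a.pointsets.items():
                ps.write_csv(directory / f"{a.animal_id}_{ch}.csv")
        self.metadata().to_csv(directory / "metadata.csv", index=False)
        (directory / "design.json").write_text(
            json.dumps(self.ground_truth.design.to_dict(), indent=2, sort_keys=True)
        )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _negbin(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    if not np.isfinite(size_param):
        return rng.poisson(mean, size=n)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _place_in_region(
    rng: np.random.Generator,
    region_voxels: np.ndarray,
    n: int,
    voxel_size: np.ndarray,
) -> np.ndarray:
    """Uniform placement: pick a region voxel, then uniform inside it."""
    if n == 0:
        return np.zeros((0, 3))
    picks = rng.integers(0, len(region_voxels), size=n)
    corners = region_voxels[picks].astype(float)
    offsets = rng.uniform(0.0, 1.0, size=(n, 3))
    return (corners + offsets) * voxel_size


def simulate_cohort(
    design: CohortDesign,
    volume: AnnotationVolume,
    ontology: RegionOntology,
) -> Cohort:
    """Draw a full multi-arm cohort from the generative model.

    For every arm (uninjured plus each severity) and animal: per-region
    lumbar counts are negative binomial, each lumbar nucleus is dual with
    the region's probability, cervical-only counts are drawn likewise,
    injury arms thin every population binomially by the severity's sparing
    fraction, nuclei are placed uniformly within their region's voxels,
    and intensities follow the correlated lognormal model with cervical
    dimming in dual cells.  The behavior score is the weighted realized
    sparing of the linked regions mapped onto [0, 9] plus noise.

    The same design (seed included) always yields an identical cohort.
    """
    design.validate_against(ontology, volume)
    rng = np.random.default_rng(design.seed)
    im = design.intensity_model
    voxel_size = np.asarray(volume.voxel_size_um, dtype=float)

    region_voxels = {
        spec.region_id: np.argwhere(volume.labels == spec.region_id)
        for spec in design.regions
    }

    cov = np.array(
        [
            [im.lumbar_scale**2, im.correlation * im.lumbar_scale * im.cervical_scale],
            [im.correlation * im.lumbar_scale * im.cervical_scale, im.cervical_scale**2],
        ]
    )
    mean_log = np.array([im.lumbar_location, im.cervical_location])

    animals: list[Animal] = []
    gt_rows: list[dict] = []
    dual_masks: dict[str, np.ndarray] = {}

    for condition in design.arms:
        for k in range(design.n_animals):
            animal_id = f"{condition}_{k + 1:02d}"
            lum_pts, lum_int, lum_dual = [], [], []
            cerv_pts, cerv_int = [], []
            spared_fracs, weights_acc = {}, {}

            for spec in design.regions:
                rid = spec.region_id
                frac = design.sparing_fraction(condition, rid)
                n_lum0 = int(_negbin(rng, spec.mean_count, design.dispersion, 1)[0])
                n_cerv0 = int(_negbin(rng, spec.cervical_mean, design.dispersion, 1)[0])
                # injury thins both descending populations
                n_lum = int(rng.binomial(n_lum0, frac)) if frac < 1.0 else n_lum0
                n_cerv = int(rng.binomial(n_cerv0, frac)) if frac < 1.0 else n_cerv0
                dual = rng.random(n_lum) < spec.dual_probability
                n_dual = int(dual.sum())

                pts = _place_in_region(rng, region_voxels[rid], n_lum, voxel_size)
                z = rng.multivariate_normal(mean_log, cov, size=n_lum, method="cholesky")
                i_lum = np.exp(z[:, 0])
                i_cerv_dual = im.dual_cervical_dimming * np.exp(z[dual, 1])

                cerv_only_pts = _place_in_region(
                    rng, region_voxels[rid], n_cerv, voxel_size
                )
                i_cerv_only = np.exp(
                    rng.normal(im.cervical_location, im.cervical_scale, size=n_cerv)
                )
                jitter = rng.normal(0.0, design.jitter_sd_um, size=(n_dual, 3))

                lum_pts.append(pts)
                lum_int.append(i_lum)
                lum_dual.append(dual)
                cerv_pts.append(pts[dual] + jitter)
                cerv_int.append(i_cerv_dual)
                cerv_pts.append(cerv_only_pts)
                cerv_int.append(i_cerv_only)

                realized = n_lum / n_lum0 if n_lum0 > 0 else frac
                spared_fracs[rid] = realized
                gt_rows.append(
                    {
                        "animal": animal_id,
                        "condition": condition,
                        "region": rid,
                        "true_lumbar": n_lum,
                        "true_cervical_only": n_cerv,
                        "true_dual": n_dual,
                        "sparing_fraction": frac,
                        "realized_sparing": realized,
                    }
                )

            lum_points = np.concatenate(lum_pts) if lum_pts else np.zeros((0, 3))
            dual_mask = (
                np.concatenate(lum_dual) if lum_dual else np.zeros(0, dtype=bool)
            )
            pointsets = {
                LUMBAR: PointSet(
                    animal_id=animal_id,
                    channel=LUMBAR,
                    points=lum_points,
                    intensity=np.concatenate(lum_int) if lum_int else np.zeros(0),
                ),
                CERVICAL: PointSet(
                    animal_id=animal_id,
                    channel=CERVICAL,
                    points=np.concatenate(cerv_pts) if cerv_pts else np.zeros((0, 3)),
                    intensity=np.concatenate(cerv_int) if cerv_int else np.zeros(0),
                ),
            }
            dual_masks[animal_id] = dual_mask

            bms = _behavior_score(design, spared_fracs, rng)
            animals.append(
                Animal(
                    animal_id=animal_id,
                    condition=condition,
                    severity=condition,
                    bms_score=bms,
                    pointsets=pointsets,
                )
            )

    gt = GroundTruth(
        design=design,
        per_region=pd.DataFrame(gt_rows),
        dual_mask=dual_masks,
    )
    return Cohort(animals=animals, ground_truth=gt)


def _behavior_score(
    design: CohortDesign, spared: dict[int, float], rng: np.random.Generator
) -> float:
    """Monotone map of weighted linked-region sparing onto the 0-9 scale."""
    link = design.behavior_link
    if link is None:
        return 9.0
    w = np.asarray(link.weights, dtype=float)
    s = np.asarray([spared[r] for r in link.region_ids])
    weighted = float(np.dot(w, s) / w.sum()) if w.sum() > 0 else 1.0
    score = 9.0 * weighted + rng.normal(0.0, link.noise_sd)
    score = float(np.clip(score, 0.0, 9.0))
    if design.quantize_bms:
        score = round(score * 2.0) / 2.0
    return score


def demo_design(seed: int = 0, n_animals: int = 4) -> CohortDesign:
    """Default cohort design emulating a graded-injury tracing study.

    Eight regions stand in for the major supraspinal populations, with
    relative lumbar abundances, dual-projection probabilities, and
    severity-dependent sparing patterned on the study conditions they
    emulate: a corticospinal-like region that is strongly hit even by
    mild injury, a red-nucleus-like region with mostly segregated
    cervical/lumbar populations (low dual probability) but good sparing,
    reticular populations with high dual probabilities, and a
    pedunculopontine-like region (id 4) whose sparing drives locomotor
    recovery.  Mild, moderate, and severe arms average roughly 57%, 24%,
    and ~0% brain-wide sparing.
    """
    regions = [
        # id, lumbar mean, dual prob, cervical-only mean
        RegionSpec(1, 300.0, 0.53, 250.0),   # corticospinal-like
        RegionSpec(2, 250.0, 0.485, 200.0),  # gigantocellular-like
        RegionSpec(3, 100.0, 0.144, 120.0),  # red-nucleus-like
        RegionSpec(4, 60.0, 0.30, 80.0),     # pedunculopontine-like
        RegionSpec(5, 120.0, 0.548, 60.0),   # hypothalamic-like
        RegionSpec(6, 80.0, 0.40, 100.0),    # pontine-reticular-like
        RegionSpec(7, 50.0, 0.25, 90.0),     # vestibular-like
        RegionSpec(8, 40.0, 0.35, 60.0),     # solitary-like
    ]
    severity_sparing = {
        "mild": {1: 0.18, 2: 0.60, 3: 0.75, 4: 0.65, 5: 0.70, 6: 0.83, 7: 0.55, 8: 0.60},
        "moderate": {1: 0.08, 2: 0.28, 3: 0.35, 4: 0.30, 5: 0.25, 6: 0.32, 7: 0.20, 8: 0.22},
        "severe": {r.region_id: 0.002 for r in regions},
    }
    return CohortDesign(
        regions=regions,
        dispersion=8.0,
        intensity_model=IntensityModel(),
        severity_sparing=severity_sparing,
        behavior_link=BehaviorLink(region_ids=(4,), weights=(1.0,), noise_sd=0.5),
        n_animals=n_animals,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Image-stack rendering
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """3D intensity stack, data indexed [z, y, x], voxel size as (x, y, z) um."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    @property
    def shape_um(self) -> tuple[float, float, float]:
        nz, ny, nx = self.data.shape
        vx, vy, vz = self.voxel_size_um
        return (nx * vx, ny * vy, nz * vz)

    def write_tiff(self, path: str | Path) -> None:
        vx, vy, vz = self.voxel_size_um
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            metadata={"spacing": vz, "unit": "um"},
            resolution=(1.0 / vx, 1.0 / vy),
        )

    @classmethod
    def read_tiff(cls, path: str | Path, voxel_size_um: tuple[float, float, float]) -> "ImageStack":
        return cls(data=tifffile.imread(path), voxel_size_um=voxel_size_um)


def simulate_nuclei_stack(
    points: PointSet,
    shape_voxels: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float] = (2.0, 2.0, 4.0),
    blob_sigma_um: tuple[float, float] = (1.5, 3.0),
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ImageStack:
    """Render nuclei as anisotropic Gaussian blobs on a noisy background.

    Each point contributes ``intensity * exp(-r^2/2)`` with sigma
    ``blob_sigma_um = (xy, z)``; light-sheet stacks are blurrier axially,
    hence the separate z sigma.  ``shape_voxels`` is (nx, ny, nz).

    Raises
    ------
    ValueError
        If any point lies outside the stack bounds.
    """
    nx, ny, nz = shape_voxels
    vx, vy, vz = voxel_size_um
    bounds = np.array([nx * vx, ny * vy, nz * vz])
    if len(points) and (
        np.any(points.points < 0) or np.any(points.points >= bounds)
    ):
        raise ValueError("point outside stack bounds")

    data = np.full((nz, ny, nx), float(background), dtype=np.float64)
    sx = sy = blob_sigma_um[0]
    sz = blob_sigma_um[1]
    sig_vox = np.array([sx / vx, sy / vy, sz / vz])  # in (x, y, z) voxel units

    for p, amp in zip(points.points, points.intensity):
        center = p / np.array([vx, vy, vz])  # voxel coords (x, y, z)
        lo = np.maximum(np.floor(center - 4 * sig_vox).astype(int), 0)
        hi = np.minimum(
            np.ceil(center + 4 * sig_vox).astype(int) + 1, np.array([nx, ny, nz])
        )
        gx = np.arange(lo[0], hi[0])
        gy = np.arange(lo[1], hi[1])
        gz = np.arange(lo[2], hi[2])
        # voxel center offsets in um
        dx = ((gx + 0.5) * vx - p[0]) / sx
        dy = ((gy + 0.5) * vy - p[1]) / sy
        dz = ((gz + 0.5) * vz - p[2]) / sz
        blob = amp * np.exp(
            -0.5
            * (
                dz[:, None, None] ** 2
                + dy[None, :, None] ** 2
                + dx[None, None, :] ** 2
            )
        )
        data[lo[2] : hi[2], lo[1] : hi[1], lo[0] : hi[0]] += blob

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return ImageStack(data=data, voxel_size_um=(vx, vy, vz))


# ---------------------------------------------------------------------------
# Lesion-section rendering
# ---------------------------------------------------------------------------


@dataclass
class GfapSection:
    """Synthetic astrocyte-stained (GFAP) spinal section around a lesion.

    ``image`` is (height, width); rows in ``lesion_band`` form the injury
    zone, GFAP-positive only within the listed bridge column spans.
    ``true_bridge_fraction`` is total span width / cord width.
    """

    image: np.ndarray
    lesion_band: tuple[int, int]
    true_bridge_fraction: float


def simulate_gfap_section(
    width_px: int,
    height_px: int,
    bridge_spans: list[tuple[int, int]],
    lesion_band: tuple[int, int] | None = None,
    positive_value: float = 1.0,
    negative_value: float = 0.0,
) -> GfapSection:
    """Render a lesion section: astrocytic tissue with bridges across a gap.

    ``bridge_spans`` are half-open column intervals [c0, c1) that remain
    GFAP-positive through the lesion band; outside the band the whole cord
    is positive.  Spans must lie within the image and not overlap.
    """
    if lesion_band is None:
        lesion_band = (height_px // 3, 2 * height_px // 3)
    r0, r1 = lesion_band
    if not (0 <= r0 < r1 <= height_px):
        raise ValueError("lesion band outside image")
    spans = sorted((int(a), int(b)) for a, b in bridge_spans)
    total = 0
    prev_end = -1
    for a, b in spans:
        if not (0 <= a < b <= width_px):
            raise ValueError(f"span ({a}, {b}) outside image width {width_px}")
        if a < prev_end:
            raise ValueError(f"span ({a}, {b}) overlaps previous span")
        prev_end = b
        total += b - a

    image = np.full((height_px, width_px), positive_value, dtype=float)
    image[r0:r1, :] = negative_value
    for a, b in spans:
        image[r0:r1, a:b] = positive_value
    return GfapSection(
        image=image,
        lesion_band=lesion_band,
        true_bridge_fraction=total / width_px,
    )
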