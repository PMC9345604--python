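"""Headline indices of the brain-wide supraspinal quantification.

* Lumbar-projection index: per region, lumbar-labeled nuclei divided by
  all supraspinal nuclei in that region (lumbar + cervical); values near
  1 mark regions terminating mostly in lumbar cord, near 0 mostly
  cervical.
* Sparing index: a post-injury region count as a percentage of the mean
  count in uninjured reference animals (uninjured average set to 100).
* Brain-wide summary: per-animal totals, per-region means with SEM, and
  the number of regions in which label was detected at all.
* Bridge fraction: in a GFAP-stained lesion section, the percentage of
  cord width spanned by astrocytic tissue continuous across the lesion.

Indices are computed per animal first and then averaged across animals
(reported with SEM over N animals); pooled per-region modes are offered
where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .atlas import RegionCounts
from .synthetic_data import CERVICAL, LUMBAR, GfapSection

__all__ = [
    "LumbarIndexTable",
    "SparingTable",
    "BrainwideSummary",
    "BridgeFractionResult",
    "lumbar_projection_index",
    "sparing_index",
    "brainwide_summary",
    "bridge_fraction",
]


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.nan if len(x) == 0 else 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


# ---------------------------------------------------------------------------
# Lumbar-projection index
# ---------------------------------------------------------------------------


@dataclass
class LumbarIndexTable:
    """Per-animal, per-region, and brain-wide lumbar-projection indices.

    ``per_animal`` keeps the numerator/denominator columns for audit;
    ``per_region`` averages defined per-animal indices across animals;
    ``brainwide`` holds one index per animal from brain-wide totals, with
    ``brainwide_mean``/``brainwide_sem`` across animals.
    """

    per_animal: pd.DataFrame
    per_region: pd.DataFrame
    brainwide: pd.DataFrame
    brainwide_mean: float
    brainwide_sem: float
    mode: str = "totals"


def lumbar_projection_index(
    counts: RegionCounts,
    lumbar_channel: str = LUMBAR,
    cervical_channel: str = CERVICAL,
    brainwide_mode: str = "totals",
) -> LumbarIndexTable:
    """Index of lumbar projection: lumbar / (lumbar + cervical) per region.

    Computed per animal and region, then averaged across animals with
    SEM; animal-region cells with zero total are undefined and excluded
    from the region average.  The brain-wide index uses per-animal
    brain-wide totals (``brainwide_mode='totals'``, default) or the mean
    of that animal's defined region indices (``'region_mean'``).
    """
    if brainwide_mode not in ("totals", "region_mean"):
        raise ValueError("brainwide_mode must be 'totals' or 'region_mean'")
    channels = set(counts.table["channel"].unique())
    for ch in (lumbar_channel, cervical_channel):
        if ch not in channels:
            raise ValueError(f"channel {ch!r} missing from counts table")

    wide = (
        counts.table.groupby(["animal", "region", "channel"], sort=True)["count"]
        .sum()
        .unstack("channel", fill_value=0)
        .reset_index()
    )
    for ch in (lumbar_channel, cervical_channel):
        if ch not in wide:
            wide[ch] = 0
    wide = wide.rename(
        columns={lumbar_channel: "lumbar", cervical_channel: "cervical"}
    )[["animal", "region", "lumbar", "cervical"]]
    total = wide["lumbar"] + wide["cervical"]
    wide["index"] = np.where(total > 0, wide["lumbar"] / total.replace(0, np.nan), np.nan)
    wide["undefined"] = total == 0

    per_region = (
        wide[~wide["undefined"]]
        .groupby("region", sort=True)["index"]
        .agg(mean_index="mean", sem=_sem, n_animals="count")
        .reset_index()
    )

    if brainwide_mode == "totals":
        bw = wide.groupby("animal", sort=True)[["lumbar", "cervical"]].sum()
        tot = bw["lumbar"] + bw["cervical"]
        bw["index"] = np.where(tot > 0, bw["lumbar"] / tot.replace(0, np.nan), np.nan)
        brainwide = bw.reset_index()[["animal", "lumbar", "cervical", "index"]]
    else:
        brainwide = (
            wide[~wide["undefined"]]
            .groupby("animal", sort=True)["index"]
            .mean()
            .reset_index()
        )
    vals = brainwide["index"].dropna().to_numpy()
    return LumbarIndexTable(
        per_animal=wide,
        per_region=per_region,
        brainwide=brainwide,
        brainwide_mean=float(np.mean(vals)) if len(vals) else np.nan,
        brainwide_sem=_sem(vals),
        mode=brainwide_mode,
    )


# ---------------------------------------------------------------------------
# Sparing index
# ---------------------------------------------------------------------------


@dataclass
class SparingTable:
    """Per-animal, per-region sparing percentages against an uninjured reference.

    ``per_animal_region`` rows carry count, reference mean, and sparing in
    percent (uninjured reference average = 100); zero-reference and
    explicitly excluded regions are flagged and omitted from brain-wide
    totals.  ``brainwide`` holds one sparing percentage per animal from
    brain-wide totals.
    """

    per_animal_region: pd.DataFrame
    per_region: pd.DataFrame
    brainwide: pd.DataFrame
    excluded_regions: list


def sparing_index(
    injured: RegionCounts,
    uninjured_reference: RegionCounts,
    exclude_regions: tuple = (),
) -> SparingTable:
    """Sparing index: post-injury counts as percent of uninjured means.

    ``sparing%(animal, region) = 100 * count / mean reference count``;
    the brain-wide value per animal is 100 * total / mean reference
    total.  Regions on ``exclude_regions`` (unreliable populations such
    as the deep cerebellar nuclei) and regions with zero reference mean
    are excluded and flagged.

    Raises
    ------
    ValueError
        If the reference cohort has fewer than 2 animals.
    """
    ref_pivot = uninjured_reference.pivot()
    if ref_pivot.shape[0] < 2:
        raise ValueError("uninjured reference cohort must have >= 2 animals")
    inj_pivot = injured.pivot()

    all_regions = sorted(set(ref_pivot.columns) | set(inj_pivot.columns))
    ref_pivot = ref_pivot.reindex(columns=all_regions, fill_value=0)
    inj_pivot = inj_pivot.reindex(columns=all_regions, fill_value=0)
    ref_mean = ref_pivot.mean(axis=0)

    excluded = [
        r
        for r in all_regions
        if r in set(exclude_regions) or ref_mean[r] <= 0
    ]
    rows = []
    for animal, row in inj_pivot.iterrows():
        for region in all_regions:
            is_exc = region in excluded
            rm = ref_mean[region]
            rows.append(
                {
                    "animal": animal,
                    "region": region,
                    "count": int(row[region]),
                    "reference_mean": float(rm),
                    "sparing_pct": 100.0 * row[region] / rm if not is_exc else np.nan,
                    "excluded": is_exc,
                }
            )
    per_animal_region = pd.DataFrame(rows)

    ok = per_animal_region[~per_animal_region["excluded"]]
    per_region = (
        ok.groupby("region", sort=True)["sparing_pct"]
        .agg(mean_sparing_pct="mean", sem=_sem, n_animals="count")
        .reset_index()
    )

    keep = [r for r in all_regions if r not in excluded]
    ref_total = ref_pivot[keep].sum(axis=1).mean()
    inj_totals = inj_pivot[keep].sum(axis=1)
    brainwide = pd.DataFrame(
        {
            "animal": inj_totals.index,
            "total_count": inj_totals.to_numpy(),
            "sparing_pct": 100.0 * inj_totals.to_numpy() / ref_total
            if ref_total > 0
            else np.nan,
        }
    )
    return SparingTable(
        per_animal_region=per_animal_region,
        per_region=per_region,
        brainwide=brainwide,
        excluded_regions=excluded,
    )


# ---------------------------------------------------------------------------
# Brain-wide summary
# ---------------------------------------------------------------------------


@dataclass
class BrainwideSummary:
    per_animal_totals: pd.DataFrame
    mean_total: float
    sem_total: float
    range_total: tuple[float, float]
    per_region: pd.DataFrame
    n_detected_regions: int


def brainwide_summary(
    counts: RegionCounts,
    channel: str | None = None,
    min_count: int = 1,
    min_animals: int = 1,
) -> BrainwideSummary:
    """Totals, per-region means with SEM, and the detected-region count.

    A region counts as detected when at least ``min_animals`` animals
    carry at least ``min_count`` nuclei in it (defaults: one nucleus in
    one animal).
    """
    t = counts.table
    if channel is not None:
        t = t[t["channel"] == channel]
    pivot = (
        t.groupby(["animal", "region"], sort=True)["count"].sum().unstack(fill_value=0)
    )
    totals = pivot.sum(axis=1)
    per_region = pd.DataFrame(
        {
            "region": pivot.columns,
            "mean_count": pivot.mean(axis=0).to_numpy(),
            "sem": [_sem(pivot[c].to_numpy()) for c in pivot.columns],
            "min": pivot.min(axis=0).to_numpy(),
            "max": pivot.max(axis=0).to_numpy(),
        }
    )
    detected = int(((pivot >= min_count).sum(axis=0) >= min_animals).sum())
    vals = totals.to_numpy(dtype=float)
    return BrainwideSummary(
        per_animal_totals=totals.reset_index(name="total"),
        mean_total=float(np.mean(vals)) if len(vals) else np.nan,
        sem_total=_sem(vals),
        range_total=(float(np.min(vals)), float(np.max(vals))) if len(vals) else (np.nan, np.nan),
        per_region=per_region,
        n_detected_regions=detected,
    )


# ---------------------------------------------------------------------------
# GFAP bridge fraction
# ---------------------------------------------------------------------------


@dataclass
class BridgeFractionResult:
    percent: float
    bridge_columns: np.ndarray
    cord_columns: np.ndarray


def bridge_fraction(
    section: GfapSection | np.ndarray,
    lesion_band: tuple[int, int] | None = None,
    gfap_threshold: float = 0.5,
) -> BridgeFractionResult:
    """Percent of cord width bridged by GFAP-positive tissue across a lesion.

    The image is binarized at ``gfap_threshold``; within the lesion band,
    8-connected components of positive pixels that touch both the first
    and last band row are astrocytic bridges.  The fraction is the number
    of cord columns covered by bridge pixels over the cord width in
    columns, times 100.  Cord columns are those containing positive
    signal outside the lesion band (the intact cord); rescaling
    intensities on either side of the threshold leaves the result
    unchanged.

    Raises
    ------
    ValueError
        If no cord columns are found (empty cord mask).
    """
    if isinstance(section, GfapSection):
        image = section.image
        if lesion_band is None:
            lesion_band = section.lesion_band
    else:
        image = np.asarray(section, dtype=float)
        if lesion_band is None:
            raise ValueError("lesion_band required when passing a bare array")
    r0, r1 = lesion_band
    if not (0 <= r0 < r1 <= image.shape[0]):
        raise ValueError("lesion band outside image")

    binary = image > gfap_threshold
    outside = np.ones(image.shape[0], dtype=bool)
    outside[r0:r1] = False
    cord_cols = np.flatnonzero(binary[outside].any(axis=0))
    if len(cord_cols) == 0:
        raise ValueError("empty cord mask: no GFAP-positive columns outside lesion")

    band = binary[r0:r1]
    labels = measure.label(band, connectivity=2)
    touches_top = set(np.unique(labels[0])) - {0}
    touches_bottom = set(np.unique(labels[-1])) - {0}
    spanning = touches_top & touches_bottom
    if spanning:
        mask = np.isin(labels, sorted(spanning))
        bridge_cols = np.flatnonzero(mask.any(axis=0))
        bridge_cols = np.intersect1d(bridge_cols, cord_cols)
    else:
        bridge_cols = np.array([], dtype=int)
    return BridgeFractionResult(
        percent=100.0 * len(bridge_cols) / len(cord_cols),
        bridge_columns=bridge_cols,
        cord_columns=cord_cols,
    )
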