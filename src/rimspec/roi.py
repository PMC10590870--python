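"""ROI extraction, resampling, NAWM placement and iron-type classification.

Implements the segmentation-side rules of the analysis: tricubic resampling
of metabolic maps onto the anatomical grid, the strict >20 mm^3 lesion size
filter, placement of fixed-volume (37 mm^3) NAWM reference ROIs at >= 5 mm
Euclidean distance from GM/CSF/lesions, and a rule-based stand-in for the
qualitative two-reader iron-accumulation categorization on SWI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import RATIOS, IronType
from .volumes import BACKGROUND, CSF, GM, WM, GridSpec, LabelVolume, RatioMap

log = logging.getLogger(__name__)

_CROSS = ndimage.generate_binary_structure(3, 1)


@dataclass
class RoiRecord:
    """One lesion or NAWM region of interest."""

    roi_id: str
    kind: str  # "lesion" | "nawm"
    voxels: np.ndarray  # (3, n) integer indices
    grid: GridSpec
    lesion_id: int | None = None
    iron_type: IronType | None = None
    means: dict[str, float] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[1]

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.shape, dtype=bool)
        m[tuple(self.voxels)] = True
        return m


def resample_tricubic(ratio_map: RatioMap, target: GridSpec) -> RatioMap:
    """Resample a map onto a target grid with a 3D cubic spline kernel.

    Exact on an identical grid, reproduces constants and trilinear ramps in
    the interior; target voxels outside the source grid are masked out.
    """
    src = ratio_map.grid
    axes = target.voxel_centers()
    coords_mm = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)
    idx = np.empty_like(coords_mm)
    for a in range(3):
        idx[a] = (coords_mm[a] - src.origin_mm[a]) / src.voxel_size_mm[a]
    inside = np.ones(target.shape, dtype=bool)
    for a in range(3):
        inside &= (idx[a] >= 0) & (idx[a] <= src.shape[a] - 1)
    if not inside.any():
        raise ValueError("source and target grids do not overlap")
    data = ndimage.map_coordinates(ratio_map.data.astype(np.float64), idx.reshape(3, -1),
                                   order=3, mode="nearest").reshape(target.shape)
    valid_frac = ndimage.map_coordinates(ratio_map.mask.astype(np.float64), idx.reshape(3, -1),
                                         order=1, mode="constant").reshape(target.shape)
    mask = inside & (valid_frac > 0.5)
    return RatioMap(ratio_map.name, data, target, mask=mask,
                    meta=dict(ratio_map.meta))


def extract_lesion_rois(
    labels: LabelVolume,
    maps: dict[str, RatioMap] | None = None,
    min_volume_mm3: float = 20.0,
    iron_types: dict[int, IronType] | None = None,
) -> list[RoiRecord]:
    """One ROI per lesion label with volume strictly above the size filter.

    Lesions at or below ``min_volume_mm3`` are dropped (logged count); the
    strict inequality mirrors the published "exceeding 20 mm^3" rule.
    """
    rois: list[RoiRecord] = []
    dropped = 0
    vv = labels.grid.voxel_volume_mm3
    for lid in labels.lesion_ids:
        voxels = np.array(np.nonzero(labels.data == lid))
        if voxels.shape[1] * vv <= min_volume_mm3:
            dropped += 1
            continue
        rec = RoiRecord(
            roi_id=f"lesion_{lid}", kind="lesion", voxels=voxels, grid=labels.grid,
            lesion_id=lid,
            iron_type=iron_types.get(lid) if iron_types else None,
        )
        rois.append(rec)
    if dropped:
        log.info("size filter dropped %d lesions at or below %.1f mm^3", dropped, min_volume_mm3)
    if maps:
        summarize_rois(rois, maps)
    return rois


def distance_to_non_wm_mm(labels: LabelVolume) -> np.ndarray:
    """Euclidean distance (mm) of every voxel to the nearest GM/CSF/lesion voxel."""
    hazard = (labels.data == GM) | (labels.data == CSF) | (labels.data >= 10)
    return ndimage.distance_transform_edt(~hazard, sampling=labels.grid.voxel_size_mm)


def place_nawm_rois(
    labels: LabelVolume,
    n_rois: int,
    seed: int | np.random.Generator = 0,
    roi_volume_mm3: float = 37.0,
    min_distance_mm: float = 5.0,
    maps: dict[str, RatioMap] | None = None,
) -> list[RoiRecord]:
    """Place compact NAWM reference blobs of fixed volume inside safe WM.

    Each ROI is the set of the n nearest voxels around a seed point, where n
    is the nearest achievable voxel count to ``roi_volume_mm3`` on the grid;
    every ROI voxel is WM and at Euclidean distance >= ``min_distance_mm``
    from any GM/CSF/lesion voxel. If fewer than ``n_rois`` fit, the ones
    that do are returned with a warning logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vv = labels.grid.voxel_volume_mm3
    n_target = max(1, round(roi_volume_mm3 / vv))
    blob_radius_mm = ((3.0 * n_target * vv) / (4.0 * np.pi)) ** (1.0 / 3.0)

    dist = distance_to_non_wm_mm(labels)
    eligible = (labels.data == WM) & (dist >= min_distance_mm)
    # seeds must allow the whole blob to stay eligible
    interior = ndimage.distance_transform_edt(eligible, sampling=labels.grid.voxel_size_mm)
    seed_ok = interior >= blob_radius_mm

    rois: list[RoiRecord] = []
    spacing = np.asarray(labels.grid.voxel_size_mm)
    taken = np.zeros(labels.grid.shape, dtype=bool)
    candidates = np.array(np.nonzero(seed_ok)).T
    if candidates.size:
        order = rng.permutation(len(candidates))
        for ci in order:
            if len(rois) >= n_rois:
                break
            c = candidates[ci]
            if taken[tuple(c)]:
                continue
            lo = np.maximum(0, (c - np.ceil(2 * blob_radius_mm / spacing)).astype(int))
            hi = np.minimum(labels.grid.shape, (c + np.ceil(2 * blob_radius_mm / spacing)).astype(int) + 1)
            sub = tuple(slice(lo[a], hi[a]) for a in range(3))
            local_idx = np.array(np.nonzero(eligible[sub] & ~taken[sub]))
            if local_idx.shape[1] < n_target:
                continue
            pts = (local_idx.T + lo) * spacing
            d = np.linalg.norm(pts - c * spacing, axis=1)
            nearest = np.argsort(d)[:n_target]
            vox = (local_idx[:, nearest].T + lo).T
            # compactness guard: reject if the blob had to reach far out
            if d[nearest[-1]] > 2.0 * blob_radius_mm:
                continue
            taken[tuple(vox)] = True
            rois.append(RoiRecord(
                roi_id=f"nawm_{len(rois) + 1}", kind="nawm", voxels=vox, grid=labels.grid))
    if len(rois) < n_rois:
        log.warning("only %d of %d NAWM ROIs could be placed", len(rois), n_rois)
    if maps:
        summarize_rois(rois, maps)
    return rois


def classify_iron_type(
    swi: RatioMap | np.ndarray,
    lesion_mask: np.ndarray,
    background_mask: np.ndarray | None = None,
    k_sd: float = 3.0,
    theta_core: float = 0.30,
    theta_area: float = 0.85,
    min_span_slices: int = 3,
    min_hypo_fraction: float = 0.05,
) -> IronType:
    """Rule-based iron-accumulation categorization from a susceptibility volume.

    Hypointense voxels are those below (background mean - k_sd * background
    SD). A lesion is ``non_iron`` unless its hypointensity spans at least
    ``min_span_slices`` contiguous axial slices and covers at least
    ``min_hypo_fraction`` of the lesion; otherwise it is ``area`` if the
    hypointense fraction reaches ``theta_area``, ``rim`` if hypointensity is
    confined to the 1-voxel outer shell (core fraction below ``theta_core``),
    and ``transition`` in between.
    """
    data = swi.data if isinstance(swi, RatioMap) else np.asarray(swi)
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    if background_mask is None:
        background_mask = np.ones_like(lesion_mask) & ~lesion_mask
    bg = data[background_mask & ~lesion_mask]
    thr = bg.mean() - k_sd * bg.std()
    hypo = lesion_mask & (data < thr)

    frac = hypo.sum() / lesion_mask.sum()
    zs = np.unique(np.nonzero(hypo)[2])
    span = _longest_run(zs)
    if span < min_span_slices or frac < min_hypo_fraction:
        return IronType.NON_IRON
    if frac >= theta_area:
        return IronType.AREA
    core = ndimage.binary_erosion(lesion_mask, structure=_CROSS)
    core_frac = (hypo & core).sum() / core.sum() if core.any() else 0.0
    if core_frac < theta_core:
        return IronType.RIM
    return IronType.TRANSITION


def _longest_run(sorted_ints: np.ndarray) -> int:
    if len(sorted_ints) == 0:
        return 0
    breaks = np.nonzero(np.diff(sorted_ints) > 1)[0]
    runs = np.split(sorted_ints, breaks + 1)
    return max(len(r) for r in runs)


def wm_background_mask(labels: LabelVolume, lesion_margin_voxels: int = 2) -> np.ndarray:
    """NAWM voxels usable as SWI background (WM away from any lesion)."""
    lesions = labels.data >= 10
    if lesions.any() and lesion_margin_voxels > 0:
        lesions = ndimage.binary_dilation(lesions, structure=_CROSS,
                                          iterations=lesion_margin_voxels)
    return (labels.data == WM) & ~lesions


def classify_lesions(labels: LabelVolume, swi: RatioMap) -> dict[int, IronType]:
    """Classify every lesion label in a volume against its NAWM background."""
    bg = wm_background_mask(labels)
    return {
        lid: classify_iron_type(swi, labels.data == lid, background_mask=bg)
        for lid in labels.lesion_ids
    }


def summarize_rois(rois: list[RoiRecord], maps: dict[str, RatioMap]) -> pd.DataFrame:
    """Per-ROI unweighted mean over unmasked voxels, per ratio.

    Fills each record's ``means`` in place and returns a tidy table; ROIs
    with zero unmasked voxels for a ratio are flagged with NaN.
    """
    rows = []
    for rec in rois:
        for name, m in maps.items():
            rec.means[name] = m.mean_over(rec.voxels)
        rows.append({
            "roi_id": rec.roi_id, "kind": rec.kind,
            "lesion_id": rec.lesion_id if rec.lesion_id is not None else -1,
            "iron_type": rec.iron_type.value if rec.iron_type else "",
            "n_voxels": rec.n_voxels, "volume_mm3": rec.volume_mm3,
            **{name: rec.means.get(name, np.nan) for name in maps},
        })
    cols = ["roi_id", "kind", "lesion_id", "iron_type", "n_voxels", "volume_mm3",
            *maps.keys()]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
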