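"""Concentric lesion-layer construction and metabolic layer profiles.

A lesion mask is dilated and eroded three times with a configurable 3D
structuring element, yielding seven disjoint layer rings from L+3 (the
outermost dilation ring, taken as the local NAWM reference) to L-3 (the
erosion-3 core). Voxels of lesion-free GM, CSF and neighboring lesions that
intrude into a ring are subtracted and tracked, never silently dropped.
Profiles are the per-layer unweighted ratio means, normalized to the L+3
mean so every eligible lesion's outermost layer is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import LAYER_NAMES, RATIOS, IronType, iron_group
from .stats import GroupComparison, compare_groups
from .volumes import CSF, GM, LabelVolume, RatioMap

INNER_LAYERS = ("L0", "L-1", "L-2", "L-3")


def structuring_element(connectivity: int = 6) -> np.ndarray:
    """3D structuring element: 6 (face), 18 (edge) or 26 (vertex) connected."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


@dataclass
class LayerStack:
    """Seven disjoint layer masks for one lesion plus exclusion bookkeeping."""

    lesion_id: int
    masks: dict[str, np.ndarray]
    excluded: dict[str, int]       # per-layer voxels removed by GM/CSF/neighbors
    original_volume_mm3: float
    voxel_volume_mm3: float
    eligible: bool = False

    @property
    def counts(self) -> dict[str, int]:
        return {name: int(m.sum()) for name, m in self.masks.items()}


def build_layer_stack(
    lesion_mask: np.ndarray,
    gm_mask: np.ndarray,
    csf_mask: np.ndarray,
    other_lesion_mask: np.ndarray,
    voxel_volume_mm3: float,
    connectivity: int = 6,
) -> LayerStack:
    """Decompose a lesion and its neighborhood into the seven layer rings.

    With D^k / E^k the k-fold dilation / erosion: L+3 = D3\\D2, L+2 = D2\\D1,
    L+1 = D1\\mask, L0 = mask\\E1, L-1 = E1\\E2, L-2 = E2\\E3, L-3 = E3.
    Lesion-free GM, CSF and neighboring-lesion voxels are then removed from
    every layer; the removed counts are recorded per layer.
    """
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    st = structuring_element(connectivity)
    d = [lesion_mask]
    for _ in range(3):
        d.append(ndimage.binary_dilation(d[-1], structure=st))
    e = [lesion_mask]
    for _ in range(3):
        e.append(ndimage.binary_erosion(e[-1], structure=st))

    raw = {
        "L+3": d[3] & ~d[2], "L+2": d[2] & ~d[1], "L+1": d[1] & ~lesion_mask,
        "L0": lesion_mask & ~e[1], "L-1": e[1] & ~e[2], "L-2": e[2] & ~e[3],
        "L-3": e[3],
    }
    exclude = (gm_mask | csf_mask | other_lesion_mask) & ~lesion_mask
    # inside the lesion nothing is excluded by construction (the lesion mask
    # itself defines the tissue); intrusions only affect the dilation rings,
    # but the subtraction is applied uniformly for safety.
    masks = {}
    excluded = {}
    for name, m in raw.items():
        keep = m & ~exclude
        masks[name] = keep
        excluded[name] = int(m.sum() - keep.sum())
    return LayerStack(
        lesion_id=-1, masks=masks, excluded=excluded,
        original_volume_mm3=float(lesion_mask.sum()) * voxel_volume_mm3,
        voxel_volume_mm3=voxel_volume_mm3,
    )


def layer_eligibility(stack: LayerStack,
                      min_volume_mm3: float = 100.0,
                      max_volume_mm3: float = 400.0) -> bool:
    """At least four layers must fit inside the lesion.

    True iff the original lesion volume lies in [100, 400] mm^3 and all four
    inner layers (L0..L-3) are non-empty after exclusions. Updates the
    stack's ``eligible`` flag.
    """
    ok_volume = min_volume_mm3 <= stack.original_volume_mm3 <= max_volume_mm3
    ok_layers = all(stack.masks[name].any() for name in INNER_LAYERS)
    stack.eligible = bool(ok_volume and ok_layers)
    return stack.eligible


@dataclass
class LayerProfile:
    """Raw and periphery-normalized per-layer means for one lesion."""

    lesion_id: int
    iron_type: IronType
    raw: dict[tuple[str, str], float] = field(default_factory=dict)   # (layer, ratio)
    norm: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for (layer, ratio), v in self.raw.items():
            rows.append({
                "lesion_id": self.lesion_id, "iron_type": self.iron_type.value,
                "iron_group": iron_group(self.iron_type), "layer": layer,
                "ratio": ratio, "raw_mean": v,
                "norm_mean": self.norm.get((layer, ratio), np.nan),
            })
        return rows


def profile_layers(stack: LayerStack, maps: dict[str, RatioMap],
                   iron_type: IronType = IronType.NON_IRON) -> LayerProfile:
    """Per-layer per-ratio means, normalized to the outermost layer (L+3)."""
    prof = LayerProfile(lesion_id=stack.lesion_id, iron_type=iron_type)
    for ratio, m in maps.items():
        ref = m.mean_over(stack.masks["L+3"]) if stack.masks["L+3"].any() else np.nan
        if not np.isfinite(ref) or ref == 0:
            raise ValueError(
                f"outermost-layer mean of {ratio!r} is zero or undefined; "
                "cannot normalize")
        for layer in LAYER_NAMES:
            if stack.masks[layer].any():
                v = m.mean_over(stack.masks[layer])
            else:
                v = np.nan  # flagged missing; dropped from group stats
            prof.raw[(layer, ratio)] = v
            prof.norm[(layer, ratio)] = v / ref
    return prof


def profiles_to_frame(profiles: list[LayerProfile]) -> pd.DataFrame:
    rows = [r for p in profiles for r in p.to_rows()]
    return pd.DataFrame(rows, columns=["lesion_id", "iron_type", "iron_group",
                                       "layer", "ratio", "raw_mean", "norm_mean"])


def cohort_layer_stacks(
    labels: LabelVolume,
    iron_types: dict[int, IronType],
    maps: dict[str, RatioMap],
    connectivity: int = 6,
    eligible_only: bool = True,
) -> list[LayerProfile]:
    """Build stacks and profiles for every (eligible) lesion in a volume."""
    gm = labels.data == GM
    csf = labels.data == CSF
    all_lesions = labels.data >= 10
    profiles = []
    for lid in labels.lesion_ids:
        mask = labels.data == lid
        stack = build_layer_stack(mask, gm, csf, all_lesions & ~mask,
                                  labels.grid.voxel_volume_mm3, connectivity)
        stack.lesion_id = lid
        layer_eligibility(stack)
        if eligible_only and not stack.eligible:
            continue
        profiles.append(profile_layers(stack, maps, iron_types.get(lid, IronType.NON_IRON)))
    return profiles


def compare_layer_groups(
    profiles: list[LayerProfile] | pd.DataFrame,
    layers: tuple[str, ...] = ("L+3", "L0", "L-3"),
    min_group_size: int = 2,
) -> dict[str, GroupComparison]:
    """ANOVA + Tukey across (iron group x layer) cells, one per ratio.

    Only every third layer enters the default comparison (L+3, L0, L-3),
    mirroring the layer statistics actually reported; normalized means are
    compared. Cells with fewer than two members are excluded with a warning.
    """
    df = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    out: dict[str, GroupComparison] = {}
    for ratio in RATIOS:
        groups: dict[str, np.ndarray] = {}
        for grp in ("non_iron", "iron"):
            for layer in layers:
                sel = (df["ratio"] == ratio) & (df["iron_group"] == grp) & (df["layer"] == layer)
                vals = df.loc[sel, "norm_mean"].dropna().to_numpy()
                if len(vals):
                    groups[f"{layer}_{grp}"] = vals
        if len(groups) >= 2:
            out[ratio] = compare_groups(groups, min_group_size=min_group_size)
    return out
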