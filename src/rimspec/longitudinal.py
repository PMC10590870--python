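"""Longitudinal tracking of newly emerging lesions.

Epochs are assumed co-registered on one grid (true for phantoms; a
documented requirement for real data). A lesion is "new" at an epoch if its
mask overlaps previous-epoch lesions by less than a configurable fraction.
The Year-0 footprint is applied verbatim at all three epochs — including
Year -1, where it samples the normal-appearing white matter that the lesion
later emerges from — and the per-epoch ratio means inside that fixed
footprint are the tracked quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EPOCHS, RATIOS, IronType, iron_group
from .stats import GroupComparison, compare_groups
from .volumes import LabelVolume, RatioMap


@dataclass
class NewLesionTrack:
    """One newly emerging lesion followed across the three epochs."""

    lesion_id: int
    iron_status: str               # "iron" | "non_iron"
    footprint: np.ndarray          # (3, n) voxel indices from Year 0
    means: dict[tuple[str, str], float] = field(default_factory=dict)  # (epoch, ratio)

    def mean(self, epoch: str, ratio: str) -> float:
        return self.means[(epoch, ratio)]


def detect_new_lesions(
    labels_prev: LabelVolume,
    labels_curr: LabelVolume,
    max_overlap_fraction: float = 0.10,
) -> list[int]:
    """Lesion ids in curr whose mask barely overlaps any prev lesion."""
    if labels_prev.grid != labels_curr.grid:
        raise ValueError("epochs must share one grid")
    prev_lesions = labels_prev.data >= 10
    new_ids = []
    for lid in labels_curr.lesion_ids:
        mask = labels_curr.data == lid
        overlap = (mask & prev_lesions).sum() / mask.sum()
        if overlap < max_overlap_fraction:
            new_ids.append(lid)
    return new_ids


def build_tracks(
    timepoints: dict[str, "object"],
    new_ids: list[int],
    iron_types: dict[int, IronType],
) -> list[NewLesionTrack]:
    """Evaluate each new lesion's Year-0 footprint at all three epochs.

    ``timepoints`` maps epoch names to objects with ``labels`` and ``maps``
    attributes. The iron classification (assessed at Year 0) collapses
    {area, transition, rim} to "iron".
    """
    missing = [e for e in EPOCHS if e not in timepoints]
    if missing:
        raise ValueError(f"missing epochs: {missing}")
    y0 = timepoints["year0"]
    tracks = []
    for lid in new_ids:
        fp = np.array(np.nonzero(y0.labels.data == lid))
        if fp.shape[1] == 0:
            raise ValueError(f"new lesion {lid} absent from the Year 0 labels")
        ym1 = timepoints["year_minus1"].labels.data[tuple(fp)]
        if np.any(ym1 >= 10):
            raise ValueError(f"Year -1 footprint of lesion {lid} contains lesion labels")
        track = NewLesionTrack(
            lesion_id=lid,
            iron_status=iron_group(iron_types[lid]),
            footprint=fp,
        )
        for epoch in EPOCHS:
            tp = timepoints[epoch]
            for ratio in RATIOS:
                track.means[(epoch, ratio)] = tp.maps[ratio].mean_over(fp)
        tracks.append(track)
    return tracks


def tracks_to_frame(tracks: list[NewLesionTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for (epoch, ratio), v in t.means.items():
            rows.append({"lesion_id": t.lesion_id, "iron_status": t.iron_status,
                         "epoch": epoch, "ratio": ratio, "mean": v})
    return pd.DataFrame(rows, columns=["lesion_id", "iron_status", "epoch", "ratio", "mean"])


def compare_epochs(
    tracks: list[NewLesionTrack],
    min_group_size: int = 2,
) -> dict[str, GroupComparison]:
    """ANOVA + Tukey across epochs within each grouping, per ratio.

    Groupings: "all_new" (every track), "iron" and "non_iron" subsets —
    each compared across Year -1 / Year 0 / Year 1 — plus iron vs non-iron
    within each epoch. Keys are "<ratio>|<grouping>" and "<ratio>|<epoch>".
    """
    out: dict[str, GroupComparison] = {}
    subsets = {
        "all_new": tracks,
        "iron": [t for t in tracks if t.iron_status == "iron"],
        "non_iron": [t for t in tracks if t.iron_status == "non_iron"],
    }
    for ratio in RATIOS:
        for gname, sub in subsets.items():
            groups = {
                epoch: np.array([t.mean(epoch, ratio) for t in sub])
                for epoch in EPOCHS
            }
            groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
            groups = {k: v for k, v in groups.items() if v.size >= min_group_size}
            if len(groups) >= 2:
                out[f"{ratio}|{gname}"] = compare_groups(
                    groups, label=f"{ratio} {gname} across epochs",
                    min_group_size=min_group_size)
        for epoch in EPOCHS:
            groups = {}
            for status in ("iron", "non_iron"):
                vals = np.array([t.mean(epoch, ratio) for t in subsets[status]])
                vals = vals[np.isfinite(vals)]
                if vals.size >= min_group_size:
                    groups[status] = vals
            if len(groups) >= 2:
                out[f"{ratio}|{epoch}"] = compare_groups(
                    groups, label=f"{ratio} iron vs non-iron at {epoch}",
                    min_group_size=min_group_size)
    return out
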