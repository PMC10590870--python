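"""Synthetic cohort generator.

Builds seeded phantoms with the statistical structure of the emulated 7 T
MRSI study: a concentric WM/GM/CSF anatomy carrying spherical lesions of
four iron-accumulation types at the published prevalences, metabolite-ratio
maps whose group means/SDs and within-lesion radial gradients follow the
published tables, an SWI-like susceptibility volume with type-specific
hypointensity patterns, and a three-timepoint longitudinal series with
newly emerging lesions.

Two variance sources are modeled separately: a multiplicative lognormal
factor per (lesion, ratio) carries the across-lesion scatter (matching the
published coefficients of variation), and additive Gaussian voxel noise
carries the within-lesion scatter. With both zeroed the generator is an
exact calibration instrument: every per-lesion volume-weighted mean equals
its recorded ground-truth value to machine precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    EPOCHS,
    RATIOS,
    IronType,
    PhantomConfig,
    iron_group,
)
from .volumes import BACKGROUND, CSF, GM, LESION_LABEL_MIN, WM, GridSpec, LabelVolume, RatioMap

#: depth (in layer-thickness units, measured inward from the lesion surface)
#: at which the radial profile reaches the L0 / L-3 anchors
_ANCHOR_DEPTH_L0 = 0.5
_ANCHOR_DEPTH_CORE = 2.5


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and type of one spherical lesion."""

    lesion_id: int
    center_mm: tuple[float, float, float]
    radius_mm: float
    iron_type: IronType
    emergence_timepoint: str = "pre_existing"  # or "year0"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.lesion_id < 1:
            raise ValueError("lesion_id must be a positive integer")


@dataclass
class GroundTruth:
    """Per-lesion generating parameters recorded for downstream validation."""

    specs: list[LesionSpec]
    #: (lesion_id, ratio) -> volume-weighted true lesion mean
    true_mean: dict[tuple[int, str], float] = field(default_factory=dict)
    #: (lesion_id, ratio) -> (L0 anchor, L-3 anchor) of the radial profile
    layer_anchors: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)
    lesion_scaling: str = "group_mean"

    def spec(self, lesion_id: int) -> LesionSpec:
        for s in self.specs:
            if s.lesion_id == lesion_id:
                return s
        raise KeyError(lesion_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.specs:
            row = {
                "lesion_id": s.lesion_id,
                "iron_type": s.iron_type.value,
                "center_x_mm": s.center_mm[0],
                "center_y_mm": s.center_mm[1],
                "center_z_mm": s.center_mm[2],
                "radius_mm": s.radius_mm,
                "emergence_timepoint": s.emergence_timepoint,
            }
            for r in RATIOS:
                row[f"true_mean {r}"] = self.true_mean.get((s.lesion_id, r), np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Anatomy and lesion placement
# ---------------------------------------------------------------------------


def _anatomy_radii(config: PhantomConfig) -> tuple[float, float, float]:
    """(WM, GM, brain) outer radii in mm for the concentric compartments."""
    extent = min(n * v for n, v in zip(config.grid_shape, config.voxel_size_mm))
    r_brain = config.brain_radius_frac * extent
    r_gm = r_brain - config.csf_thickness_mm
    r_wm = r_gm - config.gm_thickness_mm
    if r_wm <= 0:
        raise ValueError("grid too small for the configured compartment thicknesses")
    return r_wm, r_gm, r_brain


def _center_mm(config: PhantomConfig) -> np.ndarray:
    return np.array([(n - 1) * v / 2.0 for n, v in zip(config.grid_shape, config.voxel_size_mm)])


def _radius_grid_mm(config: PhantomConfig) -> np.ndarray:
    c = _center_mm(config)
    axes = [np.arange(n) * v - c[a]
            for a, (n, v) in enumerate(zip(config.grid_shape, config.voxel_size_mm))]
    xx = axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    return np.sqrt(xx)


def make_anatomy(config: PhantomConfig) -> LabelVolume:
    """Concentric-compartment brain: WM core, GM rind, CSF shell, background."""
    r_wm, r_gm, r_brain = _anatomy_radii(config)
    rr = _radius_grid_mm(config)
    data = np.full(config.grid_shape, BACKGROUND, dtype=np.int16)
    data[rr <= r_brain] = CSF
    data[rr <= r_gm] = GM
    data[rr <= r_wm] = WM
    grid = GridSpec(tuple(config.grid_shape), tuple(config.voxel_size_mm))
    return LabelVolume(data, grid)


def sample_iron_types(n: int, probs: dict[str, float], rng: np.random.Generator) -> list[IronType]:
    """Draw n iron types i.i.d. from the configured prevalences."""
    names = list(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    p = p / p.sum()
    draws = rng.choice(len(names), size=n, p=p)
    return [IronType(names[i]) for i in draws]


def sample_lesion_specs(
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
    iron_types: list[IronType] | None = None,
    n_lesions: int | None = None,
    max_attempts_per_lesion: int = 5000,
) -> list[LesionSpec]:
    """Place pairwise-disjoint spherical lesions inside the WM compartment.

    Types are i.i.d. from ``config.iron_type_probs`` unless an explicit list
    is given (exact group sizes). Centers are rejection-sampled so every
    sphere stays at least one voxel inside WM and spheres keep a one-voxel
    gap. Deterministic given the generator state.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_lesions if n_lesions is None else n_lesions
    if iron_types is None:
        iron_types = sample_iron_types(n, config.iron_type_probs, rng)
    elif len(iron_types) != n:
        raise ValueError("iron_types length must equal the lesion count")
    if n == 0:
        return []

    r_wm, _, _ = _anatomy_radii(config)
    voxel = float(min(config.voxel_size_mm))
    center = _center_mm(config)
    rmin, rmax = config.lesion_radius_range_mm

    specs: list[LesionSpec] = []
    placed = np.empty((0, 4))  # x, y, z, r
    for i, itype in enumerate(iron_types):
        radius = float(rng.uniform(rmin, rmax))
        max_c = r_wm - radius - voxel
        if max_c <= 0:
            raise RuntimeError("lesion radius too large for the WM compartment")
        for attempt in range(max_attempts_per_lesion):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = max_c * rng.uniform() ** (1.0 / 3.0)
            pos = center + u * rad
            if placed.size:
                d = np.linalg.norm(placed[:, :3] - pos, axis=1)
                if np.any(d < placed[:, 3] + radius + voxel):
                    continue
            break
        else:
            raise RuntimeError(
                f"could not place lesion {i + 1}/{n} after {max_attempts_per_lesion} "
                "attempts: configuration too dense")
        placed = np.vstack([placed, [*pos, radius]])
        specs.append(LesionSpec(
            lesion_id=LESION_LABEL_MIN + i,
            center_mm=tuple(float(x) for x in pos),
            radius_mm=radius,
            iron_type=itype,
        ))
    return specs


def rasterize_phantom(specs: list[LesionSpec], config: PhantomConfig) -> LabelVolume:
    """Label volume: concentric anatomy plus one integer label per lesion.

    A voxel belongs to a lesion iff its center lies within ``radius_mm`` of
    the lesion center. Overlapping rasterized lesions or lesion voxels
    falling outside WM raise errors.
    """
    vol = make_anatomy(config)
    data = vol.data
    spacing = np.asarray(config.voxel_size_mm)
    for s in specs:
        lo = np.maximum(0, np.floor((np.asarray(s.center_mm) - s.radius_mm) / spacing)).astype(int)
        hi = np.minimum(np.asarray(config.grid_shape),
                        np.ceil((np.asarray(s.center_mm) + s.radius_mm) / spacing) + 1).astype(int)
        sub = tuple(slice(lo[a], hi[a]) for a in range(3))
        axes = [np.arange(lo[a], hi[a]) * spacing[a] - s.center_mm[a] for a in range(3)]
        d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
              + axes[2][None, None, :] ** 2)
        inside = d2 <= s.radius_mm ** 2
        region = data[sub]
        if np.any(region[inside] >= LESION_LABEL_MIN):
            raise ValueError(f"lesion {s.lesion_id} overlaps a previously rasterized lesion")
        if np.any(region[inside] != WM):
            raise ValueError(f"lesion {s.lesion_id} extends outside the WM compartment")
        region[inside] = s.lesion_id
        data[sub] = region
    return vol


# ---------------------------------------------------------------------------
# Ground truth and ratio maps
# ---------------------------------------------------------------------------


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal draw with the requested coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv ** 2)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def draw_ground_truth(
    specs: list[LesionSpec],
    config: PhantomConfig,
    rng: np.random.Generator,
) -> GroundTruth:
    """Draw per-lesion levels and radial anchors; record them as ground truth.

    group_mean mode: true lesion mean = group mean x lognormal factor whose
    CV matches the configured group SD/mean. periphery mode: the lesion level
    is pinned to the NAWM mean (profiles continuous with the periphery) and
    the scatter is carried by the per-lesion layer anchors.
    """
    gt = GroundTruth(specs=list(specs), lesion_scaling=config.lesion_scaling)
    for s in specs:
        grp = iron_group(s.iron_type)
        t = s.iron_type.value
        for r in RATIOS:
            a_mean = config.layer_profile_means[grp][r]
            a_sd = config.layer_profile_sds[grp][r]
            a0 = max(0.05, rng.normal(a_mean["L0"], a_sd["L0"])) if a_sd["L0"] > 0 else a_mean["L0"]
            a3 = max(0.05, rng.normal(a_mean["L-3"], a_sd["L-3"])) if a_sd["L-3"] > 0 else a_mean["L-3"]
            gt.layer_anchors[(s.lesion_id, r)] = (float(a0), float(a3))
            if config.lesion_scaling == "group_mean":
                m = config.lesion_ratio_means[t][r]
                sd = config.lesion_ratio_sds[t][r]
                cv = sd / m if m > 0 else 0.0
                gt.true_mean[(s.lesion_id, r)] = m * _lognormal_factor(rng, cv)
            # periphery mode: true mean depends on voxelization; filled in
            # by generate_ratio_maps
    return gt


def radial_factor(depth_mm: np.ndarray, voxel_mm: float, a_l0: float, a_core: float) -> np.ndarray:
    """Piecewise-linear radial profile vs depth from the lesion surface.

    Anchored at the outermost in-lesion layer (depth 0.5 layer thicknesses,
    value ``a_l0``) and the erosion-3 core (depth 2.5, value ``a_core``),
    clamped outside; one layer is one voxel step.
    """
    d = np.asarray(depth_mm, dtype=float) / voxel_mm
    return np.interp(d, [_ANCHOR_DEPTH_L0, _ANCHOR_DEPTH_CORE], [a_l0, a_core])


def _smooth_field(shape, sd: float, corr_mm: float, voxel_mm: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with unit-SD renormalization."""
    if sd <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if corr_mm > 0:
        sigma = corr_mm / voxel_mm
        f = ndimage.gaussian_filter(white, sigma=sigma)
        f /= max(f.std(), 1e-12)
    else:
        f = white
    return sd * f


def _lesion_voxels(labels: LabelVolume, spec: LesionSpec):
    """Index tuple and depth-from-surface (mm) of one lesion's voxels."""
    mask = labels.data == spec.lesion_id
    idx = np.nonzero(mask)
    spacing = np.asarray(labels.grid.voxel_size_mm)
    pts = np.stack(idx, axis=1) * spacing
    dist = np.linalg.norm(pts - np.asarray(spec.center_mm), axis=1)
    depth = spec.radius_mm - dist
    return idx, depth


def generate_ratio_maps(
    labels: LabelVolume,
    truth: GroundTruth,
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, RatioMap]:
    """Metabolite-ratio maps consistent with the recorded ground truth.

    NAWM/GM/CSF voxels take the NAWM mean plus a smooth heterogeneity field
    (amplitude = configured NAWM SD) plus voxel noise. Lesion voxels take
    ``p_l * g_l(depth)`` where g_l interpolates the lesion's layer anchors
    and ``p_l`` is calibrated per lesion and ratio:

    * group_mean mode — the volume-weighted mean over the lesion's voxels
      equals the recorded true mean exactly (to 1e-9 with noise 0);
    * periphery mode — ``p_l`` equals the NAWM mean, so the profile is
      continuous with the periphery and the normalized layer profile
      reproduces the anchors.

    Negative values after noise are clipped at zero (count in ``meta``).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    for r in config.noise_sd_map:
        if r not in RATIOS:
            raise KeyError(f"unknown ratio name {r!r}")
    voxel = float(min(config.voxel_size_mm))
    tissue = labels.data > BACKGROUND
    maps: dict[str, RatioMap] = {}
    for r in RATIOS:
        data = np.zeros(labels.grid.shape, dtype=np.float64)
        data[tissue] = config.nawm_ratio_means[r]
        data[tissue] += _smooth_field(
            labels.grid.shape, config.nawm_ratio_sds[r],
            config.nawm_field_correlation_mm, voxel, rng)[tissue]

        for s in truth.specs:
            if not np.any(labels.data == s.lesion_id):
                continue
            idx, depth = _lesion_voxels(labels, s)
            a0, a3 = truth.layer_anchors[(s.lesion_id, r)]
            g = radial_factor(depth, voxel, a0, a3)
            if config.lesion_scaling == "group_mean":
                m = truth.true_mean[(s.lesion_id, r)]
                p = m / g.mean()
            else:
                p = config.nawm_ratio_means[r]
                truth.true_mean[(s.lesion_id, r)] = float(p * g.mean())
            data[idx] = p * g

        n_clip = 0
        if config.noise_sd_map[r] > 0:
            data[tissue] += rng.normal(0.0, config.noise_sd_map[r],
                                       size=int(tissue.sum()))
            neg = data < 0
            n_clip = int(neg.sum())
            data[neg] = 0.0
        maps[r] = RatioMap(r, data, labels.grid, mask=tissue.copy(),
                           meta={"n_clipped_negative": n_clip})
    return maps


# ---------------------------------------------------------------------------
# Susceptibility volume
# ---------------------------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(3, 1)  # 6-connected


def generate_susceptibility_volume(
    labels: LabelVolume,
    specs: list[LesionSpec],
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> RatioMap:
    """SWI-like scalar volume with type-specific hypointensity.

    rim: the 1-voxel outermost in-lesion shell drops by the full depth
    ``swi_delta``; area: every lesion voxel drops by the full depth;
    transition: graded drop, strongest at the shell and fading to zero at
    45% relative depth; non_iron: unchanged. Because lesion diameters exceed
    three slices, every iron-type hypointensity spans >= 3 contiguous axial
    slices by construction.
    """
    if config.swi_delta <= 0:
        raise ValueError("swi_delta must be positive")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    data = np.full(labels.grid.shape, config.swi_background, dtype=np.float64)

    for s in specs:
        mask = labels.data == s.lesion_id
        if not mask.any():
            continue
        if s.iron_type is IronType.NON_IRON:
            continue
        if s.iron_type is IronType.AREA:
            data[mask] -= config.swi_delta
        elif s.iron_type is IronType.RIM:
            shell = mask & ~ndimage.binary_erosion(mask, structure=_CROSS)
            data[shell] -= config.swi_delta
        else:  # transition: graded with depth
            idx, depth = _lesion_voxels(labels, s)
            fade = config.transition_fade_depth * s.radius_mm
            drop = config.swi_delta * np.clip(1.0 - depth / fade, 0.0, 1.0)
            data[idx] -= drop

    if config.swi_noise_sd > 0:
        data += rng.normal(0.0, config.swi_noise_sd, size=data.shape)
    return RatioMap("swi", data, labels.grid, mask=labels.brain_mask(),
                    meta={"background": config.swi_background})


# ---------------------------------------------------------------------------
# Subject bundle and longitudinal series
# ---------------------------------------------------------------------------


@dataclass
class SubjectPhantom:
    """One synthetic subject: labels, ground truth, ratio maps and SWI."""

    labels: LabelVolume
    specs: list[LesionSpec]
    truth: GroundTruth
    maps: dict[str, RatioMap]
    swi: RatioMap


def generate_subject(
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
    iron_types: list[IronType] | None = None,
) -> SubjectPhantom:
    """Full single-subject phantom (specs -> labels -> truth -> maps -> SWI)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    specs = sample_lesion_specs(config, rng=rng, iron_types=iron_types,
                                n_lesions=None if iron_types is None else len(iron_types))
    labels = rasterize_phantom(specs, config)
    truth = draw_ground_truth(specs, config, rng)
    maps = generate_ratio_maps(labels, truth, config, rng=rng)
    swi = generate_susceptibility_volume(labels, specs, config, rng=rng)
    return SubjectPhantom(labels, specs, truth, maps, swi)


@dataclass
class TimepointVolume:
    epoch: str
    labels: LabelVolume
    maps: dict[str, RatioMap]
    swi: RatioMap


@dataclass
class LongitudinalPhantom:
    """Three co-registered epochs sharing one grid, plus ground truth."""

    epochs: dict[str, TimepointVolume]
    truth: GroundTruth
    new_lesion_ids: list[int]
    #: (lesion_id, ratio) -> per-epoch true footprint means
    epoch_means: dict[tuple[int, str], tuple[float, float, float]]


def generate_longitudinal_cohort(
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> LongitudinalPhantom:
    """Three-timepoint series with newly emerging lesions.

    Pre-existing lesions keep one ground truth across epochs; newly emerging
    lesions are absent from the Year -1 label volume but their future
    footprint carries the configured per-epoch means (times a lognormal
    across-lesion factor) at every epoch, emulating pre-lesional NAWM.
    Iron-status prevalence follows ``new_lesion_iron_prob``; iron newcomers
    are given a rim-type SWI signature.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    n_pre = config.n_lesions
    n_new = config.n_new_lesions

    statuses = ["iron" if rng.uniform() < config.new_lesion_iron_prob else "non_iron"
                for _ in range(n_new)]
    new_types = [IronType.RIM if st == "iron" else IronType.NON_IRON for st in statuses]
    pre_types = sample_iron_types(n_pre, config.iron_type_probs, rng)
    all_specs = sample_lesion_specs(
        config, rng=rng, iron_types=pre_types + new_types, n_lesions=n_pre + n_new)
    pre_specs = all_specs[:n_pre]
    new_specs = [dataclasses.replace(s, emergence_timepoint="year0") for s in all_specs[n_pre:]]

    truth = draw_ground_truth(pre_specs + new_specs, config, rng)
    labels_pre = rasterize_phantom(pre_specs, config)
    labels_full = rasterize_phantom(pre_specs + new_specs, config)

    # per-(new lesion, ratio, epoch) true means
    epoch_means: dict[tuple[int, str], tuple[float, float, float]] = {}
    for s, st in zip(new_specs, statuses):
        for r in RATIOS:
            means = config.longitudinal_means[st][r]
            sds = config.longitudinal_sds[st][r]
            vals = []
            for m, sd in zip(means, sds):
                cv = sd / m if m > 0 else 0.0
                vals.append(m * _lognormal_factor(rng, cv))
            epoch_means[(s.lesion_id, r)] = tuple(vals)

    epochs: dict[str, TimepointVolume] = {}
    for ei, epoch in enumerate(EPOCHS):
        labels = labels_pre if epoch == "year_minus1" else labels_full
        maps = generate_ratio_maps(labels_pre, truth_subset(truth, pre_specs), config, rng=rng)
        # overwrite the new-lesion footprints with their epoch values
        for s in new_specs:
            fp = labels_full.data == s.lesion_id
            for r in RATIOS:
                vals = np.full(int(fp.sum()), epoch_means[(s.lesion_id, r)][ei])
                if config.noise_sd_map[r] > 0:
                    vals += rng.normal(0.0, config.noise_sd_map[r],
                                       size=vals.size)
                maps[r].data[fp] = np.clip(vals, 0.0, None)
        swi_specs = pre_specs if epoch == "year_minus1" else pre_specs + new_specs
        swi = generate_susceptibility_volume(labels, swi_specs, config, rng=rng)
        epochs[epoch] = TimepointVolume(epoch, labels, maps, swi)

    return LongitudinalPhantom(
        epochs=epochs, truth=truth,
        new_lesion_ids=[s.lesion_id for s in new_specs],
        epoch_means=epoch_means,
    )


def truth_subset(truth: GroundTruth, specs: list[LesionSpec]) -> GroundTruth:
    ids = {s.lesion_id for s in specs}
    return GroundTruth(
        specs=[s for s in truth.specs if s.lesion_id in ids],
        true_mean={k: v for k, v in truth.true_mean.items() if k[0] in ids},
        layer_anchors={k: v for k, v in truth.layer_anchors.items() if k[0] in ids},
        lesion_scaling=truth.lesion_scaling,
    )
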