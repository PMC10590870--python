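"""End-to-end cohort orchestration.

Chains the stages the way the emulated study does: synthetic cohort ->
(optional) MRSI spectral synthesis + linear-combination fitting with quality
maps -> resampling to the anatomical grid -> lesion/NAWM ROI extraction and
iron-type classification -> layer profiling -> longitudinal tracking ->
group statistics report.

Group-statistics cohorts use the generator's anatomical-grid ratio maps
(these emulate the measured, already partial-volumed maps of the study);
the MRSI stage is value-preserving on a matched grid and is exercised for
its own outputs (ratio + CRLB/SNR/FWHM maps), not to degrade the cohort
maps a second time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import INCLUDED_LESION_COUNTS, RATIOS, IronType, PhantomConfig
from .phantom import (
    LongitudinalPhantom,
    SubjectPhantom,
    generate_longitudinal_cohort,
    generate_subject,
)
from .roi import classify_lesions, extract_lesion_rois, place_nawm_rois, summarize_rois
from .layers import LayerProfile, cohort_layer_stacks, compare_layer_groups
from .longitudinal import build_tracks, compare_epochs, tracks_to_frame
from .spectral import BasisSet, FitMaps, build_basis, fit_spectra_grid, make_ratio_maps, synthesize_spectrum
from .stats import GroupComparison, compare_groups, emit_report
from .volumes import BACKGROUND, GridSpec, LabelVolume, RatioMap


def _spawn(rng: np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(int(rng.integers(0, 2 ** 31 - 1)))


def cohort_type_list(counts: dict[str, int] | None = None) -> list[IronType]:
    """Explicit iron-type list with the published included-group sizes."""
    counts = counts or INCLUDED_LESION_COUNTS
    out: list[IronType] = []
    for t, n in counts.items():
        out.extend([IronType(t)] * n)
    return out


def generate_cohort(
    config: PhantomConfig,
    rng: np.random.Generator,
    type_counts: dict[str, int] | None = None,
    n_subjects: int = 10,
) -> list[SubjectPhantom]:
    """Split a cohort's lesions across subjects and generate each phantom.

    With ``type_counts`` the cohort carries exactly those group sizes
    (shuffled across subjects); otherwise each subject draws
    ``config.n_lesions`` lesions i.i.d. from the configured prevalences.
    """
    subjects = []
    if type_counts is not None:
        types = cohort_type_list(type_counts)
        order = rng.permutation(len(types))
        types = [types[i] for i in order]
        per = int(np.ceil(len(types) / n_subjects))
        chunks = [types[i * per:(i + 1) * per] for i in range(n_subjects)]
        chunks = [c for c in chunks if c]
    else:
        chunks = [None] * n_subjects
    for chunk in chunks:
        subjects.append(generate_subject(config, rng=_spawn(rng), iron_types=chunk))
    return subjects


# ---------------------------------------------------------------------------
# MRSI stage
# ---------------------------------------------------------------------------


def mrsi_slab_grid(anat: GridSpec, n_xy: int = 32, slab_thickness_mm: float = 8.0,
                   center_z_mm: float | None = None) -> GridSpec:
    """Single-slice MRSI grid over the anatomical field of view."""
    fov = (anat.shape[0] * anat.voxel_size_mm[0], anat.shape[1] * anat.voxel_size_mm[1])
    if center_z_mm is None:
        center_z_mm = (anat.shape[2] - 1) * anat.voxel_size_mm[2] / 2.0
    return GridSpec(
        shape=(n_xy, n_xy, 1),
        voxel_size_mm=(fov[0] / n_xy, fov[1] / n_xy, slab_thickness_mm),
        origin_mm=(anat.origin_mm[0] + (fov[0] / n_xy - anat.voxel_size_mm[0]) / 2.0,
                   anat.origin_mm[1] + (fov[1] / n_xy - anat.voxel_size_mm[1]) / 2.0,
                   center_z_mm),
    )


def amplitude_maps_from_ratios(maps: dict[str, RatioMap],
                               labels: LabelVolume,
                               tcr_amplitude: float = 1.0,
                               mm_amplitude: float = 0.5) -> dict[str, np.ndarray]:
    """Metabolite amplitude volumes consistent with the ratio maps.

    Total creatine is the unit reference; mIns is derived from
    mIns/tNAA x tNAA/tCr so that the fitted mIns/tNAA and tNAA/tCr maps
    reproduce the generator's maps exactly (the independent mIns/tCr map is
    then their product — three of the four ratios can be simultaneously
    consistent with a single amplitude assignment, and these are the three
    the analysis leans on).
    """
    brain = labels.data > BACKGROUND
    a_tcr = np.where(brain, tcr_amplitude, 0.0)
    a_tnaa = maps["tNAA/tCr"].data * a_tcr
    a_mins = maps["mIns/tNAA"].data * a_tnaa
    a_tcho = maps["tCho/tCr"].data * a_tcr
    a_mm = np.where(brain, mm_amplitude, 0.0)
    return {"tNAA": a_tnaa, "tCr": a_tcr, "tCho": a_tcho, "mIns": a_mins, "MM": a_mm}


def block_average_to_grid(volume: np.ndarray, src: GridSpec, dst: GridSpec) -> np.ndarray:
    """Mean of source voxels whose centers fall inside each target voxel."""
    out = np.zeros(dst.shape, dtype=np.float64)
    cnt = np.zeros(dst.shape, dtype=np.int64)
    centers = src.voxel_centers()
    bins = []
    for a in range(3):
        edges = (np.asarray(dst.origin_mm[a]) - dst.voxel_size_mm[a] / 2.0
                 + np.arange(dst.shape[a] + 1) * dst.voxel_size_mm[a])
        bins.append(np.digitize(centers[a], edges) - 1)
    ii, jj, kk = np.meshgrid(*bins, indexing="ij")
    ok = ((ii >= 0) & (ii < dst.shape[0]) & (jj >= 0) & (jj < dst.shape[1])
          & (kk >= 0) & (kk < dst.shape[2]))
    flat = np.ravel_multi_index((ii[ok], jj[ok], kk[ok]), dst.shape)
    np.add.at(out.ravel(), flat, volume[ok])
    np.add.at(cnt.ravel(), flat, 1)
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, out / np.maximum(cnt, 1), 0.0)
    return out


@dataclass
class MrsiStage:
    grid: GridSpec
    spectra: np.ndarray
    fits: FitMaps
    ratio_maps: dict[str, RatioMap]
    basis: BasisSet


def run_mrsi_stage(
    subject: SubjectPhantom,
    rng: np.random.Generator,
    basis: BasisSet | None = None,
    spectrum_config=None,
    mrsi_grid: GridSpec | None = None,
    coverage_threshold: float = 0.5,
    crlb_exclude_percent: float = 40.0,
) -> MrsiStage:
    """Synthesize, fit and map one subject's MRSI slab.

    Amplitude volumes derived from the subject's ratio maps are block-
    averaged onto the MRSI grid, a spectrum is synthesized and fitted per
    voxel with brain coverage above threshold, and the fitted amplitudes
    yield the four ratio maps plus CRLB/SNR/FWHM quality maps.
    """
    basis = basis or build_basis(config=spectrum_config)
    spec_cfg = basis.config
    grid = mrsi_grid or mrsi_slab_grid(subject.labels.grid)
    amps = amplitude_maps_from_ratios(subject.maps, subject.labels)
    coverage = block_average_to_grid(
        (subject.labels.data > BACKGROUND).astype(float), subject.labels.grid, grid)
    avg = {name: block_average_to_grid(vol, subject.labels.grid, grid)
           for name, vol in amps.items()}
    voxel_mask = coverage >= coverage_threshold

    spectra = np.zeros(tuple(grid.shape) + (spec_cfg.n_points,), dtype=complex)
    for vox in np.ndindex(*grid.shape):
        if not voxel_mask[vox]:
            continue
        a = {name: max(0.0, float(avg[name][vox])) for name in basis.names}
        spectra[vox] = synthesize_spectrum(a, basis, spec_cfg, seed=_spawn(rng)).intensity
    fits = fit_spectra_grid(spectra, grid, basis, spec_cfg, voxel_mask=voxel_mask)
    rmaps = make_ratio_maps(fits, crlb_exclude_percent=crlb_exclude_percent)
    return MrsiStage(grid=grid, spectra=spectra, fits=fits, ratio_maps=rmaps, basis=basis)


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    roi_table: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    layer_profiles: list[LayerProfile] = field(default_factory=list)
    layer_comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    track_table: pd.DataFrame | None = None
    epoch_comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    mrsi: MrsiStage | None = None


def analyze_cohort_rois(
    subjects: list[SubjectPhantom],
    rng: np.random.Generator,
    nawm_rois_per_subject: int = 4,
    min_volume_mm3: float = 20.0,
    classify_from_swi: bool = True,
) -> pd.DataFrame:
    """Lesion + NAWM ROI table over a multi-subject cohort."""
    frames = []
    for si, subj in enumerate(subjects):
        if classify_from_swi:
            types = classify_lesions(subj.labels, subj.swi)
        else:
            types = {s.lesion_id: s.iron_type for s in subj.specs}
        lesions = extract_lesion_rois(subj.labels, min_volume_mm3=min_volume_mm3,
                                      iron_types=types)
        nawm = place_nawm_rois(subj.labels, nawm_rois_per_subject, seed=_spawn(rng))
        df = summarize_rois(lesions + nawm, subj.maps)
        df.insert(0, "subject", si)
        df["roi_id"] = [f"s{si}_{r}" for r in df["roi_id"]]
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def roi_group_comparisons(roi_table: pd.DataFrame) -> dict[str, GroupComparison]:
    """Per-ratio ANOVA + Tukey across NAWM and the four lesion types."""
    out = {}
    for ratio in RATIOS:
        groups = {"NAWM": roi_table.loc[roi_table["kind"] == "nawm", ratio].dropna().to_numpy()}
        for t in ("non_iron", "area", "transition", "rim"):
            sel = (roi_table["kind"] == "lesion") & (roi_table["iron_type"] == t)
            groups[t] = roi_table.loc[sel, ratio].dropna().to_numpy()
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) >= 2:
            out[ratio] = compare_groups(groups, label=f"{ratio} iron types vs NAWM")
    return out


def run_full_pipeline(
    config: PhantomConfig | None = None,
    seed: int = 0,
    n_subjects: int = 10,
    type_counts: dict[str, int] | None = None,
    nawm_rois_per_subject: int = 4,
    with_mrsi: bool = True,
    with_layers: bool = True,
    with_longitudinal: bool = True,
    out_dir=None,
) -> CohortResult:
    """Cohort generation -> fit -> ROIs -> layers -> tracks -> report."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    if type_counts is None:
        type_counts = dict(INCLUDED_LESION_COUNTS)

    subjects = generate_cohort(config, rng, type_counts=type_counts, n_subjects=n_subjects)
    mrsi = (run_mrsi_stage(subjects[0], rng, spectrum_config=config.spectrum)
            if with_mrsi else None)

    roi_table = analyze_cohort_rois(subjects, rng, nawm_rois_per_subject=nawm_rois_per_subject)
    comparisons = roi_group_comparisons(roi_table)

    profiles: list[LayerProfile] = []
    layer_comparisons: dict[str, GroupComparison] = {}
    if with_layers:
        for subj in subjects:
            types = {s.lesion_id: s.iron_type for s in subj.specs}
            profiles.extend(cohort_layer_stacks(subj.labels, types, subj.maps))
        if profiles:
            try:
                layer_comparisons = compare_layer_groups(profiles)
            except ValueError:
                layer_comparisons = {}

    track_table = None
    epoch_comparisons: dict[str, GroupComparison] = {}
    if with_longitudinal:
        import dataclasses as _dc
        lcfg = _dc.replace(config, seed=int(rng.integers(0, 2 ** 31 - 1)))
        lphantom = generate_longitudinal_cohort(lcfg)
        types = {s.lesion_id: s.iron_type for s in lphantom.truth.specs}
        tracks = build_tracks(lphantom.epochs, lphantom.new_lesion_ids, types)
        track_table = tracks_to_frame(tracks)
        epoch_comparisons = compare_epochs(tracks)

    if out_dir is not None:
        all_comps = {**comparisons,
                     **{f"layers {k}": v for k, v in layer_comparisons.items()},
                     **{f"tracks {k}": v for k, v in epoch_comparisons.items()}}
        emit_report(all_comps, out_dir, run_meta={"seed": seed,
                                                  "n_subjects": n_subjects,
                                                  "type_counts": type_counts})
        roi_table.to_csv(f"{out_dir}/rois.csv", index=False)
        if track_table is not None:
            track_table.to_csv(f"{out_dir}/tracks.csv", index=False)

    return CohortResult(
        roi_table=roi_table, comparisons=comparisons,
        layer_profiles=profiles, layer_comparisons=layer_comparisons,
        track_table=track_table, epoch_comparisons=epoch_comparisons,
        mrsi=mrsi,
    )
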