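"""Synthetic cohort generator: geometry, calibration and prevalences."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage, stats as sps

import rimspec as rs
from rimspec.config import LESION_RATIO_MEANS, NAWM_RATIO_MEANS, SEGMENTED_LESION_COUNTS
from rimspec.phantom import (
    draw_ground_truth,
    make_anatomy,
    radial_factor,
    sample_iron_types,
    sample_lesion_specs,
)
from rimspec.volumes import CSF, GM, WM


def small_config(**kw):
    kw.setdefault("grid_shape", (48, 48, 48))
    kw.setdefault("n_lesions", 3)
    kw.setdefault("lesion_radius_range_mm", (2.0, 3.0))
    return rs.PhantomConfig(**kw)


# -- lesion specs -----------------------------------------------------------


def test_zero_lesions_gives_empty_list():
    cfg = small_config(n_lesions=0)
    assert sample_lesion_specs(cfg) == []


def test_same_seed_same_specs():
    cfg = small_config(seed=7)
    assert sample_lesion_specs(cfg) == sample_lesion_specs(cfg)


def test_type_fractions_match_prevalences():
    """i.i.d. type draws reproduce the cohort fractions within 3 binomial SE."""
    n = 4870
    probs = rs.config.default_iron_type_probs()
    types = sample_iron_types(n, probs, np.random.default_rng(1))
    counts = {t: sum(1 for x in types if x.value == t) for t in probs}
    for t, p in probs.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[t] / n - p) < 3 * se, t
    # chi-square goodness of fit at n = 5000
    types = sample_iron_types(5000, probs, np.random.default_rng(2))
    obs = [sum(1 for x in types if x.value == t) for t in probs]
    exp = [5000 * p for p in probs.values()]
    assert sps.chisquare(obs, exp).pvalue > 0.001


def test_lesions_disjoint_and_inside_wm():
    cfg = small_config(n_lesions=5, seed=2)
    specs = sample_lesion_specs(cfg)
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            d = np.linalg.norm(np.array(a.center_mm) - b.center_mm)
            assert d > a.radius_mm + b.radius_mm
    labels = rs.rasterize_phantom(specs, cfg)
    assert sorted(labels.lesion_ids) == [s.lesion_id for s in specs]


def test_too_dense_config_raises():
    cfg = small_config(n_lesions=200)
    with pytest.raises(RuntimeError, match="dense"):
        sample_lesion_specs(cfg, max_attempts_per_lesion=50)


# -- rasterization ----------------------------------------------------------


def brute_force_ball_count(radius_vox):
    n = int(np.ceil(radius_vox)) + 1
    count = 0
    for x in range(-n, n + 1):
        for y in range(-n, n + 1):
            for z in range(-n, n + 1):
                if x * x + y * y + z * z <= radius_vox ** 2:
                    count += 1
    return count


def test_sphere_voxel_count_matches_brute_force():
    """A radius-3 sphere on a 1 mm grid covers exactly the lattice ball."""
    cfg = rs.PhantomConfig(grid_shape=(32, 32, 32), voxel_size_mm=(1.0, 1.0, 1.0),
                           n_lesions=0, lesion_radius_range_mm=(3.0, 3.0))
    center = (16.0, 16.0, 16.0)  # on a voxel center
    spec = rs.LesionSpec(lesion_id=10, center_mm=center, radius_mm=3.0,
                         iron_type=rs.IronType.NON_IRON)
    labels = rs.rasterize_phantom([spec], cfg)
    expected = brute_force_ball_count(3.0)
    assert (labels.data == 10).sum() == expected == 123


def test_zero_specs_only_tissue_labels():
    labels = rs.rasterize_phantom([], small_config())
    inside = labels.data[labels.data > 0]
    assert set(np.unique(inside)) == {WM, GM, CSF}


def test_lesion_not_adjacent_to_gm_csf():
    """26-adjacency scan: placement keeps lesions strictly inside WM."""
    cfg = small_config(n_lesions=4, seed=3)
    labels = rs.rasterize_phantom(sample_lesion_specs(cfg), cfg)
    lesions = labels.data >= 10
    grown = ndimage.binary_dilation(lesions, ndimage.generate_binary_structure(3, 3))
    touched = set(np.unique(labels.data[grown & ~lesions]))
    assert GM not in touched and CSF not in touched


def test_overlapping_specs_raise():
    cfg = small_config()
    c = tuple(x * 0.8 for x in ((np.array(cfg.grid_shape) - 1) / 2.0))
    mk = lambda i, dx: rs.LesionSpec(lesion_id=i, center_mm=(c[0] + dx, c[1], c[2]),
                                     radius_mm=3.0, iron_type=rs.IronType.RIM)
    with pytest.raises(ValueError, match="overlaps"):
        rs.rasterize_phantom([mk(10, 0.0), mk(11, 2.0)], cfg)


# -- ratio maps -------------------------------------------------------------


def test_flat_profile_noise_free_voxel_values():
    """With unit anchors and zero noise, lesion voxels equal the group mean
    and NAWM voxels equal the NAWM mean exactly."""
    cfg = small_config(seed=1).noise_free()
    flat = {g: {r: {"L0": 1.0, "L-3": 1.0} for r in rs.RATIOS}
            for g in ("non_iron", "iron")}
    cfg = dataclasses.replace(cfg, layer_profile_means=flat)
    subj = rs.generate_subject(cfg, iron_types=[rs.IronType.NON_IRON] * 3)
    m = subj.maps["mIns/tNAA"]
    lesion = subj.labels.data >= 10
    assert np.allclose(m.data[lesion], LESION_RATIO_MEANS["non_iron"]["mIns/tNAA"])
    nawm = subj.labels.data == WM
    t = subj.maps["tNAA/tCr"]
    assert np.allclose(t.data[nawm], NAWM_RATIO_MEANS["tNAA/tCr"])


def test_volume_weighted_lesion_means_exact(noise_free_subject):
    """Noise-free calibration: per-lesion volume-weighted mean equals the
    recorded ground truth to 1e-9 (direct summation oracle)."""
    subj, _ = noise_free_subject
    for s in subj.specs:
        mask = subj.labels.data == s.lesion_id
        for r in rs.RATIOS:
            direct = subj.maps[r].data[mask].sum() / mask.sum()
            assert abs(direct - subj.truth.true_mean[(s.lesion_id, r)]) < 1e-9


def test_radial_profile_monotone_for_rim(noise_free_subject):
    """mIns/tNAA increases from the lesion surface to the core in rim lesions."""
    subj, _ = noise_free_subject
    for s in subj.specs:
        if s.iron_type is not rs.IronType.RIM:
            continue
        mask = subj.labels.data == s.lesion_id
        idx = np.array(np.nonzero(mask))
        pts = idx.T * 0.8
        dist = np.linalg.norm(pts - np.array(s.center_mm), axis=1)
        vals = subj.maps["mIns/tNAA"].data[tuple(idx)]
        order = np.argsort(dist)  # core outward
        binned = np.array_split(vals[order], 4)
        means = [b.mean() for b in binned]
        assert all(means[i] >= means[i + 1] - 1e-9 for i in range(3))


def test_radial_factor_anchor_clamping():
    g = radial_factor(np.array([0.0, 0.4, 2.0, 3.0]) * 0.8, 0.8, 1.2, 1.5)
    assert g[0] == pytest.approx(1.2)      # at/outside the L0 anchor
    assert g[-1] == pytest.approx(1.5)     # core plateau
    assert 1.2 < g[2] < 1.5


def test_across_lesion_scatter_matches_cv():
    """Lognormal lesion factors reproduce the configured group SD/mean."""
    cfg = rs.PhantomConfig()
    rng = np.random.default_rng(0)
    specs = [rs.LesionSpec(lesion_id=10 + i, center_mm=(0, 0, 0), radius_mm=3.0,
                           iron_type=rs.IronType.RIM) for i in range(4000)]
    truth = draw_ground_truth(specs, cfg, rng)
    means = np.array([truth.true_mean[(s.lesion_id, "mIns/tNAA")] for s in specs])
    assert means.mean() == pytest.approx(1.53, rel=0.05)
    assert means.std(ddof=1) == pytest.approx(0.97, rel=0.10)


def test_negative_values_clipped():
    cfg = small_config(seed=4)
    cfg = dataclasses.replace(cfg, noise_sd_map={r: 0.5 for r in rs.RATIOS})
    subj = rs.generate_subject(cfg)
    m = subj.maps["tCho/tCr"]  # mean 0.46, sd 0.5 -> clipping certain
    assert (m.data >= 0).all()
    assert m.meta["n_clipped_negative"] > 0


# -- susceptibility ---------------------------------------------------------


def test_swi_patterns_noise_free(noise_free_subject):
    """rim = exact 1-voxel shell; area = whole lesion; non-iron untouched."""
    subj, cfg = noise_free_subject
    bg = cfg.swi_background
    cross = ndimage.generate_binary_structure(3, 1)
    for s in subj.specs:
        mask = subj.labels.data == s.lesion_id
        hypo = mask & (subj.swi.data < bg)
        if s.iron_type is rs.IronType.NON_IRON:
            assert not hypo.any()
        elif s.iron_type is rs.IronType.AREA:
            assert hypo.sum() == mask.sum()
        elif s.iron_type is rs.IronType.RIM:
            shell = mask & ~ndimage.binary_erosion(mask, structure=cross)
            assert np.array_equal(hypo, shell)
        else:  # transition: partial, spanning >= 3 axial slices
            assert 0 < hypo.sum() < mask.sum()
            zs = np.unique(np.nonzero(hypo)[2])
            assert len(zs) >= 3


def test_swi_requires_positive_delta():
    cfg = dataclasses.replace(small_config(), swi_delta=0.0)
    subj_specs = sample_lesion_specs(cfg)
    labels = rs.rasterize_phantom(subj_specs, cfg)
    with pytest.raises(ValueError, match="swi_delta"):
        rs.generate_susceptibility_volume(labels, subj_specs, cfg)


# -- determinism and config -------------------------------------------------


def test_subject_bitwise_deterministic():
    cfg = small_config(seed=11)
    a = rs.generate_subject(cfg)
    b = rs.generate_subject(cfg)
    assert np.array_equal(a.labels.data, b.labels.data)
    for r in rs.RATIOS:
        assert np.array_equal(a.maps[r].data, b.maps[r].data)
    assert np.array_equal(a.swi.data, b.swi.data)


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        rs.PhantomConfig(iron_type_probs={"non_iron": 0.5, "area": 0.2,
                                          "transition": 0.1, "rim": 0.1})
    with pytest.raises(ValueError, match="radius"):
        rs.PhantomConfig(lesion_radius_range_mm=(4.0, 2.0))
    with pytest.raises(ValueError, match="deviations"):
        rs.PhantomConfig(noise_sd_map={r: -1.0 for r in rs.RATIOS})


def test_config_yaml_round_trip(tmp_path):
    cfg = small_config(seed=9)
    path = tmp_path / "cfg.yaml"
    cfg.to_file(path)
    back = rs.PhantomConfig.from_file(path)
    assert back.to_dict() == cfg.to_dict()


def test_anatomy_compartment_order():
    labels = make_anatomy(small_config())
    rr = np.linalg.norm(
        (np.stack(np.nonzero(labels.data == WM)).T - (np.array(labels.grid.shape) - 1) / 2)
        * 0.8, axis=1)
    rr_gm = np.linalg.norm(
        (np.stack(np.nonzero(labels.data == GM)).T - (np.array(labels.grid.shape) - 1) / 2)
        * 0.8, axis=1)
    assert rr.max() < rr_gm.min() + 1.6  # WM strictly inside the GM rind
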