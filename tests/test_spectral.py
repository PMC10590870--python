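"""Spectral synthesis and linear-combination fitting."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

import rimspec as rs
from rimspec.config import SpectrumConfig
from rimspec.pipeline import mrsi_slab_grid, run_mrsi_stage
from rimspec.spectral import (
    component_fwhm_hz,
    estimate_noise_sd,
    fit_spectra_grid,
    lorentzian_absorption,
    make_ratio_maps,
)
from rimspec.volumes import GridSpec

CFG0 = SpectrumConfig(noise_sd=0.0)
TRUE_AMPS = {"tNAA": 1.0, "tCr": 0.6, "tCho": 0.3, "mIns": 0.4, "MM": 0.2}


def single_peak_basis(hwhm_hz=3.0, ppm=2.008, config=CFG0):
    table = pd.DataFrame([{"name": "tNAA", "ppm": ppm, "area": 1.0, "hwhm_hz": hwhm_hz}])
    return rs.build_basis(table, config)


# -- basis ------------------------------------------------------------------


def test_component_unit_max_at_nearest_axis_point():
    b = single_peak_basis()
    comp = b.component("tNAA").real
    assert comp.max() == pytest.approx(1.0)
    nearest = np.argmin(np.abs(b.ppm_axis - 2.008))
    assert np.argmax(comp) == nearest


def test_two_equal_peaks_double_the_integral():
    """Numerical-integration oracle on the unnormalized line shapes."""
    cfg = CFG0
    axis = cfg.ppm_axis
    one = lorentzian_absorption(axis, 3.0, 1.0, 4.0, cfg.transmitter_freq_mhz)
    two = one + lorentzian_absorption(axis, 2.5, 1.0, 4.0, cfg.transmitter_freq_mhz)
    assert np.trapezoid(two, axis) == pytest.approx(2 * np.trapezoid(one, axis), rel=1e-3)


def test_empty_and_invalid_tables_raise():
    with pytest.raises(ValueError, match="empty"):
        rs.build_basis(pd.DataFrame(columns=["name", "ppm", "area", "hwhm_hz"]), CFG0)
    bad = pd.DataFrame([{"name": "x", "ppm": 9.9, "area": 1.0, "hwhm_hz": 2.0}])
    with pytest.raises(ValueError, match="outside"):
        rs.build_basis(bad, CFG0)
    dup = pd.DataFrame([{"name": "x", "ppm": 2.0, "area": 1.0, "hwhm_hz": 2.0}] * 2)
    with pytest.raises(ValueError, match="duplicate"):
        rs.build_basis(dup, CFG0)


# -- synthesis --------------------------------------------------------------


def test_zero_amplitudes_zero_noise_gives_zero_spectrum(default_basis):
    cfg = dataclasses.replace(default_basis.config, noise_sd=0.0)
    sp = rs.synthesize_spectrum({n: 0.0 for n in default_basis.names}, default_basis, cfg)
    assert np.all(sp.intensity == 0)


def test_negative_amplitude_rejected(default_basis):
    with pytest.raises(ValueError, match="non-negative"):
        rs.synthesize_spectrum({"tNAA": -1.0}, default_basis)


def test_noiseless_spectrum_in_basis_span():
    """Least-squares projection oracle: residual below 1e-10."""
    b = rs.build_basis(config=CFG0)
    sp = rs.synthesize_spectrum(TRUE_AMPS, b, CFG0)
    B = b.matrix_real
    y = sp.intensity.real
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    assert np.linalg.norm(y - B @ coef) < 1e-10


def test_different_seeds_different_noise(default_basis):
    cfg = dataclasses.replace(default_basis.config, noise_sd=0.1)
    a = rs.synthesize_spectrum(TRUE_AMPS, default_basis, cfg, seed=1).intensity
    b = rs.synthesize_spectrum(TRUE_AMPS, default_basis, cfg, seed=2).intensity
    assert not np.array_equal(a, b)


# -- fitting ----------------------------------------------------------------


def test_noiseless_exact_recovery():
    b = rs.build_basis(config=CFG0)
    sp = rs.synthesize_spectrum(TRUE_AMPS, b, CFG0)
    fit = rs.fit_linear_combination(sp, b, CFG0)
    for name, v in TRUE_AMPS.items():
        assert abs(fit.amplitude(name) - v) < 1e-8


def test_fit_range_locality():
    """Perturbing the spectrum at 1.0 ppm (outside 1.8-4.2) changes nothing."""
    b = rs.build_basis(config=CFG0)
    sp = rs.synthesize_spectrum(TRUE_AMPS, b, CFG0)
    fit_a = rs.fit_linear_combination(sp, b, CFG0)
    k = np.argmin(np.abs(b.ppm_axis - 1.0))
    sp.intensity[k] += 100.0
    fit_b = rs.fit_linear_combination(sp, b, CFG0)
    assert np.array_equal(fit_a.amplitudes, fit_b.amplitudes)


@pytest.mark.parametrize("scale", [0.5, 3.0])
def test_scale_equivariance(scale):
    """Scaling the spectrum scales amplitudes and leaves ratios unchanged."""
    cfg = SpectrumConfig(noise_sd=0.0)
    b = rs.build_basis(config=cfg)
    sp = rs.synthesize_spectrum(TRUE_AMPS, b, cfg)
    base = rs.fit_linear_combination(sp, b, cfg)
    sp2 = rs.Spectrum(sp.intensity * scale, sp.ppm_axis)
    scaled = rs.fit_linear_combination(sp2, b, cfg)
    assert np.allclose(scaled.amplitudes, scale * base.amplitudes, atol=1e-10)
    assert scaled.amplitude("mIns") / scaled.amplitude("tNAA") == pytest.approx(
        base.amplitude("mIns") / base.amplitude("tNAA"))


def test_crlb_inf_sentinel_for_zero_amplitude(default_basis):
    cfg = dataclasses.replace(default_basis.config, noise_sd=0.02)
    amps = dict(TRUE_AMPS)
    amps["tCho"] = 0.0
    rng = np.random.default_rng(3)
    # tCho may come out exactly zero under NNLS; find a draw where it does
    for _ in range(50):
        sp = rs.synthesize_spectrum(amps, default_basis, cfg, seed=rng)
        fit = rs.fit_linear_combination(sp, default_basis, cfg)
        if fit.amplitude("tCho") == 0.0:
            assert np.isinf(fit.crlb("tCho"))
            return
    pytest.fail("NNLS never produced a zero amplitude")


def test_crlb_matches_monte_carlo():
    """Monte-Carlo oracle: empirical SD of the tNAA amplitude within 20% of
    the mean reported CRLB (absolute units), 200 replicates."""
    cfg = SpectrumConfig(noise_sd=0.05)
    b = rs.build_basis(config=cfg)
    rng = np.random.default_rng(42)
    amps, crlbs = [], []
    for _ in range(200):
        sp = rs.synthesize_spectrum(TRUE_AMPS, b, cfg, seed=rng)
        fit = rs.fit_linear_combination(sp, b, cfg)
        amps.append(fit.amplitude("tNAA"))
        crlbs.append(fit.crlb("tNAA") / 100.0 * fit.amplitude("tNAA"))
    ratio = np.std(amps, ddof=1) / np.mean(crlbs)
    assert 0.8 < ratio < 1.2


# -- quality metrics --------------------------------------------------------


def test_lorentzian_fwhm_analytic():
    """HWHM 5 Hz Lorentzian has FWHM 10 Hz within the axis resolution."""
    cfg = SpectrumConfig(n_points=2048, noise_sd=0.0)
    b = single_peak_basis(hwhm_hz=5.0, config=cfg)
    resolution_hz = (cfg.ppm_range[1] - cfg.ppm_range[0]) / cfg.n_points * cfg.hz_per_ppm
    assert component_fwhm_hz(b, "tNAA") == pytest.approx(10.0, abs=resolution_hz)


def test_snr_halves_when_noise_doubles(default_basis):
    rng = np.random.default_rng(5)
    snrs = {}
    for sd in (0.05, 0.10):
        cfg = dataclasses.replace(default_basis.config, noise_sd=sd)
        vals = []
        for _ in range(100):
            sp = rs.synthesize_spectrum(TRUE_AMPS, default_basis, cfg, seed=rng)
            snr, _, _ = rs.quality_metrics(sp, default_basis, cfg)
            vals.append(snr)
        snrs[sd] = np.mean(vals)
    assert snrs[0.05] / snrs[0.10] == pytest.approx(2.0, rel=0.1)


def test_quality_metrics_reject_noiseless():
    b = rs.build_basis(config=CFG0)
    sp = rs.synthesize_spectrum(TRUE_AMPS, b, CFG0)
    with pytest.raises(ValueError, match="noiseless"):
        rs.quality_metrics(sp, b, CFG0)


def test_noise_estimate_matches_truth(default_basis):
    cfg = dataclasses.replace(default_basis.config, noise_sd=0.08)
    rng = np.random.default_rng(6)
    ests = [estimate_noise_sd(
        rs.synthesize_spectrum(TRUE_AMPS, default_basis, cfg, seed=rng), cfg)
        for _ in range(100)]
    assert np.mean(ests) == pytest.approx(0.08, rel=0.1)


# -- ratio maps from fits ---------------------------------------------------


def test_ratio_map_values_and_masking():
    grid = GridSpec((2, 1, 1), (1.0, 1.0, 1.0))
    names = ["tNAA", "tCr", "tCho", "mIns", "MM"]
    amps = np.zeros((2, 1, 1, 5), dtype=np.float32)
    amps[0, 0, 0] = [2.0, 2.0, 1.0, 1.0, 0.1]
    amps[1, 0, 0] = [2.0, 0.0, 1.0, 1.0, 0.1]  # zero denominator
    crlb = np.full((2, 1, 1, 5), 5.0, dtype=np.float32)
    from rimspec.spectral import FitMaps
    fits = FitMaps(grid=grid, names=names, amplitudes=amps, crlb_percent=crlb,
                   snr_naa=np.full((2, 1, 1), 10.0), fwhm_naa_hz=np.full((2, 1, 1), 20.0),
                   fitted=np.ones((2, 1, 1), bool))
    maps = make_ratio_maps(fits)
    assert maps["tNAA/tCr"].data[0, 0, 0] == pytest.approx(1.0)
    assert not maps["tNAA/tCr"].mask[1, 0, 0]          # masked, not inf
    assert np.isfinite(maps["tNAA/tCr"].data).all()
    with pytest.raises(KeyError):
        make_ratio_maps(fits, pairs={"bad": ("nope", "tCr")})


def test_crlb_threshold_masks_voxels():
    grid = GridSpec((1, 1, 1), (1.0, 1.0, 1.0))
    from rimspec.spectral import FitMaps
    amps = np.ones((1, 1, 1, 5), dtype=np.float32)
    crlb = np.full((1, 1, 1, 5), 50.0, dtype=np.float32)  # above threshold
    fits = FitMaps(grid=grid, names=["tNAA", "tCr", "tCho", "mIns", "MM"],
                   amplitudes=amps, crlb_percent=crlb,
                   snr_naa=np.ones((1, 1, 1)), fwhm_naa_hz=np.ones((1, 1, 1)),
                   fitted=np.ones((1, 1, 1), bool))
    maps = make_ratio_maps(fits, crlb_exclude_percent=40.0)
    assert not maps["tNAA/tCr"].mask.any()
    assert maps["tNAA/tCr"].meta["n_excluded"] == 1


def test_mrsi_identity_on_matched_grid_noise_free():
    """End-to-end identity oracle: fitting noise-free spectra synthesized on
    the phantom's own slice grid reproduces the mIns/tNAA map to 1e-6."""
    cfg = rs.PhantomConfig(grid_shape=(40, 40, 40), n_lesions=2, seed=6,
                           lesion_radius_range_mm=(2.0, 2.8)).noise_free()
    subj = rs.generate_subject(cfg)
    anat = subj.labels.grid
    z = anat.shape[2] // 2
    grid = GridSpec((anat.shape[0], anat.shape[1], 1), anat.voxel_size_mm,
                    origin_mm=(0.0, 0.0, z * anat.voxel_size_mm[2]))
    rng = np.random.default_rng(0)
    stage = run_mrsi_stage(subj, rng, spectrum_config=cfg.spectrum, mrsi_grid=grid)
    fitted = stage.fits.fitted[:, :, 0]
    got = stage.ratio_maps["mIns/tNAA"]
    want = subj.maps["mIns/tNAA"].data[:, :, z]
    sel = fitted & got.mask[:, :, 0]
    assert sel.sum() > 100
    assert np.max(np.abs(got.data[:, :, 0][sel] - want[sel])) < 1e-6
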