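import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biaslab import (Volume, apply_bfactor, apply_mask, bias_variance, bic_score,
                     count_parameters, fsc, halo_score, knn_bias_variance,
                     make_mask, make_phantom, mask_fourier_width,
                     masked_fsc_experiment, mixture_prediction,
                     phase_randomize_volume, radial_profile, resolution_at)
from biaslab._fourier import fftn_center, radial_shell_index
from biaslab.diagnostics import NO_CROSSING, FSCCurve, TheoryDemoConfig
from biaslab.volume import radial_coordinates


# ---------------------------------------------------------------------------
# FSC

def test_fsc_self_and_negated(phantom32):
    c = fsc(phantom32, phantom32)
    nz = c.counts > 0
    assert np.allclose(c.values[nz], 1.0)
    cneg = fsc(phantom32, Volume(-phantom32.data, 2.0))
    assert np.allclose(cneg.values[nz], -1.0)


def test_fsc_symmetric(phantom32, phantom32_class2):
    a = fsc(phantom32, phantom32_class2)
    b = fsc(phantom32_class2, phantom32)
    assert np.allclose(a.values, b.values)


def test_fsc_white_noise_null():
    """Independent noise volumes: per-shell FSC within 4/sqrt(n_shell) of 0."""
    rng = np.random.default_rng(0)
    v1 = Volume(rng.normal(size=(48, 48, 48)), 1.0)
    v2 = Volume(rng.normal(size=(48, 48, 48)), 1.0)
    c = fsc(v1, v2)
    big = c.counts >= 100
    assert np.all(np.abs(c.values[big]) < 4.0 / np.sqrt(c.counts[big]))


def test_fsc_invariant_under_grid_rotation(phantom32, phantom32_class2):
    """A common exact 90-degree rotation of both maps leaves the FSC alone."""
    a = fsc(phantom32, phantom32_class2)
    r1 = Volume(np.rot90(phantom32.data, axes=(1, 2)).copy(), 2.0)
    r2 = Volume(np.rot90(phantom32_class2.data, axes=(1, 2)).copy(), 2.0)
    b = fsc(r1, r2)
    assert np.abs(a.values - b.values).max() < 1e-9


def test_fsc_rejects_box_mismatch(phantom32):
    with pytest.raises(ValueError):
        fsc(phantom32, make_phantom(48, 2.0, "class1", 0))


def test_resolution_threshold_crossing_interpolated():
    freqs = np.arange(17) / (32 * 2.0)
    vals = np.where(np.arange(17) <= 10, 1.0, 0.0)
    curve = FSCCurve(freqs, vals, np.ones(17, int) * 200)
    r = resolution_at(curve, 0.143)
    lo, hi = freqs[10], freqs[11]
    expected = lo + (1.0 - 0.143) / 1.0 * (hi - lo)
    assert r == pytest.approx(expected)
    assert resolution_at(FSCCurve(freqs, np.ones(17), np.ones(17, int)), 0.143) \
        == NO_CROSSING


def test_resolution_thresholds_ordered_on_monotone_curve():
    freqs = np.arange(17) / 64.0
    vals = np.linspace(1.0, -0.2, 17)
    curve = FSCCurve(freqs, vals, np.ones(17, int))
    assert resolution_at(curve, 0.5) <= resolution_at(curve, 0.143)


def test_resolution_rejects_bad_threshold():
    curve = FSCCurve(np.arange(5) / 10.0, np.ones(5), np.ones(5, int))
    with pytest.raises(ValueError):
        resolution_at(curve, 1.5)


# ---------------------------------------------------------------------------
# B factor

def test_bfactor_identity_inverse_and_fsc_invariance(phantom32, phantom32_class2):
    assert np.abs(apply_bfactor(phantom32, 0.0).data - phantom32.data).max() < 1e-12
    sharp = apply_bfactor(apply_bfactor(phantom32, -80.0), 80.0)
    assert np.abs(sharp.data - phantom32.data).max() \
        < 1e-9 * np.abs(phantom32.data).max()
    base = fsc(phantom32, phantom32_class2)
    for b in (-120.0, 50.0, 300.0):
        c = fsc(phantom32, apply_bfactor(phantom32_class2, b))
        assert np.abs(c.values - base.values).max() < 1e-6


# ---------------------------------------------------------------------------
# masks

def test_mask_of_ones_is_identity(phantom32):
    from biaslab.diagnostics import Mask
    m = Mask(data=np.ones((32, 32, 32)), kind="sphere", soft_edge=0.0)
    assert np.array_equal(apply_mask(phantom32, m).data, phantom32.data)


def test_mask_values_in_unit_interval(phantom32):
    for kind in ("sphere", "tight", "loose"):
        m = make_mask(phantom32, kind)
        assert m.data.min() >= 0.0 and m.data.max() <= 1.0


def test_masking_is_fourier_convolution():
    """FT(masked volume) equals the brute-force circular convolution of the
    volume and mask spectra (divided by N^3), on a small grid."""
    n = 16
    v = make_phantom(n, 2.0, "class1", seed=3)
    m = make_mask(v, "sphere", soft_edge=2.0, radius_frac=0.3)
    fv = np.fft.fftn(v.data)
    fm = np.fft.fftn(m.data)
    direct = np.fft.fftn(v.data * m.data)
    # brute force: C[k] = sum_j fv[j] * fm[(k - j) mod n]
    idx = np.arange(n)
    jz, jy, jx = np.meshgrid(idx, idx, idx, indexing="ij")
    conv = np.empty_like(fv)
    for kz in range(n):
        wz = (kz - jz) % n
        for ky in range(n):
            wy = (ky - jy) % n
            for kx in range(n):
                conv[kz, ky, kx] = np.sum(fv * fm[wz, wy, (kx - jx) % n])
    rel = np.abs(direct - conv / n**3).max() / np.abs(direct).max()
    assert rel < 1e-6


def test_tighter_mask_wider_in_fourier(phantom32):
    tight = make_mask(phantom32, "sphere", soft_edge=2.0, radius_frac=0.15)
    loose = make_mask(phantom32, "sphere", soft_edge=2.0, radius_frac=0.45)
    assert mask_fourier_width(tight) > mask_fourier_width(loose)


def test_masked_fsc_identical_masked_volumes(phantom32):
    m = make_mask(phantom32, "sphere")
    out = masked_fsc_experiment(phantom32, phantom32.copy(), {"sphere": m})
    nz = out["sphere"]["curve"].counts > 0
    assert np.allclose(out["sphere"]["curve"].values[nz], 1.0)


# ---------------------------------------------------------------------------
# phase randomization

def test_phase_randomization_preserves_power_exactly(phantom32):
    rng = np.random.default_rng(0)
    out = phase_randomize_volume(phantom32, 0.125, rng)
    a0 = np.abs(fftn_center(phantom32.data))
    a1 = np.abs(fftn_center(out.data))
    assert np.abs(a0 - a1).max() < 1e-9 * a0.max()


def test_phase_randomization_at_nyquist_is_identity(phantom32):
    rng = np.random.default_rng(0)
    out = phase_randomize_volume(phantom32, 0.25, rng)  # Nyquist at 2 A/voxel
    assert np.abs(out.data - phantom32.data).max() < 1e-9


def test_phase_randomization_rejects_bad_cutoff(phantom32):
    with pytest.raises(ValueError):
        phase_randomize_volume(phantom32, 0.0, np.random.default_rng(0))
    with pytest.raises(ValueError):
        phase_randomize_volume(phantom32, 0.3, np.random.default_rng(0))


def test_phase_randomization_decorrelates_beyond_cutoff(phantom32):
    rng = np.random.default_rng(1)
    cutoff = 0.0625  # shell 4 of 16
    a = phase_randomize_volume(phantom32, cutoff, rng)
    b = phase_randomize_volume(phantom32, cutoff, rng)
    c = fsc(a, b)
    assert np.all(c.values[:4] > 0.999)
    assert np.abs(c.values[6:15]).mean() < 0.3


# ---------------------------------------------------------------------------
# radial profile / halo

def test_radial_profile_uniform_ball():
    r = radial_coordinates(32)
    ball = Volume((r <= 10).astype(float), 2.0)
    radii, prof = radial_profile(ball)
    assert np.allclose(prof[:9], 1.0)
    assert np.allclose(prof[13:], 0.0)
    assert halo_score(ball, 10.0) == 0.0


def test_halo_score_rejects_large_radius(phantom32):
    with pytest.raises(ValueError):
        halo_score(phantom32, 0.48 * 32)


# ---------------------------------------------------------------------------
# bias-variance and mixture

def test_bias_variance_trivial_ensembles(phantom32):
    copies = [phantom32.copy() for _ in range(4)]
    maps = bias_variance(copies, phantom32)
    assert np.allclose(maps.bias, 0.0) and np.allclose(maps.variance, 0.0)
    delta = Volume(phantom32.data + 0.5, 2.0)
    maps = bias_variance([delta.copy() for _ in range(3)], phantom32)
    assert np.allclose(maps.bias, 0.5) and np.allclose(maps.variance, 0.0)


def test_bias_variance_identity_random_ensemble(phantom32):
    rng = np.random.default_rng(0)
    ens = [Volume(phantom32.data + rng.normal(size=phantom32.data.shape), 2.0)
           for _ in range(6)]
    maps = bias_variance(ens, phantom32)
    assert np.abs(maps.mse - (maps.bias**2 + maps.variance)).max() < 1e-12


def test_bias_variance_rejects_singleton(phantom32):
    with pytest.raises(ValueError):
        bias_variance([phantom32], phantom32)


def test_mixture_prediction_degenerate_cases(phantom32, phantom32_class2):
    assert np.allclose(mixture_prediction(phantom32, phantom32_class2, 10, 0).data,
                       phantom32.data, atol=1e-15)
    mean = mixture_prediction(phantom32, phantom32_class2, 7, 7)
    assert np.allclose(mean.data, 0.5 * (phantom32.data + phantom32_class2.data))
    with pytest.raises(ValueError):
        mixture_prediction(phantom32, phantom32_class2, -1, 2)


# ---------------------------------------------------------------------------
# parameter counting / kNN / BIC

def test_count_parameters_worked_example():
    out = count_parameters(100000, 200)
    assert out["volume_params"] == 8_000_000
    assert out["alignment_params"] == 600_000
    assert out["total_params"] == 8_600_000
    assert out["measurements"] == 4_000_000_000


def test_count_parameters_no_particles():
    out = count_parameters(0, 64)
    assert out["total_params"] == 64**3
    assert out["measurements"] == 0


def test_knn_noiseless_training_points_unbiased():
    # n_samples=11 puts training points at multiples of 0.1, so the 7
    # evaluation points 0.2 ... 0.8 coincide with training points
    cfg = TheoryDemoConfig(noise_sd=0.0, n_samples=11, k_values=(1,), n_reps=5,
                           n_eval=7, seed=0)
    rows = knn_bias_variance(cfg)
    assert rows[0]["mean_bias2"] < 1e-20
    assert rows[0]["mean_variance"] < 1e-20


def test_knn_variance_scales_as_sigma2_over_k():
    cfg = TheoryDemoConfig(noise_sd=1.0, n_samples=400, k_values=(1, 5, 25),
                           n_reps=400, seed=1)
    for row in knn_bias_variance(cfg):
        expected = row["expected_variance"]
        se = expected * np.sqrt(2.0 / (cfg.n_reps - 1))
        assert abs(row["mean_variance"] - expected) < 3 * se


def test_knn_bias_grows_with_k_for_convex_f():
    # noiseless with evaluation on training points: the bias is the exact
    # neighborhood-averaging bias, zero at k=1 and growing with k
    cfg = TheoryDemoConfig(f=lambda x: (x - 0.5) ** 2, noise_sd=0.0,
                           n_samples=201, k_values=(1, 5, 25, 201), n_reps=2,
                           n_eval=13, seed=2)
    rows = knn_bias_variance(cfg)
    b2 = [r["mean_bias2"] for r in rows]
    assert b2[0] < 1e-20
    assert all(np.diff(b2) >= -1e-15)


@given(k1=st.integers(0, 50), k2=st.integers(0, 50),
       loglik=st.floats(-1e3, 1e3), n=st.integers(2, 10**6))
@settings(max_examples=50, deadline=None)
def test_bic_penalizes_parameters(k1, k2, loglik, n):
    s1 = bic_score(loglik, k1, n)
    s2 = bic_score(loglik, k2, n)
    if k2 > k1:
        assert s2 < s1
    assert bic_score(loglik, 0, n) == loglik
    assert bic_score(loglik, k1, 1) == loglik
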