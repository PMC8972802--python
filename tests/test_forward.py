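import numpy as np
import pytest

from biaslab import (CTFParams, GeneratorConfig, NormalizationParams, Pose,
                     Volume, add_noise, apply_ctf, apply_normalization,
                     ctf_evaluate, generate_dataset, make_phantom, project)
from biaslab._fourier import fft2_center, ifft2_center
from biaslab.ctf import first_zero_frequency, phase_flip
from biaslab.forward import FourierProjector, project_real_space, support_mask_2d
from biaslab.volume import radial_coordinates


# ---------------------------------------------------------------------------
# projection

def test_project_zero_volume():
    v = Volume(np.zeros((32, 32, 32)), 2.0)
    img = project(v, Pose(30, 60, 10))
    assert np.allclose(img, 0.0)


def test_project_spherical_blob_rotation_invariant():
    r = radial_coordinates(32)
    v = Volume(np.exp(-(r**2) / 18.0), 2.0)
    a = project(v, Pose(0, 0, 0))
    b = project(v, Pose(123.0, 77.0, -45.0))
    assert np.abs(a - b).max() < 1e-3 * np.abs(a).max()


def test_projection_matches_real_space_oracle(phantom32):
    """Central-slice extraction agrees with brute-force rotate-and-sum."""
    pose = Pose(33.0, 71.0, -15.0)
    pf = project(phantom32, pose)
    pr = project_real_space(phantom32, pose)
    f1, f2 = fft2_center(pf), fft2_center(pr)
    q = np.arange(32) - 16
    qx, qy = np.meshgrid(q, q)
    band = np.sqrt(qx**2 + qy**2) <= (2 / 3) * 16
    rel = np.linalg.norm((f1 - f2)[band]) / np.linalg.norm(f2[band])
    assert rel < 0.02


def test_projection_linearity(phantom32, phantom32_class2):
    pose = Pose(15.0, 40.0, 95.0)
    combo = Volume(2.0 * phantom32.data + 3.0 * phantom32_class2.data, 2.0)
    lhs = project(combo, pose)
    rhs = 2.0 * project(phantom32, pose) + 3.0 * project(phantom32_class2, pose)
    assert np.abs(lhs - rhs).max() < 1e-10 * np.abs(rhs).max()


def test_project_shift_moves_image(phantom32):
    base = project(phantom32, Pose(10, 50, 20))
    shifted = project(phantom32, Pose(10, 50, 20, shift_x=3.0, shift_y=-2.0))
    assert np.abs(np.roll(base, (-2, 3), axis=(0, 1)) - shifted).max() \
        < 0.05 * np.abs(base).max()


# ---------------------------------------------------------------------------
# CTF

def test_ctf_zero_frequency_and_zero_defocus():
    c = CTFParams(defocus_A=15000.0, pixel_size_A=2.0)
    arr = ctf_evaluate(c, 48)
    assert arr[24, 24] == 0.0
    flat = ctf_evaluate(CTFParams(defocus_A=0.0, pixel_size_A=2.0), 48)
    assert np.allclose(flat, 0.0)


def test_ctf_bounded_by_one():
    arr = ctf_evaluate(CTFParams(defocus_A=22000.0, amplitude_contrast=0.07), 64)
    assert np.abs(arr).max() <= 1.0 + 1e-12


def test_ctf_first_zero_matches_analytic_root():
    c = CTFParams(defocus_A=15000.0, pixel_size_A=1.0)
    side = 256
    arr = ctf_evaluate(c, side)
    row = arr[side // 2, side // 2:]
    # first sign change beyond R = 0
    k = np.flatnonzero(np.diff(np.sign(row[1:])))[0] + 1
    r_measured = k / (side * c.pixel_size_A)
    assert abs(r_measured - first_zero_frequency(c)) < 1.0 / (side * c.pixel_size_A)


def test_apply_ctf_zero_image():
    assert np.allclose(apply_ctf(np.zeros((32, 32)), CTFParams()), 0.0)


def test_apply_ctf_then_phase_flip_restores_phases(phantom32):
    """Flip-after-apply leaves |CTF|-scaled amplitudes with original phases."""
    img = project(phantom32, Pose(20, 60, -30))
    c = CTFParams(defocus_A=18000.0, pixel_size_A=2.0)
    out = phase_flip(apply_ctf(img, c), c)
    f_in, f_out = fft2_center(img), fft2_center(out)
    carr = ctf_evaluate(c, 32)
    nz = np.abs(carr) > 1e-3
    assert np.allclose(f_out[nz], f_in[nz] * np.abs(carr)[nz], atol=1e-8)


def test_wrong_defocus_correction_sign_errors():
    """Flipping with defocus + delta mis-signs exactly the analytic bands."""
    c_true = CTFParams(defocus_A=15000.0, pixel_size_A=2.0)
    c_wrong = CTFParams(defocus_A=16000.0, pixel_size_A=2.0)
    t = ctf_evaluate(c_true, 64)
    w = ctf_evaluate(c_wrong, 64)
    predicted_bad = np.sign(t) * np.sign(w) < 0
    rng = np.random.default_rng(0)
    img = rng.normal(size=(64, 64))
    out = phase_flip(apply_ctf(img, c_true), c_wrong)
    f_in, f_out = fft2_center(img), fft2_center(out)
    got_bad = (f_out * np.conj(f_in)).real < 0
    sig = np.abs(t) > 0.05  # away from zero crossings the signs must match
    assert np.array_equal(predicted_bad[sig], got_bad[sig])


# ---------------------------------------------------------------------------
# noise and normalization

def test_noise_infinite_snr_identity(phantom32):
    img = project(phantom32, Pose())
    out = add_noise(img, np.inf, np.random.default_rng(0))
    assert np.array_equal(out, img)


def test_noise_rejects_nonpositive_snr():
    with pytest.raises(ValueError):
        add_noise(np.ones((16, 16)), 0.0, np.random.default_rng(0))


def test_noise_calibration_monte_carlo(phantom32):
    """Across 1000 images, realized signal/noise variance ratio is ~0.1."""
    img = project(phantom32, Pose(40, 70, 10))
    rng = np.random.default_rng(1)
    sup = support_mask_2d(32)
    sig_var = img[sup].var()
    noise_vars, means = [], []
    for _ in range(1000):
        n = add_noise(img, 0.1, rng) - img
        noise_vars.append(n.var())
        means.append(n.mean())
    ratio = sig_var / np.mean(noise_vars)
    assert abs(ratio - 0.1) < 0.005
    se = np.std(means) / np.sqrt(len(means))
    assert abs(np.mean(means)) < 3 * se + 1e-12


def test_normalization_exact_affine():
    img = np.arange(16.0).reshape(4, 4)
    assert np.array_equal(apply_normalization(img, NormalizationParams(1.0, 0.0)), img)
    assert np.array_equal(apply_normalization(img, NormalizationParams(2.0, 0.0)),
                          2.0 * img)
    out = apply_normalization(img, NormalizationParams(1.0, 3.5))
    assert out.mean() == pytest.approx(img.mean() + 3.5)


def test_normalization_rejects_zero_gain():
    with pytest.raises(ValueError):
        NormalizationParams(0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset generator

def test_generator_deterministic():
    cfg = GeneratorConfig(n_particles=20, box=32, snr=0.5, seed=9)
    s1, _ = generate_dataset(cfg)
    s2, _ = generate_dataset(cfg)
    assert np.array_equal(s1.images, s2.images)
    assert s1.truth_poses == s2.truth_poses


def test_generator_deterministic_class_counts():
    cfg = GeneratorConfig(n_particles=1000, box=32, snr=1.0, mixture=(0.7, 0.3),
                          seed=0)
    stack, _ = generate_dataset(cfg)
    counts = np.bincount(stack.truth_class, minlength=3)
    assert tuple(counts) == (700, 300, 0)


def test_generator_contamination_counts_and_images():
    cfg = GeneratorConfig(n_particles=100, box=32, snr=1.0, mixture=(0.9, 0.0),
                          contamination=0.1, seed=0)
    stack, _ = generate_dataset(cfg)
    assert np.sum(stack.truth_class == 2) == 10


def test_generator_cone_depleted_constraint():
    cfg = GeneratorConfig(n_particles=300, box=32, snr=1.0,
                          angular_distribution="cone_depleted",
                          cone_half_angle=30.0, seed=2)
    stack, _ = generate_dataset(cfg)
    tilts = np.array([p.tilt for p in stack.truth_poses])
    assert np.all(tilts >= 30.0)


def test_generator_rejects_inconsistent_fractions():
    with pytest.raises(ValueError):
        GeneratorConfig(mixture=(0.8, 0.3), contamination=0.2)


def test_generator_records_nominal_and_true_ctf_separately():
    cfg = GeneratorConfig(n_particles=5, box=32, snr=1.0, defocus_offset=1000.0,
                          pixel_size_error=1.02, seed=0)
    stack, _ = generate_dataset(cfg)
    for nom, tru in zip(stack.ctf_nominal, stack.ctf_true):
        assert tru.defocus_A == pytest.approx(nom.defocus_A + 1000.0)
        assert tru.pixel_size_A == pytest.approx(nom.pixel_size_A * 1.02)
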