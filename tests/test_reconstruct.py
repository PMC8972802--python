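import numpy as np
import pytest

from biaslab import (GeneratorConfig, Pose, SplitScheme, Volume, apply_symmetry,
                     fsc, generate_dataset, make_phantom, reconstruct,
                     reconstruct_halves)
from biaslab.ctf import CTFParams
from biaslab.forward import NormalizationParams, ParticleStack
from biaslab.geometry import angular_distance
from biaslab.reconstruct import hard_orientations, refine, split_indices
from biaslab.align import make_gallery


def test_reconstruct_self_consistency(clean_stack32):
    """Noiseless CTF-free true-pose reconstruction recovers the phantom."""
    stack, truth = clean_stack32
    rec = reconstruct(stack)
    curve = fsc(rec, truth)
    below = slice(0, int((2 / 3) * 16) + 1)
    assert np.all(curve.values[below] > 0.99)


def test_reconstruct_rejects_empty_stack(clean_stack32):
    stack, _ = clean_stack32
    with pytest.raises(ValueError):
        reconstruct(stack.subset(np.array([], dtype=int)))


def test_reconstruct_linear_in_images(clean_stack32):
    stack, _ = clean_stack32
    sub = stack.subset(np.arange(40))
    doubled = sub.subset(np.arange(40))
    doubled.images = 2.0 * doubled.images
    r1 = reconstruct(sub, reprojection_steps=0)
    r2 = reconstruct(doubled, reprojection_steps=0)
    assert np.abs(r2.data - 2.0 * r1.data).max() < 1e-9 * np.abs(r2.data).max()


def test_soft_weight_on_true_pose_equals_hard(clean_stack32):
    stack, _ = clean_stack32
    sub = stack.subset(np.arange(30))
    hard = reconstruct(sub, reprojection_steps=0)
    soft_orients = [[(p, 1.0)] for p in sub.truth_poses]
    soft = reconstruct(sub, soft_orients, reprojection_steps=0)
    assert np.array_equal(hard.data, soft.data)


def test_split_gold_deterministic_and_balanced():
    s = SplitScheme("gold", 5)
    h1a, h2a = split_indices(101, s)
    h1b, h2b = split_indices(101, s)
    assert np.array_equal(h1a, h1b) and np.array_equal(h2a, h2b)
    assert abs(len(h1a) - len(h2a)) <= 1
    assert len(np.intersect1d(h1a, h2a)) == 0


def test_split_interleaved_changes_between_calls():
    rng = np.random.default_rng(0)
    s = SplitScheme("interleaved", 0)
    parts = [split_indices(50, s, rng)[0].tobytes() for _ in range(10)]
    assert len(set(parts)) > 1


def test_split_rejects_tiny_stacks():
    with pytest.raises(ValueError):
        split_indices(1, SplitScheme("gold", 0))


def test_apply_symmetry_c1_identity_and_c2_idempotent():
    v = make_phantom(32, 2.0, "pseudo_sym", seed=0)
    assert np.array_equal(apply_symmetry(v, 1).data, v.data)
    once = apply_symmetry(v, 2)
    twice = apply_symmetry(once, 2)
    assert np.abs(twice.data - once.data).max() < 1e-6 * np.abs(once.data).max()


def test_apply_symmetry_rejects_bad_order():
    v = make_phantom(32, 2.0, "class1", seed=0)
    with pytest.raises(ValueError):
        apply_symmetry(v, 0)


def test_c2_averaging_halves_asymmetric_blob():
    """Symmetrizing the pseudo-C2 phantom moves the odd blob halfway down."""
    v = make_phantom(48, 2.0, "pseudo_sym", seed=0)
    sym = apply_symmetry(v, 2)
    from biaslab.reconstruct import _rotate_z
    asym = v.data - _rotate_z(v.data, 180.0)
    peak = np.unravel_index(np.argmax(np.abs(asym)), asym.shape)
    drop = v.data[peak] - sym.data[peak]
    assert drop == pytest.approx(0.5 * asym[peak], rel=0.1)


def test_refine_fixed_point_at_gallery_poses():
    """Noiseless data generated at gallery poses, truth initial map: the
    first iteration reassigns exactly those poses."""
    truth = make_phantom(32, 2.0, "class1", seed=1)
    gallery = make_gallery(truth, 30.0)
    idx = np.arange(0, len(gallery), 7)[:40]
    poses = [gallery.poses[i] for i in idx]
    images = gallery.images[idx]
    n = len(poses)
    stack = ParticleStack(images=images.copy(), truth_poses=poses,
                          truth_class=np.zeros(n, int), ctf_true=[CTFParams()] * n,
                          ctf_nominal=[CTFParams()] * n,
                          norm=[NormalizationParams()] * n, snr=np.inf,
                          voxel_size=2.0)
    res = refine(stack, truth, SplitScheme("gold", 0), n_iter=1,
                 angular_sampling=30.0, shift_radius=0, seed=0)
    errs = [angular_distance(p, q) for p, q in zip(res.final_poses, poses)]
    assert max(errs) < 1e-3  # degrees; float round trip through Euler angles


def test_refine_rejects_box_mismatch(clean_stack32):
    stack, _ = clean_stack32
    wrong = make_phantom(48, 2.0, "class1", seed=1)
    with pytest.raises(ValueError):
        refine(stack.subset(np.arange(10)), wrong, SplitScheme("gold", 0), n_iter=1)


def test_missing_cone_elongation():
    """Top-view-only data leaves an empty Fourier cone: map stretches along z."""
    truth = make_phantom(32, 2.0, "class1", seed=1)
    ratios = {}
    for kind in ("uniform", "preferred_orientation"):
        cfg = GeneratorConfig(n_particles=250, box=32, snr=np.inf, with_ctf=False,
                              angular_distribution=kind, preferred_fraction=1.0,
                              preferred_tilt=0.0, preferred_tilt_spread=8.0,
                              seed=6, phantom_seed=1)
        stack, _ = generate_dataset(cfg, volumes={"class1": truth})
        rec = reconstruct(stack, reprojection_steps=0)
        w = np.maximum(rec.data, 0.0)
        q = np.arange(32) - 16
        qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
        ratios[kind] = float((w * qz**2).sum() / (w * qx**2).sum())
    assert ratios["preferred_orientation"] > 1.2 * ratios["uniform"]
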