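"""Direct Fourier-inversion reconstruction, half-set splitting and refinement.

Each image's 2-D transform (on a 2x zero-padded grid) is inserted as a
central slice at each of its weighted orientations with trilinear gridding;
accumulated values are divided by accumulated interpolation (+ CTF^2)
weights with a Tikhonov floor.  An image may carry several (pose, weight)
pairs -- the soft multi-orientation weighting that maximum-likelihood
packages use -- with hard assignment as the single-pose special case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._fourier import (crop_center, fft2_center, fftn_center, ifftn_center,
                       pad_center, shift_phase_2d)
from .ctf import CTFParams, ctf_evaluate
from .forward import PAD_FACTOR, FourierProjector, ParticleStack
from .geometry import Pose
from .volume import Volume

TIKHONOV_REL = 1e-3

# (pose, weight) list per image; weights >= 0, summing to 1 per image
OrientationDistribution = Sequence[Sequence[tuple[Pose, float]]]


@dataclass(frozen=True)
class SplitScheme:
    """Half-set policy: ``gold`` fixes one seeded partition for the whole run,
    ``interleaved`` re-splits the images at every iteration."""

    mode: str = "gold"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("gold", "interleaved"):
            raise ValueError(f"unknown split mode {self.mode!r}")


@dataclass
class RefinementResult:
    final_volume: Volume
    half_volumes: list[tuple[Volume, Volume]]
    fsc_curves: list  # FSCCurve per iteration
    final_poses: list[Pose]
    log: dict


def hard_orientations(poses: Sequence[Pose]) -> list[list[tuple[Pose, float]]]:
    """Weight-1 single-pose distribution for every image."""
    return [[(p, 1.0)] for p in poses]


def reconstruct(stack: ParticleStack,
                orientations: OrientationDistribution | None = None,
                ctf_mode: str = "none",
                ctf_params_used: Sequence[CTFParams] | None = None,
                wiener_constant: float = 0.1,
                reprojection_steps: int | None = None) -> Volume:
    """Reconstruct a volume from a particle stack.

    Parameters
    ----------
    orientations : per-image (pose, weight) lists; defaults to hard
        assignment at the stack's ground-truth poses.
    ctf_mode : ``none`` (insert data as is), ``phase_flip`` (correct the CTF
        sign) or ``wiener`` (multiply by CTF and divide by CTF^2 + constant
        through the accumulated weights).
    ctf_params_used : CTF parameters assumed during correction; defaults to
        the stack's nominal (believed) parameters.  Passing deliberately
        wrong values is how systematic CTF miscorrection is modelled.
    reprojection_steps : Richardson correction passes (re-grid the residual
        between the data and the reprojected estimate) that remove the
        systematic gridding error; defaults to 1 in the CTF-free mode and 0
        otherwise, where single-pass gridding is the standard practice.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    if orientations is None:
        orientations = hard_orientations(stack.truth_poses)
    if len(orientations) != len(stack):
        raise ValueError("one orientation distribution required per image")
    if ctf_mode not in ("none", "phase_flip", "wiener"):
        raise ValueError(f"unknown ctf_mode {ctf_mode!r}")
    if ctf_params_used is None:
        ctf_params_used = stack.ctf_nominal

    n = stack.box
    m = PAD_FACTOR * n
    ctr = m // 2
    data_re = np.zeros(m**3)
    data_im = np.zeros(m**3)
    wsum = np.zeros(m**3)

    q = np.arange(m) - ctr
    qx, qy = np.meshgrid(q, q, indexing="xy")
    plane = np.stack([qx.ravel(), qy.ravel(), np.zeros(m * m)], axis=0)
    keep = (qx.ravel() ** 2 + qy.ravel() ** 2) <= (ctr - 1) ** 2
    plane = plane[:, keep]

    for i in range(len(stack)):
        entries = orientations[i]
        wtot = float(sum(w for _, w in entries))
        if wtot <= 0:
            raise ValueError(f"image {i}: orientation weights must sum > 0")
        f2 = fft2_center(pad_center(stack.images[i], m)).ravel()
        cw = np.ones(m * m)
        if ctf_mode != "none":
            c = ctf_evaluate(ctf_params_used[i], m).ravel()
            if ctf_mode == "phase_flip":
                f2 = f2 * np.sign(c)
            else:  # wiener: numerator CTF, denominator CTF^2 via the weights
                f2 = f2 * c
                cw = c * c + wiener_constant
        f2 = f2[keep]
        cw = cw[keep]

        for pose, w in entries:
            if w == 0.0:
                continue
            w = w / wtot
            f2p = f2
            if pose.shift_x or pose.shift_y:
                ramp = np.exp(2j * np.pi
                              * (plane[0] * pose.shift_x + plane[1] * pose.shift_y) / m)
                f2p = f2 * ramp
            a = pose.matrix()
            xyz = a @ plane + ctr
            _spread_trilinear(data_re, data_im, wsum, xyz, f2p,
                              w * np.broadcast_to(cw, f2p.shape), m)

    eps = TIKHONOV_REL * wsum.max()
    denom = wsum + eps
    f3 = ((data_re + 1j * data_im) / denom).reshape(m, m, m)
    vol = crop_center(ifftn_center(f3).real, n)
    out = Volume(vol * _gridding_correction(n, m), stack.voxel_size)

    if reprojection_steps is None:
        reprojection_steps = 1 if ctf_mode == "none" else 0
    for _ in range(reprojection_steps):
        proj = FourierProjector(out)
        predicted = np.empty_like(stack.images)
        for i, entries in enumerate(orientations):
            wtot = float(sum(w for _, w in entries))
            img = np.zeros((n, n))
            for pose, w in entries:
                if w:
                    img += (w / wtot) * proj.project(pose)
            predicted[i] = img
        residual = ParticleStack(
            images=stack.images - predicted, truth_poses=list(stack.truth_poses),
            truth_class=stack.truth_class, ctf_true=stack.ctf_true,
            ctf_nominal=stack.ctf_nominal, norm=stack.norm, snr=stack.snr,
            voxel_size=stack.voxel_size)
        delta = reconstruct(residual, orientations, ctf_mode="none",
                            reprojection_steps=0)
        out = Volume(out.data + delta.data, out.voxel_size)
    return out


def _gridding_correction(n: int, m: int) -> np.ndarray:
    """Undo the real-space apodization of the trilinear gridding kernel.

    Averaging spread samples convolves the spectrum with the triangle
    kernel, i.e. multiplies real space by sinc^2(x/m) per axis; divide it out
    on the cropped box."""
    q = (np.arange(n) - n // 2) / m
    c = np.sinc(q) ** 2
    inv = 1.0 / np.maximum(c, 1e-3)
    return inv[:, None, None] * inv[None, :, None] * inv[None, None, :]


def _spread_trilinear(acc_re, acc_im, acc_w, xyz, values, weights, m):
    """Trilinear scatter of complex samples onto the flattened m^3 grid."""
    base = np.floor(xyz).astype(np.int64)
    frac = xyz - base
    vr, vi = values.real, values.imag
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                wx = frac[0] if dx else 1.0 - frac[0]
                wy = frac[1] if dy else 1.0 - frac[1]
                wz = frac[2] if dz else 1.0 - frac[2]
                tw = wx * wy * wz * weights
                ix = base[0] + dx
                iy = base[1] + dy
                iz = base[2] + dz
                ok = ((ix >= 0) & (ix < m) & (iy >= 0) & (iy < m)
                      & (iz >= 0) & (iz < m) & (tw > 0))
                flat = (iz[ok] * m + iy[ok]) * m + ix[ok]
                acc_re += np.bincount(flat, vr[ok] * tw[ok], minlength=m**3)
                acc_im += np.bincount(flat, vi[ok] * tw[ok], minlength=m**3)
                acc_w += np.bincount(flat, tw[ok], minlength=m**3)


def split_indices(n: int, scheme: SplitScheme,
                  rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Partition image indices into two halves (sizes differ by <= 1).

    gold: deterministic for the scheme's seed (even/odd after a seeded
    shuffle).  interleaved: fresh random partition from the supplied rng on
    every call.
    """
    if n < 2:
        raise ValueError("need at least 2 images to split")
    if scheme.mode == "gold":
        perm = np.random.default_rng(scheme.seed).permutation(n)
    else:
        if rng is None:
            raise ValueError("interleaved splitting needs an advancing rng")
        perm = rng.permutation(n)
    return np.sort(perm[0::2]), np.sort(perm[1::2])


def reconstruct_halves(stack: ParticleStack,
                       orientations: OrientationDistribution | None = None,
                       scheme: SplitScheme = SplitScheme("gold", 0),
                       rng: np.random.Generator | None = None,
                       **kwargs) -> tuple[Volume, Volume]:
    """Reconstruct the two half-set volumes under the given split scheme."""
    if orientations is None:
        orientations = hard_orientations(stack.truth_poses)
    h1, h2 = split_indices(len(stack), scheme, rng)
    v1 = reconstruct(stack.subset(h1), [orientations[i] for i in h1], **kwargs)
    v2 = reconstruct(stack.subset(h2), [orientations[i] for i in h2], **kwargs)
    return v1, v2


def apply_symmetry(volume: Volume, order: int) -> Volume:
    """Average the volume over the Cn rotations about the z axis."""
    if order < 1:
        raise ValueError("symmetry order must be >= 1")
    if order == 1:
        return volume.copy()
    acc = np.zeros_like(volume.data)
    for k in range(order):
        ang = 360.0 * k / order
        if ang == 0.0:
            acc += volume.data
        else:
            # rotation about z = rotation in the (y, x) plane about the center
            acc += _rotate_z(volume.data, ang)
    return Volume(acc / order, volume.voxel_size)


def _rotate_z(data: np.ndarray, angle_deg: float) -> np.ndarray:
    box = data.shape[0]
    c = box // 2
    th = np.radians(angle_deg)
    ca, sa = np.cos(th), np.sin(th)
    q = np.arange(box) - c
    qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
    # sample source coordinates rotated by -angle about z
    sx = ca * qx + sa * qy
    sy = -sa * qx + ca * qy
    from scipy.ndimage import map_coordinates
    idx = np.stack([qz + c, sy + c, sx + c], axis=0).reshape(3, -1)
    out = map_coordinates(data, idx, order=3, mode="constant")
    return out.reshape(box, box, box)


def refine(stack: ParticleStack, initial_volume: Volume,
           scheme: SplitScheme = SplitScheme("gold", 0),
           n_iter: int = 5, angular_sampling: float = 30.0,
           metric: str = "correlation", ctf_mode: str = "none",
           shift_radius: int = 0, seed: int = 0) -> RefinementResult:
    """Iterative projection-matching refinement with half-set bookkeeping.

    Per iteration: (re)split per the scheme, assign poses per half against
    that half's current map (gold) or against the common previous map
    (interleaved), reconstruct the halves and record their FSC.  The final
    map pools all images at their final pose estimates.
    """
    from .align import assign_stack, make_gallery
    from .diagnostics import fsc

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if initial_volume.box != stack.box:
        raise ValueError("box mismatch between stack and initial volume")

    rng = np.random.default_rng(seed)
    maps = (initial_volume, initial_volume)
    common = initial_volume
    # every image is (re)assigned in iteration 1, so the initial poses are inert
    poses: list[Pose] = [Pose() for _ in range(len(stack))]
    half_volumes, curves, history = [], [], []

    for it in range(n_iter):
        h1, h2 = split_indices(len(stack), scheme, rng)
        history.append((h1.tolist(), h2.tolist()))
        new_poses = list(poses)
        halves = []
        for side, idx in enumerate((h1, h2)):
            ref = maps[side] if scheme.mode == "gold" else common
            gallery = make_gallery(ref, angular_sampling)
            sub = stack.subset(idx)
            est = assign_stack(sub, gallery, metric=metric, shift_radius=shift_radius)
            for j, i in enumerate(idx):
                new_poses[i] = est[j][0]
            halves.append(reconstruct(sub, hard_orientations([new_poses[i] for i in idx]),
                                      ctf_mode=ctf_mode))
        poses = new_poses
        v1, v2 = halves
        half_volumes.append((v1, v2))
        curves.append(fsc(v1, v2))
        maps = (v1, v2)
        common = Volume(0.5 * (v1.data + v2.data), v1.voxel_size)

    final = reconstruct(stack, hard_orientations(poses), ctf_mode=ctf_mode)
    log = {"scheme": scheme.mode, "n_iter": n_iter,
           "angular_sampling": angular_sampling, "metric": metric,
           "half_membership": history}
    return RefinementResult(final_volume=final, half_volumes=half_volumes,
                            fsc_curves=curves, final_poses=poses, log=log)
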