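"""Projection-matching angular assignment and reference-based 2-D classification.

Assignment compares each experimental image against a gallery of reference
projections under either the correlation or the Euclidean-distance metric,
with an exhaustive integer in-plane shift search.  The 2-D classifier is the
classic align-and-average loop; run at very low SNR with the Euclidean
metric it exhibits the attraction instability, where the class with more
members develops a cleaner background and keeps winning images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._fourier import fft2_center
from .forward import FourierProjector, ParticleStack
from .geometry import Pose, direction_to_euler, fibonacci_directions
from .volume import Volume

DEFAULT_SHIFT_RADIUS = 5


@dataclass
class ReferenceGallery:
    poses: list[Pose]
    images: np.ndarray          # (n_ref, side, side)
    sampling: float             # nominal angular step in degrees

    def __post_init__(self):
        if len(self.poses) == 0:
            raise ValueError("gallery is empty")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class AssignmentRun:
    """Per-image pose estimates (+ scores) from one assignment execution."""

    poses: list[Pose]
    scores: np.ndarray
    metric: str = "correlation"
    seed: int = 0

    def __len__(self) -> int:
        return len(self.poses)


def n_directions_for_step(angular_step: float) -> int:
    """Quasi-uniform direction count whose mean spacing matches the step.

    Allocates one direction per angular_step^2 steradian patch:
    n = 4 pi / step_rad^2 (about 46 directions at a 30 deg step).
    """
    step = np.radians(angular_step)
    return max(2, int(round(4.0 * np.pi / step**2)))


def make_gallery(volume: Volume, angular_step: float) -> ReferenceGallery:
    """CTF-free reference projections on a Fibonacci sphere lattice.

    In-plane rotation (psi) is sampled at the same nominal step.
    """
    if not 1.0 <= angular_step <= 90.0:
        raise ValueError("angular step must lie in [1, 90] degrees")
    ndir = n_directions_for_step(angular_step)
    npsi = max(1, int(round(360.0 / angular_step)))
    psis = (np.arange(npsi) * 360.0 / npsi + 180.0) % 360.0 - 180.0
    proj = FourierProjector(volume)
    poses, images = [], []
    for d in fibonacci_directions(ndir):
        rot, tilt = direction_to_euler(d)
        for psi in psis:
            pose = Pose(rot, tilt, float(psi))
            poses.append(pose)
            images.append(proj.project(pose))
    return ReferenceGallery(poses=poses, images=np.stack(images),
                            sampling=angular_step)


def _shift_window(side: int, radius: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat indices of the correlation map within the shift search window."""
    s = np.arange(-radius, radius + 1)
    sx, sy = np.meshgrid(s, s, indexing="xy")
    ix = (sx + side // 2).ravel()
    iy = (sy + side // 2).ravel()
    return iy * side + ix, sx.ravel(), sy.ravel()


def _correlation_maps(image_f: np.ndarray, gallery_f_conj: np.ndarray) -> np.ndarray:
    """Cross-correlation of one image with every reference, all shifts.

    Centered maps: entry (side//2 + sy, side//2 + sx) is <I, ref shifted by
    (sx, sy)>; circular wrap is harmless for the small search radii used.
    """
    prod = image_f[None] * gallery_f_conj
    side = image_f.shape[-1]
    cc = np.fft.ifft2(np.fft.ifftshift(prod, axes=(-2, -1)), axes=(-2, -1)).real
    return np.fft.fftshift(cc, axes=(-2, -1)) * 1.0


def assign_stack(stack_or_images, gallery: ReferenceGallery,
                 metric: str = "correlation",
                 shift_radius: int = DEFAULT_SHIFT_RADIUS
                 ) -> list[tuple[Pose, float]]:
    """Assign every image to its best gallery pose (vectorized over references).

    Returns one (pose, score) pair per image; the returned pose carries the
    best in-plane shift.  Ties break on the lowest gallery index.
    """
    if metric not in ("correlation", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    images = stack_or_images.images if isinstance(stack_or_images, ParticleStack) \
        else np.asarray(stack_or_images)
    side = images.shape[-1]
    if side != gallery.images.shape[-1]:
        raise ValueError("image and gallery sides differ")

    gal_f_conj = np.conj(fft2_center(gallery.images))
    gal_norm2 = np.sum(gallery.images**2, axis=(-2, -1))
    flat_idx, sxs, sys = _shift_window(side, shift_radius)

    out: list[tuple[Pose, float]] = []
    for img in images:
        img_f = fft2_center(img)
        cc = _correlation_maps(img_f, gal_f_conj).reshape(len(gallery), -1)
        cc_win = cc[:, flat_idx]                       # (n_ref, n_shifts)
        if metric == "correlation":
            inorm = np.linalg.norm(img)
            score = cc_win / (inorm * np.sqrt(gal_norm2)[:, None] + 1e-300)
            k = int(np.argmax(score.max(axis=1)))
            j = int(np.argmax(score[k]))
            best = float(score[k, j])
        else:
            inorm2 = float(np.sum(img**2))
            dist = inorm2 + gal_norm2[:, None] - 2.0 * cc_win
            k = int(np.argmin(dist.min(axis=1)))
            j = int(np.argmin(dist[k]))
            best = float(dist[k, j])
        pose = gallery.poses[k].with_shift(float(sxs[j]), float(sys[j]))
        out.append((pose, best))
    return out


def assign_pose(image: np.ndarray, gallery: ReferenceGallery,
                metric: str = "correlation",
                shift_radius: int = DEFAULT_SHIFT_RADIUS) -> tuple[Pose, float]:
    """Single-image convenience wrapper around :func:`assign_stack`."""
    return assign_stack(np.asarray(image)[None], gallery, metric, shift_radius)[0]


@dataclass
class Class2DResult:
    class_averages: list[np.ndarray]     # per iteration: (K, side, side)
    labels: list[np.ndarray]             # per iteration: (n,)
    occupancies: list[np.ndarray]        # per iteration: (K,), sums to 1
    metric: str = "correlation"


def classify2d(stack_or_images, n_classes: int, metric: str = "correlation",
               n_iter: int = 10, rng: np.random.Generator | int = 0,
               psi_step: float = 30.0,
               shift_radius: int = 2) -> Class2DResult:
    """Reference-free 2-D classification by iterative align-and-average.

    Random initial labels; each iteration aligns every image to every class
    average over in-plane rotations and shifts, assigns by the metric and
    recomputes averages from the aligned images.  Empty classes are reseeded
    from the worst-fitting images.  Deterministic given the rng seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    images = stack_or_images.images if isinstance(stack_or_images, ParticleStack) \
        else np.asarray(stack_or_images)
    n, side, _ = images.shape
    if n_classes < 1 or n_iter < 1:
        raise ValueError("n_classes and n_iter must be >= 1")
    if n_classes > n:
        raise ValueError("more classes than images")
    if metric not in ("correlation", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")

    psis = np.arange(0.0, 360.0, psi_step)
    labels = rng.integers(0, n_classes, n)
    transforms = np.zeros((n, 3))  # psi, sx, sy per image
    flat_idx, sxs, sys = _shift_window(side, shift_radius)

    avgs_hist, labels_hist, occ_hist = [], [], []
    averages = _class_means(images, labels, transforms, n_classes, side)
    for _ in range(n_iter):
        # rotated versions of every class average: (K * n_psi, side, side)
        refs, ref_class, ref_psi = [], [], []
        for k in range(n_classes):
            for psi in psis:
                refs.append(_rotate2d(averages[k], psi))
                ref_class.append(k)
                ref_psi.append(psi)
        refs = np.stack(refs)
        refs_f_conj = np.conj(fft2_center(refs))
        ref_norm2 = np.sum(refs**2, axis=(-2, -1))

        scores = np.empty(n)
        for i in range(n):
            img_f = fft2_center(images[i])
            cc = _correlation_maps(img_f, refs_f_conj).reshape(len(refs), -1)
            cc_win = cc[:, flat_idx]
            if metric == "correlation":
                val = cc_win / (np.linalg.norm(images[i])
                                * np.sqrt(ref_norm2)[:, None] + 1e-300)
                k = int(np.argmax(val.max(axis=1)))
                j = int(np.argmax(val[k]))
                scores[i] = val[k, j]
            else:
                val = float(np.sum(images[i]**2)) + ref_norm2[:, None] - 2.0 * cc_win
                k = int(np.argmin(val.min(axis=1)))
                j = int(np.argmin(val[k]))
                scores[i] = -val[k, j]
            labels[i] = ref_class[k]
            transforms[i] = (ref_psi[k], sxs[j], sys[j])

        # reseed empty classes from the worst-fitting images
        for k in range(n_classes):
            if not np.any(labels == k):
                worst = int(np.argmin(scores))
                labels[worst] = k
                scores[worst] = np.inf

        averages = _class_means(images, labels, transforms, n_classes, side)
        occ = np.bincount(labels, minlength=n_classes) / n
        avgs_hist.append(averages.copy())
        labels_hist.append(labels.copy())
        occ_hist.append(occ)

    return Class2DResult(class_averages=avgs_hist, labels=labels_hist,
                         occupancies=occ_hist, metric=metric)


def _class_means(images, labels, transforms, n_classes, side):
    """Average images into their classes after undoing the found transforms."""
    sums = np.zeros((n_classes, side, side))
    counts = np.zeros(n_classes)
    for i, img in enumerate(images):
        psi, sx, sy = transforms[i]
        al = np.roll(img, (-int(round(sy)), -int(round(sx))), axis=(0, 1))
        if psi:
            al = _rotate2d(al, -psi)
        sums[labels[i]] += al
        counts[labels[i]] += 1
    counts[counts == 0] = 1.0
    return sums / counts[:, None, None]


def _rotate2d(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane rotation about the centered origin (index side // 2)."""
    if angle_deg % 360.0 == 0.0:
        return img.copy()
    box = img.shape[0]
    c = box // 2
    th = np.radians(angle_deg)
    ca, sa = np.cos(th), np.sin(th)
    q = np.arange(box) - c
    qx, qy = np.meshgrid(q, q, indexing="xy")
    sx = ca * qx + sa * qy
    sy = -sa * qx + ca * qy
    idx = np.stack([sy + c, sx + c], axis=0).reshape(2, -1)
    return ndimage.map_coordinates(img, idx, order=1, mode="constant").reshape(box, box)
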