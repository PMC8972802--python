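"""Image-formation model: projection, noise, normalization and the dataset generator.

The forward model for one particle image is

    I = a * ( CTF * P_pose(V) + noise ) + b

where P_pose is the line-integral projection at the particle's pose, CTF the
microscope modulation, the noise additive zero-mean Gaussian calibrated to a
target SNR, and (a, b) a per-image linear normalization perturbation.
Projection is implemented by Fourier central-slice extraction on a 2x
zero-padded grid with trilinear interpolation; a brute-force real-space
rotation oracle (`project_real_space`) is kept for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._fourier import (crop_center, fft2_center, fftn_center, ifft2_center,
                       pad_center, shift_phase_2d)
from .ctf import CTFParams, ctf_evaluate
from .geometry import Pose
from .phantoms import make_phantom
from .volume import Volume

PAD_FACTOR = 2


@dataclass(frozen=True)
class NormalizationParams:
    """Linear intensity model I' = a * I + b."""

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("multiplicative gain a must be nonzero")


@dataclass
class ParticleStack:
    """Simulated particle images with full per-image ground truth.

    truth_class codes: 0 = class 1, 1 = class 2, 2 = contaminant.
    ``ctf_true`` holds the parameters actually used during simulation;
    ``ctf_nominal`` the unbiased values a downstream user would believe, so
    "correction with wrong parameters" is an explicit, auditable choice.
    """

    images: np.ndarray
    truth_poses: list[Pose]
    truth_class: np.ndarray
    ctf_true: list[CTFParams]
    ctf_nominal: list[CTFParams]
    norm: list[NormalizationParams]
    snr: float
    voxel_size: float

    def __post_init__(self):
        n = len(self.images)
        if not (len(self.truth_poses) == len(self.truth_class) == len(self.ctf_true)
                == len(self.ctf_nominal) == len(self.norm) == n):
            raise ValueError("per-image metadata lists must match the image count")
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a stack of square 2-D arrays")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box(self) -> int:
        return self.images.shape[1]

    def subset(self, idx: np.ndarray) -> "ParticleStack":
        idx = np.asarray(idx)
        return ParticleStack(
            images=self.images[idx],
            truth_poses=[self.truth_poses[i] for i in idx],
            truth_class=self.truth_class[idx],
            ctf_true=[self.ctf_true[i] for i in idx],
            ctf_nominal=[self.ctf_nominal[i] for i in idx],
            norm=[self.norm[i] for i in idx],
            snr=self.snr,
            voxel_size=self.voxel_size,
        )


@dataclass
class GeneratorConfig:
    """Everything the synthetic dataset generator can inject.

    Defaults are the package's standard desk-scale conditions: box 48 at
    2 Å/voxel, SNR 0.1 (the favourable end of the 0.1-0.01 range typical of
    cryo-EM micrographs), uniform orientations, a single class, no
    contamination and unbiased CTF/normalization.
    """

    n_particles: int = 500
    box: int = 48
    voxel_size: float = 2.0
    snr: float = 0.1
    angular_distribution: str = "uniform"  # uniform | cone_depleted | preferred_orientation
    cone_half_angle: float = 30.0          # cone_depleted: no tilt closer to the pole
    preferred_fraction: float = 0.8        # preferred_orientation: fraction at the preferred view
    preferred_tilt: float = 0.0            # top views: the classic missing-cone geometry
    preferred_tilt_spread: float = 5.0
    mixture: tuple[float, float] = (1.0, 0.0)  # fractions of class 1 and class 2
    contamination: float = 0.0
    shift_sigma: float = 0.0               # in-plane shift spread in pixels
    with_ctf: bool = True
    voltage_kV: float = 300.0
    amplitude_contrast: float = 0.1
    defocus_range: tuple[float, float] = (10000.0, 25000.0)
    images_per_micrograph: int = 50
    defocus_offset: float = 0.0            # systematic error added to the simulation defocus
    pixel_size_error: float = 1.0          # factor applied to the simulation pixel size
    norm_jitter_a: float = 0.0
    norm_jitter_b: float = 0.0
    norm_offset_b: float = 0.0             # systematic additive offset
    phantom_seed: int = 0
    seed: int = 0

    def __post_init__(self):
        f1, f2 = self.mixture
        if not (0 <= f1 <= 1 and 0 <= f2 <= 1 and 0 <= self.contamination <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if f1 + f2 + self.contamination > 1 + 1e-9:
            raise ValueError("mixture + contamination fractions exceed 1")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


class FourierProjector:
    """Central-slice projector with a cached padded 3-D transform.

    Build once per volume, then project at many poses cheaply.
    """

    def __init__(self, volume: Volume, pad: int = PAD_FACTOR, order: int = 3):
        self.box = volume.box
        self.voxel_size = volume.voxel_size
        self.m = pad * self.box
        self.order = order
        f3 = fftn_center(pad_center(volume.data, self.m))
        # prefiltered spline coefficients: sampling many slices is then cheap
        self._re = ndimage.spline_filter(f3.real, order=order) if order > 1 \
            else np.ascontiguousarray(f3.real)
        self._im = ndimage.spline_filter(f3.imag, order=order) if order > 1 \
            else np.ascontiguousarray(f3.imag)
        q = np.arange(self.m) - self.m // 2
        qx, qy = np.meshgrid(q, q, indexing="xy")
        self._plane = np.stack([qx.ravel(), qy.ravel(),
                                np.zeros(self.m * self.m)], axis=0)

    def slice_spectrum(self, pose: Pose) -> np.ndarray:
        """Sampled central slice (padded side), shift phase applied."""
        a = pose.matrix()
        xyz = a @ self._plane                     # (3, m*m) in (x, y, z)
        idx = xyz[::-1] + self.m // 2             # map_coordinates wants (z, y, x)
        re = ndimage.map_coordinates(self._re, idx, order=self.order,
                                     mode="constant", prefilter=False)
        im = ndimage.map_coordinates(self._im, idx, order=self.order,
                                     mode="constant", prefilter=False)
        f2 = (re + 1j * im).reshape(self.m, self.m)
        if pose.shift_x or pose.shift_y:
            f2 = f2 * shift_phase_2d(self.m, pose.shift_x, pose.shift_y)
        return f2

    def project(self, pose: Pose) -> np.ndarray:
        """Line-integral projection image, side = volume box."""
        return crop_center(ifft2_center(self.slice_spectrum(pose)).real, self.box)


def project(volume: Volume, pose: Pose) -> np.ndarray:
    """One-shot projection; use FourierProjector for many poses of one volume."""
    return FourierProjector(volume).project(pose)


def project_real_space(volume: Volume, pose: Pose) -> np.ndarray:
    """Brute-force oracle: rotate the volume grid, then sum along z.

    The volume is resampled at A @ r (spline interpolation) and integrated
    along the z index, followed by the in-plane shift.  Slow; used to verify
    the Fourier path.
    """
    a = pose.matrix()
    box = volume.box
    c = box // 2
    q = np.arange(box) - c
    qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
    pts = np.stack([qx.ravel(), qy.ravel(), qz.ravel()], axis=0).astype(float)
    rot = a @ pts
    idx = rot[::-1] + c
    vals = ndimage.map_coordinates(volume.data, idx, order=3, mode="constant")
    proj = vals.reshape(box, box, box).sum(axis=0)
    if pose.shift_x or pose.shift_y:
        proj = ifft2_center(fft2_center(proj)
                            * shift_phase_2d(box, pose.shift_x, pose.shift_y)).real
    return proj


def support_mask_2d(side: int, radius_frac: float = 0.4) -> np.ndarray:
    q = np.arange(side) - side // 2
    qx, qy = np.meshgrid(q, q, indexing="xy")
    return qx**2 + qy**2 <= (radius_frac * side) ** 2


def add_noise(image: np.ndarray, snr: float, rng: np.random.Generator,
              support: np.ndarray | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise with variance = var(signal | support)/snr.

    SNR is defined against the signal variance inside the projected particle
    support (a disk of radius 0.4 * side by default), not the full frame.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noiseless)")
    image = np.asarray(image, dtype=np.float64)
    if np.isinf(snr):
        return image.copy()
    if support is None:
        support = support_mask_2d(image.shape[0])
    sig_var = float(np.var(image[support]))
    return image + rng.normal(0.0, np.sqrt(sig_var / snr), size=image.shape)


def apply_normalization(image: np.ndarray, norm: NormalizationParams) -> np.ndarray:
    """Exact affine transform a * I + b."""
    return norm.a * np.asarray(image, dtype=np.float64) + norm.b


def _draw_poses(n: int, cfg: GeneratorConfig, rng: np.random.Generator) -> list[Pose]:
    rot = rng.uniform(-180.0, 180.0, n)
    psi = rng.uniform(-180.0, 180.0, n)
    if cfg.angular_distribution == "uniform":
        tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
    elif cfg.angular_distribution == "cone_depleted":
        # uniform over the sphere minus a polar cap of the given half-angle
        cmax = np.cos(np.radians(cfg.cone_half_angle))
        tilt = np.degrees(np.arccos(rng.uniform(-1.0, cmax, n)))
    elif cfg.angular_distribution == "preferred_orientation":
        n_pref = int(round(cfg.preferred_fraction * n))
        t_pref = np.abs(rng.normal(cfg.preferred_tilt, cfg.preferred_tilt_spread,
                                   n_pref))
        t_pref = np.clip(t_pref, 0.0, 180.0)
        t_uni = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n - n_pref)))
        tilt = np.concatenate([t_pref, t_uni])
    else:
        raise ValueError(f"unknown angular distribution {cfg.angular_distribution!r}")
    sx = rng.normal(0.0, cfg.shift_sigma, n) if cfg.shift_sigma > 0 else np.zeros(n)
    sy = rng.normal(0.0, cfg.shift_sigma, n) if cfg.shift_sigma > 0 else np.zeros(n)
    return [Pose(r, t, p, x, y) for r, t, p, x, y in zip(rot, tilt, psi, sx, sy)]


def _contaminant_image(box: int, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Random 2-D blob clutter unrelated to the phantom."""
    n_blobs = rng.integers(3, 7)
    q = np.arange(box) - box // 2
    qx, qy = np.meshgrid(q, q, indexing="xy")
    img = np.zeros((box, box))
    for _ in range(n_blobs):
        c = rng.uniform(-0.25 * box, 0.25 * box, 2)
        s = rng.uniform(box / 20.0, box / 8.0)
        a = rng.uniform(0.5, 1.5)
        img += a * np.exp(-((qx - c[0]) ** 2 + (qy - c[1]) ** 2) / (2 * s * s))
    m = support_mask_2d(box)
    std = img[m].std()
    return img * (scale / std if std > 0 else 1.0)


def generate_dataset(cfg: GeneratorConfig,
                     volumes: dict[str, Volume] | None = None
                     ) -> tuple[ParticleStack, dict[str, Volume]]:
    """Simulate a particle stack with labelled ground truth.

    Class counts follow deterministic rounding of the mixture fractions
    (contaminants, then class 2, then class 1 filling the remainder), so
    mixture predictions can be checked exactly.  Returns the stack and the
    ground-truth volume(s) used.
    """
    rng = np.random.default_rng(cfg.seed)
    if volumes is None:
        volumes = {"class1": make_phantom_cached(cfg.box, cfg.voxel_size, "class1",
                                                 cfg.phantom_seed)}
        if cfg.mixture[1] > 0:
            volumes["class2"] = make_phantom_cached(cfg.box, cfg.voxel_size, "class2",
                                                    cfg.phantom_seed)

    n = cfg.n_particles
    n_cont = int(round(cfg.contamination * n))
    n_c2 = int(round(cfg.mixture[1] * n))
    n_c1 = n - n_c2 - n_cont
    if n_c1 < 0:
        raise ValueError("inconsistent mixture/contamination fractions")
    labels = np.concatenate([np.zeros(n_c1, int), np.ones(n_c2, int),
                             np.full(n_cont, 2, int)])

    poses = _draw_poses(n, cfg, rng)

    # per-micrograph nominal defoci; simulation defocus carries the systematic offset
    n_mic = max(1, int(np.ceil(n / cfg.images_per_micrograph)))
    mic_defocus = rng.uniform(*cfg.defocus_range, n_mic)
    mic_of = np.arange(n) // cfg.images_per_micrograph

    ctf_nominal, ctf_true, norms = [], [], []
    for i in range(n):
        nom = CTFParams(voltage_kV=cfg.voltage_kV, defocus_A=float(mic_defocus[mic_of[i]]),
                        amplitude_contrast=cfg.amplitude_contrast,
                        pixel_size_A=cfg.voxel_size)
        tru = replace(nom, defocus_A=nom.defocus_A + cfg.defocus_offset,
                      pixel_size_A=nom.pixel_size_A * cfg.pixel_size_error)
        ctf_nominal.append(nom)
        ctf_true.append(tru)
        a = 1.0 + (rng.normal(0.0, cfg.norm_jitter_a) if cfg.norm_jitter_a > 0 else 0.0)
        b = cfg.norm_offset_b + (rng.normal(0.0, cfg.norm_jitter_b)
                                 if cfg.norm_jitter_b > 0 else 0.0)
        norms.append(NormalizationParams(a=a if a != 0 else 1.0, b=b))

    projectors = {k: FourierProjector(v) for k, v in volumes.items()}
    ref_scale = np.std(projectors["class1"].project(Pose())[support_mask_2d(cfg.box)])

    images = np.empty((n, cfg.box, cfg.box), dtype=np.float64)
    for i in range(n):
        if labels[i] == 2:
            img = _contaminant_image(cfg.box, rng, ref_scale)
        else:
            key = "class1" if labels[i] == 0 else "class2"
            img = projectors[key].project(poses[i])
        if cfg.with_ctf:
            c = ctf_evaluate(ctf_true[i], cfg.box)
            img = ifft2_center(fft2_center(img) * c).real
        img = add_noise(img, cfg.snr, rng)
        images[i] = apply_normalization(img, norms[i])

    stack = ParticleStack(images=images, truth_poses=poses, truth_class=labels,
                          ctf_true=ctf_true, ctf_nominal=ctf_nominal, norm=norms,
                          snr=cfg.snr, voxel_size=cfg.voxel_size)
    return stack, volumes


# tiny cache: experiments re-use the same phantom many times
_PHANTOM_CACHE: dict = {}


def make_phantom_cached(box: int, voxel_size: float, variant: str, seed: int) -> Volume:
    key = (box, voxel_size, variant, seed)
    if key not in _PHANTOM_CACHE:
        _PHANTOM_CACHE[key] = make_phantom(box, voxel_size, variant, seed)
    return _PHANTOM_CACHE[key]
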