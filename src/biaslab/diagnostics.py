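"""FSC machinery and bias-detection statistics.

Covers the Fourier shell correlation and its threshold crossings, B-factor
scaling, real-space masks and their Fourier-width bias, phase randomization
at the image and volume level, radial profiles and halo scores for CTF
miscorrection, the pointwise bias/variance/MSE decomposition of a map
ensemble, the class-mixture prediction, the parameter-counting bookkeeping
and two small statistical demonstrations (kNN bias-variance, BIC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._fourier import fft2_center, fftn_center, ifft2_center, ifftn_center, \
    radial_shell_index
from .forward import ParticleStack
from .volume import Volume, radial_coordinates

NO_CROSSING = float("inf")


# ---------------------------------------------------------------------------
# Fourier shell correlation

@dataclass
class FSCCurve:
    """Per-shell correlation between two half maps.

    frequencies are shell centers R = i / (box * voxel_size) in 1/Å;
    values lie in [-1, 1]; counts are voxels per shell.
    """

    frequencies: np.ndarray
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)

    def area(self, max_shell: int | None = None) -> float:
        """Integral of the curve over frequency (trapezoid), a scalar summary."""
        s = slice(None, max_shell)
        return float(np.trapezoid(self.values[s], self.frequencies[s]))


def shell_sums(f1: np.ndarray, f2: np.ndarray) -> tuple[np.ndarray, ...]:
    box = f1.shape[0]
    shells = radial_shell_index(f1.shape).ravel()
    nsh = box // 2 + 1
    keep = shells < nsh
    sh = shells[keep]
    cross = np.bincount(sh, (f1.ravel()[keep] * np.conj(f2.ravel()[keep])).real,
                        minlength=nsh)
    p1 = np.bincount(sh, np.abs(f1.ravel()[keep]) ** 2, minlength=nsh)
    p2 = np.bincount(sh, np.abs(f2.ravel()[keep]) ** 2, minlength=nsh)
    counts = np.bincount(sh, minlength=nsh)
    return cross, p1, p2, counts


def fsc(v1: Volume, v2: Volume) -> FSCCurve:
    """Fourier shell correlation between two maps of equal box and voxel size.

    Per integer-radius shell: Re sum(F1 conj(F2)) / sqrt(sum|F1|^2 sum|F2|^2);
    zero-energy shells report 0.
    """
    if v1.box != v2.box:
        raise ValueError(f"box mismatch: {v1.box} vs {v2.box}")
    if not np.isclose(v1.voxel_size, v2.voxel_size):
        raise ValueError("voxel size mismatch")
    f1 = fftn_center(v1.data)
    f2 = fftn_center(v2.data)
    cross, p1, p2, counts = shell_sums(f1, f2)
    denom = np.sqrt(p1 * p2)
    values = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    freqs = np.arange(len(values)) / (v1.box * v1.voxel_size)
    return FSCCurve(frequencies=freqs, values=np.clip(values, -1.0, 1.0),
                    counts=counts)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Frequency (1/Å) of the first downward crossing of the threshold.

    Linear interpolation between adjacent shells; returns ``inf``
    (NO_CROSSING) if the curve never falls below the threshold.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (-1, 1)")
    v, f = curve.values, curve.frequencies
    for i in range(1, len(v)):
        if v[i - 1] >= threshold > v[i]:
            t = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            return float(f[i - 1] + t * (f[i] - f[i - 1]))
    return NO_CROSSING


def write_fsc_tsv(curve: FSCCurve, path) -> None:
    """Two-column TSV: frequency (1/Å), FSC."""
    with open(path, "w") as fh:
        fh.write("# frequency_1_per_A\tfsc\n")
        for f, v in zip(curve.frequencies, curve.values):
            fh.write(f"{f:.6f}\t{v:.6f}\n")


# ---------------------------------------------------------------------------
# B factor

def apply_bfactor(v: Volume, b: float) -> Volume:
    """Scale Fourier amplitudes by exp(-B R^2 / 4); phases untouched.

    B in Å^2; negative B sharpens.  R is taken at the integer-binned shell
    radius -- the same binning the FSC uses -- so the weight is constant
    within each shell and the FSC is exactly invariant under the transform
    (for a continuous weight the invariance would only hold to within the
    weight's variation across one shell).
    """
    f = fftn_center(v.data)
    r2 = (radial_shell_index(v.data.shape) / (v.box * v.voxel_size)) ** 2
    out = ifftn_center(f * np.exp(-b * r2 / 4.0)).real
    return Volume(out, v.voxel_size)


def radial_shell_index_float(box: int) -> np.ndarray:
    q = np.arange(box) - box // 2
    qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
    return np.sqrt(qx**2 + qy**2 + qz**2)


# ---------------------------------------------------------------------------
# Masks

@dataclass
class Mask:
    data: np.ndarray
    kind: str
    soft_edge: float

    def __post_init__(self):
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("mask values must lie in [0, 1]")


def make_mask(v: Volume, kind: str = "sphere", soft_edge: float = 5.0,
              radius_frac: float = 0.45, lowpass_A: float = 15.0,
              quantile: float = 0.85, dilation: int = 3) -> Mask:
    """Build a real-space mask for the given volume.

    ``sphere``: soft-edged ball of radius radius_frac * box.
    ``tight``: low-pass the map to ~15 Å, threshold at the 85th percentile of
    in-support values, dilate 3 voxels, then a raised-cosine edge.
    ``loose``: the tight recipe with triple dilation and a wider edge.
    """
    box = v.box
    if kind == "sphere":
        r = radial_coordinates(box)
        data = _raised_cosine(radius_frac * box - r, soft_edge)
    elif kind in ("tight", "loose"):
        if kind == "loose":
            dilation, soft_edge = 3 * dilation, 2 * soft_edge
        sigma = lowpass_A / (2.355 * v.voxel_size)  # FWHM ~ lowpass_A
        smooth = ndimage.gaussian_filter(v.data, sigma)
        support = radial_coordinates(box) <= 0.45 * box
        thr = np.quantile(smooth[support], quantile)
        binary = smooth >= thr
        binary = ndimage.binary_dilation(binary, iterations=dilation)
        dist = ndimage.distance_transform_edt(~binary)
        data = _raised_cosine(soft_edge - dist, soft_edge)
        data[binary] = 1.0
    else:
        raise ValueError(f"unknown mask kind {kind!r}")
    return Mask(data=data, kind=kind, soft_edge=soft_edge)


def _raised_cosine(x: np.ndarray, width: float) -> np.ndarray:
    """0 for x <= -width... smooth cosine ramp to 1 at x >= 0."""
    if width <= 0:
        return (x >= 0).astype(float)
    t = np.clip(x / width, -1.0, 0.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


def apply_mask(v: Volume, mask: Mask) -> Volume:
    if mask.data.shape != v.data.shape:
        raise ValueError("mask/volume box mismatch")
    return Volume(v.data * mask.data, v.voxel_size)


def mask_fourier_width(mask: Mask) -> int:
    """Shell radius (voxels) containing 99% of the mask's spectral energy.

    Tighter masks are broader in Fourier space; this is the bias bandwidth
    the mask convolves into each half map.
    """
    f = np.abs(fftn_center(mask.data)) ** 2
    shells = radial_shell_index(f.shape)
    nsh = f.shape[0] // 2 + 1
    keep = shells < nsh
    power = np.bincount(shells[keep].ravel(), f[keep].ravel(), minlength=nsh)
    cum = np.cumsum(power) / power.sum()
    return int(np.searchsorted(cum, 0.99))


def masked_fsc_experiment(v1: Volume, v2: Volume,
                          masks: dict[str, Mask | None]) -> dict[str, dict]:
    """FSC of a half-map pair under each candidate mask.

    The summary statistic per mask is the mean FSC over shells beyond the
    unmasked 0.143 crossing -- the band where masking inflates agreement.
    """
    base = fsc(v1, v2)
    res = resolution_at(base, 0.143)
    beyond = base.frequencies > res if np.isfinite(res) \
        else np.zeros(len(base.values), dtype=bool)
    out: dict[str, dict] = {}
    for name, mask in masks.items():
        if mask is None:
            curve = base
        else:
            curve = fsc(apply_mask(v1, mask), apply_mask(v2, mask))
        mean_beyond = float(curve.values[beyond].mean()) if beyond.any() else float("nan")
        out[name] = {"curve": curve, "mean_fsc_beyond_unmasked_resolution": mean_beyond}
    return out


# ---------------------------------------------------------------------------
# Phase randomization

def phase_randomize_volume(v: Volume, cutoff: float,
                           rng: np.random.Generator) -> Volume:
    """Randomize Fourier phases beyond the cutoff frequency (1/Å).

    Per-voxel amplitudes are preserved exactly; the randomized phases come
    from the transform of a white Gaussian field, so Hermitian symmetry is
    automatic and the output stays real.
    """
    nyq = 1.0 / (2.0 * v.voxel_size)
    if not 0 < cutoff <= nyq + 1e-12:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq:.4f}]")
    f = fftn_center(v.data)
    out = _randomize(f, cutoff * v.box * v.voxel_size, rng)
    return Volume(ifftn_center(out).real, v.voxel_size)


def phase_randomize_images(stack: ParticleStack, cutoff: float,
                           rng: np.random.Generator) -> ParticleStack:
    """Image-level phase randomization (the validation-faithful variant)."""
    nyq = 1.0 / (2.0 * stack.voxel_size)
    if not 0 < cutoff <= nyq + 1e-12:
        raise ValueError(f"cutoff must lie in (0, Nyquist={nyq:.4f}]")
    r_cut = cutoff * stack.box * stack.voxel_size
    images = np.empty_like(stack.images)
    for i, img in enumerate(stack.images):
        f = fft2_center(img)
        images[i] = ifft2_center(_randomize(f, r_cut, rng)).real
    out = ParticleStack(images=images, truth_poses=list(stack.truth_poses),
                        truth_class=stack.truth_class.copy(),
                        ctf_true=list(stack.ctf_true),
                        ctf_nominal=list(stack.ctf_nominal),
                        norm=list(stack.norm), snr=stack.snr,
                        voxel_size=stack.voxel_size)
    return out


def _randomize(f: np.ndarray, r_cut: float, rng: np.random.Generator) -> np.ndarray:
    side = f.shape[0]
    if f.ndim == 3:
        shells = radial_shell_index_float(side)
    else:
        q = np.arange(side) - side // 2
        qx, qy = np.meshgrid(q, q, indexing="xy")
        shells = np.sqrt(qx**2 + qy**2)
    # corner samples beyond the Nyquist sphere count as "at Nyquist", so a
    # cutoff at Nyquist randomizes nothing
    beyond = np.minimum(shells, side // 2) > r_cut
    g = np.fft.fftshift(np.fft.fftn(rng.normal(size=f.shape)))
    phase = np.exp(1j * np.angle(g))
    out = f.copy()
    out[beyond] = np.abs(f[beyond]) * phase[beyond]
    return out


# ---------------------------------------------------------------------------
# Radial profiles and halo detection

def radial_profile(v: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Spherically averaged density: (radii in voxels, mean density)."""
    r = np.rint(radial_coordinates(v.box)).astype(int).ravel()
    nr = v.box // 2 + 1
    keep = r < nr
    sums = np.bincount(r[keep], v.data.ravel()[keep], minlength=nr)
    counts = np.bincount(r[keep], minlength=nr)
    return np.arange(nr), sums / np.maximum(counts, 1)


def halo_score(v: Volume, particle_radius: float) -> float:
    """Mean density in the annulus [1.05 r, 1.3 r] around the particle.

    Negative values flag the dark halo characteristic of systematic
    defocus/pixel-size miscorrection of a non-negative particle.
    """
    if particle_radius >= 0.38 * v.box:
        raise ValueError("particle radius too large for the halo annulus")
    r = radial_coordinates(v.box)
    annulus = (r >= 1.05 * particle_radius) & (r <= 1.3 * particle_radius)
    return float(v.data[annulus].mean())


# ---------------------------------------------------------------------------
# Ensemble bias / variance

@dataclass
class BiasVarianceMaps:
    """Pointwise decomposition of an ensemble of reconstructions vs truth.

    mse = bias^2 + variance holds to machine precision (population
    normalization)."""

    bias: np.ndarray
    variance: np.ndarray
    mse: np.ndarray
    n_ensemble: int


def bias_variance(ensemble: list[Volume], truth: Volume) -> BiasVarianceMaps:
    if len(ensemble) < 2:
        raise ValueError("ensemble must contain at least 2 volumes")
    if any(v.box != truth.box for v in ensemble):
        raise ValueError("ensemble/truth box mismatch")
    stack = np.stack([v.data for v in ensemble])
    mean = stack.mean(axis=0)
    bias = mean - truth.data
    variance = stack.var(axis=0)          # population normalization
    mse = np.mean((stack - truth.data) ** 2, axis=0)
    return BiasVarianceMaps(bias=bias, variance=variance, mse=mse,
                            n_ensemble=len(ensemble))


def mixture_prediction(v1: Volume, v2: Volume, n1: int, n2: int) -> Volume:
    """Linear mixture estimate (N1 V1 + N2 V2) / (N1 + N2).

    The bias of the class-1 estimate under an N2-image contamination from
    class 2, assuming a linear reconstruction with equal image weights.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 < 1:
        raise ValueError("need at least one image")
    v1._check_match(v2)
    return Volume((n1 * v1.data + n2 * v2.data) / (n1 + n2), v1.voxel_size)


# ---------------------------------------------------------------------------
# Parameter counting

def count_parameters(n_particles: int, box: int) -> dict[str, int]:
    """Model-size bookkeeping for an SPA refinement.

    The volume contributes box^3 parameters; each particle six (three Euler
    angles, two shifts, one class membership); measurements are the image
    pixels, n_particles * box^2.  For 100 000 particles of 200^2 this gives
    8 600 000 parameters against 4 000 000 000 measurements.
    """
    if n_particles < 0 or box < 1:
        raise ValueError("n_particles must be >= 0 and box >= 1")
    volume_params = box**3
    per_particle = 6
    alignment_params = per_particle * n_particles
    return {
        "volume_params": volume_params,
        "alignment_params": alignment_params,
        "total_params": volume_params + alignment_params,
        "measurements": n_particles * box**2,
        "per_particle": per_particle,
    }


# ---------------------------------------------------------------------------
# kNN bias-variance demo

@dataclass
class TheoryDemoConfig:
    f: callable = None                 # true regression function
    noise_sd: float = 1.0
    n_samples: int = 200
    k_values: tuple = (1, 5, 25)
    n_reps: int = 200
    n_eval: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.f is None:
            self.f = lambda x: 2.0 * x
        if any(k < 1 for k in self.k_values):
            raise ValueError("k values must be >= 1")
        if self.n_reps < 2:
            raise ValueError("need at least 2 ensemble repetitions")
        if any(k > self.n_samples for k in self.k_values):
            raise ValueError("k cannot exceed the sample size")


def knn_bias_variance(cfg: TheoryDemoConfig) -> list[dict]:
    """Monte-Carlo bias^2 / variance / MSE of kNN regression vs k.

    Fixed x design on [0, 1], fresh Gaussian noise per repetition; estimates
    are evaluated against the known f at fixed interior points.  For the
    averaging estimator the prediction variance is sigma^2 / k.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.linspace(0.0, 1.0, cfg.n_samples)
    x_eval = np.linspace(0.2, 0.8, cfg.n_eval)
    fx = cfg.f(x)
    f_eval = cfg.f(x_eval)
    # neighbor sets are a function of the fixed design only
    order = np.argsort(np.abs(x[None, :] - x_eval[:, None]), axis=1, kind="stable")

    rows = []
    for k in cfg.k_values:
        nbr = order[:, :k]
        preds = np.empty((cfg.n_reps, cfg.n_eval))
        for rep in range(cfg.n_reps):
            y = fx + rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
            preds[rep] = y[nbr].mean(axis=1)
        mean_pred = preds.mean(axis=0)
        bias2 = (mean_pred - f_eval) ** 2
        var = preds.var(axis=0)
        mse = np.mean((preds - f_eval) ** 2, axis=0)
        rows.append({
            "k": int(k),
            "mean_bias2": float(bias2.mean()),
            "mean_variance": float(var.mean()),
            "mean_mse": float(mse.mean()),
            "expected_variance": cfg.noise_sd**2 / k,
        })
    return rows


def bic_score(loglik: float, k: int, n_obs: int) -> float:
    """Bayesian information criterion on the log-likelihood scale.

    loglik - (k/2) ln N: a data-fidelity term minus a parameter-count
    penalty; the model maximizing the score is preferred.
    """
    if n_obs < 1:
        raise ValueError("need at least one observation")
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    return float(loglik - 0.5 * k * np.log(n_obs))
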