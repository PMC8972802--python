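"""Contrast transfer function model.

The CTF is evaluated as

    CTF(R) = -[ sqrt(1 - Q^2) * sin(chi) + Q * cos(chi) ],
    chi    = pi * lambda * defocus * R^2 - (pi/2) * Cs * lambda^3 * R^4,

with underfocus positive, amplitude contrast Q and spherical aberration Cs
both defaulting to zero so the default reduces to -sin(pi lambda df R^2),
the simplest oscillatory model in use in the field.  Frequencies follow the
discrete convention R = i / (N * Ts) with i the centered frequency index,
N the image side and Ts the pixel size in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fourier import fft2_center, freq_grid_2d, ifft2_center


@dataclass(frozen=True)
class CTFParams:
    voltage_kV: float = 300.0
    defocus_A: float = 15000.0
    spherical_aberration_mm: float = 0.0
    amplitude_contrast: float = 0.0
    pixel_size_A: float = 2.0

    def __post_init__(self):
        if self.voltage_kV <= 0:
            raise ValueError("voltage must be positive")
        if self.pixel_size_A <= 0:
            raise ValueError("pixel size must be positive")
        if not 0.0 <= self.amplitude_contrast < 1.0:
            raise ValueError("amplitude contrast must be in [0, 1)")

    @property
    def wavelength_A(self) -> float:
        return electron_wavelength(self.voltage_kV)


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Å for a voltage in kV."""
    v = voltage_kV * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def ctf_evaluate(ctf: CTFParams, image_side: int) -> np.ndarray:
    """Centered 2-D CTF modulation array for a square image.

    The first zero (Cs = Q = 0) sits at R = 1 / sqrt(lambda * defocus).
    """
    if image_side % 2 != 0:
        raise ValueError("image side must be even")
    qx, qy = freq_grid_2d(image_side)
    r2 = (qx**2 + qy**2) / (image_side * ctf.pixel_size_A) ** 2
    lam = ctf.wavelength_A
    cs = ctf.spherical_aberration_mm * 1e7  # mm -> Å
    chi = np.pi * lam * ctf.defocus_A * r2 - 0.5 * np.pi * cs * lam**3 * r2**2
    q = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - q * q) * np.sin(chi) + q * np.cos(chi))


def apply_ctf(image: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """Multiply the image spectrum by the CTF; output stays real."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    c = ctf_evaluate(ctf, image.shape[0])
    return ifft2_center(fft2_center(image) * c).real


def phase_flip(image: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """Correct the CTF sign only: multiply the spectrum by sign(CTF)."""
    image = np.asarray(image, dtype=np.float64)
    c = ctf_evaluate(ctf, image.shape[0])
    return ifft2_center(fft2_center(image) * np.sign(c)).real


def first_zero_frequency(ctf: CTFParams) -> float:
    """Analytic first zero crossing (1/Å) for the Cs = Q = 0 model."""
    return float(1.0 / np.sqrt(ctf.wavelength_A * abs(ctf.defocus_A)))
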