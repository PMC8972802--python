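"""Ground-truth phantom volumes.

Phantoms are sums of Gaussian blobs inside a support sphere of radius
0.4 * box, so every projection fits comfortably in the image frame.  Three
variants are provided:

``class1``
    the base blob arrangement;
``class2``
    the same arrangement with a stated subset of blobs displaced and one
    deleted, giving a known, localized structural difference for mixture
    experiments;
``pseudo_sym``
    two near-identical subunits related by a 180 deg rotation about z, with
    one extra blob in only one subunit (a pseudo-C2 particle).
"""

from __future__ import annotations

import numpy as np

from .volume import Volume, radial_coordinates

# blobs altered in the class2 variant (indices into the base blob list)
_DISPLACED = (0, 1, 2)
_DELETED = 3
_N_BLOBS = 14


def make_phantom(box: int, voxel_size: float = 2.0, variant: str = "class1",
                 seed: int = 0) -> Volume:
    """Deterministic sum-of-Gaussian-blobs phantom.

    Parameters
    ----------
    box : side length in voxels (even, >= 16; >= 32 recommended for experiments)
    voxel_size : Å per voxel
    variant : one of ``class1``, ``class2``, ``pseudo_sym``
    seed : blob-layout seed; identical seeds give identical volumes, and
        class1/class2 with the same seed differ only at the altered blobs
    """
    if box % 2 != 0 or box < 16:
        raise ValueError(f"box must be even and >= 16, got {box}")
    if variant not in ("class1", "class2", "pseudo_sym"):
        raise ValueError(f"unknown phantom variant {variant!r}")

    rng = np.random.default_rng(seed)
    if variant == "pseudo_sym":
        data = _pseudo_sym_density(box, rng)
    else:
        pos, sig, amp = _base_blobs(box, rng)
        disp = rng.normal(size=(len(_DISPLACED), 3))
        disp = 0.08 * box * disp / np.linalg.norm(disp, axis=1, keepdims=True)
        if variant == "class2":
            for j, i in enumerate(_DISPLACED):
                pos[i] = pos[i] + disp[j]
            amp[_DELETED] = 0.0
        data = _blob_density(box, pos, sig, amp)

    data[radial_coordinates(box) > 0.4 * box] = 0.0
    return Volume(data, voxel_size)


def class_difference_region(box: int, seed: int = 0, n_sigma: float = 4.0) -> np.ndarray:
    """Boolean mask of voxels where class1 and class2 may legitimately differ.

    The union of balls of radius ``n_sigma * sigma`` around each altered
    blob's original and displaced positions.
    """
    rng = np.random.default_rng(seed)
    pos, sig, _ = _base_blobs(box, rng)
    disp = rng.normal(size=(len(_DISPLACED), 3))
    disp = 0.08 * box * disp / np.linalg.norm(disp, axis=1, keepdims=True)
    centers = [pos[_DELETED]]
    radii = [n_sigma * sig[_DELETED]]
    for j, i in enumerate(_DISPLACED):
        centers += [pos[i], pos[i] + disp[j]]
        radii += [n_sigma * sig[i]] * 2
    q = np.arange(box) - box // 2
    qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
    grid = np.stack([qx, qy, qz], axis=-1).astype(float)
    mask = np.zeros((box,) * 3, dtype=bool)
    for c, r in zip(centers, radii):
        mask |= np.sum((grid - c) ** 2, axis=-1) < r * r
    return mask


def _base_blobs(box: int, rng: np.random.Generator):
    """Blob centers (voxels, relative to the center), widths and amplitudes."""
    u = rng.normal(size=(_N_BLOBS, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = 0.28 * box * rng.uniform(0.15, 1.0, size=_N_BLOBS) ** (1 / 3)
    pos = u * radii[:, None]
    sig = rng.uniform(box / 24.0, box / 14.0, size=_N_BLOBS)
    amp = rng.uniform(0.5, 1.5, size=_N_BLOBS)
    return pos, sig, amp


def _blob_density(box: int, pos: np.ndarray, sig: np.ndarray,
                  amp: np.ndarray) -> np.ndarray:
    q = np.arange(box) - box // 2
    qz, qy, qx = np.meshgrid(q, q, q, indexing="ij")
    grid = np.stack([qx, qy, qz], axis=-1).astype(float)
    data = np.zeros((box,) * 3)
    for p, s, a in zip(pos, sig, amp):
        if a == 0.0:
            continue
        d2 = np.sum((grid - p) ** 2, axis=-1)
        data += a * np.exp(-d2 / (2.0 * s * s))
    return data


def _pseudo_sym_density(box: int, rng: np.random.Generator) -> np.ndarray:
    # one subunit of 7 blobs, duplicated by Rz(180): (x, y, z) -> (-x, -y, z)
    n_sub = 7
    u = rng.normal(size=(n_sub, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = 0.28 * box * rng.uniform(0.25, 1.0, size=n_sub) ** (1 / 3)
    pos = u * radii[:, None]
    pos[:, 0] = np.abs(pos[:, 0]) + 0.04 * box  # keep the subunit on one side
    sig = rng.uniform(box / 24.0, box / 14.0, size=n_sub)
    amp = rng.uniform(0.5, 1.5, size=n_sub)
    mirrored = pos * np.array([-1.0, -1.0, 1.0])
    all_pos = np.concatenate([pos, mirrored])
    all_sig = np.concatenate([sig, sig])
    all_amp = np.concatenate([amp, amp])
    # symmetry-breaking blob in subunit 1 only
    extra_pos = pos[0] + np.array([0.0, 0.05 * box, 0.05 * box])
    all_pos = np.concatenate([all_pos, extra_pos[None]])
    all_sig = np.concatenate([all_sig, [box / 20.0]])
    all_amp = np.concatenate([all_amp, [0.9]])
    return _blob_density(box, all_pos, all_sig, all_amp)
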