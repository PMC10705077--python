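"""Shared fixtures and independent brute-force oracles.

Oracles deliberately avoid the library code paths they check: distances come
from explicit all-pairs minimization, Dice from coordinate-set arithmetic,
closing from explicit shift loops, thickness from direct sphere fitting.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteovasc.phantom import (
    MetastasisSpec,
    PhantomSpec,
    RenderSpec,
    TrabeculaeSpec,
    generate_labels,
)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_phantom():
    """One generator-default phantom with its ground truth."""
    return generate_labels(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def segmenter_fixture_spec():
    """Noise-free rodless phantom with small, wall-contained lesion breaches:
    the geometry on which morphological metastasis inference is well-posed."""
    return PhantomSpec(
        seed=7,
        trabeculae=TrabeculaeSpec(rod_count=0),
        metastases=MetastasisSpec(lesion_count=2, semi_axis_range_um=(10.0, 18.0)),
        render=RenderSpec(noise_sd=0.0, blur_um=0.0),
    )


def random_mask(rng, shape, p=0.1):
    return rng.random(shape) < p


# ---------------------------------------------------------------------------
# oracles


def brute_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice via explicit coordinate-set arithmetic."""
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def brute_distance_map(reference: np.ndarray, voxel_size) -> np.ndarray:
    """All-pairs nearest-reference Euclidean distance, voxel centers, µm."""
    h = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    ref = np.argwhere(reference) * h
    pts = np.argwhere(np.ones(reference.shape, bool)) * h
    out = np.empty(len(pts))
    for i in range(0, len(pts), 4096):
        chunk = pts[i : i + 4096]
        d2 = ((chunk[:, None, :] - ref[None, :, :]) ** 2).sum(axis=-1)
        out[i : i + 4096] = np.sqrt(d2.min(axis=1))
    return out.reshape(reference.shape)


def brute_local_thickness(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Direct maximal-inscribed-sphere fitting.

    For every candidate center c the inscribed radius is the distance to the
    nearest background voxel center minus half a voxel; a voxel p receives
    thickness 2r of the largest sphere with |p - c| <= r + h/2.
    """
    h = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    h_min = float(h.min())
    fg = np.argwhere(mask) * h
    bg = np.argwhere(~mask) * h
    r_ins = np.empty(len(fg))
    for i in range(0, len(fg), 2048):
        d2 = ((fg[i : i + 2048, None, :] - bg[None, :, :]) ** 2).sum(axis=-1)
        r_ins[i : i + 2048] = np.sqrt(d2.min(axis=1)) - 0.5 * h_min
    thick = np.zeros(len(fg))
    for i in range(0, len(fg), 2048):
        d2 = ((fg[i : i + 2048, None, :] - fg[None, :, :]) ** 2).sum(axis=-1)
        covered = d2 <= (r_ins[None, :] + 0.5 * h_min) ** 2 + 1e-9
        masked = np.where(covered, r_ins[None, :], -np.inf)
        thick[i : i + 2048] = 2.0 * masked.max(axis=1)
    out = np.zeros(mask.shape)
    out[mask] = thick
    return out


def _ball_offsets(radius_um: float, voxel_size) -> np.ndarray:
    h = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    ext = np.floor(radius_um / h + 1e-9).astype(int)
    offs = np.stack(
        np.meshgrid(*[np.arange(-e, e + 1) for e in ext], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    d2 = ((offs * h) ** 2).sum(axis=1)
    return offs[d2 <= radius_um**2 + 1e-6]


def brute_closing(mask: np.ndarray, radius_um: float, voxel_size) -> np.ndarray:
    """Explicit shift-loop ball closing with the package's border convention:
    the structure continues axially (z edge replication) and is surrounded by
    air laterally (zero padding)."""
    offs = _ball_offsets(radius_um, voxel_size)
    # np.roll wraps around; double padding keeps wrapped values out of reach
    pad = 2 * int(np.abs(offs).max()) + 2
    padded = np.pad(mask, ((pad, pad), (0, 0), (0, 0)), mode="edge")
    padded = np.pad(padded, ((0, 0), (pad, pad), (pad, pad)), mode="constant")
    dil = np.zeros_like(padded)
    for off in offs:
        dil |= np.roll(padded, off, axis=(0, 1, 2))
    ero = np.ones_like(dil)
    for off in offs:
        ero &= np.roll(dil, off, axis=(0, 1, 2))
    return ero[pad:-pad, pad:-pad, pad:-pad]
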