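"""Desk-scale patch datasets built from synthetic phantoms.

Produces the 40x40x26-voxel training blocks the detector consumes:
nodule-centred patches (with positional jitter so the target is not always
dead-centre) plus a fraction of background lung patches, intensities
standardized by the pooled dataset statistics.
"""

from __future__ import annotations

import numpy as np

from pulmocad.phantom import PhantomSpec, generate_dataset
from pulmocad.volume_io import DEFAULT_PATCH_SHAPE_XYZ, extract_patch

__all__ = ["make_patch_dataset"]


def make_patch_dataset(
    n_patches: int = 100,
    n_phantoms: int = 6,
    seed: int = 0,
    background_fraction: float = 0.2,
    jitter: int = 6,
    patch_shape_xyz: tuple = DEFAULT_PATCH_SHAPE_XYZ,
    noise_sigma: float = 0.0,
) -> list:
    """Build (image, label) pairs of shape (z, y, x) = reversed(patch shape).

    Nodule diameters are drawn uniformly from [6, 20] mm so every positive
    patch holds a well-resolved target; labels are the phantom's nodule
    truth mask.  Background patches sample nodule-free lung locations.
    Intensities are standardized by the pooled mean/std of the sampled
    patches.
    """
    rng = np.random.default_rng(seed)
    base = PhantomSpec(noise_sigma=noise_sigma)
    items = generate_dataset(
        n_phantoms,
        base_spec=base,
        diameter_sampler=lambda r: float(r.uniform(6.0, 20.0)),
        seed=seed,
    )
    n_background = int(round(background_fraction * n_patches))
    n_positive = n_patches - n_background
    pairs = []
    for i in range(n_positive):
        vol, truth = items[i % len(items)]
        nod = truth.nodules[0]
        center_zyx = np.round(vol.world_to_voxel((nod.center[2], nod.center[1], nod.center[0]))).astype(int)
        center_zyx = center_zyx + rng.integers(-jitter, jitter + 1, size=3)
        center_zyx = np.clip(center_zyx, 0, np.array(vol.shape) - 1)
        p = extract_patch(vol, center_zyx, patch_shape_xyz, label_volume=truth.nodule_mask)
        pairs.append((p.voxels, p.label.astype(np.float32)))
    for i in range(n_background):
        vol, truth = items[i % len(items)]
        lung_idx = np.argwhere(truth.lung_mask & ~truth.nodule_mask)
        center_zyx = lung_idx[rng.integers(0, len(lung_idx))]
        p = extract_patch(vol, center_zyx, patch_shape_xyz, label_volume=truth.nodule_mask)
        pairs.append((p.voxels, p.label.astype(np.float32)))
    all_vox = np.concatenate([im.ravel() for im, _ in pairs])
    mean, std = float(all_vox.mean()), float(all_vox.std())
    std = max(std, 1e-6)
    return [(((im - mean) / std).astype(np.float32), lab) for im, lab in pairs]
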