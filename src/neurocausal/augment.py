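"""Volume augmentation: Gaussian blur, one-voxel translation, flip, balancing.

The composition is pinned: per original volume the output contains the
original, one blurred copy per blur setting, one translated copy per signed
one-voxel shift along each axis, and then a left–right flip of every image so
far.  With the defaults (three blurs, six shifts) that is 2 x (1 + 3 + 6) = 20
images per original before class balancing, which then duplicates randomly
chosen minority-class images until the classes are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import ValidationError


@dataclass(frozen=True)
class AugmentationConfig:
    #: (kernel_size, spread) pairs; the blur is a Gaussian with sigma=spread
    #: truncated to the given odd kernel size.
    blur_settings: tuple[tuple[int, float], ...] = ((3, 0.7), (5, 0.7), (7, 0.6))
    translation_voxels: int = 1
    #: left–right anatomical axis; None disables flipping
    flip_axis: int | None = 0
    balance: bool = True

    def __post_init__(self):
        for k, s in self.blur_settings:
            if k % 2 != 1:
                raise ValidationError(f"blur kernel sizes must be odd, got {k}")
            if s <= 0:
                raise ValidationError(f"blur spread must be > 0, got {s}")
        if self.translation_voxels < 0:
            raise ValidationError(
                f"translation_voxels must be >= 0, got {self.translation_voxels}")
        if self.flip_axis is not None and not 0 <= self.flip_axis < 3:
            raise ValidationError(f"flip_axis must be in [0, 3), got {self.flip_axis}")


def blur_volume(vol: np.ndarray, kernel_size: int, spread: float) -> np.ndarray:
    radius = (kernel_size - 1) // 2
    # truncate so the effective kernel support matches the requested size
    return ndimage.gaussian_filter(vol, sigma=spread, truncate=radius / spread)


def translate_volume(vol: np.ndarray, axis: int, delta: int) -> np.ndarray:
    """Shift by ``delta`` voxels along ``axis``, zero-filling the vacated slab."""
    out = np.zeros_like(vol)
    src = [slice(None)] * vol.ndim
    dst = [slice(None)] * vol.ndim
    if delta >= 0:
        dst[axis] = slice(delta, None)
        src[axis] = slice(None, vol.shape[axis] - delta)
    else:
        dst[axis] = slice(None, delta)
        src[axis] = slice(-delta, None)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def flip_volume(vol: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.flip(vol, axis=axis)


def augment_dataset(volumes, labels, cfg: AugmentationConfig | None = None,
                    seed: int = 0, subject_ids=None):
    """Expand a labeled set of volumes by the pinned augmentation pipeline.

    Parameters
    ----------
    volumes : array (n, D, H, W)
    labels : int array (n,)
        Binary class labels.
    cfg : AugmentationConfig
    seed : int
        Drives the random minority-class duplication when ``cfg.balance``.
    subject_ids : sequence of str, optional
        Propagated to every augmented copy so cross-validation can keep
        test subjects (and all their augmented copies) out of training.

    Returns
    -------
    (volumes, labels, subject_ids) with augmented copies appended.
    """
    cfg = cfg or AugmentationConfig()
    volumes = np.asarray(volumes)
    labels = np.asarray(labels)
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(volumes))]
    subject_ids = list(subject_ids)
    if cfg.balance and len(np.unique(labels)) < 2:
        raise ValidationError("balance=True requires at least one volume per class")

    out_vols, out_labels, out_ids = [], [], []
    for vol, lab, sid in zip(volumes, labels, subject_ids):
        group = [vol]
        for k, s in cfg.blur_settings:
            group.append(blur_volume(vol, k, s))
        t = cfg.translation_voxels
        if t > 0:
            for axis in range(3):
                for delta in (t, -t):
                    group.append(translate_volume(vol, axis, delta))
        if cfg.flip_axis is not None:
            group = group + [flip_volume(v, cfg.flip_axis) for v in group]
        out_vols.extend(group)
        out_labels.extend([lab] * len(group))
        out_ids.extend([sid] * len(group))

    out_vols = np.stack(out_vols)
    out_labels = np.asarray(out_labels)

    if cfg.balance:
        rng = np.random.default_rng(seed)
        counts = {c: int((out_labels == c).sum()) for c in np.unique(out_labels)}
        minority = min(counts, key=counts.get)
        deficit = max(counts.values()) - counts[minority]
        if deficit > 0:
            pool = np.flatnonzero(out_labels == minority)
            picks = rng.choice(pool, size=deficit, replace=True)
            out_vols = np.concatenate([out_vols, out_vols[picks]])
            out_labels = np.concatenate([out_labels, out_labels[picks]])
            out_ids = out_ids + [out_ids[i] for i in picks]

    return out_vols, out_labels, out_ids


def expected_multiplicity(cfg: AugmentationConfig) -> int:
    """Output images per original before balancing: 2 x (1 + #blur + #shifts)."""
    n_shift = 6 if cfg.translation_voxels > 0 else 0
    flip_factor = 2 if cfg.flip_axis is not None else 1
    return flip_factor * (1 + len(cfg.blur_settings) + n_shift)
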