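"""Prediction-difference relevance analysis and ROI extraction.

A sliding 3x3x3 patch is "removed" from the image by replacing it with draws
from a multivariate normal estimated at that patch location across training
volumes.  The drop in the classifier's disease probability is scored as a
log-odds difference

    d = log[ (p0 / (1 - p0)) / (p1 / (1 - p1)) ],

where p0 is the probability on the intact image and p1 the mean probability
over the occluded copies.  d > 0 means the patch carried evidence for the
disease class.  Accumulating d over all window positions (overlaps averaged
by coverage) yields a per-voxel relevance map W on the image grid; averaging
over subjects gives the cohort map.  Voxels in the top decile of W, grouped
into connected components, form the regions of interest.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import ValidationError


def relevance_score(p0, p1, clip: float = 1e-6):
    """Log-odds difference between intact (p0) and occluded (p1) probability.

    Probabilities are clipped to [clip, 1-clip] to keep saturated softmax
    outputs finite.  Vectorized over array inputs.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    if np.any(p0 < 0) or np.any(p0 > 1) or np.any(p1 < 0) or np.any(p1 > 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    p0 = np.clip(p0, clip, 1 - clip)
    p1 = np.clip(p1, clip, 1 - clip)
    out = np.log(p0 / (1 - p0)) - np.log(p1 / (1 - p1))
    return out if out.ndim else float(out)


class PatchSampler:
    """Multivariate-normal replacement model for sliding patches.

    The mean vector and covariance at each patch location are estimated from
    the training volumes (marginal statistics of that location, flattened in
    C order).  A small ridge (`ridge`) keeps the covariance factorizable when
    the training sample is small relative to the patch size.
    """

    def __init__(self, training_volumes, patch_shape=(3, 3, 3), n_draws: int = 10,
                 ridge: float = 1e-6):
        if n_draws < 1:
            raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
        self.training = np.asarray(training_volumes, dtype=np.float64)
        if self.training.ndim != 4:
            raise ValidationError("training_volumes must be (n, D, H, W)")
        self.patch_shape = tuple(int(p) for p in patch_shape)
        self.n_draws = n_draws
        self.ridge = ridge
        self._cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        # overridable for degenerate/test samplers
        self.fixed_mean: np.ndarray | None = None
        self.fixed_chol: np.ndarray | None = None

    def _check_location(self, location):
        grid = self.training.shape[1:]
        for lo, k, dim in zip(location, self.patch_shape, grid):
            if not (0 <= lo and lo + k <= dim):
                raise ValidationError(
                    f"patch at {location} does not fit inside grid {grid}")

    def stats(self, location):
        """(mean, cholesky_factor) of the replacement normal at ``location``."""
        location = tuple(int(v) for v in location)
        self._check_location(location)
        if location in self._cache:
            return self._cache[location]
        if self.fixed_mean is not None:
            mean = self.fixed_mean.ravel()
            chol = self.fixed_chol if self.fixed_chol is not None else \
                np.zeros((mean.size, mean.size))
        else:
            sl = tuple(slice(lo, lo + k) for lo, k in zip(location, self.patch_shape))
            patches = self.training[(slice(None),) + sl].reshape(len(self.training), -1)
            mean = patches.mean(axis=0)
            cov = np.cov(patches, rowvar=False).reshape(mean.size, mean.size)
            cov[np.diag_indices_from(cov)] += self.ridge
            chol = np.linalg.cholesky(cov)
        self._cache[location] = (mean, chol)
        return mean, chol

    def draw(self, location, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` patch replacements, shape (n, *patch_shape)."""
        mean, chol = self.stats(location)
        z = rng.standard_normal((n, mean.size))
        return (mean + z @ chol.T).reshape(n, *self.patch_shape)


@dataclass
class RelevanceMap:
    """Per-voxel relevance scores W plus provenance metadata."""

    W: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ROI:
    index: int
    voxels: np.ndarray  # (m, 3) int coordinates, lexicographically sorted
    size: int
    centroid: tuple[float, float, float]
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open


@dataclass
class ROISet:
    rois: list[ROI]
    threshold: float
    percentile: float
    connectivity: int

    def __len__(self):
        return len(self.rois)

    def mask(self, grid_shape) -> np.ndarray:
        out = np.zeros(grid_shape, dtype=bool)
        for roi in self.rois:
            out[tuple(roi.voxels.T)] = True
        return out

    def label_volume(self, grid_shape) -> np.ndarray:
        out = np.zeros(grid_shape, dtype=np.int32)
        for roi in self.rois:
            out[tuple(roi.voxels.T)] = roi.index + 1
        return out

    def extract_matrix(self, volumes, roi_index: int) -> np.ndarray:
        """Subjects x voxels matrix for one ROI (lexicographic voxel order)."""
        roi = self.rois[roi_index]
        vols = np.asarray(volumes)
        return vols[(slice(None),) + tuple(roi.voxels.T)]


def occlude_patch(volume, location, sampler: PatchSampler, seed: int = 0,
                  n_draws: int | None = None) -> np.ndarray:
    """Copies of ``volume`` with the patch at ``location`` replaced by draws.

    Returns shape (n_draws, D, H, W); voxels outside the patch are
    bit-identical to the input.
    """
    volume = np.asarray(volume, dtype=np.float64)
    n = n_draws if n_draws is not None else sampler.n_draws
    rng = np.random.default_rng(seed)
    draws = sampler.draw(location, n, rng)
    out = np.repeat(volume[None], n, axis=0)
    sl = tuple(slice(lo, lo + k) for lo, k in zip(location, sampler.patch_shape))
    out[(slice(None),) + sl] = draws
    return out


def _window_starts(dim: int, k: int, stride: int) -> list[int]:
    starts = list(range(0, dim - k + 1, stride))
    # make sure the trailing voxels are always covered
    if starts and starts[-1] != dim - k:
        starts.append(dim - k)
    return starts


def _volume_seed(base_seed: int, volume: np.ndarray) -> int:
    """Content-derived seed so the map does not depend on subject ordering."""
    h = hashlib.sha256(np.ascontiguousarray(volume).tobytes())
    h.update(str(base_seed).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2 ** 31)


def compute_relevance_map(model, volumes, sampler: PatchSampler,
                          stride: int = 1, seed: int = 0,
                          batch_size: int = 64) -> RelevanceMap:
    """Slide the occlusion window over the grid and accumulate scores.

    ``model`` needs a ``predict_disease_probability(volumes) -> (n,)`` method.
    For each window location, p1 is the mean disease probability over
    ``sampler.n_draws`` occluded copies and p0 the intact-volume probability;
    the score d(p0, p1) is added to every voxel of the window.  Overlapping
    windows are averaged by coverage count and per-subject maps are averaged
    over the subject set.
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    if volumes.ndim == 3:
        volumes = volumes[None]
    grid = volumes.shape[1:]
    k = sampler.patch_shape
    p0 = np.asarray(model.predict_disease_probability(volumes), dtype=np.float64)

    acc = np.zeros(grid)
    coverage = np.zeros(grid)
    rngs = [np.random.default_rng(_volume_seed(seed, v)) for v in volumes]

    locations = [(a, b, c)
                 for a in _window_starts(grid[0], k[0], stride)
                 for b in _window_starts(grid[1], k[1], stride)
                 for c in _window_starts(grid[2], k[2], stride)]
    n_sub = len(volumes)
    nd = sampler.n_draws
    # group window locations so each model call sees a large batch
    chunk = max(1, batch_size // (n_sub * nd))
    for ci in range(0, len(locations), chunk):
        locs = locations[ci:ci + chunk]
        big = np.empty((len(locs), n_sub, nd) + grid)
        big[...] = volumes[None, :, None]
        for li, loc in enumerate(locs):
            sl = tuple(slice(lo, lo + kk) for lo, kk in zip(loc, k))
            for i in range(n_sub):
                big[(li, i, slice(None)) + sl] = sampler.draw(loc, nd, rngs[i])
        flat = big.reshape(-1, *grid)
        probs = []
        for j in range(0, len(flat), batch_size):
            probs.append(model.predict_disease_probability(flat[j:j + batch_size]))
        p1 = np.concatenate(probs).reshape(len(locs), n_sub, nd).mean(axis=2)
        for li, loc in enumerate(locs):
            sl = tuple(slice(lo, lo + kk) for lo, kk in zip(loc, k))
            acc[sl] += np.mean(relevance_score(p0, p1[li]))
            coverage[sl] += 1.0
    W = np.divide(acc, coverage, out=np.zeros(grid), where=coverage > 0)
    meta = {"n_subjects": n_sub, "n_draws": nd, "stride": stride, "seed": seed,
            "patch_shape": k}
    return RelevanceMap(W=W, meta=meta)


def select_top_regions(rmap: RelevanceMap, percentile: float = 90.0,
                       connectivity: int = 26) -> ROISet:
    """Threshold W at the given percentile and extract connected components.

    Voxels with ``W >= percentile threshold`` are retained (boundary ties
    included); components under 6- or 26-connectivity become ROIs indexed in
    decreasing size order.  A constant map has no distinguishable top decile:
    an empty set is returned with a warning.
    """
    W = rmap.W
    if not np.all(np.isfinite(W)):
        raise ValidationError("relevance map contains non-finite values")
    if connectivity not in (6, 26):
        raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")
    if np.ptp(W) == 0:
        warnings.warn("relevance map is constant; no regions selected")
        return ROISet([], threshold=float(W.flat[0]) if W.size else 0.0,
                      percentile=percentile, connectivity=connectivity)
    threshold = float(np.percentile(W, percentile))
    mask = W >= threshold
    structure = np.ones((3, 3, 3)) if connectivity == 26 else \
        ndimage.generate_binary_structure(3, 1)
    labeled, n_comp = ndimage.label(mask, structure=structure)
    rois = []
    for lab in range(1, n_comp + 1):
        voxels = np.argwhere(labeled == lab)  # argwhere is lexicographic
        size = len(voxels)
        centroid = tuple(float(c) for c in voxels.mean(axis=0))
        bbox = tuple((int(voxels[:, a].min()), int(voxels[:, a].max()) + 1)
                     for a in range(3))
        rois.append(ROI(index=-1, voxels=voxels, size=size,
                        centroid=centroid, bbox=bbox))
    rois.sort(key=lambda r: (-r.size, r.bbox))
    for i, roi in enumerate(rois):
        roi.index = i
    return ROISet(rois, threshold=threshold, percentile=percentile,
                  connectivity=connectivity)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom) if denom else 0.0
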