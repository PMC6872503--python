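"""Synthetic ground-truth data: labeled 3D volumes, genotypes, causal pairs.

Every generator is a pure function of its spec (which includes the seed):
calling it twice returns bit-identical output.  The generators emulate the
structure of a registered diffusion-imaging case/control study — spatially
smooth background noise with disease signal concentrated in known regions —
plus Hardy–Weinberg genotype matrices and bivariate cause–effect pairs drawn
from additive-noise mechanisms, so every downstream stage of the pipeline can
be tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


class ValidationError(ValueError):
    """Raised when a spec violates its invariants; names the offending field."""


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class ImageCohortSpec:
    """Case/control cohort of 3D volumes with planted signal regions.

    ``signal_regions`` are axis-aligned boxes in 0-based half-open voxel
    coordinates ``((d0, d1), (h0, h1), (w0, w1))``.  Cases get ``effect_size``
    added to every voxel inside each box.  Background noise is Gaussian with
    standard deviation ``noise_sd``; if ``smoothness_sigma > 0`` the noise
    field is smoothed with a Gaussian kernel and rescaled so its marginal
    standard deviation stays ``noise_sd`` (spatial correlation without
    changing the per-voxel scale).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_cases: int = 51
    n_controls: int = 100
    signal_regions: tuple[Box, ...] = (((10, 22), (10, 22), (10, 22)),)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    smoothness_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(g) < 1 for g in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_cases < 1:
            raise ValidationError(f"n_cases must be >= 1, got {self.n_cases}")
        if self.n_controls < 1:
            raise ValidationError(f"n_controls must be >= 1, got {self.n_controls}")
        if not self.noise_sd > 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.smoothness_sigma < 0:
            raise ValidationError(f"smoothness_sigma must be >= 0, got {self.smoothness_sigma}")
        for box in self.signal_regions:
            for (lo, hi), dim in zip(box, self.grid_shape):
                if not (0 <= lo < hi <= dim):
                    raise ValidationError(
                        f"signal_regions: box {box} does not fit inside grid {self.grid_shape}")


@dataclass(frozen=True)
class GenotypeSpec:
    """Genotype matrix spec: genes carry ordered SNP positions (base pairs)."""

    n_subjects: int
    genes: tuple[tuple[str, tuple[int, ...]], ...]
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if len(self.genes) == 0:
            raise ValidationError("genes must be a non-empty list")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for gene_id, positions in self.genes:
            if len(positions) == 0:
                raise ValidationError(f"gene {gene_id!r} has no SNP positions")
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValidationError(
                    f"gene {gene_id!r}: SNP positions must be strictly increasing")


MECHANISMS = {
    "linear": lambda x: 1.5 * x,
    "quadratic": lambda x: x ** 2,
    "sigmoid": lambda x: np.tanh(2.0 * x),
}


@dataclass(frozen=True)
class CausalPairSpec:
    """Bivariate pair from an additive-noise mechanism.

    ``direction='x_to_y'`` gives ``y = f(x) + noise`` with noise independent
    of x; ``'y_to_x'`` swaps the roles; ``'none'`` gives independent x and y.
    """

    n: int = 500
    mechanism: str = "quadratic"
    direction: str = "x_to_y"
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValidationError(f"n must be >= 10, got {self.n}")
        if self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"unknown mechanism {self.mechanism!r}; choose from {sorted(MECHANISMS)}")
        if self.direction not in ("x_to_y", "y_to_x", "none"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if not self.noise_sd > 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth echoed back by a generator (fully determined by spec+seed)."""

    kind: str
    signal_regions: tuple[Box, ...] | None = None
    true_direction: str | None = None
    params: dict = field(default_factory=dict)

    def region_mask(self, grid_shape) -> np.ndarray:
        """Boolean mask of all planted signal voxels on ``grid_shape``."""
        mask = np.zeros(grid_shape, dtype=bool)
        for (d0, d1), (h0, h1), (w0, w1) in self.signal_regions or ():
            mask[d0:d1, h0:h1, w0:w1] = True
        return mask


def generate_image_cohort(spec: ImageCohortSpec):
    """Generate ``n_cases + n_controls`` volumes with planted case signal.

    Returns ``(volumes, labels, truth)`` where ``volumes`` has shape
    ``(n, *grid_shape)``, ``labels`` is 1 for cases and 0 for controls
    (cases first), and ``truth`` records the planted regions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    vols = rng.normal(0.0, spec.noise_sd, size=(n, *spec.grid_shape))
    if spec.smoothness_sigma > 0:
        for i in range(n):
            vols[i] = ndimage.gaussian_filter(vols[i], spec.smoothness_sigma)
        # smoothing shrinks the marginal sd; rescale back to noise_sd
        sd = vols.std()
        if sd > 0:
            vols *= spec.noise_sd / sd
    labels = np.concatenate([np.ones(spec.n_cases, dtype=int),
                             np.zeros(spec.n_controls, dtype=int)])
    for (d0, d1), (h0, h1), (w0, w1) in spec.signal_regions:
        vols[:spec.n_cases, d0:d1, h0:h1, w0:w1] += spec.effect_size
    truth = SyntheticTruth(kind="image_cohort",
                           signal_regions=tuple(spec.signal_regions),
                           params={"spec": spec})
    return vols, labels, truth


def generate_genotypes(spec: GenotypeSpec):
    """Sample a subjects x SNPs genotype matrix under Hardy–Weinberg equilibrium.

    Each SNP draws a minor-allele frequency uniformly from ``maf_range``; the
    genotype is the sum of two independent Bernoulli(maf) allele copies, so
    values are in {0, 1, 2}.  SNPs are independent (no linkage disequilibrium).

    Returns ``(genotypes, gene_map)`` with ``gene_map`` a DataFrame of
    (gene_id, snp_index, position).
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for gene_id, positions in spec.genes:
        for pos in positions:
            records.append((gene_id, len(records), int(pos)))
    gene_map = pd.DataFrame(records, columns=["gene_id", "snp_index", "position"])
    n_snps = len(gene_map)
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_snps)
    geno = rng.binomial(2, mafs[None, :], size=(spec.n_subjects, n_snps))
    return geno, gene_map


def generate_causal_pair(spec: CausalPairSpec):
    """Generate one cause–effect pair; returns ``(x, y, truth)``."""
    rng = np.random.default_rng(spec.seed)
    f = MECHANISMS[spec.mechanism]
    if spec.direction == "none":
        x = rng.normal(size=spec.n)
        y = rng.normal(size=spec.n)
    elif spec.direction == "x_to_y":
        x = rng.normal(size=spec.n)
        y = f(x) + rng.normal(0.0, spec.noise_sd, size=spec.n)
    else:
        y = rng.normal(size=spec.n)
        x = f(y) + rng.normal(0.0, spec.noise_sd, size=spec.n)
    truth = SyntheticTruth(kind="causal_pair", true_direction=spec.direction,
                           params={"spec": spec})
    return x, y, truth


def write_cohort(outdir, vols, labels, truth, voxel_size=(2.0, 2.0, 2.0)):
    """Write volumes as NIfTI-1 plus a TSV manifest and truth sidecar."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*voxel_size, 1.0])
    rows = []
    for i, (vol, lab) in enumerate(zip(vols, labels)):
        sid = f"S{i:04d}"
        fname = f"{sid}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 str(outdir / fname))
        # relative paths keep the manifest byte-identical across run dirs
        rows.append((sid, fname, int(lab), "baseline"))
    manifest = pd.DataFrame(rows, columns=["subject_id", "path", "label", "timepoint"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("d0\td1\th0\th1\tw0\tw1\n")
        for (d0, d1), (h0, h1), (w0, w1) in truth.signal_regions or ():
            fh.write(f"{d0}\t{d1}\t{h0}\t{h1}\t{w0}\t{w1}\n")
    return manifest
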