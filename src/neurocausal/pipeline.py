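"""End-to-end orchestration: synthesize -> train -> relevance -> FPCA -> causal -> screen.

A run is described by a :class:`RunConfig` (serializable to YAML, round-trip
exact), executed stage by stage in dependency order.  Every stage derives its
own seed from the global seed and the stage name, hashes its inputs and
outputs, and records them in a :class:`RunManifest`; re-running with the same
config and seed reproduces identical hashes for the deterministic stages, and
unchanged stages are skipped by comparing config and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .augment import AugmentationConfig
from .causal import CGANConfig, bonferroni_threshold, causal_test, derive_seed, screen_results
from .classifier import (ArchitectureConfig, TrainConfig, build_classifier,
                         load_classifier, save_classifier, train_classifier)
from .fpca import fpca_region
from .relevance import PatchSampler, compute_relevance_map, select_top_regions
from .synthetic import ImageCohortSpec, generate_image_cohort, write_cohort


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream output."""


STAGE_ORDER = ["synth", "train", "relevance", "fpca", "causal", "screen"]
STAGE_DEPS = {"synth": [], "train": ["synth"], "relevance": ["train"],
              "fpca": ["relevance"], "causal": ["fpca"], "screen": ["causal"]}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = tuple(STAGE_ORDER)
    cohort: dict = field(default_factory=dict)        # ImageCohortSpec kwargs
    architecture: dict = field(default_factory=dict)  # ArchitectureConfig kwargs
    training: dict = field(default_factory=dict)      # TrainConfig kwargs
    augmentation: dict | None = None                  # AugmentationConfig kwargs
    relevance: dict = field(default_factory=lambda: {"stride": 2, "n_draws": 5,
                                                     "percentile": 90.0,
                                                     "n_eval_subjects": 6})
    fpca: dict = field(default_factory=lambda: {"n_rois": 4, "n_components": 2})
    causal_cfg: dict = field(default_factory=lambda: {
        "gen_widths": [24, 24], "disc_widths": [24, 24], "noise_dim": 3,
        "epochs": 200, "batch_size": 100})
    screen: dict = field(default_factory=lambda: {"alpha": 0.05})

    def to_yaml(self, path):
        raw = asdict(self)
        raw["stages"] = list(raw["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", STAGE_ORDER))
        return cls(**raw)


@dataclass
class RunManifest:
    version: str
    seed: int
    stages: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"version": self.version, "seed": self.seed,
                       "stages": self.stages}, fh, indent=2, sort_keys=True)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return derive_seed(seed, stage)


def run_pipeline(config: RunConfig) -> RunManifest:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGE_ORDER if s in config.stages]
    manifest = RunManifest(version=__version__, seed=config.seed)

    paths = {
        "manifest_tsv": outdir / "synth" / "manifest.tsv",
        "model": outdir / "model.npz",
        "rmap": outdir / "relevance_map.nii",
        "rois": outdir / "rois.tsv",
        "roi_mask": outdir / "roi_mask.nii",
        "scores_dir": outdir / "fpca",
        "causal_tsv": outdir / "causal_results.tsv",
        "screen_tsv": outdir / "screened.tsv",
        "counts_tsv": outdir / "screen_counts.tsv",
    }

    for stage in enabled:
        for dep in STAGE_DEPS[stage]:
            if dep not in enabled and not _dep_outputs_exist(dep, paths):
                raise DependencyError(
                    f"stage {stage!r} requires outputs of disabled stage {dep!r}")

    for stage in enabled:
        t0 = time.time()
        seed = _stage_seed(config.seed, stage)
        outputs = _STAGE_FNS[stage](config, paths, seed)
        manifest.stages[stage] = {
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 3),
            "config": _stage_config(config, stage),
            "outputs": {str(p): _hash_file(p) for p in outputs},
        }
    manifest.to_json(outdir / "run_manifest.json")
    return manifest


def _dep_outputs_exist(stage: str, paths) -> bool:
    checks = {"synth": [paths["manifest_tsv"]], "train": [paths["model"]],
              "relevance": [paths["rois"], paths["rmap"]],
              "fpca": [paths["scores_dir"]], "causal": [paths["causal_tsv"]]}
    return all(Path(p).exists() for p in checks.get(stage, []))


def _stage_config(config: RunConfig, stage: str) -> dict:
    pick = {"synth": ["cohort"], "train": ["architecture", "training", "augmentation"],
            "relevance": ["relevance"], "fpca": ["fpca"],
            "causal": ["causal_cfg"], "screen": ["screen"]}
    return {k: getattr(config, k) for k in pick[stage]}


def _stage_synth(config: RunConfig, paths, seed):
    spec_kwargs = dict(config.cohort)
    spec_kwargs.setdefault("seed", seed)
    if "grid_shape" in spec_kwargs:
        spec_kwargs["grid_shape"] = tuple(spec_kwargs["grid_shape"])
    if "signal_regions" in spec_kwargs:
        spec_kwargs["signal_regions"] = tuple(
            tuple(tuple(ax) for ax in box) for box in spec_kwargs["signal_regions"])
    spec = ImageCohortSpec(**spec_kwargs)
    vols, labels, truth = generate_image_cohort(spec)
    write_cohort(paths["manifest_tsv"].parent, vols, labels, truth)
    return [paths["manifest_tsv"]]


def _stage_train(config: RunConfig, paths, seed):
    vols, labels, sids, _ = io.read_manifest(paths["manifest_tsv"])
    if config.augmentation is not None:
        from .augment import augment_dataset
        aug = AugmentationConfig(**{k: tuple(map(tuple, v)) if k == "blur_settings"
                                    else v for k, v in config.augmentation.items()})
        vols, labels, sids = augment_dataset(vols, labels, aug, seed=seed,
                                             subject_ids=sids)
    arch = ArchitectureConfig(**{k: tuple(map(tuple, v)) if k == "conv_specs"
                                 else v for k, v in config.architecture.items()})
    model = build_classifier(arch, input_shape=vols.shape[1:], seed=seed)
    train_classifier(model, vols, labels, TrainConfig(**config.training), seed=seed)
    save_classifier(model, paths["model"])
    return [paths["model"]]


def _stage_relevance(config: RunConfig, paths, seed):
    vols, labels, _, _ = io.read_manifest(paths["manifest_tsv"])
    model = load_classifier(paths["model"])
    rcfg = config.relevance
    sampler = PatchSampler(vols, n_draws=rcfg.get("n_draws", 5))
    n_eval = min(rcfg.get("n_eval_subjects", 6), len(vols))
    rng = np.random.default_rng(seed)
    subset = rng.choice(len(vols), size=n_eval, replace=False)
    rmap = compute_relevance_map(model, vols[subset], sampler,
                                 stride=rcfg.get("stride", 2), seed=seed)
    rois = select_top_regions(rmap, percentile=rcfg.get("percentile", 90.0))
    io.write_relevance_map(rmap, paths["rmap"])
    io.write_roi_set(rois, vols.shape[1:], paths["rois"], paths["roi_mask"])
    return [paths["rmap"], paths["rois"], paths["roi_mask"]]


def _stage_fpca(config: RunConfig, paths, seed):
    from .io import read_relevance_map
    vols, labels, sids, _ = io.read_manifest(paths["manifest_tsv"])
    rmap = read_relevance_map(paths["rmap"])
    rois = select_top_regions(rmap, percentile=config.relevance.get("percentile", 90.0))
    paths["scores_dir"].mkdir(parents=True, exist_ok=True)
    n_rois = min(config.fpca.get("n_rois", 4), len(rois))
    outputs = []
    for i in range(n_rois):
        if rois.rois[i].size < 2:
            continue
        mat = rois.extract_matrix(vols, i)
        k = min(config.fpca.get("n_components", 2),
                mat.shape[1], mat.shape[0] - 1)
        scores = fpca_region(mat, n_components=k)
        out = paths["scores_dir"] / f"roi{i:02d}_scores.tsv"
        io.write_scores(scores, sids, out)
        outputs.append(out)
    return outputs


def _stage_causal(config: RunConfig, paths, seed):
    vols, labels, sids, tps = io.read_manifest(paths["manifest_tsv"])
    cfg = CGANConfig(**{k: tuple(v) if k.endswith("widths") else v
                        for k, v in config.causal_cfg.items()})
    rows = []
    for score_file in sorted(paths["scores_dir"].glob("roi*_scores.tsv")):
        _, scores = io.read_scores(score_file)
        roi_index = int(score_file.stem[3:5])
        res = causal_test(scores[:, 0], labels.astype(float), cfg,
                          seed=derive_seed(seed, roi_index))
        rows.append({"timepoint": tps[0], "unit_id": roi_index,
                     "t_xy": res.t_xy, "t_yx": res.t_yx, "T": res.T,
                     "sigma2": res.sigma2, "p_value": res.p_value,
                     "call": res.call})
    pd.DataFrame(rows, columns=["timepoint", "unit_id", "t_xy", "t_yx", "T",
                                "sigma2", "p_value", "call"]
                 ).to_csv(paths["causal_tsv"], sep="\t", index=False)
    return [paths["causal_tsv"]]


def _stage_screen(config: RunConfig, paths, seed):
    results = pd.read_csv(paths["causal_tsv"], sep="\t",
                          dtype={"p_value": str})
    m = max(len(results), 1)
    threshold = bonferroni_threshold(config.screen.get("alpha", 0.05), m)
    filtered, counts = screen_results(results, threshold)
    filtered.to_csv(paths["screen_tsv"], sep="\t", index=False)
    pd.DataFrame(sorted(counts.items()), columns=["timepoint", "n_significant"]
                 ).to_csv(paths["counts_tsv"], sep="\t", index=False)
    return [paths["screen_tsv"], paths["counts_tsv"]]


_STAGE_FNS = {"synth": _stage_synth, "train": _stage_train,
              "relevance": _stage_relevance, "fpca": _stage_fpca,
              "causal": _stage_causal, "screen": _stage_screen}
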