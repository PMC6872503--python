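"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as NIfTI-1 files referenced from a TSV manifest
(subject_id, path, label, timepoint); relevance maps and ROI label masks are
NIfTI-1 on the same grid; scores, ROI tables and causal results are TSV.
Genotypes are read from a subjects x SNPs dosage TSV with a positions
sidecar, and gene maps from BED-like TSV (gene_id, chrom, start, end).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .relevance import RelevanceMap, ROISet


def read_manifest(path):
    """Load a cohort manifest and its volumes.

    Returns ``(volumes, labels, subject_ids, timepoints)``.  Paths in the
    manifest are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    vols, labels, sids, tps = [], [], [], []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        vols.append(np.asarray(nib.load(str(p)).dataobj, dtype=np.float64))
        labels.append(int(row["label"]))
        sids.append(str(row["subject_id"]))
        tps.append(str(row.get("timepoint", "baseline")))
    return np.stack(vols), np.asarray(labels), sids, tps


def write_relevance_map(rmap: RelevanceMap, path, voxel_size=(2.0, 2.0, 2.0)):
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(rmap.W.astype(np.float32), affine), str(path))


def read_relevance_map(path) -> RelevanceMap:
    img = nib.load(str(path))
    return RelevanceMap(W=np.asarray(img.dataobj, dtype=np.float64))


def write_roi_set(rois: ROISet, grid_shape, tsv_path, nifti_path=None,
                  voxel_size=(2.0, 2.0, 2.0)):
    rows = []
    for roi in rois.rois:
        (d0, d1), (h0, h1), (w0, w1) = roi.bbox
        rows.append({"roi_index": roi.index, "size": roi.size,
                     "centroid_d": roi.centroid[0], "centroid_h": roi.centroid[1],
                     "centroid_w": roi.centroid[2],
                     "d0": d0, "d1": d1, "h0": h0, "h1": h1, "w0": w0, "w1": w1})
    pd.DataFrame(rows, columns=["roi_index", "size", "centroid_d", "centroid_h",
                                "centroid_w", "d0", "d1", "h0", "h1", "w0", "w1"]
                 ).to_csv(tsv_path, sep="\t", index=False)
    if nifti_path is not None:
        affine = np.diag([*voxel_size, 1.0])
        nib.save(nib.Nifti1Image(rois.label_volume(grid_shape).astype(np.int16),
                                 affine), str(nifti_path))


def write_scores(scores, subject_ids, path):
    arr = getattr(scores, "scores", scores)
    df = pd.DataFrame(arr, columns=[f"component_{i + 1}" for i in range(arr.shape[1])])
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_scores(path):
    df = pd.read_csv(path, sep="\t")
    return df["subject_id"].tolist(), df.drop(columns="subject_id").to_numpy(float)


def read_genotypes(dosage_path, positions_path):
    """Dosage TSV (subject_id + one column per SNP) plus positions sidecar.

    The sidecar has columns (snp_id, gene_id, position).  Returns
    ``(dosage DataFrame indexed by subject, positions DataFrame)``.
    """
    geno = pd.read_csv(dosage_path, sep="\t").set_index("subject_id")
    pos = pd.read_csv(positions_path, sep="\t")
    missing = set(pos["snp_id"]) - set(geno.columns)
    if missing:
        raise ValueError(f"positions sidecar lists SNPs absent from dosages: {sorted(missing)[:5]}")
    return geno, pos


def write_metrics_grid(metrics: dict, path):
    """Timepoint x timepoint metric table (rows: training, cols: prediction)."""
    tps = sorted({tp for pair in metrics for tp in pair})
    df = pd.DataFrame(index=tps, columns=tps, dtype=object)
    for (tr, te), value in metrics.items():
        df.loc[tr, te] = value
    df.index.name = "train_timepoint"
    df.to_csv(path, sep="\t")
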