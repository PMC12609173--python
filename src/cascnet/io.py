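"""File formats: phenotype CSV, NIfTI image sets, tabular outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import COHORT_COLUMNS, GMVImageSet, validate_cohort

_NUMERIC = ["wmh_volume", "age", "education_years", "tiv", "global_gmv",
            "moca", "mmse", "dst", "tmt_a"]


def read_phenotype(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort phenotype CSV (row order preserved)."""
    table = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in _NUMERIC:
        table[col] = pd.to_numeric(table[col], errors="raise")
    table["fazekas"] = table["fazekas"].astype(int)
    return validate_cohort(table[COHORT_COLUMNS].copy())


def write_phenotype(cohort: pd.DataFrame, path: Union[str, Path]) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_image_set(paths: Sequence[Union[str, Path]],
                   mask_path: Union[str, Path],
                   subject_ids: Optional[Sequence[str]] = None,
                   atol: float = 1e-4) -> GMVImageSet:
    """Stack per-subject NIfTI volumes sharing shape and affine."""
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    affine = mask_img.affine
    vols = []
    for p in paths:
        img = nib.load(str(p))
        if img.shape != mask.shape:
            raise ValueError(f"{p}: shape {img.shape} != mask {mask.shape}")
        if not np.allclose(img.affine, affine, atol=atol):
            raise ValueError(f"{p}: affine differs from mask affine")
        vols.append(np.asarray(img.dataobj, dtype=np.float64))
    if not vols:
        raise ValueError("no image paths given")
    ids = list(subject_ids) if subject_ids is not None \
        else [Path(p).name.split(".")[0] for p in paths]
    return GMVImageSet(data=np.stack(vols), mask=mask, affine=affine,
                       subject_ids=ids)


def write_image_set(images: GMVImageSet, out_dir: Union[str, Path]) -> dict:
    """Write per-subject .nii.gz volumes plus the mask; returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, sid in enumerate(images.subject_ids):
        p = out / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(images.data[i], images.affine), str(p))
        paths[sid] = str(p)
    mask_p = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(images.mask.astype(np.uint8), images.affine),
             str(mask_p))
    paths["__mask__"] = str(mask_p)
    return paths


def write_map(grid: np.ndarray, affine: np.ndarray,
              path: Union[str, Path]) -> None:
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float64), affine),
             str(path))


def write_ground_truth(truth, path: Union[str, Path]) -> None:
    from dataclasses import asdict
    payload = asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=lambda o: list(o)
                  if isinstance(o, (np.ndarray, tuple)) else o)


def write_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_graphml(graph, path: Union[str, Path]) -> None:
    """Export a causal graph (signed GC edge attributes) as GraphML."""
    import networkx as nx
    nx.write_graphml(graph.to_networkx(), str(path))
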