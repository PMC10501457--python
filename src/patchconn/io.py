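"""File round-trips: NIfTI volumes, manifests, feature tables, atlases.

All tabular artifacts are plain CSV/TSV with headers; volumes are
gzip-compressed NIfTI with the voxel size in the affine; configuration
side-cars are YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AtlasLabelVolume, FeatureMatrix, VolumeImage


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(volume: VolumeImage, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.intensities, dtype=np.float32),
        _affine(volume.voxel_size_mm),
    )
    nib.save(img, str(path))


def load_volume(
    path, mask: np.ndarray, subject_id: str = "", class_label: str = ""
) -> VolumeImage:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=np.float32)
    data[~np.asarray(mask, dtype=bool)] = 0.0
    return VolumeImage(
        intensities=data,
        brain_mask=mask,
        voxel_size_mm=zooms,
        subject_id=subject_id,
        class_label=class_label,
    )


def save_mask(mask: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm)
    )
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_cohort(volumes: list[VolumeImage], out_dir, seed: int | None = None) -> Path:
    """Write one NIfTI per subject plus the cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in volumes:
        fname = f"{v.subject_id}.nii.gz"
        save_volume(v, out_dir / fname)
        rows.append(
            {"subject_id": v.subject_id, "class_label": v.class_label, "path": fname}
        )
    manifest = pd.DataFrame(rows)
    if seed is not None:
        manifest["seed"] = seed
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(manifest_path, mask: np.ndarray) -> list[VolumeImage]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return [
        load_volume(
            manifest_path.parent / r.path,
            mask,
            subject_id=str(r.subject_id),
            class_label=str(r.class_label),
        )
        for r in df.itertuples()
    ]


def save_atlas(atlas: AtlasLabelVolume, nifti_path, names_path,
               voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(
        np.asarray(atlas.labels, dtype=np.int32), _affine(voxel_size_mm)
    )
    nib.save(img, str(nifti_path))
    pd.DataFrame(
        {"label": list(atlas.name_table), "name": list(atlas.name_table.values())}
    ).to_csv(names_path, sep="\t", index=False)


def load_atlas(nifti_path, names_path) -> AtlasLabelVolume:
    labels = np.asarray(nib.load(str(nifti_path)).dataobj).astype(np.int32)
    names = pd.read_csv(names_path, sep="\t")
    return AtlasLabelVolume(
        labels=labels,
        name_table={int(r.label): str(r.name) for r in names.itertuples()},
    )


def save_features(fm: FeatureMatrix, csv_path, sidecar: dict | None = None) -> None:
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "subject_id", fm.subject_ids)
    df.insert(1, "class_label", fm.labels)
    df.to_csv(csv_path, index=False)
    if sidecar is not None:
        Path(str(csv_path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def load_features(csv_path) -> FeatureMatrix:
    df = pd.read_csv(csv_path)
    names = [c for c in df.columns if c not in ("subject_id", "class_label")]
    return FeatureMatrix(
        values=df[names].to_numpy(float),
        feature_names=names,
        labels=df["class_label"].astype(str).tolist(),
        subject_ids=df["subject_id"].astype(str).tolist(),
    )
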