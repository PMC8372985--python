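"""Reading and writing the pipeline's on-disk artifacts.

Labeled volumes go to NIfTI via nibabel; surface point clouds and meshes
to PLY via trimesh; spheres, ground truth and run manifests to JSON;
configurations to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
import yaml

from .types import LabeledVolume, OrientedPointCloud, Sphere


def save_volume(volume: LabeledVolume, path) -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), volume.affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def load_volume(path) -> LabeledVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.uint8)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return LabeledVolume(voxels=data, spacing=spacing, affine=np.asarray(img.affine))


def save_cloud(cloud: OrientedPointCloud, path) -> None:
    pc = trimesh.PointCloud(cloud.points)
    pc.metadata["label"] = cloud.label
    # PLY point clouds with per-vertex normals
    pc.export(str(path))
    np.save(Path(path).with_suffix(".normals.npy"), cloud.normals)


def load_cloud(path, label: str = "") -> OrientedPointCloud:
    pc = trimesh.load(str(path))
    points = np.asarray(pc.vertices if hasattr(pc, "vertices") else pc.points)
    normals_path = Path(path).with_suffix(".normals.npy")
    if normals_path.exists():
        normals = np.load(normals_path)
    elif hasattr(pc, "vertex_normals"):
        normals = np.asarray(pc.vertex_normals)
    else:
        raise ValueError(f"no normals available for point cloud {path}")
    return OrientedPointCloud(points=points, normals=normals, label=label)


def save_sphere(sphere: Sphere, path) -> None:
    Path(path).write_text(json.dumps({"cent": sphere.cent.tolist(), "r": sphere.r}, indent=1))


def load_sphere(path) -> Sphere:
    d = json.loads(Path(path).read_text())
    return Sphere(cent=np.asarray(d["cent"], dtype=float), r=float(d["r"]))


def save_config(params_dict: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(params_dict, sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
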