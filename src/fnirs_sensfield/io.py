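"""On-disk formats: NIfTI volumes, PLY meshes, TSV montages and
parcellations, HDF5 recordings."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .montage import OptodeMontage, Parcellation
from .phantom import SurfaceMesh, VoxelHeadModel
from .recording import Events, Recording


def save_head_nifti(head: VoxelHeadModel, path: str | Path) -> None:
    img = nib.Nifti1Image(head.labels.astype(np.uint8), head.affine)
    img.header.set_zooms((head.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_head_nifti(path: str | Path) -> VoxelHeadModel:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int8)
    voxel = float(img.header.get_zooms()[0])
    return VoxelHeadModel(labels=labels, voxel_size_mm=voxel, affine=img.affine)


def save_mesh_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    tm = mesh.to_trimesh()
    tm.metadata["ply_raw"] = {}
    data = trimesh.exchange.ply.export_ply(tm, encoding="binary_little_endian")
    # stash the surface role in a PLY comment line
    data = data.replace(b"ply\n", b"ply\ncomment role " + mesh.role.encode() + b"\n", 1)
    Path(path).write_bytes(data)


def load_mesh_ply(path: str | Path) -> SurfaceMesh:
    raw = Path(path).read_bytes()
    role = "pial"
    for line in raw.split(b"end_header")[0].splitlines():
        if line.startswith(b"comment role "):
            role = line.split()[-1].decode()
    tm = trimesh.load(str(path), file_type="ply", process=False)
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       faces=np.asarray(tm.faces), role=role)


def save_montage_tsv(montage: OptodeMontage, path: str | Path) -> None:
    rows = []
    for i, p in enumerate(montage.sources):
        rows.append({"optode_id": f"S{i + 1}", "type": "source",
                     "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    for i, p in enumerate(montage.detectors):
        rows.append({"optode_id": f"D{i + 1}", "type": "detector",
                     "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
    for c, (s, d) in enumerate(montage.channels):
        cc = montage.channel_centers[c]
        rows.append({"optode_id": f"S{s + 1}D{d + 1}", "type": "channel",
                     "x_mm": cc[0], "y_mm": cc[1], "z_mm": cc[2]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_montage_tsv(path: str | Path) -> OptodeMontage:
    df = pd.read_csv(path, sep="\t")
    xyz = df[["x_mm", "y_mm", "z_mm"]].values
    src = xyz[df["type"] == "source"]
    det = xyz[df["type"] == "detector"]
    channels, centers = [], []
    for _, row in df[df["type"] == "channel"].iterrows():
        name = row["optode_id"]  # SxDy
        s, d = name[1:].split("D")
        channels.append((int(s) - 1, int(d) - 1))
        centers.append([row["x_mm"], row["y_mm"], row["z_mm"]])
    return OptodeMontage(sources=src, detectors=det, channels=channels,
                         channel_centers=np.array(centers))


def save_parcellation_tsv(parc: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame({"vertex": np.arange(len(parc.area_labels)),
                       "area_id": parc.area_labels})
    df["area_name"] = [parc.area_names.get(a, "") for a in parc.area_labels]
    df.to_csv(path, sep="\t", index=False)


def load_parcellation_tsv(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    names = {int(a): str(n) for a, n in
             zip(df["area_id"], df["area_name"].fillna("")) if a >= 0}
    return Parcellation(area_labels=df["area_id"].values, area_names=names)


def save_recording_h5(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=rec.intensities)
        ev = f.create_group("events")
        ev.create_dataset("onsets_s", data=np.asarray(rec.events.onsets_s))
        ev.create_dataset("durations_s", data=np.asarray(rec.events.durations_s))
        ev.attrs["conditions"] = [str(c) for c in rec.events.conditions]
        f.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        f.attrs["wavelengths_nm"] = list(rec.wavelengths_nm)


def load_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        events = Events(onsets_s=f["events/onsets_s"][()],
                        durations_s=f["events/durations_s"][()],
                        conditions=list(f["events"].attrs.get("conditions", [])))
        return Recording(intensities=f["intensity"][()],
                         sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                         events=events,
                         wavelengths_nm=tuple(int(w) for w in f.attrs["wavelengths_nm"]))
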