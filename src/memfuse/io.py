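"""File I/O: OBJ meshes, HDF5 lead fields / datasets / estimates, TSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import LeadField
from .fusion import FusedRecording
from .geometry import CorticalMesh, SensorArray, _mesh_from_vertices
from .mem import SourceEstimate
from .msp import Parcellation


# -- Wavefront OBJ ----------------------------------------------------------

def save_mesh_obj(mesh: CorticalMesh, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# memfuse cortical mesh\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def load_mesh_obj(path: str | Path, center=(0.0, 0.0, 0.0)) -> CorticalMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return _mesh_from_vertices(np.asarray(verts, float),
                               np.asarray(faces, int), np.asarray(center))


# -- HDF5 -------------------------------------------------------------------

def save_leadfield(lf: LeadField, array: SensorArray, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("G", data=lf.G)
        fh.attrs["modality"] = lf.modality
        fh.attrs["provenance"] = lf.provenance
        fh.create_dataset("positions", data=array.positions)
        if array.orientations is not None:
            fh.create_dataset("orientations", data=array.orientations)
        fh.create_dataset("labels",
                          data=np.array(array.labels, dtype=h5py.string_dtype()))


def load_leadfield(path: str | Path) -> tuple[LeadField, SensorArray]:
    with h5py.File(path, "r") as fh:
        lf = LeadField(G=fh["G"][()], modality=fh.attrs["modality"],
                       provenance="file")
        array = SensorArray(
            modality=fh.attrs["modality"],
            positions=fh["positions"][()],
            orientations=fh["orientations"][()] if "orientations" in fh else None,
            labels=[s.decode() if isinstance(s, bytes) else str(s)
                    for s in fh["labels"][()]],
        )
    return lf, array


def save_dataset(ds, path: str | Path) -> None:
    """Serialize a SimulatedDataset (ground-truth currents stored sparsely)."""
    with h5py.File(path, "w") as fh:
        for mod in ds.recordings:
            g = fh.create_group(mod)
            g.create_dataset("M", data=ds.recordings[mod])
            g.create_dataset("baseline", data=ds.baselines[mod])
        nz = np.flatnonzero(np.any(ds.jth != 0, axis=1))
        fh.create_dataset("jth_rows", data=nz)
        fh.create_dataset("jth_values", data=ds.jth[nz])
        fh.attrs["n_sources"] = ds.jth.shape[0]
        fh.attrs["seed"] = ds.seed
        fh.attrs["peak_index"] = ds.peak_index
        fh.create_dataset("spike_t", data=ds.spike.t)
        fh.create_dataset("spike_w", data=ds.spike.w)
        for k, patch in enumerate(ds.patches):
            g = fh.create_group(f"patch{k}")
            g.create_dataset("vertices", data=patch.vertices)
            g.attrs["seed_vertex"] = patch.seed_vertex
            g.attrs["extent_order"] = patch.extent_order
            g.attrs["area_cm2"] = patch.area_cm2
            g.attrs["amplitude_nam"] = patch.amplitude_nam


def save_fused(fr: FusedRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=fr.data)
        fh.create_dataset("gain", data=fr.gain)
        fh.create_dataset("baseline", data=fr.baseline)
        fh.create_dataset("noise_var", data=fr.noise_var)
        fh.create_dataset("modalities",
                          data=np.array(fr.modalities,
                                        dtype=h5py.string_dtype()))


def load_fused(path: str | Path) -> FusedRecording:
    with h5py.File(path, "r") as fh:
        mods = np.array([s.decode() if isinstance(s, bytes) else str(s)
                         for s in fh["modalities"][()]])
        return FusedRecording(data=fh["data"][()], gain=fh["gain"][()],
                              baseline=fh["baseline"][()], modalities=mods,
                              noise_var=fh["noise_var"][()])


def save_estimate(est: SourceEstimate, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("j", data=est.j)
        fh.attrs["method"] = est.method
        fh.attrs["modality"] = est.modality


def load_estimate(path: str | Path) -> SourceEstimate:
    with h5py.File(path, "r") as fh:
        return SourceEstimate(j=fh["j"][()], method=fh.attrs["method"],
                              modality=fh.attrs["modality"])


# -- tables -----------------------------------------------------------------

def save_parcellation_tsv(parcellation: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame({"vertex": np.arange(len(parcellation.labels)),
                       "parcel": parcellation.labels})
    df.to_csv(path, sep="\t", index=False)


def save_leadfield_tsv(lf: LeadField, path: str | Path) -> None:
    pd.DataFrame(lf.G).to_csv(path, sep="\t", index=False, header=False)
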