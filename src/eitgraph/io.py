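"""Persistence: HDF5 datasets and network weights, YAML configs, and a
minimal ASCII legacy-VTK writer for meshes with nodal fields."""

from __future__ import annotations

import json

import h5py
import numpy as np
import yaml

from .mesh import FEMesh
from .nets import GraphUNet, GResNet
from .train import TrainingSample


def save_samples(path, samples, attrs=None):
    with h5py.File(path, "w") as f:
        if attrs:
            for k, v in attrs.items():
                f.attrs[k] = v
        f.attrs["n_samples"] = len(samples)
        for i, s in enumerate(samples):
            g = f.create_group("sample_%05d" % i)
            g.create_dataset("ld", data=s.ld)
            g.create_dataset("truth", data=s.truth)
            g.attrs["meta"] = json.dumps(
                {k: np.asarray(v).tolist() for k, v in s.meta.items()}
            )


def load_samples(path):
    samples = []
    with h5py.File(path, "r") as f:
        for i in range(int(f.attrs["n_samples"])):
            g = f["sample_%05d" % i]
            samples.append(
                TrainingSample(
                    ld=g["ld"][()],
                    truth=g["truth"][()],
                    meta=json.loads(g.attrs["meta"]),
                )
            )
    return samples


def save_network(path, net):
    arch = {
        "kind": type(net).__name__,
    }
    if isinstance(net, GraphUNet):
        arch.update(
            channels=list(net.channels), convs_per_level=net.convs_per_level
        )
    else:
        arch.update(
            channels=net.channels,
            blocks=net.blocks,
            convs_per_block=net.convs_per_block,
        )
    with h5py.File(path, "w") as f:
        f.attrs["architecture"] = yaml.safe_dump(arch)
        for i, (W, b) in enumerate(net.weights):
            f.create_dataset("W_%03d" % i, data=W)
            f.create_dataset("b_%03d" % i, data=b)


def load_network(path):
    with h5py.File(path, "r") as f:
        arch = yaml.safe_load(f.attrs["architecture"])
        if arch["kind"] == "GraphUNet":
            net = GraphUNet(
                channels=tuple(arch["channels"]),
                convs_per_level=arch["convs_per_level"],
            )
        elif arch["kind"] == "GResNet":
            net = GResNet(
                channels=arch["channels"],
                blocks=arch["blocks"],
                convs_per_block=arch["convs_per_block"],
            )
        else:
            raise ValueError("unknown architecture kind %r" % arch["kind"])
        for i in range(len(net.weights)):
            net.weights[i][0] = f["W_%03d" % i][()]
            net.weights[i][1] = f["b_%03d" % i][()]
    return net


def save_voltage_frames(path, frames, attrs=None):
    """Store VoltageFrame objects with their pattern metadata."""
    with h5py.File(path, "w") as f:
        if attrs:
            for k, v in attrs.items():
                f.attrs[k] = v
        f.attrs["n_frames"] = len(frames)
        for i, fr in enumerate(frames):
            g = f.create_group("frame_%05d" % i)
            g.create_dataset("voltages", data=fr.voltages)
            g.attrs["noise_std"] = fr.noise_std
            g.attrs["pattern_mode"] = fr.pattern_mode


def load_voltage_frames(path):
    from .fem import VoltageFrame

    frames = []
    with h5py.File(path, "r") as f:
        for i in range(int(f.attrs["n_frames"])):
            g = f["frame_%05d" % i]
            frames.append(
                VoltageFrame(
                    voltages=g["voltages"][()],
                    noise_std=float(g.attrs["noise_std"]),
                    pattern_mode=str(g.attrs["pattern_mode"]),
                )
            )
    return frames


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def write_vtk(path, mesh: FEMesh, point_data: dict = None):
    """Legacy ASCII VTK unstructured grid with optional nodal scalars."""
    d = mesh.dim
    cell_type = 5 if d == 2 else 10  # VTK_TRIANGLE / VTK_TETRA
    nv = d + 1
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\neitgraph mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write("POINTS %d float\n" % mesh.n_nodes)
        for p in mesh.nodes:
            xyz = np.zeros(3)
            xyz[:d] = p
            f.write("%g %g %g\n" % tuple(xyz))
        E = len(mesh.simplices)
        f.write("CELLS %d %d\n" % (E, E * (nv + 1)))
        for s in mesh.simplices:
            f.write("%d %s\n" % (nv, " ".join(map(str, s))))
        f.write("CELL_TYPES %d\n" % E)
        f.write("\n".join([str(cell_type)] * E) + "\n")
        if point_data:
            f.write("POINT_DATA %d\n" % mesh.n_nodes)
            for name, vals in point_data.items():
                f.write("SCALARS %s float 1\nLOOKUP_TABLE default\n" % name)
                f.write("\n".join("%g" % v for v in np.asarray(vals)) + "\n")
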