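"""Reading and writing volumes, networks and tables.

Volumes go through SimpleITK (NRRD, MetaImage) or tifffile (TIFF stacks);
spacing is recorded in micrometres.  Networks serialise to JSON (and
GraphML via networkx); morphometry tables are plain CSV with the same
schema accepted for manual tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .centerline import Branch, CenterlineNetwork, Node
from .volume import BinaryMask, VoxelVolume

__all__ = [
    "read_volume", "write_volume",
    "network_to_json", "network_from_json",
    "save_network", "load_network", "write_graphml",
    "read_table", "write_table",
]

_SITK_EXT = {".nrrd", ".nhdr", ".mha", ".mhd"}
_TIFF_EXT = {".tif", ".tiff"}


def read_volume(path: str | Path, spacing: float | None = None) -> VoxelVolume:
    """Load a volume; spacing (μm) comes from the header unless overridden."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _SITK_EXT:
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        sp = spacing if spacing is not None else float(img.GetSpacing()[0])
        origin = np.asarray(img.GetOrigin(), float)
    elif ext in _TIFF_EXT:
        arr = tifffile.imread(str(path)).transpose(2, 1, 0)
        if spacing is None:
            raise ValueError("TIFF stacks carry no spacing; pass spacing explicitly")
        sp, origin = spacing, np.zeros(3)
    else:
        raise ValueError(f"unsupported volume format {ext!r}")
    return VoxelVolume(values=arr, spacing=sp, origin=origin)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ext = path.suffix.lower()
    arr = volume.values.astype(np.uint8) if volume.values.dtype == bool else volume.values
    if ext in _SITK_EXT:
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing((volume.spacing,) * 3)
        img.SetOrigin(tuple(np.asarray(volume.origin, float)))
        sitk.WriteImage(img, str(path), useCompression=False)
    elif ext in _TIFF_EXT:
        tifffile.imwrite(str(path), np.ascontiguousarray(arr.transpose(2, 1, 0)))
    else:
        raise ValueError(f"unsupported volume format {ext!r}")
    if isinstance(volume, BinaryMask) and volume.provenance:
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(volume.provenance, indent=2))


def network_to_json(network: CenterlineNetwork) -> dict:
    return {
        "spacing_um": network.spacing_um,
        "root_node": network.root_node,
        "root_branch": network.root_branch,
        "nodes": [
            {"id": n.id, "position_mm": list(map(float, n.position)), "kind": n.kind}
            for n in network.nodes.values()
        ],
        "branches": [
            {
                "id": b.id, "proximal": b.proximal, "distal": b.distal,
                "parent": b.parent,
                "points_mm": np.asarray(b.points, float).tolist(),
                "radii_mm": None if b.radii is None else np.asarray(b.radii, float).tolist(),
                "flags": sorted(b.flags),
            }
            for b in network.branches.values()
        ],
    }


def network_from_json(data: dict) -> CenterlineNetwork:
    nodes = {
        d["id"]: Node(d["id"], np.asarray(d["position_mm"], float), d["kind"])
        for d in data["nodes"]
    }
    branches = {
        d["id"]: Branch(
            d["id"], d["proximal"], d["distal"], np.asarray(d["points_mm"], float),
            parent=d.get("parent"),
            radii=None if d.get("radii_mm") is None else np.asarray(d["radii_mm"], float),
            flags=set(d.get("flags", [])),
        )
        for d in data["branches"]
    }
    return CenterlineNetwork(nodes=nodes, branches=branches,
                             root_node=data["root_node"],
                             root_branch=data["root_branch"],
                             spacing_um=data["spacing_um"])


def save_network(network: CenterlineNetwork, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(network_to_json(network)))


def load_network(path: str | Path) -> CenterlineNetwork:
    return network_from_json(json.loads(Path(path).read_text()))


def write_graphml(network: CenterlineNetwork, path: str | Path) -> None:
    g = nx.MultiGraph()
    for n in network.nodes.values():
        g.add_node(n.id, kind=n.kind,
                   x=float(n.position[0]), y=float(n.position[1]), z=float(n.position[2]))
    for b in network.branches.values():
        g.add_edge(b.proximal, b.distal, key=b.id, branch=b.id,
                   chord_mm=b.chord, arc_mm=b.arc_length)
    nx.write_graphml(g, str(path))


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"label": str})
    if "label" not in df.columns:
        raise ValueError("morphometry table needs a 'label' column")
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
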