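"""Volume, label-map and graph I/O.

Canonical in-memory convention
------------------------------
All volumes are numpy arrays in ``(z, y, x)`` axis order with z running
proximal → distal (the superior surface of the meniscus sits at low z).
Coordinates are 0-based voxel indices; physical positions are obtained by
multiplying with the per-axis voxel spacing in μm.  The nominal micro-CT
spacing is 30 μm isotropic; it is read from the file header where the format
stores it (NRRD) and otherwise supplied by the caller.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

DEFAULT_SPACING_UM = 30.0

#: columns of the per-segment CSV written next to the GraphML topology
SEGMENT_COLUMNS = [
    "segment_id",
    "node_a",
    "node_b",
    "length_um",
    "chord_um",
    "tortuosity",
    "mean_diameter_um",
    "volume_vox",
    "layer",
    "radial",
    "circumferential",
]


@dataclass
class GrayVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Integer grayscale values.
    spacing_um : tuple of float
        Voxel spacing (z, y, x) in μm; all entries positive.
    axis_order : str
        Axis convention tag; only ``"zyx"`` is supported.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (DEFAULT_SPACING_UM,) * 3
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single slice → degenerate z axis
            self.data = self.data[None, ...]
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("GrayVolume requires a non-empty 3D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_um}")
        if self.axis_order != "zyx":
            raise ValueError(f"unsupported axis order {self.axis_order!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer label map on the same grid as its parent :class:`GrayVolume`."""

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (DEFAULT_SPACING_UM,) * 3
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        present = set(np.unique(self.data[self.data != 0]).tolist())
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"label codes without dictionary entry: {sorted(missing)}")


_SUPPORTED_DTYPES = {
    np.dtype(np.uint8),
    np.dtype(np.int8),
    np.dtype(np.uint16),
    np.dtype(np.int16),
    np.dtype(np.uint32),
    np.dtype(np.int32),
}


def _check_dtype(arr: np.ndarray) -> None:
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported bit depth / dtype: {arr.dtype}")


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"tiff_stack", "nrrd"}:
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff_stack"
    if suffix == ".nrrd":
        return "nrrd"
    raise ValueError(f"cannot infer volume format from {path!r}")


def read_volume(
    path: str | os.PathLike,
    fmt: str | None = None,
    spacing_um: tuple[float, float, float] | None = None,
) -> GrayVolume:
    """Read a 3D volume from a multi-page TIFF or an NRRD file.

    NRRD spacing is stored in mm and converted to μm (×1000).  TIFF files do
    not carry reliable 3D spacing, so ``spacing_um`` is taken from the
    argument, falling back to the nominal 30 μm isotropic.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "tiff_stack":
        data = tifffile.imread(path)
        _check_dtype(np.asarray(data))
        return GrayVolume(np.asarray(data), spacing_um or (DEFAULT_SPACING_UM,) * 3)
    import SimpleITK as sitk

    img = sitk.ReadImage(os.fspath(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    _check_dtype(data)
    if spacing_um is None:
        sp_xyz_mm = img.GetSpacing()  # (x, y, z) in mm
        spacing_um = tuple(1000.0 * s for s in sp_xyz_mm[::-1])
    return GrayVolume(data, spacing_um)


def write_volume(volume: GrayVolume | np.ndarray, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a volume losslessly; the inverse of :func:`read_volume` for integer data."""
    if not isinstance(volume, GrayVolume):
        volume = GrayVolume(np.asarray(volume))
    _check_dtype(volume.data)
    fmt = _infer_format(path, fmt)
    if fmt == "tiff_stack":
        tifffile.imwrite(path, volume.data)
        return
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.data)
    img.SetSpacing(tuple(s / 1000.0 for s in volume.spacing_um[::-1]))  # μm → mm, (x,y,z)
    sitk.WriteImage(img, os.fspath(path), useCompression=True)


def write_label_volume(label: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label map as NRRD plus a JSON label dictionary alongside."""
    write_volume(GrayVolume(label.data.astype(np.int16), label.spacing_um), path, fmt="nrrd")
    with open(str(path) + ".labels.json", "w") as fh:
        json.dump({str(k): v for k, v in label.labels.items()}, fh, indent=1)


def write_graph(graph, out_dir: str | os.PathLike, stem: str = "vessel_graph") -> tuple[Path, Path]:
    """Write a :class:`~meniscovasc.skeleton_graph.VesselGraph` as GraphML + CSV.

    The GraphML file stores the node/segment topology; the CSV stores one row
    per segment with its geometric attributes.  ``read_graph`` reconstructs an
    equal graph from the pair.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gml_path = out_dir / f"{stem}.graphml"
    csv_path = out_dir / f"{stem}.segments.csv"

    g = nx.MultiGraph()
    for nid, rec in graph.nodes.items():
        g.add_node(int(nid), z=int(rec["coord"][0]), y=int(rec["coord"][1]),
                   x=int(rec["coord"][2]), kind=rec["kind"])
    rows = []
    for seg in graph.segments:
        g.add_edge(int(seg.node_a), int(seg.node_b), key=int(seg.segment_id),
                   segment_id=int(seg.segment_id))
        rows.append({
            "segment_id": seg.segment_id,
            "node_a": seg.node_a,
            "node_b": seg.node_b,
            "length_um": seg.length_um,
            "chord_um": seg.chord_um,
            "tortuosity": seg.tortuosity,
            "mean_diameter_um": seg.mean_diameter_um,
            "volume_vox": seg.volume_vox,
            "layer": seg.layer,
            "radial": seg.radial,
            "circumferential": seg.circumferential,
        })
    nx.write_graphml(g, gml_path)
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(csv_path, index=False)
    return gml_path, csv_path


def read_graph(out_dir: str | os.PathLike, stem: str = "vessel_graph"):
    """Reconstruct a VesselGraph written by :func:`write_graph`.

    Centerline voxel paths are not serialized; the returned graph carries the
    topology and all per-segment attributes.
    """
    from meniscovasc.skeleton_graph import SegmentRecord, VesselGraph

    out_dir = Path(out_dir)
    g = nx.read_graphml(out_dir / f"{stem}.graphml", node_type=int, force_multigraph=True)
    df = pd.read_csv(out_dir / f"{stem}.segments.csv")
    nodes = {
        int(n): {"coord": (int(d["z"]), int(d["y"]), int(d["x"])), "kind": d["kind"]}
        for n, d in g.nodes(data=True)
    }
    segments = []
    for _, row in df.iterrows():
        segments.append(SegmentRecord(
            segment_id=int(row.segment_id),
            node_a=int(row.node_a),
            node_b=int(row.node_b),
            path=None,
            length_um=float(row.length_um),
            chord_um=float(row.chord_um),
            tortuosity=float(row.tortuosity) if pd.notna(row.tortuosity) else float("nan"),
            mean_diameter_um=float(row.mean_diameter_um),
            volume_vox=int(row.volume_vox),
            layer=None if pd.isna(row.layer) else str(row.layer),
            radial=None if pd.isna(row.radial) else str(row.radial),
            circumferential=None if pd.isna(row.circumferential) else str(row.circumferential),
        ))
    return VesselGraph(nodes=nodes, segments=segments, spacing_um=(DEFAULT_SPACING_UM,) * 3)
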