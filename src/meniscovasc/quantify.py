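"""Zone-wise vascular quantification.

The central statistic is the *vascular contribution*: for a transverse layer
L and a zone Z, the percentage of the layer's vessel voxels that lie in Z,

    pct_of_layer = 100 · |vessel ∩ L ∩ Z| / |vessel ∩ L|.

The transposed orientation (share of a zone's vessels across layers,
``pct_of_zone``) is emitted alongside, since published per-zone tables are
frequently normalized that way (layer shares within a zone summing to 100).

Volume contributions are counted directly on mask voxels; per-segment
statistics (counts, diameters, tortuosity) are computed separately from the
vessel graph.  Layer/radial labels extended onto the perimeniscal shell are
used so that zone-0 vessels are attributable to a layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from meniscovasc.skeleton_graph import VesselGraph
from meniscovasc.zonation import CIRC_LABELS, LAYER_LABELS, RADIAL_LABELS, ZoneLabelMap

_AXIS_LABELS = {"circumferential": CIRC_LABELS, "radial": RADIAL_LABELS}


def zone_contributions(
    vessel_mask: np.ndarray,
    zones: ZoneLabelMap,
    axis: str = "circumferential",
) -> pd.DataFrame:
    """Tidy table of per-(layer, zone) vessel voxel counts and percentages.

    Columns: layer, axis, zone, vessel_voxels, pct_of_layer, pct_of_zone.
    ``pct_of_layer`` sums to 100 within each layer, ``pct_of_zone`` to 100
    within each zone (NaN where the corresponding total is zero).
    """
    if axis not in _AXIS_LABELS:
        raise ValueError(f"axis must be 'circumferential' or 'radial', got {axis!r}")
    vessel = np.asarray(vessel_mask, dtype=bool)
    layer_map = zones.layer_extended.data
    zone_map = zones.circumferential.data if axis == "circumferential" else zones.radial_extended.data
    zone_names = _AXIS_LABELS[axis]

    rows = []
    counts = np.zeros((len(LAYER_LABELS), len(zone_names)), dtype=np.int64)
    for i, lcode in enumerate(sorted(LAYER_LABELS)):
        in_layer = vessel & (layer_map == lcode)
        for j, zcode in enumerate(sorted(zone_names)):
            counts[i, j] = int(np.count_nonzero(in_layer & (zone_map == zcode)))
    layer_totals = counts.sum(axis=1)
    zone_totals = counts.sum(axis=0)
    for i, lcode in enumerate(sorted(LAYER_LABELS)):
        for j, zcode in enumerate(sorted(zone_names)):
            rows.append({
                "layer": LAYER_LABELS[lcode],
                "axis": axis,
                "zone": zone_names[zcode],
                "vessel_voxels": int(counts[i, j]),
                "pct_of_layer": 100.0 * counts[i, j] / layer_totals[i] if layer_totals[i] else np.nan,
                "pct_of_zone": 100.0 * counts[i, j] / zone_totals[j] if zone_totals[j] else np.nan,
            })
    return pd.DataFrame(rows)


def _segment_layer(seg, layer_map: np.ndarray) -> str | None:
    """Majority layer of a segment's centerline voxels; ties → intermediate."""
    if seg.path is None or len(seg.path) == 0:
        return None
    codes = layer_map[tuple(np.asarray(seg.path).T)]
    codes = codes[codes > 0]
    if codes.size == 0:
        return None
    counts = np.bincount(codes, minlength=4)[1:4]
    best = counts.max()
    winners = np.nonzero(counts == best)[0] + 1
    code = 2 if len(winners) > 1 else int(winners[0])
    return LAYER_LABELS[code]


def _segment_majority(seg, label_map: np.ndarray, names: dict[int, str]) -> str | None:
    if seg.path is None or len(seg.path) == 0:
        return None
    codes = label_map[tuple(np.asarray(seg.path).T)]
    codes = codes[codes > 0]
    if codes.size == 0:
        return None
    vals, cnts = np.unique(codes, return_counts=True)
    return names[int(vals[np.argmax(cnts)])]


def annotate_segments(graph: VesselGraph, zones: ZoneLabelMap) -> VesselGraph:
    """Attach layer/radial/circumferential labels to every segment (in place)."""
    for seg in graph.segments:
        seg.layer = _segment_layer(seg, zones.layer_extended.data)
        seg.radial = _segment_majority(seg, zones.radial_extended.data, RADIAL_LABELS)
        seg.circumferential = _segment_majority(seg, zones.circumferential.data, CIRC_LABELS)
    return graph


def layer_vessel_stats(graph: VesselGraph, zones: ZoneLabelMap) -> pd.DataFrame:
    """Per-layer segment count, mean ± SEM diameter and tortuosity, total volume.

    Segments are attributed to the layer holding the majority of their
    centerline voxels (ties → intermediate).  Closed loops (undefined
    tortuosity) are excluded from the tortuosity mean but still counted.
    """
    annotate_segments(graph, zones)
    rows = []
    for lcode in sorted(LAYER_LABELS):
        lname = LAYER_LABELS[lcode]
        segs = [s for s in graph.segments if s.layer == lname]
        diam = np.array([s.mean_diameter_um for s in segs], dtype=float)
        tort = np.array([s.tortuosity for s in segs], dtype=float)
        tort = tort[np.isfinite(tort)]
        rows.append({
            "layer": lname,
            "n_segments": len(segs),
            "mean_diameter_um": diam.mean() if diam.size else np.nan,
            "sem_diameter_um": _sem(diam),
            "mean_tortuosity": tort.mean() if tort.size else np.nan,
            "sem_tortuosity": _sem(tort),
            "total_vessel_volume_vox": int(sum(s.volume_vox for s in segs)),
        })
    return pd.DataFrame(rows)


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size < 2:
        return np.nan
    return float(values.std(ddof=1) / np.sqrt(values.size))


def diameter_histogram(
    graph: VesselGraph,
    bin_width_um: float = 20.0,
    range_um: tuple[float, float] = (0.0, 160.0),
) -> pd.DataFrame:
    """Per-layer segment counts by diameter bin over ``range_um``.

    Segments thicker than the range top are counted in the last bin
    (top-binned); a ``mean`` column holds the across-layer mean frequency.
    Requires segments to be annotated with layers (see
    :func:`layer_vessel_stats` / :func:`annotate_segments`).
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = range_um
    n_bins = round((hi - lo) / bin_width_um)
    if abs(n_bins * bin_width_um - (hi - lo)) > 1e-9 or n_bins < 1:
        raise ValueError("bin width must divide the diameter range")
    edges = lo + bin_width_um * np.arange(n_bins + 1)

    data = {}
    for lname in LAYER_LABELS.values():
        diam = np.array([s.mean_diameter_um for s in graph.segments if s.layer == lname])
        if diam.size:
            clipped = np.minimum(diam, hi - 1e-9)  # top-bin oversized segments
            counts, _ = np.histogram(clipped, bins=edges)
        else:
            counts = np.zeros(n_bins, dtype=int)
        data[lname] = counts
    df = pd.DataFrame(data, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
    df.index.name = "diameter_bin_um"
    df["mean"] = df[list(LAYER_LABELS.values())].mean(axis=1)
    return df
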