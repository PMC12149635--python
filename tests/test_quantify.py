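"""Zone-wise contributions, per-layer vessel statistics, diameter histograms."""

import numpy as np
import pandas as pd
import pytest

from meniscovasc.phantom import PhantomSpec, generate_phantom
from meniscovasc.quantify import (
    annotate_segments,
    diameter_histogram,
    layer_vessel_stats,
    zone_contributions,
)
from meniscovasc.segmentation import segment_vasculature
from meniscovasc.skeleton_graph import build_graph, skeletonize
from meniscovasc.zonation import CIRC_LABELS, LAYER_LABELS, build_zone_map


def bruteforce_contributions(vessel, layer_map, zone_map, zone_codes):
    """Direct triple-loop voxel counting oracle."""
    counts = {}
    nz, ny, nx = vessel.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if vessel[z, y, x]:
                    key = (int(layer_map[z, y, x]), int(zone_map[z, y, x]))
                    counts[key] = counts.get(key, 0) + 1
    out = {}
    for lc in (1, 2, 3):
        tot = sum(counts.get((lc, zc), 0) for zc in zone_codes)
        for zc in zone_codes:
            out[(lc, zc)] = (counts.get((lc, zc), 0),
                             100.0 * counts.get((lc, zc), 0) / tot if tot else np.nan)
    return out


class TestZoneContributions:
    def test_constructed_counts_give_expected_percentages(self, straight_zones):
        """A layer with 400 vessel voxels, 100 of them in one zone → 25%."""
        zones = straight_zones
        layer = zones.layer_extended.data
        circ = zones.circumferential.data
        in_zone1 = np.argwhere((layer == 2) & (circ == 2))[:300]
        in_zone2 = np.argwhere((layer == 2) & (circ == 3))[:100]
        vessel = np.zeros(layer.shape, bool)
        vessel[tuple(in_zone1.T)] = True
        vessel[tuple(in_zone2.T)] = True
        table = zone_contributions(vessel, zones, axis="circumferential")
        row = table[(table.layer == "intermediate") & (table.zone == "zone2")]
        assert row.vessel_voxels.item() == 100
        assert row.pct_of_layer.item() == pytest.approx(25.0)

    def test_all_vessels_in_one_zone(self, straight_zones):
        zones = straight_zones
        sel = (zones.layer_extended.data == 1) & (zones.circumferential.data == 2)
        vessel = sel.copy()
        table = zone_contributions(vessel, zones, axis="circumferential")
        sup = table[table.layer == "superior"].set_index("zone")
        assert sup.loc["zone1", "pct_of_layer"] == pytest.approx(100.0)
        assert sup.loc["zone2", "pct_of_layer"] == pytest.approx(0.0)

    def test_matches_bruteforce_triple_loop(self, straight_phantom, straight_zones):
        _, _, truth = straight_phantom
        zones = straight_zones
        table = zone_contributions(truth.vessel_mask_true, zones, axis="circumferential")
        oracle = bruteforce_contributions(truth.vessel_mask_true,
                                          zones.layer_extended.data,
                                          zones.circumferential.data, (1, 2, 3, 4))
        for _, row in table.iterrows():
            lc = {v: k for k, v in LAYER_LABELS.items()}[row.layer]
            zc = {v: k for k, v in CIRC_LABELS.items()}[row.zone]
            cnt, pct = oracle[(lc, zc)]
            assert row.vessel_voxels == cnt
            if np.isfinite(pct):
                assert row.pct_of_layer == pytest.approx(pct, abs=1e-9)

    def test_matches_phantom_ground_truth_exactly(self, straight_phantom, straight_zones):
        _, volume, truth = straight_phantom
        mask = segment_vasculature(volume, organ_mask=truth.organ_mask)
        gt = truth.per_zone_vessel_voxels
        for axis in ("circumferential", "radial"):
            table = zone_contributions(mask.data, straight_zones, axis=axis)
            merged = table.merge(gt[gt.axis == axis], on=["layer", "axis", "zone"],
                                 suffixes=("", "_true"))
            assert len(merged) == len(table)
            assert (merged.vessel_voxels == merged.vessel_voxels_true).all()

    def test_normalization_both_orientations(self, straight_phantom, straight_zones):
        _, _, truth = straight_phantom
        for axis in ("circumferential", "radial"):
            table = zone_contributions(truth.vessel_mask_true, straight_zones, axis=axis)
            by_layer = table.dropna(subset=["pct_of_layer"]).groupby("layer").pct_of_layer.sum()
            for v in by_layer:
                assert v == pytest.approx(100.0, abs=1e-6)
            by_zone = table.dropna(subset=["pct_of_zone"]).groupby("zone").pct_of_zone.sum()
            for v in by_zone:
                assert v == pytest.approx(100.0, abs=1e-6)

    def test_empty_layer_reported_missing(self, straight_zones):
        vessel = np.zeros(straight_zones.layer.data.shape, bool)
        sel = np.argwhere(straight_zones.layer.data == 1)[:50]
        vessel[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        table = zone_contributions(vessel, straight_zones, axis="circumferential")
        assert table[table.layer == "inferior"].pct_of_layer.isna().all()


class TestLayerVesselStats:
    def test_straight_tubes_per_layer_counts_and_tortuosity(self, straight_phantom,
                                                           straight_zones):
        spec, _, truth = straight_phantom
        mask = truth.vessel_mask_true
        graph = build_graph(skeletonize(mask), mask, spec.spacing_um)
        stats = layer_vessel_stats(graph, straight_zones)
        counts = dict(zip(stats.layer, stats.n_segments))
        assert counts == truth.per_layer_segment_counts
        mean_tort = stats.dropna(subset=["mean_tortuosity"]).mean_tortuosity
        assert (mean_tort < 1.02).all()

    def test_empty_layer_rows_are_zero_with_missing_means(self, straight_zones):
        from meniscovasc.skeleton_graph import VesselGraph

        g = VesselGraph(nodes={}, segments=[], spacing_um=(30.0,) * 3)
        stats = layer_vessel_stats(g, straight_zones)
        assert (stats.n_segments == 0).all()
        assert stats.mean_diameter_um.isna().all()

    def test_diameter_recovery_within_documented_bound(self, straight_phantom):
        """Oblique-tube diameters recover within 10% + one voxel (30 μm):
        the relative EDT accuracy plus the half-voxel-per-side rasterization
        allowance that dominates at small radii."""
        spec, _, truth = straight_phantom
        mask = truth.vessel_mask_true
        graph = build_graph(skeletonize(mask), mask, spec.spacing_um)
        assert graph.n_segments == len(truth.segments_true)
        est = sorted(s.mean_diameter_um for s in graph.segments)
        true = sorted(2 * t.radius_um for t in truth.segments_true)
        for e, t in zip(est, true):
            assert abs(e - t) <= 0.10 * t + 30.0, (e, t)


class TestDiameterHistogram:
    def test_single_segment_lands_in_its_bin(self, straight_zones):
        from meniscovasc.skeleton_graph import SegmentRecord, VesselGraph

        seg = SegmentRecord(0, 1, 2, None, 500.0, 500.0, 1.0, 75.0, 10, layer="superior")
        g = VesselGraph(nodes={}, segments=[seg], spacing_um=(30.0,) * 3)
        hist = diameter_histogram(g, bin_width_um=20.0)
        col = hist["superior"]
        assert col.sum() == 1
        assert col[pd.Interval(60.0, 80.0, closed="left")] == 1

    def test_empty_graph_all_zero(self):
        from meniscovasc.skeleton_graph import VesselGraph

        g = VesselGraph(nodes={}, segments=[], spacing_um=(30.0,) * 3)
        hist = diameter_histogram(g)
        assert (hist[["superior", "intermediate", "inferior"]].to_numpy() == 0).all()

    def test_equal_diameter_phantom_concentrates_in_one_bin(self):
        spec = PhantomSpec(n_trees=4, tree_mode="straight",
                           tree_angles_deg=(40.0, 80.0, 100.0, 140.0),
                           diameter_range_um=(150.0, 150.0), noise_sd=0.0)
        _, truth = generate_phantom(spec)
        mask = truth.vessel_mask_true
        graph = build_graph(skeletonize(mask), mask, spec.spacing_um)
        zones = build_zone_map(truth.organ_mask, margin_um=spec.margin_um,
                               spacing_um=spec.spacing_um)
        annotate_segments(graph, zones)
        hist = diameter_histogram(graph, bin_width_um=40.0)
        total = hist[["superior", "intermediate", "inferior"]].sum(axis=1)
        # all tubes are 150 μm; estimates fall in the [120,160) bin
        assert total[pd.Interval(120.0, 160.0, closed="left")] == 4

    def test_invalid_bins_raise(self):
        from meniscovasc.skeleton_graph import VesselGraph

        g = VesselGraph(nodes={}, segments=[], spacing_um=(30.0,) * 3)
        with pytest.raises(ValueError):
            diameter_histogram(g, bin_width_um=-5)
        with pytest.raises(ValueError):
            diameter_histogram(g, bin_width_um=30.0, range_um=(0.0, 160.0))
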