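"""Transverse layers, ISAKOS circumferential zones, and radial thirds."""

import numpy as np
import pytest

from meniscovasc.zonation import (
    build_zone_map,
    circumferential_zones,
    radial_thirds,
    transverse_layers,
)


def analytic_circ(annulus):
    w = (annulus["outer"] - annulus["r"]) / (annulus["outer"] - annulus["inner"])
    return np.where(w < 1 / 3, 2, np.where(w < 2 / 3, 3, 4))


def analytic_radial(annulus):
    f = (90.0 - annulus["theta"]) / 180.0
    return np.where(f < 1 / 3, 1, np.where(f < 2 / 3, 2, 3))


class TestTransverseLayers:
    def test_column_of_nine_splits_evenly(self):
        mask = np.zeros((9, 3, 3), bool)
        mask[:, 1, 1] = True
        lab = transverse_layers(mask).data[:, 1, 1]
        assert lab.tolist() == [1] * 3 + [2] * 3 + [3] * 3

    def test_single_voxel_column_is_intermediate(self):
        mask = np.zeros((5, 3, 3), bool)
        mask[2, 1, 1] = True
        assert transverse_layers(mask).data[2, 1, 1] == 2

    def test_remainder_two_goes_to_outer_layers(self):
        mask = np.zeros((5, 3, 3), bool)
        mask[1:3, 1, 1] = True
        lab = transverse_layers(mask).data[:, 1, 1]
        assert lab[1] == 1 and lab[2] == 3

    def test_flat_slab_exact_thirds(self):
        mask = np.zeros((30, 8, 8), bool)
        mask[:, 1:7, 1:7] = True
        lab = transverse_layers(mask).data
        counts = [int((lab == k).sum()) for k in (1, 2, 3)]
        assert counts == [mask.sum() // 3] * 3

    def test_superior_is_low_z(self):
        mask = np.zeros((9, 3, 3), bool)
        mask[:, 1, 1] = True
        lab = transverse_layers(mask).data
        assert lab[0, 1, 1] == 1 and lab[8, 1, 1] == 3

    def test_global_mode_cuts_z_extent(self):
        mask = np.zeros((12, 4, 4), bool)
        mask[1:10, 1, 1] = True   # thickness varies per column in general
        mask[4:7, 2, 2] = True
        lab = transverse_layers(mask, mode="global").data
        assert set(np.unique(lab[mask])) <= {1, 2, 3}
        # middle column lies entirely in the central global third
        assert (lab[4:7, 2, 2] == 2).all()

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            transverse_layers(np.zeros((3, 3, 3), bool))


class TestCircumferentialZones:
    def test_annulus_matches_analytic_radius_rule(self, annulus_mask):
        organ = annulus_mask["organ"]
        lab = circumferential_zones(organ).data
        truth = np.broadcast_to(analytic_circ(annulus_mask), organ.shape)
        assert (lab[organ] == truth[organ]).mean() >= 0.95

    def test_outer_boundary_voxel_is_zone1(self, annulus_mask):
        lab = circumferential_zones(annulus_mask["organ"]).data
        organ = annulus_mask["organ"]
        r = np.broadcast_to(annulus_mask["r"], organ.shape)
        outer_rim = organ & (r > annulus_mask["outer"] - 1.0) & (
            np.abs(np.broadcast_to(annulus_mask["theta"], organ.shape)) < 80)
        assert (lab[outer_rim] == 2).all()

    def test_zones_partition_organ(self, annulus_mask):
        organ = annulus_mask["organ"]
        lab = circumferential_zones(organ).data
        assert (((lab >= 2) & (lab <= 4)) == organ).all()

    def test_zone0_shell_outside_outer_rim(self, annulus_mask):
        organ = annulus_mask["organ"]
        lab = circumferential_zones(organ, margin_um=500.0).data
        shell = lab == 1
        assert shell.any()
        assert not (shell & organ).any()
        r = np.broadcast_to(annulus_mask["r"], organ.shape)
        assert r[shell].min() > annulus_mask["outer"] - 1.0
        # margin: 500 μm = 16.7 voxels beyond the rim
        assert r[shell].max() <= annulus_mask["outer"] + 500.0 / 30.0 + 1.5

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            circumferential_zones(np.zeros((4, 4, 4), bool))


class TestRadialThirds:
    def test_annulus_matches_analytic_angle_rule(self, annulus_mask):
        organ = annulus_mask["organ"]
        lab = radial_thirds(organ).data
        truth = np.broadcast_to(analytic_radial(annulus_mask), organ.shape)
        assert (lab[organ] == truth[organ]).mean() >= 0.95

    def test_annulus_thirds_balanced(self, annulus_mask):
        organ = annulus_mask["organ"]
        lab = radial_thirds(organ).data
        target = organ.sum() / 3
        for k in (1, 2, 3):
            assert (lab == k).sum() == pytest.approx(target, rel=0.05)

    def test_orientation_flag_selects_anterior_end(self, annulus_mask):
        organ = annulus_mask["organ"]
        lab_py = radial_thirds(organ, orientation="anterior=+y").data
        lab_my = radial_thirds(organ, orientation="anterior=-y").data
        th = np.broadcast_to(annulus_mask["theta"], organ.shape)
        assert (lab_py[organ & (th > 70)] == 1).all()
        assert (lab_my[organ & (th > 70)] == 3).all()

    def test_straight_bar_thirds_along_long_axis(self):
        bar = np.zeros((5, 12, 60), bool)
        bar[:, 3:9, 5:55] = True
        lab = radial_thirds(bar, orientation="anterior=+x").data
        counts = [int((lab == k).sum()) for k in (1, 2, 3)]
        assert sum(counts) == bar.sum()
        assert max(counts) - min(counts) <= 0.15 * bar.sum() / 3
        xs_ant = np.nonzero((lab == 1).any(axis=(0, 1)))[0]
        xs_post = np.nonzero((lab == 3).any(axis=(0, 1)))[0]
        assert xs_ant.min() > xs_post.max()   # anterior = +x end

    def test_bad_orientation_string_raises(self, annulus_mask):
        with pytest.raises(ValueError, match="orientation"):
            radial_thirds(annulus_mask["organ"], orientation="up")


class TestZoneMapComposition:
    def test_cross_tabulation_closure(self, straight_phantom, straight_zones):
        """Layer × radial × circumferential labels jointly cover the organ, and
        the zone-0 shell appears only on the circumferential axis."""
        _, _, truth = straight_phantom
        zones = straight_zones
        organ = truth.organ_mask
        assert ((zones.layer.data > 0) == organ).all()
        assert ((zones.radial.data > 0) == organ).all()
        circ = zones.circumferential.data
        assert (((circ >= 2) & (circ <= 4)) == organ).all()
        shell = circ == 1
        assert ((zones.layer_extended.data > 0) == (organ | shell)).all()
        # every organ voxel gets exactly one label per axis → triple table sums
        n = int(organ.sum())
        import numpy as _np

        table = _np.zeros((3, 3, 4), int)
        for il in range(3):
            for ir in range(3):
                for ic in range(4):
                    table[il, ir, ic] = int((organ
                                             & (zones.layer.data == il + 1)
                                             & (zones.radial.data == ir + 1)
                                             & (circ == ic + 1)).sum())
        assert table.sum() == n

    def test_rotation_invariance_of_zone_volumes(self, annulus_mask):
        """Rotating the organ 90° about z leaves per-zone volumes within 2%."""
        organ = annulus_mask["organ"]
        rotated = np.rot90(organ, k=1, axes=(1, 2)).copy()
        za = build_zone_map(organ, orientation="anterior=+y")
        zb = build_zone_map(rotated, orientation="anterior=-x")
        for attr in ("layer", "circumferential"):
            a = getattr(za, attr).data
            b = getattr(zb, attr).data
            for code in np.unique(a[a > 0]):
                va, vb = (a == code).sum(), (b == code).sum()
                assert vb == pytest.approx(va, rel=0.02), (attr, code)
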