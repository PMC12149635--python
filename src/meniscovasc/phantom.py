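"""Synthetic meniscus phantoms with exact ground truth.

The phantom emulates the gross anatomy relevant to zonation and vascular
quantification: a C-shaped half-annulus with a triangular (wedge) cross
section — thick at the outer rim, tapering to the inner free edge — filled
with tissue-intensity voxels on a darker background, and bright tubular
vessel trees that penetrate from the peripheral rim inward, with diameters
tapering per branch level over the 0–160 μm range seen at ~30 μm voxels.
Additive Gaussian noise models detector noise; reconstruction artifacts are
out of scope.

Ground truth is derived from the generating geometry, never by re-running
the image-processing pipeline on the rendered volume:

* the organ mask and true vessel mask come from the analytic wedge/tube
  geometry (tube rasterization by exact point-to-polyline distance);
* per-segment centerlines, radii and tortuosities are the generating
  polylines themselves;
* per-zone vessel voxel counts are tabulated with an independent
  *reference zonation*: straightforward brute-force implementations of the
  same label definitions the :mod:`~meniscovasc.zonation` module uses
  (per-column thickness thirds; per-slice normalized-width zones with
  distances computed by direct point-set minimization instead of a distance
  transform; radial thirds from the analytic arc angle).

Two vessel layouts are available: ``arborized`` (default; branching trees
with curvature and taper — the realistic condition) and ``straight``
(non-touching straight radial tubes at declared angles and transverse
offsets — the layout used for exact-recovery validation, where every
downstream count has a closed-form answer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from meniscovasc.volume_io import GrayVolume
from meniscovasc.zonation import CIRC_LABELS, LAYER_LABELS, RADIAL_LABELS


@dataclass
class PhantomSpec:
    """Generating parameters of a meniscus phantom.

    Defaults describe the standard validation condition: a 180° half-annulus
    of outer radius 66 / inner radius 38 voxels at 30 μm/voxel (≈ 2 mm wall
    width — a scaled-down meniscus that keeps all three zonation axes
    resolvable on a desk-sized grid), wedge height 36 voxels at the rim,
    8 vessel trees of branching depth 3 spanning 30–160 μm diameters,
    vessel/tissue/background intensities 230/90/20 and Gaussian noise with
    σ = 7 gray levels (5% of the vessel–tissue contrast).
    """

    grid_shape: tuple[int, int, int] = (45, 177, 100)
    voxel_size_um: float = 30.0
    arc_span_deg: float = 180.0
    outer_radius_vox: float = 66.0
    inner_radius_vox: float = 38.0
    max_height_vox: float = 36.0
    n_trees: int = 8
    branching_depth: int = 3
    diameter_range_um: tuple[float, float] = (30.0, 160.0)
    vessel_intensity: int = 230
    tissue_intensity: int = 90
    background_intensity: int = 20
    noise_sd: float = 7.0
    seed: int = 0
    tree_mode: str = "arborized"            # {"arborized", "straight"}
    tree_angles_deg: tuple[float, ...] | None = None
    margin_um: float = 500.0                # perimeniscal (zone-0) shell thickness

    def __post_init__(self) -> None:
        if self.arc_span_deg <= 0:
            raise ValueError("degenerate arc: span must be > 0°")
        if not (0 < self.inner_radius_vox < self.outer_radius_vox):
            raise ValueError("need 0 < inner_radius_vox < outer_radius_vox")
        dmin, dmax = self.diameter_range_um
        if not (0 < dmin <= dmax <= 200):
            raise ValueError("diameter_range_um must lie within (0, 200] μm")
        if len({self.vessel_intensity, self.tissue_intensity, self.background_intensity}) != 3:
            raise ValueError("vessel, tissue and background intensities must be distinct")
        if self.tree_mode not in ("arborized", "straight"):
            raise ValueError(f"unknown tree_mode {self.tree_mode!r}")
        nz, ny, nx = self.grid_shape
        reach = self.outer_radius_vox + self.margin_um / self.voxel_size_um + 2
        if self.arc_center_yx[1] < 1 or 2 * reach + 4 > ny or self.max_height_vox + 4 > nz:
            raise ValueError(
                f"grid {self.grid_shape} too small for annulus of outer radius "
                f"{self.outer_radius_vox} plus a {self.margin_um} μm margin")

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return (self.voxel_size_um,) * 3

    @property
    def arc_center_yx(self) -> tuple[float, float]:
        """Arc center: mid-y; x leaves room for the annulus + zone-0 shell."""
        nz, ny, nx = self.grid_shape
        reach = self.outer_radius_vox + self.margin_um / self.voxel_size_um + 2
        return ((ny - 1) / 2.0, (nx - 1) - reach)

    @property
    def z_center(self) -> float:
        return (self.grid_shape[0] - 1) / 2.0

    def wedge_thickness(self, r: np.ndarray | float):
        """Local wedge thickness (voxels) at radius r: 0 at the free edge,
        ``max_height_vox`` at the rim."""
        frac = (np.asarray(r, float) - self.inner_radius_vox) / (
            self.outer_radius_vox - self.inner_radius_vox)
        return self.max_height_vox * np.clip(frac, 0.0, None)


@dataclass
class TrueSegment:
    """One generating vessel branch: centerline polyline + radius."""

    polyline_vox: np.ndarray      # (n, 3) float voxel coordinates (z, y, x)
    radius_um: float
    length_um: float
    chord_um: float
    tortuosity: float


def _polyline_metrics(poly_vox: np.ndarray, voxel_um: float) -> tuple[float, float, float]:
    p = np.asarray(poly_vox, float) * voxel_um
    length = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    chord = float(np.linalg.norm(p[-1] - p[0]))
    tort = length / chord if chord > 0 else float("nan")
    return length, chord, tort


def place_tube(
    polyline: np.ndarray,
    radius_um: float,
    spacing_um=(30.0, 30.0, 30.0),
    grid_shape: tuple[int, int, int] = (45, 177, 100),
) -> np.ndarray:
    """Rasterize a tube: voxels within ``radius_um`` of a piecewise-linear curve.

    The result is the union of (a) the rounded positions of densely sampled
    curve points (so the tube is never broken, even below voxel width) and
    (b) all voxels whose center lies within the radius of the curve.  A
    polyline entirely outside the grid yields an empty volume with a warning.
    """
    poly = np.atleast_2d(np.asarray(polyline, dtype=float))
    if poly.shape[0] < 2 or poly.shape[1] != 3:
        raise ValueError("polyline must contain ≥ 2 points of 3 coordinates")
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    spacing = np.asarray(spacing_um, float)
    shape = np.asarray(grid_shape, int)
    out = np.zeros(grid_shape, dtype=bool)

    r_vox = radius_um / spacing
    lo = np.maximum(np.floor(poly.min(axis=0) - r_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(poly.max(axis=0) + r_vox + 1).astype(int), shape - 1)
    if np.any(hi < lo):
        warnings.warn("polyline lies outside the grid; returning an empty tube", stacklevel=2)
        return out

    # (a) dense rasterization of the centerline
    for a, b in zip(poly[:-1], poly[1:]):
        n = max(2, int(np.ceil(np.linalg.norm((b - a)) / 0.25)) + 1)
        pts = np.rint(a + np.linspace(0, 1, n)[:, None] * (b - a)).astype(int)
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        if len(pts):
            out[pts[:, 0], pts[:, 1], pts[:, 2]] = True

    # (b) exact point-to-segment distance over the bounding box
    grids = np.meshgrid(*(np.arange(lo[i], hi[i] + 1) for i in range(3)), indexing="ij")
    box = np.stack([g.ravel() for g in grids], axis=1).astype(float) * spacing
    min_d2 = np.full(len(box), np.inf)
    poly_um = poly * spacing
    for a, b in zip(poly_um[:-1], poly_um[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = ((box - a) ** 2).sum(axis=1)
        else:
            t = np.clip((box - a) @ ab / denom, 0.0, 1.0)
            d2 = ((box - (a + t[:, None] * ab)) ** 2).sum(axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    inside = min_d2 <= radius_um ** 2
    sub = tuple(g.ravel()[inside] for g in grids)
    out[sub] = True

    if not out.any():
        warnings.warn("tube rasterized to an empty volume", stacklevel=2)
    return out


def _organ_mask(spec: PhantomSpec) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    cy, cx = spec.arc_center_yx
    zz = np.arange(nz)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx)[None, None, :]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))  # 0° along +x, +90° toward +y
    half = spec.arc_span_deg / 2.0
    in_plane = ((r >= spec.inner_radius_vox) & (r <= spec.outer_radius_vox)
                & (theta >= -half) & (theta <= half))
    t = spec.wedge_thickness(r)
    return in_plane & (np.abs(zz - spec.z_center) <= t / 2.0)


# --------------------------------------------------------------------------
# vessel tree construction
# --------------------------------------------------------------------------

def _cyl_to_vox(r, theta_rad, z, spec: PhantomSpec) -> np.ndarray:
    cy, cx = spec.arc_center_yx
    r = np.asarray(r, float)
    z, y, x = np.broadcast_arrays(np.asarray(z, float),
                                  cy + r * np.sin(theta_rad),
                                  cx + r * np.cos(theta_rad))
    return np.stack([z, y, x], axis=-1)


def _clamp_z(z_rel, r, r_tube_vox, spec: PhantomSpec):
    """Keep a centerline point inside the wedge (or rim shell) with a safety margin."""
    r = np.asarray(r, float)
    t_half = np.where(r > spec.outer_radius_vox,
                      spec.max_height_vox / 2.0,
                      spec.wedge_thickness(r) / 2.0)
    zlim = np.maximum(0.0, t_half - r_tube_vox - 1.0)
    return np.clip(z_rel, -zlim, zlim)


def _min_reachable_radius(abs_z_rel: float, r_tube_vox: float, spec: PhantomSpec) -> float:
    """Smallest radius whose wedge still encloses the tube at this depth."""
    need = 2.0 * (abs_z_rel + r_tube_vox + 1.0)
    width = spec.outer_radius_vox - spec.inner_radius_vox
    return spec.inner_radius_vox + need * width / spec.max_height_vox


def _branch_polyline(r0, th0, z0, r1, th1, z1, r_tube_vox, wiggle_amp, wiggle_cycles,
                     spec: PhantomSpec) -> np.ndarray:
    n = max(4, int(abs(r0 - r1) * 1.0) + 2)
    s = np.linspace(0.0, 1.0, n)
    r = r0 + s * (r1 - r0)
    th = th0 + s * (th1 - th0)
    th = th + (wiggle_amp / np.maximum(r, 1.0)) * np.sin(np.pi * wiggle_cycles * s) * np.sin(np.pi * s)
    z_rel = z0 + s * (z1 - z0)
    z_rel = _clamp_z(z_rel, r, r_tube_vox, spec)
    # truncate where the wedge becomes too thin for this tube
    keep = np.ones(n, bool)
    for i in range(n):
        if r[i] <= spec.outer_radius_vox and r[i] < _min_reachable_radius(abs(z_rel[i]), r_tube_vox, spec):
            keep[i:] = False
            break
    r, th, z_rel = r[keep], th[keep], z_rel[keep]
    if len(r) < 2:
        return np.empty((0, 3))
    return _cyl_to_vox(r, th, spec.z_center + z_rel, spec)


def _grow_trees(spec: PhantomSpec, rng: np.random.Generator) -> list[TrueSegment]:
    half_rad = math.radians(spec.arc_span_deg / 2.0)
    dmin, dmax = spec.diameter_range_um
    segments: list[TrueSegment] = []

    # root angles, measured like the mask: 0 along +x, ± half span
    if spec.tree_angles_deg is not None:
        if len(spec.tree_angles_deg) != spec.n_trees:
            raise ValueError("tree_angles_deg length must equal n_trees")
        # declared angles are arc positions in [0, span], 0 = posterior tip (−half)
        root_angles = [math.radians(a) - half_rad for a in spec.tree_angles_deg]
    else:
        step = spec.arc_span_deg / max(spec.n_trees, 1)
        root_angles = [math.radians(-spec.arc_span_deg / 2.0 + (i + 0.5) * step)
                       for i in range(spec.n_trees)]

    if spec.tree_mode == "straight":
        offsets = [-8.0, 0.0, 8.0]
        for i, th in enumerate(root_angles):
            diam = dmax if spec.n_trees == 1 else dmax - (dmax - dmin) * i / (spec.n_trees - 1)
            r_tube = diam / 2.0 / spec.voxel_size_um
            off = offsets[i % 3]
            r_start = spec.outer_radius_vox + 4.0
            r_end = max(_min_reachable_radius(abs(off), r_tube, spec), spec.inner_radius_vox + 2.0)
            r_end = min(r_end, r_start - 4.0)
            n = max(4, int(r_start - r_end) + 1)
            r = np.linspace(r_start, r_end, n)
            poly = _cyl_to_vox(r, np.full(n, th), spec.z_center + off, spec)
            length, chord, tort = _polyline_metrics(poly, spec.voxel_size_um)
            segments.append(TrueSegment(poly, diam / 2.0, length, chord, tort))
        return segments

    width = spec.outer_radius_vox - spec.inner_radius_vox
    dr_level = (width + 6.0) / max(spec.branching_depth, 1)

    def grow(r, th, z_rel, level, diam_um):
        r_tube = diam_um / 2.0 / spec.voxel_size_um
        r_end = r - dr_level * rng.uniform(0.85, 1.15)
        th_end = float(np.clip(th + rng.uniform(-0.22, 0.22), -half_rad + 0.06, half_rad - 0.06))
        z_end = z_rel + rng.uniform(-4.0, 4.0)
        poly = _branch_polyline(r, th, z_rel, r_end, th_end, z_end, r_tube,
                                wiggle_amp=rng.uniform(0.5, 1.5),
                                wiggle_cycles=rng.uniform(1.0, 2.0), spec=spec)
        if len(poly) < 2:
            return
        length, chord, tort = _polyline_metrics(poly, spec.voxel_size_um)
        segments.append(TrueSegment(poly, diam_um / 2.0, length, chord, tort))
        if level + 1 >= spec.branching_depth:
            return
        end = poly[-1]
        cy, cx = spec.arc_center_yx
        r_e = float(np.hypot(end[1] - cy, end[2] - cx))
        th_e = float(math.atan2(end[1] - cy, end[2] - cx))
        z_e = float(end[0] - spec.z_center)
        child_d = max(diam_um * 0.68, dmin)
        for _ in range(2):
            grow(r_e, th_e, z_e, level + 1, child_d)

    for th in root_angles:
        # roots spread over the rim height: every transverse layer receives
        # its own supply, as in the real organ
        z0 = rng.uniform(-0.75, 0.75) * spec.max_height_vox / 2.0
        grow(spec.outer_radius_vox + 4.0, th, z0, 0, dmax)
    return segments


# --------------------------------------------------------------------------
# reference zonation (brute-force ground-truth labels)
# --------------------------------------------------------------------------

def _ref_boundary2d(mask2d: np.ndarray) -> np.ndarray:
    """Boundary pixels: any 4-neighbor outside the mask (image edge counts)."""
    padded = np.pad(mask2d, 1, constant_values=False)
    nb_all = (padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:])
    return mask2d & ~nb_all


def _ref_layers(organ: np.ndarray) -> np.ndarray:
    """Local-thickness thirds per column (center-biased remainder rule)."""
    out = np.zeros(organ.shape, dtype=np.int16)
    nz, ny, nx = organ.shape
    for y in range(ny):
        for x in range(nx):
            zs = np.nonzero(organ[:, y, x])[0]
            m = len(zs)
            if m == 0:
                continue
            base, rem = divmod(m, 3)
            n_sup = base + (1 if rem == 2 else 0)
            n_int = base + (1 if rem == 1 else 0)
            out[zs[:n_sup], y, x] = 1
            out[zs[n_sup:n_sup + n_int], y, x] = 2
            out[zs[n_sup + n_int:], y, x] = 3
    return out


def _ref_kasa_center(organ: np.ndarray) -> np.ndarray:
    proj = organ.any(axis=0)
    pts = np.argwhere(_ref_boundary2d(proj)).astype(float)
    y, x = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * y, 2 * x, np.ones_like(y)])
    sol, *_ = np.linalg.lstsq(A, y * y + x * x, rcond=None)
    return sol[:2]


def _ref_circumferential(organ: np.ndarray, margin_um: float, spacing: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force ISAKOS zones; returns (label volume, outer-rim 3D set)."""
    center = _ref_kasa_center(organ)
    out = np.zeros(organ.shape, dtype=np.int16)
    outer3d = np.zeros_like(organ)
    for z in range(organ.shape[0]):
        sl = organ[z]
        if not sl.any():
            continue
        boundary = _ref_boundary2d(sl)
        b = np.argwhere(boundary)
        rb = np.hypot(b[:, 0] - center[0], b[:, 1] - center[1])
        # normal-vs-radial classification, pixel by pixel (caps → neither set)
        is_outer = np.zeros(len(b), bool)
        is_inner = np.zeros(len(b), bool)
        ny, nx = sl.shape
        for k, (py, px) in enumerate(b):
            ys, xs = [], []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    qy, qx = py + dy, px + dx
                    if 0 <= qy < ny and 0 <= qx < nx and sl[qy, qx]:
                        ys.append(qy)
                        xs.append(qx)
            cnt = float(len(ys))
            vy = py - float(sum(ys)) / cnt
            vx = px - float(sum(xs)) / cnt
            vnorm = np.hypot(vy, vx)
            if vnorm == 0:
                continue
            uy = (py - center[0]) / np.maximum(rb[k], 1e-12)
            ux = (px - center[1]) / np.maximum(rb[k], 1e-12)
            s = (vy * uy + vx * ux) / vnorm
            is_outer[k] = s >= 0.5
            is_inner[k] = s <= -0.5
        if not is_outer.any() or not is_inner.any():
            tau = 0.5 * (rb.min() + rb.max())
            is_outer = rb >= tau
            is_inner = ~is_outer
        outer_pts = b[is_outer]
        inner_pts = b[is_inner]
        outer3d[z][outer_pts[:, 0], outer_pts[:, 1]] = True
        pix = np.argwhere(sl)
        if len(inner_pts) == 0:
            out[z][pix[:, 0], pix[:, 1]] = 2
            continue
        sp = spacing[1:]
        d_o = cdist(pix * sp, outer_pts * sp).min(axis=1)
        d_i = cdist(pix * sp, inner_pts * sp).min(axis=1)
        w = d_o / (d_o + d_i)
        lab = np.where(w < 1.0 / 3.0, 2, np.where(w < 2.0 / 3.0, 3, 4))
        out[z][pix[:, 0], pix[:, 1]] = lab

    # zone-0 shell by direct minimization over the two boundary sets
    pad6 = np.pad(organ, 1, constant_values=False)
    nb6 = (pad6[:-2, 1:-1, 1:-1] & pad6[2:, 1:-1, 1:-1] & pad6[1:-1, :-2, 1:-1]
           & pad6[1:-1, 2:, 1:-1] & pad6[1:-1, 1:-1, :-2] & pad6[1:-1, 1:-1, 2:])
    boundary3d = organ & ~nb6
    rest3d = boundary3d & ~outer3d
    # candidate outside voxels: cheap prefilter by Chebyshev box distance
    # 6-connected dilation covers Manhattan distance; Euclid d ⇒ Manhattan ≤ √3·d
    margin_vox = margin_um / spacing.min()
    cand = (~organ) & ndimage.binary_dilation(
        outer3d, iterations=int(np.ceil(margin_vox * math.sqrt(3.0))) + 2)
    cand_idx = np.argwhere(cand)
    outer_pts = np.argwhere(outer3d) * spacing
    rest_pts = np.argwhere(rest3d) * spacing
    if len(cand_idx) and len(outer_pts):
        from scipy.spatial import cKDTree

        pts = cand_idx * spacing
        d_o, _ = cKDTree(outer_pts).query(pts, workers=-1)
        if len(rest_pts):
            d_r, _ = cKDTree(rest_pts).query(pts, workers=-1)
        else:
            d_r = np.full(len(pts), np.inf)
        keep = (d_o <= margin_um) & (d_o <= d_r)
        z0 = cand_idx[keep]
        out[z0[:, 0], z0[:, 1], z0[:, 2]] = 1
    return out, outer3d


def _ref_radial_analytic(spec: PhantomSpec, support: np.ndarray) -> np.ndarray:
    """Radial thirds from the true arc angle (anterior = +y end of the arc)."""
    nz, ny, nx = spec.grid_shape
    cy, cx = spec.arc_center_yx
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))
    half = spec.arc_span_deg / 2.0
    f = (half - theta) / spec.arc_span_deg          # 0 at anterior (+y) tip
    lab2d = np.where(f < 1.0 / 3.0, 1, np.where(f < 2.0 / 3.0, 2, 3)).astype(np.int16)
    out = np.where(support, lab2d[None, :, :], 0).astype(np.int16)
    return out


def _extend_by_nearest(label3d: np.ndarray, organ: np.ndarray, shell: np.ndarray,
                       spacing) -> np.ndarray:
    idx = ndimage.distance_transform_edt(~organ, sampling=spacing,
                                         return_distances=False, return_indices=True)
    out = label3d.copy()
    sel = shell & ~organ
    out[sel] = label3d[tuple(idx[i][sel] for i in range(3))]
    return out


@dataclass
class PhantomGroundTruth:
    """Exact ground truth of a generated phantom (see module docstring)."""

    spec: PhantomSpec
    organ_mask: np.ndarray
    vessel_mask_true: np.ndarray
    segments_true: list[TrueSegment]

    @cached_property
    def zone_maps_true(self) -> dict[str, np.ndarray]:
        """Reference label volumes: layer, circ (with zone-0 shell), radial,
        plus shell-extended layer/radial maps."""
        spacing = np.asarray(self.spec.spacing_um, float)
        layer = _ref_layers(self.organ_mask)
        circ, _ = _ref_circumferential(self.organ_mask, self.spec.margin_um, spacing)
        shell = circ == 1
        radial = _ref_radial_analytic(self.spec, self.organ_mask)
        return {
            "layer": layer,
            "circumferential": circ,
            "radial": radial,
            "layer_extended": _extend_by_nearest(layer, self.organ_mask, shell, spacing),
            "radial_extended": _ref_radial_analytic(self.spec, self.organ_mask | shell),
        }

    @cached_property
    def per_zone_vessel_voxels(self) -> pd.DataFrame:
        """Tidy (layer, axis, zone, vessel_voxels) ground-truth counts."""
        maps = self.zone_maps_true
        vz = self.vessel_mask_true
        rows = []
        for axis, zmap, names in (
            ("circumferential", maps["circumferential"], CIRC_LABELS),
            ("radial", maps["radial_extended"], RADIAL_LABELS),
        ):
            for lcode, lname in sorted(LAYER_LABELS.items()):
                in_layer = vz & (maps["layer_extended"] == lcode)
                for zcode, zname in sorted(names.items()):
                    rows.append({
                        "layer": lname, "axis": axis, "zone": zname,
                        "vessel_voxels": int(np.count_nonzero(in_layer & (zmap == zcode))),
                    })
        return pd.DataFrame(rows)

    @cached_property
    def per_layer_segment_counts(self) -> dict[str, int]:
        """True segment count per transverse layer (majority of polyline voxels)."""
        maps = self.zone_maps_true
        counts = {name: 0 for name in LAYER_LABELS.values()}
        shape = np.asarray(self.spec.grid_shape) - 1
        for seg in self.segments_true:
            vox = np.clip(np.rint(seg.polyline_vox).astype(int), 0, shape)
            codes = maps["layer_extended"][vox[:, 0], vox[:, 1], vox[:, 2]]
            codes = codes[codes > 0]
            if codes.size == 0:
                continue
            cnt = np.bincount(codes, minlength=4)[1:4]
            winners = np.nonzero(cnt == cnt.max())[0] + 1
            code = 2 if len(winners) > 1 else int(winners[0])
            counts[LAYER_LABELS[code]] += 1
        return counts


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[GrayVolume, PhantomGroundTruth]:
    """Render a phantom volume and its exact ground truth.

    The same spec (including seed) always produces bit-identical output.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    organ = _organ_mask(spec)
    segments = _grow_trees(spec, rng) if spec.n_trees > 0 else []

    vessel = np.zeros(spec.grid_shape, dtype=bool)
    kept_segments = []
    for seg in segments:
        tube = place_tube(seg.polyline_vox, seg.radius_um, spec.spacing_um, spec.grid_shape)
        if tube.any():
            vessel |= tube
            kept_segments.append(seg)

    vol = np.full(spec.grid_shape, float(spec.background_intensity))
    vol[organ] = spec.tissue_intensity
    vol[vessel] = spec.vessel_intensity
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    truth = PhantomGroundTruth(spec=spec, organ_mask=organ, vessel_mask_true=vessel,
                               segments_true=kept_segments)
    return GrayVolume(vol, spec.spacing_um), truth
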