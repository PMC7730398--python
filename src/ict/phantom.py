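"""Synthetic spruce micro-CT phantoms with known geometry and deformation.

The phantom emulates one earlywood-to-latewood (EW->LW) growth-ring cycle of
Norway spruce as imaged by synchrotron micro-CT: a honeycomb-like lattice of
axially (Z = L) aligned tracheid lumen tubes whose radial diameter, in-plane
aspect ratio and wall thickness grade smoothly across the radial (X = R)
coordinate, ending in a sharp LW/EW discontinuity; radial (X-aligned) wood-ray
lumen tubes grouped into clusters; pit-shaped wall indentations that break the
axial symmetry of tracheids and serve as tracking landmarks; Gaussian blur to
the instrument's effective resolution; and additive acquisition noise.

Every generated feature is recorded in a :class:`GroundTruth` object so each
downstream stage (segmentation, parameterization, tracking, strain fields)
can be validated against exact geometry and exact displacement fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "GeometryError",
    "generate_phantom",
    "apply_affine_deformation",
    "apply_compression_band",
    "add_acquisition_noise",
]


class GeometryError(ValueError):
    """Raised when a phantom specification cannot be realized."""


@dataclass
class GrayVolume:
    """8-bit grayscale volume with isotropic voxel size in micrometres.

    Axis order is (x, y, z) = (R, T, L).
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim} axes")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.data.shape, dtype=float) * self.voxel_size


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and acquisition parameters of the synthetic spruce volume.

    Lengths are micrometres, intensities 8-bit counts.  ``ring_width=None``
    maps one full EW->LW ring onto the volume's R extent so both cell
    populations are present at desk scale.
    """

    volume_shape: tuple[int, int, int] = (300, 300, 600)
    voxel_size: float = 1.62
    ring_width: float | None = None
    lumen_diameter_range: tuple[float, float] = (22.0, 48.0)  # (LW min, EW max), R axis
    lumen_aspect_RT: tuple[float, float] = (1.6, 1.3)  # (EW, LW)
    wall_thickness_range: tuple[float, float] = (3.4, 4.2)  # (EW, LW)
    ray_lumen_range: tuple[float, float] = (5.0, 13.0)
    ray_voxel_fraction_target: float = 0.01
    pit_density: float = 2.0  # pits per 100 um of cell length
    pit_diameter_range: tuple[float, float] = (4.0, 8.0)
    blur_fwhm: float = 3.0
    noise_sd: float = 8.0
    texture_sd: float = 6.0  # static material-density texture, 8-bit counts
    texture_corr: float = 2.0  # texture correlation length, voxels
    wall_intensity: float = 190.0
    lumen_intensity: float = 60.0
    lattice_jitter: float = 0.1  # fraction of local pitch, additionally capped by wall
    lumen_superellipse_n: float = 4.0  # 2 = ellipse; 4 = rounded-rectangle lumens
    resin_canal: bool = False
    resin_canal_diameter: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        shape = np.asarray(self.volume_shape)
        if shape.shape != (3,) or np.any(shape < 8):
            raise GeometryError("volume_shape must be three positive extents")
        for name in (
            "voxel_size",
            "pit_density",
            "blur_fwhm",
            "noise_sd",
        ):
            if getattr(self, name) < 0 or (name == "voxel_size" and self.voxel_size <= 0):
                raise GeometryError(f"{name} must be non-negative")
        for name in ("lumen_diameter_range", "wall_thickness_range", "ray_lumen_range",
                     "pit_diameter_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise GeometryError(f"{name} must satisfy 0 < low <= high")
        if not (0 < self.ray_voxel_fraction_target <= 0.05):
            raise GeometryError("ray_voxel_fraction_target must be in (0, 0.05]")
        for name in ("wall_intensity", "lumen_intensity"):
            if not (0 <= getattr(self, name) <= 255):
                raise GeometryError(f"{name} must be an 8-bit intensity")
        extent = shape * self.voxel_size
        d_max = self.lumen_diameter_range[1]
        if d_max + 2 * self.wall_thickness_range[1] > min(extent[0], extent[1]):
            raise GeometryError(
                "lumen plus wall exceeds the in-plane extent; enlarge volume_shape"
            )

    @property
    def ring_width_um(self) -> float:
        if self.ring_width is not None:
            return float(self.ring_width)
        return float(self.volume_shape[0] * self.voxel_size)

    # piecewise ring profiles: p in [0, 1) runs EW -> LW within one ring
    def lumen_diameter_R(self, p: np.ndarray | float) -> np.ndarray | float:
        lw, ew = self.lumen_diameter_range
        return ew + (lw - ew) * np.asarray(p, dtype=float)

    def aspect_RT(self, p: np.ndarray | float) -> np.ndarray | float:
        ew, lw = self.lumen_aspect_RT
        return ew + (lw - ew) * np.asarray(p, dtype=float)

    def wall_thickness(self, p: np.ndarray | float) -> np.ndarray | float:
        ew, lw = self.wall_thickness_range
        return ew + (lw - ew) * np.asarray(p, dtype=float)


def _ring_position(x_um: np.ndarray | float, ring: float) -> np.ndarray | float:
    return np.mod(x_um, ring) / ring


def _wave(s_um: np.ndarray | float, amp: float, lam: float, phase: float):
    """Gentle axial undulation of a tube centreline (um)."""
    return amp * np.sin(2.0 * np.pi * np.asarray(s_um, dtype=float) / lam + phase)


def _accumulate_cover(crop: np.ndarray, signed_dist_px: np.ndarray) -> None:
    """Fold a feature's partial-volume coverage into the air-fraction field.

    Coverage is the linear partial-volume model clip(0.5 + d, 0, 1) of the
    signed boundary distance in voxels; features are disjoint air bodies, so
    union by maximum.  Rendering coverage instead of a binary mask preserves
    the sub-voxel position of every wall face, which is what nanometre-scale
    displacement tracking measures.
    """
    cov = np.clip(0.5 + signed_dist_px, 0.0, 1.0).astype(np.float32)
    np.maximum(crop, cov, out=crop)


@dataclass
class _AffineDeformation:
    strain: np.ndarray  # symmetric 3x3
    center: np.ndarray  # um

    def forward(self, pts: np.ndarray) -> np.ndarray:
        return self.center + (pts - self.center) @ (np.eye(3) + self.strain).T


@dataclass
class _BandDeformation:
    center_z: float  # um
    width: float  # um, equivalent width of the Gaussian strain profile
    peak_strain: float
    shear_rt: float

    def strain_zz(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.peak_strain * np.exp(-np.pi * ((z - self.center_z) / self.width) ** 2)

    def u_z(self, z: np.ndarray) -> np.ndarray:
        """Axial displacement: integral of the strain profile from 0 to z."""
        from scipy.special import erf

        z = np.asarray(z, dtype=float)
        s = self.width / np.sqrt(np.pi) / np.sqrt(2.0)
        amp = self.peak_strain * self.width / 2.0

        def cdf(v):
            return erf((v - self.center_z) / (s * np.sqrt(2.0)))

        return amp * (cdf(z) - cdf(0.0))

    def u_x(self, z: np.ndarray) -> np.ndarray:
        """Linear in-plane shift above the band producing cross-grain shear."""
        z = np.asarray(z, dtype=float)
        zb = self.center_z + self.width / 2.0
        return self.shear_rt * np.maximum(z - zb, 0.0)

    def forward(self, pts: np.ndarray) -> np.ndarray:
        out = np.array(pts, dtype=float, copy=True)
        out[..., 2] += self.u_z(pts[..., 2])
        out[..., 0] += self.u_x(pts[..., 2])
        return out


@dataclass
class GroundTruth:
    """Exact geometry and deformation state of a phantom.

    ``labels`` is the lumen label volume in the *reference* (undeformed)
    frame; ``cells`` one row per cell with analytic geometry.  The applied
    deformation is stored as the exact chain of maps used for resampling, so
    ``displacement`` and ``strain_tensor`` are analytic, not interpolated.
    """

    labels: np.ndarray
    cells: pd.DataFrame
    voxel_size: float
    deformations: list = field(default_factory=list)

    def copy(self) -> "GroundTruth":
        return GroundTruth(self.labels, self.cells, self.voxel_size,
                           list(self.deformations))

    # -- deformation bookkeeping ------------------------------------------
    def forward_map(self, pts_um: np.ndarray) -> np.ndarray:
        """Map reference-frame points (um) to their deformed positions."""
        pts = np.asarray(pts_um, dtype=float)
        out = pts
        for d in self.deformations:
            out = d.forward(out)
        return out

    def displacement(self, pts_um: np.ndarray) -> np.ndarray:
        """Exact displacement u_true (um) at reference-frame points."""
        pts = np.asarray(pts_um, dtype=float)
        return self.forward_map(pts) - pts

    @property
    def is_affine(self) -> bool:
        return all(isinstance(d, _AffineDeformation) for d in self.deformations)

    @property
    def strain_tensor(self) -> np.ndarray:
        """Total small-strain tensor for an affine deformation chain."""
        if not self.is_affine:
            raise ValueError("strain tensor is a field for non-affine deformations")
        F = np.eye(3)
        for d in self.deformations:
            F = (np.eye(3) + d.strain) @ F
        return 0.5 * (F + F.T) - np.eye(3)

    def deformed_labels(self) -> np.ndarray:
        """Ground-truth labels resampled into the deformed frame (nearest)."""
        if not self.deformations:
            return self.labels
        shape = self.labels.shape
        idx = np.indices(shape, dtype=np.float32)
        pts = np.stack([idx[0], idx[1], idx[2]], axis=-1) * self.voxel_size
        # invert the forward chain numerically: for affine chains use the
        # exact inverse, otherwise fixed-point iteration on u
        if self.is_affine:
            F = np.eye(3)
            c_eff = np.zeros(3)
            for d in self.deformations:
                M = np.eye(3) + d.strain
                c_eff = M @ c_eff + (np.eye(3) - M) @ d.center
                F = M @ F
            inv = np.linalg.inv(F)
            src = (pts.reshape(-1, 3) - c_eff) @ inv.T
        else:
            src = pts.reshape(-1, 3).copy()
            for _ in range(8):
                src = pts.reshape(-1, 3) - self.displacement(src)
        coords = (src / self.voxel_size).T.reshape(3, *shape)
        return ndi.map_coordinates(self.labels, coords, order=0, mode="constant")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _lattice_cells(spec: PhantomSpec, rng: np.random.Generator,
                   forbidden_y: list[tuple[float, float]]) -> pd.DataFrame:
    """Place tracheid ellipse centers on a jittered EW->LW graded lattice."""
    ring = spec.ring_width_um
    ext = np.asarray(spec.volume_shape, dtype=float) * spec.voxel_size
    rows = []
    x = 0.0
    col = 0
    while x < ext[0]:
        p0 = float(_ring_position(x, ring))
        d_r = float(spec.lumen_diameter_R(p0))
        t = float(spec.wall_thickness(p0))
        pitch_x = d_r + 2 * t
        cx = x + pitch_x / 2.0
        p = float(_ring_position(cx, ring))
        d_r = float(spec.lumen_diameter_R(p))
        asp = float(spec.aspect_RT(p))
        t = float(spec.wall_thickness(p))
        d_t = d_r / asp
        pitch_y = d_t + 2 * t
        y = 0.0
        row = 0
        while y < ext[1]:
            cy = y + pitch_y / 2.0
            lo = cy - d_t / 2.0 - t
            hi = cy + d_t / 2.0 + t
            blocked = next((b for b in forbidden_y if lo < b[1] and hi > b[0]), None)
            if blocked is not None:
                y = blocked[1] + 0.25  # epsilon guards float round-off
                continue
            jx = min(spec.lattice_jitter * pitch_x, 0.3 * t)
            jy = min(spec.lattice_jitter * pitch_y, 0.3 * t)
            ccx = cx + rng.uniform(-jx, jx)
            ccy = cy + rng.uniform(-jy, jy)
            # gentle centreline undulation along L: real tracheids are not
            # perfectly straight, and the undulation spreads the sub-voxel
            # phase of the wall faces (a perfectly grid-aligned face would
            # quantize to the voxel grid)
            # amplitude ~half a voxel so each wall face sweeps a full
            # sub-voxel phase along L; wavelengths shorter than a cell span
            wax, way = rng.uniform(0.6, 0.85, size=2)
            wlx, wly = rng.uniform(60.0, 160.0, size=2)
            wpx, wpy = rng.uniform(0.0, 2.0 * np.pi, size=2)
            # keep only laterally complete lumens: cells whose lumen would be
            # cut by an X/Y face are left as wall substance
            if not (
                ccx - d_r / 2.0 - wax > 1.0
                and ccx + d_r / 2.0 + wax < ext[0] - 1.0
                and ccy - d_t / 2.0 - way > 1.0
                and ccy + d_t / 2.0 + way < ext[1] - 1.0
            ):
                y += pitch_y
                row += 1
                continue
            rows.append(
                dict(
                    cx=ccx,
                    cy=ccy,
                    a=d_r / 2.0,
                    b=d_t / 2.0,
                    wall=t,
                    ring_pos=p,
                    column=col,
                    row=row,
                    wave_ax=wax, wave_lx=wlx, wave_px=wpx,
                    wave_ay=way, wave_ly=wly, wave_py=wpy,
                )
            )
            y += pitch_y
            row += 1
        x += pitch_x
        col += 1
    return pd.DataFrame(rows)


def _rasterize_lumens(cells: pd.DataFrame, shape, voxel: float,
                      n_exp: float = 4.0, cover: np.ndarray | None = None) -> np.ndarray:
    """Fill wavy superellipse lumen tubes (n=4: rounded rectangles)."""
    labels = np.zeros(shape, dtype=np.int32)
    z_um = (np.arange(shape[2], dtype=float)) * voxel
    for i, c in enumerate(cells.itertuples(), start=1):
        dx = _wave(z_um, c.wave_ax, c.wave_lx, c.wave_px) / voxel
        dy = _wave(z_um, c.wave_ay, c.wave_ly, c.wave_py) / voxel
        a_px, b_px = c.a / voxel, c.b / voxel
        cx_px, cy_px = c.cx / voxel, c.cy / voxel
        pad = float(np.max(np.abs(dx)) + np.max(np.abs(dy)))
        x0 = max(int(np.floor(cx_px - a_px - pad)) - 1, 0)
        x1 = min(int(np.ceil(cx_px + a_px + pad)) + 2, shape[0])
        y0 = max(int(np.floor(cy_px - b_px - pad)) - 1, 0)
        y1 = min(int(np.ceil(cy_px + b_px + pad)) + 2, shape[1])
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1, dtype=float)[:, None, None]
        ys = np.arange(y0, y1, dtype=float)[None, :, None]
        u = (xs - cx_px - dx[None, None, :]) / a_px
        v = (ys - cy_px - dy[None, None, :]) / b_px
        F = np.abs(u) ** n_exp + np.abs(v) ** n_exp
        inside = F <= 1.0
        crop = labels[x0:x1, y0:y1, :]
        crop[inside] = i
        if cover is not None:
            # signed distance to the implicit boundary (voxels), first order
            gradF = n_exp * np.hypot(
                np.abs(u) ** (n_exp - 1) / a_px, np.abs(v) ** (n_exp - 1) / b_px
            )
            d = (1.0 - F) / np.maximum(gradF, 1e-6)
            _accumulate_cover(cover[x0:x1, y0:y1, :], d)
    return labels


def _plan_rays(spec: PhantomSpec, rng: np.random.Generator):
    """Choose ray corridors and clusters to hit the ray voxel fraction."""
    ext = np.asarray(spec.volume_shape, dtype=float) * spec.voxel_size
    voxel = spec.voxel_size
    total_vox = float(np.prod(spec.volume_shape))
    r_lo, r_hi = spec.ray_lumen_range[0] / 2.0, spec.ray_lumen_range[1] / 2.0
    mean_r = 0.5 * (r_lo + r_hi)
    tube_vox = np.pi * (mean_r / voxel) ** 2 * spec.volume_shape[0]
    target_vox = spec.ray_voxel_fraction_target * total_vox
    mean_cluster_tubes = 4.5
    n_clusters = max(2, int(round(target_vox / (tube_vox * mean_cluster_tubes))))

    corridor_w = spec.ray_lumen_range[1] + 9.0  # lumen + ray wall + margin, um
    max_corridors = max(1, int(ext[1] // (corridor_w + 60.0)))
    n_corridors = int(np.clip(int(np.ceil(n_clusters / 4)), 1, max_corridors))
    ys = []
    margin = corridor_w
    for _ in range(200):
        if len(ys) >= n_corridors:
            break
        y = rng.uniform(margin, ext[1] - margin)
        if all(abs(y - y0) > corridor_w + 40.0 for y0 in ys):
            ys.append(y)
    corridors = sorted(ys)

    clusters = []
    cid = 0
    per = int(np.ceil(n_clusters / len(corridors)))
    for yc in corridors:
        z_slots: list[tuple[float, float]] = []
        for _ in range(per):
            n_tubes = int(rng.integers(3, 7))
            radii = rng.uniform(r_lo, r_hi, size=n_tubes)
            wall = 5.0
            height = float(np.sum(2 * radii) + wall * (n_tubes - 1))
            ok = None
            for _try in range(40):
                z0 = rng.uniform(2.0, max(ext[2] - height - 2.0, 3.0))
                if all(z0 + height + 30.0 < a or z0 > b + 30.0 for a, b in z_slots):
                    ok = z0
                    break
            if ok is None:
                continue
            z_slots.append((ok, ok + height))
            cid += 1
            zc = ok
            tubes = []
            for r in radii:
                tubes.append(dict(y=yc, z=zc + r, r=float(r)))
                zc += 2 * r + wall
            clusters.append(dict(cluster=cid, corridor=yc, tubes=tubes))
    bands = [(y - corridor_w / 2.0, y + corridor_w / 2.0) for y in corridors]
    return clusters, bands


def _rasterize_rays(clusters, spec: PhantomSpec, rng: np.random.Generator,
                    labels: np.ndarray, next_label: int,
                    cover: np.ndarray | None = None) -> list[dict]:
    """Stamp ray lumen tubes (X-aligned, modulated radius) into ``labels``."""
    voxel = spec.voxel_size
    nx, ny, nz = labels.shape
    xs_um = (np.arange(nx) + 0.5) * voxel
    ray_rows = []
    for cl in clusters:
        for tube in cl["tubes"]:
            lam1 = rng.uniform(24.0, 36.0)
            lam2 = rng.uniform(55.0, 85.0)
            ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
            r_x = tube["r"] * (
                1.0
                + 0.12 * np.sin(2 * np.pi * xs_um / lam1 + ph1)
                + 0.08 * np.sin(2 * np.pi * xs_um / lam2 + ph2)
            )
            r_px = r_x / voxel
            wy = _wave(xs_um, rng.uniform(0.10, 0.25), rng.uniform(90, 220),
                       rng.uniform(0, 2 * np.pi)) / voxel
            wz = _wave(xs_um, rng.uniform(0.10, 0.25), rng.uniform(90, 220),
                       rng.uniform(0, 2 * np.pi)) / voxel
            yc, zc = tube["y"] / voxel, tube["z"] / voxel
            rmax = float(np.max(r_px)) + float(np.max(np.abs(wy)) + np.max(np.abs(wz)))
            y0 = max(int(np.floor(yc - rmax)) - 1, 0)
            y1 = min(int(np.ceil(yc + rmax)) + 2, ny)
            z0 = max(int(np.floor(zc - rmax)) - 1, 0)
            z1 = min(int(np.ceil(zc + rmax)) + 2, nz)
            if y0 >= y1 or z0 >= z1:
                continue
            yg = np.arange(y0, y1)[None, :, None]
            zg = np.arange(z0, z1)[None, None, :]
            d2 = (yg - yc - wy[:, None, None]) ** 2 + (zg - zc - wz[:, None, None]) ** 2
            inside = d2 <= (r_px[:, None, None]) ** 2
            crop = labels[:, y0:y1, z0:z1]
            inside &= crop == 0
            crop[inside] = next_label
            if cover is not None:
                d = r_px[:, None, None] - np.sqrt(d2)
                _accumulate_cover(cover[:, y0:y1, z0:z1], d)
            ray_rows.append(
                dict(
                    label=next_label,
                    category="ray",
                    cx=float(nx * voxel / 2.0),
                    cy=tube["y"],
                    cz=tube["z"],
                    a=tube["r"],
                    b=tube["r"],
                    wall=5.0,
                    ring_pos=np.nan,
                    cluster=cl["cluster"],
                )
            )
            next_label += 1
    return ray_rows


def _stamp_pits(spec: PhantomSpec, rng: np.random.Generator, labels: np.ndarray,
                cells: pd.DataFrame, ray_mask: np.ndarray,
                cover: np.ndarray | None = None) -> int:
    """Carve hemispherical lumen-side pits into tracheid walls."""
    voxel = spec.voxel_size
    nx, ny, nz = labels.shape
    ext_z = nz * voxel
    n_total = 0
    p_lo, p_hi = (d / 2.0 for d in spec.pit_diameter_range)
    for c in cells.itertuples():
        if c.category != "tracheid":
            continue
        n_pits = rng.poisson(spec.pit_density * ext_z / 100.0)
        for _ in range(n_pits):
            zc = rng.uniform(4.0, ext_z - 4.0) / voxel
            phi = rng.uniform(0, 2 * np.pi)
            r_um = rng.uniform(p_lo, p_hi)
            r_px = r_um / voxel
            e = 2.0 / spec.lumen_superellipse_n
            u, v = np.cos(phi), np.sin(phi)
            bx = np.sign(u) * np.abs(u) ** e
            by = np.sign(v) * np.abs(v) ** e
            zum = zc * voxel
            dx = float(_wave(zum, c.wave_ax, c.wave_lx, c.wave_px))
            dy = float(_wave(zum, c.wave_ay, c.wave_ly, c.wave_py))
            cx = (c.cx + dx + c.a * bx) / voxel
            cy = (c.cy + dy + c.b * by) / voxel
            x0, x1 = int(np.floor(cx - r_px)) - 1, int(np.ceil(cx + r_px)) + 2
            y0, y1 = int(np.floor(cy - r_px)) - 1, int(np.ceil(cy + r_px)) + 2
            z0, z1 = int(np.floor(zc - r_px)) - 1, int(np.ceil(zc + r_px)) + 2
            if x0 < 0 or y0 < 0 or z0 < 0 or x1 > nx or y1 > ny or z1 > nz:
                continue
            d2 = (
                (np.arange(x0, x1)[:, None, None] - cx) ** 2
                + (np.arange(y0, y1)[None, :, None] - cy) ** 2
                + (np.arange(z0, z1)[None, None, :] - zc) ** 2
            )
            sphere = d2 <= r_px**2
            # keep clear of ray lumens (1-voxel guard)
            rcrop = ray_mask[max(x0 - 1, 0):x1 + 1, max(y0 - 1, 0):y1 + 1,
                             max(z0 - 1, 0):z1 + 1]
            if rcrop.any():
                continue
            crop = labels[x0:x1, y0:y1, z0:z1]
            # a pit must not bridge into a neighbouring lumen (2-voxel guard
            # against blur-induced merging of binarized lumens)
            near = d2 <= (r_px + 2.0) ** 2
            if np.any(near & (crop != 0) & (crop != c.label)):
                continue
            stamp = sphere & ((crop == 0) | (crop == c.label))
            crop[stamp] = c.label
            if cover is not None:
                d = r_px - np.sqrt(d2)
                _accumulate_cover(cover[x0:x1, y0:y1, z0:z1], d)
            n_total += 1
    return n_total


def generate_phantom(spec: PhantomSpec) -> tuple[GrayVolume, GroundTruth]:
    """Generate the synthetic softwood volume and its ground truth.

    Returns an 8-bit :class:`GrayVolume` (blurred, noisy) and a
    :class:`GroundTruth` whose ``labels`` hold the exact lumen geometry,
    with ``u_true = 0`` and ``eps_true = 0``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_ray, rng_pit, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    shape = tuple(int(s) for s in spec.volume_shape)
    voxel = spec.voxel_size

    clusters, forbidden = _plan_rays(spec, rng_ray)
    cells = _lattice_cells(spec, rng_geom, forbidden)
    if spec.resin_canal:
        ext = np.asarray(shape) * voxel
        rc = dict(cx=0.3 * ext[0], cy=0.5 * ext[1], r=spec.resin_canal_diameter / 2.0)
        keep = (
            np.hypot(cells.cx - rc["cx"], cells.cy - rc["cy"])
            > rc["r"] + cells.a + cells.wall
        )
        cells = cells[keep].reset_index(drop=True)
    if len(cells) < 20:
        # minimum in-plane extent for a ~5x4 lattice of the largest cells
        d = spec.lumen_diameter_range[1] + 2 * spec.wall_thickness_range[1]
        min_px = int(np.ceil(5 * d / voxel))
        raise GeometryError(
            f"volume too small: only {len(cells)} tracheids fit; "
            f"need in-plane extents of at least ~({min_px}, {min_px}) voxels"
        )
    cells = cells.copy()
    cells["label"] = np.arange(1, len(cells) + 1, dtype=np.int32)
    cells["category"] = "tracheid"

    # partial-volume (anti-aliased) air-fraction field; in the hard two-phase
    # limit (blur 0) the image is rendered from the voxel masks instead
    cover = np.zeros(shape, dtype=np.float32) if spec.blur_fwhm > 0 else None
    labels = _rasterize_lumens(cells, shape, voxel, spec.lumen_superellipse_n,
                               cover=cover)

    next_label = len(cells) + 1
    if spec.resin_canal:
        ext = np.asarray(shape) * voxel
        rc_cx, rc_cy, rc_r = 0.3 * ext[0], 0.5 * ext[1], spec.resin_canal_diameter / 2.0
        xs = (np.arange(shape[0]) + 0.0) * voxel
        ys = (np.arange(shape[1]) + 0.0) * voxel
        rho = np.sqrt((xs[:, None] - rc_cx) ** 2 + (ys[None, :] - rc_cy) ** 2)
        disk = rho <= rc_r
        labels[disk, :] = next_label
        if cover is not None:
            _accumulate_cover(cover, ((rc_r - rho) / voxel)[:, :, None]
                              * np.ones((1, 1, shape[2]), np.float32))
        cells = pd.concat(
            [
                cells,
                pd.DataFrame(
                    [
                        dict(
                            cx=rc_cx, cy=rc_cy, a=rc_r, b=rc_r,
                            wall=spec.wall_thickness_range[0], ring_pos=0.3,
                            column=-1, row=-1, label=next_label,
                            category="resin_canal",
                        )
                    ]
                ),
            ],
            ignore_index=True,
        )
        next_label += 1

    ray_rows = _rasterize_rays(clusters, spec, rng_ray, labels, next_label,
                               cover=cover)
    if ray_rows:
        cells = pd.concat([cells, pd.DataFrame(ray_rows)], ignore_index=True)
    ray_mask = np.isin(labels, [r["label"] for r in ray_rows]) if ray_rows else \
        np.zeros(shape, bool)

    _stamp_pits(spec, rng_pit, labels, cells, ray_mask, cover=cover)

    if cover is not None:
        img = spec.wall_intensity + (
            spec.lumen_intensity - spec.wall_intensity
        ) * cover
        if spec.texture_sd > 0:
            # static sub-voxel density texture of the material: real cell-wall
            # substance is heterogeneous, and the texture both dithers the
            # binarization threshold and provides correlation landmarks; it
            # deforms with the structure, like real density fluctuations
            tex = ndi.gaussian_filter(
                rng_geom.normal(0.0, 1.0, size=shape).astype(np.float32),
                spec.texture_corr,
            )
            tex *= spec.texture_sd / max(float(tex.std()), 1e-9)
            img = img + tex
        sigma = spec.blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel
        img = ndi.gaussian_filter(img, sigma)
    else:
        img = np.full(shape, spec.wall_intensity, dtype=np.float32)
        img[labels > 0] = spec.lumen_intensity
    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    vol = GrayVolume(np.clip(np.round(img), 0, 255).astype(np.uint8), voxel)

    from scipy.special import gamma as _gamma

    n_exp = spec.lumen_superellipse_n
    shape_factor = 4.0 * _gamma(1 + 1 / n_exp) ** 2 / _gamma(1 + 2 / n_exp)
    area = np.where(
        cells.category.to_numpy() == "ray",
        np.pi * cells.a.to_numpy() * cells.b.to_numpy(),
        shape_factor * cells.a.to_numpy() * cells.b.to_numpy(),
    )
    cells["lumen_area"] = area  # analytic cross-section area, um^2

    cells = cells.set_index("label", drop=False)
    gt = GroundTruth(labels=labels, cells=cells, voxel_size=voxel)
    return vol, gt


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def apply_affine_deformation(
    vol: GrayVolume,
    gt: GroundTruth,
    strain: np.ndarray,
    center: np.ndarray | None = None,
) -> tuple[GrayVolume, GroundTruth]:
    """Resample ``vol`` through the affine map x -> c + (I + eps)(x - c).

    ``strain`` must be a symmetric 3x3 small-strain tensor (rotations are not
    accepted here so the ground-truth strain stays well defined).  The
    ground truth is updated with the exact map used for resampling; repeated
    applications compose.
    """
    strain = np.asarray(strain, dtype=float)
    if strain.shape != (3, 3):
        raise ValueError("strain must be a 3x3 tensor")
    if not np.allclose(strain, strain.T, atol=1e-12):
        raise ValueError("strain must be symmetric; pass rotations separately")
    if np.max(np.abs(strain)) >= 0.5:
        raise ValueError("|strain components| must be < 0.5")
    if center is None:
        center = 0.5 * np.asarray(vol.shape, dtype=float) * vol.voxel_size
    center = np.asarray(center, dtype=float)

    M = np.eye(3) + strain
    Minv = np.linalg.inv(M)
    c_px = center / vol.voxel_size
    offset = c_px - Minv @ c_px
    data = ndi.affine_transform(
        vol.data.astype(np.float32), Minv, offset=offset, order=3, mode="nearest"
    )
    out = GrayVolume(np.clip(np.round(data), 0, 255).astype(np.uint8), vol.voxel_size)
    gt2 = gt.copy()
    gt2.deformations.append(_AffineDeformation(strain=strain, center=center))
    return out, gt2


def apply_compression_band(
    vol: GrayVolume,
    gt: GroundTruth,
    band_center_z: float,
    band_width: float,
    peak_strain_LL: float,
    shear_RT: float = 0.0,
) -> tuple[GrayVolume, GroundTruth]:
    """Apply a non-affine axial compression band (densification plane).

    The axial strain follows a Gaussian profile of equivalent width
    ``band_width`` centred at ``band_center_z`` with peak ``peak_strain_LL``
    (so the total shortening is ``|peak| * band_width``); ``shear_RT`` adds a
    linear X shift above the band.  Lengths in micrometres.
    """
    ext_z = vol.shape[2] * vol.voxel_size
    if not (0 <= band_center_z <= ext_z):
        raise ValueError("band outside volume")
    if not (-0.8 < peak_strain_LL <= 0.0):
        raise ValueError("peak_strain_LL must be in (-0.8, 0]")
    band = _BandDeformation(band_center_z, band_width, peak_strain_LL, shear_RT)
    gt2 = gt.copy()
    gt2.deformations.append(band)
    if peak_strain_LL == 0.0 and shear_RT == 0.0:
        return GrayVolume(vol.data.copy(), vol.voxel_size), gt2

    voxel = vol.voxel_size
    nz = vol.shape[2]
    z_out = (np.arange(nz, dtype=float)) * voxel
    # invert z -> z + u_z(z) on a fine monotone grid
    z_fine = np.linspace(-band_width, ext_z + band_width, 8 * nz)
    fwd = z_fine + band.u_z(z_fine)
    z_in = np.interp(z_out, fwd, z_fine)
    x_shift = band.u_x(z_in) / voxel  # px, subtracted from x coordinate

    xi = np.arange(vol.shape[0], dtype=np.float32)
    yi = np.arange(vol.shape[1], dtype=np.float32)
    coords = np.empty((3, *vol.shape), dtype=np.float32)
    coords[0] = xi[:, None, None] - x_shift[None, None, :].astype(np.float32)
    coords[1] = yi[None, :, None]
    coords[2] = (z_in / voxel)[None, None, :].astype(np.float32)
    data = ndi.map_coordinates(vol.data.astype(np.float32), coords, order=3,
                               mode="nearest")
    out = GrayVolume(np.clip(np.round(data), 0, 255).astype(np.uint8), voxel)
    return out, gt2


def add_acquisition_noise(vol: GrayVolume, noise_sd: float, seed: int) -> GrayVolume:
    """Add independent clipped Gaussian acquisition noise (deterministic per seed)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return GrayVolume(vol.data.copy(), vol.voxel_size)
    rng = np.random.default_rng(seed)
    data = vol.data.astype(np.float32) + rng.normal(0, noise_sd, vol.shape)
    return GrayVolume(np.clip(np.round(data), 0, 255).astype(np.uint8), vol.voxel_size)
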