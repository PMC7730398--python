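"""One-dimensional parameterization of tubular cells.

Each cell is reduced to per-slice records along its tube axis (Z = L for
tracheids, X = R for wood rays after transposition): lumen centroid (c_X,
c_Y), area Sigma, perimeter P, skeletonized cross-section area/perimeter
(Sigma_sk, P_sk, i.e. lumen plus owned wall out to the mid-wall), an
ellipse fit (e_a, e_b, e_Psi), the mean wall thickness t, and the local
inclination angle theta of the cell axis.  These per-slice channels are the
texture that the tracking stage correlates, so they are computed wherever
the slice cross-section is singly connected and hole-free.

Profiles are tidy tables: one row per (cell, slice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.interpolate import BSpline, make_smoothing_spline
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .segmentation import LabelVolume

__all__ = [
    "PROFILE_CHANNELS",
    "CellProfile",
    "parameterize_cell",
    "parameterize_all",
    "fit_ellipse",
    "wall_thickness",
    "inclination",
    "reslice_iterate",
    "smoothing_bandwidth_lambda",
]

#: per-slice geometry channels of the 1D cell representation i_p
PROFILE_CHANNELS = ["c_X", "c_Y", "sigma", "P", "e_a", "e_b", "e_psi", "t", "theta"]

_TABLE_COLUMNS = ["z", "valid", "c_X", "c_Y", "sigma", "P", "sigma_sk",
                  "P_sk", "e_a", "e_b", "e_psi"]


@dataclass
class CellProfile:
    """1D parameterization of one cell along its tube axis.

    ``table`` has one row per axis position with the geometry channels plus
    ``valid`` (single-connected, hole-free slice) and the skeletonized
    cross-section columns.  Lengths in micrometres, areas in um^2, angles in
    degrees.
    """

    cell_id: int
    category: str
    voxel_size: float
    table: pd.DataFrame
    axis: str = "z"
    untrackable: bool = False

    @property
    def n_valid(self) -> int:
        return int(self.table["valid"].sum())

    def channel_matrix(self, channels=PROFILE_CHANNELS) -> np.ndarray:
        return self.table[channels].to_numpy(dtype=float)


def smoothing_bandwidth_lambda(resolution_um: float, spacing_um: float) -> float:
    """Roughness penalty giving a cubic smoothing spline the requested bandwidth.

    The equivalent kernel of a cubic smoothing spline with penalty ``lam``
    fitted to data of spacing ``Delta`` has bandwidth h ~ (lam * Delta)^(1/4);
    inverting gives lam = h^4 / Delta.
    """
    return float(resolution_um**4 / spacing_um)


def _smooth_series(z_um: np.ndarray, y: np.ndarray, resolution_um: float,
                   spacing_um: float) -> BSpline:
    lam = smoothing_bandwidth_lambda(resolution_um, spacing_um)
    return make_smoothing_spline(z_um, y, lam=lam)


def fit_ellipse(mask: np.ndarray, voxel_size: float = 1.0):
    """Moments-equivalent ellipse of a 2D mask: (e_a, e_b, e_Psi).

    Axis lengths are 4*sqrt(eigenvalue) of the second central moment matrix,
    so a filled ellipse maps to itself; e_Psi is the major-axis angle from
    the first (X) image axis, degrees in (-90, 90], and 0 by convention for
    a circle (degenerate orientation).
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.sum()
    if n < 5:
        raise ValueError("mask too small for an ellipse fit (< 5 pixels)")
    xs, ys = np.nonzero(mask)
    mx, my = xs.mean(), ys.mean()
    cov = np.cov(np.stack([xs - mx, ys - my]), bias=True)
    w, v = np.linalg.eigh(cov)
    e_b, e_a = 4.0 * np.sqrt(np.maximum(w, 0.0))
    if (e_a - e_b) / max(e_a, 1e-12) < 1e-3:
        psi = 0.0
    else:
        major = v[:, 1]
        psi = np.degrees(np.arctan2(major[1], major[0]))
        if psi <= -90.0:
            psi += 180.0
        elif psi > 90.0:
            psi -= 180.0
    return e_a * voxel_size, e_b * voxel_size, psi


def wall_thickness(sigma, P, sigma_sk, P_sk, variant: str = "corrected"):
    """Mean cell-wall thickness from lumen and skeletonized cross-sections.

    The material ring between the lumen boundary (area Sigma, perimeter P)
    and the mid-wall territory boundary (Sigma_sk, P_sk) has width equal to
    the wall thickness t.  Dividing the ring area by the mean of the two
    perimeters measures that width exactly on a circular annulus:

        t = 2 (Sigma_sk - Sigma) / (P_sk + P)        [variant="corrected"]

    The alternative ``variant="printed"`` divides by (P_sk - P) instead; on
    an annulus that returns r_outer + r_inner rather than a thickness, and
    it is kept selectable only for comparison.  Both variants are
    homogeneous of degree one in lengths, so the wall-thickness *strain*
    under affine deformation does not depend on the choice.
    """
    sigma = np.asarray(sigma, dtype=float)
    P = np.asarray(P, dtype=float)
    sigma_sk = np.asarray(sigma_sk, dtype=float)
    P_sk = np.asarray(P_sk, dtype=float)
    if variant == "corrected":
        denom = P_sk + P
    elif variant == "printed":
        denom = P_sk - P
        denom = np.where(denom > 0, denom, np.nan)
    else:
        raise ValueError(f"unknown wall-thickness variant: {variant}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return 2.0 * (sigma_sk - sigma) / denom


def _psi_of(r) -> float:
    """Major-axis angle from the X (first) image axis, degrees in (-90, 90]."""
    e_a, e_b = r.axis_major_length, r.axis_minor_length
    if e_a <= 0 or (e_a - e_b) / e_a < 1e-3:
        return 0.0
    psi = np.degrees(float(r.orientation))
    if psi <= -90.0:
        psi += 180.0
    elif psi > 90.0:
        psi -= 180.0
    return float(psi)


def _slice_moments(lab2d: np.ndarray) -> dict[int, tuple]:
    """Centroid and moments-equivalent ellipse per label of one section.

    Vectorized over all labels via weighted bincounts (the per-region
    moment machinery dominates the profile sweep otherwise).  The ellipse
    axes are 4*sqrt(eigenvalue) of the second central moments; e_psi is the
    major-axis angle from +X, degrees in (-90, 90], 0 for degenerate.
    """
    flat = lab2d.reshape(-1)
    n = int(flat.max())
    if n == 0:
        return {}
    nx, ny = lab2d.shape
    xg = np.repeat(np.arange(nx, dtype=np.float64), ny)
    yg = np.tile(np.arange(ny, dtype=np.float64), nx)
    s0 = np.bincount(flat, minlength=n + 1).astype(np.float64)
    sx = np.bincount(flat, weights=xg, minlength=n + 1)
    sy = np.bincount(flat, weights=yg, minlength=n + 1)
    sxx = np.bincount(flat, weights=xg * xg, minlength=n + 1)
    syy = np.bincount(flat, weights=yg * yg, minlength=n + 1)
    sxy = np.bincount(flat, weights=xg * yg, minlength=n + 1)
    out = {}
    for i in np.nonzero(s0[1:])[0] + 1:
        m = s0[i]
        cx, cy = sx[i] / m, sy[i] / m
        mxx = sxx[i] / m - cx * cx
        myy = syy[i] / m - cy * cy
        mxy = sxy[i] / m - cx * cy
        tr2 = 0.5 * (mxx + myy)
        d = np.sqrt(max(0.25 * (mxx - myy) ** 2 + mxy * mxy, 0.0))
        lam1, lam2 = max(tr2 + d, 0.0), max(tr2 - d, 0.0)
        e_a, e_b = 4.0 * np.sqrt(lam1), 4.0 * np.sqrt(lam2)
        if e_a <= 0 or (e_a - e_b) / e_a < 1e-3:
            psi = 0.0
        else:
            psi = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
            if psi <= -90.0:
                psi += 180.0
            elif psi > 90.0:
                psi -= 180.0
        out[int(i)] = (cx, cy, e_a, e_b, psi)
    return out



def _territory_corrections(owner2d: np.ndarray, dist2d: np.ndarray,
                           voxel: float) -> np.ndarray:
    """Sub-voxel correction of territory areas at ownership midlines.

    The mid-wall boundary between two cells' territories is the locus where
    the distances to the two lumens are equal.  Voxel-wise ownership
    quantizes that boundary to the grid; interpolating the distance fields
    along each interface edge locates the true crossing and yields a signed
    area correction per label (px^2 per slice).
    """
    nmax = int(owner2d.max())
    corr = np.zeros(nmax + 1, dtype=np.float64)
    if nmax == 0:
        return corr
    d = dist2d / voxel  # voxel units
    for axis in (0, 1):
        a = owner2d[:-1, :] if axis == 0 else owner2d[:, :-1]
        b = owner2d[1:, :] if axis == 0 else owner2d[:, 1:]
        da = d[:-1, :] if axis == 0 else d[:, :-1]
        db = d[1:, :] if axis == 0 else d[:, 1:]
        m = (a > 0) & (b > 0) & (a != b)
        if not m.any():
            continue
        s = np.clip(0.5 * (db[m] - da[m] + 1.0), 0.0, 1.0) - 0.5
        np.add.at(corr, a[m], s)
        np.add.at(corr, b[m], -s)
    return corr


def _combined_labels(lv: LabelVolume) -> np.ndarray:
    if lv.wall_owner is None:
        raise ValueError("wall ownership not assigned; run assign_wall first")
    combined = lv.labels.copy()
    m = lv.wall_owner > 0
    combined[m] = lv.wall_owner[m]
    return combined


def _partial_volume_fields(lv: LabelVolume, intensity: np.ndarray,
                           band_vox: float = 2.5):
    """Air-fraction field and per-cell integration regions.

    The blurred two-phase image carries the exact sub-voxel geometry in its
    partial-volume values (blurring preserves integrals), so the air
    fraction (I_wall - I) / (I_wall - I_lumen) integrated over a cell's
    lumen plus a thin owned-wall band measures area and centroid with
    sub-voxel precision, and shared acquisition noise cancels in
    state-to-state differences.
    """
    lab = lv.labels
    lum = lab > 0
    i_lum = float(np.median(intensity[lum]))
    if lv.wall_owner is not None:
        far = (~lum) & (lv.wall_owner == 0)
    else:
        far = ~lum
    if not far.any():
        far = ~lum
    i_wall = float(np.median(intensity[far]))
    if i_wall <= i_lum:
        raise ValueError("wall is not brighter than lumen; check intensities")
    airfrac = np.clip(
        (i_wall - intensity.astype(np.float32)) / (i_wall - i_lum), 0.0, 1.0
    )
    pv_label = lab.copy()
    if lv.wall_owner is not None and lv.wall_dist is not None:
        band = (lv.wall_owner > 0) & (lv.wall_dist <= band_vox * lv.voxel_size)
        pv_label[band] = lv.wall_owner[band]
    return airfrac, pv_label


def parameterize_all(
    lv: LabelVolume,
    cell_ids=None,
    min_length: int = 82,
    wall_variant: str = "corrected",
    theta_resolution: float = 50.0,
    intensity: np.ndarray | None = None,
) -> dict[int, CellProfile]:
    """Parameterize cells slice-by-slice in one sweep over the volume.

    Returns ``{cell_id: CellProfile}``.  A slice record is valid only when
    the lumen section has single connectivity and no inner voids (Euler
    number 1) and its skeletonized section is likewise simple.  Cells with
    fewer than ``min_length`` valid slices are flagged untrackable.
    ``theta_resolution`` is the centroid smoothing bandwidth in voxels.

    When ``intensity`` (the grayscale volume, possibly denoised) is given,
    the centroid and lumen-area channels are refined with partial-volume
    (densitometric) estimates, which resolve sub-voxel boundary positions;
    the voxel-counting values are kept in ``*_bin`` columns and still feed
    the wall-thickness formula.
    """
    if cell_ids is None:
        cell_ids = [int(i) for i in lv.label_ids]
    wanted = set(int(i) for i in cell_ids)
    voxel = lv.voxel_size
    combined = _combined_labels(lv)
    labels = lv.labels
    nz = labels.shape[2]

    max_wall = (lv.params.max_wall_dist if lv.params is not None else 15.0)
    cap_records: dict[int, dict[int, bool]] = {i: {} for i in wanted}
    corr_records: dict[int, dict[int, float]] = {i: {} for i in wanted}

    pv = None
    if intensity is not None:
        airfrac, pv_label = _partial_volume_fields(lv, intensity)
        nx, ny = labels.shape[:2]
        xg = np.arange(nx, dtype=np.float64)[:, None]
        yg = np.arange(ny, dtype=np.float64)[None, :]
        pv = (airfrac, pv_label, xg, yg)

    records: dict[int, list] = {i: [] for i in wanted}
    pv_records: dict[int, dict[int, tuple]] = {i: {} for i in wanted}
    for z in range(nz):
        if pv is not None:
            airfrac, pv_label, xg, yg = pv
            pl = pv_label[:, :, z]
            af = airfrac[:, :, z].astype(np.float64)
            present = np.unique(pl)
            present = [int(i) for i in present if i > 0 and int(i) in wanted]
            if present:
                w = ndi.sum_labels(af, pl, index=present)
                wx = ndi.sum_labels(af * xg, pl, index=present)
                wy = ndi.sum_labels(af * yg, pl, index=present)
                for k, i in enumerate(present):
                    if w[k] > 1.0:
                        pv_records[i][z] = (w[k], wx[k] / w[k], wy[k] / w[k])
        if lv.wall_owner is not None and lv.wall_dist is not None:
            osl = lv.wall_owner[:, :, z]
            sk_corr = _territory_corrections(osl, lv.wall_dist[:, :, z],
                                             voxel)
            present_o = np.unique(osl)
            present_o = [int(i) for i in present_o if i > 0 and int(i) in wanted]
            if present_o:
                md = ndi.maximum(lv.wall_dist[:, :, z], osl, index=present_o)
                md = np.atleast_1d(md)
                on_face = set(
                    int(v)
                    for edge in (osl[0], osl[-1], osl[:, 0], osl[:, -1])
                    for v in np.unique(edge)
                    if v > 0
                )
                for k, i in enumerate(present_o):
                    # territory truncated by the ownership reach cap or by
                    # the volume face: those outer boundaries are metric,
                    # not material, and do not follow the deformation
                    cap_records[i][z] = bool(
                        md[k] >= 0.95 * max_wall or i in on_face
                    )
                    corr_records[i][z] = float(sk_corr[i]) \
                        if i < len(sk_corr) else 0.0
        lab2d = labels[:, :, z]
        moments = _slice_moments(lab2d)
        rp_sk = {r.label: r for r in regionprops(combined[:, :, z])}
        for r in regionprops(lab2d):
            i = int(r.label)
            if i not in wanted:
                continue
            valid = (r.euler_number == 1) and (r.area >= 5)
            rs = rp_sk.get(i)
            if rs is None:
                sk_area = sk_perim = np.nan
                valid = False
            else:
                sk_area, sk_perim = float(rs.area), float(rs.perimeter)
                valid = valid and (rs.euler_number == 1) and (rs.area >= r.area)
            cx, cy, e_a, e_b, e_psi = moments.get(
                i, (np.nan,) * 5
            )
            if not np.isfinite(e_a):
                valid = False
            records[i].append(
                (z, bool(valid), cx, cy, float(r.area),
                 float(r.perimeter), sk_area, sk_perim, e_a, e_b, e_psi)
            )

    profiles: dict[int, CellProfile] = {}
    for i in sorted(wanted):
        rows = records[i]
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=_TABLE_COLUMNS).set_index("z")
        df = df.reindex(range(int(df.index.min()), int(df.index.max()) + 1))
        df["valid"] = df["valid"].fillna(False).astype(bool)
        if pv is not None:
            pvr = pv_records[i]
            df["sigma_pv"] = [pvr.get(z, (np.nan,) * 3)[0] for z in df.index]
            df["c_X_pv"] = [pvr.get(z, (np.nan,) * 3)[1] for z in df.index]
            df["c_Y_pv"] = [pvr.get(z, (np.nan,) * 3)[2] for z in df.index]
        capr = cap_records[i]
        df["sk_capped"] = [bool(capr.get(z, False)) for z in df.index]
        corr = corr_records[i]
        df["_sk_corr"] = [corr.get(z, 0.0) for z in df.index]
        df = df.reset_index()
        _to_physical(df, voxel)
        if pv is not None:
            df["c_X_pv"] = df["c_X_pv"] * voxel
            df["c_Y_pv"] = df["c_Y_pv"] * voxel
            df["sigma_pv"] = df["sigma_pv"] * voxel**2
        # sub-voxel mid-wall boundary correction of the territory area
        df["sigma_sk"] = df["sigma_sk"] + df["_sk_corr"].fillna(0.0) * voxel**2
        df = df.drop(columns=["_sk_corr"])
        if pv is not None:
            sigma_for_t = df["sigma_pv"].where(np.isfinite(df["sigma_pv"]),
                                               df["sigma"])
        else:
            sigma_for_t = df["sigma"]
        df["t"] = wall_thickness(sigma_for_t, df["P"], df["sigma_sk"],
                                 df["P_sk"], variant=wall_variant)
        df.loc[~np.isfinite(df["t"]), "valid"] = False
        if pv is not None:
            # densitometric refinement replaces the voxel-counting centroid
            # and area channels; the raw counts stay in *_bin columns
            for col, ref in (("c_X", "c_X_pv"), ("c_Y", "c_Y_pv"),
                             ("sigma", "sigma_pv")):
                df[col + "_bin"] = df[col]
                ok = np.isfinite(df[ref])
                df.loc[ok, col] = df.loc[ok, ref]
                df.loc[~ok & df["valid"], "valid"] = False
            df = df.drop(columns=["c_X_pv", "c_Y_pv", "sigma_pv"])
        prof = CellProfile(
            cell_id=i, category=lv.category.get(i, "unclassified"),
            voxel_size=voxel, table=df,
        )
        if prof.n_valid < min_length:
            prof.untrackable = True
            prof.table["theta"] = np.nan
        else:
            _add_theta(prof, theta_resolution)
        profiles[i] = prof
    return profiles


def _to_physical(df: pd.DataFrame, voxel: float) -> None:
    for col in ("c_X", "c_Y", "P", "P_sk", "e_a", "e_b"):
        df[col] = df[col] * voxel
    for col in ("sigma", "sigma_sk"):
        df[col] = df[col] * voxel**2


def parameterize_cell(
    lv: LabelVolume, cell_id: int, min_length: int = 82, **kw
) -> CellProfile:
    """Parameterize a single cell (wrapper over the full sweep)."""
    out = parameterize_all(lv, cell_ids=[cell_id], min_length=min_length, **kw)
    if cell_id not in out:
        raise KeyError(f"cell {cell_id} not present in the label volume")
    return out[cell_id]


def _add_theta(prof: CellProfile, resolution_vox: float) -> None:
    """Inclination angle from smoothing-spline derivatives of the centroid."""
    df = prof.table
    voxel = prof.voxel_size
    z_um = df["z"].to_numpy(dtype=float) * voxel
    valid = df["valid"].to_numpy(bool)
    if valid.sum() < 4:
        df["theta"] = np.nan
        return
    res_um = resolution_vox * voxel
    sx = _smooth_series(z_um[valid], df.loc[valid, "c_X"].to_numpy(float),
                        res_um, voxel)
    sy = _smooth_series(z_um[valid], df.loc[valid, "c_Y"].to_numpy(float),
                        res_um, voxel)
    dx = sx.derivative()(z_um)
    dy = sy.derivative()(z_um)
    df["theta"] = np.degrees(np.arctan(np.hypot(dx, dy)))


def inclination(prof: CellProfile, resolution: float = 50.0) -> np.ndarray:
    """theta(z): cell-axis inclination (degrees) vs the tube axis.

    Centroid tracks are smoothed with cubic smoothing splines whose
    equivalent averaging bandwidth is ``resolution`` voxels; theta comes
    from the analytic spline derivatives.
    """
    if prof.n_valid < resolution:
        raise ValueError(
            f"cell {prof.cell_id}: {prof.n_valid} valid slices < resolution"
        )
    _add_theta(prof, resolution)
    return prof.table["theta"].to_numpy(float)


# ---------------------------------------------------------------------------
# oblique reslicing
# ---------------------------------------------------------------------------

def _plane_section(vol_f32: np.ndarray, center_px, e1, e2, uu, vv):
    pts = (
        np.asarray(center_px, dtype=float)[:, None]
        + np.outer(e1, uu.ravel())
        + np.outer(e2, vv.ravel())
    )
    return ndi.map_coordinates(vol_f32, pts, order=1,
                               mode="nearest").reshape(uu.shape) >= 0.5


def reslice_iterate(
    lv: LabelVolume,
    prof: CellProfile,
    n_iter: int = 3,
    theta_resolution: float = 50.0,
    wall_variant: str = "corrected",
) -> tuple[CellProfile, list[float]]:
    """Re-extract cross-sections perpendicular to the local cell axis.

    The inclination of the current profile defines, per slice, a sampling
    plane normal to the local axis; the label mask is sampled on that plane
    with linear interpolation (0.5 threshold) and all geometric parameters
    are recomputed.  Repeated ``n_iter`` times.  Returns the final profile
    and the per-iteration maximum relative change of the lumen area Sigma
    (convergence diagnostic; non-convergence is logged, not raised).
    """
    voxel = prof.voxel_size
    lum_f = (lv.labels == prof.cell_id).astype(np.float32)
    com_f = (_combined_labels(lv) == prof.cell_id).astype(np.float32)
    cur = prof
    diagnostics: list[float] = []
    for _ in range(n_iter):
        df = cur.table
        valid = df["valid"].to_numpy(bool)
        if valid.sum() < 4:
            break
        z_um = df["z"].to_numpy(float) * voxel
        res_um = theta_resolution * voxel
        sx = _smooth_series(z_um[valid], df.loc[valid, "c_X"].to_numpy(float),
                            res_um, voxel)
        sy = _smooth_series(z_um[valid], df.loc[valid, "c_Y"].to_numpy(float),
                            res_um, voxel)
        dsx, dsy = sx.derivative(), sy.derivative()
        halfwidth = int(
            np.ceil(0.6 * np.nanmax(df["e_a"].to_numpy(float)) / voxel)
        ) + 4
        grid = np.arange(-halfwidth, halfwidth + 1, 1.0)
        uu, vv = np.meshgrid(grid, grid, indexing="ij")
        new_rows = []
        for z in df["z"].to_numpy():
            zum = z * voxel
            cx, cy = float(sx(zum)) / voxel, float(sy(zum)) / voxel
            tau = np.array([float(dsx(zum)), float(dsy(zum)), 1.0])
            tau /= np.linalg.norm(tau)
            e1 = np.array([1.0, 0.0, 0.0]) - tau[0] * tau
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(tau, e1)
            center = [cx, cy, float(z)]
            m = _plane_section(lum_f, center, e1, e2, uu, vv)
            out = _slice_props_mask(m)
            if out is None:
                new_rows.append((z, False) + (np.nan,) * 9)
                continue
            r, vld = out
            msk = _plane_section(com_f, center, e1, e2, uu, vv) | m
            sk = _slice_props_mask(msk)
            if sk is None:
                new_rows.append((z, False) + (np.nan,) * 9)
                continue
            rs, _ = sk
            du = r.centroid[0] - halfwidth
            dv = r.centroid[1] - halfwidth
            p3 = np.asarray(center) + du * e1 + dv * e2
            try:
                e_a, e_b = float(r.axis_major_length), float(r.axis_minor_length)
                e_psi = _psi_of(r)
            except Exception:
                vld, e_a, e_b, e_psi = False, np.nan, np.nan, np.nan
            new_rows.append(
                (z, bool(vld and r.area >= 5), p3[0], p3[1], float(r.area),
                 float(r.perimeter), float(rs.area), float(rs.perimeter),
                 e_a, e_b, e_psi)
            )
        new = pd.DataFrame(new_rows, columns=_TABLE_COLUMNS)
        _to_physical(new, voxel)
        new["t"] = wall_thickness(new["sigma"], new["P"], new["sigma_sk"],
                                  new["P_sk"], variant=wall_variant)
        new.loc[~np.isfinite(new["t"]), "valid"] = False
        both = new["valid"].to_numpy(bool) & cur.table["valid"].to_numpy(bool)
        if both.any():
            rel = np.abs(
                new.loc[both, "sigma"].to_numpy(float)
                - cur.table.loc[both, "sigma"].to_numpy(float)
            ) / cur.table.loc[both, "sigma"].to_numpy(float)
            diagnostics.append(float(np.nanmax(rel)))
        cur = CellProfile(cell_id=prof.cell_id, category=prof.category,
                          voxel_size=voxel, table=new, axis=prof.axis)
        _add_theta(cur, theta_resolution)
    if diagnostics and diagnostics[-1] > 0.01:
        warnings.warn(
            f"cell {prof.cell_id}: reslicing not converged "
            f"(last max relative Sigma change {diagnostics[-1]:.3g})",
            stacklevel=2,
        )
    return cur, diagnostics


def _slice_props_mask(mask2d: np.ndarray):
    """regionprops of the largest component of a boolean section + validity."""
    lab = cc_label(mask2d, connectivity=2)
    n_comp = int(lab.max())
    if n_comp == 0:
        return None
    rp = sorted(regionprops(lab), key=lambda r: r.area, reverse=True)
    r = rp[0]
    valid = (n_comp == 1) and (r.euler_number == 1)
    return r, bool(valid)
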