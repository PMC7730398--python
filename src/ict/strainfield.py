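"""Macroscopic strain fields and derived analyses from per-cell tracks.

Scattered per-cell displacement readings u = (u_x, u_y, u_z) at the lumen
centroids (c_x, c_y, z) are turned into differentiable strain fields
eps_ij = (d_j u_i + d_i u_j) / 2 in two smoothing steps: cubic smoothing
splines along the tube axis per cell, then thin-plate smoothing splines
over the scattered in-plane sites per axial level.  One resolution knob h
(in voxels) controls both steps.  Tension is positive.

Also here: the affine/non-affine decomposition of wood-ray cluster
deformation, Poisson-ratio profiles, voxel-wise parameter correlations,
CNR-based detection of densification planes, and generic binned profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.stats import t as student_t

from .cellparam import _smooth_series

__all__ = [
    "StrainField",
    "RayStrain",
    "smooth_strain",
    "ray_affine_strain",
    "poisson_ratio",
    "correlate_parameters",
    "cnr_planes",
    "profile_by_position",
    "displacement_for_strain",
]

_COMPONENTS = ["eps_RR", "eps_TT", "eps_LL", "eps_RT", "eps_RL", "eps_TL"]


def displacement_for_strain(length_um: float, strain: float) -> float:
    """Physical displacement (nm) a strain implies over a feature size.

    E.g. a 5e-5 radial strain over a 35 um lumen is a 1.8 nm deformation;
    0.8% over a 3.5 um wall is 28 nm.
    """
    return length_um * strain * 1e3


@dataclass
class StrainField:
    """Strain tensor estimates at the sample sites and on a plane grid.

    ``samples`` holds one row per (cell, z) track sample with the smoothed
    displacement components and the six strain components evaluated at the
    site.  ``resolution`` is the smoothing bandwidth h in voxels.
    """

    samples: pd.DataFrame
    resolution: float
    voxel_size: float

    def median_components(self) -> pd.Series:
        return self.samples[_COMPONENTS].median()


def _tps_fit(sites: np.ndarray, values: np.ndarray, smooth: float):
    return RBFInterpolator(sites, values, kernel="thin_plate_spline",
                           smoothing=smooth)


def _tps_gradient(rbf, pts: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient of a fitted surface at points."""
    dx = np.array([delta, 0.0])
    dy = np.array([0.0, delta])
    gx = (rbf(pts + dx) - rbf(pts - dx)) / (2 * delta)
    gy = (rbf(pts + dy) - rbf(pts - dy)) / (2 * delta)
    return gx, gy


def smooth_strain(
    samples: pd.DataFrame,
    resolution: float = 50.0,
    voxel_size: float = 1.0,
    min_sites: int = 4,
    z_bin: float | None = None,
) -> StrainField:
    """Smooth scattered per-cell displacements into a strain-tensor field.

    ``samples`` needs columns cell_id, x, y, z (um, z = axis coordinate) and
    u_x, u_y, u_z (um).  Step 1 smooths each displacement component along z
    per cell (cubic smoothing spline, bandwidth ``resolution`` voxels),
    giving smoothed values and axial derivatives at every sample.  Step 2
    fits, per axial bin, thin-plate smoothing splines to the in-plane
    scattered sites to obtain the in-plane derivatives.  Strains are
    assembled as eps_ij = (d_j u_i + d_i u_j)/2 (tension positive).
    """
    req = {"cell_id", "x", "y", "z", "u_x", "u_y", "u_z"}
    if not req.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(req)}")
    df = samples.dropna(subset=["u_x", "u_y", "u_z"]).copy()
    if df["cell_id"].nunique() < 1 or len(df) < 10:
        raise ValueError("need at least 10 accepted samples")
    h_um = resolution * voxel_size

    # step 1: per-cell axial smoothing splines and their derivatives
    for col in ("u_x", "u_y", "u_z"):
        df[f"{col}_s"] = np.nan
        df[f"d{col}_dz"] = np.nan
    for cid, g in df.groupby("cell_id"):
        if len(g) < 8:
            continue
        z = g["z"].to_numpy(float)
        order = np.argsort(z)
        idx = g.index.to_numpy()[order]
        zs = z[order]
        uniq = np.concatenate([[True], np.diff(zs) > 0])
        for col in ("u_x", "u_y", "u_z"):
            y = g[col].to_numpy(float)[order]
            try:
                sp = _smooth_series(zs[uniq], y[uniq], h_um, voxel_size)
            except Exception:
                continue
            df.loc[idx, f"{col}_s"] = sp(zs)
            df.loc[idx, f"d{col}_dz"] = sp.derivative()(zs)
    df = df.dropna(subset=["u_x_s", "u_y_s", "u_z_s"])

    # step 2: per-axial-bin thin-plate smoothing over in-plane sites
    zb = z_bin if z_bin is not None else h_um / 2.0
    df["_bin"] = np.floor(df["z"] / zb).astype(int)
    for c in _COMPONENTS:
        df[c] = np.nan
    # the axial normal strain needs no in-plane fit
    df["eps_LL"] = df["du_z_dz"].to_numpy(float)
    # thin-plate smoothing tied to the same resolution knob as the axial
    # splines: the kernel r^2 log r has magnitude ~ h^2 log h at the
    # resolution scale, so this damps variation below h while leaving the
    # affine part (the penalty null space) untouched
    h_px = max(resolution, 1.0)
    tps_smooth_scale = float(
        len(df["cell_id"].unique()) * h_um**2 * max(np.log(h_px), 1.0)
    )
    delta = voxel_size
    for _, g in df.groupby("_bin"):
        # one site per cell: average within the bin to keep TPS well posed
        agg = g.groupby("cell_id").agg(
            x=("x", "mean"), y=("y", "mean"),
            u_x=("u_x_s", "mean"), u_y=("u_y_s", "mean"), u_z=("u_z_s", "mean"),
            duz=("du_z_dz", "mean"), dux=("du_x_dz", "mean"),
            duy=("du_y_dz", "mean"),
        )
        if len(agg) < min_sites:
            warnings.warn("axial level skipped: too few in-plane sites",
                          stacklevel=2)
            continue
        sites = agg[["x", "y"]].to_numpy(float)
        span = np.ptp(sites, axis=0)
        if min(span) <= 0 or np.linalg.matrix_rank(
            np.c_[sites - sites.mean(0), np.ones(len(sites))]
        ) < 3:
            warnings.warn("axial level skipped: collinear in-plane sites",
                          stacklevel=2)
            continue
        smooth = tps_smooth_scale
        fx = _tps_fit(sites, agg["u_x"].to_numpy(float), smooth)
        fy = _tps_fit(sites, agg["u_y"].to_numpy(float), smooth)
        fz = _tps_fit(sites, agg["u_z"].to_numpy(float), smooth)
        pts = g[["x", "y"]].to_numpy(float)
        dux_dx, dux_dy = _tps_gradient(fx, pts, delta)
        duy_dx, duy_dy = _tps_gradient(fy, pts, delta)
        duz_dx, duz_dy = _tps_gradient(fz, pts, delta)
        idx = g.index
        df.loc[idx, "eps_RR"] = dux_dx
        df.loc[idx, "eps_TT"] = duy_dy
        df.loc[idx, "eps_RT"] = 0.5 * (dux_dy + duy_dx)
        df.loc[idx, "eps_RL"] = 0.5 * (
            duz_dx + g["du_x_dz"].to_numpy(float)
        )
        df.loc[idx, "eps_TL"] = 0.5 * (
            duz_dy + g["du_y_dz"].to_numpy(float)
        )
    df = df.drop(columns=["_bin"])
    return StrainField(samples=df, resolution=resolution, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# wood-ray affine strain
# ---------------------------------------------------------------------------

@dataclass
class RayStrain:
    """Affine/non-affine decomposition of one ray cluster's deformation.

    ``eps_ray`` is the symmetric part of the least-squares linear map of the
    reference lumen-centroid lattice onto the deformed one, minus identity
    (2x2, in the LT plane); ``u_ray`` the per-lumen non-affine residual
    magnitudes (um).
    """

    cluster_id: int
    eps_ray: np.ndarray
    u_ray: np.ndarray
    members: list[int] = field(default_factory=list)
    collinear: bool = False


def ray_affine_strain(
    ref_centroids: np.ndarray,
    test_centroids: np.ndarray,
    cluster_id: int = 0,
    members: list[int] | None = None,
) -> RayStrain:
    """Least-squares affine map of a ray cluster's lumen lattice.

    ``ref_centroids`` and ``test_centroids`` are (n, 2) arrays of matched
    lumen centroids in the LT plane (um).  Requires n >= 3; for a collinear
    lattice only the 1D stretch along the lattice line is identifiable and
    the result is flagged.
    """
    R = np.asarray(ref_centroids, dtype=float)
    X = np.asarray(test_centroids, dtype=float)
    if R.shape != X.shape or R.ndim != 2 or R.shape[1] != 2:
        raise ValueError("centroid arrays must be matched (n, 2)")
    n = R.shape[0]
    if n < 3:
        raise ValueError("need at least 3 tracked lumens")
    c0 = R.mean(axis=0)
    c1 = X.mean(axis=0)
    A0 = R - c0
    A1 = X - c1
    cov = A0.T @ A0
    collinear = np.linalg.matrix_rank(cov, tol=1e-9 * max(cov.max(), 1.0)) < 2
    if collinear:
        # 1D affine fit along the dominant lattice direction
        w, v = np.linalg.eigh(cov)
        d = v[:, np.argmax(w)]
        s0 = A0 @ d
        s1 = A1 @ d
        k = float(s0 @ s1 / (s0 @ s0))
        F = np.eye(2) + (k - 1.0) * np.outer(d, d)
    else:
        F = np.linalg.solve(cov, A0.T @ A1).T
    eps = 0.5 * (F + F.T) - np.eye(2)
    resid = A1 - A0 @ F.T
    return RayStrain(
        cluster_id=cluster_id,
        eps_ray=eps,
        u_ray=np.linalg.norm(resid, axis=1),
        members=members or [],
        collinear=bool(collinear),
    )


# ---------------------------------------------------------------------------
# derived analyses
# ---------------------------------------------------------------------------

def poisson_ratio(
    eps_num: np.ndarray,
    eps_den: np.ndarray,
    noise_floor: float = 5e-5,
    floor_factor: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Pointwise Poisson ratio nu = -eps_num / eps_den and weighted average.

    Points where |eps_den| < floor_factor * noise_floor are masked; the
    average is weighted by |eps_den| so well-resolved points dominate.
    """
    num = np.asarray(eps_num, dtype=float)
    den = np.asarray(eps_den, dtype=float)
    mask = np.abs(den) >= floor_factor * noise_floor
    nu = np.full(num.shape, np.nan)
    nu[mask] = -num[mask] / den[mask]
    if not mask.any():
        warnings.warn("Poisson ratio undefined: denominator fully masked",
                      stacklevel=2)
        return nu, np.nan
    avg = float(np.average(nu[mask], weights=np.abs(den[mask])))
    return nu, avg


def correlate_parameters(fields: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p-values.

    ``fields``: co-registered samples, one column per parameter.  Returns a
    tidy matrix (rows/cols = parameters) with attrs carrying the p-values
    and the sample count per pair.  Constant columns yield missing entries.
    """
    cols = list(fields.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b_ in cols[i:]:
            ok = pd.concat([fields[a], fields[b_]], axis=1,
                           keys=["_a", "_b"]).dropna()
            if len(ok) < 3:
                continue
            xa = ok["_a"].to_numpy(float).reshape(-1)
            xb = ok["_b"].to_numpy(float).reshape(-1)
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            nn = len(ok)
            da, db = xa - xa.mean(), xb - xb.mean()
            rv = float(np.dot(da, db) / np.sqrt(np.dot(da, da) * np.dot(db, db)))
            rv = float(np.clip(rv, -1.0, 1.0))
            # two-sided p from the t approximation with n - 2 dof
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                t = rv * np.sqrt((nn - 2) / (1.0 - rv**2))
                pv = float(2.0 * student_t.sf(abs(t), nn - 2))
            r.loc[a, b_] = r.loc[b_, a] = rv
            p.loc[a, b_] = p.loc[b_, a] = pv
            n.loc[a, b_] = n.loc[b_, a] = int(nn)
    r.attrs["p_values"] = p
    r.attrs["n"] = n
    return r


def cnr_planes(
    positions: np.ndarray,
    profile: np.ndarray,
    plane_positions,
    band_width: float = 50.0,
) -> pd.DataFrame:
    """Contrast-to-noise ratio of candidate planes in a 1D profile.

    CNR = |mean(profile inside the plane band) - mean(background)| /
    std(background), where background is the profile outside all candidate
    bands.  Zero background variance flags an infinite CNR.
    """
    pos = np.asarray(positions, dtype=float)
    prof = np.asarray(profile, dtype=float)
    planes = np.atleast_1d(np.asarray(plane_positions, dtype=float))
    in_any = np.zeros(pos.shape, dtype=bool)
    for c in planes:
        in_any |= np.abs(pos - c) <= band_width / 2.0
    bg = prof[~in_any & np.isfinite(prof)]
    rows = []
    bg_sd = float(np.std(bg)) if bg.size else np.nan
    bg_mean = float(np.mean(bg)) if bg.size else np.nan
    for c in planes:
        band = prof[(np.abs(pos - c) <= band_width / 2.0) & np.isfinite(prof)]
        if band.size == 0 or not np.isfinite(bg_sd):
            rows.append((c, np.nan, True))
            continue
        if bg_sd == 0:
            rows.append((c, np.inf, True))
            continue
        rows.append((c, abs(float(np.mean(band)) - bg_mean) / bg_sd, False))
    return pd.DataFrame(rows, columns=["position", "cnr", "flagged"])


def profile_by_position(
    df: pd.DataFrame,
    position: str,
    channels,
    bin_width: float,
) -> pd.DataFrame:
    """Bin per-cell/per-slice quantities along an axis: mean and count per bin.

    Empty bins are missing values, never zeros.
    """
    channels = list(channels)
    pos = df[position].to_numpy(float)
    lo = np.floor(np.nanmin(pos) / bin_width) * bin_width
    hi = np.ceil(np.nanmax(pos) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx = np.digitize(pos, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = df.iloc[idx == b]
        row = {"position": 0.5 * (edges[b] + edges[b + 1])}
        for ch in channels:
            vals = sel[ch].dropna()
            row[ch] = vals.mean() if len(vals) else np.nan
            row[f"{ch}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows)
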