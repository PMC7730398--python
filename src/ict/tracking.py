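"""Cell registration across load states and per-cell deformation metrics.

Cells are matched between a reference and a test label volume by mutual
volumetric overlap (both directions must exceed 50%).  The axial
displacement u_z(z) of each matched cell is found by maximizing the
zero-normalized cross-correlation (ZNCC) of the two cells' 1D parameter
profiles over a sliding window, with parabolic sub-sample refinement of the
correlation peak.  The aligned test profile then yields the in-plane
displacements (centroid differences) and the relative geometric deformation
channels: lumen-area strain eps_Sigma, wall-thickness strain eps_t,
inclination change delta_theta, and ellipse-axis strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cellparam import PROFILE_CHANNELS, CellProfile
from .segmentation import LabelVolume

__all__ = [
    "CellMatch",
    "TrackResult",
    "match_cells",
    "overlap_accepted",
    "zncc",
    "track_z",
    "cell_deformation",
    "track_cell",
]


@dataclass(frozen=True)
class CellMatch:
    """A candidate reference/test cell pair with mutual overlap fractions."""

    ref_id: int
    test_id: int
    overlap_fraction_ref: float
    overlap_fraction_test: float

    @property
    def accepted(self) -> bool:
        return overlap_accepted(self.overlap_fraction_ref,
                                self.overlap_fraction_test)


def overlap_accepted(frac_ref: float, frac_test: float) -> bool:
    """Mutual-overlap rule: both fractions must be at least 50%."""
    return frac_ref >= 0.5 and frac_test >= 0.5


@dataclass
class TrackResult:
    """Co-registered cell pair with per-slice deformation channels.

    ``table`` columns: z (reference slice index), u_x, u_y, u_z (um),
    i_corr, accepted, eps_sigma, eps_t, delta_theta, delta_e_psi, eps_a,
    eps_b.  In-plane channels are defined only where the axial track was
    accepted (i_corr > min_corr).
    """

    match: CellMatch
    window: int
    table: pd.DataFrame
    category: str = "tracheid"

    @property
    def accepted_fraction(self) -> float:
        return float(self.table["accepted"].mean())


def match_cells(
    ref: LabelVolume, test: LabelVolume, min_overlap: float = 0.5
) -> tuple[list[CellMatch], list[int], list[int]]:
    """Match cells between deformation states by voxel overlap.

    Builds the overlap histogram of (reference label, test label) pairs and
    keeps pairs whose overlap is at least ``min_overlap`` of *both* cell
    volumes; if a cell passes with several partners the largest overlap wins
    (ties to the lower test id).  Returns (matches, unmatched_ref,
    unmatched_test).
    """
    a = ref.labels.reshape(-1).astype(np.int64)
    b = test.labels.reshape(-1).astype(np.int64)
    if not a.any() or not b.any():
        raise ValueError("empty label volume")
    m = (a > 0) & (b > 0)
    key = a[m] * (int(b.max()) + 1) + b[m]
    pairs, counts = np.unique(key, return_counts=True)
    ref_ids, ref_vol = np.unique(a[a > 0], return_counts=True)
    test_ids, test_vol = np.unique(b[b > 0], return_counts=True)
    vol_ref = dict(zip(ref_ids.tolist(), ref_vol.tolist()))
    vol_test = dict(zip(test_ids.tolist(), test_vol.tolist()))

    base = int(b.max()) + 1
    cand: list[CellMatch] = []
    for k, n in zip(pairs, counts):
        i, j = int(k // base), int(k % base)
        cand.append(
            CellMatch(i, j, n / vol_ref[i], n / vol_test[j])
        )
    cand = [c for c in cand if c.accepted]
    # greedy best-overlap assignment, ties to lower test id
    cand.sort(key=lambda c: (-min(c.overlap_fraction_ref,
                                  c.overlap_fraction_test), c.test_id))
    used_ref: set[int] = set()
    used_test: set[int] = set()
    matches: list[CellMatch] = []
    for c in cand:
        if c.ref_id in used_ref or c.test_id in used_test:
            continue
        matches.append(c)
        used_ref.add(c.ref_id)
        used_test.add(c.test_id)
    unmatched_ref = [int(i) for i in ref_ids if int(i) not in used_ref]
    unmatched_test = [int(j) for j in test_ids if int(j) not in used_test]
    return matches, unmatched_ref, unmatched_test


# ---------------------------------------------------------------------------
# ZNCC on 1D multi-channel profiles
# ---------------------------------------------------------------------------

def _window_standardize(win: np.ndarray) -> np.ndarray | None:
    """Standardize each channel within a window; drop zero-variance channels.

    ``win`` is (W, n_channels).  Returns the standardized window with
    zero-variance channels set to NaN (to be dropped jointly), or None if
    all channels are degenerate.
    """
    mu = win.mean(axis=0)
    sd = win.std(axis=0)
    out = np.full_like(win, np.nan)
    ok = sd > 0
    if not ok.any():
        return None
    out[:, ok] = (win[:, ok] - mu[ok]) / sd[ok]
    return out


def zncc(
    T: np.ndarray,
    T0: np.ndarray,
    z: int,
    zhat: int,
    window: int = 41,
    standardize: bool = True,
) -> float:
    """Zero-normalized cross-correlation of two profiles at one (z, zhat).

    Correlates the test profile window starting at ``z + zhat`` against the
    reference window at ``z`` (both of length ``window``), pooling all
    parameter channels.  With ``standardize`` (default) each channel is
    standardized within its window before pooling so channels of different
    physical units contribute equally; otherwise raw centered channels are
    pooled.  Returns a value in [-1, 1]; NaN when every channel is
    degenerate or the windows leave the profiles.
    """
    T = np.asarray(T, dtype=float)
    T0 = np.asarray(T0, dtype=float)
    w = window
    if z < 0 or z + w > T0.shape[0] or z + zhat < 0 or z + zhat + w > T.shape[0]:
        return np.nan
    a = T0[z:z + w]
    b = T[z + zhat:z + zhat + w]
    if np.isnan(a).any() or np.isnan(b).any():
        return np.nan
    if standardize:
        a = _window_standardize(a)
        b = _window_standardize(b)
        if a is None or b is None:
            return np.nan
        ok = ~(np.isnan(a[0]) | np.isnan(b[0]))
        if not ok.any():
            return np.nan
        a, b = a[:, ok], b[:, ok]
    else:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
    num = float(np.sum(a * b))
    den = float(np.sqrt(np.sum(a * a) * np.sum(b * b)))
    if den == 0:
        return np.nan
    return num / den


def track_z(
    T: np.ndarray,
    T0: np.ndarray,
    valid_T: np.ndarray | None = None,
    valid_T0: np.ndarray | None = None,
    window: int = 41,
    min_corr: float = 0.5,
    max_shift: int | None = None,
    voxel_size: float = 1.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Axial displacement u_z(z) by windowed ZNCC with sub-sample refinement.

    For every reference window center the integer shift maximizing the ZNCC
    is found over [-max_shift, max_shift] (ties to the smaller |shift|),
    then refined by a 3-point parabolic fit of the correlation peak.  A
    track point is accepted when the peak correlation exceeds ``min_corr``.

    Returns a DataFrame with columns z (window-center index), u_z (um),
    i_corr, accepted.
    """
    T = np.asarray(T, dtype=float)
    T0 = np.asarray(T0, dtype=float)
    n0, nch = T0.shape
    w = int(window)
    if n0 < w or T.shape[0] < w:
        raise ValueError(f"profile shorter than the correlation window ({w})")
    if max_shift is None:
        max_shift = max(3, int(round(0.1 * min(n0, T.shape[0]))))
    if valid_T0 is None:
        valid_T0 = ~np.isnan(T0).any(axis=1)
    if valid_T is None:
        valid_T = ~np.isnan(T).any(axis=1)

    half = w // 2
    shifts = np.arange(-max_shift, max_shift + 1)

    def _unit_windows(M: np.ndarray, valid: np.ndarray):
        """Per-window standardized, unit-norm channel stacks."""
        from numpy.lib.stride_tricks import sliding_window_view

        win = sliding_window_view(M, w, axis=0)  # (nw, nch, w)
        win = np.ascontiguousarray(np.swapaxes(win, 1, 2)).astype(float)
        okwin = sliding_window_view(valid.astype(bool), w).all(axis=1)
        okwin &= ~np.isnan(win).any(axis=(1, 2))
        if standardize:
            mu = win.mean(axis=1, keepdims=True)
            sd = win.std(axis=1, keepdims=True)
            keep = sd > 0
            std = np.where(keep, (win - mu) / np.where(keep, sd, 1.0), 0.0)
        else:
            std = win - np.nanmean(win, axis=1, keepdims=True)
        flat = np.nan_to_num(std.reshape(std.shape[0], -1))
        norm = np.linalg.norm(flat, axis=1)
        okwin &= norm > 0
        flat = flat / np.where(norm > 0, norm, 1.0)[:, None]
        return flat, okwin

    A, okA = _unit_windows(T0, valid_T0)
    B, okB = _unit_windows(T, valid_T)
    corr_full = A @ B.T  # (n0 windows, nT windows)

    rows = []
    nB = B.shape[0]
    for z0 in np.flatnonzero(okA):
        idx = z0 + shifts
        inb = (idx >= 0) & (idx < nB)
        corr = np.full(shifts.shape, np.nan)
        sel = inb.copy()
        sel[inb] = okB[idx[inb]]
        corr[sel] = corr_full[z0, idx[sel]]
        if np.all(np.isnan(corr)):
            continue
        best = np.nanmax(corr)
        cands = np.flatnonzero(corr == best)
        k = int(cands[np.argmin(np.abs(shifts[cands]))])
        peak = float(corr[k])
        u = float(shifts[k])
        if peak >= 1.0 - 1e-9:
            pass  # exact match: keep the integer shift
        elif 0 < k < len(shifts) - 1 and np.isfinite(corr[k - 1]) \
                and np.isfinite(corr[k + 1]):
            c_m, c_0, c_p = corr[k - 1], corr[k], corr[k + 1]
            denom = c_m - 2 * c_0 + c_p
            if denom < 0:
                delta = 0.5 * (c_m - c_p) / denom
                if abs(delta) <= 1.0:
                    u += float(delta)
                    peak = float(c_0 - 0.25 * (c_m - c_p) * delta)
        rows.append((z0 + half, u * voxel_size, peak, bool(peak > min_corr)))
    return pd.DataFrame(rows, columns=["z", "u_z", "i_corr", "accepted"])


# ---------------------------------------------------------------------------
# per-cell deformation
# ---------------------------------------------------------------------------

_REL_CHANNELS = {  # aligned-vs-reference relative channels
    "eps_sigma": ("sigma", "rel"),
    "eps_t": ("t", "rel"),
    "eps_a": ("e_a", "rel"),
    "eps_b": ("e_b", "rel"),
    "delta_theta": ("theta", "abs"),
    "delta_e_psi": ("e_psi", "abs"),
    "u_x": ("c_X", "abs"),
    "u_y": ("c_Y", "abs"),
}


def cell_deformation(
    prof_test: CellProfile,
    prof_ref: CellProfile,
    uz: pd.DataFrame,
    match: CellMatch | None = None,
    window: int = 41,
    align_resolution: float | None = 50.0,
) -> TrackResult:
    """Align the test profile onto the reference and difference the channels.

    The aligned test profile is T_hat(z, i_p) = T(z + u_z(z), i_p), built by
    cubic interpolation of each channel over the test cell's valid slices.
    ``align_resolution`` smooths the axial track with a cubic smoothing
    spline (bandwidth in voxels) before the alignment, so the jitter of the
    correlation peak is not injected into the geometric channels through
    steep landmarks.  Relative channels (eps_sigma, eps_t, eps_a, eps_b)
    are ratios minus one; angular and positional channels are differences.
    """
    ref = prof_ref.table.set_index("z")
    test = prof_test.table.set_index("z")
    voxel = prof_ref.voxel_size

    if align_resolution and len(uz) >= 8:
        from .cellparam import _smooth_series

        acc = uz["accepted"].to_numpy(bool)
        if acc.sum() >= 8:
            zu = uz.loc[acc, "z"].to_numpy(float) * voxel
            yu = uz.loc[acc, "u_z"].to_numpy(float)
            order = np.argsort(zu)
            zu, yu = zu[order], yu[order]
            keep = np.concatenate([[True], np.diff(zu) > 0])
            try:
                sp = _smooth_series(zu[keep], yu[keep],
                                    align_resolution * voxel, voxel)
                uz = uz.copy()
                uz.loc[acc, "u_z"] = sp(uz.loc[acc, "z"].to_numpy(float)
                                        * voxel)
            except Exception:
                pass

    tv = test[test["valid"]]
    interp = {}
    for col in ("c_X", "c_Y", "sigma", "t", "theta", "e_a", "e_b", "e_psi"):
        y = tv[col].to_numpy(float)
        okm = np.isfinite(y)
        if okm.sum() >= 4:
            interp[col] = CubicSpline(tv.index.to_numpy(float)[okm], y[okm],
                                      extrapolate=False)
        else:
            interp[col] = None

    out = uz.copy()
    zq = out["z"].to_numpy(float) + out["u_z"].to_numpy(float) / voxel
    ref_rows = ref.reindex(out["z"].astype(int))
    ok = out["accepted"].to_numpy(bool) & ref_rows["valid"].to_numpy(bool)
    for name, (col, kind) in _REL_CHANNELS.items():
        sp = interp[col]
        if sp is None:
            out[name] = np.nan
            continue
        that = sp(zq)
        base = ref_rows[col].to_numpy(float)
        if kind == "rel":
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = that / base - 1.0
        else:
            vals = that - base
        vals = np.where(ok, vals, np.nan)
        out[name] = vals
        if col in ("sigma", "t"):
            out[f"{col}_hat"] = np.where(ok, that, np.nan)
            out[f"{col}_ref"] = np.where(ok, base, np.nan)
    if "sk_capped" in ref.columns:
        out["sk_capped"] = ref_rows["sk_capped"].fillna(True).to_numpy(bool)
    if match is None:
        match = CellMatch(prof_ref.cell_id, prof_test.cell_id, 1.0, 1.0)
    return TrackResult(match=match, window=window, table=out,
                       category=prof_ref.category)


def track_cell(
    prof_test: CellProfile,
    prof_ref: CellProfile,
    match: CellMatch | None = None,
    window: int = 41,
    min_corr: float = 0.5,
    max_shift: int | None = None,
    standardize: bool = True,
    channels=PROFILE_CHANNELS,
    align_resolution: float | None = 50.0,
) -> TrackResult:
    """Full per-cell tracking: ZNCC axial track + channel differencing.

    ``channels`` selects the profile channels pooled by the ZNCC; small
    cross-sections (wood rays) track better on the densitometrically
    refined channels alone, because the voxel-counting shape channels carry
    grid-locked discretization error that pulls the correlation peak toward
    zero shift.
    """
    T0 = prof_ref.channel_matrix(channels)
    T = prof_test.channel_matrix(channels)
    uz = track_z(
        T, T0,
        valid_T=prof_test.table["valid"].to_numpy(bool),
        valid_T0=prof_ref.table["valid"].to_numpy(bool),
        window=window, min_corr=min_corr, max_shift=max_shift,
        voxel_size=prof_ref.voxel_size, standardize=standardize,
    )
    # track_z indexes rows of the profile tables; convert to slice indices
    z0 = float(prof_ref.table["z"].iloc[0])
    zt0 = float(prof_test.table["z"].iloc[0])
    uz = uz.copy()
    uz["z"] = uz["z"] + z0
    if zt0 != z0:
        uz["u_z"] = uz["u_z"] + (zt0 - z0) * prof_ref.voxel_size
    return cell_deformation(prof_test, prof_ref, uz, match=match,
                            window=window, align_resolution=align_resolution)
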