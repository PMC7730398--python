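"""End-to-end analysis chains: segment -> parameterize -> track -> strain.

These helpers wire the stage modules together for the common two-state
workflow (reference vs deformed test volume), for both the tracheid branch
(tube axis Z = L, correlation window 41 px, strain resolution 50 px) and
the wood-ray branch (axis X = R after transposition, coarser 100 px window
and resolution to tame the smaller lumen statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cellparam, segmentation, strainfield, tracking
from .phantom import GrayVolume
from .segmentation import BinaryVolume, LabelVolume, SegmentationParams

__all__ = [
    "ChainConfig",
    "SegmentedState",
    "segment_state",
    "transpose_for_rays",
    "track_pair",
    "pair_strain",
]


@dataclass
class ChainConfig:
    """Tunable parameters of the full chain."""

    seg: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(denoise_sigma=1.0)
    )
    window: int = 41
    min_corr: float = 0.5
    max_shift: int | None = None
    resolution: float = 50.0  # strain smoothing bandwidth, voxels
    ray_window: int = 100
    ray_resolution: float = 100.0
    ray_channels: tuple = ("c_X", "c_Y", "sigma", "theta")
    min_length: int = 82
    ray_min_length: int = 100
    wall_variant: str = "corrected"
    reslice_iterations: int = 0  # oblique reslicing off for near-axial cells
    reuse_threshold: bool = True  # binarize test states at the reference threshold
    smooth_channels: bool = True  # spline-smooth deformation channels at h


@dataclass
class SegmentedState:
    """A segmented + parameterized deformation state."""

    volume: GrayVolume
    binary: BinaryVolume
    labels: LabelVolume
    profiles: dict[int, cellparam.CellProfile]
    ray_labels: LabelVolume | None = None
    ray_profiles: dict[int, cellparam.CellProfile] | None = None


def segment_state(
    vol: GrayVolume,
    config: ChainConfig | None = None,
    threshold: float | None = None,
    rays: bool = True,
    tracheids: bool = True,
) -> SegmentedState:
    """Binarize, segment, classify, assign walls and parameterize one state."""
    config = config or ChainConfig()
    sig = config.seg.denoise_sigma
    if sig > 0:
        # mild denoising before thresholding: warping a noisy reference
        # (synthetic-deformation workflows) smooths the static noise
        # asymmetrically between states, which biases sub-voxel boundary
        # statistics; suppressing the noise equally in both states removes
        # that asymmetry
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(vol.data.astype(np.float32), sig)
    else:
        data = vol.data
    if threshold is None:
        thr = segmentation.otsu_threshold(data)
    else:
        thr = float(threshold)
    binv = BinaryVolume(lumen=data < thr, voxel_size=vol.voxel_size,
                        threshold=thr)
    lv = segmentation.segment_lumens(binv, config.seg)
    lv = segmentation.classify_cells(lv)
    lv = segmentation.assign_wall(lv, binv)
    intensity = np.asarray(data, dtype=np.float32)
    profiles: dict[int, cellparam.CellProfile] = {}
    if tracheids:
        ids = [i for i in lv.ids_of("tracheid") if not lv.border_lateral.get(i)]
        profiles = cellparam.parameterize_all(
            lv, cell_ids=ids, min_length=config.min_length,
            wall_variant=config.wall_variant, intensity=intensity,
        )
    state = SegmentedState(volume=vol, binary=binv, labels=lv, profiles=profiles)
    if rays and lv.ids_of("ray"):
        state.ray_labels = transpose_for_rays(lv)
        state.ray_profiles = cellparam.parameterize_all(
            state.ray_labels, cell_ids=state.ray_labels.ids_of("ray"),
            min_length=config.ray_min_length, wall_variant=config.wall_variant,
            intensity=np.ascontiguousarray(np.swapaxes(intensity, 0, 2)),
        )
    return state


def transpose_for_rays(lv: LabelVolume) -> LabelVolume:
    """Relabel the volume with the ray axis (X = R) as the profile axis.

    Swapping X and Z puts ray cross-sections in the (L, T) plane, so the
    generic tube parameterization applies unchanged; channel c_X then holds
    the L coordinate and c_Y the T coordinate of a ray section centroid.
    """
    ray_ids = lv.ids_of("ray")
    keep = np.isin(lv.labels, ray_ids)
    lab = np.where(keep, lv.labels, 0)
    labT = np.ascontiguousarray(np.swapaxes(lab, 0, 2))
    ownT = None
    distT = None
    if lv.wall_owner is not None:
        own = np.where(np.isin(lv.wall_owner, ray_ids), lv.wall_owner, 0)
        ownT = np.ascontiguousarray(np.swapaxes(own, 0, 2))
    if lv.wall_dist is not None:
        distT = np.ascontiguousarray(np.swapaxes(lv.wall_dist, 0, 2))
    return LabelVolume(
        labels=labT,
        voxel_size=lv.voxel_size,
        category={i: "ray" for i in ray_ids},
        detection_pass={i: lv.detection_pass.get(i, 1) for i in ray_ids},
        wall_owner=ownT,
        wall_dist=distT,
        threshold=lv.threshold,
        params=lv.params,
    )


def track_pair(
    ref: SegmentedState,
    test: SegmentedState,
    config: ChainConfig | None = None,
    branch: str = "tracheid",
) -> list[tracking.TrackResult]:
    """Match and track all cells of one branch between two states."""
    config = config or ChainConfig()
    if branch == "tracheid":
        lab_r, lab_t = ref.labels, test.labels
        prof_r, prof_t = ref.profiles, test.profiles
        window, max_shift = config.window, config.max_shift
    elif branch == "ray":
        if ref.ray_labels is None or test.ray_labels is None:
            return []
        lab_r, lab_t = ref.ray_labels, test.ray_labels
        prof_r, prof_t = ref.ray_profiles, test.ray_profiles
        window, max_shift = config.ray_window, config.max_shift
    else:
        raise ValueError(f"unknown branch {branch!r}")
    matches, _, _ = tracking.match_cells(lab_r, lab_t)
    channels = (list(config.ray_channels) if branch == "ray"
                else tracking.PROFILE_CHANNELS)
    results = []
    for m in matches:
        pr = prof_r.get(m.ref_id)
        pt = prof_t.get(m.test_id)
        if pr is None or pt is None or pr.untrackable or pt.untrackable:
            continue
        try:
            tr = tracking.track_cell(
                pt, pr, match=m, window=window, min_corr=config.min_corr,
                max_shift=max_shift, channels=channels,
                align_resolution=(config.resolution if branch == "tracheid"
                                  else config.ray_resolution),
            )
        except ValueError:
            continue
        tr.category = pr.category
        results.append(tr)
    return results


def _samples_from_tracks(
    tracks: list[tracking.TrackResult],
    profiles: dict[int, cellparam.CellProfile],
    voxel: float,
) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        prof = profiles[tr.match.ref_id].table.set_index("z")
        t = tr.table
        ok = t["accepted"].to_numpy(bool)
        if not ok.any():
            continue
        zz = t.loc[ok, "z"].astype(int)
        base = prof.reindex(zz)
        capped = base.get("sk_capped")
        eps_t_vals = t.loc[ok, "eps_t"].to_numpy(float)
        if capped is not None:
            eps_t_vals = np.where(capped.to_numpy(bool), np.nan, eps_t_vals)
        # cell-level (ratio-of-means) strains: the right statistic for
        # homogeneous deformation, immune to per-slice discretization noise
        with np.errstate(invalid="ignore"):
            s_hat = t.loc[ok, "sigma_hat"].to_numpy(float)
            s_ref = t.loc[ok, "sigma_ref"].to_numpy(float)
            eps_sigma_cell = (np.nanmean(s_hat) / np.nanmean(s_ref) - 1.0
                              if np.isfinite(s_ref).any() else np.nan)
            t_hat = t.loc[ok, "t_hat"].to_numpy(float)
            t_ref = t.loc[ok, "t_ref"].to_numpy(float)
            if capped is not None:
                uncap = ~capped.to_numpy(bool)
                t_hat = np.where(uncap, t_hat, np.nan)
                t_ref = np.where(uncap, t_ref, np.nan)
            eps_t_cell = (np.nanmean(t_hat) / np.nanmean(t_ref) - 1.0
                          if np.isfinite(t_ref).any() else np.nan)
        rows.append(pd.DataFrame(dict(
            cell_id=tr.match.ref_id,
            x=base["c_X"].to_numpy(float),
            y=base["c_Y"].to_numpy(float),
            z=zz.to_numpy(float) * voxel,
            u_x=t.loc[ok, "u_x"].to_numpy(float),
            u_y=t.loc[ok, "u_y"].to_numpy(float),
            u_z=t.loc[ok, "u_z"].to_numpy(float),
            eps_sigma=t.loc[ok, "eps_sigma"].to_numpy(float),
            eps_t=eps_t_vals,
            delta_theta=t.loc[ok, "delta_theta"].to_numpy(float),
            delta_e_psi=t.loc[ok, "delta_e_psi"].to_numpy(float),
            eps_a=t.loc[ok, "eps_a"].to_numpy(float),
            eps_b=t.loc[ok, "eps_b"].to_numpy(float),
            eps_sigma_cell=eps_sigma_cell,
            eps_t_cell=eps_t_cell,
        )))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "x", "y", "z",
                                     "u_x", "u_y", "u_z"])
    return pd.concat(rows, ignore_index=True)


def pair_strain(
    ref: SegmentedState,
    test: SegmentedState,
    config: ChainConfig | None = None,
    branch: str = "tracheid",
) -> tuple[strainfield.StrainField | None, pd.DataFrame]:
    """Track a state pair and estimate the smoothed strain field.

    Returns the :class:`StrainField` (None when too few samples) and the
    per-sample table, which also carries the geometric deformation channels
    (eps_sigma, eps_t, ...), spline-smoothed along the tube axis at the
    branch resolution when ``config.smooth_channels`` is set.
    """
    config = config or ChainConfig()
    tracks = track_pair(ref, test, config, branch=branch)
    profiles = ref.profiles if branch == "tracheid" else (ref.ray_profiles or {})
    voxel = ref.labels.voxel_size
    samples = _samples_from_tracks(tracks, profiles, voxel)
    if samples.empty:
        return None, samples
    res = config.resolution if branch == "tracheid" else config.ray_resolution
    if config.smooth_channels:
        h_um = res * voxel
        for col in ("eps_sigma", "eps_t", "delta_theta", "delta_e_psi",
                    "eps_a", "eps_b"):
            samples[col + "_s"] = np.nan
            for cid, g in samples.groupby("cell_id"):
                y = g[col].to_numpy(float)
                z = g["z"].to_numpy(float)
                ok = np.isfinite(y) & np.isfinite(z)
                if ok.sum() < 8:
                    continue
                order = np.argsort(z[ok])
                zs, ys = z[ok][order], y[ok][order]
                uniq = np.concatenate([[True], np.diff(zs) > 0])
                try:
                    sp = cellparam._smooth_series(zs[uniq], ys[uniq], h_um, voxel)
                except Exception:
                    continue
                vals = samples.loc[g.index, "z"].to_numpy(float)
                samples.loc[g.index[ok], col + "_s"] = sp(z[ok])
    try:
        sf = strainfield.smooth_strain(
            samples, resolution=res, voxel_size=voxel,
        )
    except ValueError:
        return None, samples
    return sf, sf.samples
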