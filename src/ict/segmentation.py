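"""Segmentation of tracheid, wood-ray and resin-canal lumens from tomograms.

The lumens (air voids) are the segmentation primitive: they binarize cleanly
against cell-wall substance and form approximately closed tubes.  The stages
are: Otsu binarization; two-pass morphological detection (a coarse opening
that keeps wide earlywood lumens, then a fine second pass that recovers thin
latewood lumens and ray cells); per-label classification by principal
elongation axis; skeleton-style assignment of wall substance to the nearest
lumen (the middle lamella gives no contrast, so wall ownership is geometric);
ray clustering; and density / ray-distance maps.

All morphology uses exact Euclidean structuring balls implemented through
distance transforms, which keeps large radii cheap on multi-hundred-megavoxel
volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from .phantom import GrayVolume

__all__ = [
    "BinaryVolume",
    "LabelVolume",
    "SegmentationParams",
    "RayClusterSet",
    "binarize_otsu",
    "otsu_threshold",
    "segment_lumens",
    "classify_cells",
    "assign_wall",
    "cluster_rays",
    "density_profile",
    "ray_distance_map",
]


@dataclass
class BinaryVolume:
    """Binarized lumen mask A(x,y,z): True where air/lumen."""

    lumen: np.ndarray
    voxel_size: float
    threshold: float | None = None


@dataclass
class SegmentationParams:
    """Tunable morphology parameters (voxel units unless noted).

    ``r1`` is the first-pass opening radius: lumens whose half-width is below
    it are deliberately deferred to the second pass (``r1_pass2``), which is
    how thin-walled latewood cells and ray lumens are recovered.
    """

    r1: float = 7.0
    r2: float = 2.0
    r1_pass2: float = 1.0
    r2_pass2: float = 1.0
    min_volume: int = 500
    max_labels: int = 100_000
    max_wall_dist: float = 15.0  # um
    denoise_sigma: float = 0.0  # Gaussian pre-filter before thresholding, voxels
    resin_canal_min: float = 60.0  # um, mean cross-section diameter
    restore_margin: float = 3.0  # extra reach of shape restoration, voxels


@dataclass
class LabelVolume:
    """Per-voxel lumen index plus per-label metadata.

    ``labels == 0`` means "not a lumen".  ``category`` maps label ->
    {tracheid, ray, resin_canal, unclassified}; ``detection_pass`` records
    which morphological pass found each label; ``wall_owner`` (filled by
    :func:`assign_wall`) maps every cell-wall voxel within reach to the
    geometrically closest lumen.
    """

    labels: np.ndarray
    voxel_size: float
    category: dict[int, str] = field(default_factory=dict)
    detection_pass: dict[int, int] = field(default_factory=dict)
    wall_owner: np.ndarray | None = None
    wall_dist: np.ndarray | None = None  # um, distance to nearest lumen
    border_lateral: dict[int, bool] = field(default_factory=dict)
    threshold: float | None = None
    params: SegmentationParams | None = None

    @property
    def label_ids(self) -> np.ndarray:
        out = np.unique(self.labels)
        return out[out > 0]

    def ids_of(self, category: str) -> list[int]:
        return [k for k, v in self.category.items() if v == category]


@dataclass
class RayClusterSet:
    """Grouping of ray lumen labels into wood rays."""

    clusters: dict[int, list[int]]
    centroids_LT: dict[int, np.ndarray]  # label -> (y, z) um

    def cluster_of(self, label: int) -> int:
        for cid, members in self.clusters.items():
            if label in members:
                return cid
        raise KeyError(label)


# ---------------------------------------------------------------------------
# morphology primitives (exact Euclidean balls via distance transforms)
# ---------------------------------------------------------------------------

def _erode(mask: np.ndarray, r: float) -> np.ndarray:
    if r <= 0:
        return mask.copy()
    if r <= 1:
        # a unit Euclidean ball removes exactly the face-adjacent shell
        return ndi.binary_erosion(mask)
    return ndi.distance_transform_edt(mask) > r


def _dilate(mask: np.ndarray, r: float) -> np.ndarray:
    if r <= 0:
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= r


def _open(mask: np.ndarray, r: float) -> np.ndarray:
    return _dilate(_erode(mask, r), r)


def _close(mask: np.ndarray, r: float) -> np.ndarray:
    return _erode(_dilate(mask, r), r)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def otsu_threshold(data: np.ndarray) -> float:
    """Otsu threshold of an 8-bit (or float) volume over a 256-bin histogram.

    Maximizes the between-class variance over all 256 split points; voxels
    strictly below the returned value form the lumen (air) class.  The first
    maximizing split is returned, so a two-value image splits just above the
    lower value.
    """
    flat = data.reshape(-1)
    if flat.min() == flat.max():
        raise ValueError("degenerate histogram: constant image")
    if data.dtype == np.uint8:
        hist = np.bincount(flat, minlength=256).astype(float)
        edges = np.arange(257, dtype=float)
    else:
        hist, e = np.histogram(flat, bins=256)
        hist = hist.astype(float)
        edges = e
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:]) if data.dtype != np.uint8 \
        else np.arange(256, dtype=float)
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mtot = m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = m[:-1] / w0
        m1 = (mtot - m[:-1]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
    var[~np.isfinite(var)] = -1.0
    k = int(np.argmax(var))  # split between bins k and k+1
    return float(edges[k + 1])


def binarize_otsu(vol: GrayVolume) -> BinaryVolume:
    """Threshold the 8-bit volume with Otsu's method; below-threshold = lumen."""
    thr = otsu_threshold(vol.data)
    return BinaryVolume(lumen=vol.data < thr, voxel_size=vol.voxel_size,
                        threshold=thr)


def _geodesic_expand(lab: np.ndarray, support: np.ndarray, steps: float) -> np.ndarray:
    """Propagate labels into unlabeled support voxels, one shell per step.

    Propagation is geodesic (confined to ``support``), so a label never
    crosses cell-wall substance into a neighbouring lumen.
    """
    out = lab.copy()
    for _ in range(int(np.ceil(steps))):
        grown = ndi.maximum_filter(out, size=3)
        newly = (out == 0) & support & (grown > 0)
        if not newly.any():
            break
        out[newly] = grown[newly]
    return out


def _label_and_restore(
    mask: np.ndarray,
    support: np.ndarray,
    r_open: float,
    r_close: float,
    params: SegmentationParams,
) -> np.ndarray:
    """One detection pass: open, close, label, restore shapes within support.

    Shape restoration is an opening-by-reconstruction in spirit: each label
    surviving the opening is grown back over the support voxels it was shaved
    from (including pit indentations), but growth is geodesic and capped, so
    a thin leak between two lumens is split near its midline instead of
    re-merging the pair as plain geodesic reconstruction would.
    """
    # survival of the opening is decided by the erosion alone, and the
    # restoration step regrows the exact shape from the support, so there is
    # no need to dilate the cores back; the closing (cheap diamond
    # approximation) reunites cores split by pit apertures
    cores = _erode(mask, r_open)
    if r_close > 0 and cores.any():
        cores = ndi.binary_closing(cores, iterations=int(np.ceil(r_close)))
    cores &= support
    lab = cc_label(cores, connectivity=3).astype(np.int32)
    if lab.max() == 0:
        return lab
    reach = r_open + r_close + params.restore_margin
    return _geodesic_expand(lab, support, reach)


def _reconstruct_components(mask: np.ndarray, marker_r: float) -> np.ndarray:
    """Opening by reconstruction: keep components surviving an erosion, whole.

    Components of ``mask`` that contain at least one voxel of the erosion by
    ``marker_r`` are restored exactly; the rest (specks) are dropped.  Used
    for the fine second pass, where thin latewood/ray tubes would fragment
    under a plain opening.
    """
    lab = cc_label(mask, connectivity=3).astype(np.int32)
    if lab.max() == 0:
        return lab
    marker = _erode(mask, marker_r)
    keep = np.unique(lab[marker])
    keep = keep[keep > 0]
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    lut[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return lut[lab]



def _merge_wide_contacts(labels: np.ndarray, pass_of: np.ndarray,
                         min_frac: float = 0.3):
    """Union labels meeting over wide interfaces (same-tube fragments)."""
    grown = ndi.maximum_filter(labels, size=3)
    touch = (labels > 0) & (grown > labels)
    if not touch.any():
        return labels, pass_of
    pairs, contact = np.unique(
        np.stack([labels[touch], grown[touch]], axis=1), axis=0,
        return_counts=True,
    )
    vols = np.bincount(labels.reshape(-1))
    objs = ndi.find_objects(labels)
    cross = {}
    for i in np.unique(pairs):
        sl = objs[int(i) - 1]
        if sl is None:
            continue
        length = max(sp.stop - sp.start for sp in sl)
        cross[int(i)] = vols[int(i)] / max(length, 1)
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    merged_any = False
    for (a, b), c in zip(pairs, contact):
        a, b = int(a), int(b)
        if a not in cross or b not in cross:
            continue
        if c >= min_frac * min(cross[a], cross[b]):
            pa, pb = find(a), find(b)
            if pa != pb:
                parent[max(pa, pb)] = min(pa, pb)
                merged_any = True
    if not merged_any:
        return labels, pass_of
    lut = np.arange(int(labels.max()) + 1, dtype=np.int32)
    for i in range(1, len(lut)):
        lut[i] = find(int(i)) if i in parent else i
    new_pass = pass_of.copy()
    for i in range(1, len(lut)):
        if lut[i] != i:
            new_pass[lut[i]] = min(new_pass[lut[i]], pass_of[i])
    return lut[labels], new_pass


def segment_lumens(
    binv: BinaryVolume, params: SegmentationParams | None = None
) -> LabelVolume:
    """Two-pass morphological segmentation of lumen voids.

    Pass 1 (radius ``r1``) detects wide lumens; pass 2 re-runs on the
    remaining void voxels with radius ``r1_pass2`` to capture thin latewood
    and ray lumens.  Components below ``min_volume`` voxels are discarded.
    """
    params = params or SegmentationParams()
    A = binv.lumen
    lab1 = _label_and_restore(A, A, params.r1, params.r2, params)
    remaining = A & (lab1 == 0)
    lab2 = _reconstruct_components(remaining, params.r1_pass2)

    labels = lab1.copy()
    offset = int(lab1.max())
    m2 = lab2 > 0
    labels[m2] = lab2[m2] + offset
    pass_of = np.zeros(int(labels.max()) + 1, dtype=np.int8)
    pass_of[1:offset + 1] = 1
    pass_of[offset + 1:] = 2

    # Unify fragments of one tube: a borderline cell can survive the coarse
    # opening only in patches, leaving axially stacked pieces (from either
    # pass) that meet over a wide cross-section interface.  A thin leak
    # between two distinct lumens also creates contact, but over a narrow
    # channel.  Merge label pairs whose contact area is a substantial
    # fraction of the smaller piece's characteristic cross-section.
    labels, pass_of = _merge_wide_contacts(labels, pass_of, min_frac=0.3)

    # drop undersized components, compact ids, record the pass
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= params.min_volume]
    if keep.size == 0:
        raise ValueError("no lumen labels found; check binarization/morphology")
    if keep.size > params.max_labels:
        raise ValueError(
            f"over-segmentation: {keep.size} labels; adjust opening radii"
        )
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    labels = remap[labels]
    passes = {int(remap[i]): int(pass_of[i]) for i in keep}

    out = LabelVolume(
        labels=labels,
        voxel_size=binv.voxel_size,
        detection_pass=passes,
        threshold=binv.threshold,
        params=params,
    )
    _flag_borders(out)
    return out


def _flag_borders(lv: LabelVolume) -> None:
    """Mark labels touching the lateral (X/Y) faces of the volume.

    Axially truncated cells are the norm (every tube is cut by the Z faces),
    but laterally cut cells have distorted cross-sections and are excluded
    from strain statistics.
    """
    lab = lv.labels
    faces = [lab[0], lab[-1], lab[:, 0], lab[:, -1]]
    touching = np.unique(np.concatenate([f.ravel() for f in faces]))
    touch = set(int(i) for i in touching if i > 0)
    for i in lv.label_ids:
        lv.border_lateral[int(i)] = int(i) in touch


def classify_cells(lv: LabelVolume) -> LabelVolume:
    """Assign tracheid / ray / resin_canal category per label.

    The principal elongation axis of each label's voxel cloud decides the
    category: Z-aligned tubes are tracheids (oversized ones resin canals),
    X-aligned tubes are wood rays.  Labels with fewer than 20 voxels are
    left unclassified and excluded downstream.
    """
    voxel = lv.voxel_size
    rc_min = (lv.params.resin_canal_min if lv.params else 60.0)
    objects = ndi.find_objects(lv.labels)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        coords = np.argwhere(lv.labels[sl] == i).astype(float)
        if coords.shape[0] < 20:
            lv.category[i] = "unclassified"
            continue
        c = coords - coords.mean(axis=0)
        cov = c.T @ c / coords.shape[0]
        w, v = np.linalg.eigh(cov)
        axis = v[:, np.argmax(w)]
        length = coords @ axis
        length_vox = length.max() - length.min() + 1.0
        mean_area_vox = coords.shape[0] / length_vox
        mean_diam_um = 2.0 * np.sqrt(mean_area_vox / np.pi) * voxel
        if abs(axis[2]) >= 0.7:
            lv.category[i] = (
                "resin_canal" if mean_diam_um > rc_min else "tracheid"
            )
        elif abs(axis[0]) >= 0.7:
            lv.category[i] = "ray"
        else:
            lv.category[i] = "unclassified"
    return lv


def assign_wall(lv: LabelVolume, binv: BinaryVolume) -> LabelVolume:
    """Assign cell-wall substance voxels to the geometrically closest lumen.

    Fills ``wall_owner``: for every wall voxel (material, i.e. not lumen in
    the binary mask) within ``max_wall_dist`` of a lumen, the label of the
    nearest lumen voxel (exact Euclidean distance).  The resulting per-cell
    territories extend to the mid-wall, which is what the skeletonized
    cross-section area/perimeter of the parameterization measure.
    """
    params = lv.params or SegmentationParams()
    dist, idx = ndi.distance_transform_edt(
        lv.labels == 0, sampling=lv.voxel_size, return_indices=True
    )
    owner = lv.labels[tuple(idx)]
    wall = ~binv.lumen
    owner = np.where(wall & (dist <= params.max_wall_dist), owner, 0)
    owner = owner.astype(np.int32)
    owner[lv.labels > 0] = 0  # owner stores wall voxels only
    lv.wall_owner = owner
    lv.wall_dist = dist.astype(np.float32)
    return lv


def cluster_rays(
    lv: LabelVolume, cluster_gap: float = 20.0, min_overlap: float = 0.3
) -> RayClusterSet:
    """Merge ray lumens into wood rays by LT proximity and R-extent overlap.

    Single linkage: two ray lumens join the same cluster when their (T, L)
    centroids are within ``cluster_gap`` (um) and their R extents overlap by
    at least ``min_overlap`` of the shorter extent.
    """
    voxel = lv.voxel_size
    ray_ids = lv.ids_of("ray")
    if not ray_ids:
        return RayClusterSet(clusters={}, centroids_LT={})
    cents: dict[int, np.ndarray] = {}
    extents: dict[int, tuple[float, float]] = {}
    objects = ndi.find_objects(lv.labels)
    for i in ray_ids:
        sl = objects[i - 1]
        coords = np.argwhere(lv.labels[sl] == i).astype(float)
        coords += [s.start for s in sl]
        cents[i] = coords[:, 1:3].mean(axis=0) * voxel  # (T, L) um
        extents[i] = (coords[:, 0].min() * voxel, coords[:, 0].max() * voxel)

    parent = {i: i for i in ray_ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    ids = list(ray_ids)
    for k, a in enumerate(ids):
        for b in ids[k + 1:]:
            if np.linalg.norm(cents[a] - cents[b]) > cluster_gap:
                continue
            (a0, a1), (b0, b1) = extents[a], extents[b]
            inter = min(a1, b1) - max(a0, b0)
            shorter = min(a1 - a0, b1 - b0)
            if shorter <= 0 or inter < min_overlap * shorter:
                continue
            parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for i in ray_ids:
        groups.setdefault(find(i), []).append(i)
    clusters = {ci: sorted(m) for ci, m in enumerate(groups.values(), start=1)}
    return RayClusterSet(clusters=clusters, centroids_LT=cents)


def density_profile(
    binv: BinaryVolume,
    lv: LabelVolume | None,
    axis: int | str,
    gravimetric_density: float,
    slab_um: float = 10.0,
) -> pd.DataFrame:
    """Wall-substance density profile along an axis, in kg/m^3.

    The wall-voxel indicator is averaged per slab and scaled so the
    volume-weighted mean over the whole volume equals the specimen's
    gravimetric density (the baseline normalization).  Also reports the
    ray-lumen voxel fraction per slab when labels are supplied.
    """
    if gravimetric_density <= 0:
        raise ValueError("gravimetric_density must be > 0")
    ax = {"x": 0, "y": 1, "z": 2, "R": 0, "T": 1, "L": 2}.get(axis, axis)
    wall = ~binv.lumen
    voxel = binv.voxel_size
    n = wall.shape[ax]
    other = tuple(i for i in range(3) if i != ax)
    frac = wall.mean(axis=other)
    slab = max(int(round(slab_um / voxel)), 1)
    nbin = int(np.ceil(n / slab))
    pos = np.empty(nbin)
    dens = np.empty(nbin)
    count = np.empty(nbin)
    for b in range(nbin):
        s = slice(b * slab, min((b + 1) * slab, n))
        pos[b] = (0.5 * (s.start + s.stop)) * voxel
        dens[b] = frac[s].mean()
        count[b] = s.stop - s.start
    mean_frac = float(np.average(dens, weights=count))
    scale = gravimetric_density / mean_frac
    out = pd.DataFrame({"position_um": pos, "density_kg_m3": dens * scale})
    out.attrs["wall_density_kg_m3"] = scale  # normalization constant
    if lv is not None:
        ray_ids = lv.ids_of("ray")
        ray = np.isin(lv.labels, ray_ids) if ray_ids else np.zeros_like(wall)
        rfrac = ray.mean(axis=other)
        out["ray_fraction"] = [rfrac[b * slab:min((b + 1) * slab, n)].mean()
                               for b in range(nbin)]
    return out


def ray_distance_map(lv: LabelVolume) -> np.ndarray:
    """Per-voxel Euclidean distance (um) to the nearest ray lumen voxel."""
    ray_ids = lv.ids_of("ray")
    if not ray_ids:
        warnings.warn("no ray labels; distance map is infinite", stacklevel=2)
        return np.full(lv.labels.shape, np.inf, dtype=np.float32)
    ray = np.isin(lv.labels, ray_ids)
    return ndi.distance_transform_edt(~ray, sampling=lv.voxel_size).astype(np.float32)
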