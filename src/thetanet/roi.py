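"""Data-driven region-of-interest definition from voxel activity maps.

Pipeline: select the top fraction of voxels by source power (or all
voxels within a given proximity of the maximum), cluster them with
DBSCAN (epsilon = twice the voxel edge length, so face/edge/corner grid
neighbours connect), drop voxels in excluded anatomical structures or
left unclustered, and assemble the surviving clusters into named ROIs by
their atlas labels.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
from sklearn.cluster import DBSCAN

from .containers import ROICluster, VoxelActivityMap

__all__ = [
    "threshold_voxels",
    "dbscan_cluster",
    "filter_voxels",
    "define_rois",
    "hemisphere_filter",
    "select_rois",
    "LABEL_NAMES",
    "DEFAULT_EXCLUDED_LABELS",
    "default_label_mapping",
]

# Integer atlas codes used by the synthetic label fields. The scheme is a
# compact stand-in for a full anatomical parcellation: code 0 is outside
# the brain, single digits are excluded tissue classes, tens are cortical
# regions grouped by ROI.
LABEL_NAMES: dict[int, str] = {
    0: "outside_brain",
    1: "cortex_unspecified",
    2: "white_matter",
    3: "cerebellum",
    4: "basal_ganglia",
    10: "insula",
    20: "inferior_temporal_gyrus",
    21: "temporal_pole_middle",
    22: "superior_temporal_gyrus",
    23: "middle_temporal_gyrus",
    24: "temporal_pole_superior",
    30: "ifg_opercular",
    31: "ifg_orbital",
    32: "rolandic_operculum",
    40: "lingual_gyrus",
}

#: Tissue classes removed before ROI assembly (outside-brain voxels are
#: already ignored at thresholding).
DEFAULT_EXCLUDED_LABELS = frozenset({2, 3, 4})

_ATL_LABELS = frozenset({20, 21, 22, 23, 24})
_IC_LABELS = frozenset({10})
_IFC_CORE_LABELS = frozenset({30, 31})
_LG_LABELS = frozenset({40})


def default_label_mapping(
    group: str = "adult", phase: str = "action_planning"
) -> dict[int, str]:
    """Label -> ROI name mapping for a group and phase.

    The inferior frontal ROI includes the rolandic operculum except in
    the adult perception phase; the lingual gyrus ROI exists only for the
    adolescent group.
    """
    mapping = {code: "ATL" for code in _ATL_LABELS}
    mapping.update({code: "IC" for code in _IC_LABELS})
    mapping.update({code: "IFC" for code in _IFC_CORE_LABELS})
    include_rolandic = not (group == "adult" and phase == "perception")
    if include_rolandic:
        mapping[32] = "IFC"
    if group == "adolescent":
        mapping.update({code: "LG" for code in _LG_LABELS})
    return mapping


def threshold_voxels(
    vmap: VoxelActivityMap,
    percent: float = 0.03,
    mode: str = "top_fraction",
) -> np.ndarray:
    """Select the most active voxels among in-brain voxels.

    mode="top_fraction" keeps the ``ceil(percent * N_valid)`` highest-power
    voxels; ties at the cut are all included. mode="near_max" keeps every
    voxel with power within ``percent`` of the map maximum, i.e.
    ``power >= (1 - percent) * max``.

    Returns sorted voxel indices into the map.
    """
    if not (0 < percent <= 1):
        raise ValueError("percent must be in (0, 1]")
    valid = np.flatnonzero(vmap.labels != 0)
    if valid.size == 0:
        raise ValueError("no in-brain voxels in the map")
    powers = vmap.power[valid]
    if np.ptp(powers) == 0:
        warnings.warn("all voxel powers equal; selecting every valid voxel")
        return np.sort(valid)
    if mode == "top_fraction":
        k = int(np.ceil(percent * valid.size))
        cut = np.sort(powers)[::-1][k - 1]
        chosen = valid[powers >= cut]
    elif mode == "near_max":
        chosen = valid[powers >= (1.0 - percent) * powers.max()]
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return np.sort(chosen)


def dbscan_cluster(
    points: np.ndarray, eps: float = 10.0, min_pts: int = 4
) -> np.ndarray:
    """Density-based clustering of voxel coordinates.

    Standard DBSCAN semantics: a core point has at least ``min_pts``
    points (itself included) within Euclidean distance ``eps``; noise
    points get label -1. The default eps of 10 mm is twice the 5 mm grid
    edge so that diagonal grid neighbours still connect.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_


def filter_voxels(
    selected: np.ndarray,
    vmap: VoxelActivityMap,
    exclusion_labels: Iterable[int] = DEFAULT_EXCLUDED_LABELS,
    cluster_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Drop excluded-label voxels and (optionally) unclustered voxels.

    ``cluster_labels`` aligns with ``selected``; voxels labelled -1
    (noise) are removed. Returns the retained subset of ``selected``
    (order preserved).
    """
    selected = np.asarray(selected, dtype=int)
    excl = set(exclusion_labels) | {0}
    keep = ~np.isin(vmap.labels[selected], list(excl))
    if cluster_labels is not None:
        cluster_labels = np.asarray(cluster_labels)
        if cluster_labels.shape != selected.shape:
            raise ValueError("cluster_labels must align with selected voxels")
        keep &= cluster_labels >= 0
    out = selected[keep]
    if out.size == 0 and selected.size > 0:
        warnings.warn("all selected voxels were excluded")
    return out


def hemisphere_filter(
    selected: np.ndarray,
    vmap: VoxelActivityMap,
    hemisphere: str = "right",
    positive_x_is_right: bool = True,
) -> np.ndarray:
    """Keep voxels in one hemisphere by the sign of the x coordinate."""
    selected = np.asarray(selected, dtype=int)
    x = vmap.coordinates[selected, 0]
    want_positive = (hemisphere == "right") == positive_x_is_right
    return selected[x > 0] if want_positive else selected[x < 0]


def define_rois(
    vmap: VoxelActivityMap,
    selected: np.ndarray,
    cluster_labels: np.ndarray,
    label_to_roi: Mapping[int, str],
) -> list[ROICluster]:
    """Assemble clustered voxels into named ROIs by atlas label.

    Every retained voxel's label must appear in ``label_to_roi``; an
    unmapped label raises. One ROICluster is emitted per ROI name,
    pooling all clustered voxels whose labels map to it.
    """
    selected = np.asarray(selected, dtype=int)
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.shape != selected.shape:
        raise ValueError("cluster_labels must align with selected voxels")
    in_cluster = cluster_labels >= 0
    labels = vmap.labels[selected[in_cluster]]
    unmapped = sorted(set(labels.tolist()) - set(label_to_roi))
    if unmapped:
        names = ", ".join(
            f"{code} ({LABEL_NAMES.get(code, 'unknown')})" for code in unmapped
        )
        raise KeyError(f"retained voxel labels with no ROI mapping: {names}")
    rois: list[ROICluster] = []
    by_roi: dict[str, list[int]] = {}
    for idx, clab in zip(selected[in_cluster], cluster_labels[in_cluster]):
        by_roi.setdefault(label_to_roi[vmap.labels[idx]], []).append(idx)
    for k, (name, members) in enumerate(sorted(by_roi.items())):
        members = np.asarray(members)
        rois.append(
            ROICluster(
                members=members,
                cluster_id=k,
                roi_name=name,
                centroid=vmap.coordinates[members].mean(axis=0),
            )
        )
    return rois


def select_rois(
    vmap: VoxelActivityMap,
    percent: float = 0.03,
    mode: str = "top_fraction",
    eps: float | None = None,
    min_pts: int = 4,
    exclusion_labels: Iterable[int] = DEFAULT_EXCLUDED_LABELS,
    label_to_roi: Mapping[int, str] | None = None,
    hemisphere: str | None = None,
) -> list[ROICluster]:
    """Full ROI pipeline: threshold -> cluster -> filter -> assemble."""
    if eps is None:
        eps = 2.0 * vmap.edge_length
    if label_to_roi is None:
        label_to_roi = default_label_mapping()
    selected = threshold_voxels(vmap, percent, mode)
    selected = filter_voxels(selected, vmap, exclusion_labels)
    if hemisphere is not None:
        selected = hemisphere_filter(selected, vmap, hemisphere)
    if selected.size == 0:
        return []
    clabels = dbscan_cluster(vmap.coordinates[selected], eps=eps, min_pts=min_pts)
    return define_rois(vmap, selected, clabels, label_to_roi)
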