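"""Longitudinal cell tracking across imaging sessions.

Sessions are registered to the first session by a least-squares affine
transform fitted on manually placed landmarks; each new ROI is then matched
to the nearest catalogued centroid. Pairs with duplicate targets, low mask
overlap (< 80% of the smaller mask), or centroid distance more than 2 SD
above the mean matched distance are flagged for review rather than silently
accepted; far-flagged ROIs are treated as new cells when building the
cumulative catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RoiSet",
    "TransformModel",
    "MatchTable",
    "fit_transform",
    "match_rois",
    "merge_across_sessions",
]


@dataclass
class RoiSet:
    """ROIs of one session: ids, pixel masks (Nx2 int arrays) and centroids."""

    ids: list
    masks: list[np.ndarray]
    centroids: np.ndarray
    image_size: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.ids) != len(self.masks) or len(self.ids) != len(self.centroids):
            raise ValueError("ids, masks and centroids must align")
        if len(self.ids) == 0:
            raise ValueError("empty ROI set")
        for m in self.masks:
            if np.asarray(m).size == 0:
                raise ValueError("empty ROI mask")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TransformModel:
    """2-D affine map y = A x + b (6 dof) with its fit residual in px."""

    A: np.ndarray
    b: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.b = np.asarray(self.b, dtype=float).reshape(2)
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ValueError("transform is not invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.A.T + self.b

    @classmethod
    def identity(cls) -> "TransformModel":
        return cls(A=np.eye(2), b=np.zeros(2))


@dataclass
class MatchTable:
    """Accepted and flagged centroid matches between two sessions."""

    pairs: pd.DataFrame  # ref_id, new_id, distance_px, overlap, flags
    new_cells: list = field(default_factory=list)

    @property
    def accepted(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flags"] == ""]


def fit_transform(
    landmarks_ref: np.ndarray, landmarks_new: np.ndarray
) -> TransformModel:
    """Least-squares affine map taking new-session landmarks onto reference.

    Needs at least 3 non-collinear landmark pairs.
    """
    ref = np.asarray(landmarks_ref, dtype=float)
    new = np.asarray(landmarks_new, dtype=float)
    if ref.shape != new.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("landmark arrays must be matching Nx2")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 landmark pairs")
    design = np.hstack([new, np.ones((new.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear")
    coef, _, _, _ = np.linalg.lstsq(design, ref, rcond=None)
    A = coef[:2].T
    b = coef[2]
    residual = float(np.sqrt(np.mean(np.sum((design @ coef - ref) ** 2, axis=1))))
    return TransformModel(A=A, b=b, residual=residual)


def _mask_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A ∩ B| / min(|A|, |B|) on integer pixel coordinates."""
    a = {tuple(p) for p in np.asarray(mask_a, dtype=int)}
    b = {tuple(p) for p in np.asarray(mask_b, dtype=int)}
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def _transform_roiset(rois: RoiSet, transform: TransformModel) -> RoiSet:
    masks = [np.round(transform.apply(np.asarray(m, float))).astype(int) for m in rois.masks]
    return RoiSet(
        ids=list(rois.ids),
        masks=masks,
        centroids=transform.apply(rois.centroids),
        image_size=rois.image_size,
    )


def match_rois(
    ref: RoiSet,
    new: RoiSet,
    transform: TransformModel | None = None,
    overlap_threshold: float = 0.8,
    distance_sd_factor: float = 2.0,
) -> MatchTable:
    """Nearest-centroid matching of new-session ROIs to the reference set.

    Every new ROI is assigned its nearest reference centroid after applying
    the transform; flags mark pairs needing review:

    * ``duplicate`` — two or more new ROIs share the same reference target;
    * ``low_overlap`` — mask overlap below ``overlap_threshold``;
    * ``far_centroid`` — matched distance more than ``distance_sd_factor``
      SDs above the mean matched distance (these are candidate new cells).
    """
    if transform is None:
        transform = TransformModel.identity()
    moved = _transform_roiset(new, transform)
    tree = cKDTree(ref.centroids)
    dist, nearest = tree.query(moved.centroids)

    counts = np.bincount(nearest, minlength=len(ref))
    mean_d, sd_d = float(np.mean(dist)), float(np.std(dist, ddof=1)) if len(dist) > 1 else 0.0
    far_cut = mean_d + distance_sd_factor * sd_d

    rows = []
    for k, (ref_idx, d) in enumerate(zip(nearest, dist)):
        overlap = _mask_overlap(ref.masks[ref_idx], moved.masks[k])
        flags = []
        if counts[ref_idx] > 1:
            flags.append("duplicate")
        if overlap < overlap_threshold:
            flags.append("low_overlap")
        if sd_d > 0 and d > far_cut:
            flags.append("far_centroid")
        rows.append(
            (ref.ids[ref_idx], moved.ids[k], float(d), float(overlap), "|".join(flags))
        )
    pairs = pd.DataFrame(
        rows, columns=["ref_id", "new_id", "distance_px", "overlap", "flags"]
    )
    new_cells = list(pairs.loc[pairs["flags"].str.contains("far_centroid"), "new_id"])
    return MatchTable(pairs=pairs, new_cells=new_cells)


def merge_across_sessions(
    sessions: list[tuple[RoiSet, np.ndarray]],
    reference_landmarks: np.ndarray | None = None,
    overlap_threshold: float = 0.8,
    exclusion_overlap: float = 0.5,
) -> pd.DataFrame:
    """Build a cross-session identity table of tracked neurons.

    ``sessions`` is a list of ``(RoiSet, landmarks)``; all landmark arrays
    mark the same physical points, and every session is registered to the
    first. Each session's ROIs are matched against the cumulative catalogue;
    far-centroid ROIs (and the losers of duplicate matches) found no
    counterpart and are appended as new cells. Catalogued ROIs that overlap
    another catalogued ROI by more than ``exclusion_overlap`` (mutual
    overlap; ambiguous identity) are dropped at the end.

    Returns a tidy DataFrame with columns ``global_id, session, local_id,
    flags``; accepted matches form an injective map per session.
    """
    if not sessions:
        raise ValueError("no sessions")
    first_rois, first_lm = sessions[0]
    if reference_landmarks is None:
        reference_landmarks = first_lm

    catalogue = _transform_roiset(first_rois, TransformModel.identity())
    cat_ids = [f"g{k}" for k in range(len(first_rois))]
    catalogue.ids = list(cat_ids)
    rows = [
        (cat_ids[k], 0, first_rois.ids[k], "") for k in range(len(first_rois))
    ]

    for s_idx, (rois, landmarks) in enumerate(sessions[1:], start=1):
        tf = fit_transform(reference_landmarks, landmarks)
        moved = _transform_roiset(rois, tf)
        table = match_rois(catalogue, moved, TransformModel.identity(), overlap_threshold)
        # keep only the closest new ROI per duplicated target
        best_for_ref: dict = {}
        for r in table.pairs.itertuples():
            cur = best_for_ref.get(r.ref_id)
            if cur is None or r.distance_px < cur.distance_px:
                best_for_ref[r.ref_id] = r
        for r in table.pairs.itertuples():
            is_far = "far_centroid" in r.flags
            lost_duplicate = (
                "duplicate" in r.flags and best_for_ref[r.ref_id].new_id != r.new_id
            )
            if is_far or lost_duplicate:
                gid = f"g{len(cat_ids)}"
                cat_ids.append(gid)
                k = list(moved.ids).index(r.new_id)
                catalogue.ids.append(gid)
                catalogue.masks.append(moved.masks[k])
                catalogue.centroids = np.vstack([catalogue.centroids, moved.centroids[k]])
                rows.append((gid, s_idx, r.new_id, "new_cell"))
            else:
                rows.append((r.ref_id, s_idx, r.new_id, r.flags))

    df = pd.DataFrame(rows, columns=["global_id", "session", "local_id", "flags"])

    # drop catalogued ROIs that overlap each other extensively
    drop: set = set()
    tree = cKDTree(catalogue.centroids)
    close = tree.query_pairs(r=20.0)
    for i, j in close:
        if _mask_overlap(catalogue.masks[i], catalogue.masks[j]) > exclusion_overlap:
            drop.add(catalogue.ids[i])
            drop.add(catalogue.ids[j])
    if drop:
        df = df[~df["global_id"].isin(drop)].reset_index(drop=True)
    return df
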