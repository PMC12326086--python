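"""Per-second flock membership, centroid, heading, spread and relative positions.

A flock at a timestamp is the largest connected component of the 10 m
proximity graph over bird positions (pairs within 10 m are "flying
cohesively"; chain connectivity is allowed).  The centroid is made robust to
splits by iteratively excluding members 40 m or farther from it and
recomputing, which weights the centroid toward the larger subgroup; excluded
birds may rejoin at later timestamps.  The flock's travel heading comes from
stepwise centroid displacement, and each member's offset from the centroid is
decomposed into a signed front-back component (along heading, ahead positive)
and a signed left-right component (right positive).  Absolute flock spread is
the front-back extent plus the left-right extent of the membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

DEFAULT_LINK_DIST_M = 10.0
DEFAULT_EXCL_DIST_M = 40.0
#: centroid displacement below which the previous heading is carried forward
DEFAULT_STATIONARY_THRESHOLD_M = 0.5


@dataclass
class FlockFrame:
    """Flock state at one whole second."""

    flock_id: str
    t: float
    members: tuple[str, ...]
    centroid: tuple[float, float]
    heading: tuple[float, float]
    group_size: int
    absolute_spread: float
    #: bird_id -> (distance_to_centroid, front_back, left_right, position)
    per_member: dict[str, tuple[float, float, float, str]]


def cohesive_members(positions: dict[str, tuple[float, float]],
                     link_dist_m: float = DEFAULT_LINK_DIST_M,
                     prev_centroid: tuple[float, float] | None = None,
                     ) -> set[str]:
    """Largest connected component of the proximity graph.

    Components of size 1 mean no flock (empty set).  Ties between equal-size
    components go to the component whose mean position is nearest
    ``prev_centroid`` (callers pass the previous frame's centroid, or a point
    on the release-to-home axis for the first frame; with no tiebreak point
    the lexicographically first component wins deterministically).
    """
    ids = sorted(positions)
    if len(ids) < 2:
        return set()
    pts = np.array([positions[i] for i in ids])
    adj = squareform(pdist(pts) <= link_dist_m).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    if best < 2:
        return set()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1 and prev_centroid is not None:
        means = np.array([pts[labels == c].mean(axis=0) for c in candidates])
        d = np.hypot(*(means - np.asarray(prev_centroid)).T)
        winner = candidates[int(np.argmin(d))]
    else:
        winner = candidates[0]
    return {ids[i] for i in np.flatnonzero(labels == winner)}


def robust_centroid(positions: dict[str, tuple[float, float]],
                    members: set[str],
                    excl_dist_m: float = DEFAULT_EXCL_DIST_M,
                    ) -> tuple[tuple[float, float] | None, set[str]]:
    """Mean position after iterative exclusion of members >= 40 m away.

    The farthest member at or beyond the exclusion radius is dropped and
    the centroid recomputed, repeating until every remaining member is
    within the radius (the set strictly shrinks, so at most ``|members|``
    iterations).  One-at-a-time trimming lets the centroid re-centre on the
    larger subgroup when a flock splits, so the majority dominates; the
    final centroid is the plain mean of the final member set.  Returns
    ``(None, set())`` when everything is excluded.  Exclusion is
    per-timestamp only — birds may rejoin at later timestamps.
    """
    current = set(members)
    while current:
        ids = sorted(current)
        pts = np.array([positions[i] for i in ids])
        centroid = pts.mean(axis=0)
        dist = np.hypot(*(pts - centroid).T)
        worst = int(np.argmax(dist))
        if dist[worst] < excl_dist_m:
            return (float(centroid[0]), float(centroid[1])), current
        current.remove(ids[worst])
    return None, set()


def travel_heading(centroid_now: tuple[float, float],
                   centroid_next: tuple[float, float] | None,
                   prev_heading: tuple[float, float] | None,
                   fallback: tuple[float, float],
                   stationary_threshold_m: float = DEFAULT_STATIONARY_THRESHOLD_M,
                   ) -> tuple[float, float]:
    """Unit direction of travel from the stepwise centroid displacement.

    Near-stationary steps (< 0.5 m) carry the previous heading forward; the
    first frame with no prior heading uses ``fallback`` (the release-to-home
    unit vector).
    """
    if centroid_next is not None:
        dx = centroid_next[0] - centroid_now[0]
        dy = centroid_next[1] - centroid_now[1]
        norm = float(np.hypot(dx, dy))
        if norm >= stationary_threshold_m:
            return (dx / norm, dy / norm)
    if prev_heading is not None:
        return prev_heading
    fx, fy = fallback
    norm = float(np.hypot(fx, fy))
    return (fx / norm, fy / norm)


def decompose_position(bird_pos: tuple[float, float],
                       centroid: tuple[float, float],
                       heading: tuple[float, float],
                       ) -> tuple[float, float, float, str]:
    """Signed (front_back, left_right), distance to centroid, and front/back.

    ``front_back`` is the offset projected on the heading (ahead positive);
    ``left_right`` projects on the right-pointing normal ``(hy, -hx)``
    (right positive).  ``position`` is "front" iff front_back >= 0 (ties to
    front).
    """
    dx = bird_pos[0] - centroid[0]
    dy = bird_pos[1] - centroid[1]
    hx, hy = heading
    front_back = dx * hx + dy * hy
    left_right = dx * hy - dy * hx
    distance = float(np.hypot(dx, dy))
    return (front_back, left_right, distance,
            "front" if front_back >= 0 else "back")


def absolute_spread(positions: dict[str, tuple[float, float]],
                    members, heading: tuple[float, float]) -> float:
    """Front-back extent plus left-right extent of the member positions.

    Undefined (NaN) for fewer than two members.
    """
    ids = sorted(members)
    if len(ids) < 2:
        return float("nan")
    pts = np.array([positions[i] for i in ids])
    hx, hy = heading
    fb = pts[:, 0] * hx + pts[:, 1] * hy
    lr = pts[:, 0] * hy - pts[:, 1] * hx
    return float((fb.max() - fb.min()) + (lr.max() - lr.min()))


def compute_flock_frames(per_second: pd.DataFrame, flock_id: str,
                         fallback_heading: tuple[float, float],
                         link_dist_m: float = DEFAULT_LINK_DIST_M,
                         excl_dist_m: float = DEFAULT_EXCL_DIST_M,
                         stationary_threshold_m: float = DEFAULT_STATIONARY_THRESHOLD_M,
                         ) -> pd.DataFrame:
    """Flock geometry for every whole second of one flight.

    ``per_second`` needs columns ``bird_id, t, x, y`` (one row per bird per
    second).  Returns one row per member per second with the flock-level and
    per-member variables; seconds with fewer than two cohesive birds yield no
    rows (flock variables undefined there).

    Membership and the robust centroid are resolved per second first; the
    heading at second ``t`` then uses the displacement toward the next
    second's centroid, so the decomposition pass runs once headings are
    known.
    """
    seconds = np.sort(per_second["t"].unique())
    by_second = {
        t: dict(zip(g["bird_id"], zip(g["x"], g["y"])))
        for t, g in per_second.groupby("t")
    }

    centroids: dict[float, tuple[float, float]] = {}
    memberships: dict[float, set[str]] = {}
    prev_centroid: tuple[float, float] | None = None
    for t in seconds:
        positions = by_second[t]
        members = cohesive_members(positions, link_dist_m, prev_centroid)
        if len(members) < 2:
            continue
        centroid, members = robust_centroid(positions, members, excl_dist_m)
        if centroid is None or len(members) < 2:
            continue
        centroids[t] = centroid
        memberships[t] = members
        prev_centroid = centroid

    rows = []
    flock_seconds = sorted(centroids)
    prev_heading: tuple[float, float] | None = None
    for i, t in enumerate(flock_seconds):
        nxt = flock_seconds[i + 1] if i + 1 < len(flock_seconds) else None
        heading = travel_heading(centroids[t],
                                 centroids.get(nxt) if nxt is not None else None,
                                 prev_heading, fallback_heading,
                                 stationary_threshold_m)
        prev_heading = heading
        positions = by_second[t]
        members = memberships[t]
        spread = absolute_spread(positions, members, heading)
        for bird in sorted(members):
            fb, lr, dist, pos = decompose_position(positions[bird],
                                                   centroids[t], heading)
            rows.append({
                "flock_id": flock_id, "t": t, "bird_id": bird,
                "group_size": len(members), "centroid_x": centroids[t][0],
                "centroid_y": centroids[t][1], "heading_x": heading[0],
                "heading_y": heading[1], "absolute_spread": spread,
                "distance_to_centroid": dist, "front_back": fb,
                "left_right": lr, "position": pos,
            })
    return pd.DataFrame(rows, columns=[
        "flock_id", "t", "bird_id", "group_size", "centroid_x", "centroid_y",
        "heading_x", "heading_y", "absolute_spread", "distance_to_centroid",
        "front_back", "left_right", "position"])
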