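"""Gated nearest-neighbor linking of detections into track fragments.

Centroids are linked frame-to-frame by greedy nearest-neighbor assignment
under a distance gate that grows with the temporal gap: a fragment last
seen g frames ago may claim a detection within 11*g pixels, up to 55
pixels at the maximum gap of 5 frames. A centroid is never reused by two
tracks, except through the clustering rule: when several tracked cells
converge into one large cluster detection, their fragments end and a
single fragment follows the cluster's common centroid; when the cluster
dissolves, fresh fragments start from it. Identity is deliberately not
preserved across merges — the output is conservative track *fragments*,
which downstream motility statistics treat as independent samples.
Fragments are also split wherever the luminal/abluminal state changes, so
each sub-fragment has a single state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import Detection


@dataclass(frozen=True)
class GateRule:
    """Linking gate: allowed radius is per_frame_increment * gap, capped at
    base_radius at the maximum gap (11*g px, 55 px at g=5). The fixed-radius
    alternative reading uses base_radius at every gap."""

    base_radius: float = 55.0
    per_frame_increment: float = 11.0
    max_gap: int = 5
    fixed_radius: bool = False

    def allowed_radius(self, gap: int) -> float:
        if gap < 1 or gap > self.max_gap:
            return 0.0
        if self.fixed_radius:
            return self.base_radius
        return min(self.per_frame_increment * gap, self.base_radius)


@dataclass
class TrackFragment:
    """A maximal linked centroid sequence between birth/termination events."""

    fragment_id: int
    frames: list[int] = field(default_factory=list)
    xs: list[float] = field(default_factory=list)
    ys: list[float] = field(default_factory=list)
    states: list[str] = field(default_factory=list)
    det_ids: list[int] = field(default_factory=list)
    start_reason: str = "appeared"
    end_reason: str = "video_end"
    parent_fragment: int | None = None
    is_cluster: bool = False

    def append(self, frame: int, x: float, y: float, state: str, det_id: int) -> None:
        self.frames.append(frame)
        self.xs.append(x)
        self.ys.append(y)
        self.states.append(state)
        self.det_ids.append(det_id)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_xy(self) -> tuple[float, float]:
        return self.xs[-1], self.ys[-1]

    def points(self) -> np.ndarray:
        return np.column_stack([self.frames, self.xs, self.ys])

    @property
    def bulk_state(self) -> str:
        """Majority state over the fragment's points (ties -> abluminal)."""
        n_ab = sum(s == "abluminal" for s in self.states)
        return "abluminal" if n_ab * 2 >= len(self.states) else "luminal"


def _qualifies_as_cluster(d: Detection, mean_single_area: float | None, min_count: int = 3) -> bool:
    """A detection is treated as a cluster 'bulk body' if it is estimated
    to hold >= 3 cells, or its area is >= 3x the frame's mean single area."""
    if d.single_multi == "multiple" and d.est_count >= min_count:
        return True
    if mean_single_area is not None and d.area_px >= min_count * mean_single_area:
        return True
    return False


def link(
    detections_by_frame: dict[int, list[Detection]],
    gate: GateRule = GateRule(),
    merge_clusters: bool = True,
) -> list[TrackFragment]:
    """Link detections into track fragments by gated nearest neighbors.

    Per frame, candidate (fragment, detection) pairs within the gate are
    assigned greedily in ascending distance order (ties: lower det_id,
    then older fragment), each fragment and detection used at most once.
    Unmatched detections start new fragments; fragments unmatched for more
    than ``gate.max_gap`` frames end. With ``merge_clusters``, qualifying
    cluster detections that capture two or more active fragments trigger
    the merge/split logic (see :func:`handle_merge_split` semantics).
    """
    if not detections_by_frame:
        return []
    frames = range(min(detections_by_frame), max(detections_by_frame) + 1)
    fragments: list[TrackFragment] = []
    active: list[TrackFragment] = []

    for t in frames:
        dets = sorted(detections_by_frame.get(t, []), key=lambda d: d.det_id)
        singles_area = [d.area_px for d in dets if d.single_multi == "single"]
        mean_single = float(np.mean(singles_area)) if singles_area else None

        claimed_dets: set[int] = set()
        matched_frags: set[int] = set()
        qualifying = {d.det_id for d in dets if _qualifies_as_cluster(d, mean_single)}

        # -- merge rule: >=2 active fragments converging into one big cluster
        if merge_clusters:
            for d in dets:
                if not _qualifies_as_cluster(d, mean_single):
                    continue
                captured = []
                for fr in active:
                    gap = t - fr.last_frame
                    r = gate.allowed_radius(gap)
                    if r <= 0:
                        continue
                    dx = d.centroid[0] - fr.last_xy[0]
                    dy = d.centroid[1] - fr.last_xy[1]
                    if dx * dx + dy * dy <= r * r:
                        captured.append(fr)
                non_cluster = [fr for fr in captured if not fr.is_cluster]
                if len(non_cluster) >= 2:
                    captured_ids = {fr.fragment_id for fr in captured}
                    for fr in captured:
                        fr.end_reason = "merged"
                    active = [a for a in active if a.fragment_id not in captured_ids]
                    cluster = TrackFragment(
                        fragment_id=len(fragments), start_reason="merged", is_cluster=True
                    )
                    cluster.append(t, d.centroid[0], d.centroid[1], d.state, d.det_id)
                    fragments.append(cluster)
                    active.append(cluster)
                    claimed_dets.add(d.det_id)
                    matched_frags.add(cluster.fragment_id)

        # -- greedy nearest-neighbor assignment
        pairs = []
        for fr in active:
            if fr.fragment_id in matched_frags:
                continue
            gap = t - fr.last_frame
            r = gate.allowed_radius(gap)
            if r <= 0:
                continue
            for d in dets:
                if d.det_id in claimed_dets:
                    continue
                if merge_clusters and fr.is_cluster and d.det_id not in qualifying:
                    # a cluster fragment only follows the cluster bulk body;
                    # when the cluster dissolves it ends and children restart
                    continue
                dx = d.centroid[0] - fr.last_xy[0]
                dy = d.centroid[1] - fr.last_xy[1]
                dist = (dx * dx + dy * dy) ** 0.5
                if dist <= r:
                    pairs.append((dist, d.det_id, fr.fragment_id, fr, d))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        for dist, det_id, frag_id, fr, d in pairs:
            if det_id in claimed_dets or frag_id in matched_frags:
                continue
            fr.append(t, d.centroid[0], d.centroid[1], d.state, det_id)
            claimed_dets.add(det_id)
            matched_frags.add(frag_id)

        # -- dissolution of cluster fragments / retirement of stale tracks
        still_active = []
        dissolved_clusters = []
        for fr in active:
            if fr.fragment_id in matched_frags:
                still_active.append(fr)
            elif t - fr.last_frame > gate.max_gap:
                fr.end_reason = "gap_exceeded"
            elif fr.is_cluster and any(
                d.det_id not in claimed_dets for d in dets
            ):
                # an unmatched cluster with fresh nearby detections dissolves
                near = False
                for d in dets:
                    if d.det_id in claimed_dets:
                        continue
                    r = gate.allowed_radius(t - fr.last_frame)
                    dx = d.centroid[0] - fr.last_xy[0]
                    dy = d.centroid[1] - fr.last_xy[1]
                    if r > 0 and dx * dx + dy * dy <= r * r:
                        near = True
                        break
                if near:
                    fr.end_reason = "split_from_merge"
                    dissolved_clusters.append(fr)
                else:
                    still_active.append(fr)
            else:
                still_active.append(fr)
        active = still_active

        # -- new fragments for unclaimed detections
        for d in dets:
            if d.det_id in claimed_dets:
                continue
            parent = None
            reason = "appeared"
            for cl in dissolved_clusters:
                r = gate.allowed_radius(t - cl.last_frame)
                dx = d.centroid[0] - cl.last_xy[0]
                dy = d.centroid[1] - cl.last_xy[1]
                if r > 0 and dx * dx + dy * dy <= r * r:
                    parent = cl.fragment_id
                    reason = "split_from_merge"
                    break
            fr = TrackFragment(
                fragment_id=len(fragments), start_reason=reason, parent_fragment=parent
            )
            fr.append(t, d.centroid[0], d.centroid[1], d.state, d.det_id)
            fragments.append(fr)
            active.append(fr)

    for fr in active:
        fr.end_reason = "video_end"
    return fragments


def split_on_state(fragments: list[TrackFragment]) -> list[TrackFragment]:
    """Split each fragment at luminal/abluminal state changes.

    Each maximal run of constant state becomes its own sub-fragment; runs
    chain via ``parent_fragment`` so concatenating a chain reconstructs
    the parent point sequence. No smoothing is applied: a single-frame
    state flicker yields a single-point sub-fragment.
    """
    out: list[TrackFragment] = []
    next_id = max((f.fragment_id for f in fragments), default=-1) + 1
    for fr in fragments:
        runs: list[tuple[int, int]] = []
        start = 0
        for i in range(1, fr.n_points):
            if fr.states[i] != fr.states[i - 1]:
                runs.append((start, i))
                start = i
        runs.append((start, fr.n_points))
        if len(runs) == 1:
            out.append(fr)
            continue
        prev_id = fr.parent_fragment
        for k, (a, b) in enumerate(runs):
            sub = TrackFragment(
                fragment_id=fr.fragment_id if k == 0 else next_id,
                frames=fr.frames[a:b], xs=fr.xs[a:b], ys=fr.ys[a:b],
                states=fr.states[a:b], det_ids=fr.det_ids[a:b],
                start_reason=fr.start_reason if k == 0 else "state_change",
                end_reason=fr.end_reason if k == len(runs) - 1 else "state_change",
                parent_fragment=prev_id,
                is_cluster=fr.is_cluster,
            )
            if k > 0:
                next_id += 1
            prev_id = sub.fragment_id
            out.append(sub)
    return out


def fragments_to_frame(fragments: list[TrackFragment]) -> pd.DataFrame:
    rows = []
    for fr in fragments:
        for i in range(fr.n_points):
            rows.append({
                "fragment_id": fr.fragment_id,
                "parent_fragment": fr.parent_fragment,
                "frame": fr.frames[i],
                "x": fr.xs[i],
                "y": fr.ys[i],
                "state": fr.states[i],
                "det_id": fr.det_ids[i],
                "start_reason": fr.start_reason,
                "end_reason": fr.end_reason,
            })
    return pd.DataFrame(rows, columns=[
        "fragment_id", "parent_fragment", "frame", "x", "y", "state",
        "det_id", "start_reason", "end_reason",
    ])
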