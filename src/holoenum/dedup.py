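"""Multiple-count removal for cells spanning consecutive frames.

Flow in the channel is laminar and streamwise, so a cell seen again in
the next frame keeps (to within localization error) its cross-stream
position y and its height z; the streamwise position x is useless
because cells traverse most of the field of view between frames.  A
detection q in frame i+1 is therefore a repeat of p in frame i when
|y_q - y_p| <= 3 um and |z_q - z_p| <= 50 um (the z bound is lenient
because axial localization is the weaker coordinate in in-line
holography).  Chains across 2-3 frames collapse transitively onto the
earliest detection.
"""

from __future__ import annotations

import numpy as np

from .config import DedupConfig
from .localize import CellDetection

__all__ = ["remove_multiple_counts"]


def remove_multiple_counts(
    detections: list[CellDetection], cfg: DedupConfig | None = None
) -> list[CellDetection]:
    """Return detections with repeats of the same cell removed.

    For each detection in frame f, candidate predecessors are the
    detections in frames f-1 .. f-max_frame_gap satisfying both
    proximity criteria; the nearest in (y, z) Euclidean distance claims
    it.  Matches propagate transitively and each chain keeps its
    first-frame instance.  Idempotent; preserves input order among
    survivors.
    """
    cfg = cfg or DedupConfig()
    n = len(detections)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: detections[i].frame_index)
    parent = list(range(n))

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_frame: dict[int, list[int]] = {}
    for i in order:
        by_frame.setdefault(detections[i].frame_index, []).append(i)

    for f in sorted(by_frame):
        for q in by_frame[f]:
            dq = detections[q]
            best = None
            best_dist = np.inf
            for gap in range(1, cfg.max_frame_gap + 1):
                for p in by_frame.get(f - gap, []):
                    dp = detections[p]
                    dy = abs(dq.y_um - dp.y_um)
                    dz = abs(dq.z_um - dp.z_um)
                    if dy <= cfg.dy_max_um and dz <= cfg.dz_max_um:
                        dist = float(np.hypot(dy, dz))
                        if dist < best_dist:
                            best, best_dist = p, dist
            if best is not None:
                parent[root(q)] = root(best)

    keep: dict[int, int] = {}
    for i in order:  # frame-sorted, so the first hit per root is the earliest
        r = root(i)
        if r not in keep:
            keep[r] = i
    kept = sorted(keep.values())
    return [detections[i] for i in kept]
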