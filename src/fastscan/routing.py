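"""Scan-path ordering for each measurement batch.

Each iteration hands the motors a batch of target pixels; visiting them
in ERD order would zigzag across the whole field, so the batch is
reordered into a short open path (nearest-neighbor construction followed
by 2-opt improvement).  The path starts from the motors' current
position and does not return to it; the next batch starts wherever this
one ended.  Batches are small (50 points), so the O(n^2) heuristic is
effectively instant and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Route", "optimize_route", "route_length"]


@dataclass(frozen=True)
class Route:
    points: tuple[tuple[int, int], ...]
    start: tuple[int, int]
    total_length: float

    def to_csv(self, path) -> None:
        """Visit order with cumulative path length, one row per point."""
        import csv

        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["visit_order", "row", "col", "cumulative_length"])
            pos = np.asarray(self.start, dtype=np.float64)
            cum = 0.0
            for i, p in enumerate(self.points):
                cum += float(np.hypot(p[0] - pos[0], p[1] - pos[1]))
                writer.writerow([i, p[0], p[1], f"{cum:.10g}"])
                pos = np.asarray(p, dtype=np.float64)


def route_length(points_in_order, start) -> float:
    """Sum of Euclidean legs start -> p1 -> p2 -> ... (pixel units)."""
    pts = np.asarray(list(points_in_order), dtype=np.float64).reshape(-1, 2)
    if len(pts) == 0:
        return 0.0
    path = np.vstack([np.asarray(start, dtype=np.float64), pts])
    return float(np.sqrt(((path[1:] - path[:-1]) ** 2).sum(axis=1)).sum())


def _two_opt(order: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """2-opt + or-opt for an open path; node 0 of ``dist`` is the start.

    Plain 2-opt stalls a few percent above optimal on small instances;
    interleaving or-opt (relocating runs of 1-3 points) escapes most of
    those local optima while staying deterministic.
    """
    path = np.concatenate([[0], order])
    n = len(path)
    improved = True
    while improved:
        improved = False
        # 2-opt: reverse path[i..j]; the j == n-1 tail has no right leg
        for i in range(1, n - 1):
            for j in range(i + 1, n):
                delta = dist[path[i - 1], path[j]] - dist[path[i - 1], path[i]]
                if j < n - 1:
                    delta += dist[path[i], path[j + 1]] - dist[path[j], path[j + 1]]
                if delta < -1e-12:
                    path[i : j + 1] = path[i : j + 1][::-1]
                    improved = True
        # or-opt: move a short segment elsewhere (both orientations)
        for seg in (1, 2, 3):
            for i in range(1, n - seg):
                j = i + seg - 1
                right = dist[path[j], path[j + 1]] if j + 1 < n else 0.0
                gain = dist[path[i - 1], path[i]] + right
                if j + 1 < n:
                    gain -= dist[path[i - 1], path[j + 1]]
                if gain <= 1e-12:
                    continue
                rest = np.concatenate([path[:i], path[j + 1 :]])
                segment = path[i : j + 1]
                m = len(rest)
                done = False
                for k in range(1, m):  # insert segment after rest[k-1]
                    if k == i:
                        continue
                    for sfw in (segment, segment[::-1]):
                        tail = dist[sfw[-1], rest[k]] if k < m else 0.0
                        add = dist[rest[k - 1], sfw[0]] + tail
                        if k < m:
                            add -= dist[rest[k - 1], rest[k]]
                        if add < gain - 1e-12:
                            path = np.concatenate([rest[:k], sfw, rest[k:]])
                            improved = True
                            done = True
                            break
                    if done:
                        break
    return path[1:]


def _held_karp(dist: np.ndarray) -> np.ndarray:
    """Exact shortest open path from node 0 through all others (n <= ~12)."""
    n = dist.shape[0] - 1  # points, excluding the start
    full = 1 << n
    cost = np.full((full, n), np.inf)
    parent = np.full((full, n), -1, dtype=np.intp)
    for j in range(n):
        cost[1 << j, j] = dist[0, j + 1]
    for mask in range(full):
        for j in range(n):
            if not mask & (1 << j) or not np.isfinite(cost[mask, j]):
                continue
            base = cost[mask, j]
            for k in range(n):
                if mask & (1 << k):
                    continue
                nm = mask | (1 << k)
                c = base + dist[j + 1, k + 1]
                if c < cost[nm, k]:
                    cost[nm, k] = c
                    parent[nm, k] = j
    mask = full - 1
    j = int(np.argmin(cost[mask]))
    order = []
    while j >= 0:
        order.append(j + 1)
        j2 = parent[mask, j]
        mask ^= 1 << j
        j = j2
    return np.array(order[::-1], dtype=np.intp)


def optimize_route(points, start) -> Route:
    """Short open path through ``points`` beginning at ``start``.

    Small batches (<= 8 points) are solved exactly by dynamic
    programming; larger ones use nearest-neighbor construction followed
    by 2-opt/or-opt improvement.  Deterministic; never longer than
    visiting the points in their given order.
    """
    pts = [tuple(int(x) for x in p) for p in points]
    if not pts:
        raise ValueError("no points to route")
    if len(set(pts)) != len(pts):
        raise ValueError("duplicate points in batch")
    start = (int(start[0]), int(start[1]))

    coords = np.vstack([np.asarray(start, float), np.asarray(pts, float)])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    n = len(pts)
    if n <= 8:
        order = _held_karp(dist)
    else:
        # greedy nearest-neighbor tour from the start
        unvisited = np.ones(n + 1, dtype=bool)
        unvisited[0] = False
        order = np.empty(n, dtype=np.intp)
        cur = 0
        for i in range(n):
            cand = np.flatnonzero(unvisited)
            nxt = cand[np.argmin(dist[cur, cand])]
            order[i] = nxt
            unvisited[nxt] = False
            cur = nxt
        order = _two_opt(order, dist)
    ordered = tuple(pts[i - 1] for i in order)
    length = route_length(ordered, start)

    input_length = route_length(pts, start)
    if length > input_length + 1e-12:  # 2-opt started from NN, cannot regress
        ordered, length = tuple(pts), input_length
    return Route(ordered, start, length)
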