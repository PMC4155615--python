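"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: centralities are
recomputed from Floyd-Warshall distances plus explicit shortest-path
enumeration; two-sphere SASA comes from the closed-form spherical-cap
solution; Delaunay edge membership is decided by clipping the pair's
bisector plane with the Voronoi dominance half-planes (an empty-circumsphere
feasibility test that never touches Qhull).
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


# --------------------------------------------------------------------
# graph centralities: Floyd-Warshall + explicit path enumeration
# --------------------------------------------------------------------

def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, INF)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return dist


def _shortest_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int) -> list[list[int]]:
    """All geodesics s -> t, enumerated by walking distance-decreasing steps."""
    if not np.isfinite(dist[s, t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        for v in range(adj.shape[0]):
            if adj[u, v] and dist[s, v] == dist[s, u] + 1 and \
                    dist[v, t] == dist[u, t] - 1:
                extend(path + [v])

    extend([s])
    return paths


def brute_force_centralities(adj: np.ndarray) -> dict[str, np.ndarray]:
    """Degree, fractional & indicator betweenness, both closeness variants."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    degree = adj.sum(axis=1).astype(float)
    bet = np.zeros(n)
    bet_ind = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            through = np.zeros(n)
            for path in paths:
                for v in path[1:-1]:
                    through[v] += 1
            bet += through / len(paths)
            bet_ind += (through > 0).astype(float)
    clo_inv = np.zeros(n)
    clo_mean = np.zeros(n)
    for i in range(n):
        finite = dist[i][np.isfinite(dist[i])]
        total = finite.sum()
        clo_inv[i] = 1.0 / total if total > 0 else 0.0
        clo_mean[i] = total / n
    return {
        "degree": degree,
        "betweenness": bet,
        "betweenness_indicator": bet_ind,
        "closeness_inverse_sum": clo_inv,
        "closeness_mean_distance": clo_mean,
    }


# --------------------------------------------------------------------
# SASA: closed-form two-sphere solution
# --------------------------------------------------------------------

def isolated_sphere_area(vdw_radius: float, probe: float) -> float:
    r = vdw_radius + probe
    return 4.0 * np.pi * r * r


def two_sphere_areas(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Exposed areas of two probe-inflated spheres at centre distance ``d``.

    Each sphere loses the spherical cap buried inside the other inflated
    sphere; for non-overlapping spheres the full areas are returned.
    """
    a, b = r1 + probe, r2 + probe
    if d >= a + b:
        return isolated_sphere_area(r1, probe), isolated_sphere_area(r2, probe)
    if d + a <= b:  # sphere 1 engulfed
        return 0.0, isolated_sphere_area(r2, probe)
    if d + b <= a:
        return isolated_sphere_area(r1, probe), 0.0
    # cap height on sphere 1: h1 = a - x where x is the distance from
    # centre 1 to the radical plane
    x = (d * d + a * a - b * b) / (2.0 * d)
    h1 = a - x
    h2 = b - (d - x)
    area1 = 4.0 * np.pi * a * a - 2.0 * np.pi * a * h1
    area2 = 4.0 * np.pi * b * b - 2.0 * np.pi * b * h2
    return area1, area2


# --------------------------------------------------------------------
# Delaunay edges: bisector-plane half-plane clipping
# --------------------------------------------------------------------

def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a 2-D polygon by a.x <= b."""
    if len(poly) == 0:
        return poly
    inside = poly @ a <= b
    out = []
    m = len(poly)
    for idx in range(m):
        p, q = poly[idx], poly[(idx + 1) % m]
        pin, qin = inside[idx], inside[(idx + 1) % m]
        if pin:
            out.append(p)
        if pin != qin:
            denom = a @ (q - p)
            t = (b - a @ p) / denom
            out.append(p + t * (q - p))
    return np.array(out) if out else np.empty((0, 2))


def is_delaunay_edge(points: np.ndarray, i: int, j: int, box: float = 1e7) -> bool:
    """True iff some sphere through points i and j is empty of all others.

    Centres of such spheres live on the bisector plane of (i, j); each other
    point k carves the half-plane where the centre is closer to i than to k.
    The edge exists iff the clipped region has non-zero extent.  ``box``
    bounds the search region and must dwarf the cloud diameter: facets of
    hull-adjacent edges can sit very far from the cloud.
    """
    pi, pj = points[i], points[j]
    normal = pj - pi
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("coincident points")
    normal = normal / nn
    mid = 0.5 * (pi + pj)
    # orthonormal basis (u, v) of the bisector plane
    trial = np.array([1.0, 0.0, 0.0])
    if abs(normal @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, trial)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    poly = np.array([[-box, -box], [box, -box], [box, box], [-box, box]])
    for k in range(len(points)):
        if k == i or k == j:
            continue
        pk = points[k]
        w = pk - pi
        # ||c-i||^2 <= ||c-k||^2 with c = mid + s*u + t*v  =>  linear in (s,t)
        a = 2.0 * np.array([u @ w, v @ w])
        b = pk @ pk - pi @ pi - 2.0 * (mid @ w)
        poly = _clip_halfplane(poly, a, b)
        if len(poly) == 0:
            return False
    if len(poly) < 3:
        return False
    # shoelace area of the surviving region
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return bool(area > 1e-9)


def delaunay_edge_set(points: np.ndarray) -> set[tuple[int, int]]:
    n = len(points)
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if is_delaunay_edge(points, i, j)
    }
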