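"""Skin-surface (geodesic) distances on the leg mesh.

The surface distance between two lesions is approximated by a shortest
path in a graph built from the mesh: nodes are mesh vertices plus
Steiner points subdividing every edge into 2**k segments (refinement
level k), with all boundary nodes of each triangle pairwise connected
by straight segments in the face plane.  In addition, nodes of adjacent
triangle pairs are linked whenever the straight line in the unfolding
of the two faces about their shared edge crosses that edge; the link
weight is the unfolded length — the exact two-face geodesic — which
removes the crossing-point quantization at alternate edges and
substantially tightens the approximation.  Query points are inserted as
temporary nodes with the same in-face and unfolded links.

Dijkstra then gives a deterministic upper bound on the true polyhedral
geodesic that tightens with refinement: node sets are nested across
levels (fractions j/2**k), so the path length is non-increasing in k.

This is the algorithmic analogue of the skin-surface distance-measuring
tool of 3D total-body photography platforms; accuracy well under a
percent suffices for distances reported to 0.1 cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from ._stats import mann_whitney
from .leg_model import LegSurface


class NoPathError(RuntimeError):
    """Anchors lie in disconnected mesh components."""


@dataclass
class SurfacePath:
    """Polyline on the mesh surface with its total length (cm)."""

    points: np.ndarray  # (k, 3)
    length: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)


def _anchor_tuple(anchor, mesh) -> tuple[int, np.ndarray]:
    """Normalize an anchor: a Lesion or a (face, barycentric) pair."""
    if hasattr(anchor, "face") and hasattr(anchor, "bary"):
        if anchor.face is None or anchor.bary is None:
            raise ValueError("lesion is not anchored on the surface")
        return int(anchor.face), np.asarray(anchor.bary, dtype=float)
    face, bary = anchor
    return int(face), np.asarray(bary, dtype=float)


def _anchor_point(mesh, face: int, bary: np.ndarray) -> np.ndarray:
    return bary @ np.asarray(mesh.vertices)[np.asarray(mesh.faces)[face]]


class GeodesicEngine:
    """Reusable shortest-path graph for one mesh at one refinement level."""

    def __init__(self, mesh: LegSurface, refinement: int = 3):
        if refinement < 0:
            raise ValueError("refinement must be >= 0")
        self.mesh = mesh
        self.vertices = np.asarray(mesh.vertices, dtype=float)
        self.faces = np.asarray(mesh.faces, dtype=int)
        self.refinement = refinement
        self._build()

    # -- construction ---------------------------------------------------
    def _build(self) -> None:
        nv = len(self.vertices)
        faces = self.faces
        raw = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        raw.sort(axis=1)
        edges, inverse = np.unique(raw, axis=0, return_inverse=True)
        self._edges = edges
        self._face_edge = inverse.reshape(3, -1).T  # (m, 3) edge ids
        ne = len(edges)
        s = 2 ** (self.refinement + 1) - 1  # Steiner points per edge

        coords = [self.vertices]
        if s > 0:
            fr = (np.arange(1, s + 1) / (s + 1))[None, :, None]
            a = self.vertices[edges[:, 0]][:, None, :]
            b = self.vertices[edges[:, 1]][:, None, :]
            coords.append((a + fr * (b - a)).reshape(-1, 3))
        self.node_coords = np.vstack(coords)

        def edge_nodes(e: int) -> np.ndarray:
            if s == 0:
                return np.empty(0, dtype=int)
            return nv + e * s + np.arange(s)

        self._face_nodes: list[np.ndarray] = []
        ii, jj = [], []
        for f in range(len(faces)):
            nodes = np.concatenate(
                [faces[f]] + [edge_nodes(self._face_edge[f, k]) for k in range(3)]
            )
            self._face_nodes.append(nodes)
            a_idx, b_idx = np.triu_indices(len(nodes), k=1)
            ii.append(nodes[a_idx])
            jj.append(nodes[b_idx])
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        w = np.linalg.norm(self.node_coords[ii] - self.node_coords[jj], axis=1)

        # faces incident to each undirected edge
        self._edge_faces: list[list[int]] = [[] for _ in range(ne)]
        for f in range(len(faces)):
            for e in self._face_edge[f]:
                self._edge_faces[e].append(f)

        wi, wj, ww = self._window_links()

        n = len(self.node_coords)
        self._node_faces: list[list[int]] = [[] for _ in range(n)]
        for f, nodes in enumerate(self._face_nodes):
            for node in nodes:
                self._node_faces[node].append(f)

        all_i = np.concatenate([ii, wi])
        all_j = np.concatenate([jj, wj])
        lo = np.minimum(all_i, all_j)
        hi = np.maximum(all_i, all_j)
        self.graph = self._dedupe_min(lo, hi, np.concatenate([w, ww]), n)

    @staticmethod
    def _dedupe_min(i, j, w, n) -> csr_matrix:
        """Upper-triangular sparse matrix keeping the minimum weight per
        node pair (a pair can arise from a clique and several windows)."""
        key = i.astype(np.int64) * n + j.astype(np.int64)
        order = np.lexsort((w, key))
        key_s, w_s, i_s, j_s = key[order], w[order], i[order], j[order]
        first = np.ones(len(key_s), dtype=bool)
        first[1:] = key_s[1:] != key_s[:-1]
        return csr_matrix(
            coo_matrix((w_s[first], (i_s[first], j_s[first])), shape=(n, n))
        )

    def _edge_frame(self, e: int):
        u3 = self.vertices[self._edges[e, 0]]
        v3 = self.vertices[self._edges[e, 1]]
        ev = v3 - u3
        L2 = float(ev @ ev)
        return u3, ev, L2

    def _unfold_coords(self, e: int, pts: np.ndarray):
        """(along-edge, off-edge) coordinates of points w.r.t. edge e."""
        u3, ev, L2 = self._edge_frame(e)
        d = np.atleast_2d(pts) - u3
        alpha = (d @ ev) / L2
        perp = d - alpha[:, None] * ev
        beta = np.linalg.norm(perp, axis=1)
        return alpha * np.sqrt(L2), beta, np.sqrt(L2)

    @staticmethod
    def _window_pairs(ax, ga, bx, gb, L):
        """Valid unfolded links between point sets on opposite sides of
        an edge of length L; returns (index pairs, weights)."""
        denom = ga[:, None] + gb[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = ga[:, None] / denom
            x = ax[:, None] + t * (bx[None, :] - ax[:, None])
        valid = (denom > 1e-12) & (x >= -1e-12) & (x <= L + 1e-12)
        ia, ib = np.nonzero(valid)
        wgt = np.hypot(ax[ia] - bx[ib], ga[ia] + gb[ib])
        return ia, ib, wgt

    def _window_links(self):
        out_i, out_j, out_w = [], [], []
        for e, incident in enumerate(self._edge_faces):
            if len(incident) != 2:
                continue
            fa, fb = incident
            na = self._face_nodes[fa]
            nb = self._face_nodes[fb]
            ax, ga, L = self._unfold_coords(e, self.node_coords[na])
            bx, gb, _ = self._unfold_coords(e, self.node_coords[nb])
            ka, kb = ga > 1e-12, gb > 1e-12
            if not ka.any() or not kb.any():
                continue
            ia, ib, wgt = self._window_pairs(ax[ka], ga[ka], bx[kb], gb[kb], L)
            out_i.append(na[ka][ia])
            out_j.append(nb[kb][ib])
            out_w.append(wgt)
        if not out_i:
            z = np.empty(0)
            return z.astype(int), z.astype(int), z
        return (
            np.concatenate(out_i),
            np.concatenate(out_j),
            np.concatenate(out_w),
        )

    # -- query-point insertion ------------------------------------------
    def face_nodes(self, face: int) -> np.ndarray:
        return self._face_nodes[face]

    def _anchor_links(self, pt: np.ndarray, face: int):
        """Graph links for a temporary node at ``pt`` on ``face``:
        in-face clique plus unfolded links into the adjacent faces."""
        nodes = self._face_nodes[face]
        cols = [nodes]
        ws = [np.linalg.norm(self.node_coords[nodes] - pt, axis=1)]
        for e in self._face_edge[face]:
            others = [f for f in self._edge_faces[e] if f != face]
            if not others:
                continue
            fo = others[0]
            ax, ga, L = self._unfold_coords(e, pt[None, :])
            if ga[0] <= 1e-12:
                continue
            no = self._face_nodes[fo]
            bx, gb, _ = self._unfold_coords(e, self.node_coords[no])
            kb = gb > 1e-12
            if not kb.any():
                continue
            ia, ib, wgt = self._window_pairs(ax, ga, bx[kb], gb[kb], L)
            cols.append(no[kb][ib])
            ws.append(wgt)
        return np.concatenate(cols), np.concatenate(ws)

    def _anchor_pair_weight(self, a: tuple, b: tuple, pa, pb):
        """Direct link weight between two anchors, if geometrically
        justified: same face (straight) or adjacent faces (unfolded)."""
        if a[0] == b[0]:
            return float(np.linalg.norm(pa - pb))
        shared = set(self._face_edge[a[0]]) & set(self._face_edge[b[0]])
        best = None
        for e in shared:
            ax, ga, L = self._unfold_coords(e, pa[None, :])
            bx, gb, _ = self._unfold_coords(e, pb[None, :])
            if ga[0] <= 1e-12 or gb[0] <= 1e-12:
                return float(np.linalg.norm(pa - pb))
            _ia, _ib, wgt = self._window_pairs(ax, ga, bx, gb, L)
            if len(wgt):
                w = float(wgt[0])
                best = w if best is None else min(best, w)
        return best

    def _augment(self, anchors: list[tuple[int, np.ndarray]]):
        n = self.graph.shape[0]
        pts = np.array([_anchor_point(self.mesh, f, b) for f, b in anchors])
        rows, cols, ws = [], [], []
        for k, (f, _b) in enumerate(anchors):
            c, w = self._anchor_links(pts[k], f)
            rows.append(np.full(len(c), n + k))
            cols.append(c)
            ws.append(w)
        for a in range(len(anchors)):
            for b in range(a + 1, len(anchors)):
                w = self._anchor_pair_weight(anchors[a], anchors[b], pts[a], pts[b])
                if w is not None:
                    rows.append(np.array([n + a]))
                    cols.append(np.array([n + b]))
                    ws.append(np.array([w]))
        base = coo_matrix(self.graph)
        m = n + len(anchors)
        i = np.concatenate([base.row] + rows)
        j = np.concatenate([base.col] + cols)
        w = np.concatenate([base.data] + ws)
        full = self._dedupe_min(np.minimum(i, j), np.maximum(i, j), w, m)
        return full, pts, n

    # -- queries ---------------------------------------------------------
    def distances_from(self, source, targets) -> np.ndarray:
        """Geodesic distances from one anchor to each target anchor."""
        src = _anchor_tuple(source, self.mesh)
        tgts = [_anchor_tuple(t, self.mesh) for t in targets]
        full, _pts, n = self._augment([src] + tgts)
        dist = dijkstra(full, directed=False, indices=n)
        out = dist[n + 1 : n + 1 + len(tgts)]
        if np.isinf(out).any():
            raise NoPathError("no surface path between anchors")
        return out

    def path(self, a, b) -> SurfacePath:
        ta = _anchor_tuple(a, self.mesh)
        tb = _anchor_tuple(b, self.mesh)
        # canonical endpoint order makes distance(a, b) == distance(b, a)
        # bit-exact (identical computation either way)
        key_a = (ta[0], tuple(ta[1]))
        key_b = (tb[0], tuple(tb[1]))
        flip = key_b < key_a
        lo, hi = (tb, ta) if flip else (ta, tb)
        if key_a == key_b:
            p = _anchor_point(self.mesh, *ta)
            return SurfacePath(points=np.array([p, p]), length=0.0)
        full, pts, n = self._augment([lo, hi])
        dist, pred = dijkstra(full, directed=False, indices=n, return_predecessors=True)
        if np.isinf(dist[n + 1]):
            raise NoPathError("no surface path between anchors")
        chain = [n + 1]
        while chain[-1] != n:
            chain.append(pred[chain[-1]])
        chain = chain[::-1]

        coords = np.vstack([self.node_coords, pts])
        anchor_faces = {n: [lo[0]], n + 1: [hi[0]]}

        def faces_of(node: int):
            return anchor_faces.get(node, self._node_faces[node] if node < n else [])

        points = [coords[chain[0]]]
        for u, v in zip(chain[:-1], chain[1:]):
            fold = self._fold_point(coords[u], coords[v], faces_of(u), faces_of(v))
            if fold is not None:
                points.append(fold)
            points.append(coords[v])
        points = np.asarray(points)
        if flip:
            points = points[::-1]
        return SurfacePath(points=points, length=float(dist[n + 1]))

    def _fold_point(self, pa, pb, fa_list, fb_list):
        """Bend point on the shared mesh edge for an unfolded link.

        Returns None for nodes sharing a face (straight in-face segment).
        """
        if set(fa_list) & set(fb_list):
            return None
        best = None
        for fa in fa_list:
            for fb in fb_list:
                shared = set(self._face_edge[fa]) & set(self._face_edge[fb])
                for e in shared:
                    ax, ga, L = self._unfold_coords(e, pa[None, :])
                    bx, gb, _ = self._unfold_coords(e, pb[None, :])
                    if ga[0] + gb[0] <= 1e-12:
                        continue
                    t = ga[0] / (ga[0] + gb[0])
                    x = ax[0] + t * (bx[0] - ax[0])
                    if -1e-9 <= x <= L + 1e-9:
                        length = np.hypot(ax[0] - bx[0], ga[0] + gb[0])
                        if best is None or length < best[0]:
                            u3, ev, L2 = self._edge_frame(e)
                            best = (length, u3 + (x / np.sqrt(L2)) * ev)
        return None if best is None else best[1]


def geodesic_distance(mesh, a, b, refinement: int = 3) -> SurfacePath:
    """Shortest skin-surface path between two anchored points.

    Convenience wrapper building a one-shot :class:`GeodesicEngine`; for
    many queries on one mesh, construct the engine once and reuse it.
    """
    return GeodesicEngine(mesh, refinement=refinement).path(a, b)


# ---------------------------------------------------------------------------
# cohort distance summary
# ---------------------------------------------------------------------------


class SummaryError(ValueError):
    """Distance summary requested for an empty group."""


def distance_summary(distances: pd.DataFrame) -> dict:
    """Summarize primary-to-ITM distances by primary site.

    ``distances`` needs columns ``site`` (foot / lower_leg) and
    ``distance_cm``.  Reports per-site mean, median, min and max to
    0.1 cm, plus the two-sided tie-corrected asymptotic Mann-Whitney
    comparison of the two sites when both have at least two distances.
    """
    if "site" not in distances or "distance_cm" not in distances:
        raise SummaryError("need columns 'site' and 'distance_cm'")
    out: dict = {"groups": {}}
    for site, grp in distances.groupby("site"):
        vals = grp["distance_cm"].to_numpy(dtype=float)
        if len(vals) == 0:
            raise SummaryError(f"empty distance group {site!r}")
        out["groups"][site] = {
            "n": int(len(vals)),
            "mean_cm": round(float(vals.mean()), 1),
            "median_cm": round(float(np.median(vals)), 1),
            "min_cm": round(float(vals.min()), 1),
            "max_cm": round(float(vals.max()), 1),
        }
    sites = sorted(out["groups"])
    if len(sites) == 2:
        x = distances.loc[distances["site"] == sites[0], "distance_cm"]
        y = distances.loc[distances["site"] == sites[1], "distance_cm"]
        if len(x) >= 2 and len(y) >= 2:
            res = mann_whitney(x, y)
            out["comparison"] = {
                "sites": sites,
                "u": res.u,
                "z": round(res.z, 3),
                "p": round(res.p, 3),
            }
    return out
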