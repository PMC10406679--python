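"""Independent oracles used by the tests.

These deliberately avoid the package's own measurement code paths:
volume via Monte-Carlo ray-parity point classification, point-to-surface
distance via brute-force closest-point over all triangles (trimesh's
pure-numpy triangle routines), and mesh statistics via trimesh.
"""

from __future__ import annotations

import numpy as np


def ray_parity_volume(mesh, n_samples: int = 100_000, seed: int = 0):
    """Monte-Carlo volume estimate by ray-crossing parity.

    Uniform points in the bounding box are classified inside/outside by
    the parity of +x ray crossings (vectorised Möller–Trumbore).
    Returns (estimate, standard_error).
    """
    rng = np.random.default_rng(seed)
    V = np.asarray(mesh.vertices, float)
    F = np.asarray(mesh.faces, int)
    lo, hi = V.min(axis=0), V.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    pts = lo + rng.random((n_samples, 3)) * (hi - lo)

    v0 = V[F[:, 0]]
    e1 = V[F[:, 1]] - v0
    e2 = V[F[:, 2]] - v0
    d = np.array([1.0, 0.0, 0.0])
    h = np.cross(d, e2)  # (F, 3)
    a = np.einsum("ij,ij->i", e1, h)
    valid = np.abs(a) > 1e-12
    inv_a = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)

    crossings = np.zeros(n_samples, dtype=np.int64)
    batch = max(1, 4_000_000 // max(len(F), 1))
    for s in range(0, n_samples, batch):
        p = pts[s : s + batch]  # (B, 3)
        sv = p[:, None, :] - v0[None, :, :]  # (B, F, 3)
        u = np.einsum("bfj,fj->bf", sv, h) * inv_a
        q = np.cross(sv, e1[None, :, :])
        v = np.einsum("j,bfj->bf", d, q) * inv_a
        t = np.einsum("fj,bfj->bf", e2, q) * inv_a
        hit = (
            valid[None, :]
            & (u >= 0.0)
            & (v >= 0.0)
            & (u + v <= 1.0)
            & (t > 1e-12)
        )
        crossings[s : s + batch] = hit.sum(axis=1)
    inside = crossings % 2 == 1
    p_in = inside.mean()
    est = box_vol * p_in
    se = box_vol * np.sqrt(max(p_in * (1 - p_in), 1e-12) / n_samples)
    return float(est), float(se)


def min_distance_to_surface(mesh, points: np.ndarray) -> np.ndarray:
    """Brute-force distance from each point to the nearest triangle."""
    from trimesh.triangles import closest_point

    V = np.asarray(mesh.vertices, float)
    tris = V[np.asarray(mesh.faces, int)]  # (F, 3, 3)
    points = np.asarray(points, float)
    nF = len(tris)
    out = np.empty(len(points))
    batch = max(1, 2_000_000 // max(nF, 1))
    for s in range(0, len(points), batch):
        p = points[s : s + batch]
        nB = len(p)
        tri_rep = np.repeat(tris[None, :, :, :], nB, axis=0).reshape(-1, 3, 3)
        pt_rep = np.repeat(p, nF, axis=0)
        cp = closest_point(tri_rep, pt_rep)
        dist = np.linalg.norm(cp - pt_rep, axis=1).reshape(nB, nF)
        out[s : s + batch] = dist.min(axis=1)
    return out


def to_trimesh(mesh):
    import trimesh

    return trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces), process=False
    )
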