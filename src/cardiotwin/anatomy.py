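"""Synthetic anatomies: slab and idealized biventricular tetrahedral
meshes, Laplace-Dirichlet transmural coordinate, rule-based fiber fields,
a simplified endocardial fractal Purkinje tree and torso electrodes.

These are desk-scale stand-ins for a patient-specific heart-torso model:
small structured meshes (default h = 2 mm slab / 2.5 mm biventricular)
rather than a 1 mm patient mesh.  All lengths are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

FACET_TAGS = ("ENDO_LV", "ENDO_RV", "EPI", "BASE")


@dataclass
class Mesh:
    """Tetrahedral mesh with tagged boundary triangles.

    ``vertices``: (n, 3) mm; ``tets``: (m, 4) 0-based, positively oriented;
    ``boundary_faces``: (k, 3) vertex triples; ``boundary_tags``: (k,)
    strings from FACET_TAGS; ``h``: characteristic edge length, mm.
    """

    vertices: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_tags: np.ndarray
    h: float

    def __post_init__(self):
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"non-positive volume in tet {bad}")

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
            v[:, 3] - v[:, 0],
        ) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def boundary_vertices(self, tag: str) -> np.ndarray:
        faces = self.boundary_faces[self.boundary_tags == tag]
        return np.unique(faces)

    def surface_area(self, tag: str) -> float:
        faces = self.boundary_faces[self.boundary_tags == tag]
        v = self.vertices[faces]
        return float(
            0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1).sum()
        )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class FiberField:
    """Unit fiber direction per tet, (m, 3)."""

    f0: np.ndarray

    def __post_init__(self):
        norms = np.linalg.norm(self.f0, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("fiber vectors must be unit length")


@dataclass
class PurkinjeNetwork:
    """Two seeded binary fractal trees (left / right bundle) grown on the
    endocardial surfaces, emanating from one atrioventricular-node point."""

    nodes: np.ndarray          # (n, 3)
    edges: np.ndarray          # (m, 2)
    edge_bundle: np.ndarray    # (m,) "LEFT" / "RIGHT"
    roots: dict                # bundle -> node id
    av_point: np.ndarray       # (3,)
    pmj_nodes: np.ndarray      # terminal node ids
    pmj_vertices: np.ndarray   # matching myocardial vertex ids

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.nodes[self.edges[:, 1]] - self.nodes[self.edges[:, 0]], axis=1)

    def bundle_nodes(self, bundle: str) -> np.ndarray:
        return np.unique(self.edges[self.edge_bundle == bundle])


@dataclass
class ElectrodeSet:
    """Nine labeled torso positions: precordial V1-V6 plus limb LA, RA, F."""

    positions: dict  # label -> (3,) array

    LABELS = ("V1", "V2", "V3", "V4", "V5", "V6", "LA", "RA", "F")

    def __post_init__(self):
        missing = set(self.LABELS) - set(self.positions)
        if missing:
            raise ValueError(f"missing electrodes: {sorted(missing)}")

    def array(self) -> np.ndarray:
        return np.array([self.positions[l] for l in self.LABELS])


@dataclass
class Anatomy:
    """Bundle of everything the tissue solver needs."""

    mesh: Mesh
    phi: np.ndarray            # transmural coordinate per vertex
    fibers: FiberField
    purkinje: PurkinjeNetwork
    electrodes: ElectrodeSet
    cell_types: np.ndarray     # per-vertex int codes (0 EPI, 1 MCELL, 2 ENDO)


# --------------------------------------------------------------------------
# mesh builders
# --------------------------------------------------------------------------

_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _cube_tets(corner_ids):
    """Six-tet Kuhn split of a cube given its 8 corner vertex ids indexed
    by (dx, dy, dz) bits; conforming across neighbouring cubes."""
    tets = []
    for perm in _KUHN_PERMS:
        bits = [0, 0, 0]
        path = [tuple(bits)]
        for axis in perm:
            bits[axis] = 1
            path.append(tuple(bits))
        tets.append([corner_ids[b] for b in path])
    return tets


def _orient(vertices, tets):
    tets = np.asarray(tets)
    v = vertices[tets]
    vol = np.einsum("ij,ij->i", np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), v[:, 3] - v[:, 0])
    flip = vol < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def _boundary_faces(tets):
    faces = np.concatenate([tets[:, idx] for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def build_slab_mesh(lx: float, ly: float, lz: float, h: float = 2.0) -> Mesh:
    """Structured slab: each h-cube split into 6 tets.  Endocardium is the
    z = 0 face (tagged ENDO_LV for x < lx/2, ENDO_RV beyond), epicardium
    the z = lz face, remaining sides BASE."""
    if min(lx, ly, lz) <= 0 or h <= 0:
        raise ValueError("dimensions and h must be positive")
    if h > min(lx, ly, lz):
        raise ValueError("h exceeds smallest slab dimension")
    nx, ny, nz = (int(round(d / h)) for d in (lx, ly, lz))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = {(a, b, cc): vid(i + a, j + b, k + cc) for a in (0, 1) for b in (0, 1) for cc in (0, 1)}
                tets.extend(_cube_tets(ids))
    tets = _orient(vertices, tets)

    faces = _boundary_faces(tets)
    cent = vertices[faces].mean(axis=1)
    tags = np.full(len(faces), "BASE", dtype="U8")
    eps = 1e-9 * max(lx, ly, lz)
    endo = cent[:, 2] < eps
    tags[endo & (cent[:, 0] < lx / 2)] = "ENDO_LV"
    tags[endo & (cent[:, 0] >= lx / 2)] = "ENDO_RV"
    tags[cent[:, 2] > lz - eps] = "EPI"
    return Mesh(vertices, tets, faces, tags, h)


def build_biventricular_mesh(
    rv_radii=(16.0, 16.0, 24.0),
    lv_radii=(6.0, 6.0, 10.0),
    wall: float = 4.0,
    base_cut: float = 4.0,
    h: float = 2.5,
) -> Mesh:
    """Idealized biventricular mesh: the union of two truncated-ellipsoid
    shells (dominant RV, small LV — the hypoplastic-left-heart layout),
    voxelized at size h and split into tets.

    The LV is placed beside the RV with a wall-deep overlap so the union is
    one connected body; cavities are carved out of both shells.  Boundary
    faces are tagged by the region the neighbouring (outside) voxel centre
    falls in: a cavity gives ENDO_LV / ENDO_RV, above the base plane BASE,
    elsewhere EPI.
    """
    rv_radii = np.asarray(rv_radii, float)
    lv_radii = np.asarray(lv_radii, float)
    if h > wall:
        raise ValueError("h must not exceed the wall thickness")
    rv_epi = rv_radii + wall
    lv_epi = lv_radii + wall
    rv_c = np.zeros(3)
    lv_c = np.array([rv_epi[0] + lv_epi[0] - 2.0 * wall, 0.0, rv_c[2] - rv_radii[2] + lv_radii[2]])

    def rho(x, cen, rad):
        return (((x - cen) / rad) ** 2).sum(axis=-1)

    def in_cavity(x):
        return (rho(x, rv_c, rv_radii) < 1) | (rho(x, lv_c, lv_radii) < 1)

    def in_solid(x):
        shell = (rho(x, rv_c, rv_epi) < 1) | (rho(x, lv_c, lv_epi) < 1)
        return shell & ~in_cavity(x) & (x[..., 2] <= base_cut)

    lo = np.minimum(rv_c - rv_epi, lv_c - lv_epi) - h
    hi = np.maximum(rv_c + rv_epi, lv_c + lv_epi) + h
    hi[2] = base_cut + h
    n = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    # voxel centres
    axes = [lo[d] + h * (np.arange(n[d]) + 0.5) for d in range(3)]
    C = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    keep = in_solid(C.reshape(-1, 3)).reshape(C.shape[:3])
    if not keep.any():
        raise ValueError("empty biventricular solid; check radii/wall")

    # grid vertices shared by voxels
    def vid(i, j, k):
        return (i * (n[1] + 1) + j) * (n[2] + 1) + k

    gx = [lo[d] + h * np.arange(n[d] + 1) for d in range(3)]
    X, Y, Z = np.meshgrid(*gx, indexing="ij")
    grid_vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    tets = []
    kept = np.argwhere(keep)
    for i, j, k in kept:
        ids = {(a, b, cc): vid(i + a, j + b, k + cc) for a in (0, 1) for b in (0, 1) for cc in (0, 1)}
        tets.extend(_cube_tets(ids))
    tets = np.asarray(tets)

    # compact vertex numbering
    used, inv = np.unique(tets, return_inverse=True)
    vertices = grid_vertices[used]
    tets = _orient(vertices, inv.reshape(tets.shape))

    # connectivity check (vertex-connected components of the tet graph)
    n_comp = _count_components(len(vertices), tets)
    if n_comp != 1:
        raise ValueError(f"biventricular union is not connected ({n_comp} components)")

    faces = _boundary_faces(tets)
    cent = vertices[faces].mean(axis=1)
    normals = _face_outward_normals(vertices, tets, faces)
    probe = cent + 0.5 * h * normals  # just outside, ~neighbour voxel centre
    tags = np.full(len(faces), "EPI", dtype="U8")
    tags[probe[:, 2] > base_cut] = "BASE"
    rv_cav = rho(probe, rv_c, rv_radii) < 1
    lv_cav = rho(probe, lv_c, lv_radii) < 1
    tags[rv_cav] = "ENDO_RV"
    tags[lv_cav & ~rv_cav] = "ENDO_LV"
    return Mesh(vertices, tets, faces, tags, h)


def _count_components(n_vertices, tets):
    rows = np.concatenate([tets[:, a] for a in range(4) for b in range(4) if a != b])
    cols = np.concatenate([tets[:, b] for a in range(4) for b in range(4) if a != b])
    g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_vertices, n_vertices))
    n_comp, _ = sp.csgraph.connected_components(g.tocsr(), directed=False)
    return n_comp


def _face_outward_normals(vertices, tets, faces):
    """Unit outward normal per boundary face (oriented away from the owning
    tet's centroid)."""
    tree = {}
    for ti, tet in enumerate(tets):
        for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
            key = tuple(sorted(tet[list(idx)]))
            tree.setdefault(key, ti)
    cent_t = vertices[tets].mean(axis=1)
    v = vertices[faces]
    nrm = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    fc = v.mean(axis=1)
    for fi, face in enumerate(faces):
        ti = tree[tuple(sorted(face))]
        if np.dot(nrm[fi], fc[fi] - cent_t[ti]) < 0:
            nrm[fi] = -nrm[fi]
    return nrm


# --------------------------------------------------------------------------
# P1 finite-element helpers (shared with the tissue solver)
# --------------------------------------------------------------------------

def p1_gradients(mesh: Mesh):
    """Per-tet basis-function gradients G (m, 4, 3) and volumes (m,)."""
    v = mesh.vertices[mesh.tets]
    J = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)  # (m,3,3)
    vol = np.linalg.det(J) / 6.0
    Jinv = np.linalg.inv(J)
    # gradients of barycentric coords 1..3 are rows of J^-1; coord 0 = -sum
    g123 = Jinv  # (m, 3(coord), 3(xyz))
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def stiffness_matrix(mesh: Mesh, tensor_per_tet=None) -> sp.csr_matrix:
    """P1 stiffness with an optional (m, 3, 3) diffusion tensor per tet."""
    G, vol = p1_gradients(mesh)
    if tensor_per_tet is None:
        DG = G
    else:
        DG = np.einsum("mab,mjb->mja", tensor_per_tet, G)
    K_loc = np.einsum("mia,mja,m->mij", G, DG, vol)
    m = len(mesh.tets)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(m, 4, 4)
    cols = np.tile(mesh.tets[:, None, :], (1, 4, 1))
    n = mesh.n_vertices
    return sp.coo_matrix((K_loc.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)).tocsr()


def lumped_mass(mesh: Mesh) -> np.ndarray:
    vol = mesh.tet_volumes()
    m = np.zeros(mesh.n_vertices)
    np.add.at(m, mesh.tets.ravel(), np.repeat(vol / 4.0, 4))
    return m


def consistent_mass(mesh: Mesh) -> sp.csr_matrix:
    """P1 consistent mass matrix.  The tissue solver uses it rather than
    the lumped diagonal: on the coarse desk-scale meshes lumping blocks
    wave propagation outright, while the consistent matrix conducts."""
    vol = mesh.tet_volumes()
    loc = (np.ones((4, 4)) + np.eye(4)) / 20.0
    K = np.einsum("m,ij->mij", vol, loc)
    m = len(mesh.tets)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(m, 4, 4)
    cols = np.tile(mesh.tets[:, None, :], (1, 4, 1))
    n = mesh.n_vertices
    return sp.coo_matrix((K.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)).tocsr()


def transmural_coordinate(mesh: Mesh) -> np.ndarray:
    """Laplace-Dirichlet transmural coordinate: 0 on the endocardium,
    1 on the epicardium, zero flux elsewhere."""
    endo = np.concatenate([mesh.boundary_vertices("ENDO_LV"), mesh.boundary_vertices("ENDO_RV")])
    epi = mesh.boundary_vertices("EPI")
    if len(endo) == 0 or len(epi) == 0:
        raise ValueError("mesh must have tagged ENDO and EPI facets")
    K = stiffness_matrix(mesh).tolil()
    n = mesh.n_vertices
    rhs = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    val = np.zeros(n)
    fixed[endo] = True
    fixed[epi] = True
    val[epi] = 1.0
    K_csr = K.tocsr()
    free = ~fixed
    rhs_free = -K_csr[free][:, fixed] @ val[fixed]
    phi = val.copy()
    phi[free] = spla.spsolve(K_csr[free][:, free], rhs_free)
    return phi


def assign_cell_types(phi: np.ndarray) -> np.ndarray:
    """Transmural cell-type layering: endo phi < 1/3, M-cell middle third,
    epi outer third.  Returns integer codes (0 EPI, 1 MCELL, 2 ENDO)."""
    codes = np.full(phi.shape, 1, dtype=int)
    codes[phi < 1.0 / 3.0] = 2
    codes[phi > 2.0 / 3.0] = 0
    return codes


# --------------------------------------------------------------------------
# fibers
# --------------------------------------------------------------------------

def rule_based_fibers(
    mesh: Mesh,
    phi: np.ndarray,
    alpha_endo: float = 60.0,
    alpha_epi: float = -60.0,
    beta_endo: float = -20.0,
    beta_epi: float = 20.0,
) -> FiberField:
    """Rule-based fiber field: helix angle interpolated linearly in the
    transmural coordinate (alpha_endo at phi=0 to alpha_epi at phi=1) and
    sheet tilt beta likewise; the fiber is the circumferential direction
    rotated by alpha in the wall tangent plane and tilted by beta toward
    the transmural direction."""
    G, _ = p1_gradients(mesh)
    grad_phi = np.einsum("mia,mi->ma", G, phi[mesh.tets])
    phi_bar = phi[mesh.tets].mean(axis=1)

    norm = np.linalg.norm(grad_phi, axis=1)
    e_t = np.zeros_like(grad_phi)
    ok_t = norm > 1e-12
    e_t[ok_t] = grad_phi[ok_t] / norm[ok_t, None]
    e_t[~ok_t] = (0.0, 0.0, 1.0)

    k = np.array([0.0, 0.0, 1.0])
    e_c = np.cross(np.broadcast_to(k, e_t.shape), e_t)
    c_norm = np.linalg.norm(e_c, axis=1)
    degenerate = c_norm < 1e-8
    if degenerate.all():
        # wall normal parallel to the long axis everywhere (slab): use the
        # in-plane x axis as the circumferential reference
        a = np.array([1.0, 0.0, 0.0])
        e_c = a - e_t * (e_t @ a)[:, None]
        c_norm = np.linalg.norm(e_c, axis=1)
        degenerate = c_norm < 1e-8
    e_c[~degenerate] /= c_norm[~degenerate, None]
    if degenerate.any():
        # apex-like singular frames: copy the nearest valid element's frame
        cent = mesh.tet_centroids()
        tree = cKDTree(cent[~degenerate])
        _, near = tree.query(cent[degenerate])
        src = np.nonzero(~degenerate)[0][near]
        borrowed = e_c[src]
        proj = borrowed - e_t[degenerate] * np.einsum("ij,ij->i", borrowed, e_t[degenerate])[:, None]
        proj /= np.linalg.norm(proj, axis=1, keepdims=True)
        e_c[degenerate] = proj
    e_l = np.cross(e_t, e_c)

    alpha = np.deg2rad(alpha_endo * (1 - phi_bar) + alpha_epi * phi_bar)
    beta = np.deg2rad(beta_endo * (1 - phi_bar) + beta_epi * phi_bar)
    f = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    f = np.cos(beta)[:, None] * f + np.sin(beta)[:, None] * e_t
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    return FiberField(f)


# --------------------------------------------------------------------------
# Purkinje
# --------------------------------------------------------------------------

def _closest_point_on_triangle(p, a, b, c):
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + (c - b) * w
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


class _Surface:
    """Projection helper for one tagged endocardial surface."""

    def __init__(self, mesh: Mesh, tag: str):
        self.faces = mesh.boundary_faces[mesh.boundary_tags == tag]
        if len(self.faces) == 0:
            raise ValueError(f"no boundary facets tagged {tag}")
        self.verts = mesh.vertices
        self.centroids = self.verts[self.faces].mean(axis=1)
        self.tree = cKDTree(self.centroids)
        v = self.verts[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        self.normals = n / np.linalg.norm(n, axis=1, keepdims=True)

    def project(self, p, k_nearest: int = 8):
        _, idx = self.tree.query(p, k=min(k_nearest, len(self.faces)))
        idx = np.atleast_1d(idx)
        best, dist = None, np.inf
        for fi in idx:
            a, b, c = self.verts[self.faces[fi]]
            q = _closest_point_on_triangle(p, a, b, c)
            d = np.linalg.norm(q - p)
            if d < dist:
                best, dist, nfi = q, d, fi
        return best, dist, self.normals[nfi]

    def centroid(self):
        return self.centroids.mean(axis=0)


def generate_purkinje(
    mesh: Mesh,
    seed: int = 0,
    n_generations: int = 5,
    branch_len: float = 8.0,
    branch_angle: float = 35.0,
) -> PurkinjeNetwork:
    """Grow a deterministic-given-seed binary fractal tree on each
    endocardial surface.  Children deviate +-branch_angle (with small
    seeded jitter) from the parent direction within the local tangent
    plane; segments are projected back onto the surface.  A branch whose
    projection drifts further than the mesh size from the surface is
    terminated early.  All terminals become Purkinje-myocardial junctions
    mapped to the nearest myocardial vertex."""
    rng = np.random.default_rng(seed)
    surfaces = {"LEFT": _Surface(mesh, "ENDO_LV"), "RIGHT": _Surface(mesh, "ENDO_RV")}

    seeds = {}
    for bundle, surf in surfaces.items():
        q, _, _ = surf.project(surf.centroid())
        seeds[bundle] = q
    av_point = 0.5 * (seeds["LEFT"] + seeds["RIGHT"])

    nodes, edges, edge_bundle = [], [], []
    roots, terminals = {}, []

    for bundle in ("LEFT", "RIGHT"):
        surf = surfaces[bundle]
        root_id = len(nodes)
        nodes.append(seeds[bundle])
        roots[bundle] = root_id

        # initial direction: in the tangent plane, seeded
        nrm = surf.project(seeds[bundle])[2]
        d0 = rng.standard_normal(3)
        d0 -= nrm * (d0 @ nrm)
        d0 /= np.linalg.norm(d0)

        frontier = [(root_id, d0)]
        for _gen in range(n_generations):
            nxt = []
            for parent_id, d in frontier:
                p = nodes[parent_id]
                for sign in (+1.0, -1.0):
                    ang = np.deg2rad(sign * branch_angle * (1.0 + 0.1 * rng.standard_normal()))
                    nrm_p = surf.project(p)[2]
                    d_t = d - nrm_p * (d @ nrm_p)
                    if np.linalg.norm(d_t) < 1e-12:
                        d_t = d
                    d_t /= np.linalg.norm(d_t)
                    # rotate in the tangent plane about the surface normal
                    perp = np.cross(nrm_p, d_t)
                    d_child = np.cos(ang) * d_t + np.sin(ang) * perp
                    target = p + branch_len * d_child
                    q, dist, _ = surf.project(target)
                    if np.linalg.norm(q - p) < 1e-9:
                        continue
                    child_id = len(nodes)
                    nodes.append(q)
                    edges.append((parent_id, child_id))
                    edge_bundle.append(bundle)
                    if dist > mesh.h:
                        terminals.append(child_id)  # left the surface: early PMJ
                    else:
                        nxt.append((child_id, (q - p) / np.linalg.norm(q - p)))
            frontier = nxt
        terminals.extend(nid for nid, _ in frontier)

    nodes = np.asarray(nodes)
    edges = np.asarray(edges, dtype=int)
    edge_bundle = np.asarray(edge_bundle, dtype="U5")
    pmj = np.asarray(sorted(set(terminals)), dtype=int)
    vert_tree = cKDTree(mesh.vertices)
    _, pmj_vertices = vert_tree.query(nodes[pmj])
    return PurkinjeNetwork(nodes, edges, edge_bundle, roots, av_point, pmj, pmj_vertices)


# --------------------------------------------------------------------------
# electrodes
# --------------------------------------------------------------------------

def place_electrodes(mesh: Mesh, torso_scale: float = 3.5, clearance: float = 10.0) -> ElectrodeSet:
    """Place the 9 ECG electrodes on a virtual torso box around the mesh:
    V1-V6 along an anterior (-y) arc, LA/RA lateral-superior, F inferior.
    Positions scale with the mesh bounding box; every electrode must clear
    the mesh by ``clearance`` mm."""
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    c = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    R = torso_scale * float(np.linalg.norm(half))

    pos = {}
    arc = np.deg2rad(np.linspace(-50.0, 75.0, 6))
    for label, th in zip(("V1", "V2", "V3", "V4", "V5", "V6"), arc):
        pos[label] = c + np.array([R * np.sin(th), -R * np.cos(th), -0.3 * half[2]])
    pos["LA"] = c + np.array([0.9 * R, 0.3 * R, 0.8 * R])
    pos["RA"] = c + np.array([-0.9 * R, 0.3 * R, 0.8 * R])
    pos["F"] = c + np.array([0.0, 0.0, -1.2 * R])

    tree = cKDTree(mesh.vertices)
    for label, p in pos.items():
        d, _ = tree.query(p)
        if d < clearance:
            raise ValueError(
                f"electrode {label} only {d:.1f} mm from the mesh; increase torso_scale"
            )
    return ElectrodeSet(pos)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def slab_preset(
    lx: float = 8.0,
    ly: float = 8.0,
    lz: float = 3.0,
    h: float = 0.5,
    purkinje_seed: int = 7,
    n_generations: int = 4,
    branch_len: float = 2.0,
) -> Anatomy:
    """Desk-scale default anatomy: a slab with rule-based fibers and a
    small two-bundle Purkinje tree on the endocardial face."""
    mesh = build_slab_mesh(lx, ly, lz, h)
    phi = transmural_coordinate(mesh)
    fibers = rule_based_fibers(mesh, phi)
    purk = generate_purkinje(mesh, seed=purkinje_seed, n_generations=n_generations, branch_len=branch_len)
    electrodes = place_electrodes(mesh)
    return Anatomy(mesh, phi, fibers, purk, electrodes, assign_cell_types(phi))


def hlhs_preset(h: float = 2.5, purkinje_seed: int = 7) -> Anatomy:
    """Idealized hypoplastic-left-heart biventricular anatomy (small LV)."""
    mesh = build_biventricular_mesh(h=h)
    phi = transmural_coordinate(mesh)
    fibers = rule_based_fibers(mesh, phi)
    purk = generate_purkinje(mesh, seed=purkinje_seed, n_generations=5, branch_len=6.0)
    electrodes = place_electrodes(mesh)
    return Anatomy(mesh, phi, fibers, purk, electrodes, assign_cell_types(phi))
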