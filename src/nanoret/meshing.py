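"""Tessellated nanostructure surfaces.

A SurfaceMesh is a closed triangulated boundary of a metallic body: each
triangle (tessera) carries a centroid, a flat area and an outward unit
normal, which is all the quasistatic boundary-element solver needs.  Lengths
are in nm.

Besides a subdivided-icosahedron sphere (validation geometry), two STM
nanojunction builders are provided:

* build_tip_a -- a truncated silver cone with rounded edges terminated by a
  spherical apex of 0.2 nm radius, suspended 2.0 nm above a cylindrical
  silver substrate (the STML-style junction).
* build_tip_b -- a much larger rounded tip carrying a sub-nanometric
  protrusion (0.6 nm base, 0.5 nm spherical cap) at its apex, 0.4 nm above
  the molecular plane (the TEPL-style junction).

Cone dimensions, substrate size and edge-rounding radii are not
experimentally known; they are explicit parameters whose defaults are a
documented reconstruction (see docs/methods.md).  Meshes are graded: tesserae
shrink towards the tip apex and the substrate centre, where the molecular
near fields live.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "MeshInvariantError",
    "OrientationError",
    "build_sphere",
    "build_tip_a",
    "build_tip_b",
    "combine",
    "read_mesh",
    "write_mesh",
]


class MeshInvariantError(ValueError):
    pass


class OrientationError(ValueError):
    pass


@dataclass
class SurfaceMesh:
    """Triangulated closed surface with per-tessera BEM data (lengths in nm)."""

    vertices: np.ndarray  # (V, 3) nm
    faces: np.ndarray  # (F, 3) int
    centroids: np.ndarray = field(init=False)
    areas: np.ndarray = field(init=False)
    normals: np.ndarray = field(init=False)
    label: str = "mesh"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        tri = self.vertices[self.faces]  # (F, 3, 3)
        self.centroids = tri.mean(axis=1)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(cross, axis=1)
        if np.any(nrm <= 0):
            raise MeshInvariantError("degenerate (zero-area) triangle in mesh")
        self.areas = 0.5 * nrm
        self.normals = cross / nrm[:, None]

    @property
    def n_tesserae(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward orientation."""
        return float(np.einsum("ij,ij,i->", self.centroids, self.normals, self.areas) / 3.0)

    def oriented_outward(self) -> "SurfaceMesh":
        """Return a copy with faces flipped if the net orientation is inward."""
        if self.signed_volume() < 0:
            return SurfaceMesh(self.vertices, self.faces[:, ::-1], label=self.label)
        return self

    def translated(self, shift) -> "SurfaceMesh":
        shift = np.asarray(shift, float)
        m = SurfaceMesh(self.vertices + shift, self.faces, label=self.label)
        # preserve curved-tessera overrides (see build_sphere)
        m.centroids = self.centroids + shift
        m.normals = self.normals.copy()
        m.areas = self.areas.copy()
        return m

    def validate(self, closed: bool = True):
        """Check the tessera invariants; raise MeshInvariantError on failure."""
        if np.any(self.areas <= 0):
            raise MeshInvariantError("non-positive tessera area")
        if np.max(np.abs(np.linalg.norm(self.normals, axis=1) - 1.0)) > 1e-9:
            raise MeshInvariantError("non-unit normal")
        if closed:
            resid = np.linalg.norm(self.areas @ self.normals) / self.total_area
            if resid >= 1e-3:
                raise MeshInvariantError(
                    f"closed-surface test failed: |sum A_i n_i|/sum A_i = {resid:.2e}"
                )
        # pairwise-distinct centroids (nearest-neighbour check)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.centroids).query(self.centroids, k=2)
        if np.min(d[:, 1]) <= 0:
            raise MeshInvariantError("coincident tessera centroids")
        return self


def combine(*meshes: SurfaceMesh, label: str = "combined") -> SurfaceMesh:
    """Concatenate disjoint closed bodies into one tessera list.

    The tip and the substrate are kept as two disjoint closed surfaces but
    share a single response-charge system.
    """
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    return SurfaceMesh(np.vstack(verts), np.vstack(faces), label=label)


# ---------------------------------------------------------------------------
# sphere


def build_sphere(
    radius: float,
    refinement_level: int = 3,
    center=(0.0, 0.0, 0.0),
    spherical_tesserae: bool = True,
) -> SurfaceMesh:
    """Subdivided-icosahedron sphere with 20 * 4**level tesserae.

    With spherical_tesserae (default) the per-tessera BEM data describe
    curved tesserae of the true sphere: centroids projected radially onto the
    surface, radial normals, and areas scaled to the exact sphere area.  This
    is the standard PCM treatment of curved boundaries (the single-layer
    self-term constant is calibrated for it) and is markedly more accurate
    than flat facets.  Set spherical_tesserae=False for a plain flat-faceted
    mesh (e.g. for file round-trips, where only vertices/faces persist).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if refinement_level < 0:
        raise ValueError("refinement_level must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=refinement_level, radius=radius)
    m = SurfaceMesh(
        np.asarray(ico.vertices),
        np.asarray(ico.faces),
        label=f"sphere(r={radius},level={refinement_level})",
    ).oriented_outward()
    if spherical_tesserae:
        radial = m.centroids / np.linalg.norm(m.centroids, axis=1)[:, None]
        m.centroids = radius * radial
        m.normals = radial
        m.areas = m.areas * (4.0 * np.pi * radius**2 / m.areas.sum())
    m.centroids = m.centroids + np.asarray(center, float)
    m.vertices = m.vertices + np.asarray(center, float)
    return m


# ---------------------------------------------------------------------------
# profiles of revolution

def _arc(center, radius, ang0, ang1, n=64):
    """Arc in the (rho, z) half-plane; angles measured from the -z direction
    towards +rho, so ang=0 points straight down."""
    t = np.linspace(ang0, ang1, n)
    rho = center[0] + radius * np.sin(t)
    z = center[1] - radius * np.cos(t)
    return np.column_stack([rho, z])


def _polyline_concat(parts):
    out = [parts[0]]
    for p in parts[1:]:
        if np.allclose(p[0], out[-1][-1], atol=1e-12):
            p = p[1:]
        out.append(p)
    return np.vstack(out)


def _resample_profile(profile, ds_fun, s_origin=0.0):
    """Resample a (rho,z) polyline by arc length with target spacing ds_fun(s),
    s measured from the start of the profile plus s_origin."""
    seg = np.linalg.norm(np.diff(profile, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    # march along arc length
    stops = [0.0]
    while stops[-1] < total:
        step = max(ds_fun(stops[-1] + s_origin), 1e-6)
        stops.append(min(stops[-1] + step, total))
    # avoid a tiny trailing segment
    if len(stops) > 2 and stops[-1] - stops[-2] < 0.3 * ds_fun(stops[-2] + s_origin):
        stops.pop(-2)
    stops = np.asarray(stops)
    rho = np.interp(stops, s, profile[:, 0])
    z = np.interp(stops, s, profile[:, 1])
    return np.column_stack([rho, z])


def _revolve(profile, n_phi: int, label: str) -> SurfaceMesh:
    """Revolve a (rho, z) profile (rho=0 at both ends) around the z axis.

    Rings collapse to pole vertices where rho ~ 0.  Winding is chosen so the
    resulting closed surface is outward-oriented (checked via signed volume).
    """
    rho, z = profile[:, 0], profile[:, 1]
    if rho[0] > 1e-9 or rho[-1] > 1e-9:
        raise ValueError("profile must start and end on the axis (rho = 0)")
    phis = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    cos, sin = np.cos(phis), np.sin(phis)

    verts = [np.array([0.0, 0.0, z[0]])]
    ring_index = [None]  # index of first vertex of each ring, None for poles
    for i in range(1, len(rho) - 1):
        ring_index.append(len(verts))
        verts.extend(np.column_stack([rho[i] * cos, rho[i] * sin, np.full(n_phi, z[i])]))
    ring_index.append(None)
    bottom_pole, top_pole = 0, len(verts)
    verts.append(np.array([0.0, 0.0, z[-1]]))
    verts = np.asarray(verts)

    faces = []
    nrings = len(rho) - 2
    for k in range(n_phi):
        k2 = (k + 1) % n_phi
        r0 = ring_index[1]
        faces.append([bottom_pole, r0 + k2, r0 + k])
        rl = ring_index[nrings]
        faces.append([top_pole, rl + k, rl + k2])
    for i in range(1, nrings):
        ra, rb = ring_index[i], ring_index[i + 1]
        for k in range(n_phi):
            k2 = (k + 1) % n_phi
            faces.append([ra + k, rb + k2, rb + k])
            faces.append([ra + k, ra + k2, rb + k2])
    m = SurfaceMesh(verts, np.asarray(faces), label=label)
    return m.oriented_outward()


def _graded_ds(apex_edge_length, coarse_edge_length, growth=0.35):
    """Target edge length growing linearly with arc distance from the apex."""

    def ds(s):
        return float(min(apex_edge_length + growth * s, coarse_edge_length))

    return ds


def _substrate_mesh(radius, thickness, center_edge_length, coarse_edge_length, n_phi):
    """Closed cylinder, top face at z = 0, graded finer near the centre."""
    top = np.array([[0.0, 0.0], [radius, 0.0]])
    wall = np.array([[radius, 0.0], [radius, -thickness]])
    bottom = np.array([[radius, -thickness], [0.0, -thickness]])
    prof = _polyline_concat([top, wall, bottom])
    ds = _graded_ds(center_edge_length, coarse_edge_length, growth=0.5)
    prof = _resample_profile(prof, ds)
    return _revolve(prof, n_phi, label="substrate")


def build_tip_a(
    apex_radius: float = 0.2,
    gap: float = 2.0,
    cone_half_angle: float = 45.0,
    cone_height: float = 16.0,
    substrate_radius: float = 8.0,
    substrate_thickness: float = 4.0,
    apex_edge_length: float = 0.08,
    edge_rounding: float = 1.5,
    coarse_edge_length: float = 3.0,
    n_phi: int = 26,
    substrate_n_phi: int = 22,
):
    """STML-style junction: rounded truncated cone tip above a cylinder.

    Returns (tip, substrate) as two closed SurfaceMesh bodies.  The tip's
    lowest point sits at z = gap above the substrate top face (z = 0); the
    molecular plane for this setup is at z = 1.5 nm (0.5 nm below the apex).
    """
    for name, v in [
        ("apex_radius", apex_radius),
        ("gap", gap),
        ("cone_half_angle", cone_half_angle),
        ("cone_height", cone_height),
        ("substrate_radius", substrate_radius),
        ("substrate_thickness", substrate_thickness),
        ("apex_edge_length", apex_edge_length),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    theta = np.deg2rad(cone_half_angle)
    z_top = gap + cone_height
    # spherical apex cap, tangent to the cone flank
    cap_center = (0.0, gap + apex_radius)
    cap = _arc(cap_center, apex_radius, 0.0, np.pi / 2 - theta, n=60)
    # cone flank from the tangency point up to the start of the edge rounding
    p0 = cap[-1]
    if z_top <= p0[1]:
        raise ValueError("geometrically impossible: cone_height shorter than the apex cap")
    # rounded top edge: arc of radius edge_rounding tangent to flank and top face
    flank_len_max = (z_top - p0[1]) / np.cos(theta)
    r_e = min(edge_rounding, 0.45 * flank_len_max * np.cos(theta))
    # edge arc center C sits r_e inside both the flank and the top plane:
    # C_z = z_top - r_e and C = P + r_e * n_in for the tangency point P on
    # the flank, whose inward normal is (-cos th, sin th)
    n_in = np.array([-np.cos(theta), np.sin(theta)])
    cz = z_top - r_e
    # point on flank with (C - P) . flank_dir = 0 and C = P + r_e * n_in
    # C_z = P_z + r_e * n_in_z  ->  P_z = cz - r_e*sin(theta)
    pz = cz - r_e * np.sin(theta)
    if pz <= p0[1]:
        raise ValueError("geometrically impossible: cone too short for edge rounding")
    prho = p0[0] + (pz - p0[1]) * np.tan(theta)
    C = np.array([prho, pz]) + r_e * n_in
    flank = np.array([p0, [prho, pz]])
    # arc from flank tangency to horizontal top: angle from -z axis convention
    ang0 = np.pi / 2 + theta  # radially outward + tilted by theta
    ang1 = np.pi  # pointing up (top face)
    edge = _arc(C, r_e, ang0, ang1, n=40)
    top = np.array([edge[-1], [0.0, z_top]])
    prof = _polyline_concat([cap, flank, edge, top])
    ds = _graded_ds(apex_edge_length, coarse_edge_length)
    prof = _resample_profile(prof, ds)
    tip = _revolve(prof, n_phi, label="tip_a")
    substrate = _substrate_mesh(
        substrate_radius, substrate_thickness, 6 * apex_edge_length, coarse_edge_length, substrate_n_phi
    )
    return tip.validate(), substrate.validate()


def build_tip_b(
    protrusion_base_radius: float = 0.6,
    protrusion_cap_radius: float = 0.5,
    tip_molecule_gap: float = 0.4,
    molecule_substrate_gap: float = 1.4,
    body_radius: float = 4.0,
    body_half_angle: float = 30.0,
    body_height: float = 16.0,
    substrate_radius: float = 20.0,
    substrate_thickness: float = 4.0,
    apex_edge_length: float = 0.07,
    coarse_edge_length: float = 3.0,
    n_phi: int = 26,
    substrate_n_phi: int = 22,
    include_protrusion: bool = True,
):
    """TEPL-style junction: large rounded tip with an atomistic protrusion.

    The protrusion is a spherical cap (radius protrusion_cap_radius) flaring
    to protrusion_base_radius where it joins the tip body.  Its lowest point
    sits tip_molecule_gap above the molecular plane, itself
    molecule_substrate_gap above the substrate top face.
    """
    if protrusion_cap_radius <= 0 or protrusion_base_radius < protrusion_cap_radius:
        raise ValueError("need protrusion_base_radius >= protrusion_cap_radius > 0")
    z0 = molecule_substrate_gap + tip_molecule_gap  # lowest metal point
    rc = protrusion_cap_radius
    rb = protrusion_base_radius
    parts = []
    if include_protrusion:
        cap = _arc((0.0, z0 + rc), rc, 0.0, np.pi / 2, n=48)  # to the equator
        # flare from (rc, z0+rc) out to (rb, z_base)
        z_base = z0 + rc + (rb - rc) / np.tan(np.deg2rad(35.0))
        flare = np.array([[rc, z0 + rc], [rb, z_base]])
        parts += [cap, flare]
        body_low = z_base
        start_rho = rb
    else:
        body_low = z0
        start_rho = 0.0
    # big body: sphere of radius body_radius whose surface passes through the
    # protrusion base (or whose lowest point is at z0 without protrusion)
    th = np.deg2rad(body_half_angle)
    Cz = body_low + np.sqrt(body_radius**2 - start_rho**2)
    a0 = np.arcsin(start_rho / body_radius)
    body_cap = _arc((0.0, Cz), body_radius, a0, np.pi / 2 - th, n=60)
    p0 = body_cap[-1]
    z_top = z0 + body_height
    if z_top < p0[1] + 1.0:
        raise ValueError("geometrically impossible: body_height too small")
    prho = p0[0] + (z_top - p0[1]) * np.tan(th)
    flank = np.array([p0, [prho, z_top]])
    top = np.array([[prho, z_top], [0.0, z_top]])
    parts += [body_cap, flank, top]
    prof = _polyline_concat(parts)
    ds = _graded_ds(apex_edge_length, coarse_edge_length)
    prof = _resample_profile(prof, ds)
    tip = _revolve(prof, n_phi, label="tip_b")
    substrate = _substrate_mesh(
        substrate_radius, substrate_thickness, 6 * apex_edge_length, coarse_edge_length, substrate_n_phi
    )
    return tip.validate(), substrate.validate()


# ---------------------------------------------------------------------------
# I/O: Gmsh MSH 2.2 ASCII and OFF (triangles only)


def _check_winding(faces, repair=False):
    """Closed orientable surface: every directed edge must appear exactly once.

    Returns possibly-repaired faces; raises OrientationError when inconsistent
    and repair is False.
    """
    edges = {}
    bad = False
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if (a, b) in edges:
                bad = True
            edges.setdefault((a, b), fi)
    if not bad:
        return faces
    if not repair:
        raise OrientationError(
            "inconsistent triangle winding (duplicated directed edge); "
            "pass repair=True to fix by region growing"
        )
    # region-growing repair: flip faces to agree with an arbitrary seed
    from collections import defaultdict, deque

    undirected = defaultdict(list)
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            undirected[frozenset((a, b))].append(fi)
    faces = faces.copy()
    seen = np.zeros(len(faces), dtype=bool)
    for seed in range(len(faces)):
        if seen[seed]:
            continue
        seen[seed] = True
        q = deque([seed])
        while q:
            fi = q.popleft()
            f = faces[fi]
            dir_edges = {(f[0], f[1]), (f[1], f[2]), (f[2], f[0])}
            for a, b in list(dir_edges):
                for fj in undirected[frozenset((a, b))]:
                    if fj == fi or seen[fj]:
                        continue
                    g = faces[fj]
                    if (a, b) in {(g[0], g[1]), (g[1], g[2]), (g[2], g[0])}:
                        faces[fj] = g[::-1]
                    seen[fj] = True
                    q.append(fj)
    return faces


def read_mesh(path, fmt: str | None = None, repair: bool = False) -> SurfaceMesh:
    """Read a triangle surface mesh from Gmsh MSH 2.2 ASCII or OFF."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    text = path.read_text()
    if fmt == "off":
        verts, faces = _parse_off(text)
    elif fmt == "msh":
        verts, faces = _parse_msh22(text)
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r} (use 'msh' or 'off')")
    faces = _check_winding(np.asarray(faces, int), repair=repair)
    return SurfaceMesh(np.asarray(verts, float), faces, label=path.stem).oriented_outward()


def _parse_off(text):
    tokens = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(line.split())
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    i = 4
    verts = np.array(tokens[i : i + 3 * nv], float).reshape(nv, 3)
    i += 3 * nv
    faces = []
    for _ in range(nf):
        n = int(tokens[i])
        if n != 3:
            raise ValueError(f"unsupported non-triangular face with {n} vertices")
        faces.append([int(tokens[i + 1]), int(tokens[i + 2]), int(tokens[i + 3])])
        i += 4
    return verts, faces


def _parse_msh22(text):
    lines = iter(text.splitlines())
    verts, faces = {}, []
    for line in lines:
        tag = line.strip()
        if tag == "$MeshFormat":
            ver = next(lines).split()
            if not ver[0].startswith("2.2") or ver[1] != "0":
                raise ValueError(f"unsupported MSH version/mode: {' '.join(ver)}")
            next(lines)  # $EndMeshFormat
        elif tag == "$Nodes":
            n = int(next(lines))
            for _ in range(n):
                parts = next(lines).split()
                verts[int(parts[0])] = [float(x) for x in parts[1:4]]
            next(lines)
        elif tag == "$Elements":
            n = int(next(lines))
            for _ in range(n):
                parts = [int(x) for x in next(lines).split()]
                etype, ntags = parts[1], parts[2]
                nodes = parts[3 + ntags :]
                if etype == 2:
                    faces.append(nodes)
                elif etype in (1, 15):
                    continue  # points / lines: ignored boundary entities
                else:
                    raise ValueError(f"unsupported element type {etype} (triangles only)")
            next(lines)
    if not verts or not faces:
        raise ValueError("no triangle mesh found in MSH file")
    ids = sorted(verts)
    remap = {vid: i for i, vid in enumerate(ids)}
    v = np.array([verts[i] for i in ids])
    f = np.array([[remap[a] for a in face] for face in faces], int)
    return v, f


def write_mesh(mesh: SurfaceMesh, path, fmt: str | None = None):
    """Write a SurfaceMesh to Gmsh MSH 2.2 ASCII or OFF (full precision)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "off":
        out = ["OFF", f"{len(mesh.vertices)} {len(mesh.faces)} 0"]
        out += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
        out += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    elif fmt == "msh":
        out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(len(mesh.vertices))]
        out += [
            f"{i + 1} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for i, v in enumerate(mesh.vertices)
        ]
        out += ["$EndNodes", "$Elements", str(len(mesh.faces))]
        out += [
            f"{i + 1} 2 2 0 1 {f[0] + 1} {f[1] + 1} {f[2] + 1}" for i, f in enumerate(mesh.faces)
        ]
        out += ["$EndElements"]
    else:
        raise ValueError(f"unsupported mesh format: {fmt!r}")
    path.write_text("\n".join(out) + "\n")
    return path
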