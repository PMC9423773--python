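"""Toy MEG forward model: helmet geometry, volumetric grids and lead fields.

The forward model is a single-sphere conductor (Sarvas analytic field of a
current dipole in a homogeneous conducting sphere).  It stands in for a
subject-specific boundary-element model: the analysis stages only require a
lead field with the right structure (channels x 3 orientation columns per
grid node, gains decaying with depth, planar-gradiometer pairing), not an
anatomically accurate one.

Geometry conventions
--------------------
Head frame in millimetres, origin at the sphere centre.  The sensor helmet is
a spherical cap of 102 sites; each site carries two planar gradiometers
(orthogonal tangential derivative of the radial field, fT/cm) and one
magnetometer (radial field, fT), mirroring a 306-channel whole-scalp array.
Lead-field gains are for a unit 1 nAm dipole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU0_OVER_4PI = 1e-7  # T*m/A

GRAD = "gradiometer"
MAG = "magnetometer"


class ForwardError(ValueError):
    """Raised for invalid forward-model geometry (e.g. node outside sphere)."""


@dataclass(frozen=True)
class SensorArray:
    """MEG channel geometry and metadata.

    ``pos`` (C, 3) integration point of each channel in metres; ``normal``
    (C, 3) radial unit vector at the site; ``grad_direction`` (C, 3) the
    tangential derivative direction (zero rows for magnetometers);
    ``kind`` per-channel {gradiometer, magnetometer}; ``pair_index`` the
    planar partner channel (-1 for magnetometers).
    """

    pos: np.ndarray
    normal: np.ndarray
    grad_direction: np.ndarray
    kind: tuple
    pair_index: np.ndarray
    names: tuple
    baseline_m: float = 0.0168

    @property
    def n_channels(self) -> int:
        return self.pos.shape[0]

    @property
    def units(self) -> tuple:
        return tuple("fT/cm" if k == GRAD else "fT" for k in self.kind)

    def channel_set(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kind) if k == kind], dtype=int)


def _fibonacci_cap(n: int, radius: float, z_min_frac: float = 0.05) -> np.ndarray:
    """Quasi-uniform points on the upper spherical cap z >= z_min_frac*radius."""
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n)
    # map to z in (z_min, radius), spiral in azimuth
    z = radius * (z_min_frac + (1 - z_min_frac) * (i + 0.5) / n)
    r_xy = np.sqrt(np.maximum(radius ** 2 - z ** 2, 0.0))
    phi = 2 * np.pi * i / golden
    return np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])


def default_sensor_array(n_sites: int = 102, radius: float = 0.102,
                         baseline_m: float = 0.0168) -> SensorArray:
    """Build a helmet of ``n_sites`` sites: 2 planar gradiometers + 1 magnetometer each.

    The default 102 sites give the conventional 204 + 102 channel layout.
    Channels are ordered per site as (grad-a, grad-b, mag), the two
    gradiometers of a site forming a planar pair with orthogonal derivative
    directions.
    """
    sites = _fibonacci_cap(n_sites, radius)
    pos, normal, gdir, kind, pair, names = [], [], [], [], [], []
    for s, p in enumerate(sites):
        n = p / np.linalg.norm(p)
        # tangential basis at the site
        ref = np.array([0.0, 0.0, 1.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(n, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        base = 3 * s
        for j, d in enumerate((e1, e2)):
            pos.append(p)
            normal.append(n)
            gdir.append(d)
            kind.append(GRAD)
            pair.append(base + (1 - j))
            names.append(f"MEG{s:03d}{'AB'[j]}")
        pos.append(p)
        normal.append(n)
        gdir.append(np.zeros(3))
        kind.append(MAG)
        pair.append(-1)
        names.append(f"MEG{s:03d}M")
    return SensorArray(np.asarray(pos), np.asarray(normal), np.asarray(gdir),
                       tuple(kind), np.asarray(pair, dtype=int), tuple(names),
                       baseline_m)


@dataclass(frozen=True)
class SourceGrid:
    """Volumetric source grid: ``nodes`` (N, 3) in mm, regular ``spacing`` in mm."""

    nodes: np.ndarray
    spacing: float

    def __post_init__(self):
        if self.spacing <= 0:
            raise ForwardError("grid spacing must be positive")
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise ForwardError("nodes must be (N, 3)")
        if len(np.unique(np.round(nodes, 6), axis=0)) != len(nodes):
            raise ForwardError("grid nodes must be unique")
        object.__setattr__(self, "nodes", nodes)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def nearest_node(self, xyz_mm) -> int:
        d = np.linalg.norm(self.nodes - np.asarray(xyz_mm, float), axis=1)
        return int(np.argmin(d))


def cubic_grid(center_mm=(-42.0, -24.0, 56.0), half_extent_mm: float = 9.0,
               spacing_mm: float = 3.0, head_radius_mm: float = 90.0) -> SourceGrid:
    """Regular cubic grid around ``center_mm``, clipped to the head sphere."""
    ax = np.arange(-half_extent_mm, half_extent_mm + 1e-9, spacing_mm)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) + np.asarray(center_mm)
    inside = np.linalg.norm(nodes, axis=1) < head_radius_mm
    return SourceGrid(nodes[inside], spacing_mm)


def dipole_field(r0: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of a dipole ``q`` (A*m) at ``r0`` in a conducting sphere.

    Sarvas closed-form solution, sphere centred at the origin; ``r`` (M, 3)
    field points in metres outside the conductor.  Radial dipoles (and any
    dipole at the centre) produce zero external field.
    """
    r = np.atleast_2d(r).astype(float)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ForwardError("field point coincides with the dipole")
    adotr = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn ** 2 - r @ r0)
    gradF = ((a ** 2 / rn + adotr / a + 2 * a + 2 * rn)[:, None] * r
             - (a + 2 * rn + adotr / a)[:, None] * r0)
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0 - ((r @ qxr0)[:, None]) * gradF)
    return B


@dataclass(frozen=True)
class LeadField:
    """Per-node sensor gains.

    ``full`` (N, C, 3): gain of a unit 1 nAm dipole along x/y/z at each node,
    in channel units (fT/cm for gradiometers, fT for magnetometers).
    ``reduced`` (N, C, 2) and ``singular_values`` (N, 3) are filled by the
    source stage's rank reduction.
    """

    full: np.ndarray
    grid: SourceGrid
    array: SensorArray
    reduced: np.ndarray | None = None
    singular_values: np.ndarray | None = None


def make_toy_leadfield(grid: SourceGrid, array: SensorArray,
                       head_radius_mm: float = 90.0) -> LeadField:
    """Single-sphere analytic lead field for every grid node.

    Gradiometer gains are the tangential finite-difference of the radial
    field over the planar baseline (fT/cm); magnetometer gains are the radial
    field (fT).  Coincident nodes get identical gain blocks (the model is a
    pure function of geometry).
    """
    min_sensor_r = float(np.min(np.linalg.norm(array.pos, axis=1)))
    limit_mm = min(head_radius_mm, 1000.0 * min_sensor_r)
    radii = np.linalg.norm(grid.nodes, axis=1)
    bad = np.nonzero(radii >= limit_mm)[0]
    if bad.size:
        raise ForwardError(
            f"grid node(s) {bad.tolist()} at radius >= {limit_mm:.1f} mm lie "
            "outside the sensor-enclosing sphere")

    is_grad = np.array([k == GRAD for k in array.kind])
    half = 0.5 * array.baseline_m
    # integration points: mag -> site; grad -> two points along the derivative axis
    p_plus = array.pos + half * array.grad_direction
    p_minus = array.pos - half * array.grad_direction

    full = np.empty((grid.n_nodes, array.n_channels, 3))
    eye = np.eye(3) * 1e-9  # unit dipole of 1 nAm in A*m
    for i, node_mm in enumerate(grid.nodes):
        r0 = node_mm / 1000.0
        for c in range(3):
            q = eye[c]
            b_site = dipole_field(r0, q, array.pos)
            radial = np.einsum("ij,ij->i", b_site, array.normal)
            gains = radial * 1e15  # fT
            if np.any(is_grad):
                bp = dipole_field(r0, q, p_plus[is_grad])
                bm = dipole_field(r0, q, p_minus[is_grad])
                dn = np.einsum("ij,ij->i", bp - bm, array.normal[is_grad])
                gains = gains.copy()
                gains[is_grad] = dn / (array.baseline_m * 100.0) * 1e15  # fT/cm
            full[i, :, c] = gains
    return LeadField(full=full, grid=grid, array=array)
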