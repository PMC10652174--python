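"""Quasi-static linear-elastic FE solve and mechanoregulation stimulus.

Each coupling step the callus, marrow and cortex are represented by one
effective isotropic material per voxel element (rule of mixtures over the
tissue fractions), the plate/screw load and the axial compression + bending
moment of the day are applied to the proximal face, the distal face is fully
fixed, and the small-strain equilibrium is solved with a vectorized trilinear
hexahedral assembler on scipy.sparse.

Strain output per element: principal strains, the minimum principal
(compressive) strain used for the reported region averages, and the
octahedral shear strain used as the scalar mechanoregulation stimulus.
Poroelastic constants (permeability, grain/fluid bulk moduli) are carried as
data for a biphasic stimulus extension but do not enter the default solver,
whose decision variable is a daily strain-derived stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry as geo

__all__ = [
    "MaterialProperties",
    "TISSUE_PROPERTIES",
    "cortical_modulus",
    "LoadSchedule",
    "LOAD_SCHEDULES",
    "load_at_time",
    "StrainField",
    "solve_mechanics",
    "compute_stimulus",
    "region_average_strain",
]

# Minimum effective stiffness (MPa) for nearly-empty boundary voxels.
E_FLOOR = 0.02


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic tissue properties: E (MPa), Poisson ratio, permeability
    (m^4/N s), grain and fluid bulk moduli (MPa)."""

    young_modulus: float
    poisson_ratio: float
    permeability: float
    bulk_modulus_grain: float
    bulk_modulus_fluid: float

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("E must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")


#: The seven tissue presets (permeability column is in m^4/N s).
TISSUE_PROPERTIES: dict[str, MaterialProperties] = {
    "granulation": MaterialProperties(0.2, 0.167, 1e-14, 2300.0, 2300.0),
    "fibrous": MaterialProperties(2.0, 0.167, 1e-14, 2300.0, 2300.0),
    "cartilage": MaterialProperties(10.0, 0.3, 0.5e-14, 3700.0, 2300.0),
    "immature_bone": MaterialProperties(1000.0, 0.3, 10e-14, 13940.0, 2300.0),
    "mature_bone": MaterialProperties(5000.0, 0.3, 37e-14, 13940.0, 2300.0),
    "cortical_healthy": MaterialProperties(8660.0, 0.3, 0.001e-14, 13920.0, 3200.0),
    "cortical_t2dm": MaterialProperties(6610.0, 0.3, 0.001e-14, 13920.0, 3200.0),
    "marrow": MaterialProperties(2.0, 0.167, 1e-14, 2300.0, 2300.0),
}

#: Fixation hardware (titanium).
TITANIUM = MaterialProperties(110_000.0, 0.3, 1e-20, 1e9, 1e9)

#: Effective modulus of the homogenized screw columns connecting plate and
#: cortex.  Much lower than titanium because the column lumps the bending and
#: shear compliance of slender screw shafts into a solid block; it sets the
#: translational (axial-closure) compliance of the fixation construct.
SCREW_MODULUS = 2_500.0


def cortical_modulus(group: str) -> float:
    return TISSUE_PROPERTIES[f"cortical_{group}"].young_modulus


# ---------------------------------------------------------------------------
# Load schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadSchedule:
    """Axial compression (N) and bending moment (N mm) endpoints over healing.

    Loads grow with the animal's body weight; only the initial and final
    values are specified and the schedule interpolates linearly in time.
    """

    group: str
    compression: tuple[float, float]
    bending_moment: tuple[float, float]

    def __post_init__(self) -> None:
        if self.compression[1] < self.compression[0] \
                or self.bending_moment[1] < self.bending_moment[0]:
            raise ValueError("loads must be non-decreasing over healing")


LOAD_SCHEDULES: dict[str, LoadSchedule] = {
    "healthy": LoadSchedule("healthy", (17.42, 24.07), (31.07, 42.93)),
    "t2dm": LoadSchedule("t2dm", (21.60, 24.89), (38.52, 44.40)),
}


def load_at_time(schedule: LoadSchedule, t: float,
                 t_end: float = 84.0) -> tuple[float, float]:
    """Compression (N) and bending moment (N mm) on day ``t`` of ``t_end``."""
    if not 0.0 <= t <= t_end:
        raise ValueError(f"t={t} outside [0, {t_end}]")
    w = t / t_end if t_end > 0 else 0.0
    c0, c1 = schedule.compression
    m0, m1 = schedule.bending_moment
    return c0 + w * (c1 - c0), m0 + w * (m1 - m0)


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------

def _box_matrices(dx: float, dy: float, dz: float):
    """Volumetric (lambda) and deviatoric (2 mu) stiffness integrals plus the
    center strain-displacement matrix for a dx x dy x dz trilinear hexahedron."""
    # local nodes in unit coordinates, matching the mesh connectivity order
    loc = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                    (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)], dtype=float)
    g = 0.5 + np.array([-1, 1]) / (2 * np.sqrt(3.0))
    vol = dx * dy * dz
    J = np.outer([1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]).astype(float)
    I6 = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])

    def bmat(xi, eta, zeta):
        B = np.zeros((6, 24))
        for a in range(8):
            lx, ly, lz = loc[a]
            sx = (lx * xi + (1 - lx) * (1 - xi))
            sy = (ly * eta + (1 - ly) * (1 - eta))
            sz = (lz * zeta + (1 - lz) * (1 - zeta))
            dNx = (2 * lx - 1) * sy * sz / dx
            dNy = (2 * ly - 1) * sx * sz / dy
            dNz = (2 * lz - 1) * sx * sy / dz
            c = 3 * a
            B[0, c] = dNx
            B[1, c + 1] = dNy
            B[2, c + 2] = dNz
            B[3, c] = dNy
            B[3, c + 1] = dNx
            B[4, c + 1] = dNz
            B[4, c + 2] = dNy
            B[5, c] = dNz
            B[5, c + 2] = dNx
        return B

    K1 = np.zeros((24, 24))
    K2 = np.zeros((24, 24))
    for xi in g:
        for eta in g:
            for zeta in g:
                B = bmat(xi, eta, zeta)
                K1 += B.T @ J @ B * (vol / 8.0)
                K2 += B.T @ I6 @ B * (vol / 8.0)
    return K1, K2, bmat(0.5, 0.5, 0.5)


def _fe_setup(mesh: geo.Mesh) -> dict:
    """Mesh-dependent FE data, cached on the mesh."""
    if "fe" in mesh._cache:
        return mesh._cache["fe"]
    dx = float(mesh.xs[1] - mesh.xs[0])
    dy = float(mesh.ys[1] - mesh.ys[0])
    dz_all = mesh.element_dz()
    classes, class_id = np.unique(np.round(dz_all, 9), return_inverse=True)
    K1s, K2s, Bcs = [], [], []
    for dz in classes:
        K1, K2, Bc = _box_matrices(dx, dy, float(dz))
        K1s.append(K1)
        K2s.append(K2)
        Bcs.append(Bc)
    edof = (3 * mesh.conn[:, :, None] + np.arange(3)[None, None, :])
    edof = edof.reshape(mesh.n_elements, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()

    ndof = 3 * mesh.n_nodes
    fixed_nodes = np.isclose(mesh.nodes[:, 2], mesh.zs[0])
    free = np.ones(ndof, dtype=bool)
    free[np.repeat(np.nonzero(fixed_nodes)[0] * 3, 3)
         + np.tile([0, 1, 2], int(fixed_nodes.sum()))] = False

    # Proximal-face load distribution: tributary areas of top-surface nodes.
    top_layer = len(mesh.zs) - 2
    sel = mesh.grid_index[:, 2] == top_layer
    area = np.zeros(mesh.n_nodes)
    a_elem = mesh.solid_fraction[sel] * dx * dy / 4.0
    for corner in range(4, 8):
        np.add.at(area, mesh.conn[sel, corner], a_elem)
    top = area > 0
    xbar = float(np.sum(mesh.nodes[top, 0] * area[top]) / area[top].sum())
    iw = float(np.sum(area[top] * (mesh.nodes[top, 0] - xbar) ** 2))

    fe = dict(class_id=class_id, K1=np.array(K1s), K2=np.array(K2s),
              Bc=np.array(Bcs), edof=edof, rows=rows, cols=cols,
              ndof=ndof, free=free, area=area, top=top, xbar=xbar, iw=iw)
    mesh._cache["fe"] = fe
    return fe


@dataclass
class StrainField:
    """Per-element strain state of one solve."""

    principal: np.ndarray          # (ne, 3), ascending
    octahedral_shear: np.ndarray   # (ne,)

    @property
    def min_principal(self) -> np.ndarray:
        """Minimum principal (most compressive) strain per element."""
        return self.principal[:, 0]


def solve_mechanics(mesh: geo.Mesh, young: np.ndarray, poisson: np.ndarray,
                    compression: float, moment: float) -> StrainField:
    """Solve equilibrium and return per-element strains.

    ``young``/``poisson`` are per-element effective properties (MPa, -);
    ``compression`` (N) acts axially on the proximal face together with a
    bending ``moment`` (N mm) about the y axis.  A positive moment adds
    compression on the lateral (plate, +x) side, counteracting the rotation
    induced by the plate-offset eccentricity of the axial load; the net
    intercortical bending still compresses the medial side more.  The distal
    face is fixed in all directions.
    """
    fe = _fe_setup(mesh)
    young = np.maximum(np.asarray(young, dtype=float), E_FLOOR)
    poisson = np.clip(np.asarray(poisson, dtype=float), 0.0, 0.499)
    if young.shape != (mesh.n_elements,):
        raise ValueError("one Young's modulus per element required")
    lam = young * poisson / ((1 + poisson) * (1 - 2 * poisson))
    mu = young / (2 * (1 + poisson))
    data = (lam[:, None, None] * fe["K1"][fe["class_id"]]
            + 2.0 * mu[:, None, None] * fe["K2"][fe["class_id"]])
    K = sp.coo_matrix((data.ravel(), (fe["rows"], fe["cols"])),
                      shape=(fe["ndof"], fe["ndof"])).tocsr()
    f = np.zeros(fe["ndof"])
    top, area = fe["top"], fe["area"]
    fz = (-compression * area[top] / area[top].sum()
          - moment * (mesh.nodes[top, 0] - fe["xbar"]) * area[top] / fe["iw"])
    f[np.nonzero(top)[0] * 3 + 2] = fz

    free = fe["free"]
    u = np.zeros(fe["ndof"])
    u[free] = spla.spsolve(K[free][:, free].tocsc(), f[free])
    if not np.all(np.isfinite(u)):
        raise RuntimeError("singular mechanical system (unconstrained mesh?)")

    ue = u[fe["edof"]]
    eps = np.einsum("eij,ej->ei", fe["Bc"][fe["class_id"]], ue)
    T = np.empty((mesh.n_elements, 3, 3))
    T[:, 0, 0] = eps[:, 0]
    T[:, 1, 1] = eps[:, 1]
    T[:, 2, 2] = eps[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = eps[:, 3] / 2.0
    T[:, 1, 2] = T[:, 2, 1] = eps[:, 4] / 2.0
    T[:, 0, 2] = T[:, 2, 0] = eps[:, 5] / 2.0
    principal = np.linalg.eigvalsh(T)
    d01 = principal[:, 0] - principal[:, 1]
    d12 = principal[:, 1] - principal[:, 2]
    d02 = principal[:, 0] - principal[:, 2]
    gamma = (2.0 / 3.0) * np.sqrt(d01 ** 2 + d12 ** 2 + d02 ** 2)
    return StrainField(principal=principal, octahedral_shear=gamma)


def compute_stimulus(field: StrainField, lattice: geo.Lattice) -> np.ndarray:
    """Map the element stimulus (octahedral shear strain) onto lattice sites.

    Returns a flat array over the padded site grid; sites outside the healing
    domain get zero.
    """
    se = lattice.site_element
    out = np.zeros(se.shape)
    inside = se >= 0
    out[inside] = field.octahedral_shear[se[inside]]
    return out


def region_average_strain(field: StrainField, mesh: geo.Mesh,
                          weight: np.ndarray) -> float:
    """Volume-weighted mean magnitude of the minimum principal strain, in %.

    ``weight`` is a per-element region weight (e.g. the intercortical
    footprint fraction, possibly masked to one hemi-callus).
    """
    w = np.asarray(weight, dtype=float) * mesh.volumes
    total = w.sum()
    if total <= 0:
        raise ValueError("empty region")
    return float(np.sum(w * np.abs(field.min_principal)) / total * 100.0)
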