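"""Parametric osteotomized-femur geometry, voxel FE mesh, cell lattice, regions.

The femur is idealized as a hollow cortical cylinder (30 mm tall) filled with
marrow, with a 3-mm transverse defect at mid-height, a surrounding callus
domain, and a lateral fixation plate bonded to the bone through four screw
patches.  The mesh is a tensor-product voxel grid (trilinear hexahedra) whose
z-planes are aligned with every axial feature boundary (gap, callus extent,
plate span, screw edges); in-plane curved boundaries (cortex annulus, callus
profile, plate footprint) enter each element as sub-sampled material area
fractions, which the rule-of-mixtures material model consumes directly.

Femur radii are not part of the published parameter set; the module ships a
documented fixture with nominal rat-femur dimensions (periosteal diameter of
the 4-mm class) and a thinner diabetic cortex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FemurGeometry",
    "FIXTURE_DIMENSIONS",
    "build_geometry",
    "Mesh",
    "generate_mesh",
    "Lattice",
    "build_lattice",
    "plate_zone_mask",
    "seed_initial_cells",
    "MATERIALS",
]

# Material / region codes used by the classifier.
AIR, CORTEX, MARROW, HEALING, PLATE, SCREW, SOFT = range(7)
MATERIALS = ("air", "cortex", "marrow", "healing", "plate", "screw", "soft")

#: Nominal rat-femur fixture dimensions (mm).  The diabetic femur has a
#: thinner cortex at the same periosteal envelope.  These are fixture values,
#: not published constants; everything downstream reads them from here.
FIXTURE_DIMENSIONS = {
    "healthy": {"periosteal_radius": 2.0, "endosteal_radius": 1.30},
    "t2dm": {"periosteal_radius": 2.0, "endosteal_radius": 1.315},
}


@dataclass(frozen=True)
class FemurGeometry:
    """All geometric constants of one model, in mm.

    z runs axially over [0, model_height]; the defect is centered at
    mid-height.  The plate lies on the lateral side (+x), separated from the
    periosteal surface by a soft-tissue interposition layer except at the four
    screw patches, which bond it rigidly to the cortex.
    """

    group: str
    periosteal_radius: float
    endosteal_radius: float
    gap_height: float = 3.0
    model_height: float = 30.0
    callus_outer_radius: float = 3.2
    callus_half_height: float = 4.6
    plate_standoff: float = 0.2
    plate_thickness: float = 1.6
    plate_width: float = 2.0
    plate_z: tuple[float, float] = (10.0, 20.0)
    screw_z: tuple[tuple[float, float], ...] = (
        (10.3, 11.1), (12.7, 13.5), (16.5, 17.3), (18.9, 19.7))
    screw_half_width: float = 1.0
    include_plate: bool = True

    def __post_init__(self) -> None:
        if self.endosteal_radius >= self.periosteal_radius:
            raise ValueError("endosteal radius must be smaller than periosteal")
        if self.gap_height <= 0 or self.model_height <= self.gap_height:
            raise ValueError("invalid gap/model heights")

    @property
    def cortical_thickness(self) -> float:
        return self.periosteal_radius - self.endosteal_radius

    @property
    def mid_height(self) -> float:
        return self.model_height / 2.0

    @property
    def gap_z(self) -> tuple[float, float]:
        return (self.mid_height - self.gap_height / 2.0,
                self.mid_height + self.gap_height / 2.0)

    @property
    def callus_z(self) -> tuple[float, float]:
        return (self.mid_height - self.callus_half_height,
                self.mid_height + self.callus_half_height)

    @property
    def plate_inner_x(self) -> float:
        return self.periosteal_radius + self.plate_standoff

    @property
    def plate_outer_x(self) -> float:
        return self.plate_inner_x + self.plate_thickness

    def callus_profile(self, z: np.ndarray) -> np.ndarray:
        """Outer radius of the callus bulge vs axial position (elliptic arc)."""
        zc = np.asarray(z, dtype=float) - self.mid_height
        t = 1.0 - (zc / self.callus_half_height) ** 2
        bulge = np.sqrt(np.clip(t, 0.0, None))
        return self.periosteal_radius + (self.callus_outer_radius
                                         - self.periosteal_radius) * bulge


def build_geometry(group: str, fixture: Optional[dict] = None,
                   **overrides) -> FemurGeometry:
    """Build the geometry for one animal group from the dimension fixture."""
    if group not in FIXTURE_DIMENSIONS:
        raise ValueError(f"group must be one of {sorted(FIXTURE_DIMENSIONS)}")
    dims = dict(FIXTURE_DIMENSIONS[group])
    if fixture:
        dims.update(fixture)
    return FemurGeometry(group=group, **dims, **overrides)


# ---------------------------------------------------------------------------
# Point classifier
# ---------------------------------------------------------------------------

def classify_points(geom: FemurGeometry, x: np.ndarray, y: np.ndarray,
                    z: float) -> np.ndarray:
    """Material code at points (x, y) in the cross-section at height z.

    Priority: plate and screws (metal) > cortex > medullary content >
    gap/callus healing tissue > soft interposition layer under the plate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, AIR, dtype=np.int8)
    r = np.hypot(x, y)
    gap_lo, gap_hi = geom.gap_z
    cal_lo, cal_hi = geom.callus_z
    in_gap = gap_lo <= z < gap_hi
    in_callus = cal_lo <= z < cal_hi
    Ps, Es = geom.periosteal_radius, geom.endosteal_radius

    # Medullary content: marrow along intact shaft, healing tissue near defect.
    inner = r < Es
    out[inner] = HEALING if in_callus else MARROW
    # Cortex (interrupted by the gap).
    ring = (r >= Es) & (r < Ps)
    out[ring] = HEALING if in_gap else CORTEX
    # Periosteal callus bulge.
    if in_callus:
        rc = float(geom.callus_profile(z))
        out[(r >= Ps) & (r < rc) & (out == AIR)] = HEALING

    if geom.include_plate:
        pl_lo, pl_hi = geom.plate_z
        in_plate_z = pl_lo <= z < pl_hi
        half_w = geom.plate_width / 2.0
        foot = np.abs(y) <= half_w
        if in_plate_z:
            slab = foot & (x >= geom.plate_inner_x) & (x < geom.plate_outer_x)
            out[slab] = PLATE
            # Interposition wedge between the curved periosteum and the plate.
            under = foot & (x > 0) & (x < geom.plate_inner_x) & (r >= Ps)
            gap_code = HEALING if in_callus else SOFT
            out[under & (out == AIR)] = gap_code
            in_screw = any(lo <= z < hi for lo, hi in geom.screw_z)
            if in_screw:
                col = (np.abs(y) <= geom.screw_half_width) & (x > 0) \
                    & (x < geom.plate_inner_x) & (r >= Ps)
                out[col] = SCREW
        # Keep the callus from swallowing the plate slab.
        out[(out == HEALING) & (x >= geom.plate_inner_x) & foot] = \
            SOFT if not in_plate_z else AIR
    return out


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Voxel hexahedral mesh with per-element material area fractions.

    Elements are axis-aligned boxes dx x dy x dz(layer).  ``fractions`` holds
    the sub-sampled area fraction of each material per element (rows sum to 1);
    ``healing_fraction`` is the slice of that budget that evolves during the
    simulation.  ``grid_index`` keeps the structured (i, j, layer) address of
    every element so neighborhood queries (bridging) stay trivial.
    """

    geom: FemurGeometry
    scale: float
    xs: np.ndarray           # node x planes, (nx+1,)
    ys: np.ndarray           # node y planes, (ny+1,)
    zs: np.ndarray           # node z planes, (nlayers+1,)
    grid_index: np.ndarray   # (ne, 3) int: i, j, layer
    conn: np.ndarray         # (ne, 8) compact node ids
    nodes: np.ndarray        # (nn, 3) coordinates
    fractions: np.ndarray    # (ne, 7) material area fractions
    volumes: np.ndarray      # (ne,)
    centers: np.ndarray      # (ne, 3)
    # region data
    footprint_weight: np.ndarray   # (ne,) intercortical-annulus area fraction in gap
    lateral: np.ndarray            # (ne,) bool, element center on plate side
    cortex_prox: np.ndarray        # (ne,) bool, cortex layer just above the gap
    cortex_dist: np.ndarray        # (ne,) bool, cortex layer just below the gap
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_elements(self) -> int:
        return len(self.conn)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def healing_fraction(self) -> np.ndarray:
        return self.fractions[:, HEALING]

    @property
    def solid_fraction(self) -> np.ndarray:
        return 1.0 - self.fractions[:, AIR]

    def element_dz(self) -> np.ndarray:
        dz = np.diff(self.zs)
        return dz[self.grid_index[:, 2]]

    def region_volume(self, material: int) -> float:
        return float(np.sum(self.fractions[:, material] * self.volumes))

    def element_of_point(self, x: float, y: float, z: float) -> int:
        """Compact element id containing a point (-1 if outside the mesh)."""
        i = int(np.searchsorted(self.xs, x, side="right")) - 1
        j = int(np.searchsorted(self.ys, y, side="right")) - 1
        k = int(np.searchsorted(self.zs, z, side="right")) - 1
        lut = self._elem_lookup()
        if not (0 <= i < lut.shape[0] and 0 <= j < lut.shape[1]
                and 0 <= k < lut.shape[2]):
            return -1
        return int(lut[i, j, k])

    def _elem_lookup(self) -> np.ndarray:
        if "lookup" not in self._cache:
            shape = (len(self.xs) - 1, len(self.ys) - 1, len(self.zs) - 1)
            lut = np.full(shape, -1, dtype=np.int64)
            gi = self.grid_index
            lut[gi[:, 0], gi[:, 1], gi[:, 2]] = np.arange(self.n_elements)
            self._cache["lookup"] = lut
        return self._cache["lookup"]


def _z_planes(geom: FemurGeometry, scale: float) -> np.ndarray:
    """Axial node planes: feature breakpoints subdivided to the target sizes."""
    fine = 0.2 * scale
    coarse = 0.5 * scale
    breaks = {0.0, geom.model_height, *geom.gap_z, *geom.callus_z}
    if geom.include_plate:
        breaks.update(geom.plate_z)
        for lo, hi in geom.screw_z:
            breaks.update((lo, hi))
    breaks = sorted(b for b in breaks if 0.0 <= b <= geom.model_height)
    fine_lo = geom.plate_z[0] if geom.include_plate else geom.callus_z[0]
    fine_hi = geom.plate_z[1] if geom.include_plate else geom.callus_z[1]
    planes = [0.0]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        target = fine if (lo >= fine_lo - 1e-9 and hi <= fine_hi + 1e-9) else coarse
        n = max(1, round((hi - lo) / target))
        planes.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(planes)


def generate_mesh(geom: FemurGeometry, scale: float = 1.0,
                  subsample: int = 8) -> Mesh:
    """Voxelize the geometry into a hexahedral mesh.

    ``scale`` multiplies the target edge lengths (0.2 mm in the callus/plate
    span, 0.5 mm elsewhere); ``scale > 1`` coarsens for desk-scale runs.
    ``subsample`` controls the in-plane points per element edge used to
    measure material area fractions.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    half = max(geom.callus_outer_radius,
               geom.plate_outer_x if geom.include_plate else 0.0)
    half = math.ceil(half / 0.4) * 0.4  # keep radii aligned across scales
    a_target = 0.2 * scale
    n_xy = max(4, round(2 * half / a_target))
    xs = np.linspace(-half, half, n_xy + 1)
    ys = xs.copy()
    zs = _z_planes(geom, scale)
    a = xs[1] - xs[0]
    if a >= geom.callus_outer_radius:
        raise ValueError("mesh scale too coarse for the callus")

    nlayers = len(zs) - 1
    s = subsample
    # In-plane subsample points, shared by all layers.
    sub = (np.arange(s) + 0.5) / s
    px = (xs[:-1, None] + sub[None, :] * a).ravel()   # (n_xy*s,)
    PX, PY = np.meshgrid(px, px, indexing="ij")

    frac_layers = []
    for k in range(nlayers):
        zm = 0.5 * (zs[k] + zs[k + 1])
        codes = classify_points(geom, PX, PY, zm)     # (n_xy*s, n_xy*s)
        c = codes.reshape(n_xy, s, n_xy, s)
        counts = np.zeros((n_xy, n_xy, 7), dtype=np.int32)
        for m in range(7):
            counts[:, :, m] = (c == m).sum(axis=(1, 3))
        frac_layers.append(counts / float(s * s))
    frac_grid = np.stack(frac_layers, axis=2)         # (n_xy, n_xy, nl, 7)

    solid = 1.0 - frac_grid[..., AIR]
    keep = solid >= 0.05
    ii, jj, kk = np.nonzero(keep)
    order = np.lexsort((ii, jj, kk))                  # z-major for locality
    ii, jj, kk = ii[order], jj[order], kk[order]
    grid_index = np.stack([ii, jj, kk], axis=1)
    fractions = frac_grid[ii, jj, kk]

    dz = np.diff(zs)
    volumes = a * a * dz[kk]
    centers = np.stack([
        xs[ii] + a / 2.0, ys[jj] + a / 2.0, 0.5 * (zs[kk] + zs[kk + 1])
    ], axis=1)

    # Compact node numbering over used grid nodes.
    nxn, nyn = n_xy + 1, n_xy + 1
    nzn = nlayers + 1

    def nid(i, j, k):
        return (i * nyn + j) * nzn + k

    corners = []
    for di, dj, dk in ((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                       (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)):
        corners.append(nid(ii + di, jj + dj, kk + dk))
    conn_raw = np.stack(corners, axis=1)
    used, conn = np.unique(conn_raw, return_inverse=True)
    conn = conn.reshape(conn_raw.shape).astype(np.int64)
    gi = used // (nyn * nzn)
    gj = (used // nzn) % nyn
    gk = used % nzn
    nodes = np.stack([xs[gi], ys[gj], zs[gk]], axis=1)

    # Region data ----------------------------------------------------------
    gap_lo, gap_hi = geom.gap_z
    zmid = centers[:, 2]
    in_gap = (zmid > gap_lo) & (zmid < gap_hi)
    # Intercortical footprint: annulus between Es and Ps, inside the gap.
    Ps, Es = geom.periosteal_radius, geom.endosteal_radius
    PR = np.hypot(PX, PY)
    ann = ((PR >= Es) & (PR < Ps)).reshape(n_xy, s, n_xy, s).sum(axis=(1, 3)) \
        / float(s * s)
    footprint_weight = np.where(in_gap, ann[ii, jj], 0.0)
    lateral = centers[:, 0] > 0.0

    cortex_frac = fractions[:, CORTEX]
    layer_above = int(np.searchsorted(zs, gap_hi + 1e-9, side="right")) - 1
    layer_below = int(np.searchsorted(zs, gap_lo - 1e-9, side="right")) - 1
    cortex_prox = (kk == layer_above) & (cortex_frac >= 0.3)
    cortex_dist = (kk == layer_below) & (cortex_frac >= 0.3)

    return Mesh(geom=geom, scale=scale, xs=xs, ys=ys, zs=zs,
                grid_index=grid_index, conn=conn, nodes=nodes,
                fractions=fractions, volumes=volumes, centers=centers,
                footprint_weight=footprint_weight, lateral=lateral,
                cortex_prox=cortex_prox, cortex_dist=cortex_dist)


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

# Phenotype codes on the lattice.
EMPTY, MSC, FIBROBLAST, CHONDROCYTE, OB_IMMATURE, OB_MATURE = range(6)
OUTSIDE = -1


@dataclass
class Lattice:
    """Regular cell grid over the healing (callus + gap) domain.

    Sites live on a padded 3-D grid (one-site border of ``OUTSIDE`` so that
    neighbor indexing never wraps).  ``occupancy`` is the flattened grid;
    ``site_element`` maps every in-domain site to its containing mesh element.
    Site z-coordinates are snapped to the mid-plane of their mesh layer when
    classified, which makes lattice membership and element healing fractions
    mutually consistent by construction.
    """

    geom: FemurGeometry
    spacing_um: float
    origin: np.ndarray          # (3,) coordinate of site (1,1,1) center
    shape: tuple[int, int, int]  # padded grid shape
    occupancy: np.ndarray       # (prod(shape),) int8
    site_element: np.ndarray    # (prod(shape),) int64, -1 outside
    periosteal_band: np.ndarray  # flat bool mask
    marrow_band: np.ndarray      # flat bool mask

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def strides(self) -> tuple[int, int, int]:
        _, ny, nz = self.shape
        return (ny * nz, nz, 1)

    @property
    def in_domain(self) -> np.ndarray:
        return self.site_element >= 0

    @property
    def n_sites(self) -> int:
        return int(np.count_nonzero(self.in_domain))

    def site_coords(self, flat_idx: np.ndarray) -> np.ndarray:
        sx, sy, _ = self.strides
        i = flat_idx // sx
        j = (flat_idx // self.strides[1]) % self.shape[1]
        k = flat_idx % self.shape[2]
        h = self.spacing_mm
        return self.origin[None, :] + (np.stack([i, j, k], axis=1) - 1) * h

    def counts(self) -> dict[str, int]:
        occ = self.occupancy[self.in_domain]
        names = ("msc", "fibroblast", "chondrocyte",
                 "immature_osteoblast", "mature_osteoblast")
        return {n: int(np.count_nonzero(occ == c))
                for n, c in zip(names, range(1, 6))}


def build_lattice(geom: FemurGeometry, mesh: Mesh,
                  spacing_um: float = 10.0) -> Lattice:
    """Discretize the healing domain into a cell lattice."""
    if spacing_um <= 0:
        raise ValueError("spacing must be > 0")
    h = spacing_um / 1000.0
    if h > geom.callus_outer_radius - geom.periosteal_radius:
        raise ValueError("lattice spacing exceeds the callus thickness")

    cal_lo, cal_hi = geom.callus_z
    rmax = geom.callus_outer_radius
    xmax = geom.plate_inner_x if geom.include_plate else rmax
    x0, x1 = -rmax, max(rmax, xmax)
    y0, y1 = -rmax, rmax
    z0, z1 = cal_lo, cal_hi
    nx = int(np.ceil((x1 - x0) / h))
    ny = int(np.ceil((y1 - y0) / h))
    nz = int(np.ceil((z1 - z0) / h))
    shape = (nx + 2, ny + 2, nz + 2)  # one-site pad on every face

    cx = x0 + (np.arange(nx) + 0.5) * h
    cy = y0 + (np.arange(ny) + 0.5) * h
    cz = z0 + (np.arange(nz) + 0.5) * h
    origin = np.array([cx[0], cy[0], cz[0]])

    # Snap each site's z to its mesh layer mid-plane for classification.
    layer = np.clip(np.searchsorted(mesh.zs, cz, side="right") - 1,
                    0, len(mesh.zs) - 2)
    zmid = 0.5 * (mesh.zs[layer] + mesh.zs[layer + 1])

    occupancy = np.full(shape, OUTSIDE, dtype=np.int8)
    site_element = np.full(shape, -1, dtype=np.int64)
    perio = np.zeros(shape, dtype=bool)
    marrow = np.zeros(shape, dtype=bool)

    XX, YY = np.meshgrid(cx, cy, indexing="ij")
    RR = np.hypot(XX, YY)
    lut = mesh._elem_lookup()
    ei = np.clip(np.searchsorted(mesh.xs, cx, side="right") - 1,
                 0, lut.shape[0] - 1)
    ej = np.clip(np.searchsorted(mesh.ys, cy, side="right") - 1,
                 0, lut.shape[1] - 1)
    band = 1.5 * h
    Ps, Es = geom.periosteal_radius, geom.endosteal_radius
    gap_lo, gap_hi = geom.gap_z

    for k in range(nz):
        zm = float(zmid[k])
        codes = classify_points(geom, XX, YY, zm)
        dom = codes == HEALING
        elems = lut[ei[:, None], ej[None, :], layer[k]]
        dom &= elems >= 0
        occupancy[1:-1, 1:-1, k + 1][dom] = EMPTY
        site_element[1:-1, 1:-1, k + 1][dom] = elems[dom]
        out_gap = not (gap_lo <= zm < gap_hi)
        if out_gap:
            perio[1:-1, 1:-1, k + 1] = dom & (RR >= Ps) & (RR < Ps + band)
            endo = dom & (RR < Es) & (RR >= Es - band)
        else:
            endo = np.zeros_like(dom)
        # Axial marrow entry surfaces at the ends of the healing domain.
        if min(cz[k] - cal_lo, cal_hi - cz[k]) <= band:
            endo |= dom & (RR < Es)
        marrow[1:-1, 1:-1, k + 1] = endo

    return Lattice(geom=geom, spacing_um=spacing_um, origin=origin,
                   shape=shape, occupancy=occupancy.ravel(),
                   site_element=site_element.ravel(),
                   periosteal_band=perio.ravel(), marrow_band=marrow.ravel())


def plate_zone_mask(lattice: Lattice, zone_width_um: float = 30.0) -> np.ndarray:
    """Flat mask of in-domain sites within the plate-adjacent guidance zone.

    The zone extends ``zone_width_um`` from the plate-bone contact region (the
    plate's inner face plus the thin interposition layer) into the tissue.  On
    lattices too coarse to resolve tens of micrometers the zone is floored at
    one lattice spacing beyond the contact layer, i.e. the first resolvable
    layer of tissue sites along the plate system.
    """
    geom = lattice.geom
    if not geom.include_plate:
        return np.zeros_like(lattice.in_domain)
    width = geom.plate_standoff + max(zone_width_um / 1000.0, lattice.spacing_mm)
    idx = np.nonzero(lattice.in_domain)[0]
    xyz = lattice.site_coords(idx)
    face = geom.plate_inner_x
    sel = (xyz[:, 0] >= face - width - 1e-9) & (xyz[:, 0] < face) \
        & (np.abs(xyz[:, 1]) <= geom.plate_width / 2.0) \
        & (xyz[:, 2] >= geom.plate_z[0]) & (xyz[:, 2] < geom.plate_z[1])
    mask = np.zeros(lattice.occupancy.shape, dtype=bool)
    mask[idx[sel]] = True
    return mask


def seed_initial_cells(lattice: Lattice, density_periosteum: float,
                       density_marrow: float,
                       rng: np.random.Generator) -> Lattice:
    """Seed MSCs into the periosteal and marrow bands (in place).

    Each band site independently receives an MSC with the band's density, so
    the realized count is binomial around the target fraction.
    """
    for dens in (density_periosteum, density_marrow):
        if not 0.0 <= dens <= 1.0:
            raise ValueError("seeding density must be in [0, 1]")
    occ = lattice.occupancy
    for mask, dens in ((lattice.periosteal_band, density_periosteum),
                       (lattice.marrow_band, density_marrow)):
        sites = np.nonzero(mask & (occ == EMPTY))[0]
        take = rng.random(len(sites)) < dens
        occ[sites[take]] = MSC
    return lattice
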