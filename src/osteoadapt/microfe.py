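"""Voxel-based micro finite element analysis of cortical bone.

Every bone voxel of a segmented micro-CT volume becomes one 8-node linear
hexahedral (brick) element with edge length equal to the voxel spacing.
Tissue is modeled as homogeneous isotropic linear elastic (default
E = 14.8 GPa, nu = 0.3).  The default boundary conditions reproduce an axial
compression configuration of a long-bone diaphysis:

* all nodes of the most proximal slice are fully constrained;
* all nodes on the most distal bone surface are kinematically coupled to a
  single reference whose rotation is suppressed, i.e. they share one common
  translation vector (implemented by eliminating the coupled degrees of
  freedom onto three master translations — no penalty terms);
* the total load is applied to the master translation.  The line of action
  passes through the distal-slice centroid by virtue of the rigid coupling.

Axis/sign conventions follow :mod:`osteoadapt.image`: slice 0 is distal, the
z index grows toward the proximal end.  The superior–inferior (axial,
compressive) force is applied at the distal coupling pointing toward the
constrained proximal end (+z in index space); strain energy density is
quadratic in the displacements, so this sign convention does not affect any
downstream quantity.

Loads
-----
Three load cases are supported: ``physio`` — the peak physiological walking
load scaled by body weight, 0.01355*BW N/g axially (superior–inferior) plus
0.00289*BW N/g in the posterior–anterior direction (the medial–lateral
component is negligible and not modeled); ``axial12N`` — the nominal passive
axial load of a tibial loading experiment (default peak 12 N); ``combined`` —
their superposition.

A separate analytic-test boundary condition (uniform end traction, lateral
expansion free via symmetry planes) is provided solely for closed-form
verification of the element and solver; the coupled configuration above is
the pipeline default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import LinearOperator, cg, spsolve

from .image import GrayImage
from .imageproc import BinaryMask

__all__ = [
    "Material",
    "LoadCase",
    "FEProblem",
    "FESolution",
    "SEDField",
    "load_vector",
    "build_problem",
    "build_uniaxial_test_problem",
    "solve",
    "element_sed",
    "sed_to_equivalent_strain",
]

logger = logging.getLogger(__name__)

_FACE3D = ndimage.generate_binary_structure(3, 1)

#: reduced-system size below which a sparse direct factorization is used
DIRECT_SOLVER_MAX_DOFS = 12_000


@dataclass(frozen=True)
class Material:
    """Homogeneous isotropic linear elastic tissue properties."""

    youngs_modulus: float = 14.8e9  # Pa
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")

    @property
    def elasticity_tensor(self) -> np.ndarray:
        """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx),
        engineering shear strains."""
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        c = np.zeros((6, 6))
        c[:3, :3] = lam
        c[np.arange(3), np.arange(3)] = lam + 2 * mu
        c[np.arange(3, 6), np.arange(3, 6)] = mu
        return c


@dataclass(frozen=True)
class LoadCase:
    """A loading condition for the diaphysis model.

    ``physio`` requires body weight ``bw`` (grams); ``axial12N`` uses
    ``axial_peak`` (N) only; ``combined`` superimposes both.
    """

    kind: Literal["physio", "axial12N", "combined"]
    bw: float | None = None  # grams
    axial_peak: float = 12.0  # N
    si_coeff: float = 0.01355  # N per gram body weight, superior-inferior
    ap_coeff: float = 0.00289  # N per gram body weight, posterior-anterior

    def __post_init__(self) -> None:
        if self.kind not in ("physio", "axial12N", "combined"):
            raise ValueError(f"unknown load kind {self.kind!r}")
        if self.kind in ("physio", "combined"):
            if self.bw is None or not self.bw > 0:
                raise ValueError(f"{self.kind} load requires a positive body weight")
        if self.kind in ("axial12N", "combined") and not self.axial_peak > 0:
            raise ValueError("axial_peak must be positive")


def load_vector(load: LoadCase) -> tuple[float, float, float]:
    """Total force components ``(F_ML, F_AP, F_SI)`` in newtons.

    The physiological case scales with body weight (0.01355 N/g axial,
    0.00289 N/g posterior-anterior); the passive case is a pure axial peak
    load; ``combined`` is their componentwise sum.  The medial-lateral
    component is always zero.
    """
    f_ml = f_ap = f_si = 0.0
    if load.kind in ("physio", "combined"):
        assert load.bw is not None
        f_si += load.si_coeff * load.bw
        f_ap += load.ap_coeff * load.bw
    if load.kind in ("axial12N", "combined"):
        f_si += load.axial_peak
    return (f_ml, f_ap, f_si)


def _hex_stiffness(material: Material, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Stiffness matrix (24x24) and Gauss-point strain matrices (8x6x24) of a
    cube element with edge ``h`` (meters).

    Local node ``a`` corresponds to corner offset ``(dz, dy, dx)`` with
    ``a = 4*dz + 2*dy + dx``; per-node dof order is (ux, uy, uz).
    """
    c = material.elasticity_tensor
    # corner signs in (x, y, z)
    dx = np.array([a & 1 for a in range(8)])
    dy = np.array([(a >> 1) & 1 for a in range(8)])
    dz = np.array([(a >> 2) & 1 for a in range(8)])
    xi_a, eta_a, zeta_a = 2 * dx - 1, 2 * dy - 1, 2 * dz - 1

    g = 1.0 / np.sqrt(3.0)
    ke = np.zeros((24, 24))
    b_all = np.zeros((8, 6, 24))
    det_j = (h / 2.0) ** 3
    gp = 0
    for sz in (-g, g):
        for sy in (-g, g):
            for sx in (-g, g):
                dn_dx = xi_a / 8.0 * (1 + sy * eta_a) * (1 + sz * zeta_a) * (2.0 / h)
                dn_dy = eta_a / 8.0 * (1 + sx * xi_a) * (1 + sz * zeta_a) * (2.0 / h)
                dn_dz = zeta_a / 8.0 * (1 + sx * xi_a) * (1 + sy * eta_a) * (2.0 / h)
                b = np.zeros((6, 24))
                cols = np.arange(8) * 3
                b[0, cols + 0] = dn_dx
                b[1, cols + 1] = dn_dy
                b[2, cols + 2] = dn_dz
                b[3, cols + 0] = dn_dy
                b[3, cols + 1] = dn_dx
                b[4, cols + 1] = dn_dz
                b[4, cols + 2] = dn_dy
                b[5, cols + 0] = dn_dz
                b[5, cols + 2] = dn_dx
                ke += b.T @ c @ b * det_j
                b_all[gp] = b
                gp += 1
    return ke, b_all


@dataclass
class FEProblem:
    """A voxel hexahedral elasticity problem on a bone mask.

    ``elements`` holds the (iz, iy, ix) voxel index of each brick element in
    deterministic lexicographic (z, y, x) order; ``conn`` the 8 compact node
    ids per element; ``node_grid`` the (iz, iy, ix) lattice index of each
    compact node.  ``fixed_dofs`` marks eliminated (zero) displacement
    components; ``coupled_nodes`` (if present) share one master translation
    carrying ``master_force``; ``nodal_forces`` applies loads directly to
    nodes (analytic-test variant).
    """

    mask_shape: tuple[int, int, int]
    spacing: float  # um
    material: Material
    elements: np.ndarray  # (nelem, 3) int
    conn: np.ndarray  # (nelem, 8) int
    node_grid: np.ndarray  # (nnode, 3) int
    fixed_dofs: np.ndarray  # (nnode, 3) bool
    coupled_nodes: np.ndarray | None = None
    master_force: np.ndarray | None = None  # (3,) N
    nodal_forces: np.ndarray | None = None  # (nnode, 3) N

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.node_grid)

    @property
    def element_size(self) -> float:
        """Element edge length in meters."""
        return self.spacing * 1e-6

    @property
    def element_volume(self) -> float:
        """Element volume in m^3."""
        return self.element_size**3

    def validate(self) -> None:
        if self.n_elements == 0:
            raise ValueError("problem has no elements")
        if self.coupled_nodes is not None:
            coupled = np.zeros(self.n_nodes, dtype=bool)
            coupled[self.coupled_nodes] = True
            if coupled.sum() == 0:
                raise ValueError("coupled node set is empty")
            if (coupled[:, None] & self.fixed_dofs).any():
                raise ValueError("constrained and coupled node sets overlap")
        if self.fixed_dofs.sum() == 0:
            raise ValueError("no constraints: system is singular")


def _connected_bone(mask: np.ndarray) -> np.ndarray:
    """Keep components of the mask that span both end slices; drop floating
    islands with a warning; raise if no spanning component exists."""
    labels, n = ndimage.label(mask, structure=_FACE3D)
    if n == 0:
        raise ValueError("empty mask")
    at_distal = np.unique(labels[0][mask[0]])
    at_proximal = np.unique(labels[-1][mask[-1]])
    spanning = np.intersect1d(at_distal, at_proximal)
    spanning = spanning[spanning > 0]
    if len(spanning) == 0:
        raise ValueError("no connected path between the distal and proximal end slices")
    keep = np.isin(labels, spanning) & mask
    n_dropped = int(mask.sum() - keep.sum())
    if n_dropped:
        logger.warning("dropped %d disconnected bone voxels (floating islands)", n_dropped)
    return keep


def _mesh_from_mask(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic element list, connectivity and compact node lattice."""
    m = _connected_bone(mask.values)
    nz, ny, nx = m.shape
    elements = np.argwhere(m)  # C order == lexicographic (z, y, x)
    ez, ey, ex = elements.T
    # global lattice node id, (nz+1, ny+1, nx+1) grid
    corners = np.empty((len(elements), 8), dtype=np.int64)
    for a in range(8):
        dxa, dya, dza = a & 1, (a >> 1) & 1, (a >> 2) & 1
        corners[:, a] = ((ez + dza) * (ny + 1) + (ey + dya)) * (nx + 1) + (ex + dxa)
    active = np.unique(corners)  # sorted == lexicographic (z, y, x)
    conn = np.searchsorted(active, corners)
    iz, rem = np.divmod(active, (ny + 1) * (nx + 1))
    iy, ix = np.divmod(rem, nx + 1)
    node_grid = np.stack([iz, iy, ix], axis=1)
    return elements, conn.astype(np.int64), node_grid


def build_problem(mask: BinaryMask, material: Material, load: LoadCase) -> FEProblem:
    """Build the default (kinematically coupled) problem from a bone mask.

    One brick element per bone voxel; all nodes of the most proximal slice
    fully constrained; all nodes on the most distal bone surface coupled to a
    rotation-suppressed rigid reference carrying the total load.
    """
    elements, conn, node_grid = _mesh_from_mask(mask)
    nz = mask.values.shape[0]
    fixed = np.zeros((len(node_grid), 3), dtype=bool)
    fixed[node_grid[:, 0] == nz, :] = True
    coupled = np.flatnonzero(node_grid[:, 0] == 0)
    if len(coupled) == 0:
        raise ValueError("no bone nodes on the distal end slice to couple")
    f_ml, f_ap, f_si = load_vector(load)
    # +z: compressive axial force pushes the distal surface toward the
    # constrained proximal end
    master_force = np.array([f_ml, f_ap, f_si])
    problem = FEProblem(
        mask_shape=mask.values.shape,
        spacing=mask.spacing,
        material=material,
        elements=elements,
        conn=conn,
        node_grid=node_grid,
        fixed_dofs=fixed,
        coupled_nodes=coupled,
        master_force=master_force,
    )
    problem.validate()
    return problem


def build_uniaxial_test_problem(
    mask: BinaryMask, material: Material, total_force: float
) -> FEProblem:
    """Analytic-test boundary conditions for closed-form verification.

    A uniform axial traction ``total_force / A`` is applied to the proximal
    end as consistent nodal loads; the distal end is supported on rollers
    (uz = 0) and lateral expansion is left free, with symmetry planes
    (ux = 0 at the minimum-x node plane, uy = 0 at minimum y) removing the
    remaining rigid-body modes.  For a homogeneous rectangular column the
    exact uniaxial solution lies in the trilinear FE space, so the computed
    displacement and strain energy density match F*L/(E*A) and sigma^2/(2E)
    to solver precision.
    """
    elements, conn, node_grid = _mesh_from_mask(mask)
    nz = mask.values.shape[0]
    fixed = np.zeros((len(node_grid), 3), dtype=bool)
    fixed[node_grid[:, 2] == node_grid[:, 2].min(), 0] = True  # ux symmetry
    fixed[node_grid[:, 1] == node_grid[:, 1].min(), 1] = True  # uy symmetry
    fixed[node_grid[:, 0] == 0, 2] = True  # uz rollers, distal face

    top_elems = elements[:, 0] == nz - 1
    n_top = int(top_elems.sum())
    if n_top == 0:
        raise ValueError("no elements reach the loaded end slice")
    nodal = np.zeros((len(node_grid), 3))
    per_node = total_force / (4.0 * n_top)  # consistent load, uniform traction
    for a in range(8):
        if (a >> 2) & 1 == 1:  # top-face corners of top-slice elements
            np.add.at(nodal[:, 2], conn[top_elems, a], per_node)
    problem = FEProblem(
        mask_shape=mask.values.shape,
        spacing=mask.spacing,
        material=material,
        elements=elements,
        conn=conn,
        node_grid=node_grid,
        fixed_dofs=fixed,
        nodal_forces=nodal,
    )
    problem.validate()
    return problem


def build_cantilever_test_problem(
    mask: BinaryMask, material: Material, tip_force: tuple[float, float, float]
) -> FEProblem:
    """Cantilever boundary conditions for beam-theory verification.

    All nodes of the most proximal slice are fully fixed; the resultant
    ``tip_force`` (N, components (fx, fy, fz)) is spread equally over the
    distal-slice bone nodes, leaving the tip free to rotate.  For a slender
    annulus the mean transverse tip displacement then converges on the
    Euler-Bernoulli cantilever deflection F L^3 / (3 E I); like the uniaxial
    variant this exists solely for closed-form verification.
    """
    elements, conn, node_grid = _mesh_from_mask(mask)
    nz = mask.values.shape[0]
    fixed = np.zeros((len(node_grid), 3), dtype=bool)
    fixed[node_grid[:, 0] == nz, :] = True
    tip_nodes = np.flatnonzero(node_grid[:, 0] == 0)
    if len(tip_nodes) == 0:
        raise ValueError("no bone nodes on the distal end slice")
    nodal = np.zeros((len(node_grid), 3))
    nodal[tip_nodes] = np.asarray(tip_force, dtype=float) / len(tip_nodes)
    problem = FEProblem(
        mask_shape=mask.values.shape,
        spacing=mask.spacing,
        material=material,
        elements=elements,
        conn=conn,
        node_grid=node_grid,
        fixed_dofs=fixed,
        nodal_forces=nodal,
    )
    problem.validate()
    return problem


def _element_dofs(problem: FEProblem) -> np.ndarray:
    """(nelem, 24) full dof indices in local-node order."""
    return (3 * problem.conn[:, :, None] + np.arange(3)[None, None, :]).reshape(
        problem.n_elements, 24
    )


def _assemble(problem: FEProblem) -> sparse.csr_matrix:
    ke, _ = _hex_stiffness(problem.material, problem.element_size)
    edof = _element_dofs(problem)
    n = 3 * problem.n_nodes
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    data = np.broadcast_to(ke.ravel(), (problem.n_elements, 576)).ravel()
    k = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return k


def _reduction(problem: FEProblem) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Constraint-elimination map T (full dofs x reduced dofs) and reduced rhs."""
    n_nodes = problem.n_nodes
    n_full = 3 * n_nodes
    fixed = problem.fixed_dofs.ravel()
    coupled_mask = np.zeros(n_nodes, dtype=bool)
    if problem.coupled_nodes is not None:
        coupled_mask[problem.coupled_nodes] = True
    coupled_dof = np.repeat(coupled_mask, 3)

    free = ~fixed & ~coupled_dof
    n_free = int(free.sum())
    n_red = n_free + (3 if problem.coupled_nodes is not None else 0)

    col_of_full = np.full(n_full, -1, dtype=np.int64)
    col_of_full[free] = np.arange(n_free)
    if problem.coupled_nodes is not None:
        comp = np.tile(np.arange(3), n_nodes)
        col_of_full[coupled_dof] = n_free + comp[coupled_dof]

    rows = np.flatnonzero(col_of_full >= 0)
    t = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, col_of_full[rows])), shape=(n_full, n_red)
    ).tocsr()

    f_red = np.zeros(n_red)
    if problem.nodal_forces is not None:
        f_red += t.T @ problem.nodal_forces.ravel()
    if problem.master_force is not None:
        f_red[n_free : n_free + 3] += problem.master_force
    return t, f_red


@dataclass(frozen=True)
class FESolution:
    """Equilibrium displacements of an :class:`FEProblem`.

    ``displacements`` is the nodal field in meters (n_nodes, 3).  ``work`` is
    the external work 0.5 * f.u of the reduced system, equal to the total
    strain energy at equilibrium.  ``master_displacement`` is the shared
    translation of the coupled surface (None for the analytic-test variant).
    """

    displacements: np.ndarray
    residual: float
    iterations: int
    method: str
    work: float
    master_displacement: np.ndarray | None = None


def solve(
    problem: FEProblem,
    rtol: float = 1e-8,
    maxiter: int = 200_000,
    method: Literal["auto", "direct", "cg"] = "auto",
) -> FESolution:
    """Solve for equilibrium displacements.

    Constraints are eliminated exactly (no penalties): fixed dofs are removed
    and coupled dofs are condensed onto a master translation.  Small reduced
    systems use a sparse direct factorization; larger ones a Jacobi-
    preconditioned conjugate gradient iterated to relative residual ``rtol``.
    """
    problem.validate()
    k = _assemble(problem)
    t, f_red = _reduction(problem)
    k_red = (t.T @ (k @ t)).tocsr()
    n_red = k_red.shape[0]

    fnorm = float(np.linalg.norm(f_red))
    if fnorm == 0.0:
        u_red = np.zeros(n_red)
        res, iters, used = 0.0, 0, "trivial"
    elif method == "direct" or (method == "auto" and n_red <= DIRECT_SOLVER_MAX_DOFS):
        u_red = spsolve(k_red.tocsc(), f_red)
        if not np.all(np.isfinite(u_red)):
            raise RuntimeError("direct solve produced non-finite values (singular system?)")
        res = float(np.linalg.norm(k_red @ u_red - f_red) / fnorm)
        iters, used = 1, "direct"
    else:
        d_inv = 1.0 / k_red.diagonal()
        if not np.all(np.isfinite(d_inv)):
            raise RuntimeError("zero diagonal in stiffness matrix (singular system?)")
        m = LinearOperator(k_red.shape, matvec=lambda x: d_inv * x)
        iters = 0

        def _count(_):
            nonlocal iters
            iters += 1

        u_red, info = cg(k_red, f_red, rtol=rtol, atol=0.0, maxiter=maxiter, M=m, callback=_count)
        res = float(np.linalg.norm(k_red @ u_red - f_red) / fnorm)
        if info != 0 or res > rtol * 10:
            raise RuntimeError(
                f"CG did not converge within {maxiter} iterations "
                f"(relative residual {res:.3e})"
            )
        used = "cg"
    if res > max(rtol * 10, 1e-7) and fnorm > 0:
        raise RuntimeError(f"solver residual {res:.3e} exceeds tolerance")

    u_full = (t @ u_red).reshape(problem.n_nodes, 3)
    work = 0.5 * float(f_red @ u_red)
    master = None
    if problem.coupled_nodes is not None:
        master = u_full[problem.coupled_nodes[0]].copy()
    return FESolution(
        displacements=u_full,
        residual=res,
        iterations=iters,
        method=used,
        work=work,
        master_displacement=master,
    )


@dataclass(frozen=True)
class SEDField:
    """Per-element strain energy density (Pa) with a voxel-grid view."""

    values: np.ndarray  # (nelem,) Pa
    elements: np.ndarray  # (nelem, 3) voxel indices
    mask_shape: tuple[int, int, int]
    spacing: float  # um

    @property
    def element_volume(self) -> float:
        return (self.spacing * 1e-6) ** 3

    @property
    def total_energy(self) -> float:
        """Total strain energy, sum of U_e * V_e, in joules."""
        return float(self.values.sum() * self.element_volume)

    def as_volume(self, fill: float = 0.0) -> np.ndarray:
        """SED on the image grid; non-bone voxels take ``fill``."""
        vol = np.full(self.mask_shape, fill, dtype=np.float64)
        vol[tuple(self.elements.T)] = self.values
        return vol

    def as_image(self, fill: float = 0.0) -> GrayImage:
        return GrayImage(values=self.as_volume(fill), spacing=self.spacing)

    @property
    def support(self) -> np.ndarray:
        m = np.zeros(self.mask_shape, dtype=bool)
        m[tuple(self.elements.T)] = True
        return m


def element_sed(problem: FEProblem, solution: FESolution) -> SEDField:
    """Per-element strain energy density, averaged over the 8 Gauss points.

    U_e = mean_g 0.5 * eps_g^T C eps_g.  With 2x2x2 quadrature and equal
    weights this average times the element volume is exactly the element's
    strain energy, so the field satisfies the work-energy balance
    sum U_e V_e = 0.5 f.u up to solver residual.
    """
    _, b_all = _hex_stiffness(problem.material, problem.element_size)
    c = problem.material.elasticity_tensor
    edof = _element_dofs(problem)
    ue = solution.displacements.ravel()[edof]  # (nelem, 24)
    u_dens = np.zeros(problem.n_elements)
    for g in range(8):
        eps = ue @ b_all[g].T  # (nelem, 6)
        u_dens += 0.5 * np.einsum("ij,jk,ik->i", eps, c, eps)
    u_dens /= 8.0
    u_dens = np.maximum(u_dens, 0.0)  # clip roundoff negatives
    return SEDField(
        values=u_dens,
        elements=problem.elements,
        mask_shape=problem.mask_shape,
        spacing=problem.spacing,
    )


def sed_to_equivalent_strain(u: np.ndarray | float, material: Material) -> np.ndarray | float:
    """Equivalent uniaxial strain (microstrain) of a SED value:
    eps = 1e6 * sqrt(2 U / E)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("strain energy density must be non-negative")
    out = 1e6 * np.sqrt(2.0 * u_arr / material.youngs_modulus)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out
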