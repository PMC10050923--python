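"""Small-strain linear-elastic Tet4 finite elements for two-material bills.

The bill is loaded in the two regimes a cavity excavator experiences:

* **impact** — the basal surface is fully fixed and a net axial force
  (default 10 N, -z) is spread over the tip patch, weighted by lumped
  nodal surface area;
* **torsion** — the tip patch is fixed and the base receives the
  small-rotation displacement field of a prescribed twist (default
  1.75 mrad) about the +z axis through the centroid of the bony-core
  base.

Both solve the same linear system K u = f with Dirichlet elimination and
a sparse direct factorization.  Element stresses are constant per Tet4;
nodal von Mises values are volume-weighted averages over adjacent
elements, and performance is summarised as the peak nodal von Mises
stress inside the measurement zone on the rhamphotheca surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry
from .geometry import BONE, RHAMPHOTHECA, BillSpec, TetMesh

__all__ = [
    "SolverError",
    "Material",
    "KERATIN",
    "TRABECULAR_BONE",
    "MaterialAssignment",
    "material_assignment",
    "LoadCase",
    "StressField",
    "assemble_system",
    "solve_dirichlet",
    "solve_impact",
    "solve_torsion",
    "von_mises",
    "peak_vm_in_zone",
    "convergence_study",
]


class SolverError(RuntimeError):
    """The linear solve failed or did not converge."""


@dataclass(frozen=True)
class Material:
    """Homogeneous isotropic linear-elastic material (density is metadata only)."""

    name: str
    E: float  # Young's modulus, Pa
    nu: float  # Poisson's ratio
    rho: float  # density, kg/m^3

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")
        if self.rho <= 0:
            raise ValueError("density must be positive")

    def d_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity matrix (engineering shear strains)."""
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


# nanoindentation values for toucan rhamphotheca keratin and trabecular bone,
# with nu = 0.4 assigned to both
KERATIN = Material("keratin", E=6.5e9, nu=0.4, rho=1000.0)
TRABECULAR_BONE = Material("bone", E=12.7e9, nu=0.4, rho=50.0)


@dataclass(frozen=True)
class MaterialAssignment:
    """Map from mesh material ids to materials.

    ``composite`` is the natural bill (keratin shell over bone core);
    the two homogeneous modes assign one material to both regions.
    """

    mode: str
    materials: dict[int, Material]

    def for_elements(self, material_id: np.ndarray) -> list[tuple[Material, np.ndarray]]:
        out = []
        for mid, mat in self.materials.items():
            mask = material_id == mid
            if np.any(mask):
                out.append((mat, mask))
        covered = np.zeros(len(material_id), dtype=bool)
        for _, mask in out:
            covered |= mask
        if not covered.all():
            missing = sorted(set(np.unique(material_id[~covered]).tolist()))
            raise ValueError(f"material ids without an assigned material: {missing}")
        return out


def material_assignment(
    mode: str, keratin: Material = KERATIN, bone: Material = TRABECULAR_BONE
) -> MaterialAssignment:
    if mode == "composite":
        mats = {RHAMPHOTHECA: keratin, BONE: bone}
    elif mode == "all_keratin":
        mats = {RHAMPHOTHECA: keratin, BONE: keratin}
    elif mode == "all_bone":
        mats = {RHAMPHOTHECA: bone, BONE: bone}
    else:
        raise ValueError(f"unknown material mode {mode!r}")
    return MaterialAssignment(mode=mode, materials=mats)


@dataclass(frozen=True)
class LoadCase:
    """One loading regime: impact (tip force F, -z) or torsion (base twist theta)."""

    regime: str
    F: float = 10.0  # N, total tip force for impact
    theta: float = 1.75e-3  # rad, prescribed base rotation for torsion

    def __post_init__(self) -> None:
        if self.regime not in ("impact", "torsion"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "impact" and self.F <= 0:
            raise ValueError("impact force F must be positive")
        if self.regime == "torsion" and self.theta < 0:
            raise ValueError("twist angle theta must be non-negative")


@dataclass
class StressField:
    """Result of one FE solve."""

    displacements: np.ndarray  # (N, 3), m
    element_stress: np.ndarray  # (M, 6): sxx, syy, szz, sxy, syz, szx, Pa
    nodal_vm: np.ndarray  # (N,), Pa
    strain_energy: float  # J
    applied_forces: np.ndarray | None = None  # (N, 3) external nodal forces, if any


# ---------------------------------------------------------------------------
# assembly


def _shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Constant shape-function gradients (M, 4, 3) and volumes (M,) for Tet4."""
    p = nodes[tets]
    J = p[:, 1:] - p[:, 0:1]  # rows are edge vectors
    det = np.linalg.det(J)
    vol = det / 6.0
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise geometry.ValidationError(f"inverted element {bad}: volume {vol[bad]:.3e}")
    Jinv = np.linalg.inv(J)  # d(xi_j)/d(x_k) = Jinv[k, j]
    g = np.empty((len(tets), 4, 3))
    g[:, 1:4] = np.transpose(Jinv, (0, 2, 1))  # grad xi_j as rows
    g[:, 0] = -g[:, 1:4].sum(axis=1)
    return g, vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (M, 6, 12) from shape gradients."""
    M = grads.shape[0]
    B = np.zeros((M, 6, 12))
    for i in range(4):
        gx, gy, gz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def _element_d(mesh: TetMesh, assignment: MaterialAssignment) -> np.ndarray:
    """Per-element 6x6 elasticity matrices (M, 6, 6)."""
    D = np.empty((mesh.n_tets, 6, 6))
    for mat, mask in assignment.for_elements(mesh.material_id):
        D[mask] = mat.d_matrix()
    return D


def assemble_system(mesh: TetMesh, assignment: MaterialAssignment) -> sp.csr_matrix:
    """Global stiffness matrix (3N x 3N, CSR), symmetric PSD before constraints."""
    grads, vol = _shape_gradients(mesh.nodes, mesh.tets)
    B = _b_matrices(grads)
    D = _element_d(mesh, assignment)
    Ke = np.einsum("eji,ejk,ekl,e->eil", B, D, B, vol, optimize=True)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes,) * 2).tocsr()
    return K


def _stresses(
    mesh: TetMesh, assignment: MaterialAssignment, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    grads, vol = _shape_gradients(mesh.nodes, mesh.tets)
    B = _b_matrices(grads)
    D = _element_d(mesh, assignment)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.einsum("eij,ej->ei", D, strain)
    energy = 0.5 * float(np.einsum("ei,ei,e->", stress, strain, vol))
    vm_e = von_mises(stress)
    nodal_vm = np.zeros(mesh.n_nodes)
    wsum = np.zeros(mesh.n_nodes)
    for i in range(4):
        np.add.at(nodal_vm, mesh.tets[:, i], vm_e * vol)
        np.add.at(wsum, mesh.tets[:, i], vol)
    nodal_vm /= np.maximum(wsum, 1e-300)
    return stress, nodal_vm, energy


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of symmetric tensors (..., 6) ordered
    (sxx, syy, szz, sxy, syz, szx)."""
    s = np.asarray(sigma, dtype=float)
    sxx, syy, szz, sxy, syz, szx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


# ---------------------------------------------------------------------------
# solves


def solve_dirichlet(
    mesh: TetMesh,
    assignment: MaterialAssignment,
    prescribed_nodes: np.ndarray,
    prescribed_values: np.ndarray,
    forces: np.ndarray | None = None,
    tol: float = 1e-8,
) -> StressField:
    """Solve K u = f with all three components prescribed on the given nodes."""
    n = mesh.n_nodes
    if len(prescribed_nodes) == 0:
        raise SolverError("no Dirichlet constraints: system is singular (rigid-body modes)")
    K = assemble_system(mesh, assignment)
    f = np.zeros(3 * n) if forces is None else np.asarray(forces, dtype=float).ravel().copy()

    fixed = (3 * np.asarray(prescribed_nodes, dtype=np.int64)[:, None] + np.arange(3)).ravel()
    u = np.zeros(3 * n)
    u[fixed] = np.asarray(prescribed_values, dtype=float).ravel()
    free = np.setdiff1d(np.arange(3 * n), fixed, assume_unique=False)

    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ u[fixed]
    try:
        u[free] = spla.splu(Kff).solve(rhs)
    except RuntimeError as exc:  # singular factorization -> iterative fallback
        uf, info = spla.cg(Kff, rhs, rtol=tol, maxiter=20000)
        if info != 0:
            raise SolverError(f"direct solve failed ({exc}) and CG did not converge (info={info})")
        u[free] = uf
    denom = max(float(np.linalg.norm(rhs)), 1e-300)
    resid = float(np.linalg.norm(Kff @ u[free] - rhs)) / denom
    if resid > max(tol, 1e-8):
        raise SolverError(f"linear solve residual {resid:.2e} exceeds tolerance")

    stress, nodal_vm, energy = _stresses(mesh, assignment, u)
    return StressField(
        displacements=u.reshape(-1, 3),
        element_stress=stress,
        nodal_vm=nodal_vm,
        strain_energy=energy,
        applied_forces=None if forces is None else f.reshape(-1, 3),
    )


def tip_force_distribution(mesh: TetMesh, F: float) -> np.ndarray:
    """Nodal forces (N, 3) summing exactly to (0, 0, -F), spread over the tip
    patch weighted by lumped nodal boundary area."""
    tip = mesh.node_sets["tip_patch"]
    tip_set = set(tip.tolist())
    faces = mesh.boundary_faces()
    on_tip = np.array([all(v in tip_set for v in f) for f in faces])
    w = np.zeros(mesh.n_nodes)
    if np.any(on_tip):
        areas = geometry._face_areas(mesh.nodes, faces[on_tip])
        for i in range(3):
            np.add.at(w, faces[on_tip][:, i], areas / 3.0)
    else:  # very coarse mesh: fall back to uniform weights
        w[tip] = 1.0
    w = w / w.sum()
    forces = np.zeros((mesh.n_nodes, 3))
    forces[:, 2] = -F * w
    return forces


def solve_impact(mesh: TetMesh, assignment: MaterialAssignment, case: LoadCase | None = None) -> StressField:
    """Impact regime: base fully fixed, net tip force F in -z."""
    case = case or LoadCase("impact")
    if case.regime != "impact":
        raise ValueError("load case regime must be 'impact'")
    base = mesh.node_sets["base"]
    forces = tip_force_distribution(mesh, case.F)
    field = solve_dirichlet(mesh, assignment, base, np.zeros((len(base), 3)), forces=forces)
    return field


def _bone_base_centroid(mesh: TetMesh) -> np.ndarray:
    """Centroid (x, y) of the bony-core nodes on the basal plane."""
    bone_nodes = np.unique(mesh.tets[mesh.material_id == BONE])
    base = np.intersect1d(mesh.node_sets["base"], bone_nodes)
    if len(base) == 0:
        base = mesh.node_sets["base"]
    return mesh.nodes[base, :2].mean(axis=0)


def solve_torsion(mesh: TetMesh, assignment: MaterialAssignment, case: LoadCase | None = None) -> StressField:
    """Torsion regime: tip patch fixed; base nodes receive the small-rotation
    displacements of a twist theta about +z through the bone-core base centroid."""
    case = case or LoadCase("torsion")
    if case.regime != "torsion":
        raise ValueError("load case regime must be 'torsion'")
    base = mesh.node_sets["base"]
    tip = np.setdiff1d(mesh.node_sets["tip_patch"], base)
    cx, cy = _bone_base_centroid(mesh)
    ub = np.zeros((len(base), 3))
    ub[:, 0] = -case.theta * (mesh.nodes[base, 1] - cy)
    ub[:, 1] = case.theta * (mesh.nodes[base, 0] - cx)
    nodes = np.concatenate([base, tip])
    values = np.concatenate([ub, np.zeros((len(tip), 3))])
    return solve_dirichlet(mesh, assignment, nodes, values)


def peak_vm_in_zone(field: StressField, mesh: TetMesh) -> float:
    """Peak nodal von Mises stress over the measurement-zone node set."""
    zone = mesh.node_sets.get("measurement_zone")
    if zone is None or len(zone) == 0:
        raise ValueError("measurement_zone node set is empty; tag the mesh first")
    return float(field.nodal_vm[zone].max())


# ---------------------------------------------------------------------------
# convergence


def convergence_study(
    spec: BillSpec,
    assignment: MaterialAssignment,
    case: LoadCase,
    resolutions: list[tuple[int, int]],
    threshold_pct: float = 5.0,
):
    """Peak zone von Mises stress across a mesh-refinement ladder.

    ``resolutions`` is a list of (n_axial, n_circumferential) pairs of
    strictly increasing element count.  Reports the percent change between
    successive levels and flags the first level where |change| drops below
    the convergence threshold (default 5%).
    """
    import pandas as pd

    if len(resolutions) < 3:
        raise ValueError("need at least 3 resolutions for a convergence study")
    rows = []
    last_count = 0
    for n_ax, n_ci in resolutions:
        mesh = geometry.make_bill_mesh(spec, n_axial=n_ax, n_circumferential=n_ci)
        if mesh.n_tets <= last_count:
            raise ValueError("resolutions must strictly increase the element count")
        last_count = mesh.n_tets
        if case.regime == "impact":
            f = solve_impact(mesh, assignment, case)
        else:
            f = solve_torsion(mesh, assignment, case)
        rows.append({"n_axial": n_ax, "n_circ": n_ci, "element_count": mesh.n_tets,
                     "peak_vm": peak_vm_in_zone(f, mesh)})
    df = pd.DataFrame(rows)
    prev = df["peak_vm"].shift(1)
    df["pct_change"] = 100.0 * (df["peak_vm"] - prev) / prev
    df["converged"] = df["pct_change"].abs() < threshold_pct
    df.loc[0, "converged"] = False
    return df
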