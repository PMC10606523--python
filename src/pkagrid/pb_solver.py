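"""Finite-difference linearized Poisson-Boltzmann solver.

Solves div(eps grad phi) - eps*kappa^2*phi = -4*pi*rho on the regular grid
of a DielectricMap: 7-point stencil with harmonic-mean permittivities on
cell faces, trilinear charge spreading, screened-monopole (Debye) boundary
conditions, conjugate gradients with a Jacobi preconditioner, and two-level
focusing for fine spacings around a site.  Screening acts only in
solvent-labelled voxels outside a Stern (ion-exclusion) shell around the
solute.  Energies are returned in kcal/mol; potentials are stored in kT/e.

The grid self-energy of a spread point charge is large and
discretization-dependent; all energy routines that need a solvation
difference therefore run the *same* charge set on two maps sharing one grid
placement, so the self-energy cancels exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from . import constants
from .dielectric_model import DielectricMap, GridSpec, _ball_footprint

__all__ = [
    "SolverSettings",
    "PotentialGrid",
    "SolverError",
    "solve",
    "potential_at",
    "dielectric_response_energy",
    "interaction_energy",
    "background_energy",
    "coulomb_energy",
]

ChargeSet = Sequence[tuple[np.ndarray, float]]


class SolverError(RuntimeError):
    def __init__(self, message: str, residual_history: list[float] | None = None):
        super().__init__(message)
        self.residual_history = residual_history or []


@dataclass
class SolverSettings:
    ionic_strength: float = 0.2
    temperature: float = 298.0
    convergence_tol: float = 1e-6
    max_iterations: int = 5000
    boundary: str = "debye_dipole"  # screened monopole sum; 'coulombic' disables screening
    focusing_levels: int = 2
    stern_radius: float = 2.0

    def __post_init__(self):
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be non-negative")


@dataclass
class PotentialGrid:
    grid: GridSpec
    phi: np.ndarray  # kT/e at settings.temperature
    source_charges: list
    temperature: float = 298.0
    residual_history: list[float] = field(default_factory=list)


def _charge_arrays(charges: ChargeSet) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([np.asarray(p, dtype=float) for p, _ in charges]).reshape(-1, 3)
    q = np.array([float(qq) for _, qq in charges])
    return pos, q


def _boundary_potential(
    points: np.ndarray,
    pos: np.ndarray,
    q: np.ndarray,
    eps_solvent: float,
    settings: SolverSettings,
) -> np.ndarray:
    """Analytic screened-monopole potential (kcal/mol/e) of all source
    charges, used as the Dirichlet condition on the box faces."""
    if len(pos) == 0:
        return np.zeros(len(points))
    if settings.boundary == "coulombic" or settings.ionic_strength == 0:
        kappa = 0.0
    else:
        kappa = math.sqrt(
            constants.eps_kappa_sq(settings.ionic_strength, settings.temperature) / eps_solvent
        )
    d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    return (constants.COULOMB_KCAL_A / eps_solvent) * np.sum(
        q[None, :] * np.exp(-kappa * d) / d, axis=1
    )


def _screening_array(dmap: DielectricMap, settings: SolverSettings) -> np.ndarray:
    """eps*kappa^2*h^2 per node: nonzero only in solvent voxels outside the
    Stern shell around non-solvent regions."""
    if settings.ionic_strength == 0:
        return np.zeros(dmap.grid.dims)
    ionic = dmap.solvent_mask.copy()
    solute = ~dmap.solvent_mask
    if solute.any() and settings.stern_radius > 0:
        foot = _ball_footprint(settings.stern_radius / dmap.grid.spacing)
        ionic &= ~ndimage.binary_dilation(solute, structure=foot)
    k2 = constants.eps_kappa_sq(settings.ionic_strength, settings.temperature)
    return np.where(ionic, k2 * dmap.grid.spacing**2, 0.0)


def _spread_charges(grid: GridSpec, pos: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Trilinear assignment of point charges to the 8 surrounding nodes."""
    rho = np.zeros(grid.dims)
    o = np.asarray(grid.origin)
    h = grid.spacing
    frac = (pos - o) / h
    base = np.floor(frac).astype(int)
    if np.any(base < 0) or np.any(base + 1 >= np.asarray(grid.dims)):
        raise SolverError("charge outside grid interior")
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz), w * q)
    return rho


def _solve_on_grid(
    dmap: DielectricMap,
    pos: np.ndarray,
    q: np.ndarray,
    settings: SolverSettings,
    boundary_values: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Solve on the map's own grid; returns phi in kcal/mol/e."""
    grid = dmap.grid
    nx, ny, nz = grid.dims
    h = grid.spacing
    eps = dmap.eps
    k2h2 = _screening_array(dmap, settings)

    phi = np.zeros(grid.dims)
    bmask = np.zeros(grid.dims, dtype=bool)
    bmask[0, :, :] = bmask[-1, :, :] = True
    bmask[:, 0, :] = bmask[:, -1, :] = True
    bmask[:, :, 0] = bmask[:, :, -1] = True
    if boundary_values is None:
        bpts = np.argwhere(bmask) * h + np.asarray(grid.origin)
        phi[bmask] = _boundary_potential(bpts, pos, q, dmap.eps_solvent, settings)
    else:
        phi[bmask] = boundary_values

    # face permittivities (harmonic mean between adjacent nodes)
    fx = 2 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    fy = 2 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    fz = 2 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])

    unknown = -np.ones(grid.dims, dtype=np.int64)
    interior = ~bmask
    n_unknown = int(interior.sum())
    unknown[interior] = np.arange(n_unknown)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_unknown)
    b = np.zeros(n_unknown)
    rho = _spread_charges(grid, pos, q)
    b += 4.0 * math.pi * constants.COULOMB_KCAL_A * rho[interior] / h
    diag += k2h2[interior]

    def couple(face: np.ndarray, shift_axis: int):
        # face[i] couples node i and i+1 along shift_axis
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[shift_axis] = slice(0, -1)
        hi[shift_axis] = slice(1, None)
        u_lo = unknown[tuple(lo)]
        u_hi = unknown[tuple(hi)]
        phi_lo = phi[tuple(lo)]
        phi_hi = phi[tuple(hi)]
        both = (u_lo >= 0) & (u_hi >= 0)
        np.add.at(diag, u_lo[u_lo >= 0], face[u_lo >= 0])
        np.add.at(diag, u_hi[u_hi >= 0], face[u_hi >= 0])
        rows.append(u_lo[both])
        cols.append(u_hi[both])
        vals.append(-face[both])
        # Dirichlet neighbours contribute to the RHS
        lb = (u_lo >= 0) & (u_hi < 0)
        np.add.at(b, u_lo[lb], face[lb] * phi_hi[lb])
        hb = (u_hi >= 0) & (u_lo < 0)
        np.add.at(b, u_hi[hb], face[hb] * phi_lo[hb])

    couple(fx, 0)
    couple(fy, 1)
    couple(fz, 2)

    r = np.concatenate(rows + cols)
    c = np.concatenate(cols + rows)
    v = np.concatenate(vals + vals)
    A = coo_matrix((v, (r, c)), shape=(n_unknown, n_unknown)).tocsr()
    A += coo_matrix((diag, (np.arange(n_unknown), np.arange(n_unknown))), shape=A.shape)

    M = LinearOperator(A.shape, matvec=lambda x: x / diag)
    history: list[float] = []
    bnorm = np.linalg.norm(b) or 1.0

    def callback(xk):
        history.append(float(np.linalg.norm(b - A @ xk) / bnorm))

    x, info = cg(
        A,
        b,
        rtol=settings.convergence_tol,
        maxiter=settings.max_iterations,
        M=M,
        callback=callback,
    )
    if info != 0:
        raise SolverError(
            f"PB solver did not converge in {settings.max_iterations} iterations "
            f"(last relative residual {history[-1] if history else float('nan'):.3e})",
            residual_history=history,
        )
    phi[interior] = x
    return phi, history


def potential_at(pgrid: PotentialGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the potential (kT/e) at Cartesian points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    o = np.asarray(pgrid.grid.origin)
    h = pgrid.grid.spacing
    frac = (pts - o) / h
    base = np.floor(frac).astype(int)
    if np.any(base < 0) or np.any(base + 1 >= np.asarray(pgrid.grid.dims)):
        raise SolverError("evaluation point outside grid")
    t = frac - base
    out = np.zeros(len(pts))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                out += w * pgrid.phi[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
    return out


def solve(
    dmap: DielectricMap,
    charges: ChargeSet,
    settings: SolverSettings | None = None,
    focus_center: np.ndarray | None = None,
    focus_halfwidth: float | None = None,
    fine_spacing: float | None = None,
) -> PotentialGrid:
    """Solve the linearized PB equation; optionally focus a fine sub-grid.

    With focusing, the coarse solution on the map's grid supplies Dirichlet
    values on the faces of a fine box of half-width ``focus_halfwidth``
    centred on ``focus_center``; charges outside the fine box act only
    through those boundary values.
    """
    settings = settings or SolverSettings()
    pos, q = _charge_arrays(charges) if len(charges) else (np.zeros((0, 3)), np.zeros(0))
    kt = constants.kt_kcal(settings.temperature)

    phi, history = _solve_on_grid(dmap, pos, q, settings)
    coarse = PotentialGrid(
        grid=dmap.grid, phi=phi / kt, source_charges=list(charges),
        temperature=settings.temperature, residual_history=history,
    )
    if focus_center is None or settings.focusing_levels < 2 or fine_spacing is None:
        return coarse

    center = np.asarray(focus_center, dtype=float)
    half = float(focus_halfwidth if focus_halfwidth is not None else 8.0)
    n = int(math.ceil(2 * half / fine_spacing)) + 1
    fine_grid = GridSpec(origin=tuple(center - half), spacing=fine_spacing, dims=(n, n, n))
    if not dmap.grid.contains(np.array([fine_grid.origin, fine_grid.upper])):
        raise SolverError("focus box extends beyond the coarse grid")
    fine_map = dmap.refine(fine_grid)

    bmask = np.zeros(fine_grid.dims, dtype=bool)
    bmask[0, :, :] = bmask[-1, :, :] = True
    bmask[:, 0, :] = bmask[:, -1, :] = True
    bmask[:, :, 0] = bmask[:, :, -1] = True
    bpts = np.argwhere(bmask) * fine_spacing + np.asarray(fine_grid.origin)
    bvals = potential_at(coarse, bpts) * kt

    inside = np.all(np.abs(pos - center) < half - fine_spacing, axis=1) if len(pos) else np.zeros(0, bool)
    phi_f, history_f = _solve_on_grid(fine_map, pos[inside], q[inside], settings, boundary_values=bvals)
    return PotentialGrid(
        grid=fine_grid, phi=phi_f / kt, source_charges=list(charges),
        temperature=settings.temperature, residual_history=history + history_f,
    )


def _self_energy(pgrid: PotentialGrid, charges: ChargeSet) -> float:
    """(1/2) sum q_i phi(r_i) in kcal/mol, phi interpolated consistently with
    the trilinear spreading so that grid self-terms cancel between paired runs."""
    pos, q = _charge_arrays(charges)
    kt = constants.kt_kcal(pgrid.temperature)
    return 0.5 * float(np.sum(q * potential_at(pgrid, pos))) * kt


def dielectric_response_energy(
    env_map: DielectricMap,
    ref_map: DielectricMap,
    charges: ChargeSet,
    settings: SolverSettings | None = None,
    focus_center: np.ndarray | None = None,
    focus_halfwidth: float | None = None,
    fine_spacing: float | None = None,
) -> float:
    """Transfer (dielectric response / generalized Born) energy in kcal/mol:
    G_resp(env) - G_resp(ref) for the same charge set.

    Both runs use identical grid placement (enforced), identical charge
    spreading and identical focusing, so the infinite grid self-energy
    cancels and only the reaction-field difference survives.
    """
    if len(charges) == 0:
        raise ValueError("site charge set is empty")
    if env_map.grid != ref_map.grid:
        raise SolverError("paired runs require identical grid placement")
    kwargs = dict(
        settings=settings,
        focus_center=focus_center,
        focus_halfwidth=focus_halfwidth,
        fine_spacing=fine_spacing,
    )
    g_env = _self_energy(solve(env_map, charges, **kwargs), charges)
    g_ref = _self_energy(solve(ref_map, charges, **kwargs), charges)
    return g_env - g_ref


def interaction_energy(
    dmap: DielectricMap,
    charges_i: ChargeSet,
    charges_j: ChargeSet,
    settings: SolverSettings | None = None,
) -> float:
    """Screened interaction energy sum_b q_b^(j) phi_i(r_b), kcal/mol."""
    pos_i, q_i = _charge_arrays(charges_i)
    pos_j, q_j = _charge_arrays(charges_j)
    if len(q_j) == 0 or not np.any(q_j):
        return 0.0
    d = np.linalg.norm(pos_i[:, None, :] - pos_j[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise SolverError("overlapping charge positions between interacting sites")
    pgrid = solve(dmap, charges_i, settings)
    kt = constants.kt_kcal(pgrid.temperature)
    return float(np.sum(q_j * potential_at(pgrid, pos_j))) * kt


def background_energy(
    dmap: DielectricMap,
    site,
    background_charges: ChargeSet,
    settings: SolverSettings | None = None,
) -> float:
    """Energy of the site's protonation charge difference in the field of the
    permanent background charges, kcal/mol."""
    if len(background_charges) == 0:
        return 0.0
    site_charges = site.charge_set("delta")
    pos_b, q_b = _charge_arrays(background_charges)
    pos_s, _ = _charge_arrays(site_charges)
    d = np.linalg.norm(pos_b[:, None, :] - pos_s[None, :, :], axis=2)
    if np.any(d < 1e-6):
        raise SolverError("background set contains atoms of the titratable group")
    pgrid = solve(dmap, background_charges, settings)
    kt = constants.kt_kcal(pgrid.temperature)
    total = 0.0
    for p, dq in site_charges:
        total += dq * float(potential_at(pgrid, p)[0])
    return total * kt


def coulomb_energy(charges_i: ChargeSet, charges_j: ChargeSet, eps: float) -> float:
    """Closed-form Coulomb interaction in a homogeneous medium (kcal/mol);
    the brute-force oracle used in tests."""
    pos_i, q_i = _charge_arrays(charges_i)
    pos_j, q_j = _charge_arrays(charges_j)
    d = np.linalg.norm(pos_i[:, None, :] - pos_j[None, :, :], axis=2)
    return float(constants.COULOMB_KCAL_A / eps * np.sum(q_i[:, None] * q_j[None, :] / d))
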