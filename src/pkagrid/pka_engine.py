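"""Assembly of Poisson-Boltzmann energy components into intrinsic pKas and
the site-site interaction matrix.

Each titratable site gets three contributions on top of its model pKa:

* dielectric response (Born-type) shift -- transfer of the protonation
  charge difference from the site's model compound in water into the
  protein/membrane environment.  Burying a site destabilizes its charged
  form, so the shift is +ddG/ln10kT for acids and -ddG/ln10kT for bases.
* background shift -- the permanent partial charges of the protein act on
  the protonation charge difference; a field that stabilizes the charged
  form moves the pKa so the site stays charged, i.e. -dG_back/ln10kT for
  acids and bases alike (sign bookkeeping lives in one place here,
  :func:`shift_signs`).
* pairwise coupling W between the charge differences of site pairs,
  handled downstream by the titration model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from .dielectric_model import DielectricMap, DielectricScene, GridSpec
from .pb_solver import (
    SolverSettings,
    SolverError,
    dielectric_response_energy,
    potential_at,
    solve,
)
from .structure_io import (
    ParameterizedStructure,
    TitratableSite,
    background_charge_set,
)
from .titration import MicrostateModel, titrate_exact

__all__ = [
    "EngineSettings",
    "EnergyLedger",
    "shift_signs",
    "compute_intrinsic_pka",
    "compute_ledger",
    "compute_interaction_matrix",
    "build_microstate_model",
    "sensitivity_scan",
]


@dataclass
class EngineSettings:
    solver: SolverSettings = field(default_factory=SolverSettings)
    fine_spacing: float = 0.5
    focus_pad: float = 6.0
    focus_background: bool = True

    @property
    def ln10kt(self) -> float:
        return constants.ln10_kt(self.solver.temperature)


@dataclass
class EnergyLedger:
    """Per-site energy components (pKa units) and the pairwise matrix."""

    site_ids: list[str]
    model_pka: np.ndarray
    born_shift: np.ndarray
    background_shift: np.ndarray
    W: np.ndarray
    frame_id: int = 0

    @property
    def intrinsic_pka(self) -> np.ndarray:
        return self.model_pka + self.born_shift + self.background_shift

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "model_pka": self.model_pka,
                "born_shift": self.born_shift,
                "background_shift": self.background_shift,
                "intrinsic_pka": self.intrinsic_pka,
            }
        )

    def write(self, directory: str | Path, prefix: str = "ledger") -> None:
        directory = Path(directory)
        self.to_frame().to_csv(directory / f"{prefix}.tsv", sep="\t", index=False)
        pd.DataFrame(self.W, index=self.site_ids, columns=self.site_ids).to_csv(
            directory / f"{prefix}_W.tsv", sep="\t"
        )


def shift_signs(acid_or_base: str) -> tuple[float, float]:
    """(born, background) sign conventions for the pKa shift.

    Signs multiply energies computed with the protonated-minus-deprotonated
    charge distribution.  Acids: burial raises the pKa (+1), a field
    favouring protonation raises it (-dG, hence -1).  Bases: burial lowers
    the pKa (-1); the background rule is the same -1 because dq points the
    same way for both classes.
    """
    if acid_or_base == "acid":
        return (1.0, -1.0)
    if acid_or_base == "base":
        return (-1.0, -1.0)
    raise ValueError(f"unknown acid_or_base {acid_or_base!r}")


def _model_compound_map(
    structure: ParameterizedStructure,
    site: TitratableSite,
    scene: DielectricScene,
    grid: GridSpec,
) -> DielectricMap:
    """The site's own residue alone in pure water, on the same grid."""
    res_atoms = [
        a
        for a in structure.atoms
        if a.chain_id == site.chain_id and a.residue_number == site.residue_number
    ]
    ref_scene = replace(
        scene,
        structure=ParameterizedStructure(atoms=res_atoms),
        slab=None,
        eps_solvent=81.0,
    )
    return ref_scene.rasterize(grid)


def _site_focus(site: TitratableSite, settings: EngineSettings) -> tuple[np.ndarray, float]:
    pos = np.array(list(site.atom_positions.values()))
    center = pos.mean(axis=0)
    spread = float(np.max(np.linalg.norm(pos - center, axis=1))) if len(pos) else 0.0
    return center, spread + settings.focus_pad


def compute_intrinsic_pka(
    site: TitratableSite,
    dmap: DielectricMap,
    structure: ParameterizedStructure,
    settings: EngineSettings | None = None,
    background_potential=None,
) -> tuple[float, float, float]:
    """(born_shift, background_shift, intrinsic_pka) for one site, pKa units.

    ``background_potential`` may carry a pre-solved PotentialGrid of the
    permanent charges to avoid re-solving per site.
    """
    settings = settings or EngineSettings()
    if dmap.scene is None:
        raise ValueError("map must carry its scene (built by build_eps_map)")
    center, half = _site_focus(site, settings)
    if not dmap.grid.contains(np.array(list(site.atom_positions.values()))):
        raise SolverError("site atoms outside the grid")
    ref_map = _model_compound_map(structure, site, dmap.scene, dmap.grid)
    ddg = dielectric_response_energy(
        dmap,
        ref_map,
        site.charge_set("delta"),
        settings.solver,
        focus_center=center,
        focus_halfwidth=half,
        fine_spacing=settings.fine_spacing,
    )
    s_born, s_back = shift_signs(site.acid_or_base)
    born_shift = s_born * ddg / settings.ln10kt

    background_shift = 0.0
    if background_potential is not None:
        kt = constants.kt_kcal(settings.solver.temperature)
        dg_back = 0.0
        for name, dq in site.delta_charges.items():
            dg_back += dq * float(potential_at(background_potential, site.atom_positions[name])[0]) * kt
        background_shift = s_back * dg_back / settings.ln10kt

    intrinsic = site.model_pka + born_shift + background_shift
    return born_shift, background_shift, float(intrinsic)


def _background_grid(
    structure: ParameterizedStructure,
    sites: Sequence[TitratableSite],
    dmap: DielectricMap,
    settings: EngineSettings,
    focus_site: TitratableSite | None = None,
):
    charges = background_charge_set(structure, sites)
    if not charges:
        return None
    if focus_site is not None and settings.focus_background:
        center, half = _site_focus(focus_site, settings)
        return solve(
            dmap, charges, settings.solver,
            focus_center=center, focus_halfwidth=half, fine_spacing=settings.fine_spacing,
        )
    return solve(dmap, charges, settings.solver)


def compute_interaction_matrix(
    sites: Sequence[TitratableSite],
    dmap: DielectricMap,
    settings: EngineSettings | None = None,
) -> np.ndarray:
    """Symmetric site-site coupling matrix in pKa units (zero diagonal).

    W_ij is the screened interaction between the protonation charge
    differences of sites i and j, symmetrized as (W_ij + W_ji)/2; the
    asymmetry before averaging is a discretization diagnostic.
    """
    settings = settings or EngineSettings()
    n = len(sites)
    W = np.zeros((n, n))
    if n < 2:
        return W
    kt = constants.kt_kcal(settings.solver.temperature)
    grids = []
    for s in sites:
        grids.append(solve(dmap, s.charge_set("delta"), settings.solver))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total = 0.0
            for name, dq in sites[j].delta_charges.items():
                total += dq * float(potential_at(grids[i], sites[j].atom_positions[name])[0])
            W[i, j] = total * kt / settings.ln10kt
    return 0.5 * (W + W.T)


def compute_ledger(
    structure: ParameterizedStructure,
    sites: Sequence[TitratableSite],
    dmap: DielectricMap,
    settings: EngineSettings | None = None,
    frame_id: int = 0,
) -> EnergyLedger:
    """Full energy ledger: per-site shifts plus the interaction matrix."""
    settings = settings or EngineSettings()
    born = np.zeros(len(sites))
    back = np.zeros(len(sites))
    coarse_background = None
    for i, site in enumerate(sites):
        if settings.focus_background:
            bg = _background_grid(structure, sites, dmap, settings, focus_site=site)
        else:
            if coarse_background is None:
                coarse_background = _background_grid(structure, sites, dmap, settings)
            bg = coarse_background
        b, g, _ = compute_intrinsic_pka(site, dmap, structure, settings, background_potential=bg)
        born[i], back[i] = b, g
    W = compute_interaction_matrix(sites, dmap, settings)
    return EnergyLedger(
        site_ids=[s.site_id for s in sites],
        model_pka=np.array([s.model_pka for s in sites]),
        born_shift=born,
        background_shift=back,
        W=W,
        frame_id=frame_id,
    )


def build_microstate_model(
    ledger: EnergyLedger, sites: Sequence[TitratableSite], ph_grid=None
) -> MicrostateModel:
    kwargs = {} if ph_grid is None else {"ph_grid": np.asarray(ph_grid)}
    return MicrostateModel(
        site_ids=list(ledger.site_ids),
        intrinsic_pka=ledger.intrinsic_pka,
        is_acid=np.array([s.acid_or_base == "acid" for s in sites]),
        W=ledger.W,
        **kwargs,
    )


def sensitivity_scan(
    structure: ParameterizedStructure,
    sites: Sequence[TitratableSite],
    base_scene: DielectricScene,
    grid: GridSpec,
    variants: Sequence[dict],
    settings: EngineSettings | None = None,
) -> pd.DataFrame:
    """pKa deltas versus baseline for membrane/solvent parameter variants.

    Each variant is a dict of overrides: ``eps_core``, ``eps_head`` (slab
    fields) and/or ``ionic_strength``.  Deltas are reported to 0.01 pKa
    units.
    """
    settings = settings or EngineSettings()

    def run(scene: DielectricScene, solver: SolverSettings) -> np.ndarray:
        dmap = scene.rasterize(grid)
        eng = replace(settings, solver=solver)
        ledger = compute_ledger(structure, sites, dmap, eng)
        result = titrate_exact(build_microstate_model(ledger, sites))
        return result.pkas()

    base = run(base_scene, settings.solver)
    rows = []
    for variant in variants:
        scene = base_scene
        solver = settings.solver
        slab_over = {k: v for k, v in variant.items() if k in ("eps_core", "eps_head")}
        if slab_over:
            if scene.slab is None:
                raise ValueError("variant changes membrane parameters but scene has no slab")
            scene = replace(scene, slab=replace(scene.slab, **slab_over))
        if "ionic_strength" in variant:
            solver = replace(solver, ionic_strength=variant["ionic_strength"])
            scene = replace(scene, ionic_strength=variant["ionic_strength"])
        pkas = run(scene, solver)
        for sid, d in zip([s.site_id for s in sites], np.round(pkas - base, 2)):
            rows.append({"variant": str(variant), "site_id": sid, "delta_pka": d})
    return pd.DataFrame(rows)
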