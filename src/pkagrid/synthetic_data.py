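"""Synthetic fixtures with analytic or constructed ground truth.

Every input class the pipeline consumes can be generated here without any
downloads: Born spheres and charge pairs with closed-form energies, ideal
helical peptides carrying titratable residues in a membrane slab,
Gaussian-jitter pseudo-trajectories standing in for MD snapshots, and toy
coding sequences with an exactly known residue census.  Pseudo-trajectories
are deliberately non-physical (independent per-atom jitter, no bonded
constraints); they exercise the fluctuation statistics, not force-field
dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import constants
from .dielectric_model import MembraneSlab
from .structure_io import Atom, ParameterizedStructure

__all__ = [
    "FixtureSpec",
    "make_born_sphere",
    "make_charge_pair",
    "make_helix_in_slab",
    "make_pseudo_trajectory",
    "make_toy_cds",
    "reference_psbs_composition",
    "make_reference_like_cds",
    "write_frames_pdb",
]


@dataclass
class FixtureSpec:
    kind: str
    parameters: dict = field(default_factory=dict)

    KINDS = ("born_sphere", "charge_pair", "helix_in_slab", "pseudo_trajectory", "toy_cds")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def make_born_sphere(
    q: float = 1.0, a: float = 2.0, eps_from: float = 81.0, eps_to: float = 4.0
) -> tuple[ParameterizedStructure, float]:
    """Single charged sphere plus the analytic transfer energy between two
    homogeneous exteriors: (C q^2 / 2a) (1/eps_to - 1/eps_from), kcal/mol."""
    if a <= 0:
        raise ValueError("sphere radius must be positive")
    if eps_from < 1 or eps_to < 1:
        raise ValueError("permittivities must be >= 1")
    atom = Atom(
        serial=1, name="C", element="C", residue_name="SPH", residue_number=1,
        chain_id="A", position=np.zeros(3), partial_charge=q, radius=a,
    )
    analytic = constants.COULOMB_KCAL_A * q * q / (2.0 * a) * (1.0 / eps_to - 1.0 / eps_from)
    return ParameterizedStructure(atoms=[atom]), analytic


def make_charge_pair(
    q1: float, q2: float, r: float, eps: float, atom_radius: float = 1.0
) -> tuple[ParameterizedStructure, float]:
    """Two point charges r apart plus their Coulomb energy C q1 q2/(eps r)."""
    if r <= 2 * atom_radius:
        raise ValueError(f"separation {r} below contact distance {2*atom_radius}")
    atoms = [
        Atom(serial=1, name="C", element="C", residue_name="ION", residue_number=1,
             chain_id="A", position=np.array([0.0, 0.0, 0.0]), partial_charge=q1,
             radius=atom_radius),
        Atom(serial=2, name="C", element="C", residue_name="ION", residue_number=2,
             chain_id="A", position=np.array([r, 0.0, 0.0]), partial_charge=q2,
             radius=atom_radius),
    ]
    analytic = constants.COULOMB_KCAL_A * q1 * q2 / (eps * r)
    return ParameterizedStructure(atoms=atoms), analytic


# ---------------------------------------------------------------------------
# Ideal helix builder

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = math.radians(100.0)
HELIX_RADIUS = 2.3  # CA helix radius

# side chains built outward along the CA radial direction; (name, element,
# distance from CA, lateral offset) -- canonical rotamer-0-like geometry,
# adequate for electrostatics
SIDECHAINS: dict[str, list[tuple[str, str, float, float]]] = {
    "ALA": [("CB", "C", 1.53, 0.0)],
    "ASP": [("CB", "C", 1.53, 0.0), ("CG", "C", 2.9, 0.0),
            ("OD1", "O", 3.9, 0.9), ("OD2", "O", 3.9, -0.9)],
    "GLU": [("CB", "C", 1.53, 0.0), ("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.0),
            ("OE1", "O", 5.2, 0.9), ("OE2", "O", 5.2, -0.9)],
    "LYS": [("CB", "C", 1.53, 0.0), ("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.0),
            ("CE", "C", 5.5, 0.0), ("NZ", "N", 6.6, 0.0)],
    "ARG": [("CB", "C", 1.53, 0.0), ("CG", "C", 2.9, 0.0), ("CD", "C", 4.2, 0.0),
            ("NE", "N", 5.4, 0.0), ("CZ", "C", 6.5, 0.0),
            ("NH1", "N", 7.3, 1.0), ("NH2", "N", 7.3, -1.0)],
    "TYR": [("CB", "C", 1.53, 0.0), ("CG", "C", 2.9, 0.0),
            ("CD1", "C", 3.6, 1.2), ("CD2", "C", 3.6, -1.2),
            ("CE1", "C", 4.9, 1.2), ("CE2", "C", 4.9, -1.2),
            ("CZ", "C", 5.6, 0.0), ("OH", "O", 7.0, 0.0)],
    "HIS": [("CB", "C", 1.53, 0.0), ("CG", "C", 2.9, 0.0),
            ("ND1", "N", 3.8, 1.1), ("CD2", "C", 3.8, -1.1),
            ("CE1", "C", 5.0, 0.7), ("NE2", "N", 5.0, -0.7)],
    "CYS": [("CB", "C", 1.53, 0.0), ("SG", "S", 3.0, 0.0)],
}


def make_helix_in_slab(
    placements: Sequence[tuple[str, int]] = (),
    n_residues: int = 20,
    slab: MembraneSlab | None = None,
    seed: int = 0,
    z_offset: float = 0.0,
    xy_offset: tuple[float, float] = (0.0, 0.0),
    chain_id: str = "A",
) -> ParameterizedStructure:
    """Ideal poly-Ala alpha-helix along z with titratable residues placed at
    requested 1-based positions; deterministic for a given seed.

    The helix axis is the membrane normal, so a residue's z position
    controls whether its side chain sits in the acyl core, the headgroup
    band or the solvent.  ``slab`` is accepted for interface symmetry; the
    geometry itself does not depend on it.
    """
    del slab, seed  # geometry is fully deterministic
    placed: dict[int, str] = {}
    for resname, pos in placements:
        if not 1 <= pos <= n_residues:
            raise ValueError(f"placement position {pos} outside helix of {n_residues} residues")
        if pos in placed:
            raise ValueError(f"clashing placements at position {pos}")
        if resname not in SIDECHAINS:
            raise ValueError(f"unsupported residue {resname!r}")
        placed[pos] = resname

    atoms: list[Atom] = []
    serial = 1
    x0, y0 = xy_offset
    for i in range(1, n_residues + 1):
        theta = HELIX_TWIST * (i - 1)
        z = z_offset + HELIX_RISE * (i - 1)
        ca = np.array([x0 + HELIX_RADIUS * math.cos(theta), y0 + HELIX_RADIUS * math.sin(theta), z])
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        lateral = np.array([-math.sin(theta), math.cos(theta), 0.0])
        resname = placed.get(i, "ALA")
        backbone = [
            ("N", "N", ca - 0.8 * radial - np.array([0, 0, 0.9])),
            ("CA", "C", ca),
            ("C", "C", ca - 0.7 * radial + np.array([0, 0, 0.95])),
            ("O", "O", ca - 1.8 * radial + np.array([0, 0, 1.1])),
        ]
        for name, element, pos in backbone:
            atoms.append(Atom(serial=serial, name=name, element=element, residue_name=resname,
                              residue_number=i, chain_id=chain_id, position=pos))
            serial += 1
        for name, element, dist, lat in SIDECHAINS[resname]:
            pos = ca + dist * radial + lat * lateral
            atoms.append(Atom(serial=serial, name=name, element=element, residue_name=resname,
                              residue_number=i, chain_id=chain_id, position=pos))
            serial += 1
    return ParameterizedStructure(atoms=atoms)


def make_pseudo_trajectory(
    base: ParameterizedStructure,
    jitter_sigma: float,
    n_frames: int,
    seed: int = 0,
) -> list[ParameterizedStructure]:
    """Frames = base + iid Gaussian displacement per atom (sigma in A).

    A stand-in for MD snapshots: bonds are not preserved, which is
    acceptable for electrostatic-fluctuation statistics.
    """
    if jitter_sigma < 0:
        raise ValueError("jitter sigma must be non-negative")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        noise = rng.normal(0.0, jitter_sigma, size=(len(base.atoms), 3))
        atoms = []
        for a, d in zip(base.atoms, noise):
            atoms.append(Atom(
                serial=a.serial, name=a.name, element=a.element,
                residue_name=a.residue_name, residue_number=a.residue_number,
                chain_id=a.chain_id, position=a.position + d,
                partial_charge=a.partial_charge, radius=a.radius,
            ))
        frames.append(ParameterizedStructure(atoms=atoms, frame_id=f))
    return frames


def write_frames_pdb(frames: Sequence[ParameterizedStructure], path: str | Path) -> None:
    """Write frames as a multi-model PDB (fixed wwPDB columns)."""
    lines = []
    for f in frames:
        lines.append(f"MODEL     {f.frame_id + 1:>4d}")
        for a in f.atoms:
            lines.append(
                f"ATOM  {a.serial:>5d} {a.name:<4s} {a.residue_name:<3s} {a.chain_id:1s}"
                f"{a.residue_number:>4d}    {a.position[0]:>8.3f}{a.position[1]:>8.3f}"
                f"{a.position[2]:>8.3f}  1.00  0.00          {a.element:>2s}"
            )
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\nEND\n")


# ---------------------------------------------------------------------------
# Toy coding sequences

# fixed codon choice per amino acid (round-trippable reverse translation)
CODON: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def make_toy_cds(
    composition: dict[str, int],
    length: int,
    leader: str = "",
    filler: str = "A",
    seed: int = 0,
    cds_id: str = "toy",
):
    """ATG-initiated, stop-terminated CDS whose translated product is
    ``M + leader_rest + mature`` with the mature part containing exactly
    ``composition`` (letter -> count) in ``length`` residues, padded with
    ``filler``; residue order is shuffled deterministically by ``seed``."""
    from .seq_features import CodingSequence

    total = sum(composition.values())
    if total > length:
        raise ValueError(f"composition ({total}) exceeds mature length {length}")
    mature = []
    for aa, count in sorted(composition.items()):
        if aa not in CODON:
            raise ValueError(f"unknown amino acid {aa!r}")
        mature.extend([aa] * count)
    mature.extend([filler] * (length - total))
    rng = np.random.default_rng(seed)
    mature = [mature[i] for i in rng.permutation(len(mature))]

    if leader:
        if not leader.startswith("M"):
            raise ValueError("leader must start with Met")
        protein = leader + "".join(mature)
    else:
        # prepend the initiator Met so the requested census stays intact
        protein = "M" + "".join(mature)
    nts = "".join(CODON[aa] for aa in protein) + "TAA"
    return CodingSequence(nucleotides=nts, id=cds_id)


def reference_psbs_composition() -> dict:
    """Printed census targets for the algal PsbS precursor: a 41-residue
    chloroplast transit peptide carrying 5 Arg / 1 Lys / 1 His, and a
    210-residue mature protein with 42 ionogenic residues
    (9R, 12K, 4Y, 10E, 7D) and no His or Cys."""
    return {
        "transit_peptide_length": 41,
        "mature_length": 210,
        "transit_composition": {"R": 5, "K": 1, "H": 1},
        "mature_composition": {"R": 9, "K": 12, "Y": 4, "E": 10, "D": 7},
    }


def make_reference_like_cds(seed: int = 0):
    """Synthetic stand-in for the PsbS coding sequence: 756 nt -> 251-aa
    precursor -> 210-aa mature protein reproducing the printed ionogenic
    census.  The nucleotide sequence itself is constructed (the real CDS is
    not bundled); only the counts are meaningful."""
    ref = reference_psbs_composition()
    rng = np.random.default_rng(seed)
    tp = ["A"] * (ref["transit_peptide_length"] - 1)
    k = 0
    for aa, count in sorted(ref["transit_composition"].items()):
        for _ in range(count):
            tp[k] = aa
            k += 1
    tp = [tp[i] for i in rng.permutation(len(tp))]
    leader = "M" + "".join(tp)
    return make_toy_cds(
        ref["mature_composition"],
        length=ref["mature_length"],
        leader=leader,
        seed=seed,
        cds_id="synthetic-psbs-like",
    )


def ground_truth_sidecar(spec: FixtureSpec, truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"fixture": spec.kind, **truth}, indent=2) + "\n")
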