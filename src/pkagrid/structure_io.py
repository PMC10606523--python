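"""Structure input/output and electrostatic parameterization.

Reads PDB (via gemmi) and PQR structures, attaches PARSE-style partial
charges and Pauling van der Waals radii from a bundled YAML table, writes
PQR, and identifies titratable sites (Asp, Glu, Tyr, Lys, Arg, His, Cys and
chain termini) together with their two protonation charge states.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "ParameterizedStructure",
    "TitratableSite",
    "ParameterTable",
    "SitePolicy",
    "StructureError",
    "ParameterError",
    "read_structure",
    "read_frames",
    "write_pqr",
    "assign_parse",
    "find_titratable_sites",
    "load_parameter_table",
]

SOLVENT_RESIDUES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA"}


class StructureError(ValueError):
    """Malformed structure input."""


class ParameterError(ValueError):
    """Missing or inconsistent electrostatic parameters."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    partial_charge: float | None = None
    radius: float | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial} {self.name}: bad position {self.position}")
        if self.radius is not None and self.radius < 0:
            raise StructureError(f"atom {self.serial} {self.name}: negative radius")
        if not self.chain_id:
            raise StructureError(f"atom {self.serial} {self.name}: empty chain id")


@dataclass
class ParameterizedStructure:
    """An ordered atom list with optional charges/radii attached.

    ``frame_id`` is 0 for a single structure and the model number for
    trajectory snapshots read from a multi-model PDB.
    """

    atoms: list[Atom]
    frame_id: int = 0

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array(
            [a.partial_charge if a.partial_charge is not None else np.nan for a in self.atoms]
        )

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius if a.radius is not None else np.nan for a in self.atoms])

    @property
    def is_parameterized(self) -> bool:
        return all(a.partial_charge is not None and a.radius is not None for a in self.atoms)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Group atom indices by (chain, residue_number, residue_name), file order."""
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(i)
        return list(groups.items())

    def polar_sidechain_indices(self) -> np.ndarray:
        """Indices of side-chain O and N atoms (backbone N/O/OXT excluded)."""
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.element in ("N", "O") and a.name not in BACKBONE_ATOMS
        ]
        return np.array(idx, dtype=int)


@dataclass
class TitratableSite:
    """A protonatable residue with model pKa and its two charge states.

    ``protonated_charges`` / ``deprotonated_charges`` map atom name to charge
    (e) over the variant atoms; their sums differ by exactly +1 e.
    ``atom_positions`` maps the same atom names to coordinates.
    """

    site_id: str
    residue_type: str
    acid_or_base: str
    model_pka: float
    protonated_charges: dict[str, float]
    deprotonated_charges: dict[str, float]
    chain_id: str
    residue_number: int
    atom_positions: dict[str, np.ndarray] = field(default_factory=dict)
    atom_indices: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        dq = sum(self.protonated_charges.values()) - sum(self.deprotonated_charges.values())
        if abs(dq - 1.0) > 1e-9:
            raise ParameterError(f"site {self.site_id}: protonated-deprotonated sum {dq}, not +1")
        if self.acid_or_base not in ("acid", "base"):
            raise ParameterError(f"site {self.site_id}: acid_or_base={self.acid_or_base!r}")

    @property
    def delta_charges(self) -> dict[str, float]:
        return {
            k: self.protonated_charges[k] - self.deprotonated_charges[k]
            for k in self.protonated_charges
        }

    def charge_set(self, which: str = "delta") -> list[tuple[np.ndarray, float]]:
        """(position, q) pairs for 'delta', 'protonated' or 'deprotonated' charges."""
        table = {
            "delta": self.delta_charges,
            "protonated": self.protonated_charges,
            "deprotonated": self.deprotonated_charges,
        }[which]
        return [(self.atom_positions[n], q) for n, q in table.items()]


# ---------------------------------------------------------------------------
# Parameter table


@dataclass
class ParameterTable:
    radii_by_element: dict[str, float]
    backbone: dict[str, float]
    residues: dict[str, dict]
    cter_patch: dict
    nter_patch: dict
    version: int = 1

    def residue_charges(self, resname: str, variant: str | None = None) -> dict[str, float]:
        """Full atom-name -> charge map for one residue (one variant if titratable)."""
        if resname not in self.residues:
            raise ParameterError(f"residue {resname} not in parameter table")
        entry = self.residues[resname]
        charges = dict(self.backbone)
        charges.update(entry.get("atoms", {}))
        if entry.get("titratable"):
            if variant is None:
                variant = "deprotonated" if entry["acid_or_base"] == "acid" else "protonated"
            charges.update(entry[variant])
        return charges

    def formal_charge(self, resname: str, variant: str | None = None) -> int:
        entry = self.residues[resname]
        if not entry.get("titratable"):
            return int(entry.get("formal_charge", 0))
        if variant is None:
            variant = "deprotonated" if entry["acid_or_base"] == "acid" else "protonated"
        if entry["acid_or_base"] == "acid":
            return -1 if variant == "deprotonated" else 0
        return 1 if variant == "protonated" else 0

    def radius(self, atom_name: str, element: str) -> float:
        if element in self.radii_by_element:
            return self.radii_by_element[element]
        raise ParameterError(f"no radius for element {element!r} (atom {atom_name})")


def load_parameter_table(path: str | Path | None = None) -> ParameterTable:
    """Load the bundled PARSE-style table, or a user-supplied YAML file."""
    if path is None:
        ref = importlib.resources.files("pkagrid.data").joinpath("parse_params.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    table = ParameterTable(
        radii_by_element=raw["radii_by_element"],
        backbone=raw["backbone"],
        residues=raw["residues"],
        cter_patch=raw.get("cter_patch", {}),
        nter_patch=raw.get("nter_patch", {}),
        version=raw.get("version", 1),
    )
    _validate_table(table)
    return table


def _validate_table(table: ParameterTable) -> None:
    for name, entry in table.residues.items():
        if entry.get("titratable"):
            for variant in ("protonated", "deprotonated"):
                total = sum(table.residue_charges(name, variant).values())
                expected = table.formal_charge(name, variant)
                if abs(total - expected) > 1e-6:
                    raise ParameterError(
                        f"{name} {variant}: charge sum {total:.6f} != formal {expected}"
                    )
        else:
            total = sum(table.residue_charges(name).values())
            if abs(total - entry.get("formal_charge", 0)) > 1e-6:
                raise ParameterError(f"{name}: charge sum {total:.6f} != formal charge")


# ---------------------------------------------------------------------------
# Readers / writers


def _looks_like_path(source: str | Path) -> bool:
    if isinstance(source, Path):
        return True
    return "\n" not in source and len(source) < 4096


def _source_text(source: str | Path) -> str:
    if _looks_like_path(source):
        return Path(source).read_text()
    return source


def _detect_format(source: str | Path, text: str) -> str:
    if _looks_like_path(source):
        suffix = Path(source).suffix.lower()
        if suffix == ".pqr":
            return "pqr"
        if suffix in (".pdb", ".ent"):
            return "pdb"
    # PQR rows have ten or eleven whitespace-separated fields ending in two floats
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            fields = line.split()
            if len(fields) in (10, 11):
                try:
                    float(fields[-1]), float(fields[-2])
                    # PDB fixed columns put occupancy/B-factor there too; PQR
                    # lines are whitespace-delimited and shorter than 80 cols
                    if len(line) < 70 or len(fields) == 11:
                        return "pqr"
                except ValueError:
                    pass
            return "pdb"
    raise StructureError("no ATOM/HETATM records found")


def read_structure(
    source: str | Path,
    fmt: str | None = None,
    strip_solvent: bool = False,
    model: int = 0,
) -> ParameterizedStructure:
    """Read a PDB or PQR structure (first model unless ``model`` given).

    PDB atoms come back with charges/radii unset; PQR charges and radii are
    carried through.  Alternate locations keep the highest-occupancy copy.
    """
    text = _source_text(source)
    fmt = fmt or _detect_format(source, text)
    if fmt == "pqr":
        return _read_pqr(text, strip_solvent=strip_solvent)
    frames = read_frames(text, fmt="pdb", strip_solvent=strip_solvent)
    if model >= len(frames):
        raise StructureError(f"model {model} not present ({len(frames)} models)")
    return frames[model]


def read_frames(
    source: str | Path, fmt: str | None = None, strip_solvent: bool = False
) -> list[ParameterizedStructure]:
    """Read all models of a (multi-model) PDB as a list of frames."""
    text = _source_text(source)
    st = gemmi.read_pdb_string(text)
    frames = []
    for imodel, gmodel in enumerate(st):
        atoms: list[Atom] = []
        seen: set[tuple[str, int, str]] = set()
        for chain in gmodel:
            for res in chain:
                if strip_solvent and res.name.strip() in SOLVENT_RESIDUES:
                    continue
                best: dict[str, gemmi.Atom] = {}
                for ga in res:
                    prev = best.get(ga.name)
                    if prev is None or (ga.occ or 0.0) > (prev.occ or 0.0):
                        best[ga.name] = ga
                for ga in res:
                    if best[ga.name] is not ga:
                        continue
                    key = (chain.name, res.seqid.num, ga.name)
                    if key in seen:
                        raise StructureError(f"duplicate atom {key}")
                    seen.add(key)
                    atoms.append(
                        Atom(
                            serial=ga.serial,
                            name=ga.name,
                            element=ga.element.name.upper(),
                            residue_name=res.name.strip(),
                            residue_number=res.seqid.num,
                            chain_id=chain.name or "A",
                            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        )
                    )
        if atoms:
            frames.append(ParameterizedStructure(atoms=atoms, frame_id=imodel))
    if not frames:
        raise StructureError("no atoms parsed from PDB input")
    return frames


def _read_pqr(text: str, strip_solvent: bool = False) -> ParameterizedStructure:
    atoms: list[Atom] = []
    seen: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        try:
            if len(fields) == 11:
                _, serial, name, resname, chain, resnum, x, y, z, q, r = fields
            elif len(fields) == 10:
                _, serial, name, resname, resnum, x, y, z, q, r = fields
                chain = "A"
            else:
                raise ValueError(f"{len(fields)} fields")
            atom = Atom(
                serial=int(serial),
                name=name,
                element=_element_from_name(name),
                residue_name=resname,
                residue_number=int(resnum),
                chain_id=chain,
                position=np.array([float(x), float(y), float(z)]),
                partial_charge=float(q),
                radius=float(r),
            )
        except (ValueError, StructureError) as exc:
            raise StructureError(f"malformed PQR record at line {lineno}: {exc}") from exc
        if strip_solvent and atom.residue_name in SOLVENT_RESIDUES:
            continue
        key = (atom.chain_id, atom.residue_number, atom.name)
        if key in seen:
            raise StructureError(f"duplicate atom {key} at line {lineno}")
        seen.add(key)
        atoms.append(atom)
    if not atoms:
        raise StructureError("no ATOM/HETATM records in PQR input")
    return ParameterizedStructure(atoms=atoms)


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def write_pqr(structure: ParameterizedStructure, path: str | Path | None = None) -> str:
    """Write a whitespace-delimited PQR; returns the text (and writes if path given)."""
    lines = []
    for a in structure.atoms:
        if a.partial_charge is None or a.radius is None:
            raise ParameterError(f"atom {a.serial} {a.name} has no charge/radius; assign first")
        lines.append(
            f"ATOM  {a.serial:>5d} {a.name:<4s} {a.residue_name:<4s}{a.chain_id:1s} "
            f"{a.residue_number:>4d} {a.position[0]:>8.3f} {a.position[1]:>8.3f} "
            f"{a.position[2]:>8.3f} {a.partial_charge:>8.4f} {a.radius:>7.4f}"
        )
    text = "\n".join(lines) + "\nEND\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Parameter assignment


def assign_parse(
    structure: ParameterizedStructure,
    table: ParameterTable | None = None,
    variants: Mapping[tuple[str, int], str] | None = None,
) -> ParameterizedStructure:
    """Attach PARSE-style charges and radii to every atom.

    Titratable residues get their charged reference variant by default
    (acids deprotonated, bases protonated); ``variants`` overrides per
    (chain_id, residue_number).  Unknown residues or atom names raise a
    ParameterError listing every offender -- atoms are never silently
    zero-charged.
    """
    table = table or load_parameter_table()
    variants = variants or {}
    offenders: list[str] = []
    new_atoms = [replace(a) for a in structure.atoms]
    for (chain, resnum, resname), indices in structure.residues():
        names = {structure.atoms[i].name for i in indices}
        has_oxt = "OXT" in names
        try:
            charges = table.residue_charges(resname, variants.get((chain, resnum)))
            expected = table.formal_charge(resname, variants.get((chain, resnum)))
        except ParameterError:
            offenders.append(f"{chain}/{resnum}/{resname}: unknown residue")
            continue
        if has_oxt and table.cter_patch:
            charges.update(table.cter_patch["deprotonated"])
            expected -= 1
        assigned = 0.0
        for i in indices:
            atom = new_atoms[i]
            if atom.element == "H":
                atom.partial_charge = 0.0  # polar-H charges are folded into heavy atoms
                atom.radius = table.radius(atom.name, "H")
                continue
            if atom.name not in charges:
                offenders.append(f"{chain}/{resnum}/{resname}: unknown atom {atom.name}")
                continue
            atom.partial_charge = charges[atom.name]
            atom.radius = table.radius(atom.name, atom.element)
            assigned += atom.partial_charge
        missing = set(charges) - names
        if not offenders and missing:
            # partial residues (chain breaks) are tolerated only if the
            # missing atoms are neutral
            if any(abs(charges[m]) > 1e-12 for m in missing):
                offenders.append(
                    f"{chain}/{resnum}/{resname}: missing charged atoms {sorted(missing)}"
                )
        if not offenders and abs(assigned - expected) > 1e-6:
            offenders.append(
                f"{chain}/{resnum}/{resname}: charge sum {assigned:.6f} != formal {expected}"
            )
    if offenders:
        raise ParameterError("parameter assignment failed:\n  " + "\n  ".join(offenders))
    return ParameterizedStructure(atoms=new_atoms, frame_id=structure.frame_id)


# ---------------------------------------------------------------------------
# Titratable-site discovery


@dataclass
class SitePolicy:
    """Which residue types become titratable sites.

    ``tyr_whitelist`` restricts Tyr sites to explicit (chain, residue_number)
    pairs when Tyr is not globally included, mirroring protocols that
    titrate only selected tyrosines.
    """

    residues: frozenset[str] = frozenset({"ASP", "GLU", "TYR", "LYS", "ARG"})
    tyr_whitelist: frozenset[tuple[str, int]] | None = None
    include_termini: bool = False

    def wants(self, resname: str, chain: str, resnum: int) -> bool:
        if resname in self.residues:
            return True
        if resname == "TYR" and self.tyr_whitelist is not None:
            return (chain, resnum) in self.tyr_whitelist
        return False


def find_titratable_sites(
    structure: ParameterizedStructure,
    policy: SitePolicy | None = None,
    table: ParameterTable | None = None,
) -> list[TitratableSite]:
    """Identify titratable sites, ordered by (chain, residue_number)."""
    if not structure.is_parameterized:
        raise ParameterError("structure must be parameterized before site discovery")
    policy = policy or SitePolicy()
    table = table or load_parameter_table()
    sites: list[TitratableSite] = []
    for (chain, resnum, resname), indices in structure.residues():
        entry = table.residues.get(resname)
        if entry is None or not entry.get("titratable"):
            continue
        if not policy.wants(resname, chain, resnum):
            continue
        name_to_idx = {structure.atoms[i].name: i for i in indices}
        variant_atoms = entry["variant_atoms"]
        missing = [n for n in variant_atoms if n not in name_to_idx]
        if missing:
            raise StructureError(
                f"titratable residue {chain}/{resnum}/{resname} missing side-chain atoms {missing}"
            )
        sites.append(
            TitratableSite(
                site_id=f"{chain}{resnum}{resname}",
                residue_type=resname,
                acid_or_base=entry["acid_or_base"],
                model_pka=float(entry["model_pka"]),
                protonated_charges={n: float(entry["protonated"][n]) for n in variant_atoms},
                deprotonated_charges={n: float(entry["deprotonated"][n]) for n in variant_atoms},
                chain_id=chain,
                residue_number=resnum,
                atom_positions={
                    n: structure.atoms[name_to_idx[n]].position.copy() for n in variant_atoms
                },
                atom_indices={n: name_to_idx[n] for n in variant_atoms},
            )
        )
    if policy.include_termini:
        sites.extend(_terminus_sites(structure, table))
    sites.sort(key=lambda s: (s.chain_id, s.residue_number))
    return sites


def _terminus_sites(
    structure: ParameterizedStructure, table: ParameterTable
) -> list[TitratableSite]:
    """N-terminal amine per chain; C-terminal carboxylate where OXT exists."""
    sites = []
    by_chain: dict[str, list[tuple[tuple[str, int, str], list[int]]]] = {}
    for item in structure.residues():
        by_chain.setdefault(item[0][0], []).append(item)
    for chain, residues in by_chain.items():
        (first_key, first_idx), (last_key, last_idx) = residues[0], residues[-1]
        names_first = {structure.atoms[i].name: i for i in first_idx}
        if "N" in names_first and table.nter_patch:
            sites.append(
                TitratableSite(
                    site_id=f"{chain}{first_key[1]}NTER",
                    residue_type="NTER",
                    acid_or_base="base",
                    model_pka=float(table.nter_patch.get("model_pka", 7.5)),
                    protonated_charges={"N": float(table.nter_patch["protonated"]["N"])},
                    deprotonated_charges={"N": float(table.nter_patch["deprotonated"]["N"])},
                    chain_id=chain,
                    residue_number=first_key[1],
                    atom_positions={"N": structure.atoms[names_first["N"]].position.copy()},
                    atom_indices={"N": names_first["N"]},
                )
            )
        names_last = {structure.atoms[i].name: i for i in last_idx}
        if "OXT" in names_last and table.cter_patch:
            patch = table.cter_patch
            keys = [k for k in patch["protonated"]]
            if all(k in names_last for k in keys):
                sites.append(
                    TitratableSite(
                        site_id=f"{chain}{last_key[1]}CTER",
                        residue_type="CTER",
                        acid_or_base="acid",
                        model_pka=float(patch.get("model_pka", 3.8)),
                        protonated_charges={k: float(patch["protonated"][k]) for k in keys},
                        deprotonated_charges={k: float(patch["deprotonated"][k]) for k in keys},
                        chain_id=chain,
                        residue_number=last_key[1],
                        atom_positions={
                            k: structure.atoms[names_last[k]].position.copy() for k in keys
                        },
                        atom_indices={k: names_last[k] for k in keys},
                    )
                )
    return sites


def background_charge_set(
    structure: ParameterizedStructure, sites: Sequence[TitratableSite]
) -> list[tuple[np.ndarray, float]]:
    """All permanent partial charges: every atom except the variable-charge
    atoms of every titratable site."""
    excluded = {idx for s in sites for idx in s.atom_indices.values()}
    out = []
    for i, a in enumerate(structure.atoms):
        if i in excluded:
            continue
        if a.partial_charge is None:
            raise ParameterError("structure not fully parameterized")
        if abs(a.partial_charge) > 1e-12:
            out.append((a.position, a.partial_charge))
    return out
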