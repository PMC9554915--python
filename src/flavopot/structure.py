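"""Protein structure model: PDB parsing and flavin cofactor geometry.

The internal model is deliberately small: chains of residues of named,
element-typed atoms in Å coordinates, plus a list of hetero groups.  PDB
records are read through gemmi; on top of that this module applies the
conventions used throughout the package:

* only the first model of multi-model files is read;
* for alternate locations, only the highest-occupancy altloc is retained
  per atom name (ties prefer altloc ``A``);
* hydrogens are retained in the model but excluded from every distance
  computation and atom count downstream;
* waters and non-flavin hetero groups never enter residue-environment
  descriptors.

A located flavin (FMN or FAD) is summarised as a :class:`FlavinSite`: the
isoalloxazine ring-system atoms, their unweighted barycenter (the center of
the r1 descriptor sphere) and the N5 position (the reference point for the
nearest-residue descriptors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .properties import CANONICAL_RESIDUES, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Isoalloxazine ring-system atom names (three fused rings, including the
#: C7M/C8M methyls and the O2/O4 carbonyl oxygens).
ISOALLOXAZINE_RING_ATOMS: tuple[str, ...] = (
    "N1", "C2", "O2", "N3", "C4", "O4", "C4A", "N5", "C5A",
    "C6", "C7", "C7M", "C8", "C8M", "C9", "C9A", "N10",
)

#: FAD chemical-component aliases for two ring atoms.
RING_ATOM_ALIASES: dict[str, str] = {"C4X": "C4A", "C5X": "C5A"}

FLAVIN_RESIDUE_NAMES: frozenset[str] = frozenset({"FMN", "FAD"})

_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


class StructureParseError(ValueError):
    """No parseable coordinate records in the input."""


class NoCofactorError(ValueError):
    """Structure contains no FMN/FAD hetero group."""


class MissingRingAtomError(ValueError):
    """A flavin hetero group lacks a required isoalloxazine atom."""


@dataclass(frozen=True)
class Atom:
    """One atom: PDB name, element symbol, coordinates in Å."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """A residue (or hetero group) with its retained atoms in file order."""

    name: str
    chain_id: str
    seq_number: int
    atoms: list[Atom] = field(default_factory=list)
    is_standard_aa: bool = False

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if not a.is_hydrogen]
        return np.asarray(coords, dtype=float).reshape(len(coords), 3)

    def min_distance(self, point: np.ndarray) -> float:
        """Minimum non-hydrogen-atom Euclidean distance to ``point``."""
        coords = self.heavy_coords()
        if coords.size == 0:
            return np.inf
        return float(np.min(np.linalg.norm(coords - np.asarray(point, float), axis=1)))


@dataclass
class ProteinStructure:
    """Chains of protein residues plus non-polymer hetero groups."""

    chains: dict[str, list[Residue]]
    hetero_groups: list[Residue]
    source_id: str = ""

    def protein_residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues]

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.protein_residues() if r.is_standard_aa]

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain's standard residues, author order."""
        return "".join(
            THREE_TO_ONE[r.name] for r in self.chains.get(chain_id, []) if r.is_standard_aa
        )


@dataclass
class FlavinSite:
    """A located FMN/FAD cofactor and its isoalloxazine geometry."""

    cofactor_kind: str
    ring_atoms: dict[str, np.ndarray]
    barycenter: np.ndarray
    n5_coord: np.ndarray
    chain_id: str

    def __post_init__(self):
        if "N5" not in self.ring_atoms:
            raise MissingRingAtomError("N5")


def ring_barycenter(ring_atoms: dict[str, np.ndarray]) -> np.ndarray:
    """Unweighted arithmetic mean of the ring-atom coordinates."""
    if not ring_atoms:
        raise ValueError("empty ring-atom set")
    return np.mean(np.asarray(list(ring_atoms.values()), dtype=float), axis=0)


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties prefer altloc A/blank."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        else:
            incumbent = best[atom.name]
            key = lambda a: (a.occupancy, a.altloc in ("", "A"))
            if key(atom) > key(incumbent):
                best[atom.name] = atom
    return [best[name] for name in order]


def parse_structure(pdb_text: str, source_id: str = "") -> ProteinStructure:
    """Parse PDB text into the internal structure model.

    Standard-residue ATOM records are grouped per chain in file order;
    HETATM groups (cofactors, waters, ligands) are collected separately.
    Unknown residue names appearing as ATOM records are kept with
    ``is_standard_aa=False`` and a logged warning.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureParseError("no models in input")
    st.setup_entities()
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    hetero: list[Residue] = []
    n_atoms = 0
    for chain in model:
        for res in chain:
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            if not atoms:
                continue
            atoms = _dedupe_altlocs(atoms)
            n_atoms += len(atoms)
            is_het = res.het_flag == "H"
            is_standard = res.name in CANONICAL_RESIDUES
            residue = Residue(
                name=res.name,
                chain_id=chain.name,
                seq_number=res.seqid.num,
                atoms=atoms,
                is_standard_aa=is_standard and not is_het,
            )
            if is_het:
                hetero.append(residue)
            else:
                if not is_standard:
                    logger.warning(
                        "%s: unknown residue %s %s%d kept as non-standard",
                        source_id, res.name, chain.name, res.seqid.num,
                    )
                chains.setdefault(chain.name, []).append(residue)
    if n_atoms == 0:
        raise StructureParseError("no parseable coordinate records")
    return ProteinStructure(chains=chains, hetero_groups=hetero, source_id=source_id)


def _owning_chain(structure: ProteinStructure, barycenter: np.ndarray) -> str:
    """Protein chain whose residues come closest (any heavy atom) to a point.

    The choice of "associated chain" for a cofactor is a package convention
    (nearest chain); it is configurable by callers that know better.
    """
    best_chain, best_dist = "", np.inf
    for chain_id, residues in structure.chains.items():
        for res in residues:
            d = res.min_distance(barycenter)
            if d < best_dist:
                best_chain, best_dist = chain_id, d
    if not best_chain:
        raise ValueError("structure has no protein residues with heavy atoms")
    return best_chain


def locate_flavin_sites(structure: ProteinStructure) -> list[FlavinSite]:
    """One :class:`FlavinSite` per FMN/FAD hetero group, in file order."""
    sites: list[FlavinSite] = []
    for group in structure.hetero_groups:
        if group.name not in FLAVIN_RESIDUE_NAMES:
            continue
        ring: dict[str, np.ndarray] = {}
        for atom in group.atoms:
            name = RING_ATOM_ALIASES.get(atom.name, atom.name)
            if name in ISOALLOXAZINE_RING_ATOMS and name not in ring:
                ring[name] = atom.coord
        missing = [n for n in ISOALLOXAZINE_RING_ATOMS if n not in ring]
        if missing:
            raise MissingRingAtomError(
                f"{group.name} {group.chain_id}{group.seq_number}: missing ring "
                f"atom(s) {', '.join(missing)}"
            )
        center = ring_barycenter(ring)
        sites.append(
            FlavinSite(
                cofactor_kind=group.name,
                ring_atoms=ring,
                barycenter=center,
                n5_coord=ring["N5"],
                chain_id=_owning_chain(structure, center),
            )
        )
    return sites


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize the retained atoms back to minimal PDB text.

    Used for round-trip testing and for exporting synthetic fixtures; only
    ATOM/HETATM/TER/END records are emitted.
    """
    lines: list[str] = []
    serial = 1

    def emit(record: str, res: Residue):
        nonlocal serial
        for atom in res.atoms:
            x, y, z = atom.coord
            lines.append(
                f"{record:<6}{serial:>5} {_format_atom_name(atom.name, atom.element)}"
                f"{atom.altloc or ' '}{res.name:>3} {res.chain_id[:1] or 'A'}"
                f"{res.seq_number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2}"
            )
            serial += 1

    for chain_id, residues in structure.chains.items():
        for res in residues:
            emit("ATOM", res)
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for group in structure.hetero_groups:
        emit("HETATM", group)
    lines.append("END")
    return "\n".join(lines) + "\n"
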