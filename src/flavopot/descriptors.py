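"""Region and N5-environment descriptors of the flavin neighbourhood.

Three spatial scopes share one set of 55 physicochemical descriptors:

* ``Protein.X`` — every standard residue of the structure;
* ``Bar.X`` — residues with any heavy atom within ``r1`` of the
  isoalloxazine barycenter;
* ``Ring.X`` — residues with any heavy atom within ``r2`` of *any*
  isoalloxazine ring atom (union of per-atom spheres).

The 55 values per scope are: 20 residue-type counts, 11 class counts
(total, polar, apolar, charged, positive, negative, hydrophobic, aromatic,
small, H-bond donor/acceptor residues), 8 property sums and 8 property means
(volume, flexibility, hydrophobicity, steric hindrance, polarity index,
isoelectric point, helix and sheet propensity), 4 side-chain element-count
sums and 4 derived counts (net formal charge, aromatic/donor/acceptor atom
counts).  The ``Ring`` scope adds three atom counts (N/O/C protein atoms
within ``r2`` of the ring, each atom counted once).

The N5 block describes the residue nearest to the flavin N5 atom
(``N5_nearest_X``: 20-dim identity indicator + 8 property values) and that
residue together with its two sequence neighbours (``Around_N5.X``:
identity counts + property sums).

All distances are Euclidean in Å over non-hydrogen atoms; empty regions
yield all-zero blocks (means included).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable

import numpy as np

from .properties import (
    CANONICAL_RESIDUES,
    CLASS_NAMES,
    ELEMENT_COUNT_NAMES,
    PROPERTY_NAMES,
    PropertyTable,
)
from .structure import FlavinSite, ProteinStructure, Residue

PROPERTY_LABELS: dict[str, str] = {
    "volume": "Volume",
    "flexibility": "Flexibility",
    "hydrophobicity": "Hydrophobicity",
    "steric_hindrance": "Steric hindrance",
    "polarity_index": "Polarity index",
    "isoelectric_point": "Isoelectric point",
    "helix_propensity": "Helix propensity",
    "sheet_propensity": "Sheet propensity",
}

ELEMENT_LABELS: dict[str, str] = {
    "n_N": "nNats in side chain",
    "n_O": "nOats in side chain",
    "n_C": "nCats in side chain",
    "n_S": "nSats in side chain",
}

#: (feature label, class flag) pairs for the 11 residue-count descriptors.
COUNT_DESCRIPTORS: tuple[tuple[str, str | None], ...] = (
    ("ResTot", None),
    ("ResPolar", "polar"),
    ("ResApolar", "apolar"),
    ("ResCharged", "charged"),
    ("ResPositive", "positive"),
    ("ResNegative", "negative"),
    ("ResHydrophobic", "hydrophobic"),
    ("ResAromatic", "aromatic"),
    ("ResSmall", "small"),
    ("ResHBondDonor", "hbond_donor"),
    ("ResHBondAcceptor", "hbond_acceptor"),
)

#: (feature label, per-residue atom-count column) for 3 of the 4 derived counts;
#: the fourth derived descriptor is the net formal charge.
DERIVED_ATOM_DESCRIPTORS: tuple[tuple[str, str], ...] = (
    ("nAromatic atoms", "n_aromatic_atoms"),
    ("nHBondDonor atoms", "n_donor_atoms"),
    ("nHBondAcceptor atoms", "n_acceptor_atoms"),
)

RING_ATOM_COUNT_NAMES: tuple[str, ...] = (
    "Nitrogen_Around", "Oxygen_Around", "Carbon_Around",
)


def region_feature_names() -> list[str]:
    """The 55 bare (un-prefixed) region descriptor names, fixed order."""
    names: list[str] = list(CANONICAL_RESIDUES)
    names += [label for label, _ in COUNT_DESCRIPTORS]
    names += [PROPERTY_LABELS[p] for p in PROPERTY_NAMES]
    names += [f"Mean {PROPERTY_LABELS[p]}" for p in PROPERTY_NAMES]
    names += [ELEMENT_LABELS[e] for e in ELEMENT_COUNT_NAMES]
    names += ["Net charge"] + [label for label, _ in DERIVED_ATOM_DESCRIPTORS]
    assert len(names) == 55
    return names


def n5_feature_names() -> list[str]:
    """The 28 bare N5-block names: 20 identities + 8 properties."""
    return list(CANONICAL_RESIDUES) + [PROPERTY_LABELS[p] for p in PROPERTY_NAMES]


def _residue_names(residues: Iterable[Residue | str]) -> list[str]:
    return [r if isinstance(r, str) else r.name for r in residues]


def region_descriptors(
    residues: Iterable[Residue | str], table: PropertyTable | None = None
) -> OrderedDict[str, float]:
    """The 55 region descriptors for a set of standard residues.

    Accepts :class:`Residue` objects or bare 3-letter codes; only residue
    identity matters.  Order-free: any permutation of the input yields the
    same values.  An empty region returns all zeros (means included).
    """
    table = table or PropertyTable.default()
    # sorted so that sums are bit-identical for any input order
    names = sorted(_residue_names(residues))
    out: OrderedDict[str, float] = OrderedDict()
    for code in CANONICAL_RESIDUES:
        out[code] = float(names.count(code))
    total = len(names)
    out["ResTot"] = float(total)
    for label, cls in COUNT_DESCRIPTORS[1:]:
        members = table.class_members(cls)
        out[label] = float(sum(1 for n in names if n in members))
    for prop in PROPERTY_NAMES:
        out[PROPERTY_LABELS[prop]] = float(sum(table.value(n, prop) for n in names))
    for prop in PROPERTY_NAMES:
        label = PROPERTY_LABELS[prop]
        out[f"Mean {label}"] = out[label] / total if total else 0.0
    for elem in ELEMENT_COUNT_NAMES:
        out[ELEMENT_LABELS[elem]] = float(sum(table.value(n, elem) for n in names))
    out["Net charge"] = out["ResPositive"] - out["ResNegative"]
    for label, col in DERIVED_ATOM_DESCRIPTORS:
        out[label] = float(sum(table.value(n, col) for n in names))
    return out


def _protein_heavy_atoms(structure: ProteinStructure):
    """Stack heavy atoms of all standard residues: (coords, residue idx, elements)."""
    coords, idx, elements = [], [], []
    residues = structure.standard_residues()
    for i, res in enumerate(residues):
        for atom in res.heavy_atoms():
            coords.append(atom.coord)
            idx.append(i)
            elements.append(atom.element.upper())
    coords = np.asarray(coords, dtype=float).reshape(len(coords), 3)
    return residues, coords, np.asarray(idx, dtype=int), np.asarray(elements)


def residues_in_sphere(
    structure: ProteinStructure, center: np.ndarray, radius: float
) -> list[Residue]:
    """Standard residues with ≥1 heavy atom within ``radius`` Å of ``center``.

    Cofactors, waters and other hetero groups are never part of the result.
    Returned in structure order (chain insertion order, then residue order).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    residues, coords, idx, _ = _protein_heavy_atoms(structure)
    if coords.size == 0:
        return []
    dist = np.linalg.norm(coords - np.asarray(center, float), axis=1)
    hit = np.unique(idx[dist <= radius])
    return [residues[i] for i in hit]


def ring_union_region(
    structure: ProteinStructure, site: FlavinSite, r2: float
) -> list[Residue]:
    """Union over ring atoms ``a`` of ``residues_in_sphere(structure, a, r2)``."""
    if r2 < 0:
        raise ValueError("r2 must be non-negative")
    residues, coords, idx, _ = _protein_heavy_atoms(structure)
    if coords.size == 0:
        return []
    centers = np.asarray(list(site.ring_atoms.values()), dtype=float)
    dist = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    hit = np.unique(idx[np.any(dist <= r2, axis=1)])
    return [residues[i] for i in hit]


def ring_atom_counts(
    structure: ProteinStructure, site: FlavinSite, r2: float
) -> tuple[int, int, int]:
    """(N, O, C) protein-atom counts within ``r2`` of any ring atom.

    Each atom is counted once even if it falls inside several per-ring-atom
    spheres; hydrogens and cofactor atoms are excluded.
    """
    if r2 < 0:
        raise ValueError("r2 must be non-negative")
    _, coords, _, elements = _protein_heavy_atoms(structure)
    if coords.size == 0:
        return (0, 0, 0)
    centers = np.asarray(list(site.ring_atoms.values()), dtype=float)
    dist = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    within = np.any(dist <= r2, axis=1)
    return (
        int(np.sum(within & (elements == "N"))),
        int(np.sum(within & (elements == "O"))),
        int(np.sum(within & (elements == "C"))),
    )


def n5_nearest_residue(structure: ProteinStructure, site: FlavinSite) -> Residue:
    """Standard residue minimising the heavy-atom distance to the N5 atom.

    Exact ties are broken by structure order (chain order, then lower
    sequence number), i.e. the first residue encountered wins.
    """
    best: Residue | None = None
    best_dist = np.inf
    for res in structure.standard_residues():
        d = res.min_distance(site.n5_coord)
        if d < best_dist:
            best, best_dist = res, d
    if best is None:
        raise ValueError("structure has no standard residues")
    return best


def _sequence_neighbors(structure: ProteinStructure, res: Residue) -> list[Residue]:
    """``res`` plus its immediate predecessors/successors in its chain list."""
    chain = structure.chains.get(res.chain_id, [])
    standard = [r for r in chain if r.is_standard_aa]
    i = next(
        (k for k, r in enumerate(standard)
         if r.seq_number == res.seq_number and r.name == res.name), None,
    )
    if i is None:
        return [res]
    return standard[max(0, i - 1): i + 2]


def n5_descriptors(
    structure: ProteinStructure,
    site: FlavinSite,
    table: PropertyTable | None = None,
) -> tuple[OrderedDict[str, float], OrderedDict[str, float]]:
    """(``N5_nearest`` block, ``Around_N5`` block), 28 bare-named values each.

    The nearest block is a one-hot residue identity plus that residue's 8
    property values.  The around block counts/sums over the nearest residue
    and its two sequence neighbours (chain termini contribute fewer).
    """
    table = table or PropertyTable.default()
    nearest = n5_nearest_residue(structure, site)
    near_block: OrderedDict[str, float] = OrderedDict()
    for code in CANONICAL_RESIDUES:
        near_block[code] = 1.0 if nearest.name == code else 0.0
    for prop in PROPERTY_NAMES:
        near_block[PROPERTY_LABELS[prop]] = float(table.value(nearest.name, prop))

    triple = _sequence_neighbors(structure, nearest)
    names = [r.name for r in triple]
    around_block: OrderedDict[str, float] = OrderedDict()
    for code in CANONICAL_RESIDUES:
        around_block[code] = float(names.count(code))
    for prop in PROPERTY_NAMES:
        around_block[PROPERTY_LABELS[prop]] = float(
            sum(table.value(n, prop) for n in names)
        )
    return near_block, around_block
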