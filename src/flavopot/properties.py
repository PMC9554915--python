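"""Per-amino-acid physicochemical property table and residue class sets.

Every counting and summing descriptor in the package resolves its lookups
through the :class:`PropertyTable` bundled here.  The table is a plain TSV
data file (one row per canonical residue) assembled from standard published
scales — residue volume, flexibility, hydropathy, steric parameter, polarity,
isoelectric point and secondary-structure propensities — plus side-chain
heavy-atom element counts and overlapping class flags (polar, charged,
aromatic, ...).  Users may swap in their own table with the same schema via
:meth:`PropertyTable.from_file`.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from pathlib import Path

import pandas as pd

#: 3-letter codes of the 20 canonical amino acids, alphabetical.
CANONICAL_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Numeric (scalar) property columns, in the order used by descriptor blocks.
PROPERTY_NAMES: tuple[str, ...] = (
    "volume",
    "flexibility",
    "hydrophobicity",
    "steric_hindrance",
    "polarity_index",
    "isoelectric_point",
    "helix_propensity",
    "sheet_propensity",
)

#: Side-chain heavy-atom element-count columns.
ELEMENT_COUNT_NAMES: tuple[str, ...] = ("n_N", "n_O", "n_C", "n_S")

#: Residue class flag columns.
CLASS_NAMES: tuple[str, ...] = (
    "polar", "apolar", "hydrophobic", "charged", "positive", "negative",
    "aromatic", "small", "hbond_donor", "hbond_acceptor",
)

#: Derived per-residue atom-count columns used by region descriptors.
ATOM_COUNT_NAMES: tuple[str, ...] = (
    "n_aromatic_atoms", "n_donor_atoms", "n_acceptor_atoms",
)


class UnknownResidueError(KeyError):
    """Raised when a lookup names a residue outside the canonical 20."""


class UnknownPropertyError(KeyError):
    """Raised when a lookup names a column outside the table schema."""


class PropertyTable:
    """Immutable per-residue property table.

    Parameters
    ----------
    frame
        DataFrame indexed by 3-letter residue code with the documented
        schema (see the bundled ``data/aa_properties.tsv``).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(CANONICAL_RESIDUES) - set(frame.index)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        extra = set(frame.index) - set(CANONICAL_RESIDUES)
        if extra:
            raise ValueError(f"property table has non-canonical rows: {sorted(extra)}")
        needed = set(PROPERTY_NAMES) | set(ELEMENT_COUNT_NAMES) | set(CLASS_NAMES) \
            | set(ATOM_COUNT_NAMES) | {"letter"}
        missing_cols = needed - set(frame.columns)
        if missing_cols:
            raise ValueError(f"property table missing columns: {sorted(missing_cols)}")
        # basic chemistry sanity: positive/negative are charged and disjoint
        pos = set(frame.index[frame["positive"] == 1])
        neg = set(frame.index[frame["negative"] == 1])
        chg = set(frame.index[frame["charged"] == 1])
        if not (pos <= chg and neg <= chg and not pos & neg):
            raise ValueError("inconsistent charge class flags")
        self._frame = frame.loc[list(CANONICAL_RESIDUES)].copy()

    @classmethod
    def from_file(cls, path: str | Path) -> "PropertyTable":
        frame = pd.read_csv(path, sep="\t", comment="#", index_col="name")
        return cls(frame)

    @classmethod
    def default(cls) -> "PropertyTable":
        """The bundled table (cached singleton)."""
        return _default_table()

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def value(self, residue_name: str, prop: str) -> float:
        """Scalar property or element/atom count for one residue."""
        if residue_name not in self._frame.index:
            raise UnknownResidueError(residue_name)
        if prop not in self._frame.columns:
            raise UnknownPropertyError(prop)
        return self._frame.at[residue_name, prop]

    def class_members(self, class_name: str) -> frozenset[str]:
        """Set of 3-letter codes carrying a class flag."""
        if class_name not in CLASS_NAMES:
            raise UnknownPropertyError(class_name)
        col = self._frame[class_name]
        return frozenset(col.index[col == 1])

    def is_member(self, residue_name: str, class_name: str) -> bool:
        return residue_name in self.class_members(class_name)


@lru_cache(maxsize=1)
def _default_table() -> PropertyTable:
    ref = importlib.resources.files("flavopot.data").joinpath("aa_properties.tsv")
    with importlib.resources.as_file(ref) as path:
        return PropertyTable.from_file(path)


def property_value(residue_name: str, prop: str) -> float:
    """Module-level shortcut into the bundled table."""
    return PropertyTable.default().value(residue_name, prop)


def class_members(class_name: str) -> frozenset[str]:
    """Module-level shortcut into the bundled table."""
    return PropertyTable.default().class_members(class_name)
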