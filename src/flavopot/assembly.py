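"""Assembly of the named 246-descriptor vector and radius-grid design matrices.

One record (a structure plus an E_m measurement, optionally with assay pH)
maps to one 246-vector at a given radius configuration ``(r1, r2)``:

=====================  =====
block                  width
=====================  =====
``Protein.X``             55
``Bar.X``                 55
``Ring.X``                55
ring atom counts           3
``N5_nearest_X``          28
``Around_N5.X``           28
CTD                       21
pH                         1
=====================  =====

Structures holding several flavin cofactors contribute the element-wise
mean of their per-site vectors (one row per record).  Records sharing a
structure at different pH yield distinct rows with identical structural
descriptors.  The design matrix appends the E_m label (247 columns); the
study scans r1 = 8..16 Å × r2 = 3..6 Å (36 configurations).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import ctd as ctd_mod
from . import descriptors as desc
from .properties import PropertyTable
from .structure import (
    FlavinSite,
    NoCofactorError,
    ProteinStructure,
    locate_flavin_sites,
    parse_structure,
)

LABEL_COLUMN = "Em"

R1_VALUES: tuple[int, ...] = tuple(range(8, 17))
R2_VALUES: tuple[int, ...] = (3, 4, 5, 6)


@dataclass
class StudyRecord:
    """One E_m measurement tied to a structure (and optionally an assay pH)."""

    structure_id: str
    pdb_source: str | Path | None
    E_m: float
    pH: float | None = None
    pdb_text: str | None = None

    def read_pdb_text(self) -> str:
        if self.pdb_text is not None:
            return self.pdb_text
        if self.pdb_source is None:
            raise ValueError(f"record {self.structure_id}: no PDB source")
        return Path(self.pdb_source).read_text()


def feature_names(ctd_attribute: str = ctd_mod.DEFAULT_ATTRIBUTE) -> list[str]:
    """The 246 descriptor names in canonical order (CSV header contract)."""
    names: list[str] = []
    for scope in ("Protein", "Bar", "Ring"):
        names += [f"{scope}.{bare}" for bare in desc.region_feature_names()]
    names += list(desc.RING_ATOM_COUNT_NAMES)
    names += [f"N5_nearest_{bare}" for bare in desc.n5_feature_names()]
    names += [f"Around_N5.{bare}" for bare in desc.n5_feature_names()]
    names += ctd_mod.ctd_feature_names()
    names.append("pH")
    assert len(names) == 246
    return names


def radius_grid() -> list[tuple[int, int]]:
    """The full (r1, r2) Cartesian grid, r1 ascending then r2 ascending."""
    return [(r1, r2) for r1 in R1_VALUES for r2 in R2_VALUES]


def _site_vector(
    structure: ProteinStructure,
    site: FlavinSite,
    r1: float,
    r2: float,
    table: PropertyTable,
    ctd_attribute: str,
) -> dict[str, float]:
    values: dict[str, float] = {}
    scopes = {
        "Protein": structure.standard_residues(),
        "Bar": desc.residues_in_sphere(structure, site.barycenter, r1),
        "Ring": desc.ring_union_region(structure, site, r2),
    }
    for scope, residues in scopes.items():
        block = desc.region_descriptors(residues, table)
        values.update({f"{scope}.{k}": v for k, v in block.items()})
    n_count, o_count, c_count = desc.ring_atom_counts(structure, site, r2)
    values["Nitrogen_Around"] = float(n_count)
    values["Oxygen_Around"] = float(o_count)
    values["Carbon_Around"] = float(c_count)
    near, around = desc.n5_descriptors(structure, site, table)
    values.update({f"N5_nearest_{k}": v for k, v in near.items()})
    values.update({f"Around_N5.{k}": v for k, v in around.items()})
    sequence = structure.chain_sequence(site.chain_id)
    values.update(ctd_mod.ctd_features(sequence, ctd_attribute))
    return values


def aggregate_multi_cofactor(per_site_vectors: list[pd.Series]) -> pd.Series:
    """Element-wise mean of per-site vectors; identity for a single site."""
    if not per_site_vectors:
        raise ValueError("no per-site vectors to aggregate")
    first = per_site_vectors[0]
    for vec in per_site_vectors[1:]:
        if list(vec.index) != list(first.index):
            raise ValueError("inconsistent feature naming across sites")
    return pd.concat(per_site_vectors, axis=1).mean(axis=1)


def build_feature_vector(
    structure: ProteinStructure,
    pH: float | None = None,
    r1: float = 13.0,
    r2: float = 3.0,
    table: PropertyTable | None = None,
    ctd_attribute: str = ctd_mod.DEFAULT_ATTRIBUTE,
) -> pd.Series:
    """The full named 246-vector for one structure at one (r1, r2).

    Multi-cofactor structures are averaged over their flavin sites; the pH
    slot is filled from the record (NaN when missing, imputed later).
    """
    table = table or PropertyTable.default()
    sites = locate_flavin_sites(structure)
    if not sites:
        raise NoCofactorError(
            f"{structure.source_id or 'structure'}: no FMN/FAD cofactor found"
        )
    names = feature_names(ctd_attribute)
    per_site = []
    for site in sites:
        values = _site_vector(structure, site, r1, r2, table, ctd_attribute)
        values["pH"] = np.nan if pH is None else float(pH)
        per_site.append(pd.Series([values[n] for n in names], index=names, dtype=float))
    return aggregate_multi_cofactor(per_site)


def build_design_matrix(
    records: list[StudyRecord],
    r1: float,
    r2: float,
    table: PropertyTable | None = None,
    ctd_attribute: str = ctd_mod.DEFAULT_ATTRIBUTE,
    skip_errors: bool = False,
) -> pd.DataFrame:
    """One row per record, 246 features + the E_m label (247 columns).

    Structures are parsed once and shared across records (e.g. the same
    protein measured at several pH values).  A failing record raises an
    error naming it unless ``skip_errors`` is set, in which case it is
    dropped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    table = table or PropertyTable.default()
    cache: dict[str, ProteinStructure] = {}
    rows, index = [], []
    for record in records:
        try:
            key = str(record.pdb_source) if record.pdb_source else record.structure_id
            if key not in cache:
                cache[key] = parse_structure(record.read_pdb_text(), record.structure_id)
            vec = build_feature_vector(
                cache[key], record.pH, r1, r2, table, ctd_attribute
            )
        except Exception as exc:
            if skip_errors:
                logger.warning("skipping record %s: %s", record.structure_id, exc)
                continue
            raise type(exc)(f"record {record.structure_id}: {exc}") from exc
        vec[LABEL_COLUMN] = float(record.E_m)
        rows.append(vec)
        index.append(record.structure_id)
    matrix = pd.DataFrame(rows)
    matrix.index = pd.Index(index, name="structure_id")
    matrix.attrs["r1"], matrix.attrs["r2"] = r1, r2
    return matrix


def write_design_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a design matrix CSV with round-trippable float formatting."""
    matrix.to_csv(path)


def read_design_matrix(path: str | Path) -> pd.DataFrame:
    """Read a design matrix CSV back to full precision.

    Uses round-trip float parsing so that write → read is the identity on
    every value (the default fast parser can lose the last ulp).
    """
    return pd.read_csv(path, index_col="structure_id",
                       float_precision="round_trip")


def load_records(csv_path: str | Path) -> list[StudyRecord]:
    """Read a record table CSV (structure_id, pdb_path, E_m_mV, pH)."""
    frame = pd.read_csv(csv_path)
    base = Path(csv_path).parent
    records = []
    for _, row in frame.iterrows():
        pdb_path = Path(str(row["pdb_path"]))
        if not pdb_path.is_absolute():
            pdb_path = base / pdb_path
        pH = row.get("pH")
        records.append(
            StudyRecord(
                structure_id=str(row["structure_id"]),
                pdb_source=pdb_path,
                E_m=float(row["E_m_mV"]),
                pH=None if pd.isna(pH) else float(pH),
            )
        )
    return records


class FlavinFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: study records → 246-column feature frame.

    Stateless (``fit`` records only the output feature names), so it can sit
    at the head of an sklearn :class:`~sklearn.pipeline.Pipeline`.

    Parameters
    ----------
    r1, r2 : float
        Barycenter-sphere and per-ring-atom-sphere radii in Å.
    ctd_attribute : str
        Residue attribute for the CTD block.
    """

    def __init__(self, r1: float = 13.0, r2: float = 3.0,
                 ctd_attribute: str = ctd_mod.DEFAULT_ATTRIBUTE):
        self.r1 = r1
        self.r2 = r2
        self.ctd_attribute = ctd_attribute

    def fit(self, X, y=None):
        self.feature_names_out_ = feature_names(self.ctd_attribute)
        return self

    def transform(self, X: list[StudyRecord]) -> pd.DataFrame:
        matrix = build_design_matrix(list(X), self.r1, self.r2,
                                     ctd_attribute=self.ctd_attribute)
        return matrix.drop(columns=[LABEL_COLUMN])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.ctd_attribute), dtype=object)
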