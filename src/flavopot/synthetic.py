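"""Synthetic fixtures: PDB structures with a flavin site, and planted datasets.

Two generators make every pipeline stage testable without downloads:

* :func:`generate_structure` writes PDB text containing an idealized
  isoalloxazine ring system (HETATM ``FMN``/``FAD`` with standard atom
  names) plus protein residues placed at controlled distances from the ring
  barycenter or from a named ring atom.  Residues carry backbone N/CA/C/O
  and the full heavy side-chain atom set, so element-count descriptors are
  exact.  Everything the generator decides (placements, atom counts, band
  membership) is returned as ground truth.

* :func:`generate_planted_dataset` draws a labeled feature table over the
  246 descriptor names with a sparse linear signal: a small support set of
  features carries coefficients in mV per sd, labels get Gaussian noise and
  are centred on the study's label distribution (mean −223 mV, sd 109 mV).
  Exact duplicate and constant columns are planted to exercise the
  correlation/variance filter, and a configurable fraction of pH values is
  set missing.

Neither generator aims at physically valid protein folds: geometry is only
as real as the distance-based descriptors require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import StudyRecord, feature_names
from .structure import ISOALLOXAZINE_RING_ATOMS

#: Study label distribution targets (mV).
LABEL_MEAN_MV = -223.0
LABEL_SD_MV = 109.0

_BOND = 1.40  # aromatic C-C bond length, Å

#: Heavy side-chain atom names per residue (element = first letter).
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


def isoalloxazine_template() -> dict[str, np.ndarray]:
    """Idealized planar coordinates (Å, z = 0) of the ring-system atoms.

    Three fused flat-topped hexagons with 1.40 Å edges: the benzo ring
    (C5A,C6,C7,C8,C9,C9A), the central pyrazine (N5,C5A,C9A,N10,C10,C4A)
    and the pyrimidinedione (N1,C2,N3,C4,C4A,C10), plus the C7M/C8M methyls
    and O2/O4 carbonyls extended radially from their ring carbons.
    """
    s3 = math.sqrt(3.0)
    b = _BOND
    coords: dict[str, np.ndarray] = {}

    def put(name, x, y):
        coords[name] = np.array([x * b, y * b, 0.0])

    # benzo ring centered at (0,0); shared edge with pyrazine at x = +s3/2
    put("C9A", s3 / 2, 0.5)
    put("C5A", s3 / 2, -0.5)
    put("C9", 0.0, 1.0)
    put("C8", -s3 / 2, 0.5)
    put("C7", -s3 / 2, -0.5)
    put("C6", 0.0, -1.0)
    # pyrazine centered at (s3, 0)
    put("N10", s3, 1.0)
    put("N5", s3, -1.0)
    put("C10", 3 * s3 / 2, 0.5)
    put("C4A", 3 * s3 / 2, -0.5)
    # pyrimidinedione centered at (2*s3, 0)
    put("N1", 2 * s3, 1.0)
    put("C2", 5 * s3 / 2, 0.5)
    put("N3", 5 * s3 / 2, -0.5)
    put("C4", 2 * s3, -1.0)

    def substituent(name, parent, ring_center_x, length):
        direction = coords[parent] - np.array([ring_center_x * b, 0.0, 0.0])
        coords[name] = coords[parent] + direction / np.linalg.norm(direction) * length

    substituent("C7M", "C7", 0.0, 1.50)
    substituent("C8M", "C8", 0.0, 1.50)
    substituent("O2", "C2", 2 * s3, 1.23)
    substituent("O4", "C4", 2 * s3, 1.23)
    # C10 is emitted too (a genuine cofactor atom) but is not part of the
    # counted 17-atom ring set.
    assert set(ISOALLOXAZINE_RING_ATOMS) <= set(coords)
    return coords


@dataclass
class ResiduePlacement:
    """One residue at a controlled distance from a reference point."""

    residue_name: str
    distance: float                    # anchor distance from the reference, Å
    chain_id: str = "A"
    reference: str = "barycenter"      # or a ring-atom name such as "N5"
    cofactor_index: int = 0


@dataclass
class CofactorSpec:
    kind: str = "FMN"                  # FMN or FAD
    chain_id: str = "X"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class StructureSpec:
    """Recipe for one synthetic structure (placements are ground truth)."""

    cofactors: list[CofactorSpec] = field(default_factory=lambda: [CofactorSpec()])
    placements: list[ResiduePlacement] = field(default_factory=list)
    seed: int = 0
    min_separation: float = 2.0        # between atoms of distinct placements
    residue_radius: float = 1.0        # all residue atoms within this of anchor


@dataclass
class StructureGroundTruth:
    """What the generator decided; recoverable by the pipeline stages."""

    cofactor_kinds: list[str]
    barycenters: list[np.ndarray]
    n5_coords: list[np.ndarray]
    ring_atom_names: list[str]
    residues: list[dict]               # name/chain/seq/anchor/distance/reference
    atom_count: int                    # all heavy atoms incl. cofactors
    protein_atom_count: int


def _sphere_points(n: int, radius: float) -> np.ndarray:
    """Deterministic golden-spiral points on a sphere."""
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = math.pi * (1 + 5**0.5) * idx
    return radius * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def _residue_atoms(name: str, anchor: np.ndarray, radius: float):
    atoms = list(_BACKBONE) + [(a, a[0]) for a in SIDE_CHAIN_ATOMS[name]]
    offsets = _sphere_points(len(atoms), radius)
    return [(atom, elem, anchor + off) for (atom, elem), off in zip(atoms, offsets)]


def _format_atom(record, serial, name, elem, resname, chain, seq, pos):
    padded = f" {name:<3}" if len(name) <= 3 else f"{name:<4}"
    return (
        f"{record:<6}{serial:>5} {padded} {resname:>3} {chain}{seq:>4}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {elem:>2}"
    )


def generate_structure(spec: StructureSpec) -> tuple[str, StructureGroundTruth]:
    """Emit PDB text and ground truth for a synthetic flavin-site structure."""
    rng = np.random.default_rng(spec.seed)
    template = isoalloxazine_template()
    bary_local = np.mean([template[n] for n in ISOALLOXAZINE_RING_ATOMS], axis=0)

    cof_atoms: list[tuple[str, str, np.ndarray, CofactorSpec]] = []
    barycenters, n5s = [], []
    for cof in spec.cofactors:
        if cof.kind not in ("FMN", "FAD"):
            raise ValueError(f"unsupported cofactor kind {cof.kind!r}")
        origin = np.asarray(cof.origin, dtype=float)
        for name in template:
            out_name = name
            if cof.kind == "FAD":
                out_name = {"C4A": "C4X", "C5A": "C5X"}.get(name, name)
            cof_atoms.append((out_name, name[0], template[name] + origin, cof))
        barycenters.append(bary_local + origin)
        n5s.append(template["N5"] + origin)

    placed_coords: list[np.ndarray] = [a[2] for a in cof_atoms]
    residues: list[dict] = []
    chain_seq: dict[str, int] = {}
    for placement in spec.placements:
        cof_i = placement.cofactor_index
        if placement.reference == "barycenter":
            ref = barycenters[cof_i]
        else:
            origin = np.asarray(spec.cofactors[cof_i].origin, dtype=float)
            ref = template[placement.reference] + origin
        anchor = None
        for _ in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = ref + placement.distance * direction
            atoms = _residue_atoms(placement.residue_name, candidate, spec.residue_radius)
            coords = np.array([a[2] for a in atoms])
            others = np.array(placed_coords)
            dmin = np.min(
                np.linalg.norm(coords[:, None, :] - others[None, :, :], axis=2)
            )
            if dmin >= spec.min_separation:
                anchor = candidate
                break
        if anchor is None:
            raise RuntimeError(
                f"could not pack {placement.residue_name} at {placement.distance} Å "
                f"after 500 attempts"
            )
        placed_coords.extend(a[2] for a in atoms)
        seq = chain_seq.get(placement.chain_id, 0) + 1
        chain_seq[placement.chain_id] = seq
        residues.append({
            "name": placement.residue_name,
            "chain_id": placement.chain_id,
            "seq_number": seq,
            "anchor": anchor,
            "distance": placement.distance,
            "reference": placement.reference,
            "cofactor_index": cof_i,
            "atoms": atoms,
        })

    lines: list[str] = []
    serial = 1
    protein_atom_count = 0
    for chain_id in sorted({r["chain_id"] for r in residues}):
        for res in [r for r in residues if r["chain_id"] == chain_id]:
            for atom_name, elem, pos in res["atoms"]:
                lines.append(_format_atom(
                    "ATOM", serial, atom_name, elem, res["name"],
                    chain_id, res["seq_number"], pos,
                ))
                serial += 1
                protein_atom_count += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for cof_index, cof in enumerate(spec.cofactors):
        for atom_name, elem, pos, owner in cof_atoms:
            if owner is cof:
                lines.append(_format_atom(
                    "HETATM", serial, atom_name, elem, cof.kind,
                    cof.chain_id, 900 + cof_index, pos,
                ))
                serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    truth = StructureGroundTruth(
        cofactor_kinds=[c.kind for c in spec.cofactors],
        barycenters=barycenters,
        n5_coords=n5s,
        ring_atom_names=list(ISOALLOXAZINE_RING_ATOMS),
        residues=[{k: v for k, v in r.items() if k != "atoms"} | {
            "atom_coords": {a: p for a, _, p in r["atoms"]},
        } for r in residues],
        atom_count=protein_atom_count + len(cof_atoms),
        protein_atom_count=protein_atom_count,
    )
    return pdb_text, truth


# ---------------------------------------------------------------------------
# Planted feature tables.

#: Default informative descriptors for planted datasets (spread over blocks).
DEFAULT_SUPPORT: tuple[str, ...] = (
    "Bar.nNats in side chain",
    "Protein.GLN",
    "Bar.HIS",
    "Around_N5.Hydrophobicity",
    "Ring.Net charge",
)


@dataclass
class PlantedDatasetSpec:
    """Recipe for a labeled feature table with a sparse linear signal."""

    n_rows: int = 141
    support: tuple[str, ...] = DEFAULT_SUPPORT
    coefficients: tuple[float, ...] | None = None   # mV per feature sd
    noise_sd: float = 20.0                          # mV
    label_mean: float = LABEL_MEAN_MV
    label_sd: float = LABEL_SD_MV
    missing_ph_fraction: float = 0.2
    n_duplicate_pairs: int = 3
    n_constant: int = 1
    seed: int = 0


@dataclass
class PlantedGroundTruth:
    support: tuple[str, ...]
    coefficients: np.ndarray
    noise_sd: float
    duplicates: list[tuple[str, str]]      # (original, copy)
    constant_columns: list[str]
    label_mean_target: float
    label_sd_target: float


def generate_planted_dataset(
    spec: PlantedDatasetSpec,
) -> tuple[pd.DataFrame, PlantedGroundTruth]:
    """Feature table (246 named columns + ``Em``) with planted sparse signal.

    Features are standard normal; labels are ``label_mean + Σ cⱼ xⱼ + ε``
    with ``ε ~ N(0, noise_sd²)``.  When coefficients are not given they are
    equal-magnitude, alternating-sign values chosen so the label variance
    hits the target sd exactly in expectation (no post-hoc rescaling, so
    the stated noise sd is the true residual scale).
    """
    rng = np.random.default_rng(spec.seed)
    names = feature_names()
    missing = set(spec.support) - set(names)
    if missing:
        raise ValueError(f"support names not in descriptor contract: {sorted(missing)}")
    k = len(spec.support)
    if spec.coefficients is None:
        signal_var = spec.label_sd**2 - spec.noise_sd**2
        if signal_var <= 0:
            raise ValueError("noise sd exceeds target label sd")
        mag = math.sqrt(signal_var / k)
        coefs = np.array([mag * (-1) ** i for i in range(k)])
    else:
        coefs = np.asarray(spec.coefficients, dtype=float)
        if coefs.shape != (k,):
            raise ValueError("coefficients must match support length")

    X = pd.DataFrame(
        rng.standard_normal((spec.n_rows, len(names))), columns=names
    )
    # realistic pH column (unless pH is itself in the support)
    if "pH" not in spec.support:
        X["pH"] = rng.normal(7.0, 0.7, size=spec.n_rows)

    eligible = [n for n in names if n not in spec.support and n != "pH"]
    constant_columns = eligible[: spec.n_constant]
    for col in constant_columns:
        X[col] = 0.0
    dup_candidates = eligible[spec.n_constant:]
    duplicates = []
    for i in range(spec.n_duplicate_pairs):
        original, copy = dup_candidates[2 * i], dup_candidates[2 * i + 1]
        X[copy] = X[original].to_numpy()
        duplicates.append((original, copy))

    # plant the label location/scale exactly: the realized noise vector is
    # standardized to the stated sd and the realized signal component to
    # sqrt(label_sd^2 - noise_sd^2), so the achieved label moments sit at
    # the targets up to the (small) signal-noise sample covariance
    eps = rng.standard_normal(spec.n_rows)
    eps = (eps - eps.mean()) / eps.std() * spec.noise_sd
    signal = X[list(spec.support)].to_numpy() @ coefs
    if spec.coefficients is None:
        # auto-chosen coefficients are calibrated to the realized draw;
        # user-specified coefficients are honoured verbatim
        signal_sd_target = math.sqrt(max(spec.label_sd**2 - spec.noise_sd**2, 0.0))
        realized_sd = signal.std()
        if realized_sd > 0 and signal_sd_target > 0:
            coefs = coefs * (signal_sd_target / realized_sd)
            signal = signal * (signal_sd_target / realized_sd)
    y = spec.label_mean + (signal - signal.mean()) + eps
    if spec.missing_ph_fraction > 0:
        n_missing = int(round(spec.missing_ph_fraction * spec.n_rows))
        idx = rng.choice(spec.n_rows, size=n_missing, replace=False)
        X.iloc[idx, X.columns.get_loc("pH")] = np.nan

    matrix = X.copy()
    matrix["Em"] = y
    truth = PlantedGroundTruth(
        support=tuple(spec.support),
        coefficients=coefs,
        noise_sd=spec.noise_sd,
        duplicates=duplicates,
        constant_columns=constant_columns,
        label_mean_target=spec.label_mean,
        label_sd_target=spec.label_sd,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Ready-made record sets for end-to-end runs.

_DEMO_RESIDUES = ("ARG", "HIS", "GLN", "ASP", "TRP", "SER", "LEU", "TYR",
                  "LYS", "GLU", "ALA", "PHE")


def generate_record_set(
    n_structures: int = 12, seed: int = 0, workdir=None,
) -> tuple[list[StudyRecord], list[StructureGroundTruth]]:
    """A small set of synthetic flavoprotein records with E_m labels.

    Each structure carries an FMN site with residues placed in an inner
    shell (4–7 Å), a mid shell (9–12 Å) and an outer shell (18–24 Å).
    Labels are drawn from the study distribution (mean −223 mV, sd 109 mV);
    pH is present for 80% of records.  If ``workdir`` is given, PDB files
    are written there and records reference them by path.
    """
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n_structures):
        picks = rng.choice(len(_DEMO_RESIDUES), size=9, replace=True)
        shells = [rng.uniform(4, 7, 3), rng.uniform(9, 12, 3), rng.uniform(18, 24, 3)]
        placements = [
            ResiduePlacement(_DEMO_RESIDUES[picks[3 * s + j]], float(shells[s][j]))
            for s in range(3) for j in range(3)
        ]
        struct_spec = StructureSpec(placements=placements, seed=int(rng.integers(2**31)))
        pdb_text, truth = generate_structure(struct_spec)
        pH = float(rng.normal(7.0, 0.7)) if rng.random() > 0.2 else None
        em = float(rng.normal(LABEL_MEAN_MV, LABEL_SD_MV))
        record = StudyRecord(
            structure_id=f"SYN{i:03d}", pdb_source=None, E_m=em, pH=pH,
            pdb_text=pdb_text,
        )
        if workdir is not None:
            from pathlib import Path

            path = Path(workdir) / f"SYN{i:03d}.pdb"
            path.write_text(pdb_text)
            record.pdb_source = path
        records.append(record)
        truths.append(truth)
    return records, truths
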