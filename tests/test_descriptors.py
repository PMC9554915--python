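"""Region and N5 descriptors against brute-force oracles."""

import numpy as np
import pytest

from flavopot.descriptors import (
    n5_descriptors,
    n5_nearest_residue,
    region_descriptors,
    region_feature_names,
    residues_in_sphere,
    ring_atom_counts,
    ring_union_region,
)
from flavopot.properties import CANONICAL_RESIDUES, PropertyTable
from flavopot.structure import (
    FlavinSite,
    ProteinStructure,
    locate_flavin_sites,
    parse_structure,
)
from flavopot.synthetic import ResiduePlacement, StructureSpec, generate_structure

from conftest import random_structure


# --- independent oracles ---------------------------------------------------

def oracle_sphere(structure, center, radius):
    """Exhaustive all-atoms scan, no vectorization shared with the engine."""
    hits = []
    for res in structure.standard_residues():
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            if float(np.linalg.norm(atom.coord - center)) <= radius:
                hits.append((res.chain_id, res.seq_number, res.name))
                break
    return hits


def oracle_union(structure, site, r2):
    seen, out = set(), []
    for name, coord in site.ring_atoms.items():
        for key in oracle_sphere(structure, coord, r2):
            if key not in seen:
                seen.add(key)
                out.append(key)
    return sorted(out)


def oracle_atom_counts(structure, site, r2):
    counts = {"N": 0, "O": 0, "C": 0}
    for res in structure.standard_residues():
        for atom in res.atoms:
            if atom.is_hydrogen or atom.element not in counts:
                continue
            if any(
                np.linalg.norm(atom.coord - c) <= r2
                for c in site.ring_atoms.values()
            ):
                counts[atom.element] += 1
    return counts["N"], counts["O"], counts["C"]


def oracle_region(names, table):
    """Recount every descriptor from the raw table, value by value."""
    frame = table.frame
    out = {}
    for code in CANONICAL_RESIDUES:
        out[code] = sum(1 for n in names if n == code)
    out["ResTot"] = len(names)
    for label, cls in [
        ("ResPolar", "polar"), ("ResApolar", "apolar"), ("ResCharged", "charged"),
        ("ResPositive", "positive"), ("ResNegative", "negative"),
        ("ResHydrophobic", "hydrophobic"), ("ResAromatic", "aromatic"),
        ("ResSmall", "small"), ("ResHBondDonor", "hbond_donor"),
        ("ResHBondAcceptor", "hbond_acceptor"),
    ]:
        out[label] = sum(int(frame.at[n, cls]) for n in names)
    for prop, label in [
        ("volume", "Volume"), ("flexibility", "Flexibility"),
        ("hydrophobicity", "Hydrophobicity"), ("steric_hindrance", "Steric hindrance"),
        ("polarity_index", "Polarity index"), ("isoelectric_point", "Isoelectric point"),
        ("helix_propensity", "Helix propensity"), ("sheet_propensity", "Sheet propensity"),
    ]:
        out[label] = sum(frame.at[n, prop] for n in names)
        out[f"Mean {label}"] = out[label] / len(names) if names else 0.0
    for col, label in [("n_N", "nNats in side chain"), ("n_O", "nOats in side chain"),
                       ("n_C", "nCats in side chain"), ("n_S", "nSats in side chain")]:
        out[label] = sum(int(frame.at[n, col]) for n in names)
    out["Net charge"] = out["ResPositive"] - out["ResNegative"]
    for col, label in [("n_aromatic_atoms", "nAromatic atoms"),
                       ("n_donor_atoms", "nHBondDonor atoms"),
                       ("n_acceptor_atoms", "nHBondAcceptor atoms")]:
        out[label] = sum(int(frame.at[n, col]) for n in names)
    return out


def _key(res):
    return (res.chain_id, res.seq_number, res.name)


# --- sphere membership -----------------------------------------------------

class TestSphereMembership:
    def test_zero_radius_empty(self, parsed_banded):
        st, truth = parsed_banded
        assert residues_in_sphere(st, truth.barycenters[0], 0.0) == []

    def test_ball_nesting(self, parsed_banded):
        st, truth = parsed_banded
        prev = set()
        for r in (4, 8, 12, 20, 30):
            cur = {_key(res) for res in residues_in_sphere(st, truth.barycenters[0], r)}
            assert prev <= cur
            prev = cur

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        st, truth = random_structure(seed)
        center = truth.barycenters[0]
        for radius in (6.0, 9.0, 15.0):
            got = sorted(_key(r) for r in residues_in_sphere(st, center, radius))
            assert got == sorted(oracle_sphere(st, center, radius))

    def test_generator_band_counts(self, parsed_banded):
        st, truth = parsed_banded
        # 3 residues placed inside 8 Å, 5 placed beyond 20 Å
        assert len(residues_in_sphere(st, truth.barycenters[0], 8.0)) == 3
        assert len(residues_in_sphere(st, truth.barycenters[0], 30.0)) == 10


class TestRingUnion:
    def test_zero_radius_empty(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        assert ring_union_region(st, site, 0.0) == []

    def test_degenerate_single_atom_ring_equals_sphere(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        collapsed = FlavinSite(
            cofactor_kind="FMN",
            ring_atoms={"N5": site.n5_coord},
            barycenter=site.n5_coord,
            n5_coord=site.n5_coord,
            chain_id=site.chain_id,
        )
        for r in (3.0, 6.0, 10.0):
            union = [_key(x) for x in ring_union_region(st, collapsed, r)]
            sphere = [_key(x) for x in residues_in_sphere(st, site.n5_coord, r)]
            assert sorted(union) == sorted(sphere)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_union(self, seed):
        st, _ = random_structure(seed)
        site = locate_flavin_sites(st)[0]
        for r2 in (3.0, 5.0):
            got = sorted(_key(r) for r in ring_union_region(st, site, r2))
            assert got == oracle_union(st, site, r2)


class TestRegionDescriptors:
    def test_empty_region_is_all_zero(self):
        values = region_descriptors([])
        assert len(values) == 55
        assert all(v == 0.0 for v in values.values())

    def test_single_glutamine(self):
        values = region_descriptors(["GLN"])
        assert values["GLN"] == 1
        assert values["ResTot"] == 1
        assert values["nNats in side chain"] == 1
        assert values["ResPolar"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names = list(rng.choice(CANONICAL_RESIDUES, size=30))
        table = PropertyTable.default()
        got = region_descriptors(names, table)
        expected = oracle_region(names, table)
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k], rel=1e-9), k

    def test_order_free(self):
        names = ["ARG", "GLY", "TRP", "ARG", "SER"]
        assert region_descriptors(names) == region_descriptors(names[::-1])

    def test_feature_name_schema(self):
        names = region_feature_names()
        assert len(names) == 55
        assert len(set(names)) == 55
        assert "nNats in side chain" in names
        assert "Steric hindrance" in names


class TestRingAtomCounts:
    def test_zero_radius(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        assert ring_atom_counts(st, site, 0.0) == (0, 0, 0)

    def test_monotone_in_radius(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        prev = (0, 0, 0)
        for r2 in (2, 4, 6, 10):
            cur = ring_atom_counts(st, site, r2)
            assert all(c >= p for c, p in zip(cur, prev))
            prev = cur

    def test_planted_nitrogen_near_n5(self):
        # a residue anchored 2.5 Å from N5: its atoms lie within 3.5 Å
        spec = StructureSpec(
            placements=[ResiduePlacement("GLY", 2.5, reference="N5"),
                        ResiduePlacement("ALA", 25.0)],
            seed=3,
        )
        pdb_text, _ = generate_structure(spec)
        st = parse_structure(pdb_text)
        site = locate_flavin_sites(st)[0]
        n, o, c = ring_atom_counts(st, site, 4.0)
        assert n >= 1
        assert (n, o, c) == oracle_atom_counts(st, site, 4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        st, _ = random_structure(seed)
        site = locate_flavin_sites(st)[0]
        for r2 in (3.0, 5.0):
            assert ring_atom_counts(st, site, r2) == oracle_atom_counts(st, site, r2)


def _rotate(structure: ProteinStructure, R, t):
    import copy

    st = copy.deepcopy(structure)
    for res in st.protein_residues() + st.hetero_groups:
        for atom in res.atoms:
            object.__setattr__(atom, "coord", R @ atom.coord + t)
    return st


class TestN5Descriptors:
    def test_planted_nearest_residue(self):
        spec = StructureSpec(
            placements=[ResiduePlacement("TRP", 3.0, reference="N5"),
                        ResiduePlacement("ALA", 12.0), ResiduePlacement("GLY", 15.0)],
            seed=5,
        )
        pdb_text, _ = generate_structure(spec)
        st = parse_structure(pdb_text)
        site = locate_flavin_sites(st)[0]
        assert n5_nearest_residue(st, site).name == "TRP"

    def test_tie_breaks_to_first_in_chain_order(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        # force an exact tie by duplicating the winning residue's coordinates
        # at a later sequence position
        import copy

        st2 = copy.deepcopy(st)
        winner = n5_nearest_residue(st2, site)
        clone = copy.deepcopy(winner)
        clone.seq_number = 999
        st2.chains[winner.chain_id].append(clone)
        assert n5_nearest_residue(st2, site).seq_number == winner.seq_number

    def test_rotation_invariance(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        before = n5_nearest_residue(st, site)
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        st_rot = _rotate(st, Q, np.array([5.0, -3.0, 2.0]))
        site_rot = locate_flavin_sites(st_rot)[0]
        after = n5_nearest_residue(st_rot, site_rot)
        assert (before.chain_id, before.seq_number) == (after.chain_id, after.seq_number)

    def test_identity_blocks(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        near, around = n5_descriptors(st, site)
        assert len(near) == 28 and len(around) == 28
        identity_near = sum(near[c] for c in CANONICAL_RESIDUES)
        identity_around = sum(around[c] for c in CANONICAL_RESIDUES)
        assert identity_near == 1.0
        assert 1.0 <= identity_around <= 3.0

    def test_terminal_residue_uses_two_neighbors(self):
        # nearest residue is the first in its chain: only 2 residues contribute
        spec = StructureSpec(
            placements=[ResiduePlacement("ALA", 3.0, reference="N5"),
                        ResiduePlacement("GLY", 9.0), ResiduePlacement("SER", 11.0)],
            seed=9,
        )
        pdb_text, _ = generate_structure(spec)
        st = parse_structure(pdb_text)
        site = locate_flavin_sites(st)[0]
        assert n5_nearest_residue(st, site).seq_number == 1
        _, around = n5_descriptors(st, site)
        assert sum(around[c] for c in CANONICAL_RESIDUES) == 2.0

    def test_around_hydrophobicity_is_table_sum(self, parsed_banded):
        st, _ = parsed_banded
        site = locate_flavin_sites(st)[0]
        table = PropertyTable.default()
        nearest = n5_nearest_residue(st, site)
        chain = [r for r in st.chains[nearest.chain_id] if r.is_standard_aa]
        i = next(k for k, r in enumerate(chain) if r.seq_number == nearest.seq_number)
        triple = chain[max(0, i - 1): i + 2]
        expected = sum(table.value(r.name, "hydrophobicity") for r in triple)
        _, around = n5_descriptors(st, site)
        assert around["Hydrophobicity"] == pytest.approx(expected, rel=1e-9)


def test_all_region_blocks_rotation_invariant(parsed_banded):
    st, _ = parsed_banded
    site = locate_flavin_sites(st)[0]
    rng = np.random.default_rng(7)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    st_rot = _rotate(st, Q, np.array([-4.0, 8.0, 1.0]))
    site_rot = locate_flavin_sites(st_rot)[0]
    for r1, r2 in [(8.0, 3.0), (13.0, 3.0)]:
        a = region_descriptors([r.name for r in residues_in_sphere(st, site.barycenter, r1)])
        b = region_descriptors(
            [r.name for r in residues_in_sphere(st_rot, site_rot.barycenter, r1)]
        )
        assert a == b
        assert ring_atom_counts(st, site, r2) == ring_atom_counts(st_rot, site_rot, r2)


def test_protein_scope_equals_huge_sphere(parsed_banded):
    st, _ = parsed_banded
    site = locate_flavin_sites(st)[0]
    whole = region_descriptors([r.name for r in st.standard_residues()])
    huge = region_descriptors(
        [r.name for r in residues_in_sphere(st, site.barycenter, 1e6)]
    )
    assert whole == huge
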