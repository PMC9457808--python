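import math

import numpy as np
import pandas as pd
import pytest

from qstrtox.config import Conventions
from qstrtox.descriptors import (
    DESCRIPTOR_COLUMNS, b05_pair, compute_descriptor_table, dls05, h4m,
    influence_matrix, loc_index, nct, nrocon, sp_pos_a_rg, unsat_breakdown,
)
from qstrtox.molecule_io import Atom, Bond, Molecule, heavy_graph, parse_smiles, permute_atoms


def _mol_from_points(points):
    """Bare carbon chain with given 3D positions (for geometry unit tests)."""
    n = len(points)
    return Molecule(
        id="points",
        atoms=[Atom("C", 12.011, 0, 2)] * n,
        bonds=[Bond(i, i + 1, 1, False) for i in range(n - 1)],
        coords=np.asarray(points, dtype=float),
    )


class TestLocIndex:
    def test_single_node_zero(self):
        assert loc_index(heavy_graph(parse_smiles("C"))) == 0.0

    def test_butane_one_bit(self):
        # two pruning rounds of two atoms each: entropy of {2,2}/4 = 1 bit
        assert loc_index(heavy_graph(parse_smiles("CCCC"))) == pytest.approx(1.0)

    def test_benzene_degenerate_partition(self):
        assert loc_index(heavy_graph(parse_smiles("c1ccccc1"))) == 0.0

    def test_pentane_hand_entropy(self):
        # rounds remove {2, 2}, core {1}: -2*(2/5)lg(2/5) - (1/5)lg(1/5)
        expected = -2 * (0.4 * math.log2(0.4)) - 0.2 * math.log2(0.2)
        assert loc_index(heavy_graph(parse_smiles("CCCCC"))) == pytest.approx(expected)

    def test_toluene_core_plus_terminal(self):
        expected = -(1 / 7) * math.log2(1 / 7) - (6 / 7) * math.log2(6 / 7)
        assert loc_index(heavy_graph(parse_smiles("Cc1ccccc1"))) == pytest.approx(expected)

    def test_entropy_bound(self, toys):
        for t in toys.values():
            g = heavy_graph(t.molecule())
            assert loc_index(g) <= math.log2(g.n) + 1e-12

    def test_disconnected_rejected(self):
        g = heavy_graph(parse_smiles("CC.OCO", largest_fragment=False))
        with pytest.raises(ValueError, match="connected"):
            loc_index(g)


class TestCounts:
    @pytest.mark.parametrize("smiles,expected", [
        ("CC(C)C", 1),          # isobutane
        ("CC(C)(C)C", 0),       # neopentane: quaternary centre
        ("CC(C)C(C)C", 2),
        ("CC(C)C(C)C(C)C", 3),
        ("CC(C)O", 0),          # O neighbour disqualifies
        ("CC(C)c1ccccc1", 1),   # cumene: two methyls + aryl C still count as 3 C
    ])
    def test_tertiary_carbon_count(self, smiles, expected):
        assert nct(parse_smiles(smiles)) == expected

    @pytest.mark.parametrize("smiles,expected", [
        ("CNC(=O)OC", 1),            # O-methyl: aliphatic
        ("CNC(=O)Oc1ccccc1", 0),     # O-aryl
        ("NC(=O)O", 0),              # carbamic acid: H on the sp3 oxygen
        ("CC(C)(C)OC(=O)N", 1),      # O-tert-butyl
        ("CC(C)(SC)C=NOC(=O)NC", 0), # oxime carbamate: O-N, no carbon substituent
        ("CCO", 0),                  # no carbamate at all
    ])
    def test_nrocon(self, smiles, expected):
        assert nrocon(parse_smiles(smiles)) == expected


class TestB05:
    def test_hexylamine_lag5(self):
        g = heavy_graph(parse_smiles("NCCCCCC"))
        assert b05_pair(g, "C", "N") == 1
        assert b05_pair(g, "N", "O") == 0

    def test_ethanol_no_lag5(self):
        g = heavy_graph(parse_smiles("CCO"))
        for a, b in (("C", "N"), ("N", "O"), ("C", "O"), ("C", "C")):
            assert b05_pair(g, a, b) == 0

    def test_amino_butanol_no_lag5_at_four(self):
        g = heavy_graph(parse_smiles("NCCCCO"))
        assert b05_pair(g, "N", "O") == 1
        assert b05_pair(g, "C", "N") == 0

    def test_brute_force_oracle(self, toys, rng):
        # all-pairs check against an explicit BFS-free path enumeration
        import networkx as nx
        for tid in ("propoxur", "methomyl", "carbofuran", "propham"):
            mol = toys[tid].molecule()
            g = heavy_graph(mol)
            G = nx.from_numpy_array(g.adjacency.astype(int))
            spl = dict(nx.all_pairs_shortest_path_length(G))
            for ea, eb in (("C", "N"), ("N", "O")):
                expected = int(any(
                    spl[i].get(j) == 5
                    for i in range(g.n) if g.elements[i] == ea
                    for j in range(g.n) if g.elements[j] == eb))
                assert b05_pair(g, ea, eb) == expected


class TestUnsat:
    def test_ethane_saturated(self):
        ub = unsat_breakdown(parse_smiles("CC"))
        assert (ub.nrg567, ub.nDB, ub.nTB, ub.nAB) == (0, 0, 0, 0)
        assert ub.unsat == 0.0

    def test_ethane_literal_convention(self):
        ub = unsat_breakdown(parse_smiles("CC"), Conventions(unsat_literal=True))
        assert ub.unsat == 0.5

    def test_benzene(self):
        ub = unsat_breakdown(parse_smiles("c1ccccc1"))
        assert ub.nrg567 == 1 and ub.nAB == 6
        assert ub.unsat == pytest.approx(1 + (6 + 1) / 2)
        assert ub.unsat_p is None  # every ring carbon carries an H

    def test_butyne(self):
        ub = unsat_breakdown(parse_smiles("CC#CC"))
        assert ub.nTB == 1 and ub.unsat == 2.0

    def test_cyclooctane_ring_not_counted(self):
        ub = unsat_breakdown(parse_smiles("C1CCCCCCC1"))
        assert ub.nrg567 == 0 and ub.unsat == 0.0

    def test_carbofuran_fused_rings(self, toys):
        ub = unsat_breakdown(toys["carbofuran"].molecule())
        assert ub.nrg567 == 2       # benzene + dihydrofuran
        assert ub.nAB == 6 and ub.nDB == 1
        assert ub.unsat == pytest.approx(2 + 1 + 3.5)

    def test_heteroatom_counts(self):
        ub = unsat_breakdown(parse_smiles("CNC(=O)OC"))
        assert ub.nNO == 3 and ub.nC3 == 2
        assert ub.unsat_p == pytest.approx(1.0 / 3.0)


class TestDls05:
    @pytest.mark.parametrize("smiles,expected", [
        ("CNC(=O)OC", 1.0),       # both rules hold
        ("CCN(CC)CC", 1.0),       # saturated amine, ratio 1/6, unsat 0
        ("CCO", 0.5),             # ratio ok, Unsat-p undefined
        ("CC(C)C", 0.0),          # no heteroatoms, Unsat-p undefined
        ("c1ccccc1", 0.0),
        ("CC(C)(C)C", 0.5),       # ratio 0 fails, Unsat-p = 0 passes
    ])
    def test_rule_scores(self, smiles, expected):
        assert dls05(parse_smiles(smiles)) == expected


class TestGeometry:
    def test_two_atom_eigenproblem(self):
        # two atoms at 1.5 A: eigenvalues +-1/2.25, positive sum / 2
        mol = _mol_from_points([(0, 0, 0), (1.5, 0, 0)])
        assert sp_pos_a_rg(mol) == pytest.approx((1 / 2.25) / 2, rel=1e-12)

    def test_scaling_homogeneity(self, toys):
        mol = toys["propoxur"].molecule()
        base = sp_pos_a_rg(mol)
        scaled = toys["propoxur"].molecule()
        scaled.coords = scaled.coords * 2.0
        assert sp_pos_a_rg(scaled) == pytest.approx(base / 4.0, rel=1e-9)

    def test_rigid_motion_invariance(self, toys, rng):
        mol = toys["aldicarb"].molecule()
        base_sp, base_h4m = sp_pos_a_rg(mol), h4m(mol)
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = toys["aldicarb"].molecule()
        moved.coords = mol.coords @ q + np.array([3.0, -1.0, 7.5])
        assert sp_pos_a_rg(moved) == pytest.approx(base_sp, rel=1e-9)
        assert h4m(moved) == pytest.approx(base_h4m, rel=1e-9)

    def test_coincident_atoms_rejected(self):
        mol = _mol_from_points([(0, 0, 0), (0, 0, 1e-9), (1, 0, 0)])
        with pytest.raises(ValueError, match="coincident"):
            sp_pos_a_rg(mol)

    def test_missing_coords_rejected(self):
        mol = parse_smiles("CCCCCC")
        with pytest.raises(ValueError, match="coordinates"):
            sp_pos_a_rg(mol)
        with pytest.raises(ValueError, match="coordinates"):
            h4m(mol)

    def test_influence_matrix_trace_and_leverage_range(self, toys):
        for tid in ("propoxur", "carbaryl", "hexylamine"):
            mol = toys[tid].molecule()
            idx = mol.heavy_indices()
            H = influence_matrix(mol.coords[idx])
            rank = np.linalg.matrix_rank(mol.coords[idx] - mol.coords[idx].mean(0))
            assert np.trace(H) == pytest.approx(rank, abs=1e-8)
            diag = np.diag(H)
            assert np.all(diag >= -1e-12) and np.all(diag <= 1 + 1e-12)

    def test_h4m_small_molecule_zero(self, toys):
        assert h4m(toys["ethanol"].molecule()) == 0.0    # 3 heavy atoms
        assert h4m(toys["isobutane"].molecule()) == 0.0  # 4 heavy atoms

    def test_h4m_brute_force_oracle(self, toys):
        def brute(mol):
            idx = [i for i, a in enumerate(mol.atoms) if a.symbol != "H"]
            m = mol.coords[idx] - mol.coords[idx].mean(axis=0)
            hmat = m @ np.linalg.pinv(m.T @ m) @ m.T
            g = heavy_graph(mol)
            w = [mol.atoms[a].mass / 12.011 for a in idx]
            total = 0.0
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    if g.topo_dist[i, j] == 4 and hmat[i, j] > 0:
                        total += hmat[i, j] * w[i] * w[j]
            return total

        for tid in ("hexylamine", "propoxur", "aldicarb", "carbofuran"):
            mol = toys[tid].molecule()
            assert h4m(mol) == pytest.approx(brute(mol), rel=1e-12)
        # frozen golden number for the fixture chain geometry
        assert h4m(toys["hexylamine"].molecule()) == pytest.approx(
            0.002932730180, abs=1e-9)

    def test_planar_molecule_uses_pseudoinverse(self, toys):
        # exactly planar geometry: rank(M) = 2, the influence matrix must
        # still evaluate through the pseudo-inverse
        mol = toys["benzene"].molecule()
        assert h4m(mol) == 0.0  # a 6-cycle has max topological distance 3
        flat = mol.coords[mol.heavy_indices()].copy()
        flat[:, 2] = 0.0
        H = influence_matrix(flat)
        assert np.trace(H) == pytest.approx(2.0, abs=1e-8)


class TestToyLabelsAndTable:
    def test_hand_labels_match_computed(self, toys):
        for t in toys.values():
            mol = t.molecule()
            g = heavy_graph(mol)
            computed = {
                "nCt": nct(mol),
                "nROCON": nrocon(mol),
                "B05_CN": b05_pair(g, "C", "N"),
                "B05_NO": b05_pair(g, "N", "O"),
                "DLS_05": dls05(mol),
            }
            for key, expected in t.expected.items():
                assert computed[key] == expected, f"{t.id}: {key}"

    def test_descriptor_permutation_invariance(self, toys, rng):
        for tid in ("propoxur", "methomyl", "carbofuran"):
            mol = toys[tid].molecule()
            g = heavy_graph(mol)
            base = (nct(mol), nrocon(mol), b05_pair(g, "C", "N"), dls05(mol),
                    loc_index(g), round(sp_pos_a_rg(mol), 10), round(h4m(mol), 10))
            perm = rng.permutation(mol.n_atoms).tolist()
            pm = permute_atoms(mol, perm)
            pg = heavy_graph(pm)
            permuted = (nct(pm), nrocon(pm), b05_pair(pg, "C", "N"), dls05(pm),
                        loc_index(pg), round(sp_pos_a_rg(pm), 10), round(h4m(pm), 10))
            assert base == permuted

    def test_full_table_assembly(self, toys):
        mols = [t.molecule() for t in toys.values()]
        elec = pd.DataFrame({"id": [t.id for t in toys.values()],
                             "EA": [t.ea for t in toys.values()],
                             "qC": [t.qc for t in toys.values()]})
        table = compute_descriptor_table(mols, elec)
        assert list(table.columns) == ["id"] + DESCRIPTOR_COLUMNS
        assert len(table) == len(mols)
        assert set(table["nROCON"].unique()) <= {0, 1}
        assert set(table["B05_CN"].unique()) <= {0, 1}
        assert set(table["B05_NO"].unique()) <= {0, 1}
        assert table[["EA", "qC", "LOC", "SpPosA_RG", "H4m"]].notna().all().all()

    def test_missing_coords_flagged_not_zero(self, toys):
        mols = [parse_smiles("CNC(=O)Oc1ccccc1", "no_coords")]
        elec = pd.DataFrame({"id": ["no_coords"], "EA": [-7.9], "qC": [0.19]})
        table = compute_descriptor_table(mols, elec)
        assert np.isnan(table.loc[0, "SpPosA_RG"])
        assert np.isnan(table.loc[0, "H4m"])
        assert table.loc[0, "LOC"] > 0

    def test_missing_electronic_id_raises(self, toys):
        mols = [toys["propoxur"].molecule()]
        elec = pd.DataFrame({"id": ["someone_else"], "EA": [-8.0], "qC": [0.19]})
        with pytest.raises(ValueError, match="propoxur"):
            compute_descriptor_table(mols, elec)

    def test_plausibility_corridor_soft(self, toys, recwarn):
        """Carbamate-like fixtures should land near the worked-example ranges;
        excursions warn rather than fail (the fixture geometries are embedded,
        not quantum-chemically optimised)."""
        import warnings
        for tid in ("phenyl_methylcarbamate", "carbaryl", "propoxur",
                    "methomyl", "carbofuran", "propham"):
            mol = toys[tid].molecule()
            loc = loc_index(heavy_graph(mol))
            sp = sp_pos_a_rg(mol)
            h4 = h4m(mol)
            assert loc >= 0 and sp >= 0 and h4 >= 0
            if not 1.0 <= loc <= 3.0:
                warnings.warn(f"{tid}: LOC {loc:.3f} outside corridor [1, 3]")
            if not 0.3 <= sp <= 0.6:
                warnings.warn(f"{tid}: SpPosA_RG {sp:.3f} outside corridor [0.3, 0.6]")
            if not 0.0 <= h4 <= 0.5:
                warnings.warn(f"{tid}: H4m {h4:.3f} outside corridor [0, 0.5]")
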