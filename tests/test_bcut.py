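"""Descriptor-engine tests: PEOE charges, Crippen weights, Burden matrices."""

import numpy as np
import pytest
import scipy.linalg
from rdkit import Chem
from rdkit.Chem import Crippen

from sibcut.bcut import (
    BCUT_COLUMNS,
    DescriptorTable,
    MolecularGraph,
    StructureError,
    bcut_from_matrix,
    bcut_vector,
    build_burden_matrix,
    build_descriptor_table,
    compute_crippen_contributions,
    compute_peoe_charges,
    natural_nucleoside_smiles,
)

# Gasteiger (a, b, c) parameters for the elements in the oracle molecules
_PEOE_PARAMS = {"H": (7.17, 6.24, -0.56), "C": (7.98, 9.18, 1.88), "O": (14.18, 12.92, 1.39)}


def _reference_peoe(molh, n_iter=12):
    """Independent PEOE iteration: damped charge flow along bonds."""
    syms = [a.GetSymbol() for a in molh.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in molh.GetBonds()]
    q = np.zeros(len(syms))
    for it in range(1, n_iter + 1):
        chi = np.array(
            [a + b * qi + c * qi**2 for (a, b, c), qi in zip((_PEOE_PARAMS[s] for s in syms), q)]
        )
        dq = np.zeros_like(q)
        for i, j in bonds:
            lo = i if chi[i] <= chi[j] else j
            chi_plus = 20.02 if syms[lo] == "H" else sum(_PEOE_PARAMS[syms[lo]])
            t = (chi[j] - chi[i]) / chi_plus * 0.5**it
            dq[i] += t
            dq[j] -= t
        q += dq
    return q


@pytest.mark.parametrize(
    "smiles, net_charge",
    [("C", 0), ("CCO", 0), ("c1ccccc1O", 0), ("CC(=O)[O-]", -1), ("C[NH3+]", 1)],
)
def test_peoe_charges_sum_to_net_formal_charge(smiles, net_charge):
    charges = compute_peoe_charges(smiles)
    assert charges.sum() == pytest.approx(net_charge, abs=1e-6)


def test_peoe_matches_independent_gasteiger_iteration():
    """Per-atom ethanol charges agree with a from-scratch PEOE loop."""
    molh = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    expected_h = _reference_peoe(molh)
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    folded = expected_h[heavy].copy()
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() == 1:
            folded[heavy.index(atom.GetNeighbors()[0].GetIdx())] += expected_h[atom.GetIdx()]
    np.testing.assert_allclose(compute_peoe_charges("CCO"), folded, atol=1e-4)


@pytest.mark.parametrize("smiles", ["C", "CCO", "c1ccc2ccccc2c1", "CC(=O)NC1=CC=CC=C1"])
def test_crippen_contributions_are_additive(smiles):
    """Per-atom logP/MR sums reproduce the whole-molecule Crippen values."""
    slogp, smr = compute_crippen_contributions(smiles)
    mol = Chem.MolFromSmiles(smiles)
    assert slogp.sum() == pytest.approx(Crippen.MolLogP(mol), abs=1e-4)
    assert smr.sum() == pytest.approx(Crippen.MolMR(mol), abs=1e-4)


def test_crippen_contributions_invariant_under_atom_reordering():
    mol = Chem.MolFromSmiles("CC(=O)OC1=CC=CC=C1C(=O)O")
    renumbered = Chem.RenumberAtoms(mol, list(reversed(range(mol.GetNumAtoms()))))
    a = np.sort(compute_crippen_contributions(mol)[0])
    b = np.sort(compute_crippen_contributions(renumbered)[0])
    np.testing.assert_allclose(a, b, atol=1e-12)


class TestBurdenMatrix:
    def test_single_atom(self):
        np.testing.assert_allclose(build_burden_matrix("C", [0.7]), [[0.7]])

    def test_ethane_terminal_bond_convention(self):
        B = build_burden_matrix("CC", [0.3, -0.2])
        np.testing.assert_allclose(B, [[0.3, 0.11], [0.11, -0.2]])

    def test_matches_brute_force_pairwise_rules(self):
        smiles = "c1ccccc1C(=O)O"  # aromatic ring, double bond, terminals
        mol = Chem.MolFromSmiles(smiles)
        n = mol.GetNumAtoms()
        diag = np.linspace(-1, 1, n)
        B = build_burden_matrix(mol, diag)
        degree = np.zeros(n)
        order = {}
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            order[(i, j)] = order[(j, i)] = 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()
            degree[i] += 1
            degree[j] += 1
        expected = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    expected[i, j] = diag[i]
                elif (i, j) in order:
                    expected[i, j] = 0.1 * order[(i, j)] + (
                        0.01 if degree[i] == 1 or degree[j] == 1 else 0.0
                    )
                else:
                    expected[i, j] = 0.001
        np.testing.assert_allclose(B, expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="heavy atoms"):
            build_burden_matrix("CC", [0.1, 0.2, 0.3])


class TestEigenSummaries:
    def test_single_eigenvalue_repeats(self):
        assert bcut_from_matrix([[0.42]]) == pytest.approx((0.42,) * 4)

    @pytest.mark.parametrize("a, c", [(0.0, 0.5), (1.2, -0.3), (-0.7, 0.9)])
    def test_two_by_two_closed_form(self, a, c):
        lo, hi = a - abs(c), a + abs(c)
        expected = (lo, a - abs(c) / 3, a + abs(c) / 3, hi)
        assert bcut_from_matrix([[a, c], [c, a]]) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 17, 50])
    def test_matches_dense_eigensolver_oracle(self, n):
        rng = np.random.default_rng(n)
        M = rng.normal(size=(n, n))
        B = (M + M.T) / 2
        evals = scipy.linalg.eigh(B, eigvals_only=True)
        expected = np.quantile(np.sort(evals), [0, 1 / 3, 2 / 3, 1])
        np.testing.assert_allclose(bcut_from_matrix(B), expected, atol=1e-9)

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError, match="symmetric"):
            bcut_from_matrix([[0.0, 1.0], [0.0, 0.0]])


class TestBcutVector:
    def test_methane_single_heavy_atom(self):
        v = bcut_vector("C")
        np.testing.assert_allclose(v[[f"BCUT_PEOE_{k}" for k in range(4)]], 0.0, atol=1e-6)
        slogp = v[[f"BCUT_SLOGP_{k}" for k in range(4)]].to_numpy()
        assert np.ptp(slogp) == pytest.approx(0.0, abs=1e-12)
        assert slogp[0] == pytest.approx(Crippen.MolLogP(Chem.MolFromSmiles("C")), abs=1e-6)

    @pytest.mark.parametrize("symbol", list("ACGUT"))
    def test_summaries_nondecreasing_within_each_property(self, symbol):
        v = bcut_vector(natural_nucleoside_smiles()[symbol]).to_numpy()
        for block in range(3):
            assert np.all(np.diff(v[4 * block : 4 * block + 4]) >= -1e-12)

    def test_invariant_under_heavy_atom_reindexing(self):
        mol = Chem.MolFromSmiles(natural_nucleoside_smiles()["G"])
        renumbered = Chem.RenumberAtoms(mol, list(reversed(range(mol.GetNumAtoms()))))
        np.testing.assert_allclose(
            bcut_vector(mol).to_numpy(), bcut_vector(renumbered).to_numpy(), atol=1e-9
        )

    def test_adenosine_snapshot_for_drift(self):
        """Frozen regression values for the packaged adenosine structure.

        These are this engine's own numbers (the commercial convention
        behind the shipped natural-nucleotide table is not public); the
        test guards against silent drift, not external agreement.
        """
        v = bcut_vector(natural_nucleoside_smiles()["A"]).to_numpy()
        expected = [
            -0.408230, -0.214260, 0.230957, 0.445321,
            -0.611164, -0.373662, 0.136375, 0.613791,
            1.077388, 2.211826, 3.990655, 4.880876,
        ]
        np.testing.assert_allclose(v, expected, atol=1e-5)

    def test_unparsable_smiles_raises_structure_error(self):
        with pytest.raises(StructureError):
            bcut_vector("not-a-smiles")


class TestMolecularGraph:
    def test_equivalent_to_smiles_route(self):
        graph = MolecularGraph(
            atoms=(("C", 0, 3), ("C", 0, 2), ("O", 0, 1)),
            bonds=((0, 1, 1), (1, 2, 1)),
        )
        np.testing.assert_allclose(
            bcut_vector(graph).to_numpy(), bcut_vector("CCO").to_numpy(), atol=1e-10
        )

    def test_self_bond_rejected(self):
        with pytest.raises(StructureError, match="self-bond"):
            MolecularGraph(atoms=(("C", 0, 4),), bonds=((0, 0, 1),))

    def test_dangling_bond_index_rejected(self):
        with pytest.raises(StructureError, match="missing atom"):
            MolecularGraph(atoms=(("C", 0, 4),), bonds=((0, 3, 1),))


class TestDescriptorTableBuilding:
    def test_five_nucleosides_give_table_with_canonical_header(self):
        table = build_descriptor_table(natural_nucleoside_smiles())
        assert len(table) == 5
        assert list(table.frame.columns) == list(BCUT_COLUMNS)
        assert sorted(table.symbols) == ["A", "C", "G", "T", "U"]

    def test_input_order_does_not_change_content(self):
        smiles = natural_nucleoside_smiles()
        forward = build_descriptor_table(smiles)
        backward = build_descriptor_table(dict(reversed(list(smiles.items()))))
        assert forward.frame.equals(backward.frame)

    def test_empty_input_gives_empty_table(self):
        assert len(build_descriptor_table({})) == 0

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_descriptor_table([("A", "C"), ("A", "CC")])

    def test_tsv_round_trip(self, tmp_path):
        table = build_descriptor_table({"A": "C", "B": "CCO"})
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        reread = DescriptorTable.from_tsv(path)
        np.testing.assert_allclose(reread.frame.to_numpy(), table.frame.to_numpy(), atol=1e-12)
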