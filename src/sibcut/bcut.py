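"""Burden-matrix eigenvalue (BCUT) descriptors for nucleotide monomers.

A BCUT descriptor summarises how an atomic property (partial charge,
logP contribution, molar refractivity contribution) is distributed over
a molecular graph.  The property values are placed on the diagonal of a
modified adjacency matrix (the Burden matrix); the eigenvalue spectrum
of that matrix is then reduced to four order statistics.  Three atomic
properties x four summaries give the 12-descriptor vector used to
characterise each nucleotide:

* ``BCUT_PEOE_0..3``  — Gasteiger PEOE partial charges (charge distribution)
* ``BCUT_SLOGP_0..3`` — Wildman–Crippen atomic logP (hydrophobicity)
* ``BCUT_SMR_0..3``   — Wildman–Crippen atomic molar refractivity
  (polarizability)

Burden-matrix convention used here (heavy atoms only, hydrogen
contributions folded onto their heavy neighbours):

* diagonal: the atomic property value;
* bonded pair: 0.1 x bond order (aromatic = 1.5), plus 0.01 if either
  atom is terminal (heavy-atom degree 1);
* non-bonded pair: 0.001.

The four summaries are the minimum, the one-third and two-thirds
quantiles (linear interpolation between sorted eigenvalues), and the
maximum — always non-decreasing, and all equal for a one-atom graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

logger = logging.getLogger(__name__)

#: Column order of a descriptor vector / table (fixed across the package).
BCUT_COLUMNS: tuple[str, ...] = tuple(
    f"BCUT_{prop}_{k}" for prop in ("PEOE", "SLOGP", "SMR") for k in range(4)
)

_QUANTILES = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


class StructureError(ValueError):
    """Raised when a molecular structure cannot be parsed or sanitized."""


@dataclass(frozen=True)
class MolecularGraph:
    """Minimal chemical-graph container convertible to an RDKit Mol.

    ``atoms`` is a list of ``(element, formal_charge, n_hydrogens)``
    tuples; ``bonds`` a list of ``(i, j, order)`` with order in
    ``{1, 2, 3, "aromatic"}``.
    """

    atoms: tuple[tuple[str, int, int], ...]
    bonds: tuple[tuple[int, int, object], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if i == j:
                raise StructureError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise StructureError(f"bond ({i}, {j}) references a missing atom")

    def to_rdkit(self) -> Chem.Mol:
        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
            "aromatic": Chem.BondType.AROMATIC,
        }
        em = Chem.RWMol()
        for element, charge, nh in self.atoms:
            atom = Chem.Atom(element)
            atom.SetFormalCharge(charge)
            atom.SetNumExplicitHs(nh)
            atom.SetNoImplicit(True)
            em.AddAtom(atom)
        for i, j, order in self.bonds:
            em.AddBond(i, j, order_map[order])
        mol = em.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - rdkit error text varies
            raise StructureError(f"graph does not sanitize: {exc}") from exc
        return mol


def _as_mol(mol) -> Chem.Mol:
    """Accept a SMILES string, MolecularGraph, or RDKit Mol."""
    if isinstance(mol, Chem.Mol):
        return mol
    if isinstance(mol, MolecularGraph):
        return mol.to_rdkit()
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise StructureError(f"unparsable SMILES: {mol!r}")
        return parsed
    raise TypeError(f"cannot interpret {type(mol).__name__} as a molecule")


def _with_explicit_hs(mol: Chem.Mol) -> Chem.Mol:
    return Chem.AddHs(_as_mol(mol))


def _fold_hydrogens(molh: Chem.Mol, values: np.ndarray) -> np.ndarray:
    """Sum hydrogen values onto their heavy neighbour; return heavy-atom array."""
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    pos = {idx: k for k, idx in enumerate(heavy)}
    out = np.array([values[i] for i in heavy], dtype=float)
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        neighbors = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if neighbors:
            out[pos[neighbors[0].GetIdx()]] += values[atom.GetIdx()]
    return out


def compute_peoe_charges(mol) -> np.ndarray:
    """Gasteiger PEOE partial charges, one per heavy atom.

    Hydrogen charges are folded onto their heavy neighbour, so the
    returned values sum to the molecule's net formal charge.
    """
    molh = _with_explicit_hs(mol)
    AllChem.ComputeGasteigerCharges(molh)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()])
    if not np.all(np.isfinite(q)):
        bad = {molh.GetAtomWithIdx(int(i)).GetSymbol() for i in np.flatnonzero(~np.isfinite(q))}
        raise StructureError(
            f"PEOE charges undefined for element(s) {sorted(bad)}: "
            "outside the electronegativity parameter set"
        )
    return _fold_hydrogens(molh, q)


def compute_crippen_contributions(mol) -> tuple[np.ndarray, np.ndarray]:
    """Wildman–Crippen per-heavy-atom (logP, MR) contributions.

    Atoms that fail to match a published Crippen atom type fall back to
    the wildcard type inside RDKit; a warning is logged when the summed
    logP differs from the typed expectation (the wildcard contributes 0).
    """
    molh = _with_explicit_hs(mol)
    contribs = rdMolDescriptors._CalcCrippenContribs(molh)
    logp = np.array([c[0] for c in contribs], dtype=float)
    mr = np.array([c[1] for c in contribs], dtype=float)
    if np.any(logp == 0.0) and np.any(mr == 0.0):
        untyped = [
            molh.GetAtomWithIdx(i).GetSymbol()
            for i in range(molh.GetNumAtoms())
            if contribs[i] == (0.0, 0.0)
        ]
        if untyped:
            logger.warning(
                "Crippen wildcard fallback for %d atom(s): %s", len(untyped), untyped
            )
    return _fold_hydrogens(molh, logp), _fold_hydrogens(molh, mr)


def build_burden_matrix(mol, diag: Sequence[float]) -> np.ndarray:
    """Burden matrix over heavy atoms with ``diag`` on the diagonal."""
    m = _as_mol(mol)
    heavy = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() > 1]
    n = len(heavy)
    diag = np.asarray(diag, dtype=float)
    if diag.shape != (n,):
        raise ValueError(f"diag has length {diag.size}, expected {n} heavy atoms")
    pos = {idx: k for k, idx in enumerate(heavy)}
    degree = np.zeros(n, dtype=int)
    bond_list = []
    for bond in m.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        i, j = pos[a.GetIdx()], pos[b.GetIdx()]
        order = 1.5 if bond.GetIsAromatic() else bond.GetBondTypeAsDouble()
        bond_list.append((i, j, order))
        degree[i] += 1
        degree[j] += 1
    B = np.full((n, n), 0.001)
    for i, j, order in bond_list:
        val = 0.1 * order
        if degree[i] == 1 or degree[j] == 1:
            val += 0.01
        B[i, j] = B[j, i] = val
    np.fill_diagonal(B, diag)
    return B


def bcut_from_matrix(B: np.ndarray) -> tuple[float, float, float, float]:
    """Four eigenvalue summaries (min, 1/3 quantile, 2/3 quantile, max)."""
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("Burden matrix must be square")
    if not np.allclose(B, B.T, atol=1e-12):
        raise ValueError("Burden matrix must be symmetric")
    evals = np.linalg.eigvalsh(B)
    return tuple(float(v) for v in np.quantile(evals, _QUANTILES))


def bcut_vector(mol) -> pd.Series:
    """The full 12-descriptor BCUT vector of a molecule.

    Returns a Series indexed by :data:`BCUT_COLUMNS`.
    """
    m = _as_mol(mol)
    peoe = compute_peoe_charges(m)
    slogp, smr = compute_crippen_contributions(m)
    values: list[float] = []
    for weights in (peoe, slogp, smr):
        values.extend(bcut_from_matrix(build_burden_matrix(m, weights)))
    return pd.Series(values, index=list(BCUT_COLUMNS))


@dataclass
class DescriptorTable:
    """Map from nucleotide token to its 12 BCUT descriptor values.

    The bridge between chemistry and sequence space: each alphabet token
    (single letters for natural nucleotides, multi-character tokens such
    as ``mA`` or ``LG`` for chemically modified ones) owns one row.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(BCUT_COLUMNS)))

    def __post_init__(self) -> None:
        missing = [c for c in BCUT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"descriptor table missing column(s): {missing}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate nucleotide symbol(s): {dupes}")
        self.frame = self.frame.loc[:, list(BCUT_COLUMNS)].astype(float)
        if not np.all(np.isfinite(self.frame.to_numpy())) and len(self.frame):
            raise ValueError("descriptor table contains non-finite values")

    @property
    def symbols(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.frame.index

    def row(self, symbol: str) -> np.ndarray:
        return self.frame.loc[symbol].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "NT", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DescriptorTable":
        frame = pd.read_csv(path, sep="\t")
        if "NT" not in frame.columns:
            raise ValueError(f"{path}: missing 'NT' column")
        missing = [c for c in BCUT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing descriptor column(s) {missing}")
        for col in BCUT_COLUMNS:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value in column {col}, row {bad.index[0] + 2}"
                )
        frame = frame.set_index("NT")
        frame.index = frame.index.astype(str)
        return cls(frame)


def build_descriptor_table(structures: Mapping[str, object]) -> DescriptorTable:
    """Compute BCUT vectors for every ``symbol -> structure`` pair.

    Structures may be SMILES strings, :class:`MolecularGraph` objects or
    RDKit Mols.  Deterministic: the output is sorted by symbol.
    """
    if isinstance(structures, Mapping):
        items = list(structures.items())
    else:
        items = [(symbol, structure) for symbol, structure in structures]
    symbols = [symbol for symbol, _ in items]
    if len(set(symbols)) != len(symbols):
        seen: set[str] = set()
        dupes = [s for s in symbols if s in seen or seen.add(s)]
        raise ValueError(f"duplicate symbol(s): {dupes}")
    rows = {symbol: bcut_vector(structure) for symbol, structure in items}
    if not rows:
        return DescriptorTable()
    frame = pd.DataFrame(rows).T.reindex(sorted(rows))
    frame.index.name = "NT"
    return DescriptorTable(frame)


def natural_descriptor_table() -> DescriptorTable:
    """The packaged descriptor table for the five natural nucleotides."""
    with resources.as_file(
        resources.files("sibcut.data").joinpath("natural_nt_bcut.tsv")
    ) as path:
        return DescriptorTable.from_tsv(path)


def natural_nucleoside_smiles() -> dict[str, str]:
    """Packaged nucleoside SMILES (ribonucleosides; thymidine for T)."""
    text = resources.files("sibcut.data").joinpath("natural_nucleosides.smi").read_text()
    return read_smiles_table(text.splitlines())


def read_smiles_table(lines: Iterable[str]) -> dict[str, str]:
    """Parse ``symbol<TAB>SMILES`` lines into an ordered dict."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'symbol<TAB>SMILES'")
        symbol, smiles = parts
        if symbol in out:
            raise ValueError(f"line {lineno}: duplicate symbol {symbol!r}")
        out[symbol] = smiles
    return out


def read_sdf_structures(path, symbol_property: str = "NT") -> dict[str, Chem.Mol]:
    """Read an SDF file into ``symbol -> Mol`` using a named property."""
    out: dict[str, Chem.Mol] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            raise StructureError(f"{path}: unparsable SDF record")
        if not mol.HasProp(symbol_property):
            raise ValueError(f"{path}: SDF record lacks property {symbol_property!r}")
        symbol = mol.GetProp(symbol_property)
        if symbol in out:
            raise ValueError(f"{path}: duplicate symbol {symbol!r}")
        out[symbol] = mol
    return out
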