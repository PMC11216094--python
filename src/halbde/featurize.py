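"""Molecular graphs with atomic-descriptor node features.

Each reagent SMILES becomes an attributed graph: atoms are nodes carrying a
real feature vector, bonds are undirected edges (stored as symmetric directed
pairs).  Node features are the concatenation, in fixed order, of up to three
descriptor blocks:

``species``
    One-hot element identity over the library vocabulary
    (C, N, O, F, S, Cl, Br, I, H).
``charge``
    An empirical partial charge from an iterative electronegativity-
    equalization scheme (damped charge transfer along bonds, seeded from
    formal charges and Pauling electronegativities), plus the formal charge.
``neighbor_info``
    Local environment descriptors: heavy-atom degree, hydrogen count,
    neighbor counts by element class (C / N / O / S / halogen),
    hybridization flags (sp / sp2 / sp3), local unsaturation (sum of bond
    orders minus degree), aromaticity and ring-membership flags.

Hydrogens are implicit by default (heavy-atom graphs); an explicit-H mode is
available through :class:`DescriptorConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import FeaturizationError
from .registry import parse_smiles

ELEMENT_VOCAB = ("C", "N", "O", "F", "S", "Cl", "Br", "I", "H")

# Pauling electronegativities for the library vocabulary
_PAULING = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
            "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66}
_HALOGEN = {"F", "Cl", "Br", "I"}

_CHARGE_ITERATIONS = 6
_CHARGE_DAMPING = 0.5
_CHARGE_HARDNESS = 4.0


def equalization_charges(mol: Chem.Mol) -> np.ndarray:
    """Empirical partial charges by damped electronegativity equalization.

    Charges start at the formal charges; at iteration k each bond transfers
    ``damping**k * (chi_j - chi_i) / (eta_i + eta_j)`` electrons from the
    less to the more electronegative atom.  The effective electronegativity
    ``chi_i = chi_i0 + eta * q_i`` falls as an atom accumulates negative
    charge, so transfer is self-limiting and the damped iteration converges.
    Total molecular charge is conserved exactly.
    """
    n = mol.GetNumAtoms()
    q = np.array([a.GetFormalCharge() for a in mol.GetAtoms()], dtype=float)
    chi0 = np.empty(n)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _PAULING:
            raise FeaturizationError(
                f"no electronegativity parameter for atom {atom.GetIdx()} "
                f"({sym})")
        chi0[atom.GetIdx()] = _PAULING[sym]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    damp = _CHARGE_DAMPING
    for k in range(1, _CHARGE_ITERATIONS + 1):
        chi = chi0 + _CHARGE_HARDNESS * q
        dq = np.zeros(n)
        for i, j in bonds:
            t = damp ** k * (chi[j] - chi[i]) / (2.0 * _CHARGE_HARDNESS)
            dq[i] += t
            dq[j] -= t
        q += dq
    if not np.all(np.isfinite(q)):
        bad = int(np.flatnonzero(~np.isfinite(q))[0])
        raise FeaturizationError(f"charge computation diverged at atom {bad}")
    return q


@dataclass(frozen=True)
class DescriptorConfig:
    """Which descriptor blocks enter the node feature vector."""

    use_species: bool = True
    use_charge: bool = True
    use_neighbor_info: bool = True
    explicit_hydrogens: bool = False
    element_vocab: tuple[str, ...] = ELEMENT_VOCAB

    def __post_init__(self):
        if not (self.use_species or self.use_charge or self.use_neighbor_info):
            raise ValueError("at least one descriptor block must be enabled")

    @property
    def species_width(self) -> int:
        return len(self.element_vocab) if self.use_species else 0

    @property
    def charge_width(self) -> int:
        return 2 if self.use_charge else 0

    @property
    def neighbor_width(self) -> int:
        return 13 if self.use_neighbor_info else 0

    @property
    def feature_length(self) -> int:
        return self.species_width + self.charge_width + self.neighbor_width

    @property
    def name(self) -> str:
        blocks = [n for n, on in (("species", self.use_species),
                                  ("charge", self.use_charge),
                                  ("neighbors", self.use_neighbor_info)) if on]
        return "+".join(blocks)


#: The ablation grid: each block alone, and all three together.
ABLATION_CONFIGS = (
    DescriptorConfig(True, False, False),
    DescriptorConfig(False, True, False),
    DescriptorConfig(False, False, True),
    DescriptorConfig(True, True, True),
)


def featurize_atom(mol: Chem.Mol, atom_idx: int, config: DescriptorConfig,
                   charges: np.ndarray | None = None) -> np.ndarray:
    """Feature vector of one atom: [species | charge | neighbor_info]."""
    atom = mol.GetAtomWithIdx(atom_idx)
    parts: list[np.ndarray] = []
    if config.use_species:
        onehot = np.zeros(len(config.element_vocab))
        sym = atom.GetSymbol()
        if sym not in config.element_vocab:
            raise FeaturizationError(
                f"element {sym} of atom {atom_idx} not in vocabulary")
        onehot[config.element_vocab.index(sym)] = 1.0
        parts.append(onehot)
    if config.use_charge:
        if charges is None:
            charges = equalization_charges(mol)
        parts.append(np.array([charges[atom_idx],
                               float(atom.GetFormalCharge())]))
    if config.use_neighbor_info:
        counts = dict.fromkeys(("C", "N", "O", "S", "X"), 0)
        for nb in atom.GetNeighbors():
            sym = nb.GetSymbol()
            key = "X" if sym in _HALOGEN else sym
            if key in counts:
                counts[key] += 1
        hyb = atom.GetHybridization()
        bond_order_sum = sum(b.GetBondTypeAsDouble() for b in atom.GetBonds())
        parts.append(np.array([
            float(atom.GetDegree()),
            float(atom.GetTotalNumHs()),
            counts["C"], counts["N"], counts["O"], counts["S"], counts["X"],
            1.0 if hyb == Chem.HybridizationType.SP else 0.0,
            1.0 if hyb == Chem.HybridizationType.SP2 else 0.0,
            1.0 if hyb == Chem.HybridizationType.SP3 else 0.0,
            bond_order_sum - atom.GetDegree(),   # local unsaturation
            1.0 if atom.GetIsAromatic() else 0.0,
            1.0 if atom.IsInRing() else 0.0,
        ]))
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        raise FeaturizationError(f"non-finite feature for atom {atom_idx}")
    return vec


@dataclass
class MolecularGraph:
    """Attributed molecular graph: node feature matrix + symmetric edge list."""

    node_features: np.ndarray          # (n_nodes, feature_length)
    edge_index: np.ndarray             # (2, n_directed_edges), symmetric
    reagent_key: tuple | None = None
    smiles: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edge_index.shape[1] // 2

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for u, v in self.edge_index.T:
            adj[int(u)].append(int(v))
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_nodes

    def save_npz(self, path) -> None:
        np.savez(path, node_features=self.node_features,
                 edge_index=self.edge_index,
                 smiles=np.array(self.smiles or ""))

    @classmethod
    def load_npz(cls, path) -> "MolecularGraph":
        data = np.load(path, allow_pickle=False)
        smiles = str(data["smiles"]) or None
        return cls(data["node_features"], data["edge_index"], smiles=smiles)


def mol_to_graph(smiles: str, config: DescriptorConfig | None = None,
                 reagent_key: tuple | None = None) -> MolecularGraph:
    """Convert a SMILES string into an attributed molecular graph.

    One node per atom (heavy atoms only unless ``config.explicit_hydrogens``),
    one symmetric pair of directed edges per bond, no self-loops.
    """
    config = config or DescriptorConfig()
    mol = parse_smiles(smiles)
    if config.explicit_hydrogens:
        mol = Chem.AddHs(mol)
    charges = equalization_charges(mol) if config.use_charge else None
    feats = np.stack([featurize_atom(mol, i, config, charges)
                      for i in range(mol.GetNumAtoms())])
    src, dst = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    return MolecularGraph(feats, edge_index, reagent_key=reagent_key,
                          smiles=smiles)
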