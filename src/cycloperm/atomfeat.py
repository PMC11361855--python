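"""Atom-level inputs for the structure-enhanced transformer.

Heavy atoms are nodes.  Each atom gets a 30-dimensional feature row (six
one-hot blocks plus two boolean flags) and every atom pair gets three scalar
relations: a bond-type weight, the shortest-path graph distance and the 3D
Euclidean distance.  The two distance matrices are passed through an
inverse-distance attenuation so attention between remote atoms is weakened;
the resulting Strength matrices have unit diagonal and lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .errors import DegeneracyError, InputError

N_NODE_FEATURES = 30
N_MAX_DEFAULT = 128

_ATOM_TYPES = {6: 0, 7: 1, 8: 2, 16: 3, 9: 4, 17: 5, 35: 6}  # other -> 7
_CHARGES = {-1: 0, 0: 1, 1: 2}  # other -> 3

_BOND_WEIGHTS = (0.0, 1.0, 1.4, 1.5, 2.0, 3.0)


def node_features(mol: Chem.Mol) -> np.ndarray:
    """N x 30 node-feature matrix (heavy atoms only).

    Blocks: atom type (8: C,N,O,S,F,Cl,Br,other), heavy degree (5: 1..4,
    other), H count (5: 0..4, clipped), formal charge (4: -1,0,+1,other),
    hybridization (3: sp, sp2, sp3/other), chirality (3: none, CW, CCW),
    then in-ring and aromatic booleans.
    """
    n = mol.GetNumAtoms()
    out = np.zeros((n, N_NODE_FEATURES))
    for i, atom in enumerate(mol.GetAtoms()):
        out[i, _ATOM_TYPES.get(atom.GetAtomicNum(), 7)] = 1
        deg = atom.GetDegree()
        out[i, 8 + (deg - 1 if 1 <= deg <= 4 else 4)] = 1
        out[i, 13 + min(atom.GetTotalNumHs(), 4)] = 1
        out[i, 18 + _CHARGES.get(atom.GetFormalCharge(), 3)] = 1
        hyb = atom.GetHybridization()
        if hyb == Chem.HybridizationType.SP:
            out[i, 22] = 1
        elif hyb == Chem.HybridizationType.SP2:
            out[i, 23] = 1
        else:
            out[i, 24] = 1
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            out[i, 26] = 1
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            out[i, 27] = 1
        else:
            out[i, 25] = 1
        out[i, 28] = float(atom.IsInRing())
        out[i, 29] = float(atom.GetIsAromatic())
    return out


def bond_matrix(mol: Chem.Mol) -> np.ndarray:
    """N x N bond-type weights.

    Precedence per bonded pair: aromatic 1.5, triple 3.0, double 2.0,
    conjugated single 1.4, single 1.0; non-bonded pairs and the diagonal 0.
    Higher weights on bonds with more electron participation strengthen
    message exchange between those atoms.
    """
    n = mol.GetNumAtoms()
    out = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bond.GetIsAromatic():
            w = 1.5
        elif bond.GetBondType() == Chem.BondType.TRIPLE:
            w = 3.0
        elif bond.GetBondType() == Chem.BondType.DOUBLE:
            w = 2.0
        elif bond.GetIsConjugated():
            w = 1.4
        else:
            w = 1.0
        out[i, j] = out[j, i] = w
    return out


def graph_distance_matrix(mol: Chem.Mol) -> np.ndarray:
    """All-pairs shortest path lengths on the heavy-atom bond graph."""
    if len(Chem.GetMolFrags(mol)) != 1:
        raise InputError("graph distances require a connected molecule")
    return Chem.GetDistanceMatrix(mol).astype(float).copy()


def conf_distance_matrix(coordinates: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (A) from heavy-atom coordinates."""
    coordinates = np.asarray(coordinates, dtype=float)
    if not np.all(np.isfinite(coordinates)):
        raise InputError("non-finite coordinates")
    diff = coordinates[:, None, :] - coordinates[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def attenuation(distance: np.ndarray, mask: np.ndarray | None = None
                ) -> np.ndarray:
    """Inverse-distance attenuation: diag 1, off-diagonal 1/d clipped to 1.

    Entries involving padded (masked-out) atoms are 0.  Distances below 1 A
    would give strengths above 1; they are clipped so the output stays a
    [0, 1] attention attenuator.  A zero distance between two distinct real
    atoms is degenerate and raises.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    real = np.outer(mask, mask)
    off = ~np.eye(n, dtype=bool)
    if np.any((distance == 0) & real & off):
        raise DegeneracyError("zero distance between distinct real atoms")
    with np.errstate(divide="ignore"):
        s = np.where(off, 1.0 / np.where(distance > 0, distance, np.inf), 1.0)
    s = np.minimum(s, 1.0)
    s = np.where(real, s, 0.0)
    return s


@dataclass
class AtomFeatureSet:
    """Padded atom-branch inputs for one replica of one peptide."""

    node: np.ndarray            # (N_max, 30)
    bond: np.ndarray            # (N_max, N_max)
    graph: np.ndarray           # (N_max, N_max)
    conf: np.ndarray            # (N_max, N_max)
    strength_graph: np.ndarray  # (N_max, N_max) in [0, 1]
    strength_conf: np.ndarray   # (N_max, N_max) in [0, 1]
    mask: np.ndarray            # (N_max,) bool, True = real atom

    @property
    def n_atoms(self) -> int:
        return int(self.mask.sum())


def _pad_square(m: np.ndarray, n_max: int) -> np.ndarray:
    n = m.shape[0]
    out = np.zeros((n_max, n_max), dtype=m.dtype)
    out[:n, :n] = m
    return out


def featurize_atoms(smiles: str, coordinates: np.ndarray,
                    n_max: int = N_MAX_DEFAULT) -> AtomFeatureSet:
    """Build the full padded :class:`AtomFeatureSet` for one SMILES rendering.

    The atom order follows the SMILES atom order, so enumerated SMILES of the
    same molecule yield row/column-permuted features.  ``coordinates`` must be
    in the same order.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    n = mol.GetNumAtoms()
    if n > n_max:
        raise InputError(f"{n} atoms exceed padding size {n_max}")
    mask = np.zeros(n_max, dtype=bool)
    mask[:n] = True
    node = np.zeros((n_max, N_NODE_FEATURES))
    node[:n] = node_features(mol)
    graph = graph_distance_matrix(mol)
    conf = conf_distance_matrix(coordinates)
    if conf.shape[0] != n:
        raise InputError("coordinates do not match the SMILES atom count")
    sub_mask = np.ones(n, dtype=bool)
    return AtomFeatureSet(
        node=node,
        bond=_pad_square(bond_matrix(mol), n_max),
        graph=_pad_square(graph, n_max),
        conf=_pad_square(conf, n_max),
        strength_graph=_pad_square(attenuation(graph, sub_mask), n_max),
        strength_conf=_pad_square(attenuation(conf, sub_mask), n_max),
        mask=mask,
    )
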