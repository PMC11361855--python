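"""Replica-based data augmentation for cyclic peptides.

Each peptide is expanded into R replicas (60 by default) that share its
label.  Replica k combines three coupled augmentations: a re-ordered SMILES
rendering (which permutes the atom-branch inputs), a fresh conformer of the
peptide and of every monomer (which perturbs all 3D-dependent features), and
a translated/rotated placement of the monomer-descriptor rows in the padded
sequence frame.  Replica 0 is always the canonical, unaugmented rendering so
a single-replica run equals plain featurization.  During inference the model
prediction is averaged over the same replicas.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .atomfeat import AtomFeatureSet, N_MAX_DEFAULT, conf_distance_matrix, \
    attenuation, bond_matrix, graph_distance_matrix, node_features, _pad_square
from .chem import PeptideRecord, divide_monomers, generate_conformers
from .descriptors import DescriptorVector, compute_descriptors, \
    morgan_fingerprint, N_DESCRIPTORS
from .errors import InputError, SizeError

MAX_MONOMERS_DEFAULT = 12
DEFAULT_REPLICAS = 60


def derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string/int parts."""
    text = ":".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# SMILES enumeration
# ---------------------------------------------------------------------------

def _renumbered(mol: Chem.Mol, perm: np.ndarray) -> tuple[Chem.Mol, str]:
    mol_k = Chem.RenumberAtoms(mol, [int(i) for i in perm])
    return mol_k, Chem.MolToSmiles(mol_k, canonical=False)


def enumerate_smiles(smiles: str, n: int, seed: int) -> list[str]:
    """n re-ordered SMILES renderings of one molecule (seeded, reproducible).

    Every output canonicalizes back to the parent's canonical SMILES.  The
    first rendering is the identity ordering.
    """
    if n < 1:
        raise InputError("need n >= 1 enumerated SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        perm = (np.arange(mol.GetNumAtoms()) if k == 0
                else rng.permutation(mol.GetNumAtoms()))
        out.append(_renumbered(mol, perm)[1])
    return out


# ---------------------------------------------------------------------------
# sequence arrangements
# ---------------------------------------------------------------------------

def sequence_arrangements(matrix: np.ndarray, max_len: int, n: int,
                          seed: int) -> list[np.ndarray]:
    """Translated + rotated placements of an L x D cyclic descriptor matrix.

    The arrangement grid is all (rotation, offset) pairs: L cyclic row
    rotations times (max_len - L + 1) translations within the zero-padded
    frame.  Arrangements are drawn uniformly without replacement until the
    grid is exhausted, then uniformly with replacement.
    """
    matrix = np.asarray(matrix, dtype=float)
    L = matrix.shape[0]
    if L > max_len:
        raise SizeError(f"sequence length {L} exceeds frame {max_len}")
    rng = np.random.default_rng(seed)
    grid = [(s, t) for s in range(L) for t in range(max_len - L + 1)]
    picks: list[tuple[int, int]] = []
    while len(picks) < n:
        remaining = n - len(picks)
        if remaining >= 1 and len(picks) < len(grid):
            order = rng.permutation(len(grid))
            picks.extend(grid[i] for i in order[:remaining])
        else:
            picks.extend(grid[rng.integers(len(grid))] for _ in range(remaining))
    out = []
    for s, t in picks[:n]:
        frame = np.zeros((max_len, matrix.shape[1]))
        frame[t:t + L] = np.roll(matrix, -s, axis=0)
        out.append(frame)
    return out


def place_sequence(matrix: np.ndarray, max_len: int, rotation: int = 0,
                   offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One explicit (rotation, offset) placement plus its row mask."""
    matrix = np.asarray(matrix, dtype=float)
    L = matrix.shape[0]
    if L > max_len:
        raise SizeError(f"sequence length {L} exceeds frame {max_len}")
    frame = np.zeros((max_len, matrix.shape[1]))
    frame[offset:offset + L] = np.roll(matrix, -rotation, axis=0)
    mask = np.zeros(max_len, dtype=bool)
    mask[offset:offset + L] = True
    return frame, mask


# ---------------------------------------------------------------------------
# replica construction
# ---------------------------------------------------------------------------

@dataclass
class ReplicaInput:
    """All model inputs for one replica of one peptide (unstandardized)."""

    peptide_id: str
    replica_index: int
    atom_features: AtomFeatureSet
    monomer_matrix: np.ndarray      # (max_len, 16)
    monomer_mask: np.ndarray        # (max_len,) bool
    peptide_descriptors: np.ndarray  # (16,)
    fingerprint: np.ndarray         # (2048,) uint8
    label: float | None


# monomer descriptors depend only on (capped smiles, conformer seed); cache
# them so repeated monomers across peptides are computed once
_MONOMER_DESC_CACHE: dict[tuple[str, int], np.ndarray] = {}


def _monomer_descriptors(capped_smiles: str, seed: int) -> np.ndarray:
    key = (capped_smiles, seed)
    if key not in _MONOMER_DESC_CACHE:
        conf = generate_conformers(capped_smiles, 1, seed, capped_smiles)
        vec = compute_descriptors(capped_smiles, conf.coordinates[0])
        _MONOMER_DESC_CACHE[key] = vec.values
    return _MONOMER_DESC_CACHE[key]


def build_replicas(record: PeptideRecord, r: int = DEFAULT_REPLICAS,
                   seed: int = 0, n_max: int = N_MAX_DEFAULT,
                   max_len: int = MAX_MONOMERS_DEFAULT) -> list[ReplicaInput]:
    """Build the r augmented feature bundles for one peptide.

    Replica k uses: enumerated atom order k (identity for k=0), peptide
    conformer k, monomer conformers k, and sequence arrangement k (identity
    placement for k=0).  All replicas carry the parent's label.  Fully
    reproducible from (record, r, seed).
    """
    if r < 1:
        raise InputError("replica count must be >= 1")
    mol = record.mol()
    if mol is None:
        raise InputError(f"{record.id}: unparsable SMILES")
    units = divide_monomers(record)
    L = len(units)
    if L > max_len:
        raise SizeError(f"{record.id}: {L} monomers exceed frame {max_len}")

    fingerprint = morgan_fingerprint(record.smiles)
    node_parent = node_features(mol)
    bond_parent = bond_matrix(mol)
    graph_parent = graph_distance_matrix(mol)
    n = mol.GetNumAtoms()
    if n > n_max:
        raise SizeError(f"{record.id}: {n} atoms exceed padding {n_max}")

    conf_seed = derive_seed(seed, record.id, "peptide-conf")
    conformers = generate_conformers(record.smiles, r, conf_seed, record.id)

    perm_rng = np.random.default_rng(derive_seed(seed, record.id, "atom-order"))
    arr_rng_seed = derive_seed(seed, record.id, "arrangement")

    mono_raw = {}  # (pos, k) -> 16-vector; computed lazily below

    replicas = []
    arrangements = None
    sub_mask = np.ones(n, dtype=bool)
    for k in range(r):
        perm = np.arange(n) if k == 0 else perm_rng.permutation(n)
        mol_k = Chem.RenumberAtoms(mol, [int(i) for i in perm])
        # coordinates follow the same renumbering: new atom i was old perm[i]
        coords_k = conformers.coordinates[k][perm]
        node = np.zeros((n_max, node_parent.shape[1]))
        node[:n] = node_features(mol_k)
        bond = bond_matrix(mol_k)
        graph = graph_distance_matrix(mol_k)
        conf = conf_distance_matrix(coords_k)
        mask = np.zeros(n_max, dtype=bool)
        mask[:n] = True
        atom_features = AtomFeatureSet(
            node=node,
            bond=_pad_square(bond, n_max),
            graph=_pad_square(graph, n_max),
            conf=_pad_square(conf, n_max),
            strength_graph=_pad_square(attenuation(graph, sub_mask), n_max),
            strength_conf=_pad_square(attenuation(conf, sub_mask), n_max),
            mask=mask,
        )

        pep_desc = compute_descriptors(record.smiles,
                                       conformers.coordinates[k]).values

        rows = np.empty((L, N_DESCRIPTORS))
        for u in units:
            mono_seed = derive_seed(seed, u.capped_smiles, "mono-conf", k)
            rows[u.position] = _monomer_descriptors(u.capped_smiles, mono_seed)
        if k == 0:
            frame, mono_mask = place_sequence(rows, max_len, 0, 0)
        else:
            if arrangements is None:
                arrangements = _arrangement_picks(L, max_len, r - 1,
                                                  arr_rng_seed)
            s, t = arrangements[k - 1]
            frame, mono_mask = place_sequence(rows, max_len, s, t)

        replicas.append(ReplicaInput(
            peptide_id=record.id,
            replica_index=k,
            atom_features=atom_features,
            monomer_matrix=frame,
            monomer_mask=mono_mask,
            peptide_descriptors=pep_desc,
            fingerprint=fingerprint,
            label=record.label,
        ))
    return replicas


def _arrangement_picks(L: int, max_len: int, n: int, seed: int
                       ) -> list[tuple[int, int]]:
    """(rotation, offset) draws: without replacement, then with, once spent."""
    rng = np.random.default_rng(seed)
    grid = [(s, t) for s in range(L) for t in range(max_len - L + 1)]
    picks: list[tuple[int, int]] = []
    while len(picks) < n:
        if len(picks) < len(grid):
            order = rng.permutation(len(grid))
            picks.extend(grid[i] for i in order[:n - len(picks)])
        else:
            picks.extend(grid[rng.integers(len(grid))]
                         for _ in range(n - len(picks)))
    return picks[:n]
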