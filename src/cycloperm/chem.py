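"""Molecule handling for cyclic peptides.

A cyclic peptide is represented by a :class:`PeptideRecord`.  The macrocycle
is divided into residue-level monomers by cleaving only the backbone amide
(C(=O)-N) and ester (C(=O)-O) bonds that lie inside the largest ring; the cut
ends are chemically capped so each monomer keeps realistic local
physicochemistry: the amine nitrogen (or ester oxygen) gains a methyl group
and the acyl carbon becomes an aldehyde.  3D conformations are produced with
seeded distance-geometry embedding followed by UFF minimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import (
    ChemistryError,
    ConformerError,
    DivisionError,
    InputError,
    SizeError,
)

RDLogger.DisableLog("rdApp.*")

MAX_HEAVY_ATOMS = 128  # largest peptide the featurization is sized for
MACROCYCLE_MIN_SIZE = 9  # smallest ring treated as a peptide macrocycle


@dataclass
class MonomerUnit:
    """One residue of a divided macrocycle, in cyclic order."""

    position: int
    atom_indices: tuple[int, ...]
    capped_smiles: str


@dataclass
class PeptideRecord:
    """A single cyclic peptide with optional monomer annotation and label."""

    id: str
    smiles: str
    monomers: list[MonomerUnit] | None = None
    label: float | None = None
    assay: str | None = None

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class ConformerSet:
    """Heavy-atom coordinate ensembles for one molecule (parent atom order)."""

    parent_id: str
    coordinates: list[np.ndarray] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)


def parse_peptide(
    id: str,
    smiles: str,
    monomer_smiles: list[str] | None = None,
    label: float | None = None,
    assay: str | None = None,
    max_heavy_atoms: int = MAX_HEAVY_ATOMS,
) -> PeptideRecord:
    """Validate a SMILES and build a :class:`PeptideRecord`.

    ``monomer_smiles``, when given, is an ordered list of capped monomer
    SMILES attached as annotation (atom indices unknown).
    """
    if not smiles:
        raise InputError(f"{id}: empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"{id}: unparsable SMILES {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise InputError(f"{id}: SMILES is not a single connected molecule")
    if mol.GetNumHeavyAtoms() > max_heavy_atoms:
        raise SizeError(
            f"{id}: {mol.GetNumHeavyAtoms()} heavy atoms exceeds "
            f"maximum {max_heavy_atoms}"
        )
    monomers = None
    if monomer_smiles is not None:
        monomers = []
        for pos, msmi in enumerate(monomer_smiles):
            if Chem.MolFromSmiles(msmi) is None:
                raise InputError(f"{id}: unparsable monomer SMILES {msmi!r}")
            monomers.append(MonomerUnit(pos, (), Chem.CanonSmiles(msmi)))
    return PeptideRecord(id=id, smiles=smiles, monomers=monomers,
                         label=label, assay=assay)


# ---------------------------------------------------------------------------
# monomer division
# ---------------------------------------------------------------------------

def _largest_macrocycle(mol: Chem.Mol) -> list[int] | None:
    rings = [list(r) for r in Chem.GetSymmSSSR(mol)]
    rings = [r for r in rings if len(r) >= MACROCYCLE_MIN_SIZE]
    if not rings:
        return None
    return max(rings, key=len)


def _is_acyl_carbon(atom: Chem.Atom) -> bool:
    """Carbon double-bonded to an oxygen (carbonyl carbon)."""
    if atom.GetAtomicNum() != 6:
        return False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def _backbone_cleavage_bonds(mol: Chem.Mol, ring: list[int]) -> list[tuple[int, int]]:
    """(acyl C, N/O) index pairs of amide/ester bonds inside the macrocycle."""
    ring_set = set(ring)
    n = len(ring)
    pairs = []
    for i in range(n):
        a_idx, b_idx = ring[i], ring[(i + 1) % n]
        bond = mol.GetBondBetweenAtoms(a_idx, b_idx)
        if bond is None or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = mol.GetAtomWithIdx(a_idx), mol.GetAtomWithIdx(b_idx)
        for c_at, x_at in ((a, b), (b, a)):
            if not _is_acyl_carbon(c_at):
                continue
            if x_at.GetAtomicNum() in (7, 8) and x_at.GetIdx() in ring_set:
                pairs.append((c_at.GetIdx(), x_at.GetIdx()))
                break
    return pairs


def cap_fragment(fragment: Chem.Mol) -> str:
    """Cap the cleaved ends of a monomer fragment and return its SMILES.

    The fragment carries one dummy atom per cleaved bond end.  A dummy bonded
    to N (cleaved amide) or O (cleaved ester) is turned into a methyl carbon;
    a dummy bonded to the acyl carbon is removed so the carbonyl becomes an
    aldehyde.  A fragment without dummies is returned unchanged (canonical).
    """
    em = Chem.RWMol(fragment)
    to_remove = []
    for atom in em.GetAtoms():
        if atom.GetAtomicNum() != 0:
            continue
        neighbors = atom.GetNeighbors()
        if len(neighbors) != 1:
            raise ChemistryError("cleavage marker with unexpected connectivity")
        nb = neighbors[0]
        if nb.GetAtomicNum() in (7, 8):
            atom.SetAtomicNum(6)  # methyl cap on amine N / ester O
            atom.SetIsotope(0)
        else:
            to_remove.append(atom.GetIdx())  # acyl end: aldehyde via implicit H
    for idx in sorted(to_remove, reverse=True):
        em.RemoveAtom(idx)
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - valence pathologies
        raise ChemistryError(f"capping produced invalid molecule: {exc}") from exc
    return Chem.MolToSmiles(mol)


def divide_monomers(record: PeptideRecord) -> list[MonomerUnit]:
    """Divide a macrocyclic peptide into capped, cyclically ordered monomers.

    Only backbone amide/ester bonds inside the largest macrocycle are cleaved;
    side-chain bonds are untouched.  Units are ordered N->C starting from the
    unit containing the atom of lowest canonical rank.  A record carrying a
    monomer annotation is returned as annotated.
    """
    if record.monomers:
        return record.monomers
    mol = record.mol()
    if mol is None:
        raise InputError(f"{record.id}: unparsable SMILES")
    ring = _largest_macrocycle(mol)
    if ring is None:
        raise DivisionError(f"{record.id}: no macrocycle of size >= "
                            f"{MACROCYCLE_MIN_SIZE} found")
    cleave = _backbone_cleavage_bonds(mol, ring)
    if not cleave:
        raise DivisionError(f"{record.id}: no backbone amide/ester bonds in "
                            "the macrocycle")
    bond_ids = [mol.GetBondBetweenAtoms(c, x).GetIdx() for c, x in cleave]
    frag_mol = Chem.FragmentOnBonds(mol, bond_ids, addDummies=True)
    n_parent = mol.GetNumAtoms()
    frag_indices = Chem.GetMolFrags(frag_mol)
    frag_mols = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)

    atom_to_frag = {}
    for fi, indices in enumerate(frag_indices):
        for idx in indices:
            if idx < n_parent:
                atom_to_frag[idx] = fi

    # successor chain: cleaved bond (acyl C in unit u) -> (N/O in next unit)
    successor = {atom_to_frag[c]: atom_to_frag[x] for c, x in cleave}
    if len(successor) != len(frag_indices):
        raise DivisionError(f"{record.id}: division produced a non-cyclic "
                            "fragment arrangement")

    ranks = list(Chem.CanonicalRankAtoms(mol))
    frag_rank = [
        min(ranks[idx] for idx in indices if idx < n_parent)
        for indices in frag_indices
    ]
    start = int(np.argmin(frag_rank))
    order = [start]
    while len(order) < len(frag_indices):
        nxt = successor[order[-1]]
        if nxt in order:
            raise DivisionError(f"{record.id}: fragment cycle shorter than "
                                "fragment count")
        order.append(nxt)

    units = []
    for pos, fi in enumerate(order):
        parent_atoms = tuple(sorted(i for i in frag_indices[fi] if i < n_parent))
        units.append(MonomerUnit(pos, parent_atoms, cap_fragment(frag_mols[fi])))
    return units


# ---------------------------------------------------------------------------
# conformer generation
# ---------------------------------------------------------------------------

UFF_MAX_ITERS = 200
EMBED_RETRIES = 5


def _embed_once(molh: Chem.Mol, seed: int, random_coords: bool) -> int:
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.useRandomCoords = random_coords
    return AllChem.EmbedMolecule(molh, params)


def generate_conformers(smiles: str, n: int, base_seed: int,
                        parent_id: str = "", uff_max_iters: int = UFF_MAX_ITERS
                        ) -> ConformerSet:
    """Generate ``n`` UFF-minimized distance-geometry conformers.

    Conformer ``k`` uses seed ``base_seed + k``; embedding is retried up to
    :data:`EMBED_RETRIES` times with a random-coordinate fallback before
    raising :class:`ConformerError`.  Coordinates are heavy atoms only, in the
    parent atom order, in Angstrom.
    """
    if n < 1:
        raise InputError("conformer count must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    n_heavy = mol.GetNumHeavyAtoms()
    out = ConformerSet(parent_id=parent_id or smiles)
    for k in range(n):
        seed = base_seed + k
        molh = Chem.AddHs(Chem.Mol(mol))
        conf_id = -1
        for attempt in range(EMBED_RETRIES):
            conf_id = _embed_once(molh, seed + 7919 * attempt, attempt > 0)
            if conf_id >= 0:
                break
        if conf_id < 0:
            raise ConformerError(
                f"embedding failed for {out.parent_id!r} (smiles {smiles!r})"
            )
        try:
            ff = AllChem.UFFGetMoleculeForceField(molh)
            if ff is not None:
                ff.Minimize(maxIts=uff_max_iters)
        except Exception:
            pass  # keep the unminimized embedding
        coords = molh.GetConformer().GetPositions()[:n_heavy].astype(np.float64)
        if not np.all(np.isfinite(coords)):
            raise ConformerError(f"non-finite coordinates for {out.parent_id!r}")
        out.coordinates.append(coords)
        out.seeds.append(seed)
    return out


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def parse_helm_sequence(helm: str) -> list[str]:
    """Extract an ordered monomer-id list from a HELM-style string.

    Accepts either a bare dot-separated list (``Gly.Ala.Sar``) or a simple
    polymer section (``PEPTIDE1{Gly.Ala.Sar}$$$$``).
    """
    text = helm.strip()
    if "{" in text:
        try:
            text = text.split("{", 1)[1].split("}", 1)[0]
        except IndexError as exc:
            raise InputError(f"malformed HELM string {helm!r}") from exc
    ids = [t.strip().strip("[]") for t in text.split(".") if t.strip()]
    if not ids:
        raise InputError(f"no monomer ids in HELM string {helm!r}")
    return ids


def read_monomer_library(path) -> dict[str, str]:
    """Read a monomer library CSV with columns monomer_id,smiles."""
    df = pd.read_csv(path)
    for col in ("monomer_id", "smiles"):
        if col not in df.columns:
            raise InputError(f"monomer library missing column {col!r}")
    return dict(zip(df["monomer_id"].astype(str), df["smiles"].astype(str)))


def read_records_csv(path, monomer_library: dict[str, str] | None = None,
                     use_helm: bool = True) -> list[PeptideRecord]:
    """Read peptide records from a CSV with columns id,smiles[,helm][,label].

    ``use_helm=False`` skips the monomer annotation entirely (for commands
    that only need structures, e.g. splitting).
    """
    df = pd.read_csv(path)
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise InputError(f"records CSV missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        monomer_smiles = None
        if (use_helm and "helm" in df.columns
                and isinstance(row.get("helm"), str) and row["helm"]):
            if monomer_library is None:
                raise InputError("HELM column present but no monomer library given")
            ids = parse_helm_sequence(row["helm"])
            try:
                monomer_smiles = [monomer_library[i] for i in ids]
            except KeyError as exc:
                raise InputError(f"unknown monomer id {exc.args[0]!r}") from exc
        label = None
        if "label" in df.columns and pd.notna(row.get("label")):
            label = float(row["label"])
        records.append(parse_peptide(str(row["id"]), str(row["smiles"]),
                                     monomer_smiles, label))
    return records


def write_conformers_sdf(conformers: ConformerSet, smiles: str, path) -> None:
    """Write each conformer as one SDF record tagged with parent id and seed."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    writer = Chem.SDWriter(str(path))
    try:
        for coords, seed in zip(conformers.coordinates, conformers.seeds):
            m = Chem.Mol(mol)
            conf = Chem.Conformer(m.GetNumAtoms())
            for i in range(m.GetNumAtoms()):
                conf.SetAtomPosition(i, tuple(float(v) for v in coords[i]))
            m.AddConformer(conf, assignId=True)
            m.SetProp("parent_id", conformers.parent_id)
            m.SetProp("seed", str(seed))
            writer.write(m)
    finally:
        writer.close()
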