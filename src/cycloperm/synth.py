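"""Synthetic cyclic-peptide datasets with a known structure->label function.

Peptides are head-to-tail macrocycles of 5-12 residues drawn from a ~26
monomer alphabet (natural, N-methylated and D amino acids, echoing the
dominance of non-natural residues in measured permeability libraries).  The
ground-truth label is a clipped linear function of cohort-z-scored
lipophilicity (Crippen logP), topological polar surface area and H-bond
donor count plus Gaussian noise - the descriptor families known to drive
passive membrane permeation - so the learning task is realistic and the
pipeline's recovery of the relationship is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .augment import derive_seed
from .chem import MonomerUnit, PeptideRecord
from .errors import ChemistryError, InputError

#: monomer id -> SMILES (free amine + free carboxylic acid)
ALPHABET: dict[str, str] = {
    # natural L-amino acids (small/medium side chains)
    "Gly": "NCC(=O)O",
    "Ala": "N[C@@H](C)C(=O)O",
    "Abu": "N[C@@H](CC)C(=O)O",
    "Val": "N[C@@H](C(C)C)C(=O)O",
    "Leu": "N[C@@H](CC(C)C)C(=O)O",
    "Ile": "N[C@@H]([C@@H](C)CC)C(=O)O",
    "Pro": "OC(=O)[C@@H]1CCCN1",
    "Phe": "N[C@@H](Cc1ccccc1)C(=O)O",
    "Ser": "N[C@@H](CO)C(=O)O",
    "Thr": "N[C@@H]([C@@H](O)C)C(=O)O",
    "Met": "N[C@@H](CCSC)C(=O)O",
    "Asn": "N[C@@H](CC(N)=O)C(=O)O",
    "Gln": "N[C@@H](CCC(N)=O)C(=O)O",
    "Tyr": "N[C@@H](Cc1ccc(O)cc1)C(=O)O",
    # N-methylated
    "Sar": "CNCC(=O)O",
    "MeAla": "CN[C@@H](C)C(=O)O",
    "MeVal": "CN[C@@H](C(C)C)C(=O)O",
    "MeLeu": "CN[C@@H](CC(C)C)C(=O)O",
    "MeIle": "CN[C@@H]([C@@H](C)CC)C(=O)O",
    "MePhe": "CN[C@@H](Cc1ccccc1)C(=O)O",
    # D-amino acids
    "dAla": "N[C@H](C)C(=O)O",
    "dVal": "N[C@H](C(C)C)C(=O)O",
    "dLeu": "N[C@H](CC(C)C)C(=O)O",
    "dPhe": "N[C@H](Cc1ccccc1)C(=O)O",
    "dPro": "OC(=O)[C@H]1CCCN1",
    "dMeAla": "CN[C@H](C)C(=O)O",
}

_AMINE = Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O)]")
_CARBOXYL = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")


@dataclass
class SynthConfig:
    n_peptides: int = 100
    length_range: tuple[int, int] = (5, 12)
    alphabet: dict[str, str] = field(default_factory=lambda: dict(ALPHABET))
    label_coefficients: tuple[float, float, float] = (0.8, 0.5, 0.4)
    noise_sd: float = 0.3
    seed: int = 0
    max_heavy_atoms: int = 128

    def __post_init__(self):
        if self.length_range[0] < 3:
            raise InputError("minimum length must be >= 3")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")

    def to_manifest(self) -> dict:
        return {
            "n_peptides": self.n_peptides,
            "length_range": list(self.length_range),
            "alphabet": dict(self.alphabet),
            "label_coefficients": list(self.label_coefficients),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "max_heavy_atoms": self.max_heavy_atoms,
        }

    @classmethod
    def from_manifest(cls, d: dict) -> "SynthConfig":
        return cls(n_peptides=d["n_peptides"],
                   length_range=tuple(d["length_range"]),
                   alphabet=dict(d["alphabet"]),
                   label_coefficients=tuple(d["label_coefficients"]),
                   noise_sd=d["noise_sd"], seed=d["seed"],
                   max_heavy_atoms=d.get("max_heavy_atoms", 128))


def _reactive_sites(mol: Chem.Mol) -> tuple[int, int, int]:
    """(amine N, carboxyl C, hydroxyl O) indices of one amino-acid monomer."""
    am = mol.GetSubstructMatches(_AMINE)
    cx = mol.GetSubstructMatches(_CARBOXYL)
    if len(am) < 1 or len(cx) < 1:
        raise ChemistryError("monomer lacks a free amine or carboxylic acid")
    n_idx = am[0][0]
    c_idx, _, oh_idx = cx[0]
    return n_idx, c_idx, oh_idx


def _capped_monomer_smiles(smiles: str) -> str:
    """The capped (N-methyl + aldehyde) form a division of the cycle yields."""
    mol = Chem.MolFromSmiles(smiles)
    n_idx, c_idx, oh_idx = _reactive_sites(mol)
    em = Chem.RWMol(mol)
    new_c = em.AddAtom(Chem.Atom(6))
    em.AddBond(n_idx, new_c, Chem.BondType.SINGLE)
    em.RemoveAtom(oh_idx)
    out = em.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def assemble_macrocycle(monomer_smiles: list[str]
                        ) -> tuple[str, list[tuple[int, ...]]]:
    """Head-to-tail condensation of monomers into one macrocyclic SMILES.

    Returns the SMILES and, per monomer, the tuple of its heavy-atom indices
    in the assembled molecule.
    """
    mols = []
    sites = []
    for smi in monomer_smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InputError(f"unparsable monomer SMILES {smi!r}")
        mols.append(mol)
        sites.append(_reactive_sites(mol))
    combined = mols[0]
    offsets = [0]
    for mol in mols[1:]:
        offsets.append(combined.GetNumAtoms())
        combined = Chem.CombineMols(combined, mol)
    em = Chem.RWMol(combined)
    L = len(mols)
    remove = []
    for i in range(L):
        n_i, c_i, oh_i = sites[i]
        nxt = (i + 1) % L
        em.AddBond(offsets[i] + c_i, offsets[nxt] + sites[nxt][0],
                   Chem.BondType.SINGLE)
        remove.append(offsets[i] + oh_i)
    for idx in sorted(remove, reverse=True):
        em.RemoveAtom(idx)
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise ChemistryError(f"cyclization failed: {exc}") from exc
    removed = np.array(sorted(remove))
    member_indices = []
    for i in range(L):
        block = range(offsets[i],
                      offsets[i] + mols[i].GetNumAtoms())
        kept = []
        for idx in block:
            if idx in remove:
                continue
            kept.append(idx - int(np.searchsorted(removed, idx)))
        member_indices.append(tuple(kept))
    smiles = Chem.MolToSmiles(mol)
    # the canonical SMILES re-parses in the writer's output order; remap the
    # recorded indices into that order so they match record.mol()
    out_order = mol.GetPropsAsDict(
        includePrivate=True, includeComputed=True)["_smilesAtomOutputOrder"]
    new_of_old = {int(old): new for new, old in enumerate(out_order)}
    member_indices = [tuple(sorted(new_of_old[a] for a in grp))
                      for grp in member_indices]
    return smiles, member_indices


def sample_peptide(config: SynthConfig, index: int) -> PeptideRecord:
    """Draw one cyclic peptide (deterministic in (config.seed, index)).

    The record carries a ground-truth monomer annotation with true atom
    indices; oversized draws are rejected and resampled.
    """
    names = sorted(config.alphabet)
    lo, hi = config.length_range
    for attempt in range(50):
        rng = np.random.default_rng(
            derive_seed(config.seed, "peptide", index, attempt))
        length = int(rng.integers(lo, hi + 1))
        chosen = [names[i] for i in rng.integers(0, len(names), length)]
        smiles, members = assemble_macrocycle(
            [config.alphabet[c] for c in chosen])
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None and mol.GetNumHeavyAtoms() <= config.max_heavy_atoms:
            units = [
                MonomerUnit(pos, members[pos],
                            _capped_monomer_smiles(config.alphabet[c]))
                for pos, c in enumerate(chosen)
            ]
            rec = PeptideRecord(id=f"synth-{index:05d}", smiles=smiles,
                                monomers=units, assay="synthetic")
            rec.sequence = chosen  # type: ignore[attr-defined]
            return rec
    raise ChemistryError(f"could not sample a valid peptide at index {index}")


def label_drivers(record: PeptideRecord) -> tuple[float, float, float]:
    """(Crippen logP, TPSA, H-bond donor count) of the whole macrocycle."""
    mol = record.mol()
    return (float(Crippen.MolLogP(mol)),
            float(Descriptors.TPSA(mol)),
            float(rdMolDescriptors.CalcNumHBD(mol)))


def synth_label(record: PeptideRecord, config: SynthConfig,
                driver_stats: tuple[np.ndarray, np.ndarray]) -> float:
    """Ground-truth log10 permeability for one record.

    label = clip(-6.5 + c1 z(logP) - c2 z(TPSA) - c3 z(HBD) + eps, -8, -4)
    with eps ~ N(0, noise_sd^2) drawn deterministically per record id and
    z-scores taken against the cohort statistics in ``driver_stats``.
    """
    means, stds = driver_stats
    z = (np.array(label_drivers(record)) - means) / np.where(stds > 0, stds, 1)
    c1, c2, c3 = config.label_coefficients
    rng = np.random.default_rng(derive_seed(config.seed, "label", record.id))
    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
    raw = -6.5 + c1 * z[0] - c2 * z[1] - c3 * z[2] + eps
    return float(np.clip(raw, -8.0, -4.0))


def make_dataset(config: SynthConfig
                 ) -> tuple[list[PeptideRecord], dict]:
    """Generate the labelled cohort plus a manifest for exact regeneration."""
    records = [sample_peptide(config, i) for i in range(config.n_peptides)]
    drivers = np.array([label_drivers(r) for r in records])
    stats = (drivers.mean(axis=0), drivers.std(axis=0, ddof=0))
    for rec in records:
        rec.label = synth_label(rec, config, stats)
    manifest = {"config": config.to_manifest(),
                "driver_means": stats[0].tolist(),
                "driver_stds": stats[1].tolist()}
    return records, manifest


def dataset_frame(records: list[PeptideRecord]) -> pd.DataFrame:
    """The standard records table (id, smiles, helm, label)."""
    return pd.DataFrame({
        "id": [r.id for r in records],
        "smiles": [r.smiles for r in records],
        "helm": [".".join(getattr(r, "sequence", []))
                 if getattr(r, "sequence", None) else "" for r in records],
        "label": [r.label for r in records],
    })


def alphabet_frame(config: SynthConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {"monomer_id": list(config.alphabet),
         "smiles": [config.alphabet[k] for k in config.alphabet]})
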