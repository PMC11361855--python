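"""Physicochemical descriptors, fingerprints, standardization and selection.

Peptides and monomers are each summarized by the same 16 descriptors
(7 topological, 9 conformation-dependent), dominated by lipophilicity,
density and charged-surface-area terms — the descriptor families that drive
passive membrane permeation.  Descriptors originally defined in commercial
or unavailable software are computed here from documented open equivalents:
Gasteiger partial charges, FreeSASA solvent-accessible areas, a group-
contribution van der Waals volume and a convex-hull 3D volume (see
docs/methods.md for the mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Descriptors3D, Fragments
from rdkit.Chem import rdFreeSASA, rdMolDescriptors
from scipy.spatial import ConvexHull, QhullError
from sklearn.ensemble import RandomForestRegressor

from .errors import DescriptorError, FitError, InputError, SelectionError

#: the 16 descriptors, in decreasing importance order (7 x 2D then 9 x 3D)
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Vsa_EState9",
    "density",
    "MolLogP",
    "fr_Al_OH",
    "logP_ow",
    "lip_violation",
    "h_logD",
    "dens",
    "FNSA4",
    "RNCS",
    "FASA_neg",
    "FCASA_pos",
    "FAsa_P",
    "FNSA2",
    "FNSA5",
    "vsurf_Wp2",
)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)


@dataclass
class DescriptorVector:
    names: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False


# ---------------------------------------------------------------------------
# volume / surface helpers
# ---------------------------------------------------------------------------

# Zhao-style group-contribution atomic van der Waals volumes (A^3)
_ATOM_VOLUME = {
    1: 7.24, 6: 20.58, 7: 15.60, 8: 14.71, 9: 13.31, 15: 24.43,
    16: 24.43, 17: 22.45, 35: 26.52, 53: 32.52,
}


def _vdw_volume_2d(mol: Chem.Mol) -> float:
    """Group-contribution van der Waals volume with ring/bond corrections."""
    v = 0.0
    n_h = 0
    for atom in mol.GetAtoms():
        v += _ATOM_VOLUME.get(atom.GetAtomicNum(), 20.0)
        n_h += atom.GetTotalNumHs()
    v += n_h * _ATOM_VOLUME[1]
    n_bonds = mol.GetNumBonds() + n_h
    ri = mol.GetRingInfo()
    n_arom = sum(1 for r in ri.BondRings()
                 if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in r))
    n_ali = ri.NumRings() - n_arom
    return v - 5.92 * n_bonds - 14.7 * n_arom - 3.8 * n_ali


def _hull_volume(coordinates: np.ndarray) -> float | None:
    if coordinates.shape[0] < 4:
        return None
    try:
        return float(ConvexHull(coordinates).volume)
    except QhullError:
        return None


_POLAR_Z = (7, 8, 16)  # N, O, S


def _gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    AllChem.ComputeGasteigerCharges(mol)
    q = np.empty(mol.GetNumAtoms())
    for i, atom in enumerate(mol.GetAtoms()):
        qi = atom.GetDoubleProp("_GasteigerCharge")
        if atom.HasProp("_GasteigerHCharge"):
            qi += atom.GetDoubleProp("_GasteigerHCharge")
        q[i] = qi
    if not np.all(np.isfinite(q)):
        raise DescriptorError("Gasteiger charges are non-finite")
    return q


def _atom_sasa(mol: Chem.Mol, coordinates: np.ndarray) -> np.ndarray:
    """Per-heavy-atom solvent-accessible surface area (A^2) via FreeSASA."""
    m = Chem.Mol(mol)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i in range(m.GetNumAtoms()):
        conf.SetAtomPosition(i, tuple(float(v) for v in coordinates[i]))
    m.AddConformer(conf, assignId=True)
    pt = Chem.GetPeriodicTable()
    radii = [pt.GetRvdw(a.GetAtomicNum()) for a in m.GetAtoms()]
    rdFreeSASA.CalcSASA(m, radii)
    return np.array([float(a.GetProp("SASA")) for a in m.GetAtoms()])


def _cpsa_family(mol: Chem.Mol, coordinates: np.ndarray) -> dict[str, float]:
    """Charged-partial-surface-area descriptors (Stanton–Jurs style).

    All fractional terms are normalized by the total SASA; see methods note
    for the exact version definitions used here.
    """
    q = _gasteiger_charges(mol)
    sasa = _atom_sasa(mol, coordinates)
    total = float(sasa.sum())
    if total <= 0:
        raise DescriptorError("zero total surface area")
    neg = q < 0
    pos = q > 0
    q_neg_total = float(q[neg].sum())  # <= 0
    pnsa1 = float(sasa[neg].sum())
    pnsa2 = pnsa1 * q_neg_total
    pnsa3 = float((q[neg] * sasa[neg]).sum())
    n_neg = max(int(neg.sum()), 1)
    out = {
        "FNSA2": pnsa2 / total,
        "FNSA4": (pnsa1 * (q_neg_total / n_neg)) / total,
        "FNSA5": (pnsa3 / n_neg) / total,
        "FASA_neg": pnsa1 / total,
        "FCASA_pos": float((q[pos] * sasa[pos]).sum()) / total,
    }
    polar = np.array([a.GetAtomicNum() in _POLAR_Z for a in mol.GetAtoms()])
    out["FAsa_P"] = float(sasa[polar].sum()) / total
    if neg.any() and q_neg_total < 0:
        i_min = int(np.argmin(q))
        out["RNCS"] = float(sasa[i_min]) * (q[i_min] / q_neg_total)
    else:
        out["RNCS"] = 0.0
    return out


_ACID_SMARTS = Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-]")
_BASE_SMARTS = Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O);!$(N=*)]")


def compute_descriptors(smiles: str, coordinates: np.ndarray) -> DescriptorVector:
    """Compute the 16-descriptor vector for one molecule + one conformation.

    ``coordinates`` are heavy-atom positions (A) matching the SMILES atom
    order, e.g. one member of a :class:`~cycloperm.chem.ConformerSet`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (mol.GetNumHeavyAtoms(), 3):
        raise InputError("coordinates do not match the molecule's heavy atoms")
    values: dict[str, float] = {}
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    try:
        values["Vsa_EState9"] = float(Descriptors.VSA_EState9(mol))
        values["density"] = mw / max(_vdw_volume_2d(mol), 1e-6)
        values["MolLogP"] = logp
        values["fr_Al_OH"] = float(Fragments.fr_Al_OH(mol))
        values["logP_ow"] = float(Crippen.MolLogP(Chem.AddHs(mol)))
        hbd = rdMolDescriptors.CalcNumHBD(mol)
        hba = rdMolDescriptors.CalcNumHBA(mol)
        values["lip_violation"] = float(
            (mw > 500) + (logp > 5) + (hbd > 5) + (hba > 10)
        )
        n_ionizable = len(mol.GetSubstructMatches(_ACID_SMARTS)) + len(
            mol.GetSubstructMatches(_BASE_SMARTS)
        )
        values["h_logD"] = logp - 1.0 * n_ionizable
        hull = _hull_volume(coordinates)
        values["dens"] = mw / hull if hull and hull > 1.0 else mw / max(
            _vdw_volume_2d(mol), 1e-6
        )
        values.update(_cpsa_family(mol, coordinates))
        pt = Chem.GetPeriodicTable()
        values["vsurf_Wp2"] = float(sum(
            4.0 / 3.0 * np.pi * pt.GetRvdw(a.GetAtomicNum()) ** 3
            for a in mol.GetAtoms() if a.GetAtomicNum() in _POLAR_Z
        ))
    except DescriptorError:
        raise
    except Exception as exc:
        raise DescriptorError(f"descriptor computation failed: {exc}") from exc
    vec = np.array([values[n] for n in DESCRIPTOR_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(DESCRIPTOR_NAMES, vec) if not np.isfinite(v)]
        raise DescriptorError(f"non-finite descriptors: {bad}")
    return DescriptorVector(DESCRIPTOR_NAMES, vec)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class Standardizer:
    """Z-score standardization with statistics frozen at fit time.

    Population standard deviation (ddof=0); columns with zero spread are
    rejected at fit so a standardized column always has unit variance on the
    fitting table.
    """

    def __init__(self, means: np.ndarray, stds: np.ndarray,
                 names: tuple[str, ...] | None = None):
        self.means = np.asarray(means, dtype=float)
        self.stds = np.asarray(stds, dtype=float)
        self.names = names

    @classmethod
    def fit(cls, table: np.ndarray, names: tuple[str, ...] | None = None,
            on_constant: str = "error") -> "Standardizer":
        """Fit column means/stds.  A zero-spread column is an error by
        default; ``on_constant="unit"`` keeps it with unit scale instead
        (its standardized values are exactly 0), which the featurization
        pipeline uses for descriptors that are legitimately constant on a
        cohort (e.g. rule-of-five violations over single residues)."""
        table = np.asarray(table, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2:
            raise FitError("standardizer needs a 2D table with >= 2 rows")
        means = table.mean(axis=0)
        stds = table.std(axis=0, ddof=0)
        zero = np.nonzero(stds <= 0)[0]
        if zero.size:
            if on_constant == "unit":
                stds = stds.copy()
                stds[zero] = 1.0
            else:
                labels = ([names[i] for i in zero] if names is not None
                          else zero.tolist())
                raise FitError(f"zero-spread columns: {labels}")
        return cls(means, stds, names)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means) / self.stds

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.stds + self.means

    def apply_vector(self, vector: DescriptorVector) -> DescriptorVector:
        return DescriptorVector(vector.names, self.apply(vector.values),
                                standardized=True)

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "stds": self.stds.tolist(),
                "names": list(self.names) if self.names else None}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        names = tuple(d["names"]) if d.get("names") else None
        return cls(np.array(d["means"]), np.array(d["stds"]), names)


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def morgan_fingerprint(smiles: str) -> np.ndarray:
    """2048-bit Morgan fingerprint: 1024 bits radius 2 then 1024 bits radius 3."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    out = np.zeros(2048, dtype=np.uint8)
    for half, radius in enumerate((2, 3)):
        bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=1024)
        for bit in bv.GetOnBits():
            out[half * 1024 + bit] = 1
    return out


# ---------------------------------------------------------------------------
# descriptor pool + selection
# ---------------------------------------------------------------------------

def compute_descriptor_pool(smiles: str, coordinates: np.ndarray
                            ) -> tuple[dict[str, float], dict[str, str]]:
    """A wide descriptor pool (all RDKit 2D descriptors + 3D shape/CPSA terms).

    Returns (values, tags) where tags maps each descriptor name to "2D"/"3D".
    Used to exercise the selection pipeline; the production feature set is
    the fixed 16 of :data:`DESCRIPTOR_NAMES`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES {smiles!r}")
    values: dict[str, float] = {}
    tags: dict[str, str] = {}
    for name, fn in Descriptors.descList:
        try:
            values[name] = float(fn(mol))
        except Exception:
            values[name] = np.nan
        tags[name] = "2D"
    m3 = Chem.Mol(mol)
    conf = Chem.Conformer(m3.GetNumAtoms())
    for i in range(m3.GetNumAtoms()):
        conf.SetAtomPosition(i, tuple(float(v) for v in coordinates[i]))
    m3.AddConformer(conf, assignId=True)
    for name in ("Asphericity", "Eccentricity", "InertialShapeFactor",
                 "NPR1", "NPR2", "PMI1", "PMI2", "PMI3",
                 "RadiusOfGyration", "SpherocityIndex"):
        try:
            values[name] = float(getattr(Descriptors3D, name)(m3))
        except Exception:
            values[name] = np.nan
        tags[name] = "3D"
    for name, val in _cpsa_family(mol, np.asarray(coordinates, float)).items():
        values[name] = val
        tags[name] = "3D"
    return values, tags


def select_descriptors(table: pd.DataFrame, labels: np.ndarray,
                       tags: dict[str, str], k2d: int, k3d: int,
                       seed: int = 0) -> list[str]:
    """Three-stage descriptor selection.

    1. drop constant (zero-spread) columns;
    2. for column pairs with \\|Pearson r\\| >= 0.9 (processed in descending
       \\|r\\|, ties by table order) drop the member less correlated with the
       labels;
    3. rank survivors by impurity-based random-forest importance, fitted
       separately on the 2D and 3D blocks, and keep the top ``k2d`` + ``k3d``.
    """
    labels = np.asarray(labels, dtype=float)
    if len(table) != len(labels):
        raise InputError("table and labels are not aligned")
    table = table.loc[:, table.notna().all(axis=0)]
    # 1. constants
    spread = table.std(axis=0, ddof=0)
    cols = [c for c in table.columns if spread[c] > 0]
    order = {c: i for i, c in enumerate(table.columns)}
    # 2. correlation pruning
    sub = table[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cmat = np.corrcoef(sub, rowvar=False)
        label_r = np.array([
            abs(np.corrcoef(sub[:, i], labels)[0, 1]) for i in range(len(cols))
        ])
    label_r = np.nan_to_num(label_r)
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = cmat[i, j]
            if np.isfinite(r) and abs(r) >= 0.9:
                pairs.append((abs(r), order[cols[i]], order[cols[j]], i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(range(len(cols)))
    for _, _, _, i, j in pairs:
        if i in alive and j in alive:
            if label_r[i] < label_r[j]:
                alive.discard(i)
            elif label_r[j] < label_r[i]:
                alive.discard(j)
            else:  # tie: keep the earlier column
                alive.discard(j)
    survivors = [cols[i] for i in sorted(alive)]
    # 3. RF importance per block
    selected: list[str] = []
    for tag, k in (("2D", k2d), ("3D", k3d)):
        block = [c for c in survivors if tags.get(c) == tag]
        if len(block) < k:
            raise SelectionError(
                f"only {len(block)} {tag} descriptors survive, {k} requested"
            )
        if k == 0:
            continue
        rf = RandomForestRegressor(n_estimators=500, random_state=seed,
                                   n_jobs=1)
        rf.fit(table[block].to_numpy(dtype=float), labels)
        ranked = sorted(zip(rf.feature_importances_, block),
                        key=lambda t: (-t[0], order[t[1]]))
        selected.extend(name for _, name in ranked[:k])
    return selected
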