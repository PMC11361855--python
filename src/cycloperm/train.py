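"""Dataset preparation, training with replica-expanded batches, inference.

Labels are log10 permeabilities (cm/s) clipped to the assay's reliable
window [-8, -4].  The test set is chosen by the deterministic Kennard-Stone
procedure on Morgan fingerprints so it spans the chemical space; validation
folds are random and mutually disjoint.  Training minimizes the fusion MSE
plus the auxiliary sub-model and layer losses; every replica of a peptide is
an independent training row carrying the parent label, while at inference
the per-replica fusion outputs of a peptide are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import ReplicaInput
from .descriptors import Standardizer
from .errors import FitError, InputError
from .nets import FusionModel

LABEL_FLOOR = -8.0
LABEL_CEIL = -4.0


def clip_labels(values) -> np.ndarray:
    """Clip log10 permeabilities into [-8, -4] (detection-limit rounding)."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("labels must be finite")
    return np.clip(arr, LABEL_FLOOR, LABEL_CEIL)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def kennard_stone_split(fingerprints: np.ndarray, fraction: float
                        ) -> list[int]:
    """Classic Kennard-Stone selection of ceil(fraction * n) diverse samples.

    Seeds with the pair at maximum Euclidean distance, then repeatedly adds
    the sample whose minimum distance to the selected set is largest.
    Deterministic; ties resolved toward the lower index.
    """
    X = np.asarray(fingerprints, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise InputError("need at least 2 samples")
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie in (0, 1)")
    k = int(np.ceil(fraction * n))
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [min(i, j), max(i, j)][:max(k, 1)]
    if k == 1:
        return [int(selected[0])]
    min_d = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d2[nxt])
        min_d[nxt] = -np.inf
    return [int(s) for s in selected]


@dataclass
class SplitPlan:
    """Disjoint test / three validation folds / train id lists."""

    test_ids: list[str]
    validation_ids: list[list[str]]
    train_ids: list[str]

    def all_ids(self) -> list[str]:
        out = list(self.test_ids) + list(self.train_ids)
        for fold in self.validation_ids:
            out.extend(fold)
        return out

    def train_pool(self, fold: int) -> list[str]:
        """Training ids for run ``fold``: everything but test and that fold."""
        pool = list(self.train_ids)
        for f, ids in enumerate(self.validation_ids):
            if f != fold:
                pool.extend(ids)
        return pool


def make_split(ids: list[str], fingerprints: np.ndarray,
               test_fraction: float = 0.05, val_fraction: float = 0.05,
               n_val_folds: int = 3, seed: int = 0) -> SplitPlan:
    """Kennard-Stone test set + disjoint random validation folds."""
    ids = list(ids)
    test_idx = set(kennard_stone_split(fingerprints, test_fraction))
    remaining = [i for i in range(len(ids)) if i not in test_idx]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(remaining))
    per_fold = int(np.ceil(val_fraction * len(ids)))
    if per_fold * n_val_folds > len(remaining):
        raise InputError("not enough samples for the validation folds")
    folds = []
    cursor = 0
    for _ in range(n_val_folds):
        take = perm[cursor:cursor + per_fold]
        folds.append([ids[remaining[t]] for t in take])
        cursor += per_fold
    train = [ids[remaining[t]] for t in perm[cursor:]]
    return SplitPlan(test_ids=[ids[i] for i in sorted(test_idx)],
                     validation_ids=folds, train_ids=train)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class ReplicaDataset:
    """Stacked model-ready arrays over replica rows."""

    arrays: dict[str, np.ndarray]
    ids: np.ndarray  # (R,) peptide id per row
    n_max: int

    def __len__(self) -> int:
        return len(self.ids)

    def take(self, idx) -> dict[str, np.ndarray]:
        return {k: v[idx] for k, v in self.arrays.items()}

    def rows_for(self, peptide_ids) -> np.ndarray:
        wanted = set(peptide_ids)
        return np.nonzero([i in wanted for i in self.ids])[0]

    def subset(self, idx) -> "ReplicaDataset":
        idx = np.asarray(idx)
        return ReplicaDataset({k: v[idx] for k, v in self.arrays.items()},
                              self.ids[idx], self.n_max)


def stack_replicas(replicas: list[ReplicaInput], n_max: int | None = None
                   ) -> ReplicaDataset:
    """Stack per-replica features into batched arrays (float32 storage).

    ``n_max`` trims the atom padding to the cohort's largest molecule when
    None; pass an explicit value to keep a fixed frame.
    """
    if not replicas:
        raise InputError("no replicas to stack")
    widest = max(r.atom_features.n_atoms for r in replicas)
    nm = widest if n_max is None else n_max
    if nm < widest:
        raise InputError("n_max smaller than the largest molecule")

    def sq(a):
        return a[:nm, :nm]

    arrays = {
        "node": np.stack([r.atom_features.node[:nm] for r in replicas]
                         ).astype(np.float32),
        "bond": np.stack([sq(r.atom_features.bond) for r in replicas]
                         ).astype(np.float32),
        "strength_graph": np.stack([sq(r.atom_features.strength_graph)
                                    for r in replicas]).astype(np.float32),
        "strength_conf": np.stack([sq(r.atom_features.strength_conf)
                                   for r in replicas]).astype(np.float32),
        "atom_mask": np.stack([r.atom_features.mask[:nm] for r in replicas]),
        "monomer": np.stack([r.monomer_matrix for r in replicas]
                            ).astype(np.float32),
        "monomer_mask": np.stack([r.monomer_mask for r in replicas]),
        "desc": np.stack([r.peptide_descriptors for r in replicas]
                         ).astype(np.float32),
        "fp": np.stack([r.fingerprint for r in replicas]).astype(np.float32),
        "label": np.array([np.nan if r.label is None else r.label
                           for r in replicas], dtype=np.float32),
    }
    ids = np.array([r.peptide_id for r in replicas])
    return ReplicaDataset(arrays, ids, nm)


def fit_feature_standardizers(dataset: ReplicaDataset, train_rows: np.ndarray
                              ) -> tuple[Standardizer, Standardizer]:
    """Fit peptide- and monomer-descriptor standardizers on training rows only.

    The monomer standardizer is fitted jointly over all real monomer rows of
    the training replicas.
    """
    desc = dataset.arrays["desc"][train_rows].astype(float)
    pep_std = Standardizer.fit(desc, on_constant="unit")
    mono = dataset.arrays["monomer"][train_rows].astype(float)
    mask = dataset.arrays["monomer_mask"][train_rows]
    rows = mono[mask]
    if rows.shape[0] < 2:
        raise FitError("not enough monomer rows to fit a standardizer")
    mono_std = Standardizer.fit(rows, on_constant="unit")
    return pep_std, mono_std


def apply_standardizers(dataset: ReplicaDataset, pep_std: Standardizer,
                        mono_std: Standardizer) -> ReplicaDataset:
    """Return a standardized copy; padded monomer rows stay exactly zero."""
    arrays = dict(dataset.arrays)
    arrays["desc"] = pep_std.apply(arrays["desc"].astype(float)
                                   ).astype(np.float32)
    mono = mono_std.apply(arrays["monomer"].astype(float))
    mono[~dataset.arrays["monomer_mask"]] = 0.0
    arrays["monomer"] = mono.astype(np.float32)
    return ReplicaDataset(arrays, dataset.ids, dataset.n_max)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    patience: int = 20  # early stopping on validation MAE; 0 disables
    seed: int = 0


def _batch_cast(batch: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    from .autodiff import get_dtype
    dt = get_dtype()
    return {k: v if v.dtype in (bool, dt) else v.astype(dt)
            for k, v in batch.items()}


def train(model: FusionModel, train_data: ReplicaDataset,
          val_data: ReplicaDataset | None = None,
          config: TrainConfig | None = None,
          verbose: bool = False) -> pd.DataFrame:
    """Minimize the total auxiliary-loss objective over replica rows.

    Replica rows are shuffled across peptides each epoch.  When validation
    data and a patience are given, training stops once the validation MAE has
    not improved for ``patience`` epochs and the best weights are restored.
    Returns the per-epoch history.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = model.optimizer(lr=cfg.lr)
    labels = train_data.arrays["label"].astype(float)
    if np.any(np.isnan(labels)):
        raise InputError("training rows must all carry labels")
    n = len(train_data)
    if n == 0:
        raise InputError("empty training split")
    history = []
    best = (np.inf, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_loss = 0.0
        fus_loss = 0.0
        abs_err = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = _batch_cast(train_data.take(idx))
            bundle, layer_means = model.forward(batch)
            loss, breakdown = model.total_loss(bundle, layer_means,
                                               batch["label"])
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += breakdown.total * len(idx)
            fus_loss += breakdown.L_fusion * len(idx)
            abs_err += np.abs(bundle.out_fusion.data[:, 0]
                              - batch["label"]).sum()
        row = {"epoch": epoch, "total_loss": tot_loss / n,
               "fusion_loss": fus_loss / n, "train_mae": abs_err / n}
        if val_data is not None and len(val_data):
            val_pred = predict_rows(model, val_data)
            row["val_mae"] = float(np.abs(
                val_pred - val_data.arrays["label"].astype(float)).mean())
            if row["val_mae"] < best[0] - 1e-12:
                best = (row["val_mae"],
                        {k: v.copy() for k, v in model.state_arrays().items()},
                        epoch)
        history.append(row)
        if verbose:
            print({k: round(v, 4) if isinstance(v, float) else v
                   for k, v in row.items()})
        if (val_data is not None and cfg.patience
                and epoch - best[2] >= cfg.patience and best[1] is not None):
            break
    if best[1] is not None:
        model.load_state(best[1])
    return pd.DataFrame(history)


def predict_rows(model: FusionModel, data: ReplicaDataset,
                 batch_size: int = 64) -> np.ndarray:
    """Per-replica-row fusion predictions."""
    out = np.empty(len(data))
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        out[idx] = model.predict(_batch_cast(data.take(idx)))
    return out


def predict_ensemble(model: FusionModel, replicas: ReplicaDataset) -> float:
    """Ensemble prediction for one peptide: mean fusion output over replicas."""
    if len(replicas) == 0:
        raise InputError("no replicas to predict from")
    if len(set(replicas.ids.tolist())) != 1:
        raise InputError("predict_ensemble expects replicas of one peptide")
    return float(predict_rows(model, replicas).mean())


def predict_peptides(model: FusionModel, data: ReplicaDataset) -> pd.DataFrame:
    """Replica-averaged predictions per peptide id."""
    rows = predict_rows(model, data)
    df = pd.DataFrame({"id": data.ids, "prediction": rows,
                       "label": data.arrays["label"].astype(float)})
    agg = df.groupby("id", sort=False).agg(
        prediction=("prediction", "mean"), label=("label", "first"),
        n_replicas=("prediction", "size")).reset_index()
    return agg


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    mae: float
    mse: float
    r: float
    r2: float
    degenerate: bool = field(default=False)

    def to_dict(self) -> dict:
        return {"mae": self.mae, "mse": self.mse, "r": self.r,
                "r2": self.r2, "degenerate": self.degenerate}


def evaluate(predictions, labels) -> MetricReport:
    """MAE, MSE, Pearson R and R^2 = 1 - SS_res / SS_tot."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or len(p) < 2:
        raise InputError("need aligned 1D predictions and labels, n >= 2")
    mae = float(np.abs(p - y).mean())
    mse_v = float(((p - y) ** 2).mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return MetricReport(mae, mse_v, float("nan"), float("nan"),
                            degenerate=True)
    r = float(np.corrcoef(p, y)[0, 1]) if p.std() > 0 else float("nan")
    r2 = 1.0 - float(((p - y) ** 2).sum()) / ss_tot
    return MetricReport(mae, mse_v, r, r2, degenerate=not np.isfinite(r))
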