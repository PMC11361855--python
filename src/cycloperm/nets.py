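"""The three-branch permeability model and its auxiliary-loss objective.

Atom branch: a structure-enhanced transformer.  Node features are embedded
together with the bond matrix (which acts as a relative positional
encoding); the encoder runs two parallel blocks whose attention is
attenuated by the graph-distance and 3D-distance Strength matrices, and the
pooled block outputs are blended with the weight lambda_g.

Monomer branch: stacked 1D convolutions (plain or circular) over the L x 16
matrix of monomer descriptors in cyclic order, globally mean-pooled.

Peptide branch: two MLPs — one over the 16 whole-molecule descriptors, one
over the 2048-bit Morgan fingerprint — concatenated.

Fusion: the three latent vectors are concatenated and passed through a
shared MLP for the scalar log10 permeability.  Training adds, to the fusion
MSE, gamma_sub-weighted per-branch losses and gamma_layer-weighted losses on
the mean of each branch's per-layer pooled outputs; only the fusion output
is used at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, conv1d, layer_norm, relu, softmax
from .errors import ConfigError

GAMMA_SUB = 0.10
GAMMA_LAYER = 0.05


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class AtomModelConfig:
    d_model: int = 64
    h: int = 4
    layers_per_block: int = 2
    lambda_g: float = 0.5
    ffn_width: int = 128
    dropout: float = 0.0
    latent: int = 32
    n_max: int = 128
    n_node_features: int = 30
    strength_mode: str = "prob"  # "prob": mask attention probabilities;
    #                              "matmul": left-multiply the block output

    def __post_init__(self):
        if self.d_model % self.h:
            raise ConfigError("d_model must be divisible by h")
        if not 0.0 <= self.lambda_g <= 1.0:
            raise ConfigError("lambda_g must lie in [0, 1]")
        if self.strength_mode not in ("prob", "matmul"):
            raise ConfigError(f"unknown strength_mode {self.strength_mode!r}")


@dataclass
class MonomerModelConfig:
    conv_kind: str = "plain"  # "plain" | "cyclic"
    channels: tuple[int, ...] = (32, 32)
    kernel: int = 3
    latent: int = 32
    max_len: int = 12
    n_desc: int = 16

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ConfigError("kernel width must be odd")
        if len(self.channels) < 1:
            raise ConfigError("need at least one convolution layer")
        if len(set(self.channels)) != 1:
            raise ConfigError("all conv layers must share one width "
                              "(layer outputs are averaged for the layer loss)")
        if self.conv_kind not in ("plain", "cyclic"):
            raise ConfigError(f"unknown conv_kind {self.conv_kind!r}")

    @property
    def num_cnn(self) -> int:
        return len(self.channels)


@dataclass
class PeptideModelConfig:
    hidden: int = 64
    n_layers: int = 2
    latent: int = 32
    n_desc: int = 16
    n_fp: int = 2048

    def __post_init__(self):
        if self.n_layers < 1:
            raise ConfigError("need at least one MLP layer per branch")


@dataclass
class FusionModelConfig:
    hidden: int = 64
    gamma_sub: float = GAMMA_SUB
    gamma_layer: float = GAMMA_LAYER


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class LatentBundle:
    out_atom: Tensor
    out_monomer: Tensor
    out_peptide: Tensor
    out_fusion: Tensor  # (B, 1) scalar predictions


@dataclass
class LossBreakdown:
    L_fusion: float
    L_atom: float
    L_monomer: float
    L_peptide: float
    L_layer_a: float
    L_layer_m: float
    L_layer_p: float
    gamma_sub: float = GAMMA_SUB
    gamma_layer: float = GAMMA_LAYER
    total: float = field(default=0.0)

    @staticmethod
    def combine(l_fusion, l_atom, l_monomer, l_peptide,
                l_layer_a, l_layer_m, l_layer_p,
                gamma_sub=GAMMA_SUB, gamma_layer=GAMMA_LAYER):
        return (l_fusion
                + gamma_sub * (l_atom + l_monomer + l_peptide)
                + gamma_layer * (l_layer_a + l_layer_m + l_layer_p))


# ---------------------------------------------------------------------------
# parameter helpers
# ---------------------------------------------------------------------------

class _ParamStore:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: dict[str, Tensor] = {}

    def weight(self, name: str, shape: tuple[int, ...], fan_in: int | None = None
               ) -> Tensor:
        fan = fan_in if fan_in is not None else shape[0]
        t = Tensor(self.rng.normal(0.0, 1.0 / np.sqrt(max(fan, 1)), shape),
                   requires_grad=True)
        self.params[name] = t
        return t

    def zeros(self, name: str, shape: tuple[int, ...]) -> Tensor:
        t = Tensor(np.zeros(shape), requires_grad=True)
        self.params[name] = t
        return t

    def ones(self, name: str, shape: tuple[int, ...]) -> Tensor:
        t = Tensor(np.ones(shape), requires_grad=True)
        self.params[name] = t
        return t


def _linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return x @ w + b


def _ln_affine(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    return layer_norm(x) * gamma + beta


def _masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over the sequence axis counting only real positions.

    x: (B, N, d); mask: (B, N) boolean."""
    m = mask.astype(float)[..., None]
    denom = np.maximum(m.sum(axis=1), 1.0)  # (B, 1)
    return (x * Tensor(m)).sum(axis=1) * Tensor(1.0 / denom)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=float))
    return (diff * diff).mean()


# ---------------------------------------------------------------------------
# atom model
# ---------------------------------------------------------------------------

class AtomModel:
    def __init__(self, config: AtomModelConfig, rng: np.random.Generator,
                 store: _ParamStore, prefix: str = "atom"):
        self.cfg = config
        c = config
        self.p = store
        pre = prefix
        store.weight(f"{pre}.W_node", (c.n_node_features, c.d_model))
        store.weight(f"{pre}.W_bond", (c.n_max, c.d_model))
        for block in ("graph", "conf"):
            for l in range(c.layers_per_block):
                base = f"{pre}.{block}.{l}"
                for nm in ("Wq", "Wk", "Wv", "Wo"):
                    store.weight(f"{base}.{nm}", (c.d_model, c.d_model))
                store.weight(f"{base}.ffn.W1", (c.d_model, c.ffn_width))
                store.zeros(f"{base}.ffn.b1", (c.ffn_width,))
                store.weight(f"{base}.ffn.W2", (c.ffn_width, c.d_model))
                store.zeros(f"{base}.ffn.b2", (c.d_model,))
                for ln in ("ln1", "ln2"):
                    store.ones(f"{base}.{ln}.g", (c.d_model,))
                    store.zeros(f"{base}.{ln}.b", (c.d_model,))
        store.weight(f"{pre}.head.W", (2 * c.d_model, c.latent))
        store.zeros(f"{pre}.head.b", (c.latent,))
        self.prefix = prefix

    def _attention(self, x: Tensor, strength: np.ndarray, mask: np.ndarray,
                   base: str) -> Tensor:
        c = self.cfg
        P = self.p.params
        B, N, d = x.shape
        dk = d // c.h
        q = (x @ P[f"{base}.Wq"]).reshape(B, N, c.h, dk).transpose(0, 2, 1, 3)
        k = (x @ P[f"{base}.Wk"]).reshape(B, N, c.h, dk).transpose(0, 2, 1, 3)
        v = (x @ P[f"{base}.Wv"]).reshape(B, N, c.h, dk).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(c.d_model))
        # padded keys get -inf-like scores so real rows stay a simplex
        neg = np.where(mask[:, None, None, :], 0.0, -1e9)
        probs = softmax(scores + Tensor(neg))
        if c.strength_mode == "prob":
            probs = probs * Tensor(strength[:, None, :, :])
        heads = probs @ v  # (B, h, N, dk)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, N, d)
        out = merged @ P[f"{base}.Wo"]
        if c.strength_mode == "matmul":
            out = Tensor(strength) @ out
        return out

    def forward(self, node: np.ndarray, bond: np.ndarray,
                strength_graph: np.ndarray, strength_conf: np.ndarray,
                mask: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Returns (out_atom latent (B, latent), per-layer pooled outputs)."""
        c = self.cfg
        P = self.p.params
        mcol = Tensor(mask.astype(float)[..., None])
        x0 = (Tensor(node) @ P[f"{self.prefix}.W_node"]
              + Tensor(bond) @ P[f"{self.prefix}.W_bond"]) \
            * (1.0 / np.sqrt(c.d_model))
        x0 = x0 * mcol  # zero padded rows
        pools: list[Tensor] = []
        finals = {}
        for block, strength in (("graph", strength_graph),
                                ("conf", strength_conf)):
            x = x0
            for l in range(c.layers_per_block):
                base = f"{self.prefix}.{block}.{l}"
                focus = self._attention(x, strength, mask, base)
                x = _ln_affine(x + focus, P[f"{base}.ln1.g"], P[f"{base}.ln1.b"])
                ffn = _linear(relu(_linear(x, P[f"{base}.ffn.W1"],
                                           P[f"{base}.ffn.b1"])),
                              P[f"{base}.ffn.W2"], P[f"{base}.ffn.b2"])
                x = _ln_affine(x + ffn, P[f"{base}.ln2.g"], P[f"{base}.ln2.b"])
                x = x * mcol
                pools.append(_masked_mean(x, mask))
            finals[block] = _masked_mean(x, mask)
        blended = concat([finals["graph"] * c.lambda_g,
                          finals["conf"] * (1.0 - c.lambda_g)], axis=-1)
        out = _linear(blended, P[f"{self.prefix}.head.W"],
                      P[f"{self.prefix}.head.b"])
        return out, pools


# ---------------------------------------------------------------------------
# monomer model
# ---------------------------------------------------------------------------

class MonomerModel:
    def __init__(self, config: MonomerModelConfig, rng: np.random.Generator,
                 store: _ParamStore, prefix: str = "monomer"):
        self.cfg = config
        self.p = store
        self.prefix = prefix
        cin = config.n_desc
        for l, cout in enumerate(config.channels):
            store.weight(f"{prefix}.conv{l}.W", (config.kernel, cin, cout),
                         fan_in=config.kernel * cin)
            store.zeros(f"{prefix}.conv{l}.b", (cout,))
            cin = cout
        store.weight(f"{prefix}.head.W", (config.channels[-1], config.latent))
        store.zeros(f"{prefix}.head.b", (config.latent,))

    def forward(self, matrix: np.ndarray, mask: np.ndarray
                ) -> tuple[Tensor, list[Tensor]]:
        c = self.cfg
        P = self.p.params
        x = Tensor(matrix)
        mcol = Tensor(mask.astype(float)[..., None])
        pools: list[Tensor] = []
        for l in range(c.num_cnn):
            x = relu(conv1d(x, P[f"{self.prefix}.conv{l}.W"],
                            P[f"{self.prefix}.conv{l}.b"],
                            circular=(c.conv_kind == "cyclic")))
            x = x * mcol  # keep padded rows exactly zero between layers
            pools.append(_masked_mean(x, mask))
        out = _linear(pools[-1], P[f"{self.prefix}.head.W"],
                      P[f"{self.prefix}.head.b"])
        return out, pools


# ---------------------------------------------------------------------------
# peptide model
# ---------------------------------------------------------------------------

class PeptideModel:
    def __init__(self, config: PeptideModelConfig, rng: np.random.Generator,
                 store: _ParamStore, prefix: str = "peptide"):
        self.cfg = config
        self.p = store
        self.prefix = prefix
        for branch, nin in (("desc", config.n_desc), ("fp", config.n_fp)):
            w = nin
            for l in range(config.n_layers):
                store.weight(f"{prefix}.{branch}.{l}.W", (w, config.hidden))
                store.zeros(f"{prefix}.{branch}.{l}.b", (config.hidden,))
                w = config.hidden
        store.weight(f"{prefix}.head.W", (2 * config.hidden, config.latent))
        store.zeros(f"{prefix}.head.b", (config.latent,))

    def forward(self, desc: np.ndarray, fp: np.ndarray
                ) -> tuple[Tensor, list[Tensor]]:
        c = self.cfg
        P = self.p.params
        pools: list[Tensor] = []
        outs = {}
        for branch, data in (("desc", desc), ("fp", fp)):
            x = Tensor(np.asarray(data, dtype=float))
            for l in range(c.n_layers):
                x = relu(_linear(x, P[f"{self.prefix}.{branch}.{l}.W"],
                                 P[f"{self.prefix}.{branch}.{l}.b"]))
                pools.append(x)
            outs[branch] = x
        out = _linear(concat([outs["desc"], outs["fp"]], axis=-1),
                      P[f"{self.prefix}.head.W"], P[f"{self.prefix}.head.b"])
        return out, pools


# ---------------------------------------------------------------------------
# fusion model
# ---------------------------------------------------------------------------

class FusionModel:
    """The full three-branch model with auxiliary heads."""

    def __init__(self, atom_cfg: AtomModelConfig | None = None,
                 monomer_cfg: MonomerModelConfig | None = None,
                 peptide_cfg: PeptideModelConfig | None = None,
                 fusion_cfg: FusionModelConfig | None = None,
                 seed: int = 0):
        self.atom_cfg = atom_cfg or AtomModelConfig()
        self.monomer_cfg = monomer_cfg or MonomerModelConfig()
        self.peptide_cfg = peptide_cfg or PeptideModelConfig()
        self.fusion_cfg = fusion_cfg or FusionModelConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        store = _ParamStore(rng)
        self.store = store
        self.atom = AtomModel(self.atom_cfg, rng, store)
        self.monomer = MonomerModel(self.monomer_cfg, rng, store)
        self.peptide = PeptideModel(self.peptide_cfg, rng, store)
        latents = (self.atom_cfg.latent + self.monomer_cfg.latent
                   + self.peptide_cfg.latent)
        store.weight("fusion.W1", (latents, self.fusion_cfg.hidden))
        store.zeros("fusion.b1", (self.fusion_cfg.hidden,))
        store.weight("fusion.W2", (self.fusion_cfg.hidden, 1))
        store.zeros("fusion.b2", (1,))
        # auxiliary scalar heads
        store.weight("aux.atom.W", (self.atom_cfg.latent, 1))
        store.zeros("aux.atom.b", (1,))
        store.weight("aux.monomer.W", (self.monomer_cfg.latent, 1))
        store.zeros("aux.monomer.b", (1,))
        store.weight("aux.peptide.W", (self.peptide_cfg.latent, 1))
        store.zeros("aux.peptide.b", (1,))
        store.weight("aux.layer_a.W", (self.atom_cfg.d_model, 1))
        store.zeros("aux.layer_a.b", (1,))
        store.weight("aux.layer_m.W", (self.monomer_cfg.channels[-1], 1))
        store.zeros("aux.layer_m.b", (1,))
        store.weight("aux.layer_p.W", (self.peptide_cfg.hidden, 1))
        store.zeros("aux.layer_p.b", (1,))

    @property
    def params(self) -> dict[str, Tensor]:
        return self.store.params

    def forward(self, batch: dict[str, np.ndarray]
                ) -> tuple[LatentBundle, dict[str, Tensor]]:
        """Run all branches.  ``batch`` holds numpy arrays keyed
        node/bond/strength_graph/strength_conf/atom_mask/monomer/monomer_mask/
        desc/fp."""
        P = self.params
        out_a, pools_a = self.atom.forward(
            batch["node"], batch["bond"], batch["strength_graph"],
            batch["strength_conf"], batch["atom_mask"])
        out_m, pools_m = self.monomer.forward(batch["monomer"],
                                              batch["monomer_mask"])
        out_p, pools_p = self.peptide.forward(batch["desc"], batch["fp"])
        fused = concat([out_a, out_m, out_p], axis=-1)
        hidden = relu(_linear(fused, P["fusion.W1"], P["fusion.b1"]))
        out_f = _linear(hidden, P["fusion.W2"], P["fusion.b2"])
        layer_means = {
            "atom": _mean_tensors(pools_a),
            "monomer": _mean_tensors(pools_m),
            "peptide": _mean_tensors(pools_p),
        }
        return LatentBundle(out_a, out_m, out_p, out_f), layer_means

    def total_loss(self, bundle: LatentBundle, layer_means: dict[str, Tensor],
                   labels: np.ndarray) -> tuple[Tensor, LossBreakdown]:
        """Fusion MSE plus gamma-weighted sub-model and layer losses."""
        P = self.params
        y = np.asarray(labels, dtype=float).reshape(-1, 1)
        l_fus = mse(bundle.out_fusion, y)
        l_atom = mse(_linear(bundle.out_atom, P["aux.atom.W"],
                             P["aux.atom.b"]), y)
        l_mono = mse(_linear(bundle.out_monomer, P["aux.monomer.W"],
                             P["aux.monomer.b"]), y)
        l_pep = mse(_linear(bundle.out_peptide, P["aux.peptide.W"],
                            P["aux.peptide.b"]), y)
        l_la = mse(_linear(layer_means["atom"], P["aux.layer_a.W"],
                           P["aux.layer_a.b"]), y)
        l_lm = mse(_linear(layer_means["monomer"], P["aux.layer_m.W"],
                           P["aux.layer_m.b"]), y)
        l_lp = mse(_linear(layer_means["peptide"], P["aux.layer_p.W"],
                           P["aux.layer_p.b"]), y)
        g_s, g_l = self.fusion_cfg.gamma_sub, self.fusion_cfg.gamma_layer
        total = (l_fus + g_s * (l_atom + l_mono + l_pep)
                 + g_l * (l_la + l_lm + l_lp))
        breakdown = LossBreakdown(
            l_fus.item(), l_atom.item(), l_mono.item(), l_pep.item(),
            l_la.item(), l_lm.item(), l_lp.item(),
            gamma_sub=g_s, gamma_layer=g_l, total=total.item())
        return total, breakdown

    def predict(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Fusion-head predictions (the only output used at inference)."""
        bundle, _ = self.forward(batch)
        return bundle.out_fusion.data[:, 0].copy()

    def optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(list(self.params.values()), lr=lr)

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        from .autodiff import get_dtype
        for k, t in self.params.items():
            t.data = np.asarray(arrays[k], dtype=get_dtype()).copy()

    def config_dict(self) -> dict:
        return {
            "atom": asdict(self.atom_cfg),
            "monomer": asdict(self.monomer_cfg),
            "peptide": asdict(self.peptide_cfg),
            "fusion": asdict(self.fusion_cfg),
            "seed": self.seed,
        }

    @classmethod
    def from_config_dict(cls, d: dict) -> "FusionModel":
        return cls(AtomModelConfig(**d["atom"]),
                   MonomerModelConfig(**{**d["monomer"],
                                         "channels": tuple(d["monomer"]["channels"])}),
                   PeptideModelConfig(**d["peptide"]),
                   FusionModelConfig(**d["fusion"]),
                   seed=d.get("seed", 0))


def _mean_tensors(tensors: list[Tensor]) -> Tensor:
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out * (1.0 / len(tensors))


def save_checkpoint(path, model: FusionModel, extra: dict | None = None) -> None:
    """Single-file archive: weights + config (+ standardizer state etc.)."""
    meta = {"config": model.config_dict(), "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_arrays().items()}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path) -> tuple[FusionModel, dict]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        model = FusionModel.from_config_dict(meta["config"])
        model.load_state({k[len("param/"):]: data[k]
                          for k in data.files if k.startswith("param/")})
    return model, meta.get("extra", {})
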