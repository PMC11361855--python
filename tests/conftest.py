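import numpy as np
import pytest

import cycloperm as cp
from cycloperm import autodiff

CYCLO_GLY3 = "C1NC(=O)CNC(=O)CNC1=O"


@pytest.fixture
def gly3_record():
    return cp.parse_peptide("gly3", CYCLO_GLY3, None, -6.0)


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 (for finite-difference checks)."""
    autodiff.set_dtype(np.float64)
    yield
    autodiff.set_dtype(np.float32)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-peptide synthetic cohort featurized with one replica each."""
    cfg = cp.SynthConfig(n_peptides=10, seed=101)
    records, manifest = cp.make_dataset(cfg)
    replicas = []
    for rec in records:
        replicas.extend(cp.build_replicas(rec, r=1, seed=5, max_len=12))
    dataset = cp.stack_replicas(replicas)
    return {"config": cfg, "records": records, "manifest": manifest,
            "replicas": replicas, "dataset": dataset}


def tiny_model(n_max: int, seed: int = 0, **kw) -> cp.FusionModel:
    """A small but complete fusion model for fast tests."""
    atom = dict(d_model=16, h=2, layers_per_block=1, ffn_width=32,
                latent=8, n_max=n_max)
    atom.update(kw.pop("atom", {}))
    mono = dict(channels=(8, 8), latent=8)
    mono.update(kw.pop("monomer", {}))
    pep = dict(hidden=16, n_layers=1, latent=8)
    pep.update(kw.pop("peptide", {}))
    fusion = kw.pop("fusion", {})
    return cp.FusionModel(cp.AtomModelConfig(**atom),
                          cp.MonomerModelConfig(**mono),
                          cp.PeptideModelConfig(**pep),
                          cp.FusionModelConfig(**fusion),
                          seed=seed)
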