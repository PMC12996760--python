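import numpy as np
import pytest

from thc_correct.core_io import Collocation, DFTensors, OrbitalSystem
from thc_correct.synthetic import GeneratorConfig, generate_corpus, generate_system


def random_closed_shell(seed, n_o=2, n_v=3, n_aux=12, scale=0.2):
    """Small unstructured closed-shell system with symmetric DF factors."""
    rng = np.random.default_rng(seed)
    eps = np.concatenate([np.sort(rng.uniform(-1.5, -0.4, n_o)),
                          np.sort(rng.uniform(0.2, 1.5, n_v))])
    B = rng.normal(size=(n_o + n_v, n_o + n_v, n_aux)) * scale
    B = (B + B.transpose(1, 0, 2)) / 2.0
    system = OrbitalSystem(f"rand{seed}", eps, n_o, n_v, e_scf=-float(rng.uniform(5, 50)))
    df = DFTensors(B[:n_o, :n_o], B[:n_o, n_o:], B[n_o:, n_o:])
    return system, df


def full_rank_grids(system, seed, multiplier=3.0):
    """Parent collocations whose pair spaces are full rank (exact-THC limit)."""
    rng = np.random.default_rng(seed)
    n_o, n_v = system.n_occ_active, system.n_vir
    n = n_o + n_v
    n_grid = max(int(multiplier * n), n_o * n_v + 2, n_v * (n_v + 1) // 2 + 2)
    X = rng.normal(size=(n, n_grid))
    return {"oo": Collocation("oo", X[:n_o], X[:n_o]),
            "ov": Collocation("ov", X[:n_o], X[n_o:]),
            "vv": Collocation("vv", X[n_o:], X[n_o:])}


@pytest.fixture(scope="session")
def small_synthetic():
    """One default-generator species (deterministic)."""
    return generate_system(GeneratorConfig(seed=11), 0)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Twelve default-generator species for ensemble-level checks."""
    return generate_corpus(GeneratorConfig(seed=5), 12)
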