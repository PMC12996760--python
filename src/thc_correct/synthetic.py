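"""Seeded generators for systems, reactions, and planted regression data.

The system generator emulates the *statistical shape* of closed-shell
correlated-wavefunction inputs: a gapped orbital spectrum, PSD
density-fitted pair integrals with a decaying auxiliary spectrum, and
collocation matrices whose pair metrics prune nontrivially under a
pivoted-Cholesky threshold.

Species are drawn from a shared "basis universe": corpus-level master
collocation profiles, DF weight patterns, and residual tails, which each
species inherits (sub-blocked to its size class) with a small private
jitter.  Real molecules likewise share atomic basis functions and
quadrature grids, which is what makes THC errors *systematic* across a
database rather than independent noise; the jitter amplitude controls
how far the synthetic ensemble departs from that ideal.  Per-species
diversity enters through the size class, the orbital spectrum, the
grid-importance decay (fit quality), occupied/virtual block strengths
(diagram-class ratios), and an overall interaction strength.

The interaction strength is calibrated so the largest first-order
amplitude sits near ``t_max_target``: gapped closed-shell references are
perturbative by selection, and unbounded random tensors are not.

A single global seed fans out to per-species streams through
``numpy.random.SeedSequence(seed, index)`` so a corpus can be extended
without reshuffling existing species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Collocation, DFTensors, OrbitalSystem, ReactionScheme

#: (n_occ, n_vir) size classes species are drawn from.
SIZE_CLASSES = ((3, 8), (4, 10), (5, 12))


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic corpus; defaults give a desk-scale ensemble.

    ``grid_multiplier`` sets the parent grid as a multiple of the orbital
    count.  ``collocation_decay_range`` controls the geometric decay of
    grid-point importance (and with it the THC fit quality a given
    pruning tolerance achieves); ``jitter`` is the relative amplitude of
    per-species deviations from the corpus master structures.
    """

    seed: int = 0
    size_classes: tuple = SIZE_CLASSES
    n_aux: int = 40
    grid_multiplier: float = 4.0
    gap_min: float = 0.15
    df_decay: float = 0.85
    t_max_target: float = 0.12
    strength_sigma: float = 0.15
    block_sigma: float = 0.15
    df_tail: float = 0.02
    df_weight_pow: float = 2.0
    collocation_decay_range: tuple = (0.85, 0.95)
    jitter: float = 0.003
    e_scf_per_valence: tuple = (-15.0, -5.0)

    def __post_init__(self):
        self.size_classes = tuple((int(a), int(b)) for a, b in self.size_classes)
        if not self.size_classes:
            raise ValueError("size_classes must be non-empty")
        if any(a < 1 or b < 1 for a, b in self.size_classes):
            raise ValueError("size classes need at least one occupied and one virtual")
        if self.gap_min <= 0:
            raise ValueError("gap_min must be > 0")
        if not 0 < self.df_decay <= 1:
            raise ValueError("df_decay must lie in (0, 1]")
        lo, hi = self.collocation_decay_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("collocation_decay_range must lie in (0, 1]")
        if self.jitter < 0 or self.strength_sigma < 0 or self.block_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def n_occ_max(self) -> int:
        return max(a for a, _ in self.size_classes)

    @property
    def n_orb_max(self) -> int:
        return max(a + b for a, b in self.size_classes)

    @property
    def n_grid_max(self) -> int:
        pairs_max = max(a * b for a, b in self.size_classes)
        return max(int(round(self.grid_multiplier * self.n_orb_max)), pairs_max + 1)


def _species_rng(cfg: GeneratorConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed,
                                                        spawn_key=(index,)))


def _master_structures(cfg: GeneratorConfig):
    """Corpus-level orbital profiles, DF weights and residual tail.

    Deterministic in the corpus seed; drawn from a stream disjoint from
    every per-species stream (distinct spawn key).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed,
                                                       spawn_key=(2**20,)))
    n_rows = cfg.n_occ_max + cfg.n_orb_max  # occupied rows, then virtual rows
    P = rng.normal(size=(n_rows, cfg.n_grid_max))
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    W = rng.normal(size=(cfg.n_grid_max, cfg.n_aux))
    T = rng.normal(size=(n_rows, n_rows, cfg.n_aux))
    T = (T + T.transpose(1, 0, 2)) / 2.0
    return P, W, T


def generate_system(cfg: GeneratorConfig, index: int):
    """One synthetic species: ``(OrbitalSystem, DFTensors, parent_grids)``.

    Occupied energies fall in [-1.5, -0.3] Hartree; virtuals start at
    least ``gap_min`` above the HOMO and stay below 2.0.  DF factors are
    symmetric three-index arrays built from collocation pair products
    (with a small off-grid tail), so the induced pair integrals are PSD
    by construction and the THC fit error is controlled by the
    grid-importance decay rather than by unstructured noise.
    """
    P_m, W_m, T_m = _master_structures(cfg)
    rng = _species_rng(cfg, index)

    n_o, n_v = cfg.size_classes[int(rng.integers(0, len(cfg.size_classes)))]
    n = n_o + n_v
    n_aux = cfg.n_aux

    eps_occ = np.sort(rng.uniform(-1.5, -0.3, n_o))
    lumo_lo = eps_occ[-1] + cfg.gap_min
    lumo = rng.uniform(lumo_lo, min(lumo_lo + 0.5, 1.9))
    eps_vir = np.sort(np.concatenate([[lumo], rng.uniform(lumo, 2.0, n_v - 1)]))
    eps = np.concatenate([eps_occ, eps_vir])

    system = OrbitalSystem(
        species_id=f"s{index:04d}",
        eps=eps, n_occ_active=n_o, n_vir=n_v,
        n_frozen=int(rng.integers(0, 3)),
        # mean-field energy is roughly extensive in the electron count
        e_scf=float(2 * n_o * rng.uniform(*cfg.e_scf_per_valence)),
    )

    # collocation: master orbital profiles (occupied rows first, then the
    # virtual block) with private jitter; grid-point importance decays
    # geometrically across columns, which gives the pair-metric Cholesky
    # diagonals a smooth falloff for the pruning threshold to bite into
    n_grid = max(int(round(cfg.grid_multiplier * n)), n_o * n_v + 1)
    rows = list(range(n_o)) + list(range(cfg.n_occ_max, cfg.n_occ_max + n_v))
    prof = (P_m[rows][:, :n_grid]
            + cfg.jitter * rng.normal(size=(n, n_grid)) / np.sqrt(n_grid))
    cd = rng.uniform(*cfg.collocation_decay_range)
    colw = cd ** (np.arange(n_grid) * 24.0 / n_grid)
    X = prof * colw[None, :]
    # molecular orbitals are normalized functions
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    X_o, X_v = X[:n_o], X[n_o:]

    # DF factors from collocation pair products: grid points with little
    # orbital amplitude carry correspondingly little integral weight
    # (df_weight_pow), so pruned pair directions hold a small share of
    # the integrals — the regime in which LS-THC is useful.  A small
    # off-grid tail bounds the attainable fit quality.
    weights = cfg.df_decay ** np.arange(n_aux)
    colnorm = np.sum(X**2, axis=0)
    u = (colnorm / colnorm.max()) ** cfg.df_weight_pow
    Wj = W_m[:n_grid, :n_aux] + cfg.jitter * rng.normal(size=(n_grid, n_aux))
    B = np.einsum("pP,qP,PJ->pqJ", X, X, (u[:, None] * Wj) / np.sqrt(n_grid))
    tj = rng.normal(size=(n, n, n_aux))
    tail = (T_m[np.ix_(rows, rows)][:, :, :n_aux]
            + cfg.jitter * (tj + tj.transpose(1, 0, 2)) / 2.0)
    B += cfg.df_tail * np.linalg.norm(B) / np.sqrt(B.size) * tail
    B *= weights[None, None, :]

    # occupied/virtual block strengths vary across species (diagram-class
    # ratios differ between bonding situations); block-constant positive
    # scalings keep the induced pair Gram matrix PSD
    s_o, s_v = rng.lognormal(0.0, cfg.block_sigma, size=2)
    B_oo = B[:n_o, :n_o] * (s_o * s_o)
    B_ov = B[:n_o, n_o:] * (s_o * s_v)
    B_vv = B[n_o:, n_o:] * (s_v * s_v)

    # calibrate the interaction strength so the largest first-order
    # amplitude sits near t_max_target, with a mild lognormal spread
    g_oovv = np.einsum("iaJ,jbJ->ijab", B_ov, B_ov)
    D = (eps[:n_o, None, None, None] + eps[None, :n_o, None, None]
         - eps[None, None, n_o:, None] - eps[None, None, None, n_o:])
    t_inf = np.abs(g_oovv / D).max()
    strength = (cfg.t_max_target / t_inf) * float(rng.lognormal(0.0, cfg.strength_sigma))
    for blk in (B_oo, B_ov, B_vv):
        blk *= np.sqrt(strength)

    df = DFTensors(B_oo, B_ov, B_vv)
    grids = {
        "oo": Collocation("oo", X_o, X_o),
        "ov": Collocation("ov", X_o, X_v),
        "vv": Collocation("vv", X_v, X_v),
    }
    return system, df, grids


def generate_corpus(cfg: GeneratorConfig, n_species: int) -> list:
    """List of ``(system, df, grids)`` for indices ``0..n_species-1``."""
    return [generate_system(cfg, i) for i in range(n_species)]


def generate_reactions(species_ids, n_rxn: int, seed: int) -> list:
    """Random valid reaction schemes over the given species.

    Each scheme has 2-5 members with stoichiometric numbers in
    {-2, -1, +1, +2} and at least one reactant and one product.
    """
    species_ids = list(species_ids)
    if len(species_ids) < 2:
        raise ValueError("need at least 2 species to form reactions")
    rng = np.random.default_rng(seed)
    schemes = []
    for r in range(n_rxn):
        n_mem = int(rng.integers(2, 6))
        n_mem = min(n_mem, len(species_ids))
        picks = rng.choice(len(species_ids), size=n_mem, replace=False)
        signs = rng.choice([-1, 1], size=n_mem)
        signs[0], signs[1] = -1, 1  # guarantee both sides populated
        mags = rng.integers(1, 3, size=n_mem)
        members = [(species_ids[p], int(s * m))
                   for p, s, m in zip(picks, signs, mags)]
        schemes.append(ReactionScheme(f"r{r:04d}", members))
    return schemes


@dataclass
class PlantedTruth:
    """Ground truth of a planted regression problem."""

    c_true: np.ndarray
    intercept: float
    amplitude: float
    bandwidth: float
    center: np.ndarray
    sigma: float


def generate_planted_regression(N: int, K: int, seed: int, *,
                                c_scale: float = 1.0,
                                intercept: float = 0.0,
                                amplitude: float = 0.0,
                                bandwidth: float = 1.0,
                                sigma: float = 0.0):
    """Linear signal plus an optional Gaussian bump plus Gaussian noise.

    ``y = X c + b + A exp(-||x - x0||^2 / (2 l^2)) + eps`` with
    ``eps ~ N(0, sigma^2)``.  Returns ``(X, y, PlantedTruth)``.
    """
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(N, K))
    c_true = c_scale * rng.normal(size=K)
    center = rng.normal(size=K) * 0.5
    bump = amplitude * np.exp(-np.sum((X - center) ** 2, axis=1) / (2.0 * bandwidth**2))
    y = X @ c_true + intercept + bump + sigma * rng.normal(size=N)
    truth = PlantedTruth(c_true, intercept, amplitude, bandwidth, center, sigma)
    return X, y, truth
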