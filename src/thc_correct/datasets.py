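"""Label sets, reaction assembly, and cross-validation folds.

Four label kinds are supported:

- ``molecule``:        canonical MP3 total energy per species, in
                       kcal/mol per valence electron;
- ``delta_molecule``:  the THC error ``E_MP3 - E_MP3b`` per species,
                       same unit;
- ``reaction``:        canonical MP3 reaction energy per scheme, kcal/mol;
- ``delta_reaction``:  THC error of the reaction energy, kcal/mol.

Reaction energies are stoichiometric combinations of *unnormalized*
kcal/mol species energies; the sum-|nu| normalization is a training-time
option for models trained directly on reaction labels, not part of the
label definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import HARTREE_TO_KCAL, ReactionScheme, ValidationError

LABEL_KINDS = ("molecule", "delta_molecule", "reaction", "delta_reaction")


@dataclass
class LabelSet:
    """Rows of (id, y) for one label kind."""

    kind: str
    table: pd.DataFrame  # columns: id, y

    def __post_init__(self):
        if self.kind not in LABEL_KINDS:
            raise ValidationError(f"unknown label kind {self.kind!r}")
        if list(self.table.columns) != ["id", "y"]:
            raise ValidationError("label table must have columns [id, y]")
        if not np.all(np.isfinite(self.table["y"].to_numpy(dtype=float))):
            raise ValidationError("labels contain non-finite values")

    @property
    def N(self) -> int:
        return len(self.table)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=float)

    @property
    def ids(self) -> list:
        return list(self.table["id"])


def _totals(breakdowns_by_species: dict, variant: str) -> dict:
    out = {}
    for sid, bds in breakdowns_by_species.items():
        if variant not in bds:
            raise ValidationError(f"species {sid} missing variant {variant!r}")
        out[sid] = bds[variant].total
    return out


def build_molecule_labels(breakdowns_by_species: dict, n_valence: dict,
                          kind: str = "molecule") -> LabelSet:
    """Per-species labels in kcal/mol per valence electron.

    ``molecule`` labels are canonical MP3 totals; ``delta_molecule``
    labels are ``E_MP3 - E_MP3b``.
    """
    if kind not in ("molecule", "delta_molecule"):
        raise ValidationError(f"kind must be a molecule kind, got {kind!r}")
    e_mp3 = _totals(breakdowns_by_species, "canonical")
    rows = []
    if kind == "molecule":
        for sid, e in e_mp3.items():
            rows.append((sid, e * HARTREE_TO_KCAL / n_valence[sid]))
    else:
        e_mp3b = _totals(breakdowns_by_species, "mp3b")
        for sid, e in e_mp3.items():
            rows.append((sid, (e - e_mp3b[sid]) * HARTREE_TO_KCAL / n_valence[sid]))
    return LabelSet(kind, pd.DataFrame(rows, columns=["id", "y"]))


def reaction_energy(scheme: ReactionScheme, per_species_values: dict,
                    normalize: bool = False) -> float:
    """Stoichiometric combination ``sum_i nu_i E_i``.

    With ``normalize`` the result is divided by ``sum_i |nu_i|`` (a
    training-time convention, not part of the reported energy).
    """
    total = 0.0
    for sid, nu in scheme.members:
        if sid not in per_species_values:
            raise ValidationError(f"reaction {scheme.reaction_id}: missing species {sid}")
        total += nu * per_species_values[sid]
    if normalize:
        total /= scheme.nu_abs_sum
    return float(total)


def build_reaction_labels(schemes, breakdowns_by_species: dict,
                          kind: str = "reaction", normalize: bool = False) -> LabelSet:
    """Per-scheme labels in kcal/mol (from unnormalized species energies)."""
    if kind not in ("reaction", "delta_reaction"):
        raise ValidationError(f"kind must be a reaction kind, got {kind!r}")
    e_mp3 = {sid: e * HARTREE_TO_KCAL
             for sid, e in _totals(breakdowns_by_species, "canonical").items()}
    rows = []
    if kind == "reaction":
        for s in schemes:
            rows.append((s.reaction_id, reaction_energy(s, e_mp3, normalize)))
    else:
        e_mp3b = {sid: e * HARTREE_TO_KCAL
                  for sid, e in _totals(breakdowns_by_species, "mp3b").items()}
        for s in schemes:
            diff = (reaction_energy(s, e_mp3, normalize)
                    - reaction_energy(s, e_mp3b, normalize))
            rows.append((s.reaction_id, diff))
    return LabelSet(kind, pd.DataFrame(rows, columns=["id", "y"]))


@dataclass
class FoldAssignment:
    """k-fold partition of N rows; sizes differ by at most one."""

    fold: np.ndarray
    k: int
    seed: int

    def test_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold == j)

    def train_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold != j)


def make_folds(N: int, k: int, seed: int) -> FoldAssignment:
    """Seeded shuffle followed by round-robin assignment."""
    if k > N:
        raise ValidationError(f"cannot make {k} folds from {N} rows")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    fold = np.empty(N, dtype=int)
    fold[order] = np.arange(N) % k
    return FoldAssignment(fold, k, seed)
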