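"""Per-species feature vectors and the unit-normal scaler.

The default feature census is 24 columns per species: the Hartree-Fock
energy, the two MP2 components for the MP2a and MP2b variants, the ten
MP3b diagram components, the HOMO-LUMO gap and total eigenvalue span,
three log-transformed THC goodness-of-fit measures, and four norms of the
two-electron integrals and first-order amplitudes.  Supplying the ten
MP3d diagram components from an external table extends this to 34.

Size-extensive quantities (energy components and Frobenius norms) are
divided by the number of active valence electrons; max-element norms,
gap/span and fit measures are size-intensive already and left alone.
Energy-component features are reported in kcal/mol per valence electron,
the same unit as the molecule-set labels, so that component-scaling
coefficients are dimensionless and near one; gap/span and norms stay in
atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import HARTREE_TO_KCAL, OrbitalSystem, ValidationError

#: Floor for 1 - f before the log transform: the exact-THC limit has f = 1.
F_CLAMP = 1e-16

MP3D_COLUMNS = tuple(f"E{n}_d" for n in range(1, 11))

FEATURE_COLUMNS_24 = (
    "E_HF",
    "EC_a", "EX_a",
    "EC_b", "EX_b",
    *(f"E{n}_b" for n in range(1, 11)),
    "gap", "span",
    "f_ab", "f_ai", "f_ij",
    "norm_g_F", "norm_t_F",
    "norm_g_inf", "norm_t_inf",
)

FEATURE_COLUMNS_34 = FEATURE_COLUMNS_24 + MP3D_COLUMNS

#: The ten unscaled component features used by the SCS-style model.
SCS_COLUMNS = tuple(f"E{n}_b" for n in range(1, 11))


def goodness_of_fit(B: np.ndarray, B_thc: np.ndarray) -> float:
    """f = 1 - ||B - B_THC||_F / ||B||_F for one pair type."""
    nB = np.linalg.norm(B)
    if nB == 0.0:
        raise ValidationError("goodness of fit undefined for zero DF factors")
    if B.shape != B_thc.shape:
        raise ValidationError("B and B_THC shapes differ")
    return float(1.0 - np.linalg.norm(np.asarray(B) - np.asarray(B_thc)) / nB)


def f_transform(f: float) -> float:
    """log(1 - f) with the argument clamped at F_CLAMP (natural log)."""
    return float(np.log(max(1.0 - f, F_CLAMP)))


def extract_features(breakdowns: dict, fit_info: dict, system: OrbitalSystem,
                     mp3d_components: np.ndarray | None = None) -> dict:
    """Assemble the named feature map for one species.

    ``breakdowns`` must hold the canonical, mp2a, mp2b and mp3b
    :class:`~thc_correct.mp_theory.EnergyBreakdown` objects;
    ``fit_info`` is the sidecar from
    :func:`~thc_correct.thc.thc_energy_suite`.
    """
    for variant in ("canonical", "mp2a", "mp2b", "mp3b"):
        if variant not in breakdowns:
            raise ValidationError(f"missing breakdown for variant {variant!r}")
    n_val = system.n_valence
    per_e = HARTREE_TO_KCAL / n_val  # Hartree -> kcal/mol per valence electron
    mp2a, mp3b = breakdowns["mp2a"], breakdowns["mp3b"]

    feats = {
        "E_HF": system.e_scf * per_e,
        "EC_a": mp2a.E_C * per_e,
        "EX_a": mp2a.E_X * per_e,
        "EC_b": mp3b.E_C * per_e,
        "EX_b": mp3b.E_X * per_e,
    }
    for n in range(10):
        feats[f"E{n + 1}_b"] = mp3b.E[n] * per_e
    feats["gap"] = system.gap
    feats["span"] = system.span
    feats["f_ab"] = f_transform(fit_info["f_vv"])
    feats["f_ai"] = f_transform(fit_info["f_ov"])
    feats["f_ij"] = f_transform(fit_info["f_oo"])
    feats["norm_g_F"] = fit_info["norm_g_F"] / n_val
    feats["norm_t_F"] = fit_info["norm_t_F"] / n_val
    feats["norm_g_inf"] = fit_info["norm_g_inf"]
    feats["norm_t_inf"] = fit_info["norm_t_inf"]
    if mp3d_components is not None:
        comps = np.asarray(mp3d_components, dtype=float)
        if comps.shape != (10,):
            raise ValidationError("mp3d_components must hold 10 values")
        for n in range(10):
            feats[f"E{n + 1}_d"] = comps[n] * per_e
    expected = FEATURE_COLUMNS_34 if mp3d_components is not None else FEATURE_COLUMNS_24
    vec = {name: feats[name] for name in expected}
    bad = [k for k, v in vec.items() if not np.isfinite(v)]
    if bad:
        raise ValidationError(f"non-finite features for {system.species_id}: {bad}")
    return vec


def features_frame(rows: dict) -> pd.DataFrame:
    """Species-indexed feature table with the fixed column order."""
    frame = pd.DataFrame.from_dict(rows, orient="index")
    order = FEATURE_COLUMNS_34 if set(MP3D_COLUMNS) <= set(frame.columns) else FEATURE_COLUMNS_24
    frame = frame.loc[:, list(order)]
    frame.index.name = "species_id"
    return frame


@dataclass
class Scaler:
    """Column-wise unit-normal scaler with explicit serializable state.

    Fitted on training rows only; constant columns (std == 0) map to zero
    and invert back to their mean.
    """

    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    columns: list = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, table: pd.DataFrame) -> "Scaler":
        values = table.to_numpy(dtype=float)
        self.columns = list(table.columns)
        self.mean = values.mean(axis=0)
        self.std = values.std(axis=0, ddof=0)
        return self

    def _check(self, table: pd.DataFrame) -> None:
        if not self.fitted:
            raise ValidationError("scaler has not been fitted")
        if list(table.columns) != self.columns:
            raise ValidationError("column mismatch between scaler and table")

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check(table)
        safe_std = np.where(self.std > 0, self.std, 1.0)
        return (table - self.mean) / safe_std

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        self._check(table)
        safe_std = np.where(self.std > 0, self.std, 1.0)
        return table * safe_std + self.mean

    # 1-D conveniences for label vectors
    def transform_vector(self, y: np.ndarray) -> np.ndarray:
        return self.transform(pd.DataFrame({self.columns[0]: np.asarray(y, float)})).to_numpy().ravel()

    def inverse_transform_vector(self, y: np.ndarray) -> np.ndarray:
        return self.inverse_transform(pd.DataFrame({self.columns[0]: np.asarray(y, float)})).to_numpy().ravel()

    def to_dict(self) -> dict:
        if not self.fitted:
            raise ValidationError("scaler has not been fitted")
        return {"columns": self.columns,
                "mean": self.mean.tolist(),
                "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(mean=np.asarray(d["mean"], float),
                   std=np.asarray(d["std"], float),
                   columns=list(d["columns"]))


def fit_scaler(table: pd.DataFrame) -> Scaler:
    return Scaler().fit(table)


def apply_scaler(table: pd.DataFrame, state: Scaler) -> pd.DataFrame:
    return state.transform(table)
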