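"""Closed-shell DF-MP2/MP3 with the 10-component diagrammatic decomposition.

The total energy through third order is split as

    E = E_SCF + E_C + E_X + sum_{n=1..10} E_n

where ``E_C``/``E_X`` are the direct/exchange MP2 terms (related to the
spin components by ``E_OS = E_C/2`` and ``E_SS = E_C/2 + E_X``) and
``E1..E10`` are the third-order Goldstone-diagram components in the fixed
order

    E1, E2   particle-particle ladder (prefactors +2, -1; integrals <ab|ef>)
    E3, E4   hole-hole ladder         (prefactors +2, -1; integrals <mn|ij>)
    E5..E10  ring diagrams            (prefactors +8, -4, -4, +2, -8, +4)

All contractions are dense closed-shell spatial-orbital expressions using
only opposite-spin integrals ``g^{pr}_{qs} = <pr|qs>`` and the doubles
amplitudes ``t[1]``; singles vanish for a canonical reference and are
never stored.  Everything is in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import HARTREE_TO_KCAL, DFTensors, OrbitalSystem, ValidationError

#: Denominators with magnitude below this (Hartree) signal a (near-)degenerate
#: reference, which the canonical formulas cannot handle.
TOL_DENOM = 1e-8

#: Fixed component order used everywhere (CSV columns, feature names).
COMPONENT_NAMES = tuple(f"E{n}" for n in range(1, 11))

VARIANTS = ("canonical", "mp2a", "mp2b", "mp3b")


class DegenerateReferenceError(ValueError):
    """An orbital-energy denominator is (numerically) zero."""


@dataclass
class IntegralBlocks:
    """Dense opposite-spin integral blocks needed through third order.

    Index conventions (physicists' notation, ``<pr|qs>``):

    - ``g_oovv[i,j,a,b] = <ij|ab>``
    - ``g_vvvv[a,b,e,f] = <ab|ef>``
    - ``g_oooo[m,n,i,j] = <mn|ij>``
    - ``g_ovvo[m,b,e,j] = <mb|ej>``  (direct ring)
    - ``g_ovov[m,b,j,e] = <mb|je>``  (exchange ring)
    """

    g_oovv: np.ndarray
    g_vvvv: np.ndarray
    g_oooo: np.ndarray
    g_ovvo: np.ndarray
    g_ovov: np.ndarray

    def __post_init__(self):
        for name in ("g_oovv", "g_vvvv", "g_oooo", "g_ovvo", "g_ovov"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite entries")


@dataclass
class Amplitudes:
    """First-order doubles ``t[i,j,a,b]`` (dimensionless); singles are zero."""

    t_oovv: np.ndarray

    def __post_init__(self):
        self.t_oovv = np.asarray(self.t_oovv, dtype=float)
        if not np.all(np.isfinite(self.t_oovv)):
            raise ValidationError("amplitudes contain non-finite entries")


@dataclass
class EnergyBreakdown:
    """Energy components for one species under one variant (Hartree)."""

    species_id: str
    variant: str
    E_SCF: float
    E_C: float
    E_X: float
    E: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.E.size not in (0, 10):
            raise ValidationError("E must hold 0 or 10 components")

    @property
    def E_OS(self) -> float:
        return self.E_C / 2.0

    @property
    def E_SS(self) -> float:
        return self.E_C / 2.0 + self.E_X

    @property
    def total(self) -> float:
        """Total energy with all scaling coefficients equal to one."""
        return self.E_SCF + self.E_C + self.E_X + float(self.E.sum())

    @property
    def correlation(self) -> float:
        return self.total - self.E_SCF


@dataclass
class CoefficientVector:
    """Ten diagram-scaling coefficients, absolute (c_n) or delta (c_n - 1)."""

    c: np.ndarray
    basis: str = "absolute"

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (10,) or not np.all(np.isfinite(self.c)):
            raise ValidationError("coefficient vector must be 10 finite reals")
        if self.basis not in ("absolute", "delta"):
            raise ValidationError(f"unknown basis {self.basis!r}")


def energy_denominators(system: OrbitalSystem) -> np.ndarray:
    """D[i,j,a,b] = eps_i + eps_j - eps_a - eps_b (negative for a gapped system)."""
    eo, ev = system.eps_occ, system.eps_vir
    return (eo[:, None, None, None] + eo[None, :, None, None]
            - ev[None, None, :, None] - ev[None, None, None, :])


def build_integral_blocks(df: DFTensors) -> IntegralBlocks:
    """Assemble dense integral blocks from three-index DF factors.

    ``<pr|qs> = (pq|rs) = sum_J B[p,q,J] B[r,s,J]`` with the chemists'
    pairings read off each block's occupancy pattern.
    """
    Boo, Bov, Bvv = df.B_oo, df.B_ov, df.B_vv
    g_oovv = np.einsum("iaJ,jbJ->ijab", Bov, Bov)
    g_vvvv = np.einsum("aeJ,bfJ->abef", Bvv, Bvv)
    g_oooo = np.einsum("miJ,njJ->mnij", Boo, Boo)
    g_ovvo = np.einsum("meJ,jbJ->mbej", Bov, Bov)
    g_ovov = np.einsum("mjJ,beJ->mbje", Boo, Bvv)
    return IntegralBlocks(g_oovv, g_vvvv, g_oooo, g_ovvo, g_ovov)


def first_order_amplitudes(system: OrbitalSystem, g_oovv: np.ndarray,
                           tol_denom: float = TOL_DENOM) -> Amplitudes:
    """t[1]_ij^ab = g_ij^ab / (eps_i + eps_j - eps_a - eps_b)."""
    D = energy_denominators(system)
    if g_oovv.shape != D.shape:
        raise ValidationError(
            f"g_oovv shape {g_oovv.shape} does not match system {D.shape}")
    bad = np.abs(D) <= tol_denom
    if bad.any():
        idx = tuple(int(k) for k in np.argwhere(bad)[0])
        raise DegenerateReferenceError(
            f"near-zero denominator at (i,j,a,b)={idx}: D={D[idx]:.3e}")
    return Amplitudes(g_oovv / D)


def mp2_components(t: Amplitudes, g_oovv: np.ndarray) -> tuple[float, float]:
    """MP2 direct and exchange energies (E_C, E_X)."""
    tt = t.t_oovv
    if tt.shape != g_oovv.shape:
        raise ValidationError("amplitude/integral shape mismatch")
    E_C = 2.0 * np.einsum("ijab,ijab->", tt, g_oovv)
    E_X = -np.einsum("jiab,ijab->", tt, g_oovv)
    return float(E_C), float(E_X)


def mp3_components(t: Amplitudes, blocks: IntegralBlocks) -> np.ndarray:
    """The ten third-order diagram energies E1..E10, in fixed printed order."""
    tt = t.t_oovv
    n_o, _, n_v, _ = tt.shape
    if blocks.g_vvvv.shape != (n_v,) * 4 or blocks.g_oooo.shape != (n_o,) * 4:
        raise ValidationError("ladder block shape mismatch")
    if blocks.g_ovvo.shape != (n_o, n_v, n_v, n_o) or blocks.g_ovov.shape != (n_o, n_v, n_o, n_v):
        raise ValidationError("ring block shape mismatch")
    gv, go, gd, gx = blocks.g_vvvv, blocks.g_oooo, blocks.g_ovvo, blocks.g_ovov
    E = np.empty(10)
    # particle-particle ladder: t_ij^ab <ab|ef> t_ij^ef
    E[0] = 2.0 * np.einsum("ijab,abef,ijef->", tt, gv, tt)
    E[1] = -np.einsum("jiab,abef,ijef->", tt, gv, tt)
    # hole-hole ladder: t_ij^ab <mn|ij> t_mn^ab
    E[2] = 2.0 * np.einsum("ijab,mnij,mnab->", tt, go, tt)
    E[3] = -np.einsum("jiab,mnij,mnab->", tt, go, tt)
    # rings: t_ij^ab <mb|ej> t_im^ae and permuted partners
    E[4] = 8.0 * np.einsum("ijab,mbej,imae->", tt, gd, tt)
    E[5] = -4.0 * np.einsum("ijab,mbje,imae->", tt, gx, tt)
    E[6] = -4.0 * np.einsum("jiab,mbje,miae->", tt, gx, tt)
    E[7] = 2.0 * np.einsum("jiab,mbej,miae->", tt, gd, tt)
    E[8] = -8.0 * np.einsum("ijab,mbej,miae->", tt, gd, tt)
    E[9] = 4.0 * np.einsum("ijab,mbje,miae->", tt, gx, tt)
    return E


def parameterized_energy(bd: EnergyBreakdown, c: CoefficientVector) -> float:
    """Component-scaled energy: absolute basis gives
    ``E_SCF + E_C + E_X + sum c_n E_n``; delta basis gives the correction
    ``sum (c_n - 1) E_n`` alone."""
    if bd.E.size != 10:
        raise ValidationError(
            f"variant {bd.variant!r} has no third-order components to scale")
    contrib = float(np.dot(c.c, bd.E))
    if c.basis == "absolute":
        return bd.E_SCF + bd.E_C + bd.E_X + contrib
    return contrib


def canonical_breakdown(system: OrbitalSystem, df: DFTensors) -> EnergyBreakdown:
    """Full DF-MP3 breakdown with exact (non-THC) integrals and amplitudes."""
    blocks = build_integral_blocks(df)
    t = first_order_amplitudes(system, blocks.g_oovv)
    E_C, E_X = mp2_components(t, blocks.g_oovv)
    E = mp3_components(t, blocks)
    return EnergyBreakdown(system.species_id, "canonical", system.e_scf, E_C, E_X, E)


# --- tabular serialization -------------------------------------------------

BREAKDOWN_COLUMNS = ["species_id", "variant", "E_SCF", "E_C", "E_X", *COMPONENT_NAMES]


def breakdowns_to_frame(breakdowns) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for bd in breakdowns:
        comps = bd.E if bd.E.size == 10 else np.full(10, np.nan)
        rows.append([bd.species_id, bd.variant, bd.E_SCF, bd.E_C, bd.E_X, *comps])
    return pd.DataFrame(rows, columns=BREAKDOWN_COLUMNS)


def frame_to_breakdowns(frame) -> list:
    out = []
    for row in frame.itertuples(index=False):
        comps = np.array([getattr(row, name) for name in COMPONENT_NAMES], dtype=float)
        if np.isnan(comps).all():
            comps = np.zeros(0)
        out.append(EnergyBreakdown(row.species_id, row.variant,
                                   float(row.E_SCF), float(row.E_C), float(row.E_X), comps))
    return out


def write_breakdowns(breakdowns, path) -> None:
    breakdowns_to_frame(breakdowns).to_csv(path, index=False, float_format="%.15g")


def read_breakdowns(path) -> list:
    import pandas as pd

    return frame_to_breakdowns(pd.read_csv(path))
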