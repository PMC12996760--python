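"""Least-squares tensor hypercontraction (LS-THC) machinery.

A four-index integral block over orbital pairs ``(pq)`` x ``(rs)`` is
factorized as

    g^{pr}_{qs} ~ sum_{PQ} X_p^P X_q^P  V_PQ  X_r^Q X_s^Q

where ``X`` collocates orbitals on a pruned grid and the core matrix ``V``
is the least-squares fit of the density-fitted integrals onto the grid
product basis.  Per-pair-type grids (oo, ov, vv) are pruned from a parent
grid by pivoted Cholesky factorization of the pair metric

    S_PQ = sum_{pq} X_p^P X_q^P X_p^Q X_q^Q

keeping points while the running pivot diagonal stays above
``10^-delta`` times the largest initial diagonal.  Smaller ``delta``
means a smaller grid, cheaper THC, and a larger factorization error.

The first-order amplitudes get their own core matrix ``T1`` by the same
least-squares fit applied to the denominator-weighted THC integrals; this
yields the MP2b/MP3b variants (both integrals and amplitudes
approximated), while MP2a approximates only the integrals.

Everything here is dense: the subject is factorization accuracy, not the
reduced-scaling contraction algorithms THC enables at production scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Collocation, DFTensors, OrbitalSystem, ValidationError
from .mp_theory import (Amplitudes, EnergyBreakdown, IntegralBlocks,
                        build_integral_blocks, energy_denominators,
                        first_order_amplitudes, mp2_components, mp3_components)

#: Relative eigenvalue cutoff for the metric pseudo-inverse.
PINV_CUTOFF = 1e-10


def pair_basis(X: Collocation) -> np.ndarray:
    """Z[(pq), P] = X_left[p, P] * X_right[q, P], pairs in row-major (p, q) order."""
    nl, ng = X.X_left.shape
    nr = X.X_right.shape[0]
    return (X.X_left[:, None, :] * X.X_right[None, :, :]).reshape(nl * nr, ng)


def fit_metric(X: Collocation) -> np.ndarray:
    """Grid-space Gram matrix of orbital-pair products (symmetric PSD)."""
    S = (X.X_left.T @ X.X_left) * (X.X_right.T @ X.X_right)
    return (S + S.T) / 2.0


def psd_pinv(S: np.ndarray, cutoff: float = PINV_CUTOFF) -> tuple[np.ndarray, int]:
    """Eigenvalue-cutoff pseudo-inverse of a symmetric PSD matrix.

    Eigenvalues below ``cutoff * lambda_max`` are dropped.  Returns the
    pseudo-inverse and the retained rank.
    """
    w, U = np.linalg.eigh((S + S.T) / 2.0)
    lam_max = w.max(initial=0.0)
    if lam_max <= 0.0:
        raise ValidationError("zero-rank metric: no grid support")
    keep = w > cutoff * lam_max
    rank = int(keep.sum())
    Uk = U[:, keep]
    return (Uk / w[keep]) @ Uk.T, rank


def prune_grid(parent: Collocation, delta: float) -> Collocation:
    """Select grid points by pivoted Cholesky on the parent pair metric.

    Greedy: at each step pick the largest residual diagonal (lowest index
    wins ties) and accept it while it is at least ``10^-delta`` times the
    largest *initial* diagonal.
    """
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    S = fit_metric(parent)
    n = S.shape[0]
    d = np.array(np.diag(S), dtype=float)
    threshold = 10.0 ** (-delta) * d.max()
    if d.max() < threshold or d.max() <= 0.0:
        raise ValidationError(
            "pruning selected no grid points; decrease delta or check collocation")
    L = np.zeros((n, 0))
    selected: list[int] = []
    while True:
        dres = d.copy()
        dres[selected] = -np.inf
        piv = int(np.argmax(dres))  # argmax returns the lowest index on ties
        if dres[piv] < threshold:
            break
        col = (S[:, piv] - L @ L[piv]) / np.sqrt(dres[piv])
        L = np.hstack([L, col[:, None]])
        d = d - col**2
        selected.append(piv)
        if len(selected) == n:
            break
    if not selected:
        raise ValidationError(
            "pruning selected no grid points; decrease delta or check collocation")
    return parent.subset(np.array(selected, dtype=int))


def project_df(X: Collocation, B: np.ndarray) -> np.ndarray:
    """E[P, J] = sum_{pq} X_p^P X_q^P B[p, q, J] (grid projection of DF factors)."""
    return np.einsum("pP,qP,pqJ->PJ", X.X_left, X.X_right, B)


def fit_core_V(bra: Collocation, ket: Collocation,
               B_bra: np.ndarray, B_ket: np.ndarray,
               S_bra_pinv: np.ndarray | None = None,
               S_ket_pinv: np.ndarray | None = None) -> np.ndarray:
    """Least-squares core matrix V for one block pairing.

    Normal equations of the fit ``g ~ Z_bra V Z_ket^T`` with
    ``g = B_bra B_ket^T`` in vectorized pair space:
    ``V = S_bra^+ (Z_bra^T B_bra) (Z_ket^T B_ket)^T S_ket^+``, evaluated
    by projecting each DF factor onto its grid then contracting over the
    auxiliary index.
    """
    if B_bra.shape[2] != B_ket.shape[2]:
        raise ValidationError("auxiliary dimension mismatch between bra and ket")
    if S_bra_pinv is None:
        S_bra_pinv, _ = psd_pinv(fit_metric(bra))
    if S_ket_pinv is None:
        S_ket_pinv, _ = psd_pinv(fit_metric(ket))
    E_bra = project_df(bra, B_bra)
    E_ket = project_df(ket, B_ket)
    return S_bra_pinv @ E_bra @ E_ket.T @ S_ket_pinv


def reconstruct_integrals(bra: Collocation, ket: Collocation, V: np.ndarray) -> np.ndarray:
    """Dense THC reconstruction ``g[p,q,r,s] = sum_PQ X_p^P X_q^P V_PQ X_r^Q X_s^Q``.

    Index order: (bra left, bra right, ket left, ket right).
    """
    if V.shape != (bra.n_grid, ket.n_grid):
        raise ValidationError("core matrix shape does not match grids")
    half = np.einsum("pP,qP,PQ->pqQ", bra.X_left, bra.X_right, V)
    return np.einsum("pqQ,rQ,sQ->pqrs", half, ket.X_left, ket.X_right)


def fit_core_T1(ov: Collocation, g_thc_oovv: np.ndarray, system: OrbitalSystem,
                S_ov_pinv: np.ndarray | None = None) -> np.ndarray:
    """LS fit of the denominator-weighted THC integrals onto the ov grid.

    The target is ``t~ = g_THC / D`` with the usual orbital-energy
    denominators; ``T1 = S^+ (Z^T t~ Z) S^+`` with ``Z`` the ov pair
    basis.  Dense by design.
    """
    D = energy_denominators(system)
    t_target = first_order_amplitudes(system, g_thc_oovv).t_oovv  # checks degeneracy
    del D
    if S_ov_pinv is None:
        S_ov_pinv, _ = psd_pinv(fit_metric(ov))
    Z = pair_basis(ov)  # pairs in (i, a) row-major order
    n_o, _, n_v, _ = t_target.shape
    M = t_target.transpose(0, 2, 1, 3).reshape(n_o * n_v, n_o * n_v)  # (ia) x (jb)
    return S_ov_pinv @ (Z.T @ M @ Z) @ S_ov_pinv


@dataclass
class PairFit:
    """Per-pair-type THC fit artifacts."""

    pruned: Collocation
    S: np.ndarray
    S_pinv: np.ndarray
    rank: int
    n_grid_parent: int


@dataclass
class THCFactorization:
    """All grids, metrics and core matrices for one species at one delta."""

    delta: float
    pairs: dict            # pair_type -> PairFit
    V: dict                # (bra_type, ket_type) -> core matrix
    T1: np.ndarray


def factorize(df: DFTensors, parent_grids: dict, system: OrbitalSystem,
              delta: float) -> THCFactorization:
    """Prune grids, fit metrics and all core matrices needed through MP3."""
    pairs = {}
    for pt in ("oo", "ov", "vv"):
        pruned = prune_grid(parent_grids[pt], delta)
        S = fit_metric(pruned)
        S_pinv, rank = psd_pinv(S)
        pairs[pt] = PairFit(pruned, S, S_pinv, rank, parent_grids[pt].n_grid)

    def V_for(bt, kt):
        return fit_core_V(pairs[bt].pruned, pairs[kt].pruned,
                          df.block(bt), df.block(kt),
                          pairs[bt].S_pinv, pairs[kt].S_pinv)

    V = {("ov", "ov"): V_for("ov", "ov"),
         ("vv", "vv"): V_for("vv", "vv"),
         ("oo", "oo"): V_for("oo", "oo"),
         ("oo", "vv"): V_for("oo", "vv")}

    g_thc_oovv = thc_integral_blocks(pairs, V).g_oovv
    T1 = fit_core_T1(pairs["ov"].pruned, g_thc_oovv, system, pairs["ov"].S_pinv)
    return THCFactorization(delta, pairs, V, T1)


def thc_integral_blocks(pairs: dict, V: dict) -> IntegralBlocks:
    """Dense THC-approximated integral blocks in mp_theory's index order."""
    ov, vv, oo = pairs["ov"].pruned, pairs["vv"].pruned, pairs["oo"].pruned
    # ov x ov reconstruction is (i, a, j, b); <ij|ab> wants (i, j, a, b)
    g_ovov_pairs = reconstruct_integrals(ov, ov, V[("ov", "ov")])
    g_oovv = g_ovov_pairs.transpose(0, 2, 1, 3)
    # vv x vv is (a, e, b, f); <ab|ef> wants (a, b, e, f)
    g_vvvv = reconstruct_integrals(vv, vv, V[("vv", "vv")]).transpose(0, 2, 1, 3)
    # oo x oo is (m, i, n, j); <mn|ij> wants (m, n, i, j)
    g_oooo = reconstruct_integrals(oo, oo, V[("oo", "oo")]).transpose(0, 2, 1, 3)
    # direct ring <mb|ej> = (me|bj): ov x ov gives (m, e, j, b) -> (m, b, e, j)
    g_ovvo = g_ovov_pairs.transpose(0, 3, 1, 2)
    # exchange ring <mb|je> = (mj|be): oo x vv gives (m, j, b, e) -> (m, b, j, e)
    g_ovov = reconstruct_integrals(oo, vv, V[("oo", "vv")]).transpose(0, 2, 1, 3)
    return IntegralBlocks(g_oovv, g_vvvv, g_oooo, g_ovvo, g_ovov)


def thc_amplitudes(fact: THCFactorization) -> Amplitudes:
    """Amplitudes reconstructed from the fitted T1 core (MP2b/MP3b)."""
    ov = fact.pairs["ov"].pruned
    t_pairs = reconstruct_integrals(ov, ov, fact.T1)  # (i, a, j, b)
    return Amplitudes(t_pairs.transpose(0, 2, 1, 3))


def goodness_of_fit_all(df: DFTensors, fact: THCFactorization) -> dict:
    """f_pq = 1 - ||B - B_THC||_F / ||B||_F per pair type.

    ``B_THC`` is the orthogonal projection of the vectorized DF factors
    onto the span of the THC pair basis (``Z S^+ Z^T B``).
    """
    out = {}
    for pt in ("vv", "ov", "oo"):
        pf = fact.pairs[pt]
        B = df.block(pt)
        nB = np.linalg.norm(B)
        if nB == 0.0:
            raise ValidationError(f"zero DF factor norm for pair type {pt}")
        Z = pair_basis(pf.pruned)
        Bmat = B.reshape(Z.shape[0], -1)
        B_thc = Z @ (pf.S_pinv @ (Z.T @ Bmat))
        out[pt] = 1.0 - np.linalg.norm(Bmat - B_thc) / nB
    return out


def thc_energy_suite(system: OrbitalSystem, df: DFTensors, parent_grids: dict,
                     delta: float) -> tuple[dict, dict]:
    """Canonical DF plus MP2a/MP2b/MP3b breakdowns for one species.

    Returns ``(breakdowns, fit_info)`` where ``breakdowns`` maps variant
    name to :class:`EnergyBreakdown` and ``fit_info`` carries per-pair
    goodness-of-fit and grid sizes for the feature layer.
    """
    sid, e_scf = system.species_id, system.e_scf

    blocks = build_integral_blocks(df)
    t_exact = first_order_amplitudes(system, blocks.g_oovv)
    E_C, E_X = mp2_components(t_exact, blocks.g_oovv)
    canonical = EnergyBreakdown(sid, "canonical", e_scf, E_C, E_X,
                                mp3_components(t_exact, blocks))

    fact = factorize(df, parent_grids, system, delta)
    thc_blocks = thc_integral_blocks(fact.pairs, fact.V)

    # MP2a: THC integrals, amplitudes by exact division of the THC integrals
    t_a = first_order_amplitudes(system, thc_blocks.g_oovv)
    E_C_a, E_X_a = mp2_components(t_a, thc_blocks.g_oovv)
    mp2a = EnergyBreakdown(sid, "mp2a", e_scf, E_C_a, E_X_a)

    # MP2b/MP3b: both integrals and amplitudes THC-approximated
    t_b = thc_amplitudes(fact)
    E_C_b, E_X_b = mp2_components(t_b, thc_blocks.g_oovv)
    mp2b = EnergyBreakdown(sid, "mp2b", e_scf, E_C_b, E_X_b)
    mp3b = EnergyBreakdown(sid, "mp3b", e_scf, E_C_b, E_X_b,
                           mp3_components(t_b, thc_blocks))

    f = goodness_of_fit_all(df, fact)
    fit_info = {
        "species_id": sid,
        "f_vv": f["vv"], "f_ov": f["ov"], "f_oo": f["oo"],
        "norm_g_F": float(np.linalg.norm(blocks.g_oovv)),
        "norm_t_F": float(np.linalg.norm(t_exact.t_oovv)),
        "norm_g_inf": float(np.abs(blocks.g_oovv).max()),
        "norm_t_inf": float(np.abs(t_exact.t_oovv).max()),
        "grids": {pt: {"parent": fact.pairs[pt].n_grid_parent,
                       "pruned": fact.pairs[pt].pruned.n_grid,
                       "rank": fact.pairs[pt].rank}
                  for pt in ("oo", "ov", "vv")},
    }
    breakdowns = {"canonical": canonical, "mp2a": mp2a, "mp2b": mp2b, "mp3b": mp3b}
    return breakdowns, fit_info
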