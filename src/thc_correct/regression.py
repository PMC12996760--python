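"""Regression models that learn and remove THC errors, plus evaluation.

Three model families:

- ``scs``: component scaling in the spirit of spin-component-scaled MP2 —
  a zero-intercept linear fit of the ten unscaled MP3b diagram components
  against the part of the label the fixed MP3b baseline misses.  The
  fitted coefficients are the delta-basis scalings ``c' = c - 1``.
- ``mlr``: multiple linear regression with intercept on the full scaled
  feature table and scaled labels.
- ``krr``: kernel ridge regression with an RBF (Gaussian) kernel
  ``K_ik = exp(-gamma ||x_i - x_k||^2)`` and ridge strength ``alpha``,
  trained in scaled feature/label space.

Hyperparameters are tuned by a cross-validated grid search refined with
Nelder-Mead in ``(log10 alpha, log10 gamma)`` space.  Evaluation is
k-fold cross-validation with per-fold scaler fits (no test-row leakage),
reported in original units next to the uncorrected-THC baseline and the
fractional improvement %IMP = (X_base - X_pred)/X_base * 100.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core_io import HARTREE_TO_KCAL, ValidationError
from .datasets import LabelSet, make_folds, reaction_energy
from .features import SCS_COLUMNS, Scaler

logger = logging.getLogger(__name__)

MODEL_KINDS = ("scs", "mlr", "krr")

#: Labels with |y| at or below this (label units) are excluded from MAPE.
TOL_MAPE = 1e-12

MODEL_FORMAT_VERSION = "thc-correct-model/1"


# --- core fits -------------------------------------------------------------

def fit_linear(X: np.ndarray, y: np.ndarray, intercept: bool = True):
    """Least-squares linear fit; returns ``(coef, intercept_value)``.

    Requires more rows than parameters; a rank-deficient design warns and
    falls back to the minimum-norm solution (which lstsq provides).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    n_par = k + (1 if intercept else 0)
    if n <= n_par:
        raise ValidationError(f"need N > K: N={n}, parameters={n_par}")
    design = np.hstack([np.ones((n, 1)), X]) if intercept else X
    sol, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; returning minimum-norm solution",
                      stacklevel=2)
    if intercept:
        return sol[1:], float(sol[0])
    return sol, 0.0


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :]
          - 2.0 * A @ B.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def fit_krr_dual(X_scaled: np.ndarray, y_scaled: np.ndarray,
                 alpha: float, gamma: float) -> np.ndarray:
    """Dual weights solving ``(K + alpha I) w = y`` in scaled space."""
    K = rbf_kernel(X_scaled, X_scaled, gamma)
    A = K + alpha * np.eye(len(K))
    try:
        from scipy.linalg import cho_factor, cho_solve

        return cho_solve(cho_factor(A, lower=True), y_scaled)
    except np.linalg.LinAlgError:
        warnings.warn("kernel system not positive definite; least-squares fallback",
                      stacklevel=2)
        return np.linalg.lstsq(A, y_scaled, rcond=None)[0]
    except Exception:
        warnings.warn("Cholesky solve failed; least-squares fallback", stacklevel=2)
        return np.linalg.lstsq(A, y_scaled, rcond=None)[0]


@dataclass
class RegressionModel:
    """A trained model with everything needed for bit-reproducible prediction."""

    kind: str
    feature_names: list
    coef: np.ndarray | None = None
    intercept: float = 0.0
    alpha: float | None = None
    gamma: float | None = None
    dual_weights: np.ndarray | None = None
    support: np.ndarray | None = None        # scaled training features (krr)
    feature_scaler: Scaler | None = None
    label_scaler: Scaler | None = None
    seed: int | None = None

    def predict(self, features: pd.DataFrame, baseline: np.ndarray | None = None) -> np.ndarray:
        """Predict labels in original units.

        ``baseline`` (the uncorrected per-row prediction) is required for
        the scs kind, whose fit targets the residual from that baseline.
        """
        X = features.loc[:, self.feature_names]
        if self.kind == "scs":
            if baseline is None:
                raise ValidationError("scs prediction requires baseline values")
            return np.asarray(baseline, float) + X.to_numpy(float) @ self.coef
        Xs = self.feature_scaler.transform(X).to_numpy(float)
        if self.kind == "mlr":
            ys = Xs @ self.coef + self.intercept
        elif self.kind == "krr":
            ys = rbf_kernel(Xs, self.support, self.gamma) @ self.dual_weights
        else:
            raise ValidationError(f"unknown model kind {self.kind!r}")
        return self.label_scaler.inverse_transform_vector(ys)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {"format_version": MODEL_FORMAT_VERSION, "kind": self.kind,
             "feature_names": list(self.feature_names),
             "intercept": self.intercept, "seed": self.seed,
             "alpha": self.alpha, "gamma": self.gamma}
        for name in ("coef", "dual_weights", "support"):
            arr = getattr(self, name)
            d[name] = None if arr is None else np.asarray(arr).tolist()
        for name in ("feature_scaler", "label_scaler"):
            sc = getattr(self, name)
            d[name] = None if sc is None else sc.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValidationError("unsupported model format")

        def arr(x):
            return None if x is None else np.asarray(x, float)

        def sc(x):
            return None if x is None else Scaler.from_dict(x)

        return cls(kind=d["kind"], feature_names=list(d["feature_names"]),
                   coef=arr(d["coef"]), intercept=float(d["intercept"]),
                   alpha=d["alpha"], gamma=d["gamma"],
                   dual_weights=arr(d["dual_weights"]), support=arr(d["support"]),
                   feature_scaler=sc(d["feature_scaler"]),
                   label_scaler=sc(d["label_scaler"]), seed=d["seed"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RegressionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_model(kind: str, features: pd.DataFrame, y: np.ndarray,
                baseline: np.ndarray | None = None,
                alpha: float = 1e-6, gamma: float = 1e-2,
                seed: int | None = None) -> RegressionModel:
    """Train one model on the given (training) rows.

    For ``scs`` the fit is zero-intercept on the ten unscaled MP3b
    components against ``y - baseline``; for ``mlr``/``krr`` features and
    labels are standardized on these rows first.
    """
    y = np.asarray(y, float)
    if kind == "scs":
        X = features.loc[:, list(SCS_COLUMNS)]
        if baseline is None:
            raise ValidationError("scs training requires baseline values")
        coef, _ = fit_linear(X.to_numpy(float), y - np.asarray(baseline, float),
                             intercept=False)
        return RegressionModel("scs", list(SCS_COLUMNS), coef=coef, seed=seed)
    fsc = Scaler().fit(features)
    lsc = Scaler().fit(pd.DataFrame({"y": y}))
    Xs = fsc.transform(features).to_numpy(float)
    ys = lsc.transform_vector(y)
    if kind == "mlr":
        coef, icpt = fit_linear(Xs, ys, intercept=True)
        return RegressionModel("mlr", list(features.columns), coef=coef,
                               intercept=icpt, feature_scaler=fsc,
                               label_scaler=lsc, seed=seed)
    if kind == "krr":
        w = fit_krr_dual(Xs, ys, alpha, gamma)
        return RegressionModel("krr", list(features.columns), alpha=alpha,
                               gamma=gamma, dual_weights=w, support=Xs,
                               feature_scaler=fsc, label_scaler=lsc, seed=seed)
    raise ValidationError(f"unknown model kind {kind!r}")


# --- metrics ---------------------------------------------------------------

def metrics(y: np.ndarray, yhat: np.ndarray,
            tol_mape: float = TOL_MAPE) -> tuple[float, float, float]:
    """(RMSE, MAE, MAPE); rows with |y| <= tol are excluded from MAPE."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValidationError("y and yhat lengths differ")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ok = np.abs(y) > tol_mape
    n_excl = int((~ok).sum())
    if n_excl:
        logger.info("MAPE: excluded %d rows with |y| <= %g", n_excl, tol_mape)
    mape = float(100.0 * np.mean(np.abs(err[ok] / y[ok]))) if ok.any() else float("nan")
    return rmse, mae, mape


def pct_improvement(x_base: float, x_pred: float) -> float:
    """Fractional improvement over the uncorrected baseline, in percent."""
    if not x_base > 0:
        raise ValidationError("baseline error statistic must be positive")
    return (x_base - x_pred) / x_base * 100.0


def round_pct(p: float) -> int:
    """Integer percent, half rounded away from zero (reporting convention)."""
    return int(np.sign(p) * np.floor(np.abs(p) + 0.5))


# --- cross-validation ------------------------------------------------------

@dataclass
class CVReport:
    """Per-fold test metrics, their summary, baseline, and improvements."""

    model_kind: str
    label_kind: str
    k: int
    seed: int
    per_fold: pd.DataFrame          # fold, rmse, mae, mape (model and baseline)
    predictions: pd.DataFrame       # id, fold, y, yhat, baseline
    alpha: float | None = None
    gamma: float | None = None

    def _summary(self, prefix: str) -> dict:
        out = {}
        for m in ("rmse", "mae", "mape"):
            col = self.per_fold[f"{prefix}{m}"]
            out[m] = {"mean": float(col.mean()), "std": float(col.std(ddof=0))}
        return out

    @property
    def model_metrics(self) -> dict:
        return self._summary("")

    @property
    def baseline_metrics(self) -> dict:
        return self._summary("base_")

    def pct_imp(self, which: str = "rmse") -> float:
        return pct_improvement(self.baseline_metrics[which]["mean"],
                               self.model_metrics[which]["mean"])

    def to_dict(self) -> dict:
        imp = {}
        for m in ("rmse", "mae", "mape"):
            base = self.baseline_metrics[m]["mean"]
            if np.isfinite(base) and base > 0:
                imp[m] = pct_improvement(base, self.model_metrics[m]["mean"])
            else:
                imp[m] = None
        return {"model_kind": self.model_kind, "label_kind": self.label_kind,
                "k": self.k, "seed": self.seed,
                "alpha": self.alpha, "gamma": self.gamma,
                "model": self.model_metrics, "baseline": self.baseline_metrics,
                "pct_imp": imp,
                "per_fold": self.per_fold.to_dict(orient="list")}


def cross_validate(features: pd.DataFrame, labels: LabelSet,
                   baseline: np.ndarray, model_kind: str, k: int = 10,
                   seed: int = 0, alpha: float = 1e-6,
                   gamma: float = 1e-2) -> CVReport:
    """k-fold CV of one model kind against the uncorrected-THC baseline.

    ``features`` is indexed by id and aligned to ``labels`` rows;
    ``baseline`` holds the uncorrected prediction per row (the MP3b value
    for absolute kinds, zero for delta kinds).  Scalers are fitted inside
    each training split only.
    """
    ids = labels.ids
    X = features.loc[ids]
    y = labels.y
    baseline = np.asarray(baseline, float)
    if len(baseline) != len(ids):
        raise ValidationError("baseline length mismatch")
    folds = make_folds(len(ids), k, seed)
    fold_rows, pred_rows = [], []
    for j in range(k):
        tr, te = folds.train_indices(j), folds.test_indices(j)
        if len(te) < 2:
            raise ValidationError(f"fold {j} has fewer than 2 test rows")
        model = train_model(model_kind, X.iloc[tr], y[tr],
                            baseline=baseline[tr], alpha=alpha, gamma=gamma,
                            seed=seed)
        yhat = model.predict(X.iloc[te], baseline=baseline[te])
        rmse, mae, mape = metrics(y[te], yhat)
        b_rmse, b_mae, b_mape = metrics(y[te], baseline[te])
        fold_rows.append((j, rmse, mae, mape, b_rmse, b_mae, b_mape, len(te)))
        for i, idx in enumerate(te):
            pred_rows.append((ids[idx], j, y[idx], yhat[i], baseline[idx]))
    per_fold = pd.DataFrame(fold_rows, columns=[
        "fold", "rmse", "mae", "mape", "base_rmse", "base_mae", "base_mape", "n"])
    predictions = pd.DataFrame(pred_rows, columns=["id", "fold", "y", "yhat", "baseline"])
    return CVReport(model_kind, labels.kind, k, seed, per_fold, predictions,
                    alpha=alpha if model_kind == "krr" else None,
                    gamma=gamma if model_kind == "krr" else None)


# --- hyperparameter tuning -------------------------------------------------

DEFAULT_ALPHA_GRID = tuple(10.0 ** np.arange(-9, 4, dtype=float))
DEFAULT_GAMMA_GRID = tuple(10.0 ** np.arange(-7, 2, dtype=float))


def _cv_rmse_krr(features: pd.DataFrame, y: np.ndarray, alpha: float,
                 gamma: float, folds) -> float:
    losses = []
    for j in range(folds.k):
        tr, te = folds.train_indices(j), folds.test_indices(j)
        model = train_model("krr", features.iloc[tr], y[tr],
                            alpha=alpha, gamma=gamma)
        yhat = model.predict(features.iloc[te])
        losses.append(np.sqrt(np.mean((y[te] - yhat) ** 2)))
    return float(np.mean(losses))


def tune_hyperparameters(features: pd.DataFrame, y: np.ndarray,
                         grid_alpha=DEFAULT_ALPHA_GRID,
                         grid_gamma=DEFAULT_GAMMA_GRID,
                         k: int = 10, seed: int = 0,
                         nm_maxiter: int = 200,
                         nm_ftol: float = 1e-4):
    """Grid search then Nelder-Mead refinement of (alpha, gamma).

    Both stages minimize mean k-fold CV RMSE.  The simplex walks in
    ``(log10 alpha, log10 gamma)``; if refinement fails to improve, the
    grid optimum is kept.  Returns ``(alpha, gamma, trace)`` where the
    trace records every evaluated point for heatmap export.
    """
    grid_alpha = list(grid_alpha)
    grid_gamma = list(grid_gamma)
    if not grid_alpha or not grid_gamma:
        raise ValidationError("hyperparameter grids must be non-empty")
    y = np.asarray(y, float)
    folds = make_folds(len(y), k, seed)
    trace = []

    def loss(alpha, gamma, stage):
        val = _cv_rmse_krr(features, y, alpha, gamma, folds)
        trace.append((stage, alpha, gamma, val))
        return val

    best = None
    for a in grid_alpha:
        for g in grid_gamma:
            val = loss(a, g, "grid")
            if best is None or val < best[2]:
                best = (a, g, val)
    a0, g0, f0 = best

    if len(grid_alpha) * len(grid_gamma) > 1:
        res = minimize(lambda p: loss(10.0 ** p[0], 10.0 ** p[1], "simplex"),
                       x0=[np.log10(a0), np.log10(g0)], method="Nelder-Mead",
                       options={"maxiter": nm_maxiter, "fatol": nm_ftol * max(f0, 1e-300),
                                "xatol": 1e-3})
        if np.isfinite(res.fun) and res.fun <= f0:
            a0, g0, f0 = 10.0 ** res.x[0], 10.0 ** res.x[1], float(res.fun)
        else:
            warnings.warn("simplex refinement did not improve; keeping grid optimum",
                          stacklevel=2)
    trace_frame = pd.DataFrame(trace, columns=["stage", "alpha", "gamma", "cv_rmse"])
    return float(a0), float(g0), trace_frame


# --- reaction evaluation from molecule-trained models ----------------------

def reaction_cv_from_molecule(molecule_report: CVReport, schemes,
                              n_valence: dict, breakdowns_by_species: dict,
                              k: int = 10, seed: int = 0) -> CVReport:
    """Evaluate reaction energies from out-of-fold species predictions.

    Per-species predictions come from the molecule-set CV (each species
    predicted by the model that held it out), are rescaled by the valence
    electron count, and combined stoichiometrically.  Reactions get their
    own fold split for summary statistics; canonical MP3 reaction
    energies are the reference and uncorrected MP3b ones the baseline.
    """
    if molecule_report.label_kind not in ("molecule", "delta_molecule"):
        raise ValidationError("reaction evaluation needs a molecule-kind report")
    delta_mode = molecule_report.label_kind == "delta_molecule"
    pred = dict(zip(molecule_report.predictions["id"], molecule_report.predictions["yhat"]))
    e_mp3 = {sid: bds["canonical"].total * HARTREE_TO_KCAL
             for sid, bds in breakdowns_by_species.items()}
    e_mp3b = {sid: bds["mp3b"].total * HARTREE_TO_KCAL
              for sid, bds in breakdowns_by_species.items()}
    # species prediction in kcal/mol (undo per-valence-electron scaling)
    e_pred = {}
    for sid, yhat in pred.items():
        val = yhat * n_valence[sid]
        e_pred[sid] = e_mp3b[sid] + val if delta_mode else val

    rows = []
    for s in schemes:
        rows.append((s.reaction_id,
                     reaction_energy(s, e_mp3),
                     reaction_energy(s, e_pred),
                     reaction_energy(s, e_mp3b)))
    table = pd.DataFrame(rows, columns=["id", "y", "yhat", "baseline"])
    folds = make_folds(len(table), k, seed)
    fold_rows = []
    table["fold"] = folds.fold
    for j in range(k):
        sub = table[table["fold"] == j]
        rmse, mae, mape = metrics(sub["y"], sub["yhat"])
        b_rmse, b_mae, b_mape = metrics(sub["y"], sub["baseline"])
        fold_rows.append((j, rmse, mae, mape, b_rmse, b_mae, b_mape, len(sub)))
    per_fold = pd.DataFrame(fold_rows, columns=[
        "fold", "rmse", "mae", "mape", "base_rmse", "base_mae", "base_mape", "n"])
    kind = "delta_reaction" if delta_mode else "reaction"
    return CVReport(molecule_report.model_kind, kind, k, seed, per_fold,
                    table[["id", "fold", "y", "yhat", "baseline"]],
                    alpha=molecule_report.alpha, gamma=molecule_report.gamma)
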