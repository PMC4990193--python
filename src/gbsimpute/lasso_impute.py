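"""LASSO-penalized regression imputation of genotype dosages.

Each site with missing genotypes is imputed from the other markers on
the chromosome, ignoring marker order and distance: the method models a
target site as a sparse linear combination of the most-correlated
markers and exploits whatever statistical LD the sample carries.

Per target site the procedure is:

1. initialize every missing entry on the chromosome to the site mean;
2. rank all other sites by |Pearson correlation| with the target on the
   mean-filled matrix and keep the top ``k_markers`` (default 60);
3. restrict to individuals with an *observed* target dosage, fit the
   L1-penalized least squares model over a log-spaced path of
   ``n_lambda`` penalty values, choosing λ by minimum mean squared
   error in ``cv_folds``-fold cross-validation;
4. predict the missing entries and clip to [0, 2].

The coordinate-descent path solver is scikit-learn's
:func:`~sklearn.linear_model.lasso_path`; path construction, CV, λ
selection and standardization live here.  λ is expressed on the
per-observation scale ((1/2n)·RSS + λ·Σ|β_j|), for which
``λ_max = max_j |<standardized x_j, centered y>| / n`` is the smallest
penalty shrinking every coefficient to zero.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .genolik import DosageMatrix

#: coordinate-descent duality-gap tolerance (the scikit-learn default),
#: pinned explicitly because the OLS-limit contract of fit_lasso_cv
#: (exact signals recovered at tiny λ) depends on it
_CD_TOL = 1e-4

__all__ = [
    "ImputationConfig",
    "LassoFit",
    "initialize_means",
    "preselect_markers",
    "fit_lasso_cv",
    "impute_matrix",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ImputationConfig:
    """Tunables of the per-site LASSO imputer.

    ``k_markers`` preselected predictors (60), ``n_lambda`` penalty
    values (10) log-spaced from λ_max down to
    ``λ_max * lambda_min_ratio``, ``cv_folds``-fold CV (5) choosing λ by
    minimum CV mean squared error.  ``clip`` bounds predictions to
    [0, 2].  ``seed`` drives CV fold assignment, the only randomness.
    """

    k_markers: int = 60
    n_lambda: int = 10
    cv_folds: int = 5
    lambda_min_ratio: float = 0.01
    clip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_markers < 1:
            raise ValueError("k_markers must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.lambda_min_ratio <= 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1]")


@dataclasses.dataclass
class LassoFit:
    """One fitted per-site model, coefficients on the original scale."""

    target: int | None
    predictors: np.ndarray
    intercept: float
    coef: np.ndarray
    lambda_: float
    lambdas: np.ndarray
    cv_mse: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef


def _values(d) -> np.ndarray:
    if isinstance(d, DosageMatrix):
        return d.values
    return np.asarray(d, dtype=float)


def initialize_means(d) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing entries with the per-site mean of observed dosages.

    Returns ``(filled, missing_mask)``.  A site with no observed
    genotype is flagged (warning) and filled with the overall mean.
    """
    values = _values(d)
    mask = np.isnan(values)
    filled = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        site_means = np.nanmean(values, axis=1)
    empty = np.isnan(site_means)
    if empty.any():
        overall = np.nanmean(values)
        logger.warning("%d site(s) with no observed genotype filled with the "
                       "overall mean", int(empty.sum()))
        site_means[empty] = 0.0 if np.isnan(overall) else overall
    rows, cols = np.nonzero(mask)
    filled[rows, cols] = site_means[rows]
    return filled, mask


def _standardized_rows(filled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized matrix and a validity mask (zero-variance rows False)."""
    mu = filled.mean(axis=1, keepdims=True)
    sd = filled.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.where(ok[:, None], (filled - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, ok


def preselect_markers(filled, target: int, k: int = 60,
                      _z_cache: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> np.ndarray:
    """Indices of the <= k sites most correlated with ``target``.

    Correlations are computed on the mean-filled matrix; sites with zero
    variance (undefined r) are excluded, and ties broken toward the
    smaller site index.
    """
    filled = _values(filled)
    z, ok = _z_cache if _z_cache is not None else _standardized_rows(filled)
    n = filled.shape[1]
    if not ok[target]:
        return np.empty(0, dtype=np.intp)
    c = np.abs(z @ (z[target] / n))
    c[target] = -np.inf
    c[~ok] = -np.inf
    eligible = np.nonzero(np.isfinite(c) & (c > -np.inf))[0]
    # sort by descending |r|, ascending index on ties
    order = np.lexsort((eligible, -c[eligible]))
    return eligible[order[:k]]


def _cv_folds_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.intp)
    for f in range(n_folds):
        fold_of[perm[f::n_folds]] = f
    return fold_of


def fit_lasso_cv(X: np.ndarray, y: np.ndarray,
                 cfg: ImputationConfig = ImputationConfig(),
                 target: int | None = None,
                 predictors: Sequence[int] | None = None,
                 rng: np.random.Generator | None = None,
                 lambdas: Sequence[float] | None = None) -> LassoFit:
    """Cross-validated LASSO fit of ``y`` on predictor columns ``X``.

    Predictors are standardized for fitting; returned coefficients are
    on the original scale.  λ is chosen as the minimizer of mean squared
    CV error over the log-spaced path (largest λ wins ties, i.e. the
    sparser model).  ``lambdas`` overrides the automatic path with an
    explicit one (a single value skips cross-validation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with n matching y")
    n, p = X.shape
    if n < cfg.cv_folds:
        raise ValueError(
            f"only {n} observed individuals for {cfg.cv_folds}-fold CV")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    keep = xs > 0
    ym = y.mean()
    yc = y - ym

    if not keep.any() or np.allclose(yc, 0.0):
        # no usable predictor / constant target: intercept-only model
        lambdas = np.array([0.0])
        return LassoFit(target, np.asarray(predictors if predictors is not None
                                           else np.arange(p)),
                        ym, np.zeros(p), 0.0, lambdas, np.full(1, np.nan))

    Z = (X[:, keep] - xm[keep]) / xs[keep]
    if lambdas is not None:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    else:
        lam_max = np.max(np.abs(Z.T @ yc)) / n
        if lam_max <= 0:
            lam_max = 1e-12
        lambdas = np.logspace(np.log10(lam_max),
                              np.log10(lam_max * cfg.lambda_min_ratio),
                              cfg.n_lambda)

    if len(lambdas) > 1:
        fold_of = _cv_folds_assignment(n, cfg.cv_folds, rng)
        sse = np.zeros(len(lambdas))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            for f in range(cfg.cv_folds):
                test = fold_of == f
                train = ~test
                Zt = Z[train]
                yt = yc[train]
                mu_t = yt.mean()
                _, coefs, _ = lasso_path(Zt, yt - mu_t, alphas=lambdas,
                                         tol=_CD_TOL)
                pred = Z[test] @ coefs + mu_t  # (n_test, n_lambda)
                sse += ((yc[test, None] - pred) ** 2).sum(axis=0)
        cv_mse = sse / n
        best = int(np.argmin(cv_mse))  # first minimum = largest λ on ties
    else:
        cv_mse = np.full(1, np.nan)
        best = 0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        _, coefs, _ = lasso_path(Z, yc, alphas=lambdas, tol=_CD_TOL)
    beta_std = coefs[:, best]
    coef = np.zeros(p)
    coef[keep] = beta_std / xs[keep]
    intercept = ym - float(coef @ xm)
    return LassoFit(target,
                    np.asarray(predictors if predictors is not None
                               else np.arange(p)),
                    intercept, coef, float(lambdas[best]), lambdas, cv_mse)


def impute_matrix(d, cfg: ImputationConfig = ImputationConfig(),
                  extra_individuals=None) -> DosageMatrix | np.ndarray:
    """Impute every missing dosage with the per-site LASSO procedure.

    ``extra_individuals`` (e.g. reference-panel dosages over the same
    sites) are pooled as additional training rows; only the study
    matrix's missing entries are predicted.  Observed study entries are
    returned bit-identical.  Per-site fallbacks (too few observed
    individuals for CV) degrade to mean imputation with a warning,
    never abort.  Deterministic given ``cfg.seed``.
    """
    values = _values(d)
    filled, mask = initialize_means(values)
    n_sites = values.shape[0]

    if extra_individuals is not None:
        extra = _values(extra_individuals)
        if extra.shape[0] != n_sites:
            raise ValueError("extra individuals must cover the same sites")
        efilled, emask = initialize_means(extra)
        train_filled = np.hstack([filled, efilled])
        train_orig = np.hstack([values, extra])
    else:
        train_filled = filled
        train_orig = values

    out = values.copy()
    z_cache = _standardized_rows(train_filled)
    n_fallback = 0
    for t in range(n_sites):
        miss = mask[t]
        if not miss.any():
            continue
        obs = ~np.isnan(train_orig[t])
        preds = preselect_markers(train_filled, t, cfg.k_markers, _z_cache=z_cache)
        site_rng = np.random.default_rng([cfg.seed, t])
        fallback = len(preds) == 0 or obs.sum() < cfg.cv_folds
        if fallback:
            n_fallback += 1
            yhat = np.full(miss.sum(), filled[t, miss].mean())
        else:
            X = train_filled[np.ix_(preds, obs)].T
            y = train_orig[t, obs]
            fit = fit_lasso_cv(X, y, cfg, target=t, predictors=preds,
                               rng=site_rng)
            yhat = fit.predict(filled[np.ix_(preds, miss)].T)
        if cfg.clip:
            yhat = np.clip(yhat, 0.0, 2.0)
        out[t, miss] = yhat
    if n_fallback:
        logger.warning("mean-imputation fallback at %d site(s) "
                       "(fewer observed individuals than CV folds)", n_fallback)
    if isinstance(d, DosageMatrix):
        return DosageMatrix(out, sites=d.sites, samples=d.samples)
    return out
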