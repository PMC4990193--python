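"""Masking cross-validation and accuracy analyses.

The accuracy experiment masks validation genotypes in 10 disjoint folds,
re-imputes each masked matrix, and scores the sample Pearson correlation
r between observed (validation) and imputed dosages, per site and per
individual within each fold.  Per-unit accuracy is the median of the
defined r values across folds; site-level summaries drop fold records
with fewer than ``min_L`` masked genotypes (default 30), where r is too
noisy to be informative.

r is undefined (NaN here) when a unit has fewer than two masked
genotypes in a fold or when either vector is invariant; such units are
reported, never silently dropped.

Also in this module: MAF estimation from dosages, binned covariate
summaries, the VanRaden realized additive relationship matrix and its
eigen-decomposition PCA, and :func:`run_cv`, the end-to-end engine the
CLI wraps.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal

import numpy as np
import pandas as pd

from . import lasso_impute
from .callers import ValidationSet, caller_A, caller_B
from .genolik import DosageMatrix, ErrorModel, dosage_matrix, likelihood_set
from .io_vcf import AlleleDepthMatrix

__all__ = [
    "FoldPartition",
    "partition_validation",
    "mask_fold",
    "pearson_r",
    "fold_accuracies",
    "median_over_folds",
    "estimate_maf",
    "site_stats",
    "bin_summary",
    "relationship_matrix",
    "pca_from_relationship",
    "CvResult",
    "run_cv",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FoldPartition:
    """Disjoint split M1..Mk of a validation set, sizes within 1.

    ``folds[i]`` holds indices into the :class:`ValidationSet` entry
    arrays; their union is the full set.
    """

    folds: list[np.ndarray]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.folds)


def partition_validation(vs: ValidationSet, n_folds: int = 10,
                         seed: int | None = None) -> FoldPartition:
    """Random equal split of validation entries into ``n_folds`` folds.

    A uniform random permutation is dealt round-robin, so fold sizes
    differ by at most one.
    """
    n = len(vs)
    if n < n_folds:
        raise ValueError(f"{n} validation entries cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [np.sort(perm[f::n_folds]) for f in range(n_folds)]
    return FoldPartition(folds=folds, seed=seed)


def mask_fold(d: DosageMatrix, vs: ValidationSet,
              fold: np.ndarray) -> DosageMatrix:
    """Set exactly the fold's coordinates to missing.

    A coordinate that is already missing signals a caller bug and raises.
    """
    out = d.copy()
    si = vs.site_idx[fold]
    sj = vs.sample_idx[fold]
    if np.isnan(out.values[si, sj]).any():
        raise ValueError("fold contains a coordinate that is already missing")
    out.values[si, sj] = np.nan
    return out


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN when undefined.

    Undefined when fewer than two pairs or when either vector is
    invariant (zero variance), e.g. a site imputed to one constant
    dosage for all masked genotypes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc * yc).sum() / (sx * sy))


def fold_accuracies(vs: ValidationSet, imputed: DosageMatrix,
                    fold: np.ndarray, by: Literal["site", "individual"],
                    fold_id: int = 0) -> pd.DataFrame:
    """Per-site or per-individual accuracy records for one fold.

    For each unit with masked coordinates in the fold, records ``L``
    (number of masked validation genotypes at the unit) and ``r``
    between validation and imputed dosages (NaN when undefined).
    """
    if by not in ("site", "individual"):
        raise ValueError("by must be 'site' or 'individual'")
    si = vs.site_idx[fold]
    sj = vs.sample_idx[fold]
    observed = vs.dosage[fold]
    predicted = imputed.values[si, sj]
    unit = si if by == "site" else sj
    records = []
    for u in np.unique(unit):
        sel = unit == u
        records.append({
            "unit": int(u),
            "fold": fold_id,
            "L": int(sel.sum()),
            "r": pearson_r(observed[sel], predicted[sel]),
        })
    return pd.DataFrame(records, columns=["unit", "fold", "L", "r"])


def median_over_folds(records: pd.DataFrame, min_L: int = 30) -> pd.DataFrame:
    """Median of defined per-fold r values per unit.

    Records with ``L < min_L`` are excluded first (use ``min_L=0`` for
    individual-level summaries; the L filter is a site-level device).
    Units whose r is undefined in every retained fold are reported with
    ``median_r = NaN``, so exclusion counts stay auditable; attrs carry
    ``n_excluded_small_L`` and ``n_units_all_undefined``.
    """
    kept = records[records["L"] >= min_L]
    out = (
        kept.groupby("unit")
        .agg(median_r=("r", "median"), n_folds=("r", "size"),
             n_defined=("r", lambda s: int(s.notna().sum())),
             total_L=("L", "sum"))
        .reset_index()
    )
    out.attrs["n_excluded_small_L"] = int((records["L"] < min_L).sum())
    out.attrs["n_units_all_undefined"] = int((out["n_defined"] == 0).sum())
    return out


def estimate_maf(d: DosageMatrix) -> np.ndarray:
    """Per-site minor allele frequency from observed dosages.

    ``p̂ = mean(observed dosages) / 2``; MAF is ``min(p̂, 1 − p̂)`` since
    the minor allele may be either REF or ALT.  All-missing sites give
    NaN.
    """
    values = _vals(d)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(values), axis=1)
        p = np.where(counts > 0,
                     np.nansum(values, axis=1) / np.maximum(counts, 1) / 2.0,
                     np.nan)
    return np.minimum(p, 1.0 - p)


def site_stats(adm: AlleleDepthMatrix, d: DosageMatrix) -> pd.DataFrame:
    """Per-site MAF, missing proportion and mean read depth."""
    return pd.DataFrame({
        "site": np.arange(adm.n_sites),
        "maf": estimate_maf(d),
        "missing": adm.missing_fraction,
        "mean_depth": adm.total_depth.mean(axis=1),
    })


def bin_summary(x, acc, n_bins: int, lo: float = 0.0,
                hi: float | None = None) -> pd.DataFrame:
    """Mean/median accuracy in left-open right-closed covariate bins.

    Bin i covers ``(lo + i*w, lo + (i+1)*w]`` with ``w = (hi − lo) /
    n_bins`` (e.g. MAF with n_bins=5, hi=0.5 gives (0, 0.1], …,
    (0.4, 0.5]).  Values at or below ``lo`` fall outside every bin.
    Empty bins are reported with NaN summaries, not an error.
    """
    x = np.asarray(x, dtype=float)
    acc = np.asarray(acc, dtype=float)
    if x.shape != acc.shape:
        raise ValueError("covariate and accuracy vectors must have equal length")
    if hi is None:
        hi = float(np.nanmax(x)) if x.size else lo + 1.0
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    w = (hi - lo) / n_bins
    idx = np.ceil((x - lo) / w).astype(float) - 1  # bin 0 is (lo, lo+w]
    rows = []
    for b in range(n_bins):
        sel = (idx == b) & ~np.isnan(acc)
        vals = acc[sel]
        rows.append({
            "bin_left": lo + b * w,
            "bin_right": lo + (b + 1) * w,
            "n": int(sel.sum()),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "median": float(np.median(vals)) if vals.size else np.nan,
        })
    return pd.DataFrame(rows)


def _vals(d) -> np.ndarray:
    return d.values if isinstance(d, DosageMatrix) else np.asarray(d, dtype=float)


def relationship_matrix(d, max_missing: float = 0.5,
                        freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden realized additive relationship matrix.

    Sites with missing fraction above ``max_missing`` are excluded and
    remaining missing dosages mean-imputed.  With W the individuals x
    sites matrix of dosages centered by ``2 p_k`` (allele-B frequency),
    ``A = W Wᵀ / (2 Σ_k p_k (1 − p_k))``.

    ``freqs`` supplies base-population allele-B frequencies (one per
    input site, before filtering); by default the sample's own
    frequencies are used.  Pedigree expectations (e.g. 0.5 for full
    sibs) hold relative to the base population, so pass founder
    frequencies when the sample is dominated by close families.
    """
    values = _vals(d)
    if values.shape[1] < 2:
        raise ValueError("need at least two individuals")
    missing = np.isnan(values).mean(axis=1)
    keep = missing <= max_missing
    if not keep.any():
        raise ValueError("no sites retained by the missingness filter")
    filled, _ = lasso_impute.initialize_means(values[keep])
    if freqs is not None:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape[0] != values.shape[0]:
            raise ValueError("freqs must give one frequency per site")
        p = freqs[keep]
    else:
        p = filled.mean(axis=1) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all retained sites are monomorphic")
    w = filled.T - 2.0 * p  # individuals x sites
    return (w @ w.T) / denom


def pca_from_relationship(A: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Component scores from eigen-decomposition of a relationship matrix.

    Scores are the top eigenvectors scaled by sqrt(eigenvalue), with the
    sign convention that each component's largest-magnitude loading is
    positive.  Negative eigenvalues (numerical) are truncated at zero.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("relationship matrix must be symmetric")
    w, v = np.linalg.eigh(A)
    order = np.argsort(w)[::-1][:n_components]
    scores = np.empty((A.shape[0], len(order)))
    for k, i in enumerate(order):
        vec = v[:, i]
        if vec[np.argmax(np.abs(vec))] < 0:
            vec = -vec
        scores[:, k] = vec * np.sqrt(max(w[i], 0.0))
    return scores


# ---------------------------------------------------------------------------
# end-to-end cross-validation engine


@dataclasses.dataclass
class CvResult:
    """Outputs of one masking cross-validation experiment."""

    per_site: pd.DataFrame
    per_individual: pd.DataFrame
    site_records: pd.DataFrame
    individual_records: pd.DataFrame
    site_stats: pd.DataFrame
    maf_bins: pd.DataFrame
    missing_bins: pd.DataFrame
    summary: dict


def run_cv(adm: AlleleDepthMatrix,
           caller: Literal["A", "B"] = "B",
           min_depth: int = 7,
           ratio: float = 10.0,
           n_folds: int = 10,
           min_L: int = 30,
           error_model: ErrorModel = ErrorModel(),
           impute_cfg: lasso_impute.ImputationConfig | None = None,
           extra_individuals: DosageMatrix | None = None,
           seed: int = 0,
           imputer=None) -> CvResult:
    """Masking cross-validation of an imputer on an allele-depth matrix.

    Computes likelihoods and dosages, defines validation genotypes with
    Caller A (depth >= ``min_depth``) or Caller B (likelihood ratio >=
    ``ratio``), splits them into ``n_folds`` folds, and per fold masks,
    imputes (the LASSO imputer by default; pass ``imputer(masked) ->
    DosageMatrix`` to score external dosages) and scores r per site and
    per individual.  Per-unit medians across folds apply the ``min_L``
    filter at the site level only.

    Separate random streams derived from ``seed`` drive partitioning and
    CV fold assignment, so stages are independently reproducible.
    """
    lik = likelihood_set(adm, error_model)
    dosages = dosage_matrix(adm, lik)
    if caller == "A":
        vs = caller_A(adm, dosages, min_depth=min_depth)
    elif caller == "B":
        vs = caller_B(lik, dosages, ratio=ratio)
    else:
        raise ValueError("caller must be 'A' or 'B'")
    logger.info("caller %s: %d validation genotypes (%.1f%% of entries)",
                caller, len(vs), 100.0 * len(vs) / dosages.values.size)

    part_seed, cv_seed = _child_seeds(seed)
    partition = partition_validation(vs, n_folds=n_folds, seed=part_seed)
    if impute_cfg is None:
        impute_cfg = lasso_impute.ImputationConfig(seed=cv_seed)
    else:
        impute_cfg = dataclasses.replace(impute_cfg, seed=cv_seed)

    site_recs = []
    ind_recs = []
    for f, fold in enumerate(partition.folds):
        masked = mask_fold(dosages, vs, fold)
        if imputer is not None:
            imputed = imputer(masked)
        else:
            imputed = lasso_impute.impute_matrix(
                masked, impute_cfg, extra_individuals=extra_individuals)
        site_recs.append(fold_accuracies(vs, imputed, fold, "site", fold_id=f))
        ind_recs.append(fold_accuracies(vs, imputed, fold, "individual",
                                        fold_id=f))
        logger.info("fold %d/%d scored (%d masked genotypes)",
                    f + 1, n_folds, len(fold))
    site_records = pd.concat(site_recs, ignore_index=True)
    ind_records = pd.concat(ind_recs, ignore_index=True)

    per_site = median_over_folds(site_records, min_L=min_L)
    per_ind = median_over_folds(ind_records, min_L=0)
    stats = site_stats(adm, dosages)
    merged = per_site.merge(stats, left_on="unit", right_on="site", how="left")
    maf_bins = bin_summary(merged["maf"].to_numpy(),
                           merged["median_r"].to_numpy(), n_bins=5, hi=0.5)
    missing_bins = bin_summary(merged["missing"].to_numpy(),
                               merged["median_r"].to_numpy(), n_bins=10, hi=1.0)

    summary = {
        "caller": caller,
        "n_sites": adm.n_sites,
        "n_individuals": adm.n_samples,
        "n_validation": int(len(vs)),
        "n_folds": n_folds,
        "min_L": min_L,
        "seed": seed,
        "median_per_site_r": float(per_site["median_r"].median()),
        "median_per_individual_r": float(per_ind["median_r"].median()),
        "n_sites_estimable": int(per_site["median_r"].notna().sum()),
        "n_sites_excluded_small_L": per_site.attrs["n_excluded_small_L"],
    }
    return CvResult(per_site=per_site, per_individual=per_ind,
                    site_records=site_records, individual_records=ind_records,
                    site_stats=stats, maf_bins=maf_bins,
                    missing_bins=missing_bins, summary=summary)


def _child_seeds(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    a, b = ss.spawn(2)
    return int(a.generate_state(1)[0] % (2 ** 31)), \
        int(b.generate_state(1)[0] % (2 ** 31))
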