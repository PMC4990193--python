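"""Genotype likelihoods, posteriors and dosages from allelic read depths.

At a biallelic SNP the observed data for one individual are the allele
counts ``(n_A, n_B)``.  Conditional on the true genotype ``g`` in
``{AA, AB, BB}`` and a fixed per-read error rate ``e``, the count of the
B allele is binomial::

    P(n_A, n_B | g, e) = C(n_A + n_B, n_B) * (1 - p_B)^n_A * p_B^n_B

with ``p_B = e`` for AA, ``0.5`` for AB and ``1 - e`` for BB.  A uniform
genotype prior turns the likelihood triple into a posterior triple, whose
mean B-allele count is the *genotype dosage* in ``[0, 2]``.  Zero total
depth means missing: the likelihoods are flat and the dosage is NA.

All computations run in log space so high depths do not underflow.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, TYPE_CHECKING

import numpy as np
from scipy.special import gammaln

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .io_vcf import AlleleDepthMatrix, Site

__all__ = [
    "ErrorModel",
    "LikelihoodSet",
    "DosageMatrix",
    "genotype_likelihoods",
    "posterior_triple",
    "dosage_from_posterior",
    "phred_normalize",
    "likelihood_set",
    "dosage_matrix",
]

#: genotype order used throughout: AA, AB, BB (count of allele B: 0, 1, 2)
GENOTYPES = ("AA", "AB", "BB")

#: Phred value written for zero-likelihood genotypes
PL_CAP = 255

UNIFORM_PRIOR = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclasses.dataclass(frozen=True)
class ErrorModel:
    """Per-read sequencing error rate ``e``, with ``0 < e < 0.5``."""

    e: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.e < 0.5:
            raise ValueError(f"error rate must lie in (0, 0.5), got {self.e}")

    @property
    def p_b(self) -> np.ndarray:
        """Probability that a read carries allele B, per genotype (AA, AB, BB)."""
        return np.array([self.e, 0.5, 1.0 - self.e])


@dataclasses.dataclass
class LikelihoodSet:
    """Per-(site, individual) genotype likelihoods, posteriors and PL values.

    Arrays have shape ``(n_sites, n_samples, 3)`` with the genotype axis
    ordered AA, AB, BB.  ``L`` holds raw likelihoods in [0, 1], ``P``
    uniform-prior posteriors summing to 1, and ``PL`` integer normalized
    Phred-scaled likelihoods with minimum entry 0.
    """

    L: np.ndarray
    P: np.ndarray
    PL: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.P.shape == self.PL.shape):
            raise ValueError("L, P and PL must share one shape")
        if self.L.shape[-1] != 3:
            raise ValueError("last axis must index the three genotypes")


@dataclasses.dataclass
class DosageMatrix:
    """Sites x individuals genotype dosages; ``NaN`` marks missing entries.

    Dosage counts copies of allele B (the VCF ALT allele), so values lie
    in ``[0, 2]``.  Before imputation an entry is missing iff the
    individual had zero reads at the site.
    """

    values: np.ndarray
    sites: Sequence["Site"] | None = None
    samples: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dosage values must be 2-D (sites x samples)")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "DosageMatrix":
        return DosageMatrix(self.values.copy(), self.sites, self.samples)


def _as_counts(n_a, n_b) -> tuple[np.ndarray, np.ndarray]:
    n_a = np.asarray(n_a)
    n_b = np.asarray(n_b)
    if np.any(n_a < 0) or np.any(n_b < 0):
        raise ValueError("read counts must be non-negative")
    return n_a.astype(float), n_b.astype(float)


def genotype_likelihoods(n_a, n_b, model: ErrorModel = ErrorModel()) -> np.ndarray:
    """Binomial genotype likelihoods for observed allele counts.

    Parameters
    ----------
    n_a, n_b
        Counts of allele A and allele B; scalars or broadcastable arrays.
    model
        Error model supplying the per-read error rate ``e``.

    Returns
    -------
    numpy.ndarray
        Likelihood triples ``(L_AA, L_AB, L_BB)`` stacked on a trailing
        axis of length 3.  Zero depth yields ``(1, 1, 1)``.
    """
    n_a, n_b = _as_counts(n_a, n_b)
    n = n_a + n_b
    log_comb = gammaln(n + 1.0) - gammaln(n_a + 1.0) - gammaln(n_b + 1.0)
    p_b = model.p_b  # (3,)
    # broadcast counts against the genotype axis
    n_a3 = n_a[..., None]
    n_b3 = n_b[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_l = log_comb[..., None] + n_a3 * np.log1p(-p_b) + n_b3 * np.log(p_b)
    return np.exp(log_l)


def posterior_triple(L, prior=UNIFORM_PRIOR) -> np.ndarray:
    """Posterior genotype probabilities ``P_g ∝ prior_g * L_g``.

    ``L`` may be one triple or an array with trailing genotype axis.
    Raises on all-zero likelihoods (no data support for any genotype).
    """
    L = np.asarray(L, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if L.shape[-1] != 3 or prior.shape != (3,):
        raise ValueError("likelihoods and prior must have a genotype axis of 3")
    w = L * prior
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total == 0.0):
        raise ValueError("all-zero likelihood triple: posterior undefined")
    return w / total


def dosage_from_posterior(P) -> np.ndarray:
    """Posterior-mean dosage ``0*P_AA + 1*P_AB + 2*P_BB``."""
    P = np.asarray(P, dtype=float)
    return P[..., 1] + 2.0 * P[..., 2]


def phred_normalize(L) -> np.ndarray:
    """Normalized, Phred-scaled likelihoods as integers.

    ``PL_g = round(-10 * log10(L_g / max(L)))`` with ties rounded up, so
    the most likely genotype gets 0.  Zero-likelihood entries are capped
    at 255 per VCF practice.
    """
    L = np.asarray(L, dtype=float)
    if L.shape[-1] != 3:
        raise ValueError("expected a trailing genotype axis of 3")
    lmax = L.max(axis=-1, keepdims=True)
    if np.any(lmax <= 0.0):
        raise ValueError("all-zero likelihood triple: PL undefined")
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(L / lmax)
    # nearest integer, ties up (VCF convention chosen here); cap at 255
    pl = np.floor(pl + 0.5)
    pl = np.where(np.isfinite(pl), pl, PL_CAP)
    return np.minimum(pl, PL_CAP).astype(int)


def likelihood_set(adm: "AlleleDepthMatrix", model: ErrorModel = ErrorModel()) -> LikelihoodSet:
    """Compute L, P and PL for every (site, individual) of a depth matrix."""
    n_a = adm.depths[..., 0]
    n_b = adm.depths[..., 1]
    L = genotype_likelihoods(n_a, n_b, model)
    P = posterior_triple(L)
    PL = phred_normalize(L)
    return LikelihoodSet(L=L, P=P, PL=PL)


def dosage_matrix(adm: "AlleleDepthMatrix", lik: LikelihoodSet | None = None,
                  model: ErrorModel = ErrorModel()) -> DosageMatrix:
    """Posterior-mean dosages with zero-depth entries set to NA."""
    if lik is None:
        lik = likelihood_set(adm, model)
    values = dosage_from_posterior(lik.P)
    depth = adm.depths.sum(axis=-1)
    values = np.where(depth > 0, values, np.nan)
    return DosageMatrix(values, sites=adm.sites, samples=adm.samples)
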