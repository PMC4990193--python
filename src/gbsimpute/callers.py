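"""Validation-genotype callers for masking cross-validation.

A *validation genotype* is an observed genotype confident enough to act
as truth when masked and re-imputed.  Two callers define such sets:

* **Caller A** keeps a genotype if the individual was surveyed at least
  ``min_depth`` times at the site (total reads, default 7).
* **Caller B** keeps a genotype if the most likely genotype is at least
  ``ratio`` times more likely than the second most likely (default 10).

Both attach the observed posterior-mean dosage as the validation value.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genolik import DosageMatrix, LikelihoodSet
from .io_vcf import AlleleDepthMatrix

__all__ = ["ValidationSet", "caller_A", "caller_B"]


@dataclasses.dataclass
class ValidationSet:
    """Coordinates of maskable genotypes and their validation dosages.

    Parallel arrays: ``site_idx`` and ``sample_idx`` are 0-based indices
    into the dosage matrix; ``dosage`` holds the observed (posterior
    mean) dosage at each coordinate.  Each coordinate appears at most
    once and every entry has nonzero observed depth.
    """

    site_idx: np.ndarray
    sample_idx: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.site_idx = np.asarray(self.site_idx, dtype=np.intp)
        self.sample_idx = np.asarray(self.sample_idx, dtype=np.intp)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if not (len(self.site_idx) == len(self.sample_idx) == len(self.dosage)):
            raise ValueError("coordinate arrays must have equal length")

    def __len__(self) -> int:
        return len(self.site_idx)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (site, sample) coordinates."""
        return np.column_stack([self.site_idx, self.sample_idx])


def _from_mask(mask: np.ndarray, dosages: DosageMatrix) -> ValidationSet:
    site_idx, sample_idx = np.nonzero(mask)
    return ValidationSet(site_idx, sample_idx,
                         dosages.values[site_idx, sample_idx])


def caller_A(adm: AlleleDepthMatrix, dosages: DosageMatrix,
             min_depth: int = 7) -> ValidationSet:
    """Depth-based caller: keep entries surveyed >= ``min_depth`` times."""
    if dosages.values.shape != (adm.n_sites, adm.n_samples):
        raise ValueError("dosage dimensions do not match the depth matrix")
    mask = adm.total_depth >= min_depth
    return _from_mask(mask, dosages)


def caller_B(lik: LikelihoodSet, dosages: DosageMatrix,
             ratio: float = 10.0) -> ValidationSet:
    """Likelihood-ratio caller: best genotype >= ``ratio`` x second best.

    The comparison uses raw likelihoods (a Phred gap of 10·log10(ratio)
    before rounding).  Zero-depth entries have flat likelihoods (ratio
    1) and can never qualify, so every entry has nonzero depth.
    """
    if lik.L.shape[:2] != dosages.values.shape:
        raise ValueError("likelihood dimensions do not match the dosages")
    top2 = np.sort(lik.L, axis=-1)[..., 1:]  # (second-max, max)
    mask = top2[..., 1] >= ratio * top2[..., 0]
    return _from_mask(mask, dosages)
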