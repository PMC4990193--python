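"""File-level interoperability with external Beagle v.4.

Beagle v.4 consumes genotype likelihoods (``gl=`` VCF with PL) and an
optional phased reference panel (``ref=``), and emits posterior mean
genotypes (DS) per individual and site.  This module prepares those
inputs, emits the command line, and parses Beagle output back into a
:class:`~gbsimpute.genolik.DosageMatrix` — it never reimplements the
model.  Documented external defaults (not implemented here): five
burn-in plus five sampling iterations, four sampled haplotype pairs per
individual.

The evaluation machinery is imputer-agnostic: a parsed dosage matrix
drops into :func:`gbsimpute.eval_cv.fold_accuracies` unchanged.
"""

from __future__ import annotations

import dataclasses
import subprocess
import warnings
from pathlib import Path
from typing import Literal

import numpy as np

from .genolik import DosageMatrix, ErrorModel, LikelihoodSet
from .io_vcf import AlleleDepthMatrix, Site, VcfFormatError, write_vcf

__all__ = ["ScenarioSpec", "BeagleInputs", "prepare_inputs", "parse_output"]


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One of the three imputation scenarios.

    ``no_reference`` imputes the study sample alone; ``cosmopolitan``
    uses a large diverse reference panel; ``best_match`` a panel matched
    to the study sample's ancestry.  A reference is present iff the
    scenario requires one.
    """

    scenario: Literal["no_reference", "cosmopolitan", "best_match"]
    study_vcf: str | Path
    reference_vcf: str | Path | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("no_reference", "cosmopolitan", "best_match"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        has_ref = self.reference_vcf is not None
        if has_ref != (self.scenario != "no_reference"):
            raise ValueError(
                "reference panel must be present iff the scenario uses one")


@dataclasses.dataclass
class BeagleInputs:
    """Prepared input files plus the (not yet executed) command line."""

    study_vcf: Path
    reference_vcf: Path | None
    command: list[str]


def prepare_inputs(spec: ScenarioSpec,
                   adm: AlleleDepthMatrix,
                   lik: LikelihoodSet,
                   ref_adm: AlleleDepthMatrix | None = None,
                   ref_haplotypes: np.ndarray | None = None,
                   out_prefix: str | Path = "beagle_out",
                   beagle_jar: str = "beagle.jar",
                   error_model: ErrorModel = ErrorModel()) -> BeagleInputs:
    """Write Beagle's input VCFs and emit its command line.

    The study VCF carries GT:AD:PL; the reference VCF (scenarios with a
    panel) is phased from ``ref_haplotypes`` (shape ``(n_sites, n_ref,
    2)``) and must be complete — a missing reference genotype refuses.
    The returned command uses ``gl=``/``ref=``/``out=`` and is not
    executed; run it yourself or via an explicit subprocess call.
    """
    study_path = write_vcf(adm, spec.study_vcf, likelihoods=lik,
                           error_model=error_model)
    ref_path: Path | None = None
    if spec.scenario != "no_reference":
        if ref_adm is None or ref_haplotypes is None:
            raise ValueError("reference scenarios require ref_adm and "
                             "ref_haplotypes")
        ref_haplotypes = np.asarray(ref_haplotypes, dtype=float)
        if np.any(np.isnan(ref_haplotypes)) or np.any(ref_haplotypes < 0):
            raise ValueError(
                "reference genotypes must be non-missing and phased")
        ref_path = write_vcf(ref_adm, spec.reference_vcf, phased=True,
                             haplotypes=ref_haplotypes.astype(int),
                             error_model=error_model)
    command = ["java", "-jar", beagle_jar, f"gl={study_path}"]
    if ref_path is not None:
        command.append(f"ref={ref_path}")
    command.append(f"out={out_prefix}")
    return BeagleInputs(study_vcf=study_path, reference_vcf=ref_path,
                        command=command)


def run_beagle(inputs: BeagleInputs, really_run: bool = False
               ) -> subprocess.CompletedProcess | None:
    """Optionally execute the emitted command (external binary required).

    Guarded by ``really_run`` so nothing in the package depends on a
    Beagle installation.
    """
    if not really_run:
        return None
    return subprocess.run(inputs.command, check=True, capture_output=True)


def parse_output(vcf_path) -> DosageMatrix:
    """Read imputed dosages from a Beagle output VCF.

    Uses DS when present; otherwise derives the posterior mean from GP
    (``P(AB) + 2 P(BB)``), renormalizing (with a warning) genotype
    probability triples whose sum strays from 1 by more than 0.05.
    Values are clipped to [0, 2].
    """
    from cyvcf2 import VCF

    sites: list[Site] = []
    rows: list[np.ndarray] = []
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    warned = False
    def fmt(variant, key):
        try:
            return variant.format(key)
        except KeyError:  # subfield absent from the header entirely
            return None

    for variant in vcf:
        sites.append(Site(variant.CHROM, variant.POS, variant.REF,
                          variant.ALT[0] if variant.ALT else "N"))
        ds = fmt(variant, "DS")
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).reshape(len(samples)))
            continue
        gp = fmt(variant, "GP")
        if gp is None:
            raise VcfFormatError(
                f"{vcf_path}: {variant.CHROM}:{variant.POS} has neither DS "
                "nor GP")
        gp = np.asarray(gp, dtype=float).reshape(len(samples), 3)
        sums = gp.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.05) and not warned:
            warnings.warn("GP triples do not sum to 1 within 0.05; "
                          "renormalizing", stacklevel=2)
            warned = True
        rows.append((gp[:, 1] + 2.0 * gp[:, 2]) / sums)
    values = np.clip(np.array(rows, dtype=float), 0.0, 2.0) if rows else \
        np.zeros((0, len(samples)))
    return DosageMatrix(values, sites=sites, samples=samples)
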