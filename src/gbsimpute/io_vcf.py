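"""VCF and table I/O for the GBS imputation pipeline.

Reads per-genotype allelic depths (the AD FORMAT subfield) into an
:class:`AlleleDepthMatrix`, merges technical/biological replicate
columns, applies the per-site missingness filter, and writes VCF v4.2
with GT:AD:PL (and optionally DS) for downstream tools.

Conventions: allele A is the VCF REF allele, allele B the ALT allele;
dosage counts copies of allele B.  A genotype is *missing* iff it has
zero reads (AD absent, "." or 0,0).  Coordinates are 1-based in files,
0-based in arrays.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from . import genolik
from .genolik import DosageMatrix, ErrorModel, LikelihoodSet

__all__ = [
    "Site",
    "SampleName",
    "AlleleDepthMatrix",
    "VcfParseError",
    "VcfFormatError",
    "read_allele_depths",
    "read_phred_likelihoods",
    "merge_replicates",
    "filter_sites",
    "write_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
]

_SNP_ALLELES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class VcfFormatError(ValueError):
    """Raised when VCF content violates the biallelic-SNP/AD contract."""


@dataclasses.dataclass(frozen=True, order=True)
class Site:
    """One biallelic SNP: chromosome, 1-based position, REF (A), ALT (B)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclasses.dataclass(frozen=True)
class SampleName:
    """VCF sample ID of the form ``ShortName:LibraryPrepID``.

    Samples sharing a ShortName are replicates of one individual.  A
    name without a colon is its own short name (no library ID).
    """

    short_name: str
    library_prep_id: str = ""

    @classmethod
    def parse(cls, raw: str) -> "SampleName":
        short, sep, lib = raw.partition(":")
        return cls(short_name=short, library_prep_id=lib)

    def __str__(self) -> str:
        if self.library_prep_id:
            return f"{self.short_name}:{self.library_prep_id}"
        return self.short_name


@dataclasses.dataclass
class AlleleDepthMatrix:
    """Sites x individuals grid of observed allele-count pairs.

    ``depths`` has shape ``(n_sites, n_samples, 2)``; the last axis holds
    ``(N_A, N_B)``, the read counts of the REF and ALT allele.  Sites are
    strictly increasing by position within each chromosome and all are
    biallelic SNPs.
    """

    sites: list[Site]
    samples: list[str]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.shape != (len(self.sites), len(self.samples), 2):
            raise ValueError(
                f"depths shape {self.depths.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples x 2"
            )
        if self.depths.size and self.depths.min() < 0:
            raise ValueError("allele depths must be non-negative")
        last: dict[str, int] = {}
        for s in self.sites:
            if len(s.ref) != 1 or len(s.alt) != 1 or s.ref == s.alt \
                    or s.ref not in _SNP_ALLELES or s.alt not in _SNP_ALLELES:
                raise ValueError(f"not a biallelic SNP: {s}")
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(f"sites not strictly increasing at {s}")
            last[s.chrom] = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total_depth(self) -> np.ndarray:
        """Per-(site, individual) read depth ``N_A + N_B``."""
        return self.depths.sum(axis=-1)

    @property
    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of individuals with zero reads."""
        return (self.total_depth == 0).mean(axis=1)


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in _SNP_ALLELES
        and alts[0] in _SNP_ALLELES
    )


def _read_vcf_rows(vcf_path):
    """Yield (site, format_dict, sample_fields) from a text VCF.

    A small line-oriented reader is used instead of htslib so parse
    errors can name the offending line; only the FORMAT subfields the
    pipeline touches (AD, PL) are extracted.
    """
    path = Path(vcf_path)
    samples: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfParseError(f"{path}:{lineno}: no sample columns")
                samples = cols[9:]
                continue
            if samples is None:
                raise VcfParseError(f"{path}:{lineno}: data before #CHROM header")
            cols = line.split("\t")
            if len(cols) != 9 + len(samples):
                raise VcfParseError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, got {len(cols)}"
                )
            chrom, pos, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise VcfParseError(f"{path}:{lineno}: bad POS {pos!r}") from exc
            fmt = cols[8].split(":")
            yield lineno, chrom, pos_i, ref, alt.split(","), fmt, cols[9:], samples


def read_allele_depths(vcf_path) -> AlleleDepthMatrix:
    """Read the AD subfield of a VCF into an :class:`AlleleDepthMatrix`.

    Non-biallelic or non-SNP records are dropped (ALT cardinality 1 and
    single-base A/C/G/T alleles are required), matching the upstream
    biallelic-site filter.  A genotype with AD absent or "." contributes
    ``(0, 0)``; GT/DP/GQ/PL subfields are ignored.

    Raises
    ------
    VcfParseError
        Malformed VCF, naming the offending line.
    VcfFormatError
        AD with a number of values other than 2 at a biallelic site.
    """
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    samples: list[str] | None = None
    for lineno, chrom, pos, ref, alts, fmt, fields, smp in _read_vcf_rows(vcf_path):
        samples = smp
        if not _is_biallelic_snp(ref, alts):
            continue
        try:
            ad_idx = fmt.index("AD")
        except ValueError:
            ad_idx = None
        pair = np.zeros((len(fields), 2), dtype=np.int32)
        for j, field in enumerate(fields):
            if ad_idx is None:
                continue
            parts = field.split(":")
            ad = parts[ad_idx] if ad_idx < len(parts) else "."
            if ad in (".", "", "./.", ".,."):
                continue
            vals = ad.split(",")
            if len(vals) != 2:
                raise VcfFormatError(
                    f"{vcf_path}:{lineno}: AD has {len(vals)} values at biallelic site "
                    f"{chrom}:{pos}"
                )
            try:
                pair[j] = [int(v) if v != "." else 0 for v in vals]
            except ValueError as exc:
                raise VcfParseError(f"{vcf_path}:{lineno}: bad AD {ad!r}") from exc
        sites.append(Site(chrom, pos, ref, alts[0]))
        rows.append(pair)
    if samples is None:
        raise VcfParseError(f"{vcf_path}: no #CHROM header found")
    depths = (
        np.stack(rows) if rows else np.zeros((0, len(samples), 2), dtype=np.int32)
    )
    return AlleleDepthMatrix(sites=sites, samples=list(samples), depths=depths)


def read_phred_likelihoods(vcf_path) -> np.ndarray:
    """Read integer PL triples; shape (n_sites, n_samples, 3), -1 = absent."""
    rows = []
    for lineno, chrom, pos, ref, alts, fmt, fields, _smp in _read_vcf_rows(vcf_path):
        if not _is_biallelic_snp(ref, alts):
            continue
        try:
            pl_idx = fmt.index("PL")
        except ValueError:
            pl_idx = None
        tri = np.full((len(fields), 3), -1, dtype=np.int32)
        for j, field in enumerate(fields):
            if pl_idx is None:
                continue
            parts = field.split(":")
            pl = parts[pl_idx] if pl_idx < len(parts) else "."
            if pl in (".", ""):
                continue
            vals = pl.split(",")
            if len(vals) != 3:
                raise VcfFormatError(
                    f"{vcf_path}:{lineno}: PL has {len(vals)} values at {chrom}:{pos}"
                )
            tri[j] = [int(v) for v in vals]
        rows.append(tri)
    return np.stack(rows) if rows else np.zeros((0, 0, 3), dtype=np.int32)


def merge_replicates(adm: AlleleDepthMatrix) -> AlleleDepthMatrix:
    """Sum replicate columns sharing a ShortName into one column.

    Column order follows the first occurrence of each short name; read
    counts are summed element-wise, so total depth per site is preserved.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, raw in enumerate(adm.samples):
        short = SampleName.parse(raw).short_name
        if short not in groups:
            groups[short] = []
            order.append(short)
        groups[short].append(j)
    merged = np.empty((adm.n_sites, len(order), 2), dtype=adm.depths.dtype)
    for k, short in enumerate(order):
        merged[:, k, :] = adm.depths[:, groups[short], :].sum(axis=1)
    return AlleleDepthMatrix(sites=list(adm.sites), samples=order, depths=merged)


def filter_sites(adm: AlleleDepthMatrix, max_missing: float) -> AlleleDepthMatrix:
    """Drop sites whose zero-read fraction exceeds ``max_missing``.

    Retention is ``missing_fraction <= max_missing`` (strict ">" removal),
    preserving site order.  An empty result is allowed.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    keep = adm.missing_fraction <= max_missing
    sites = [s for s, k in zip(adm.sites, keep) if k]
    return AlleleDepthMatrix(sites=sites, samples=list(adm.samples),
                             depths=adm.depths[keep])


def _gt_string(dosage: float, phased: bool, hap: tuple[int, int] | None) -> str:
    if hap is not None:
        sep = "|" if phased else "/"
        return f"{hap[0]}{sep}{hap[1]}"
    if np.isnan(dosage):
        return "./."
    g = int(min(2, max(0, np.floor(dosage + 0.5))))
    if phased:
        return ("0|0", "0|1", "1|1")[g]
    return ("0/0", "0/1", "1/1")[g]


def write_vcf(
    adm: AlleleDepthMatrix,
    path,
    likelihoods: LikelihoodSet | None = None,
    dosages: DosageMatrix | None = None,
    phased: bool = False,
    haplotypes: np.ndarray | None = None,
    error_model: ErrorModel = ErrorModel(),
) -> Path:
    """Write a VCF v4.2 with FORMAT ``GT:AD:PL`` and optionally ``DS``.

    PL values are integers normalized so the minimum is 0; likelihoods
    are computed from AD with ``error_model`` when not supplied.  GT is
    the rounded dosage (posterior-mean dosage when ``dosages`` is
    absent), "./." where missing.  ``phased=True`` writes "|"-separated
    genotypes — the reference-panel dialect, which must be non-missing —
    using ``haplotypes`` (shape ``(n_sites, n_samples, 2)``) when given,
    else 0|1 for rounded heterozygotes.
    """
    if likelihoods is None:
        likelihoods = genolik.likelihood_set(adm, error_model)
    if dosages is None:
        dosages = genolik.dosage_matrix(adm, likelihoods)
    if dosages.values.shape != (adm.n_sites, adm.n_samples):
        raise ValueError("dosage dimensions do not match the depth matrix")
    if phased and haplotypes is None and np.isnan(dosages.values).any():
        raise ValueError("phased output requires non-missing genotypes")
    if haplotypes is not None:
        haplotypes = np.asarray(haplotypes)
        if haplotypes.shape != (adm.n_sites, adm.n_samples, 2):
            raise ValueError("haplotypes must have shape (n_sites, n_samples, 2)")
        if phased and (np.any(haplotypes < 0) or np.any(np.isnan(haplotypes.astype(float)))):
            raise ValueError("phased output requires non-missing genotypes")

    path = Path(path)
    fmt = "GT:AD:PL" + (":DS" if dosages is not None else "")
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in adm.sites):
            out.write(f"##contig=<ID={chrom}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        out.write('##FORMAT=<ID=PL,Number=G,Type=Integer,'
                  'Description="Normalized Phred-scaled genotype likelihoods">\n')
        out.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(adm.samples) + "\n")
        for i, site in enumerate(adm.sites):
            cells = []
            for j in range(adm.n_samples):
                hap = None
                if haplotypes is not None:
                    hap = (int(haplotypes[i, j, 0]), int(haplotypes[i, j, 1]))
                gt = _gt_string(dosages.values[i, j], phased, hap)
                ad = f"{adm.depths[i, j, 0]},{adm.depths[i, j, 1]}"
                pl = ",".join(str(v) for v in likelihoods.PL[i, j])
                cell = f"{gt}:{ad}:{pl}"
                ds = dosages.values[i, j]
                cell += ":." if np.isnan(ds) else f":{ds:.6g}"
                cells.append(cell)
            out.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )
    return path


def write_dosage_tsv(d: DosageMatrix, path) -> Path:
    """Tab-separated dosage table: sites as rows, samples as columns, NA missing."""
    path = Path(path)
    samples = list(d.samples) if d.samples is not None else [
        f"S{j + 1}" for j in range(d.n_samples)
    ]
    with open(path, "w") as out:
        out.write("chrom\tpos\tref\talt\t" + "\t".join(samples) + "\n")
        for i in range(d.n_sites):
            if d.sites is not None:
                s = d.sites[i]
                head = f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}"
            else:
                head = f".\t{i + 1}\t.\t."
            vals = "\t".join(
                "NA" if np.isnan(v) else f"{v:.6g}" for v in d.values[i]
            )
            out.write(head + "\t" + vals + "\n")
    return path


def read_dosage_tsv(path) -> DosageMatrix:
    """Read a dosage table written by :func:`write_dosage_tsv`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        sites: list[Site] = []
        rows = []
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            sites.append(Site(cols[0], int(cols[1]), cols[2], cols[3]))
            rows.append([np.nan if v == "NA" else float(v) for v in cols[4:]])
    values = np.array(rows, dtype=float) if rows else np.zeros((0, len(samples)))
    return DosageMatrix(values, sites=sites, samples=samples)
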