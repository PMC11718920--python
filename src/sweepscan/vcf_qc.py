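"""Site-level quality control for phased variant data.

Reads a phased diploid VCF into a per-chromosome haplotype matrix with
alleles polarized as 0 = ancestral / 1 = derived, and applies the standard
site filters used ahead of a haplotype-based selection scan:

* GATK-style INFO thresholds (QD, FS, MQ, MQRankSum, ReadPosRankSum),
* per-site missing-call rate,
* minor allele frequency,
* an exact Hardy-Weinberg equilibrium test.

Bi-allelic enforcement and sex-chromosome exclusion happen at read time;
the remaining filters are per-site predicates applied by :func:`apply_qc`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

#: Chromosome names excluded from an autosomal scan by default.
DEFAULT_SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

#: GATK VariantFiltration hard thresholds: field -> (comparison, limit).
#: A site fails when the INFO value is present and strictly beyond the limit.
INFO_THRESHOLDS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}


class UnphasedGenotypeError(ValueError):
    """A genotype in the input VCF is not phased."""


@dataclass
class HaplotypeMatrix:
    """Phased alleles for one chromosome.

    ``alleles`` is an ``n_haplotypes x n_sites`` int8 matrix with values
    0 (ancestral), 1 (derived) or -1 (missing).  Rows ``2i`` and ``2i+1``
    are the two haplotypes of diploid individual ``i``.
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    alleles: np.ndarray
    sample_ids: list[str]
    site_info: list[dict] | None = None  # optional per-site INFO values

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions / alleles shape mismatch")
        if self.alleles.shape[0] % 2:
            raise ValueError("haplotype count must be even (phased diploids)")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.chrom}: positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Per-site derived allele frequency among non-missing calls."""
        called = self.alleles != MISSING
        n_called = called.sum(axis=0)
        n_derived = (self.alleles == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, n_derived / np.maximum(n_called, 1), np.nan)

    def missing_rate(self) -> np.ndarray:
        return (self.alleles == MISSING).mean(axis=0)

    def genotype_counts(self) -> np.ndarray:
        """``n_sites x 3`` counts of (anc/anc, het, der/der) diploid genotypes.

        A genotype is counted only when both of the individual's alleles
        are called at the site.
        """
        a = self.alleles[0::2, :]
        b = self.alleles[1::2, :]
        ok = (a != MISSING) & (b != MISSING)
        g = np.where(ok, a + b, MISSING)
        out = np.empty((self.n_sites, 3), dtype=np.int64)
        for k in range(3):
            out[:, k] = (g == k).sum(axis=0)
        return out

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        info = None
        if self.site_info is not None:
            info = [self.site_info[i] for i in np.atleast_1d(index)]
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[index],
            alleles=self.alleles[:, index],
            sample_ids=list(self.sample_ids),
            site_info=info,
        )


@dataclass
class ReadReport:
    """Counts of sites set aside while reading a VCF."""

    n_records: int = 0
    n_kept: int = 0
    n_sex_chrom: int = 0
    n_not_biallelic: int = 0
    n_unknown_ancestral: int = 0


def read_phased_vcf(
    path,
    ancestral_source: str = "REF",
    sex_chroms: Iterable[str] = DEFAULT_SEX_CHROMS,
    collect_info: bool = True,
) -> tuple[list[HaplotypeMatrix], ReadReport]:
    """Read a phased VCF into per-chromosome haplotype matrices.

    Parameters
    ----------
    ancestral_source : {"REF", "AA"}
        How to polarize alleles.  ``"REF"`` treats the reference base as
        ancestral; ``"AA"`` reads the ancestral base from the AA INFO tag
        and drops (and counts) sites where the tag is absent or matches
        neither allele.
    sex_chroms
        Chromosome names to exclude.

    Any non-missing unphased genotype raises :class:`UnphasedGenotypeError`
    naming the offending record.  Non-bi-allelic SNP records are dropped
    and counted.
    """
    from cyvcf2 import VCF

    if ancestral_source not in ("REF", "AA"):
        raise ValueError("ancestral_source must be 'REF' or 'AA'")
    sex_chroms = set(sex_chroms)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    report = ReadReport()

    by_chrom: dict[str, dict] = {}
    for v in vcf:
        report.n_records += 1
        if v.CHROM in sex_chroms:
            report.n_sex_chrom += 1
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            report.n_not_biallelic += 1
            continue
        flip = False
        if ancestral_source == "AA":
            aa = v.INFO.get("AA")
            if aa == v.REF:
                flip = False
            elif aa == v.ALT[0]:
                flip = True
            else:
                report.n_unknown_ancestral += 1
                continue
        row = np.empty(2 * len(samples), dtype=np.int8)
        for j, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased and (a >= 0 or b >= 0):
                raise UnphasedGenotypeError(
                    f"unphased genotype for sample {samples[j]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            row[2 * j] = a if a >= 0 else MISSING
            row[2 * j + 1] = b if b >= 0 else MISSING
        if flip:
            seen = row != MISSING
            row[seen] = 1 - row[seen]
        acc = by_chrom.setdefault(
            v.CHROM, {"pos": [], "rows": [], "info": []}
        )
        acc["pos"].append(v.POS)
        acc["rows"].append(row)
        if collect_info:
            acc["info"].append(
                {k: v.INFO.get(k) for k in INFO_THRESHOLDS if v.INFO.get(k) is not None}
            )
        report.n_kept += 1

    matrices = []
    for chrom, acc in by_chrom.items():
        matrices.append(
            HaplotypeMatrix(
                chrom=chrom,
                positions=np.array(acc["pos"], dtype=np.int64),
                alleles=np.column_stack(acc["rows"]) if acc["rows"] else np.empty((2 * len(samples), 0), np.int8),
                sample_ids=samples,
                site_info=acc["info"] if collect_info else None,
            )
        )
    return matrices, report


def filter_info_thresholds(
    record_info: Mapping[str, object], strict: bool = False
) -> dict[str, bool]:
    """Evaluate GATK hard thresholds on one record's INFO fields.

    Returns a field -> pass/fail map.  Absent fields pass by default
    (``strict=True`` fails them); comparisons are strict inequalities, so
    boundary values (QD exactly 2.0 etc.) pass.
    """
    flags: dict[str, bool] = {}
    for name, (op, limit) in INFO_THRESHOLDS.items():
        value = record_info.get(name)
        if value is None:
            flags[name] = not strict
            continue
        try:
            x = float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric INFO value {name}={value!r}") from exc
        flags[name] = not (x < limit if op == "<" else x > limit)
    return flags


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Computes the probability, conditional on the observed allele counts, of
    every heterozygote count no more probable than the observed one, using
    the exact genotype-count distribution (Levene/Haldane; the procedure
    popularized by Wigginton et al. for SNP QC).  Exact rational arithmetic
    is used throughout, so ties between equally probable configurations are
    resolved exactly and the result is symmetric in ``n_AA <-> n_aa``.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa  # minor-or-not does not matter; symmetric
    rare = min(n_a, 2 * n - n_a)
    # heterozygote counts share the parity of the rare allele count
    h_min = rare % 2
    # unnormalized probabilities via the recurrence
    #   P(h+2)/P(h) = (r - h)(c - h) / ((h+2)(h+1))
    # with homozygote counts implied by h; start from h_min with weight 1.
    common = 2 * n - rare
    probs: dict[int, Fraction] = {}
    p = Fraction(1)
    h = h_min
    while True:
        probs[h] = p
        if h + 2 > rare:
            break
        p = p * Fraction((rare - h) * (common - h), (h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    obs = probs.get(n_Aa)
    if obs is None:  # inconsistent observed het parity cannot happen
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    tail = sum(q for q in probs.values() if q <= obs)
    return float(Fraction(tail, total))


@dataclass
class QCThresholds:
    """Site-filter thresholds for :func:`apply_qc`."""

    max_missing: float = 0.10   # exclude missing rate strictly greater
    min_maf: float = 0.05       # exclude MAF strictly below
    min_hwe_p: float = 1e-6     # exclude HWE p strictly below
    strict_info: bool = False


@dataclass
class SiteQCRecord:
    chrom: str
    position: int
    maf: float
    missing_rate: float
    hwe_p: float
    info_flags: dict[str, bool] = field(default_factory=dict)
    kept: bool = True
    fail_reason: str | None = None  # first failed filter in order


#: Filter application order used for attribution in the QC report.
QC_FILTER_ORDER = ("info", "missing", "maf", "hwe")


def apply_qc(
    hm: HaplotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[HaplotypeMatrix, list[SiteQCRecord]]:
    """Apply per-site filters and return the clean matrix plus a QC report.

    Each filter is a per-site predicate, so the retained set is independent
    of application order; a failing site is attributed to the first failed
    filter in the order info -> missing -> maf -> hwe.
    """
    th = thresholds or QCThresholds()
    freq = hm.derived_freq()
    miss = hm.missing_rate()
    gcounts = hm.genotype_counts()
    records: list[SiteQCRecord] = []
    keep = np.ones(hm.n_sites, dtype=bool)
    for i in range(hm.n_sites):
        f = freq[i]
        maf = min(f, 1.0 - f) if np.isfinite(f) else 0.0
        info = hm.site_info[i] if hm.site_info is not None else {}
        flags = filter_info_thresholds(info, strict=th.strict_info)
        hwe_p = hwe_exact_test(*(int(c) for c in gcounts[i]))
        reason = None
        if not all(flags.values()):
            reason = "info"
        elif miss[i] > th.max_missing:
            reason = "missing"
        elif maf < th.min_maf:
            reason = "maf"
        elif hwe_p < th.min_hwe_p:
            reason = "hwe"
        records.append(
            SiteQCRecord(
                chrom=hm.chrom,
                position=int(hm.positions[i]),
                maf=float(maf),
                missing_rate=float(miss[i]),
                hwe_p=hwe_p,
                info_flags=flags,
                kept=reason is None,
                fail_reason=reason,
            )
        )
        keep[i] = reason is None
    out = hm.take_sites(np.nonzero(keep)[0])
    if out.n_sites == 0:
        warnings.warn(f"{hm.chrom}: no sites survive QC", stacklevel=2)
    return out, records


def qc_report_frame(records: Sequence[SiteQCRecord]):
    """QC records as a pandas DataFrame (one row per site)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.position for r in records],
            "maf": [r.maf for r in records],
            "missing_rate": [r.missing_rate for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "kept": [r.kept for r in records],
            "fail_reason": [r.fail_reason or "" for r in records],
        }
    )
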