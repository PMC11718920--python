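"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan.vcf_qc import MISSING, HaplotypeMatrix


def make_matrix(
    alleles, positions=None, chrom: str = "chr1", start: int = 1_000, spacing: int = 1_000
) -> HaplotypeMatrix:
    """HaplotypeMatrix from a (n_hap, n_sites) array, evenly spaced sites."""
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = start + spacing * np.arange(alleles.shape[1])
    n_dip = alleles.shape[0] // 2
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        sample_ids=[f"S{i}" for i in range(n_dip)],
    )


def random_matrix(
    rng: np.random.Generator,
    n_hap: int,
    n_sites: int,
    missing_rate: float = 0.0,
    max_spacing: int = 5_000,
) -> HaplotypeMatrix:
    """Random polymorphic-ish matrix with irregular site spacing."""
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    if missing_rate > 0:
        alleles[rng.random(alleles.shape) < missing_rate] = MISSING
    gaps = rng.integers(1, max_spacing, size=n_sites)
    positions = np.cumsum(gaps) + 100
    return make_matrix(alleles, positions=positions)


def ehh_oracle(
    hm: HaplotypeMatrix, core_index: int, core_allele: int, site_index: int
) -> float:
    """Brute-force EHH: fraction of carrier pairs identical from the core
    through ``site_index``, counting a pair as broken if either haplotype
    has a missing call anywhere on the stretch."""
    core = hm.alleles[:, core_index]
    carriers = np.nonzero(core == core_allele)[0]
    lo, hi = sorted((core_index, site_index))
    span = hm.alleles[carriers, lo : hi + 1]
    n_c = carriers.size
    matches = 0
    for i in range(n_c):
        for j in range(i + 1, n_c):
            a, b = span[i], span[j]
            if np.all((a != MISSING) & (b != MISSING) & (a == b)):
                matches += 1
    return matches / (n_c * (n_c - 1) / 2)


def ehh_oracle_curve(
    hm: HaplotypeMatrix, core_index: int, core_allele: int, direction: str
) -> list[float]:
    """Brute-force EHH at every extension site out to the chromosome end.

    For each pair of core-allele carriers, tracks whether the pair is still
    identical (both called, equal) at every site walked from the core; the
    EHH value at step k is the fraction of pairs identical through site k.
    """
    core = hm.alleles[:, core_index]
    carriers = np.nonzero(core == core_allele)[0]
    step = 1 if direction == "downstream" else -1
    if step > 0:
        cols = range(core_index + 1, hm.n_sites)
    else:
        cols = range(core_index - 1, -1, -1)
    span = hm.alleles[np.ix_(carriers, list(cols))]
    ok = (
        (span[:, None, :] == span[None, :, :])
        & (span[:, None, :] != MISSING)
        & (span[None, :, :] != MISSING)
    )
    iu = np.triu_indices(carriers.size, k=1)
    pair_ok = ok[iu]  # (n_pairs, n_steps)
    still = np.logical_and.accumulate(pair_ok, axis=1)
    return still.mean(axis=0).tolist()


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by direct enumeration with rational arithmetic.

    Enumerates every heterozygote count compatible with the allele counts
    and computes each configuration's conditional probability from
    multinomial coefficients (independent of the recurrence used by the
    implementation)."""
    from fractions import Fraction
    from math import comb

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa

    def weight(het: int) -> int:
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        # orderings of genotype assignments x allele arrangements (2^het)
        return comb(n, het) * comb(n - het, hom_a) * 2**het

    hets = [h for h in range(min(n_a, 2 * n - n_a) + 1) if (n_a - h) % 2 == 0]
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_Aa]
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
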