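"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

For a core SNP, EHH at distance x is the probability that two randomly
chosen carriers of a core allele are identical over every site from the
core out to x:

    EHH(x) = sum_h C(n_h, 2) / C(n_c, 2)

where the n_c carriers are partitioned into extended-haplotype groups h of
size n_h at distance x.  Integrating EHH against physical distance in both
directions (trapezoid rule, truncated where EHH first drops below a cutoff)
gives iHH, and the unstandardized score at a site is

    uiHS = ln(iHH_A / iHH_D)

for ancestral (A) and derived (D) carriers.  Scores are standardized within
derived-allele-frequency bins to mean 0 and unit standard deviation, which
makes |iHS| comparable across frequencies; large |iHS| flags sites on
unusually long homozygous haplotypes, the footprint of a recent sweep.

All integration is over physical bp (no genetic map).  A gap larger than
``max_gap_bp`` between consecutive sites during extension invalidates the
core site (conservative treatment of assembly gaps / sparse regions), as
does running off the end of the chromosome before reaching the EHH cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from numba import njit

from .vcf_qc import HaplotypeMatrix

ANCESTRAL, DERIVED = 0, 1

Direction = Literal["upstream", "downstream"]


@dataclass(frozen=True)
class ScanOptions:
    """Tunable parameters of the EHH/iHS scan.

    ``min_carriers`` is the minimum copy number of *each* allele for a
    site to be scored.  Two carriers is the mathematical minimum for EHH;
    the default of 5 avoids iHH ratios dominated by sampling noise when an
    allele is carried by only a handful of haplotypes, which matters at
    the small sample sizes this package targets.
    """

    ehh_cutoff: float = 0.05
    max_gap_bp: int = 800_000
    min_carriers: int = 5
    #: "truncate": a long gap invalidates the score (default).
    #: "cap": the gap's distance contribution is capped at max_gap_bp.
    gap_rule: Literal["truncate", "cap"] = "truncate"


@dataclass
class EHHCurve:
    """EHH decay for one core site / allele / direction.

    ``points`` are (distance_bp, ehh) pairs starting at (0, 1.0); the last
    point is the first one below the cutoff unless the curve was truncated
    by a gap ("gap") or by the chromosome end ("edge").
    """

    core_position: int
    core_allele: int
    direction: Direction
    points: list[tuple[int, float]]
    truncated: str | None = None  # None | "gap" | "edge"

    @property
    def complete(self) -> bool:
        return self.truncated is None


def ehh(
    hm: HaplotypeMatrix,
    core_index: int,
    core_allele: int,
    direction: Direction,
    ehh_cutoff: float = 0.05,
    max_gap_bp: int = 800_000,
    gap_rule: str = "truncate",
) -> EHHCurve:
    """Extend haplotype homozygosity from a core site in one direction.

    Carriers missing at the core are excluded; a carrier with a missing
    allele at an extension site becomes a permanent singleton group (it can
    never be shown identical to another haplotype, biasing EHH downward).
    Raises ``ValueError`` with fewer than two carriers.
    """
    core = hm.alleles[:, core_index]
    n_c = int((core == core_allele).sum())
    if n_c < 2:
        raise ValueError(
            f"need >=2 carriers of allele {core_allele} at site {core_index}"
        )
    step = 1 if direction == "downstream" else -1
    dist, val, n_points, trunc = _ehh_walk(
        hm.alleles,
        hm.positions,
        core_index,
        core_allele,
        step,
        ehh_cutoff,
        max_gap_bp,
        gap_rule == "cap",
    )
    points = [(int(dist[k]), float(val[k])) for k in range(n_points)]
    return EHHCurve(
        core_position=int(hm.positions[core_index]),
        core_allele=core_allele,
        direction=direction,
        points=points,
        truncated={0: None, 1: "gap", 2: "edge"}[int(trunc)],
    )


@njit(cache=True)
def _ehh_walk(alleles, positions, core_index, core_allele, step, cutoff, max_gap, cap_gaps):  # pragma: no cover - exercised via ehh()
    """Extension walk shared by every EHH curve.

    Only groups of >=2 still-identical carriers can contribute pairs; a
    carrier that becomes a singleton (or hits a missing call) can never
    rejoin a group, so it is deactivated permanently.  Group labels are
    compacted every step, keeping ids < 2 * n_carriers + 2.
    """
    n_sites = alleles.shape[1]
    n_hap = alleles.shape[0]
    carriers = np.empty(n_hap, dtype=np.int32)
    n_c = 0
    for i in range(n_hap):
        if alleles[i, core_index] == core_allele:
            carriers[n_c] = i
            n_c += 1
    pair_total = n_c * (n_c - 1) // 2
    core_pos = positions[core_index]

    dist = np.zeros(n_sites + 1, dtype=np.int64)
    val = np.zeros(n_sites + 1, dtype=np.float64)
    val[0] = 1.0
    n_points = 1

    group = np.zeros(n_c, dtype=np.int32)
    active = np.ones(n_c, dtype=np.bool_)
    counts = np.zeros(n_c + 1, dtype=np.int32)
    remap = np.empty(2 * n_c + 2, dtype=np.int32)
    trunc = 0
    j = core_index
    while True:
        nj = j + step
        if nj < 0 or nj >= n_sites:
            trunc = 2
            break
        gap = positions[nj] - positions[j] if step > 0 else positions[j] - positions[nj]
        if gap > max_gap:
            if not cap_gaps:
                trunc = 1
                break
            gap = max_gap
        j = nj
        # split each group by the allele at site j; drop missing carriers
        for i in range(n_c):
            if active[i]:
                a = alleles[carriers[i], j]
                if a < 0:
                    active[i] = False
                else:
                    group[i] = 2 * group[i] + a
        # compact relabel, count group sizes
        remap[:] = -1
        next_id = 0
        counts[:] = 0
        for i in range(n_c):
            if active[i]:
                k = group[i]
                if remap[k] < 0:
                    remap[k] = next_id
                    next_id += 1
                group[i] = remap[k]
                counts[group[i]] += 1
        for i in range(n_c):
            if active[i] and counts[group[i]] < 2:
                active[i] = False
        pairs = 0
        for g in range(next_id):
            c = counts[g]
            pairs += c * (c - 1) // 2
        value = pairs / pair_total
        if cap_gaps:
            dist[n_points] = dist[n_points - 1] + gap
        else:
            d = positions[j] - core_pos
            dist[n_points] = d if d >= 0 else -d
        val[n_points] = value
        n_points += 1
        if value < cutoff:
            break
    return dist, val, n_points, trunc


def ihh(curve_up: EHHCurve, curve_down: EHHCurve) -> float:
    """Integrated haplotype homozygosity: trapezoid area of both curves.

    Each curve contributes the trapezoid integral of EHH against distance
    up to and including its first sub-cutoff point.  Truncated curves are
    rejected — callers flag the score invalid instead.
    """
    total = 0.0
    for curve in (curve_up, curve_down):
        if not curve.complete:
            raise ValueError(f"curve truncated ({curve.truncated}); score is invalid")
        d = np.array([p[0] for p in curve.points], dtype=float)
        v = np.array([p[1] for p in curve.points], dtype=float)
        total += float(np.trapezoid(v, d))
    return total


@dataclass
class IHSScore:
    """Per-site integrated haplotype score and its provenance."""

    chrom: str
    position: int
    derived_freq: float
    ihh_a: float = math.nan
    ihh_d: float = math.nan
    uihs: float = math.nan
    bin_index: int = -1
    ihs_std: float = math.nan
    valid: bool = False
    reason: str | None = None


def unstandardized_ihs(
    hm: HaplotypeMatrix, core_index: int, opts: ScanOptions | None = None
) -> IHSScore:
    """Compute iHH for both alleles at a site and the log-ratio uiHS.

    uiHS is computed as ``log(iHH_A) - log(iHH_D)`` so that swapping the
    ancestral/derived labels negates the score exactly.  The score is
    flagged invalid (with a reason) when either allele has fewer than two
    called carriers, any of the four EHH curves is gap- or edge-truncated,
    or an integral is zero.
    """
    opts = opts or ScanOptions()
    core = hm.alleles[:, core_index]
    n_anc = int((core == ANCESTRAL).sum())
    n_der = int((core == DERIVED).sum())
    n_called = n_anc + n_der
    freq = n_der / n_called if n_called else math.nan
    score = IHSScore(
        chrom=hm.chrom, position=int(hm.positions[core_index]), derived_freq=freq
    )
    if min(n_anc, n_der) < opts.min_carriers:
        score.reason = "too_few_carriers"
        return score
    curves = {}
    for allele in (ANCESTRAL, DERIVED):
        for direction in ("upstream", "downstream"):
            c = ehh(
                hm,
                core_index,
                allele,
                direction,
                ehh_cutoff=opts.ehh_cutoff,
                max_gap_bp=opts.max_gap_bp,
                gap_rule=opts.gap_rule,
            )
            if not c.complete:
                score.reason = f"{c.truncated}_truncated"
                return score
            curves[allele, direction] = c
    score.ihh_a = ihh(curves[ANCESTRAL, "upstream"], curves[ANCESTRAL, "downstream"])
    score.ihh_d = ihh(curves[DERIVED, "upstream"], curves[DERIVED, "downstream"])
    if score.ihh_a <= 0 or score.ihh_d <= 0:
        score.reason = "zero_ihh"
        return score
    score.uihs = math.log(score.ihh_a) - math.log(score.ihh_d)
    score.valid = True
    return score


def scan_chromosome(
    hm: HaplotypeMatrix, opts: ScanOptions | None = None
) -> list[IHSScore]:
    """Unstandardized iHS at every site of one chromosome.

    Sites that cannot be scored (too few carriers, truncation, zero iHH)
    are returned with ``valid=False`` and a reason, so downstream reporting
    can account for every input site.
    """
    opts = opts or ScanOptions()
    return [unstandardized_ihs(hm, i, opts) for i in range(hm.n_sites)]


@dataclass
class StandardizationBins:
    """Frequency-bin moments used to standardize uiHS."""

    n_bins: int
    edges: np.ndarray              # len n_bins + 1, spanning (0, 1)
    merged_group: np.ndarray       # per original bin -> merged group id
    mean: np.ndarray               # per merged group E_p
    sd: np.ndarray                 # per merged group SD_p (ddof=1)
    count: np.ndarray              # per merged group


def standardize(
    scores: Iterable[IHSScore], n_bins: int = 100, min_per_bin: int = 2
) -> tuple[list[IHSScore], StandardizationBins]:
    """Standardize uiHS within derived-allele-frequency bins.

    Scores are binned by derived frequency into ``n_bins`` equal-width bins
    on (0, 1); adjacent bins are merged until every occupied group holds at
    least ``min_per_bin`` valid scores.  Within each group,
    ``ihs_std = (uihs - E_p) / SD_p`` with the sample standard deviation
    (n-1 denominator).  Scores in a group with zero spread are flagged
    invalid ("degenerate_bin").  Raises if no valid scores exist.
    """
    scores = list(scores)
    valid = [s for s in scores if s.valid]
    if not valid:
        raise ValueError("no valid scores to standardize")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    freqs = np.array([s.derived_freq for s in valid])
    bin_of = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)

    counts = np.bincount(bin_of, minlength=n_bins)
    merged_group = _merge_bins(counts, min_per_bin)
    n_groups = int(merged_group.max()) + 1
    group_of = merged_group[bin_of]

    mean = np.zeros(n_groups)
    sd = np.zeros(n_groups)
    gcount = np.zeros(n_groups, dtype=np.int64)
    u = np.array([s.uihs for s in valid])
    for g in range(n_groups):
        sel = group_of == g
        gcount[g] = int(sel.sum())
        if gcount[g] >= 2:
            mean[g] = float(u[sel].mean())
            sd[g] = float(u[sel].std(ddof=1))
        elif gcount[g] == 1:
            mean[g] = float(u[sel][0])
            sd[g] = 0.0

    for s, b, g in zip(valid, bin_of, group_of):
        s.bin_index = int(b)
        if gcount[g] < 2 or sd[g] == 0.0:
            s.valid = False
            s.reason = "degenerate_bin"
            s.ihs_std = math.nan
        else:
            s.ihs_std = (s.uihs - mean[g]) / sd[g]
    bins = StandardizationBins(
        n_bins=n_bins,
        edges=edges,
        merged_group=merged_group,
        mean=mean,
        sd=sd,
        count=gcount,
    )
    return scores, bins


def _merge_bins(counts: np.ndarray, min_per_bin: int) -> np.ndarray:
    """Assign each original bin to a merged group with >= min_per_bin scores.

    Walk left to right accumulating bins into the current group and close
    the group once it reaches the minimum; an undersized trailing group is
    folded into its predecessor.
    """
    n = counts.size
    group = np.zeros(n, dtype=np.int64)
    gid = 0
    acc = 0
    for i in range(n):
        group[i] = gid
        acc += int(counts[i])
        if acc >= min_per_bin and i < n - 1:
            gid += 1
            acc = 0
    if acc and acc < min_per_bin and gid > 0:
        group[group == gid] = gid - 1
    return group


def scores_frame(scores: Sequence[IHSScore]):
    """Scores as a pandas DataFrame (one row per site)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in scores],
            "pos": [s.position for s in scores],
            "derived_freq": [s.derived_freq for s in scores],
            "ihh_a": [s.ihh_a for s in scores],
            "ihh_d": [s.ihh_d for s in scores],
            "uihs": [s.uihs for s in scores],
            "ihs_std": [s.ihs_std for s in scores],
            "valid": [s.valid for s in scores],
            "reason": [s.reason or "" for s in scores],
        }
    )
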