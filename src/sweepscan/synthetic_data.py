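"""Forward Wright-Fisher simulation of phased haplotype samples.

Generates neutral background variation on a single chromosome, optionally
with a hard selective sweep at a known position, and writes the result as a
phased VCF plus toy gene/QTL annotation files.  This gives every downstream
stage of the scan (QC, EHH/iHS, window calling, annotation, enrichment) a
fully known ground truth without any external data.

Model
-----
Discrete non-overlapping generations of ``n_diploids`` randomly mating
diploids.  Each offspring haplotype is a gamete from a parent chosen with
probability proportional to fitness; the gamete is a crossover mosaic of the
parent's two haplotypes with a Poisson(rho * L) number of breakpoints at
uniform positions.  Mutations arrive as Poisson(mu * L) per gamete per
generation at uniform bp positions under the infinite-sites convention
(positions already used are rejected), each creating a new derived allele on
one haplotype.  Selection acts at a single site with genotype fitnesses
1, 1+hs, 1+s for 0/1/2 copies of the derived (beneficial) allele.

At desk scale this is run with a small population and rescaled mu, rho and s
(large ``4 N mu L``-equivalent diversity from a short run), which preserves
the haplotype structure a sweep produces without requiring genome-size
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .vcf_qc import MISSING, HaplotypeMatrix

#: The six trait classes used by cattle QTL catalogues.
QTL_CLASSES = (
    "Exterior",
    "Health",
    "Meat and Carcass",
    "Milk",
    "Production",
    "Reproduction",
)


class SweepLostError(RuntimeError):
    """The beneficial allele was lost in every attempted replicate."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of one forward simulation.

    mu and rho are per-bp per-generation rates; ``s`` is the selection
    coefficient of the derived allele at ``sweep_pos`` (0 disables the
    sweep) and ``h`` its dominance.  ``sweep_intro_gen`` is the generation
    at which the beneficial mutation is injected, allowing a neutral
    burn-in before the sweep starts.  ``sweep_freq_range`` optionally
    conditions the replicate on the swept allele's final sample frequency
    falling inside ``(lo, hi)`` — the sweep phase of a replicate outside
    the band is re-run from the saved burn-in state, the usual way partial
    (ongoing) sweeps are simulated.  ``missing_rate`` masks genotype calls
    i.i.d. after sampling and is capped below the downstream QC threshold
    so default fixtures survive QC.
    """

    n_diploids: int = 200
    n_generations: int = 800
    seq_length: int = 1_000_000
    mu: float = 8e-7
    rho: float = 1.5e-6
    s: float = 0.0
    h: float = 0.5
    sweep_pos: int | None = None
    sweep_intro_gen: int = 0
    sweep_freq_range: tuple[float, float] | None = None
    sample_n: int = 60
    missing_rate: float = 0.0
    seed: int = 0
    max_retries: int = 100
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 0.1):
            raise ValueError("missing_rate must be in [0, 0.1)")
        if self.sample_n > 2 * self.n_diploids:
            raise ValueError("sample_n cannot exceed 2 * n_diploids")
        if self.sample_n % 2:
            raise ValueError("sample_n must be even (phased diploids)")
        if self.mu < 0 or self.rho < 0:
            raise ValueError("mu and rho must be non-negative")
        if self.s < 0:
            raise ValueError("s must be non-negative")
        if not (0 <= self.h <= 1):
            raise ValueError("h must be in [0, 1]")
        if self.s > 0:
            if self.sweep_pos is None:
                raise ValueError("sweep_pos required when s > 0")
            if not (1 <= self.sweep_pos <= self.seq_length):
                raise ValueError("sweep_pos outside the simulated sequence")
            if not (0 <= self.sweep_intro_gen < self.n_generations):
                raise ValueError("sweep_intro_gen outside the simulated span")
            if self.sweep_freq_range is not None:
                lo, hi = self.sweep_freq_range
                if not (0 < lo < hi <= 1):
                    raise ValueError("sweep_freq_range must satisfy 0 < lo < hi <= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a simulated dataset (present iff a sweep was run)."""

    sweep_pos: int | None
    s: float
    final_derived_freq: float | None
    n_attempts: int = 1


def simulate_population(params: SimParams) -> tuple[HaplotypeMatrix, TruthRecord]:
    """Run the forward simulation and sample ``sample_n`` haplotypes.

    For a sweep, the neutral burn-in up to ``sweep_intro_gen`` is evolved
    once (stream seeded by ``seed``); the sweep phase is then attempted
    with a fresh per-attempt stream (seeded by ``(seed, attempt)``), and an
    attempt in which the beneficial allele is lost — or, with
    ``sweep_freq_range`` set, ends outside the requested frequency band —
    is retried from the saved burn-in state, up to ``params.max_retries``
    additional attempts.  Exhausting them raises :class:`SweepLostError`.
    Output is bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    state = _PopState.initial(params)
    if params.s == 0:
        _evolve(params, rng, state, params.n_generations, select=False)
        hm, freq = _sample(params, rng, state)
        return hm, TruthRecord(sweep_pos=None, s=0.0, final_derived_freq=None)

    _evolve(params, rng, state, params.sweep_intro_gen, select=False)
    sweep_gens = params.n_generations - params.sweep_intro_gen
    for attempt in range(params.max_retries + 1):
        rng_a = np.random.default_rng([params.seed, attempt])
        trial = state.copy()
        trial.inject_sweep(params, rng_a)
        ok = _evolve(params, rng_a, trial, sweep_gens, select=True)
        if not ok:
            continue  # allele lost
        hm, freq = _sample(params, rng_a, trial)
        if params.sweep_freq_range is not None and not (
            params.sweep_freq_range[0] <= freq <= params.sweep_freq_range[1]
        ):
            continue
        return hm, TruthRecord(
            sweep_pos=params.sweep_pos,
            s=params.s,
            final_derived_freq=freq,
            n_attempts=attempt + 1,
        )
    raise SweepLostError(
        f"beneficial allele lost or out of the frequency band in all "
        f"{params.max_retries + 1} attempts (seed {params.seed}); increase "
        "s, the generations after introduction, or max_retries"
    )


@njit(cache=True)
def _make_gametes(hap, positions, parents, which, breakpoints, offsets):  # pragma: no cover - exercised via simulate_population
    """Assemble one generation of gametes as crossover mosaics.

    ``breakpoints[offsets[g]:offsets[g+1]]`` are gamete g's crossover
    positions (unsorted); the gamete copies parent haplotype ``which`` and
    switches source at each breakpoint (site at position >= breakpoint).
    """
    two_n, m = hap.shape
    new = np.empty_like(hap)
    for g in range(two_n):
        a = 2 * parents[g] + which[g]
        b = 2 * parents[g] + 1 - which[g]
        lo, hi = offsets[g], offsets[g + 1]
        if lo == hi:
            new[g, :] = hap[a, :]
            continue
        bp = np.sort(breakpoints[lo:hi])
        k = 0
        n_bp = hi - lo
        src = a
        for c in range(m):
            pos = positions[c]
            while k < n_bp and bp[k] <= pos:
                src = b if src == a else a
                k += 1
            new[g, c] = hap[src, c]
    return new


class _PopState:
    """Mutable population state: haplotypes, site positions, used positions."""

    __slots__ = ("hap", "positions", "used", "sweep_on", "sweep_fixed")

    @classmethod
    def initial(cls, p: SimParams) -> "_PopState":
        st = cls()
        st.hap = np.zeros((2 * p.n_diploids, 0), dtype=np.int8)
        st.positions = np.empty(0, dtype=np.int64)
        st.used = set()
        if p.s > 0:
            st.used.add(int(p.sweep_pos))
        st.sweep_on = False
        st.sweep_fixed = False
        return st

    def copy(self) -> "_PopState":
        st = _PopState()
        st.hap = self.hap.copy()
        st.positions = self.positions.copy()
        st.used = set(self.used)
        st.sweep_on = self.sweep_on
        st.sweep_fixed = self.sweep_fixed
        return st

    def inject_sweep(self, p: SimParams, rng: np.random.Generator) -> None:
        """Place one copy of the beneficial allele on a random haplotype."""
        two_n = self.hap.shape[0]
        col = np.zeros((two_n, 1), dtype=np.int8)
        col[rng.integers(0, two_n), 0] = 1
        j = int(np.searchsorted(self.positions, p.sweep_pos))
        self.positions = np.insert(self.positions, j, p.sweep_pos)
        self.hap = np.concatenate([self.hap[:, :j], col, self.hap[:, j:]], axis=1)
        self.sweep_on = True


def _evolve(
    p: SimParams,
    rng: np.random.Generator,
    st: _PopState,
    n_generations: int,
    select: bool,
) -> bool:
    """Evolve ``st`` in place; False iff the sweep allele was lost."""
    two_n = 2 * p.n_diploids
    L = p.seq_length
    exp_mut = p.mu * L          # per gamete per generation
    exp_rec = p.rho * L
    fitness = np.array([1.0, 1.0 + p.h * p.s, 1.0 + p.s])

    for _ in range(n_generations):
        if select and st.sweep_on:
            sc = int(np.searchsorted(st.positions, p.sweep_pos))
            g = st.hap[0::2, sc].astype(np.int64) + st.hap[1::2, sc]
            w = fitness[g]
            probs = w / w.sum()
            parents = rng.choice(p.n_diploids, size=two_n, p=probs)
        else:
            parents = rng.integers(0, p.n_diploids, size=two_n)

        n_x = rng.poisson(exp_rec, size=two_n)
        which = rng.integers(0, 2, size=two_n).astype(np.int64)
        breakpoints = rng.integers(1, L + 1, size=int(n_x.sum()))
        offsets = np.zeros(two_n + 1, dtype=np.int64)
        np.cumsum(n_x, out=offsets[1:])
        st.hap = _make_gametes(
            st.hap, st.positions, parents.astype(np.int64), which, breakpoints, offsets
        )

        n_mut = rng.poisson(exp_mut * two_n)
        if n_mut:
            rows = rng.integers(0, two_n, size=n_mut)
            new_pos = np.empty(n_mut, dtype=np.int64)
            for k in range(n_mut):
                while True:
                    pos = int(rng.integers(1, L + 1))
                    if pos not in st.used:
                        st.used.add(pos)
                        new_pos[k] = pos
                        break
            order = np.argsort(new_pos, kind="stable")
            new_pos = new_pos[order]
            rows = rows[order]
            cols = np.zeros((two_n, n_mut), dtype=np.int8)
            cols[rows, np.arange(n_mut)] = 1
            insert_at = np.searchsorted(st.positions, new_pos)
            st.positions = np.insert(st.positions, insert_at, new_pos)
            st.hap = np.insert(st.hap, insert_at, cols, axis=1)

        counts = st.hap.sum(axis=0, dtype=np.int64)
        lost = counts == 0
        fixed = counts == two_n
        if st.sweep_on:
            sc = int(np.searchsorted(st.positions, p.sweep_pos))
            if lost[sc]:
                return False
            if fixed[sc]:
                st.sweep_fixed = True
                st.sweep_on = False
        drop = lost | fixed
        if drop.any():
            keep = ~drop
            st.positions = st.positions[keep]
            st.hap = st.hap[:, keep]
    return True


def _sample(p: SimParams, rng: np.random.Generator, st: _PopState):
    """Draw the phased diploid sample and compute the sweep frequency."""
    inds = rng.choice(p.n_diploids, size=p.sample_n // 2, replace=False)
    rows = np.ravel(np.column_stack([2 * inds, 2 * inds + 1]))
    sample = st.hap[rows].copy()

    freq = None
    if p.s > 0:
        if st.sweep_fixed:
            freq = 1.0
        else:
            sc = int(np.searchsorted(st.positions, p.sweep_pos))
            freq = float(sample[:, sc].mean())

    der = sample.sum(axis=0, dtype=np.int64)
    seg = (der > 0) & (der < sample.shape[0])
    sample = sample[:, seg]
    positions = st.positions[seg]

    if p.missing_rate > 0:
        mask = rng.random(sample.shape) < p.missing_rate
        sample[mask] = MISSING

    hm = HaplotypeMatrix(
        chrom=p.chrom,
        positions=positions,
        alleles=sample,
        sample_ids=[f"S{i:03d}" for i in range(p.sample_n // 2)],
    )
    return hm, freq


def simulate_genome(
    base: SimParams, n_chromosomes: int, sweep_chrom_index: int | None = 0
) -> tuple[list[HaplotypeMatrix], list[TruthRecord]]:
    """Concatenate independent single-chromosome runs into a toy genome.

    Chromosomes are named ``chr1..chrN``; the sweep (if ``base.s > 0``) is
    placed only on the chromosome with index ``sweep_chrom_index`` and the
    rest are run neutrally.  Seeds are spaced so replicate retries of one
    chromosome cannot collide with another.
    """
    matrices, truths = [], []
    for c in range(n_chromosomes):
        sweep_here = base.s > 0 and c == sweep_chrom_index
        params = replace(
            base,
            chrom=f"chr{c + 1}",
            seed=base.seed + 1000 * c,
            s=base.s if sweep_here else 0.0,
            sweep_pos=base.sweep_pos if sweep_here else None,
            sweep_intro_gen=base.sweep_intro_gen if sweep_here else 0,
        )
        hm, truth = simulate_population(params)
        matrices.append(hm)
        truths.append(truth)
    return matrices, truths


def write_vcf(matrices: HaplotypeMatrix | Sequence[HaplotypeMatrix], path) -> None:
    """Write haplotype matrices as a phased VCFv4.2 file.

    REF is the ancestral base, ALT the derived base, and the AA INFO tag
    records the ancestral base explicitly.  Missing calls are written as
    ``.|.``.  Raises on an empty matrix or unsorted sites.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = [matrices]
    if not matrices or all(hm.n_sites == 0 for hm in matrices):
        raise ValueError("refusing to write a VCF with no sites")
    samples = matrices[0].sample_ids
    for hm in matrices:
        if hm.sample_ids != samples:
            raise ValueError("all chromosomes must share the same samples")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-synthetic\n")
        for hm in matrices:
            length = int(hm.positions[-1]) if hm.n_sites else 0
            fh.write(f"##contig=<ID={hm.chrom},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for hm in matrices:
            if hm.n_sites and np.any(np.diff(hm.positions) <= 0):
                raise ValueError(f"{hm.chrom}: unsorted site positions")
            for i in range(hm.n_sites):
                col = hm.alleles[:, i]
                gts = []
                for d in range(len(samples)):
                    a, b = col[2 * d], col[2 * d + 1]
                    gts.append(
                        f"{'.' if a == MISSING else int(a)}|"
                        f"{'.' if b == MISSING else int(b)}"
                    )
                fh.write(
                    f"{hm.chrom}\t{int(hm.positions[i])}\t.\tA\tG\t.\tPASS\t"
                    f"AA=A\tGT\t" + "\t".join(gts) + "\n"
                )


def write_toy_annotations(
    gene_regions: Sequence[tuple],
    path_genes,
    path_qtls,
    *,
    trait_counts: Mapping[str, int] | None = None,
    trait_classes: Mapping[str, str] | None = None,
    qtl_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    chrom: str = "chr1",
    seq_length: int = 1_000_000,
    qtl_span: int = 20_000,
    seed: int = 0,
) -> None:
    """Write toy gene (BED) and QTL (TSV) annotation files.

    ``gene_regions`` is a list of ``(chrom, start0, end0[, name])`` 0-based
    half-open intervals.  QTLs are drawn per trait: ``trait_counts`` gives
    the number of intervals per trait name, ``trait_classes`` maps each
    trait to one of the six standard classes, and ``qtl_regions``
    optionally confines a trait's intervals to given (start0, end0) target
    regions — useful for planting a known enrichment.  The QTL TSV uses
    1-based inclusive coordinates (chrom, start, end, trait_name,
    trait_class).
    """
    rng = np.random.default_rng(seed)
    if trait_counts is None:
        trait_counts = {"Milk": 10, "Reproduction": 10}
    if trait_classes is None:
        trait_classes = {
            name: (name if name in QTL_CLASSES else QTL_CLASSES[i % len(QTL_CLASSES)])
            for i, name in enumerate(trait_counts)
        }
    for t in trait_counts:
        cls = trait_classes.get(t)
        if cls not in QTL_CLASSES:
            raise ValueError(f"trait {t!r} has unknown class {cls!r}")

    with Path(path_genes).open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for k, region in enumerate(gene_regions):
            c, start0, end0 = region[0], int(region[1]), int(region[2])
            name = region[3] if len(region) > 3 else f"GENE{k + 1:03d}"
            fh.write(f"{c}\t{start0}\t{end0}\t{name}\n")

    with Path(path_qtls).open("w") as fh:
        fh.write("chrom\tstart\tend\ttrait_name\ttrait_class\n")
        for trait, count in trait_counts.items():
            targets = (qtl_regions or {}).get(trait)
            for _ in range(int(count)):
                if targets:
                    t0, t1 = targets[rng.integers(0, len(targets))]
                    span = min(qtl_span, t1 - t0)
                    start0 = int(rng.integers(t0, max(t0 + 1, t1 - span + 1)))
                else:
                    span = qtl_span
                    start0 = int(rng.integers(0, max(1, seq_length - span)))
                end0 = min(start0 + span, seq_length)
                fh.write(
                    f"{chrom}\t{start0 + 1}\t{end0}\t{trait}\t"
                    f"{trait_classes[trait]}\n"
                )
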