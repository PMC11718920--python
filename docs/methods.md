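# Methods

## Scan procedure

`sweepscan` implements the integrated-haplotype-score (iHS) workflow for
detecting recent positive selection in phased diploid data.

**Site QC** (`vcf_qc`).  Reading keeps bi-allelic autosomal SNPs with fully
phased genotypes (any non-missing unphased call is an error naming the
record; sex chromosomes are excluded by a configurable name list, default
`{X, Y, chrX, chrY}`).  Alleles are polarized to 0 = ancestral / 1 =
derived, either taking REF as ancestral (default) or reading the AA INFO
tag; with the AA source, sites whose tag matches neither allele are
dropped and counted.  Per-site filters, applied as independent predicates
and attributed in the order INFO → missing → MAF → HWE:

* GATK-style INFO thresholds — fail iff a present field violates QD < 2.0,
  FS > 60.0, MQ < 40.0, MQRankSum < −12.5, ReadPosRankSum < −8.0 (strict
  inequalities, so boundary values pass; absent fields pass by default).
* missing rate > 0.10 excluded (exactly 0.10 is retained — the common
  "max-missing 0.9" convention means ≥ 90 % called),
* MAF < 0.05 excluded,
* two-sided exact Hardy–Weinberg p < 1e-6 excluded.

The HWE test is the exact conditional test on genotype counts given allele
counts (the Levene/Haldane distribution, computed by the recurrence
popularized for SNP QC by Wigginton et al.).  It is evaluated in exact
rational arithmetic: configurations with exactly equal probabilities then
tie-break deterministically, the result is exactly symmetric in the two
homozygote classes, and agreement with brute-force enumeration is exact
rather than within floating-point slop.  The cost is irrelevant at scan
scale (micro- to milliseconds per site).

**EHH and iHS** (`ehh_ihs`).  From each core site, carriers of each allele
are extended site by site; carriers are partitioned into
extended-haplotype groups, and EHH = Σ C(n_h,2)/C(n_c,2).  A carrier with
a missing call becomes a permanent singleton (it can never again be shown
identical to another haplotype), biasing EHH conservatively downward;
haplotypes missing at the core are not carriers at all.  Extension stops
at the first point below the EHH cutoff (default 0.05, the standard
Selscan-style truncation).  Two failure modes invalidate a core site's
score rather than biasing it: an inter-SNP gap above 800 kb during
extension (an optional "cap" rule instead counts the gap as 800 kb of
distance, mirroring the two ways scan tools treat large gaps), and
reaching a chromosome end before the cutoff (edge truncation).  iHH is the
trapezoid integral of EHH against physical distance (no genetic map),
summed over both directions and including the final sub-cutoff trapezoid.
The unstandardized score is computed as `log(iHH_A) − log(iHH_D)`, which
makes the ancestral/derived label swap an exact negation in floating
point.

Scoring requires at least `min_carriers` copies of *each* allele.  The
mathematical minimum is 2; the default is 5 because with the small samples
this package targets, iHH for a 2–4-copy allele is dominated by sampling
noise and inflates the neutral tails.  At typical resequencing scale
(hundreds of haplotypes, MAF ≥ 5 %) the setting is inactive.

**Standardization.**  Valid scores are binned by derived-allele frequency
into 100 equal-width bins on (0, 1); adjacent bins are merged left-to-right
until every group holds ≥ 2 scores.  Within each group the score is
centered and scaled by the sample mean and the n−1 standard deviation, so
every occupied group has mean 0 and sd 1 by construction; a group with
zero spread flags its scores invalid rather than dividing by zero.

**Window scan** (`window_scan`).  A site at 1-based position P belongs to
the 50 kb window `floor((P−1)/50000)`; the window statistic is the mean of
|iHS| over its valid sites (the |mean| is reported alongside — the two
differ when positive and negative scores mix, and mean-of-absolute is the
standard ranking choice).  Windows with fewer than 10 SNPs are discarded
(n = 10 is kept, resolving the "more than 10" vs "less than 10 filtered"
wording ambiguity in favour of the count arithmetic that a 1 %-of-retained
selection implies).  Exactly `floor(0.01 × retained)` windows are selected,
ranked by the statistic, ties at the boundary broken by (chrom, start)
with a warning; the realized threshold is the smallest selected statistic.
Labels are printed 1-based with end = start + 50,000 (the convention of
published cattle scans); internal arithmetic is half-open.

**Annotation and enrichment** (`annotate`, `qtl_enrich`).  Genes are read
from BED (0-based half-open) or GTF (1-based inclusive, `gene` features,
`gene_name` falling back to `gene_id`) and intersected with the selected
regions under ≥ 1 bp overlap semantics — the behaviour of a default
bedtools intersect; abutting intervals with zero shared bases do not
count.  QTL intervals carry a trait name and one of six classes (Exterior,
Health, Meat and Carcass, Milk, Production, Reproduction).  Each database
QTL overlapping any selected region is counted once; per-class and
per-trait percentages are reported.  Enrichment per trait uses the
one-sided hypergeometric tail P(X ≥ x) with X ~ Hypergeom(N = database
size, K = trait's database count, n = total overlapping QTLs), a richness
factor (trait's share among overlapping QTLs ÷ its database share), and
Benjamini–Hochberg adjustment across all database traits with significance
at FDR < 0.05.  The hypergeometric test is this package's explicit,
fully-specified choice of enrichment statistic; published GALLO-based
analyses do not document theirs precisely, so numerical agreement with any
particular published table is not expected.

## The synthetic-data generator

A discrete-generation forward Wright–Fisher model: N diploids, random
mating, per-gamete Poisson(ρL) crossovers at uniform positions,
per-gamete Poisson(µL) infinite-sites mutations (duplicate positions
rejected), viability selection at one site with fitnesses 1, 1+hs, 1+s.
A sweep is started by injecting one copy of the beneficial allele at a
configurable generation; replicates that lose the allele — or, when a
target band is set, end outside the requested final-frequency range — are
re-run with an incremented seed (the standard way of conditioning on a
partial, ongoing sweep).  Sampling returns `sample_n` haplotypes as phased
diploids, keeps sites segregating in the sample, and applies i.i.d.
missingness capped below the QC threshold.  Output is bit-identical for a
fixed seed; multi-chromosome genomes concatenate independent runs under
distinct names.

Default study conditions (chosen once, as a desk-scale rescaling of a
resequenced cattle population, and used unchanged by the tests and the
acceptance script):

| parameter | value | rationale |
|---|---|---|
| N (diploids) | 200 | smallest population whose neutral iHS noise leaves a window scan usable |
| generations | 800 = 4N | mutation–drift equilibrium from a monomorphic start |
| sequence | 1 Mb/chromosome, 6 chromosomes | ~110 retained 50 kb windows, so a top-1 % selection is exactly one window |
| µ | 8e-7 /bp/gen | ≈ 1,700 sample-segregating sites per Mb → ~45 scored SNPs per window, keeping window means stable |
| ρ | 1.5e-6 /bp/gen | scaled ρ = 4Nρ ≈ 1,200/Mb: EHH decays below 0.05 well inside a chromosome, limiting edge truncation |
| s | 0.35 (h = 0.5) | 2Ns = 140: strong selection, but slow enough (~45 generations) that the swept haplotype scale 1/(ρ·t) ≈ 15 kb concentrates the signal inside one 50 kb window |
| sweep introduction | generation 756 | leaves the sweep ongoing at sampling |
| final frequency band | 0.65–0.9 | iHS power peaks for partial sweeps; completed sweeps erase the derived-allele contrast |
| sample | 60 haplotypes (100 in the recovery benchmark) | resequencing-panel scale |

What the generator emulates: neutral coalescent-like variation with
recombination, a hard partial sweep, known ancestral states, missingness.
What it does not: demographic history (bottlenecks, admixture — the real
populations these scans target are admixed), variable recombination/
mutation rate, genotyping error, phasing error, background selection, soft
sweeps.  Passing tests therefore demonstrate the *machinery* is correct
and that the statistic has power under textbook conditions; they do not
certify power or false-positive rates on real livestock data.

## Numerical choices and degenerate inputs

* Trapezoid integration over bp; integral includes the first sub-cutoff
  point's trapezoid.
* Scores invalid (with a reason) rather than numeric when: either allele
  below `min_carriers`, any curve gap- or edge-truncated, an iHH integral
  is zero, or the frequency group is degenerate.
* Monomorphic HWE tables give p = 1; empty QC output warns, not errors.
* Selection of top-k with k = 0 warns and returns empty.
* `numba` JIT compiles the two inner kernels (EHH extension walk, gamete
  assembly); all random draws stay in `numpy.random.Generator`, so results
  are bit-reproducible and the kernels are validated against brute-force
  oracles in the tests.
* Scan problem sizes in the tests (6 × 1 Mb genomes, 20 replicate seeds
  for recovery; 2–3 chromosomes for calibration checks) were chosen so the
  full suite runs on a single CPU at desk scale.

## Known limitations

* Localization power at desk scale: with the default study conditions the
  exact 50 kb window containing a planted partial sweep ranks first among
  the ~110 retained windows in roughly half to three-quarters of
  conditioned replicates; in the rest the |iHS| peak falls in an adjacent
  window or — when the conditioned trajectory lingered at low frequency on
  an old, recombined haplotype — the signal is genuinely weak.  This
  mirrors the published power range of iHS for partial sweeps; genome-scale
  data with large N<sub>e</sub> fares better.  The replicate recovery rate
  is measured, not assumed: `scripts/acceptance.py` recomputes it on every
  run.
* Physical distance only; no genetic-map integration.
* Single ongoing-sweep model; no soft sweeps or selection on standing
  variation in the generator.
* The enrichment statistic is a plain hypergeometric overlap test on QTL
  record counts; it inherits the usual caveat that QTL database records
  are not independent observations.
* Unphased data must be phased upstream; the reader rejects it outright.
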