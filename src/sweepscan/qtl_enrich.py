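"""QTL annotation of selected regions and per-trait enrichment testing.

Given a table of trait-labelled QTL intervals (the dialect of the Animal
QTLdb, pre-converted to TSV) and a set of candidate selected regions, this
module reports which QTLs overlap the regions, the share of each trait and
trait class among the overlapping QTLs, and a per-trait enrichment test:

* richness factor = (trait share among overlapping QTLs)
                    / (trait share in the whole database),
* one-sided hypergeometric p-value
  ``P(X >= x)`` with ``X ~ Hypergeom(N=n_db, K=n_trait_db, n=n_overlap_total)``,
* Benjamini-Hochberg FDR across all tested traits, with significance
  called at FDR < 0.05 by default.

Overlap uses the same >= 1 bp half-open semantics as gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotate import Region
from .synthetic_data import QTL_CLASSES


@dataclass(frozen=True)
class QTLRecord:
    chrom: str
    start: int      # 0-based half-open
    end: int
    trait_name: str
    trait_class: str


@dataclass(frozen=True)
class EnrichmentResult:
    trait_name: str
    trait_class: str
    n_overlap: int
    n_overlap_total: int
    n_trait_db: int
    n_db: int
    richness_factor: float
    p_value: float
    fdr: float
    significant: bool


def read_qtl_table(path) -> list[QTLRecord]:
    """Read a QTL TSV (chrom, start, end, trait_name, trait_class).

    Coordinates in the file are 1-based inclusive and converted to the
    internal half-open convention.  A trait class outside the six standard
    categories raises an error naming the row.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "trait_name", "trait_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.trait_class not in QTL_CLASSES:
            raise ValueError(
                f"{Path(path).name}: line {i}: unknown trait class "
                f"{row.trait_class!r} (trait {row.trait_name!r})"
            )
        records.append(
            QTLRecord(
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                trait_name=str(row.trait_name),
                trait_class=str(row.trait_class),
            )
        )
    return records


def annotate_qtls(
    regions: Sequence[Region], qtls: Sequence[QTLRecord]
) -> tuple[list[QTLRecord], pd.DataFrame, pd.DataFrame]:
    """QTLs overlapping the selected regions, with trait/class shares.

    Each database QTL is counted at most once however many regions it
    overlaps.  Returns the overlapping records plus two percentage tables:
    per trait class and per trait (share of all overlapping QTLs, in %).
    """
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        s, e = r.interval0
        if e > s:
            trees.setdefault(r.chrom, IntervalTree()).addi(s, e)
    hits = [
        q
        for q in qtls
        if q.chrom in trees and q.end > q.start and trees[q.chrom].overlap(q.start, q.end)
    ]
    n = len(hits)
    by_class = pd.Series([q.trait_class for q in hits], dtype="object").value_counts()
    by_trait = pd.Series(
        [(q.trait_name, q.trait_class) for q in hits], dtype="object"
    ).value_counts()
    class_table = pd.DataFrame(
        {
            "trait_class": by_class.index,
            "n_overlap": by_class.values,
            "percent": 100.0 * by_class.values / n if n else 0.0,
        }
    )
    trait_table = pd.DataFrame(
        {
            "trait_name": [t for t, _ in by_trait.index],
            "trait_class": [c for _, c in by_trait.index],
            "n_overlap": by_trait.values,
            "percent": 100.0 * by_trait.values / n if n else 0.0,
        }
    )
    return hits, class_table, trait_table


def enrich(
    overlapping: Sequence[QTLRecord],
    database: Sequence[QTLRecord],
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-trait hypergeometric enrichment of regions' QTL content.

    Every trait present in the database is tested (a trait found among the
    overlapping QTLs but absent from the database is an error).  P-values
    are upper-tail hypergeometric; BH step-up adjustment is applied across
    all tested traits and results are sorted by ascending FDR.
    """
    if not overlapping:
        raise ValueError("no overlapping QTLs; enrichment is undefined")
    n_db = len(database)
    n_total = len(overlapping)
    db_by_trait: dict[str, list[QTLRecord]] = {}
    for q in database:
        db_by_trait.setdefault(q.trait_name, []).append(q)
    for q in overlapping:
        if q.trait_name not in db_by_trait:
            raise ValueError(f"trait {q.trait_name!r} absent from the database")
    ov_counts: dict[str, int] = {}
    for q in overlapping:
        ov_counts[q.trait_name] = ov_counts.get(q.trait_name, 0) + 1

    traits = sorted(db_by_trait)
    rows = []
    for t in traits:
        k_db = len(db_by_trait[t])
        x = ov_counts.get(t, 0)
        p = float(hypergeom.sf(x - 1, n_db, k_db, n_total))
        rf = (x / n_total) / (k_db / n_db)
        rows.append((t, db_by_trait[t][0].trait_class, x, k_db, min(p, 1.0), rf))
    pvals = [r[4] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            trait_name=t,
            trait_class=cls,
            n_overlap=x,
            n_overlap_total=n_total,
            n_trait_db=k_db,
            n_db=n_db,
            richness_factor=rf,
            p_value=p,
            fdr=float(f),
            significant=bool(f < fdr_threshold),
        )
        for (t, cls, x, k_db, p, rf), f in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.trait_name))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Enrichment results as a table (Trait, Richness Factor, FDR, QTL Type
    plus the underlying counts)."""
    return pd.DataFrame(
        {
            "Trait": [r.trait_name for r in results],
            "Richness Factor": [r.richness_factor for r in results],
            "FDR": [r.fdr for r in results],
            "QTL Type": [r.trait_class for r in results],
            "n_overlap": [r.n_overlap for r in results],
            "n_overlap_total": [r.n_overlap_total for r in results],
            "n_trait_db": [r.n_trait_db for r in results],
            "n_db": [r.n_db for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
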