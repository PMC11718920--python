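"""Gene annotation of candidate selected regions by interval intersection.

Reads gene annotations from BED (0-based half-open) or GTF (1-based
inclusive, Ensembl dialect, feature type ``gene``) and intersects them with
selected regions using >= 1 bp overlap semantics — the behaviour of a
default ``bedtools intersect``.  Coordinates are normalized to a single
internal convention (0-based half-open) at read time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

from intervaltree import IntervalTree


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int       # 0-based half-open
    end: int
    gene_id: str
    gene_name: str
    line_number: int = 0


class Region(Protocol):
    """Anything with a chromosome and an internal half-open interval."""

    @property
    def chrom(self) -> str: ...

    @property
    def interval0(self) -> tuple[int, int]: ...


@dataclass
class RegionAnnotation:
    region: Region
    genes: list[GeneFeature]


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_annotation(path, fmt: str | None = None) -> list[GeneFeature]:
    """Read gene intervals from a BED or GTF file.

    ``fmt`` is inferred from the file suffix when omitted.  BED rows need
    at least chrom/start/end (name optional); GTF rows are filtered to
    feature type ``gene`` and the gene name falls back to the gene id when
    absent.  Malformed rows raise with the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "GTF" if path.suffix.lower() in (".gtf", ".gff") else "BED"
    fmt = fmt.upper()
    if fmt not in ("BED", "GTF"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes: list[GeneFeature] = []
    saw_rows = False
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"bed_{ln}"
                    genes.append(
                        GeneFeature(chrom, start, end, name, name, ln)
                    )
                else:
                    saw_rows = True
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 GTF columns")
                    if fields[2] != "gene":
                        continue
                    chrom = fields[0]
                    start1, end1 = int(fields[3]), int(fields[4])
                    attrs = dict(_GTF_ATTR.findall(fields[8]))
                    gid = attrs.get("gene_id", f"gtf_{ln}")
                    gname = attrs.get("gene_name", gid)
                    genes.append(
                        GeneFeature(chrom, start1 - 1, end1, gid, gname, ln)
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path.name}:{ln}: malformed {fmt} row: {exc}") from exc
    for g in genes:
        if g.start > g.end:
            raise ValueError(f"{path.name}:{g.line_number}: start > end")
    if fmt == "GTF" and saw_rows and not genes:
        warnings.warn(f"{path.name}: no 'gene' feature rows found", stacklevel=2)
    return genes


def intersect(
    regions: Sequence[Region], genes: Sequence[GeneFeature]
) -> list[RegionAnnotation]:
    """Report, for each region, the genes overlapping it by >= 1 bp.

    Half-open semantics: an interval abutting a region with zero shared
    bases is not reported.  Gene order within a region follows (start,
    end, gene_id).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.end > g.start:
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out = []
    for r in regions:
        s, e = r.interval0
        hits = trees[r.chrom].overlap(s, e) if r.chrom in trees else ()
        found = sorted(
            (iv.data for iv in hits), key=lambda g: (g.start, g.end, g.gene_id)
        )
        out.append(RegionAnnotation(region=r, genes=found))
    return out


def annotation_summary(annotations: Sequence[RegionAnnotation]) -> dict:
    """Counts mirroring a scan report: regions with genes, distinct genes."""
    distinct = {g.gene_id for a in annotations for g in a.genes}
    return {
        "n_regions": len(annotations),
        "n_regions_with_genes": sum(1 for a in annotations if a.genes),
        "n_distinct_genes": len(distinct),
        "genes": sorted(distinct),
    }


def annotation_frame(annotations: Sequence[RegionAnnotation]):
    """Region-to-gene table as a pandas DataFrame (one row per pair)."""
    import pandas as pd

    rows = []
    for a in annotations:
        s, e = a.region.interval0
        if not a.genes:
            rows.append((a.region.chrom, s + 1, e, "", ""))
        for g in a.genes:
            rows.append((a.region.chrom, s + 1, e, g.gene_id, g.gene_name))
    return pd.DataFrame(
        rows, columns=["chrom", "region_start", "region_end", "gene_id", "gene_name"]
    )
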