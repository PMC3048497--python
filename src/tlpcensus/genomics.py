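"""Tandem family-cluster detection and transposable-element coverage.

A tandem cluster is a maximal run of family genes on one chromosome where
each next family gene starts within ``gap_bp`` of the previous one's end;
its span runs from the first gene's start to the last gene's end, and the
cluster is *exclusive* when no non-family gene overlaps that span.
Coverage statistics are computed on interval unions (overlaps within a
class are never double-counted) after clipping repeats to the region;
enrichment against genome-background fractions is a plain ratio, matching
the descriptive percentages such analyses report.  All interval math is
0-based half-open and strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from tlpcensus.io_formats import GeneModel, RepeatInterval


@dataclass
class GeneCluster:
    """A tandem array of family genes on one chromosome."""

    chrom: str
    members: list[str]
    span: tuple[int, int]
    exclusive: bool

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class CoverageStats:
    """Per-class and total TE coverage of a genomic region."""

    region: tuple[str, int, int]
    class_bp: dict[str, int]
    class_fraction: dict[str, float]
    total_bp: int
    total_fraction: float
    enrichment: dict[str, float] = field(default_factory=dict)

    @property
    def region_bp(self) -> int:
        return self.region[2] - self.region[1]


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Length of the set-union of 0-based half-open intervals on one
    chromosome."""
    ivs = sorted(intervals)
    total = 0
    cur_start = cur_end = None
    for start, end in ivs:
        if start >= end:
            raise ValueError(f"empty interval ({start}, {end})")
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def te_coverage(
    region: tuple[str, int, int],
    repeats: Iterable[RepeatInterval],
    background: dict[str, float] | None = None,
) -> CoverageStats:
    """Union coverage of ``region`` per TE class and overall.

    Repeats extending past the region are clipped; repeats on other
    chromosomes are ignored.  When per-class ``background`` fractions are
    supplied, enrichment is reported as region fraction / background
    fraction.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError(f"empty region ({start}, {end})")
    length = end - start
    by_class: dict[str, list[tuple[int, int]]] = {}
    clipped_all: list[tuple[int, int]] = []
    for rep in repeats:
        if rep.chrom != chrom:
            continue
        s, e = max(rep.start, start), min(rep.end, end)
        if s >= e:
            continue
        by_class.setdefault(rep.te_class, []).append((s, e))
        clipped_all.append((s, e))
    class_bp = {cls: interval_union_length(ivs) for cls, ivs in by_class.items()}
    class_fraction = {cls: bp / length for cls, bp in class_bp.items()}
    total_bp = interval_union_length(clipped_all) if clipped_all else 0
    enrichment = {}
    if background:
        for cls, frac in class_fraction.items():
            bg = background.get(cls)
            if bg:
                enrichment[cls] = frac / bg
    return CoverageStats(
        region=region,
        class_bp=class_bp,
        class_fraction=class_fraction,
        total_bp=total_bp,
        total_fraction=total_bp / length,
        enrichment=enrichment,
    )


def find_clusters(
    genes: Sequence[GeneModel],
    gap_bp: int = 100_000,
    min_size: int = 3,
    require_family_only: bool = False,
) -> list[GeneCluster]:
    """Detect tandem arrays of family genes.

    Family genes on a chromosome are chained while each next one starts at
    most ``gap_bp`` after the previous one's end; runs shorter than
    ``min_size`` are dropped.  ``exclusive`` records whether any non-family
    gene overlaps the cluster span; with ``require_family_only`` such
    non-exclusive clusters are dropped as well.  The result is independent
    of input order and of strand.
    """
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        family = [g for g in chrom_genes if g.family_flag]
        runs: list[list[GeneModel]] = []
        for g in family:
            if runs and g.start - runs[-1][-1].end <= gap_bp:
                runs[-1].append(g)
            else:
                runs.append([g])
        for run in runs:
            if len(run) < min_size:
                continue
            span = (run[0].start, run[-1].end)
            exclusive = not any(
                (not g.family_flag) and g.start < span[1] and g.end > span[0]
                for g in chrom_genes
            )
            if require_family_only and not exclusive:
                continue
            clusters.append(
                GeneCluster(
                    chrom=chrom,
                    members=[g.gene_id for g in run],
                    span=span,
                    exclusive=exclusive,
                )
            )
    return clusters


def exon_count_profile(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Literal exon counts per gene, joinable with clade assignments to
    reproduce clade <-> gene-structure tables."""
    return {g.gene_id: g.n_exons for g in genes}
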