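"""Orchestration of the full census: scan -> classify -> properties ->
phylogeny -> genomics, with a consolidated, deterministic report.

Optional inputs degrade gracefully: without an alignment there is no tree
or clade column, without gene models there are no clusters, without repeats
no coverage table — the corresponding report sections are empty, never
null-ridden.  Re-running with identical inputs, configuration and seed
reproduces every output byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tlpcensus.classify import classify_architecture
from tlpcensus.config import CensusConfig
from tlpcensus.genomics import CoverageStats, GeneCluster, exon_count_profile, find_clusters, te_coverage
from tlpcensus.io_formats import (
    CENSUS_COLUMNS,
    read_alignment,
    read_fasta,
    read_gff3,
    read_repeats,
    write_census_table,
    write_newick,
)
from tlpcensus.phylo import assign_clades, bootstrap_support
from tlpcensus.properties import isoelectric_point, molecular_weight
from tlpcensus.tree import TreeNode

logger = logging.getLogger("tlpcensus")

LABELS = ("typical", "small", "tlp_kinase", "small_tlp_kinase", "incomplete")


@dataclass
class CensusReport:
    """Consolidated per-protein table plus summary blocks."""

    rows: pd.DataFrame
    summary: dict
    tree: TreeNode | None = None
    tree_diagnostics: dict = field(default_factory=dict)
    clusters: list[GeneCluster] = field(default_factory=list)
    coverage: list[CoverageStats] = field(default_factory=list)
    exon_counts: dict[str, int] = field(default_factory=dict)
    resolved_config: dict = field(default_factory=dict)


def _stage(name: str, record_id: str | None = None):
    ctx = f" [{record_id}]" if record_id else ""
    return f"stage {name}{ctx}"


def run_census(
    fasta: str | Path,
    msa: str | Path | None = None,
    gff: str | Path | None = None,
    repeats: str | Path | None = None,
    family_ids: list[str] | None = None,
    config: CensusConfig | None = None,
    seed: int | None = None,
    msa_format: str = "fasta",
) -> CensusReport:
    """Run the complete census over a protein FASTA plus optional alignment,
    gene models and repeat annotations."""
    config = config or CensusConfig()
    records = read_fasta(fasta)
    logger.info("%s: %d proteins", _stage("read_fasta"), len(records))

    rows = []
    for rec in records:
        try:
            cls = classify_architecture(rec, config)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"{_stage('classify', rec.id)}: {exc}") from exc
        has_x = "X" in rec.sequence
        row = {
            "id": rec.id,
            "organism_code": rec.organism_code,
            "label": cls.label,
            "domain_start": cls.domain.start if cls.domain else "",
            "domain_end": cls.domain.end if cls.domain else "",
            "domain_len": cls.domain.length if cls.domain else "",
            "n_cys": cls.domain.n_cysteines if cls.domain else "",
            "coverage": cls.domain.coverage if cls.domain else None,
            "mw_kda": None if has_x else molecular_weight(rec.sequence) / 1000.0,
            "pi": None if has_x else isoelectric_point(rec.sequence),
            "clade": "",
            "cluster_id": "",
        }
        rows.append(row)
    logger.info("%s: done", _stage("classify+properties"))

    tree = None
    diagnostics: dict = {}
    if msa is not None:
        alignment = read_alignment(msa, format=msa_format)
        tree, diagnostics = bootstrap_support(
            alignment,
            n_reps=config.phylo.bootstrap_reps,
            seed=seed if seed is not None else config.phylo.seed,
        )
        logger.info("%s: %d bootstrap replicates", _stage("phylo"), config.phylo.bootstrap_reps)
        if config.clades:
            assignment = assign_clades(tree, {c: set(v) for c, v in config.clades.items()})
            for row in rows:
                row["clade"] = assignment.assignment.get(row["id"], "")

    clusters: list[GeneCluster] = []
    coverage: list[CoverageStats] = []
    exon_counts: dict[str, int] = {}
    if gff is not None:
        genes = read_gff3(gff, family_ids=family_ids or [r["id"] for r in rows])
        exon_counts = exon_count_profile(genes)
        clusters = find_clusters(
            genes,
            gap_bp=config.cluster.gap_bp,
            min_size=config.cluster.min_size,
            require_family_only=config.cluster.require_family_only,
        )
        member_of = {
            gid: f"cluster{k}" for k, cl in enumerate(clusters) for gid in cl.members
        }
        for row in rows:
            row["cluster_id"] = member_of.get(row["id"], "")
        logger.info("%s: %d clusters", _stage("genomics"), len(clusters))
        if repeats is not None:
            reps = read_repeats(repeats)
            for cl in clusters:
                coverage.append(
                    te_coverage(
                        (cl.chrom, *cl.span), reps, background=config.te_background or None
                    )
                )

    label_counts = {lab: 0 for lab in LABELS}
    for row in rows:
        label_counts[row["label"]] = label_counts.get(row["label"], 0) + 1
    clade_counts: dict[str, int] = {}
    for row in rows:
        if row["clade"]:
            clade_counts[row["clade"]] = clade_counts.get(row["clade"], 0) + 1
    summary = {
        "n_proteins": len(rows),
        "label_counts": label_counts,
        "clade_counts": clade_counts,
        "n_clusters": len(clusters),
    }
    frame = pd.DataFrame(rows, columns=list(CENSUS_COLUMNS))
    return CensusReport(
        rows=frame,
        summary=summary,
        tree=tree,
        tree_diagnostics=diagnostics,
        clusters=clusters,
        coverage=coverage,
        exon_counts=exon_counts,
        resolved_config=config.to_dict(),
    )


def write_report(report: CensusReport, outdir: str | Path) -> None:
    """Write census.tsv, tree.nwk, clusters.tsv, coverage.tsv and the
    resolved configuration into ``outdir`` (deterministic bytes)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_census_table(report.rows.to_dict("records"), out / "census.tsv")
    if report.tree is not None:
        write_newick(report.tree, out / "tree.nwk")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tchrom\tstart\tend\tspan_bp\tsize\texclusive\tmembers\n")
        for k, cl in enumerate(report.clusters):
            fh.write(
                f"cluster{k}\t{cl.chrom}\t{cl.span[0]}\t{cl.span[1]}\t{cl.span_bp}\t"
                f"{cl.size}\t{str(cl.exclusive).lower()}\t{','.join(cl.members)}\n"
            )
    with open(out / "coverage.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tte_class\tcovered_bp\tfraction\tenrichment\n")
        for cov in report.coverage:
            chrom, start, end = cov.region
            for cls in sorted(cov.class_bp):
                enr = cov.enrichment.get(cls)
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{cls}\t{cov.class_bp[cls]}\t"
                    f"{cov.class_fraction[cls]:.4f}\t"
                    f"{'' if enr is None else f'{enr:.3f}'}\n"
                )
            fh.write(
                f"{chrom}\t{start}\t{end}\ttotal\t{cov.total_bp}\t"
                f"{cov.total_fraction:.4f}\t\n"
            )
    import yaml

    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(report.resolved_config, sort_keys=True)
    )
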