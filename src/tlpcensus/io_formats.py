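"""Readers and writers for every external format the census pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ProteinRecord`, :class:`Alignment`, :class:`GeneModel` and
:class:`RepeatInterval`.  Coordinates are 0-based half-open internally;
GFF3's 1-based closed convention is converted at this boundary and nowhere
else.  Strand only affects reporting order, never interval arithmetic.

Repeat annotations are consumed as a plain tab-delimited interval table
(chrom, start, end, te_class, family with a one-line header); converting a
repeat-detector's native output into that table is the caller's concern.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from tlpcensus.errors import ParseError
from tlpcensus.tree import TreeNode

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
SEQUENCE_CHARS = STANDARD_AA | {"X"}
GAP = "-"

TE_CLASSES = ("LTR_Gypsy", "LTR_Copia", "LTR_other", "DNA_transposon", "other")

_ORG_RE = re.compile(r"^([A-Z][a-z]{4})[-_]")

#: fixed column order of the TSV census report
CENSUS_COLUMNS = (
    "id",
    "organism_code",
    "label",
    "domain_start",
    "domain_end",
    "domain_len",
    "n_cys",
    "coverage",
    "mw_kda",
    "pi",
    "clade",
    "cluster_id",
)


# ---------------------------------------------------------------------------
# protein sequences


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier and provenance.

    ``organism_code`` follows the five-letter convention (first three letters
    of the genus + first two of the species, e.g. ``Poptr``); it is parsed
    from the id prefix when present.  ``stop_stripped`` records that a single
    trailing ``*`` (stop codon) was removed at parse time.
    """

    id: str
    sequence: str
    description: str = ""
    organism_code: str = ""
    stop_stripped: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_CHARS
        if bad:
            raise ValueError(
                f"{self.id}: illegal residue(s) {sorted(bad)}; allowed are the 20 "
                "standard amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def organism_code_of(identifier: str) -> str:
    m = _ORG_RE.match(identifier)
    return m.group(1) if m else ""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA file.

    Sequences are upper-cased; a single trailing ``*`` is stripped and
    flagged on the record; an internal ``*`` or any character outside the
    20 standard residues plus X is a :class:`ParseError` naming the line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[tuple[int, str]] = []

    def flush() -> None:
        nonlocal header
        if header is None:
            return
        ident = header.split()[0]
        desc = header[len(ident):].strip()
        if ident in seen:
            raise ParseError(f"duplicate FASTA id {ident!r}", line=header_line)
        seen.add(ident)
        seq_parts: list[str] = []
        for lineno, chunk in chunks:
            up = chunk.upper()
            star = up.find("*")
            if star != -1:
                is_last_chunk = (lineno, chunk) == chunks[-1]
                if not (is_last_chunk and star == len(up) - 1):
                    raise ParseError(
                        f"{ident}: internal stop codon '*'", line=lineno
                    )
            bad = set(up) - SEQUENCE_CHARS - {"*"}
            if bad:
                raise ParseError(
                    f"{ident}: illegal residue(s) {sorted(bad)}", line=lineno
                )
            seq_parts.append(up)
        seq = "".join(seq_parts)
        stripped = seq.endswith("*")
        if stripped:
            seq = seq[:-1]
        if not seq:
            raise ParseError(f"{ident}: empty sequence", line=header_line)
        records.append(
            ProteinRecord(
                id=ident,
                sequence=seq,
                description=desc,
                organism_code=organism_code_of(ident),
                stop_stripped=stripped,
            )
        )
        header = None
        chunks.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                if not header:
                    raise ParseError("empty FASTA header", line=lineno)
            else:
                if header is None:
                    raise ParseError("sequence data before first '>'", line=lineno)
                chunks.append((lineno, line))
    flush()
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment with gap character ``-``."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            bad = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise ValueError(f"ragged alignment rows: {bad}")
        for ident, row in zip(self.ids, self.rows):
            bad = set(row) - SEQUENCE_CHARS - {GAP}
            if bad:
                raise ValueError(f"{ident}: illegal alignment character(s) {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, ident: str) -> str:
        try:
            return self.rows[self.ids.index(ident)]
        except ValueError:
            raise KeyError(f"no alignment row with id {ident!r}") from None

    def ungapped(self, ident: str) -> str:
        return self.row(ident).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def take_columns(self, indices: Sequence[int]) -> "Alignment":
        rows = tuple("".join(r[j] for j in indices) for r in self.rows)
        return Alignment(self.ids, rows)


def _normalize_aln_row(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment in aligned-FASTA or Clustal format.

    ``.`` gap characters are normalized to ``-``.  Ragged FASTA rows raise a
    :class:`ParseError` listing the offending ids.
    """
    from Bio import AlignIO, SeqIO

    if format == "fasta":
        pairs = [
            (rec.id, _normalize_aln_row(str(rec.seq)))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        if not pairs:
            raise ParseError(f"no alignment rows in {path}")
        ref_len = len(pairs[0][1])
        ragged = [ident for ident, row in pairs if len(row) != ref_len]
        if ragged:
            raise ParseError(f"ragged alignment rows for ids: {ragged}")
    elif format == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise ParseError(f"invalid clustal file {path}: {exc}") from None
        pairs = [(rec.id, _normalize_aln_row(str(rec.seq))) for rec in aln]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    ids, rows = zip(*pairs)
    return Alignment(tuple(ids), tuple(rows))


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio import AlignIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=ident, description="")
        for ident, row in zip(aln.ids, aln.rows)
    )
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    AlignIO.write(msa, str(path), format)


# ---------------------------------------------------------------------------
# gene models (GFF3)


@dataclass
class GeneModel:
    """A gene with exon and CDS intervals in 0-based half-open coordinates.

    Exons are stored sorted in genome order and must be non-overlapping;
    every CDS interval must fall inside an exon.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    family_flag: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        self.exons = sorted(self.exons)
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty exon interval ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = end
        self.cds_intervals = sorted(self.cds_intervals)
        for cs, ce in self.cds_intervals:
            if cs >= ce:
                raise ValueError(f"{self.gene_id}: empty CDS interval ({cs},{ce})")
            if not any(cs >= es and ce <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS ({cs},{ce}) not contained in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def read_gff3(path: str | Path, family_ids: Iterable[str] = ()) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Genes whose ID is in ``family_ids`` get ``family_flag=True``.
    """
    import gffutils

    family = set(family_ids)
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) >= 5:
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"non-numeric coordinates: {line!r}", line=lineno)
            if end < start:
                raise ParseError(
                    f"feature end {end} < start {start}", line=lineno
                )
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="CDS", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons if exons else [(gene.start - 1, gene.end)],
                cds_intervals=cds,
                family_flag=gene.id in family,
            )
        )
    return genes


def format_gff3(genes: Iterable[GeneModel]) -> str:
    """Render gene/mRNA/exon/CDS features, converting back to 1-based closed."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            f"{g.chrom}\ttlpcensus\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.1"
        lines.append(
            f"{g.chrom}\ttlpcensus\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\ttlpcensus\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{i};Parent={mrna}"
            )
        for i, (s, e) in enumerate(g.cds_intervals, 1):
            lines.append(
                f"{g.chrom}\ttlpcensus\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={mrna}.cds{i};Parent={mrna}"
            )
    return "\n".join(lines) + "\n"


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    Path(path).write_text(format_gff3(genes))


# ---------------------------------------------------------------------------
# repeat intervals


@dataclass(frozen=True)
class RepeatInterval:
    """A transposable-element annotation on a chromosome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    te_class: str
    family: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"repeat interval start {self.start} >= end {self.end} on {self.chrom}"
            )
        if self.te_class not in TE_CLASSES:
            raise ValueError(
                f"unknown te_class {self.te_class!r}; allowed: {', '.join(TE_CLASSES)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_repeats(path: str | Path) -> list[RepeatInterval]:
    """Read the tab-delimited repeat table (chrom, start, end, te_class, family)
    with its one-line header."""
    repeats: list[RepeatInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if lineno == 1 or not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"expected >= 4 tab-separated columns", line=lineno)
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(f"non-numeric repeat coordinates", line=lineno)
            try:
                repeats.append(
                    RepeatInterval(
                        chrom=cols[0],
                        start=start,
                        end=end,
                        te_class=cols[3],
                        family=cols[4] if len(cols) > 4 else "",
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
    return repeats


def format_repeats(repeats: Iterable[RepeatInterval]) -> str:
    lines = ["chrom\tstart\tend\tte_class\tfamily"]
    lines += [f"{r.chrom}\t{r.start}\t{r.end}\t{r.te_class}\t{r.family}" for r in repeats]
    return "\n".join(lines) + "\n"


def write_repeats(repeats: Iterable[RepeatInterval], path: str | Path) -> None:
    Path(path).write_text(format_repeats(repeats))


# ---------------------------------------------------------------------------
# trees and reports


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick with 6-decimal branch lengths and integer bootstrap
    percentages as internal-node labels."""
    Path(path).write_text(tree.format_newick(precision=6) + "\n")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.from_newick(Path(path).read_text())


def write_census_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write the per-protein census TSV in the fixed documented column order."""

    def fmt(key: str, value) -> str:
        if value is None or value == "":
            return ""
        if key in ("coverage",):
            return f"{value:.4f}"
        if key in ("mw_kda",):
            return f"{value:.3f}"
        if key in ("pi",):
            return f"{value:.2f}"
        return str(value)

    with open(path, "w") as fh:
        fh.write("\t".join(CENSUS_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(c, row.get(c)) for c in CENSUS_COLUMNS) + "\n")
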