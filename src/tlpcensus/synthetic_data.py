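"""Seeded generators for every input the census pipeline consumes.

Three generators cover the pipeline end to end, each returning its ground
truth alongside the data so that round-trip tests can compare pipeline
output against planted values field by field:

* :func:`generate_protein` builds TLP scaffolds of the four architectures
  (typical ~215-residue domain with 16 cysteines, small ~150 with 10,
  and their kinase fusions at ~650 aa total with a transmembrane stretch
  and an anchored kinase segment).
* :func:`evolve_alignment` evolves a root sequence along a tree under a
  uniform-jump substitution process (the 20-state analogue of Jukes-Cantor)
  whose expected pairwise difference depends only on path length.
* :func:`generate_locus` lays out tandem gene arrays with planted exon
  counts and repeat intervals hitting per-class coverage fractions exactly.

Filler alphabets deliberately exclude the letters that seed boundary,
kinase or transmembrane motifs (C, N, Y, W everywhere; additionally G, H,
D and the strongly hydrophobic residues downstream of the domain), so the
planted motifs are the only ones present and ground-truth coordinates are
exact.  Inter-cysteine spacing follows a fixed template (evenly spaced
through the domain body), so coordinates are stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from tlpcensus.io_formats import (
    Alignment,
    GeneModel,
    ProteinRecord,
    RepeatInterval,
    format_gff3,
    format_repeats,
)
from tlpcensus.tree import TreeNode

ARCHITECTURES = ("typical", "small", "tlp_kinase", "small_tlp_kinase")

#: filler inside the thaumatin domain: standard residues minus C/N/Y/W
DOMAIN_FILLER = "ADEFGHIKLMPQRSTV"
#: filler for leaders, linkers, tails and the kinase body: polar residues only,
#: with G/H/D also excluded so no spurious kinase anchors can arise downstream
LINKER_FILLER = "AEKMPQRST"
#: transmembrane stretch alphabet (Kyte-Doolittle >= 2.8 each)
TM_ALPHABET = "ILVF"

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TYPICAL_DOMAIN_LEN = 215
_SMALL_DOMAIN_LEN = 150
_TYPICAL_N_CYS = 16
_SMALL_N_CYS = 10

# segment lengths of the kinase fusion layout (sums to 650 for a typical
# domain, matching the ~650 aa reported for TLP-kinases)
_K_LEADER, _K_LINK1, _K_TM, _K_LINK2, _K_KINASE, _K_TAIL = 25, 20, 19, 20, 320, 31
_GLOOP_OFFSET, _HXD_OFFSET, _DXG_OFFSET = 0, 100, 130
_PLAIN_LEADER = 5
_PLAIN_TAIL = 5


@dataclass
class ScaffoldSpec:
    """Recipe for one synthetic TLP protein."""

    architecture: str = "typical"
    domain_len: int | None = None
    n_cys: int | None = None
    reddd_fracs: tuple[float, ...] = (0.30, 0.45, 0.55, 0.65, 0.80)
    organism_code: str = "Poptr"
    protein_id: str | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        small = self.architecture in ("small", "small_tlp_kinase")
        if self.domain_len is None:
            self.domain_len = _SMALL_DOMAIN_LEN if small else _TYPICAL_DOMAIN_LEN
        if self.n_cys is None:
            self.n_cys = _SMALL_N_CYS if small else _TYPICAL_N_CYS
        if self.n_cys < 2 or self.n_cys > self.domain_len - 20:
            raise ValueError(
                f"cannot place {self.n_cys} cysteines in a {self.domain_len}-residue domain"
            )

    @property
    def has_kinase(self) -> bool:
        return self.architecture.endswith("kinase")


@dataclass
class ProteinTruth:
    """Ground-truth coordinates recorded next to each generated protein."""

    architecture: str
    length: int
    domain_start: int
    domain_end: int
    n_motif_start: int
    c_motif_start: int
    cys_positions: tuple[int, ...]
    reddd_positions: tuple[int, ...]
    kinase_start: int | None = None
    kinase_end: int | None = None
    catalytic_asp_positions: tuple[int, int] | None = None
    tm_start: int | None = None
    tm_end: int | None = None


def _domain_layout(spec: ScaffoldSpec) -> tuple[list[int], list[int]]:
    """Fixed cysteine / REDDD positions (domain-relative) for a spec."""
    L, k = spec.domain_len, spec.n_cys
    cys = [2, L - 2]  # the boundary-motif cysteines
    interior = np.round(np.linspace(12, L - 12, k - 2)).astype(int) if k > 2 else []
    cys = sorted(set(cys) | set(int(x) for x in interior))
    if len(cys) != k:
        raise ValueError("cysteine template collision; use a longer domain")
    occupied = set(cys) | set(range(0, 8)) | set(range(L - 7, L))
    reddd = []
    for frac in spec.reddd_fracs:
        pos = int(round(frac * L))
        while pos in occupied:
            pos += 1
        occupied.add(pos)
        reddd.append(pos)
    return cys, reddd


def _fill(rng: np.random.Generator, n: int, alphabet: str) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), n)]


def _build_domain(spec: ScaffoldSpec, rng: np.random.Generator) -> tuple[str, list[int], list[int]]:
    L = spec.domain_len
    cys, reddd = _domain_layout(spec)
    seq = _fill(rng, L, DOMAIN_FILLER)
    # N-terminal motif: N x C x x x V W
    seq[0], seq[2], seq[6], seq[7] = "N", "C", "V", "W"
    # C-terminal motif: Y x I x F C x
    seq[L - 7], seq[L - 5], seq[L - 3], seq[L - 2] = "Y", "I", "F", "C"
    for pos in cys:
        seq[pos] = "C"
    for pos, aa in zip(reddd, "REDDD"):
        seq[pos] = aa
    return "".join(seq), cys, reddd


def _build_kinase_segment(rng: np.random.Generator) -> str:
    seq = _fill(rng, _K_KINASE, LINKER_FILLER)
    g = _GLOOP_OFFSET
    seq[g], seq[g + 2], seq[g + 5] = "G", "G", "G"
    seq[_HXD_OFFSET : _HXD_OFFSET + 3] = list("HRD")
    seq[_DXG_OFFSET : _DXG_OFFSET + 3] = list("DFG")
    return "".join(seq)


def generate_protein(
    spec: ScaffoldSpec | None = None, seed: int = 0
) -> tuple[ProteinRecord, ProteinTruth]:
    """Build one synthetic TLP protein and its ground truth, deterministically
    under ``(spec, seed)``."""
    spec = spec or ScaffoldSpec()
    rng = np.random.default_rng(seed)
    domain, cys_rel, reddd_rel = _build_domain(spec, rng)
    L = spec.domain_len

    if spec.has_kinase:
        leader = "".join(_fill(rng, _K_LEADER, LINKER_FILLER))
        link1 = "".join(_fill(rng, _K_LINK1, LINKER_FILLER))
        tm = "".join(_fill(rng, _K_TM, TM_ALPHABET))
        link2 = "".join(_fill(rng, _K_LINK2, LINKER_FILLER))
        kinase = _build_kinase_segment(rng)
        tail = "".join(_fill(rng, _K_TAIL, LINKER_FILLER))
        sequence = leader + domain + link1 + tm + link2 + kinase + tail
        d0 = len(leader)
        tm0 = d0 + L + len(link1)
        k0 = tm0 + _K_TM + len(link2)
        truth = ProteinTruth(
            architecture=spec.architecture,
            length=len(sequence),
            domain_start=d0,
            domain_end=d0 + L,
            n_motif_start=d0,
            c_motif_start=d0 + L - 7,
            cys_positions=tuple(d0 + c for c in cys_rel),
            reddd_positions=tuple(d0 + r for r in reddd_rel),
            kinase_start=k0,
            kinase_end=len(sequence),
            catalytic_asp_positions=(k0 + _HXD_OFFSET + 2, k0 + _DXG_OFFSET),
            tm_start=tm0,
            tm_end=tm0 + _K_TM,
        )
    else:
        leader = "".join(_fill(rng, _PLAIN_LEADER, LINKER_FILLER))
        tail = "".join(_fill(rng, _PLAIN_TAIL, LINKER_FILLER))
        sequence = leader + domain + tail
        d0 = len(leader)
        truth = ProteinTruth(
            architecture=spec.architecture,
            length=len(sequence),
            domain_start=d0,
            domain_end=d0 + L,
            n_motif_start=d0,
            c_motif_start=d0 + L - 7,
            cys_positions=tuple(d0 + c for c in cys_rel),
            reddd_positions=tuple(d0 + r for r in reddd_rel),
        )

    ident = spec.protein_id or f"{spec.organism_code}-{spec.architecture}{seed:05d}"
    record = ProteinRecord(
        id=ident,
        sequence=sequence,
        description=f"synthetic {spec.architecture} TLP scaffold",
        organism_code=spec.organism_code,
    )
    return record, truth


def generate_census_bundle(
    counts: dict[str, int] | None = None, seed: int = 0
) -> tuple[list[ProteinRecord], dict[str, ProteinTruth]]:
    """A set of scaffolds per architecture (defaults mirror the poplar census
    composition: 38 typical + 4 TLP-kinase)."""
    counts = counts or {"typical": 38, "tlp_kinase": 4}
    records: list[ProteinRecord] = []
    truths: dict[str, ProteinTruth] = {}
    k = 0
    for arch in ARCHITECTURES:
        for _ in range(counts.get(arch, 0)):
            spec = ScaffoldSpec(architecture=arch, protein_id=f"Poptr-TLP{k:04d}")
            rec, truth = generate_protein(spec, seed=seed * 100_003 + k)
            records.append(rec)
            truths[rec.id] = truth
            k += 1
    return records, truths


# ---------------------------------------------------------------------------
# sequence evolution


def expected_p(d: float) -> float:
    """Expected proportion of differing sites between two sequences separated
    by path length ``d`` under the uniform-jump process:
    E[p] = (19/20) * (1 - exp(-20 d / 19))."""
    return (19.0 / 20.0) * (1.0 - np.exp(-20.0 * d / 19.0))


def corrected_distance(p: float) -> float:
    """Invert :func:`expected_p`: the back-substitution-corrected distance
    estimate d = -(19/20) ln(1 - (20/19) p)."""
    return -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * p)


def evolve_alignment(
    tree: TreeNode,
    root_sequence: str,
    freeze: Iterable[int] = (),
    seed: int | None = None,
) -> Alignment:
    """Evolve ``root_sequence`` along ``tree`` and return the gap-free
    alignment of leaf sequences (leaves in tree order).

    The substitution process is the 20-state uniform-jump chain with rate 1
    substitution per site per unit branch length: on a branch of length b a
    site resamples uniformly over all 20 letters with probability
    1 - exp(-20 b / 19) (the exact transition marginal of the chain whose
    jumps go uniformly to the other 19 residues).  Positions in ``freeze``
    (e.g. cysteines, REDDD) never change.
    """
    rng = np.random.default_rng(seed)
    L = len(root_sequence)
    frozen = np.zeros(L, dtype=bool)
    fr = list(freeze)
    if fr:
        frozen[np.asarray(fr, dtype=int)] = True
    codes = {aa: i for i, aa in enumerate(AA20)}
    root = np.array([codes[aa] for aa in root_sequence], dtype=np.int8)

    ids: list[str] = []
    rows: list[str] = []

    def rec(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            s = seq.copy()
            lam = 1.0 - np.exp(-20.0 * child.length / 19.0)
            mask = (rng.random(L) < lam) & ~frozen
            n_sub = int(mask.sum())
            if n_sub:
                s[mask] = rng.integers(0, 20, n_sub)
            if child.is_leaf:
                ids.append(child.name)
                rows.append("".join(AA20[c] for c in s))
            else:
                rec(child, s)

    rec(tree, root)
    return Alignment(tuple(ids), tuple(rows))


def random_tree(
    n_leaves: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bl_range: tuple[float, float] = (0.01, 1.0),
    labels: Sequence[str] | None = None,
) -> TreeNode:
    """A random unrooted binary topology (random edge insertion) with iid
    uniform branch lengths."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i}" for i in range(n_leaves)]
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    root = TreeNode(children=[TreeNode(name=labels[i]) for i in range(3)])
    for i in range(3, n_leaves):
        edges = [
            (node, child)
            for node in root.walk()
            for child in node.children
        ]
        parent, child = edges[int(rng.integers(0, len(edges)))]
        mid = TreeNode(children=[child, TreeNode(name=labels[i])])
        parent.children[parent.children.index(child)] = mid
    lo, hi = bl_range
    for node in root.walk():
        if node is not root:
            node.length = float(rng.uniform(lo, hi))
    return root


def random_protein_sequence(
    length: int, rng: np.random.Generator, alphabet: str = AA20
) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


# ---------------------------------------------------------------------------
# genomic loci


@dataclass
class ClusterPlan:
    """Layout of the tandem family array (defaults reproduce an 11-gene
    array spanning exactly 350 kb, mean inter-gene gap 32.8 kb)."""

    chrom: str = "chr1"
    start: int = 100_000
    span: int = 350_000
    gene_len: int = 2_000
    exon_counts: tuple[int, ...] = ()
    interleave_other: int = 0
    intron_len: int = 200


@dataclass
class TEPlan:
    """Per-class coverage fractions of the cluster span (defaults give 52%
    total with Gypsy at 37%)."""

    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "LTR_Gypsy": 0.37,
            "DNA_transposon": 0.10,
            "LTR_Copia": 0.05,
        }
    )
    piece: int = 4_000
    spacer: int = 1_000


@dataclass
class LocusTruth:
    chrom: str
    family_ids: list[str]
    other_ids: list[str]
    cluster_members: list[str]
    cluster_span: tuple[int, int]
    cluster_exclusive: bool
    exon_counts: dict[str, int]
    te_fractions: dict[str, float]


def _split_exons(
    start: int, gene_len: int, n_exons: int, intron_len: int
) -> list[tuple[int, int]]:
    coding = gene_len - (n_exons - 1) * intron_len
    if coding < n_exons:
        raise ValueError("gene too short for requested exon count")
    base, extra = divmod(coding, n_exons)
    exons = []
    pos = start
    for i in range(n_exons):
        length = base + (1 if i < extra else 0)
        exons.append((pos, pos + length))
        pos += length + intron_len
    return exons


def generate_locus(
    n_family: int = 11,
    n_other: int = 5,
    cluster_plan: ClusterPlan | None = None,
    te_plan: TEPlan | None = None,
    seed: int = 0,
) -> tuple[str, str, LocusTruth]:
    """Build a toy genomic locus: GFF3 text, repeat-table text and truth.

    All ``n_family`` family genes form one evenly spaced tandem array whose
    span is exactly ``cluster_plan.span``; repeat intervals are tiled inside
    the span so each class covers its planned fraction exactly (plans whose
    fractions round to non-representable bp, overflow the span, or exceed
    100% raise).  ``n_other`` non-family genes are placed far downstream,
    plus ``interleave_other`` non-family genes inside the span.
    """
    plan = cluster_plan or ClusterPlan()
    te = te_plan or TEPlan()
    if sum(te.fractions.values()) > 1.0:
        raise ValueError("TE coverage fractions exceed 100%")
    if n_family < 2:
        raise ValueError("need at least two family genes for a tandem array")
    inter = plan.span - n_family * plan.gene_len
    if inter < 0:
        raise ValueError("genes do not fit in the cluster span")
    gap, rem = divmod(inter, n_family - 1)
    if rem:
        raise ValueError(
            "cluster span minus total gene length must divide evenly across gaps"
        )

    exon_counts = plan.exon_counts or tuple([2] * n_family)
    if len(exon_counts) != n_family:
        raise ValueError("exon_counts must have one entry per family gene")

    genes: list[GeneModel] = []
    truth_exons: dict[str, int] = {}
    family_ids: list[str] = []
    for i in range(n_family):
        gid = f"TLPfam{i:03d}"
        gstart = plan.start + i * (plan.gene_len + gap)
        exons = _split_exons(gstart, plan.gene_len, exon_counts[i], plan.intron_len)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=plan.chrom,
                strand="+" if i % 2 == 0 else "-",
                exons=exons,
                cds_intervals=list(exons),
                family_flag=True,
            )
        )
        family_ids.append(gid)
        truth_exons[gid] = exon_counts[i]

    other_ids: list[str] = []
    for i in range(plan.interleave_other):
        gid = f"other_in{i:03d}"
        # drop the gene into the middle of gap i+1
        anchor = plan.start + (i + 1) * (plan.gene_len + gap) - gap // 2
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=plan.chrom,
                strand="+",
                exons=[(anchor, anchor + 1_000)],
                cds_intervals=[(anchor, anchor + 1_000)],
                family_flag=False,
            )
        )
        other_ids.append(gid)
        truth_exons[gid] = 1
    span_end = plan.start + plan.span
    for i in range(n_other):
        gid = f"other_out{i:03d}"
        gstart = span_end + 200_000 + i * 150_000
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=plan.chrom,
                strand="+",
                exons=[(gstart, gstart + 1_500)],
                cds_intervals=[(gstart, gstart + 1_500)],
                family_flag=False,
            )
        )
        other_ids.append(gid)
        truth_exons[gid] = 1

    repeats: list[RepeatInterval] = []
    pos = plan.start
    achieved: dict[str, float] = {}
    for cls in sorted(te.fractions):
        bp = int(round(te.fractions[cls] * plan.span))
        achieved[cls] = bp / plan.span
        remaining = bp
        j = 0
        while remaining > 0:
            piece = min(te.piece, remaining)
            if pos + piece > span_end:
                raise ValueError("TE plan does not fit inside the cluster span")
            repeats.append(
                RepeatInterval(
                    chrom=plan.chrom,
                    start=pos,
                    end=pos + piece,
                    te_class=cls,
                    family=f"{cls}_fam{j}",
                )
            )
            pos += piece + te.spacer
            remaining -= piece
            j += 1
    achieved["total"] = sum(
        int(round(f * plan.span)) for f in te.fractions.values()
    ) / plan.span

    truth = LocusTruth(
        chrom=plan.chrom,
        family_ids=family_ids,
        other_ids=other_ids,
        cluster_members=family_ids,
        cluster_span=(plan.start, span_end),
        cluster_exclusive=plan.interleave_other == 0,
        exon_counts=truth_exons,
        te_fractions=achieved,
    )
    return format_gff3(genes), format_repeats(repeats), truth
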