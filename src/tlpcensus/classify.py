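"""Architecture classification of thaumatin-like proteins.

Four architectures are distinguished on top of the motif-delimited thaumatin
domain: typical TLPs (~215 aa domain, 16 cysteines), small-TLPs (~150 aa,
10 cysteines), and their kinase fusions (TLP-K / sTLP-K, ~650 aa proteins
carrying a C-terminal protein-kinase domain, in the small case separated
from the thaumatin domain by a predicted transmembrane stretch).

Kinase domains are recognized by a self-contained three-anchor motif
heuristic (glycine-rich loop G-x-G-x-x-G, catalytic H-x-D, and D-x-G of the
activation segment, in order and within spacing windows) rather than a
profile HMM; the two catalytic aspartates are those of the H-x-D and D-x-G
anchors.  Transmembrane segments are called by the classic Kyte-Doolittle
sliding-window rule (window 19, mean hydropathy >= 1.6).

The module also scores conservation of the acidic-cleft REDDD residues
across an alignment, with charge-preserving equivalences ({R,K} and {D,E}),
and bins per-column residue diversity into four conservation levels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from tlpcensus.config import CensusConfig, ClassifyConfig
from tlpcensus.domain_scan import ThaumatinDomain, extract_domain
from tlpcensus.io_formats import GAP, Alignment, ProteinRecord

_STD = "ACDEFGHIKLMNPQRSTVWY"

_GLOOP = re.compile(rf"(?=(G[{_STD}]G[{_STD}]{{2}}G))")
_HXD = re.compile(rf"(?=(H[{_STD}]D))")
_DXG = re.compile(rf"(?=(D[{_STD}]G))")

#: Kyte-Doolittle hydropathy index; the ambiguity letter X is scored neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

REDDD_CANONICAL = "REDDD"
#: charge-preserving acceptable swaps per canonical residue
REDDD_EQUIVALENT = {"R": {"K"}, "E": {"D"}, "D": {"E"}}


@dataclass(frozen=True)
class KinaseRegion:
    """A putative protein-kinase domain located by the anchor-motif triad."""

    start: int
    end: int
    motif_positions: dict
    catalytic_asp_positions: tuple[int, int]


@dataclass(frozen=True)
class TMRegion:
    """A predicted transmembrane segment (maximal Kyte-Doolittle window)."""

    start: int
    end: int
    mean_hydropathy: float


@dataclass
class TLPClassification:
    """Architecture label plus the per-criterion evidence that produced it."""

    protein_id: str
    label: str  # typical | small | tlp_kinase | small_tlp_kinase | incomplete
    domain: ThaumatinDomain | None
    kinase_region: KinaseRegion | None = None
    tm_region: TMRegion | None = None
    evidence: dict = field(default_factory=dict)


@dataclass
class ReddddReport:
    """Conservation of the five acidic-cleft (REDDD) positions across an
    alignment, scored per sequence as identical / equivalent / divergent."""

    reference_id: str
    columns: tuple[int, ...]
    residues: dict[str, str]
    status: dict[str, tuple[str, ...]]
    summary: dict

    @property
    def n_fully_conserved(self) -> int:
        """Sequences where all five positions are identical or equivalent."""
        return self.summary["n_fully_conserved"]


def detect_kinase_domain(
    sequence: str, config: ClassifyConfig | None = None, offset: int = 0
) -> KinaseRegion | None:
    """Locate a kinase domain via its three ordered anchor motifs.

    The glycine loop, H-x-D and D-x-G anchors must occur in order with
    start-to-start spacings inside the configured windows, and the resulting
    region (anchored at the glycine loop, extended ``kinase_tail`` residues
    past D-x-G but clipped to the protein) must reach ``min_kinase_len``.
    Coordinates are reported shifted by ``offset`` (use it when scanning a
    downstream slice of the full protein).
    """
    config = config or ClassifyConfig()
    g_starts = [m.start() for m in _GLOOP.finditer(sequence)]
    h_starts = [m.start() for m in _HXD.finditer(sequence)]
    d_starts = [m.start() for m in _DXG.finditer(sequence)]
    lo1, hi1 = config.gloop_to_hxd
    lo2, hi2 = config.hxd_to_dxg
    for g in g_starts:
        for h in h_starts:
            if not (lo1 <= h - g <= hi1):
                continue
            for d in d_starts:
                if not (lo2 <= d - h <= hi2):
                    continue
                end = min(len(sequence), d + 3 + config.kinase_tail)
                if end - g < config.min_kinase_len:
                    continue
                return KinaseRegion(
                    start=g + offset,
                    end=end + offset,
                    motif_positions={
                        "glycine_loop": g + offset,
                        "catalytic_hxd": h + offset,
                        "activation_dxg": d + offset,
                    },
                    catalytic_asp_positions=(h + 2 + offset, d + offset),
                )
    return None


def detect_tm_segment(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    region: tuple[int, int] | None = None,
) -> TMRegion | None:
    """Return the maximal-scoring Kyte-Doolittle window if its mean
    hydropathy reaches ``threshold``; ``region`` restricts the search to a
    slice of the protein (e.g. between thaumatin and kinase domains)."""
    lo, hi = region if region is not None else (0, len(sequence))
    segment = sequence[lo:hi]
    if len(segment) < window:
        return None
    values = np.array([KYTE_DOOLITTLE[a] for a in segment])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    best = int(np.argmax(means))
    if means[best] < threshold:
        return None
    return TMRegion(
        start=lo + best, end=lo + best + window, mean_hydropathy=float(means[best])
    )


def classify_architecture(
    record: ProteinRecord, config: CensusConfig | None = None
) -> TLPClassification:
    """Assign one of typical / small / tlp_kinase / small_tlp_kinase /
    incomplete, with per-criterion evidence booleans."""
    config = config or CensusConfig()
    ccfg = config.classify
    domain = extract_domain(record, config.domain)
    evidence: dict = {"complete_domain": bool(domain and domain.complete)}
    if domain is None or not domain.complete:
        evidence["failure_reasons"] = list(domain.failure_reasons) if domain else [
            "no boundary motif found"
        ]
        return TLPClassification(record.id, "incomplete", domain, evidence=evidence)

    small_len = domain.length < ccfg.small_cutoff
    small_cys = ccfg.small_cys[0] <= domain.n_cysteines <= ccfg.small_cys[1]
    typical_cys = ccfg.typical_cys[0] <= domain.n_cysteines <= ccfg.typical_cys[1]
    is_small = small_len and small_cys
    evidence.update(
        small_domain_length=small_len,
        small_cys_band=small_cys,
        typical_cys_band=typical_cys,
    )

    kinase = detect_kinase_domain(record.sequence[domain.end :], ccfg, offset=domain.end)
    evidence["kinase_downstream"] = kinase is not None
    tm = None
    if kinase is not None:
        tm = detect_tm_segment(
            record.sequence,
            window=ccfg.tm_window,
            threshold=ccfg.tm_threshold,
            region=(domain.end, kinase.start),
        )
        evidence["tm_between_domains"] = tm is not None
        label = "small_tlp_kinase" if is_small else "tlp_kinase"
    elif is_small:
        label = "small"
    elif typical_cys:
        label = "typical"
    else:
        label = "typical"
        evidence["atypical_cysteine_count"] = True
    return TLPClassification(
        record.id, label, domain, kinase_region=kinase, tm_region=tm, evidence=evidence
    )


def reddd_score(
    alignment: Alignment,
    reference_id: str,
    reference_positions: tuple[int, int, int, int, int],
) -> ReddddReport:
    """Score conservation of the five acidic-cleft positions.

    ``reference_positions`` are 0-based *ungapped* positions on the reference
    sequence; they are mapped through the reference row's gap structure to
    alignment columns.  Every row is then scored per position as identical
    (the canonical R,E,D,D,D letter), equivalent (charge-preserving swap:
    K for R, D/E interchange) or divergent; a gap scores divergent.
    """
    if len(reference_positions) != 5:
        raise ValueError("exactly 5 reference positions are required")
    ref_row = alignment.row(reference_id)  # KeyError when absent
    ungapped_to_col = [j for j, c in enumerate(ref_row) if c != GAP]
    columns = []
    for pos in reference_positions:
        if not (0 <= pos < len(ungapped_to_col)):
            raise ValueError(
                f"reference position {pos} outside ungapped reference "
                f"(length {len(ungapped_to_col)})"
            )
        columns.append(ungapped_to_col[pos])

    residues: dict[str, str] = {}
    status: dict[str, tuple[str, ...]] = {}
    per_position = [dict(identical=0, equivalent=0, divergent=0) for _ in range(5)]
    n_full = 0
    for ident, row in zip(alignment.ids, alignment.rows):
        res = "".join(row[c] for c in columns)
        verdicts = []
        for k, (aa, canon) in enumerate(zip(res, REDDD_CANONICAL)):
            if aa == canon:
                v = "identical"
            elif aa in REDDD_EQUIVALENT.get(canon, ()):
                v = "equivalent"
            else:
                v = "divergent"
            per_position[k][v] += 1
            verdicts.append(v)
        residues[ident] = res
        status[ident] = tuple(verdicts)
        if all(v != "divergent" for v in verdicts):
            n_full += 1
    return ReddddReport(
        reference_id=reference_id,
        columns=tuple(columns),
        residues=residues,
        status=status,
        summary={
            "n_sequences": alignment.n_rows,
            "n_fully_conserved": n_full,
            "per_position": per_position,
        },
    )


def column_conservation(alignment: Alignment) -> np.ndarray:
    """Four-level per-column conservation code from residue variety.

    Level 1: one distinct non-gap residue; level 2: 2-3; level 3: 4-6;
    level 4: >= 7.  Gaps are ignored; an all-gap column scores level 1.
    """
    if alignment.n_rows == 0:
        raise ValueError("empty alignment")
    levels = np.empty(alignment.n_columns, dtype=int)
    for j in range(alignment.n_columns):
        k = len({r[j] for r in alignment.rows} - {GAP})
        if k <= 1:
            levels[j] = 1
        elif k <= 3:
            levels[j] = 2
        elif k <= 6:
            levels[j] = 3
        else:
            levels[j] = 4
    return levels
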