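"""Thaumatin-domain delimitation from its two boundary sequence motifs.

The thaumatin domain is delimited by an N-terminal ``N-x-C-x(3)-V/I-W``
motif (8 residues) and a C-terminal ``Y-x-I/V-x-F-C-x`` motif (7 residues).
The wildcard ``x`` matches any of the 20 standard amino acids but not the
ambiguity letter X: an unknown residue cannot certify a domain boundary.

A domain is *complete* when both motifs are found, its length lies within
configured bounds, and it contains at least a minimum number of cysteines;
incomplete domains carry the list of failed criteria so that census reports
can say why a gene model was excluded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from tlpcensus.config import DomainConfig
from tlpcensus.io_formats import ProteinRecord

_STD = "ACDEFGHIKLMNPQRSTVWY"

#: N-terminal boundary: N, x, C, x, x, x, V-or-I, W  (8 residues)
N_MOTIF_LEN = 8
#: C-terminal boundary: Y, x, I-or-V, x, F, C, x  (7 residues)
C_MOTIF_LEN = 7

_N_PATTERN = re.compile(rf"(?=(N[{_STD}]C[{_STD}]{{3}}[VI]W))")
_C_PATTERN = re.compile(rf"(?=(Y[{_STD}][IV][{_STD}]FC[{_STD}]))")


@dataclass(frozen=True)
class BoundaryMotifHit:
    """One match of a boundary motif on the protein (0-based half-open)."""

    kind: str  # "N-terminal" | "C-terminal"
    start: int
    end: int
    residues: str


@dataclass
class ThaumatinDomain:
    """A delimited thaumatin domain with its completeness verdict."""

    protein_id: str
    start: int
    end: int
    sequence: str
    n_cysteines: int
    has_n_motif: bool
    has_c_motif: bool
    coverage: float
    complete: bool = False
    failure_reasons: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_boundary_motifs(sequence: str) -> list[BoundaryMotifHit]:
    """Report every (possibly overlapping) boundary-motif match, sorted by
    position."""
    hits = [
        BoundaryMotifHit("N-terminal", m.start(), m.start() + N_MOTIF_LEN, m.group(1))
        for m in _N_PATTERN.finditer(sequence)
    ]
    hits += [
        BoundaryMotifHit("C-terminal", m.start(), m.start() + C_MOTIF_LEN, m.group(1))
        for m in _C_PATTERN.finditer(sequence)
    ]
    return sorted(hits, key=lambda h: (h.start, h.kind))


def _choose_pair(
    n_hits: list[BoundaryMotifHit],
    c_hits: list[BoundaryMotifHit],
    config: DomainConfig,
) -> tuple[BoundaryMotifHit, BoundaryMotifHit] | None:
    """Pick the (N, C) hit pair spanning the longest domain whose length is
    within bounds; ties go to the smallest start.  Falls back to the longest
    out-of-bounds pair so that validation can report the length failure."""
    pairs = [
        (n, c)
        for n in n_hits
        for c in c_hits
        if n.start < c.start and c.end > n.end
    ]
    if not pairs:
        return None
    in_bounds = [
        (n, c)
        for n, c in pairs
        if config.min_len <= c.end - n.start <= config.max_len
    ]
    pool = in_bounds if in_bounds else pairs
    return min(pool, key=lambda nc: (-(nc[1].end - nc[0].start), nc[0].start))


def extract_domain(
    record: ProteinRecord, config: DomainConfig | None = None
) -> ThaumatinDomain | None:
    """Delimit the thaumatin domain of ``record``.

    Returns ``None`` when neither boundary motif is found.  When only one
    boundary is found the domain extends to the corresponding protein end and
    is marked incomplete (missing motif); absence is a value, not an error.
    """
    config = config or DomainConfig()
    hits = scan_boundary_motifs(record.sequence)
    n_hits = [h for h in hits if h.kind == "N-terminal"]
    c_hits = [h for h in hits if h.kind == "C-terminal"]
    if not n_hits and not c_hits:
        return None

    pair = _choose_pair(n_hits, c_hits, config)
    if pair is not None:
        start, end = pair[0].start, pair[1].end
        has_n, has_c = True, True
    elif n_hits:
        start, end = n_hits[0].start, len(record.sequence)
        has_n, has_c = True, False
    else:
        start, end = 0, c_hits[-1].end
        has_n, has_c = False, True

    seq = record.sequence[start:end]
    domain = ThaumatinDomain(
        protein_id=record.id,
        start=start,
        end=end,
        sequence=seq,
        n_cysteines=seq.count("C"),
        has_n_motif=has_n,
        has_c_motif=has_c,
        coverage=len(seq) / len(record.sequence),
    )
    domain.complete, domain.failure_reasons = validate_complete(domain, config)
    return domain


def validate_complete(
    domain: ThaumatinDomain, config: DomainConfig | None = None
) -> tuple[bool, list[str]]:
    """Check a delimited domain against the completeness criteria.

    Complete iff both boundary motifs were found, the length lies in
    ``[min_len, max_len]`` and the cysteine count reaches ``min_cys``.
    The returned reasons enumerate *every* failed criterion.
    """
    config = config or DomainConfig()
    reasons: list[str] = []
    if not domain.has_n_motif:
        reasons.append("missing N-terminal motif")
    if not domain.has_c_motif:
        reasons.append("missing C-terminal motif")
    if not (config.min_len <= domain.length <= config.max_len):
        reasons.append(
            f"domain length {domain.length} outside [{config.min_len}, {config.max_len}]"
        )
    if domain.n_cysteines < config.min_cys:
        reasons.append(
            f"too few cysteines ({domain.n_cysteines} < {config.min_cys})"
        )
    return (not reasons, reasons)
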