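"""Run configuration: one dataclass per pipeline stage, loadable from YAML.

Every threshold that the census report depends on is exposed here so that a
run can record the exact parameter set it used (the pipeline writes the
resolved configuration next to its outputs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class DomainConfig:
    """Thaumatin-domain completeness thresholds.

    ``min_len``/``max_len`` bound the motif-delimited domain length in residues
    (120-330 admits small-TLP domains near 150 aa and long ascomycete domains
    near 280 aa while rejecting fragments); ``min_cys`` is the minimum cysteine
    count for a complete domain.
    """

    min_len: int = 120
    max_len: int = 330
    min_cys: int = 8


@dataclass
class ClassifyConfig:
    """Architecture-classification thresholds.

    ``small_cutoff`` splits the ~150 aa small-TLP domains from the ~215 aa
    typical ones at a gap midpoint.  The cysteine bands tolerate the 1-2
    residue deviations seen in divergent sequences instead of demanding exact
    16/10 counts.  Kinase detection is a three-anchor motif heuristic
    (glycine loop, HxD catalytic, DxG) with spacing windows in residues;
    transmembrane detection is a Kyte-Doolittle sliding window.
    """

    small_cutoff: int = 180
    typical_cys: tuple[int, int] = (14, 16)
    small_cys: tuple[int, int] = (9, 11)
    gloop_to_hxd: tuple[int, int] = (60, 140)
    hxd_to_dxg: tuple[int, int] = (15, 45)
    min_kinase_len: int = 200
    kinase_tail: int = 170
    tm_window: int = 19
    tm_threshold: float = 1.6


@dataclass
class PhyloConfig:
    bootstrap_reps: int = 1000
    seed: int | None = None


@dataclass
class ClusterConfig:
    gap_bp: int = 100_000
    min_size: int = 3
    require_family_only: bool = False


@dataclass
class CensusConfig:
    domain: DomainConfig = field(default_factory=DomainConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    pka_table: str = "emboss"
    # clade anchors: clade label -> list of leaf ids defining the clade
    clades: dict[str, list[str]] = field(default_factory=dict)
    # TE background fractions per class for enrichment ratios (user-supplied)
    te_background: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CensusConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CensusConfig":
        kwargs = {}
        for name, sub in (
            ("domain", DomainConfig),
            ("classify", ClassifyConfig),
            ("phylo", PhyloConfig),
            ("cluster", ClusterConfig),
        ):
            section = dict(raw.get(name, {}))
            for key in ("typical_cys", "small_cys", "gloop_to_hxd", "hxd_to_dxg"):
                if key in section:
                    section[key] = tuple(section[key])
            kwargs[name] = sub(**section)
        for key in ("pka_table", "clades", "te_background"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
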