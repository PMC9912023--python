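"""Threshold and run configuration.

Every numeric cutoff used anywhere in the pipeline lives in
:class:`ThresholdConfig`, so that a run is fully described by one object
and the serialized copy written next to the outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass(frozen=True)
class ThresholdConfig:
    """All filtering and selection thresholds.

    Attributes
    ----------
    min_quality:
        Minimum Phred base quality for a base call to count, both for
        conversion events and for pileup coverage (Q20 ~ 1% error).
    max_alt_frac:
        Positions where the non-reference fraction is *strictly greater*
        than this are blacklisted as putative SNPs.
    min_coverage:
        Positions with coverage *strictly below* this are blacklisted as
        too shallow to judge.
    k_sd_select:
        A gene is called highly labeled when its rate exceeds
        mean + k_sd_select * SD of all scored genes.
    k_sd_pca:
        Looser analogue used to restrict the PCA input matrix.
    sc_min_conversions:
        Distinct converted positions a molecule (UMI) must carry to be
        flagged labeled and removed.
    sc_min_units / sc_min_frac:
        Per-(gene, cell type) reporting filter: at least ``sc_min_units``
        units with at least ``sc_min_frac`` of them labeled.
    report_min_removed / report_min_frac:
        Removal-report filter: genes with at least ``report_min_removed``
        removed reads and removal fraction >= ``report_min_frac``.
    consensus_min_samples:
        Number of samples a gene must be selected in to enter the
        consensus set.
    """

    min_quality: int = 20
    max_alt_frac: float = 0.25
    min_coverage: int = 10
    k_sd_select: float = 5.0
    k_sd_pca: float = 1.0
    sc_min_conversions: int = 2
    sc_min_units: int = 250
    sc_min_frac: float = 0.10
    report_min_removed: int = 3
    report_min_frac: float = 0.05
    consensus_min_samples: int = 3

    def __post_init__(self) -> None:
        for name in ("max_alt_frac", "sc_min_frac", "report_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "min_quality",
            "min_coverage",
            "sc_min_conversions",
            "sc_min_units",
            "report_min_removed",
            "consensus_min_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kwargs) -> "ThresholdConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run.

    Precedence when building from a YAML file plus CLI flags is
    CLI > file > defaults; the resolved object is serialized into the
    output directory so a rerun reproduces the outputs bit for bit.
    """

    alignments: Optional[str] = None
    reference: Optional[str] = None
    annotation: Optional[str] = None
    celltype_map: Optional[str] = None
    output_dir: str = "dissoscan_out"
    rate_mode: str = "observation"  # or "site"
    genomic_only: bool = False
    keep_antisense: bool = False
    use_blacklist_sc: bool = False
    umi_conversion_mode: str = "union"  # or "any_read"
    summary_unit: str = "umi"  # or "read"
    tc_only_blacklist: bool = False
    on_missing_md: str = "skip"  # or "error"
    max_missing_md_frac: float = 0.5
    seed: int = 0
    log_level: str = "INFO"
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        if isinstance(thr, ThresholdConfig):
            cfg.thresholds = thr
        else:
            cfg.thresholds = ThresholdConfig.from_dict(thr or {})
        return cfg

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        thr = dict(d.pop("thresholds", {}) or {})
        thr.update(overrides.pop("thresholds", {}) or {})
        d.update({k: v for k, v in overrides.items() if v is not None})
        d["thresholds"] = thr
        return cls.from_dict(d)
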