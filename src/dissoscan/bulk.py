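"""Per-gene labeling rates and labeled-gene selection for bulk samples.

The labeling rate of a gene is the fraction of non-blacklisted
transcript-strand T positions showing quality-passing T-to-C
conversions. Two denominators are exposed: ``observation`` mode divides
converted base calls by all T base calls (coverage-weighted, the
standard SLAM-seq estimator) and ``site`` mode divides converted T sites
by covered T sites. Genes whose rate exceeds mean + k*SD of all scored
genes are called part of the dissociation response.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .blacklist import Blacklist, PositionPileup
from .conversion import ConversionEvent
from .reads import GeneModel

log = logging.getLogger(__name__)

RATE_MODES = ("observation", "site")


@dataclass
class GeneLabelingStats:
    """Labeling evidence for one gene in one bulk sample."""

    gene_id: str
    t_observations: int
    converted_observations: int
    t_sites: int
    converted_sites: int
    rate: Optional[float]
    read_count: int = 0

    def __post_init__(self):
        if self.converted_observations > self.t_observations:
            raise ValueError(f"{self.gene_id}: converted_observations > t_observations")
        if self.converted_sites > self.t_sites:
            raise ValueError(f"{self.gene_id}: converted_sites > t_sites")


def gene_labeling_rate(
    events: Iterable[ConversionEvent],
    pileup: PositionPileup,
    blacklist: Blacklist,
    gene_models: Sequence[GeneModel],
    mode: str = "observation",
    read_counts: Optional[Dict[str, int]] = None,
) -> List[GeneLabelingStats]:
    """Score every gene's labeling rate.

    Denominators come from the pileup (coverage at non-blacklisted
    transcript-strand T positions inside the gene extent), numerators
    from the quality-filtered conversion events; blacklisted positions
    contribute to neither. Genes with a zero denominator get a missing
    rate (``None``) and are excluded from downstream mean/SD statistics.
    The pileup must be built from the same gene-assigned reads that
    produced the events, or the conversion counts can exceed coverage.
    """
    if mode not in RATE_MODES:
        raise ValueError(f"mode must be one of {RATE_MODES}, got {mode!r}")

    conv_obs: Dict[str, int] = {}
    conv_sites: Dict[str, Set[int]] = {}
    for ev in events:
        if not ev.is_tc:
            continue
        if blacklist.contains(ev.contig, ev.genomic_pos):
            continue
        conv_obs[ev.gene_id] = conv_obs.get(ev.gene_id, 0) + 1
        conv_sites.setdefault(ev.gene_id, set()).add(ev.genomic_pos)

    out: List[GeneLabelingStats] = []
    for gene in gene_models:
        t_obs = t_sites = 0
        if gene.contig in pileup.contigs():
            ref = pileup.ref_array(gene.contig)[gene.start : gene.end]
            cov = pileup.coverage_array(gene.contig)[gene.start : gene.end]
            t_base = ord("T") if gene.strand == "+" else ord("A")
            clean = blacklist.clean_mask(gene.contig, len(pileup.ref_array(gene.contig)))
            tmask = (ref == t_base) & clean[gene.start : gene.end]
            t_obs = int(cov[tmask].sum())
            t_sites = int((cov[tmask] > 0).sum())
        c_obs = conv_obs.get(gene.gene_id, 0)
        c_sites = len(conv_sites.get(gene.gene_id, ()))
        if mode == "observation":
            rate = c_obs / t_obs if t_obs else None
        else:
            rate = c_sites / t_sites if t_sites else None
        out.append(
            GeneLabelingStats(
                gene_id=gene.gene_id,
                t_observations=t_obs,
                converted_observations=c_obs,
                t_sites=t_sites,
                converted_sites=c_sites,
                rate=rate,
                read_count=(read_counts or {}).get(gene.gene_id, 0),
            )
        )
    return out


@dataclass
class LabeledGeneSet:
    """Genes whose labeling rate exceeds mean + k*SD for one sample."""

    sample_id: str
    mean_rate: float
    sd_rate: float
    k: float
    genes: Set[str]

    @property
    def threshold(self) -> float:
        return self.mean_rate + self.k * self.sd_rate


def select_labeled_genes(
    stats: Sequence[GeneLabelingStats],
    k: float,
    sample_id: str = "sample",
) -> LabeledGeneSet:
    """Select genes with rate strictly above mean + k*SD.

    Mean and SD (n-1 sample estimator) are computed over all genes with
    a non-missing rate. When all rates are identical (SD = 0) the strict
    inequality leaves the selection empty.
    """
    rates = np.array([s.rate for s in stats if s.rate is not None], dtype=float)
    if rates.size < 2:
        raise ValueError("need >= 2 genes with non-missing rates")
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1))
    thr = mean + k * sd
    genes = {s.gene_id for s in stats if s.rate is not None and s.rate > thr}
    return LabeledGeneSet(sample_id=sample_id, mean_rate=mean, sd_rate=sd, k=k, genes=genes)


@dataclass
class SampleComparison:
    """Per-gene classification of two samples' labeled sets."""

    classification: Dict[str, str]  # gene -> high_in_A_only/high_in_B_only/high_in_both/background
    rates_a: Dict[str, Optional[float]]
    rates_b: Dict[str, Optional[float]]
    only_in_a: Set[str] = field(default_factory=set)  # genes absent from sample B
    only_in_b: Set[str] = field(default_factory=set)

    def genes_in_class(self, cls: str) -> Set[str]:
        return {g for g, c in self.classification.items() if c == cls}


def compare_samples(
    stats_a: Sequence[GeneLabelingStats],
    stats_b: Sequence[GeneLabelingStats],
    k: float,
) -> SampleComparison:
    """Classify genes by labeled-set membership in two samples.

    Genes present in only one sample's universe are reported separately
    (never silently dropped); disjoint gene universes are an error.
    """
    ids_a = {s.gene_id for s in stats_a}
    ids_b = {s.gene_id for s in stats_b}
    shared = ids_a & ids_b
    if not shared:
        raise ValueError("samples share no genes; comparison is undefined")
    set_a = select_labeled_genes(stats_a, k, "A").genes
    set_b = select_labeled_genes(stats_b, k, "B").genes
    rates_a = {s.gene_id: s.rate for s in stats_a}
    rates_b = {s.gene_id: s.rate for s in stats_b}
    classification = {}
    for g in shared:
        ina, inb = g in set_a, g in set_b
        if ina and inb:
            classification[g] = "high_in_both"
        elif ina:
            classification[g] = "high_in_A_only"
        elif inb:
            classification[g] = "high_in_B_only"
        else:
            classification[g] = "background"
    return SampleComparison(
        classification=classification,
        rates_a=rates_a,
        rates_b=rates_b,
        only_in_a=ids_a - ids_b,
        only_in_b=ids_b - ids_a,
    )


def consensus_genes(samples: Sequence[LabeledGeneSet], min_samples: int) -> Set[str]:
    """Genes selected in at least ``min_samples`` of the given samples."""
    if min_samples > len(samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({len(samples)})"
        )
    tally: Dict[str, int] = {}
    for s in samples:
        for g in s.genes:
            tally[g] = tally.get(g, 0) + 1
    return {g for g, n in tally.items() if n >= min_samples}


def pca_input_matrix(
    stats_per_sample: Sequence[Sequence[GeneLabelingStats]],
    k: float,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Genes x samples rate matrix restricted to informative genes.

    A gene enters the matrix when it has a non-missing rate in *every*
    sample and a rate strictly above mean + k*SD in at least one sample.
    The PCA itself is performed externally on the written matrix.
    """
    if len(stats_per_sample) < 2:
        raise ValueError("need >= 2 samples")
    if sample_ids is None:
        sample_ids = [f"sample{i + 1}" for i in range(len(stats_per_sample))]
    thresholds = [select_labeled_genes(s, k, sid).threshold
                  for s, sid in zip(stats_per_sample, sample_ids)]
    rate_maps = [{s.gene_id: s.rate for s in stats} for stats in stats_per_sample]
    universe = set(rate_maps[0])
    for m in rate_maps[1:]:
        universe &= set(m)
    rows = []
    for g in sorted(universe):
        rates = [m[g] for m in rate_maps]
        if any(r is None for r in rates):
            continue
        if any(r > thr for r, thr in zip(rates, thresholds)):
            rows.append([g] + rates)
    if not rows:
        log.warning("no gene passed the PCA input filter; matrix is empty")
        return pd.DataFrame(columns=list(sample_ids), index=pd.Index([], name="gene_id"))
    df = pd.DataFrame(rows, columns=["gene_id"] + list(sample_ids)).set_index("gene_id")
    return df


def stats_to_frame(
    stats: Sequence[GeneLabelingStats], selected: Optional[Set[str]] = None
) -> pd.DataFrame:
    """Tabular view of per-gene stats for TSV output."""
    rows = []
    for s in stats:
        rows.append(
            {
                "gene_id": s.gene_id,
                "t_observations": s.t_observations,
                "converted_observations": s.converted_observations,
                "t_sites": s.t_sites,
                "converted_sites": s.converted_sites,
                "rate": math.nan if s.rate is None else s.rate,
                "read_count": s.read_count,
                "selected": bool(selected and s.gene_id in selected),
            }
        )
    return pd.DataFrame(rows)


def stats_from_frame(df: pd.DataFrame) -> List[GeneLabelingStats]:
    out = []
    for row in df.itertuples(index=False):
        rate = None if pd.isna(row.rate) else float(row.rate)
        out.append(
            GeneLabelingStats(
                gene_id=str(row.gene_id),
                t_observations=int(row.t_observations),
                converted_observations=int(row.converted_observations),
                t_sites=int(row.t_sites),
                converted_sites=int(row.converted_sites),
                rate=rate,
                read_count=int(getattr(row, "read_count", 0)),
            )
        )
    return out
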