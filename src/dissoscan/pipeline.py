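"""End-to-end bulk and single-cell runs.

Each run streams alignments once, building the pileup and conversion
events together, then applies blacklisting, rate computation and
selection (bulk) or UMI grouping and matrix regeneration (single-cell).
Every output directory receives the resolved configuration, the tool
version and a JSON summary with counts at every filter stage, so reruns
are reproducible and discard paths auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .blacklist import Blacklist, PositionPileup, build_blacklist, build_pileup
from .bulk import (
    GeneLabelingStats,
    LabeledGeneSet,
    gene_labeling_rate,
    select_labeled_genes,
    stats_to_frame,
)
from .config import RunConfig, ThresholdConfig
from .conversion import (
    SUBSTITUTION_TYPES,
    ConversionEvent,
    SubstitutionTable,
    call_conversions,
    extract_mismatches,
)
from .reads import (
    AMBIGUOUS,
    AlignedRead,
    GeneIndex,
    ReferenceGenome,
    iter_alignments,
    read_gtf,
)
from .singlecell import (
    CellCountMatrix,
    GroupingDiagnostics,
    RemovalReport,
    UMIRecord,
    celltype_gene_labeling_summary,
    gradual_removal,
    group_umis,
    per_cell_labeled_gene_fraction,
    regenerate_count_matrix,
    removal_report,
)

log = logging.getLogger(__name__)

_BASE_ROW = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_ROW[_b] = _i


class PipelineError(RuntimeError):
    """Unrecoverable pipeline condition with a one-line diagnostic."""


def spectrum_from_pileup(pileup: PositionPileup, blacklist: Optional[Blacklist]) -> SubstitutionTable:
    """Substitution spectrum computed directly from pileup counts.

    The pileup already applies the quality filter, so the C count at a
    reference-T position *is* the T-to-C event count and the coverage is
    the observation count. Equivalent to
    :func:`dissoscan.conversion.substitution_spectrum` over the same
    reads (tested as a dual-route invariant), but vectorized.
    """
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    observations = {b: 0 for b in "ACGT"}
    for contig in pileup.contigs():
        arr = pileup.counts_array(contig)
        ref = pileup.ref_array(contig)
        clean = (
            blacklist.clean_mask(contig, arr.shape[1])
            if blacklist is not None
            else np.ones(arr.shape[1], dtype=bool)
        )
        for ri, rbase in enumerate("ACGT"):
            cols = (ref == ord(rbase)) & clean
            if not cols.any():
                continue
            sub = arr[:, cols]
            observations[rbase] += int(sub.sum())
            for ai, abase in enumerate("ACGT"):
                if ai != ri:
                    counts[(rbase, abase)] += int(sub[ai].sum())
    return SubstitutionTable(counts=counts, observations=observations)


def events_to_frame(events: Sequence[ConversionEvent]) -> pd.DataFrame:
    """Per-event table; positions are 1-based at this text boundary."""
    return pd.DataFrame(
        [
            {
                "contig": e.contig,
                "pos": e.genomic_pos + 1,
                "ref": e.ref_base,
                "alt": e.read_base,
                "quality": e.base_quality,
                "read_id": e.read_id,
                "gene_id": e.gene_id,
                "is_tc": e.is_tc,
            }
            for e in events
        ],
        columns=["contig", "pos", "ref", "alt", "quality", "read_id", "gene_id", "is_tc"],
    )


def _handle_md(read: AlignedRead, cfg: RunConfig, counters: Dict[str, int]) -> bool:
    """True when the read can be used; updates the missing-MD counter."""
    if read.md_tag is not None:
        return True
    if cfg.on_missing_md == "error":
        raise PipelineError(f"read {read.read_id} has no MD tag (strict mode)")
    counters["n_missing_md"] += 1
    return False


@dataclass
class BulkRunResult:
    config: RunConfig
    stats: List[GeneLabelingStats]
    selected: Optional[LabeledGeneSet]
    blacklist: Blacklist
    pileup: PositionPileup
    spectrum: SubstitutionTable
    events: List[ConversionEvent]
    summary: Dict[str, int]


def run_bulk(cfg: RunConfig, write: bool = True) -> BulkRunResult:
    """Pileup -> blacklist -> conversion calling -> rates -> selection.

    Reads are assigned to genes by overlap; reads overlapping no gene,
    more than one gene, or aligned antisense to their gene are discarded
    (and counted). The pileup is built from exactly the reads that feed
    the rate computation, so the blacklist judges the same evidence.
    """
    thr = cfg.thresholds
    reference = ReferenceGenome(cfg.reference)
    genes = read_gtf(cfg.annotation)
    index = GeneIndex(genes)
    pileup = PositionPileup(thr.min_quality)
    events: List[ConversionEvent] = []
    read_counts: Dict[str, int] = {}
    counters = {
        "n_reads": 0,
        "n_missing_md": 0,
        "n_unassigned": 0,
        "n_ambiguous_gene": 0,
        "n_antisense": 0,
        "n_reads_used": 0,
        "n_events_prefilter": 0,
        "n_events_q20": 0,
    }
    for read in iter_alignments(cfg.alignments):
        counters["n_reads"] += 1
        if not _handle_md(read, cfg, counters):
            continue
        gene_id = index.assign(read)
        if gene_id is None:
            counters["n_unassigned"] += 1
            continue
        if gene_id is AMBIGUOUS or gene_id == AMBIGUOUS:
            counters["n_ambiguous_gene"] += 1
            continue
        gene = index.by_id[gene_id]
        if not cfg.keep_antisense and read.is_reverse != (gene.strand == "-"):
            counters["n_antisense"] += 1
            continue
        counters["n_reads_used"] += 1
        read_counts[gene_id] = read_counts.get(gene_id, 0) + 1
        pileup.add_read(read, reference)
        mism = extract_mismatches(read)
        counters["n_events_prefilter"] += len(mism)
        evs = call_conversions(
            mism, gene_id, gene.strand, thr.min_quality, genomic_only=cfg.genomic_only
        )
        counters["n_events_q20"] += len(evs)
        events.extend(evs)

    if counters["n_reads"]:
        md_frac = counters["n_missing_md"] / counters["n_reads"]
        if md_frac > cfg.max_missing_md_frac:
            raise PipelineError(
                f"{md_frac:.1%} of reads lack MD tags "
                f"(limit {cfg.max_missing_md_frac:.1%}); run samtools calmd first"
            )
    else:
        log.warning("no reads in input; writing empty outputs")

    blk = build_blacklist(pileup, thr, tc_only=cfg.tc_only_blacklist)
    spectrum = spectrum_from_pileup(pileup, blk)
    stats = gene_labeling_rate(
        events, pileup, blk, genes, mode=cfg.rate_mode, read_counts=read_counts
    )
    n_scored = sum(1 for s in stats if s.rate is not None)
    selected: Optional[LabeledGeneSet] = None
    if n_scored >= 2:
        selected = select_labeled_genes(stats, thr.k_sd_select, sample_id=cfg.output_dir)
    else:
        log.warning("fewer than 2 genes with non-missing rates; selection skipped")
    summary = dict(counters)
    summary.update(
        n_tc_events=sum(1 for e in events if e.is_tc),
        n_blacklisted_positions=len(blk),
        n_genes=len(genes),
        n_genes_scored=n_scored,
        n_genes_selected=len(selected.genes) if selected else 0,
    )

    result = BulkRunResult(cfg, stats, selected, blk, pileup, spectrum, events, summary)
    if write:
        _write_bulk(result)
    return result


def _write_bulk(res: BulkRunResult) -> None:
    out = Path(res.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_to_frame(res.events).to_csv(out / "events.tsv", sep="\t", index=False)
    pd.DataFrame(res.spectrum.as_rows()).to_csv(out / "spectrum.tsv", sep="\t", index=False)
    res.blacklist.to_bed(out / "blacklist.bed")
    res.blacklist.to_tsv(out / "blacklist.tsv")
    selected_genes = res.selected.genes if res.selected else set()
    stats_to_frame(res.stats, selected_genes).to_csv(out / "gene_stats.tsv", sep="\t", index=False)
    (out / "labeled_genes.txt").write_text("".join(f"{g}\n" for g in sorted(selected_genes)))
    if res.selected:
        sel_meta = {
            "sample_id": res.selected.sample_id,
            "mean_rate": res.selected.mean_rate,
            "sd_rate": res.selected.sd_rate,
            "k": res.selected.k,
            "threshold": res.selected.threshold,
        }
        (out / "selection.json").write_text(json.dumps(sel_meta, indent=2, sort_keys=True) + "\n")
    _write_run_metadata(out, res.config, res.summary)


def _write_run_metadata(out: Path, cfg: RunConfig, summary: Dict) -> None:
    cfg.to_yaml(out / "config.yaml")
    payload = {"version": __version__, "seed": cfg.seed, **summary}
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_celltype_map(path) -> Dict[str, str]:
    """Barcode -> cell-type TSV (two columns, optional header)."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0] in ("barcode", "cell_barcode"):
                continue
            mapping[parts[0]] = parts[1]
    return mapping


@dataclass
class ScRunResult:
    config: RunConfig
    umis: List[UMIRecord]
    diagnostics: GroupingDiagnostics
    raw: CellCountMatrix
    corrected: CellCountMatrix
    removed: pd.DataFrame
    per_cell: pd.Series
    celltype_summary: Optional[pd.DataFrame]
    report: Optional[RemovalReport]
    gradual: Optional[List[CellCountMatrix]]
    summary: Dict[str, int]


def run_sc(
    cfg: RunConfig,
    fractions: Optional[Sequence[float]] = None,
    write: bool = True,
) -> ScRunResult:
    """Conversion calling -> UMI grouping -> corrected matrices -> reports.

    Requires CB/UB/GX tags on a nonzero fraction of reads. When a
    cell-type map is configured, per-(gene, cell type) labeling and
    removal reports are produced; when ``fractions`` is given, matrices
    with those fractions of labeled UMIs removed are emitted as well.
    """
    thr = cfg.thresholds
    reference = ReferenceGenome(cfg.reference)
    genes = read_gtf(cfg.annotation)
    index = GeneIndex(genes)
    counters = {
        "n_reads": 0,
        "n_missing_md": 0,
        "n_untagged": 0,
        "n_unknown_gene": 0,
        "n_antisense": 0,
        "n_reads_used": 0,
        "n_events_prefilter": 0,
        "n_events_q20": 0,
    }
    tagged_reads: List[Tuple[str, str, str, str]] = []
    events: List[ConversionEvent] = []
    read_t_positions: Dict[str, np.ndarray] = {}
    pileup_reads: List[AlignedRead] = []

    for read in iter_alignments(cfg.alignments):
        counters["n_reads"] += 1
        if not _handle_md(read, cfg, counters):
            continue
        if not (read.cell_barcode and read.umi and read.gene_id):
            counters["n_untagged"] += 1
            continue
        if read.gene_id not in index.by_id:
            counters["n_unknown_gene"] += 1
            continue
        gene = index.by_id[read.gene_id]
        if not cfg.keep_antisense and read.is_reverse != (gene.strand == "-"):
            counters["n_antisense"] += 1
            continue
        counters["n_reads_used"] += 1
        tagged_reads.append((read.read_id, read.cell_barcode, read.umi, read.gene_id))
        mism = extract_mismatches(read)
        counters["n_events_prefilter"] += len(mism)
        evs = call_conversions(
            mism, read.gene_id, gene.strand, thr.min_quality, genomic_only=cfg.genomic_only
        )
        counters["n_events_q20"] += len(evs)
        events.extend(e for e in evs if e.is_tc)
        read_t_positions[read.read_id] = _covered_t_positions(
            read, reference, gene.strand, thr.min_quality
        )
        if cfg.use_blacklist_sc:
            pileup_reads.append(read)

    if counters["n_reads"] and not tagged_reads:
        raise PipelineError("no reads carry CB/UB/GX tags; is this single-cell data?")
    if not counters["n_reads"]:
        log.warning("no reads in input; writing empty outputs")

    blk = None
    if cfg.use_blacklist_sc:
        blk = build_blacklist(build_pileup(pileup_reads, reference, thr.min_quality), thr)

    umis, diag = group_umis(
        tagged_reads,
        events,
        thr,
        blacklist=blk,
        conversion_mode=cfg.umi_conversion_mode,
        read_t_positions=read_t_positions,
    )
    raw, _ = regenerate_count_matrix(umis, remove_labeled=False)
    corrected, removed = regenerate_count_matrix(umis, remove_labeled=True)
    per_cell = per_cell_labeled_gene_fraction(umis, min_events=1)

    ct_summary = None
    report = None
    if cfg.celltype_map:
        ct_map = read_celltype_map(cfg.celltype_map)
        ct_summary = celltype_gene_labeling_summary(umis, ct_map, thr, unit=cfg.summary_unit)
        report = removal_report(raw, corrected, umis, ct_map, thr)

    gradual = None
    if fractions is not None:
        gradual = gradual_removal(umis, fractions, cfg.seed)

    summary = dict(counters)
    summary.update(
        n_umis=len(umis),
        n_umis_labeled=sum(1 for u in umis if u.labeled),
        n_multi_gene_umis=diag.n_multi_gene_umis,
        n_cells=len(raw.barcodes),
        n_genes=len(raw.gene_ids),
        raw_total=raw.total(),
        corrected_total=corrected.total(),
    )

    result = ScRunResult(
        cfg, umis, diag, raw, corrected, removed, per_cell, ct_summary, report,
        gradual, summary,
    )
    if write:
        _write_sc(result, fractions)
    return result


def _covered_t_positions(
    read: AlignedRead, reference: ReferenceGenome, strand: str, min_quality: int
) -> np.ndarray:
    """Quality-passing transcript-strand T sites covered by the read."""
    ref = reference.contig_array(read.contig)
    tbase = ord("T") if strand == "+" else ord("A")
    quals = np.asarray(read.base_qualities)
    out = []
    for roff, rpos, n in read.aligned_blocks():
        ok = (ref[rpos : rpos + n] == tbase) & (quals[roff : roff + n] >= min_quality)
        out.append(rpos + np.nonzero(ok)[0])
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def umis_to_frame(umis: Sequence[UMIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_barcode": u.cell_barcode,
                "umi": u.umi,
                "gene_id": u.gene_id,
                "read_count": u.read_count,
                "conversion_count": u.conversion_count,
                "labeled": u.labeled,
            }
            for u in umis
        ],
        columns=["cell_barcode", "umi", "gene_id", "read_count", "conversion_count", "labeled"],
    )


def _write_sc(res: ScRunResult, fractions: Optional[Sequence[float]]) -> None:
    out = Path(res.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.raw.write_10x(out / "raw")
    res.corrected.write_10x(out / "corrected")
    res.removed.to_csv(out / "removed_umis.tsv", sep="\t", index=False)
    umis_to_frame(res.umis).to_csv(out / "umis.tsv", sep="\t", index=False)
    res.per_cell.rename_axis("cell_barcode").reset_index().to_csv(
        out / "per_cell_labeled_gene_pct.tsv", sep="\t", index=False
    )
    if res.celltype_summary is not None:
        res.celltype_summary.to_csv(out / "celltype_gene_summary.tsv", sep="\t", index=False)
    if res.report is not None:
        res.report.per_gene_celltype.to_csv(out / "removal_report.tsv", sep="\t", index=False)
        res.report.removed_gene_rates.to_csv(
            out / "removed_gene_rates.tsv", sep="\t", index=False
        )
    if res.gradual is not None and fractions is not None:
        for f, m in zip(fractions, res.gradual):
            m.write_10x(out / f"gradual_{f:g}")
    _write_run_metadata(out, res.config, res.summary)
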