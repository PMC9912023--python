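"""Labeled-UMI removal and corrected count matrices for single-cell data.

Reads carrying corrected cell barcode (CB), UMI (UB) and gene (GX) tags
are grouped into molecules; a molecule is flagged labeled when it shows
at least ``sc_min_conversions`` distinct converted positions across its
supporting reads. Corrected matrices omit labeled molecules only — no
gene is ever dropped wholesale — so downstream clustering sees the same
gene universe minus the dissociation-induced transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import ThresholdConfig
from .conversion import ConversionEvent

log = logging.getLogger(__name__)

UNKNOWN_CELL_TYPE = "unknown"


@dataclass
class UMIRecord:
    """One (cell barcode, UMI, gene) molecule and its conversion evidence."""

    cell_barcode: str
    umi: str
    gene_id: str
    read_ids: List[str]
    conversion_positions: Set[int]
    labeled: bool
    max_single_read_conversions: int = 0
    t_positions: Optional[Set[int]] = None  # covered transcript-strand T sites

    @property
    def read_count(self) -> int:
        return len(self.read_ids)

    @property
    def conversion_count(self) -> int:
        return len(self.conversion_positions)

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.cell_barcode, self.umi, self.gene_id)


@dataclass
class GroupingDiagnostics:
    n_reads: int = 0
    n_missing_tags: int = 0
    n_multi_gene_umis: int = 0  # same (cell, umi) seen with >1 gene


def group_umis(
    reads,
    events: Iterable[ConversionEvent],
    config: ThresholdConfig,
    blacklist=None,
    conversion_mode: str = "union",
    read_t_positions: Optional[Mapping[str, Iterable[int]]] = None,
) -> Tuple[List[UMIRecord], GroupingDiagnostics]:
    """Group tagged reads into molecules and flag labeled ones.

    ``reads`` may be AlignedRead objects or plain (read_id, cb, umi,
    gene) tuples. Conversion positions of a molecule are the union of
    quality-passing T-to-C positions over its supporting reads; with
    ``conversion_mode='any_read'`` the labeled flag instead requires a
    single read to carry the threshold number of distinct conversions.
    A (cell, umi) pair assigned to two genes stays two records (matching
    upstream tag semantics) and is counted in the diagnostics. Reads
    lacking any tag are counted and skipped. An optional blacklist drops
    conversion positions before counting.
    """
    if conversion_mode not in ("union", "any_read"):
        raise ValueError(f"unknown conversion_mode {conversion_mode!r}")

    tc_by_read: Dict[str, Set[int]] = {}
    for ev in events:
        if not ev.is_tc:
            continue
        if blacklist is not None and blacklist.contains(ev.contig, ev.genomic_pos):
            continue
        tc_by_read.setdefault(ev.read_id, set()).add(ev.genomic_pos)

    diag = GroupingDiagnostics()
    records: Dict[Tuple[str, str, str], UMIRecord] = {}
    genes_per_cell_umi: Dict[Tuple[str, str], Set[str]] = {}
    for read in reads:
        if isinstance(read, tuple):
            read_id, cb, umi, gene = read
        else:
            read_id, cb, umi, gene = read.read_id, read.cell_barcode, read.umi, read.gene_id
        diag.n_reads += 1
        if not (cb and umi and gene):
            diag.n_missing_tags += 1
            continue
        key = (cb, umi, gene)
        rec = records.get(key)
        if rec is None:
            rec = UMIRecord(cb, umi, gene, [], set(), False)
            records[key] = rec
            genes_per_cell_umi.setdefault((cb, umi), set()).add(gene)
        rec.read_ids.append(read_id)
        conv = tc_by_read.get(read_id)
        if conv:
            rec.conversion_positions |= conv
            rec.max_single_read_conversions = max(rec.max_single_read_conversions, len(conv))
        if read_t_positions is not None:
            tp = read_t_positions.get(read_id)
            if tp is not None:
                if rec.t_positions is None:
                    rec.t_positions = set()
                rec.t_positions.update(tp)

    diag.n_multi_gene_umis = sum(1 for v in genes_per_cell_umi.values() if len(v) > 1)
    if diag.n_multi_gene_umis:
        log.info("%d (cell, UMI) pairs assigned to more than one gene", diag.n_multi_gene_umis)

    out = sorted(records.values(), key=lambda r: r.key)
    for rec in out:
        n = rec.conversion_count if conversion_mode == "union" else rec.max_single_read_conversions
        rec.labeled = n >= config.sc_min_conversions
    return out, diag


@dataclass
class CellCountMatrix:
    """Genes x cells matrix of UMI counts (CSR, integer)."""

    gene_ids: List[str]
    barcodes: List[str]
    matrix: sp.csr_matrix
    variant: str = "raw"

    def total(self) -> int:
        return int(self.matrix.sum())

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def write_10x(self, outdir) -> None:
        """10x-style triplet: matrix.mtx, features.tsv, barcodes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.matrix))
        (outdir / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in self.gene_ids)
        )
        (outdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in self.barcodes))

    @classmethod
    def read_10x(cls, outdir, variant: str = "raw") -> "CellCountMatrix":
        outdir = Path(outdir)
        m = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")))
        genes = [l.split("\t")[0] for l in (outdir / "features.tsv").read_text().splitlines()]
        barcodes = (outdir / "barcodes.tsv").read_text().splitlines()
        return cls(genes, barcodes, m, variant)


def _axes(umis: Sequence[UMIRecord]) -> Tuple[List[str], List[str]]:
    genes = sorted({u.gene_id for u in umis})
    cells = sorted({u.cell_barcode for u in umis})
    return genes, cells


def _count(umis: Iterable[UMIRecord], genes: List[str], cells: List[str]) -> sp.csr_matrix:
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: i for i, c in enumerate(cells)}
    rows, cols = [], []
    for u in umis:
        rows.append(gi[u.gene_id])
        cols.append(ci[u.cell_barcode])
    data = np.ones(len(rows), dtype=np.int32)
    return sp.csr_matrix(
        sp.coo_matrix((data, (rows, cols)), shape=(len(genes), len(cells)), dtype=np.int32)
    )


def regenerate_count_matrix(
    umis: Sequence[UMIRecord],
    remove_labeled: bool = True,
) -> Tuple[CellCountMatrix, pd.DataFrame]:
    """Build a count matrix from molecules, optionally dropping labeled ones.

    Returns the matrix and the audit table of removed molecules (empty
    when ``remove_labeled`` is false). Gene and cell axes always cover
    every input molecule, so raw and corrected matrices share shapes and
    satisfy raw = corrected + removed entry-wise.
    """
    genes, cells = _axes(umis)
    kept = [u for u in umis if not (remove_labeled and u.labeled)]
    removed = [u for u in umis if remove_labeled and u.labeled]
    matrix = _count(kept, genes, cells)
    removed_df = pd.DataFrame(
        [
            {
                "cell_barcode": u.cell_barcode,
                "umi": u.umi,
                "gene_id": u.gene_id,
                "read_count": u.read_count,
                "conversion_count": u.conversion_count,
                "conversion_positions": ",".join(map(str, sorted(u.conversion_positions))),
            }
            for u in removed
        ],
        columns=[
            "cell_barcode",
            "umi",
            "gene_id",
            "read_count",
            "conversion_count",
            "conversion_positions",
        ],
    )
    variant = "corrected" if remove_labeled else "raw"
    return CellCountMatrix(genes, cells, matrix, variant), removed_df


def per_cell_labeled_gene_fraction(
    umis: Sequence[UMIRecord], min_events: int = 1
) -> pd.Series:
    """Percentage of each cell's detected genes with a labeled molecule.

    A gene counts for a cell when at least one of its molecules in that
    cell carries >= ``min_events`` distinct conversions; the denominator
    is the number of genes with >= 1 molecule in the cell.
    """
    detected: Dict[str, Set[str]] = {}
    labeled: Dict[str, Set[str]] = {}
    for u in umis:
        detected.setdefault(u.cell_barcode, set()).add(u.gene_id)
        if u.conversion_count >= min_events:
            labeled.setdefault(u.cell_barcode, set()).add(u.gene_id)
    values = {}
    for cell, genes in detected.items():
        if not genes:  # unreachable from UMIRecords; kept for the contract
            log.warning("cell %s has zero detected genes; excluded", cell)
            continue
        values[cell] = 100.0 * len(labeled.get(cell, ())) / len(genes)
    return pd.Series(values, name="pct_labeled_genes").sort_index()


def celltype_gene_labeling_summary(
    umis: Sequence[UMIRecord],
    celltype_map: Mapping[str, str],
    config: ThresholdConfig,
    unit: str = "umi",
) -> pd.DataFrame:
    """Per (gene, cell type) labeling summary for heatmap-style reporting.

    ``unit`` is the molecule (UMI, default) or the read. A gene passes
    the filter when, in at least one cell type, it has at least
    ``sc_min_units`` units of which at least ``sc_min_frac`` are
    labeled; the flag is broadcast to all rows of the gene.
    Barcodes missing from the map fall into the "unknown" type.
    """
    if unit not in ("umi", "read"):
        raise ValueError(f"unit must be 'umi' or 'read', got {unit!r}")
    totals: Dict[Tuple[str, str], int] = {}
    labeled: Dict[Tuple[str, str], int] = {}
    for u in umis:
        ct = celltype_map.get(u.cell_barcode, UNKNOWN_CELL_TYPE)
        w = 1 if unit == "umi" else u.read_count
        key = (u.gene_id, ct)
        totals[key] = totals.get(key, 0) + w
        if u.labeled:
            labeled[key] = labeled.get(key, 0) + w
    rows = []
    for (gene, ct), tot in sorted(totals.items()):
        lab = labeled.get((gene, ct), 0)
        rows.append(
            {
                "gene_id": gene,
                "cell_type": ct,
                "units_total": tot,
                "units_labeled": lab,
                "fraction": lab / tot if tot else float("nan"),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "cell_type", "units_total", "units_labeled", "fraction"]
    )
    if df.empty:
        df["passes_filter"] = pd.Series(dtype=bool)
        return df
    ok = (df["units_total"] >= config.sc_min_units) & (df["fraction"] >= config.sc_min_frac)
    passing_genes = set(df.loc[ok, "gene_id"])
    df["passes_filter"] = df["gene_id"].isin(passing_genes)
    return df


@dataclass
class RemovalReport:
    """Removal statistics per (gene, cell type) plus per-gene rates."""

    per_gene_celltype: pd.DataFrame  # gene_id, cell_type, reads_total, reads_removed, removal_fraction, listed
    removed_gene_rates: pd.DataFrame  # gene_id, removed_t_sites, removed_converted_sites, removed_rate


def removal_report(
    raw: CellCountMatrix,
    corrected: CellCountMatrix,
    umis: Sequence[UMIRecord],
    celltype_map: Mapping[str, str],
    config: ThresholdConfig,
) -> RemovalReport:
    """Report read-removal fractions per gene and cell type.

    A gene/cell-type pair is *listed* when at least
    ``report_min_removed`` reads were removed and the removal fraction
    is at least ``report_min_frac``. The labeling rate within removed
    molecules uses the bulk site-mode formula restricted to removed
    reads: distinct converted T sites over distinct covered T sites
    (the latter requires molecules grouped with T-position tracking).
    Raw and corrected totals are checked for conservation.
    """
    if raw.total() != corrected.total() + sum(1 for u in umis if u.labeled):
        raise ValueError("raw != corrected + removed; matrices and molecules disagree")
    totals: Dict[Tuple[str, str], int] = {}
    removed: Dict[Tuple[str, str], int] = {}
    conv_sites: Dict[str, Set[int]] = {}
    t_sites: Dict[str, Set[int]] = {}
    for u in umis:
        ct = celltype_map.get(u.cell_barcode, UNKNOWN_CELL_TYPE)
        key = (u.gene_id, ct)
        totals[key] = totals.get(key, 0) + u.read_count
        if u.labeled:
            removed[key] = removed.get(key, 0) + u.read_count
            conv_sites.setdefault(u.gene_id, set()).update(u.conversion_positions)
            if u.t_positions is not None:
                t_sites.setdefault(u.gene_id, set()).update(u.t_positions)
    rows = []
    for (gene, ct), tot in sorted(totals.items()):
        rem = removed.get((gene, ct), 0)
        frac = rem / tot if tot else float("nan")
        rows.append(
            {
                "gene_id": gene,
                "cell_type": ct,
                "reads_total": tot,
                "reads_removed": rem,
                "removal_fraction": frac,
                "listed": rem >= config.report_min_removed and frac >= config.report_min_frac,
            }
        )
    per_gc = pd.DataFrame(
        rows,
        columns=["gene_id", "cell_type", "reads_total", "reads_removed",
                 "removal_fraction", "listed"],
    )
    rate_rows = []
    for gene in sorted(conv_sites):
        ts = t_sites.get(gene)
        cs = conv_sites[gene]
        denom = len(ts) if ts else 0
        rate_rows.append(
            {
                "gene_id": gene,
                "removed_t_sites": denom,
                "removed_converted_sites": len(cs),
                "removed_rate": len(cs) / denom if denom else float("nan"),
            }
        )
    rates = pd.DataFrame(
        rate_rows,
        columns=["gene_id", "removed_t_sites", "removed_converted_sites", "removed_rate"],
    )
    return RemovalReport(per_gene_celltype=per_gc, removed_gene_rates=rates)


def gradual_removal(
    umis: Sequence[UMIRecord],
    fractions: Sequence[float],
    seed: int,
) -> List[CellCountMatrix]:
    """Remove random subsets of the labeled molecules at given fractions.

    For each fraction f, a uniformly random subset of round(f * n)
    labeled molecules (half-up rounding) is removed; the subsets are
    nested and fully determined by the seed, so f=0 reproduces the raw
    matrix and f=1 the corrected one.
    """
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
    genes, cells = _axes(umis)
    labeled = [u for u in umis if u.labeled]
    order = np.random.default_rng(seed).permutation(len(labeled))
    out = []
    for f in fractions:
        k = int(np.floor(f * len(labeled) + 0.5))
        drop = {labeled[i].key for i in order[:k]}
        kept = [u for u in umis if u.key not in drop]
        out.append(
            CellCountMatrix(genes, cells, _count(kept, genes, cells), f"gradual_{f:g}")
        )
    return out
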