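"""UMI grouping, labeled-molecule removal, matrices and reports."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dissoscan.config import ThresholdConfig
from dissoscan.conversion import ConversionEvent, MismatchEvent, call_conversions
from dissoscan.singlecell import (
    CellCountMatrix,
    celltype_gene_labeling_summary,
    gradual_removal,
    group_umis,
    per_cell_labeled_gene_fraction,
    regenerate_count_matrix,
    removal_report,
)

CFG = ThresholdConfig()


def _tc(read_id, pos):
    return ConversionEvent("c1", pos, "T", "C", 30, read_id, "g1", "+", True)


def _reads(n, cb="cellA", umi="u1", gene="g1"):
    return [(f"{cb}_{umi}_r{i}", cb, umi, gene) for i in range(n)]


def _umis(spec):
    """Build UMIRecords from (cell, gene, n_umis, n_labeled[, reads_per_umi])."""
    reads, events = [], []
    k = 0
    for item in spec:
        cell, gene, n, n_lab = item[:4]
        rpu = item[4] if len(item) > 4 else 1
        for i in range(n):
            k += 1
            umi = f"u{k}"
            for j in range(rpu):
                rid = f"{cell}_{umi}_r{j}"
                reads.append((rid, cell, umi, gene))
                if i < n_lab and j == 0:
                    events += [_tc(rid, 10 * k), _tc(rid, 10 * k + 1)]
    umis, _ = group_umis(reads, events, CFG)
    return umis


class TestGroupUmis:
    def test_conversions_union_across_reads(self):
        reads = _reads(3)
        events = [_tc(reads[0][0], 100), _tc(reads[1][0], 100), _tc(reads[1][0], 105)]
        (rec,), diag = group_umis(reads, events, CFG)
        assert rec.conversion_positions == {100, 105}
        assert rec.conversion_count == 2 and rec.labeled
        assert rec.read_count == 3 and diag.n_reads == 3

    def test_repeated_single_position_not_labeled(self):
        reads = _reads(3)
        events = [_tc(r[0], 100) for r in reads]
        (rec,), _ = group_umis(reads, events, CFG)
        assert rec.conversion_count == 1 and not rec.labeled

    def test_low_quality_conversions_never_reach_grouping(self):
        """A Q19 mismatch is dropped by calling, so the UMI stays unlabeled."""
        reads = _reads(1)
        mism = [
            MismatchEvent("c1", 100, "T", "C", 19, reads[0][0]),
            MismatchEvent("c1", 105, "T", "C", 21, reads[0][0]),
        ]
        events = call_conversions(mism, "g1", "+", CFG.min_quality)
        (rec,), _ = group_umis(reads, events, CFG)
        assert rec.conversion_positions == {105} and not rec.labeled

    def test_any_read_mode_requires_single_read_evidence(self):
        reads = _reads(2)
        events = [_tc(reads[0][0], 100), _tc(reads[1][0], 105)]
        (union_rec,), _ = group_umis(reads, events, CFG)
        assert union_rec.labeled  # union across reads = 2 positions
        (any_rec,), _ = group_umis(reads, events, CFG, conversion_mode="any_read")
        assert not any_rec.labeled  # no single read carries 2

    def test_untagged_reads_counted_and_skipped(self):
        reads = _reads(2) + [("orphan", None, None, None)]
        umis, diag = group_umis(reads, [], CFG)
        assert diag.n_missing_tags == 1 and len(umis) == 1

    def test_same_cell_umi_two_genes_stay_distinct(self):
        reads = [("r1", "c", "u", "gA"), ("r2", "c", "u", "gB")]
        umis, diag = group_umis(reads, [], CFG)
        assert {u.gene_id for u in umis} == {"gA", "gB"}
        assert diag.n_multi_gene_umis == 1

    def test_blacklisted_positions_do_not_count(self):
        from dissoscan.blacklist import Blacklist

        blk = Blacklist({"c1": np.array([0] * 100 + [1], dtype=np.int8)})
        reads = _reads(1)
        events = [_tc(reads[0][0], 100), _tc(reads[0][0], 99)]
        (rec,), _ = group_umis(reads, events, CFG, blacklist=blk)
        assert rec.conversion_positions == {99}


class TestRegenerateCountMatrix:
    def test_labeled_umis_removed_from_counts(self):
        umis = _umis([("cellA", "g1", 5, 2)])
        raw, removed_raw = regenerate_count_matrix(umis, remove_labeled=False)
        corrected, removed = regenerate_count_matrix(umis, remove_labeled=True)
        assert raw.total() == 5 and corrected.total() == 3
        assert removed_raw.empty and len(removed) == 2
        assert raw.variant == "raw" and corrected.variant == "corrected"

    def test_unreachable_threshold_is_identity(self):
        cfg = CFG.replace(sc_min_conversions=10**6)
        reads = _reads(2)
        events = [_tc(reads[0][0], 100), _tc(reads[0][0], 105)]
        umis, _ = group_umis(reads, events, cfg)
        raw, _ = regenerate_count_matrix(umis, remove_labeled=False)
        corrected, removed = regenerate_count_matrix(umis, remove_labeled=True)
        assert (raw.matrix != corrected.matrix).nnz == 0 and removed.empty

    def test_entrywise_conservation(self, sc_run):
        diff = np.asarray((sc_run.raw.matrix - sc_run.corrected.matrix).todense())
        assert (diff >= 0).all()
        assert diff.sum() == len(sc_run.removed)
        assert sc_run.raw.total() == sc_run.corrected.total() + len(sc_run.removed)

    def test_lowering_threshold_removes_at_least_as_much(self, sc_dataset):
        from dissoscan.pipeline import run_sc
        # monotonicity via grouped records directly
        reads = [(r.read_id, r.cell_barcode, r.umi, r.gene_id) for r in sc_dataset.reads]
        from dissoscan.conversion import extract_mismatches

        events = []
        strand = {g.gene_id: g.strand for g in sc_dataset.genes}
        for r in sc_dataset.reads:
            events += [
                e
                for e in call_conversions(
                    extract_mismatches(r), r.gene_id, strand[r.gene_id], 20
                )
                if e.is_tc
            ]
        removed_by_thr = []
        for thr in (1, 2, 3):
            umis, _ = group_umis(reads, events, CFG.replace(sc_min_conversions=thr))
            removed_by_thr.append(sum(u.labeled for u in umis))
        assert removed_by_thr == sorted(removed_by_thr, reverse=True)

    def test_10x_round_trip(self, tmp_path):
        umis = _umis([("cellA", "g1", 3, 1), ("cellB", "g2", 2, 0)])
        raw, _ = regenerate_count_matrix(umis, remove_labeled=False)
        raw.write_10x(tmp_path / "m")
        back = CellCountMatrix.read_10x(tmp_path / "m")
        assert back.gene_ids == raw.gene_ids and back.barcodes == raw.barcodes
        assert (back.matrix != raw.matrix).nnz == 0


class TestPerCellFraction:
    def test_fraction_of_detected_genes(self):
        umis = _umis([("cellA", f"g{i}", 1, 1 if i <= 3 else 0) for i in range(1, 11)])
        frac = per_cell_labeled_gene_fraction(umis, min_events=1)
        assert frac["cellA"] == pytest.approx(30.0)

    def test_unlabeled_cell_is_zero(self):
        umis = _umis([("cellB", "g1", 4, 0)])
        assert per_cell_labeled_gene_fraction(umis)[\
            "cellB"] == 0.0


class TestCelltypeSummary:
    def _summary(self, n_umis, n_labeled):
        umis = _umis([("cellA", "gX", n_umis, n_labeled)])
        return celltype_gene_labeling_summary(umis, {"cellA": "microglia"}, CFG)

    def test_passes_at_300_umis_15_percent(self):
        df = self._summary(300, 45)
        assert df.passes_filter.all()
        assert df.loc[0, "fraction"] == pytest.approx(0.15)

    def test_fails_below_unit_floor_or_fraction(self):
        assert not self._summary(200, 40).passes_filter.any()  # 20% but <250 units
        assert not self._summary(1000, 50).passes_filter.any()  # 5% < 10%

    def test_unknown_barcode_bucketed(self):
        umis = _umis([("cellZ", "g1", 2, 0)])
        df = celltype_gene_labeling_summary(umis, {}, CFG)
        assert set(df.cell_type) == {"unknown"}

    def test_read_unit_weighs_by_read_count(self):
        umis = _umis([("cellA", "g1", 2, 1, 3)])  # 2 UMIs x 3 reads
        df = celltype_gene_labeling_summary(umis, {"cellA": "t"}, CFG, unit="read")
        assert df.loc[0, "units_total"] == 6 and df.loc[0, "units_labeled"] == 3


class TestRemovalReport:
    def _report(self, spec, celltypes):
        umis = _umis(spec)
        raw, _ = regenerate_count_matrix(umis, remove_labeled=False)
        corrected, _ = regenerate_count_matrix(umis, remove_labeled=True)
        return removal_report(raw, corrected, umis, celltypes, CFG)

    def test_listed_requires_min_reads_and_fraction(self):
        rep = self._report([("cellA", "g1", 100, 7)], {"cellA": "microglia"})
        row = rep.per_gene_celltype.iloc[0]
        assert row.removal_fraction == pytest.approx(0.07) and row.listed

    def test_two_removed_reads_of_ten_not_listed(self):
        rep = self._report([("cellA", "g1", 10, 2)], {"cellA": "t"})
        row = rep.per_gene_celltype.iloc[0]
        assert row.reads_removed == 2 and not row.listed

    def test_totals_conserved_across_celltypes(self, sc_run, sc_dataset):
        ct = {cb: ("even" if int(cb[2:]) % 2 else "odd") for cb in sc_run.raw.barcodes}
        rep = removal_report(sc_run.raw, sc_run.corrected, sc_run.umis, ct, CFG)
        df = rep.per_gene_celltype
        assert df.reads_removed.sum() == sum(
            u.read_count for u in sc_run.umis if u.labeled
        )
        assert (df.removal_fraction.dropna() <= 1).all()

    def test_removed_rate_uses_site_formula(self, sc_run):
        rep = removal_report(
            sc_run.raw, sc_run.corrected, sc_run.umis, {}, CFG
        )
        df = rep.removed_gene_rates
        ok = df.dropna(subset=["removed_rate"])
        assert ((ok.removed_rate >= 0) & (ok.removed_rate <= 1)).all()
        assert (ok.removed_converted_sites <= ok.removed_t_sites).all()


class TestGradualRemoval:
    def test_endpoints_match_raw_and_corrected(self):
        umis = _umis([("cellA", "g1", 10, 4), ("cellB", "g1", 10, 6)])
        raw, _ = regenerate_count_matrix(umis, remove_labeled=False)
        corrected, _ = regenerate_count_matrix(umis, remove_labeled=True)
        m0, m1 = gradual_removal(umis, [0.0, 1.0], seed=7)
        assert (m0.matrix != raw.matrix).nnz == 0
        assert (m1.matrix != corrected.matrix).nnz == 0

    def test_exact_count_and_seed_determinism(self):
        umis = _umis([("cellA", "g1", 100, 100)])
        (m,) = gradual_removal(umis, [0.25], seed=3)
        assert m.total() == 75  # exactly 25 of 100 removed
        (m2,) = gradual_removal(umis, [0.25], seed=3)
        assert (m.matrix != m2.matrix).nnz == 0
        (m3,) = gradual_removal(umis, [0.25], seed=4)
        assert m3.total() == 75

    def test_half_up_rounding(self):
        umis = _umis([("cellA", "g1", 3, 3)])
        (m,) = gradual_removal(umis, [0.5], seed=1)
        assert m.total() == 1  # 1.5 rounds half-up to 2 removed

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gradual_removal([], [1.5], seed=0)
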