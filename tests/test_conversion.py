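"""Mismatch extraction and conversion calling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dissoscan.benchmarks import brute_force_mismatches
from dissoscan.conversion import (
    MDConsistencyError,
    MismatchEvent,
    call_conversions,
    extract_mismatches,
    substitution_spectrum,
)
from dissoscan.reads import AlignedRead
from dissoscan.simulate import SimConfig, simulate, simulate_reference, simulate_structured_reads

from conftest import mk_read


def _read(cigar, seq, md, start=1000, quals=None):
    if quals is None:
        quals = np.full(len(seq), 30, dtype=np.uint8)
    return AlignedRead(
        read_id="r1",
        contig="chr1",
        start=start,
        cigar=cigar,
        sequence=seq,
        base_qualities=np.asarray(quals, dtype=np.uint8),
        md_tag=md,
        is_reverse=False,
    )


class TestExtractMismatches:
    def test_perfect_match_yields_nothing(self):
        read = _read([("M", 50)], "A" * 50, "50")
        assert extract_mismatches(read) == []

    def test_single_substitution_position_and_quality(self):
        seq = "A" * 5 + "C" + "A" * 14
        quals = np.full(20, 30, dtype=np.uint8)
        quals[5] = 27
        read = _read([("M", 20)], seq, "5T14", start=1000, quals=quals)
        (ev,) = extract_mismatches(read)
        assert (ev.genomic_pos, ev.ref_base, ev.read_base, ev.base_quality) == (1005, "T", "C", 27)
        # cross-check against a base-by-base diff of the implied reference
        ref = {"chr1": "N" * 1000 + "A" * 5 + "T" + "A" * 14 + "N" * 10}
        assert {(ev.genomic_pos, ev.ref_base, ev.read_base)} == brute_force_mismatches(read, ref)

    def test_insertion_shifts_read_offset_not_reference(self):
        # 8M 2I 10M: MD "18" = clean; MD "10C7" = mismatch at read offset 12
        seq = "A" * 8 + "GG" + "A" * 10
        assert extract_mismatches(_read([("M", 8), ("I", 2), ("M", 10)], seq, "18")) == []
        seq2 = "A" * 8 + "GG" + "AA" + "T" + "A" * 7
        quals = np.arange(20, dtype=np.uint8) + 20
        (ev,) = extract_mismatches(
            _read([("M", 8), ("I", 2), ("M", 10)], seq2, "10C7", start=500, quals=quals)
        )
        assert (ev.genomic_pos, ev.ref_base, ev.read_base) == (510, "C", "T")
        assert ev.base_quality == int(quals[12])
        ref = {"chr1": "N" * 500 + "A" * 10 + "C" + "A" * 10}
        assert {(ev.genomic_pos, ev.ref_base, ev.read_base)} == brute_force_mismatches(
            _read([("M", 8), ("I", 2), ("M", 10)], seq2, "10C7", start=500, quals=quals), ref
        )

    def test_deletion_and_skip_advance_reference_only(self):
        # 5M 2D 5M with mismatch in second block; 5M 10N 5M likewise
        seq = "A" * 5 + "A" * 2 + "C" + "A" * 2
        (ev,) = extract_mismatches(_read([("M", 5), ("D", 2), ("M", 5)], seq, "5^GG2T2", start=0))
        assert ev.genomic_pos == 9  # 5 + 2 deleted + 2 matched
        (ev,) = extract_mismatches(_read([("M", 5), ("N", 10), ("M", 5)], seq, "7T2", start=0))
        assert ev.genomic_pos == 17  # MD does not cover the skipped region

    def test_n_bases_produce_no_events(self):
        read = _read([("M", 10)], "AAAAANAAAA", "5T4")
        assert extract_mismatches(read) == []

    @pytest.mark.parametrize(
        "cigar, seq, md",
        [
            ([("M", 10)], "A" * 10, "12"),  # MD longer than CIGAR
            ([("M", 10)], "A" * 10, "3A"),  # MD shorter
            ([("M", 5), ("D", 2), ("M", 5)], "A" * 10, "5^G5"),  # deletion length
            ([("M", 10)], "A" * 10, "4A5"),  # MD mismatch but read equals ref
        ],
    )
    def test_inconsistent_md_raises_with_read_id(self, cigar, seq, md):
        with pytest.raises(MDConsistencyError, match="r1"):
            extract_mismatches(_read(cigar, seq, md))

    def test_missing_md_raises(self):
        with pytest.raises(ValueError, match="no MD tag"):
            extract_mismatches(_read([("M", 5)], "AAAAA", None))


class TestOracleEquivalence:
    def test_structured_reads_match_reference_diff(self):
        """CIGAR-rich reads: extraction equals base-by-base reference diff."""
        _, contigs = simulate_reference(SimConfig(seed=9, n_genes=4, gene_length=1500))
        reads, truths = simulate_structured_reads(contigs, 400, seed=10)
        for read, truth in zip(reads, truths):
            got = {(e.genomic_pos, e.ref_base, e.read_base) for e in extract_mismatches(read)}
            assert got == truth
            assert got == brute_force_mismatches(read, contigs)

    def test_agreement_with_pysam_aligned_pairs(self, bulk_dataset, tmp_path):
        """Independent cross-check via pysam's MD-aware aligned pairs."""
        import pysam

        paths = bulk_dataset.write(tmp_path / "sim")
        with pysam.AlignmentFile(str(paths["sam"]), "r") as fh:
            for aln in [a for a in fh][:300]:
                want = {
                    (rpos, ref.upper(), aln.query_sequence[qpos])
                    for qpos, rpos, ref in aln.get_aligned_pairs(with_seq=True, matches_only=True)
                    if ref.islower()
                }
                got = {
                    (e.genomic_pos, e.ref_base, e.read_base)
                    for e in extract_mismatches(AlignedRead.from_pysam(aln))
                }
                assert got == want

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_random_gapless_reads(self, seed):
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), size=80))
        seq = list(ref[10:50])
        for off in rng.choice(40, size=rng.integers(0, 6), replace=False):
            seq[off] = "ACGT"[int(rng.integers(0, 4))]
        read = mk_read(ref, "".join(seq), start=10)
        got = {(e.genomic_pos, e.ref_base, e.read_base) for e in extract_mismatches(read)}
        assert got == brute_force_mismatches(read, {"chrT": ref})


class TestCallConversions:
    EV = MismatchEvent("chr1", 100, "T", "C", 20, "r1")

    def test_quality_threshold_inclusive(self):
        kept = call_conversions([self.EV], "g1", "+", min_quality=20)
        assert len(kept) == 1 and kept[0].is_tc
        low = MismatchEvent("chr1", 100, "T", "C", 19, "r1")
        assert call_conversions([low], "g1", "+", min_quality=20) == []

    def test_strand_rule(self):
        ag = MismatchEvent("chr1", 100, "A", "G", 30, "r1")
        assert call_conversions([ag], "g1", "-", 20)[0].is_tc
        assert not call_conversions([ag], "g1", "+", 20)[0].is_tc
        tc = MismatchEvent("chr1", 100, "T", "C", 30, "r1")
        assert not call_conversions([tc], "g1", "-", 20)[0].is_tc

    def test_genomic_only_ignores_strand(self):
        ag = MismatchEvent("chr1", 100, "A", "G", 30, "r1")
        assert not call_conversions([ag], "g1", "-", 20, genomic_only=True)[0].is_tc
        tc = MismatchEvent("chr1", 100, "T", "C", 30, "r1")
        assert call_conversions([tc], "g1", "-", 20, genomic_only=True)[0].is_tc

    def test_non_tc_events_retained_for_spectrum(self):
        ga = MismatchEvent("chr1", 100, "G", "A", 30, "r1")
        out = call_conversions([ga], "g1", "+", 20)
        assert len(out) == 1 and not out[0].is_tc

    def test_unknown_strand_errors(self):
        with pytest.raises(ValueError, match="strand"):
            call_conversions([self.EV], "g1", ".", 20)

    def test_quality_monotonicity(self, bulk_dataset):
        """Raising min_quality never increases the event count."""
        mism = [m for r in bulk_dataset.reads[:500] for m in extract_mismatches(r)]
        counts = [len(call_conversions(mism, "g", "+", q)) for q in (0, 13, 20, 30, 38)]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry(self):
        """Flipping gene strand + complementing conversions preserves is_tc count."""
        plus_events = [MismatchEvent("c", p, "T", "C", 30, f"r{p}") for p in range(10)]
        minus_events = [MismatchEvent("c", p, "A", "G", 30, f"r{p}") for p in range(10)]
        n_plus = sum(e.is_tc for e in call_conversions(plus_events, "g", "+", 20))
        n_minus = sum(e.is_tc for e in call_conversions(minus_events, "g", "-", 20))
        assert n_plus == n_minus == 10


class TestSubstitutionSpectrum:
    def test_empty_input_all_missing(self):
        table = substitution_spectrum([], min_quality=20)
        assert all(table.rate(r, a) is None for r, a in table.counts)

    def test_single_read_rate_one_tenth(self):
        ref = "T" * 10
        read = mk_read(ref, "TTTCTTTTTT", quals=np.full(10, 30))
        table = substitution_spectrum([read], min_quality=20)
        assert table.rate("T", "C") == pytest.approx(0.1)
        assert table.observations["T"] == 10
        assert all(table.rate(r, a) in (0, None) for r, a in table.counts if (r, a) != ("T", "C"))

    def test_error_free_unlabeled_sim_is_all_zero(self):
        ds = simulate(
            SimConfig(seed=5, n_genes=5, gene_length=300, reads_per_gene=30,
                      conversion_prob=0.0, error_rate=0.0),
            "bulk",
        )
        table = substitution_spectrum(ds.reads, min_quality=20)
        rates = [table.rate(r, a) for r, a in table.counts]
        assert all(r == 0 for r in rates if r is not None)

    def test_planted_tc_rate_matches_truth(self):
        """T>C rate equals exact planted conversions over T observations."""
        ds = simulate(
            SimConfig(seed=6, n_genes=10, gene_length=500, reads_per_gene=200,
                      strand_mix=0.0, labeled_fraction=0.5, conversion_prob=0.02,
                      error_rate=0.0),
            "bulk",
        )
        table = substitution_spectrum(ds.reads, min_quality=20)
        n_planted = sum(
            len(p.split(",")) if p else 0
            for p in ds.truth.reads.conversion_positions.fillna("")
        )
        assert table.counts[("T", "C")] == n_planted
        assert table.rate("T", "C") == pytest.approx(
            n_planted / (table.observations["T"]), abs=0
        )
        others = [table.rate(r, a) for r, a in table.counts if (r, a) != ("T", "C")]
        assert all(r == 0 for r in others if r is not None)
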