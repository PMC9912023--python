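"""Per-position pileups and the SNP / low-coverage blacklist.

Genomic positions where more than ``max_alt_frac`` of quality-passing
base calls deviate from the reference look like SNPs rather than
labeling and are excluded from rate computation, as are positions whose
coverage is below ``min_coverage`` (too shallow to judge). Both
inequalities are strict, exactly as worded: an alt fraction of exactly
25% or a coverage of exactly 10 passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .config import ThresholdConfig
from .reads import AlignedRead, ReferenceGenome

_BASES = "ACGT"
_BASE_ROW = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_ROW[ord(_b)] = _i

PROV_ALT_FRACTION = "alt_fraction"
PROV_LOW_COVERAGE = "low_coverage"


class PositionPileup:
    """Quality-filtered base-call counts per genomic position.

    Backed by one ``(4, contig_length)`` count array per contig plus the
    reference sequence, which keeps construction vectorized. Coverage is
    the sum of the four base counts; N read bases are never counted and
    positions whose reference base is N accumulate nothing.
    """

    def __init__(self, min_quality: int):
        self.min_quality = min_quality
        self._counts: Dict[str, np.ndarray] = {}
        self._ref: Dict[str, np.ndarray] = {}

    def contigs(self) -> List[str]:
        return sorted(self._counts)

    def counts_array(self, contig: str) -> np.ndarray:
        return self._counts[contig]

    def ref_array(self, contig: str) -> np.ndarray:
        return self._ref[contig]

    def coverage_array(self, contig: str) -> np.ndarray:
        return self._counts[contig].sum(axis=0)

    def get(self, contig: str, pos: int) -> Tuple[int, Dict[str, int], str]:
        """(coverage, per-base counts, ref_base) at one position."""
        col = self._counts[contig][:, pos]
        counts = {b: int(col[i]) for i, b in enumerate(_BASES)}
        return int(col.sum()), counts, chr(self._ref[contig][pos])

    def _ensure(self, contig: str, reference: ReferenceGenome) -> np.ndarray:
        arr = self._counts.get(contig)
        if arr is None:
            ref = reference.contig_array(contig)
            arr = np.zeros((4, len(ref)), dtype=np.int32)
            self._counts[contig] = arr
            self._ref[contig] = ref
        return arr

    def add_read(self, read: AlignedRead, reference: ReferenceGenome) -> None:
        arr = self._ensure(read.contig, reference)
        ref = self._ref[read.contig]
        seq = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        quals = np.asarray(read.base_qualities)
        for roff, rpos, n in read.aligned_blocks():
            rows = _BASE_ROW[seq[roff : roff + n]]
            ok = (
                (quals[roff : roff + n] >= self.min_quality)
                & (rows >= 0)
                & (_BASE_ROW[ref[rpos : rpos + n]] >= 0)
            )
            idx = np.nonzero(ok)[0]
            if idx.size:
                np.add.at(arr, (rows[idx], rpos + idx), 1)


def build_pileup(
    reads: Iterable[AlignedRead],
    reference: ReferenceGenome,
    min_quality: int = 20,
) -> PositionPileup:
    """Count every aligned, quality-passing base call at its position.

    Deletions and skips contribute nothing. Raises ``KeyError`` when a
    read's contig is absent from the reference.
    """
    pileup = PositionPileup(min_quality)
    for read in reads:
        pileup.add_read(read, reference)
    return pileup


@dataclass(frozen=True)
class BlacklistEntry:
    contig: str
    genomic_pos: int
    provenance: str


class Blacklist:
    """Set of excluded genomic positions with per-entry provenance.

    Internally per-contig provenance arrays (0 = clean, 1 = SNP-like alt
    fraction, 2 = low coverage) so membership tests over position arrays
    stay vectorized.
    """

    _PROV = {1: PROV_ALT_FRACTION, 2: PROV_LOW_COVERAGE}

    def __init__(self, provenance_arrays: Optional[Dict[str, np.ndarray]] = None):
        self._prov: Dict[str, np.ndarray] = provenance_arrays or {}

    def contains(self, contig: str, pos: int) -> bool:
        arr = self._prov.get(contig)
        return bool(arr is not None and 0 <= pos < len(arr) and arr[pos])

    def mask(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: which of ``positions`` are blacklisted."""
        arr = self._prov.get(contig)
        if arr is None:
            return np.zeros(len(positions), dtype=bool)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        inb = (positions >= 0) & (positions < len(arr))
        out[inb] = arr[positions[inb]] != 0
        return out

    def clean_mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean array over [0, length): True where NOT blacklisted."""
        arr = self._prov.get(contig)
        if arr is None:
            return np.ones(length, dtype=bool)
        return arr[:length] == 0

    def __len__(self) -> int:
        return int(sum((a != 0).sum() for a in self._prov.values()))

    def entries(self) -> Iterator[BlacklistEntry]:
        for contig in sorted(self._prov):
            arr = self._prov[contig]
            for pos in np.nonzero(arr)[0]:
                yield BlacklistEntry(contig, int(pos), self._PROV[int(arr[pos])])

    def positions(self) -> set:
        return {(e.contig, e.genomic_pos) for e in self.entries()}

    def union(self, other: "Blacklist") -> "Blacklist":
        """Union across samples; alt_fraction provenance wins on overlap."""
        merged: Dict[str, np.ndarray] = {}
        for contig in set(self._prov) | set(other._prov):
            a = self._prov.get(contig)
            b = other._prov.get(contig)
            if a is None:
                merged[contig] = b.copy()
            elif b is None:
                merged[contig] = a.copy()
            else:
                n = max(len(a), len(b))
                aa = np.zeros(n, dtype=np.int8)
                bb = np.zeros(n, dtype=np.int8)
                aa[: len(a)] = a
                bb[: len(b)] = b
                out = np.maximum(aa, bb)
                out[(aa == 1) | (bb == 1)] = 1
                merged[contig] = out
        return Blacklist(merged)

    def to_bed(self, path) -> None:
        """0-based half-open BED, one interval per position, name = provenance."""
        with open(path, "w") as fh:
            for e in self.entries():
                fh.write(f"{e.contig}\t{e.genomic_pos}\t{e.genomic_pos + 1}\t{e.provenance}\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tgenomic_pos\tprovenance\n")
            for e in self.entries():
                fh.write(f"{e.contig}\t{e.genomic_pos}\t{e.provenance}\n")


def build_blacklist(
    pileup: PositionPileup,
    config: ThresholdConfig,
    tc_only: bool = False,
) -> Blacklist:
    """Blacklist SNP-like and under-covered positions of a pileup.

    A position is excluded when its non-reference fraction is strictly
    greater than ``max_alt_frac``, or its coverage strictly below
    ``min_coverage`` (zero-coverage positions included). With
    ``tc_only`` the alt-fraction test counts only the T-to-C-like
    alternative (C calls at reference T, G calls at reference A) instead
    of all non-reference calls; the coverage rule is unchanged.
    """
    prov: Dict[str, np.ndarray] = {}
    for contig in pileup.contigs():
        counts = pileup.counts_array(contig)
        ref = pileup.ref_array(contig)
        cov = counts.sum(axis=0)
        ref_rows = _BASE_ROW[ref]
        valid_ref = ref_rows >= 0
        ref_counts = np.zeros(counts.shape[1], dtype=np.int64)
        cols = np.nonzero(valid_ref)[0]
        ref_counts[cols] = counts[ref_rows[cols], cols]
        if tc_only:
            alt = np.zeros(counts.shape[1], dtype=np.int64)
            t_cols = ref == ord("T")
            a_cols = ref == ord("A")
            alt[t_cols] = counts[_BASE_ROW[ord("C")], t_cols]
            alt[a_cols] = counts[_BASE_ROW[ord("G")], a_cols]
        else:
            alt = cov - ref_counts
        arr = np.zeros(counts.shape[1], dtype=np.int8)
        with np.errstate(invalid="ignore"):
            snp_like = (cov > 0) & valid_ref & (alt > config.max_alt_frac * cov)
        arr[cov < config.min_coverage] = 2
        arr[snp_like] = 1
        prov[contig] = arr
    return Blacklist(prov)
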