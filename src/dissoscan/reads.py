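"""Alignment records, reference access and gene models.

The pipeline consumes coordinate-sorted SAM/BAM written by an external
mapper, with MD tags present (``samtools calmd`` is the documented
pre-step when the mapper did not emit them). Records are converted into
lightweight :class:`AlignedRead` objects that carry exactly the fields
downstream stages need; base qualities are kept as a ``numpy`` array so
large runs stay compact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

log = logging.getLogger(__name__)

# CIGAR op consumption (read, reference)
_CONSUMES = {
    "M": (True, True),
    "I": (True, False),
    "D": (False, True),
    "N": (False, True),
    "S": (True, False),
    "H": (False, False),
    "P": (False, False),
    "=": (True, True),
    "X": (True, True),
}
_OP_CHARS = "MIDNSHP=X"

AMBIGUOUS = "__ambiguous__"


@dataclass(slots=True)
class AlignedRead:
    """One aligned read with the auxiliary fields the pipeline uses."""

    read_id: str
    contig: str
    start: int  # 0-based genomic position of first aligned base
    cigar: List[Tuple[str, int]]
    sequence: str
    base_qualities: np.ndarray  # uint8 Phred scores, one per sequence base
    md_tag: Optional[str]
    is_reverse: bool
    cell_barcode: Optional[str] = None
    umi: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.base_qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.base_qualities)}"
            )
        read_len = sum(n for op, n in self.cigar if _CONSUMES[op][0])
        if read_len != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: CIGAR consumes {read_len} read bases "
                f"but sequence has {len(self.sequence)}"
            )

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.start + sum(n for op, n in self.cigar if _CONSUMES[op][1])

    def aligned_blocks(self) -> Iterator[Tuple[int, int, int]]:
        """Yield (read_offset, ref_pos, length) for each M/=/X block."""
        roff, rpos = 0, self.start
        for op, n in self.cigar:
            cr, cf = _CONSUMES[op]
            if cr and cf:
                yield roff, rpos, n
            if cr:
                roff += n
            if cf:
                rpos += n

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedRead":
        cig = [(_OP_CHARS[op], n) for op, n in (aln.cigartuples or [])]
        quals = aln.query_qualities
        return cls(
            read_id=aln.query_name,
            contig=aln.reference_name,
            start=aln.reference_start,
            cigar=cig,
            sequence=aln.query_sequence or "",
            base_qualities=np.asarray(quals, dtype=np.uint8)
            if quals is not None
            else np.zeros(len(aln.query_sequence or ""), dtype=np.uint8),
            md_tag=aln.get_tag("MD") if aln.has_tag("MD") else None,
            is_reverse=aln.is_reverse,
            cell_barcode=aln.get_tag("CB") if aln.has_tag("CB") else None,
            umi=aln.get_tag("UB") if aln.has_tag("UB") else None,
            gene_id=aln.get_tag("GX") if aln.has_tag("GX") else None,
        )


def iter_alignments(path, require_md: bool = False) -> Iterator[AlignedRead]:
    """Stream primary mapped alignments from a SAM/BAM file.

    Secondary/supplementary/unmapped records are skipped. With
    ``require_md`` a missing MD tag raises; otherwise such reads are
    yielded as-is (callers decide how to treat them).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            read = AlignedRead.from_pysam(aln)
            if require_md and read.md_tag is None:
                raise ValueError(f"read {read.read_id} has no MD tag")
            yield read


class ReferenceGenome:
    """FASTA-backed reference with cached per-contig byte arrays."""

    def __init__(self, path):
        self._fasta = Fasta(str(path), rebuild=True, as_raw=True, sequence_always_upper=True)
        self._arrays: dict[str, np.ndarray] = {}

    def contigs(self) -> List[str]:
        return list(self._fasta.keys())

    def length(self, contig: str) -> int:
        self._check(contig)
        return len(self._fasta[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        self._check(contig)
        return str(self._fasta[contig][start:end])

    def contig_array(self, contig: str) -> np.ndarray:
        """Full contig sequence as uint8 ASCII codes (cached)."""
        self._check(contig)
        arr = self._arrays.get(contig)
        if arr is None:
            arr = np.frombuffer(str(self._fasta[contig][:]).encode(), dtype=np.uint8)
            self._arrays[contig] = arr
        return arr

    def _check(self, contig: str) -> None:
        if contig not in self._fasta:
            raise KeyError(f"contig {contig!r} absent from reference")


@dataclass(frozen=True)
class GeneModel:
    """Single gene extent; coordinates 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def read_gtf(path) -> List[GeneModel]:
    """Parse gene extents from a GTF file.

    ``gene`` features are used when present; otherwise extents are the
    union of each gene's ``exon`` features. GTF coordinates are 1-based
    inclusive and converted to 0-based half-open here.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            contig, _, feature, start, end, _, strand, _, attrs = f[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            gid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gid = part.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                continue
            s, e = int(start) - 1, int(end)
            rec = genes.setdefault(
                gid, {"contig": contig, "start": s, "end": e, "strand": strand, "has_gene": False}
            )
            if feature == "gene":
                rec.update(contig=contig, start=s, end=e, strand=strand, has_gene=True)
            elif not rec["has_gene"]:
                rec["start"] = min(rec["start"], s)
                rec["end"] = max(rec["end"], e)
    return [
        GeneModel(gid, r["contig"], r["start"], r["end"], r["strand"])
        for gid, r in sorted(genes.items())
    ]


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            for feature in ("gene", "exon"):
                fh.write(
                    f"{g.contig}\tdissoscan\t{feature}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


class GeneIndex:
    """Interval lookup from genomic span to gene, with ambiguity detection."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.by_id: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.by_id[g.gene_id] = g
            self._trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g.gene_id)

    def strand(self, gene_id: str) -> str:
        return self.by_id[gene_id].strand

    def assign(self, read: AlignedRead) -> Optional[str]:
        """Gene overlapping the read's aligned span.

        Returns the gene_id for a unique overlap, ``None`` for no
        overlap, and :data:`AMBIGUOUS` when the read overlaps more than
        one gene (such reads are excluded from all genes).
        """
        tree = self._trees.get(read.contig)
        if tree is None:
            return None
        hits = tree.overlap(read.start, read.reference_end)
        if not hits:
            return None
        if len(hits) > 1:
            return AMBIGUOUS
        return next(iter(hits)).data
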