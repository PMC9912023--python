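"""T-to-C conversion calling from alignment mismatches.

4sU incorporated into nascent RNA reads out as T-to-C substitutions
after alkylation. This module reconstructs every reference mismatch of a
read by walking the CIGAR string and the MD tag jointly, then flags the
subset that are transcript-strand T-to-C at sufficient base quality.

Strand resolution: for a gene annotated on the minus strand, a labeled
transcript produces genomic A-to-G mismatches (the read is stored in
reference orientation), so those count as T-to-C unless the caller asks
for a strand-naive, genomic-only reading.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .reads import AlignedRead

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")
_BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the 12 possible substitution types, reference base first
SUBSTITUTION_TYPES: List[Tuple[str, str]] = [
    (r, a) for r in _BASES for a in _BASES if r != a
]


class MDConsistencyError(ValueError):
    """MD tag and CIGAR/sequence disagree for a read."""


@dataclass(frozen=True, slots=True)
class MismatchEvent:
    """One reference mismatch observed on a read (0-based coordinates)."""

    contig: str
    genomic_pos: int
    ref_base: str
    read_base: str
    base_quality: int
    read_id: str


@dataclass(frozen=True, slots=True)
class ConversionEvent:
    """A mismatch resolved against its gene's strand.

    ``is_tc`` is true iff the event is a transcript-strand T-to-C:
    genomic T>C on a plus-strand gene or genomic A>G on a minus-strand
    gene (or genomic T>C regardless of strand in genomic-only mode).
    """

    contig: str
    genomic_pos: int
    ref_base: str
    read_base: str
    base_quality: int
    read_id: str
    gene_id: str
    gene_strand: str
    is_tc: bool


def _parse_md(md: str, read_id: str):
    tokens = []
    consumed = 0
    for m in _MD_TOKEN.finditer(md):
        consumed += len(m.group(0))
        if m.group(1) is not None:
            n = int(m.group(1))
            if n:
                tokens.append(("match", n))
        elif m.group(2) is not None:
            tokens.append(("del", m.group(2).upper()))
        else:
            tokens.append(("sub", m.group(3).upper()))
    if consumed != len(md):
        raise MDConsistencyError(f"read {read_id}: unparsable MD tag {md!r}")
    return tokens


def extract_mismatches(read: AlignedRead) -> List[MismatchEvent]:
    """Reconstruct all reference mismatches of a read from CIGAR + MD.

    Insertions and soft clips advance the read only; deletions and skips
    (N) advance the reference only; the MD tag covers aligned and
    deleted reference bases but not skipped ones. Mismatches where
    either base is N are dropped.

    Raises
    ------
    MDConsistencyError
        When the MD tag cannot be reconciled with the CIGAR/sequence;
        the message names the read.
    ValueError
        When the read has no MD tag.
    """
    if read.md_tag is None:
        raise ValueError(f"read {read.read_id} has no MD tag")
    tokens = _parse_md(read.md_tag, read.read_id)
    ti = 0  # token index
    pending = 0  # remaining bases of the current match run
    events: List[MismatchEvent] = []
    roff, rpos = 0, read.start
    seq = read.sequence
    quals = read.base_qualities

    def bad(msg: str):
        return MDConsistencyError(f"read {read.read_id}: MD/CIGAR mismatch ({msg})")

    for op, n in read.cigar:
        if op in ("S", "I"):
            roff += n
        elif op == "N":
            rpos += n
        elif op in ("H", "P"):
            pass
        elif op == "D":
            if pending:
                raise bad("deletion inside MD match run")
            if ti >= len(tokens) or tokens[ti][0] != "del" or len(tokens[ti][1]) != n:
                raise bad(f"expected {n}-base deletion token")
            ti += 1
            rpos += n
        elif op in ("M", "=", "X"):
            remaining = n
            while remaining:
                if pending == 0:
                    if ti >= len(tokens):
                        raise bad("MD exhausted before CIGAR")
                    kind, val = tokens[ti]
                    ti += 1
                    if kind == "match":
                        pending = val
                        continue
                    if kind == "del":
                        raise bad("deletion token within aligned block")
                    # substitution
                    ref_base = val
                    read_base = seq[roff]
                    if ref_base != "N" and read_base != "N":
                        if ref_base == read_base:
                            raise bad(
                                f"MD reports mismatch at {rpos} but read base equals reference"
                            )
                        events.append(
                            MismatchEvent(
                                contig=read.contig,
                                genomic_pos=rpos,
                                ref_base=ref_base,
                                read_base=read_base,
                                base_quality=int(quals[roff]),
                                read_id=read.read_id,
                            )
                        )
                    roff += 1
                    rpos += 1
                    remaining -= 1
                else:
                    step = min(pending, remaining)
                    pending -= step
                    remaining -= step
                    roff += step
                    rpos += step
        else:  # pragma: no cover - unknown op letters rejected upstream
            raise bad(f"unsupported CIGAR op {op!r}")

    if pending or any(t[0] != "match" for t in tokens[ti:]):
        raise bad("MD longer than CIGAR")
    return events


def call_conversions(
    mismatches: Iterable[MismatchEvent],
    gene_id: str,
    gene_strand: str,
    min_quality: int,
    genomic_only: bool = False,
) -> List[ConversionEvent]:
    """Quality-filter mismatches and flag transcript-strand T-to-C.

    Non-T-to-C events passing the quality filter are retained with
    ``is_tc=False`` so the substitution spectrum can be computed from
    the same stream.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError(f"unknown strand symbol {gene_strand!r}")
    out: List[ConversionEvent] = []
    for ev in mismatches:
        if ev.base_quality < min_quality:
            continue
        if genomic_only:
            is_tc = ev.ref_base == "T" and ev.read_base == "C"
        elif gene_strand == "+":
            is_tc = ev.ref_base == "T" and ev.read_base == "C"
        else:
            is_tc = ev.ref_base == "A" and ev.read_base == "G"
        out.append(
            ConversionEvent(
                contig=ev.contig,
                genomic_pos=ev.genomic_pos,
                ref_base=ev.ref_base,
                read_base=ev.read_base,
                base_quality=ev.base_quality,
                read_id=ev.read_id,
                gene_id=gene_id,
                gene_strand=gene_strand,
                is_tc=is_tc,
            )
        )
    return out


@dataclass
class SubstitutionTable:
    """Rates of the 12 substitution types over a read set.

    ``counts[(ref, alt)]`` is the number of quality-passing mismatch
    events; ``observations[ref]`` the number of quality-passing aligned
    observations of that reference base (shared denominator of the three
    substitutions from ``ref``). ``rate`` is missing (None) when the
    denominator is zero.
    """

    counts: Dict[Tuple[str, str], int]
    observations: Dict[str, int]

    def rate(self, ref: str, alt: str) -> Optional[float]:
        obs = self.observations.get(ref, 0)
        if obs == 0:
            return None
        return self.counts.get((ref, alt), 0) / obs

    def as_rows(self) -> List[dict]:
        rows = []
        for ref, alt in SUBSTITUTION_TYPES:
            r = self.rate(ref, alt)
            rows.append(
                {
                    "ref_base": ref,
                    "read_base": alt,
                    "event_count": self.counts.get((ref, alt), 0),
                    "ref_base_observations": self.observations.get(ref, 0),
                    "rate": float("nan") if r is None else r,
                }
            )
        return rows


def substitution_spectrum(
    reads: Iterable[AlignedRead],
    blacklist=None,
    min_quality: int = 20,
) -> SubstitutionTable:
    """Tally the 12 genomic substitution rates over a read stream.

    Both numerator (mismatch events) and denominator (aligned
    observations of each reference base) apply the same quality filter
    and exclude blacklisted positions; N reference or read bases count
    for neither. The reference base at matching positions equals the
    read base, and at mismatching positions comes from the MD tag, so no
    FASTA access is needed.
    """
    counts: Dict[Tuple[str, str], int] = {t: 0 for t in SUBSTITUTION_TYPES}
    observations: Dict[str, int] = {b: 0 for b in _BASES}
    base_idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_idx[ord(b)] = i

    obs_vec = np.zeros(4, dtype=np.int64)
    for read in reads:
        mism = extract_mismatches(read)
        seq = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
        quals = np.asarray(read.base_qualities)
        passing_pos: set[int] = set()
        for roff, rpos, n in read.aligned_blocks():
            rows = base_idx[seq[roff : roff + n]]
            ok = (quals[roff : roff + n] >= min_quality) & (rows >= 0)
            if blacklist is not None:
                ok &= ~blacklist.mask(read.contig, np.arange(rpos, rpos + n))
            # provisional denominator keyed by the READ base; mismatching
            # positions are re-keyed to the reference base below
            obs_vec += np.bincount(rows[ok], minlength=4)
            if mism:
                passing_pos.update((rpos + np.nonzero(ok)[0]).tolist())
        for ev in mism:
            if ev.genomic_pos in passing_pos:
                obs_vec[base_idx[ord(ev.read_base)]] -= 1
                obs_vec[base_idx[ord(ev.ref_base)]] += 1
                counts[(ev.ref_base, ev.read_base)] += 1
    for i, b in enumerate(_BASES):
        observations[b] = int(obs_vec[i])
    return SubstitutionTable(counts=counts, observations=observations)
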