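"""Ground-truthed synthetic SLAM-seq data.

The generator emulates the data regime the pipeline is built for:
single-exon genes (one per contig) on both strands, a labeled read or
molecule subpopulation whose transcript-strand T positions convert to C
with a fixed probability, uniform sequencing errors across all twelve
substitution types (each base errors with rate e, uniformly to the
three alternatives, so the background T-to-C rate is e/3),
heterozygous/homozygous SNP positions, a two-point base-quality mixture,
and — in single-cell mode — multiple reads per UMI sharing one
molecule's labeled status and planted conversions.

Every run is fully determined by the seed, byte for byte. Planted
conversions, SNP draws and errors are mutually exclusive per base, so
the mismatch set of every emitted read equals their union exactly; this
is what makes the generator usable as an oracle for the extraction and
removal stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .reads import AlignedRead, GeneModel, write_gtf

_BASES = b"ACGT"
_BASE_ROW = np.full(256, -1, dtype=np.int8)
for _i in range(4):
    _BASE_ROW[_BASES[_i]] = _i
_CODE = np.frombuffer(_BASES, dtype=np.uint8)


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population in single-cell mode.

    ``extra_labeled_umis`` adds that many *labeled* molecules per cell
    for each listed gene on top of the shared baseline expression — the
    knob for emulating a dissociation-activated subpopulation that
    differs from its parent only in nascent transcripts.
    """

    name: str
    n_cells: int
    labeled_fraction: float = 0.0
    extra_labeled_umis: Dict[str, int] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Parameters of one simulated experiment (see module docstring)."""

    seed: int = 0
    n_genes: int = 50
    gene_length: int = 1000
    strand_mix: float = 0.5  # fraction of minus-strand genes (exact count)
    reads_per_gene: int = 200
    read_length: int = 90
    labeled_fraction: float = 0.5
    conversion_prob: float = 0.04
    error_rate: float = 1e-3
    snp_positions: List[Tuple[int, int, float]] = field(default_factory=list)
    # (gene index, offset within gene, alt fraction); alt base = next base cyclically
    quality_high: int = 37
    quality_low: int = 12
    low_quality_fraction: float = 0.0
    conversions_high_quality: bool = True
    spiked_genes: Dict[str, float] = field(default_factory=dict)
    # single-cell mode
    n_cells: int = 100
    umis_per_cell: int = 20
    reads_per_umi: int = 2
    populations: Optional[List[PopulationSpec]] = None

    def __post_init__(self):
        for name in ("strand_mix", "labeled_fraction", "conversion_prob",
                     "error_rate", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_genes <= 0 or self.gene_length <= 0:
            raise ValueError("n_genes and gene_length must be positive")
        if self.read_length > self.gene_length:
            raise ValueError("read_length exceeds gene_length")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        pops = d.get("populations")
        if pops:
            d["populations"] = [PopulationSpec(**p) for p in pops]
        if d.get("snp_positions"):
            d["snp_positions"] = [tuple(x) for x in d["snp_positions"]]
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class SimTruth:
    """Ground-truth tables emitted alongside the alignments."""

    reads: pd.DataFrame  # read_id, gene_id, labeled, conversion/error/snp positions
    molecules: Optional[pd.DataFrame]  # single-cell only
    snps: pd.DataFrame  # contig, genomic_pos, ref_base, alt_base, alt_fraction
    genes: pd.DataFrame  # gene_id, contig, strand, labeled_fraction

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        if self.molecules is not None:
            self.molecules.to_csv(outdir / "truth_molecules.tsv", sep="\t", index=False)
        self.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


@dataclass
class SimDataset:
    """In-memory simulated dataset."""

    config: SimConfig
    genes: List[GeneModel]
    contigs: Dict[str, str]  # contig -> sequence
    reads: List[AlignedRead]
    truth: SimTruth

    def write(self, outdir) -> Dict[str, Path]:
        """Write FASTA, GTF, SAM and truth TSVs; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "gtf": outdir / "genes.gtf",
            "sam": outdir / "alignments.sam",
        }
        write_fasta(self.contigs, paths["fasta"])
        write_gtf(self.genes, paths["gtf"])
        write_sam(self.reads, {c: len(s) for c, s in self.contigs.items()}, paths["sam"])
        self.truth.write(outdir)
        return paths


def write_fasta(contigs: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(reads: Sequence[AlignedRead], contig_lengths: Dict[str, int], path) -> None:
    """Write reads as plain SAM text with MD (and CB/UB/GX when present)."""
    order = {c: i for i, c in enumerate(contig_lengths)}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for r in sorted(reads, key=lambda r: (order[r.contig], r.start, r.read_id)):
            flag = 16 if r.is_reverse else 0
            cigar = "".join(f"{n}{op}" for op, n in r.cigar)
            qual = "".join(chr(int(q) + 33) for q in r.base_qualities)
            tags = []
            if r.md_tag is not None:
                tags.append(f"MD:Z:{r.md_tag}")
            if r.cell_barcode:
                tags.append(f"CB:Z:{r.cell_barcode}")
            if r.umi:
                tags.append(f"UB:Z:{r.umi}")
            if r.gene_id:
                tags.append(f"GX:Z:{r.gene_id}")
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig}\t{r.start + 1}\t255\t{cigar}\t*\t0\t0\t"
                f"{r.sequence}\t{qual}" + ("\t" + "\t".join(tags) if tags else "") + "\n"
            )


def build_md(ref_window: np.ndarray, read_window: np.ndarray) -> str:
    """MD tag for a gapless alignment of two equal-length byte arrays."""
    diff = np.nonzero(ref_window != read_window)[0]
    parts = []
    prev = 0
    for off in diff:
        parts.append(str(int(off) - prev))
        parts.append(chr(ref_window[off]))
        prev = int(off) + 1
    parts.append(str(len(ref_window) - prev))
    return "".join(parts)


def md_for_alignment(ops: Sequence[Tuple[str, np.ndarray, Optional[np.ndarray]]]) -> str:
    """MD tag for a gapped alignment.

    ``ops`` lists aligned blocks in order: ("M", ref_bytes, read_bytes)
    or ("D", ref_bytes, None). Skips (N), insertions and clips are not
    represented in MD and must be omitted.
    """
    parts: List[str] = []
    run = 0
    for kind, ref, read in ops:
        if kind == "M":
            for rb, qb in zip(ref, read):
                if rb == qb:
                    run += 1
                else:
                    parts.append(str(run))
                    parts.append(chr(rb))
                    run = 0
        elif kind == "D":
            parts.append(str(run))
            run = 0
            parts.append("^" + ref.tobytes().decode())
        else:
            raise ValueError(f"unsupported MD op {kind!r}")
    parts.append(str(run))
    return "".join(parts)


def simulate_reference(config: SimConfig) -> Tuple[List[GeneModel], Dict[str, str]]:
    """Random reference: one single-exon gene per contig, mixed strands.

    The minus-strand count is exactly ``round(strand_mix * n_genes)``;
    which genes are minus-strand is a seeded permutation so spiked genes
    fall on both strands.
    """
    rng = np.random.default_rng(config.seed)
    n_minus = int(round(config.strand_mix * config.n_genes))
    strands = np.array(["+"] * config.n_genes, dtype=object)
    strands[rng.permutation(config.n_genes)[:n_minus]] = "-"
    genes: List[GeneModel] = []
    contigs: Dict[str, str] = {}
    for i in range(config.n_genes):
        contig = f"chr{i + 1:04d}"
        gene_id = f"gene{i + 1:04d}"
        seq = _CODE[rng.integers(0, 4, size=config.gene_length)].tobytes().decode()
        contigs[contig] = seq
        genes.append(GeneModel(gene_id, contig, 0, config.gene_length, str(strands[i])))
    return genes, contigs


def _snp_table(config: SimConfig, genes: List[GeneModel], contigs: Dict[str, str]):
    """Resolve configured SNPs to (contig, pos, ref, alt, fraction) rows."""
    rows = []
    for gene_idx, offset, alt_fraction in config.snp_positions:
        g = genes[gene_idx]
        ref = contigs[g.contig][offset]
        alt = chr(_CODE[(int(_BASE_ROW[ord(ref)]) + 1) % 4])
        rows.append(
            {
                "contig": g.contig,
                "genomic_pos": offset,
                "ref_base": ref,
                "alt_base": alt,
                "alt_fraction": alt_fraction,
                "gene_id": g.gene_id,
            }
        )
    return pd.DataFrame(
        rows, columns=["contig", "genomic_pos", "ref_base", "alt_base", "alt_fraction", "gene_id"]
    )


def _gene_labeled_fraction(config: SimConfig, gene_id: str) -> float:
    return min(1.0, config.labeled_fraction * config.spiked_genes.get(gene_id, 1.0))


def _apply_reads_for_gene(
    rng: np.random.Generator,
    config: SimConfig,
    gene: GeneModel,
    ref: np.ndarray,
    starts: np.ndarray,
    conv_mask_rows,  # callable(i, window_slice) -> bool mask of conversions to express
    snp_df: pd.DataFrame,
):
    """Shared read-body machinery: SNP draws, errors, qualities, MD.

    Returns (windows_current, quality_matrix, conv_expressed, err_mask,
    snp_drawn_positions per read).
    """
    n = len(starts)
    rl = config.read_length
    win = ref[starts[:, None] + np.arange(rl)]
    cur = win.copy()
    touched = np.zeros((n, rl), dtype=bool)
    snp_cols_mask = np.zeros(len(ref), dtype=bool)
    snp_drawn: List[List[int]] = [[] for _ in range(n)]
    gene_snps = snp_df[snp_df["gene_id"] == gene.gene_id]
    for snp in gene_snps.itertuples(index=False):
        pos = int(snp.genomic_pos)
        snp_cols_mask[pos] = True
        cols = pos - starts
        covered = (cols >= 0) & (cols < rl)
        drawn = covered & (rng.random(n) < snp.alt_fraction)
        idx = np.nonzero(drawn)[0]
        cur[idx, cols[idx]] = ord(snp.alt_base)
        touched[idx, cols[idx]] = True
        for i in idx:
            snp_drawn[int(i)].append(pos)
    # conversions (eligibility excludes SNP positions entirely)
    elig = ~touched & ~snp_cols_mask[starts[:, None] + np.arange(rl)]
    conv = conv_mask_rows(win, elig)
    tc_to = ord("C") if gene.strand == "+" else ord("G")
    cur[conv] = tc_to
    touched |= conv
    # uniform errors on untouched bases, uniformly to the 3 alternatives
    err = ~touched & (rng.random((n, rl)) < config.error_rate)
    shift = rng.integers(1, 4, size=(n, rl))
    alt_codes = _CODE[(_BASE_ROW[cur].astype(np.int64) + shift) % 4]
    cur[err] = alt_codes[err]
    # qualities: two-point mixture; planted conversions ride high quality
    quals = np.full((n, rl), config.quality_high, dtype=np.uint8)
    if config.low_quality_fraction > 0:
        low = rng.random((n, rl)) < config.low_quality_fraction
        quals[low] = config.quality_low
        if config.conversions_high_quality:
            quals[conv] = config.quality_high
    return win, cur, quals, conv, err, snp_drawn


def _pos_list(offsets: np.ndarray, start: int) -> str:
    return ",".join(str(start + int(o)) for o in np.nonzero(offsets)[0])


def simulate_bulk(config: SimConfig) -> SimDataset:
    """Bulk-mode dataset: per-read labeled flags, planted conversions."""
    genes, contigs = simulate_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    snp_df = _snp_table(config, genes, contigs)
    reads: List[AlignedRead] = []
    truth_rows = []
    rl = config.read_length
    for gene in genes:
        ref = np.frombuffer(contigs[gene.contig].encode(), dtype=np.uint8)
        n = config.reads_per_gene
        starts = rng.integers(0, len(ref) - rl + 1, size=n)
        f_g = _gene_labeled_fraction(config, gene.gene_id)
        labeled = rng.random(n) < f_g
        tbase = ord("T") if gene.strand == "+" else ord("A")

        def conv_mask(win, elig, _labeled=labeled, _tbase=tbase):
            return (
                (win == _tbase)
                & elig
                & _labeled[:, None]
                & (rng.random(win.shape) < config.conversion_prob)
            )

        win, cur, quals, conv, err, snp_drawn = _apply_reads_for_gene(
            rng, config, gene, ref, starts, conv_mask, snp_df
        )
        for i in range(n):
            read_id = f"{gene.gene_id}_r{i:06d}"
            reads.append(
                AlignedRead(
                    read_id=read_id,
                    contig=gene.contig,
                    start=int(starts[i]),
                    cigar=[("M", rl)],
                    sequence=cur[i].tobytes().decode(),
                    base_qualities=quals[i].copy(),
                    md_tag=build_md(win[i], cur[i]),
                    is_reverse=gene.strand == "-",
                )
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "gene_id": gene.gene_id,
                    "contig": gene.contig,
                    "start": int(starts[i]),
                    "labeled": bool(labeled[i]),
                    "conversion_positions": _pos_list(conv[i], int(starts[i])),
                    "error_positions": _pos_list(err[i], int(starts[i])),
                    "snp_positions": ",".join(map(str, snp_drawn[i])),
                }
            )
    truth = SimTruth(
        reads=pd.DataFrame(truth_rows),
        molecules=None,
        snps=snp_df,
        genes=pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "contig": [g.contig for g in genes],
                "strand": [g.strand for g in genes],
                "labeled_fraction": [_gene_labeled_fraction(config, g.gene_id) for g in genes],
            }
        ),
    )
    return SimDataset(config, genes, contigs, reads, truth)


def simulate_single_cell(config: SimConfig) -> SimDataset:
    """Single-cell dataset: molecules with shared planted conversions.

    Each molecule spans its gene; labeled molecules convert each
    transcript-strand T position independently with ``conversion_prob``.
    Every supporting read expresses the molecule's conversions that fall
    inside its window, so reads of one UMI share labeled status and
    planted conversions. The truth table records, per molecule, both the
    labeled flag and the number of distinct planted conversion positions
    actually covered by its emitted reads — the operational ground truth
    for removal benchmarking.
    """
    genes, contigs = simulate_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    snp_df = _snp_table(config, genes, contigs)
    populations = config.populations or [
        PopulationSpec("pop1", config.n_cells, config.labeled_fraction)
    ]
    rl = config.read_length
    ref_arrays = {g.gene_id: np.frombuffer(contigs[g.contig].encode(), np.uint8) for g in genes}
    tpos_by_gene = {}
    for g in genes:
        tbase = ord("T") if g.strand == "+" else ord("A")
        mask = ref_arrays[g.gene_id] == tbase
        for snp in snp_df[snp_df["gene_id"] == g.gene_id].itertuples(index=False):
            mask[int(snp.genomic_pos)] = False
        tpos_by_gene[g.gene_id] = np.nonzero(mask)[0]

    reads: List[AlignedRead] = []
    truth_reads = []
    truth_mols = []
    umi_counter = 0
    cell_counter = 0
    for pop in populations:
        for _ in range(pop.n_cells):
            cell_counter += 1
            cb = f"CB{cell_counter:06d}"
            gene_idx = rng.integers(0, config.n_genes, size=config.umis_per_cell)
            molecule_specs: List[Tuple[GeneModel, bool]] = []
            for gi in gene_idx:
                g = genes[int(gi)]
                f_g = min(1.0, pop.labeled_fraction * config.spiked_genes.get(g.gene_id, 1.0))
                molecule_specs.append((g, bool(rng.random() < f_g)))
            for gid, n_extra in sorted(pop.extra_labeled_umis.items()):
                g = next(x for x in genes if x.gene_id == gid)
                molecule_specs.extend((g, True) for _ in range(n_extra))
            for g, lab in molecule_specs:
                umi_counter += 1
                umi = f"U{umi_counter:08d}"
                ref = ref_arrays[g.gene_id]
                tpos = tpos_by_gene[g.gene_id]
                if lab and len(tpos):
                    planted = tpos[rng.random(len(tpos)) < config.conversion_prob]
                else:
                    planted = np.empty(0, dtype=np.int64)
                planted_mask = np.zeros(len(ref), dtype=bool)
                planted_mask[planted] = True
                n = config.reads_per_umi
                starts = rng.integers(0, len(ref) - rl + 1, size=n)

                def conv_mask(win, elig, _pm=planted_mask, _starts=starts):
                    return elig & _pm[_starts[:, None] + np.arange(rl)]

                win, cur, quals, conv, err, snp_drawn = _apply_reads_for_gene(
                    rng, config, g, ref, starts, conv_mask, snp_df
                )
                covered = set()
                for i in range(n):
                    read_id = f"{cb}_{umi}_r{i}"
                    covered.update((int(starts[i]) + np.nonzero(conv[i])[0]).tolist())
                    reads.append(
                        AlignedRead(
                            read_id=read_id,
                            contig=g.contig,
                            start=int(starts[i]),
                            cigar=[("M", rl)],
                            sequence=cur[i].tobytes().decode(),
                            base_qualities=quals[i].copy(),
                            md_tag=build_md(win[i], cur[i]),
                            is_reverse=g.strand == "-",
                            cell_barcode=cb,
                            umi=umi,
                            gene_id=g.gene_id,
                        )
                    )
                    truth_reads.append(
                        {
                            "read_id": read_id,
                            "gene_id": g.gene_id,
                            "contig": g.contig,
                            "start": int(starts[i]),
                            "labeled": lab,
                            "conversion_positions": _pos_list(conv[i], int(starts[i])),
                            "error_positions": _pos_list(err[i], int(starts[i])),
                            "snp_positions": ",".join(map(str, snp_drawn[i])),
                        }
                    )
                truth_mols.append(
                    {
                        "cell_barcode": cb,
                        "umi": umi,
                        "gene_id": g.gene_id,
                        "population": pop.name,
                        "labeled": lab,
                        "n_planted": int(len(planted)),
                        "n_planted_covered": len(covered),
                        "detectable": bool(lab and len(covered) >= 2),
                        "planted_positions": ",".join(map(str, planted.tolist())),
                    }
                )
    truth = SimTruth(
        reads=pd.DataFrame(truth_reads),
        molecules=pd.DataFrame(truth_mols),
        snps=snp_df,
        genes=pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "contig": [g.contig for g in genes],
                "strand": [g.strand for g in genes],
                "labeled_fraction": [_gene_labeled_fraction(config, g.gene_id) for g in genes],
            }
        ),
    )
    return SimDataset(config, genes, contigs, reads, truth)


def simulate(config: SimConfig, mode: str) -> SimDataset:
    if mode == "bulk":
        return simulate_bulk(config)
    if mode in ("sc", "single_cell"):
        return simulate_single_cell(config)
    raise ValueError(f"unknown simulation mode {mode!r}")


def simulate_structured_reads(
    reference_contigs: Dict[str, str],
    n_reads: int,
    seed: int,
    mismatch_prob: float = 0.03,
) -> Tuple[List[AlignedRead], List[set]]:
    """Reads with mixed CIGARs (soft clips, insertions, deletions, skips).

    Exercises the full CIGAR/MD walking logic. Returns the reads and,
    per read, the true set of (genomic_pos, ref_base, read_base)
    mismatches implied by construction.
    """
    rng = np.random.default_rng(seed)
    names = sorted(reference_contigs)
    arrays = {c: np.frombuffer(reference_contigs[c].encode(), np.uint8) for c in names}
    reads: List[AlignedRead] = []
    truths: List[set] = []
    for idx in range(n_reads):
        contig = names[int(rng.integers(0, len(names)))]
        ref = arrays[contig]
        start = int(rng.integers(0, max(1, len(ref) - 220)))
        cigar: List[Tuple[str, int]] = []
        seq_parts: List[np.ndarray] = []
        md_ops: List[Tuple[str, np.ndarray, Optional[np.ndarray]]] = []
        truth: set = set()
        rpos = start
        if rng.random() < 0.4:
            n = int(rng.integers(1, 6))
            cigar.append(("S", n))
            seq_parts.append(_CODE[rng.integers(0, 4, size=n)])
        n_blocks = int(rng.integers(1, 4))
        for b in range(n_blocks):
            m = int(rng.integers(8, 30))
            ref_block = ref[rpos : rpos + m].copy()
            read_block = ref_block.copy()
            mism = np.nonzero(rng.random(m) < mismatch_prob)[0]
            for o in mism:
                read_block[o] = _CODE[(int(_BASE_ROW[read_block[o]]) + int(rng.integers(1, 4))) % 4]
                truth.add((rpos + int(o), chr(ref_block[o]), chr(read_block[o])))
            cigar.append(("M", m))
            seq_parts.append(read_block)
            md_ops.append(("M", ref_block, read_block))
            rpos += m
            if b < n_blocks - 1:
                kind = ["I", "D", "N"][int(rng.integers(0, 3))]
                if kind == "I":
                    n = int(rng.integers(1, 4))
                    cigar.append(("I", n))
                    seq_parts.append(_CODE[rng.integers(0, 4, size=n)])
                elif kind == "D":
                    n = int(rng.integers(1, 4))
                    cigar.append(("D", n))
                    md_ops.append(("D", ref[rpos : rpos + n].copy(), None))
                    rpos += n
                else:
                    n = int(rng.integers(3, 15))
                    cigar.append(("N", n))
                    rpos += n
        if rng.random() < 0.4:
            n = int(rng.integers(1, 6))
            cigar.append(("S", n))
            seq_parts.append(_CODE[rng.integers(0, 4, size=n)])
        seq = np.concatenate(seq_parts)
        reads.append(
            AlignedRead(
                read_id=f"struct_r{idx:06d}",
                contig=contig,
                start=start,
                cigar=cigar,
                sequence=seq.tobytes().decode(),
                base_qualities=np.full(len(seq), 37, dtype=np.uint8),
                md_tag=md_for_alignment(md_ops),
                is_reverse=False,
            )
        )
        truths.append(truth)
    return reads, truths
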