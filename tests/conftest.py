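"""Shared fixtures: hand-built reads and small simulated datasets."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from dissoscan.reads import AlignedRead, GeneModel, ReferenceGenome
from dissoscan.simulate import SimConfig, SimDataset, build_md, simulate, write_fasta


def mk_read(
    ref: str,
    seq: str,
    start: int = 0,
    contig: str = "chrT",
    quals=None,
    read_id: str = "r1",
    is_reverse: bool = False,
    md: str | None = "auto",
    **tags,
) -> AlignedRead:
    """Gapless read against a reference string, MD computed from the diff."""
    if quals is None:
        quals = np.full(len(seq), 37, dtype=np.uint8)
    else:
        quals = np.asarray(quals, dtype=np.uint8)
    if md == "auto":
        ref_win = np.frombuffer(ref[start : start + len(seq)].encode(), np.uint8)
        md = build_md(ref_win, np.frombuffer(seq.encode(), np.uint8))
    return AlignedRead(
        read_id=read_id,
        contig=contig,
        start=start,
        cigar=[("M", len(seq))],
        sequence=seq,
        base_qualities=quals,
        md_tag=md,
        is_reverse=is_reverse,
        **tags,
    )


@pytest.fixture()
def tiny_reference(tmp_path) -> tuple[ReferenceGenome, dict]:
    contigs = {"chrT": "ACGT" * 25 + "T" * 20 + "ACGT" * 25}
    fasta = tmp_path / "ref.fa"
    write_fasta(contigs, fasta)
    return ReferenceGenome(fasta), contigs


@pytest.fixture(scope="session")
def bulk_dataset() -> SimDataset:
    """Small bulk simulation with SNPs and both strands."""
    cfg = SimConfig(
        seed=42,
        n_genes=12,
        gene_length=600,
        reads_per_gene=120,
        read_length=80,
        labeled_fraction=0.5,
        conversion_prob=0.04,
        error_rate=1e-3,
        snp_positions=[(0, 300, 0.5), (1, 200, 1.0), (2, 150, 0.5)],
        low_quality_fraction=0.1,
    )
    return simulate(cfg, "bulk")


@pytest.fixture(scope="session")
def bulk_run(bulk_dataset, tmp_path_factory):
    """The bulk dataset written to disk and run through the pipeline."""
    import dissoscan as ds

    tmp = tmp_path_factory.mktemp("bulk_run")
    paths = bulk_dataset.write(tmp / "sim")
    cfg = ds.RunConfig(
        alignments=str(paths["sam"]),
        reference=str(paths["fasta"]),
        annotation=str(paths["gtf"]),
        output_dir=str(tmp / "out"),
        seed=42,
    )
    return ds.run_bulk(cfg)


@pytest.fixture(scope="session")
def sc_dataset() -> SimDataset:
    cfg = SimConfig(
        seed=43,
        n_genes=15,
        gene_length=600,
        read_length=80,
        conversion_prob=0.15,
        error_rate=1e-3,
        labeled_fraction=0.3,
        n_cells=40,
        umis_per_cell=15,
        reads_per_umi=2,
    )
    return simulate(cfg, "sc")


@pytest.fixture(scope="session")
def sc_run(sc_dataset, tmp_path_factory):
    import dissoscan as ds

    tmp = tmp_path_factory.mktemp("sc_run")
    paths = sc_dataset.write(tmp / "sim")
    cfg = ds.RunConfig(
        alignments=str(paths["sam"]),
        reference=str(paths["fasta"]),
        annotation=str(paths["gtf"]),
        output_dir=str(tmp / "out"),
        seed=43,
    )
    return ds.run_sc(cfg)
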