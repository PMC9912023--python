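"""Ground-truth validation experiments.

Each function simulates a dataset with known truth, runs the pipeline on
the written files end to end, and measures how well the relevant stage
recovers the truth. The brute-force oracles used for comparison
(base-by-base read-vs-reference diffing, naive per-position tallies)
deliberately avoid the code paths they check: the mismatch oracle reads
the reference FASTA slice implied by the CIGAR and never touches the MD
tag.

Problem sizes are chosen so each experiment finishes in minutes on one
CPU while keeping the statistical margins of the expected effects wide;
docs/methods.md discusses the power analysis behind the spike and
consensus designs.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .blacklist import build_blacklist, build_pileup
from .config import RunConfig, ThresholdConfig
from .pipeline import run_bulk, run_sc
from .reads import AlignedRead, ReferenceGenome
from .simulate import (
    PopulationSpec,
    SimConfig,
    SimDataset,
    simulate,
    simulate_reference,
    simulate_structured_reads,
)


def _seeds(seed: int, n: int) -> List[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def brute_force_mismatches(read: AlignedRead, reference) -> Set[Tuple[int, str, str]]:
    """Mismatch set by direct base-by-base comparison against the FASTA.

    Walks the CIGAR only (never the MD tag) and diffs the read against
    the reference slice each aligned block implies. N bases on either
    side are skipped, mirroring the event contract.
    """
    if isinstance(reference, dict):
        contig_seq = reference[read.contig]
    else:
        contig_seq = reference.fetch(read.contig, 0, reference.length(read.contig))
    out: Set[Tuple[int, str, str]] = set()
    for roff, rpos, n in read.aligned_blocks():
        for k in range(n):
            rb = contig_seq[rpos + k]
            qb = read.sequence[roff + k]
            if rb != qb and rb != "N" and qb != "N":
                out.add((rpos + k, rb, qb))
    return out


def naive_pileup_tally(
    reads: Sequence[AlignedRead], contigs: Dict[str, str], min_quality: int
) -> Dict[Tuple[str, int], Dict[str, int]]:
    """Per-position base tally by plain dict counting (pileup oracle)."""
    tally: Dict[Tuple[str, int], Dict[str, int]] = {}
    for read in reads:
        seq = contigs[read.contig]
        for roff, rpos, n in read.aligned_blocks():
            for k in range(n):
                base = read.sequence[roff + k]
                if base not in "ACGT" or seq[rpos + k] not in "ACGT":
                    continue
                if read.base_qualities[roff + k] < min_quality:
                    continue
                d = tally.setdefault((read.contig, rpos + k), {b: 0 for b in "ACGT"})
                d[base] += 1
    return tally


def _run_bulk_dataset(ds: SimDataset, outdir: Path, seed: int, **cfg_kwargs):
    paths = ds.write(outdir / "sim")
    cfg = RunConfig(
        alignments=str(paths["sam"]),
        reference=str(paths["fasta"]),
        annotation=str(paths["gtf"]),
        output_dir=str(outdir / "out"),
        seed=seed,
        **cfg_kwargs,
    )
    return run_bulk(cfg)


def mismatch_extraction_benchmark(seed: int, n_reads: int = 2000) -> Dict[str, float]:
    """CIGAR/MD extraction vs brute-force reference diff (set equality).

    Reads carry mixed CIGARs: soft clips, insertions, deletions and
    skips, plus plain gapless reads from the main generator.
    """
    s1, s2, s3 = _seeds(seed, 3)
    genes, contigs = simulate_reference(SimConfig(seed=s1, n_genes=10, gene_length=2000))
    n_structured = n_reads // 2
    reads, _ = simulate_structured_reads(contigs, n_structured, seed=s2)
    bulk = simulate(
        SimConfig(
            seed=s3,
            n_genes=10,
            gene_length=300,
            reads_per_gene=(n_reads - n_structured) // 10,
            conversion_prob=0.04,
            error_rate=5e-3,
            low_quality_fraction=0.2,
        ),
        "bulk",
    )
    from .conversion import extract_mismatches

    n_total = 0
    n_agree = 0
    for read_set, ref in ((reads, contigs), (bulk.reads, bulk.contigs)):
        for read in read_set:
            got = {(e.genomic_pos, e.ref_base, e.read_base) for e in extract_mismatches(read)}
            want = brute_force_mismatches(read, ref)
            n_total += 1
            n_agree += got == want
    return {
        "n_reads": n_total,
        "n_agreeing_reads": n_agree,
        "agreement_fraction": n_agree / n_total,
    }


def blacklist_benchmark(seed: int, workdir: Optional[Path] = None) -> Dict[str, float]:
    """Planted-SNP recovery and conversion-site specificity.

    50 heterozygous SNPs (alt fraction 0.5) planted at deeply covered
    mid-gene positions; conversion sites at conversion_prob 0.02 must
    not be alt-fraction-blacklisted. Specificity is judged on
    adequately covered sites (coverage >= the low-coverage cutoff),
    since shallower sites are excluded by the coverage rule by design.
    """
    (s1,) = _seeds(seed, 1)
    n_genes = 25
    snps = [(g, off, 0.5) for g in range(n_genes) for off in (200, 300)]
    cfg = SimConfig(
        seed=s1,
        n_genes=n_genes,
        gene_length=500,
        reads_per_gene=2000,
        read_length=90,
        labeled_fraction=0.5,
        conversion_prob=0.02,
        error_rate=1e-3,
        snp_positions=snps,
    )
    ds = simulate(cfg, "bulk")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        res = _run_bulk_dataset(ds, Path(tmp), seed)
    thr = ThresholdConfig()
    blk = res.blacklist
    snp_df = ds.truth.snps
    snp_positions = set(zip(snp_df.contig, snp_df.genomic_pos))
    n_snp_covered = n_snp_blacklisted = 0
    for contig, pos in snp_positions:
        cov = int(res.pileup.coverage_array(contig)[pos])
        if cov >= 20:
            n_snp_covered += 1
            n_snp_blacklisted += blk.contains(contig, pos)
    # conversion-only sites: planted conversion positions that are not SNPs
    conv_sites: Set[Tuple[str, int]] = set()
    tr = ds.truth.reads
    for contig, plist in zip(tr.contig, tr.conversion_positions):
        if isinstance(plist, str) and plist:
            for p in plist.split(","):
                conv_sites.add((contig, int(p)))
    conv_sites -= snp_positions
    n_conv_adequate = n_conv_blacklisted = 0
    for contig, pos in conv_sites:
        if int(res.pileup.coverage_array(contig)[pos]) >= thr.min_coverage:
            n_conv_adequate += 1
            n_conv_blacklisted += blk.contains(contig, pos)
    return {
        "n_snps_covered": n_snp_covered,
        "snp_blacklist_recall": n_snp_blacklisted / max(n_snp_covered, 1),
        "n_conversion_sites": n_conv_adequate,
        "n_conversion_sites_blacklisted": n_conv_blacklisted,
    }


def rate_recovery_benchmark(seed: int, workdir: Optional[Path] = None) -> Dict[str, float]:
    """Observation-mode rates vs the closed-form expectation.

    For labeled fraction f, per-T conversion probability p and uniform
    error rate e, the expected conversion probability per T base call is
    f*p + (1 - f*p) * e/3. The fraction of genes within 3 binomial
    standard errors of that value is reported.
    """
    (s1,) = _seeds(seed, 1)
    f, p, e = 0.5, 0.04, 1e-3
    cfg = SimConfig(
        seed=s1,
        n_genes=500,
        gene_length=1000,
        reads_per_gene=200,
        read_length=90,
        labeled_fraction=f,
        conversion_prob=p,
        error_rate=e,
    )
    ds = simulate(cfg, "bulk")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        res = _run_bulk_dataset(ds, Path(tmp), seed)
    expected = f * p + (1 - f * p) * e / 3
    n_scored = n_within = 0
    for s in res.stats:
        if s.rate is None:
            continue
        n_scored += 1
        se = np.sqrt(expected * (1 - expected) / s.t_observations)
        n_within += abs(s.rate - expected) <= 3 * se
    return {
        "n_genes_scored": n_scored,
        "expected_rate": expected,
        "mean_rate": float(np.mean([s.rate for s in res.stats if s.rate is not None])),
        "fraction_within_3se": n_within / max(n_scored, 1),
    }


_SPIKE_GENES = [f"gene{i:04d}" for i in range(1, 11)]


def _spike_config(seed: int, conversion_prob: float) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_genes=1000,
        gene_length=1000,
        reads_per_gene=300,
        read_length=90,
        labeled_fraction=0.01,
        conversion_prob=conversion_prob,
        error_rate=1e-3,
        spiked_genes={g: 20.0 for g in _SPIKE_GENES},
    )


def spike_recovery_benchmark(seed: int, workdir: Optional[Path] = None) -> Dict[str, float]:
    """Spiked-gene recovery at k=5 plus the matched null control.

    10 of 1000 genes are spiked to 20x the background labeled fraction;
    the null arm repeats the simulation with conversion probability 0
    (errors only) and must select almost nothing.
    """
    s1, s2 = _seeds(seed, 2)
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        res = _run_bulk_dataset(simulate(_spike_config(s1, 0.04), "bulk"), Path(tmp) / "a", seed)
        null = _run_bulk_dataset(simulate(_spike_config(s2, 0.0), "bulk"), Path(tmp) / "b", seed)
    sel = res.selected.genes
    nsel = null.selected.genes
    return {
        "n_spikes": len(_SPIKE_GENES),
        "n_spikes_recovered": sum(g in sel for g in _SPIKE_GENES),
        "n_selected": len(sel),
        "n_selected_null": len(nsel),
        "null_selected_fraction": len(nsel) / 1000,
        "null_smaller_than_spiked": float(len(nsel) < len(sel)),
    }


_CORE_GENES = [f"gene{i:04d}" for i in range(1, 18)]  # 17-gene planted core


def consensus_benchmark(
    seed: int, n_samples: int = 5, workdir: Optional[Path] = None
) -> Dict[str, float]:
    """Consensus over replicate samples sharing a 17-gene core.

    Each of five samples shares the same strongly labeled core and adds
    two sample-private spiked genes; the 3-of-5 consensus should return
    exactly the planted core.
    """
    seeds = _seeds(seed, n_samples)
    from .bulk import consensus_genes

    sets = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for i, s in enumerate(seeds):
            private = [f"gene{100 + 2 * i + j:04d}" for j in (1, 2)]
            spiked = {g: 40.0 for g in _CORE_GENES + private}
            cfg = SimConfig(
                seed=s,
                n_genes=1000,
                gene_length=1000,
                reads_per_gene=200,
                read_length=90,
                labeled_fraction=0.01,
                conversion_prob=0.04,
                error_rate=1e-3,
                spiked_genes=spiked,
            )
            res = _run_bulk_dataset(simulate(cfg, "bulk"), Path(tmp) / f"s{i}", seed)
            sets.append(res.selected)
    core = consensus_genes(sets, min_samples=3)
    planted = set(_CORE_GENES)
    return {
        "n_consensus": len(core),
        "n_planted_core": len(planted),
        "n_core_recovered": len(core & planted),
        "n_spurious": len(core - planted),
        "exact_match": float(core == planted),
    }


def umi_removal_benchmark(seed: int, workdir: Optional[Path] = None) -> Dict[str, float]:
    """Labeled-UMI removal vs per-molecule ground truth.

    500 cells x 20 UMIs x 2 reads at conversion probability 0.04 and
    read length 90. Recall/precision are measured against the
    *detectable* molecules (labeled with >= 2 distinct planted
    conversion positions covered by their reads); sensitivity against
    the raw labeled flag is reported alongside, since a molecule whose
    reads happen to carry fewer than two conversions is invisible to any
    caller at this threshold. Also checks entry-wise count conservation
    and that an unreachable threshold removes nothing.
    """
    (s1,) = _seeds(seed, 1)
    cfg = SimConfig(
        seed=s1,
        n_genes=50,
        gene_length=1000,
        read_length=90,
        conversion_prob=0.04,
        error_rate=1e-3,
        labeled_fraction=0.3,
        n_cells=500,
        umis_per_cell=20,
        reads_per_umi=2,
    )
    ds = simulate(cfg, "sc")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        paths = ds.write(Path(tmp) / "sim")
        base = dict(
            alignments=str(paths["sam"]),
            reference=str(paths["fasta"]),
            annotation=str(paths["gtf"]),
            seed=seed,
        )
        res = run_sc(RunConfig(output_dir=str(Path(tmp) / "out"), **base))
        hi = RunConfig(output_dir=str(Path(tmp) / "hi"), **base)
        hi.thresholds = hi.thresholds.replace(sc_min_conversions=10**9)
        res_hi = run_sc(hi)
    mols = ds.truth.molecules
    detectable = {
        (r.cell_barcode, r.umi, r.gene_id)
        for r in mols.itertuples(index=False)
        if r.detectable
    }
    labeled_truth = {
        (r.cell_barcode, r.umi, r.gene_id) for r in mols.itertuples(index=False) if r.labeled
    }
    removed = {u.key for u in res.umis if u.labeled}
    tp = len(removed & detectable)
    conserved = (res.raw.matrix - res.corrected.matrix).min() >= 0 and res.raw.total() == (
        res.corrected.total() + len(res.removed)
    )
    per_entry = res.raw.matrix - res.corrected.matrix
    removed_mat = np.zeros(per_entry.shape, dtype=np.int64)
    gi = {g: i for i, g in enumerate(res.raw.gene_ids)}
    ci = {c: i for i, c in enumerate(res.raw.barcodes)}
    for u in res.umis:
        if u.labeled:
            removed_mat[gi[u.gene_id], ci[u.cell_barcode]] += 1
    entrywise = bool((np.asarray(per_entry.todense()) == removed_mat).all())
    return {
        "n_molecules": len(mols),
        "n_detectable": len(detectable),
        "n_removed": len(removed),
        "removal_recall": tp / max(len(detectable), 1),
        "removal_precision": tp / max(len(removed), 1),
        "sensitivity_vs_labeled_flag": len(removed & labeled_truth) / max(len(labeled_truth), 1),
        "count_conservation": float(bool(conserved) and entrywise),
        "threshold_inf_identity": float(
            (res_hi.raw.matrix != res_hi.corrected.matrix).nnz == 0
        ),
    }


STRESS_GENES = [f"gene{i:04d}" for i in range(1, 21)]


def stress_correction_benchmark(seed: int, workdir: Optional[Path] = None) -> Dict[str, float]:
    """Desk-scale analogue of activated-cluster merging after correction.

    A parent population and a pseudo-activated subpopulation differ only
    in extra labeled molecules on 20 stress genes. The between-centroid
    Euclidean distance on those genes is measured on the raw and the
    corrected matrix; correction should collapse it.
    """
    (s1,) = _seeds(seed, 1)
    cfg = SimConfig(
        seed=s1,
        n_genes=30,
        gene_length=1000,
        read_length=90,
        conversion_prob=0.2,
        error_rate=1e-3,
        labeled_fraction=0.05,
        umis_per_cell=120,
        reads_per_umi=2,
        populations=[
            PopulationSpec("parent", 150, 0.05),
            PopulationSpec("activated", 75, 0.05, {g: 4 for g in STRESS_GENES}),
        ],
    )
    ds = simulate(cfg, "sc")
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        paths = ds.write(Path(tmp) / "sim")
        res = run_sc(
            RunConfig(
                alignments=str(paths["sam"]),
                reference=str(paths["fasta"]),
                annotation=str(paths["gtf"]),
                output_dir=str(Path(tmp) / "out"),
                seed=seed,
            )
        )
    mols = ds.truth.molecules
    pop_of = dict(zip(mols.cell_barcode, mols.population))
    cells = np.array([pop_of[c] for c in res.raw.barcodes])
    gmask = np.array([g in STRESS_GENES for g in res.raw.gene_ids])

    def centroid_distance(mat) -> float:
        dense = np.asarray(mat.todense(), dtype=float)[gmask]
        a = dense[:, cells == "parent"].mean(axis=1)
        b = dense[:, cells == "activated"].mean(axis=1)
        return float(np.linalg.norm(a - b))

    d_raw = centroid_distance(res.raw.matrix)
    d_cor = centroid_distance(res.corrected.matrix)
    return {
        "raw_centroid_distance": d_raw,
        "corrected_centroid_distance": d_cor,
        "distance_ratio": d_cor / d_raw if d_raw else float("nan"),
    }


def _hash_tree(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def determinism_benchmark(seed: int, workdir: Optional[Path] = None) -> Dict[str, float]:
    """Byte-identity of repeated runs with the same seed and config."""
    (s1,) = _seeds(seed, 1)
    bulk_cfg = SimConfig(
        seed=s1, n_genes=20, gene_length=500, reads_per_gene=50,
        snp_positions=[(0, 250, 0.5)], low_quality_fraction=0.1,
    )
    sc_cfg = SimConfig(
        seed=s1, n_genes=10, gene_length=500, n_cells=30, umis_per_cell=10,
        reads_per_umi=2, conversion_prob=0.1, labeled_fraction=0.3,
    )
    hashes = []
    cwd = os.getcwd()
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        for rep in ("r1", "r2"):
            # identical relative paths per rep, so the serialized configs
            # (which record the input locations) are comparable bytes
            rep_dir = tmp / rep
            rep_dir.mkdir()
            os.chdir(rep_dir)
            try:
                d = simulate(bulk_cfg, "bulk")
                d.write("bulk_sim")
                run_bulk(
                    RunConfig(
                        alignments="bulk_sim/alignments.sam",
                        reference="bulk_sim/reference.fa",
                        annotation="bulk_sim/genes.gtf",
                        output_dir="bulk_out",
                        seed=seed,
                    )
                )
                ds = simulate(sc_cfg, "sc")
                ds.write("sc_sim")
                run_sc(
                    RunConfig(
                        alignments="sc_sim/alignments.sam",
                        reference="sc_sim/reference.fa",
                        annotation="sc_sim/genes.gtf",
                        output_dir="sc_out",
                        seed=seed,
                    ),
                    fractions=[0.0, 0.5, 1.0],
                )
            finally:
                os.chdir(cwd)
            # the FASTA index is a cache written by the reader, not an output
            for fai in rep_dir.rglob("*.fai"):
                fai.unlink()
            hashes.append(_hash_tree(rep_dir))
    return {"identical_reruns": float(hashes[0] == hashes[1])}


def run_all(seed: int) -> Dict[str, Dict[str, float]]:
    """Run every validation experiment with seeds derived from one seed."""
    s = _seeds(seed, 8)
    return {
        "mismatch_extraction": mismatch_extraction_benchmark(s[0]),
        "snp_blacklist": blacklist_benchmark(s[1]),
        "rate_recovery": rate_recovery_benchmark(s[2]),
        "spike_recovery": spike_recovery_benchmark(s[3]),
        "consensus": consensus_benchmark(s[4]),
        "umi_removal": umi_removal_benchmark(s[5]),
        "stress_correction": stress_correction_benchmark(s[6]),
        "determinism": determinism_benchmark(s[7]),
    }
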