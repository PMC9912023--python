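# Methods

## Model and assumptions

`dissoscan` treats metabolic labeling during dissociation as a mark on
nascent transcripts: 4sU incorporated while a gene is transcribed converts,
after alkylation and reverse transcription, to a T→C substitution on the
transcript strand. The pipeline therefore assumes

- reads come from a sense-stranded 3'-tag style library, so a read's
  alignment strand should match its gene's annotated strand; antisense reads
  are uninterpretable under the chemistry and are discarded by default
  (configurable);
- alignments carry MD tags (added by the mapper or `samtools calmd`), so
  mismatches are reconstructable without touching the reference during
  extraction;
- conversions are rare per molecule and independent across T positions,
  while SNPs are positionally fixed — which is what makes a per-position
  allele-fraction filter effective at separating the two.

Conversions are resolved to the transcript strand: genomic A→G on a
minus-strand gene counts as T→C. Whether the original analysis
strand-resolved or counted genomic T→C only is not documented for the method
this package re-implements; both modes are provided (`genomic_only`), with
strand resolution the default because strand-naive counting forfeits the
signal on minus-strand genes. The substitution *spectrum*, by contrast, is
reported in genomic orientation over all 12 substitution types, which is the
conventional diagnostic plot.

## Thresholds

All cutoffs live in `ThresholdConfig`; defaults are the assay's published
operating points and are deliberately not auto-tuned.

| parameter | default | meaning |
|---|---|---|
| `min_quality` | 20 (Phred) | base calls below Q20 (≈1 % error) count nowhere — neither conversions nor coverage |
| `max_alt_frac` | 0.25 | non-reference fraction strictly above this marks a SNP-like site |
| `min_coverage` | 10 | coverage strictly below this is too shallow to judge |
| `k_sd_select` | 5 | response genes: rate > mean + 5·SD of all scored genes |
| `k_sd_pca` | 1 | looser 1·SD rule restricting the PCA input matrix |
| `sc_min_conversions` | 2 | distinct converted positions flagging a molecule as labeled |
| `sc_min_units` / `sc_min_frac` | 250 / 0.10 | per-(gene, cell type) reporting floor |
| `report_min_removed` / `report_min_frac` | 3 / 0.05 | removal-report gene filter (reads) |
| `consensus_min_samples` | 3 | replicates a gene must be selected in |

Inequality conventions are fixed once and used everywhere: the alt-fraction
and coverage rules are strict exactly as worded ("more than 25 %", "below
10"), so 3/12 alternative calls or coverage exactly 10 pass; the SD
selection uses strict ">" (source wording alternates between "over" and
"≥" across figure captions, so one convention had to be declared); the
single-cell reporting floors are inclusive ("at least"). The SD is the n−1
sample estimator over genes with non-missing rates. Genes with zero T
coverage are reported as missing, not rate 0 — a zero would drag the
mean/SD and misstate absence of evidence.

Two readings of the per-gene rate are exposed because the phrase "fraction
of non-blacklisted T-positions" is genuinely ambiguous: `observation` mode
(converted T base calls / all T base calls) is coverage-weighted and is the
standard SLAM-seq estimator — it is the default — while `site` mode
(converted T sites / covered T sites) preserves the literal wording. Both
are tested.

The 25 % rule counts all non-reference calls by default; a `tc_only` switch
restricts it to the T→C-like alternative (C at reference T, G at reference
A), matching a narrower reading of the filter's description.

For single-cell removal, "2 or more labeling events" per UMI counts
*distinct converted reference positions unioned across the molecule's
reads*: a UMI denotes one molecule and its conversions are molecular
properties. An `any_read` alternative (max within a single read) is provided
since the original code's convention is not documented. No SNP blacklist is
applied in single-cell mode by default — the published filter names only the
Q20 rule there — but `use_blacklist` enables it. For the per-(gene, cell
type) summary the unit is the UMI by default ("reads" appears in one caption,
"UMIs" in the text); both are selectable.

## Pipeline mechanics and numerical choices

- Coordinates are 0-based half-open internally (BAM convention); 1-based
  only in text outputs (events TSV) and GTF.
- The CIGAR+MD walk emits one event per mismatching aligned position;
  insertions/soft clips advance the read only, deletions/skips the reference
  only (MD covers deletions but not N skips). Mismatches involving N on
  either side are dropped, and N bases never count as observations.
  MD/CIGAR inconsistencies raise an error naming the read; missing MD tags
  are skipped with a counted warning by default (hard-fail mode available),
  and a run aborts when more than `max_missing_md_frac` of reads lack MD.
- Reads overlapping no gene, more than one gene, or antisense to their gene
  are excluded from all genes and counted in the run summary. The bulk
  pileup is built from exactly the reads that feed the rates, so the
  blacklist judges the same evidence the rate uses; the blacklist is
  per-sample, with a union operation for cross-sample masking.
- Overlapping mate pairs would be double-counted; the targeted libraries are
  single-end, and deduplication is documented as an upstream step rather
  than re-implemented.
- The pileup is stored as one 4×L count array per contig, so blacklisting
  and per-gene denominators are vectorized; the substitution spectrum is
  computable both per read (from MD alone) and from pileup marginals, and
  the two routes are asserted identical in the tests.
- `gradual_removal` removes round(f·n) (half-up) of the n labeled molecules,
  drawn without replacement from a permutation seeded once — subsets are
  nested across fractions, f=0 reproduces the raw matrix and f=1 the
  corrected one.
- All randomness (simulator, gradual removal) flows from explicit seeds; an
  output directory always contains the resolved config, tool version and a
  JSON summary counting every discard path, and a rerun from the same
  config/seed is byte-identical.

## The simulator

`dissoscan.simulate` emulates the data regime the pipeline targets:
single-exon genes, one per contig (splicing is out of scope), exact
plus/minus strand split per `strand_mix`; a labeled subpopulation of reads
(bulk) or molecules (single-cell) converting each transcript-strand T with
probability `conversion_prob`; uniform errors at rate `error_rate` per base,
uniform over the three alternatives so the background rate of any specific
substitution is e/3 — an analytic check for the spectrum; SNP positions
emitting a fixed alternative at a configured allele fraction; a two-point
quality mixture (Q37/Q12) exercising the Q20 filter, with planted
conversions on high quality by default; and, in single-cell mode,
`reads_per_umi` reads per molecule sharing the molecule's labeled flag and
planted conversion set, with CB/UB/GX tags. Planted conversions, SNP draws
and errors are mutually exclusive per base, so each read's mismatch set
equals their union exactly — this is what lets the generator serve as an
oracle for the extraction stage. MD tags are computed by the generator and
cross-checked against `samtools calmd` in the tests.

Defaults describe a realistic 3'-tag experiment: 90 bp reads, conversion
probability 0.04 per T in labeled units, error 10⁻³ per base, labeled
fraction 0.5 (bulk two-sample designs) — values chosen once to match the
assay's working regime.

What the simulator does **not** model: fragment-length/GC bias, PCR
duplication structure, spliced alignments, barcode sequencing errors,
expression heterogeneity beyond uniform gene sampling, and doublets.
Passing tests therefore demonstrate correctness of the *computational*
contract (extraction, filtering, counting, selection, removal), not
robustness to every artifact of real libraries.

## Validation experiment designs

Problem sizes were chosen so each experiment completes in minutes on one
CPU while keeping effects many standard errors wide:

- **Mismatch extraction** — 2 000 reads, half with mixed CIGARs (soft clips,
  insertions, deletions, skips); exact set-equality against a brute-force
  base-by-base diff of each read versus the reference FASTA slice (the
  oracle never reads MD).
- **Blacklist** — 50 heterozygous SNPs (alt fraction 0.5) at deeply covered
  mid-gene positions among 25 genes at ~400× coverage; recall is evaluated
  on SNPs with coverage ≥ 20, specificity on conversion-only sites with
  coverage ≥ 10, since shallower sites are excluded by the coverage rule by
  design.
- **Rate recovery** — 500 genes × 200 reads, f = 0.5, p = 0.04, e = 10⁻³;
  observation-mode rates versus f·p + (1−f·p)·e/3. The low-quality base
  fraction is 0 here because the closed form presumes the Q20 filter is
  neutral between numerator and denominator, while planted conversions ride
  high quality. Per-read labeled status correlates the ~22 T calls within a
  read, inflating the per-gene SD to ≈1.2× the binomial SE, so a 3-binomial-SE
  band captures ≈99 % of genes rather than 99.7 %.
- **Spike recovery** — 10 of 1 000 genes at 20× the background labeled
  fraction (0.01), 300 reads/gene. The spiked fraction must stay near 1 %:
  spikes inflate the population SD, and above w ≈ 1/26 the mean + 5·SD
  threshold overtakes the spikes themselves. The null arm repeats the
  simulation with conversion probability 0.
- **Consensus** — five samples, a shared 17-gene core plus two private
  spiked genes each at 40× over 1 000 genes; the larger multiplier keeps
  each core gene ≈3 SE above threshold per sample so the 3-of-5 consensus
  is exact with high probability.
- **UMI removal** — 500 cells × 20 UMIs × 2 reads, p = 0.04, 90 bp reads.
  At these settings a labeled molecule exposes ~45 T calls, so it carries
  ≥ 2 distinct conversions with probability only ≈0.5 — a chemistry limit no
  caller can beat. Recall/precision are therefore measured against the
  *detectable* truth (labeled molecules with ≥ 2 planted conversion
  positions covered by their reads at passing quality), which isolates
  caller correctness; sensitivity against the raw labeled flag is reported
  alongside as the chemistry-level figure.
- **Stress correction** — parent (150 cells) and pseudo-activated (75
  cells) populations identical except for 4 extra labeled molecules per
  cell on each of 20 stress genes, p = 0.2 so labeled molecules are almost
  always detectable; the between-centroid Euclidean distance on the stress
  genes is compared raw versus corrected.
- **Determinism** — two full bulk + single-cell runs from identical
  configs/seeds, compared by hashing every output byte (the FASTA `.fai`
  index, a reader-side cache, is excluded).

## Known limitations

- Gene assignment is by unique interval overlap (bulk) or the upstream GX
  tag (single-cell); overlapping gene models reduce usable reads rather
  than being apportioned.
- The blacklist stores per-contig position masks — appropriate for the
  simulator's contig-per-gene references and for targeted panels; a
  whole-genome run would want an interval-compressed store.
- No estimation of the labeled fraction per gene (new/old RNA mixture
  modeling) is attempted: the statistic is the raw conversion rate plus an
  SD rule, as in the protocol this package operationalizes.
- Plotting is left to downstream tools; outputs are plain TSV/BED/MTX
  chosen to drop into pandas, genome browsers and 10x-compatible loaders.
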