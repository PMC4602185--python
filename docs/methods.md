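# Methods

## Pipeline model and assumptions

The analysis treats one gene's data as a pair of non-negative count tracks
over the CDS (ribo-seq and mRNA-seq, one value per nucleotide, CDS
coordinates, frame 0). All inference happens at codon resolution: the codon
value is the mean of its three nucleotide counts. Peak positions denote the
ribosomal A-site; no additional P-site correction is applied at mapping
time. Coordinates are 0-based half-open internally; the wiggle I/O boundary
is 1-based.

Assumptions worth making explicit:

- mRNA-seq counts fluctuate around a per-gene mean much more tightly than
  ribo-seq counts do, so the RD/mRNA ratio removes shared library biases
  while preserving dwell-time signal.
- The first 20 codons are initiation-biased and are excluded from every
  statistic (masked, not deleted).
- Extreme stalls are *rare, isolated* codons; this motivates both the
  mean + 4·SD peak rule and the 20 % bound on how much of a protein the
  union of USRs may cover (beyond that, randomizing peak positions within
  the gene is no longer meaningful and the gene is excluded from the
  permutation tests).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `exclude_first` | 20 codons | initiation region masked everywhere |
| `min_nonzero_fraction` | 0.40 | minimum non-zero fraction of the ribo codon profile (over unmasked codons) for a gene to be analysed; 0.60 available as a stricter check |
| `k_sd` | 4.0 | peak threshold in SDs above the gene mean (non-zero, unmasked codons; sample SD, strict inequality) |
| `tunnel_window` | 31 codons | USR length = exit-tunnel occupancy |
| `n_randomizations` | 1000 | null draws for empirical p-values |
| `alpha` | 0.05 | classification level; BH-FDR annotated at 0.05 and 0.10 |
| `max_usr_coverage` | 0.20 | per-gene bound on the USR union before the gene is dropped from randomization |
| SD filter | GGAGGU, ≤ 1 mismatch, spacings {8, 9, 10, 11} | prokaryote-only exclusion of Shine–Dalgarno-driven pauses; the literal spacing set {8, 9, 11} is available (`LITERAL_SD_SPACINGS`) because published descriptions of the rule disagree on whether 10 is included — neither behaviour is asserted as the intended one |

Design choices where the procedure was genuinely open:

- **Coverage scaling.** "Gene coverage" is the simple mean over unmasked
  codons, zeros included (`exclude_zeros_in_scaling` switches to the
  zero-excluding mean). Including zeros keeps the ratio well defined and
  matches coverage as conventionally computed.
- **Moments for peak calling.** The zero- and first-20 exclusions are
  applied to the SD as well as the mean — the coherent reading when both
  moments describe the same background distribution.
- **Incomplete USRs.** Peaks at codon index < 31 have truncated USRs and
  are excluded from enrichment (reported separately): truncated windows
  would bias per-amino-acid occurrence probabilities.
- **Shared null draws.** One set of 1000 randomized peak placements is
  shared by all 20 amino-acid tests, both charge tests and the positional
  flags. Sharing changes nothing in expectation and makes the whole result
  set jointly reproducible from one seed; per-gene substreams are derived
  from a hash of the gene id, so gene input order cannot change any result.
- **Eligible random positions** are unmasked codons with index ≥ 31
  (complete random USRs, mRNA-valid), sampled without replacement per gene.
- **Underrepresentation** uses the mirrored counting formula
  `#{null ≤ observed}/N`; both sides count ties, so the two one-sided
  p-values sum to ≥ 1.
- **BH family.** The 20 per-amino-acid enrichment p-values of one dataset;
  the charge-class tests are reported with raw p-values only.
- **p = 0** is stored as 0.0 and printed as "< 1/N".
- **Positional flags.** The significance rule behind high/low flags is not
  uniquely determined by the figure it mirrors; the default is a two-sided
  empirical test (level 0.05) of each (amino acid, position) probability
  against the randomized-peak null, reusing the enrichment draws. A
  within-row percentile mode (`flag_row_percentile`) implements the
  alternative reading.
- **tAI.** W(codon) = Σ (1 − s) · tGCN over the Watson–Crick and single
  wobble anticodon of the codon's third-base class; w = W/max W, zero-W
  codons get the geometric mean of the non-zero weights. Default s-values
  (shipped in `stallscan/data/s_values.yaml`, overridable): Watson–Crick 0,
  G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68. The P-site codon is taken one
  codon upstream of the A-site peak (`use_peak_codon` switches to the peak
  codon itself).
- **Aggregation** depth-normalizes each dataset by its total read count and
  averages per gene; coverage scaling and RD/mRNA normalization are applied
  to the aggregate afterwards, matching the stage order of the filtering
  cascade.

## Synthetic data: what it emulates and what it does not

`SyntheticConfig` generates CDSs (ATG + body codons drawn from a codon-usage
table over the 61 sense codons + one stop) and paired count profiles:

- mRNA-seq: negative-binomial counts per nucleotide around a per-gene mean
  drawn log-uniformly from `mrna_mean_range` (default 5–50 reads/nt;
  dispersion 0.1, Poisson as dispersion → 0). The log-uniform spread
  produces sparse low-expression genes that exercise the 40 % filter.
- ribo-seq: per-codon counts with mean `reads_per_gene_scale × dwell ×
  local mRNA abundance`, spread multinomially over the codon's three
  nucleotides. Total reads scale linearly with `reads_per_gene_scale`.
- dwell model: a codon's dwell time is multiplied by `stall_multiplier`
  when any amino acid from `stalling_amino_acids` occurs within
  `tunnel_window` codons upstream — the trigger sits inside the USR of the
  elevated codon, the geometry the analysis is built to detect.

Not emulated: UTRs, introns, isoforms, raw reads/alignment, sequence-driven
library biases (GC, ligation), 5′ ramp effects, or real codon-usage tables.
Passing tests therefore demonstrate the correctness and calibration of the
*statistics* under the stated generative model, not robustness to every
artefact of real profiling libraries.

### Benchmark conditions

- **Null calibration** (`make_null_config`): 200 genes × 300 codons,
  uniform codon usage, `stall_multiplier = 1`. Peaks are pure noise
  outliers; across 20 replicates the fraction of amino acids classified
  significant (either direction, two one-sided tests at 0.05) is expected
  near the nominal ~10 % minus discreteness losses; the test band is
  0.5–12 %.
- **Planted-signal recovery** (`make_recovery_config`): default gene set
  (200 genes × 250–350 codons), planted amino acids at total codon mass
  0.002 each (`rare_aa_usage`), `stall_multiplier = 30`, and the dwell
  elevation placed at the single codon immediately downstream of each
  trigger (generator `tunnel_window = 1`). The last choice is deliberate:
  elevating the full 31-codon window downstream of a trigger produces a
  *run* of peaks whose USRs all share one trigger window. Such peaks are
  pseudo-replicates — their USR compositions are almost perfectly
  correlated — which violates the exchangeability the randomized-peak null
  assumes; no permutation scheme that redraws positions independently is
  calibrated for them, and empirically they inflate false positives for
  high-frequency amino acids. Real extreme stalls are isolated codons, so
  the isolated-peak benchmark is both the statistically sound and the more
  faithful construction. Recovery of the planted amino acid itself succeeds
  under either geometry.

## Numerical notes

- Sample SD (ddof = 1) throughout peak calling; ties at exactly
  mean + k·SD are not peaks (conservative strict inequality).
- Genes with fewer than two positive unmasked codons yield no peaks (SD
  undefined); genes with more peaks than eligible positions are skipped by
  the randomization with a warning.
- Randomized placements are drawn by ranking uniform keys (argpartition),
  exact sampling without replacement; with k equal to the eligible-set size
  the draw is the eligible set itself.
- Degenerate inputs raise typed errors (`InputError`,
  `ConfigurationError`) rather than propagating NaNs; an empty peak set
  classifies every amino acid "not_significant" with a warning.
- All randomness flows from explicit integer seeds; identical seeds give
  byte-identical output tables.

## Known limitations

- Empirical p-values are bounded below by 1/N (N = 1000 by default);
  FDR-adjusted q-values inherit that granularity.
- The positional-flag null reuses the enrichment placements, so flags and
  enrichment calls are correlated diagnostics, not independent evidence.
- The SD filter is string matching only; it does not model hybridization
  energetics.
- `aggregate_datasets` requires equal CDS lengths per gene across datasets
  (no isoform reconciliation).
- Validation sizes (20 replicates for calibration/recovery, 1000
  randomizations, toy enumeration instances of ~10³ placements) were chosen
  to keep the full validation suite in the single-digit-minutes range on
  one CPU while leaving the Monte-Carlo error well below the decision
  margins it is compared against.
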