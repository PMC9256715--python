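# Methods

## The problem

miRNA maturation is a two-cut process: Drosha crops the primary transcript
into a hairpin precursor, and Dicer trims the hairpin into the mature
duplex. Both cuts are imprecise. A shift of the 5' cut by even one
nucleotide moves the seed (nt 2–7 from the 5' end) and therefore rewires
the target repertoire — such 5'-shifted products are 5'-isomiRs. This
package quantifies 5'-isomiRs from small-RNA-seq reads, expresses each
isoform's output as an **isomiR ratio**, compares ratios between
conditions and cohorts, associates them with pri-miRNA cis-motifs and
RNA-binding-protein (RBP) signals, stratifies survival, and predicts the
shifted-seed target sites. A synthetic cohort generator with exported
ground truth makes every stage testable without external downloads.

## Quantification model

Reads (adapters already removed) are collapsed to unique sequences with
per-sample counts, then aligned ungapped against the hairpin catalog. The
hairpins are short enough that an exhaustive substring scan is exact, so
the aligner is built in: an index of all 15–35-nt windows for exact
matching, and a sliding-window comparison for the optional 1–2-mismatch
mode. Windows containing N never match.

Each alignment is classified by its signed offset from the nearest
annotated mature 5' end on that arm (within `max_offset`, default 5 nt;
ties between arms go to 5p). **Sign convention:** positive offsets start
downstream of the canonical 5' end (a "+1" isomiR is one nucleotide
shorter at its 5' end). The opposite convention is available via
`flip_sign`. 3'-end variants of the same 5' end collapse to a single key
— the 5' end defines the seed — but the per-key distribution over 3'
offsets is retained, since the Dicer cut depends partially on the 5' end
(5'-counting rule) and this profile is the diagnostic for it.

Multi-mapping reads contribute count/k to each of k classified loci by
default ("fractional"; "discard" and "all" are available). Counts become
reads-per-million over the assigned total by default (an external
mapped-read total is accepted). Expression filtering keeps keys with
>= 1 RPM in >= 7 samples by default.

**Re-annotation.** When, summed over the discovery cohort, a non-zero
offset strictly out-counts the annotated canonical product on an arm, the
canonical 5' end is moved there and every offset is re-expressed relative
to the new anchor (the former canonical becomes the isoform at −d). The
rule uses summed raw counts (robust to per-sample noise), is idempotent,
and is applied before expression filtering. Both mature start and end are
shifted by d, preserving mature length; only the start matters for
5'-offset keys because 3' ends are collapsed.

## IsomiR ratio and statistics

The ratio of isoform i in sample s is
`RPM_i(s) / (RPM_canonical(s) + Σ_j RPM_j(s))` over all isoforms j of the
same (locus, arm) — the fraction of the arm's total output. The
canonical-only denominator is available behind a flag. Ratios are missing
(never imputed) where the arm total is zero.

* **Differential ratio:** one-way ANOVA on per-sample ratios between
  groups. With zero within-group variance the F statistic degenerates;
  the implementation reports p = 1 when all values are equal and a tiny
  floor (1e-300) when the groups are separated, the F-limit behavior.
  Keys without >= 2 non-missing values per group are reported untested.
* **Differential expression:** one-tailed Wilcoxon rank-sum for unpaired
  designs, signed-rank (zero differences removed) for paired designs,
  defaulting to "up in tumor".
* **FDR:** Benjamini–Hochberg step-up, one family per (test, cohort);
  "cohort-consistent" isomiRs are those at q <= alpha in *every* cohort.
* **Abundance regression:** OLS of isomiR RPM on canonical RPM and the
  isomiR ratio after min-max scaling of all variables to [0, 1], so
  coefficients are comparable across cohorts.
* **Cross-cohort stability:** Pearson r of per-key mean ratios over keys
  shared between cohort pairs.
* **qPCR:** relative expression 2^−(Target Ct − Control Ct).

## Cis-motifs and RBP association

The scanner reports the Microprocessor-orienting motifs on the flanked
hairpin (default 250-nt flanks): a literal UG in a window upstream of the
5p mature start (default [−17, −11], around the ~13-nt basal-junction
distance), UGU/GUG in the apical loop, CNNC with its first C in
[+15, +21] downstream of the 3p mature end, and maximal poly-U runs
(>= 4 nt, hnRNPC-type binding tracts) anywhere in the flanks. Windows
are configurable; the structure-dependent mGHG element is out of scope
because it requires duplex modeling.

eCLIP peaks are intersected with pre-miRNA ± flank windows in BED
0-based half-open arithmetic (strand-blind by default). RBP–ratio
association reports per-cohort Pearson r/p and a multivariate OLS
coefficient for the RBP controlling for host-transcript and canonical
miRNA levels (min-max scaled), BH-corrected across RBPs.

## Target sites

Seeds are nt 2–7 (extended 2–8). On the UTR read 5'→3', a site anchored
at a seed6 reverse-complement match is typed by the m8 base (one
upstream) and the A1 adenosine (one downstream): 8mer > 7mer-m8 >
7mer-A1 > 6mer. A gene qualifies as a putative target with any 7/8mer
site, or a 6mer carrying an externally supplied context score below
−0.1; the scoring model itself is consumed, never computed. Shared
targets of two isoforms are the intersection of qualifying genes, with
gained/lost sets relative to the canonical miRNA. With multiple
transcripts per gene, the longest supplied UTR is used.

## Survival

Markers (expression or ratio) are split at the median; ties at the
median go to "low" (deterministic). Kaplan–Meier estimation and Cox
proportional hazards come from lifelines; ties are handled by Efron's
method, the default of R's `coxph` that the field's survival analyses
use. Wald z = log-HR / SE with a two-sided p. Perfect separation is
flagged, not estimated. An isomiR is "clinically relevant" when its
ratio is differential in all cohorts and its Wald p <= 0.05 in at least
one dataset.

## Synthetic cohorts

The generator mirrors the biology the pipeline measures:

* **Catalog:** random 72-nt hairpins, 5p mature at [12, 34), 3p at
  [38, 60), 250-nt flanks, optional planted basal UG / CNNC / poly-U
  motifs at fixed, scanner-visible positions.
* **5' offsets:** per-locus baseline distribution π over −2..+2 drawn
  from a Dirichlet with mean P(0) = 0.75 (most loci process precisely;
  some are sloppy), plus per-sample log-weight jitter (sd 0.15) for
  biological variability.
* **Group effect:** a per-sample RBP expression (non-tumor mean 1.0,
  tumor mean 2.0, sd 0.25) acts log-additively on the ±1 offset weights
  at planted loci, calibrated in closed form so the mean tumor shift of
  P(+1)+P(−1) equals `delta_ratio` (default 0.15). Any monotone link
  would do for testing; log-additive is the simplest.
* **Counts:** locus abundances are log-normal (sigma 1); per-sample
  totals are negative binomial (gamma–Poisson, dispersion 20); offsets
  are multinomial within the total. Default depth 50,000 assigned reads
  per sample across 50 loci (a nominal 1,000 reads per locus per
  sample) — large enough for sub-0.01 pooled-ratio precision at typical
  loci, small enough for seconds-scale tests.
* **3' ends:** duplex length ~ round(Normal(22, 1)) measured from the
  drawn 5' end, so the 3' end tracks the 5' end (+1 isoforms end ~+1 on
  average; +1 vs −1 differ by ~2 nt). Optional untemplated tailing
  (default 2%) appends a base chosen to never match the hairpin, so
  tailed reads exercise the aligner's mismatch policy.
* **Survival:** exponential event times with hazard ∝
  exp(beta_surv × marker), independent exponential censoring whose rate
  is solved analytically for the target censoring fraction (default
  40%).

Everything is a deterministic function of the seed, and the exported
ground truth contains exactly the per-sample distributions the sampler
used, so pipeline estimates can be compared with their true
expectations rather than with re-simulated values.

**What the generator does not emulate:** sequencing error, adapter
artifacts, GC or ligation bias, genomic multi-mapping across homologous
families, structure-driven cleavage preferences, or correlated
locus–locus regulation. Passing the synthetic checks demonstrates the
pipeline's correctness on its own model, not the upstream mapping
choices of any particular cohort.

## Validation experiments and problem sizes

The `evaluation` module (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs:

* **Recovery:** default cohort through the full read/aligner path;
  pooled per-locus offset fractions vs count-weighted truth at loci
  with >= 1,000 reads per sample, where counting noise (sigma <= 0.005)
  makes the ±0.02 bound a 4-sigma statement.
* **Power/FDR:** 10 loci planted at delta 0.15 among 40 nulls, 20+20
  samples, 20 reps. Power is locus-level recall; FDP is key-level
  (significant keys from null loci over all significant keys) — the
  level at which ANOVA + BH operate, since the planted shift
  renormalizes every offset at a planted locus.
* **Null calibration:** 50 null cohorts (40 loci); rejection fraction at
  q <= 0.05 for both tests.
* **Oracle equivalence:** aligner vs exhaustive scan (100 reads), site
  finder vs brute-force typing (200 pairs), BH vs an independent
  step-up (1,000 vectors), motif scanner vs window enumeration (50
  loci) — all exact.
* **Re-annotation:** 5 of 10 loci built with dominant +1 processing;
  exact locus set, idempotence, offset remap.
* **Cox:** true HR 2.0 per covariate unit at n = 500 with ~50%
  censoring, 50 reps. The covariate is N(0, 1.5²): with ~250 events the
  Wald SE is ~1/(1.5·√events) ≈ 0.042, so the [1.8, 2.2] band is a
  ~2.3-sigma interval; a unit-variance covariate would leave the check
  hovering at its own noise floor. Null Wald p-values are KS-tested for
  uniformity.

## Known limitations

* The aligner is ungapped and hairpin-local by design; reads from
  unannotated loci or with indels are unassigned.
* Offset classification trusts the annotated (or re-annotated) mature
  5' ends; systematically mis-annotated arms outside the `max_offset`
  window are invisible.
* The ANOVA on ratios treats them as unbounded; for ratios near 0 or 1
  with tiny samples a rank or beta-regression approach would be more
  defensible (not implemented).
* The RBP association is correlational; the generator's planted link is
  the only causal ground truth available to the tests.
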