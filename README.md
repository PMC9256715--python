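# isomirshift

5'-isomiR quantification and cohort statistics for small-RNA sequencing.

miRNA 5' ends are set by imprecise Drosha/Dicer cleavage. A 1-nt shift of
the 5' end moves the seed (nt 2–7) and rewires the miRNA's target set —
these 5'-shifted isoforms (**5'-isomiRs**) can behave as distinct
regulators, and their production rate can change with cellular context
(for example through RNA-binding proteins acting on the primary
transcript). `isomirshift` is for computational biologists who want to

* quantify 5'-isomiRs from reads against hairpin annotations
  (miRBase-style FASTA + GFF3), collapsing 3'-end variants while keeping
  the per-isoform 3'-offset profile;
* compute **isomiR ratios** — an isoform's share of its hairpin arm's
  output, `RPM_i / (RPM_canonical + Σ RPM_isomiRs)` — and compare them
  between conditions (one-way ANOVA), cohorts (Pearson), and against
  expression (one-tailed Wilcoxon), with Benjamini–Hochberg FDR and
  cross-cohort intersection;
* re-annotate arms whose dominant 5' end disagrees with the annotation;
* scan pri-miRNA cis-motifs (basal UG, apical UGU/GUG, CNNC, poly-U),
  overlap eCLIP peaks with pre-miRNA flanks, and associate RBP
  expression with isomiR ratios;
* stratify survival by marker medians (Kaplan–Meier, Cox + Wald);
* predict shifted-seed target sites (8mer / 7mer-m8 / 7mer-A1 / 6mer);
* simulate complete cohorts — cleavage-offset distributions, a Dicer
  5'-counting 3'-end model, RBP-driven group shifts, negative-binomial
  counts, survival — with exported ground truth.

## Worked example

Simulate three cohorts (25 loci, 20 non-tumor + 20 tumor samples each)
in which 5 loci shift their ±1-offset output by 0.15 in tumors, run the
full flow, and intersect significance across cohorts:

```python
from isomirshift.pipeline import RunConfig, run_synthetic_pipeline
from isomirshift.synthetic_data import SimConfig

sims = {
    f"cohort{i}": SimConfig(seed=100 + i, n_loci=25, n_planted=5,
                            depth=15_000, beta_surv=(2.0 if i == 0 else 0.0))
    for i in range(3)
}
result = run_synthetic_pipeline(sims, RunConfig())
print(len(result.specific_keys), result.specific_keys[0])
print(len(result.clinically_relevant))
```

prints

```
9 ('sim001', '5p', 'miR-sim-1-5p', -1)
4
```

Nine isomiR keys (all from the five planted loci) have a differential
ratio at q <= 0.05 in **every** cohort; the first is the −1 isoform of
locus `sim001` — in cohort0 its mean ratio rises from 0.095 (non-tumor)
to 0.179 (tumor), ANOVA F = 50.5, q = 7.0e-07. Four of the nine are
additionally associated with simulated overall survival (Cox Wald
p <= 0.05 in at least one dataset), the package's definition of a
clinically relevant isomiR.

The same flow is scriptable from the shell:

```bash
isomir-shift simulate --seed 5 --out sim/
isomir-shift validate --hairpins sim/hairpins.fa --gff sim/matures.gff3
isomir-shift run --seed 2 --out run/
```

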