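# sigselect

Joint analysis of mutation and selection for cancer driver mutations:

- **channels** — parse somatic SNV tables (generic/TCGA/ICGC dialects),
  classify substitutions into the 96 trinucleotide channels under the
  pyrimidine-strand convention, and build per-sample channel count matrices.
- **exposures** — fit per-sample mutational-signature exposures by
  non-negative least squares against a signature catalog (the 30-signature
  COSMIC v2 matrix is bundled), optionally rescaled to exome trinucleotide
  frequencies, with a simulation-based calibration of the minimum-mutation
  cutoff.
- **association** — find recurrent driver mutations, map each to its causal
  channel, select channel-enriched candidate signatures, test
  carrier/non-carrier exposure differences (one-sided Mann–Whitney U) with
  Benjamini–Hochberg FDR control, and estimate detection power by
  simulation.
- **selection** — quantify differential selection between driver mutations:
  per-sample causal-channel probabilities, an exact Poisson binomial
  two-tailed test, maximum-likelihood relative-risk estimation with
  bootstrap confidence intervals, and a variance-explained regression.
- **simulate** — synthetic cohorts with known ground truth: Dirichlet
  exposures, multinomial channel draws, and driver mutations planted under
  the multistage initiation model with specified relative risks.
- **pipeline / cli** — configuration-driven orchestration with deterministic
  per-stage seeding.

## CLI

All stages are subcommands of `sigselect` (add `-v` for INFO logging,
including per-filter in/out counts):

```bash
# synthetic cohort with two planted drivers
sigselect simulate --spec examples/cohort.yaml --seed 1 --out sim/

# per-sample exposures (bundled COSMIC v2 by default)
sigselect exposures --mutations sim/mutations.tsv \
    --signatures sim/signatures.tsv --min-mutations 20 --out exposures.tsv

# signature/driver-mutation association scan
sigselect associate --mutations sim/mutations.tsv --min-recurrence 4 \
    --min-mutations 20 --fdr 0.05 --out associations.tsv

# pairwise differential-selection scan
sigselect select --mutations sim/mutations.tsv --genes KRAS,BRAF \
    --cancer-type SYNTH --min-occurrence 10 --common-fraction 0.01 \
    --bootstrap 100 --seed 1 --out selection.tsv

# minimum-mutation cutoff calibration
sigselect calibrate --n-grid 5,10,20,50 --n-decoys 14 --reps 200 \
    --seed 1 --out calibration.tsv

# config-driven pipeline (stages share one seed via named substreams)
sigselect run --config run.yaml --stages exposures,associate,select
```

A `simulate` spec file is YAML, e.g.:

```yaml
n_samples: 200
n_signatures: 5
burden_mean: 200
burden_dispersion: 1.0   # null for fixed burden
exposure_alpha: 0.5
drivers:
  - {label: "KRAS:G12C", channel: "C[C>A]A", gene: KRAS, relative_risk: 2.0}
  - {label: "KRAS:G12D", channel: "A[C>T]G", gene: KRAS, relative_risk: 1.0}
```

## File formats

- Mutation TSV (generic dialect): columns `sample_id, cancer_type, chrom,
  pos, ref, alt, context, gene, effect`; 1-based coordinates; `context` is
  the reference trinucleotide around the variant on the reported strand.
  TCGA MAF and ICGC simple-somatic-mutation column names are built in and
  overridable.
- Signature matrix TSV: first column `Channel` in COSMIC notation
  (`A[C>A]A`), one column per signature, channels in canonical COSMIC order.
- Driver gene list: one symbol per line (an editable default list is
  bundled, as are default genome/exome trinucleotide frequencies).

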