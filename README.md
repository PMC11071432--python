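# tmtqc

Post-search harmonization QC and technical validation for large multi-site,
multi-batch TMT (tandem mass tag) proteomes, such as the multi-center brain
cohorts profiled in Alzheimer's disease research.

Quantified protein-group × sample matrices from isobaric-labeling experiments
carry strong technical structure: unequal protein loading per channel,
intensity-dependent missing values, processing-batch offsets, and occasional
globally aberrant samples. `tmtqc` implements the standard harmonization
pipeline for such data, the diagnostics used to judge whether it worked, and
three biology-anchored validation analyses — together with a synthetic cohort
generator with fully known ground truth, so every stage is testable without
access to restricted human data.

## What the pipeline does

Given a raw abundance matrix `A` (proteins `p` × samples `j`) and sample
metadata (batch, site, sex, race, diagnosis, age, CERAD, Braak, APOE
genotype):

1. **Missingness filter** — keep protein `p` iff its missing fraction is
   ≤ 50% (a protein missing in exactly half the samples is retained).
2. **Loading normalization** — `r_pj = a_pj / Σ_p a_pj` over observed
   entries, so each sample's observed column sums to 1.
3. **log2 transform** — `y_pj = log2 r_pj`.
4. **Iterative PCA outlier removal** — repeat: compute sample scores on the
   leading principal components (protein-centered, per-protein mean
   imputation inside PCA only); remove every sample whose score on PC1 or
   PC2 lies more than 4 SD from the component mean; stop when a round
   removes nothing.
5. **Batch regression** — per protein, OLS of `y` on batch as a categorical
   factor on observed entries; fitted batch deviations are subtracted and
   the protein grand mean restored, equalizing per-batch means.

Diagnostics: classical (Torgerson) MDS of samples, and per-protein variance
partitioning — a mixed model with random intercepts for each categorical
factor (sex, race, diagnosis, batch) and a fixed age effect, fit by REML
(method-of-moments fallback), reporting each factor's variance fraction
`σ²_f / σ²_total`.

Validation: one-way ANOVA differential abundance with Benjamini–Hochberg
adjustment; Jonckheere–Terpstra ordinal trend (permutation p) of a protein
across CERAD/Braak stages; and APOE ε4 "proteotype" calling — thresholding
the ε4-specific tryptic peptide signal (LGADMEDVR) via a two-component
Gaussian mixture and scoring concordance with recorded *APOE* genotype.

## Worked example

```bash
tmtqc simulate --seed 1 --out run/sim
tmtqc qc --matrix run/sim/abundance.tsv --metadata run/sim/metadata.csv --out run/qc
tmtqc validate apoe --matrix run/qc/processed.tsv --metadata run/sim/metadata.csv \
      --out run/apoe.tsv
```

prints (structured log lines):

```
INFO tmtqc :: step=simulate n_proteins=401 n_samples=240 n_batches=16 missing_frac=0.147
INFO tmtqc :: step=filter_missing max_missing_frac=0.5 proteins 401 -> 395
INFO tmtqc :: step=normalize_log2 n_samples=240
INFO tmtqc :: step=detect_outliers rounds=0 removed=0 samples 240 -> 240
INFO tmtqc :: step=regress_batch batch_factor=batch n_batches=16
INFO tmtqc :: step=apoe concordance=0.9868 fp=1 fn=2 fold_change=7.41 threshold=-12.762
```

Reading: 6 of 401 simulated proteins exceeded 50% missingness and were
dropped; no sample was more than 4 SD out on PC1/PC2 of the normalized data;
batch means were equalized across the 16 batches; and the ε4-specific
peptide signal reproduced the recorded APOE genotype for 98.7% of donors
(the planted genotype-error rate is 2%). The carrier/non-carrier fold change
on the fully processed matrix is ~7.4×; measured on the generated
intensities before loading normalization and batch regression it is ~9×
(those steps slightly shrink the bimodal separation). The per-sample calls
land in `run/apoe.tsv`, the auditable QC trail in `run/qc/qc_report.json`.

Python API mirrors the CLI:

```python
from tmtqc import SimulationConfig, simulate_cohort, apply_missingness, run_qc

cfg = SimulationConfig(seed=1)
matrix, metadata, truth = simulate_cohort(cfg)
matrix = apply_missingness(matrix, cfg)
corrected, report = run_qc(matrix, metadata)
```

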