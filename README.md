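# bastage — molecular staging of biliary atresia liver disease

Biliary atresia is an infant cholangiopathy that obstructs the
extrahepatic bile ducts and progresses to cirrhosis; roughly half of the
affected infants reach liver transplant or death within two years of the
Kasai portoenterostomy. At diagnosis most livers show a mixture of
portal inflammation and fibrosis, and routine histology stages only a
minority of them cleanly. `bastage` implements a molecular staging
workflow for this setting: it derives an inflammation-vs-fibrosis gene
expression signature from the histologically unambiguous biopsies and
uses it to assign every biopsy — including the mixed ones — to a
molecular stage that can then be tested against age at surgery and
transplant-free survival.

The package is aimed at transcriptomics analysts working with bulk
expression cohorts (normalized log2 probe × sample matrices plus a
clinical sample table). It ships a synthetic-cohort generator with known
ground truth, so every stage of the workflow is testable end to end
without access to patient data.

## The method

1. **Histology differential score.** Each biopsy carries pathologist
   scores for portal inflammation (grade *I* ∈ 0–3) and fibrosis (stage
   *F* ∈ 0–3). The differential score is *D = I − F*; biopsies with
   *D* ≥ 2 (inflammation-predominant) or *D* ≤ −2 (fibrosis-predominant)
   form the labelled seed set, the rest are "mixed".
2. **Signature derivation** between the two seed groups: per-gene median
   normalization (log2), a strict fold-change filter
   2^|Δmean| > 2, Welch's unequal-variance *t*-test, and
   Benjamini–Hochberg FDR (retain *q* < 0.05).
3. **Nearest-shrunken-centroid (PAM) classification** on the signature
   probes. Standardized contrasts
   *d*<sub>ik</sub> = (x̄<sub>ik</sub> − x̄<sub>i</sub>) / (m<sub>k</sub>(s<sub>i</sub> + s₀))
   are soft-thresholded, *d′* = sign(*d*)·max(|*d*| − Δ, 0), and a
   sample is assigned by minimizing
   δ<sub>k</sub>(x) = Σ<sub>i</sub> (x<sub>i</sub> − x̄′<sub>ik</sub>)² / (s<sub>i</sub> + s₀)² − 2 log π<sub>k</sub>.
   The threshold Δ is chosen by stratified 10-fold cross-validation
   (largest Δ at the minimum error).
4. **Repeated-CV majority voting.** Ten independent stratified 10-fold
   partitions of the seed set give every sample ten votes — out-of-fold
   votes for seed samples, per-repetition fold-model majorities for the
   mixed samples. A sample is assigned to the class winning ≥ 6 of 10
   votes, otherwise left unclassified. Seed samples can be reclassified
   by their own out-of-fold votes.
5. **Clinical association** of the molecular groups: Fisher's exact test
   for categorical covariates, Wilcoxon rank-sum for age (exact by
   enumeration for small samples, tie-corrected normal approximation
   otherwise), Gaussian-kernel age densities (Silverman bandwidth),
   odds ratio with conditional-exact CI for the two-year outcome,
   Kaplan–Meier curves with the log-rank test, and binary logistic
   models of outcome against age and group.

## Worked example

```python
from bastage import (SimConfig, simulate_cohort, write_cohort,
                     PipelineConfig, run_pipeline)

cohort = simulate_cohort(SimConfig(rng_seed=1, seed_group_counts=(9, 5)))
write_cohort(cohort, "demo")
result = run_pipeline(PipelineConfig(
    expression_tsv="demo/expression.tsv",
    sample_csv="demo/samples.csv",
    output_dir="demo/out",
    rng_seed=1,
))
t = result.signature.trail
print(f"filter trail: {t.n_input} -> {t.n_after_fc} -> {t.n_after_fdr}")
print("molecular groups:", result.molecular_groups.value_counts().to_dict())
print(result.associations[["variable", "test", "statistic", "p"]]
      .round(4).to_string(index=False))
```

prints

```
filter trail: 2000 -> 147 -> 147
molecular groups: {'fibrosis': 28, 'inflammation': 19}
                variable                         test  statistic      p
                age_days            wilcoxon_rank_sum   268.0000 0.0000
              age_center         gaussian_kde_centers        NaN 0.0000
                     sex                 fisher_exact        NaN 0.0358
           clinical_type                 fisher_exact        NaN 1.0000
             cholangitis                 fisher_exact        NaN 0.6972
                 ascites                 fisher_exact        NaN 1.0000
                event_2y                 fisher_exact        NaN 0.0150
                event_2y odds_ratio_conditional_exact     4.8487 0.0150
transplant_free_survival                      logrank     6.3605 0.0117
            event_2y~age          logistic_regression     0.0367 0.1184
      event_2y~age+group          logistic_regression     1.5807 0.0565
```

Reading the output: of the 2,000 simulated probes, 147 pass the
fold-change filter between the 9-vs-5 seed groups and all of them
survive the FDR step (the cohort plants 150 truly differential probes).
Repeated-CV voting assigns all 47 samples (19 inflammation,
28 fibrosis). The fibrosis group is older at surgery (Wilcoxon
p < 10⁻⁴), carries a 4.8-fold higher odds of transplant/death by two
years, and has significantly worse transplant-free survival (log-rank
p = 0.012) — the clinical picture the staging is designed to expose.

The same workflow is available from the shell:

```bash
bastage simulate --seed 1 --out-dir demo
bastage classify-histology --samples demo/samples.csv --out demo/groups.csv
bastage run-all --config config.yaml
```

`config.yaml` is a flat key-value file naming the inputs and options
(see `bastage.io.PipelineConfig`; `save_pipeline_config` writes one).

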