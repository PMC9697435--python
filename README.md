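# onset-omics

Paired tumor–normal transcriptome and methylome contrast analysis for
cohorts split by age of onset, modelled on early- vs late-onset colorectal
carcinoma (EOCRC, onset ≤ 40 years; LOCRC, onset > 40 years) studies in
which each patient contributes a tumor sample and an adjacent-normal
sample. The package is for biostatisticians and computational biologists
who need the full analysis chain — normalization, per-feature mixed ANOVA,
gene-set ANOVA, differential-methylation calling with an interaction-based
marker partition, enrichment scoring and clinical contingency tests — as
tested, reusable model objects rather than point-and-click software.

## The models

**Paired mixed ANOVA.** For one feature (a log2 expression probe or a CpG
beta value) with observations Y_ijk on tissue i (tumor/normal) of person j:

    Y_ijk = μ + Tissue_i + Person_j + ε_ijk,    ε ~ N(0, δ²)

Tissue is a fixed effect, Person a random effect. Variance components
(σ²_person, σ²_error) are estimated by the method of moments from the
expected mean squares; on a paired design the tissue F-test is exactly the
square of the paired t-test. Effects on the log2 scale are reported as
signed fold changes with the −1/x convention (−1.12 means 12% lower in
tumor) with t-based 95% CIs mapped endpoint-wise.

**Tissue × onset interaction.** Whether the tumor–normal effect differs by
onset group is tested with

    Y_ijk = μ + Tissue_i + Onset_j + (Tissue × Onset)_ij + ε_ijk

a fixed-effects two-way layout, alongside per-group paired fits that give
the familiar two-column (late-onset / early-onset) table of fold changes.

**Gene-set ANOVA.** A set of genes is tested jointly with

    Y = μ + T + P + G + S(T*P) + ε

where G is a fixed gene effect and S(T*P) a random sample effect nested in
tissue × person; probes are averaged to genes first, and the set-level
effect is the average of the member genes' tissue effects.

**Differential methylation.** Beta values are M/(M+U) from methylated and
unmethylated intensities. Deep-sea CpGs (> 4 kb from an island) are
excluded; each remaining locus is tested per onset group with the paired
model, Benjamini–Hochberg FDR is applied within each group, and DML
(q ≤ 0.05) are partitioned into five classes by group membership crossed
with the interaction test (class IV = early-onset-specific markers).

**Clinical contingency analyses.** Person-level covariates (stage, LVI,
PNI, MSI status, ...) are cross-tabulated against onset group and tested
with the uncorrected Pearson chi-square, optionally stratified by stage;
the same 2×2 chi-square yields the enrichment score −log10(p) for gene
categories among significant genes.

Because no patient-level data is released with such studies, the package
ships a synthetic-data generator (`onset_omics.simulate`) that reproduces
the statistical structure of the cohort — paired samples with person-level
random effects, gene-set-structured interaction effects, bounded beta-value
noise on the logit scale, and clinical tables with the published category
proportions — so the entire pipeline runs and is validated end to end with
no external inputs.

## Worked example

```python
import numpy as np
from onset_omics import SimulationConfig, simulate_expression, GeneSetAnova

cfg = SimulationConfig(seed=42)          # 67 EOCRC + 98 LOCRC paired persons
matrix, sheet, truth = simulate_expression(cfg)
res = GeneSetAnova(matrix, sheet, truth.gene_sets["SET01"],
                   truth.annotation(), set_name="SET01",
                   with_interaction=True).fit()
print(res.summary())
```

prints

```
Gene-set ANOVA: SET01 (12 genes, 12 probes)
overall: fold change 1.113 (1.088 to 1.138), p = 3.387e-17
LOCRC: fold change 1.148 (1.118 to 1.179), p = 4.714e-17
EOCRC: fold change 1.063 (1.025 to 1.102), p = 1.422e-03
tissue x onset interaction p = 6.140e-01
variance components: person=0.9493, sample=0.0018, error=0.2414
```

The generator's defaults plant a 1.09-fold tumour effect on set genes in
the early-onset group and 1.14-fold in the late-onset group over person
noise of SD 1.0 (log2): the per-group fold changes recover those magnitudes
(1.148 and 1.063 here), the variance components recover σ²_person = 1.0 and
σ²_error = 0.25, and the interaction p illustrates that at this cohort size
the person-free interaction test has limited power for a 1.14-vs-1.09
contrast — the magnitude is seen in the group columns, the formal
interaction call needs larger effects or samples.

A command-line interface covers every stage:

```
onset-omics simulate --seed 1 --out demo/
onset-omics anova paired --matrix demo/expression.tsv --sheet demo/sample_sheet.tsv --out fits.tsv
onset-omics dml --beta demo/methylation_beta.tsv --sheet demo/sample_sheet.tsv \
    --manifest demo/cpg_manifest.tsv --out dml.tsv --summary dml_summary.tsv
onset-omics run --config run.yaml        # the whole chain + manifest.json
```

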