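# snpmeta

Case-control SNP meta-analysis from aggregate genotype counts.

Genetic-association studies of a biallelic variant report genotype counts
CC/CT/TT in cases and controls.  Individual studies are often small and
conflicting; the standard way to resolve them is a meta-analysis of crude
odds ratios under the three genotype-collapsing contrasts — allele
(T vs. C), dominant (CT+TT vs. CC) and recessive (TT vs. CT+CC) — with
random-effects pooling when the studies are heterogeneous.  `snpmeta`
implements that pipeline end to end for epidemiologists and statistical
geneticists working from published count tables:

* per-study 2×2 tables and Woolf log odds ratios
  (log OR = ln(ad/bc), SE = √(1/a+1/b+1/c+1/d));
* Cochran's Q, I² = max(0, (Q−df)/Q), and DerSimonian–Laird
  τ² = max(0, (Q−df)/(S₁−S₂/S₁)); random effects selected when
  p(Q) < 0.1 or I² > 50%, inverse-variance fixed effects otherwise;
* Pearson χ² Hardy–Weinberg screening of control groups (1 df);
* subgroup analyses by ethnicity and source of controls, and
  leave-one-out sensitivity analysis;
* Egger regression and Begg–Mazumdar rank-correlation tests for
  small-study effects, with funnel-plot data series;
* random-effects meta-regression on study-level moderators
  (method-of-moments residual τ²);
* post-hoc power for a detectable odds ratio;
* a seeded synthetic-ensemble generator (HWE controls, multiplicative
  per-allele risk, optional heterogeneity and small-study bias) for
  calibration and testing.

A curated 13-study prostate-cancer dataset for the MSMB promoter variant
rs10993994 (31,584 cases, 30,251 controls) ships with the package.

## Worked example

```python
import snpmeta as sm

studies = sm.load_fixture()          # the bundled 13-study dataset
print(sm.totals(studies))            # (31584, 30251, 13)

for model in sm.GeneticModel:
    r = sm.analyze(studies, model)
    print(f"{model.value:>13}: OR {r.pooled_or:.2f} "
          f"({r.ci_low:.2f}, {r.ci_high:.2f})  I2 {r.i2:.1f}%  "
          f"model {r.model_used.value}")

print(f"power {sm.meta_power(studies, or_=1.27).power:.3f}")
```

prints

```
      T vs. C: OR 1.23 (1.13, 1.34)  I2 90.6%  model Random
 CT+TT vs. CC: OR 1.27 (1.14, 1.41)  I2 86.9%  model Random
 TT vs. CT+CC: OR 1.37 (1.21, 1.56)  I2 85.2%  model Random
power 1.000
```

Read: carriers of the risk allele (dominant contrast) have 1.27 times
the odds of disease (95% CI 1.14–1.41); I² near 87% says most of the
between-study variability is real heterogeneity, so the pooled estimate
uses DerSimonian–Laird random effects; and a sample this large had
essentially certain power to detect an OR of 1.27 at α = 0.05.

The same pipeline runs from the shell:

```sh
snpmeta run --input fixture --format text      # full analysis, summary
snpmeta run --input my_studies.csv --out report.json
snpmeta simulate --n-studies 13 --or 1.3 --seed 7 --out sim.csv
snpmeta power --or 1.27
snpmeta validate --input my_studies.csv        # schema + HWE screen
```

Input CSVs have one row per study with the header
`study_id,year,ethnicity,soc,case_cc,case_ct,case_tt,control_cc,control_ct,control_tt[,nos]`.

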