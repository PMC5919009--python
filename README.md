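# mpepi

Molecular pathological epidemiology of tumor subtypes in matched
case-control studies.

## The problem

Many exposures show inconsistent associations with cancer risk across
studies. One candidate explanation is intertumoral heterogeneity: an
exposure may raise the risk of one molecular subtype of a cancer while
lowering the risk of another, so the overall association depends on the
subtype mix of each study population. Testing this requires relating
prediagnostic exposures (circulating biomarkers, germline genotypes) to
the risk of *mutually exclusive* tumor subtypes — for colorectal cancer,
classically the KRAS-mutated, BRAF-mutated, and KRAS/BRAF wild-type
pathways — inside a matched (nested) case-control design, while coping
with the fact that tumor mutation data are missing for some cases for
reasons that may not be random.

`mpepi` implements that full analysis as a tested, reusable pipeline:

1. **Multivariate screening** — a discrete Bayesian network is learned by
   hill-climbing on an AIC score (local score = multinomial log-likelihood
   − free parameters), averaged over nonparametric bootstrap replicates.
   The *edge confidence* of a pair of variables is the fraction of
   replicate networks containing an edge between them; an edge is kept
   when its confidence exceeds a threshold estimated by fitting a
   two-point {0, 1} mixture to the confidence distribution in L1 distance.
   Exposures are ranked by their edge confidence with the 4-level outcome
   node (control / KRAS / BRAF / wild-type).
2. **Univariate follow-up** — subtype-specific odds ratios per variant
   allele (SNPs) or per 1 control-SD of log concentration (biomarkers) by
   conditional logistic regression over the matched sets,
   `l(β) = Σ_s [η_case − log Σ_i exp(η_i)]`, with a likelihood-ratio test
   of effect heterogeneity across subtypes and Cochran's Q across cohorts.
3. **Selection-bias sensitivity analysis** — a logistic model for tumor-
   data availability among cases yields fitted probabilities `p_i`; the
   subtype models are refit with inverse-probability weights (1 for
   controls, `1/p_i` for cases with tumor data, 0 otherwise), with a
   weighted-refit balance check.
4. **Case-case replication** — multinomial logistic regression of subtype
   vs wild-type among cases only; exponentiated slopes are ratios of odds
   ratios (RORs), with a 2-df heterogeneity LRT.

Because individual-level cohort data of this kind are not public, the
package ships a first-class synthetic cohort generator
(`mpepi.simulate`) that reproduces the design — 1:2 matching on sex, age
(±2 y), cohort and fasting; 14 correlated log-normal biomarkers; 17
Hardy-Weinberg SNPs; configurable subtype-specific effects; covariate-
dependent tumor-data availability; 0–3% missingness — with the generating
truth retained for parameter-recovery testing.

## Worked example

```python
import numpy as np
from mpepi import (SimulationConfig, simulate_cohort, MatchedDesign,
                   subtype_specific_fit)

truth = {"rs1021737": (np.log(0.72), np.log(1.56), np.log(0.94))}
cfg = SimulationConfig(n_cases=3000, effect_spec=truth,
                       missingness_rate=0.0, seed=19)
cohort = simulate_cohort(cfg)
res = subtype_specific_fit(MatchedDesign(data=cohort.data,
                                         exposure="rs1021737"))
print(res.to_frame()[["subtype", "n_cases", "OR", "CI_low", "CI_high", "P_het"]])
```

```
  subtype  n_cases        OR    CI_low   CI_high         P_het
0    KRAS      748  0.776427  0.679678  0.886948  7.810410e-19
1    BRAF      729  1.749792  1.517907  2.017100  7.810410e-19
2      WT     1523  0.879779  0.800609  0.966779  7.810410e-19
```

The three odds ratios recover the generating per-allele effects (0.72,
1.56, 0.94) within sampling error, and the heterogeneity likelihood-ratio
test (2 df) strongly rejects a common effect across subtypes — the
pattern of a variant that lowers the risk of one subtype while raising
the risk of another.

The same analysis is available from the shell:

```bash
mpepi simulate --seed 1 --out cohort.tsv
mpepi discretize --in cohort.tsv --config cohort.config.yaml \
      --rules-out rules.yaml --out discrete.tsv
mpepi bn-learn --in discrete.tsv --outcome outcome --bootstrap 1000 \
      --seed 1 --out network
mpepi clogit --in cohort.tsv --exposure rs1021737 --out ors.tsv
mpepi pipeline --seed 1 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `mpepi.simulate` | `SimulationConfig`, `simulate_cohort`, tumor-data availability, case-only generator |
| `mpepi.preprocess` | control-based tertiles/quartiles, per-SD log scaler, genotype encodings, Cockcroft-Gault eGFR, discrete dataset assembly |
| `mpepi.bayesnet` | AIC local scores, `HillClimbBayesNet`, `BootstrapAveragedNetwork`, threshold estimation, outcome ranking |
| `mpepi.matched` | `ConditionalLogisticRegression`, subtype-specific fits, heterogeneity LRT, Cochran's Q |
| `mpepi.ipw` | availability model, weight assignment, weighted conditional logit, balance check |
| `mpepi.casecase` | case-case multinomial model, RORs, consistency with case-control contrasts |
| `mpepi.pipeline` / `mpepi.cli` | end-to-end orchestration, manifest, `mpepi` console script |

See `docs/methods.md` for the statistical details and design choices.
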