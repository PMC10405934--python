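# crlm-cea

Decision-analytic cost-effectiveness model comparing three imaging
strategies — contrast-enhanced CT (CE-CT), liver MRI with contrast, and
18F-FDG PET/CT — for detecting colorectal liver metastases (CRLM) that are
eligible for hepatic resection. It is written for health-economics and
radiology researchers who want a tested, configurable re-implementation of
this published US-payer analysis: every input is a named parameter, every
structural assumption is a documented toggle, and every figure-level result
is reproducible from the command line.

## Model

A diagnostic decision tree splits a cohort of 68-year-old patients under
staging (CRLM prevalence 27.5%) into true/false positives and negatives
given each modality's sensitivity and specificity. True positives undergo
immediate resection ($21,592; success probability 0.70); false negatives
carry an undiagnosed tumour until clinical detection, then undergo delayed
resection at 1.3× the timely cost; false positives are charged a futile
surgical work-up; true negatives are tumour-free. The cohort then cycles
annually through a five-state Markov model

    tumor-free · undiagnosed tumor · resected · recurrence · death

with age-dependent background mortality (life table, ages 65–100) combined
multiplicatively with disease-specific mortality. Costs and utilities are
discounted at 3%/year and accumulated as expected discounted dollars and
QALYs per strategy.

On top of the cohort engine the package computes:

- **ICER and dominance** — ICER = (e₁−e₀)/(q₁−q₀), with strict/extended
  dominance and the efficiency frontier;
- **net monetary benefit** — NMB = WTP·q − e at WTP $100,000/QALY;
- **deterministic sensitivity analysis** — one-way (tornado) and two-way
  winner maps;
- **probabilistic sensitivity analysis** — Monte Carlo over beta
  (probabilities, utilities) and gamma (costs) distributions fitted by the
  method of moments, with cost-effectiveness acceptability curves;
- **a microsimulation oracle** — an individual-level replay of the same
  transition rules used to cross-validate the cohort recursion in the tests.

## Worked example

The committed calibration (`config/calibration.yaml`) fixes the structural
choices — a 13-cycle horizon, the active-CRLM annual expense applied while
metastases are undetected, recurrence mortality annualised from 3-year
survival, and an itemised surgical work-up for false positives:

```bash
python analysis/01_basecase.py
```

```
strategy      cost  incr_cost  qaly  incr_qaly  icer    status
     MRI 44,747.07        NaN  7.94        NaN   NaN  frontier
   CE-CT 45,270.27     523.20  7.93      -0.01   NaN dominated
  PET/CT 46,126.31     856.04  7.93       0.00   NaN dominated
MRI vs CE-CT: dominant
MRI vs PET/CT: dominant
```

MRI is the cheapest strategy *and* yields the most QALYs, so both
comparators are strictly dominated and the frontier contains MRI alone —
no ICER is defined against it. The probabilistic analysis
(`analysis/04_psa.py`, 50,000 iterations) prints

```
acceptability at WTP $100,000 (50,000 iterations, seed 1):
  CE-CT      6.57%
  MRI       83.61%
  PET/CT     9.82%
```

i.e. MRI is the cost-effective choice in ~84% of parameter draws, and it
leads the acceptability curve at every WTP between $20,000 and $200,000.
`analysis/02_tornado.py` shows that the two specificities (MRI, PET/CT)
carry the largest one-way spreads, and `analysis/03_twoway.py` maps the
hypothetical "breaking point" at which a much more sensitive CE-CT would
overtake a degraded MRI.

The same computations are available as a CLI
(`crlm-cea basecase|tornado|twoway|psa|validate`), each writing CSVs plus a
`run_manifest.json` with the fully resolved configuration.

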