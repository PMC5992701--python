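# metsmarkov

Discrete-time Markov modelling of metabolic-syndrome (MetS) progression
from longitudinal health check-up panels.

MetS — the co-occurrence of at least three of obesity, hyperglycemia,
hypertension and dyslipidemia — develops through intermediate states that
individuals enter and leave over years. This package is for
epidemiologists and health-services analysts who hold repeated annual
check-up records and want to (a) classify each visit into a 7-state
progression model, (b) estimate annual transition matrices per sex and
age group, (c) project cohort state distributions over a horizon, and
(d) simulate component-targeted interventions.

## The model

Each check-up maps to four binary components under the CDS (Chinese
Diabetes Society) criteria: BMI ≥ 25 kg/m², fasting glucose ≥ 6.1 mmol/L
(or history), blood pressure ≥ 140/90 mmHg (or history), and TG ≥ 1.7
mmol/L or low HDL (< 0.9 men, < 1.0 women). The component count defines
7 mutually exclusive states:

> no components · isolated hypertension · isolated obesity · isolated
> hyperglycemia · isolated dyslipidemia · 2 components · MetS (≥ 3)

A first-order, time-homogeneous chain governs annual transitions: with
occupancy row vector M⁽ⁿ⁾ and row-stochastic matrix P = (p_ij),

    M⁽ⁿ⁺¹⁾ = M⁽ⁿ⁾ P

Transition probabilities are estimated per sex × entry-age-band group
(men/women, 20–40/40–60) as observed frequencies between consecutive
calendar years, then averaged unweighted across year-pairs. The four
published group matrices ship as packaged fixtures. Interventions assume
a fraction f (default ½) of individuals in a targeted isolated state
revert to the no-component state each year; the relative reduction is
100 · (natural − intervened) / natural MetS prevalence at the horizon.

## Worked example

Project a healthy 50-year-old male cohort forward ten years:

```python
import metsmarkov as mm

matrix = mm.load_fixture_matrix("men_40_60")
start = mm.unit_distribution(mm.MetsState.NO_COMPONENTS)
traj = mm.project(start, matrix, 10)
print(100 * mm.state_prevalence(traj, mm.MetsState.METS, 10))  # 25.82
```

After one year 1.03% of the cohort is in the MetS state (the first-row
MetS entry of the matrix); occupancy then compounds through the
intermediate states to 25.82% at year ten. The same from the shell, plus
the intervention report:

```sh
metsmarkov predict --matrix men_40_60.csv --start no_components --years 10 --out traj.csv
metsmarkov report --fixtures builtin --years 10
```

```
               men_20_40  men_40_60  women_20_40  women_40_60
intervention
hypertension        4.17       6.29         4.39        11.86
obesity            20.65      11.89        16.86        17.34
hyperglycemia       2.10       3.65         1.71         5.52
dyslipidemia        9.79       6.09         0.95         4.46
combined           38.72      31.91        23.15        39.80
```

Each cell is the percent relative reduction in 10-year MetS prevalence
when half of the individuals in the targeted isolated state revert to
the healthy state each year: the obesity intervention dominates every
other single-component intervention in every group, and combining all
four roughly doubles its effect.

A full synthetic pipeline (generate → classify → estimate → project):

```sh
metsmarkov simulate --seed 1 --out panel.csv
metsmarkov classify --input panel.csv --output classified.csv
metsmarkov estimate --input classified.csv --outdir matrices/
metsmarkov predict --matrix matrices/men_20_40.csv --start no_components --years 10 --out traj.csv
```

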