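# workability

Work-ability evaluation from physiological test batteries: a fuzzy-logic
expert system plus random-forest classification, for occupational-health
researchers and practitioners who screen employees with short physical
test sessions instead of questionnaires.

## What it does

A subject performs 21 tests covering three body systems —
**cardiovascular** (systolic/diastolic blood pressure, Ruffier index),
**muscular** (trunk and side-plank endurance, plank asymmetry, leg
strength, sit-down/bend and turn-over transitions) and **nervous**
(static-balance mistake counts, tapping mobility/poverty/mistakes).
The pipeline has three stages:

1. **Fuzzy scoring.** Each feature's range is partitioned by expert
   thresholds into 3 or 5 levels scored 1 (worst) to 5 (best).  Around
   every internal threshold *t* a transition zone [*t* − σ/2, *t* + σ/2]
   is built from the local data spread σ, inside which adjacent levels
   overlap with complementary linear ramps (trapezoidal membership
   functions μ_l).  The crisp score is the membership-weighted average
   Σ_l μ_l(x)·s_l / Σ_l μ_l(x); because the memberships form a partition
   of unity, plateau values return the integer table score exactly.  The
   subject's grade is the sum of all 21 scores (range 21–105).
2. **Quartile labeling.** Grades are split at the cohort's first and
   third quartiles (ranks (n+1)/4 and 3(n+1)/4, interpolated) into
   classes C1 (poor, below Q1), C2 (moderate) and C3 (good, at/above
   Q3) — overall and per subsystem.
3. **Random-forest evaluation.** Per subsystem (and once on all 21
   features), a random forest with entropy splits is trained on repeated
   stratified 70/30 splits (50 iterations by default, 5-fold CV as an
   overfitting diagnostic) and judged with from-scratch micro/macro
   precision, recall, F1 and accuracy; features with mean importance
   below 0.05 are flagged as removable in the all-features model.

No field data ship with the package; a latent-health-factor simulator
(`workability.simulate`) reproduces the reference cohort's printed
means ± SDs so that every stage is testable offline.

## Worked example

```python
from workability import FuzzyScorer, TrainConfig, default_config, generate_cohort
from workability.experiment import comparison_table, run_three_system_evaluation
from workability.labeling import label_cohort
from workability.simulate import SynthConfig

cohort = generate_cohort(SynthConfig(n=98, seed=1, loading=0.8))
scorer = FuzzyScorer().fit(cohort.frame)          # fits transition zones
table = scorer.score_table(cohort.frame)          # 21 scores + grade sums
labels = label_cohort(table)                      # C1/C2/C3, overall + per system
results = run_three_system_evaluation(
    table[default_config().feature_names], labels, TrainConfig(n_iterations=10, seed=1)
)
print(comparison_table(results).round(3))
```

prints

```
                        all_features  cardiovascular  muscular  nervous
Accuracy, ACC                  0.867           0.880     0.857    0.850
Micro precision, mi P          0.867           0.880     0.857    0.850
Micro recall, mi R             0.867           0.880     0.857    0.850
Micro F-1 score, mi F1         0.867           0.880     0.857    0.850
Macro precision, ma P          0.887           0.893     0.872    0.860
Macro recall, ma R             0.852           0.887     0.850    0.848
Macro F-1 score, ma F1         0.869           0.889     0.860    0.853
```

Each column is one classifier; rows are the averaged held-out metrics
over the repeated splits.  The micro rows duplicating the accuracy row
is a property of single-label multi-class metrics, not a bug; the macro
rows weight the scarce C1 class equally and are the informative ones.
On this synthetic cohort the grade sums determine the labels, so all
four models score well; the interesting quantities on real data are the
differences between subsystems.

The same pipeline is available from the shell:

```bash
workability simulate --n 98 --seed 1 --out cohort.csv
workability score cohort.csv --out scored.csv
workability label scored.csv --out labeled.csv
workability train labeled.csv --seed 1 --out results.json --table table6.csv
workability report labeled.csv --subject S001 --out report.json
```

`report` emits a six-axis "hexagon web" summary (axis sums min–max
scaled against the cohort) with left/right asymmetry flags, plus
rule-based recommendations: a 4-week training plan for any subsystem at
C2 or worse, and a doctor-referral flag whenever a subsystem is C1.

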