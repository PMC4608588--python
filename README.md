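# dlogit — defective logistic regression for one-sided label noise

`dlogit` estimates a logistic discrimination function from case-control
training data in which the **control sample is contaminated**: some rows
labeled control (`z = 0`) are in truth cases (`y = 1`), while every row
labeled case (`z = 1`) really is one.  This one-sided mislabeling is common
in epidemiology and microbiology — environmental "control" samples that
contain pathogenic strains, self-reported non-hypertensives who are
hypertensive, gold standards with imperfect sensitivity.  Ignoring it
shrinks coefficient estimates toward the null and miscalibrates predicted
probabilities.

## The model

Let the true status follow a logistic regression,

    P(y = 1 | x) = expit(β₀ + βᵀx),

and let λ = P(z = 0 | y = 1) be the mislabeling probability, assumed
independent of x.  The observed label then follows a **defective** logistic
curve that saturates at 1 − λ instead of 1:

    P(z = 1 | x) = (1 − λ) · expit(β₀ + βᵀx)
    P(z = 0 | x) = 1 − (1 − λ) · expit(β₀ + βᵀx)

— formally a zero-inflated Bernoulli regression.  All parameters
(β₀, β, λ) are estimated jointly by maximum likelihood; internally the
package works with μ = λ/(1 − λ), which is unbounded above and puts the
no-contamination boundary at a plain 0.  The fit starts at the standard
logistic solution (λ = 0), so its likelihood never falls below the
ordinary logistic regression it nests.  Useful by-products:

* **n₁·μ̂** — the expected number of truly-case rows hiding in the control
  sample (n₁ = number of `z = 1` rows), with a Wald confidence interval;
* **P(y = 1 | z = 0, x) = λ·P(y=1|x) / P(z=0|x)** — the posterior
  probability that a given labeled control is a mislabeled case, used to
  flag suspicious controls at a chosen cutoff;
* Wald and likelihood-ratio tests of λ = 0, with explicit warnings that
  the null lies on the boundary of the parameter space, plus the profile
  likelihood of λ for inspection.

## Worked example

Simulate a case-control study with 200 true cases and 776 true controls,
relabel 67 randomly chosen cases as controls, and fit:

```python
import dlogit as dl

clean = dl.generate_dataset(dl.example_study_config(seed=11, contamination=None))
data  = dl.contaminate(clean, k=67, seed=0)

model = dl.DefectiveLogit(data)
lr, res = model.fit_logistic(), model.fit()
print(res.summary())
```

```
Defective logistic regression, n = 976 (n1 = 133 labeled cases, n0 = 843 labeled controls)
variable                estimate        SE
mu                         0.407     0.341
const                     -2.278     0.304
x1                         1.370     0.207
x2                         1.003     0.275
lambda = mu/(1+mu)         0.289
-2*log(L) = 644.50
expected mislabeled controls n1*mu = 54.16 (reported 54)
```

The fit estimates λ̂ = 0.289, i.e. about 54 of the 843 labeled controls are
suspected cases; the injected truth (67) lies inside the 95% interval:

```python
print(res.confint_mislabeled())       # 54 (95% CI: 0 to 143)
print(res.lr_test(lr))                # lrt: statistic = 2.573, df = 1, one-sided P = 0.1087
rep = dl.classification_report(res, data, cutoff=0.35)
print(rep)
```

```
cutoff 0.35: 15 of 843 labeled controls flagged as probable cases
  truly mislabeled cases flagged: 9 of 67 (sensitivity 0.13)
  true controls left unflagged: 770 of 776 (specificity 0.99)
```

Flagged rows are those whose posterior P(y = 1 | z = 0, x) strictly
exceeds the cutoff.  Note the single-draw estimate μ̂ is noisy at this
sample size: its sampling distribution is wide and has an atom at the
λ = 0 boundary (see `dlogit.recovery_experiment` to explore this).

The same analyses run from the shell on delimited text files, with
covariate transforms `COLUMN[:shift[:scale[:power]]]`:

```
dlogit fit study.tsv --label z --true-label y --term "age:50:10" \
       --term "age:50:10:2" --term tobacco --term "alcohol:50:10"
dlogit profile study.tsv --term ... --out profile.tsv
dlogit predict study.tsv --term ... --cutoff 0.35 --out posteriors.tsv
dlogit simulate design.cfg --mode recovery --reps 200 --out recovery.tsv
```

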