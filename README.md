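# refbias

Apparent vs true binary-classification accuracy under imperfect
reference standards.

Classification accuracy — in medical diagnosis, remote sensing,
machine-learning evaluation — is assessed by cross-tabulating a
classifier's labels against a reference standard. Nearly every
published property of the usual metrics (recall, precision,
specificity, NPV, Youden's J, F1, MCC, likelihood ratios) assumes that
reference is a *gold standard*. In practice it rarely is, and the
observed ("apparent") confusion matrix can differ badly from the true
one, in a direction and magnitude that depend on prevalence and on
whether the reference's errors are independent of, or correlated with,
the classifier's. `refbias` makes those distortions computable: it
gives the closed-form forward models, the full metric suite, prevalence
sweeps, a case-level Monte-Carlo sampler, and the inverse map that
corrects the bias when reference quality is known.

## The model

A classifier with per-class correctness rates `Recall_C`, `Spec_C` at
prevalence `p`, scored against truth, yields (proportions; reference in
columns, classifier in rows)

    TP = p·Recall_C          FP = (1−p)(1−Spec_C)
    FN = p·(1−Recall_C)      TN = (1−p)·Spec_C

Against an imperfect reference (`Recall_R`, `Spec_R`) the apparent
cells are, with **independent** errors,

    TP′ = p·Recall_R·Recall_C + (1−p)(1−Spec_R)(1−Spec_C)

(and analogously for FP′, FN′, TN′), while with **maximally
correlated** errors every reference mistake lands on a case the
classifier also got wrong (FN → TN′, FP → TP′). Both structures leave
the classifier's row marginals fixed and shift the reference-positive
marginal to the apparent prevalence
`p′ = p·Recall_R + (1−p)(1−Spec_R)`; inverting that map (and its
per-row generalisation) recovers the true prevalence and classifier
rates — the Rogan–Gladen-style correction implemented in
`correct_independent`. See `docs/methods.md` for the full derivations
and assumptions.

## Worked example

A good classifier (`Recall_C = Spec_C = 0.8`) at prevalence 0.1,
scored against a 10%-error reference (`Recall_R = Spec_R = 0.9`) whose
errors are independent of the classifier's, N = 1000. The apparent
matrix is (TP′, FP′, FN′, TN′) = (90, 170, 90, 650):

```
$ refbias metrics 90 170 90 650
metric               value   display
accuracy              0.74      0.74
recall                 0.5      0.50
precision     0.3461538462      0.35
specificity   0.7926829268      0.79
npv           0.8783783784      0.88
youden_j      0.2926829268      0.29
f1            0.4090909091      0.41
mcc           0.2563527816      0.26
lr_pos         2.411764706      2.41
lr_neg        0.6307692308      0.63
prevalence            0.18      0.18
```

Every number here is distorted: true accuracy is 0.80 (apparent 0.74),
true recall 0.80 (apparent 0.50), true J 0.60 (apparent 0.29), and the
apparent prevalence is 0.18 — nearly double the true 0.10. Knowing the
reference's quality, the correction inverts the distortion exactly:

```
$ refbias correct --tp 90 --fp 170 --fn 90 --tn 650 --recall-r 0.9 --spec-r 0.9
prevalence  0.100
recall_c    0.800
spec_c      0.800
```

Sweeping all built-in scenarios over the 21-point prevalence grid and
summarising apparent MCC:

```python
from refbias import default_scenarios, run_sweep, summarize_extrema
table = run_sweep(default_scenarios())          # 294 rows
print(summarize_extrema(table, "mcc").to_string(index=False))
```

```
   scenario  p_at_max      min      max  n_undefined
      ind02      0.50 0.083194 0.576000            0
      ind10      0.50 0.037856 0.480000            0
      ind18      0.50 0.024138 0.384000            0
     corr02      0.50 0.316623 0.640000            0
     corr10      0.50 0.675168 0.800000            0
     corr18      0.50 0.938441 0.960000            0
poor_corr30      0.01 0.600000 0.652199            0
```

The same 0.8/0.8 classifier (true MCC = 0.60 at p = 0.5) shows
apparent MCC anywhere from 0.02 (18% independent error, rare class) to
0.96 (18% correlated error) — and the `poor_corr30` row shows a
coin-tossing classifier (true MCC = 0 everywhere) earning an apparent
MCC of 0.65 from a 30%-error correlated reference. A high MCC against
an imperfect reference is not evidence of a good classifier.

The `simulate` subcommand draws per-case (truth, reference, classifier)
label triples with the matching joint distribution and z-scores the
empirical crosstab against the closed forms; `sweep --config file.yaml`
runs user-defined scenarios.

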