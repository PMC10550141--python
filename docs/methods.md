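# Methods

`refbias` models how binary-classification accuracy assessment goes
wrong when the reference standard used to score the classifier is
itself imperfect, and when class prevalence varies. Everything is
closed-form and deterministic; the case-level sampler exists to verify
the closed forms by Monte Carlo and to provide finite-sample data.

## The forward models

A classifier is described by its per-class correctness rates against
ground truth: recall (sensitivity) `Recall_C` on positives,
specificity `Spec_C` on negatives. At prevalence `p`, scoring against
a **gold standard** gives the true matrix in proportions (reference in
columns, classifier in rows):

    TP = p·Recall_C          FP = (1−p)(1−Spec_C)
    FN = p·(1−Recall_C)      TN = (1−p)·Spec_C

An imperfect reference has its own rates `Recall_R`, `Spec_R` and an
**error structure**:

**Independent errors.** Reference mistakes are conditionally
independent of classifier mistakes given the true class. Each apparent
(primed) cell is the sum of the two joint routes into it, e.g.

    TP′ = p·Recall_R·Recall_C + (1−p)(1−Spec_R)(1−Spec_C)

and analogously for the other three cells (both labellings correct for
the cell's classes, or both wrong). One published source for this
family of equations prints two of the four cells with obvious
typographical defects (a dropped `Spec_R` factor and an unbalanced
expression); we use the joint-independence derivation, which exactly
reproduces the standard worked case-count arithmetic (e.g.
FP′ = 8 + 162 = 170 at p = 0.1, classifier 0.8/0.8, reference 0.9/0.9,
N = 1000).

**Correlated errors.** We model *maximal* conditional dependence:
every reference error lands on a case the classifier also mislabelled.
Truly positive cases called negative by both move FN → TN′; truly
negative cases called positive by both move FP → TP′:

    TP′ = p·Recall_C + (1−p)(1−Spec_R)     FP′ = (1−p)(Spec_R − Spec_C)
    FN′ = p·(Recall_R − Recall_C)          TN′ = (1−p)·Spec_C + p·(1−Recall_R)

This requires the reference to be at least as accurate as the
classifier on each class (`Recall_R ≥ Recall_C`, `Spec_R ≥ Spec_C`);
outside that region the construction has no probabilistic meaning and
we raise an error rather than truncate. Partial correlation is not
parameterised — the deterministic relabelling scheme defines only the
maximal case.

Under both structures the classifier's row marginals are conserved and
the reference-positive marginal — the **apparent prevalence** — is the
same linear map `p′ = p·Recall_R + (1−p)(1−Spec_R)`.

## Metrics

From any matrix, eleven quantities: accuracy, recall, precision,
specificity, NPV, Youden's J (= recall + specificity − 1), F1
(= 2TP/(2TP+FN+FP)), MCC (phi correlation of the two label vectors),
LR+ = recall/(1−specificity), LR− = (1−recall)/specificity, and
prevalence. All are scale-invariant in the cells, so proportions and
expected counts give identical values. A zero denominator yields a
NaN sentinel (empty CSV field / JSON null), never an exception, so
grid sweeps at extreme prevalence complete; perfect specificity gives
LR+ = +inf (zero specificity likewise for LR−). Display rounding is
two decimals; full precision is kept internally.

## Scenario sweeps

The standard grid is {0.01, 0.05, 0.10, …, 0.95, 0.99} — 0.05 steps
with the endpoints pulled in so neither class is empty — built from
integer hundredths to keep equality checks exact. The built-in set is
seven scenarios at N = 1000: a good classifier (0.8/0.8, J = 0.6)
against references with 2%, 10% and 18% per-class error (0.98, 0.90,
0.82), each under both error structures, plus a coin-tossing
classifier (0.5/0.5, J = 0) against a 30%-error (0.7/0.7) correlated
reference. The gold-standard baseline is emitted as the paired
"true" row at each grid point rather than as an eighth scenario.
Headline behaviour the sweep reproduces: apparent MCC reaches 0.96
(18% correlated, balanced prevalence), the coin tosser's apparent MCC
reaches 0.65 despite a true MCC of 0 everywhere, apparent prevalence
at p = 0.01 with 18% error is 0.1864 (over 18× inflation), and
apparent LR+ under 18% correlated error peaks near 909.3 at p = 0.99
(published rounding gives 909.2; we agree to within 0.1% and attribute
the last digit to intermediate rounding upstream).

## Transition points

`transition_prevalence` returns the classical expressions
`(1−Spec_R)/(2−Recall_R−Spec_R)` (precision; also the prevalence fixed
point) and `(1−Recall_R)/(2−Recall_R−Spec_R)` (NPV). For prevalence
this is exact: it is where the apparent-prevalence map crosses the
identity. For precision and NPV it should be read as the classical
reference-only approximation: under the independent-error forward
model the exact sign change of apparent minus true precision is
classifier-dependent, at `p/(1−p) = (1−Spec_R)(1−Spec_C) /
(Recall_C·(1−Recall_R))`, and coincides with the classical expression
only when `Recall_C + Spec_C = 1`. (For the 0.8/0.8 classifier against
a symmetric 0.9/0.9 reference the exact crossing is p = 0.2, not 0.5.)
The tests pin both facts.

## Bias correction

When reference errors are independent and reference quality is known,
the forward map is linear and invertible row by row. Writing
a = p·Recall_C, b = (1−p)(1−Spec_C) (top row) and c = p(1−Recall_C),
d = (1−p)·Spec_C (bottom row), each observed row is the mixing matrix
[[Recall_R, 1−Spec_R], [1−Recall_R, Spec_R]] applied to its pair, with
determinant `Recall_R + Spec_R − 1`. Solving gives p = a + c
(equivalently the Rogan–Gladen inversion of the apparent prevalence),
Recall_C = a/p, Spec_C = d/(1−p). A reference with
Recall_R + Spec_R = 1 is uninformative (singular map) and rejected.
On noisy or inconsistent empirical matrices the recovered values can
leave [0,1]; they are clamped and the result flagged rather than
raised, and a recovered p of exactly 0 or 1 leaves one rate 0/0,
reported as NaN with the same flag. Round-trip recovery on
model-generated matrices is exact to 1e−10 over a parameter lattice.
No closed-form inverse is offered for correlated errors (the maximal
model is a boundary case, not a family).

## Case-level sampler

`sample_cases` draws n independent triples (truth, classifier label,
reference label): truth ~ Bernoulli(p); the classifier is correct with
probability Recall_C / Spec_C by class. Independent structure draws
the reference correctness the same way, independently given truth.
Correlated structure lets the reference err *only* on classifier-error
cases, with conditional probability `(1−Recall_R)/(1−Recall_C)` on
positives and `(1−Spec_R)/(1−Spec_C)` on negatives — the sampling
analogue of the deterministic relabelling, chosen so the marginal
reference error rates are exactly `1−Recall_R`, `1−Spec_R` and the
expected crosstab equals the closed-form apparent matrix. A 0/0
conditional (classifier perfect on a class, which feasibility forces
the reference to match) is taken as 0. One `numpy` generator per
sample from a single explicit integer seed; no global RNG state.

What the generator emulates is exactly the assumptions of the closed
forms: homogeneous per-class error rates, exchangeable cases, and
either zero or maximal error dependence. Real data violate all three
(covariate-dependent errors, clustered sampling, partial correlation),
so passing Monte-Carlo checks demonstrate internal consistency of the
models, not robustness of the conclusions to those violations.

`mc_check` z-scores each observed cell proportion against its
closed-form expectation with the binomial SE √(q(1−q)/n) and passes
iff all |z| ≤ 4 (default). At n = 10⁶ the per-cell SE is ≈ 5·10⁻⁴, so
the check is sharp enough to catch any mis-specified cell while the
4-SE band keeps the false-alarm rate negligible.

## Problem sizes and numerics

Everything closed-form runs on the 21-point grid at N = 1000 in
milliseconds. Monte-Carlo verification uses n between 2·10⁵ and 10⁶
draws — ample for 4-SE cell checks (SE ≤ 1.1·10⁻³) while keeping the
whole suite under a few seconds. Tiny negative cell masses from float
cancellation (≥ −10⁻⁹) are clamped to zero at construction; anything
more negative is treated as a real modelling error and rejected.

## Known limitations

- Only the two extreme error structures (independence, maximal
  correlation) are modelled; real conditional dependence is
  intermediate and not identifiable from a single 2×2 table.
- Reference quality is an input, never estimated; latent-class or
  multi-reference estimation is out of scope.
- Binary classes only; no multi-class MCC, no ROC/PR curve
  construction, no confidence intervals on sweep outputs.
- The correction assumes the stated reference quality is exact;
  mis-stated quality propagates directly into the recovered rates.
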