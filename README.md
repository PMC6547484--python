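# mchequity

Wealth-related inequity analysis for maternal & child health (MCH) service
utilization, built around the concentration-index toolkit used in health
economics: weighted fractional ranks, concentration curves, the convenient-
regression estimator with standard errors, covariate standardization of the
index, between-survey difference tests, and survey-weighted logistic
modelling of institutional delivery — together with a DHS-like synthetic
survey generator whose wealth gradients are known ground truth.

## Who this is for

Analysts measuring whether services such as antenatal care (ANC) visits,
postnatal care (PNC) reviews, or facility delivery are concentrated among
richer or poorer women, and whether that concentration changed between two
survey rounds (for example before and after a financing reform).  Real
survey recode files are restricted-access, so the package ships a generator
that emulates a two-stage cluster design (enumeration areas, then
households) with configurable wealth gradients; every estimator is
validated against that known truth.

## The statistic

With records sorted by a wealth score, normalized weights `w_i`, and the
weighted mid-rank `r_i = Σ_{j<i} w_j + w_i/2`, the concentration index of an
outcome `h` with weighted mean `μ` is

```
CI = (2/μ) Σ_i w_i h_i (r_i − r̄)
```

— twice the area between the concentration curve and the 45° line of
equality; positive = pro-rich.  The convenient regression

```
2 σ_r² (h_i/μ) = α + β r_i + ε_i     (WLS, weights w_i)
```

has slope `β = CI` exactly and yields a standard error.  The adjusted
(standardized) CI replaces `h` with predictions from a weighted model of
`h` on wealth quintiles plus controls, evaluated with every control frozen
at its weighted mean; its SE comes from regressing the adjusted outcome on
the rescaled rank `(μ/2σ_r²)·r_i`, whose slope is again the CI.  Two survey
rounds are compared with `z = |CI_a − CI_b| / √(SE_a² + SE_b²)`.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

```python
import mchequity as m

cfg = m.PopulationConfig(seed=3, wealth_gradient_anc=0.4,
                         wealth_gradient_delivery=0.8)
bundle = m.run_survey_analysis(m.RunConfig(simulation=cfg, outcomes=("anc", "pnc")))
print(bundle.estimates)
```

prints (7 766 records, 353 clusters × 22 households):

```
outcome     method  adjusted  estimate  standard_error    n
    anc regression     False  0.076288        0.003274 7766
    anc covariance     False  0.076288             NaN 7766
    anc       area     False  0.076288             NaN 7766
    anc regression      True  0.065234        0.000211 7766
    pnc regression     False  0.098607        0.022894 7766
    pnc covariance     False  0.098607             NaN 7766
    pnc       area     False  0.098607             NaN 7766
    pnc regression      True  0.049115        0.000244 7766
```

The three unadjusted routes agree to machine precision — the convenient
regression is algebraically identical to the covariance formula, and the
area under the individual-level curve matches to O(1/n).  The positive ANC
index (+0.076) says ANC visits are concentrated among richer women, as
built into the generator; adjusting for education, occupation, residence,
ethnicity, religion, age and parity attenuates it to +0.065 (the part of the
gradient running through those covariates is removed) and shrinks the SE,
since the standardized outcome is a smooth prediction.  A comparison table
for two rounds comes from `m.compare_surveys(bundle_a, bundle_b)`.

The same pipeline is scriptable from the shell:

```bash
mchequity simulate --seed 3 --out run/sim
mchequity analyze --input run/sim/records.csv --out run/analysis
mchequity compare --input-a a.csv --input-b b.csv --out run/cmp
mchequity report --analysis-dir run/analysis --out run/curves.png
```

## Analysis scripts

`analysis/01_simulate_surveys.py` … `04_compare_surveys.py` run a full
two-round study on synthetic data: round one calibrated to a mildly
pro-rich ANC index and a near-zero PNC index, round two to a weaker ANC
gradient and a mildly pro-poor PNC index, with strongly pro-rich facility
delivery in both.  They write per-round estimate tables, curve coordinates,
odds-ratio tables and the comparison tables under `results/`.

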