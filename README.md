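# ccmtmm — cross-classified multitrait–multimethod models for rated data

When several interchangeable raters score the ideas that target persons
produce on several divergent-thinking tasks (say, alternate uses for a rope,
a garbage bag and a paperclip, each judged for cleverness and for creative
quality), the resulting ratings are **cross-classified**: variance can come
from the targets, from the raters, from rater–target interactions, from the
particular task object, and from measurement error. Standard CFA pipelines
average over raters first and confound object-specific variance with error.
`ccmtmm` implements a CTC(M−1) multitrait–multimethod factor model that
keeps all of these components apart, for researchers in creativity
assessment and rater-agreement psychometrics.

## The models

With targets *t*, raters *r*, indicators (task objects) *i* (reference
*i* = 1) and constructs *j*, the cross-classified model (**DTCC**) is

```
Y_rt1j = μ_1j +          T_tj +          R_rj +            INT_rtj           + ε_rt1j
Y_rtij = μ_ij + λT_ij·T_tj + λR_ij·R_rj + λINT_ij·INT_rtj + OM_tij + ε_rtij   (i ≠ 1)
```

where `T_tj` is the trait in the metric of the reference task, `OM_tij` the
target-level object-method residual of a non-reference task, `R_rj` a rater
effect and `INT_rtj` a rater–target interaction; all loadings of the
reference indicator are fixed to 1 and all latent variables within an
equation are orthogonal. The two-level simplification (**DTTL**)
conglomerates rater and interaction effects into a unique method effect
`UM_rtj` and admits a marginal maximum likelihood. From either parameter
set the package evaluates the complete true-score decomposition: the
model-implied ICC (`MIICC`, share of true-score variance due to targets),
rater/interaction/unique-method specificity (`RMS`, `IMS`, `UMS`),
target-level and total consistency vs object-method specificity (`L2Con`,
`L2OMS`, `L1Con`, `L1OMS`) and reliability (`REL`).

Estimation: conjugate Gibbs sampling (both variants) with Gelman–Rubin
convergence monitoring and posterior predictive χ² checking, and two-level
FIML (DTTL only) with the exact-fit test, RMSEA and level-wise SRMRs.
Preprocessing: 0.75-quantile aggregation of idea-level ratings and
average-measure absolute-agreement ICCs. A simulator generates data from
any parameter set for recovery studies.

## Worked example

Evaluating the decomposition at the two-level ML estimates of a published
alternate-uses study (202 targets, 4 cleverness and 3 creative-quality
raters, tasks rope/garbage bag/paperclip, shipped in `ccmtmm.datasets`):

```python
import ccmtmm as cc
params = cc.aut_study_estimates("dttl-ml")
dec = cc.decompose(params)
print(dec.rounded(3).loc[["miicc", "ums", "l2con", "rel"]])
```

prints

```
construct cleverness                       creative_quality
indicator       rope garbage_bag paperclip             rope garbage_bag paperclip
miicc          0.842       0.904     0.928            0.394       0.410     0.661
ums            0.158       0.096     0.072            0.606       0.590     0.339
l2con            NaN       0.256     0.260              NaN       0.247     0.220
rel            0.682       0.721     0.693            0.656       0.738     0.560
```

Cleverness raters agree strongly (MIICC ≈ 0.84–0.93: most true-score
variance is target-driven) while creative-quality scores carry substantial
rater-related method variance (UMS ≈ 0.34–0.61). The low L2Con values say
that only about a quarter of a non-reference task's target-level variance
is explained by the reference task — the task objects behave more like
different instruments than interchangeable forms. `l2con` is undefined
(NaN) for the reference task itself. Reliability stays above 0.55
throughout.

The `examples/` directory contains one short script per capability
(aggregation + ICC, decomposition, ML fitting, Gibbs sampling + posterior
predictive checking), and the `ccmtmm` command line exposes the same steps
as subcommands (`simulate`, `aggregate`, `icc`, `fit-bayes`, `fit-ml`,
`decompose`, `run`).

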