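# mrcorge

Core-instrument sensitivity analysis for two-sample Mendelian
randomization (MR).

MR estimates the causal effect of a polygenic exposure on an outcome
from GWAS summary statistics, using genetic variants as instruments.
Its Achilles' heel is horizontal pleiotropy: variants that affect the
outcome through pathways other than the exposure. Under the core gene
hypothesis, instruments with stronger variant–exposure associations are
more likely to act through core genes with direct biological impact,
while weaker (peripheral) instruments are more likely to be pleiotropic.

`mrcorge` operationalizes that idea as a sensitivity analysis. Given
harmonized exposure/outcome summary statistics, it:

1. ranks the J instruments by a coreness metric — |β̂_j| (default),
   per-variant heritability f_j(1−f_j)β̂_j², significance |β̂_j|/SE_j,
   or sample-size-normalized significance |β̂_j|/(SE_j√N_j) — with
   seeded random tie-breaking;
2. partitions them into K near-equal groups (group 1 = putative core);
3. computes group-specific and cumulative causal estimates for each
   group with the inverse-variance weighted (IVW), weighted median and
   weighted mode estimators, plus a mean F-statistic per group.

The group-1 estimates are the primary output. If the estimate drifts as
weaker groups enter the cumulative trajectory, pleiotropy in the
periphery is the prime suspect; if it is stable, the causal reading
gains support. A seeded simulator generates synthetic summary
statistics with an explicit core/peripheral architecture and
configurable pleiotropy for validating the approach end to end.

See `docs/methods.md` for the estimator formulas, harmonization rules,
the generative model and known limitations.

## Worked example

Simulate a null exposure–outcome pair (θ = 0) in which the 90 peripheral
instruments carry directional pleiotropy while the 10 core instruments
are valid, then run the analysis:

```bash
cat > scenario.yaml <<EOF
n_core: 10
n_peripheral: 90
theta: 0.0
pleiotropy_model: directional
pleiotropy_mean: 0.02
pleiotropy_scale: 0.02
seed: 7
EOF
mr-corge simulate --scenario scenario.yaml --out pleio
mr-corge run --exposure pleio.exposure.tsv --outcome pleio.outcome.tsv \
    --k 10 --methods ivw,weighted_median --seed 3 --n-boot 500 \
    --plot pleio.svg --out pleio
```

The cumulative IVW rows of `pleio.trajectory.tsv` (also drawn in
`pleio.svg`):

```
 k  n_instruments   beta  ci_low  ci_high   pval  f_statistic
 1             10 0.0150 -0.0463   0.0763 0.6313     644.2447
 2             20 0.0274 -0.0412   0.0959 0.4342     363.9366
 4             40 0.0709 -0.0056   0.1474 0.0694     215.1238
 6             60 0.1356  0.0400   0.2312 0.0054     158.0290
 8             80 0.1803  0.0877   0.2728 0.0001     129.0363
10            100 0.2196  0.1220   0.3172 0.0000     108.5877
```

The primary (group-1, putative core) estimate is 0.015 with p = 0.63 —
correctly consistent with the true null — and its mean F-statistic of
644 shows no weak-instrument concern. As progressively more peripheral
instruments accumulate, the estimate inflates to 0.22 with p < 10⁻⁴: an
all-instrument analysis would confidently report a causal effect that
does not exist. The trajectory's drift is the diagnostic signature of
peripheral pleiotropy.

`mr-corge run` also writes the harmonized instruments
(`*.instruments.tsv`), per-variant ranks and groups (`*.groups.tsv`), a
rejection report (`*.rejects.tsv`) and a JSON provenance manifest.
`mr-corge benchmark` runs a replicated Monte-Carlo comparison of group-1
versus all-instrument estimates under a scenario YAML. The same
functionality is available as a library (`mrcorge.mr_corge`,
`mrcorge.run_benchmark`, ...).

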