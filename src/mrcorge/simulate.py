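"""Synthetic two-sample GWAS summary statistics with a core/peripheral
instrument architecture.

The generator instantiates the two assumptions behind core-instrument
MR sensitivity analysis: (i) a small number of core instruments have
large direct effects on the exposure and act only through it, and (ii)
the many peripheral instruments have smaller exposure effects and may
carry horizontal pleiotropy (direct variant-to-outcome effects).

For each variant j:

* the effect-allele frequency f_j is uniform on a configurable range;
* the true per-allele exposure effect is b_j ~ Normal(0, scale^2) with
  a class-specific scale (core > peripheral), redrawn until
  |b_j| / se_j exceeds ``min_instrument_z`` (default 5.45, the
  genome-wide significance threshold p < 5e-8) — candidate instruments
  in real analyses are selected for genome-wide significance in the
  exposure GWAS, so summary tables never contain near-null exposure
  effects; conditioning on the true rather than the observed effect
  keeps exposure estimates unbiased (no winner's curse);
* the direct outcome effect is a_j = sign(b_j) * d_j with
  d_j ~ Normal(pleiotropy_mean, pleiotropy_scale^2) for targeted
  classes — signing relative to the exposure-increasing allele makes
  "directional" pleiotropy directional on the causal-effect scale,
  which is how pleiotropy biases real analyses where instruments are
  oriented to raise the exposure;
* the true outcome effect is theta * b_j + a_j;
* observed effects add independent sampling noise with the standard
  GWAS approximation for a unit-variance trait,
  se_j = 1 / sqrt(2 f_j (1 - f_j) N), independently in the two
  (non-overlapping) samples; p-values are two-sided normal.

Variants receive non-palindromic allele pairs by default so that
harmonization passes everything; ``palindrome_fraction`` injects
palindromic variants for harmonization tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corge_core import (CorgeConfig, derive_seed, estimate_all_instruments,
                         _estimate)
from .exceptions import EstimationError, ParameterError
from .ranking import rank_and_group
from .summary_io import VariantAssociation, harmonize

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of the synthetic core/peripheral architecture.

    Defaults describe a typical polygenic exposure: 10 core instruments
    with per-allele effect sd 0.1 and 90 peripheral instruments with sd
    0.02, GWAS sample sizes of 100 000 in both non-overlapping samples,
    no pleiotropy, and a null causal effect.
    """

    n_core: int = 10
    n_peripheral: int = 90
    theta: float = 0.0
    core_beta_scale: float = 0.1
    peripheral_beta_scale: float = 0.02
    pleiotropy_model: str = "none"          # none | balanced | directional
    pleiotropy_scale: float = 0.02
    pleiotropy_mean: float = 0.0
    pleiotropy_targets: str = "peripheral_only"  # peripheral_only | all
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    min_instrument_z: float | None = 5.45  # ~ p < 5e-8 instrument selection
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    palindrome_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_core < 0 or self.n_peripheral < 0:
            raise ParameterError("instrument counts must be non-negative")
        if self.n_core + self.n_peripheral < 1:
            raise ParameterError("at least one instrument is required")
        if min(self.core_beta_scale, self.peripheral_beta_scale,
               self.pleiotropy_scale) < 0:
            raise ParameterError("effect scales must be non-negative")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ParameterError("sample sizes must be positive")
        if self.pleiotropy_model not in ("none", "balanced", "directional"):
            raise ParameterError(
                f"unknown pleiotropy model {self.pleiotropy_model!r}")
        if self.pleiotropy_targets not in ("peripheral_only", "all"):
            raise ParameterError(
                f"unknown pleiotropy target {self.pleiotropy_targets!r}")
        if not (0 < self.eaf_low < self.eaf_high < 1):
            raise ParameterError("require 0 < eaf_low < eaf_high < 1")
        if not (0 <= self.palindrome_fraction <= 1):
            raise ParameterError("palindrome_fraction must be in [0, 1]")
        if self.pleiotropy_model == "balanced" and self.pleiotropy_mean != 0:
            raise ParameterError("balanced pleiotropy requires mean 0")


def _gwas_se(eaf: np.ndarray, n: float) -> np.ndarray:
    """Standard GWAS approximation of the per-allele SE for a
    unit-variance trait."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _observed_table(variant_id, ea, oa, eaf, true_beta, n, rng) -> pd.DataFrame:
    se = _gwas_se(eaf, n)
    beta = true_beta + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame({
        "variant_id": variant_id,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": n,
    })


def simulate_summary_stats(
    scenario: SimulationScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (exposure table, outcome table, truth table).

    The summary tables carry the canonical columns (variant_id,
    effect_allele, other_allele, eaf, beta, se, pval, n); the truth
    table records each variant's class, true exposure effect ``true_b``
    and direct outcome effect ``true_a``.  Byte-identical output for
    identical scenarios (seed included).
    """
    sc = scenario
    J = sc.n_core + sc.n_peripheral
    rng = np.random.default_rng(sc.seed)

    variant_id = np.array([f"rs{j + 1:06d}" for j in range(J)])
    classes = np.array(["core"] * sc.n_core + ["peripheral"] * sc.n_peripheral)
    eaf = rng.uniform(sc.eaf_low, sc.eaf_high, J)

    scale = np.where(classes == "core", sc.core_beta_scale,
                     sc.peripheral_beta_scale)
    b = rng.normal(0.0, 1.0, J) * scale
    if sc.min_instrument_z is not None:
        # instrument selection: redraw until the variant's true exposure
        # association is detectable at the design threshold
        if np.any(sc.min_instrument_z * _gwas_se(eaf, sc.n_exposure) > 6 * scale):
            raise ParameterError(
                "min_instrument_z is unattainable for the given effect "
                "scales and exposure sample size")
        se_exp = _gwas_se(eaf, sc.n_exposure)
        weak = np.abs(b) < sc.min_instrument_z * se_exp
        while np.any(weak):
            b[weak] = rng.normal(0.0, 1.0, int(weak.sum())) * scale[weak]
            weak = np.abs(b) < sc.min_instrument_z * se_exp

    a = np.zeros(J)
    if sc.pleiotropy_model != "none" and sc.pleiotropy_scale + abs(
            sc.pleiotropy_mean) > 0:
        targeted = (np.ones(J, bool) if sc.pleiotropy_targets == "all"
                    else classes == "peripheral")
        d = rng.normal(sc.pleiotropy_mean, sc.pleiotropy_scale, J)
        a = np.where(targeted, np.where(b >= 0, 1.0, -1.0) * d, 0.0)

    # Allele assignment: cycle non-palindromic pairs; optionally convert
    # a seeded random subset into palindromes.
    pairs = [_NONPALINDROMIC_PAIRS[j % len(_NONPALINDROMIC_PAIRS)]
             for j in range(J)]
    if sc.palindrome_fraction > 0:
        n_pal = int(round(sc.palindrome_fraction * J))
        pal_idx = rng.choice(J, size=n_pal, replace=False)
        for i, j in enumerate(pal_idx):
            pairs[j] = _PALINDROMIC_PAIRS[i % len(_PALINDROMIC_PAIRS)]
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])

    exposure = _observed_table(variant_id, ea, oa, eaf, b, sc.n_exposure, rng)
    outcome = _observed_table(variant_id, ea, oa, eaf, sc.theta * b + a,
                              sc.n_outcome, rng)
    truth = pd.DataFrame({
        "variant_id": variant_id,
        "class": classes,
        "true_b": b,
        "true_a": a,
    })
    return exposure, outcome, truth


def table_to_associations(df: pd.DataFrame) -> list[VariantAssociation]:
    """Convert a canonical summary-stat DataFrame to records."""
    return [VariantAssociation(
        variant_id=str(r.variant_id),
        effect_allele=str(r.effect_allele),
        other_allele=str(r.other_allele),
        beta=float(r.beta), se=float(r.se),
        eaf=float(r.eaf), pval=float(r.pval), n=float(r.n),
    ) for r in df.itertuples(index=False)]


def run_benchmark(scenario: SimulationScenario,
                  config: CorgeConfig,
                  n_replicates: int) -> pd.DataFrame:
    """Monte-Carlo benchmark of group-1 versus all-instrument estimates.

    For each replicate: simulate summary statistics, harmonize, rank and
    group, then compute the group-1 (putative core) and all-instrument
    estimate for every configured method.  Returns one row per
    (method, scope) with bias, empirical SD, RMSE, 95% CI coverage and
    rejection rate at alpha = 0.05 against the scenario's true effect,
    plus Monte-Carlo standard errors for bias and the two proportions.
    """
    if n_replicates < 2:
        raise ParameterError("n_replicates must be >= 2")
    theta = scenario.theta
    estimates: dict[tuple[str, str], list] = {
        (m, s): [] for m in config.methods for s in ("group1", "all")}

    for rep in range(n_replicates):
        rep_scenario = replace(scenario,
                               seed=derive_seed(scenario.seed, "sim", rep, "rep"))
        exposure, outcome, _ = simulate_summary_stats(rep_scenario)
        records, _ = harmonize(table_to_associations(exposure),
                               table_to_associations(outcome))
        ranked = rank_and_group(records, config.criterion, config.K,
                                config.seed)
        group1 = ranked.group(1)
        for method in config.methods:
            rep_master = derive_seed(config.seed, "bench", rep, method)
            for scope, recs in (("group1", group1), ("all", records)):
                try:
                    est = _estimate(method, recs, config,
                                    derive_seed(rep_master, method, 0, scope))
                except EstimationError:
                    continue
                estimates[(method, scope)].append(est)

    rows = []
    for (method, scope), ests in estimates.items():
        if len(ests) < 2:
            continue
        betas = np.array([e.beta for e in ests])
        covered = np.array([e.ci_low <= theta <= e.ci_high for e in ests])
        rejected = np.array([e.pval < 0.05 for e in ests])
        R = len(ests)
        sd = betas.std(ddof=1)
        rows.append({
            "method": method,
            "scope": scope,
            "n_replicates": R,
            "mean_estimate": betas.mean(),
            "bias": betas.mean() - theta,
            "empirical_sd": sd,
            "rmse": float(np.sqrt(np.mean((betas - theta) ** 2))),
            "coverage": covered.mean(),
            "rejection_rate": rejected.mean(),
            "mc_se_bias": sd / np.sqrt(R),
            "mc_se_coverage": float(np.sqrt(covered.mean()
                                            * (1 - covered.mean()) / R)),
            "mc_se_rejection": float(np.sqrt(rejected.mean()
                                             * (1 - rejected.mean()) / R)),
        })
    return pd.DataFrame(rows)
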