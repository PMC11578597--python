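"""MR Corge orchestration: group-specific and cumulative estimates.

Given harmonized instruments, the procedure ranks them by a coreness
metric, partitions them into K near-equal groups (group 1 = putative
core instruments), and computes, for every requested estimator:

* the *group-specific* estimate for each group k (instruments in group
  k only), and
* the *cumulative* estimate for each k (all instruments in groups
  1..k), so the trajectory from putative core to all instruments can be
  inspected.

Estimates based on the first group are the primary estimates: they are
the ones least likely to be biased by horizontal pleiotropy under the
core gene hypothesis.  A mean F-statistic accompanies every group as a
weak-instrument diagnostic.

Bootstrap seeds are derived deterministically from the master seed,
method name, group index and scope, so results are reproducible and
independent of evaluation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, EstimationError, ParameterError
from .estimators import (METHODS, MIN_INSTRUMENTS_ROBUST, MREstimate, ivw,
                         f_statistic, weighted_median, weighted_mode)
from .ranking import RankedInstrumentSet, canonical_criterion, rank_and_group
from .summary_io import InstrumentRecord


def derive_seed(master_seed: int, method: str, k: int, scope: str) -> int:
    """Deterministic sub-seed for the bootstrap of one estimate.

    Hashes (master seed, method, k, scope) with BLAKE2b and returns a
    31-bit integer, making every estimate's random stream independent of
    the order in which estimates are computed.  Group 1 and the first
    cumulative set contain the same instruments, so they share a seed
    (their estimates are emitted as identical rows).
    """
    if scope == "group" and k == 1:
        scope = "cumulative"
    token = f"{master_seed}:{method}:{k}:{scope}".encode()
    digest = hashlib.blake2b(token, digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


@dataclass(frozen=True)
class CorgeConfig:
    """Configuration of one MR Corge run."""

    K: int
    criterion: str = "abs_beta"
    methods: tuple[str, ...] = METHODS
    seed: int = 0
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    ivw_mode: str = "multiplicative_random"
    min_instruments_robust: int = MIN_INSTRUMENTS_ROBUST

    def __post_init__(self):
        if self.K < 1:
            raise ParameterError(f"K must be >= 1, got {self.K}")
        if not self.methods:
            raise ParameterError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ParameterError(f"unknown methods: {sorted(unknown)}")
        canonical_criterion(self.criterion)


@dataclass(frozen=True)
class CorgeResult:
    """Grid of group-specific and cumulative estimates.

    ``group_estimates`` and ``cumulative_estimates`` map (k, method) to
    an :class:`MREstimate`, or to None when the group is smaller than
    the method's minimum instrument count (reason in ``missing``).
    ``primary`` holds the group-1 estimates, the primary MR Corge
    output.
    """

    ranked_set: RankedInstrumentSet
    group_estimates: Mapping[tuple[int, str], MREstimate | None]
    cumulative_estimates: Mapping[tuple[int, str], MREstimate | None]
    group_f: Mapping[int, float]
    config: CorgeConfig
    missing: Mapping[tuple[int, str, str], str] = field(default_factory=dict)

    @property
    def primary(self) -> dict[str, MREstimate | None]:
        return {m: self.group_estimates[(1, m)] for m in self.config.methods}


def _estimate(method: str, records: Sequence[InstrumentRecord],
              config: CorgeConfig, seed: int) -> MREstimate:
    if method == "ivw":
        return ivw(records, mode=config.ivw_mode)
    if method == "weighted_median":
        return weighted_median(records, n_boot=config.n_boot, seed=seed,
                               min_instruments=config.min_instruments_robust)
    if method == "weighted_mode":
        return weighted_mode(records, bandwidth_factor=config.bandwidth_factor,
                             n_boot=config.n_boot, seed=seed,
                             min_instruments=config.min_instruments_robust)
    raise ParameterError(f"unknown method {method!r}")


def estimate_all_instruments(records: Sequence[InstrumentRecord],
                             config: CorgeConfig, method: str) -> MREstimate:
    """Single-call estimate on the full instrument set, using the same
    derived seed and the same (ranked) record ordering as the k = K
    cumulative estimate, so the two are identical to the bit."""
    ranked = rank_and_group(records, config.criterion, config.K, config.seed)
    seed = derive_seed(config.seed, method, config.K, "cumulative")
    return _estimate(method, ranked.cumulative(config.K), config, seed)


def mr_corge(records: Sequence[InstrumentRecord],
             config: CorgeConfig) -> CorgeResult:
    """Run the MR Corge sensitivity analysis.

    Ranks and partitions the instruments once, then fills the
    (group/cumulative) x method x k grid of estimates.  Groups smaller
    than an estimator's minimum instrument count yield a missing entry
    with a recorded reason rather than aborting the run.
    """
    if len(records) == 0:
        raise DataError("no instruments to analyse")
    ranked = rank_and_group(records, config.criterion, config.K, config.seed)

    group_estimates: dict[tuple[int, str], MREstimate | None] = {}
    cumulative_estimates: dict[tuple[int, str], MREstimate | None] = {}
    missing: dict[tuple[int, str, str], str] = {}
    group_f: dict[int, float] = {}

    for k in range(1, config.K + 1):
        group_records = ranked.group(k)
        cumulative_records = ranked.cumulative(k)
        group_f[k] = f_statistic(group_records)
        for method in config.methods:
            for scope, recs, store in (
                ("group", group_records, group_estimates),
                ("cumulative", cumulative_records, cumulative_estimates),
            ):
                seed = derive_seed(config.seed, method, k, scope)
                try:
                    store[(k, method)] = _estimate(method, recs, config, seed)
                except EstimationError as exc:
                    store[(k, method)] = None
                    missing[(k, method, scope)] = str(exc)
    return CorgeResult(
        ranked_set=ranked,
        group_estimates=group_estimates,
        cumulative_estimates=cumulative_estimates,
        group_f=group_f,
        config=config,
        missing=missing,
    )


def trajectory_table(result: CorgeResult) -> pd.DataFrame:
    """Tidy long-format table of the estimate trajectories.

    One row per (k, scope, method) with columns k, scope, method,
    n_instruments, beta, se, ci_low, ci_high, pval, f_statistic —
    directly plottable as group-specific and cumulative forest panels.
    Missing estimates (groups below an estimator's minimum size) are
    omitted; their reasons live in ``result.missing``.
    """
    rows = []
    for scope, grid in (("group", result.group_estimates),
                        ("cumulative", result.cumulative_estimates)):
        for (k, method), est in grid.items():
            if est is None:
                continue
            rows.append({
                "k": k, "scope": scope, "method": method,
                "n_instruments": est.n_instruments,
                "beta": est.beta, "se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "pval": est.pval, "f_statistic": est.f_statistic,
            })
    df = pd.DataFrame(rows, columns=["k", "scope", "method", "n_instruments",
                                     "beta", "se", "ci_low", "ci_high",
                                     "pval", "f_statistic"])
    return df.sort_values(["scope", "method", "k"], ignore_index=True)
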