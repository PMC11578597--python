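"""Coreness ranking and grouping of genetic instruments.

Under the core gene hypothesis, instruments with stronger variant-
exposure associations are more likely to act through core genes and
less likely to carry horizontal pleiotropy.  Instruments are therefore
ranked in descending order of one of four strength metrics, all
computed from the exposure GWAS:

``abs_beta`` (default)
    |b_j|, the absolute per-allele effect.
``per_variant_h2``
    f_j (1 - f_j) b_j^2, proportional to the variance in the exposure
    explained by the variant (f_j = effect-allele frequency; the
    expression is symmetric in f vs 1-f).
``significance``
    |b_j| / SE_j, the association z-score.
``n_normalized_significance``
    |b_j| / (SE_j * sqrt(N_j)), which can differ from the z-score when
    per-variant sample sizes vary (e.g. GWAS meta-analyses).

Ties are broken by a seeded random shuffle applied after sorting the
records canonically by variant_id, so results do not depend on input
row order.  The ranked list is then cut into K contiguous groups with
sizes differing by at most one; when J is not divisible by K the larger
groups come first, so the putative-core end is never under-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .summary_io import InstrumentRecord

CRITERIA = ("abs_beta", "per_variant_h2", "significance",
            "n_normalized_significance")

#: Short CLI aliases for the four criteria.
CRITERION_ALIASES = {
    "beta": "abs_beta",
    "h2": "per_variant_h2",
    "z": "significance",
    "zn": "n_normalized_significance",
}


def canonical_criterion(name: str) -> str:
    crit = CRITERION_ALIASES.get(name, name)
    if crit not in CRITERIA:
        raise ParameterError(
            f"unknown ranking criterion {name!r}; choose from "
            f"{CRITERIA} or aliases {tuple(CRITERION_ALIASES)}")
    return crit


def compute_metric(record: InstrumentRecord, criterion: str) -> float:
    """Coreness metric of one instrument (non-negative, exposure side)."""
    crit = canonical_criterion(criterion)
    if crit == "abs_beta":
        return abs(record.beta_exposure)
    if crit == "per_variant_h2":
        f = record.eaf_exposure
        if f is None:
            raise ParameterError(
                f"{record.variant_id}: eaf_exposure required for "
                "per_variant_h2 ranking")
        return f * (1.0 - f) * record.beta_exposure ** 2
    if crit == "significance":
        return abs(record.beta_exposure) / record.se_exposure
    # n_normalized_significance
    n = record.n_exposure
    if n is None or n <= 0:
        raise ParameterError(
            f"{record.variant_id}: positive n_exposure required for "
            "n_normalized_significance ranking")
    return abs(record.beta_exposure) / (record.se_exposure * math.sqrt(n))


@dataclass(frozen=True)
class RankedInstrumentSet:
    """Instruments ordered by decreasing coreness metric.

    ``records[i]`` has rank ``i + 1``; rank 1 is the most core-like
    instrument.  ``group_labels`` are 1..K, non-decreasing along ranks;
    group 1 holds the putative core instruments.
    """

    records: tuple[InstrumentRecord, ...]
    criterion: str
    metric_values: np.ndarray
    group_labels: np.ndarray
    K: int
    seed: int

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.records) + 1)

    def group(self, k: int) -> list[InstrumentRecord]:
        """Instruments in group k (1-based)."""
        return [r for r, g in zip(self.records, self.group_labels) if g == k]

    def cumulative(self, k: int) -> list[InstrumentRecord]:
        """Instruments in groups 1..k (the kth cumulative set)."""
        return [r for r, g in zip(self.records, self.group_labels) if g <= k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": [r.variant_id for r in self.records],
            "criterion": self.criterion,
            "metric_value": self.metric_values,
            "rank": self.ranks,
            "group": self.group_labels,
        })


def group_sizes(n_instruments: int, k_groups: int) -> list[int]:
    """Partition sizes: ceil(J/K) for the first J mod K groups, floor
    for the rest, so sizes differ by at most one and the core end gets
    the remainder."""
    base, extra = divmod(n_instruments, k_groups)
    return [base + 1] * extra + [base] * (k_groups - extra)


def suggest_k(n_instruments: int, target_group_size: int = 7) -> int:
    """Suggest a group count so each group holds roughly 5-10
    instruments (K = round(J / target size), at least 1)."""
    return max(1, round(n_instruments / target_group_size))


def rank_and_group(
    records: Sequence[InstrumentRecord],
    criterion: str = "abs_beta",
    K: int = 1,
    seed: int = 0,
) -> RankedInstrumentSet:
    """Rank instruments by a coreness metric and partition into K groups.

    Deterministic given (records, criterion, K, seed) regardless of the
    input order: records are first sorted by variant_id, tie-breaking
    noise is drawn from a generator seeded with ``seed``, and the sort
    on (metric descending, noise) yields the final ranking.

    Raises
    ------
    ParameterError
        if K < 1 or K exceeds the number of instruments.
    """
    crit = canonical_criterion(criterion)
    J = len(records)
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    if K > J:
        raise ParameterError(f"K ({K}) exceeds instrument count ({J})")

    canonical = sorted(records, key=lambda r: r.variant_id)
    metrics = np.array([compute_metric(r, crit) for r in canonical])
    rng = np.random.default_rng(seed)
    tie_noise = rng.random(J)
    # lexsort: last key is primary. Descending metric, then random noise
    # within exact-tie blocks.
    order = np.lexsort((tie_noise, -metrics))

    labels = np.repeat(np.arange(1, K + 1), group_sizes(J, K))
    return RankedInstrumentSet(
        records=tuple(canonical[i] for i in order),
        criterion=crit,
        metric_values=metrics[order],
        group_labels=labels,
        K=K,
        seed=seed,
    )
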