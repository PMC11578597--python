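"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization needs per-variant association
statistics for an exposure and an outcome, aligned to a common effect
allele.  This module reads tab/comma-delimited summary tables into
validated :class:`VariantAssociation` records, harmonizes exposure and
outcome tables into :class:`InstrumentRecord` objects (handling allele
swaps, strand flips and palindromic variants), and writes the
harmonized instrument table back out as TSV.

Variants are assumed to be pre-clumped to approximate linkage
equilibrium; LD-aware operations (clumping, proxy search) are out of
scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import DataError, FormatError, ParameterError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NUCLEOTIDES = frozenset(_COMPLEMENT)
_PALINDROMIC_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: Canonical column order of the harmonized instrument TSV.
INSTRUMENT_COLUMNS = [
    "variant_id", "effect_allele", "other_allele",
    "eaf_exposure", "beta_exposure", "se_exposure", "pval_exposure", "n_exposure",
    "eaf_outcome", "beta_outcome", "se_outcome", "pval_outcome", "n_outcome",
]

SUMMARY_COLUMNS = ["variant_id", "effect_allele", "other_allele",
                   "eaf", "beta", "se", "pval", "n"]
_REQUIRED_SUMMARY = ["variant_id", "effect_allele", "other_allele", "beta", "se"]


@dataclass(frozen=True, slots=True)
class VariantAssociation:
    """One variant's association statistics with a single trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: float | None = None

    def validation_failure(self) -> str | None:
        """Return the first violated invariant, or None if valid."""
        if not self.variant_id:
            return "empty variant_id"
        if not self.effect_allele or not self.other_allele:
            return "empty allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "nonpositive se"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "eaf outside (0, 1)"
        if self.pval is not None and not (0.0 <= self.pval <= 1.0):
            return "pval outside [0, 1]"
        if self.n is not None and not self.n > 0:
            return "nonpositive n"
        return None

    @property
    def is_snv(self) -> bool:
        return (self.effect_allele in _NUCLEOTIDES
                and self.other_allele in _NUCLEOTIDES)

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC_PAIRS

    def flipped(self) -> "VariantAssociation":
        """Swap effect/other allele, negating beta and mirroring eaf."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "VariantAssociation":
        """Express both alleles on the opposite strand."""
        return replace(
            self,
            effect_allele=_COMPLEMENT[self.effect_allele],
            other_allele=_COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True, slots=True)
class InstrumentRecord:
    """A harmonized instrument: exposure and outcome statistics on the
    same effect-allele orientation."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    pval_exposure: float | None = None
    n_exposure: float | None = None
    eaf_outcome: float | None = None
    pval_outcome: float | None = None
    n_outcome: float | None = None


@dataclass(frozen=True, slots=True)
class Rejection:
    """One excluded row/variant with the stage and reason."""

    variant_id: str
    stage: str
    reason: str


def rejections_frame(rejections: Sequence[Rejection]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variant_id, r.stage, r.reason) for r in rejections],
        columns=["variant_id", "stage", "reason"],
    )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[VariantAssociation], list[Rejection]]:
    """Read a GWAS summary-statistics table.

    Parameters
    ----------
    path:
        Tab- or comma-delimited file with a header row; ``.gz`` accepted.
    column_map:
        Optional mapping from file headers to canonical field names
        (``variant_id``, ``effect_allele``, ``other_allele``, ``eaf``,
        ``beta``, ``se``, ``pval``, ``n``).

    Returns
    -------
    (records, rejections):
        Validated records plus a per-row rejection report for rows that
        violate field invariants.  Rows are never silently dropped.

    Raises
    ------
    FormatError
        if a required column is absent.
    DataError
        if a variant identifier occurs more than once.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED_SUMMARY if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    dup = df["variant_id"].astype(str)[df["variant_id"].astype(str).duplicated()]
    if len(dup):
        raise DataError(
            "duplicate variant_id: " + ", ".join(sorted(set(dup)))
        )

    records: list[VariantAssociation] = []
    rejections: list[Rejection] = []
    has = {c: c in df.columns for c in ("eaf", "pval", "n")}
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        try:
            rec = VariantAssociation(
                variant_id=str(rowd["variant_id"]),
                effect_allele=str(rowd["effect_allele"]).upper(),
                other_allele=str(rowd["other_allele"]).upper(),
                beta=float(rowd["beta"]),
                se=float(rowd["se"]),
                eaf=_opt_float(rowd["eaf"]) if has["eaf"] else None,
                pval=_opt_float(rowd["pval"]) if has["pval"] else None,
                n=_opt_float(rowd["n"]) if has["n"] else None,
            )
        except (TypeError, ValueError) as exc:
            rejections.append(Rejection(str(rowd["variant_id"]), "read",
                                        f"unparsable value: {exc}"))
            continue
        failure = rec.validation_failure()
        if failure is not None:
            rejections.append(Rejection(rec.variant_id, "read", failure))
        else:
            records.append(rec)
    if rejections:
        logger.warning("%s: rejected %d of %d rows during read",
                       path, len(rejections), len(df))
    return records, rejections


def _align_nonpalindromic(
    exp: VariantAssociation, out: VariantAssociation
) -> VariantAssociation | None:
    """Orient a non-palindromic outcome record onto the exposure's
    alleles, or return None if the alleles are incompatible."""
    for candidate in (out, out.complemented()):
        if (candidate.effect_allele == exp.effect_allele
                and candidate.other_allele == exp.other_allele):
            return candidate
        if (candidate.effect_allele == exp.other_allele
                and candidate.other_allele == exp.effect_allele):
            return candidate.flipped()
    return None


def _align_palindromic(
    exp: VariantAssociation,
    out: VariantAssociation,
    maf_threshold: float,
) -> VariantAssociation | str:
    """Adjudicate a palindromic variant by allele-frequency concordance.

    Returns the oriented outcome record, or a rejection reason string.
    Frequencies near 0.5 cannot distinguish strands, hence the minor
    allele frequency cutoff (exposure side, the instrument-selection
    GWAS).
    """
    if frozenset({out.effect_allele, out.other_allele}) != frozenset(
            {exp.effect_allele, exp.other_allele}):
        return "incompatible alleles"
    if exp.eaf is None:
        return "palindromic, missing exposure frequency"
    maf = min(exp.eaf, 1.0 - exp.eaf)
    if maf > maf_threshold:
        return "palindromic, ambiguous frequency"
    # Label alignment first, then assume a strand flip if the minor
    # alleles disagree (complement + swap restores the exposure labels).
    aligned = out if out.effect_allele == exp.effect_allele else out.flipped()
    if aligned.eaf is None:
        return "palindromic, missing outcome frequency"
    if (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
        aligned = aligned.complemented().flipped()
    return aligned


def harmonize(
    exposure: Iterable[VariantAssociation],
    outcome: Iterable[VariantAssociation],
    palindrome_maf_threshold: float = 0.42,
    strict_palindromes: bool = False,
) -> tuple[list[InstrumentRecord], list[Rejection]]:
    """Harmonize exposure and outcome summary statistics.

    Intersects the two tables on ``variant_id`` and aligns the outcome
    statistics to the exposure's effect allele: swapped alleles flip the
    outcome beta sign (and mirror its frequency); strand flips are
    resolved by complementing; palindromic variants (A/T or C/G) whose
    exposure minor allele frequency exceeds ``palindrome_maf_threshold``
    are excluded as strand-ambiguous, otherwise they are oriented by
    allele-frequency concordance.  With ``strict_palindromes`` every
    palindrome is dropped.

    Variants with ``beta_exposure == 0`` are rejected (they cannot enter
    ratio-based estimators); indels/non-ACGT alleles are rejected rather
    than guessed at.

    Returns the harmonized records (exposure table order) and the
    rejection report.  ``len(records) + len(stage=="harmonize"
    rejections)`` equals the size of the variant_id intersection.
    """
    if not (0.0 < palindrome_maf_threshold <= 0.5):
        raise ParameterError(
            f"palindrome MAF threshold must be in (0, 0.5], got "
            f"{palindrome_maf_threshold}")
    exposure = list(exposure)
    outcome_by_id = {r.variant_id: r for r in outcome}

    records: list[InstrumentRecord] = []
    rejections: list[Rejection] = []
    shared = 0
    for exp in exposure:
        out = outcome_by_id.get(exp.variant_id)
        if out is None:
            rejections.append(Rejection(exp.variant_id, "intersect",
                                        "missing in outcome"))
            continue
        shared += 1

        def reject(reason: str, vid=exp.variant_id) -> None:
            rejections.append(Rejection(vid, "harmonize", reason))

        if not (exp.is_snv and out.is_snv):
            reject("indel or non-ACGT alleles")
            continue
        if exp.beta == 0.0:
            reject("zero exposure effect")
            continue
        if exp.is_palindromic:
            if strict_palindromes:
                reject("palindromic, strict mode")
                continue
            aligned = _align_palindromic(exp, out, palindrome_maf_threshold)
            if isinstance(aligned, str):
                reject(aligned)
                continue
        else:
            aligned = _align_nonpalindromic(exp, out)
            if aligned is None:
                reject("incompatible alleles")
                continue
        records.append(InstrumentRecord(
            variant_id=exp.variant_id,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            eaf_exposure=exp.eaf,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            pval_exposure=exp.pval,
            n_exposure=exp.n,
            eaf_outcome=aligned.eaf,
            beta_outcome=aligned.beta,
            se_outcome=aligned.se,
            pval_outcome=aligned.pval,
            n_outcome=aligned.n,
        ))
    exposure_ids = {r.variant_id for r in exposure}
    for out in outcome_by_id.values():
        if out.variant_id not in exposure_ids:
            rejections.append(Rejection(out.variant_id, "intersect",
                                        "missing in exposure"))
    if shared == 0:
        raise DataError("no shared instruments between exposure and outcome")
    return records, rejections


def split_instruments(
    records: Iterable[InstrumentRecord],
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Split harmonized records back into exposure/outcome association
    lists (both on the harmonized allele orientation)."""
    exposure, outcome = [], []
    for r in records:
        exposure.append(VariantAssociation(
            r.variant_id, r.effect_allele, r.other_allele,
            r.beta_exposure, r.se_exposure,
            eaf=r.eaf_exposure, pval=r.pval_exposure, n=r.n_exposure))
        outcome.append(VariantAssociation(
            r.variant_id, r.effect_allele, r.other_allele,
            r.beta_outcome, r.se_outcome,
            eaf=r.eaf_outcome, pval=r.pval_outcome, n=r.n_outcome))
    return exposure, outcome


def instruments_frame(records: Iterable[InstrumentRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in fields(InstrumentRecord)}
            for r in records]
    return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def write_instruments(records: Sequence[InstrumentRecord],
                      path: str | Path) -> None:
    """Write harmonized instruments as a canonical TSV ("NA" = missing)."""
    if len(records) == 0:
        logger.warning("writing header-only instrument table to %s", path)
    instruments_frame(records).to_csv(path, sep="\t", index=False,
                                      na_rep="NA", float_format="%.17g")


def read_instruments(path: str | Path) -> list[InstrumentRecord]:
    """Read a harmonized instrument TSV produced by write_instruments."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"variant_id": str}, float_precision="round_trip")
    missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(InstrumentRecord(
            variant_id=str(d["variant_id"]),
            effect_allele=str(d["effect_allele"]),
            other_allele=str(d["other_allele"]),
            beta_exposure=float(d["beta_exposure"]),
            se_exposure=float(d["se_exposure"]),
            beta_outcome=float(d["beta_outcome"]),
            se_outcome=float(d["se_outcome"]),
            eaf_exposure=_opt_float(d["eaf_exposure"]),
            pval_exposure=_opt_float(d["pval_exposure"]),
            n_exposure=_opt_float(d["n_exposure"]),
            eaf_outcome=_opt_float(d["eaf_outcome"]),
            pval_outcome=_opt_float(d["pval_outcome"]),
            n_outcome=_opt_float(d["n_outcome"]),
        ))
    return records
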