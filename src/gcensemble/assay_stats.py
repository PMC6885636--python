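"""Reduction of reporter-assay summary statistics.

Works from published-style summary tables (per-variant mean, standard
error of the mean, replicate count) for three read-outs of heterologous
sGC activity in bacterial cells: luciferase activity (RLU/mg protein),
extracellular cGMP and extracellular cAMP (pmol/mg protein x 10^3).
Derived quantities:

* fold-increase of a variant over wild type (ratio of means),
* cGMP/cAMP specificity ratio of one variant,
* a two-sample t test from summary statistics (pooled Student by
  default, Welch optional) with the conventional star annotation
  (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "Measure",
    "AssayGroup",
    "ComparisonResult",
    "fold_increase",
    "specificity_ratio",
    "two_sample_t",
    "stars_for_p",
]

logger = logging.getLogger(__name__)


class Measure(str, Enum):
    LUCIFERASE = "luciferase"  # RLU/mg protein
    CGMP = "cgmp"              # pmol cGMP/mg protein x 10^3
    CAMP = "camp"              # pmol cAMP/mg protein x 10^3


@dataclass(frozen=True)
class AssayGroup:
    """Summary statistics of one variant under one measure."""

    variant: str
    measure: Measure
    mean: float
    sem: float
    n: int = 3

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("assay means are non-negative")
        if self.sem < 0:
            raise ValueError("standard error must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")

    @property
    def sd(self) -> float:
        """Sample standard deviation recovered from the SEM."""
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class ComparisonResult:
    """Derived comparison of a variant against wild type."""

    fold: float
    t_statistic: float
    p_value: float
    stars: str


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def fold_increase(variant: AssayGroup, wildtype: AssayGroup, decimals: int = 1) -> float:
    """Variant mean over wild-type mean, rounded half-up to ``decimals``.

    Both groups must carry the same measure; published tables print this
    at one decimal place, computed from the (unrounded) means.
    """
    if variant.measure != wildtype.measure:
        raise ValueError(
            f"measure mismatch: {variant.measure.value} vs {wildtype.measure.value}"
        )
    if wildtype.mean <= 0:
        raise ZeroDivisionError("wild-type mean must be positive for a fold change")
    return _round_half_up(variant.mean / wildtype.mean, decimals)


def specificity_ratio(cgmp: AssayGroup, camp: AssayGroup, decimals: int = 1) -> float:
    """cGMP mean over cAMP mean for the same variant (substrate specificity)."""
    if cgmp.measure != Measure.CGMP or camp.measure != Measure.CAMP:
        raise ValueError("specificity ratio needs a cGMP and a cAMP group, in that order")
    if cgmp.variant != camp.variant:
        raise ValueError(f"variant mismatch: {cgmp.variant!r} vs {camp.variant!r}")
    if camp.mean <= 0:
        raise ZeroDivisionError("cAMP mean must be positive for a ratio")
    return _round_half_up(cgmp.mean / camp.mean, decimals)


def stars_for_p(p: float) -> str:
    """Conventional significance annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_sample_t(
    variant: AssayGroup,
    wildtype: AssayGroup,
    kind: str = "student",
    decimals: int = 1,
) -> ComparisonResult:
    """Two-sided two-sample t test from summary statistics.

    The sample standard deviation is recovered as ``sd = sem * sqrt(n)``.
    ``kind="student"`` pools the variances (equal-variance assumption,
    the convention of the assay tables reproduced here);
    ``kind="welch"`` uses the Welch-Satterthwaite correction.  Both agree
    exactly when n and sd match across groups.
    """
    if kind not in ("student", "welch"):
        raise ValueError(f"unknown test variant {kind!r}")
    if variant.measure != wildtype.measure:
        raise ValueError("t test requires matching measures")
    res = stats.ttest_ind_from_stats(
        mean1=variant.mean, std1=variant.sd, nobs1=variant.n,
        mean2=wildtype.mean, std2=wildtype.sd, nobs2=wildtype.n,
        equal_var=(kind == "student"),
    )
    t, p = float(res.statistic), float(res.pvalue)
    if variant.mean == wildtype.mean and variant.sd == wildtype.sd and variant.n == wildtype.n:
        # identical summary statistics: t is exactly 0, p exactly 1
        t, p = 0.0, 1.0
    return ComparisonResult(
        fold=fold_increase(variant, wildtype, decimals=decimals),
        t_statistic=t,
        p_value=p,
        stars=stars_for_p(p),
    )


def reduce_table(rows: list[dict], wildtype_label: str, decimals: int = 1) -> list[dict]:
    """Derive fold-increase / ratio / t-test columns for a summary table.

    ``rows`` carry keys variant, measure, mean, sem and optionally n
    (default 3, logged loudly because published tables often omit it).
    Returns one record per variant with the derived columns filled in
    where the needed inputs exist.
    """
    groups: dict[tuple[str, Measure], AssayGroup] = {}
    for row in rows:
        n = row.get("n")
        if n is None or (isinstance(n, float) and np.isnan(n)):
            logger.warning(
                "replicate count missing for %s/%s; defaulting to n=3 "
                "(p-values are approximate)", row["variant"], row["measure"],
            )
            n = 3
        group = AssayGroup(
            variant=str(row["variant"]),
            measure=Measure(row["measure"]),
            mean=float(row["mean"]),
            sem=float(row["sem"]),
            n=int(n),
        )
        groups[(group.variant, group.measure)] = group

    variants: list[str] = []
    for variant, _ in groups:
        if variant not in variants:
            variants.append(variant)
    wt = {m: groups.get((wildtype_label, m)) for m in Measure}

    out = []
    for variant in variants:
        rec: dict = {"variant": variant}
        for measure, column in [
            (Measure.LUCIFERASE, "luciferase"),
            (Measure.CGMP, "cgmp"),
            (Measure.CAMP, "camp"),
        ]:
            group = groups.get((variant, measure))
            if group is None:
                continue
            rec[f"{column}_mean"] = group.mean
            rec[f"{column}_sem"] = group.sem
            reference = wt[measure]
            if reference is not None and reference.mean > 0:
                rec[f"{column}_fold"] = fold_increase(group, reference, decimals=decimals)
                if measure == Measure.LUCIFERASE and variant != wildtype_label:
                    comparison = two_sample_t(group, reference)
                    rec["p_value"] = comparison.p_value
                    rec["stars"] = comparison.stars
        cg = groups.get((variant, Measure.CGMP))
        ca = groups.get((variant, Measure.CAMP))
        if cg is not None and ca is not None and ca.mean > 0:
            rec["cgmp_camp_ratio"] = specificity_ratio(cg, ca, decimals=decimals)
        out.append(rec)
    return out
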