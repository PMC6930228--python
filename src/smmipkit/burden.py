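"""Case-control rare-variant burden testing with an exact Fisher test.

Patients are collapsed to carrier / non-carrier of any qualifying variant
in a stratum (for example all VUS, or variants with a high CADD score),
counted into a 2x2 contingency table against the control cohort, and
compared with a two-sided Fisher's exact test. Only variants lying in
regions adequately covered in *both* cohorts are comparable, so an
interval-intersection step restricts the analysis first.

The Fisher p-value is computed here by explicit enumeration of the
hypergeometric distribution over all tables sharing the observed margins,
summing the probability of every table no more likely than the observed
one (with a small relative tolerance for floating-point ties). No
multiple-testing correction is applied across strata; raw p-values are
reported.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from math import exp, lgamma
from typing import Dict, List, Sequence

import pandas as pd

from smmipkit._intervals import Interval, intersect

#: relative tolerance when comparing outcome probabilities to the observed one
TIE_RELATIVE_TOLERANCE = 1e-7

STRATA = ("all", "VUS", "predicted_pathogenic")


class BurdenError(ValueError):
    """Invalid contingency input."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts: a/b = case carriers/non-carriers, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise BurdenError(f"negative cell in {self}")
        if self.total == 0:
            raise BurdenError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class BurdenConfig:
    alpha: float = 0.05
    cadd_high: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BurdenResult:
    stratum: str
    table: ContingencyTable2x2
    p_value: float
    significant: bool
    alpha: float

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "case_carriers": self.table.a,
            "case_noncarriers": self.table.b,
            "control_carriers": self.table.c,
            "control_noncarriers": self.table.d,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
        }


def shared_covered_regions(
    case_bed: Sequence[Interval], control_bed: Sequence[Interval]
) -> List[Interval]:
    """Intersection of the two cohorts' covered regions (merged, sorted)."""
    return intersect(case_bed, control_bed)


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value by hypergeometric enumeration.

    Conditional on the observed margins, each possible table has
    hypergeometric probability; the p-value is the total probability of
    all tables whose probability does not exceed the observed table's
    (within a relative tolerance of 1e-7 to absorb floating-point ties in
    log space). Probabilities use exact log-factorials via ``lgamma``.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    n = table.total
    denom = _log_comb(n, c1)

    def log_pmf(k: int) -> float:
        return _log_comb(r1, k) + _log_comb(r2, c1 - k) - denom

    lp_obs = log_pmf(table.a)
    cutoff = exp(lp_obs) * (1.0 + TIE_RELATIVE_TOLERANCE)
    k_min, k_max = max(0, c1 - r2), min(r1, c1)
    p = 0.0
    for k in range(k_min, k_max + 1):
        pk = exp(log_pmf(k))
        if pk <= cutoff:
            p += pk
    return min(p, 1.0)


def _stratum_mask(variants: pd.DataFrame, stratum: str, config: BurdenConfig) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=variants.index)
    if stratum == "VUS":
        return variants["classification"] == "VUS"
    if stratum == "predicted_pathogenic":
        return variants["cadd"].notna() & (variants["cadd"] > config.cadd_high)
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def _in_regions(variants: pd.DataFrame, regions: Sequence[Interval]) -> pd.Series:
    mask = []
    for row in variants.itertuples(index=False):
        chrom, pos = getattr(row, "chrom", None), getattr(row, "pos", None)
        mask.append(
            any(c == chrom and s <= int(pos) < e for c, s, e in regions)
            if chrom is not None and pos is not None and not pd.isna(pos)
            else False
        )
    return pd.Series(mask, index=variants.index)


def count_carriers(
    variants: pd.DataFrame,
    stratum: str = "all",
    config: BurdenConfig | None = None,
    regions: Sequence[Interval] | None = None,
) -> int:
    """Number of distinct patients carrying >=1 qualifying variant.

    A patient with several qualifying variants counts once. When
    ``regions`` is given the table must carry ``chrom``/``pos`` columns
    and only variants inside the regions qualify.
    """
    if config is None:
        config = BurdenConfig()
    if len(variants) == 0:
        return 0
    mask = _stratum_mask(variants, stratum, config)
    if regions is not None:
        if not {"chrom", "pos"} <= set(variants.columns):
            raise BurdenError(
                "region restriction requires chrom/pos columns in the variant table"
            )
        mask &= _in_regions(variants, regions)
    return int(variants.loc[mask, "patient_id"].nunique())


def burden_test(
    case_variants: pd.DataFrame,
    control_variants: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    stratum: str = "all",
    config: BurdenConfig | None = None,
    shared_regions: Sequence[Interval] | None = None,
) -> BurdenResult:
    """Collapse each cohort to carrier counts and run the exact test.

    ``case_variants``/``control_variants`` are post-filter annotated
    tables (one row per patient x variant). Carrier counts exceeding the
    stated cohort size are a contract violation.
    """
    if config is None:
        config = BurdenConfig()
    a = count_carriers(case_variants, stratum, config, shared_regions)
    c = count_carriers(control_variants, stratum, config, shared_regions)
    if a > n_cases or c > n_controls:
        raise BurdenError(
            f"carrier count exceeds cohort size (cases {a}/{n_cases}, "
            f"controls {c}/{n_controls})"
        )
    table = ContingencyTable2x2(a=a, b=n_cases - a, c=c, d=n_controls - c)
    p = fisher_exact_two_sided(table)
    return BurdenResult(
        stratum=stratum,
        table=table,
        p_value=p,
        significant=p < config.alpha,
        alpha=config.alpha,
    )


def write_burden_results(
    results: Sequence[BurdenResult], path: str | os.PathLike
) -> None:
    payload: Dict[str, dict] = {r.stratum: r.to_dict() for r in results}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
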