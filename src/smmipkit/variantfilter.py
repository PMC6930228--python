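"""Rare-variant filter cascade over annotated cohort variant tables.

A germline screening panel reports one row per patient x variant with
population allele frequencies, an in-house observation count, consequence
class, CADD deleteriousness score and a clinical classification. The
cascade keeps a variant only when every rule holds:

* 1000-genomes allele frequency below ``max_pop_af`` (default 1%),
* ExAC allele frequency below ``max_pop_af``,
* seen fewer than ``max_inhouse`` times in the in-house database,
* not synonymous,
* intronic only within ``intron_cutoff`` bases of an exon boundary
  (default +/- 8 bp),
* not classified benign or likely benign.

The rules are independent predicates joined by conjunction, so their
order never changes the passing set — only the "first failing rule" audit
column. A missing population frequency counts as 0 (absence from the
population databases is itself evidence of rarity); a missing CADD score
never excludes a variant, since CADD is used for prioritization, not
filtering.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

CONSEQUENCES = {
    "missense",
    "synonymous",
    "intronic",
    "inframe_indel",
    "splice_region",
    "other",
}

CLASSIFICATIONS = {
    "benign",
    "likely_benign",
    "VUS",
    "likely_pathogenic",
    "pathogenic",
    "unclassified",
}

# numeric ACMG-style class labels accepted on input
_CLASS_ALIASES = {
    "1": "benign",
    "2": "likely_benign",
    "3": "VUS",
    "4": "likely_pathogenic",
    "5": "pathogenic",
}

REQUIRED_COLUMNS = [
    "patient_id",
    "cdna_change",
    "protein_change",
    "consequence",
    "intron_distance",
    "af_1000g",
    "af_exac",
    "inhouse_count",
    "cadd",
    "classification",
]


class VariantTableError(ValueError):
    """Malformed annotated-variant table."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; all comparisons are strict as documented."""

    max_pop_af: float = 0.01  # population AF must be strictly below this
    max_inhouse: int = 50  # in-house observations must be strictly below this
    intron_cutoff: int = 8  # intronic variants retained within +/- this many bp
    cadd_high: float = 20.0  # "high in-silico prediction" stratum is CADD > this

    def __post_init__(self) -> None:
        if min(self.max_pop_af, self.max_inhouse, self.intron_cutoff, self.cadd_high) <= 0:
            raise ValueError("all filter thresholds must be positive")


def load_variant_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an annotated-variant TSV and validate/normalize its columns.

    Numeric ACMG class labels ('1'..'5') are normalized to their names;
    empty allele frequencies become 0 and empty CADD becomes NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing column(s): {', '.join(missing)}")
    return normalize_variant_table(df, source=str(path))


def normalize_variant_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    df = df.copy()
    for col in ("af_1000g", "af_exac"):
        values = []
        for rownum, raw in enumerate(df[col].astype(str), start=2):
            raw = raw.strip()
            if raw in ("", "nan", "NA", "."):
                values.append(0.0)
                continue
            try:
                af = float(raw)
            except ValueError as exc:
                raise VariantTableError(
                    f"{source}: row {rownum}: malformed {col} value {raw!r}"
                ) from exc
            if not 0 <= af <= 1:
                raise VariantTableError(
                    f"{source}: row {rownum}: {col} out of [0, 1]: {af}"
                )
            values.append(af)
        df[col] = values
    cadd_raw = df["cadd"].astype(str).str.strip().replace({"nan": "", ".": "", "-": ""})
    df["cadd"] = pd.to_numeric(cadd_raw.where(cadd_raw != "", None), errors="coerce")
    df["inhouse_count"] = pd.to_numeric(df["inhouse_count"], errors="raise").astype(int)
    df["intron_distance"] = pd.to_numeric(df["intron_distance"], errors="raise").astype(int)
    df["classification"] = df["classification"].astype(str).str.strip().replace(_CLASS_ALIASES)
    bad_class = set(df["classification"]) - CLASSIFICATIONS
    if bad_class:
        raise VariantTableError(f"{source}: unknown classification(s): {sorted(bad_class)}")
    bad_csq = set(df["consequence"]) - CONSEQUENCES
    if bad_csq:
        raise VariantTableError(f"{source}: unknown consequence(s): {sorted(bad_csq)}")
    if (df["inhouse_count"] < 0).any() or (df["intron_distance"] < 0).any():
        raise VariantTableError(f"{source}: negative count or intron distance")
    return df


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

RuleFn = Callable[[pd.DataFrame, FilterConfig], pd.Series]


def _fail_af_1000g(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    return df["af_1000g"] >= cfg.max_pop_af


def _fail_af_exac(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    return df["af_exac"] >= cfg.max_pop_af


def _fail_inhouse(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    return df["inhouse_count"] >= cfg.max_inhouse


def _fail_synonymous(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    return df["consequence"] == "synonymous"


def _fail_deep_intronic(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    return (df["consequence"] == "intronic") & (df["intron_distance"] > cfg.intron_cutoff)


def _fail_benign_class(df: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    return df["classification"].isin(["benign", "likely_benign"])


RULES: Dict[str, RuleFn] = {
    "af_1000g": _fail_af_1000g,
    "af_exac": _fail_af_exac,
    "inhouse": _fail_inhouse,
    "synonymous": _fail_synonymous,
    "deep_intronic": _fail_deep_intronic,
    "benign_classification": _fail_benign_class,
}

DEFAULT_RULE_ORDER: Tuple[str, ...] = tuple(RULES)


def apply_filter_cascade(
    variants: pd.DataFrame,
    config: FilterConfig | None = None,
    rule_order: Sequence[str] | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the rare-variant cascade; return (passing table, trace).

    The trace has one row per input variant with ``passed``, the first
    failing rule in ``rule_order`` (empty when passing) and all failing
    rules joined by commas. Because the cascade is a conjunction, the
    passing set does not depend on ``rule_order``.
    """
    if config is None:
        config = FilterConfig()
    order = tuple(rule_order) if rule_order is not None else DEFAULT_RULE_ORDER
    unknown = set(order) - set(RULES)
    if unknown or len(set(order)) != len(RULES):
        raise ValueError(f"rule_order must be a permutation of {sorted(RULES)}")
    df = normalize_variant_table(variants) if len(variants) else variants.copy()
    fail_masks = {name: RULES[name](df, config) for name in order} if len(df) else {}
    rows = []
    passing_mask = []
    for idx in df.index:
        failing = [name for name in order if bool(fail_masks[name].loc[idx])]
        passing_mask.append(not failing)
        rows.append(
            {
                "patient_id": df.at[idx, "patient_id"],
                "cdna_change": df.at[idx, "cdna_change"],
                "passed": not failing,
                "first_failing_rule": failing[0] if failing else "",
                "failing_rules": ",".join(failing),
            }
        )
    trace = pd.DataFrame(
        rows,
        columns=["patient_id", "cdna_change", "passed", "first_failing_rule", "failing_rules"],
    )
    passing = df.loc[passing_mask].reset_index(drop=True) if len(df) else df
    return passing, trace


def summarize_cohort(
    passing: pd.DataFrame,
    config: FilterConfig | None = None,
    cohort_size: int = 373,
) -> dict:
    """Cohort-level summary of the variants surviving the cascade.

    Distinct variants are keyed on the cDNA change string. "Biallelic
    candidates" are patients carrying a pathogenic (class 5) variant plus
    at least one further variant, reported also as a percentage of the
    cohort (1 decimal place).
    """
    if config is None:
        config = FilterConfig()
    if len(passing) == 0:
        return {
            "distinct_variants": 0,
            "carrier_patients": 0,
            "distinct_vus": 0,
            "distinct_cadd_high": 0,
            "biallelic_candidate_patients": 0,
            "biallelic_candidate_pct": 0.0,
            "cohort_size": cohort_size,
        }
    distinct = passing.drop_duplicates("cdna_change")
    per_patient = passing.groupby("patient_id")
    biallelic = [
        pid
        for pid, grp in per_patient
        if (grp["classification"] == "pathogenic").any() and len(grp) >= 2
    ]
    return {
        "distinct_variants": int(len(distinct)),
        "carrier_patients": int(passing["patient_id"].nunique()),
        "distinct_vus": int((distinct["classification"] == "VUS").sum()),
        "distinct_cadd_high": int((distinct["cadd"] > config.cadd_high).sum()),
        "biallelic_candidate_patients": len(biallelic),
        "biallelic_candidate_pct": round(100.0 * len(biallelic) / cohort_size, 1),
        "cohort_size": cohort_size,
    }


def load_cohort_fixture() -> pd.DataFrame:
    """The packaged 373-patient dystonia-cohort rare-variant table.

    One row per patient x variant for the 22 carrier patients; cDNA and
    protein changes, CADD scores and classifications are the published
    screening results, while the frequency/consequence annotation columns
    are synthetic values consistent with every row having survived the
    cascade (the study's in-house database is not redistributable).
    """
    ref = resources.files("smmipkit").joinpath("fixtures/atm_dystonia_cohort_variants.tsv")
    with resources.as_file(ref) as path:
        return load_variant_table(path)


def write_filter_outputs(
    passing: pd.DataFrame,
    trace: pd.DataFrame,
    summary: dict,
    outdir: str | os.PathLike,
) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    passing.to_csv(os.path.join(outdir, "passing.tsv"), sep="\t", index=False)
    trace.to_csv(os.path.join(outdir, "trace.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
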