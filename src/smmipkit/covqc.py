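"""Coverage QC over condensed reads and probe-pool rebalancing.

Coverage figures are computed on condensed reads only: PCR duplicates have
zero base qualities and therefore contribute no depth, so every captured
molecule counts once. Pool rebalancing converts observed per-probe
condensed depths into pipetting factors that push underperforming probes
up and overperforming probes down, which is how targeted panels are tuned
toward uniform coverage after pilot runs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from smmipkit import _intervals
from smmipkit.dedup import ZERO_QUAL_CHAR, CondensedReadSet, _insert_footprint
from smmipkit.probe_model import ProbeSet


@dataclass(frozen=True)
class CoverageConfig:
    """depth_threshold: minimum depth a base must reach to count as covered
    (20x is the conventional germline-calling floor); target_depth_per_probe:
    the per-probe molecule target the experiment was sized for (500)."""

    depth_threshold: int = 20
    target_depth_per_probe: int = 500

    def __post_init__(self) -> None:
        if self.depth_threshold < 1 or self.target_depth_per_probe < 1:
            raise ValueError("coverage thresholds must be >= 1")


@dataclass
class CoverageReport:
    median_depth: float
    fraction_at_threshold: float  # percentage in [0, 100]
    depth_threshold: int
    n_target_bases: int
    per_probe_depth: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "median_depth": self.median_depth,
            "fraction_at_threshold_pct": self.fraction_at_threshold,
            "depth_threshold": self.depth_threshold,
            "n_target_bases": self.n_target_bases,
            "per_probe_depth": dict(sorted(self.per_probe_depth.items())),
        }


@dataclass
class RebalancePlan:
    factors: Dict[str, float]
    clamp_lo: float
    clamp_hi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.factors.items()), columns=["probe_id", "factor"]
        )


def per_base_depth(
    condensed: CondensedReadSet,
    probes: ProbeSet,
    intervals: Sequence[_intervals.Interval] | None = None,
) -> Dict[str, np.ndarray]:
    """Condensed per-base depth over the target intervals.

    Only bases with non-zero quality contribute (duplicates are silent).
    Returns one depth array per interval keyed "chrom:start-end"; when
    ``intervals`` is omitted the probe set's merged target BED is used.
    """
    if intervals is None:
        from smmipkit.probe_model import probes_to_target_bed

        intervals = probes_to_target_bed(probes)
    intervals = _intervals.merge(intervals)
    arrays = {
        f"{c}:{s}-{e}": np.zeros(e - s, dtype=np.int64) for c, s, e in intervals
    }
    index = [(c, s, e, arrays[f"{c}:{s}-{e}"]) for c, s, e in intervals]
    for read in condensed.reads:
        probe = probes[read.probe_id]
        for pos, _base, q in _insert_footprint(read, probes):
            if q == ZERO_QUAL_CHAR:
                continue
            for chrom, start, end, arr in index:
                if chrom == probe.chrom and start <= pos < end:
                    arr[pos - start] += 1
                    break
    return arrays


def coverage_summary(
    depths: Iterable[int] | Mapping[str, np.ndarray],
    config: CoverageConfig | None = None,
    per_probe_depth: Mapping[str, int] | None = None,
) -> CoverageReport:
    """Median target depth and the percentage of target bases at threshold.

    ``depths`` is the per-base condensed depth over the target regions,
    either flat or keyed per interval (as from :func:`per_base_depth`).
    The median of an even count is the mean of the two middle values.
    """
    if config is None:
        config = CoverageConfig()
    if isinstance(depths, Mapping):
        flat = np.concatenate([np.asarray(v) for v in depths.values()]) if depths else np.array([])
    else:
        flat = np.asarray(list(depths) if not isinstance(depths, np.ndarray) else depths)
    if flat.size == 0:
        raise ValueError("empty target: no per-base depths supplied")
    if (flat < 0).any():
        raise ValueError("negative depth")
    fraction = 100.0 * float((flat >= config.depth_threshold).sum()) / flat.size
    return CoverageReport(
        median_depth=float(np.median(flat)),
        fraction_at_threshold=fraction,
        depth_threshold=config.depth_threshold,
        n_target_bases=int(flat.size),
        per_probe_depth=dict(per_probe_depth or {}),
    )


def rebalance_pool(
    depths: Mapping[str, float],
    clamp_lo: float = 0.2,
    clamp_hi: float = 5.0,
) -> RebalancePlan:
    """Per-probe concentration factors from observed condensed depths.

    Each probe's raw factor is median(depths) / depth — probes below the
    median get more material, probes above get less; a zero-depth probe
    gets the upper clamp. Factors are clamped to [clamp_lo, clamp_hi] and
    normalized to mean 1 so the total pool amount is conserved (the clamp
    and normalization are iterated to a fixed point satisfying both).
    """
    if not depths:
        raise ValueError("no probes")
    if not clamp_lo < clamp_hi:
        raise ValueError("clamp_lo must be < clamp_hi")
    ids = sorted(depths)
    d = np.array([float(depths[i]) for i in ids])
    if (d < 0).any():
        raise ValueError("negative depth")
    if np.all(d == 0):
        raise ValueError("no signal: all probe depths are zero")
    med = float(np.median(d))
    with np.errstate(divide="ignore"):
        raw = np.where(d > 0, med / np.where(d > 0, d, 1.0), clamp_hi)
    f = raw
    for _ in range(100):
        f = np.clip(f, clamp_lo, clamp_hi)
        mean = f.mean()
        if abs(mean - 1.0) < 1e-12:
            break
        f = f / mean
    f = np.clip(f, clamp_lo, clamp_hi)
    return RebalancePlan(
        factors={pid: float(x) for pid, x in zip(ids, f)},
        clamp_lo=clamp_lo,
        clamp_hi=clamp_hi,
    )


def coefficient_of_variation(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or arr.mean() == 0:
        raise ValueError("CV undefined for empty or zero-mean input")
    return float(arr.std(ddof=0) / arr.mean())


def write_coverage_report(report: CoverageReport, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def write_rebalance_plan(plan: RebalancePlan, path: str | os.PathLike) -> None:
    plan.to_frame().to_csv(path, sep="\t", index=False)


def load_depth_table(path: str | os.PathLike) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["probe_id"], df["condensed_depth"]))
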