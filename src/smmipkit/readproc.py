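"""UMI extraction and probe assignment for smMIP read pairs.

Each read pair is first stripped of its UMI (by declared contract, the
first bases of read 2), then matched to its source probe by comparing the
start of read 1 against every probe's extension arm under a Hamming
mismatch budget. The remaining read-1 bases are the gap-fill insert used
for coverage and calling. No genome alignment is performed: the matched
probe's target coordinates position the insert.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from smmipkit.mipsim import ReadPair
from smmipkit.probe_model import ProbeSet

#: Sentinel probe id for pairs that could not be attributed to any probe.
UNASSIGNED = "UNASSIGNED"

#: Reject-bin reasons.
REASON_SHORT_READ = "short_read"
REASON_AMBIGUOUS_UMI = "ambiguous_umi"


class ReadRejected(Exception):
    """A pair failed UMI extraction; ``reason`` names the reject bin."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ReadStructure:
    """Where the UMI sits in the pair (default: first 8 bases of read 2)."""

    umi_read: str = "read2"
    umi_offset: int = 0
    umi_length: int = 8

    def __post_init__(self) -> None:
        if self.umi_read not in ("read1", "read2"):
            raise ValueError("umi_read must be 'read1' or 'read2'")
        if self.umi_offset < 0 or self.umi_length < 1:
            raise ValueError("umi_offset must be >= 0 and umi_length >= 1")


@dataclass(frozen=True)
class AssignedPair:
    """A pair with its UMI removed, attributed to a probe (or UNASSIGNED)."""

    read_id: str
    probe_id: str
    umi: str
    arm_mismatches: int
    insert_seq: str
    insert_qual: str


def extract_umi(pair: ReadPair, structure: ReadStructure) -> Tuple[str, ReadPair]:
    """Cut the UMI out of the designated read; qualities removed in lockstep.

    Raises :class:`ReadRejected` with reason ``short_read`` when the read
    cannot contain a full UMI and ``ambiguous_umi`` when the UMI contains
    any non-ACGT base.
    """
    if structure.umi_read == "read2":
        seq, qual = pair.r2_seq, pair.r2_qual
    else:
        seq, qual = pair.r1_seq, pair.r1_qual
    end = structure.umi_offset + structure.umi_length
    if len(seq) < end:
        raise ReadRejected(REASON_SHORT_READ)
    umi = seq[structure.umi_offset : end]
    if not set(umi) <= {"A", "C", "G", "T"}:
        raise ReadRejected(REASON_AMBIGUOUS_UMI)
    rest_seq = seq[: structure.umi_offset] + seq[end:]
    rest_qual = qual[: structure.umi_offset] + qual[end:]
    if structure.umi_read == "read2":
        remainder = ReadPair(pair.read_id, pair.r1_seq, pair.r1_qual, rest_seq, rest_qual)
    else:
        remainder = ReadPair(pair.read_id, rest_seq, rest_qual, pair.r2_seq, pair.r2_qual)
    return umi, remainder


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_arm(
    observed: str, probes: ProbeSet, max_mismatch: int = 1
) -> Tuple[str, int]:
    """Attribute a read to the probe whose extension arm best matches its start.

    The observed sequence's prefix is compared against each probe's
    extension arm by Hamming distance (no indels). The unique probe at
    minimal distance <= ``max_mismatch`` wins; a tie at the minimum, or no
    probe within budget, yields ``(UNASSIGNED, -1)``.
    """
    if not observed:
        raise ValueError("observed sequence must be non-empty")
    best_id, best_d, tie = UNASSIGNED, max_mismatch + 1, False
    for probe in probes:
        arm = probe.ext_arm_seq
        if len(observed) < len(arm):
            continue
        d = _hamming(observed[: len(arm)], arm)
        if d < best_d:
            best_id, best_d, tie = probe.probe_id, d, False
        elif d == best_d:
            tie = True
    if tie or best_d > max_mismatch:
        return UNASSIGNED, -1
    return best_id, best_d


@dataclass
class AssignmentSummary:
    assigned: int = 0
    unassigned: int = 0
    short_read: int = 0
    ambiguous_umi: int = 0
    per_probe: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.assigned + self.unassigned + self.short_read + self.ambiguous_umi

    def to_dict(self) -> dict:
        return {
            "assigned": self.assigned,
            "unassigned": self.unassigned,
            "short_read": self.short_read,
            "ambiguous_umi": self.ambiguous_umi,
            "total": self.total,
            "per_probe": dict(sorted(self.per_probe.items())),
        }


def assign_pairs(
    pairs: Iterable[ReadPair],
    probes: ProbeSet,
    structure: ReadStructure | None = None,
    max_mismatch: int = 1,
) -> Tuple[List[AssignedPair], AssignmentSummary]:
    """Run UMI extraction and arm matching over a stream of read pairs.

    Every input pair lands in exactly one bin: assigned (with its probe),
    unassigned (arm match failed), or rejected (``short_read`` /
    ``ambiguous_umi``); counts are conserved in the summary. The insert
    carried by each :class:`AssignedPair` is read 1 with the matched
    probe's extension arm trimmed off.
    """
    if structure is None:
        structure = ReadStructure()
    out: List[AssignedPair] = []
    summary = AssignmentSummary()
    for pair in pairs:
        try:
            umi, remainder = extract_umi(pair, structure)
        except ReadRejected as rej:
            if rej.reason == REASON_SHORT_READ:
                summary.short_read += 1
            else:
                summary.ambiguous_umi += 1
            continue
        probe_id, mismatches = match_arm(remainder.r1_seq, probes, max_mismatch)
        if probe_id == UNASSIGNED:
            summary.unassigned += 1
            out.append(
                AssignedPair(pair.read_id, UNASSIGNED, umi, -1, remainder.r1_seq, remainder.r1_qual)
            )
            continue
        arm_len = len(probes[probe_id].ext_arm_seq)
        out.append(
            AssignedPair(
                read_id=pair.read_id,
                probe_id=probe_id,
                umi=umi,
                arm_mismatches=mismatches,
                insert_seq=remainder.r1_seq[arm_len:],
                insert_qual=remainder.r1_qual[arm_len:],
            )
        )
        summary.assigned += 1
        summary.per_probe[probe_id] = summary.per_probe.get(probe_id, 0) + 1
    return out, summary


ASSIGNED_COLUMNS = ["read_id", "probe_id", "umi", "mismatches", "insert_seq", "insert_qual"]


def write_assigned(
    assigned: Iterable[AssignedPair],
    path: str | os.PathLike,
    summary: AssignmentSummary | None = None,
    summary_path: str | os.PathLike | None = None,
) -> None:
    df = pd.DataFrame(
        [
            (a.read_id, a.probe_id, a.umi, a.arm_mismatches, a.insert_seq, a.insert_qual)
            for a in assigned
        ],
        columns=ASSIGNED_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
    if summary is not None and summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary.to_dict(), fh, indent=1)


def read_assigned(path: str | os.PathLike) -> List[AssignedPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        AssignedPair(
            read_id=row.read_id,
            probe_id=row.probe_id,
            umi=row.umi,
            arm_mismatches=int(row.mismatches),
            insert_seq=row.insert_seq,
            insert_qual=row.insert_qual,
        )
        for row in df.itertuples(index=False)
    ]
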