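"""smMIP probe-set model: parsing, validation and target-region derivation.

A single-molecule molecular inversion probe (smMIP) carries two
target-complementary arms -- the extension arm and the ligation arm --
flanking a gap that is filled with a copy of the genomic target, plus a
random unique molecular identifier (UMI) that tags each captured molecule.
This module parses MIPGen-style design tables into :class:`ProbeSet`
objects and derives the merged target regions as BED intervals.

Coordinates are 0-based half-open throughout; arm sequences are stored as
written on the probe oligo (reverse-complementing for read matching is the
caller's concern).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence

from smmipkit import _intervals

DNA_ALPHABET = frozenset("ACGT")

REQUIRED_COLUMNS = (
    "probe_id",
    "chrom",
    "ext_probe_sequence",
    "lig_probe_sequence",
    "target_start",
    "target_end",
    "strand",
)


class ProbeFormatError(ValueError):
    """Design-table file does not conform to the expected dialect."""


class ProbeValidationError(ValueError):
    """Design-table contents violate a probe-set invariant."""


def _check_dna(seq: str, what: str, row: int | None = None) -> None:
    if not seq or not DNA_ALPHABET.issuperset(seq):
        where = f" (row {row})" if row is not None else ""
        raise ProbeValidationError(
            f"{what} must be a non-empty DNA string over A/C/G/T{where}: {seq!r}"
        )


@dataclass(frozen=True)
class ProbeDefinition:
    """One smMIP: arms, gap-fill target interval, strand and UMI length.

    ``target_start``/``target_end`` delimit the gap-fill (captured) region,
    0-based half-open. ``strand`` is '+' when the probe copies the sense
    strand and '-' for the antisense strand.
    """

    probe_id: str
    chrom: str
    ext_arm_seq: str
    lig_arm_seq: str
    target_start: int
    target_end: int
    strand: str
    umi_length: int = 8

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ProbeValidationError("probe_id must be non-empty")
        _check_dna(self.ext_arm_seq, f"extension arm of {self.probe_id}")
        _check_dna(self.lig_arm_seq, f"ligation arm of {self.probe_id}")
        if self.target_end <= self.target_start:
            raise ProbeValidationError(
                f"{self.probe_id}: target_end ({self.target_end}) must exceed "
                f"target_start ({self.target_start})"
            )
        if self.target_start < 0:
            raise ProbeValidationError(f"{self.probe_id}: negative target_start")
        if self.strand not in ("+", "-"):
            raise ProbeValidationError(
                f"{self.probe_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.umi_length < 1:
            raise ProbeValidationError(f"{self.probe_id}: umi_length must be >= 1")

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class ProbeSet:
    """An ordered collection of probes with unique ids."""

    probes: Sequence[ProbeDefinition]
    design_name: str = "design"
    _by_id: Dict[str, ProbeDefinition] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.probes:
            raise ProbeValidationError("a ProbeSet needs at least one probe")
        self.probes = list(self.probes)
        self._by_id = {}
        for probe in self.probes:
            if probe.probe_id in self._by_id:
                raise ProbeValidationError(f"duplicate probe_id {probe.probe_id!r}")
            self._by_id[probe.probe_id] = probe

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[ProbeDefinition]:
        return iter(self.probes)

    def __getitem__(self, probe_id: str) -> ProbeDefinition:
        return self._by_id[probe_id]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    @property
    def probe_ids(self) -> List[str]:
        return [p.probe_id for p in self.probes]


def umi_capacity(umi_length: int) -> int:
    """Number of distinct UMI sequences of the given length (4**length).

    An 8-base UMI distinguishes 4**8 = 65,536 molecules per probe.
    """
    if umi_length < 0:
        raise ValueError(f"umi_length must be >= 0, got {umi_length}")
    return 4**umi_length


def load_probe_design(
    path: str | os.PathLike, design_name: str | None = None, umi_length: int = 8
) -> ProbeSet:
    """Parse a MIPGen-style tab-separated probe design table.

    Required columns: probe_id, chrom, ext_probe_sequence,
    lig_probe_sequence, target_start, target_end, strand. Extra columns are
    ignored; row order is preserved. Coordinates in the file are 0-based
    half-open.
    """
    path = os.fspath(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ProbeFormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        probes: List[ProbeDefinition] = []
        seen_rows: Dict[str, int] = {}
        for rownum, row in enumerate(reader, start=2):  # row 1 is the header
            probe_id = row["probe_id"].strip()
            if probe_id in seen_rows:
                raise ProbeValidationError(
                    f"{path}: duplicate probe_id {probe_id!r} on rows "
                    f"{seen_rows[probe_id]} and {rownum}"
                )
            seen_rows[probe_id] = rownum
            ext = row["ext_probe_sequence"].strip().upper()
            lig = row["lig_probe_sequence"].strip().upper()
            for arm, label in ((ext, "ext_probe_sequence"), (lig, "lig_probe_sequence")):
                if not arm or not DNA_ALPHABET.issuperset(arm):
                    raise ProbeValidationError(
                        f"{path}: row {rownum}: {label} contains non-DNA "
                        f"characters: {arm!r}"
                    )
            try:
                start = int(row["target_start"])
                end = int(row["target_end"])
            except ValueError as exc:
                raise ProbeFormatError(f"{path}: row {rownum}: {exc}") from exc
            probes.append(
                ProbeDefinition(
                    probe_id=probe_id,
                    chrom=row["chrom"].strip(),
                    ext_arm_seq=ext,
                    lig_arm_seq=lig,
                    target_start=start,
                    target_end=end,
                    strand=row["strand"].strip(),
                    umi_length=umi_length,
                )
            )
    if design_name is None:
        design_name = os.path.splitext(os.path.basename(path))[0]
    return ProbeSet(probes=probes, design_name=design_name)


def write_probe_design(probe_set: ProbeSet, path: str | os.PathLike) -> None:
    """Write a ProbeSet back to the tab-separated design dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for p in probe_set:
            writer.writerow(
                [
                    p.probe_id,
                    p.chrom,
                    p.ext_arm_seq,
                    p.lig_arm_seq,
                    p.target_start,
                    p.target_end,
                    p.strand,
                ]
            )


def probes_to_target_bed(probe_set: ProbeSet) -> List[_intervals.Interval]:
    """Merged, sorted union of all gap-fill target intervals.

    Strand is ignored: sense and antisense probes over the same region
    contribute one interval. Output is 0-based half-open, BED-ready.
    """
    return _intervals.merge(
        (p.chrom, p.target_start, p.target_end) for p in probe_set
    )


write_bed = _intervals.write_bed
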