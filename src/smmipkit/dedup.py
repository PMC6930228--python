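"""UMI duplicate grouping, quality-zero condensing, and a naive genotyper.

Reads sharing a (probe, UMI) key descend from one captured molecule; they
are grouped into :class:`MoleculeGroup` partitions, and all but one
representative per group have every base quality set to zero. The
condensed read set keeps every read (counts are conserved) but only
representatives carry signal, so coverage and allele counting see each
molecule exactly once. A deliberately simple threshold genotyper closes
the loop for end-to-end tests on simulated data; it is not a production
variant caller.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from smmipkit.mipsim import revcomp
from smmipkit.probe_model import ProbeSet
from smmipkit.readproc import UNASSIGNED, AssignedPair

#: Phred+33 character for quality zero.
ZERO_QUAL_CHAR = "!"


class ContractViolation(ValueError):
    """Input breaks a precondition of the dedup stage."""


@dataclass
class MoleculeGroup:
    """All reads sharing one (probe_id, UMI) key — one captured molecule."""

    probe_id: str
    umi: str
    members: List[AssignedPair]
    representative_index: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ContractViolation("empty molecule group")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def representative(self) -> AssignedPair:
        return self.members[self.representative_index]


@dataclass
class CondensedReadSet:
    """Every input read, with non-representative qualities zeroed."""

    reads: List[AssignedPair]
    depth_per_probe: Dict[str, int]

    @property
    def raw_depth_per_probe(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for r in self.reads:
            counts[r.probe_id] = counts.get(r.probe_id, 0) + 1
        return counts


def _qual_sum(qual: str) -> int:
    return sum(ord(c) - 33 for c in qual)


def group_molecules(assigned: Iterable[AssignedPair]) -> List[MoleculeGroup]:
    """Partition assigned pairs by exact (probe_id, UMI) key.

    The same UMI on two different probes is two molecules. Groups are
    returned sorted by (probe_id, umi); members keep input order. Any
    UNASSIGNED pair in the input is a contract violation — route reads
    through :func:`smmipkit.readproc.assign_pairs` first.
    """
    buckets: Dict[Tuple[str, str], List[AssignedPair]] = {}
    for pair in assigned:
        if pair.probe_id == UNASSIGNED:
            raise ContractViolation(
                f"read {pair.read_id} is UNASSIGNED; grouping requires assigned pairs"
            )
        buckets.setdefault((pair.probe_id, pair.umi), []).append(pair)
    return [
        MoleculeGroup(probe_id=key[0], umi=key[1], members=members)
        for key, members in sorted(buckets.items())
    ]


def _pick_representative(group: MoleculeGroup) -> int:
    # highest summed base quality wins; ties broken by smallest read id
    best = min(
        range(len(group.members)),
        key=lambda i: (-_qual_sum(group.members[i].insert_qual), group.members[i].read_id),
    )
    return best


def condense(groups: Sequence[MoleculeGroup]) -> CondensedReadSet:
    """Silence PCR duplicates by zeroing their base qualities.

    Per group one representative (highest summed base quality, ties to the
    lexicographically smallest read id) keeps its qualities; every other
    member's qualities become all-zero (Phred+33 '!'). Sequence bases are
    never touched, so duplicate evidence remains inspectable while
    coverage and allele counting ignore it. Idempotent: condensing a
    condensed set changes nothing.
    """
    reads: List[AssignedPair] = []
    depth: Dict[str, int] = {}
    for group in groups:
        rep = _pick_representative(group)
        group.representative_index = rep
        depth[group.probe_id] = depth.get(group.probe_id, 0) + 1
        for i, member in enumerate(group.members):
            if i == rep:
                reads.append(member)
            else:
                reads.append(
                    replace(member, insert_qual=ZERO_QUAL_CHAR * len(member.insert_qual))
                )
    return CondensedReadSet(reads=reads, depth_per_probe=depth)


# ---------------------------------------------------------------------------
# Naive pileup genotyper
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_fraction", "genotype"]


def _insert_footprint(read: AssignedPair, probes: ProbeSet):
    """Yield (reference position, base, qual_char) for each insert base.

    For '+' probes the insert runs left to right from target_start. For
    '-' probes the insert is the reverse complement of the gap-fill, so
    base i of the insert reports reference position target_end - 1 - i,
    complemented back to the sense strand.
    """
    probe = probes[read.probe_id]
    if probe.strand == "+":
        for i, (base, q) in enumerate(zip(read.insert_seq, read.insert_qual)):
            pos = probe.target_start + i
            if pos < probe.target_end:
                yield pos, base, q
    else:
        for i, (base, q) in enumerate(zip(read.insert_seq, read.insert_qual)):
            pos = probe.target_end - 1 - i
            if pos >= probe.target_start:
                yield pos, revcomp(base), q


def call_variants_naive(
    condensed: CondensedReadSet,
    probes: ProbeSet,
    reference: str,
    min_depth: int = 8,
    het_band: Tuple[float, float] = (0.2, 0.8),
    hom_lo: float = 0.8,
) -> pd.DataFrame:
    """Threshold genotyper over the condensed pileup.

    Counts alleles per reference position using only bases with non-zero
    quality (duplicates therefore never vote). A site is emitted when its
    condensed depth is at least ``min_depth`` and the most frequent
    non-reference allele's fraction falls in the het band (genotype
    ``het``) or at/above ``hom_lo`` (genotype ``hom``). Positions are
    1-based in the output table.
    """
    counts: Dict[Tuple[str, int], Dict[str, int]] = {}
    chroms: Dict[int, str] = {}
    for read in condensed.reads:
        probe = probes[read.probe_id]
        if probe.target_end > len(reference):
            raise ContractViolation(
                f"probe {probe.probe_id} target extends past the reference"
            )
        for pos, base, q in _insert_footprint(read, probes):
            if q == ZERO_QUAL_CHAR:
                continue
            key = (probe.chrom, pos)
            counts.setdefault(key, {})
            counts[key][base] = counts[key].get(base, 0) + 1
    rows = []
    for (chrom, pos), alleles in sorted(counts.items()):
        depth = sum(alleles.values())
        if depth < min_depth:
            continue
        ref_base = reference[pos]
        alts = {b: n for b, n in alleles.items() if b != ref_base}
        if not alts:
            continue
        alt, alt_n = max(alts.items(), key=lambda kv: (kv[1], kv[0]))
        frac = alt_n / depth
        if frac >= hom_lo:
            genotype = "hom"
        elif het_band[0] <= frac <= het_band[1]:
            genotype = "het"
        else:
            continue
        rows.append((chrom, pos + 1, ref_base, alt, depth, frac, genotype))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

def write_condensed(condensed: CondensedReadSet, path: str | os.PathLike) -> None:
    from smmipkit.readproc import write_assigned

    write_assigned(condensed.reads, path)


def write_depth_table(condensed: CondensedReadSet, path: str | os.PathLike) -> None:
    pd.DataFrame(
        sorted(condensed.depth_per_probe.items()), columns=["probe_id", "condensed_depth"]
    ).to_csv(path, sep="\t", index=False)
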