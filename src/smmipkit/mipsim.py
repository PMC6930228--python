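"""Synthetic smMIP capture simulator with molecular ground truth.

Emulates the data-generating process of an smMIP experiment well enough to
exercise every downstream stage: per-probe molecule capture, per-molecule
8-base UMIs, PCR duplication, substitution sequencing errors, and variant
spike-ins at a chosen allele fraction. Every run also emits a
:class:`SimTruth` record (molecule counts, UMI assignments, duplicate
groups, carrier molecules) so tests can compare pipeline output against
known truth instead of against another tool.

Read layout contract (shared with :mod:`smmipkit.readproc`):

* read 1 = extension arm + gap-fill insert, truncated to ``read_length``;
* read 2 = UMI + ligation arm + reverse-complement of the insert,
  truncated to ``read_length``;
* for '-' strand probes the insert is the reverse complement of the
  reference gap-fill region.

Base qualities are a constant Q30 before duplicate marking, which makes
downstream quality-zeroing directly observable.
"""

from __future__ import annotations

import gzip
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from smmipkit.probe_model import ProbeDefinition, ProbeSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Phred+33 character for Q30, the constant pre-dedup base quality.
Q30_CHAR = "?"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationError(ValueError):
    """Configuration inconsistent with the reference or probe set."""


@dataclass(frozen=True)
class SpikedVariant:
    """A substitution planted into carrier molecules at a given allele fraction."""

    chrom: str
    pos: int  # 0-based reference position
    ref: str
    alt: str
    allele_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.allele_fraction <= 1):
            raise SimulationError(
                f"allele fraction must be in (0, 1], got {self.allele_fraction}"
            )
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise SimulationError(f"only SNVs supported: {self.ref}>{self.alt}")


@dataclass
class SimulationConfig:
    """Knobs of one simulated capture.

    Defaults mirror a typical production panel run: 500 captured molecules
    per probe (the sequencing target per smMIP per sample), 2x125 bp
    paired-end reads, 8-base UMIs, a mean of 3 PCR copies per captured
    molecule, and a Q30-consistent error rate of 1e-3 per base.
    """

    seed: int = 0
    n_molecules_per_probe: int | Mapping[str, int] = 500
    pcr_duplication_mean: float = 3.0
    seq_error_rate: float = 1e-3
    umi_length: int = 8
    read_length: int = 125
    spiked_variants: Sequence[SpikedVariant] = ()
    capture_efficiency: float | Mapping[str, float] = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.seq_error_rate < 0.5):
            raise SimulationError("seq_error_rate must be in [0, 0.5)")
        if self.pcr_duplication_mean < 1:
            raise SimulationError("pcr_duplication_mean must be >= 1")
        if self.umi_length < 1 or self.read_length < 1:
            raise SimulationError("umi_length and read_length must be >= 1")

    def molecules_for(self, probe_id: str) -> int:
        if isinstance(self.n_molecules_per_probe, Mapping):
            return int(self.n_molecules_per_probe[probe_id])
        return int(self.n_molecules_per_probe)

    def efficiency_for(self, probe_id: str) -> float:
        if isinstance(self.capture_efficiency, Mapping):
            eff = float(self.capture_efficiency[probe_id])
        else:
            eff = float(self.capture_efficiency)
        if not (0 <= eff <= 1):
            raise SimulationError(
                f"capture efficiency for {probe_id} must be in [0, 1], got {eff}"
            )
        return eff


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str


@dataclass(frozen=True)
class MoleculeTruth:
    molecule_id: int
    probe_id: str
    umi: str
    n_copies: int
    variants: Tuple[SpikedVariant, ...] = ()


@dataclass
class SimTruth:
    """Ground truth of one simulated capture."""

    molecules: List[MoleculeTruth] = field(default_factory=list)
    read_to_molecule: Dict[str, int] = field(default_factory=dict)

    @property
    def per_probe_molecule_count(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for mol in self.molecules:
            counts[mol.probe_id] = counts.get(mol.probe_id, 0) + 1
        return counts

    def has_umi_collision(self) -> bool:
        """True if two distinct molecules of the same probe drew the same UMI."""
        seen = set()
        for mol in self.molecules:
            key = (mol.probe_id, mol.umi)
            if key in seen:
                return True
            seen.add(key)
        return False

    def carrier_molecules(self, variant: SpikedVariant) -> List[MoleculeTruth]:
        return [m for m in self.molecules if variant in m.variants]


def build_reference(length: int, seed: int) -> str:
    """Deterministic pseudo-random reference sequence over A/C/G/T."""
    if length < 1:
        raise ValueError(f"reference length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def write_fasta(sequence: str, path: str | os.PathLike, name: str = "ref") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(sequence), id=name, description="")], os.fspath(path), "fasta")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq
    # substitute with one of the three *other* bases, uniformly
    idx = {b: i for i, b in enumerate(_BASES)}
    offsets = rng.integers(1, 4, size=n_hit)
    positions = np.nonzero(hit)[0]
    for p, off in zip(positions, offsets):
        arr[p] = _BASES[(idx[arr[p]] + off) % 4]
    return arr.tobytes().decode("ascii")


def simulate_capture(
    reference: str, probes: ProbeSet, config: SimulationConfig
) -> Tuple[List[ReadPair], SimTruth]:
    """Simulate one sample's smMIP capture and sequencing.

    For each probe: draw the captured-molecule count (binomial thinning of
    the configured molecule number by the probe's capture efficiency), tag
    each molecule with a uniform random UMI, plant spiked variants into
    carrier molecules *before* PCR so every duplicate of a carrier shares
    the variant, copy each molecule ``1 + Poisson(mean - 1)`` times, then
    apply per-base substitution errors independently to every read.
    """
    rng = np.random.default_rng(config.seed)
    for probe in probes:
        if probe.target_start < 0 or probe.target_end > len(reference):
            raise SimulationError(
                f"probe {probe.probe_id} target "
                f"[{probe.target_start}, {probe.target_end}) lies outside the "
                f"reference (length {len(reference)})"
            )
    for var in config.spiked_variants:
        covered = any(
            p.chrom == var.chrom and p.target_start <= var.pos < p.target_end
            for p in probes
        )
        if not covered:
            warnings.warn(
                f"spiked variant {var.chrom}:{var.pos + 1} {var.ref}>{var.alt} "
                "overlaps no probe target and will be unobservable",
                stacklevel=2,
            )

    reads: List[ReadPair] = []
    truth = SimTruth()
    mol_id = 0
    read_counter = 0
    for probe in probes:
        n_conf = config.molecules_for(probe.probe_id)
        eff = config.efficiency_for(probe.probe_id)
        n_mol = int(rng.binomial(n_conf, eff)) if eff < 1 else n_conf
        overlapping = [
            v
            for v in config.spiked_variants
            if v.chrom == probe.chrom and probe.target_start <= v.pos < probe.target_end
        ]
        for v in overlapping:
            ref_base = reference[v.pos]
            if ref_base != v.ref:
                raise SimulationError(
                    f"spiked variant at {v.chrom}:{v.pos + 1} expects reference "
                    f"base {v.ref} but the reference has {ref_base}"
                )
        gap_ref = reference[probe.target_start : probe.target_end]
        for _ in range(n_mol):
            umi = _random_dna(rng, config.umi_length)
            gap = gap_ref
            carried: List[SpikedVariant] = []
            for v in overlapping:
                if rng.random() < v.allele_fraction:
                    off = v.pos - probe.target_start
                    gap = gap[:off] + v.alt + gap[off + 1 :]
                    carried.append(v)
            insert = revcomp(gap) if probe.strand == "-" else gap
            n_copies = 1 + int(rng.poisson(config.pcr_duplication_mean - 1))
            truth.molecules.append(
                MoleculeTruth(
                    molecule_id=mol_id,
                    probe_id=probe.probe_id,
                    umi=umi,
                    n_copies=n_copies,
                    variants=tuple(carried),
                )
            )
            r1_template = (probe.ext_arm_seq + insert)[: config.read_length]
            r2_template = (umi + probe.lig_arm_seq + revcomp(insert))[: config.read_length]
            for _ in range(n_copies):
                r1 = _apply_errors(r1_template, config.seq_error_rate, rng)
                r2 = _apply_errors(r2_template, config.seq_error_rate, rng)
                read_id = f"sim_{read_counter:08d}"
                read_counter += 1
                reads.append(
                    ReadPair(
                        read_id=read_id,
                        r1_seq=r1,
                        r1_qual=Q30_CHAR * len(r1),
                        r2_seq=r2,
                        r2_qual=Q30_CHAR * len(r2),
                    )
                )
                truth.read_to_molecule[read_id] = mol_id
            mol_id += 1
    return reads, truth


def write_fastq_pairs(
    reads: Sequence[ReadPair], r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> None:
    """Write paired reads as (optionally gzipped, by extension) FASTQ."""

    def _open(path):
        path = os.fspath(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for rp in reads:
            fh1.write(f"@{rp.read_id}/1\n{rp.r1_seq}\n+\n{rp.r1_qual}\n")
            fh2.write(f"@{rp.read_id}/2\n{rp.r2_seq}\n+\n{rp.r2_qual}\n")


def read_fastq_pairs(
    r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> List[ReadPair]:
    """Load paired FASTQ back into ReadPair records (ids must correspond)."""
    from Bio import SeqIO

    def _open(path):
        path = os.fspath(path)
        return gzip.open(path, "rt") if path.endswith(".gz") else open(path)

    out: List[ReadPair] = []
    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        for rec1, rec2 in zip(
            SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq"), strict=True
        ):
            rid = rec1.id.rsplit("/", 1)[0]
            out.append(
                ReadPair(
                    read_id=rid,
                    r1_seq=str(rec1.seq),
                    r1_qual="".join(
                        chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
                    ),
                    r2_seq=str(rec2.seq),
                    r2_qual="".join(
                        chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
                    ),
                )
            )
    return out


def write_truth(truth: SimTruth, path: str | os.PathLike) -> None:
    rows = [
        {
            "molecule_id": m.molecule_id,
            "probe_id": m.probe_id,
            "umi": m.umi,
            "n_copies": m.n_copies,
            "variants": ";".join(
                f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in m.variants
            ),
        }
        for m in truth.molecules
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Toy panel design
# ---------------------------------------------------------------------------

def design_toy_panel(
    reference: str,
    n_probes: int,
    arm_length: int = 20,
    target_length: int = 100,
    chrom: str = "chr11",
    both_strands: bool = True,
    design_name: str = "toy_panel",
) -> ProbeSet:
    """Tile a reference with a deterministic toy probe panel.

    Arms are taken from the reference flanks of each target so that arm
    matching against simulated reads is realistic: a '+' probe's extension
    arm is the sequence immediately upstream of the target, a '-' probe's
    is the reverse complement of the downstream flank. With
    ``both_strands`` probes alternate strand, mirroring panels that tile
    sense and antisense to guard against single-strand DNA damage
    artifacts.
    """
    footprint = target_length + 2 * arm_length
    span = len(reference) - footprint
    if span < 0:
        raise SimulationError("reference shorter than one probe footprint")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    step = max(1, span // max(1, n_probes - 1)) if n_probes > 1 else 0
    probes: List[ProbeDefinition] = []
    for i in range(n_probes):
        start = arm_length + min(i * step, span)
        end = start + target_length
        strand = "-" if (both_strands and i % 2 == 1) else "+"
        upstream = reference[start - arm_length : start]
        downstream = reference[end : end + arm_length]
        if strand == "+":
            ext, lig = upstream, downstream
        else:
            ext, lig = revcomp(downstream), revcomp(upstream)
        probes.append(
            ProbeDefinition(
                probe_id=f"mip_{i + 1:04d}",
                chrom=chrom,
                ext_arm_seq=ext,
                lig_arm_seq=lig,
                target_start=start,
                target_end=end,
                strand=strand,
            )
        )
    return ProbeSet(probes=probes, design_name=design_name)


# ---------------------------------------------------------------------------
# Cohort-level synthesis (annotated variant tables for filter + burden tests)
# ---------------------------------------------------------------------------

VARIANT_TABLE_COLUMNS = [
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
    "chrom",
    "pos",
]


def _make_variant_pool(
    rng: np.random.Generator,
    pool_size: int,
    regions: Sequence[Tuple[str, int, int]],
) -> List[dict]:
    """Synthesize a pool of rare qualifying variants for cohort tables.

    Variants are rare missense VUS (population AF < 1%, in-house count
    < 50) with CADD drawn uniformly over [10, 35), positioned uniformly
    within the given covered regions.
    """
    pool = []
    for i in range(pool_size):
        chrom, start, end = regions[int(rng.integers(len(regions)))]
        pos = int(rng.integers(start, end))
        pool.append(
            {
                "cdna_change": f"c.{1000 + 7 * i}A>G",
                "protein_change": f"p.(Xaa{300 + i}Yaa)",
                "consequence": "missense",
                "intron_distance": 0,
                "af_1000g": float(rng.uniform(0, 0.005)),
                "af_exac": float(rng.uniform(0, 0.005)),
                "inhouse_count": int(rng.integers(0, 20)),
                "cadd": float(rng.uniform(10, 35)),
                "classification": "VUS",
                "chrom": chrom,
                "pos": pos,
            }
        )
    return pool


def _make_background_variant(rng: np.random.Generator, i: int) -> dict:
    """A common or synonymous variant that the filter cascade must remove."""
    if rng.random() < 0.5:
        return {
            "cdna_change": f"c.{5000 + 3 * i}G>A",
            "protein_change": f"p.(Zaa{900 + i}=)",
            "consequence": "synonymous",
            "intron_distance": 0,
            "af_1000g": float(rng.uniform(0, 0.2)),
            "af_exac": float(rng.uniform(0, 0.2)),
            "inhouse_count": int(rng.integers(0, 200)),
            "cadd": float(rng.uniform(0, 10)),
            "classification": "benign",
            "chrom": "chr11",
            "pos": int(rng.integers(0, 10_000)),
        }
    return {
        "cdna_change": f"c.{7000 + 3 * i}C>T",
        "protein_change": f"p.(Waa{700 + i}Vaa)",
        "consequence": "missense",
        "intron_distance": 0,
        "af_1000g": float(rng.uniform(0.02, 0.4)),  # too common to qualify
        "af_exac": float(rng.uniform(0.02, 0.4)),
        "inhouse_count": int(rng.integers(50, 500)),
        "cadd": float(rng.uniform(0, 25)),
        "classification": "likely_benign",
        "chrom": "chr11",
        "pos": int(rng.integers(0, 10_000)),
    }


def simulate_cohort_tables(
    n_cases: int = 373,
    n_controls: int = 404,
    case_carrier_freq: float = 0.059,
    control_carrier_freq: float = 0.05,
    seed: int = 0,
    pool_size: int = 24,
    background_rate: float = 0.0,
    regions: Sequence[Tuple[str, int, int]] | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate annotated-variant tables for a synthetic case/control study.

    Each patient independently carries one qualifying variant (drawn
    uniformly from a rare-VUS pool) with the cohort's carrier frequency;
    ``background_rate`` optionally adds per-patient non-qualifying rows
    that downstream filtering must remove. Default cohort sizes match a
    373-case dystonia cohort screened against 404 reference-population
    controls; the default case carrier frequency is the observed 22/373.

    Returns (case table, control table, truth) where truth records the
    carrier patients of each cohort.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("cohort sizes must be >= 1")
    rng = np.random.default_rng(seed)
    if regions is None:
        regions = [("chr11", 0, 10_000)]
    pool = _make_variant_pool(rng, pool_size, regions)

    truth = {"case_carriers": [], "control_carriers": []}
    frames = {}
    for label, n, freq, truth_key in (
        ("case", n_cases, case_carrier_freq, "case_carriers"),
        ("control", n_controls, control_carrier_freq, "control_carriers"),
    ):
        rows = []
        bg_counter = 0
        for i in range(n):
            patient = f"{label}_{i + 1:04d}"
            if rng.random() < freq:
                var = pool[int(rng.integers(len(pool)))]
                rows.append({"patient_id": patient, **var})
                truth[truth_key].append(patient)
            if background_rate and rng.random() < background_rate:
                rows.append(
                    {"patient_id": patient, **_make_background_variant(rng, bg_counter)}
                )
                bg_counter += 1
        frames[label] = pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)
    return frames["case"], frames["control"], truth


def write_cohort(
    outdir: str | os.PathLike,
    n_cases: int = 373,
    n_controls: int = 404,
    case_carrier_freq: float = 0.059,
    control_carrier_freq: float = 0.05,
    seed: int = 0,
    pool_size: int = 24,
    background_rate: float = 0.0,
    regions: Sequence[Tuple[str, int, int]] | None = None,
    probes: ProbeSet | None = None,
    reference: str | None = None,
    fastq_samples: int = 0,
) -> dict:
    """Write a synthetic case/control cohort to disk.

    Always writes ``cases.tsv``, ``controls.tsv`` and ``truth.json``; when
    ``fastq_samples`` > 0 (and a probe set plus reference are supplied)
    additionally writes paired FASTQ for that many case samples so that the
    read-level pipeline can be exercised on cohort members.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    cases, controls, truth = simulate_cohort_tables(
        n_cases=n_cases,
        n_controls=n_controls,
        case_carrier_freq=case_carrier_freq,
        control_carrier_freq=control_carrier_freq,
        seed=seed,
        pool_size=pool_size,
        background_rate=background_rate,
        regions=regions,
    )
    cases.to_csv(os.path.join(outdir, "cases.tsv"), sep="\t", index=False)
    controls.to_csv(os.path.join(outdir, "controls.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    if fastq_samples > 0:
        if probes is None or reference is None:
            raise ValueError("fastq_samples > 0 requires probes and reference")
        for i in range(fastq_samples):
            cfg = SimulationConfig(seed=seed + 1 + i)
            reads, sample_truth = simulate_capture(reference, probes, cfg)
            stem = os.path.join(outdir, f"case_{i + 1:04d}")
            write_fastq_pairs(reads, stem + "_R1.fastq.gz", stem + "_R2.fastq.gz")
            write_truth(sample_truth, stem + "_truth.tsv")
    return truth
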