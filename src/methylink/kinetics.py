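"""IPD-ratio computation and m6A/m4C modification calling.

Single-molecule sequencing kinetics slow down when the polymerase crosses a
methylated template base: the interpulse duration (IPD) at that position is
elevated relative to an unmethylated control. The ratio of case to control
IPD at the same position/strand is the detection signal. A position is
called modified when its base is callable (A -> m6A, C -> m4C), its
per-strand coverage exceeds the minimum, and the IPD ratio reaches the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import GenomeSequence

#: base -> modification type produced when that base is methylated
MOD_TYPE = {"A": "m6A", "C": "m4C"}


class UndefinedRatioError(ValueError):
    """Control IPD of zero makes the ratio undefined."""


@dataclass(frozen=True)
class KineticsRecord:
    position: int
    strand: str
    base: str
    coverage: int
    ipd_case: float
    ipd_control: float


@dataclass(frozen=True)
class ModificationCall:
    position: int
    strand: str
    base: str
    mod_type: str
    ipd_ratio: float
    coverage: int


@dataclass(frozen=True)
class CallParameters:
    """Thresholds for modification calling.

    ``min_coverage_per_strand`` is exclusive (coverage must be strictly
    greater), matching a "minimum >25x per strand" sequencing design.
    The IPD-ratio cutoff is a configurable heuristic (default 2.0) and is
    echoed in all output metadata.
    """

    min_coverage_per_strand: int = 25
    min_ipd_ratio: float = 2.0
    bases_considered: tuple[str, ...] = ("A", "C")

    def __post_init__(self) -> None:
        if self.min_coverage_per_strand < 1:
            raise ValueError("min_coverage_per_strand must be >= 1")
        if self.min_ipd_ratio <= 1:
            raise ValueError("min_ipd_ratio must be > 1")


@dataclass(frozen=True)
class MethylomeSummary:
    """Genome-wide methylation census against the both-strand A/C denominators."""

    n_calls: int
    n_m6A: int
    n_m4C: int
    n_sites_collapsed: int  # unique positions, paired-strand sites counted once
    pct_m6A: float  # of both-strand adenines
    pct_m4C: float  # of both-strand cytosines
    pct_AC: float  # of both-strand A+C
    per_strand: dict  # mod_type -> {"+": count, "-": count, "pct_+": .., "pct_-": ..}


def ipd_ratio(record: KineticsRecord) -> float:
    """Case IPD divided by control IPD at the same position/strand."""
    if record.ipd_control <= 0:
        raise UndefinedRatioError(
            f"control IPD is {record.ipd_control} at position {record.position} "
            f"strand {record.strand}"
        )
    return record.ipd_case / record.ipd_control


def call_modifications(
    records: Iterable[KineticsRecord], params: CallParameters | None = None
) -> list[ModificationCall]:
    """Threshold kinetics records into modification calls, sorted by (position, strand)."""
    params = params or CallParameters()
    calls = []
    for rec in records:
        if rec.base not in params.bases_considered:
            continue
        if rec.coverage <= params.min_coverage_per_strand:
            continue
        ratio = ipd_ratio(rec)
        if ratio >= params.min_ipd_ratio:
            calls.append(
                ModificationCall(
                    position=rec.position,
                    strand=rec.strand,
                    base=rec.base,
                    mod_type=MOD_TYPE[rec.base],
                    ipd_ratio=ratio,
                    coverage=rec.coverage,
                )
            )
    calls.sort(key=lambda c: (c.position, c.strand))
    return calls


def summarize_calls(
    calls: Sequence[ModificationCall], genome: GenomeSequence
) -> MethylomeSummary:
    """Counts and percentages of methylated A/C sites over both-strand denominators.

    Percentages use the duplex (both-strand) base counts: a forward T is an
    adenine site on the reverse strand. The total is reported both
    strand-specifically (``n_calls``) and collapsed over paired strands
    (``n_sites_collapsed``; unique genome positions).
    """
    from .genome_io import base_composition

    for c in calls:
        genome_base = genome.base_at(c.position)
        expected = c.base if c.strand == "+" else {"A": "T", "C": "G"}[c.base]
        if genome_base != expected:
            raise ValueError(
                f"call at {c.position}{c.strand} claims base {c.base} but genome "
                f"forward base is {genome_base}"
            )

    comp = base_composition(genome)
    n_a = sum(1 for c in calls if c.mod_type == "m6A")
    n_c = sum(1 for c in calls if c.mod_type == "m4C")
    per_strand: dict = {}
    fwd = comp["forward"]
    # strand-specific denominators: adenines on the minus strand are forward Ts
    strand_denoms = {
        "m6A": {"+": fwd["A"], "-": fwd["T"]},
        "m4C": {"+": fwd["C"], "-": fwd["G"]},
    }
    for mod in ("m6A", "m4C"):
        plus = sum(1 for c in calls if c.mod_type == mod and c.strand == "+")
        minus = sum(1 for c in calls if c.mod_type == mod and c.strand == "-")
        dp, dm = strand_denoms[mod]["+"], strand_denoms[mod]["-"]
        per_strand[mod] = {
            "+": plus,
            "-": minus,
            "pct_+": 100 * plus / dp if dp else 0.0,
            "pct_-": 100 * minus / dm if dm else 0.0,
        }
    denom_ac = comp["both_strand_AC"]
    return MethylomeSummary(
        n_calls=len(calls),
        n_m6A=n_a,
        n_m4C=n_c,
        n_sites_collapsed=len({c.position for c in calls}),
        pct_m6A=100 * n_a / comp["both_strand_A"] if comp["both_strand_A"] else 0.0,
        pct_m4C=100 * n_c / comp["both_strand_C"] if comp["both_strand_C"] else 0.0,
        pct_AC=100 * len(calls) / denom_ac if denom_ac else 0.0,
        per_strand=per_strand,
    )


# ---------------------------------------------------------------------------
# I/O

KINETICS_COLUMNS = ["position", "strand", "base", "coverage", "ipd_case", "ipd_control"]


def read_kinetics_tsv(path: str | Path) -> list[KineticsRecord]:
    df = pd.read_csv(str(path), sep="\t")
    missing = set(KINETICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: kinetics TSV missing columns {sorted(missing)}")
    return [
        KineticsRecord(
            position=int(r.position),
            strand=str(r.strand),
            base=str(r.base),
            coverage=int(r.coverage),
            ipd_case=float(r.ipd_case),
            ipd_control=float(r.ipd_control),
        )
        for r in df.itertuples(index=False)
    ]


def write_kinetics_tsv(records: Iterable[KineticsRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "position": r.position,
                "strand": r.strand,
                "base": r.base,
                "coverage": r.coverage,
                "ipd_case": round(r.ipd_case, 6),
                "ipd_control": round(r.ipd_control, 6),
            }
            for r in records
        ],
        columns=KINETICS_COLUMNS,
    ).to_csv(str(path), sep="\t", index=False)


def write_calls_gff3(
    calls: Iterable[ModificationCall],
    genome: GenomeSequence,
    params: CallParameters,
    path: str | Path,
) -> None:
    """GFF3 export mirroring the PacBio modifications.gff dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##methylink min_coverage_per_strand={params.min_coverage_per_strand} "
            f"min_ipd_ratio={params.min_ipd_ratio}\n"
        )
        for c in calls:
            fh.write(
                f"{genome.id}\tmethylink\tmodified_DNA_base\t{c.position + 1}\t"
                f"{c.position + 1}\t.\t{c.strand}\t.\t"
                f"mod_type={c.mod_type};ipd_ratio={c.ipd_ratio:.4f};coverage={c.coverage}\n"
            )


def write_calls_bed(
    calls: Iterable[ModificationCall], genome: GenomeSequence, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{genome.id}\t{c.position}\t{c.position + 1}\t{c.mod_type}\t0\t{c.strand}\n"
            )
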