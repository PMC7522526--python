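"""Nearest-neighbor duplex stability and melting-temperature profiling.

Duplex formation free energy is modeled as the sum of dinucleotide-stack
contributions plus duplex-initiation terms that depend on the terminal
base pairs (the unified Watson-Crick parameter set for 1 M NaCl). The
genome-scale profiler averages stack free energies over tiling windows
(default 100 kb), which tracks local GC content and hence duplex
stability along the chromosome.

``duplex_dG37`` reports stacks + initiation only; the self-complementarity
symmetry correction enters ``melting_temperature`` (via the entropy term
and the CT/x rule) so that dG37 remains strictly reverse-complement
invariant, a property the windowed profile relies on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .genome_io import GenomeSequence

R_GAS = 1.987  # cal/(mol*K)

_COMP = str.maketrans("ACGT", "TGCA")


class MaskedWindowError(ValueError):
    """Sequence too N-rich to score."""


@dataclass(frozen=True)
class NNParameterSet:
    dG37: dict  # 16 stacks -> kcal/mol
    dH: dict  # kcal/mol
    dS: dict  # cal/(mol*K)
    init_dG37: dict  # terminal base-pair class ("AT"/"GC") -> kcal/mol
    init_dH: dict
    init_dS: dict
    sym_dG37: float
    sym_dH: float
    sym_dS: float
    salt_conc: float
    version: str

    def __post_init__(self) -> None:
        stacks = {a + b for a in "ACGT" for b in "ACGT"}
        if set(self.dG37) != stacks:
            raise ValueError("parameter set must define all 16 stacks")
        for s in stacks:
            rc = s.translate(_COMP)[::-1]
            if not math.isclose(self.dG37[s], self.dG37[rc], abs_tol=1e-9):
                raise ValueError(f"stack table not complement-symmetric at {s}/{rc}")


def load_parameters(path: str | Path | None = None) -> NNParameterSet:
    """Load a parameter JSON; default is the packaged unified 1 M NaCl table."""
    if path is None:
        raw = json.loads(
            resources.files("methylink.data")
            .joinpath("nn_unified_1M_NaCl.json")
            .read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    stacks = raw["stacks"]
    init = raw["initiation"]
    sym = raw["symmetry_correction"]
    return NNParameterSet(
        dG37={k: v["dG37"] for k, v in stacks.items()},
        dH={k: v["dH"] for k, v in stacks.items()},
        dS={k: v["dS"] for k, v in stacks.items()},
        init_dG37={k: v["dG37"] for k, v in init.items()},
        init_dH={k: v["dH"] for k, v in init.items()},
        init_dS={k: v["dS"] for k, v in init.items()},
        sym_dG37=sym["dG37"],
        sym_dH=sym["dH"],
        sym_dS=sym["dS"],
        salt_conc=raw["salt_conc_molar"],
        version=raw["version"],
    )


def _terminal_class(base: str) -> str:
    return "AT" if base in "AT" else "GC"


def _check_seq(seq: str, max_n_fraction: float) -> str:
    if len(seq) < 2:
        raise ValueError("need at least 2 bases")
    n_frac = seq.count("N") / len(seq)
    if n_frac > max_n_fraction:
        raise MaskedWindowError(f"N fraction {n_frac:.3f} exceeds {max_n_fraction}")
    return seq


def is_self_complementary(seq: str) -> bool:
    return seq == seq.translate(_COMP)[::-1]


def duplex_dG37(
    seq: str, params: NNParameterSet, max_n_fraction: float = 0.0
) -> float:
    """Stack-sum free energy of the duplex at 37 C (kcal/mol), plus initiation."""
    seq = _check_seq(seq.upper(), max_n_fraction)
    if "N" in seq:
        raise MaskedWindowError("N bases present; use window_profile for masking")
    total = params.init_dG37[_terminal_class(seq[0])]
    total += params.init_dG37[_terminal_class(seq[-1])]
    for i in range(len(seq) - 1):
        total += params.dG37[seq[i : i + 2]]
    return total


def melting_temperature(
    seq: str,
    params: NNParameterSet,
    strand_conc: float = 1e-4,
) -> float:
    """Two-state melting temperature in degrees Celsius.

    Tm = dH / (dS + R ln(CT/x)) - 273.15 with x = 4 for non-self-complementary
    duplexes and x = 1 (plus the symmetry entropy correction) for
    self-complementary ones. ``strand_conc`` is total strand molarity CT.
    """
    seq = _check_seq(seq.upper(), 0.0)
    if "N" in seq:
        raise MaskedWindowError("cannot compute Tm over N bases")
    dh = params.init_dH[_terminal_class(seq[0])] + params.init_dH[_terminal_class(seq[-1])]
    ds = params.init_dS[_terminal_class(seq[0])] + params.init_dS[_terminal_class(seq[-1])]
    for i in range(len(seq) - 1):
        dh += params.dH[seq[i : i + 2]]
        ds += params.dS[seq[i : i + 2]]
    if is_self_complementary(seq):
        dh += params.sym_dH
        ds += params.sym_dS
        x = 1.0
    else:
        x = 4.0
    denom = ds + R_GAS * math.log(strand_conc / x)
    if denom == 0:
        raise ZeroDivisionError("entropy plus concentration term is zero; Tm undefined")
    return dh * 1000.0 / denom - 273.15


@dataclass(frozen=True)
class MeltingProfile:
    window_start: int
    window_size: int
    mean_dG37: float  # kcal/mol per stack, NaN when masked
    masked: bool


def window_profile(
    genome: GenomeSequence,
    params: NNParameterSet,
    window: int = 100_000,
    step: int | None = None,
    max_n_fraction: float = 0.1,
) -> list[MeltingProfile]:
    """Per-window mean stack dG37 across the genome.

    Non-overlapping tiles by default (``step = window``); a smaller step
    gives a sliding profile. On circular genomes the final window wraps
    through the origin so that windows tile the full length. Windows whose
    N fraction exceeds ``max_n_fraction`` are flagged masked (NaN mean);
    N-containing stacks are always excluded from the mean.
    """
    if window > genome.length:
        raise ValueError("window larger than genome")
    if window < 2:
        raise ValueError("window must cover at least one stack")
    step = step or window
    extended = genome.seq + (genome.seq[:window] if genome.circular else "")
    profiles = []
    for start in range(0, genome.length, step):
        chunk = extended[start : start + window]
        if len(chunk) < 2:
            continue
        n_frac = chunk.count("N") / len(chunk)
        if n_frac > max_n_fraction:
            profiles.append(MeltingProfile(start, len(chunk), math.nan, True))
            continue
        total, n_stacks = 0.0, 0
        for i in range(len(chunk) - 1):
            stack = chunk[i : i + 2]
            if "N" in stack:
                continue
            total += params.dG37[stack]
            n_stacks += 1
        mean = total / n_stacks if n_stacks else math.nan
        profiles.append(MeltingProfile(start, len(chunk), mean, n_stacks == 0))
    return profiles


def write_bedgraph(
    profiles: Sequence[MeltingProfile],
    genome: GenomeSequence,
    path: str | Path,
    negate: bool = False,
) -> None:
    """bedGraph export; ``negate=True`` emits -dG37 ("melting energy") for plotting."""
    sign = -1.0 if negate else 1.0
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="mean_dG37{"_negated" if negate else ""}"\n')
        for p in profiles:
            if p.masked:
                continue
            end = min(p.window_start + p.window_size, genome.length)
            fh.write(f"{genome.id}\t{p.window_start}\t{end}\t{sign * p.mean_dG37:.5f}\n")


def write_circos_track(
    profiles: Sequence[MeltingProfile],
    genome: GenomeSequence,
    path: str | Path,
    negate: bool = True,
) -> None:
    sign = -1.0 if negate else 1.0
    with open(path, "w") as fh:
        for p in profiles:
            if p.masked:
                continue
            end = min(p.window_start + p.window_size, genome.length)
            fh.write(f"{genome.id}\t{p.window_start}\t{end}\t{sign * p.mean_dG37:.5f}\n")
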