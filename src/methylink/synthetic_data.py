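"""Seeded generators for every input the pipeline consumes, with planted truth.

The default scenario emulates the structure of a small-bacterium
multi-omics study: a circular GC~0.45 chromosome densely tiled with
genes, a planted bipartite 16-nt recognition motif whose central adenine
is methylated in most instances, per-condition methylation with
configurable gene/intergenic split and gene-level co-occurrence with
differential expression, triplicate log-scale expression, a proteome with
intensity-dependent dropout, and codon-pair evolution at configurable
omega for the selection screen. Every generator is driven by one integer
seed (NumPy PCG64) and returns machine-readable planted truth so recovery
tests never consult the generator's internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneAnnotation,
    GenomeSequence,
    IUPACMotif,
    IUPAC_CODES,
    MotifHit,
    reverse_complement_iupac,
)
from .kaks import BASES, CodonAlignment, _code
from .kinetics import KineticsRecord

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of the synthetic study; defaults are the desk-scale conditions."""

    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.45
    n_genes: int = 200
    gene_length_mean: float = 900.0
    gene_length_sd: float = 200.0
    motif_pattern: str = "CTAYNNNNNNNNTRTC"
    motif_offset: int = 2
    n_motifs: int = 20
    conditions: tuple[str, ...] = ("T26", "T4", "UV")
    control_condition: str = "T26"
    #: P(motif instance methylated) per condition
    motif_methylation_rate: Mapping[str, float] = field(
        default_factory=lambda: {"T26": 0.97, "T4": 0.97, "UV": 0.92}
    )
    #: fraction of genes carrying background methylation per condition (exact count)
    p_gene_methylated: Mapping[str, float] = field(
        default_factory=lambda: {"T26": 0.25, "T4": 0.21, "UV": 0.16}
    )
    sites_per_methylated_gene: int = 2
    p_site_in_body: float = 0.8  # vs the 500-bp upstream window
    #: target fraction of background calls in gene body or upstream window
    in_gene_fraction: float = 0.52
    upstream_len: int = 500
    # expression
    n_replicates: int = 3
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    p_down_given_methylated: float = 0.78
    p_up_given_methylated: float = 0.22
    p_de_unmethylated: float = 0.02
    de_effect_log2fc_mean: float = 2.0
    de_effect_log2fc_sd: float = 0.5
    noise_sd: float = 0.25
    # proteome
    proteome_attenuation: float = 1.0
    proteome_noise_sd: float = 0.25
    proteome_missing_rate: float = 0.1
    proteome_missing_slope: float = 1.0
    # kinetics
    ipd_control_mu: float = 0.0
    ipd_control_sigma: float = 0.25
    ipd_multiplier: float = 4.0
    ipd_noise_sigma: float = 0.2
    coverage_mean: float = 60.0
    n_background_kinetics_sites: int = 20_000
    # ortholog simulation
    omega_list: tuple[float, ...] = (0.2, 0.5, 1.0)
    branch_length: float = 0.3  # expected mutation proposals per codon

    def __post_init__(self) -> None:
        for p in [self.gc_content, self.p_site_in_body, self.in_gene_fraction,
                  self.proteome_missing_rate, self.p_de_unmethylated]:
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_down_given_methylated + self.p_up_given_methylated > 1 + 1e-9:
            raise ValueError("P(down|meth) + P(up|meth) must be <= 1")
        if self.genome_length < 10 * self.gene_length_mean:
            raise ValueError("genome too short for the requested gene sizes")
        if self.control_condition not in self.conditions:
            raise ValueError("control condition missing from conditions")

    @property
    def motif(self) -> IUPACMotif:
        return IUPACMotif(self.motif_pattern, self.motif_offset)


# ---------------------------------------------------------------------------
# scenario (de)serialization: flat key=value config


def scenario_to_config(scenario: SyntheticScenario) -> str:
    lines = []
    for key, value in asdict(scenario).items():
        if isinstance(value, Mapping):
            for sub, v in value.items():
                lines.append(f"{key}.{sub}={v}")
        elif isinstance(value, (tuple, list)):
            lines.append(f"{key}={','.join(str(v) for v in value)}")
        else:
            lines.append(f"{key}={value}")
    return "\n".join(lines) + "\n"


def scenario_from_config(text: str) -> SyntheticScenario:
    defaults = SyntheticScenario()
    kwargs: dict = {}
    maps: dict[str, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if "." in key:
            base_key, sub = key.split(".", 1)
            maps.setdefault(base_key, {})[sub] = float(raw)
            continue
        default = getattr(defaults, key)  # KeyError -> unknown key, let it raise
        if isinstance(default, bool):
            kwargs[key] = raw.lower() in {"1", "true", "yes"}
        elif isinstance(default, int):
            kwargs[key] = int(raw)
        elif isinstance(default, float):
            kwargs[key] = float(raw)
        elif isinstance(default, tuple):
            elem = default[0] if default else ""
            conv = float if isinstance(elem, float) else str
            kwargs[key] = tuple(conv(v) for v in raw.split(",") if v != "")
        else:
            kwargs[key] = raw
    kwargs.update(maps)
    return SyntheticScenario(**kwargs)


# ---------------------------------------------------------------------------
# genome + annotation + motifs


def _concretize_motif(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else rng.choice(list(IUPAC_CODES[c])) for c in pattern
    )


def generate_genome(
    scenario: SyntheticScenario,
) -> tuple[GenomeSequence, list[GeneAnnotation], list[MotifHit]]:
    """Background i.i.d. genome with planted motifs and sequentially packed genes.

    Genes are laid head-to-tail with exponential intergenic gaps (bacterial
    coding density); motif instances are written over the background at
    uniform positions on random strands. Returns the planted motif hits as
    ground truth (the scanner may additionally find chance matches).
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.genome_length
    gc = scenario.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.array(list("ACGT")), size=L, p=p)

    # plant motifs at non-overlapping positions on random strands
    motif = scenario.motif
    m = motif.length
    planted: list[MotifHit] = []
    occupied: set[int] = set()
    attempts = 0
    while len(planted) < scenario.n_motifs and attempts < scenario.n_motifs * 200:
        attempts += 1
        start = int(rng.integers(0, L))
        span = {(start + k) % L for k in range(m)}
        if span & occupied:
            continue
        occupied |= span
        strand = "+" if rng.random() < 0.5 else "-"
        concrete = _concretize_motif(motif.pattern, rng)
        window = concrete if strand == "+" else concrete.translate(_COMP)[::-1]
        for k, base in enumerate(window):
            seq[(start + k) % L] = base
        meth_pos = (
            (start + motif.methylated_offset) % L
            if strand == "+"
            else (start + m - 1 - motif.methylated_offset) % L
        )
        planted.append(
            MotifHit(start=start, strand=strand, methylated_position=meth_pos,
                     methylated_strand=strand, pattern=motif.pattern)
        )
    if len(planted) < scenario.n_motifs:
        raise RuntimeError("could not pack the requested number of motifs")

    genome = GenomeSequence(id=f"synthetic_{scenario.seed}", seq="".join(seq))

    # sequential gene packing with exponential gaps
    lengths = np.maximum(
        150,
        rng.normal(scenario.gene_length_mean, scenario.gene_length_sd, scenario.n_genes),
    ).astype(int)
    total = int(lengths.sum())
    if total >= L:
        raise ValueError("gene lengths exceed genome length: infeasible packing")
    # exponential gaps rescaled to tile the genome exactly
    raw_gaps = rng.exponential(1.0, scenario.n_genes + 1)
    gaps = (raw_gaps / raw_gaps.sum() * (L - total)).astype(int)
    genes = []
    cursor = int(gaps[0])
    for i, length in enumerate(lengths):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                locus_tag=f"SYN_{i:04d}", start=cursor, end=cursor + int(length),
                strand=strand, product=f"synthetic protein {i}",
            )
        )
        cursor += int(length) + int(gaps[i + 1])
    assert genes[-1].end <= L
    return genome, genes, planted


# ---------------------------------------------------------------------------
# methylation truth


def generate_methylation_truth(
    scenario: SyntheticScenario,
    genome: GenomeSequence,
    genes: Sequence[GeneAnnotation],
    motif_hits: Sequence[MotifHit],
) -> dict:
    """Per-condition planted methylated sites (position, strand, base) with origins.

    For each condition an exact-count subset of genes carries background
    methylation (sites in the body or upstream window), intergenic sites
    are added to meet the target in-gene fraction, and each motif instance
    is methylated with the per-condition rate at its marked adenine.
    ``motif_hits`` should normally be the scanner's output on the final
    genome (planted instances plus chance matches), mirroring a
    methyltransferase that recognizes every occurrence of its site.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    L = genome.length
    up = scenario.upstream_len

    # boolean masks for genic and genic+upstream space
    body_mask = np.zeros(L, dtype=bool)
    region_mask = np.zeros(L, dtype=bool)
    for g in genes:
        idx = np.arange(g.start, g.end) % L
        body_mask[idx] = True
        region_mask[idx] = True
        if g.strand == "+":
            uidx = np.arange(g.start - up, g.start) % L
        else:
            uidx = np.arange(g.end, g.end + up) % L
        region_mask[uidx] = True
    intergenic_positions = np.flatnonzero(~region_mask)

    seq_arr = np.frombuffer(genome.seq.encode(), dtype="S1").astype("U1")

    def random_ac_site(positions: np.ndarray) -> tuple[int, str, str]:
        """A uniformly chosen methylatable (A or C on either strand) site."""
        while True:
            pos = int(rng.choice(positions))
            fwd = seq_arr[pos]
            options = []
            if fwd in ("A", "C"):
                options.append((pos, "+", fwd))
            if fwd in ("T", "G"):
                options.append((pos, "-", {"T": "A", "G": "C"}[fwd]))
            if options:
                return options[int(rng.integers(len(options)))]

    truth: dict = {}
    for cond in scenario.conditions:
        sites: list[dict] = []
        used: set[tuple[int, str]] = set()

        def add(pos: int, strand: str, base: str, origin: str, gene: str | None) -> None:
            if (pos, strand) in used:
                return
            used.add((pos, strand))
            sites.append(
                dict(position=pos, strand=strand, base=base, origin=origin, gene=gene)
            )

        # exact-count methylated gene subset
        n_meth = int(round(scenario.p_gene_methylated[cond] * len(genes)))
        meth_idx = rng.choice(len(genes), size=n_meth, replace=False)
        meth_genes = [genes[i] for i in sorted(meth_idx)]
        for g in meth_genes:
            for _ in range(scenario.sites_per_methylated_gene):
                if rng.random() < scenario.p_site_in_body:
                    span = np.arange(g.start, g.end) % L
                else:
                    span = (
                        np.arange(g.start - up, g.start) % L
                        if g.strand == "+"
                        else np.arange(g.end, g.end + up) % L
                    )
                pos, strand, base = random_ac_site(span)
                add(pos, strand, base, "gene_background", g.locus_tag)

        # intergenic sites to meet the target in-gene fraction
        n_genic = len(sites)
        f = scenario.in_gene_fraction
        n_intergenic = int(round(n_genic * (1 - f) / f)) if f > 0 else 0
        for _ in range(n_intergenic):
            if len(intergenic_positions) == 0:
                break
            pos, strand, base = random_ac_site(intergenic_positions)
            add(pos, strand, base, "intergenic_background", None)

        # motif-anchored methylation
        methylated_motifs = []
        rate = scenario.motif_methylation_rate[cond]
        for k, hit in enumerate(motif_hits):
            if rng.random() < rate:
                add(hit.methylated_position, hit.methylated_strand, "A", "motif", None)
                methylated_motifs.append(k)

        truth[cond] = {
            "sites": sites,
            "methylated_genes": [g.locus_tag for g in meth_genes],
            "methylated_motif_indices": methylated_motifs,
            "n_genic_background": n_genic,
            "n_intergenic_background": n_intergenic,
        }
    return truth


# ---------------------------------------------------------------------------
# kinetics


def generate_kinetics(
    scenario: SyntheticScenario,
    genome: GenomeSequence,
    truth: Mapping[str, dict],
) -> dict[str, list[KineticsRecord]]:
    """Per-condition kinetics tables: all truth sites plus background A/C sites.

    Control IPDs are lognormal; case IPD = control x multiplier at
    methylated sites (x1 elsewhere) with multiplicative lognormal noise;
    coverage is Poisson around the scenario mean.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    L = genome.length
    seq_arr = np.frombuffer(genome.seq.encode(), dtype="S1").astype("U1")

    # shared background site panel across conditions (like resequencing the
    # same genome): positions where either strand offers an A or C
    n_bg = min(scenario.n_background_kinetics_sites, L)
    bg_positions = rng.choice(L, size=n_bg, replace=False)

    out: dict[str, list[KineticsRecord]] = {}
    for cond in scenario.conditions:
        meth = {(s["position"], s["strand"]) for s in truth[cond]["sites"]}
        rows: list[KineticsRecord] = []
        seen: set[tuple[int, str]] = set()

        def emit(pos: int, strand: str, base: str) -> None:
            key = (pos, strand)
            if key in seen:
                return
            seen.add(key)
            control = float(
                np.exp(rng.normal(scenario.ipd_control_mu, scenario.ipd_control_sigma))
            )
            mult = scenario.ipd_multiplier if key in meth else 1.0
            noise = (
                float(np.exp(rng.normal(0.0, scenario.ipd_noise_sigma)))
                if scenario.ipd_noise_sigma > 0
                else 1.0
            )
            rows.append(
                KineticsRecord(
                    position=pos,
                    strand=strand,
                    base=base,
                    coverage=int(rng.poisson(scenario.coverage_mean)),
                    ipd_case=control * mult * noise,
                    ipd_control=control,
                )
            )

        for s in truth[cond]["sites"]:
            emit(s["position"], s["strand"], s["base"])
        for pos in bg_positions:
            fwd = seq_arr[pos]
            if fwd in ("A", "C"):
                emit(int(pos), "+", str(fwd))
            else:
                emit(int(pos), "-", {"T": "A", "G": "C"}[str(fwd)])
        rows.sort(key=lambda r: (r.position, r.strand))
        out[cond] = rows
    return out


# ---------------------------------------------------------------------------
# expression + proteome


def generate_expression(
    scenario: SyntheticScenario,
    genes: Sequence[GeneAnnotation],
    truth: Mapping[str, dict],
) -> tuple[pd.DataFrame, dict]:
    """Transcript matrix (linear intensities) with planted DE truth.

    The control condition sets per-gene baselines; in each treatment,
    genes methylated there go down with P(down|methylated), up with
    P(up|methylated); unmethylated genes are DE with a small symmetric
    probability. Effects are log2 shifts drawn from the scenario's effect
    distribution; replicate noise is Gaussian in log2 space.
    """
    rng = np.random.default_rng(scenario.seed + 3)
    tags = [g.locus_tag for g in genes]
    control = scenario.control_condition
    baseline = rng.normal(
        scenario.baseline_log2_mean, scenario.baseline_log2_sd, len(tags)
    )

    de_truth: dict = {cond: {} for cond in scenario.conditions if cond != control}
    effect: dict[str, np.ndarray] = {control: np.zeros(len(tags))}
    for cond in scenario.conditions:
        if cond == control:
            continue
        meth_genes = set(truth[cond]["methylated_genes"])
        eff = np.zeros(len(tags))
        for i, tag in enumerate(tags):
            u = rng.random()
            if tag in meth_genes:
                if u < scenario.p_down_given_methylated:
                    direction = "down"
                elif u < scenario.p_down_given_methylated + scenario.p_up_given_methylated:
                    direction = "up"
                else:
                    direction = None
            else:
                if u < scenario.p_de_unmethylated / 2:
                    direction = "down"
                elif u < scenario.p_de_unmethylated:
                    direction = "up"
                else:
                    direction = None
            if direction is None:
                de_truth[cond][tag] = {"direction": None, "log2fc": 0.0}
                continue
            size = abs(
                rng.normal(scenario.de_effect_log2fc_mean, scenario.de_effect_log2fc_sd)
            )
            signed = size if direction == "up" else -size
            eff[i] = signed
            de_truth[cond][tag] = {"direction": direction, "log2fc": float(signed)}
        effect[cond] = eff

    columns = {}
    for cond in scenario.conditions:
        for rep in range(1, scenario.n_replicates + 1):
            noise = (
                rng.normal(0.0, scenario.noise_sd, len(tags))
                if scenario.noise_sd > 0
                else np.zeros(len(tags))
            )
            columns[f"{cond}_{rep}"] = 2.0 ** (baseline + effect[cond] + noise)
    matrix = pd.DataFrame(columns, index=pd.Index(tags, name="feature_id"))
    return matrix, de_truth


def generate_proteome(
    scenario: SyntheticScenario,
    transcript_matrix: pd.DataFrame,
    de_truth: Mapping[str, Mapping[str, dict]],
) -> tuple[pd.DataFrame, dict]:
    """Proteome intensities: attenuated transcript effects + noise + MNAR dropout.

    Dropout probability follows a logistic curve in log2 intensity around
    the matrix mean: lower-intensity measurements are more likely missing,
    with overall rate bounded by ``proteome_missing_rate``.
    """
    rng = np.random.default_rng(scenario.seed + 4)
    tags = list(transcript_matrix.index)
    control = scenario.control_condition
    base = np.log2(
        transcript_matrix[
            [c for c in transcript_matrix.columns if c.rsplit("_", 1)[0] == control]
        ]
    ).mean(axis=1).to_numpy()

    columns = {}
    for col in transcript_matrix.columns:
        cond = col.rsplit("_", 1)[0]
        eff = np.array(
            [
                scenario.proteome_attenuation
                * de_truth.get(cond, {}).get(t, {}).get("log2fc", 0.0)
                for t in tags
            ]
        )
        noise = (
            rng.normal(0.0, scenario.proteome_noise_sd, len(tags))
            if scenario.proteome_noise_sd > 0
            else np.zeros(len(tags))
        )
        columns[col] = 2.0 ** (base + eff + noise)
    matrix = pd.DataFrame(columns, index=pd.Index(tags, name="feature_id"))

    missing_truth: dict = {}
    if scenario.proteome_missing_rate > 0:
        logged = np.log2(matrix.to_numpy())
        center = logged.mean()
        p_miss = scenario.proteome_missing_rate * 2 / (
            1 + np.exp(scenario.proteome_missing_slope * (logged - center))
        )
        mask = rng.random(logged.shape) < p_miss
        values = matrix.to_numpy().astype(float)
        values[mask] = np.nan
        matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
        missing_truth = {
            "n_missing": int(mask.sum()),
            "fraction_missing": float(mask.mean()),
        }
    return matrix, missing_truth


# ---------------------------------------------------------------------------
# ortholog pairs


def generate_ortholog_pair(
    cds_length: int,
    omega: float,
    branch_length: float,
    seed: int,
    table_id: int = 1,
) -> tuple[CodonAlignment, dict]:
    """Evolve one sequence from a random sense-codon ancestor.

    Single-base proposals arrive at ``branch_length`` expected proposals
    per codon; synonymous proposals are always accepted, nonsynonymous ones
    with probability ``omega``, and proposals creating stop codons are
    rejected. Returns the pair plus realized substitution counts.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = np.random.default_rng(seed)
    aa_of, stops = _code(table_id)
    sense = sorted(set(aa_of) - stops)
    codons = [sense[i] for i in rng.integers(0, len(sense), cds_length)]
    ancestor = "".join(codons)

    n_proposals = int(rng.poisson(branch_length * cds_length))
    realized_syn = realized_non = 0
    for _ in range(n_proposals):
        ci = int(rng.integers(cds_length))
        pos = int(rng.integers(3))
        current = codons[ci]
        base = BASES[int(rng.integers(4))]
        if base == current[pos]:
            continue
        mutant = current[:pos] + base + current[pos + 1 :]
        if mutant in stops:
            continue
        if aa_of[mutant] == aa_of[current]:
            codons[ci] = mutant
            realized_syn += 1
        elif rng.random() < omega:
            codons[ci] = mutant
            realized_non += 1
    derived = "".join(codons)
    aln = CodonAlignment(
        id_pair=(f"ancestor_{seed}", f"derived_{seed}"), seqA=ancestor, seqB=derived
    )
    truth = {
        "omega": omega,
        "branch_length": branch_length,
        "n_proposals": n_proposals,
        "realized_synonymous": realized_syn,
        "realized_nonsynonymous": realized_non,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# truth serialization


def write_truth_json(truth: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
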