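"""Pairwise Ka/Ks estimation by counting, with pair filters and a selection screen.

The estimator is Nei-Gojobori-style counting: fractional synonymous and
nonsynonymous site counts per codon, pathway-averaged difference counting
for codons differing at more than one position, and a Jukes-Cantor
multiple-hit correction. Mutations that would create stop codons are
excluded from the site denominators (with renormalization, so each codon
contributes exactly 3 sites) and mutational pathways passing through stop
codons are dropped unless no stop-free path exists. Significance of
Ka != Ks is assessed with a two-tailed Fisher exact test on the rounded
2x2 site/difference table. A ratio below 1 indicates purifying selection,
about 1 neutrality, above 1 positive selection.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

BASES = "ACGT"


def _code(table_id: int = 1) -> tuple[dict, set]:
    """(codon -> amino acid, stop codon set) for an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), set(table.stop_codons)


@dataclass(frozen=True)
class CodonAlignment:
    """A frame-preserved pairwise coding alignment; gaps allowed, excluded codon-wise."""

    id_pair: tuple[str, str]
    seqA: str
    seqB: str

    def __post_init__(self) -> None:
        if len(self.seqA) != len(self.seqB):
            raise ValueError(f"{self.id_pair}: aligned lengths differ")
        if len(self.seqA) % 3:
            raise ValueError(f"{self.id_pair}: aligned length not a multiple of 3")

    def ungapped_codon_pairs(self, table_id: int = 1) -> list[tuple[str, str]]:
        """Codon pairs with any-gap and any-N codons removed; stop codons flagged."""
        _, stops = _code(table_id)
        pairs = []
        n_codons = len(self.seqA) // 3
        for i in range(n_codons):
            ca = self.seqA[3 * i : 3 * i + 3].upper()
            cb = self.seqB[3 * i : 3 * i + 3].upper()
            if set(ca + cb) - set(BASES):
                continue  # gap or ambiguous column, excluded pairwise
            if ca in stops or cb in stops:
                raise ValueError(
                    f"{self.id_pair}: in-frame stop codon at codon {i}"
                )
            pairs.append((ca, cb))
        return pairs


@dataclass(frozen=True)
class KaKsResult:
    id_pair: tuple[str, str]
    S: float  # synonymous sites (pair average)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    p_value: float | None
    n_codons: int
    filtered: bool = False
    filter_reason: str = ""
    flag: str = ""  # "", "saturated", "ks_zero", "identical"

    @property
    def total_substitutions(self) -> int:
        return round(self.Sd + self.Nd)


def count_sites(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    For each position, the fraction of single-base mutations that preserve
    the amino acid, with mutations to stop codons excluded from the
    denominator; the two fractions sum to 1 per position, so S + N = 3.
    """
    codon = codon.upper()
    if set(codon) - set(BASES) or len(codon) != 3:
        raise ValueError(f"invalid codon {codon!r}")
    aa_of, stops = _code(table_id)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site counts")
    s_total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in stops:
                continue
            nonstop += 1
            if aa_of[mutant] == aa_of[codon]:
                syn += 1
        s_total += syn / nonstop if nonstop else 0.0
    return s_total, 3.0 - s_total


def _pathway_differences(
    ca: str, cb: str, table_id: int = 1
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two codons.

    Equal weight over all minimal mutational orders that avoid stop-codon
    intermediates; if every order passes through a stop, weight over all
    orders instead.
    """
    aa_of, stops = _code(table_id)
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> tuple[float, float] | None:
        syn = non = 0
        current = ca
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in stops:
                return None
            if aa_of[nxt] == aa_of[current]:
                syn += 1
            else:
                non += 1
            current = nxt
        return float(syn), float(non)

    paths = [walk(order) for order in permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # all orders hit stops; fall back to unrestricted averaging
        def walk_any(order: Sequence[int]) -> tuple[float, float]:
            # steps into or out of a stop codon count as nonsynonymous
            syn = non = 0
            current = ca
            for pos in order:
                nxt = current[:pos] + cb[pos] + current[pos + 1 :]
                if (current not in stops and nxt not in stops
                        and aa_of[nxt] == aa_of[current]):
                    syn += 1
                else:
                    non += 1
                current = nxt
            return float(syn), float(non)

        valid = [walk_any(order) for order in permutations(diff_pos)]
    s = sum(p[0] for p in valid) / len(valid)
    n = sum(p[1] for p in valid) / len(valid)
    return s, n


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def kaks_pair(aln: CodonAlignment, table_id: int = 1) -> KaKsResult:
    """NG86-style Ka/Ks for one aligned coding-sequence pair."""
    pairs = aln.ungapped_codon_pairs(table_id)
    if not pairs:
        raise ValueError(f"{aln.id_pair}: no comparable codons")
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in pairs:
        sa, _ = count_sites(ca, table_id)
        sb, _ = count_sites(cb, table_id)
        s_sites += (sa + sb) / 2
        ds, dn = _pathway_differences(ca, cb, table_id)
        sd += ds
        nd += dn
    n_sites = 3.0 * len(pairs) - s_sites

    if sd + nd == 0:
        return KaKsResult(
            id_pair=aln.id_pair, S=s_sites, N=n_sites, Sd=0.0, Nd=0.0,
            Ka=0.0, Ks=0.0, ratio=None, p_value=None,
            n_codons=len(pairs), flag="identical",
        )

    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    flag = ""
    if ks is None or ka is None:
        flag = "saturated"
        ratio = None
    elif ks == 0:
        flag = "ks_zero"
        ratio = None
    else:
        ratio = ka / ks

    table = [
        [round(sd), round(nd)],
        [round(s_sites - sd), round(n_sites - nd)],
    ]
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return KaKsResult(
        id_pair=aln.id_pair, S=s_sites, N=n_sites, Sd=sd, Nd=nd,
        Ka=ka, Ks=ks, ratio=ratio, p_value=float(p_value),
        n_codons=len(pairs), flag=flag,
    )


def filter_pairs(
    results: Iterable[KaKsResult],
    min_substitutions: int = 3,
    max_p: float = 0.05,
    require_both: bool = False,
) -> tuple[list[KaKsResult], list[KaKsResult]]:
    """Apply the pair-exclusion filters; returns (retained, removed-with-reasons).

    Default removes a pair failing either criterion (too few substitutions,
    or a nonsignificant Ka != Ks test); ``require_both=True`` removes only
    pairs failing both.
    """
    retained, removed = [], []
    for r in results:
        reasons = []
        if r.total_substitutions < min_substitutions:
            reasons.append("too_few_substitutions")
        if r.p_value is None or r.p_value > max_p:
            reasons.append("nonsignificant")
        fails = (len(reasons) == 2) if require_both else bool(reasons)
        if fails:
            removed.append(
                KaKsResult(**{**r.__dict__, "filtered": True,
                              "filter_reason": ";".join(reasons)})
            )
        else:
            retained.append(r)
    return retained, removed


def selection_screen(
    gene_sets: Mapping[str, Sequence[KaKsResult]]
) -> pd.DataFrame:
    """Per-gene distribution summary of retained Ka/Ks ratios.

    Returns median and quartiles per gene plus a purifying flag
    (median < 1); genes with no usable ratios are flagged no_data.
    """
    rows = []
    for gene, results in gene_sets.items():
        ratios = [r.ratio for r in results if not r.filtered and r.ratio is not None]
        if not ratios:
            rows.append(
                dict(gene=gene, n_pairs=0, median=None, q1=None, q3=None,
                     flag="no_data")
            )
            continue
        qs = statistics.quantiles(ratios, n=4) if len(ratios) >= 2 else [ratios[0]] * 3
        median = statistics.median(ratios)
        rows.append(
            dict(
                gene=gene,
                n_pairs=len(ratios),
                median=median,
                q1=qs[0],
                q3=qs[2],
                flag="purifying" if median < 1 else "not_purifying",
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_pair_fasta(path: str | Path) -> CodonAlignment:
    """Read a two-record aligned FASTA as a codon alignment."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: need two aligned records")
    a, b = records[0], records[1]
    return CodonAlignment(
        id_pair=(a.id, b.id), seqA=str(a.seq).upper(), seqB=str(b.seq).upper()
    )


def write_pair_fasta(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.id_pair[0]}\n{aln.seqA}\n>{aln.id_pair[1]}\n{aln.seqB}\n")


def results_frame(results: Sequence[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seqA": r.id_pair[0],
                "seqB": r.id_pair[1],
                "n_codons": r.n_codons,
                "S": r.S,
                "N": r.N,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "Ka": r.Ka,
                "Ks": r.Ks,
                "ratio": r.ratio,
                "p_value": r.p_value,
                "filtered": r.filtered,
                "filter_reason": r.filter_reason,
                "flag": r.flag,
            }
            for r in results
        ]
    )


def write_results_tsv(results: Sequence[KaKsResult], path: str | Path) -> None:
    results_frame(results).to_csv(str(path), sep="\t", index=False)
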