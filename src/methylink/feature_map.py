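"""Assign methylation calls to gene bodies, upstream windows, or intergenic space.

A call is categorized ``gene_body`` when its position falls inside any
annotated gene span, ``upstream500`` when it falls in the fixed-length
window 5' of a gene's start (strand-aware: for minus-strand genes the
window sits at [end, end + upstream_len) in forward-frame coordinates),
and ``intergenic`` otherwise. Precedence is gene_body > upstream500;
``locus_tags`` retains every associated gene, including genes whose
upstream window a gene-body call also overlaps. The strand of the call
itself is ignored — methylation on either strand within a span counts for
that gene. Upstream windows are a flat fixed length and are not truncated
at neighboring genes. Circular genomes wrap.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome_io import GeneAnnotation, GenomeSequence, MotifHit
from .kinetics import ModificationCall

CATEGORIES = ("gene_body", "upstream500", "intergenic")


@dataclass(frozen=True)
class FeatureAssignment:
    call: ModificationCall
    category: str
    locus_tags: tuple[str, ...]  # empty iff intergenic


@dataclass
class GeneMethylationProfile:
    locus_tag: str
    n_m6A_body: int = 0
    n_m4C_body: int = 0
    n_m6A_upstream: int = 0
    n_m4C_upstream: int = 0

    @property
    def any_methylation(self) -> bool:
        return (self.n_m6A_body + self.n_m4C_body
                + self.n_m6A_upstream + self.n_m4C_upstream) > 0

    @property
    def body_methylation(self) -> bool:
        return (self.n_m6A_body + self.n_m4C_body) > 0


def _interval_trees(
    genes: Sequence[GeneAnnotation], genome_length: int, upstream_len: int, circular: bool
) -> tuple[IntervalTree, IntervalTree]:
    """Build body and upstream trees; circular spans are inserted modulo L, split at the origin."""

    def add(tree: IntervalTree, start: int, end: int, tag: str) -> None:
        if end <= start:
            return
        if not circular:
            s, e = max(0, start), min(genome_length, end)
            if e > s:
                tree.addi(s, e, tag)
            return
        span = min(end - start, genome_length)
        start %= genome_length
        end = start + span
        if end <= genome_length:
            tree.addi(start, end, tag)
        else:  # wraps through origin
            tree.addi(start, genome_length, tag)
            tree.addi(0, end - genome_length, tag)

    body, upstream = IntervalTree(), IntervalTree()
    for g in genes:
        add(body, g.start, g.end, g.locus_tag)
        if g.strand == "+":
            add(upstream, g.start - upstream_len, g.start, g.locus_tag)
        else:
            add(upstream, g.end, g.end + upstream_len, g.locus_tag)
    return body, upstream


def assign_sites(
    calls: Sequence[ModificationCall],
    genes: Sequence[GeneAnnotation],
    genome: GenomeSequence,
    upstream_len: int = 500,
) -> list[FeatureAssignment]:
    """Categorize every call as gene_body / upstream500 / intergenic."""
    if upstream_len < 0:
        raise ValueError("upstream_len must be >= 0")
    body, upstream = _interval_trees(genes, genome.length, upstream_len, genome.circular)
    out = []
    for c in calls:
        pos = c.position % genome.length
        body_tags = sorted(iv.data for iv in body[pos])
        up_tags = sorted(iv.data for iv in upstream[pos])
        if body_tags:
            tags = tuple(dict.fromkeys(body_tags + up_tags))
            out.append(FeatureAssignment(c, "gene_body", tags))
        elif up_tags:
            out.append(FeatureAssignment(c, "upstream500", tuple(up_tags)))
        else:
            out.append(FeatureAssignment(c, "intergenic", ()))
    return out


def fraction_in_gene_and_upstream(assignments: Sequence[FeatureAssignment]) -> float:
    """Percentage of calls landing in gene bodies or upstream windows."""
    if not assignments:
        raise ValueError("no assignments: fraction undefined")
    hit = sum(1 for a in assignments if a.category != "intergenic")
    return 100.0 * hit / len(assignments)


def gene_profiles(
    assignments: Sequence[FeatureAssignment],
    genes: Sequence[GeneAnnotation],
    genome_length: int | None = None,
) -> dict[str, GeneMethylationProfile]:
    """Per-gene body/upstream methylation counts by modification type.

    A gene-body call also inside another gene's upstream window increments
    the body count of the former and the upstream count of the latter.
    """
    profiles = {g.locus_tag: GeneMethylationProfile(g.locus_tag) for g in genes}
    spans = {g.locus_tag: g for g in genes}
    for a in assignments:
        for tag in a.locus_tags:
            prof = profiles.get(tag)
            if prof is None:
                continue
            in_body = _position_in_span(a.call.position, spans[tag], genome_length)
            field = {
                ("m6A", True): "n_m6A_body",
                ("m4C", True): "n_m4C_body",
                ("m6A", False): "n_m6A_upstream",
                ("m4C", False): "n_m4C_upstream",
            }[(a.call.mod_type, in_body)]
            setattr(prof, field, getattr(prof, field) + 1)
    return profiles


def _position_in_span(pos: int, gene: GeneAnnotation, genome_length: int | None) -> bool:
    if gene.start <= pos < gene.end:
        return True
    # wrap-spanning gene: end beyond the origin, interpreted modulo genome length
    if genome_length is not None and gene.end > genome_length:
        return gene.start <= pos + genome_length < gene.end
    return False


def percent_genes_methylated(
    assignments: Sequence[FeatureAssignment],
    genes: Sequence[GeneAnnotation],
    include_upstream: bool = True,
) -> float:
    """Percentage of genes carrying at least one assigned call.

    ``include_upstream=True`` counts body-or-upstream association; the
    body-only variant is available because published gene-level figures do
    not always state which convention they use.
    """
    if not genes:
        raise ValueError("no genes")
    hit: set[str] = set()
    for a in assignments:
        if a.category == "gene_body" or (include_upstream and a.category == "upstream500"):
            hit.update(a.locus_tags)
    tags = {g.locus_tag for g in genes}
    return 100.0 * len(hit & tags) / len(tags)


def motif_methylation_fraction(
    hits: Sequence[MotifHit], calls: Sequence[ModificationCall]
) -> dict:
    """Fraction of motif instances whose modified-base position carries a call.

    Reported per pattern and pooled; 0 when there are no motif hits.
    """
    called = {(c.position, c.strand) for c in calls}
    per_pattern: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for h in hits:
        key = h.pattern
        per_pattern[key][1] += 1
        if (h.methylated_position, h.methylated_strand) in called:
            per_pattern[key][0] += 1
    out = {
        pattern: (m / n if n else 0.0) for pattern, (m, n) in per_pattern.items()
    }
    total_m = sum(m for m, _ in per_pattern.values())
    total_n = sum(n for _, n in per_pattern.values())
    out["pooled"] = total_m / total_n if total_n else 0.0
    return out


def strand_balance(calls: Sequence[ModificationCall]) -> dict:
    """Per modification type: plus/minus counts and their ratio (inf flag when minus is 0)."""
    out = {}
    for mod in ("m6A", "m4C"):
        plus = sum(1 for c in calls if c.mod_type == mod and c.strand == "+")
        minus = sum(1 for c in calls if c.mod_type == mod and c.strand == "-")
        if minus > 0:
            ratio: float | None = plus / minus
            flag = "ok"
        elif plus > 0:
            ratio, flag = math.inf, "infinite"
        else:
            ratio, flag = None, "undefined"
        out[mod] = {"+": plus, "-": minus, "ratio": ratio, "flag": flag}
    return out


def write_assignments_tsv(
    assignments: Iterable[FeatureAssignment], path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "position": a.call.position,
                "strand": a.call.strand,
                "mod_type": a.call.mod_type,
                "category": a.category,
                "locus_tags": ";".join(a.locus_tags),
            }
            for a in assignments
        ]
    ).to_csv(str(path), sep="\t", index=False)


_CATEGORY_RGB = {"gene_body": "31,119,180", "upstream500": "255,127,14", "intergenic": "127,127,127"}


def write_assignments_bed(
    assignments: Iterable[FeatureAssignment], genome: GenomeSequence, path: str | Path
) -> None:
    """BED9 with itemRgb by category."""
    with open(path, "w") as fh:
        for a in assignments:
            s, e = a.call.position, a.call.position + 1
            fh.write(
                f"{genome.id}\t{s}\t{e}\t{a.category}\t0\t{a.call.strand}\t{s}\t{e}\t"
                f"{_CATEGORY_RGB[a.category]}\n"
            )
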