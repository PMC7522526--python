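"""Genome and annotation I/O, IUPAC motif scanning, sequence utilities.

All coordinates are 0-based, half-open, on the forward frame. Bacterial
chromosomes are treated as circular by default, so motif windows (and the
500-bp upstream windows built on top of them elsewhere) may wrap through
the origin; wrap-spanning windows are counted exactly once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class FormatError(ValueError):
    """Raised on malformed sequence/annotation input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A nucleotide sequence with a circular/linear topology flag."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError("empty genome sequence")
        bad = next((i for i, c in enumerate(self.seq) if c not in VALID_BASES), None)
        if bad is not None:
            raise FormatError(
                f"non-nucleotide character {self.seq[bad]!r} at position {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def base_at(self, position: int) -> str:
        return self.seq[position % self.length]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene span: [start, end) forward-frame; wrap-spanning genes have end > genome length."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.locus_tag}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise FormatError(f"{self.locus_tag}: require 0 <= start < end")


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate recognition pattern with the modified base marked by offset."""

    pattern: str
    methylated_offset: int

    def __post_init__(self) -> None:
        for c in self.pattern:
            if c not in IUPAC_CODES:
                raise FormatError(f"invalid IUPAC code {c!r} in motif")
        if not 0 <= self.methylated_offset < len(self.pattern):
            raise FormatError("methylated_offset outside motif")

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif match; start is the forward-frame window start (mod genome length)."""

    start: int
    strand: str
    methylated_position: int
    methylated_strand: str
    pattern: str


def read_fasta(path: str | Path, circular: bool = True) -> GenomeSequence:
    """Read the first record of a FASTA file as an uppercase GenomeSequence."""
    records = SeqIO.parse(str(path), "fasta")
    rec = next(iter(records), None)
    if rec is None:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSequence(id=rec.id, seq=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse-complement under the degenerate IUPAC alphabet (Y<->R, K<->M, ...)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(pattern))
    except KeyError as exc:
        raise FormatError(f"invalid IUPAC code {exc.args[0]!r}") from None


def _iupac_regex(pattern: str) -> re.Pattern:
    # N in the genome never matches any pattern character (conservative: no
    # phantom hits in gap regions), so character classes list concrete bases only.
    parts = []
    for c in pattern:
        bases = IUPAC_CODES[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def scan_motif(
    genome: GenomeSequence, motif: IUPACMotif, strand: str = "both"
) -> list[MotifHit]:
    """Find all (possibly overlapping) matches of a degenerate motif.

    Minus-strand hits are matches of the motif read on the reverse strand,
    reported in forward-frame coordinates; ``methylated_position`` is the
    genome coordinate of the modified base on ``methylated_strand``. For a
    circular genome, windows spanning the origin are reported once with
    start in ``[0, length)``.
    """
    if motif.length > genome.length:
        raise ValueError("motif longer than genome")
    if strand not in {"+", "-", "both"}:
        raise ValueError("strand must be '+', '-' or 'both'")

    L = genome.length
    m = motif.length
    search_space = genome.seq + (genome.seq[: m - 1] if genome.circular else "")
    hits: list[MotifHit] = []

    def _find(pattern: str) -> list[int]:
        rx = _iupac_regex(pattern)
        # overlapping matches via manual restart
        out, pos = [], 0
        while True:
            match = rx.search(search_space, pos)
            if match is None:
                break
            if match.start() < L:
                out.append(match.start())
            pos = match.start() + 1
        return out

    if strand in {"+", "both"}:
        for s in _find(motif.pattern):
            hits.append(
                MotifHit(
                    start=s,
                    strand="+",
                    methylated_position=(s + motif.methylated_offset) % L,
                    methylated_strand="+",
                    pattern=motif.pattern,
                )
            )
    if strand in {"-", "both"}:
        rc = reverse_complement_iupac(motif.pattern)
        for s in _find(rc):
            # window [s, s+m) on forward frame matches motif on the minus strand;
            # the modified base sits offset positions from the minus-strand 5' end.
            hits.append(
                MotifHit(
                    start=s,
                    strand="-",
                    methylated_position=(s + m - 1 - motif.methylated_offset) % L,
                    methylated_strand="-",
                    pattern=motif.pattern,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def base_composition(genome: GenomeSequence) -> dict:
    """Forward-strand base counts plus both-strand A/C counts.

    On a duplex, every forward A pairs with a reverse T, so the both-strand
    adenine count is forward A + forward T, and likewise C + G for cytosine;
    both-strand A+C therefore equals genome length minus N count.
    """
    fwd = {b: genome.seq.count(b) for b in "ACGT"}
    n = genome.seq.count("N")
    both_a = fwd["A"] + fwd["T"]
    both_c = fwd["C"] + fwd["G"]
    return {
        "forward": fwd,
        "n_count": n,
        "both_strand_A": both_a,
        "both_strand_C": both_c,
        "both_strand_AC": both_a + both_c,
    }


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read a 4/5-column TSV: locus_tag, start, end, strand[, product] (0-based half-open)."""
    df = pd.read_csv(str(path), sep="\t")
    required = {"locus_tag", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation TSV needs columns {sorted(required)}")
    genes = [
        GeneAnnotation(
            locus_tag=str(r.locus_tag),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            product=str(getattr(r, "product", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]
    tags = [g.locus_tag for g in genes]
    if len(set(tags)) != len(tags):
        raise FormatError(f"{path}: duplicate locus_tags")
    return genes


def write_annotation_tsv(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "locus_tag": g.locus_tag,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
            }
            for g in genes
        ]
    ).to_csv(str(path), sep="\t", index=False)


def read_annotation_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene/CDS features from a GFF3 file (1-based inclusive -> 0-based half-open)."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    df = df[df["type"].isin(["gene", "CDS"])]
    genes = []
    seen = set()
    for r in df.itertuples(index=False):
        attrs = dict(
            kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv
        )
        tag = attrs.get("locus_tag") or attrs.get("ID") or f"{r.seqid}:{r.start}"
        if tag in seen:
            continue
        seen.add(tag)
        genes.append(
            GeneAnnotation(
                locus_tag=tag,
                start=int(r.start) - 1,
                end=int(r.end),
                strand=str(r.strand),
                product=attrs.get("product", ""),
            )
        )
    return genes


def write_annotation_gff3(
    genes: Iterable[GeneAnnotation], genome_id: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{genome_id}\tmethylink\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_motif_bed(hits: Iterable[MotifHit], genome: GenomeSequence, path: str | Path) -> None:
    """BED6 export of motif hits (name = pattern, score = 0)."""
    with open(path, "w") as fh:
        for h in hits:
            end = h.start + len(h.pattern)
            fh.write(
                f"{genome.id}\t{h.start}\t{end}\t{h.pattern}\t0\t{h.strand}\n"
            )
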