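"""Gene-body / upstream-window assignment and gene-level methylation summaries."""

from __future__ import annotations

import numpy as np
import pytest

from methylink.feature_map import (
    assign_sites,
    fraction_in_gene_and_upstream,
    gene_profiles,
    motif_methylation_fraction,
    percent_genes_methylated,
    strand_balance,
)
from methylink.genome_io import GeneAnnotation, GenomeSequence, MotifHit
from methylink.kinetics import ModificationCall


def _call(pos, strand="+", base="A"):
    mod = "m6A" if base == "A" else "m4C"
    return ModificationCall(pos, strand, base, mod, 3.0, 40)


def _genome(length=10_000, circular=True, seed=0):
    rng = np.random.default_rng(seed)
    return GenomeSequence("g", "".join(rng.choice(list("ACGT"), size=length)), circular)


PLUS_GENE = GeneAnnotation("gA", 1000, 2000, "+")
MINUS_GENE = GeneAnnotation("gB", 1000, 2000, "-")


class TestAssignSites:
    @pytest.mark.parametrize(
        "gene,pos,category",
        [
            (PLUS_GENE, 1500, "gene_body"),
            (PLUS_GENE, 700, "upstream500"),  # window [500, 1000)
            (PLUS_GENE, 499, "intergenic"),
            (PLUS_GENE, 2100, "intergenic"),
            (MINUS_GENE, 2300, "upstream500"),  # window [2000, 2500)
            (MINUS_GENE, 700, "intergenic"),
            (PLUS_GENE, 1000, "gene_body"),  # start inclusive
            (PLUS_GENE, 2000, "intergenic"),  # end exclusive
        ],
    )
    def test_category_examples(self, gene, pos, category):
        [a] = assign_sites([_call(pos)], [gene], _genome())
        assert a.category == category
        assert (a.locus_tags == ()) == (category == "intergenic")

    def test_call_strand_ignored(self):
        [a] = assign_sites([_call(1500, strand="-")], [PLUS_GENE], _genome())
        assert a.category == "gene_body"

    def test_body_precedence_keeps_both_associations(self):
        # call inside gene X's body and gene Y's upstream window
        x = GeneAnnotation("x", 1000, 2000, "+")
        y = GeneAnnotation("y", 2100, 3000, "+")  # upstream window [1600, 2100)
        [a] = assign_sites([_call(1800)], [x, y], _genome())
        assert a.category == "gene_body"
        assert set(a.locus_tags) == {"x", "y"}

    def test_upstream_window_wraps_origin(self):
        g = _genome(5000)
        gene = GeneAnnotation("w", 100, 900, "+")  # upstream [-400, 100) -> [4600, 5000) + [0, 100)
        [a] = assign_sites([_call(4700)], [gene], g)
        assert a.category == "upstream500"
        [b] = assign_sites([_call(50)], [gene], g)
        assert b.category == "upstream500"

    def test_strand_reflection_oracle(self):
        """Minus-strand assignment must equal the plus rule on the reflected genome."""
        rng = np.random.default_rng(4)
        L = 8000
        genome = _genome(L, seed=4)
        genes = [
            GeneAnnotation(f"m{i}", s, s + 600, "-")
            for i, s in enumerate(range(600, 7000, 1600))
        ]
        positions = rng.integers(0, L, size=300)
        got = assign_sites([_call(int(p)) for p in positions], genes, genome)
        # reflect: position p -> L-1-p; gene [s, e) on '-' -> [L-e, L-s) on '+'
        refl_genes = [
            GeneAnnotation(g.locus_tag, L - g.end, L - g.start, "+") for g in genes
        ]
        refl = assign_sites(
            [_call(int(L - 1 - p)) for p in positions], refl_genes, genome
        )
        assert [a.category for a in got] == [a.category for a in refl]

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(13)
        L = 6000
        genome = _genome(L, seed=13)
        genes = []
        cursor = 150
        for i in range(8):
            length = int(rng.integers(200, 700))
            if cursor + length > L:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnotation(f"g{i}", cursor, cursor + length, strand))
            cursor += length + int(rng.integers(50, 500))
        calls = [_call(int(p)) for p in rng.integers(0, L, size=400)]
        got = assign_sites(calls, genes, genome, upstream_len=500)

        def brute(pos: int) -> str:
            in_body = any(g.start <= pos < g.end for g in genes)
            if in_body:
                return "gene_body"
            for g in genes:
                window = (
                    range(g.start - 500, g.start) if g.strand == "+"
                    else range(g.end, g.end + 500)
                )
                if any(pos == w % L for w in window):
                    return "upstream500"
            return "intergenic"

        assert [a.category for a in got] == [brute(c.position) for c in calls]

    def test_rotation_invariance(self):
        L = 4000
        genome = _genome(L, seed=2)
        genes = [GeneAnnotation("r0", 500, 1200, "+"), GeneAnnotation("r1", 2000, 2900, "-")]
        calls = [_call(p) for p in (0, 450, 600, 1500, 2950, 3300, 3999)]
        base = [a.category for a in assign_sites(calls, genes, genome)]
        for shift in (137, 1900, 3500):
            rot_genome = GenomeSequence("g", genome.seq[-shift:] + genome.seq[:-shift])
            rot_genes = [
                GeneAnnotation(g.locus_tag, (g.start + shift) % L,
                               (g.start + shift) % L + (g.end - g.start), g.strand)
                for g in genes
            ]
            rot_calls = [_call((c.position + shift) % L) for c in calls]
            rotated = [a.category for a in assign_sites(rot_calls, rot_genes, rot_genome)]
            assert rotated == base

    def test_every_call_gets_exactly_one_category(self, study):
        from methylink.kinetics import call_modifications

        calls = call_modifications(study["kinetics"]["T4"])
        assignments = assign_sites(calls, study["genes"], study["genome"])
        assert len(assignments) == len(calls)
        counts = {"gene_body": 0, "upstream500": 0, "intergenic": 0}
        for a in assignments:
            counts[a.category] += 1
        assert sum(counts.values()) == len(calls)


class TestFractions:
    def test_all_intergenic_is_zero(self):
        a = assign_sites([_call(5000)], [PLUS_GENE], _genome())
        assert fraction_in_gene_and_upstream(a) == 0.0

    def test_definitional_percentage(self):
        calls = [_call(1500)] * 49 + [_call(5000)] * 51
        a = assign_sites(calls, [PLUS_GENE], _genome())
        assert fraction_in_gene_and_upstream(a) == pytest.approx(49.0)

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            fraction_in_gene_and_upstream([])

    def test_planted_in_gene_fraction_recovered(self):
        """Generator's in-gene/upstream split recovered within 3 sigma binomial."""
        from methylink.synthetic_data import (
            SyntheticScenario,
            generate_genome,
            generate_methylation_truth,
        )

        sc = SyntheticScenario(seed=31, n_motifs=0, in_gene_fraction=0.52)
        genome, genes, _ = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, [])
        sites = truth["T26"]["sites"]
        calls = [_call(s["position"], s["strand"], s["base"]) for s in sites]
        frac = fraction_in_gene_and_upstream(assign_sites(calls, genes, genome)) / 100
        n = len(sites)
        assert abs(frac - 0.52) <= 3 * (0.52 * 0.48 / n) ** 0.5 + 1 / n

    def test_percent_genes_methylated(self):
        genes = [GeneAnnotation(f"g{i}", 1000 * i, 1000 * i + 800, "+") for i in range(3)]
        a = assign_sites([_call(100), _call(1100)], genes, _genome())
        assert percent_genes_methylated(a, genes) == pytest.approx(200 / 3)
        assert percent_genes_methylated([], genes) == 0.0

    def test_body_only_variant_excludes_upstream(self):
        g2 = GeneAnnotation("u", 2000, 2800, "+")
        a = assign_sites([_call(1700)], [g2], _genome())  # upstream of u
        assert percent_genes_methylated(a, [g2], include_upstream=True) == 100.0
        assert percent_genes_methylated(a, [g2], include_upstream=False) == 0.0

    def test_exact_planted_gene_percentage_with_deterministic_generator(self):
        from methylink.synthetic_data import (
            SyntheticScenario,
            generate_genome,
            generate_methylation_truth,
        )

        sc = SyntheticScenario(seed=8, n_motifs=0, in_gene_fraction=1.0,
                               p_gene_methylated={"T26": 0.25, "T4": 0.25, "UV": 0.25})
        genome, genes, _ = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, [])
        calls = [
            _call(s["position"], s["strand"], s["base"]) for s in truth["T26"]["sites"]
        ]
        a = assign_sites(calls, genes, genome)
        # every planted site sits in its gene's body or upstream window, and
        # exactly 25% of genes were selected
        assert percent_genes_methylated(a, genes) >= 25.0
        assert set(truth["T26"]["methylated_genes"]) <= {
            t for x in a for t in x.locus_tags
        }


class TestMotifMethylationFraction:
    def _hits(self, n):
        return [MotifHit(100 * i, "+", 100 * i + 2, "+", "CTAYNNNNNNNNTRTC") for i in range(n)]

    def test_no_calls_zero(self):
        assert motif_methylation_fraction(self._hits(5), [])["pooled"] == 0.0

    def test_all_called_one(self):
        hits = self._hits(4)
        calls = [_call(h.methylated_position) for h in hits]
        assert motif_methylation_fraction(hits, calls)["pooled"] == 1.0

    def test_partial_fraction(self):
        hits = self._hits(100)
        calls = [_call(h.methylated_position) for h in hits[:92]]
        assert motif_methylation_fraction(hits, calls)["pooled"] == pytest.approx(0.92)

    def test_strand_must_match(self):
        hits = self._hits(1)
        wrong = [_call(hits[0].methylated_position, strand="-")]
        assert motif_methylation_fraction(hits, wrong)["pooled"] == 0.0


class TestStrandBalance:
    def test_balanced(self):
        calls = [_call(i, "+") for i in range(10)] + [_call(100 + i, "-") for i in range(10)]
        assert strand_balance(calls)["m6A"]["ratio"] == pytest.approx(1.0)

    def test_empty_undefined_flag(self):
        sb = strand_balance([])
        assert sb["m6A"]["flag"] == "undefined"
        assert sb["m6A"]["ratio"] is None

    def test_infinite_flag(self):
        sb = strand_balance([_call(1, "+")])
        assert sb["m6A"]["flag"] == "infinite"

    def test_planted_strand_probabilities_recovered(self):
        rng = np.random.default_rng(17)
        n = 4000
        strands = rng.choice(["+", "-"], size=n, p=[0.6, 0.4])
        calls = [_call(i, s) for i, s in enumerate(strands)]
        ratio = strand_balance(calls)["m6A"]["ratio"]
        # binomial error on the plus fraction propagated to the ratio
        assert ratio == pytest.approx(1.5, rel=0.1)


def test_gene_profiles_split_body_and_upstream(study):
    genes = [GeneAnnotation("p", 1000, 2000, "+")]
    calls = [_call(1500, base="A"), _call(1600, base="C"), _call(700, base="A")]
    a = assign_sites(calls, genes, _genome())
    prof = gene_profiles(a, genes, 10_000)["p"]
    assert (prof.n_m6A_body, prof.n_m4C_body, prof.n_m6A_upstream) == (1, 1, 1)
    assert prof.any_methylation and prof.body_methylation
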