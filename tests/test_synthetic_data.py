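"""Generator contracts: determinism, planted-truth bookkeeping, recovery regimes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methylink.expression import transcript_de
from methylink.genome_io import scan_motif
from methylink.kinetics import CallParameters, call_modifications
from methylink.synthetic_data import (
    SyntheticScenario,
    generate_expression,
    generate_genome,
    generate_kinetics,
    generate_methylation_truth,
    generate_ortholog_pair,
    generate_proteome,
    scenario_from_config,
    scenario_to_config,
)


def _small(seed=5, **kw) -> SyntheticScenario:
    defaults = dict(seed=seed, genome_length=50_000, n_genes=40, n_motifs=5,
                    n_background_kinetics_sites=3000)
    defaults.update(kw)
    return SyntheticScenario(**defaults)


class TestScenario:
    def test_config_round_trip(self):
        sc = _small(noise_sd=0.1, omega_list=(0.3, 1.0))
        back = scenario_from_config(scenario_to_config(sc))
        assert back == sc

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(gc_content=1.5)

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(genome_length=5000, gene_length_mean=900)


class TestGenerateGenome:
    def test_fixed_seed_reproducible(self):
        g1, genes1, m1 = generate_genome(_small())
        g2, genes2, m2 = generate_genome(_small())
        assert g1.seq == g2.seq
        assert genes1 == genes2
        assert m1 == m2

    def test_zero_density_leaves_only_chance_matches(self):
        sc = _small(n_motifs=0)
        genome, _, planted = generate_genome(sc)
        assert planted == []
        hits = scan_motif(genome, sc.motif, "+")
        p = 1 / 16384  # per-strand match probability at GC 0.5; GC 0.45 similar
        bound = sc.genome_length * p + 4 * (sc.genome_length * p) ** 0.5 + 3
        assert len(hits) <= bound

    def test_scanner_recovers_all_planted_motifs(self):
        sc = _small(n_motifs=30, genome_length=100_000)
        genome, _, planted = generate_genome(sc)
        assert len(planted) == 30
        found = {(h.start, h.strand) for h in scan_motif(genome, sc.motif, "both")}
        assert {(h.start, h.strand) for h in planted} <= found

    def test_genes_non_overlapping_and_within_genome(self):
        sc = _small()
        _, genes, _ = generate_genome(sc)
        assert len(genes) == sc.n_genes
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
        assert genes[-1].end <= sc.genome_length

    def test_infeasible_packing_rejected(self):
        sc = _small(genome_length=40_000, n_genes=60, gene_length_mean=900,
                    gene_length_sd=0.0)
        with pytest.raises(ValueError, match="packing"):
            generate_genome(sc)


class TestGenerateKinetics:
    def test_noise_free_multiplier_recovers_truth_exactly(self):
        sc = _small(ipd_noise_sigma=0.0, ipd_multiplier=4.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        kin = generate_kinetics(sc, genome, truth)
        for cond in sc.conditions:
            calls = call_modifications(kin[cond])
            got = {(c.position, c.strand) for c in calls}
            want = {(s["position"], s["strand"]) for s in truth[cond]["sites"]}
            assert got == want

    def test_unit_multiplier_yields_no_calls_without_noise_tail(self):
        sc = _small(ipd_noise_sigma=0.0, ipd_multiplier=1.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        kin = generate_kinetics(sc, genome, truth)
        assert call_modifications(kin["T26"]) == []

    def test_low_coverage_fails_filter(self):
        sc = _small(coverage_mean=10.0, ipd_noise_sigma=0.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        kin = generate_kinetics(sc, genome, truth)
        calls = call_modifications(kin["T26"])
        # Poisson(10) essentially never exceeds 25
        assert len(calls) <= 2

    def test_deterministic_tables(self):
        sc = _small()
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        k1 = generate_kinetics(sc, genome, truth)
        k2 = generate_kinetics(sc, genome, truth)
        assert k1 == k2


class TestGenerateExpression:
    def test_zero_noise_recovers_truth_exactly(self):
        sc = _small(noise_sd=0.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        matrix, de_truth = generate_expression(sc, genes, truth)
        res = transcript_de(matrix, "T4", "T26")
        for r in res:
            planted_dir = de_truth["T4"][r.feature_id]["direction"]
            if planted_dir is None:
                assert not r.significant
            else:
                assert r.significant
                assert (r.log2fc < 0) == (planted_dir == "down")
                assert r.log2fc == pytest.approx(
                    de_truth["T4"][r.feature_id]["log2fc"], abs=1e-9
                )

    def test_null_scenario_type_one_rate(self):
        sc = _small(seed=23, n_genes=400, genome_length=400_000,
                    p_gene_methylated={"T26": 0.0, "T4": 0.0, "UV": 0.0},
                    p_de_unmethylated=0.0, n_motifs=0)
        genome, genes, _ = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, [])
        matrix, _ = generate_expression(sc, genes, truth)
        res = transcript_de(matrix, "T4", "T26")
        frac = sum(r.significant for r in res) / len(res)
        assert frac <= 0.05 + 3 * (0.05 * 0.95 / len(res)) ** 0.5

    def test_planted_effect_sizes_recovered(self):
        sc = _small(noise_sd=0.1)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        matrix, de_truth = generate_expression(sc, genes, truth)
        res = {r.feature_id: r for r in transcript_de(matrix, "T4", "T26")}
        planted_fc = [
            (de_truth["T4"][t]["log2fc"], res[t].log2fc)
            for t in res
            if de_truth["T4"][t]["direction"] is not None
        ]
        assert planted_fc
        err = [abs(a - b) for a, b in planted_fc]
        assert np.mean(err) < 0.2  # replicate-averaged noise at sd 0.1


class TestGenerateProteome:
    def test_zero_missing_rate_complete(self):
        sc = _small(proteome_missing_rate=0.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        matrix, de_truth = generate_expression(sc, genes, truth)
        prot, missing = generate_proteome(sc, matrix, de_truth)
        assert not prot.isna().any().any()
        assert missing == {}

    def test_missingness_concentrates_at_low_intensity(self):
        sc = _small(seed=6, proteome_missing_rate=0.25, proteome_missing_slope=2.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        matrix, de_truth = generate_expression(sc, genes, truth)
        prot, missing = generate_proteome(sc, matrix, de_truth)
        assert 0 < missing["fraction_missing"] < 0.5
        observed = np.log2(prot.to_numpy())
        row_missing = prot.isna().sum(axis=1)
        baseline = np.log2(matrix.to_numpy()).mean(axis=1)
        # rows with dropout sit lower in the intensity distribution
        assert baseline[row_missing > 0].mean() < baseline[row_missing == 0].mean()

    def test_faithful_transfer_without_attenuation(self):
        sc = _small(proteome_attenuation=1.0, proteome_noise_sd=0.0,
                    proteome_missing_rate=0.0, noise_sd=0.0)
        genome, genes, planted = generate_genome(sc)
        truth = generate_methylation_truth(sc, genome, genes, planted)
        matrix, de_truth = generate_expression(sc, genes, truth)
        prot, _ = generate_proteome(sc, matrix, de_truth)
        from methylink.expression import proteome_preprocess, proteome_de

        res = proteome_de(proteome_preprocess(prot), "T4", "T26")
        for r in res:
            planted_fc = de_truth["T4"][r.feature_id]["log2fc"]
            assert r.log2fc == pytest.approx(planted_fc, abs=1e-9)


class TestGenerateOrthologPair:
    def test_omega_zero_is_purely_synonymous(self):
        aln, truth = generate_ortholog_pair(200, 0.0, 0.5, seed=2)
        assert truth["realized_nonsynonymous"] == 0

    def test_determinism(self):
        a1, t1 = generate_ortholog_pair(150, 0.4, 0.3, seed=77)
        a2, t2 = generate_ortholog_pair(150, 0.4, 0.3, seed=77)
        assert a1.seqB == a2.seqB and t1 == t2

    def test_no_stop_codons_ever(self):
        from methylink.kaks import _code

        _, stops = _code(1)
        for s in range(4):
            aln, _ = generate_ortholog_pair(150, 0.8, 0.6, seed=s)
            for seq in (aln.seqA, aln.seqB):
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert not (codons & stops)

    def test_divergence_scales_with_branch_length(self):
        def diffs(bl, seed):
            aln, _ = generate_ortholog_pair(500, 0.5, bl, seed=seed)
            return sum(a != b for a, b in zip(aln.seqA, aln.seqB))

        short = np.mean([diffs(0.05, 30 + s) for s in range(3)])
        long = np.mean([diffs(0.6, 30 + s) for s in range(3)])
        assert long > 3 * short


def test_methylation_truth_fraction_and_gene_counts(study):
    sc, truth, genes = study["scenario"], study["truth"], study["genes"]
    for cond in sc.conditions:
        expected = int(round(sc.p_gene_methylated[cond] * len(genes)))
        assert len(truth[cond]["methylated_genes"]) == expected
        n_genic = truth[cond]["n_genic_background"]
        n_inter = truth[cond]["n_intergenic_background"]
        got = n_genic / (n_genic + n_inter)
        assert got == pytest.approx(sc.in_gene_fraction, abs=0.05)
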