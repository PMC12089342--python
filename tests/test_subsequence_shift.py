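"""Codon counting, shift statistic and amino-acid-level mixed-model test."""

import numpy as np
import pandas as pd
import pytest

import stallscan as ss
from stallscan.codons import ALL_CODONS
from stallscan.subsequence_shift import CodonFrequencyTable

from conftest import ALA_CODONS, simulate_rpfs


def table_from_counts(counts: dict[str, dict[str, int]], offset=15) -> CodonFrequencyTable:
    df = pd.DataFrame(0, index=sorted(counts), columns=list(ALL_CODONS))
    for gene, cc in counts.items():
        for codon, n in cc.items():
            df.loc[gene, codon] = n
    return CodonFrequencyTable(offset=offset, counts=df)


def single_read_rpfs(gene, pos, length=30):
    return pd.DataFrame(
        {
            "read_id": ["r1"],
            "gene_id": [gene],
            "transcript_id": [gene],
            "cds_relative_5p": [pos],
            "length": [length],
            "frame": [pos % 3],
        }
    )


class TestCountCodons:
    def test_single_read_direct_indexing(self):
        seq = "ATGGCAGGT" + "GAA" * 25 + "TAA"  # 90 nt
        rpfs = single_read_rpfs("g1", 0)
        tab = ss.count_codons_at_offset(rpfs, {"g1": seq}, offset=15)
        assert tab.counts.loc["g1", seq[15:18]] == 1
        assert tab.gene_totals["g1"] == 1

    def test_matches_simulation_truth_table(self, medium_transcriptome, medium_seqs):
        config = ss.SimulationConfig(n_reads=50_000, seed=31)
        reads = ss.simulate_footprints(
            medium_transcriptome, ss.StallingProfile({"GGA": 2.0}), config
        )
        rpfs = ss.to_aligned_rpfs(reads)
        tab = ss.count_codons_at_offset(rpfs, medium_seqs, offset=15)
        kept = reads[reads["length"] >= 27]
        truth = (
            kept.groupby(["gene_id", "a_site_codon"]).size().unstack(fill_value=0)
        )
        for gene in truth.index:
            for codon in truth.columns:
                assert tab.counts.loc[gene, codon] == truth.loc[gene, codon]

    def test_p_site_offset_shifts_codon_identity(self, small_transcriptome, small_seqs):
        rpfs = simulate_rpfs(small_transcriptome, {}, seed=5, n_reads=20_000)
        t15 = ss.count_codons_at_offset(rpfs, small_seqs, offset=15)
        t12 = ss.count_codons_at_offset(rpfs, small_seqs, offset=12)
        # same reads counted, one codon upstream: totals match gene by gene
        assert (t15.gene_totals == t12.gene_totals).all()

    def test_out_of_frame_reads_contribute_nothing(self):
        seq = "ATG" + "GAA" * 28 + "TAA"
        rpfs = single_read_rpfs("g1", 1)  # frame 1: 15 nt later is off-frame
        tab = ss.count_codons_at_offset(rpfs, {"g1": seq}, offset=15)
        assert tab.counts.to_numpy().sum() == 0

    def test_missing_sequence_aborts_with_gene_name(self):
        rpfs = single_read_rpfs("gX", 0)
        with pytest.raises(KeyError, match="gX"):
            ss.count_codons_at_offset(rpfs, {"other": "ATG" + "TAA"}, offset=15)

    def test_frequencies_sum_to_one_per_gene(self, small_transcriptome, small_seqs):
        rpfs = simulate_rpfs(small_transcriptome, {}, seed=5, n_reads=10_000)
        tab = ss.count_codons_at_offset(rpfs, small_seqs, offset=15)
        sums = tab.frequencies().sum(axis=1)
        assert np.allclose(sums[tab.gene_totals > 0], 1.0)


class TestComputeShifts:
    def test_identity_gives_zero_shifts(self, small_transcriptome, small_seqs):
        rpfs = simulate_rpfs(small_transcriptome, {}, seed=5, n_reads=20_000)
        tab = ss.count_codons_at_offset(rpfs, small_seqs, offset=15)
        shifts = ss.compute_shifts(tab, tab, min_gene_count=100)
        assert (shifts["shift"] == 0).all()

    def test_hand_built_two_gene_example(self):
        cond = table_from_counts(
            {"g1": {"GCA": 2, "AAA": 8}, "g2": {"GCA": 4, "AAA": 16}}
        )
        ctrl = table_from_counts(
            {"g1": {"GCA": 1, "AAA": 9}, "g2": {"GCA": 2, "AAA": 18}}
        )
        shifts = ss.compute_shifts(cond, ctrl, min_gene_count=10)
        row = shifts.set_index("codon").loc["GCA"]
        assert row["mean_freq_condition"] == pytest.approx(0.2)
        assert row["mean_freq_control"] == pytest.approx(0.1)
        assert row["shift"] == pytest.approx(1.0)
        assert row["n_genes_used"] == 2

    def test_ala_stall_produces_top_four_ala_shifts(self, medium_transcriptome, medium_seqs):
        cond = simulate_rpfs(
            medium_transcriptome, {c: 3.0 for c in ALA_CODONS}, seed=41, n_reads=200_000
        )
        ctrl = simulate_rpfs(medium_transcriptome, {}, seed=42, n_reads=200_000)
        tc = ss.count_codons_at_offset(cond, medium_seqs, offset=15)
        tk = ss.count_codons_at_offset(ctrl, medium_seqs, offset=15)
        shifts = ss.compute_shifts(tc, tk)
        top4 = shifts.nlargest(4, "shift")
        assert set(top4["codon"]) == set(ALA_CODONS)
        assert (top4["shift"] > 0).all()

    def test_shift_invariant_to_uniform_count_scaling(self):
        cond = table_from_counts({"g1": {"GCA": 20, "AAA": 180}})
        ctrl = table_from_counts({"g1": {"GCA": 10, "AAA": 190}})
        scaled = CodonFrequencyTable(offset=15, counts=cond.counts * 7)
        s1 = ss.compute_shifts(cond, ctrl, min_gene_count=10)
        s2 = ss.compute_shifts(scaled, ctrl, min_gene_count=10)
        pd.testing.assert_frame_equal(s1, s2)

    def test_swapping_samples_maps_shift_to_its_dual(self, small_transcriptome, small_seqs):
        cond = simulate_rpfs(small_transcriptome, {"GGA": 2.5}, seed=51, n_reads=50_000)
        ctrl = simulate_rpfs(small_transcriptome, {}, seed=52, n_reads=50_000)
        tc = ss.count_codons_at_offset(cond, small_seqs, offset=15)
        tk = ss.count_codons_at_offset(ctrl, small_seqs, offset=15)
        fwd = ss.compute_shifts(tc, tk).set_index("codon")["shift"]
        rev = ss.compute_shifts(tk, tc).set_index("codon")["shift"]
        common = fwd.index.intersection(rev.index)
        expected = 1.0 / (1.0 + fwd[common]) - 1.0
        assert np.allclose(rev[common], expected)

    def test_min_gene_count_threshold_applies_to_both_samples(self):
        cond = table_from_counts({"g1": {"GCA": 200}, "g2": {"GCA": 5}})
        ctrl = table_from_counts({"g1": {"GCA": 5}, "g2": {"GCA": 200}})
        with pytest.raises(ValueError, match="min_gene_count"):
            ss.compute_shifts(cond, ctrl, min_gene_count=100)

    def test_zero_control_mean_is_flagged_not_dropped(self):
        cond = table_from_counts({"g1": {"GCA": 10, "AAA": 90}})
        ctrl = table_from_counts({"g1": {"AAA": 100}})
        shifts = ss.compute_shifts(cond, ctrl, min_gene_count=10)
        row = shifts.set_index("codon").loc["GCA"]
        assert not row["defined"]
        assert np.isnan(row["shift"])


class TestAminoAcidTest:
    def test_all_zero_shifts_give_no_significance(self):
        rows = pd.DataFrame(
            {
                "codon": list(ss.SENSE_CODONS),
                "amino_acid": [ss.CODON_TO_AA[c] for c in ss.SENSE_CODONS],
                "shift": 0.0,
                "defined": True,
            }
        )
        res = ss.test_amino_acids({"rep1": rows, "rep2": rows.copy()})
        assert (res["t_value"] == 0).all()
        assert (res["p_value"] == 1).all()
        assert (res["p_adjusted"] >= res["p_value"]).all()

    def test_recovers_simulated_alanine_stall(self, medium_transcriptome, medium_seqs):
        reps = {}
        for r in range(3):
            cond = simulate_rpfs(
                medium_transcriptome,
                {c: 3.0 for c in ALA_CODONS},
                seed=100 + r,
                n_reads=100_000,
            )
            ctrl = simulate_rpfs(medium_transcriptome, {}, seed=200 + r, n_reads=100_000)
            tc = ss.count_codons_at_offset(cond, medium_seqs, offset=15)
            tk = ss.count_codons_at_offset(ctrl, medium_seqs, offset=15)
            reps[f"rep{r + 1}"] = ss.compute_shifts(tc, tk)
        res = ss.test_amino_acids(reps)
        best = res.loc[res["p_adjusted"].idxmin()]
        assert best["amino_acid"] == "A"
        assert best["t_value"] > 0

    def test_zero_codon_variance_reduces_to_ols(self):
        """With identical codon effects the fallback equals a plain linear model."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        codons = list(ss.SENSE_CODONS)
        aas = [ss.CODON_TO_AA[c] for c in codons]
        effects = {aa: i * 0.01 for i, aa in enumerate(sorted(set(aas)))}
        # noise centred per codon: every codon's mean equals its amino acid's
        # effect exactly, so the codon random-effect variance is 0
        noise = rng.normal(0, 0.02, size=(3, len(codons)))
        noise -= noise.mean(axis=0, keepdims=True)
        reps = {}
        for r in range(3):
            reps[f"rep{r}"] = pd.DataFrame(
                {
                    "codon": codons,
                    "amino_acid": aas,
                    "shift": [effects[a] + noise[r, i] for i, a in enumerate(aas)],
                    "defined": True,
                }
            )
        res = ss.test_amino_acids(reps)

        data = pd.concat(reps.values(), ignore_index=True)
        levels = sorted(data["amino_acid"].unique())
        exog = pd.get_dummies(data["amino_acid"], dtype=float)[levels].to_numpy()
        k = len(levels)
        ols = sm.OLS(data["shift"].to_numpy(), exog).fit()
        tt = ols.t_test(np.eye(k) - np.full((k, k), 1.0 / k))
        assert np.allclose(res["t_value"].to_numpy(), np.asarray(tt.tvalue), rtol=1e-6)

    def test_bh_adjustment_is_monotone(self):
        rows = []
        rng = np.random.default_rng(1)
        for c in ss.SENSE_CODONS:
            rows.append(
                {
                    "codon": c,
                    "amino_acid": ss.CODON_TO_AA[c],
                    "shift": rng.normal(0, 0.05),
                    "defined": True,
                }
            )
        df = pd.DataFrame(rows)
        df2 = df.copy()
        df2["shift"] = df2["shift"] + rng.normal(0, 0.05, len(df2))
        res = ss.test_amino_acids({"rep1": df, "rep2": df2})
        assert (res["p_adjusted"] >= res["p_value"] - 1e-12).all()
        # BH preserves the p-value ordering
        order = res.sort_values("p_value")
        assert order["p_adjusted"].is_monotonic_increasing

    def test_requires_two_replicates(self):
        df = pd.DataFrame(
            {"codon": ["GCA"], "amino_acid": ["A"], "shift": [0.1], "defined": [True]}
        )
        with pytest.raises(ValueError, match="replicates"):
            ss.test_amino_acids({"rep1": df})


class TestWeightedAveraging:
    def test_count_weighted_average_equals_pooled_frequencies(self):
        """Weighting genes by totals reproduces the pooled-count frequency."""
        cond = table_from_counts(
            {"g1": {"GCA": 2, "AAA": 8}, "g2": {"GCA": 4, "AAA": 16}}
        )
        ctrl = table_from_counts(
            {"g1": {"GCA": 1, "AAA": 9}, "g2": {"GCA": 2, "AAA": 18}}
        )
        shifts = ss.compute_shifts(cond, ctrl, min_gene_count=10, weight_by_counts=True)
        row = shifts.set_index("codon").loc["GCA"]
        assert row["mean_freq_condition"] == pytest.approx(6 / 30)
        assert row["mean_freq_control"] == pytest.approx(3 / 30)
        assert row["shift"] == pytest.approx(1.0)
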