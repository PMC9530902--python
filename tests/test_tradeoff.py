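import numpy as np
import pandas as pd
import pytest

from mutgrowth import ConfigurationError, default_media, synthetic, tradeoff

from conftest import SEED


def table_on_line(alpha, log10_m_inf, mus, medium="LB", collection="MG"):
    """Rate table whose points lie exactly on one trade-off line."""
    rows = [
        {
            "collection": collection,
            "strain": f"s{i}",
            "genome_reduced": 0,
            "mmr_deficient": 0,
            "medium": medium,
            "growth_rate": mu,
            "growth_se": 0.0,
            "mutation_rate": 10 ** (log10_m_inf + alpha * mu),
            "mutation_se": 0.0,
            "n_replicates": 1,
        }
        for i, mu in enumerate(mus)
    ]
    return pd.DataFrame(rows)


class TestFitTradeoff:
    def test_noiseless_fit_is_exact(self):
        table = table_on_line(-9.5, -3.0, [0.4, 0.5, 0.6, 0.7, 0.8])
        fit = tradeoff.fit_tradeoff(table, "LB")
        assert fit.alpha == pytest.approx(-9.5, abs=1e-9)
        assert np.log10(fit.m_inf) == pytest.approx(-3.0, abs=1e-9)
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-9)

    def test_three_collinear_points_perfect_negative_correlation(self):
        fit = tradeoff.fit_tradeoff(table_on_line(-12.8, -5.2, [0.1, 0.2, 0.3]), "LB")
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_recovery_within_ten_percent(self):
        """Seeded generation at the fitted per-medium parameters recovers
        each slope within +-10%."""
        for spec in default_media():
            mu, m = synthetic.sample_rates_on_law(spec, 20, 0.2, seed=SEED)
            table = synthetic.law_rate_table(spec, mu, m)
            fit = tradeoff.fit_tradeoff(table, spec.name)
            assert fit.alpha == pytest.approx(spec.alpha_true, rel=0.10)

    def test_invariant_to_row_order_and_relabeling(self):
        table = table_on_line(-9.5, -3.0, [0.45, 0.52, 0.61, 0.75])
        shuffled = table.sample(frac=1, random_state=3).reset_index(drop=True)
        shuffled["strain"] = [f"x{i}" for i in range(len(shuffled))]
        a = tradeoff.fit_tradeoff(table, "LB")
        b = tradeoff.fit_tradeoff(shuffled, "LB")
        assert a.alpha == pytest.approx(b.alpha, rel=1e-12)
        assert a.m_inf == pytest.approx(b.m_inf, rel=1e-12)

    def test_pooled_across_collections(self, noiseless_table):
        """The fit uses all collections jointly; noiseless data lie on one
        common line so residuals vanish despite genotype variety."""
        fit = tradeoff.fit_tradeoff(noiseless_table, "LB")
        assert noiseless_table["collection"].nunique() == 3
        assert fit.n_points == 34
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-9)

    def test_degenerate_and_small_inputs(self):
        constant = table_on_line(-9.5, -3.0, [0.5, 0.5, 0.5])
        with pytest.raises(ConfigurationError, match="constant growth"):
            tradeoff.fit_tradeoff(constant, "LB")
        with pytest.raises(ConfigurationError, match=">= 3"):
            tradeoff.fit_tradeoff(table_on_line(-9.5, -3.0, [0.4, 0.5]), "LB")


class TestPrediction:
    def fit(self):
        return tradeoff.TradeoffFit("LB", -9.5, 1e-3, -1.0, 0.0, 5)

    def test_intercept_is_maximal_rate(self):
        assert tradeoff.predict_mutation_rate(self.fit(), 0.0) == pytest.approx(1e-3)

    def test_closed_form(self):
        # 10^(-3 - 9.5*0.5) = 10^-7.75
        assert tradeoff.predict_mutation_rate(self.fit(), 0.5) == pytest.approx(
            10**-7.75, rel=1e-9
        )

    def test_inverse_round_trip(self):
        fit = self.fit()
        for mu in (0.1, 0.37, 0.8):
            m = tradeoff.predict_mutation_rate(fit, mu)
            assert tradeoff.growth_rate_for_mutation_rate(fit, m) == pytest.approx(
                mu, abs=1e-9
            )


class TestMutationsPerGenome:
    def test_rich_medium_exceeds_thousand(self):
        assert tradeoff.mutations_per_genome(1e-3, 4e6) == 4000 > 1000

    def test_poor_medium_a_few_dozen(self):
        assert tradeoff.mutations_per_genome(7e-6, 4e6) == pytest.approx(28)

    def test_zero_genome(self):
        assert tradeoff.mutations_per_genome(1e-3, 0) == 0


class TestMediaShift:
    def test_identical_rates_no_shift(self):
        lb = table_on_line(-9.5, -3.0, [0.4, 0.5, 0.6, 0.7])
        m63 = lb.assign(medium="M63")
        table = pd.concat([lb, m63], ignore_index=True)
        res = tradeoff.compare_media_distributions(table, "LB", "M63")
        assert res["median_log10_shift"] == 0.0 and res["p_value"] == 1.0

    def test_mutator_panel_shifts_up_in_rich_medium(self):
        """13 strains each half a decade higher in LB than M63: positive
        median shift, significant at the exact signed-rank level 2/2^13."""
        m63_rates = 10.0 ** np.linspace(-10, -8, 13)
        rows = []
        for i, r in enumerate(m63_rates):
            for medium, rate in (("M63", r), ("LB", r * 10**0.5)):
                rows.append(
                    {
                        "collection": "MDS", "strain": f"s{i}",
                        "genome_reduced": 1, "mmr_deficient": 1,
                        "medium": medium, "growth_rate": 0.3 + 0.01 * i,
                        "growth_se": 0.0, "mutation_rate": rate,
                        "mutation_se": 0.0, "n_replicates": 3,
                    }
                )
        res = tradeoff.compare_media_distributions(pd.DataFrame(rows), "LB", "M63")
        assert res["median_log10_shift"] == pytest.approx(0.5)
        assert res["p_value"] == pytest.approx(2 / 2**13, rel=1e-6)
        assert res["p_value"] < 0.05

    def test_reduced_genome_panel_shifts_down(self):
        """Reduced genomes mutate faster in the poor medium: negative LB
        vs M63 shift."""
        rows = []
        for i in range(10):
            base = 10.0 ** (-9 + 0.1 * i)
            for medium, rate in (("M63", base * 4), ("LB", base)):
                rows.append(
                    {
                        "collection": "KHK", "strain": f"k{i}",
                        "genome_reduced": 1, "mmr_deficient": 0,
                        "medium": medium, "growth_rate": 0.3,
                        "growth_se": 0.0, "mutation_rate": rate,
                        "mutation_se": 0.0, "n_replicates": 3,
                    }
                )
        res = tradeoff.compare_media_distributions(pd.DataFrame(rows), "LB", "M63")
        assert res["median_log10_shift"] < 0

    def test_too_few_pairs(self):
        table = table_on_line(-9.5, -3.0, [0.4, 0.5])
        with pytest.raises(ConfigurationError):
            tradeoff.compare_media_distributions(table, "LB", "M63")


class TestCrossMediaCorrelation:
    def test_identical_rates_perfect_correlation(self):
        lb = table_on_line(-9.5, -3.0, [0.4, 0.5, 0.6, 0.7])
        table = pd.concat(
            [lb, lb.assign(medium="MAA"), lb.assign(medium="M63")],
            ignore_index=True,
        )
        res = tradeoff.cross_media_correlation(table, "mutation")
        np.testing.assert_allclose(res["pearson_r"], 1.0, rtol=1e-9)
        assert len(res[res["group"] == "pooled"]) == 3  # three media pairs

    def test_generated_panel_all_positive(self, true_table):
        for kind in ("mutation", "growth"):
            res = tradeoff.cross_media_correlation(
                true_table, kind, per_collection=False
            )
            assert (res["pearson_r"] > 0).all()

    def test_insufficient_shared_strains_skipped(self):
        lb = table_on_line(-9.5, -3.0, [0.4, 0.5])
        maa = lb.assign(medium="MAA")
        extra = table_on_line(-9.5, -3.0, [0.4, 0.5, 0.6], medium="LB")
        extra["strain"] = ["a", "b", "c"]
        table = pd.concat([lb, maa, extra], ignore_index=True)
        table = table.drop_duplicates(subset=["strain", "medium"])
        with pytest.warns(UserWarning, match="skipping"):
            res = tradeoff.cross_media_correlation(table, "mutation",
                                                   per_collection=False)
        assert res.empty


class TestFoldChanges:
    def make_table(self, factor_m=100.0, factor_mu=0.8):
        rows = []
        for strain, fm, fmu in [("MDS42", 1.0, 1.0), ("d1", factor_m, factor_mu)]:
            rows.append(
                {
                    "collection": "MDS", "strain": strain,
                    "genome_reduced": 1, "mmr_deficient": int(strain != "MDS42"),
                    "medium": "LB", "growth_rate": 0.6 * fmu,
                    "growth_se": 0.0, "mutation_rate": 1e-9 * fm,
                    "mutation_se": 0.0, "n_replicates": 3,
                }
            )
        return pd.DataFrame(rows)

    def test_identical_to_parent_is_zero(self):
        fc = tradeoff.disturbance_fold_changes(
            self.make_table(1.0, 1.0), {"d1": "MDS42"}
        )
        assert fc["log10_mutation_ratio"].iloc[0] == pytest.approx(0.0)
        assert fc["log10_growth_ratio"].iloc[0] == pytest.approx(0.0)

    def test_hundredfold_is_two_decades(self):
        fc = tradeoff.disturbance_fold_changes(self.make_table(100.0), {"d1": "MDS42"})
        assert fc["log10_mutation_ratio"].iloc[0] == pytest.approx(2.0)

    def test_generated_mutator_signature(self, noiseless_table):
        """Mutators drawn slower-growing than their parent land above it on
        the trade-off line: mutation ratio > 0, growth ratio < 0."""
        panel = synthetic.make_strain_panel({"MDS": 14, "KHK": 10, "MG": 10},
                                            seed=SEED)
        fc = tradeoff.disturbance_fold_changes(
            noiseless_table, synthetic.parent_map(panel)
        )
        lb_mds = fc[(fc["medium"] == "LB") & (fc["parent"] == "MDS42")]
        assert (lb_mds["log10_mutation_ratio"] > 0).all()
        assert (lb_mds["log10_growth_ratio"] < 0).all()

    def test_missing_parent_named(self):
        table = self.make_table().iloc[1:]  # drop the parent row
        with pytest.raises(ConfigurationError, match="MDS42"):
            tradeoff.disturbance_fold_changes(table, {"d1": "MDS42"})
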