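"""JTT model sanity, ML distances, divergence ratios, expansions."""

import itertools
import statistics

import numpy as np
import pandas as pd
import pytest

from locusforge.comparative_evolution import (
    AlignmentError,
    DivergenceRatios,
    ExpansionCriteria,
    detect_expansions,
    divergence_ratios,
    fit_residual_model,
    jtt_model,
    ml_pairwise_distance,
    select_divergent,
)
from locusforge.synthetic_fixtures import simulate_protein_family


class TestSubstitutionModel:
    def test_rate_matrix_invariants(self):
        m = jtt_model()
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-10
        assert m.pi.sum() == pytest.approx(1.0, abs=1e-12)
        flux = m.pi[:, None] * m.Q
        assert np.abs(flux - flux.T).max() < 1e-12  # detailed balance
        # unit expected substitution rate at stationarity
        assert -np.dot(m.pi, np.diag(m.Q)) == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [0.01, 0.3, 2.0, 10.0])
    def test_transition_matrix_stochastic_and_stationary(self, t):
        m = jtt_model()
        P = m.transition_matrix(t)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-8
        assert (P >= -1e-12).all()
        assert np.abs(m.pi @ P - m.pi).max() < 1e-8


class TestMlPairwiseDistance:
    def test_identical_sequences_give_zero(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 5
        assert ml_pairwise_distance(seq, seq).t == pytest.approx(0.0, abs=1e-6)

    def test_distance_is_symmetric(self):
        fam = simulate_protein_family(n_sites=400, seed=3)
        a = fam.sequences["focal0"]
        b = fam.sequences["ant0"]
        assert ml_pairwise_distance(a, b).t == pytest.approx(
            ml_pairwise_distance(b, a).t, abs=1e-6
        )

    def test_too_few_comparable_columns_rejected(self):
        with pytest.raises(AlignmentError):
            ml_pairwise_distance("ACDEF", "ACDEF")

    def test_gap_columns_are_excluded_pairwise(self):
        fam = simulate_protein_family(n_sites=300, seed=5)
        a = fam.sequences["focal0"]
        b = fam.sequences["ant0"]
        gapped = "-" * 50 + a[50:]
        d_full = ml_pairwise_distance(a, b).t
        d_gap = ml_pairwise_distance(gapped, b)
        assert d_gap.n_sites == 250
        assert d_gap.t == pytest.approx(d_full, abs=0.15)

    def test_recovers_simulated_divergence(self):
        # tips at branch length 0.15 each -> true pairwise distance 0.3
        fam = simulate_protein_family(
            n_sites=10_000,
            branch_lengths={"focal": 0.15, "ant": 0.15, "bee": 0.15},
            seed=11,
        )
        d = ml_pairwise_distance(
            fam.sequences["focal0"], fam.sequences["ant0"]
        )
        assert d.t == pytest.approx(0.3, abs=0.05)

    def test_monotone_in_simulated_divergence(self):
        """Mean estimates rank-order exactly with true divergence."""
        times = [0.05, 0.2, 0.5, 0.9, 1.5]
        means = []
        for i, t in enumerate(times):
            ests = []
            for rep in range(3):
                fam = simulate_protein_family(
                    n_sites=2000,
                    branch_lengths={"focal": t / 2, "ant": t / 2, "bee": 0.1},
                    seed=100 + 10 * i + rep,
                )
                ests.append(
                    ml_pairwise_distance(
                        fam.sequences["focal0"], fam.sequences["ant0"]
                    ).t
                )
            means.append(statistics.mean(ests))
        assert means == sorted(means)


class TestDivergenceRatios:
    def test_equal_medians_give_two_thirds(self):
        dr = DivergenceRatios("g", "og", an=0.4, bn=0.4, ab=0.4)
        assert dr.ratio == pytest.approx(2.0 / 3.0)

    def test_zero_focal_divergence_gives_zero(self):
        dr = DivergenceRatios("g", "og", an=0.0, bn=0.0, ab=0.5)
        assert dr.ratio == 0.0

    def test_ratio_decomposes_exactly(self):
        dr = DivergenceRatios("g", "og", an=0.3, bn=0.5, ab=0.2)
        assert dr.ratio == pytest.approx(dr.ratio_ant + dr.ratio_bee)

    def test_toy_group_matches_pair_enumeration_oracle(self):
        fam = simulate_protein_family(
            n_ant=2, n_bee=2, n_focal=1, n_sites=500, seed=21
        )
        result = divergence_ratios(fam.sequences, fam.clades, group="og1")
        assert len(result) == 1
        dr = result[0]
        dist = lambda a, b: ml_pairwise_distance(
            fam.sequences[a], fam.sequences[b]
        ).t
        an = statistics.median([dist("focal0", "ant0"), dist("focal0", "ant1")])
        bn = statistics.median([dist("focal0", "bee0"), dist("focal0", "bee1")])
        ab = statistics.median(
            dist(a, b)
            for a, b in itertools.product(["ant0", "ant1"], ["bee0", "bee1"])
        )
        assert dr.an == pytest.approx(an)
        assert dr.bn == pytest.approx(bn)
        assert dr.ab == pytest.approx(ab)
        assert dr.ratio == pytest.approx((an + bn) / (an + bn + ab))

    def test_group_without_all_clades_is_skipped(self):
        fam = simulate_protein_family(n_ant=1, n_bee=0, n_focal=1, n_sites=300)
        assert divergence_ratios(fam.sequences, fam.clades) == []


class TestResidualModel:
    def test_noise_only_response_has_near_zero_coefficients(self):
        rng = np.random.default_rng(4)
        n = 300
        ratios = pd.Series(
            1 / (1 + np.exp(-rng.normal(0.7, 0.3, n)))
        )
        cov = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        groups = pd.Series([f"og{i}" for i in range(n)])
        fit = fit_residual_model(ratios, cov, groups)
        assert abs(fit.coefficients["x1"]) < 0.1
        assert abs(fit.coefficients["x2"]) < 0.1
        assert fit.residuals.mean() == pytest.approx(0.0, abs=1e-8)

    def test_planted_effect_recovered_within_two_se(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(size=n)
        latent = 0.5 + 0.8 * x + rng.normal(0, 0.4, n)
        ratios = pd.Series(1 / (1 + np.exp(-latent)))
        cov = pd.DataFrame({"x": x})
        groups = pd.Series([f"og{i}" for i in range(n)])
        fit = fit_residual_model(ratios, cov, groups)
        # OLS on the logit scale recovers the planted slope
        se = 0.4 / np.sqrt(n)
        assert abs(fit.coefficients["x"] - 0.8) < 4 * se

    def test_group_effect_removed_when_groups_repeat(self):
        rng = np.random.default_rng(13)
        n_groups, per = 40, 5
        effects = rng.normal(0, 1.0, n_groups)
        rows, labels = [], []
        for g in range(n_groups):
            for _ in range(per):
                rows.append(effects[g] + rng.normal(0, 0.2))
                labels.append(f"og{g}")
        ratios = pd.Series(1 / (1 + np.exp(-np.array(rows))))
        cov = pd.DataFrame({"x": rng.normal(size=len(rows))})
        fit = fit_residual_model(ratios, cov, pd.Series(labels))
        assert fit.group_variance > 0
        # removing group means shrinks residual spread far below raw spread
        raw = np.log(ratios / (1 - ratios))
        assert fit.residuals.std() < 0.5 * raw.std()

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            fit_residual_model(
                pd.Series([0.5] * 30),
                pd.DataFrame({"x": range(30)}),
                pd.Series(["og"] * 30),
            )


class TestSelectDivergent:
    def test_hundred_distinct_residuals_give_five_and_five(self):
        r = pd.Series(np.arange(100.0), index=[f"g{i}" for i in range(100)])
        fast, slow = select_divergent(r, "compound")
        assert len(fast) == 5 and len(slow) == 5
        assert fast == {f"g{i}" for i in range(95, 100)}
        assert slow == {f"g{i}" for i in range(5)}

    def test_intersection_mode_returns_set_intersection(self):
        idx = [f"g{i}" for i in range(100)]
        a = pd.Series(np.arange(100.0), index=idx)
        # second vector agrees on the top 13 of the top 20 only
        b_vals = np.arange(100.0)
        b_vals[80:87] = 0.0  # demote 7 of a's top-20 genes
        b = pd.Series(b_vals, index=idx)
        fast, _ = select_divergent(a, "intersection", residuals_b=b)
        fast_a = set(a.index[a > np.percentile(a, 80)])
        fast_b = set(b.index[b > np.percentile(b, 80)])
        assert fast == fast_a & fast_b
        assert len(fast) == 13

    def test_all_ties_select_nothing(self):
        r = pd.Series(np.zeros(50))
        fast, slow = select_divergent(r, "compound")
        assert fast == set() and slow == set()

    def test_strict_percentile_count_formula(self):
        for n in (20, 21, 40, 99, 100, 101):
            r = pd.Series(np.arange(float(n)))
            fast, slow = select_divergent(r, "compound")
            hi = np.percentile(r, 95)
            assert len(fast) == int((r > hi).sum())
            lo = np.percentile(r, 5)
            assert len(slow) == int((r < lo).sum())

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            select_divergent(pd.Series(np.arange(10.0)), "compound")


def copy_df(rows, species):
    return pd.DataFrame(rows, columns=species, index=[f"og{i}" for i in range(len(rows))])


class TestDetectExpansions:
    SPECIES = ["wasp", "ant1", "ant2", "bee1", "fly", "beetle", "aphid", "daphnia"]
    TAX = {
        "wasp": "focal",
        "ant1": "other_hymenoptera",
        "ant2": "other_hymenoptera",
        "bee1": "other_hymenoptera",
        "fly": "other_arthropod",
        "beetle": "other_arthropod",
        "aphid": "other_arthropod",
        "daphnia": "other_arthropod",
    }

    def test_focal_expansion_detected(self):
        table = copy_df([[4, 1, 1, 1, 1, 1, 1, 1]], self.SPECIES)
        assert detect_expansions(table, self.TAX) == ["og0"]

    def test_duplicate_in_other_hymenopteran_excludes(self):
        table = copy_df([[4, 2, 1, 1, 1, 1, 1, 1]], self.SPECIES)
        assert detect_expansions(table, self.TAX) == []

    def test_insufficient_presence_excludes(self):
        # present in 4/7 other species (57 %) -> below the 80 % bar
        table = copy_df([[4, 1, 1, 1, 1, 0, 0, 0]], self.SPECIES)
        assert detect_expansions(table, self.TAX) == []

    def test_single_focal_copy_is_not_an_expansion(self):
        table = copy_df([[1, 1, 1, 1, 1, 1, 1, 1]], self.SPECIES)
        assert detect_expansions(table, self.TAX) == []

    def test_unknown_species_label_rejected(self):
        table = copy_df([[1, 1, 1, 1, 1, 1, 1, 1]], self.SPECIES)
        with pytest.raises(ValueError):
            detect_expansions(table, {**self.TAX, "fly": "mystery"})

    def test_random_tables_match_rule_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        crit = ExpansionCriteria()
        table = copy_df(
            rng.integers(0, 4, size=(50, len(self.SPECIES))).tolist(),
            self.SPECIES,
        )
        got = set(detect_expansions(table, self.TAX, crit))
        others = [sp for sp in self.SPECIES if self.TAX[sp] != "focal"]
        hyms = [sp for sp in self.SPECIES if self.TAX[sp] == "other_hymenoptera"]
        want = set()
        for og, row in table.iterrows():
            ok = row["wasp"] >= 2
            ok &= sum(row[sp] >= 1 for sp in others) / len(others) > 0.8
            ok &= all(row[sp] <= 1 for sp in hyms)
            if ok:
                want.add(og)
        assert got == want
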