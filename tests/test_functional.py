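import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aktsubtypes import (
    CohortConfig,
    enrich_cohort,
    enrich_sample,
    generate_cohort,
    hypergeom_term_test,
    per_sample_deg,
    subgroup_profile,
    term_prevalence,
)

from conftest import make_matrix


def hypergeom_enumeration_oracle(n_universe, term, gene_list):
    """P[overlap >= observed] by literal enumeration of all draws of
    |gene_list| elements from the universe."""
    universe = list(range(n_universe))
    observed = len(set(gene_list) & set(term))
    hits = total = 0
    for draw in itertools.combinations(universe, len(gene_list)):
        total += 1
        hits += len(set(draw) & set(term)) >= observed
    return hits / total


class TestPerSampleDeg:
    def test_twofold_threshold_inclusive(self):
        # gene medians 5.0; sample s2 at exactly +1 log2 is "up", +0.9 is not
        m = make_matrix([[5.0, 5.0, 6.0], [5.0, 5.0, 5.9]])
        up, down = per_sample_deg(m, "s2")
        assert up == {"g0"}
        assert "g1" not in up and "g1" not in down

    def test_down_direction_symmetric(self):
        m = make_matrix([[5.0, 5.0, 4.0], [5.0, 5.0, 4.1]])
        up, down = per_sample_deg(m, "s2")
        assert down == {"g0"}

    def test_centered_matrix_thresholds_at_plus_minus_one(self):
        m = make_matrix([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0], [0.0, 0.0, 0.99]],
                        centered=True)
        up, down = per_sample_deg(m, "s2")
        assert up == {"g0"} and down == {"g1"}

    def test_unknown_sample_errors(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(KeyError):
            per_sample_deg(m, "nope")


class TestHypergeomTermTest:
    def test_matches_literal_enumeration(self):
        # universe 20, term 5, list 6, overlap 3
        universe = set(range(20))
        term = set(range(5))
        gene_list = {0, 1, 2, 10, 11, 12}
        p = hypergeom_term_test(gene_list, term, universe)
        assert p == pytest.approx(hypergeom_enumeration_oracle(20, term, gene_list))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_small_configs_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        universe = set(range(n))
        term = set(rng.choice(n, size=int(rng.integers(1, n)), replace=False).tolist())
        gene_list = set(rng.choice(n, size=int(rng.integers(0, n)), replace=False).tolist())
        p = hypergeom_term_test(gene_list, term, universe)
        assert p == pytest.approx(hypergeom_enumeration_oracle(n, term, gene_list))

    def test_zero_overlap_gives_p_one(self):
        p = hypergeom_term_test({10, 11}, {0, 1, 2}, set(range(20)))
        assert p == pytest.approx(1.0)

    def test_list_equals_term_gives_minimal_p(self):
        # full overlap of list=term of size n: p = 1 / C(N, n)
        universe = set(range(10))
        term = {0, 1, 2}
        p = hypergeom_term_test(term, term, universe)
        assert p == pytest.approx(1 / math.comb(10, 3))

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_term_test(set(), set(), set())


@pytest.fixture(scope="module")
def planted():
    return generate_cohort(
        CohortConfig(n_samples=45, n_genes=400, seed=17,
                     term_plant={1: "GO:PLANT1"})
    )


class TestEnrichSample:
    def test_planted_term_recovered_in_its_subtype(self, planted):
        enr = enrich_cohort(planted.expression, planted.gene_sets)
        labels = planted.truth_labels
        members = labels.index[labels == 1]
        hit = enr[(enr["term"] == "GO:PLANT1") & (enr["direction"] == "up")
                  & enr["enriched"] & enr["sample"].isin(members)]
        assert hit["sample"].nunique() / len(members) >= 0.8

    def test_no_signal_controls_false_enrichment(self, planted):
        enr = enrich_cohort(planted.expression, planted.gene_sets)
        labels = planted.truth_labels
        outsiders = labels.index[labels != 1]
        null_terms = [t for t in planted.gene_sets if t.startswith("GO:NULL")]
        null_hits = enr[enr["term"].isin(null_terms) & enr["enriched"]
                        & enr["sample"].isin(outsiders)]
        frac = len(null_hits) / max(1, len(outsiders) * len(null_terms) * 2)
        assert frac <= 0.05

    def test_bh_q_is_monotone_step_transform(self, planted):
        enr = enrich_sample(planted.expression, "S0000", planted.gene_sets)
        s = enr.sort_values("p")
        assert (s["q"] >= s["p"] - 1e-12).all()
        assert s["q"].cummax().equals(s["q"])  # nondecreasing along sorted p

    def test_missing_sample_errors(self, planted):
        with pytest.raises(KeyError):
            enrich_sample(planted.expression, "nope", planted.gene_sets)


class TestTermPrevalence:
    def _enr(self, rows):
        return pd.DataFrame(rows, columns=["sample", "term", "direction", "p", "q",
                                           "enriched"])

    def test_prevalence_arithmetic_and_strict_cutoff(self):
        labels = pd.Series({f"s{i}": 1 for i in range(10)})
        rows = [(f"s{i}", "T30", "up", 0.001, 0.01, True) for i in range(3)]
        rows += [(f"s{i}", "T20", "up", 0.001, 0.01, True) for i in range(2)]
        table = term_prevalence(self._enr(rows), labels, min_prevalence=0.20)
        assert set(table["term"]) == {"T30"}  # 30% kept, 20% excluded (strict >)
        assert table.loc[table["term"] == "T30", "prevalence"].iloc[0] == pytest.approx(0.3)

    def test_highlight_at_forty_percent(self):
        labels = pd.Series({f"s{i}": 1 for i in range(10)})
        rows = [(f"s{i}", "T40", "down", 0.001, 0.01, True) for i in range(4)]
        table = term_prevalence(self._enr(rows), labels)
        assert table["highlighted"].iloc[0]

    def test_counts_reproduce_percentages_exactly(self):
        labels = pd.Series({f"s{i}": (1 if i < 7 else 2) for i in range(14)})
        rows = [(f"s{i}", "T", "up", 0.001, 0.01, True) for i in range(5)]
        table = term_prevalence(self._enr(rows), labels)
        row = table.iloc[0]
        assert row["prevalence"] == pytest.approx(row["n_enriched"] / row["n_samples"],
                                                  abs=1e-9)

    def test_planted_term_specific_to_its_subgroup(self):
        """The planted term dominates its own subgroup. Because a shift in a
        third of the cohort drags the per-gene median up, other subgroups can
        show a weak mirrored *down* enrichment; specificity therefore holds
        for the up direction and at the 40% highlight level."""
        cohort = generate_cohort(
            CohortConfig(n_samples=45, n_genes=400, seed=23,
                         term_plant={2: "GO:PLANT2"})
        )
        enr = enrich_cohort(cohort.expression, cohort.gene_sets)
        labels = cohort.truth_labels
        up_hits = enr[(enr["term"] == "GO:PLANT2") & (enr["direction"] == "up")
                      & enr["enriched"]]
        assert set(labels.loc[up_hits["sample"]].unique()) == {2}
        table = term_prevalence(enr, labels)
        planted = table[table["term"] == "GO:PLANT2"].set_index("subgroup")
        assert planted["prevalence"].idxmax() == 2
        assert planted.loc[2, "prevalence"] >= 0.8
        assert set(planted.index[planted["highlighted"]]) == {2}


class TestSubgroupProfile:
    def _analytes(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.normal(size=(3, n)),
            index=["pAKT", "pS6", "other"],
            columns=[f"s{i}" for i in range(n)],
        )
        labels = pd.Series([1] * (n // 2) + [2] * (n - n // 2), index=data.columns)
        return data, labels

    def test_duplicated_analyte_correlates_perfectly(self):
        data, labels = self._analytes()
        data.loc["pS6"] = data.loc["pAKT"]
        _, corr = subgroup_profile(data, labels, pair=("pAKT", "pS6"))
        assert np.allclose(corr["r"], 1.0)

    def test_independent_analytes_uncorrelated(self):
        cover = 0
        for seed in range(20):
            data, labels = self._analytes(n=40, seed=seed)
            _, corr = subgroup_profile(data, labels, pair=("pAKT", "pS6"))
            for _, row in corr.iterrows():
                se = 1 / np.sqrt(row["n"] - 3)
                z = np.arctanh(row["r"])
                cover += abs(z) < 1.96 * se
        assert cover / 40 >= 0.9  # 95% CI covers zero in most subgroups

    def test_coupled_pair_in_one_subgroup_has_highest_r(self):
        rng = np.random.default_rng(7)
        data, labels = self._analytes(n=40, seed=7)
        latent = rng.normal(size=20)
        ids = labels.index[labels == 1]
        data.loc["pAKT", ids] = 0.9 * latent + 0.2 * rng.normal(size=20)
        data.loc["pS6", ids] = 0.9 * latent + 0.2 * rng.normal(size=20)
        _, corr = subgroup_profile(data, labels, pair=("pAKT", "pS6"))
        corr = corr.set_index("subgroup")
        assert corr.loc[1, "r"] == corr["r"].max()
        assert corr.loc[1, "r"] > 0.7

    def test_small_group_correlation_withheld(self):
        data, labels = self._analytes(n=10)
        labels.iloc[:2] = 9  # subgroup of size 2
        _, corr = subgroup_profile(data, labels, pair=("pAKT", "pS6"),
                                   min_group_size=3)
        assert np.isnan(corr.set_index("subgroup").loc[9, "r"])

    def test_group_means_shape(self):
        data, labels = self._analytes()
        means, _ = subgroup_profile(data, labels)
        assert list(means.columns) == [1, 2]
        assert list(means.index) == ["pAKT", "pS6", "other"]
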