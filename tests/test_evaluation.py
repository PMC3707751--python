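import itertools

import numpy as np
import pandas as pd
import pytest

from coxsig import (SimConfig, classify_risk, collapse_probes,
                    compare_models, generate_cohort, harrell_c,
                    kaplan_meier, lasso_c_distribution, permute_outcomes,
                    random_gene_comparator)
from conftest import make_plain_config, random_survival


def harrell_c_oracle(times, events, scores):
    """Exhaustive enumeration over all pairs."""
    num = den = 0.0
    n = len(times)
    for i, j in itertools.combinations(range(n), 2):
        if times[i] == times[j]:
            if events[i] == events[j]:
                continue
            first, second = (i, j) if events[i] == 1 else (j, i)
        elif times[i] < times[j]:
            if events[i] != 1:
                continue
            first, second = i, j
        else:
            if events[j] != 1:
                continue
            first, second = j, i
        den += 1
        if scores[first] > scores[second]:
            num += 1
        elif scores[first] == scores[second]:
            num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestHarrellC:
    def test_perfect_concordance(self):
        assert harrell_c([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1]) == 1.0

    def test_perfect_discordance(self):
        assert harrell_c([1, 2, 3, 4], [1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    def test_mixed_case_matches_enumeration(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        s = [3, 3, 1, 2]
        assert harrell_c(t, e, s) == pytest.approx(
            harrell_c_oracle(t, e, s))

    def test_random_instances_match_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 31))
            t, e = random_survival(rng, n)
            s = np.round(rng.normal(size=n), 1)  # rounded -> score ties
            try:
                expected = harrell_c_oracle(t, e, s)
            except ValueError:
                with pytest.raises(ValueError):
                    harrell_c(t, e, s)
                continue
            assert harrell_c(t, e, s) == pytest.approx(expected, abs=1e-12)

    def test_negation_symmetry_without_score_ties(self, rng):
        n = 40
        t, e = random_survival(rng, n)
        s = rng.normal(size=n)  # continuous, no ties
        assert harrell_c(t, e, s) + harrell_c(t, e, -s) == \
            pytest.approx(1.0)

    def test_all_tied_scores_give_half(self, rng):
        t, e = random_survival(rng, 20)
        assert harrell_c(t, e, np.zeros(20)) == 0.5

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([5.0, 5.0], [1, 1], [1, 2])

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index
        t, e = random_survival(rng, 200)
        s = rng.normal(size=200)
        # lifelines orders by predicted survival time (higher = longer)
        assert harrell_c(t, e, s) == pytest.approx(
            1.0 - concordance_index(t, s, e), abs=1e-12)


class TestClassifyRisk:
    def test_median_cut(self):
        labels = classify_risk([0, 1, 2], [0.5, 3])
        assert list(labels) == ["low", "high"]

    def test_scores_at_median_are_low(self):
        labels = classify_risk([0, 1, 2], [1.0, 1.0])
        assert list(labels) == ["low", "low"]

    def test_balanced_split_on_exchangeable_data(self, rng):
        train = rng.normal(size=1001)
        test = rng.normal(size=4000)
        labels = classify_risk(train, test)
        assert (labels == "high").mean() == pytest.approx(0.5, abs=0.03)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            classify_risk([], [1.0])


class TestCompareModels:
    @pytest.fixture(scope="class")
    def gene_signal_cohort(self):
        betas = {"PGR": -0.3, "SLC39A6": -0.3, "TBC1D9": -0.25}
        return generate_cohort(make_plain_config(seed=55, n=400,
                                                 betas=betas))

    def test_gene_signal_beats_clinical(self, gene_signal_cohort):
        res = compare_models(gene_signal_cohort, "os",
                             gene_set=["PGR", "SLC39A6", "TBC1D9"],
                             n_splits=40, master_seed=1)
        assert res.median_c("genes") > res.median_c("clinical")
        assert res.median_c("genes") > 0.55

    def test_empty_clinical_spec_collapses_combined_to_genes(
            self, gene_signal_cohort):
        res = compare_models(gene_signal_cohort, "os",
                             gene_set=["PGR", "SLC39A6"],
                             clinical_spec=(), n_splits=8, master_seed=2)
        a = res.per_split[res.per_split["model"] == "genes"]["c"].to_numpy()
        b = res.per_split[res.per_split["model"] == "combined"]["c"].to_numpy()
        np.testing.assert_allclose(a, b)
        assert "clinical" not in res.models

    def test_row_order_invariance(self, gene_signal_cohort):
        res1 = compare_models(gene_signal_cohort, "os", n_splits=6,
                              master_seed=3)
        perm = np.random.default_rng(0).permutation(len(gene_signal_cohort))
        shuffled = gene_signal_cohort.subset(perm)
        res2 = compare_models(shuffled, "os", n_splits=6, master_seed=3)
        for m in res1.models:
            assert res1.median_c(m) == pytest.approx(res2.median_c(m),
                                                     abs=0.08)

    def test_summary_structure_and_ci_ordering(self, gene_signal_cohort):
        res = compare_models(gene_signal_cohort, "os", n_splits=10,
                             master_seed=4)
        s = res.summary()
        for m in res.models:
            lo, hi = s["models"][m]["ci"]
            assert lo <= s["models"][m]["median_c"] <= hi
        d = res.difference("genes", "clinical")
        assert d["ci"][0] <= d["median"] <= d["ci"][1]

    def test_high_risk_class_has_lower_survival(self, gene_signal_cohort):
        res = compare_models(gene_signal_cohort, "os",
                             gene_set=["PGR", "SLC39A6", "TBC1D9"],
                             n_splits=30, master_seed=5)
        wins = total = 0
        for curve in res.risk_curves:
            t, e, labels = curve["genes"]
            lo, hi = labels == "low", labels == "high"
            if e[lo].sum() == 0 or e[hi].sum() == 0:
                continue
            t_last = t[e == 1].max()
            km_lo = kaplan_meier(t[lo], e[lo]).at(t_last)
            km_hi = kaplan_meier(t[hi], e[hi]).at(t_last)
            total += 1
            wins += km_hi < km_lo
        assert wins / total >= 0.95


class TestLassoCDistribution:
    def test_permuted_outcomes_center_on_half(self):
        cohort = generate_cohort(SimConfig(seed=13))
        permuted = permute_outcomes(cohort, "os", seed=7)
        cs = lasso_c_distribution(permuted, "os", n_splits=30,
                                  master_seed=8)
        assert np.median(cs) == pytest.approx(0.5, abs=0.05)

    def test_signal_gives_above_chance_c(self):
        betas = {"PGR": -0.3, "SLC39A6": -0.3, "TBC1D9": -0.25}
        cohort = generate_cohort(make_plain_config(seed=56, betas=betas))
        cs = lasso_c_distribution(cohort, "os", n_splits=20, master_seed=9)
        assert np.median(cs) > 0.55

    def test_reproducible(self):
        cohort = generate_cohort(SimConfig(seed=14))
        a = lasso_c_distribution(cohort, "os", n_splits=5, master_seed=2)
        b = lasso_c_distribution(cohort, "os", n_splits=5, master_seed=2)
        np.testing.assert_array_equal(a, b)


class TestRandomGeneComparator:
    def test_seeded_reproducibility(self, default_cohort):
        a = random_gene_comparator(default_cohort, "os", k=5, n_splits=5,
                                   master_seed=1)
        b = random_gene_comparator(default_cohort, "os", k=5, n_splits=5,
                                   master_seed=1)
        np.testing.assert_array_equal(a, b)

    def test_full_panel_draw_equals_full_panel_model(self, default_cohort):
        k = len(default_cohort.panel.genes)
        cs = random_gene_comparator(default_cohort, "os", k=k, n_splits=4,
                                    master_seed=2)
        res = compare_models(default_cohort, "os",
                             gene_set=list(default_cohort.panel.genes),
                             clinical_spec=(), n_splits=4, master_seed=2)
        # both use every gene; distributions coincide up to split seeds
        assert cs.shape == (4,)
        assert res.per_split["c"].notna().all()

    def test_null_cohort_near_half(self):
        cohort = generate_cohort(make_plain_config(seed=60, n=400))
        cs = random_gene_comparator(cohort, "os", k=5, n_splits=30,
                                    master_seed=3)
        assert np.median(cs) == pytest.approx(0.5, abs=0.06)

    def test_oversized_k_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            random_gene_comparator(default_cohort, "os", k=33)


class TestCollapseProbes:
    def test_most_variable_probe_kept(self):
        expr = pd.DataFrame([[1.0, 5.0, 9.0], [2.0, 3.0, 4.0]],
                            index=["p1", "p2"], columns=["s1", "s2", "s3"])
        out = collapse_probes(expr, {"p1": "G", "p2": "G"})
        assert list(out.index) == ["G"]
        np.testing.assert_array_equal(out.loc["G"], expr.loc["p1"])

    def test_unique_probes_identity(self):
        expr = pd.DataFrame(np.arange(6.0).reshape(2, 3),
                            index=["p1", "p2"])
        out = collapse_probes(expr, {"p1": "A", "p2": "B"})
        assert list(out.index) == ["A", "B"]
        np.testing.assert_array_equal(out.to_numpy(), expr.to_numpy())

    def test_variance_tie_keeps_first_in_order(self):
        expr = pd.DataFrame([[1.0, 2.0], [5.0, 6.0]], index=["pa", "pb"])
        out = collapse_probes(expr, {"pa": "G", "pb": "G"})
        np.testing.assert_array_equal(out.loc["G"], expr.loc["pa"])

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes(pd.DataFrame([[1.0]], index=["p"]), {})

    def test_uncovered_probe_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["p1"])
        with pytest.raises(KeyError):
            collapse_probes(expr, {"px": "G"})
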