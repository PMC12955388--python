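import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from famshare.cohort import DistanceMatrix, FamilyCohort
from famshare.quantify import (
    bray_curtis,
    child_parent_trend,
    diversity_similarity_trend,
    rpkm,
    shannon,
    shannon_table,
    within_between_test,
)
from conftest import make_sample


class TestRpkm:
    def test_zero_count(self):
        m = pd.DataFrame([[0, 100]], index=["s1"], columns=["a", "b"])
        out = rpkm(m, {"a": 1000, "b": 1000}, {"s1": 1_000_000})
        assert out.loc["s1", "a"] == 0.0

    def test_hand_arithmetic(self):
        # 1000 / ((2e6/1000) * (1e7/1e6)) = 1000/(2000*10) = 0.05
        m = pd.DataFrame([[1000]], index=["s1"], columns=["a"])
        out = rpkm(m, {"a": 2_000_000}, {"s1": 10_000_000})
        assert out.loc["s1", "a"] == pytest.approx(0.05)

    def test_scale_invariance(self):
        m = pd.DataFrame([[10, 20]], index=["s1"], columns=["a", "b"])
        one = rpkm(m, {"a": 5000, "b": 8000}, {"s1": 1000})
        two = rpkm(2 * m, {"a": 5000, "b": 8000}, {"s1": 2000})
        assert np.allclose(one.to_numpy(), two.to_numpy())

    def test_zero_total_names_sample(self):
        m = pd.DataFrame([[0]], index=["bad_sample"], columns=["a"])
        with pytest.raises(ValueError, match="bad_sample"):
            rpkm(m, {"a": 1000})


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon(np.array([5.0, 0.0, 0.0])).shannon == 0.0

    def test_uniform_closed_form(self):
        assert shannon(np.ones(4)).shannon == pytest.approx(np.log(4), abs=1e-12)

    def test_direct_formula(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.039721
        r = shannon(np.array([0.5, 0.25, 0.25]))
        assert r.shannon == pytest.approx(1.039721, abs=1e-6)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon(np.zeros(3))

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=10))
    @settings(max_examples=100)
    def test_uniform_is_maximal(self, values):
        k = len(values)
        h = shannon(np.array(values)).shannon
        assert h <= np.log(k) + 1e-9
        near_uniform = abs(h - np.log(k)) < 1e-12
        all_equal = len(set(values)) == 1
        if all_equal:
            assert near_uniform


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2], [1, 2]], index=["a", "b"])
        assert bray_curtis(m).get("a", "b") == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[1, 0], [0, 3]], index=["a", "b"])
        assert bray_curtis(m).get("a", "b") == 1.0

    def test_hand_arithmetic(self):
        # (|6-2| + |2-2|) / (8 + 4) = 4/12 = 1/3
        m = pd.DataFrame([[6, 2], [2, 2]], index=["a", "b"])
        assert bray_curtis(m).get("a", "b") == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_row_pair_errors(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="a.*b"):
            bray_curtis(m)

    @given(
        st.integers(2, 6).flatmap(
            lambda n: st.lists(
                st.lists(st.floats(0.01, 50), min_size=3, max_size=3),
                min_size=n, max_size=n,
            )
        )
    )
    @settings(max_examples=50)
    def test_invariants_hold(self, rows):
        m = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        d = bray_curtis(m)
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


class TestWithinBetween:
    def test_pair_enumeration(self):
        cohort = FamilyCohort(
            [make_sample("s1", "F1"), make_sample("s2", "F1"),
             make_sample("s3", "F2")]
        )
        d = DistanceMatrix(["s1", "s2", "s3"],
                           [[0, .1, .5], [.1, 0, .6], [.5, .6, 0]])
        within, between, _ = within_between_test(d, cohort)
        assert list(within) == [0.1]
        assert sorted(between) == [0.5, 0.6]

    def test_identical_distributions_p_one(self):
        cohort = FamilyCohort(
            [make_sample("s1", "F1"), make_sample("s2", "F1"),
             make_sample("s3", "F2"), make_sample("s4", "F2")]
        )
        d = DistanceMatrix(
            ["s1", "s2", "s3", "s4"],
            0.3 * (np.ones((4, 4)) - np.eye(4)),
        )
        _, _, p = within_between_test(d, cohort)
        assert p == 1.0

    def test_pair_counts_sum(self, family_cohort):
        rng = np.random.default_rng(0)
        n = len(family_cohort)
        x = rng.uniform(0.1, 1, size=(n, n))
        d = np.triu(x, 1) + np.triu(x, 1).T
        dm = DistanceMatrix(family_cohort.sample_ids, d)
        within, between, _ = within_between_test(dm, family_cohort)
        assert len(within) + len(between) == n * (n - 1) // 2

    def test_no_within_pair_errors(self):
        cohort = FamilyCohort([make_sample("s1", "F1"), make_sample("s2", "F2")])
        d = DistanceMatrix(["s1", "s2"], [[0, .5], [.5, 0]])
        with pytest.raises(ValueError, match="within-family"):
            within_between_test(d, cohort)

    def test_planted_family_effect_direction(self, default_cohort):
        from famshare.quantify import bray_curtis

        bc = bray_curtis(default_cohort.abundance)
        within, between, p = within_between_test(bc, default_cohort.cohort)
        assert np.median(within) < np.median(between)
        assert p < 0.05


def _trio_cohort(ages):
    samples = []
    for i, age in enumerate(ages):
        fam = f"F{i}"
        samples += [
            make_sample(f"p{i}", fam, "father", age=40),
            make_sample(f"c{i}", fam, "child", age=age),
        ]
    return FamilyCohort(samples)


def _dist_for(cohort, child_parent):
    labels = cohort.sample_ids
    n = len(labels)
    d = np.full((n, n), 0.5)
    np.fill_diagonal(d, 0)
    for (a, b), v in child_parent.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d)


class TestChildParentTrend:
    def test_monotone_rho_one(self):
        cohort = _trio_cohort([2, 5, 9])
        d = _dist_for(cohort, {("c0", "p0"): .2, ("c1", "p1"): .5,
                               ("c2", "p2"): .9})
        assert child_parent_trend(d, cohort).spearman_rho == pytest.approx(1.0)

    def test_constant_distances_rho_zero(self):
        cohort = _trio_cohort([2, 5, 9])
        d = _dist_for(cohort, {("c0", "p0"): .4, ("c1", "p1"): .4,
                               ("c2", "p2"): .4})
        t = child_parent_trend(d, cohort)
        assert t.spearman_rho == 0.0
        assert t.p_value == 1.0

    def test_rank_formula_hand_value(self):
        # ages (1,2,3,4), distances (0.4,0.1,0.3,0.2) -> rho = -0.4
        cohort = _trio_cohort([1, 2, 3, 4])
        d = _dist_for(cohort, {("c0", "p0"): .4, ("c1", "p1"): .1,
                               ("c2", "p2"): .3, ("c3", "p3"): .2})
        t = child_parent_trend(d, cohort)
        assert t.spearman_rho == pytest.approx(-0.4, abs=1e-12)
        assert t.n_pairs == 4

    def test_too_few_pairs(self):
        cohort = _trio_cohort([2, 5])
        d = _dist_for(cohort, {("c0", "p0"): .2, ("c1", "p1"): .5})
        with pytest.raises(ValueError, match=">=3"):
            child_parent_trend(d, cohort)


class TestDiversitySimilarityTrend:
    def _cohort3(self):
        samples = []
        for i in range(3):
            samples += [make_sample(f"a{i}", f"F{i}"), make_sample(f"b{i}", f"F{i}")]
        return FamilyCohort(samples)

    def _inputs(self, shannons, dists):
        cohort = self._cohort3()
        div = pd.DataFrame(
            {"sample_id": cohort.sample_ids,
             "shannon": [h for pair in shannons for h in pair]}
        )
        d = _dist_for(cohort, {(f"a{i}", f"b{i}"): v for i, v in enumerate(dists)})
        return d, div, cohort

    def test_opposed_monotone_rho_minus_one(self):
        d, div, cohort = self._inputs([(1, 1), (2, 2), (3, 3)], [.9, .5, .1])
        assert diversity_similarity_trend(d, div, cohort).spearman_rho == -1.0

    def test_order_invariance(self):
        d, div, cohort = self._inputs([(1, 2), (3, 1), (2, 3)], [.3, .8, .5])
        rho1 = diversity_similarity_trend(d, div, cohort).spearman_rho
        shuffled = FamilyCohort(list(reversed(cohort.samples)))
        rho2 = diversity_similarity_trend(d, div, shuffled).spearman_rho
        assert rho1 == pytest.approx(rho2)

    def test_coupled_simulation_negative_rho(self):
        # diversity-coupled sharing: rho < 0 in >= 90% of replicates
        from famshare.quantify import bray_curtis
        from famshare.simulate import SimulationConfig, generate_cohort

        neg = 0
        n_reps = 20
        for seed in range(n_reps):
            cfg = SimulationConfig(
                n_families=10, members_per_family=2, n_species=6,
                genome_length=900, family_effect_size=0.3,
                diversity_coupling=0.95, seed=seed,
            )
            c = generate_cohort(cfg)
            bc = bray_curtis(c.abundance)
            t = diversity_similarity_trend(
                bc, shannon_table(c.abundance), c.cohort
            )
            if t.spearman_rho < 0:
                neg += 1
        assert neg >= 0.9 * n_reps
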