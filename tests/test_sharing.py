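import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from famshare.ani import AniParams
from famshare.cohort import DistanceMatrix, FamilyCohort, SNVProfile, SNVSite
from famshare.sharing import (
    CandidatePopulation,
    analyze_population,
    classical_mds,
    count_sharing,
    family_association,
    genetic_composition_distance,
    select_candidates,
)
from conftest import make_genome, make_sample


def cohort_of(n_families, members=2):
    samples = []
    for f in range(n_families):
        for m in range(members):
            samples.append(make_sample(f"s{f}_{m}", f"F{f}"))
    return FamilyCohort(samples)


def genomes_for(cohort, species, sample_ids, seqlen=0):
    return [
        make_genome(f"{sid}.{species}", sample_id=sid, species=species)
        for sid in sample_ids
    ]


class TestSelectCandidates:
    def test_boundary_inclusive_30_percent(self):
        cohort = cohort_of(10)
        sids = [f"s{f}_{m}" for f in range(3) for m in range(2)]
        pops = select_candidates(genomes_for(cohort, "sp1", sids), cohort)
        assert len(pops) == 1
        assert pops[0].families_with_pairs == ["F0", "F1", "F2"]

    def test_one_member_per_family_excluded(self):
        cohort = cohort_of(10)
        sids = [f"s{f}_0" for f in range(10)]
        assert select_candidates(genomes_for(cohort, "sp1", sids), cohort) == []

    def test_two_of_ten_families_excluded(self):
        cohort = cohort_of(10)
        sids = [f"s{f}_{m}" for f in range(2) for m in range(2)]
        assert select_candidates(genomes_for(cohort, "sp1", sids), cohort) == []

    def test_duplicate_sample_genomes_best_kept(self):
        cohort = cohort_of(2)
        genomes = genomes_for(
            cohort, "sp1", ["s0_0", "s0_1", "s1_0", "s1_1"]
        )
        extra = make_genome("dup", sample_id="s0_0", species="sp1",
                            completeness=99, contamination=0)
        (pop,) = select_candidates(genomes + [extra], cohort, min_family_frac=0.5)
        ids = [g.genome_id for g in pop.genomes]
        assert "dup" in ids and "s0_0.sp1" not in ids


class TestFamilyAssociation:
    def test_planted_transmissions_flagged(self, planted_cohort):
        c = planted_cohort
        pops = select_candidates(c.genomes, c.cohort)
        params = AniParams(fragment_len=500)
        flagged = set()
        for pop in pops:
            stats = family_association(pop, c.cohort, params, n_perm=199, seed=0)
            if stats.shared_flag:
                flagged.add(pop.species_label)
        assert flagged == c.truth.shared_species == {"sp1"}

    def test_single_family_population_rejected(self):
        cohort = cohort_of(2)
        pop = CandidatePopulation(
            "sp1", genomes_for(cohort, "sp1", ["s0_0", "s0_1"]), ["F0"]
        )
        with pytest.raises(ValueError, match="between-family"):
            family_association(pop, cohort)

    def test_equidistant_matrix_not_flagged(self):
        # all pairwise distances equal: F = 1 for every labelling, p = 1
        cohort = cohort_of(3)
        sids = [f"s{f}_{m}" for f in range(3) for m in range(2)]
        pop = CandidatePopulation("sp1", genomes_for(cohort, "sp1", sids),
                                  ["F0", "F1", "F2"])
        n = 6
        d = 0.02 * (np.ones((n, n)) - np.eye(n))
        dist = DistanceMatrix([g.genome_id for g in pop.genomes], d)
        stats = family_association(pop, cohort, dist=dist, n_perm=199, seed=0)
        assert not stats.shared_flag
        assert stats.p_value > 0.9

    def test_shuffled_labels_rarely_flagged(self, planted_cohort):
        # null: permute which family each genome claims; joint threshold
        # (R2>0.5 AND p<0.05) should fire in <=10% of replicates
        c = planted_cohort
        (pop,) = [
            p for p in select_candidates(c.genomes, c.cohort)
            if p.species_label == "sp1"
        ]
        from famshare.sharing import population_distance_matrix

        dist = population_distance_matrix(pop, AniParams(fragment_len=500))
        rng = np.random.default_rng(0)
        fam = {s.sample_id: s.family_id for s in c.cohort.samples}
        families = [fam[g.sample_id] for g in pop.genomes]
        hits = 0
        n_rep = 50
        from famshare.permanova import permanova_single

        for _ in range(n_rep):
            shuffled = list(rng.permutation(families))
            res = permanova_single(dist, shuffled, n_perm=99,
                                   seed=int(rng.integers(1 << 31)))
            if res.r_squared > 0.5 and res.p_value < 0.05:
                hits += 1
        assert hits <= 0.10 * n_rep


class TestCountSharing:
    def _make(self, cohort, sids, ani_by_pair, species="sp1"):
        pop = CandidatePopulation(species, genomes_for(cohort, species, sids),
                                  [])
        labels = [g.genome_id for g in pop.genomes]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                key = (sids[i], sids[j])
                ani = ani_by_pair.get(key, ani_by_pair.get(key[::-1], 90.0))
                d[i, j] = d[j, i] = 1 - ani / 100
        return pop, DistanceMatrix(labels, d)

    def test_three_member_family_all_pairs(self):
        cohort = cohort_of(1, members=3)
        sids = ["s0_0", "s0_1", "s0_2"]
        pop, dist = self._make(
            cohort, sids,
            {(a, b): 99.9 for a in sids for b in sids if a < b},
        )
        stats = count_sharing(pop, cohort, dist)
        assert stats.sharing_times == 3
        assert stats.family_prevalence == 1

    def test_no_pair_reaches_threshold(self):
        cohort = cohort_of(2)
        sids = ["s0_0", "s0_1", "s1_0", "s1_1"]
        pop, dist = self._make(cohort, sids, {})
        stats = count_sharing(pop, cohort, dist)
        assert (stats.sharing_times, stats.family_prevalence) == (0, 0)

    def test_two_families_one_pair_each(self):
        cohort = cohort_of(2)
        sids = ["s0_0", "s0_1", "s1_0", "s1_1"]
        pop, dist = self._make(
            cohort, sids,
            {("s0_0", "s0_1"): 99.8, ("s1_0", "s1_1"): 99.6},
        )
        stats = count_sharing(pop, cohort, dist)
        assert (stats.sharing_times, stats.family_prevalence) == (2, 2)

    def test_invariants_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cohort = cohort_of(3, members=3)
            sids = [f"s{f}_{m}" for f in range(3) for m in range(3)]
            pairs = {
                (a, b): float(rng.uniform(95, 100))
                for i, a in enumerate(sids) for b in sids[i + 1:]
            }
            pop, dist = self._make(cohort, sids, pairs)
            stats = count_sharing(pop, cohort, dist)
            assert stats.family_prevalence <= stats.sharing_times
            assert stats.sharing_times <= 3 * 3  # 3 families x C(3,2)


class TestClassicalMds:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(["a", "b", "c"], d)
        coords = classical_mds(dm, k=2)
        rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_planar_recovery(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"p{i}" for i in range(10)], d)
        coords = classical_mds(dm, k=2)
        rec = squareform(pdist(coords.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_duplicate_points_coincide(self):
        pts = np.array([[0, 0], [0, 0], [3, 4], [6, 0]], float)
        d = squareform(pdist(pts))
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        coords = classical_mds(dm, k=2)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_fewer_axes_with_warning(self):
        # 3 collinear points have one positive eigenvalue
        pts = np.array([[0.0], [1.0], [2.0]])
        dm = DistanceMatrix(["a", "b", "c"], squareform(pdist(pts)))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords = classical_mds(dm, k=2)
        assert coords.shape[1] == 1

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        dm = DistanceMatrix([f"p{i}" for i in range(6)],
                            squareform(pdist(pts)))
        c1 = classical_mds(dm, k=2)
        c2 = classical_mds(dm, k=2)
        assert c1.equals(c2)
        for ax in c1.columns:
            assert c1[ax].abs().max() == c1[ax].max()


def _site(contig, pos, ref, counts):
    return SNVSite(contig, pos, ref, counts)


class TestGeneticCompositionDistance:
    def _genomes(self):
        return [
            make_genome("gA", sample_id="sA", species="sp1"),
            make_genome("gB", sample_id="sB", species="sp1"),
        ]

    def test_identical_profiles_zero(self):
        profiles = [
            SNVProfile("gA", [_site("sp1", 5, "A", {"A": 5, "C": 5})]),
            SNVProfile("gB", [_site("sp1", 5, "A", {"A": 5, "C": 5})]),
        ]
        d = genetic_composition_distance(profiles, self._genomes())
        assert d.get("sA", "sB") == 0.0

    def test_disjoint_species_distance_one(self):
        genomes = [
            make_genome("gA", sample_id="sA", species="sp1"),
            make_genome("gB", sample_id="sB", species="sp2"),
        ]
        profiles = [
            SNVProfile("gA", [_site("sp1", 5, "A", {"A": 5, "C": 5})]),
            SNVProfile("gB", [_site("sp2", 9, "G", {"G": 5, "T": 5})]),
        ]
        d = genetic_composition_distance(profiles, genomes)
        assert d.get("sA", "sB") == 1.0

    def test_hand_arithmetic(self):
        # sample A: site1 monomorphic (major 1.0), site2 major 0.5
        # sample B: both sites major 0.5 -> d = 0.5 / 2.5 = 0.2
        profiles = [
            SNVProfile("gA", [_site("sp1", 20, "A", {"A": 5, "G": 5})]),
            SNVProfile("gB", [
                _site("sp1", 10, "C", {"C": 5, "T": 5}),
                _site("sp1", 20, "A", {"A": 5, "G": 5}),
            ]),
        ]
        d = genetic_composition_distance(profiles, self._genomes())
        assert d.get("sA", "sB") == pytest.approx(0.2, abs=1e-12)

    def test_missing_sample_errors_when_cohort_given(self):
        cohort = FamilyCohort(
            [make_sample("sA", "F1"), make_sample("sB", "F1"),
             make_sample("sC", "F2")]
        )
        profiles = [
            SNVProfile("gA", [_site("sp1", 5, "A", {"A": 5, "C": 5})]),
            SNVProfile("gB", [_site("sp1", 5, "A", {"A": 5, "C": 5})]),
        ]
        with pytest.raises(ValueError, match="sC"):
            genetic_composition_distance(profiles, self._genomes(), cohort)


class TestEndToEndRecovery:
    def test_flagged_set_equals_planted_set(self, planted_cohort):
        c = planted_cohort
        pops = select_candidates(c.genomes, c.cohort)
        assert {p.species_label for p in pops} == {"sp1", "sp2"}
        params = AniParams(fragment_len=500)
        flagged = set()
        for pop in pops:
            stats, dist = analyze_population(
                pop, c.cohort, params, n_perm=199, seed=1
            )
            if stats.shared_flag:
                flagged.add(pop.species_label)
                assert stats.sharing_times >= len(c.cohort.families)
                assert stats.family_prevalence == len(c.cohort.families)
        assert flagged == c.truth.shared_species
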