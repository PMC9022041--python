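"""Nearest-selected-site affiliation: geometry rules, expectations, chi-square."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from paraclust import (
    AffiliationTable,
    SiteSet,
    affiliation_chi_square,
    build_instances,
    expected_affiliations,
    nearest_affiliations,
    neighbor_test,
)
from paraclust.io_mapping import ResidueCoordinate, StructureModel
from paraclust.neighbor_affiliation import SiteInstance


def chain_structure(n, spacing=3.8):
    return StructureModel(
        "A",
        tuple(
            ResidueCoordinate(i + 1, "GLY", i * spacing, 0.0, 0.0)
            for i in range(n)
        ),
    )


def brute_force_affiliations(instances):
    """Independent all-pairs oracle applying the twin and shared rules."""
    out = {"A_same": 0, "A_other": 0, "B_same": 0, "B_other": 0}
    for i, inst in enumerate(instances):
        candidates = []
        for j, other in enumerate(instances):
            if j == i:
                continue
            if (inst.shared and other.shared
                    and inst.residue_index == other.residue_index
                    and inst.paralog != other.paralog):
                continue
            d = float(np.linalg.norm(inst.coord - other.coord))
            candidates.append((d, other.residue_index,
                               {"A": 0, "B": 1}[other.paralog], other))
        best = min(candidates)[3]
        same = best.paralog == inst.paralog or best.shared
        out[f"{inst.paralog}_{'same' if same else 'other'}"] += 1
    return (out["A_same"], out["A_other"], out["B_same"], out["B_other"])


class TestBuildInstances:
    def test_shared_column_contributes_two_instances(self):
        structure = chain_structure(10)
        mapping = {c: c for c in range(1, 11)}
        inst = build_instances(
            SiteSet("A", frozenset({1, 2})), SiteSet("B", frozenset({2})),
            mapping, structure,
        )
        assert len(inst) == 3
        shared = [i for i in inst if i.shared]
        assert len(shared) == 2
        assert {i.paralog for i in shared} == {"A", "B"}
        assert shared[0].coordinate == shared[1].coordinate

    def test_unshared_sites(self):
        structure = chain_structure(10)
        mapping = {c: c for c in range(1, 11)}
        inst = build_instances(
            SiteSet("A", frozenset({1})), SiteSet("B", frozenset({9})),
            mapping, structure,
        )
        assert len(inst) == 2
        assert not any(i.shared for i in inst)

    def test_unmapped_columns_dropped_with_log(self, caplog):
        structure = chain_structure(5)
        mapping = {1: 1, 2: 2}
        with caplog.at_level("WARNING"):
            inst = build_instances(
                SiteSet("A", frozenset({1, 7})), SiteSet("B", frozenset({2})),
                mapping, structure,
            )
        assert len(inst) == 2
        assert "dropped 1" in caplog.text

    def test_all_unmapped_errors(self):
        structure = chain_structure(5)
        with pytest.raises(ValueError, match="no selected column"):
            build_instances(SiteSet("A", frozenset({9})),
                            SiteSet("B", frozenset({8})), {}, structure)


class TestNearestAffiliations:
    def test_segregated_blocks_all_same(self):
        structure = chain_structure(10)
        mapping = {c: c for c in range(1, 11)}
        inst = build_instances(
            SiteSet("A", frozenset({1, 2})), SiteSet("B", frozenset({9, 10})),
            mapping, structure,
        )
        assert nearest_affiliations(inst) == (2, 0, 2, 0)

    def test_alternating_all_other(self):
        inst = [
            SiteInstance("A" if i % 2 == 0 else "B", i + 1,
                         (float(i), 0.0, 0.0))
            for i in range(4)
        ]
        assert nearest_affiliations(inst) == (0, 2, 0, 2)

    def test_shared_neighbor_counts_as_same_for_either_paralog(self):
        # B site whose nearest neighbor is a shared site: counted B->same
        structure = chain_structure(10)
        mapping = {c: c for c in range(1, 11)}
        inst = build_instances(
            SiteSet("A", frozenset({1, 5})), SiteSet("B", frozenset({5, 6})),
            mapping, structure,
        )
        a_same, a_other, b_same, b_other = nearest_affiliations(inst)
        assert b_same == 2 and b_other == 0

    def test_twin_not_eligible_as_own_neighbor(self):
        structure = chain_structure(3)
        mapping = {c: c for c in range(1, 4)}
        inst = build_instances(
            SiteSet("A", frozenset({2})), SiteSet("B", frozenset({2, 3})),
            mapping, structure,
        )
        # the shared A@2 instance must pick residue 3 (B), not its twin B@2;
        # neighbor is plain B -> "other" for the A instance
        assert nearest_affiliations(inst)[1] == 1

    def test_requires_both_paralogs(self):
        inst = [SiteInstance("A", 1, (0.0, 0.0, 0.0)),
                SiteInstance("A", 2, (1.0, 0.0, 0.0))]
        with pytest.raises(ValueError, match="both paralogs"):
            nearest_affiliations(inst)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            pts = rng.normal(scale=8, size=(n, 3))
            labels = rng.choice(["A", "B"], size=n)
            if len(set(labels)) < 2:
                labels[0], labels[1] = "A", "B"
            inst = [SiteInstance(str(l), i + 1, tuple(pts[i]))
                    for i, l in enumerate(labels)]
            if rng.random() < 0.5:  # add one shared pair
                inst.append(SiteInstance("A", n + 1, tuple(pts[0] + 1.0), True))
                inst.append(SiteInstance("B", n + 1, tuple(pts[0] + 1.0), True))
            assert nearest_affiliations(inst) == brute_force_affiliations(inst)

    def test_rigid_transform_preserves_counts(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(scale=10, size=(12, 3))
        labels = ["A"] * 7 + ["B"] * 5
        inst = [SiteInstance(l, i + 1, tuple(pts[i]))
                for i, l in enumerate(labels)]
        rot = Rotation.from_rotvec([1.0, -0.4, 0.2]).as_matrix()
        moved = [
            SiteInstance(l, i + 1, tuple(rot @ pts[i] + np.array([5, -3, 2])))
            for i, l in enumerate(labels)
        ]
        assert nearest_affiliations(inst) == nearest_affiliations(moved)


class TestExpectedAndChiSquare:
    def test_small_symmetric_example(self):
        assert expected_affiliations(2, 2) == pytest.approx(
            (2 / 3, 4 / 3, 2 / 3, 4 / 3)
        )

    def test_study_sized_proportions(self):
        ea = expected_affiliations(62, 30)
        assert ea[0] / 62 == pytest.approx(61 / 91)
        assert ea[1] / 62 == pytest.approx(30 / 91)
        assert ea[0] + ea[1] == pytest.approx(62)
        assert ea[2] + ea[3] == pytest.approx(30)

    def test_degenerate_counts_error(self):
        with pytest.raises(ValueError):
            expected_affiliations(3, 0)
        with pytest.raises(ValueError):
            expected_affiliations(1, 1)

    def test_chi_square_df3_closed_form(self):
        table = AffiliationTable(
            observed=(4, 0, 4, 0),
            expected=(8 / 3, 4 / 3, 8 / 3, 4 / 3),
        )
        chi2, p = affiliation_chi_square(table)
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 3), abs=1e-12)
        assert p == pytest.approx(0.2615, abs=5e-4)

    def test_observed_equal_expected_gives_p_one(self):
        table = AffiliationTable(observed=(4, 2, 2, 4),
                                 expected=(4.0, 2.0, 2.0, 4.0))
        chi2, p = affiliation_chi_square(table)
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_independent_cell_summation(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n_a, n_b = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            oa = int(rng.integers(0, n_a + 1))
            ob = int(rng.integers(0, n_b + 1))
            obs = (oa, n_a - oa, ob, n_b - ob)
            exp = expected_affiliations(n_a, n_b)
            chi2, p = affiliation_chi_square(
                AffiliationTable(observed=obs, expected=exp)
            )
            ref = stats.chisquare(obs, exp)  # k-1 = 3 df
            assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_totals_preserved_in_table(self):
        with pytest.raises(ValueError, match="totals"):
            AffiliationTable(observed=(3, 1, 2, 2),
                             expected=(2.0, 1.0, 2.0, 2.0))


class TestNullBehavior:
    def test_permuted_label_level_recorded_not_anticonservative(self):
        """Labels shuffled over fixed positions, no shared sites: the 3-df
        chi-square reference is conservative here (measured level ~0.04)."""
        rng = np.random.default_rng(21)
        pos = rng.normal(scale=10, size=(40, 3))
        n_a, n_b = 26, 14
        rej, n_sim = 0, 300
        for _ in range(n_sim):
            labels = np.array(["A"] * n_a + ["B"] * n_b)
            rng.shuffle(labels)
            inst = [SiteInstance(str(l), i + 1, tuple(pos[i]))
                    for i, l in enumerate(labels)]
            res = neighbor_test(inst)
            rej += res.p_value <= 0.05
        rate = rej / n_sim
        assert rate <= 0.10, f"anticonservative under label permutation: {rate}"

    def test_permutation_null_calibrated(self):
        """The permutation variant attains its nominal level."""
        rej, n_sim = 0, 100
        for k in range(n_sim):
            rng = np.random.default_rng(5_000 + k)
            pts = rng.normal(scale=10, size=(14, 3))
            labels = np.array(["A"] * 8 + ["B"] * 6)
            rng.shuffle(labels)
            inst = [SiteInstance(str(l), i + 1, tuple(pts[i]))
                    for i, l in enumerate(labels)]
            res = neighbor_test(inst, null="permutation",
                                n_permutations=200, seed=k)
            rej += res.p_value <= 0.05
        lo = stats.binom.ppf(0.005, n_sim, 0.05)
        hi = stats.binom.ppf(0.995, n_sim, 0.05)
        assert lo <= rej <= hi, f"permutation level {rej / n_sim}"

    def test_permutation_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=6, size=(10, 3))
        inst = [SiteInstance("A" if i < 6 else "B", i + 1, tuple(pts[i]))
                for i in range(10)]
        a = neighbor_test(inst, null="permutation", n_permutations=150, seed=8)
        b = neighbor_test(inst, null="permutation", n_permutations=150, seed=8)
        assert a.p_value == b.p_value
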