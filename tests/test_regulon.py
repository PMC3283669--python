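"""Redundancy/influence metrics, mode classification, clustering and set tests."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from regulon_shift.contrasts import ContrastResult
from regulon_shift.motifs import STRE, scan_promoters
from regulon_shift.regulon import (
    GeneSet,
    RegulationProfile,
    classify_mode,
    cluster_profiles,
    group_response_test,
    influence_ratio,
    motif_enrichment_test,
    orientation_bias_test,
    redundancy_coefficient,
    set_overlap_test,
)

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)


def _contrast(values: dict[str, float]) -> ContrastResult:
    table = pd.DataFrame(
        {"log2_ratio": pd.Series(values), "s2": 0.1, "df": 8.0, "scale": 0.8}
    )
    return ContrastResult("log", "gis1", "wt", table)


class TestCoefficients:
    @pytest.mark.parametrize(
        "g, r, expected", [(1.0, -0.5, 0.5), (-2, 1, 1.0), (0.3, 0.3, 0.0)]
    )
    def test_influence_hand_checks(self, g, r, expected):
        assert influence_ratio(g, r) == pytest.approx(expected)

    @given(finite, finite)
    @settings(max_examples=100, deadline=None)
    def test_influence_antisymmetry(self, g, r):
        assert influence_ratio(g, r) == pytest.approx(-influence_ratio(r, g))

    @pytest.mark.parametrize(
        "g, r, d, expected",
        [
            (0, 0, 1.7, 1.0),     # effect only in the double mutant
            (0.5, 0.5, 1.0, 0.0),  # additive singles
            (1.0, 0.5, 1.0, -0.5),  # singles exceed the double
        ],
    )
    def test_redundancy_hand_checks(self, g, r, d, expected):
        assert redundancy_coefficient(g, r, d) == pytest.approx(expected)

    def test_redundancy_undefined_at_zero_double(self):
        assert math.isnan(redundancy_coefficient(0.5, 0.5, 0.0))

    @given(finite, finite, st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=100, deadline=None)
    def test_redundancy_symmetric_in_singles(self, g, r, d):
        assert redundancy_coefficient(g, r, d) == pytest.approx(
            redundancy_coefficient(r, g, d)
        )


class TestClassifyMode:
    def test_double_only_redundant_repression(self):
        prof = RegulationProfile("g", g=0.1, r=0.1, d=1.0)  # redundancy 0.8
        assert classify_mode(prof, False, False, True) == "redundant-repression"

    def test_synergistic_repression(self):
        prof = RegulationProfile("g", g=0.7, r=0.1, d=1.0)  # redundancy 0.2
        assert classify_mode(prof, True, False, True) == "synergistic-repression"

    def test_opposite_signs(self):
        prof = RegulationProfile("g", g=1.0, r=-1.0, d=0.1)
        assert classify_mode(prof, True, True, False) == "opposite"

    def test_single_factor_modes(self):
        up = RegulationProfile("g", g=1.0, r=0.0, d=0.0)
        assert classify_mode(up, True, False, False) == "repressed-by-1"
        down = RegulationProfile("g", g=0.0, r=-1.0, d=0.0)
        assert classify_mode(down, False, True, False) == "activated-by-2"

    def test_nothing_significant_is_unclear(self):
        prof = RegulationProfile("g", g=1.0, r=1.0, d=1.0)
        assert classify_mode(prof, False, False, False) == "unclear"

    def test_redundant_activation(self):
        prof = RegulationProfile("g", g=-0.1, r=-0.1, d=-1.0)
        assert classify_mode(prof, False, False, True) == "redundant-activation"


class TestClustering:
    def test_two_identical_groups_separate(self):
        profiles = pd.DataFrame(
            [[1, 2, 3]] * 5 + [[3, 1, -2]] * 5,
            index=[f"g{i}" for i in range(10)],
            dtype=float,
        )
        labels = cluster_profiles(profiles, k=2).labels
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_affine_transform_merges_first(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(5)
        profiles = pd.DataFrame(
            {
                "a": base,
                "b": 3 * base + 2,  # Pearson distance 0 to a
                "c": rng.standard_normal(5),
                "d": rng.standard_normal(5),
            }
        ).T
        assignment = cluster_profiles(profiles, k=3)
        assert assignment.labels["a"] == assignment.labels["b"]
        assert assignment.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_agglomeration_oracle(self):
        """Average linkage on 1-Pearson vs a brute-force O(n^3) agglomerator."""
        rng = np.random.default_rng(4)
        profiles = pd.DataFrame(
            rng.standard_normal((30, 5)), index=[f"g{i:02d}" for i in range(30)]
        )
        k = 4
        assignment = cluster_profiles(profiles, k=k)

        # independent oracle: flat average-linkage agglomeration to k clusters
        x = profiles.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        xc /= np.linalg.norm(xc, axis=1, keepdims=True)
        dist = 1 - xc @ xc.T
        clusters = {i: [i] for i in range(30)}
        while len(clusters) > k:
            best = None
            for a, b in combinations(sorted(clusters), 2):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
            _, a, b = best
            clusters[a] = clusters[a] + clusters.pop(b)
        oracle = np.empty(30, dtype=int)
        for label, members in enumerate(clusters.values()):
            oracle[members] = label
        ours = assignment.labels.to_numpy()
        # same partition up to label renaming
        pairs_ours = {(i, j) for i, j in combinations(range(30), 2) if ours[i] == ours[j]}
        pairs_oracle = {(i, j) for i, j in combinations(range(30), 2) if oracle[i] == oracle[j]}
        assert pairs_ours == pairs_oracle

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(9)
        profiles = pd.DataFrame(rng.standard_normal((20, 4)))
        heights = cluster_profiles(profiles, k=3).merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_zero_variance_profile_rejected(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1, 2, 3], [0, 1, 0], [2, 0, 1]],
            index=["flat", "a", "b", "c"],
        )
        with pytest.raises(ValueError, match="flat"):
            cluster_profiles(profiles, k=2)


class TestSetOverlap:
    def test_exact_enumeration_example(self):
        universe = GeneSet("u", [f"g{i}" for i in range(10)])
        a = GeneSet("a", ["g0", "g1", "g2", "g3"])
        b = GeneSet("b", ["g0", "g1", "g2", "g8", "g9"])
        res = set_overlap_test(a, b, universe)
        assert res.overlap == 3
        # P(X>=3) = [C(4,3)C(6,2) + C(4,4)C(6,1)] / C(10,5) = 66/252
        assert res.p_value == pytest.approx(66 / 252)

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_univ = int(rng.integers(5, 26))
            universe = GeneSet("u", [f"g{i}" for i in range(n_univ)])
            ids = list(universe)
            a = GeneSet("a", rng.choice(ids, size=rng.integers(1, n_univ + 1), replace=False))
            b = GeneSet("b", rng.choice(ids, size=rng.integers(1, n_univ + 1), replace=False))
            res = set_overlap_test(a, b, universe)
            K, n, N = len(a), len(b), n_univ
            p_exact = sum(
                comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
                for x in range(res.overlap, min(K, n) + 1)
            ) / comb(N, n, exact=True)
            assert res.p_value == pytest.approx(p_exact)

    def test_symmetry_and_trivial_tail(self):
        universe = GeneSet("u", [f"g{i}" for i in range(12)])
        a = GeneSet("a", ["g0", "g1", "g2"])
        b = GeneSet("b", ["g5", "g6"])
        assert set_overlap_test(a, b, universe).p_value == pytest.approx(
            set_overlap_test(b, a, universe).p_value
        )
        assert set_overlap_test(a, b, universe).p_value == pytest.approx(1.0)

    def test_subset_overlap_is_minimal_p(self):
        universe = GeneSet("u", [f"g{i}" for i in range(12)])
        b = GeneSet("b", [f"g{i}" for i in range(6)])
        a_in = GeneSet("a", ["g0", "g1"])
        p_full = set_overlap_test(a_in, b, universe).p_value
        # any other placement of a 2-gene set has a lower or equal overlap
        a_out = GeneSet("a2", ["g0", "g11"])
        assert p_full <= set_overlap_test(a_out, b, universe).p_value


class TestGroupResponse:
    def test_exact_enumeration_example(self):
        contrast = _contrast({"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0})
        res = group_response_test(GeneSet("grp", ["g3", "g4"]), contrast)
        assert res.p_value == pytest.approx(1 / 3)  # two-sided, 2*1/C(4,2)
        assert res.direction == "up"

    def test_all_below_is_down(self):
        contrast = _contrast({"g1": -3.0, "g2": -2.0, "g3": 1.0, "g4": 2.0, "g5": 3.0})
        res = group_response_test(GeneSet("grp", ["g1", "g2"]), contrast)
        assert res.direction == "down"

    def test_group_covering_everything_rejected(self):
        contrast = _contrast({"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValueError, match="complement"):
            group_response_test(GeneSet("grp", ["g1", "g2"]), contrast)


class TestEnrichment:
    @staticmethod
    def _table(counts: dict[str, int]):
        seqs = {g: "AGGGG" * c + "ACGTACT" * (4 - c) for g, c in counts.items()}
        return scan_promoters(seqs, [STRE])

    def test_welch_oracle(self):
        table = self._table({"a": 2, "b": 2, "c": 2, "d": 0, "e": 0, "f": 0, "g": 0})
        res = motif_enrichment_test(GeneSet("s", ["a", "b", "c"]), table, "STRE")
        assert res.set_mean == pytest.approx(2.0)
        assert res.background_mean == pytest.approx(0.0)
        assert res.p_enrichment < 0.05
        assert res.p_enrichment + res.p_depletion == pytest.approx(1.0)

    def test_equal_means_give_half(self):
        table = self._table({"a": 1, "b": 2, "c": 1, "d": 2, "e": 1, "f": 2})
        res = motif_enrichment_test(GeneSet("s", ["a", "b"]), table, "STRE")
        # set mean 1.5 equals background mean 1.5 -> one-sided p = 0.5
        assert res.p_enrichment == pytest.approx(0.5, abs=0.02)

    def test_set_equal_to_table_rejected(self):
        table = self._table({"a": 1, "b": 2})
        with pytest.raises(ValueError, match="whole table"):
            motif_enrichment_test(GeneSet("s", ["a", "b"]), table, "STRE")


class TestOrientationBias:
    @staticmethod
    def _table(fwd_rev: dict[str, tuple[int, int]]):
        seqs = {
            g: "AGGGG" * f + "CCCCT" * r + "ACTACTA"
            for g, (f, r) in fwd_rev.items()
        }
        return scan_promoters(seqs, [STRE])

    def test_exact_tail_example(self):
        # population 100 fwd / 100 rev, the set holds 10 occurrences, 9 fwd
        layout = {"set1": (9, 1)}
        layout |= {f"bg{i}": (1, 0) for i in range(91)}
        layout |= {f"bgr{i}": (0, 1) for i in range(99)}
        table = self._table(layout)
        res = orientation_bias_test(GeneSet("s", ["set1"]), table, "STRE")
        assert (res.population_fwd, res.population_total) == (100, 200)
        assert (res.set_fwd, res.set_total) == (9, 10)
        # P(X>=9), X ~ Hypergeom(200, 100, 10): the two top tail terms
        p_exact = (
            comb(100, 9, exact=True) * comb(100, 1, exact=True)
            + comb(100, 10, exact=True)
        ) / comb(200, 10, exact=True)
        assert res.p_value == pytest.approx(p_exact)
        assert res.p_value == pytest.approx(0.00924, abs=5e-5)
        assert res.direction == "forward"

    def test_matching_fraction_is_insignificant(self):
        layout = {"a": (2, 2), "b": (3, 3), "c": (5, 5)}
        table = self._table(layout)
        res = orientation_bias_test(GeneSet("s", ["a"]), table, "STRE")
        assert res.p_value >= 0.5

    def test_whole_population_sample_p_one(self):
        table = self._table({"a": (2, 1), "b": (1, 2)})
        res = orientation_bias_test(GeneSet("s", ["a", "b"]), table, "STRE")
        assert res.p_value == pytest.approx(1.0)

    def test_empty_set_occurrences_rejected(self):
        table = self._table({"a": (1, 1), "b": (0, 0)})
        with pytest.raises(ValueError, match="no occurrences"):
            orientation_bias_test(GeneSet("s", ["b"]), table, "STRE")
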