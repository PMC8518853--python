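import numpy as np
import pandas as pd
import pytest

from nichepart import (
    IncidenceSummary,
    chao2,
    family_rollup,
    incidence_summary,
    levins,
    samples_needed,
    sharing_summary,
    wpoo,
)
from nichepart.diet_metrics import expected_richness


def _occ(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T.fillna(0).astype(int)


class TestWpoo:
    def test_two_sample_hand_value(self):
        # sample A detects {x, y}, sample B detects {x}:
        # p_x = (1/2)(1/2 + 1) = 0.75, p_y = (1/2)(1/2) = 0.25
        occ = _occ({"A": {"x": 1, "y": 1}, "B": {"x": 1}})
        p = wpoo(occ)
        assert p["x"] == pytest.approx(0.75)
        assert p["y"] == pytest.approx(0.25)

    def test_single_sample_is_uniform(self):
        occ = _occ({"A": {"a": 1, "b": 1, "c": 1, "d": 1}})
        assert all(v == pytest.approx(0.25) for v in wpoo(occ))

    def test_sums_to_one_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            occ = pd.DataFrame(
                rng.integers(0, 2, size=(6, 10)),
                index=[f"s{i}" for i in range(6)],
                columns=[f"m{j}" for j in range(10)],
            )
            if not (occ.sum(axis=1) > 0).any():
                continue
            assert wpoo(occ).sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_sample_order_and_duplication(self):
        occ = _occ({"A": {"x": 1, "y": 1}, "B": {"x": 1, "z": 1}})
        p1 = wpoo(occ)
        p2 = wpoo(occ.iloc[::-1])
        pd.testing.assert_series_equal(p1.sort_index(), p2.sort_index())
        doubled = pd.concat(
            [occ, occ.set_axis([f"{i}_copy" for i in occ.index])]
        )
        p3 = wpoo(doubled)
        pd.testing.assert_series_equal(p1.sort_index(), p3.sort_index())

    def test_all_empty_group_rejected(self):
        occ = _occ({"A": {"x": 0}, "B": {"x": 0}})
        with pytest.raises(ValueError, match="no detections"):
            wpoo(occ)

    def test_wpoo_matches_manifest(self, worked):
        table, manifest = worked["table"], worked["manifest"]
        p = wpoo(table.subset(["A1", "A2", "A3"]))
        for prey, expected in manifest["wpoo_auritus"].items():
            assert p[prey] == pytest.approx(expected)


class TestChao2:
    def test_classic_hand_value(self):
        inc = IncidenceSummary(m=4, S_obs=10, Q1=3, Q2=1)
        assert chao2(inc) == pytest.approx(13.375)

    def test_no_uniques_estimate_is_observed(self):
        inc = IncidenceSummary(m=4, S_obs=10, Q1=0, Q2=2)
        assert chao2(inc) == pytest.approx(10.0)

    def test_bias_corrected_branch_at_zero_duplicates(self):
        # S_obs + ((m-1)/m) * Q1(Q1-1) / (2(Q2+1)) = 10 + 0.75 * 6/2
        inc = IncidenceSummary(m=4, S_obs=10, Q1=3, Q2=0)
        assert chao2(inc) == pytest.approx(12.25)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            chao2(IncidenceSummary(m=1, S_obs=3, Q1=2, Q2=1))

    def test_never_below_observed(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = int(rng.integers(1, 30))
            q1 = int(rng.integers(0, s + 1))
            q2 = int(rng.integers(0, s - q1 + 1))
            inc = IncidenceSummary(m=int(rng.integers(2, 20)), S_obs=s,
                                   Q1=q1, Q2=q2)
            assert chao2(inc) >= inc.S_obs

    def test_monte_carlo_asymptote(self):
        # incidence data simulated from a known pool: the median Chao2 over
        # 200 replicates should land within 10% of the true pool size
        rng = np.random.default_rng(42)
        pool, m, p_detect = 50, 30, 0.15
        estimates = []
        for _ in range(200):
            inc_matrix = rng.random((m, pool)) < p_detect
            freq = inc_matrix.sum(axis=0)
            inc = IncidenceSummary(
                m=m,
                S_obs=int((freq > 0).sum()),
                Q1=int((freq == 1).sum()),
                Q2=int((freq == 2).sum()),
            )
            estimates.append(chao2(inc))
        assert abs(np.median(estimates) - pool) <= 0.1 * pool


class TestSamplesNeeded:
    def test_hand_value(self):
        inc = IncidenceSummary(m=4, S_obs=10, Q1=3, Q2=1)
        assert samples_needed(inc, 0.95) == 13

    def test_extrapolation_consistency(self):
        # 13 total = 9 additional samples; the curve must cross the target
        # exactly there
        inc = IncidenceSummary(m=4, S_obs=10, Q1=3, Q2=1)
        target = 0.95 * chao2(inc)
        assert expected_richness(inc, 9) >= target
        assert expected_richness(inc, 8) < target

    def test_already_satisfied_returns_m(self):
        inc = IncidenceSummary(m=4, S_obs=10, Q1=3, Q2=1)
        # 0.7 * 13.375 = 9.36 <= 10 observed
        assert samples_needed(inc, 0.7) == 4

    def test_non_decreasing_in_target(self):
        inc = IncidenceSummary(m=6, S_obs=40, Q1=12, Q2=5)
        values = [samples_needed(inc, g) for g in (0.8, 0.85, 0.9, 0.95)]
        assert values == sorted(values)


class TestLevins:
    def test_uniform_profile(self):
        assert levins(pd.Series([0.2] * 5)) == pytest.approx(5.0)

    def test_single_prey(self):
        assert levins(pd.Series([1.0])) == pytest.approx(1.0)

    def test_hand_value(self):
        assert levins(pd.Series([0.5, 0.25, 0.25])) == pytest.approx(8 / 3)

    def test_scale_free(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = rng.random(8) + 0.01
            assert levins(pd.Series(w)) == pytest.approx(
                levins(pd.Series(17.3 * w))
            )

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            levins(pd.Series(dtype=float))


class TestFamilyRollup:
    def test_additivity_within_family(self):
        recs = {
            "a": _rec("a", "F1"), "b": _rec("b", "F1"), "c": _rec("c", "F2"),
        }
        p = pd.Series({"a": 0.3, "b": 0.2, "c": 0.5})
        rolled = family_rollup(p, recs)
        assert rolled["F1"] == pytest.approx(0.5)
        assert rolled.sum() == pytest.approx(1.0)

    def test_distinct_families_preserve_values(self):
        recs = {"a": _rec("a", "F1"), "b": _rec("b", "F2")}
        rolled = family_rollup(pd.Series({"a": 0.6, "b": 0.4}), recs)
        assert rolled["F1"] == pytest.approx(0.6)
        assert rolled["F2"] == pytest.approx(0.4)

    def test_rollup_never_increases_breadth(self):
        # merging prey into families concentrates mass, so Levins breadth
        # can only shrink or stay equal; brute-force over random profiles
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = 6
            fams = [f"F{rng.integers(0, 3)}" for _ in range(n)]
            recs = {f"p{i}": _rec(f"p{i}", fams[i]) for i in range(n)}
            p = pd.Series(rng.dirichlet(np.ones(n)),
                          index=[f"p{i}" for i in range(n)])
            assert levins(family_rollup(p, recs)) <= levins(p) + 1e-9

    def test_missing_family_bucketed_to_order(self):
        recs = {"a": _rec("a", "", order="Diptera")}
        rolled = family_rollup(pd.Series({"a": 1.0}), recs)
        assert rolled.index[0] == "order:Diptera"


def _rec(motu, family, order="Lepidoptera"):
    from nichepart import MotuAssignment

    return MotuAssignment(
        motu_id=motu, best_identity=99.5, best_coverage=99.0,
        order=order, family=family, assigned_rank="species",
    )


class TestSharingSummary:
    def test_three_way_intersection(self):
        regions = sharing_summary(
            {"A": {"x", "y"}, "B": {"y", "z"}, "C": {"y"}}
        )
        assert regions["A+B+C"] == 1

    def test_disjoint_sets(self):
        regions = sharing_summary({"A": {"x"}, "B": {"y"}})
        assert set(regions) == {"A", "B"}

    def test_regions_partition_the_union(self):
        rng = np.random.default_rng(4)
        pool = [f"p{i}" for i in range(30)]
        sets = {
            k: set(rng.choice(pool, size=rng.integers(5, 20), replace=False))
            for k in ("A", "B", "C")
        }
        regions = sharing_summary(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))


class TestIncidenceSummary:
    def test_from_occurrence(self, worked):
        table, manifest = worked["table"], worked["manifest"]
        inc = incidence_summary(table.subset(["B1", "B2", "B3"]))
        expected = manifest["incidence_austriacus"]
        assert (inc.m, inc.S_obs, inc.Q1, inc.Q2) == (
            expected["m"], expected["S_obs"], expected["Q1"], expected["Q2"]
        )
        assert chao2(inc) == pytest.approx(manifest["chao2_austriacus"])
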