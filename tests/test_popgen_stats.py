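"""Diversity, AMOVA F_ST and hierarchical F-statistics."""

import numpy as np
import pandas as pd
import pytest

from temporal_demes import (
    GroupedGenotypes,
    SyntheticSpec,
    amova_fst,
    diversity_summary,
    generate_synthetic_microsat,
    hierarchical_f,
    pairwise_fst,
)

from oracles import amova_components_oracle, fst_oracle


class TestDiversity:
    def test_hand_worked_single_locus(self):
        gg = GroupedGenotypes.from_pairs(
            [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]], labels={"g": ["a"] * 4}
        )
        res = diversity_summary(gg, "g").per_group.iloc[0]
        assert res["H_O"] == pytest.approx(0.5)
        assert res["H_S"] == pytest.approx((8 / 7) * 0.5)
        assert res["n_a"] == 2

    def test_monomorphic_locus(self):
        gg = GroupedGenotypes.from_pairs(
            [[(5, 5)], [(5, 5)], [(5, 5)]], labels={"g": ["a"] * 3}
        )
        res = diversity_summary(gg, "g").per_group.iloc[0]
        assert (res["n_a"], res["H_O"], res["H_S"]) == (1, 0.0, 0.0)

    def test_missing_calls_excluded_not_counted(self, microsat_table):
        res = diversity_summary(microsat_table, "site")
        row = res.per_locus
        em01_msb = row[(row["group"] == "Em01") & (row["locus"] == "msB")]
        assert int(em01_msb["n"].iloc[0]) == 11  # one missing call dropped

    def test_overall_weightings_both_available(self, microsat_table):
        res = diversity_summary(microsat_table, ["site", "stage"])
        uw = res.overall(weight_by_loci=False)
        w = res.overall(weight_by_loci=True)
        assert np.isfinite(uw["H_S"]) and np.isfinite(w["H_S"])


class TestAmovaFst:
    def test_fixed_difference_gives_one(self):
        gg = GroupedGenotypes.from_pairs(
            [[(1, 1)] * 3] * 4 + [[(2, 2)] * 3] * 4,
            labels={"deme": ["A"] * 4 + ["B"] * 4},
        )
        assert amova_fst(gg, "deme", n_perm=0).fst == pytest.approx(1.0)

    def test_duplicated_group_nonpositive(self):
        block = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]]
        gg = GroupedGenotypes.from_pairs(
            block + block, labels={"deme": ["A"] * 4 + ["B"] * 4}
        )
        assert amova_fst(gg, "deme", n_perm=0).fst <= 0

    def test_matches_bruteforce_oracle_toy(self, toy_two_groups):
        res = amova_fst(toy_two_groups, "deme", n_perm=0)
        oracle = amova_components_oracle(toy_two_groups, "deme")
        got = res.per_locus[["sigma_a", "sigma_b", "sigma_c"]].to_numpy()
        assert np.allclose(got, np.array(oracle), atol=1e-12)
        assert res.fst == pytest.approx(fst_oracle(toy_two_groups, "deme"), abs=1e-12)

    def test_matches_bruteforce_oracle_microsats(self, microsat_table):
        res = amova_fst(microsat_table, ["site", "stage"], n_perm=0)
        oracle = amova_components_oracle(
            # oracle takes a single label column; collapse the pair
            _with_joined_label(microsat_table),
            "joined",
        )
        got = res.per_locus[["sigma_a", "sigma_b", "sigma_c"]].to_numpy()
        assert np.allclose(got, np.array(oracle), atol=1e-10)

    def test_monomorphic_dataset_flagged_nan(self):
        gg = GroupedGenotypes.from_pairs(
            [[(1, 1)]] * 6, labels={"deme": ["A"] * 3 + ["B"] * 3}
        )
        res = amova_fst(gg, "deme", n_perm=0)
        assert res.monomorphic and np.isnan(res.fst)

    def test_percent_variation_sums_to_100(self, microsat_table):
        res = amova_fst(microsat_table, "site", n_perm=0)
        assert res.levels["percent"].sum() == pytest.approx(100.0)

    def test_permutation_p_detects_fixed_difference(self, rng):
        gg = GroupedGenotypes.from_pairs(
            [[(1, 1)] * 4] * 6 + [[(2, 2)] * 4] * 6,
            labels={"deme": ["A"] * 6 + ["B"] * 6},
        )
        res = amova_fst(gg, "deme", n_perm=199, rng=rng)
        assert res.p_fst == pytest.approx(1 / 200)

    def test_requires_two_groups_of_two(self):
        gg = GroupedGenotypes.from_pairs(
            [[(1, 2)], [(1, 1)], [(2, 2)]], labels={"deme": ["A", "A", "B"]}
        )
        with pytest.raises(ValueError):
            amova_fst(gg, "deme", n_perm=0)


def _with_joined_label(data: GroupedGenotypes) -> GroupedGenotypes:
    lab = data.labels.copy()
    lab["joined"] = lab["site"] + "/" + lab["stage"]
    return GroupedGenotypes(data.calls, data.loci, lab)


class TestPairwiseFst:
    def test_symmetry_and_oracle(self, microsat_table):
        f_ab, _ = pairwise_fst(microsat_table, "Em01", "Em08", "site", n_perm=0)
        f_ba, _ = pairwise_fst(microsat_table, "Em08", "Em01", "site", n_perm=0)
        assert f_ab == pytest.approx(f_ba, abs=1e-14)
        assert f_ab == pytest.approx(fst_oracle(microsat_table, "site"), abs=1e-12)

    def test_self_comparison_nonpositive(self, microsat_table):
        half = microsat_table.subset(np.arange(12))
        lab = half.labels.copy()
        lab["copy"] = ["x"] * 6 + ["y"] * 6
        doubled = GroupedGenotypes(half.calls, half.loci, lab)
        f, _ = pairwise_fst(doubled, "x", "y", "copy", n_perm=0)
        assert f < 0.1


class TestHierarchicalF:
    def test_two_level_equals_amova(self):
        data = generate_synthetic_microsat(SyntheticSpec(theta=0.1, n_loci=6, seed=3))
        h = hierarchical_f(data, ["population"], n_boot=0)
        a = amova_fst(data, "population", n_perm=0)
        assert h.levels["f"].iloc[0] == pytest.approx(a.fst, abs=1e-9)

    def test_constant_top_level_f_zero(self, microsat_table):
        lab = microsat_table.labels.copy()
        lab["const"] = "all"
        gg = GroupedGenotypes(microsat_table.calls, microsat_table.loci, lab)
        h = hierarchical_f(gg, ["const", "site"], n_boot=0)
        assert h.levels["f"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_level_nesting_runs_and_orders(self, microsat_table):
        h = hierarchical_f(microsat_table, ["site", "stage"], n_boot=100,
                           rng=np.random.default_rng(0))
        assert list(h.levels["level"]) == [
            "site/total", "stage/total", "individual/total",
        ]
        # components are reported raw, so cumulative ratios need not be
        # monotone; they must be finite and bounded by 1
        assert np.isfinite(h.levels["f"]).all()
        assert (h.levels["f"] <= 1.0).all()

    def test_no_bootstrap_leaves_ci_empty(self, microsat_table):
        h = hierarchical_f(microsat_table, ["site"], n_boot=0)
        assert h.levels["ci_low"].isna().all() or (
            h.levels["ci_low"].iloc[0] is None
        )

    def test_bootstrap_ci_brackets_point(self, microsat_table):
        data = generate_synthetic_microsat(
            SyntheticSpec(theta=0.15, n_loci=12, seed=5)
        )
        h = hierarchical_f(data, ["population"], n_boot=300,
                           rng=np.random.default_rng(1))
        row = h.levels.iloc[0]
        assert row["ci_low"] <= row["f"] <= row["ci_high"]
        assert row["significant"] in (True, False)

    def test_single_locus_ci_unavailable(self):
        gg = GroupedGenotypes.from_pairs(
            [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)], [(1, 1)], [(2, 2)]],
            labels={"g": ["A", "A", "A", "B", "B", "B"]},
        )
        with pytest.warns(UserWarning):
            h = hierarchical_f(gg, ["g"], n_boot=100)
        assert h.levels["ci_low"].iloc[0] is None


class TestEstimatorCalibration:
    @pytest.mark.parametrize("theta", [0.01, 0.05, 0.2])
    def test_balding_nichols_theta_recovery(self, theta):
        vals = []
        for i in range(20):
            d = generate_synthetic_microsat(
                SyntheticSpec(
                    theta=theta, n_loci=20, n_per_group=50, seed=10_000 + i
                )
            )
            vals.append(amova_fst(d, "population", n_perm=0).fst)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - theta) < 3 * se
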