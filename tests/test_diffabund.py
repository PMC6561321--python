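import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tmtquant as tq
from tmtquant.design import CONDITIONS, STRAIN_CONDITIONS
from tmtquant.diffabund import (
    AbundanceTable,
    anova_per_protein,
    classify,
    control_relative_log2,
    count_differential,
    fold_change_from_log2,
    hierarchical_cluster,
    records_to_frame,
)
from helpers import anova_oneway_bruteforce


def abundance_table(values_by_column, proteins=None):
    """values_by_column: {(condition, plex): array}."""
    df = pd.DataFrame(values_by_column)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["condition", "plex"])
    if proteins is not None:
        df.index = proteins
    return AbundanceTable(values=df)


def random_table(n=20, seed=0):
    rng = np.random.default_rng(seed)
    cols = {
        (cond, plex): rng.normal(10, 2, size=n)
        for cond in CONDITIONS
        for plex in ("plex1", "plex2")
    }
    return abundance_table(cols)


class TestControlRelativeLog2:
    def test_strain_equal_to_control_gives_zero(self):
        base = np.array([10.0, 12.0])
        cols = {
            (cond, plex): base.copy()
            for cond in CONDITIONS
            for plex in ("plex1", "plex2")
        }
        ratios = control_relative_log2(abundance_table(cols))
        assert np.allclose(ratios, 0.0)
        assert "ground_control" not in ratios.columns

    def test_doubled_strain_gives_one(self):
        base = np.array([10.0, 12.0])
        cols = {}
        for plex in ("plex1", "plex2"):
            cols[("ground_control", plex)] = base.copy()
            for cond in STRAIN_CONDITIONS:
                cols[(cond, plex)] = base + (1.0 if cond == "dark_space" else 0)
        ratios = control_relative_log2(abundance_table(cols))
        assert np.allclose(ratios["dark_space"], 1.0)
        assert np.allclose(ratios["uv_space"], 0.0)

    def test_matches_direct_recomputation(self):
        table = random_table(seed=3)
        ratios = control_relative_log2(table)
        for cond in STRAIN_CONDITIONS:
            manual = 0.5 * (
                (table.values[(cond, "plex1")]
                 - table.values[("ground_control", "plex1")])
                + (table.values[(cond, "plex2")]
                   - table.values[("ground_control", "plex2")])
            )
            assert np.allclose(ratios[cond], manual, rtol=1e-12)

    @given(shift=st.floats(-3, 3, allow_nan=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_antisymmetry_under_control_swap(self, shift):
        """Swapping the control with a strain negates that strain's ratio."""
        base = np.array([8.0, 9.0, 11.0])
        cols = {}
        for plex in ("plex1", "plex2"):
            cols[("ground_control", plex)] = base.copy()
            for cond in STRAIN_CONDITIONS:
                cols[(cond, plex)] = (
                    base + shift if cond == "uv_mars" else base.copy()
                )
        forward = control_relative_log2(abundance_table(cols))
        swapped_cols = dict(cols)
        for plex in ("plex1", "plex2"):
            swapped_cols[("ground_control", plex)] = cols[("uv_mars", plex)]
            swapped_cols[("uv_mars", plex)] = cols[("ground_control", plex)]
        backward = control_relative_log2(abundance_table(swapped_cols))
        assert np.allclose(
            backward["uv_mars"], -forward["uv_mars"], atol=1e-12
        )


class TestFoldChangeConversion:
    @pytest.mark.parametrize(
        "log2,magnitude,direction",
        [
            (-1.264, 2.4, "down"),  # DLST, Dark-Space
            (1.328, 2.5, "up"),     # universal stress protein, UV-Space
            (0.0, 1.0, "none"),
            (-1.0, 2.0, "down"),
            (0.664, 1.6, "up"),
        ],
    )
    def test_reported_conversions(self, log2, magnitude, direction):
        fc = fold_change_from_log2(log2, ndigits=1)
        assert fc.magnitude == magnitude
        assert fc.direction == direction

    def test_unrounded_magnitude(self):
        fc = fold_change_from_log2(2.0)
        assert fc.magnitude == pytest.approx(4.0, rel=1e-15)

    def test_rounding_is_half_up(self):
        assert fold_change_from_log2(np.log2(1.25), ndigits=1).magnitude == 1.3

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_change_from_log2(float("nan"))


class TestAnovaPerProtein:
    def test_constant_protein_flagged_with_p_one(self):
        cols = {
            (cond, plex): np.full(3, 5.0)
            for cond in CONDITIONS
            for plex in ("plex1", "plex2")
        }
        res = anova_per_protein(abundance_table(cols))
        assert (res["p_value"] == 1.0).all()
        assert (res["degenerate"] == "constant").all()

    def test_separation_without_residual_flagged_with_p_zero(self):
        cols = {}
        for plex in ("plex1", "plex2"):
            for cond in CONDITIONS:
                cols[(cond, plex)] = np.array(
                    [5.0 if cond == "dark_space" else 0.0]
                )
        res = anova_per_protein(abundance_table(cols))
        assert res["p_value"].iloc[0] == 0.0
        assert res["degenerate"].iloc[0] == "zero_residual"

    def test_matches_scipy_and_bruteforce(self):
        table = random_table(n=30, seed=9)
        res = anova_per_protein(table)
        for i in range(0, 30, 7):
            groups = [
                [
                    table.values[(cond, plex)].iloc[i]
                    for plex in ("plex1", "plex2")
                ]
                for cond in CONDITIONS
            ]
            scipy_p = stats.f_oneway(*groups).pvalue
            assert res["p_value"].iloc[i] == pytest.approx(scipy_p, rel=1e-9)
            assert res["p_value"].iloc[i] == pytest.approx(
                anova_oneway_bruteforce(groups), rel=1e-9
            )

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(77)
        cols = {
            (cond, plex): rng.normal(size=2000)
            for cond in CONDITIONS
            for plex in ("plex1", "plex2")
        }
        res = anova_per_protein(abundance_table(cols))
        frac = (res["p_value"] <= 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_monotone_power_with_effect_size(self):
        rng = np.random.default_rng(78)
        power = {}
        for fold in (2.0, 4.0):
            cols = {
                (cond, plex): rng.normal(0, 0.3, size=1000)
                for cond in CONDITIONS
                for plex in ("plex1", "plex2")
            }
            for plex in ("plex1", "plex2"):
                cols[("dark_space", plex)] += np.log2(fold)
            res = anova_per_protein(abundance_table(cols))
            power[fold] = (res["p_value"] <= 0.05).mean()
        assert power[4.0] >= power[2.0]


class TestClassify:
    def make_records(self, ratios, pvals=None):
        if pvals is None:
            pvals = pd.Series(1.0, index=ratios.index)
        return classify(ratios, pvals)

    def test_threshold_boundary_inclusive(self):
        ratios = pd.DataFrame(
            {"uv_space": [0.58, 0.585, -0.585, -0.58]},
            index=["a", "b", "c", "d"],
        )
        records = self.make_records(ratios)
        calls = {r.protein_id: r.call_by_strain["uv_space"] for r in records}
        assert calls == {
            "a": "unchanged", "b": "up", "c": "down", "d": "unchanged"
        }

    def test_reported_example_call(self):
        # PTS fructose transporter subunit IIB, Dark-Space
        ratios = pd.DataFrame({"dark_space": [-1.990]}, index=["500857289"])
        rec = self.make_records(ratios)[0]
        assert rec.call_by_strain["dark_space"] == "down"

    def test_hand_enumerated_fixture(self):
        rng = np.random.default_rng(10)
        ratios = pd.DataFrame(
            rng.uniform(-2, 2, size=(20, 4)), columns=list(STRAIN_CONDITIONS)
        )
        pvals = pd.Series(rng.uniform(0, 1, size=20), index=ratios.index)
        cut = np.log2(1.5)
        records = classify(ratios, pvals)
        for rec, (_, row) in zip(records, ratios.iterrows()):
            for strain in STRAIN_CONDITIONS:
                expected = (
                    "up" if row[strain] >= cut
                    else "down" if row[strain] <= -cut
                    else "unchanged"
                )
                assert rec.call_by_strain[strain] == expected
        assert [r.significant for r in records] == list(pvals <= 0.05)


class TestCounts:
    def build(self, membership, strains=STRAIN_CONDITIONS):
        """membership: list of (set of differential strains)."""
        rows = []
        records = []
        for i, hits in enumerate(membership):
            ratios = {s: (1.0 if s in hits else 0.0) for s in strains}
            records.append(
                tq.DifferentialRecord(
                    protein_id=f"P{i}",
                    log2_ratio_by_strain=ratios,
                    anova_p=1.0,
                    call_by_strain={
                        s: ("up" if s in hits else "unchanged")
                        for s in strains
                    },
                    significant=False,
                )
            )
        return records

    def test_no_calls_no_counts(self):
        counts = count_differential(self.build([set(), set()]))
        assert counts.union_count == 0
        assert all(v == 0 for v in counts.per_strain_total.values())

    def test_multi_strain_protein_counts_in_totals_not_uniques(self):
        counts = count_differential(
            self.build([{"uv_space", "dark_space"}])
        )
        assert counts.per_strain_total["uv_space"] == 1
        assert counts.per_strain_total["dark_space"] == 1
        assert counts.per_strain_unique["uv_space"] == 0
        assert counts.multi_strain_count == 1
        assert counts.consistent()

    def test_study_shaped_fixture_reproduced(self):
        """Construction that realizes totals (238, 62, 126, 109) with
        uniques (117, 17, 21, 9) and union 301."""
        us, um, ds, dm = "uv_space", "uv_mars", "dark_space", "dark_mars"
        membership = (
            [{ds}] * 117 + [{us}] * 17 + [{um}] * 21 + [{dm}] * 9
            + [{us, um, ds, dm}] * 45
            + [{ds, um, dm}] * 7
            + [{ds, um}] * 37
            + [{ds, dm}] * 32
            + [{um, dm}] * 16
        )
        counts = count_differential(self.build(membership))
        assert counts.per_strain_total == {us: 62, um: 126, ds: 238, dm: 109}
        assert counts.per_strain_unique == {us: 17, um: 21, ds: 117, dm: 9}
        assert counts.union_count == 301
        assert counts.consistent()

    @given(st.lists(
        st.sets(st.sampled_from(list(STRAIN_CONDITIONS))),
        min_size=0, max_size=40,
    ))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_union_identity_on_arbitrary_memberships(self, membership):
        counts = count_differential(self.build(membership))
        assert counts.consistent()
        assert counts.union_count == sum(1 for h in membership if h)


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=50)
        ratios = pd.DataFrame({"s1": a, "s2": a, "s3": a + 5.0})
        result = hierarchical_cluster(ratios)
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_heavily_perturbed_strain_is_outgroup(self):
        """A strain with far more perturbed proteins joins the tree last,
        the pattern behind one strain not clustering with the others."""
        rng = np.random.default_rng(13)
        n = 400
        ratios = pd.DataFrame(
            rng.normal(0, 0.1, size=(n, 4)), columns=list(STRAIN_CONDITIONS)
        )
        idx = rng.choice(n, size=160, replace=False)
        ratios.loc[idx, "dark_space"] += rng.choice([-1.5, 1.5], size=160)
        idx2 = rng.choice(n, size=40, replace=False)
        for s in ("uv_space", "uv_mars", "dark_mars"):
            ratios.loc[idx2, s] += rng.choice([-1.0, 1.0], size=40)
        result = hierarchical_cluster(ratios)
        last = result.linkage[-1]
        dark = result.labels.index("dark_space")
        # the root merge joins the dark_space singleton with the rest
        assert int(last[0]) == dark or int(last[1]) == dark

    def test_distances_match_bruteforce_euclidean(self):
        rng = np.random.default_rng(14)
        ratios = pd.DataFrame(rng.normal(size=(30, 4)),
                              columns=list(STRAIN_CONDITIONS))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(ratios.to_numpy().T))
        for i in range(4):
            for j in range(4):
                manual = np.sqrt(
                    ((ratios.iloc[:, i] - ratios.iloc[:, j]) ** 2).sum()
                )
                assert d[i, j] == pytest.approx(manual, rel=1e-12)

    def test_newick_is_parseable(self):
        rng = np.random.default_rng(15)
        ratios = pd.DataFrame(rng.normal(size=(20, 4)),
                              columns=list(STRAIN_CONDITIONS))
        result = hierarchical_cluster(ratios)
        import skbio
        tree = skbio.TreeNode.read([result.newick])
        assert {t.name for t in tree.tips()} == set(STRAIN_CONDITIONS)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame({"only": [1.0, 2.0]}))


def test_records_frame_mirrors_published_layout():
    ratios = pd.DataFrame(
        {"uv_space": [1.2, 0.1], "dark_space": [-0.7, 0.0]},
        index=["A", "B"],
    )
    pvals = pd.Series([0.01, 0.9], index=["A", "B"])
    frame = records_to_frame(classify(ratios, pvals))
    assert list(frame["star"]) == ["*", ""]
    assert frame.loc[0, "uv_space"] == 1.2
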