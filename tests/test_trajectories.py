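import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comland.data_model import CountTable, RelAbundTable, SampleMetadata
from comland.trajectories import (PropensityBootstrap,
                                  TippingPointClassifier, assign_groups,
                                  bootstrap_propensities,
                                  classify_trajectories, group_abundance,
                                  propensity, threshold_classify)


def metadata_for(parent_classes):
    """Metadata + final class labels for parents with 4 replicates each."""
    rows, labels = [], {}
    for parent, classes in parent_classes.items():
        rows.append((parent, "start", parent, pd.NA))
        for r, c in enumerate(classes, start=1):
            sid = f"{parent}_r{r}"
            rows.append((sid, "final", parent, r))
            if c is not None:
                labels[sid] = c
    meta = pd.DataFrame(rows, columns=["sample_id", "time_point",
                                       "parent_id", "replicate"]
                        ).set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype("Int64")
    return SampleMetadata(meta), pd.Series(labels)


class TestClassifyTrajectories:
    def test_convergent_and_divergent_definitions(self):
        meta, labels = metadata_for({
            "p1": [1, 1, 1, 1], "p2": [1, 1, 1, 2], "p3": [2, 2, 2, 2]})
        traj = classify_trajectories(meta, labels)
        assert traj.types.to_dict() == {"p1": "C1", "p2": "D", "p3": "C2"}
        # the parent and all four replicates carry the trajectory type
        assert traj.sample_types["p1"] == "C1"
        assert traj.sample_types["p1_r3"] == "C1"

    def test_incomplete_parents_excluded(self):
        meta, labels = metadata_for({"p1": [1, 1, 1, 1],
                                     "p2": [1, 1, 1, None]})
        traj = classify_trajectories(meta, labels)
        assert list(traj.table.index) == ["p1"]
        assert traj.excluded == ["p2"]


def toy_propensity_table():
    """10 communities, 4 of type C1; the ASV sits in those 4 plus 1 other."""
    counts = np.zeros((10, 2), dtype=int)
    counts[:, 1] = 5            # second ASV everywhere
    counts[:4, 0] = 3           # focal ASV in all C1 communities
    counts[4, 0] = 2            # ... and exactly one other community
    types = pd.Series(["C1"] * 4 + ["C2"] * 3 + ["D"] * 3,
                      index=[f"c{i}" for i in range(10)])
    t = CountTable(pd.DataFrame(counts, index=types.index,
                                columns=["focal", "ubiquitous"]))
    return t, types


class TestPropensity:
    def test_worked_example_is_ln2(self):
        t, types = toy_propensity_table()
        pt = propensity(t, types)
        focal_c1 = pt[(pt.asv_id == "focal") & (pt.traj_type == "C1")]
        assert focal_c1.propensity.iloc[0] == pytest.approx(np.log(2),
                                                            abs=1e-12)

    def test_ubiquitous_asv_has_zero_propensity_everywhere(self):
        t, types = toy_propensity_table()
        pt = propensity(t, types)
        ubi = pt[pt.asv_id == "ubiquitous"]
        assert np.allclose(ubi.propensity, 0.0)

    def test_absent_from_one_type_gives_minus_infinity(self):
        t, types = toy_propensity_table()
        pt = propensity(t, types)
        focal_d = pt[(pt.asv_id == "focal") & (pt.traj_type == "D")]
        assert focal_d.propensity.iloc[0] == -np.inf

    def test_missing_type_for_a_community_rejected(self):
        t, types = toy_propensity_table()
        with pytest.raises(ValueError, match="without a trajectory type"):
            propensity(t, types.iloc[:-1])

    @given(st.integers(0, 2**31 - 1))
    def test_total_probability_identity(self, seed):
        """sum_T P(T) exp(prop_T) == 1 for finite-propensity ASVs."""
        rng = np.random.default_rng(seed)
        counts = (rng.random((12, 6)) < 0.6).astype(int)
        counts[0] = 1  # no all-absent ASVs
        types = pd.Series(rng.choice(["C1", "C2", "D"], 12),
                          index=[f"c{i}" for i in range(12)])
        types.iloc[:3] = ["C1", "C2", "D"]
        pt = propensity(CountTable(pd.DataFrame(
            counts, index=types.index,
            columns=[f"a{j}" for j in range(6)])), types)
        pt["w"] = pt.n_type / 12
        for _, grp in pt.groupby("asv_id"):
            if np.isfinite(grp.propensity).all():
                total = (grp.w * np.exp(grp.propensity)).sum()
                assert total == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        t, types = toy_propensity_table()
        a = bootstrap_propensities(t, types, n_boot=50, seed=9)
        b = bootstrap_propensities(t, types, n_boot=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(2)
        n = 200
        types = pd.Series(["C1"] * 70 + ["C2"] * 70 + ["D"] * 60,
                          index=[f"c{i}" for i in range(n)])
        pres = np.zeros((n, 1), dtype=int)
        pres[:70, 0] = rng.random(70) < 0.9
        pres[70:, 0] = rng.random(130) < 0.3
        pres[0, 0] = 1
        t = CountTable(pd.DataFrame(pres, index=types.index, columns=["e"]))
        est = PropensityBootstrap(n_boot=300, seed=0).fit(t, types)
        c1 = est.types_.index("C1")
        # analytic planted value: ln(0.9 / mixture marginal)
        marginal = (70 * 0.9 + 130 * 0.3) / 200
        assert est.propensity_[c1, 0] == pytest.approx(
            np.log(0.9 / marginal), abs=0.1)
        assert est.significant_positive_[c1, 0]

    def test_never_present_type_cannot_be_significant(self):
        t, types = toy_propensity_table()
        pt = bootstrap_propensities(t, types, n_boot=50, seed=1)
        focal_d = pt[(pt.asv_id == "focal") & (pt.traj_type == "D")].iloc[0]
        assert focal_d.propensity == -np.inf
        assert not focal_d.significant_positive


def make_pt(cells, asvs=("x",)):
    """Long propensity frame from {(asv, type): (ci_low, finite)} cells."""
    rows = []
    for asv in asvs:
        for ty in ("C1", "C2", "D"):
            lo, finite = cells.get((asv, ty), (-1.0, True))
            prop = 0.5 if finite else -np.inf
            rows.append({"asv_id": asv, "traj_type": ty,
                         "propensity": prop, "ci_low": lo,
                         "ci_high": lo + 1.0,
                         "significant_positive": lo > 0,
                         "significant_nonnegative": finite and lo >= 0,
                         "p_present_type": 0.5, "p_present": 0.5,
                         "n_type": 10})
    return pd.DataFrame(rows)


class TestAssignGroups:
    def test_sf1_definition(self):
        start = make_pt({("x", "C1"): (0.2, True)})
        final = make_pt({("x", "C1"): (0.3, True)})
        out = assign_groups(start, final)
        assert out.loc["x", "group"] == "SF1"

    def test_all_six_cells_positive_is_cosmopolitan_not_sf1(self):
        cells = {("x", t): (0.1, True) for t in ("C1", "C2", "D")}
        out = assign_groups(make_pt(cells), make_pt(cells))
        assert out.loc["x", "group"] == "cosmopolitan"

    def test_zero_pinned_ubiquity_is_cosmopolitan_by_default(self):
        cells = {("x", t): (0.0, True) for t in ("C1", "C2", "D")}
        out = assign_groups(make_pt(cells), make_pt(cells))
        assert out.loc["x", "group"] == "cosmopolitan"
        strict = assign_groups(make_pt(cells), make_pt(cells),
                               cosmopolitan_rule="strict")
        assert strict.loc["x", "group"] != "cosmopolitan"

    def test_start_only_signature_label(self):
        start = make_pt({("x", "C1"): (0.2, True)})
        final = make_pt({})
        out = assign_groups(start, final)
        assert out.loc["x", "group"] == "start-C1"


class TestGroupAbundance:
    def test_whole_table_sums_to_one_and_empty_to_zero(self, rng):
        comp = rng.dirichlet(np.full(5, 1.0), size=3)
        t = RelAbundTable(pd.DataFrame(
            comp, index=list("xyz"), columns=[f"a{i}" for i in range(5)]))
        np.testing.assert_allclose(
            group_abundance(t, t.asv_ids), 1.0, atol=1e-12)
        assert (group_abundance(t, []) == 0).all()

    def test_toy_sum(self):
        t = RelAbundTable(pd.DataFrame([[0.2, 0.1, 0.7]], index=["s"],
                                       columns=["a", "b", "c"]))
        assert group_abundance(t, ["a", "b"]).loc["s"] == pytest.approx(0.3)

    def test_average_across_replicates(self):
        meta, _ = metadata_for({"p1": [1, 1, 1, 1]})
        t = RelAbundTable(pd.DataFrame(
            [[0.2, 0.8], [0.4, 0.6], [0.2, 0.8], [0.2, 0.8]],
            index=[f"p1_r{r}" for r in range(1, 5)], columns=["a", "b"]))
        out = group_abundance(t, ["a"], meta, average_replicates=True)
        assert out.loc["p1"] == pytest.approx(0.25)


class TestThresholdClassify:
    @pytest.mark.parametrize("sf1,cosmo,expected", [
        (0.5, 0.05, "C1"),
        (0.01, 0.6, "C2"),
        (0.3, 0.3, "D"),
        (0.05, 0.05, "D"),
    ])
    def test_rule(self, sf1, cosmo, expected):
        assert threshold_classify(sf1, cosmo) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_classify(1.5, 0.1)

    def test_classifier_predict_matches_scalar_rule(self, rng):
        X = rng.random((50, 2))
        clf = TippingPointClassifier().fit(X)
        preds = clf.predict(X)
        for row, p in zip(X, preds):
            assert p == threshold_classify(row[0], row[1])

    def test_threshold_search_beats_or_matches_defaults(self, rng):
        X = np.column_stack([rng.random(100), rng.random(100)])
        y = TippingPointClassifier().fit(X).predict(X)
        tuned = TippingPointClassifier(optimise=True, grid_size=20).fit(X, y)
        default_acc = (TippingPointClassifier().fit(X).predict(X) == y).mean()
        assert tuned.best_accuracy_ >= default_acc - 1e-12
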