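import numpy as np
import pandas as pd
import pytest

from tumorhet import (SchemaError, ValidationError, apply_gating, binarize,
                      case_composition, classify_case_subtype,
                      composition_table, default_gating_tree,
                      estimate_threshold, rank_sum_test)
from tumorhet.cycif import GatingTree
from tumorhet.simulate import CycifSimParams, simulate_cycif_cohort


class TestEstimateThreshold:
    def test_gmm2_separates_two_lognormal_populations(self, rng):
        rng = np.random.default_rng(11)
        low = np.exp(rng.normal(1.0, 0.3, 1000))
        high = np.exp(rng.normal(3.0, 0.3, 1000))
        values = np.concatenate([low, high])
        thr = estimate_threshold(values, "gmm2")
        assert np.median(low) < thr < np.median(high)
        misclass = (np.sum(low >= thr) + np.sum(high < thr)) / 2000
        assert misclass < 0.02

    def test_otsu_lies_between_populations(self):
        rng = np.random.default_rng(11)
        low = np.exp(rng.normal(1.0, 0.3, 1000))
        high = np.exp(rng.normal(3.0, 0.3, 1000))
        thr = estimate_threshold(np.concatenate([low, high]), "otsu")
        assert np.median(low) < thr < np.median(high)

    def test_constant_input_and_small_n_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            estimate_threshold(np.full(100, 3.0), "gmm2")
        with pytest.raises(ValidationError, match=">= 50"):
            estimate_threshold(np.arange(10.0), "gmm2")

    def test_manual_is_identity_and_requires_value(self):
        assert estimate_threshold([], "manual", manual_value=5) == 5
        with pytest.raises(ValidationError):
            estimate_threshold([], "manual")

    def test_threshold_strictly_inside_observed_range(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(1.0, 500)
        for method in ("gmm2", "otsu"):
            thr = estimate_threshold(vals, method)
            assert vals.min() < thr < vals.max()


class TestBinarize:
    def test_inclusive_threshold_rule(self):
        cells = pd.DataFrame({"CD3": [10.0, 5.0, 4.99]})
        out = binarize(cells, {"CD3": 5.0})
        assert list(out["CD3_bin"]) == [1, 1, 0]  # >= is positive

    def test_missing_threshold_marker_raises(self):
        with pytest.raises(SchemaError, match="CD8"):
            binarize(pd.DataFrame({"CD3": [1.0]}), {"CD8": 1.0})


class TestGating:
    def _cells(self, **binaries):
        n = max(len(v) for v in binaries.values())
        df = pd.DataFrame({"case_id": "c0", "cell_id": [f"x{i}" for i in range(n)],
                           "x": 0.0, "y": 0.0})
        for m, vals in binaries.items():
            df[m + "_bin"] = vals
        return df

    def test_immune_subtype_assignment(self):
        tree = GatingTree.from_config([
            {"name": "immune", "level": "lineage", "requires": {"CD45": "+"}},
            {"name": "CD8 T", "level": "subtype", "parent": "immune",
             "requires": {"CD45": "+", "CD8": "+"}, "output_label": "CD8 T"},
        ])
        cells = self._cells(CD45=[1, 1, 0], CD8=[1, 0, 1], HER2=[0, 0, 0],
                            ER=[0, 0, 0])
        out = apply_gating(cells, tree)
        assert list(out["lineage"]) == ["immune", "immune", "unassigned"]
        assert list(out["subtype"]) == ["CD8 T", "unassigned", "unassigned"]

    def test_tumor_receptor_categories(self):
        tree = GatingTree.from_config([
            {"name": "tumor", "level": "lineage", "requires": {"CK": "+"}}])
        cells = self._cells(CK=[1, 1, 1, 1, 0], HER2=[1, 0, 1, 0, 1],
                            ER=[0, 1, 1, 0, 0])
        out = apply_gating(cells, tree)
        assert list(out["receptor"]) == ["HER2", "ER", "HER2+ER+", "DN", ""]

    def test_document_order_and_subtype_priority(self):
        # FoxP3+CD8+ precedes CD8 T, so a triple-positive cell takes it
        tree = default_gating_tree()
        markers = {m for r in tree.rules for m in r.requires} | {"HER2", "ER"}
        binaries = {m: [0] for m in markers}
        for m in ("CD45", "CD3", "CD8", "FoxP3"):
            binaries[m] = [1]
        out = apply_gating(self._cells(**binaries), tree)
        assert out["subtype"].iloc[0] == "FoxP3+CD8+ T"

    def test_unknown_marker_in_tree_is_config_error(self):
        tree = GatingTree.from_config([
            {"name": "tumor", "level": "lineage", "requires": {"NOPE": "+"}}])
        with pytest.raises(SchemaError, match="NOPE"):
            tree.validate_panel(["CK", "CD45"])

    def test_gating_is_order_independent(self, rng):
        cells, _, _ = simulate_cycif_cohort(CycifSimParams(n_cases=2,
                                                           cells_per_case=100, seed=4))
        tree = default_gating_tree()
        panel = sorted({m for r in tree.rules for m in r.requires} | {"HER2", "ER"})
        thr = {m: 10.0 for m in panel}
        out = apply_gating(binarize(cells, thr), tree)
        perm = rng.permutation(len(cells))
        out2 = apply_gating(binarize(cells.iloc[perm].reset_index(drop=True), thr), tree)
        assert (out2["lineage"].to_numpy() == out["lineage"].to_numpy()[perm]).all()


class TestComposition:
    def _gated(self, rows):
        df = pd.DataFrame(rows)
        df["case_id"] = df.get("case_id", "c0")
        return df

    def test_receptor_frequencies(self):
        g = self._gated([{"lineage": "tumor", "receptor": "HER2", "subtype": ""}] * 3
                        + [{"lineage": "tumor", "receptor": "DN", "subtype": ""}])
        comp = case_composition(g)[0]
        assert comp.tumor_receptor_freq == pytest.approx(
            {"HER2": 0.75, "ER": 0.0, "HER2+ER+": 0.0, "DN": 0.25})

    def test_immune_entropy_two_equal_categories(self):
        g = self._gated([{"lineage": "immune", "subtype": "CD8 T", "receptor": ""}] * 2
                        + [{"lineage": "immune", "subtype": "B cell", "receptor": ""}] * 2)
        comp = case_composition(g)[0]
        assert comp.immune_entropy == pytest.approx(np.log(2), abs=5e-5)
        assert comp.n_tumor == 0 and np.isnan(comp.receptor_entropy)

    def test_macrophage_variants_fold_into_parent_category(self):
        g = self._gated([{"lineage": "immune", "subtype": "macrophage", "receptor": ""},
                         {"lineage": "immune", "subtype": "GZM+ macrophage", "receptor": ""}])
        comp = case_composition(g)[0]
        assert comp.immune_freq["macrophage"] == 1.0

    def test_case_without_immune_cells_flagged(self):
        g = self._gated([{"lineage": "tumor", "receptor": "ER", "subtype": ""}])
        comp = case_composition(g)[0]
        assert comp.immune_freq == {} and np.isnan(comp.immune_entropy)


class TestCaseSubtype:
    def _comp(self, case_id, freq):
        from tumorhet.cycif import CaseComposition
        return CaseComposition(case_id=case_id, n_tumor=100,
                               tumor_receptor_freq=freq)

    def test_archetype_cases_split_and_labeled(self, rng):
        comps = []
        for i in range(4):
            f = np.clip([0.9, 0.02, 0.03, 0.05] + rng.normal(0, 0.01, 4), 0, 1)
            f = f / f.sum()
            comps.append(self._comp(f"h{i}", dict(zip(
                ("HER2", "ER", "HER2+ER+", "DN"), f))))
        for i in range(4):
            f = np.clip([0.05, 0.03, 0.02, 0.9] + rng.normal(0, 0.01, 4), 0, 1)
            f = f / f.sum()
            comps.append(self._comp(f"d{i}", dict(zip(
                ("HER2", "ER", "HER2+ER+", "DN"), f))))
        out = classify_case_subtype(comps, n_groups=2)
        by_case = out.set_index("case_id")["subtype_group"]
        assert set(by_case[[f"h{i}" for i in range(4)]]) == {"HER2"}
        assert set(by_case[[f"d{i}" for i in range(4)]]) == {"DN"}

    def test_identical_cases_share_group_and_duplication_invariant(self):
        freqs = [
            {"HER2": 0.8, "ER": 0.1, "HER2+ER+": 0.05, "DN": 0.05},
            {"HER2": 0.8, "ER": 0.1, "HER2+ER+": 0.05, "DN": 0.05},
            {"HER2": 0.1, "ER": 0.7, "HER2+ER+": 0.1, "DN": 0.1},
            {"HER2": 0.1, "ER": 0.1, "HER2+ER+": 0.1, "DN": 0.7},
        ]
        comps = [self._comp(f"c{i}", f) for i, f in enumerate(freqs)]
        out = classify_case_subtype(comps, n_groups=3).set_index("case_id")
        assert out.loc["c0", "group"] == out.loc["c1", "group"]
        doubled = comps + [self._comp(f"c{i}b", f) for i, f in enumerate(freqs)]
        out2 = classify_case_subtype(doubled, n_groups=3).set_index("case_id")
        for i in range(4):
            assert out2.loc[f"c{i}", "group"] == out2.loc[f"c{i}b", "group"]
        assert (out2.loc[[f"c{i}" for i in range(4)], "subtype_group"].to_numpy()
                == out.loc[[f"c{i}" for i in range(4)], "subtype_group"].to_numpy()).all()

    def test_no_dominant_mean_is_mixed(self):
        comps = [self._comp(f"c{i}", {"HER2": 0.4, "ER": 0.3,
                                      "HER2+ER+": 0.2, "DN": 0.1})
                 for i in range(3)]
        out = classify_case_subtype(comps, n_groups=1)
        assert set(out["subtype_group"]) == {"mixed"}

    def test_fewer_cases_than_groups_raises(self):
        comps = [self._comp("c0", {"HER2": 1.0, "ER": 0, "HER2+ER+": 0, "DN": 0})]
        with pytest.raises(ValidationError):
            classify_case_subtype(comps, n_groups=2)


def test_end_to_end_pcr_association_on_synthetic_cohort():
    """Responders carry a higher HER2+ tumor fraction; the full pipeline
    (thresholding, gating, composition, rank-sum) must detect it."""
    cells, case_truth, _ = simulate_cycif_cohort(CycifSimParams(seed=7))
    tree = default_gating_tree()
    panel = sorted({m for r in tree.rules for m in r.requires} | {"HER2", "ER"})
    thr = {m: estimate_threshold(cells[m].to_numpy()) for m in panel}
    gated = apply_gating(binarize(cells, thr), tree)
    comp = composition_table(case_composition(gated)).set_index("case_id")
    pcr = case_truth.set_index("case_id")["pcr"]
    her2 = comp["receptor:HER2"] + comp["receptor:HER2+ER+"]
    _, p = rank_sum_test(her2[pcr].to_numpy(), her2[~pcr].to_numpy())
    assert p < 0.05
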