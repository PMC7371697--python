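import numpy as np
import pandas as pd
import pytest

from phosphodrug import activity
from phosphodrug.datatypes import (
    DataError,
    IntensityMatrix,
    PsiteAnnotation,
    SetCollection,
)


def matrix_from(arr, features, cells=None, kind="protein"):
    arr = np.asarray(arr, dtype=float)
    cells = cells or [f"C{j}" for j in range(arr.shape[1])]
    return IntensityMatrix(pd.DataFrame(arr, index=features, columns=cells), kind)


class TestPathwayActivity:
    def test_single_member_equals_rescaled_feature(self):
        protein = matrix_from([[1.0, 2.0, 4.0]], ["A"])
        act = activity.pathway_activity(
            protein, None, SetCollection({"PW": ["A"]}), min_members=1
        )
        np.testing.assert_allclose(
            act.relative.loc["PW"].to_numpy(), [0.0, 1 / 3, 1.0], atol=1e-12
        )

    def test_constant_members_flagged_flat(self):
        protein = matrix_from([[2.0, 2.0, 2.0]], ["A"])
        act = activity.pathway_activity(
            protein, None, SetCollection({"PW": ["A"]}), min_members=1
        )
        assert "PW" in act.flat
        assert act.relative.loc["PW"].isna().all()

    def test_small_pathways_dropped(self):
        protein = matrix_from([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]], ["A", "B"])
        act = activity.pathway_activity(
            protein, None, SetCollection({"PW": ["A", "B"], "TINY": ["A"]}),
            min_members=2,
        )
        assert "TINY" not in act.raw.index

    def test_member_psites_contribute(self):
        protein = matrix_from([[1.0, 2.0, 3.0]], ["A"])
        psite = matrix_from([[3.0, 2.0, 1.0]], ["A_pS5"], kind="p-site")
        act = activity.pathway_activity(
            protein, psite, SetCollection({"PW": ["A"]}), min_members=1
        )
        assert act.provenance["PW"]["member_psites"] == ["A_pS5"]
        # protein z and site z cancel exactly
        np.testing.assert_allclose(act.raw.loc["PW"].to_numpy(), 0.0, atol=1e-12)

    def test_planted_group_occupies_top_relative_scores(self, default_dataset):
        protein, psite, pathways, _, _, _, ann, truth = default_dataset
        act = activity.pathway_activity(protein, psite, pathways, ann)
        for name, cells in truth.active_pathway_cells.items():
            rel = act.relative.loc[name]
            top = rel.sort_values(ascending=False).head(len(cells)).index
            assert set(top) <= set(cells)

    def test_empty_collection_raises(self):
        protein = matrix_from([[1.0, 2.0]], ["A"])
        with pytest.raises(DataError):
            activity.pathway_activity(protein, None, SetCollection({}))


class TestKinaseActivity:
    def _single_channel_setup(self):
        protein = matrix_from([[1.0, 2.0, 3.0]], ["OTHER"])
        psite = matrix_from([[1.0, 2.0, 4.0]], ["SUB_pY9"], kind="p-site")
        sets = SetCollection({"KIN": ["SUB_pY9"]})
        return protein, psite, sets

    def test_single_channel_equals_that_channel(self):
        protein, psite, sets = self._single_channel_setup()
        act = activity.kinase_activity(protein, psite, sets)
        z = activity.zscore_features(psite).loc["SUB_pY9"]
        np.testing.assert_allclose(act.raw.loc["KIN"].to_numpy(), z.to_numpy(), atol=1e-12)
        assert act.provenance["KIN"]["channels"] == ["substrates"]

    def test_inhibitory_substrate_negated(self):
        protein, psite, sets = self._single_channel_setup()
        ann = [PsiteAnnotation("SUB_pY9", "SUB", "Y", 9, "inhibitory")]
        act = activity.kinase_activity(protein, psite, sets, ann)
        z = activity.zscore_features(psite).loc["SUB_pY9"]
        np.testing.assert_allclose(
            act.raw.loc["KIN"].to_numpy(), -z.to_numpy(), atol=1e-12
        )

    def test_all_channels_constant_flat(self):
        protein = matrix_from([[5.0, 5.0, 5.0]], ["KIN"])
        psite = matrix_from([[2.0, 2.0, 2.0]], ["KIN_pS1"], kind="p-site")
        act = activity.kinase_activity(
            protein, psite, SetCollection({"KIN": ["KIN_pS1"]})
        )
        assert "KIN" in act.flat

    def test_kinase_without_channels_dropped(self):
        protein = matrix_from([[1.0, 2.0, 3.0]], ["OTHER"])
        psite = matrix_from([[1.0, 2.0, 3.0]], ["X_pS2"], kind="p-site")
        sets = SetCollection({"GONE": ["NOT_THERE_pY1"], "OK": ["X_pS2"]})
        act = activity.kinase_activity(protein, psite, sets)
        assert "GONE" not in act.raw.index
        assert "OK" in act.raw.index

    def test_channel_order_permutation_invariant(self):
        rng = np.random.default_rng(0)
        protein = matrix_from(rng.normal(7, 1, (2, 6)), ["KIN", "HOST"])
        psite = matrix_from(
            rng.normal(7, 1, (2, 6)), ["KIN_pY10", "HOST_pS3"], kind="p-site"
        )
        s1 = SetCollection({"KIN": ["HOST_pS3"]})
        act1 = activity.kinase_activity(protein, psite, s1)
        # reversing feature order must not change the combined score
        protein2 = protein.subset_features(["HOST", "KIN"])
        psite2 = psite.subset_features(["HOST_pS3", "KIN_pY10"])
        act2 = activity.kinase_activity(protein2, psite2, s1)
        np.testing.assert_allclose(
            act1.raw.loc["KIN"].to_numpy(), act2.raw.loc["KIN"].to_numpy(), atol=1e-12
        )

    def test_planted_kinase_reaches_relative_one(self, default_dataset):
        protein, psite, _, kinases, _, _, ann, truth = default_dataset
        act = activity.kinase_activity(protein, psite, kinases, ann)
        for kinase, cells in truth.active_kinase_per_group.items():
            assert act.relative.loc[kinase, cells[0]] == pytest.approx(1.0)


class TestRelativeScores:
    def test_affine_invariance_of_relative(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.normal(size=(3, 6)))
        rel1, _ = activity._relative_from_raw(raw)
        rel2, _ = activity._relative_from_raw(raw * 3.7 + 11.0)
        pd.testing.assert_frame_equal(rel1, rel2)

    def test_minmax_bounds(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.normal(size=(4, 9)))
        rel, flat = activity._relative_from_raw(raw)
        assert not flat
        assert rel.min(axis=1).eq(0).all()
        assert rel.max(axis=1).eq(1).all()


class TestWaterfall:
    def _act(self):
        raw = pd.DataFrame(
            [[0.1, 0.9], [0.5, 0.5], [0.9, 0.1]],
            index=["A", "B", "C"],
            columns=["C1", "C2"],
        )
        rel, flat = activity._relative_from_raw(raw)
        return activity.ActivityMatrix(raw=raw, relative=rel, flat=flat)

    def test_strict_descending_order(self):
        wf = activity.waterfall(self._act(), "C1")
        assert list(wf["entity"]) == ["C", "A"] or list(wf["entity"])[:1] == ["C"]
        assert (wf["relative"].diff().dropna() <= 0).all()

    def test_tie_broken_lexicographically(self):
        raw = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]],
            index=["ZED", "ABLE", "OTHER"],
            columns=["C1", "C2"],
        )
        rel, flat = activity._relative_from_raw(raw)
        act = activity.ActivityMatrix(raw=raw, relative=rel, flat=flat)
        wf = activity.waterfall(act, "C1")
        assert list(wf["entity"])[:2] == ["ABLE", "ZED"]

    def test_unknown_cell_line_raises(self):
        with pytest.raises(DataError):
            activity.waterfall(self._act(), "NOPE")

    def test_planted_kinase_first(self, default_dataset):
        protein, psite, _, kinases, _, _, ann, truth = default_dataset
        act = activity.kinase_activity(protein, psite, kinases, ann)
        for kinase, cells in truth.active_kinase_per_group.items():
            wf = activity.waterfall(act, cells[0])
            assert wf["entity"].iloc[0] == kinase


class TestLandscape:
    def _single_peak_act(self):
        raw = pd.DataFrame(
            np.vstack([np.eye(1, 8).ravel(), np.linspace(0, 1, 8)]),
            index=["PEAK", "SPREAD"],
            columns=[f"C{j}" for j in range(8)],
        )
        rel, flat = activity._relative_from_raw(raw)
        return activity.ActivityMatrix(raw=raw, relative=rel, flat=flat)

    def test_peak_at_hot_cell_line(self):
        act = self._single_peak_act()
        land = activity.build_landscape(act, grid=40, bandwidth=None)
        h = land.heights["PEAK"]
        iy, ix = np.unravel_index(np.argmax(h), h.shape)
        gx, gy = land.grid_x[ix], land.grid_y[iy]
        cx, cy = land.coordinates.loc["C0"]
        # the grid maximum sits at the hot cell line's position
        d_hot = np.hypot(gx - cx, gy - cy)
        others = land.coordinates.drop(index="C0")
        d_rest = np.hypot(others["x"] - gx, others["y"] - gy).min()
        assert d_hot < d_rest

    def test_uniform_scores_constant_height(self):
        raw = pd.DataFrame(
            np.array([[0.0, 1.0, 0.5, 0.25]]), index=["E"], columns=list("abcd")
        )
        rel = pd.DataFrame(
            np.full((1, 4), 0.5), index=["E"], columns=list("abcd")
        )
        act = activity.ActivityMatrix(raw=raw, relative=rel, flat=set())
        land = activity.build_landscape(act, grid=10)
        np.testing.assert_allclose(land.heights["E"], 0.5, atol=1e-9)

    def test_heights_within_unit_interval(self, default_dataset):
        protein, psite, _, kinases, _, _, ann, _ = default_dataset
        act = activity.kinase_activity(protein, psite, kinases, ann)
        land = activity.build_landscape(act, grid=20)
        for h in land.heights.values():
            assert (h >= 0).all() and (h <= 1).all()

    def test_reproducible_embedding(self, default_dataset):
        protein, psite, _, kinases, _, _, ann, _ = default_dataset
        act = activity.kinase_activity(protein, psite, kinases, ann)
        l1 = activity.build_landscape(act, grid=15, seed=3)
        l2 = activity.build_landscape(act, grid=15, seed=3)
        pd.testing.assert_frame_equal(l1.coordinates, l2.coordinates)
        np.testing.assert_array_equal(l1.heights["P0101"], l2.heights["P0101"])

    def test_too_few_cell_lines_raises(self):
        raw = pd.DataFrame([[0.0, 1.0]], index=["E"], columns=["a", "b"])
        rel, flat = activity._relative_from_raw(raw)
        act = activity.ActivityMatrix(raw=raw, relative=rel, flat=flat)
        with pytest.raises(DataError):
            activity.build_landscape(act)
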