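"""Engagement metric engine: labelling, metric families, identities."""

import numpy as np
import pandas as pd
import pytest

from icnengage import (
    GeometryError,
    StatMap,
    ZMapSet,
    activation_metrics,
    build_atlas,
    engage,
    label_activation,
    spatial_metrics,
)
from icnengage.engagement import NormalizationError

from conftest import random_statmap, random_zmapset, simple_geometry
from _oracles import oracle_metrics


def mask_map(atlas, mask, value=5.0):
    return StatMap(
        geometry=atlas.geometry, values=np.where(mask, value, 0.0), stat_kind="Z"
    )


class TestLabelling:
    def test_activation_equal_to_one_component(self, two_component_atlas):
        atlas = two_component_atlas
        m = mask_map(atlas, atlas.binary[0].astype(bool))
        la = label_activation(m, atlas)
        assert la.counts_binary[0] == atlas.binary_sizes()[0]
        assert la.counts_binary[1] == 0
        # exclusive labelled counts come only from label-1 voxels
        assert la.counts_label[0] == atlas.labelled_sizes()[0]
        assert la.counts_label[1] == 0
        assert la.n_active == 8

    def test_empty_activation(self, two_component_atlas):
        m = mask_map(two_component_atlas, np.zeros((4, 4, 4), bool))
        la = label_activation(m, two_component_atlas)
        assert la.counts_binary.sum() == 0 and la.n_active == 0
        assert np.isnan(la.L).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_match_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        zmaps = random_zmapset(rng, shape=(6, 6, 6), k=3)
        atlas = build_atlas(zmaps, 3.0)
        m = random_statmap(rng, atlas.geometry)
        la = label_activation(m, atlas)
        k = atlas.n_components
        exp_bin = np.zeros(k, int)
        exp_lab = np.zeros(k, int)
        for idx in np.ndindex(m.values.shape):
            v = m.values[idx]
            if np.isfinite(v) and v != 0:
                for i in range(k):
                    if atlas.binary[(i, *idx)]:
                        exp_bin[i] += 1
                lab = atlas.labels[idx]
                if not np.isnan(lab):
                    exp_lab[int(lab) - 1] += 1
        assert list(la.counts_binary) == list(exp_bin)
        assert list(la.counts_label) == list(exp_lab)

    def test_geometry_mismatch_is_hard_error(self, two_component_atlas):
        other = StatMap(
            geometry=simple_geometry((5, 5, 5)), values=np.ones((5, 5, 5))
        )
        with pytest.raises(GeometryError, match="resample"):
            label_activation(other, two_component_atlas)


class TestSpatialMetrics:
    def test_perfect_overlap(self, two_component_atlas):
        atlas = two_component_atlas
        m = mask_map(atlas, atlas.binary[0].astype(bool))
        t = spatial_metrics(label_activation(m, atlas), atlas)
        row = t.per_icn.loc["A"]
        assert row[["I", "IR", "OL", "SQ", "J"]].tolist() == [1, 1, 1, 1, 1]
        assert t.per_icn.loc["B", "I"] == 0

    def test_arithmetic_example(self):
        """|SPM|=10, |ICN_1|=20, intersection 5 -> I=0.25, OL=0.5, J=0.2, SQ=1/3."""
        geom = simple_geometry((40, 1, 1))
        z = np.full((1, 40, 1, 1), -1.0)
        z[0, :20] = 9.0  # |ICN_1| = 20
        atlas = build_atlas(
            ZMapSet(geometry=geom, z=z, component_names=["c"]), 3.0
        )
        mask = np.zeros((40, 1, 1), bool)
        mask[15:25] = True  # 10 active, 5 inside
        t = spatial_metrics(label_activation(mask_map(atlas, mask), atlas), atlas)
        row = t.per_icn.loc["c"]
        assert row["I"] == 0.25
        assert row["OL"] == 0.5
        assert row["J"] == pytest.approx(5 / 25)
        assert row["SQ"] == pytest.approx(1 / 3)
        assert row["SQ"] == pytest.approx(2 * row["J"] / (1 + row["J"]))

    def test_global_is_size_weighted_mean(self):
        """Sizes 10 and 30 with intersections 1 and 3 -> I_T = 4/40."""
        geom = simple_geometry((40, 1, 1))
        z = np.full((2, 40, 1, 1), -1.0)
        z[0, :10] = 9.0
        z[1, 10:40] = 9.0
        atlas = build_atlas(
            ZMapSet(geometry=geom, z=z, component_names=["a", "b"]), 3.0
        )
        mask = np.zeros((40, 1, 1), bool)
        mask[9] = True            # 1 voxel in a
        mask[10:13] = True        # 3 voxels in b
        t = spatial_metrics(label_activation(mask_map(atlas, mask), atlas), atlas)
        assert t.per_icn["I"].tolist() == [0.1, 0.1]
        assert t.global_metrics["I_T"] == pytest.approx(0.1)

    def test_undefined_for_empty_map(self, two_component_atlas):
        m = mask_map(two_component_atlas, np.zeros((4, 4, 4), bool))
        t = spatial_metrics(label_activation(m, two_component_atlas),
                            two_component_atlas)
        assert t.per_icn["IR"].isna().all()
        assert t.per_icn["OL"].isna().all()
        assert (t.per_icn["I"] == 0).all()


class TestActivationMetrics:
    def test_two_voxel_hand_evaluation(self):
        """Two active voxels {min+d, max}: MA_N = (d + (max-min))/(2(max-min))."""
        geom = simple_geometry((4, 1, 1))
        z = np.full((1, 4, 1, 1), 9.0)
        atlas = build_atlas(ZMapSet(geometry=geom, z=z, component_names=["c"]), 3.0)
        vmin, d, vmax = 4.0, 1.0, 8.0
        vals = np.zeros((4, 1, 1))
        vals[0, 0, 0] = vmin          # the map minimum
        vals[1, 0, 0] = vmin + d
        vals[2, 0, 0] = vmax
        # third active voxel keeps bounds; restrict component to voxels 1-2
        z2 = np.full((1, 4, 1, 1), -1.0)
        z2[0, 1:3] = 9.0
        atlas2 = build_atlas(ZMapSet(geometry=geom, z=z2, component_names=["c"]), 3.0)
        m = StatMap(geometry=geom, values=vals, stat_kind="Z")
        t = activation_metrics(label_activation(m, atlas2), atlas2)
        expected = (d + (vmax - vmin)) / (vmax - vmin) / 2
        assert t.per_icn.loc["c", "MA_N"] == pytest.approx(expected)

    def test_all_voxels_at_maximum(self, two_component_atlas):
        atlas = two_component_atlas
        vals = np.zeros((4, 4, 4))
        vals[atlas.binary[0].astype(bool)] = 7.0
        vals[0, 0, 3] = 2.0  # sets the minimum, outside both components
        m = StatMap(geometry=atlas.geometry, values=vals)
        t = activation_metrics(label_activation(m, atlas), atlas)
        assert t.per_icn.loc["A", "MA_N"] == pytest.approx(1.0)
        assert t.per_icn.loc["A", "RA_N"] == pytest.approx(1.0)
        assert np.isnan(t.per_icn.loc["B", "MA_N"])  # undefined, not 0

    @pytest.mark.parametrize("seed", range(10))
    def test_accumulation_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        zmaps = random_zmapset(rng, shape=(6, 6, 6), k=3)
        atlas = build_atlas(zmaps, 3.0)
        m = random_statmap(rng, atlas.geometry)
        la = label_activation(m, atlas)
        spat = spatial_metrics(la, atlas)
        act = activation_metrics(la, atlas)
        per = pd.concat([spat.per_icn, act.per_icn], axis=1)
        exp_per, exp_glob = oracle_metrics(
            m.values, atlas.binary, atlas.binary_sizes().astype(float)
        )
        for metric, exp in exp_per.items():
            np.testing.assert_allclose(
                per[metric].to_numpy(), exp, atol=1e-12, err_msg=metric,
                equal_nan=True,
            )
        merged = {**spat.global_metrics, **act.global_metrics}
        for metric, exp in exp_glob.items():
            np.testing.assert_allclose(merged[metric], exp, atol=1e-12,
                                       err_msg=metric, equal_nan=True)
        # sum identities
        assert np.nansum(per["RA_N"]) == pytest.approx(1.0)
        assert np.nansum(per["IR"]) == pytest.approx(1.0)

    def test_constant_map_raises(self, two_component_atlas):
        atlas = two_component_atlas
        m = mask_map(atlas, atlas.binary[0].astype(bool), value=5.0)
        with pytest.raises(NormalizationError, match="constant"):
            activation_metrics(label_activation(m, atlas), atlas)

    def test_bad_bounds_warn_and_clip(self, two_component_atlas):
        atlas = two_component_atlas
        vals = np.zeros((4, 4, 4))
        vals[atlas.binary[0].astype(bool)] = np.linspace(4, 9, 8)
        m = StatMap(geometry=atlas.geometry, values=vals)
        la = label_activation(m, atlas)
        with pytest.warns(UserWarning, match="bracket"):
            t = activation_metrics(la, atlas, bounds=(5.0, 8.0))
        assert t.per_icn.loc["A", "MA_N"] <= 1.0

    def test_shared_bounds_change_ma_n_not_i(self, two_component_atlas):
        atlas = two_component_atlas
        vals = np.zeros((4, 4, 4))
        vals[atlas.binary[0].astype(bool)] = np.linspace(4, 6, 8)
        m = StatMap(geometry=atlas.geometry, values=vals)
        la = label_activation(m, atlas)
        own = activation_metrics(la, atlas)
        shared = activation_metrics(la, atlas, bounds=(0.0, 10.0))
        assert own.per_icn.loc["A", "MA_N"] != shared.per_icn.loc["A", "MA_N"]
        s1 = spatial_metrics(la, atlas).per_icn["I"]
        assert s1.loc["A"] == 1.0  # spatial family untouched by bounds

    def test_correlation_with_own_prototype_is_high(self, small_atlas):
        """A map proportional to one prototype correlates most with it."""
        atlas = small_atlas
        vals = np.where(np.isfinite(atlas.z_masked[2]), atlas.z_masked[2], 0.0)
        m = StatMap(geometry=atlas.geometry, values=vals)
        t = activation_metrics(label_activation(m, atlas), atlas)
        r = t.per_icn["r"]
        assert r.idxmax() == atlas.component_names[2]
        assert r.max() > 0.9


class TestEngagePipeline:
    def test_composition_equals_stagewise(self, small_atlas):
        from icnengage import make_activation_fixture, threshold_map

        rng = np.random.default_rng(5)
        m, _ = make_activation_fixture(
            small_atlas, rng.uniform(0.2, 0.6, small_atlas.n_components), seed=5
        )
        table = engage(m, small_atlas, input_threshold=3.0)
        thr = threshold_map(m, 3.0)
        la = label_activation(thr, small_atlas)
        la.raw_values = m.values
        spat = spatial_metrics(la, small_atlas)
        act = activation_metrics(la, small_atlas)
        expected = pd.concat([spat.per_icn, act.per_icn], axis=1)
        pd.testing.assert_frame_equal(table.per_icn, expected[table.per_icn.columns])

    def test_unthresholded_covers_thresholded(self, small_atlas):
        from icnengage import make_activation_fixture

        m, _ = make_activation_fixture(
            small_atlas, np.full(small_atlas.n_components, 0.4), seed=3,
            value_floor=1.0,  # some active voxels below the Z>3 cut
        )
        raw = engage(m, small_atlas, input_threshold=None)
        cut = engage(m, small_atlas, input_threshold=3.0)
        assert (raw.per_icn["I"] >= cut.per_icn["I"] - 1e-12).all()
        assert raw.meta["n_active"] >= cut.meta["n_active"]

    def test_monotone_in_growing_activation(self, two_component_atlas):
        atlas = two_component_atlas
        vals_small = np.zeros((4, 4, 4))
        vals_small[0, 0, 0] = 4.0
        vals_small[0, 0, 1] = 6.0
        vals_big = vals_small.copy()
        vals_big[1, 1, 1] = 5.0
        t_small = engage(StatMap(geometry=atlas.geometry, values=vals_small),
                         atlas, input_threshold=None)
        t_big = engage(StatMap(geometry=atlas.geometry, values=vals_big),
                       atlas, input_threshold=None)
        assert (t_big.per_icn["I"] >= t_small.per_icn["I"]).all()
        assert t_big.global_metrics["I_T"] >= t_small.global_metrics["I_T"]

    def test_scale_invariance_of_spatial_family(self, small_atlas):
        from icnengage import make_activation_fixture

        m, _ = make_activation_fixture(
            small_atlas, np.full(small_atlas.n_components, 0.3), seed=8
        )
        m2 = StatMap(geometry=m.geometry, values=m.values * 2.5)
        a = engage(m, small_atlas, input_threshold=None)
        b = engage(m2, small_atlas, input_threshold=None)
        for metric in ["I", "IR", "OL", "SQ", "J"]:
            pd.testing.assert_series_equal(a.per_icn[metric], b.per_icn[metric])
        # MA_N invariant too when bounds come from the same map
        np.testing.assert_allclose(
            a.per_icn["MA_N"].to_numpy(), b.per_icn["MA_N"].to_numpy(), atol=1e-12
        )

    def test_label_counting_switch(self, small_atlas):
        from icnengage import make_activation_fixture

        m, _ = make_activation_fixture(
            small_atlas, np.full(small_atlas.n_components, 0.5), seed=9
        )
        tb = engage(m, small_atlas, input_threshold=None, counting="binary")
        tl = engage(m, small_atlas, input_threshold=None, counting="labels")
        # label-based sizes are no larger than binary sizes
        assert (small_atlas.labelled_sizes() <= small_atlas.binary_sizes()).all()
        assert np.isfinite(tl.per_icn["I"]).all()
        assert tb.meta["counting"] == "binary" and tl.meta["counting"] == "labels"

    def test_tidy_output_marks_undefined(self, two_component_atlas):
        atlas = two_component_atlas
        vals = np.zeros((4, 4, 4))
        sel = atlas.binary[0].astype(bool)
        vals[sel] = np.linspace(4, 8, sel.sum())
        t = engage(StatMap(geometry=atlas.geometry, values=vals), atlas,
                   input_threshold=None)
        tidy = t.to_tidy()
        undef = tidy[(tidy["basemap"] == "B") & (tidy["metric"] == "MA_N")]
        assert not undef["defined"].item()
        assert undef["value"].isna().item()
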