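"""Synthetic scene and flow-mixture generators: closed forms, invariants,
reproducibility."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colidecay import profiles as pf
from colidecay import scene as sc


def _single_colony_gt(**overrides):
    params = dict(
        pixel_size=2.0,
        image_shape=(150, 300),
        producer_colonies=[sc.Colony(center=(150.0, 150.0), radius=100.0)],
        toxin_amplitude=1000.0,
        decay_length=100.0,
        noise_sd=0.0,
        seed=3,
    )
    params.update(overrides)
    return sc.SceneGroundTruth(**params)


class TestToxinField:
    def test_amplitude_on_colony_boundary_and_half_at_lambda_ln2(self):
        gt = _single_colony_gt()
        field = sc.simulate_toxin_field(gt)
        xx, yy = gt.grid_um()
        cx, cy = gt.producer_colonies[0].center
        r = np.hypot(xx - cx, yy - cy)
        # on/inside the footprint the field is the full amplitude
        assert np.allclose(field[r <= 100.0], 1000.0)
        # at edge distance λ·ln2 the field is half the amplitude
        target = np.abs(r - (100.0 + 100.0 * np.log(2))) < 0.5
        assert np.allclose(field[target], 500.0, rtol=2e-2)

    def test_closed_form_at_arbitrary_distance(self):
        # independent evaluation of A·exp(-(r-R)/λ) at r-R = 250 µm
        gt = _single_colony_gt(image_shape=(150, 400))
        field = sc.simulate_toxin_field(gt)
        # pixel on the horizontal ray at x = cx + 100 + 250
        row, col = 75, int((150.0 + 350.0) / 2.0)
        expected = 1000.0 * np.exp(-2.5)
        assert field[row, col] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(82.08, abs=0.005)

    def test_field_nonincreasing_with_distance(self):
        gt = _single_colony_gt()
        field = sc.simulate_toxin_field(gt)
        ray = field[75, int(150 / 2.0):]  # outward along +x from the centre
        assert np.all(np.diff(ray) <= 1e-12)

    def test_multi_colony_max_combination_keeps_single_colony_form(self):
        colonies = [
            sc.Colony(center=(150.0, 150.0), radius=100.0),
            sc.Colony(center=(450.0, 150.0), radius=100.0),
        ]
        gt = _single_colony_gt(image_shape=(150, 400), producer_colonies=colonies)
        field = sc.simulate_toxin_field(gt, combine="max")
        # near the first colony's edge the nearer colony dominates exactly
        assert field[75, int(260 / 2.0)] == pytest.approx(
            1000.0 * np.exp(-10.0 / 100.0), rel=1e-9
        )
        total = sc.simulate_toxin_field(gt, combine="sum")
        assert np.all(total >= field - 1e-12)

    def test_no_producers_is_an_error(self):
        with pytest.raises(ValueError, match="no source"):
            sc.simulate_toxin_field(
                dataclasses.replace(_single_colony_gt(), producer_colonies=[])
            )


class TestRenderScene:
    def test_degenerate_gain_gives_flat_baseline(self):
        gt = _single_colony_gt(yfp_gain=0.0, yfp_baseline=100.0)
        img = sc.render_scene(gt)
        xx, yy = gt.grid_um()
        cx, cy = gt.producer_colonies[0].center
        lawn = np.hypot(xx - cx, yy - cy) > 100.0
        assert np.all(img.channels["YFP"][lawn] == 100)

    def test_noise_free_yfp_matches_closed_form_along_ray(self, exp_lawn_gt):
        img = sc.render_scene(exp_lawn_gt)
        yfp = img.channels["YFP"].astype(float)
        row = int(110.0 / 2.0)
        cols = np.arange(int(220.0 / 2.0) + 5, 700)
        d = cols * 2.0 - 210.0  # edge at x = 210 µm
        expected = 1000.0 * np.exp(-d / 100.0)
        assert np.max(np.abs(yfp[row, cols] - expected)) <= 0.5  # quantization

    def test_mcherry_confined_to_producer_footprint(self, exp_lawn_gt):
        img = sc.render_scene(exp_lawn_gt)
        xx, yy = exp_lawn_gt.grid_um()
        lawn = np.hypot(xx - 110.0, yy - 110.0) > 102.0
        assert np.all(img.channels["mCherry"][lawn] == 0)

    def test_gain_scaling_doubles_response(self):
        base = sc.render_scene(_single_colony_gt(yfp_baseline=50.0))
        double = sc.render_scene(_single_colony_gt(yfp_baseline=50.0, yfp_gain=2.0))
        y1 = base.channels["YFP"].astype(float) - 50.0
        y2 = double.channels["YFP"].astype(float) - 50.0
        lawn = y1 > 0
        assert np.allclose(y2[lawn], 2.0 * y1[lawn], atol=1.0)

    def test_same_seed_renders_bit_identical_images(self):
        gt = _single_colony_gt(noise_sd=25.0, seed=99)
        a = sc.render_scene(gt)
        b = sc.render_scene(gt)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_colony_outside_image_rejected(self):
        with pytest.raises(ValueError, match="inside the image"):
            _single_colony_gt(
                producer_colonies=[sc.Colony(center=(50.0, 50.0), radius=100.0)]
            )

    def test_overlapping_reporter_and_producer_rejected(self):
        gt = _single_colony_gt(
            reporter_lawn=False,
            reporter_colonies=[sc.Colony(center=(250.0, 150.0), radius=100.0)],
        )
        with pytest.raises(ValueError, match="overlap"):
            sc.render_scene(gt)


class TestColonyPair:
    def _pair_gt(self, pixel_size=5.0):
        return sc.SceneGroundTruth(
            pixel_size=pixel_size,
            image_shape=(100, 220),
            producer_colonies=[sc.Colony(center=(150.0, 250.0), radius=100.0)],
            reporter_lawn=False,
            toxin_amplitude=1000.0,
            decay_length=100.0,
            noise_sd=0.0,
            seed=1,
        )

    @staticmethod
    def _edge_gap_px(img):
        """Brute-force nearest-edge distance between the two footprints."""
        mch = img.channels["mCherry"] > 100
        cfp = img.channels["CFP"] > 100
        py, px = np.nonzero(mch)
        ry, rx = np.nonzero(cfp)
        d2 = (px[:, None] - rx[None, :]) ** 2 + (py[:, None] - ry[None, :]) ** 2
        return float(np.sqrt(d2.min()))

    def test_tangent_pair_at_gap_zero(self):
        img = sc.render_colony_pair(self._pair_gt(), gap=0.0, reporter_radius=100.0)
        assert self._edge_gap_px(img) <= np.sqrt(2) + 1e-9  # adjacent pixels

    def test_gap_150um_measures_30px(self):
        img = sc.render_colony_pair(self._pair_gt(), gap=150.0, reporter_radius=100.0)
        assert self._edge_gap_px(img) == pytest.approx(30.0, abs=1.0)

    def test_zero_gain_leaves_reporter_flat(self):
        gt = dataclasses.replace(self._pair_gt(), yfp_gain=0.0, yfp_baseline=80.0)
        img = sc.render_colony_pair(gt, gap=200.0, reporter_radius=100.0)
        reporter = img.channels["CFP"] > 100
        assert np.all(img.channels["YFP"][reporter] == 80)

    def test_gap_beyond_image_rejected(self):
        with pytest.raises(ValueError, match="leaves the image"):
            sc.render_colony_pair(self._pair_gt(), gap=2000.0, reporter_radius=100.0)


class TestFlowEvents:
    def test_label_counts_sum_to_n_events(self, flow_spec):
        df = sc.sample_flow_events(flow_spec)
        assert len(df) == flow_spec.n_events
        assert set(df["label"]).issubset(set(sc.FLOW_LABELS))

    def test_no_responders_when_fraction_zero(self):
        spec = sc.FlowPopulationSpec(n_events=5_000, responder_fraction=0.0, seed=2)
        df = sc.sample_flow_events(spec)
        assert (df["label"] == "reporter-responder").sum() == 0

    def test_empty_table_keeps_schema(self):
        df = sc.sample_flow_events(sc.FlowPopulationSpec(n_events=0))
        assert list(df.columns) == list(sc.FLOW_COLUMNS)
        assert len(df) == 0

    def test_doublets_double_area_not_height(self, flow_spec):
        df = sc.sample_flow_events(flow_spec)
        singlet = df["label"].isin(["reporter-responder", "reporter-nonresponder"])
        doublet = df["label"] == "doublet"
        r_singlet = (df.loc[singlet, "FSC_A"] / df.loc[singlet, "FSC_H"]).median()
        r_doublet = (df.loc[doublet, "FSC_A"] / df.loc[doublet, "FSC_H"]).median()
        assert r_doublet == pytest.approx(2.0 * r_singlet, rel=0.05)

    def test_seeded_generation_bit_reproducible(self, flow_spec):
        a = sc.sample_flow_events(flow_spec)
        b = sc.sample_flow_events(flow_spec)
        assert a.equals(b)

    def test_responder_ground_truth_fraction_exact(self):
        spec = sc.FlowPopulationSpec(n_events=100_000, responder_fraction=0.4, seed=4)
        df = sc.sample_flow_events(spec)
        reporters = df["label"].isin(["reporter-responder", "reporter-nonresponder"])
        frac = (df["label"] == "reporter-responder").sum() / reporters.sum()
        assert frac == pytest.approx(0.4, abs=0.5e-3)

    @given(frac=st.floats(0.0, 1.0), n=st.integers(0, 2_000))
    @settings(max_examples=25, deadline=None)
    def test_label_conservation_property(self, frac, n):
        spec = sc.FlowPopulationSpec(
            n_events=n, responder_fraction=frac, seed=0
        )
        df = sc.sample_flow_events(spec)
        assert len(df) == n

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sc.FlowPopulationSpec(responder_fraction=1.5)
        with pytest.raises(ValueError, match="sum to more than 1"):
            sc.FlowPopulationSpec(
                debris_fraction=0.5, doublet_fraction=0.4, lysed_fraction=0.2
            )


class TestSceneIO:
    def test_scene_roundtrip_pixel_identical(self, tmp_path, exp_lawn_gt):
        gt = dataclasses.replace(exp_lawn_gt, noise_sd=15.0)
        paths = sc.write_scene(gt, tmp_path, "demo")
        img = pf.read_image_set(
            {ch: paths[ch] for ch in ("CFP", "YFP", "mCherry")}, gt.pixel_size
        )
        rendered = sc.render_scene(gt)
        for ch in rendered.channels:
            np.testing.assert_array_equal(img.channels[ch], rendered.channels[ch])

    def test_ground_truth_sidecar_roundtrip(self, tmp_path, exp_lawn_gt):
        paths = sc.write_scene(exp_lawn_gt, tmp_path, "demo")
        back = sc.read_ground_truth(paths["ground_truth"])
        assert back == exp_lawn_gt

    def test_flow_csv_roundtrip(self, tmp_path, flow_spec):
        df = sc.sample_flow_events(dataclasses.replace(flow_spec, n_events=500))
        path = tmp_path / "events.csv"
        sc.write_flow_csv(df, path)
        back = sc.read_flow_csv(path)
        assert list(back.columns) == list(sc.FLOW_COLUMNS)
        np.testing.assert_allclose(back["YFP_A"], df["YFP_A"], rtol=1e-12)
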