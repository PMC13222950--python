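"""Detector assembly, variant wiring, parameter and FLOP accounting."""

import numpy as np
import pytest

from dsadet import nn
from dsadet.config import detector_preset
from dsadet.detector import (
    DetectorConfig,
    build_detector,
    count_flops,
    count_params,
    forward_detect,
)
from dsadet.nn import functional as F
from dsadet.nn.tensor import Tensor, counting_macs


@pytest.fixture(scope="module")
def desk_models():
    nn.seed_all(0)
    return {
        v: build_detector(detector_preset("desk", variant=v))
        for v in ("baseline", "daspmnet_only", "hsate_only", "escu_only", "dsadet")
    }


class TestConstruction:
    def test_baseline_uses_aifi_and_plain_upsampling(self, desk_models):
        names = {n for n, _ in desk_models["baseline"].named_parameters()}
        assert any("intra.linear1" in n for n in names)  # AIFI FFN
        assert not any("alpha" in n for n in names)
        assert any("up1.lateral" in n for n in names)
        assert not any("up1.conv.dw" in n for n in names)

    def test_dsadet_contains_all_three_modules(self, desk_models):
        names = {n for n, _ in desk_models["dsadet"].named_parameters()}
        assert any("sabs" in n for n in names)  # DASPMNet
        assert any("attn.alpha" in n for n in names)  # HSATE / PLA
        assert any("up1.conv.dw" in n for n in names)  # ESCU

    def test_escu_only_differs_from_baseline_only_at_upsample_sites(self, desk_models):
        base = {n for n, _ in desk_models["baseline"].named_parameters()}
        escu = {n for n, _ in desk_models["escu_only"].named_parameters()}
        changed = base.symmetric_difference(escu)
        assert changed and all(".up1." in n or ".up2." in n for n in changed)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(variant="nonsense")

    def test_parameter_additivity_across_module_swaps(self, desk_models):
        """params(dsadet) = params(baseline) − removed + added, computed
        by name-set accounting over the three swap sites."""

        def psum(model, pred):
            return sum(p.size for n, p in model.named_parameters() if pred(n))

        full = {v: m.num_parameters() for v, m in desk_models.items()}
        d_back = (
            psum(desk_models["daspmnet_only"], lambda n: n.startswith("backbone."))
            - psum(desk_models["baseline"], lambda n: n.startswith("backbone."))
        )
        d_intra = (
            psum(desk_models["hsate_only"], lambda n: ".intra." in n)
            - psum(desk_models["baseline"], lambda n: ".intra." in n)
        )
        d_up = (
            psum(desk_models["escu_only"], lambda n: ".up1." in n or ".up2." in n)
            - psum(desk_models["baseline"], lambda n: ".up1." in n or ".up2." in n)
        )
        assert full["dsadet"] == full["baseline"] + d_back + d_intra + d_up


class TestProfiler:
    def test_linear_layer_closed_form(self):
        assert nn.Linear(10, 5).num_parameters() == 10 * 5 + 5

    def test_conv_layer_closed_form(self):
        assert nn.Conv2d(2, 4, 3).num_parameters() == 9 * 2 * 4 + 4

    def test_flop_counter_single_conv(self):
        x = Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
        w = Tensor(np.zeros((1, 1, 1, 1), dtype=np.float32))
        with counting_macs() as macs:
            F.conv2d(x, w, None)
        assert 2 * macs[0] == 8  # 2·k²·Cin·Cout·Hout·Wout

    def test_conv_flops_scale_quadratically_with_resolution(self):
        w = Tensor(np.zeros((4, 3, 3, 3), dtype=np.float32))
        def macs_at(s):
            x = Tensor(np.zeros((1, 3, s, s), dtype=np.float32))
            with counting_macs() as m:
                F.conv2d(x, w, None, padding=1)
            return m[0]
        assert macs_at(16) == 4 * macs_at(8)

    def test_desk_profile_reports(self, desk_models):
        rep = count_flops(desk_models["baseline"], 64)
        assert rep.params_millions > 0 and rep.gflops > 0
        assert rep.input_size == 64
        assert count_params(desk_models["baseline"]).params_millions == pytest.approx(
            rep.params_millions
        )


class TestPublishedStructuralBudgets:
    """Whole-model parameter budgets of the ablation grid, at the full
    preset, within the ±5% tolerance used for configurations whose stage
    widths are not published."""

    published_params = {
        "baseline": 19.9,
        "daspmnet_only": 13.6,
        "hsate_only": 21.6,
        "escu_only": 20.0,
        "dsadet": 15.4,
    }

    @pytest.mark.parametrize("variant", sorted(published_params))
    def test_parameter_budget(self, variant):
        nn.seed_all(0)
        det = build_detector(detector_preset("full", variant=variant))
        got = det.num_parameters() / 1e6
        want = self.published_params[variant]
        assert abs(got - want) / want < 0.05, (got, want)

    def test_daspmnet_strictly_lighter_than_baseline(self):
        nn.seed_all(0)
        base = build_detector(detector_preset("full", variant="baseline"))
        dasp = build_detector(detector_preset("full", variant="daspmnet_only"))
        assert dasp.num_parameters() < base.num_parameters()


class TestForwardDetect:
    def test_query_budget_and_score_range(self, desk_models, rng):
        det = desk_models["baseline"]
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        dets = forward_detect(det, img, score_threshold=0.0)
        assert len(dets) <= det.cfg.num_queries
        assert all(0.0 <= d.score <= 1.0 for d in dets)
        assert all(d.box[0] < d.box[2] and d.box[1] < d.box[3] for d in dets)

    def test_threshold_one_empties_output(self, desk_models, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        assert forward_detect(desk_models["baseline"], img, score_threshold=1.0) == []

    def test_eval_mode_deterministic(self, desk_models, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        a = forward_detect(desk_models["dsadet"], img, score_threshold=0.0)
        b = forward_detect(desk_models["dsadet"], img, score_threshold=0.0)
        assert [(d.class_id, d.score, d.box) for d in a] == [
            (d.class_id, d.score, d.box) for d in b
        ]

    def test_wrong_input_size_rejected(self, desk_models, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            forward_detect(desk_models["baseline"], img)
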