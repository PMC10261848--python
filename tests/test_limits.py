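"""LOB/LOD thresholds, the positivity rule and the VAF t-tests."""

import math

import numpy as np
import pytest
from scipy import stats

from seegmosaic import (
    DdpcrQuantResult,
    DetectionThresholds,
    NegativeControlSet,
    classify_sample,
    compute_lob,
    compute_lod,
    estimate_lambda_fp,
    single_observation_t_test,
    vaf_t_test,
)
from seegmosaic.ddpcr import qc_filter_wells, quantify_sample
from seegmosaic.pipeline import thresholds_from_simulated_controls
from seegmosaic.synthetic import (
    ElectrodeSpec,
    simulate_electrode_sample,
    simulate_negative_control_ddpcr,
)


def quant_result(fam_pos: int, vaf: float = 0.0, sample_id: str = "S") -> DdpcrQuantResult:
    return DdpcrQuantResult(
        sample_id=sample_id,
        lambda_mut=vaf * 0.04,
        lambda_wt=(1 - vaf) * 0.04,
        fractional_abundance=vaf,
        fam_pos_count=fam_pos,
        wells_used=4,
    )


class TestLambdaFp:
    def test_all_clean_controls(self):
        controls = NegativeControlSet(fam_pos_counts=[0, 0, 0, 0])
        assert estimate_lambda_fp(controls) == 0.0

    def test_mean(self):
        assert estimate_lambda_fp(NegativeControlSet([1, 0, 2, 1])) == 1.0

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            NegativeControlSet([1])

    def test_simulated_controls_recover_fp_rate(self, config):
        """20 controls x 80,000 droplets at fp 1e-5: Lambda_FP near 0.8."""
        rng = np.random.default_rng(11)
        lams = []
        for _ in range(30):
            counts = [
                quantify_sample(simulate_negative_control_ddpcr(config, rng)).fam_pos_count
                for _ in range(20)
            ]
            lams.append(np.mean(counts))
        se = np.std(lams, ddof=1) / math.sqrt(len(lams))
        assert abs(np.mean(lams) - 0.8) < 3 * se


class TestLobLod:
    # (lambda_fp, lob, lod_real, lod)
    CASES = [
        (0.0, 0.8, 4.152, 5),
        (0.8, 3.0713, 7.61, 8),
        (1.0, 3.445, 8.138, 9),
    ]

    @pytest.mark.parametrize("lam,lob,lod_real,lod", CASES)
    def test_closed_forms(self, lam, lob, lod_real, lod):
        assert compute_lob(lam) == pytest.approx(lob, abs=5e-4)
        assert compute_lod(compute_lob(lam), rounded=False) == pytest.approx(lod_real, abs=5e-3)
        assert compute_lod(compute_lob(lam)) == lod

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_lob(-0.1)
        with pytest.raises(ValueError):
            compute_lod(-0.1)

    def test_monotone_and_lod_dominates_lob(self):
        grid = np.linspace(0.0, 10.0, 401)
        lobs = [compute_lob(x) for x in grid]
        lods = [compute_lod(lob) for lob in lobs]
        assert all(b <= a for a, b in zip(lobs[1:], lobs))
        assert all(b <= a for a, b in zip(lods[1:], lods))
        assert all(lod >= lob for lob, lod in zip(lobs, lods))

    def test_ceiling_on_lod_not_lob(self):
        """Rounding the LOB before the LOD formula would inflate LOD 8 to 9."""
        lam = 0.8
        assert compute_lod(compute_lob(lam)) == 8
        assert compute_lod(math.ceil(compute_lob(lam))) == 9

    def test_applicability_flag(self):
        low = DetectionThresholds.from_controls(NegativeControlSet([0, 0, 0, 0, 0]))
        assert low.lambda_fp == 0.0 and not low.applicable
        ok = DetectionThresholds.from_controls(NegativeControlSet([1, 0, 2, 1]))
        assert ok.applicable


class TestClassification:
    def thresholds(self):  # Lambda_FP = 0.8 -> LOD 8
        return DetectionThresholds.from_controls(
            NegativeControlSet([1, 1, 1, 0, 1], scheme="per-duplicate-mean")
        )

    def test_strictly_above_lod_is_positive(self):
        th = self.thresholds()
        assert th.lod == 8
        assert classify_sample(quant_result(9, vaf=0.004), th).call == "positive"

    def test_count_at_lod_is_negative(self):
        call = classify_sample(quant_result(8, vaf=0.004), self.thresholds())
        assert call.call == "negative"
        assert call.vaf is None  # "ns" semantics

    def test_nonstrict_switch(self):
        call = classify_sample(quant_result(8, vaf=0.004), self.thresholds(), strict=False)
        assert call.call == "positive"
        assert call.vaf == 0.004

    def test_zero_count_negative_for_any_lod(self):
        assert classify_sample(quant_result(0), self.thresholds()).call == "negative"

    def test_inapplicable_thresholds_suppress_calls(self):
        th = DetectionThresholds.from_controls(NegativeControlSet([0, 0, 0, 0]))
        call = classify_sample(quant_result(50, vaf=0.01), th)
        assert call.call == "not-evaluable"
        assert "thresholds-not-applicable" in call.flags

    def test_scheme_mismatch_rejected(self):
        th = DetectionThresholds.from_controls(
            NegativeControlSet([1, 0, 2, 1], scheme="pooled")
        )
        with pytest.raises(ValueError, match="scheme"):
            classify_sample(quant_result(9), th)


class TestVafTTest:
    def test_identical_groups(self):
        t, p = vaf_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        """t = 0.4 / (0.1*sqrt(2/3)) = 4.899, p = 0.0080 at df 4."""
        t, p = vaf_t_test([0.5, 0.6, 0.7], [0.1, 0.2, 0.3])
        assert t == pytest.approx(0.4 / (0.1 * math.sqrt(2 / 3)), rel=1e-6)
        assert p == pytest.approx(2 * stats.t.sf(4.8990, 4), rel=1e-3)
        assert p == pytest.approx(0.0080, abs=5e-4)

    def test_degenerate_variance(self):
        assert vaf_t_test([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        t, p = vaf_t_test([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and t < 0

    def test_single_observation_form(self):
        ref = [0.0011, 0.0016, 0.0019, 0.0022, 0.0028]
        x = 0.0039
        t, p = single_observation_t_test(x, ref)
        mean, sd, n = np.mean(ref), np.std(ref, ddof=1), len(ref)
        t_expect = (x - mean) / (sd * math.sqrt(1 + 1 / n))
        assert t == pytest.approx(t_expect, rel=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expect), n - 1), rel=1e-9)

    def test_single_observation_at_reference_mean(self):
        t, p = single_observation_t_test(0.5, [0.4, 0.5, 0.6])
        assert t == 0.0 and p == pytest.approx(1.0)


class TestOperatingCharacteristics:
    def test_null_positive_rate_bounded(self, config):
        """False-call rate on mutation-free samples stays within the 5% design."""
        n_null, positives = 0, 0
        for batch in range(4):
            rng = np.random.default_rng(100 + batch)
            th, _ = thresholds_from_simulated_controls(config, rng)
            spec = ElectrodeSpec("N", "P", "NIN", False, False, 50.0, 0.0)
            for _ in range(500):
                res = quantify_sample(
                    qc_filter_wells(simulate_electrode_sample(spec, config, rng))
                )
                positives += classify_sample(res, th).call == "positive"
                n_null += 1
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_null)
        assert positives / n_null <= bound

    def test_sensitivity_envelope_at_and_above_lod(self, config):
        """Mutant signal at the LOD detects >= 40% of the time; at 2x LOD >= 95%."""
        rng = np.random.default_rng(77)
        th, _ = thresholds_from_simulated_controls(config, rng)
        copies = 4 * config.copies_per_well
        for factor, floor in ((1, 0.40), (2, 0.95)):
            vaf = factor * th.lod / copies  # expected mutant-droplet count = factor*LOD
            spec = ElectrodeSpec("E", "P", "EZN", False, False, 50.0, vaf)
            hits = sum(
                classify_sample(
                    quantify_sample(simulate_electrode_sample(spec, config, rng)), th
                ).call
                == "positive"
                for _ in range(400)
            )
            assert hits / 400 >= floor

    def test_null_round_trip_reports_no_vaf(self, config):
        """quantify+classify on mutation-free electrodes never asserts a VAF."""
        rng = np.random.default_rng(5)
        th, controls = thresholds_from_simulated_controls(config, rng)
        spec = ElectrodeSpec("N", "P", "NIN", False, False, 50.0, 0.0)
        for _ in range(50):
            res = quantify_sample(simulate_electrode_sample(spec, config, rng))
            call = classify_sample(res, th, controls=controls)
            if call.call != "positive":
                assert call.vaf is None
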