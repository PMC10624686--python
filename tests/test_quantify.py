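import math
import random

import numpy as np
import pytest

from spddpcr.droplet_sim import (
    Channel,
    PartitionConfig,
    SelectivityModel,
    WellCount,
    simulate_assay_run,
)
from spddpcr.errors import InputError
from spddpcr.quantify import (
    LodEstimate,
    OverUnityWarning,
    SingleReplicateWarning,
    VafMeasurement,
    aggregate_replicates,
    classify_detection,
    compute_vaf,
    estimate_lambda,
    estimate_lod,
    fit_dilution,
    mass_to_genome_equivalents,
    quantify_replicate_set,
    vaf_from_cq,
    vaf_from_reads,
)


class TestEstimateLambda:
    def test_no_positives_no_copies(self):
        est = estimate_lambda(WellCount(0, 20_000, Channel.SSP))
        assert est.lambda_per_droplet == 0.0
        assert est.copies_per_reaction == 0.0
        assert not est.saturated_flag

    def test_saturated_well_flagged(self):
        est = estimate_lambda(WellCount(100, 100, Channel.SSP))
        assert est.saturated_flag
        assert math.isinf(est.lambda_per_droplet)

    def test_closed_form_half_occupancy(self):
        est = estimate_lambda(WellCount(7869, 20_000, Channel.STANDARD))
        assert est.lambda_per_droplet == pytest.approx(0.500, abs=5e-4)

    def test_ci_contains_point_estimate(self):
        est = estimate_lambda(WellCount(5000, 20_000, Channel.SSP))
        assert est.ci95[0] <= est.lambda_per_droplet <= est.ci95[1]

    def test_monotone_in_positives(self):
        lams = [
            estimate_lambda(WellCount(p, 20_000, Channel.SSP)).lambda_per_droplet
            for p in range(0, 20_000, 500)
        ]
        assert all(a < b for a, b in zip(lams, lams[1:]))

    def test_volume_scaling(self):
        config = PartitionConfig(20_000, 0.85, 20.0)
        est = estimate_lambda(WellCount(7869, 20_000, Channel.SSP), config)
        assert est.copies_in_partition == pytest.approx(
            est.lambda_per_droplet * 20_000
        )
        assert est.copies_per_reaction == pytest.approx(
            est.copies_per_microliter * 20.0
        )


class TestVafArithmetic:
    def test_zero_and_scale_invariance(self):
        assert compute_vaf(0, 10_000) == 0.0
        assert compute_vaf(561, 10_000) == pytest.approx(
            compute_vaf(5.61, 100.0)
        )

    def test_apc_scale_example(self):
        assert compute_vaf(561, 10_000) == pytest.approx(5.61)

    def test_over_unity_warns(self):
        with pytest.warns(OverUnityWarning):
            assert compute_vaf(110, 100) == pytest.approx(110.0)

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            compute_vaf(1, 0)

    @pytest.mark.parametrize(
        "variant, total, expected",
        [
            (61, 142, 42.96),
            (4, 63, 6.35),
            (11, 152, 7.24),
            (5, 46, 10.87),
            (3, 44, 6.82),
            (4, 148, 2.70),
            (4, 146, 2.74),
        ],
    )
    def test_read_based_vaf_matches_report_rounding(self, variant, total, expected):
        assert vaf_from_reads(variant, total) == expected

    def test_read_vaf_equals_copy_vaf_before_rounding(self):
        rng = random.Random(0)
        for _ in range(50):
            total = rng.randint(1, 500)
            var = rng.randint(0, total)
            assert vaf_from_reads(var, total) == pytest.approx(
                compute_vaf(var, total), abs=0.005 + 1e-12
            )


class TestAggregate:
    def test_constant_replicates(self):
        agg = aggregate_replicates([5, 5, 5])
        assert (agg.mean, agg.sd, agg.sem) == (5.0, 0.0, 0.0)

    def test_single_value_warns_sd_zero(self):
        with pytest.warns(SingleReplicateWarning):
            agg = aggregate_replicates([2.5])
        assert (agg.mean, agg.sd, agg.n) == (2.5, 0.0, 1)

    def test_matches_textbook_formula(self):
        rng = random.Random(17)
        for _ in range(20):
            vals = [rng.uniform(0, 10) for _ in range(3)]
            agg = aggregate_replicates(vals)
            mean = sum(vals) / 3
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
            assert agg.mean == pytest.approx(mean)
            assert agg.sd == pytest.approx(sd)
            assert agg.sem == pytest.approx(sd / math.sqrt(3))


class TestLod:
    def test_worked_summary_examples(self):
        assert LodEstimate.from_summary(0.19, 0.07).lod_percent == pytest.approx(0.40)
        assert LodEstimate.from_summary(0.05, 0.03).lod_percent == pytest.approx(0.14)
        assert LodEstimate.from_summary(0.05, 0.02).lod_percent == pytest.approx(0.11)

    def test_zero_sd_lod_equals_mean(self):
        est = estimate_lod([0.1] * 9)
        assert est.lod_percent == pytest.approx(0.1)
        assert not est.low_n_warning

    def test_low_replicate_warning_flag(self):
        assert estimate_lod([0.1, 0.2, 0.3]).low_n_warning
        assert not estimate_lod([0.1, 0.2] * 5).low_n_warning

    def test_order_invariance(self):
        values = [0.08, 0.02, 0.15, 0.05, 0.11, 0.04, 0.09, 0.03, 0.07]
        a = estimate_lod(values)
        b = estimate_lod(values[::-1])
        assert a.lod_percent == pytest.approx(b.lod_percent, abs=1e-12)
        assert a.n_replicates == b.n_replicates
        assert a.low_n_warning == b.low_n_warning

    def test_too_few_measurements_rejected(self):
        with pytest.raises(InputError):
            estimate_lod([0.1])


class TestDetection:
    def _measurement(self, mean):
        return VafMeasurement(0, 1, mean, (mean,), mean, 0.0)

    def test_below_lod_not_detected(self):
        lod = LodEstimate.from_summary(0.19, 0.07)  # 0.40%
        assert classify_detection(self._measurement(0.18), lod) == "not_detected"

    def test_above_lod_detected(self):
        lod = LodEstimate.from_summary(0.05, 0.03)  # 0.14%
        assert classify_detection(self._measurement(0.51), lod) == "detected"

    def test_tie_is_not_detected(self):
        lod = LodEstimate.from_summary(0.1, 0.0)
        assert classify_detection(self._measurement(0.1), lod) == "not_detected"


class TestDilutionFit:
    def test_identity_data(self):
        fit = fit_dilution([1, 0.5, 0.25, 0.13, 0], [1, 0.5, 0.25, 0.13, 0])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_doubled_data_keeps_perfect_correlation(self):
        fit = fit_dilution([1, 0.5, 0.25], [2, 1.0, 0.5])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(2.0)

    def test_matches_normal_equations_oracle(self):
        x = [1.0, 0.5, 0.25, 0.13, 0.0]
        y = [1.08, 0.61, 0.27, 0.16, 0.02]
        n = len(x)
        sx, sy = sum(x), sum(y)
        sxx = sum(v * v for v in x)
        sxy = sum(a * b for a, b in zip(x, y))
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        fit = fit_dilution(x, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert 0 < fit.p_value <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            fit_dilution([1, 1, 1], [0, 1, 2])
        with pytest.raises(InputError):
            fit_dilution([1, 2], [1, 2])


class TestConversions:
    def test_genome_equivalents(self):
        result = mass_to_genome_equivalents(33.0)
        assert result.rounded == 10_000
        assert mass_to_genome_equivalents(0.0).exact == 0.0
        assert mass_to_genome_equivalents(33.0, 3.5).exact == pytest.approx(
            9428.5714, abs=1e-3
        )

    def test_cq_identity_and_doubling(self):
        assert vaf_from_cq(30.0, 30.0) == pytest.approx(100.0)
        assert vaf_from_cq(30.0, 30.0, efficiency=1.9) == pytest.approx(100.0)
        assert vaf_from_cq(36.64, 30.0) == pytest.approx(1.00, abs=0.01)

    def test_non_finite_cq_not_detected(self):
        assert vaf_from_cq(math.inf, 30.0) is None
        assert vaf_from_cq(math.nan, 30.0) is None

    def test_bad_efficiency_rejected(self):
        with pytest.raises(InputError):
            vaf_from_cq(30, 30, efficiency=2.5)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("truth", [10.0, 1.0, 0.25])
    def test_vaf_estimates_unbiased_with_perfect_selectivity(self, truth):
        sel = SelectivityModel(1.0, 0.0, 1.0)
        values = []
        for seed in range(40):
            rs = simulate_assay_run(truth, 10_000, 1, sel, seed=seed)
            values.append(quantify_replicate_set(rs).mean)
        arr = np.array(values)
        se = arr.std(ddof=1) / math.sqrt(arr.size)
        assert abs(arr.mean() - truth) < 2 * se + 1e-9
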