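import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinfo import infotheory as it
from retinfo.infotheory import (
    BinnedResponse,
    JointDistribution,
    bin_quanta,
    estimate_joint,
    fano_factor,
    info_rate_and_efficiency,
    mutual_information,
    shuffle_corrected_information,
)
from retinfo.quantal import QuantalSeries
from retinfo.regimes import StimulusProtocol


def _joint(table):
    table = np.asarray(table, float)
    return JointDistribution(
        stimuli=np.arange(table.shape[0]),
        quanta=np.arange(table.shape[1]),
        table=table,
    )


class TestBinning:
    def test_multi_event_bin_sums_quanta(self, caplog):
        series = QuantalSeries(
            np.array([0.005, 0.025, 0.027]), np.array([1, 1, 1]), 1.0
        )
        proto = StimulusProtocol.constant(50.0, 0.2)
        with caplog.at_level("WARNING"):
            binned = bin_quanta(series, proto)
        assert list(binned.counts[:3]) == [1, 2, 0]
        assert "more than one event" in caplog.text

    def test_empty_series_zero_bins(self):
        series = QuantalSeries(np.empty(0), np.empty(0, int), 1.0)
        binned = bin_quanta(series, StimulusProtocol.constant(10.0, 1.0))
        assert binned.counts.size == 50
        assert not binned.counts.any()
        assert binned.bin_width == 0.020

    def test_bins_labelled_by_trial_contrast(self):
        proto = StimulusProtocol(
            contrasts=(10.0, 20.0),
            schedule=((10.0, 0.1), (20.0, 0.1)),
            temporal_freq=5.0,
        )
        series = QuantalSeries(np.array([0.05, 0.15]), np.array([2, 3]), 1.0)
        binned = bin_quanta(series, proto)
        assert binned.stimuli[2] == 10.0 and binned.stimuli[7] == 20.0
        assert binned.counts[2] == 2 and binned.counts[7] == 3

    def test_alphabet_clipping_logged(self, caplog):
        series = QuantalSeries(np.array([0.005]), np.array([9]), 1.0)
        with caplog.at_level("WARNING"):
            binned = bin_quanta(series, StimulusProtocol.constant(5.0, 0.1))
        assert binned.counts.max() == it.KMAX


class TestJoint:
    def test_hand_counted_table(self):
        # {s1: 3 bins q0, 1 bin q1; s2: 2 bins q0, 2 bins q1}, uniform prior
        binned = BinnedResponse(
            counts=np.array([0, 0, 0, 1, 0, 0, 1, 1]),
            stimuli=np.array([1.0, 1, 1, 1, 2, 2, 2, 2]),
        )
        joint = estimate_joint(binned, kmax=1)
        assert joint.table[0, 0] == pytest.approx(0.375)
        assert joint.table[0, 1] == pytest.approx(0.125)
        assert joint.table[1, 0] == pytest.approx(0.25)
        assert joint.table[1, 1] == pytest.approx(0.25)

    def test_conditional_rows_normalised(self):
        rng = np.random.default_rng(0)
        binned = BinnedResponse(
            counts=rng.integers(0, 3, 400), stimuli=rng.choice([1.0, 2, 3], 400)
        )
        joint = estimate_joint(binned)
        assert np.allclose(joint.p_q_given_s.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_stimulus_rejected(self):
        binned = BinnedResponse(counts=np.array([1]), stimuli=np.array([5.0]))
        with pytest.raises(ValueError):
            estimate_joint(binned, prior=np.array([0.5, 0.5]))


class TestMutualInformation:
    def test_independence_gives_zero(self):
        joint = _joint(np.outer([0.3, 0.7], [0.5, 0.25, 0.25]))
        assert mutual_information(joint).I == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_channel_log2_11(self):
        # 11 equiprobable stimuli with distinct deterministic responses
        joint = _joint(np.eye(11) / 11.0)
        res = mutual_information(joint)
        assert res.I == pytest.approx(np.log2(11), abs=1e-12)
        assert res.H_S == pytest.approx(np.log2(11), abs=1e-12)

    def test_binary_asymmetric_channel(self):
        # direct summation over the 3-cell joint table: I ~ 0.3113 bits
        joint = _joint([[0.5, 0.0], [0.25, 0.25]])
        assert mutual_information(joint).I == pytest.approx(0.311278, abs=1e-5)

    def test_symmetry_of_mutual_information(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = rng.random((4, 5))
            joint = _joint(t / t.sum())
            res = mutual_information(joint)
            # I = H(Q) - H(Q|S) computed from the transpose
            joint_t = _joint(joint.table.T)
            res_t = mutual_information(joint_t)
            assert res.I == pytest.approx(res_t.I, abs=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_information_bounds(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.random((3, 4)) ** 3
        joint = _joint(t / t.sum())
        res = mutual_information(joint)
        h_q = -np.sum(joint.p_q[joint.p_q > 0] * np.log2(joint.p_q[joint.p_q > 0]))
        assert -1e-12 <= res.I <= min(res.H_S, h_q) + 1e-12


class TestRatesAndEfficiency:
    def test_rate_arithmetic(self):
        rate, eff = info_rate_and_efficiency(0.02, 0.020, 2.0)
        assert rate == pytest.approx(1.0)
        assert eff == pytest.approx(0.5)

    def test_zero_release_rate_flagged(self):
        rate, eff = info_rate_and_efficiency(0.02, 0.020, 0.0)
        assert np.isnan(eff)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            info_rate_and_efficiency(0.1, 0.02, -1.0)


class TestFano:
    def test_identical_counts_zero(self):
        times = np.arange(0.05, 2.0, 0.2)  # one event per cycle
        series = QuantalSeries(times, np.full(times.size, 2), 1.0)
        fano = fano_factor(series, StimulusProtocol.constant(50.0, 2.0))
        assert fano[50.0] == pytest.approx(0.0)

    def test_sample_variance_convention(self):
        # counts {1, 2, 3}: sample variance 1, mean 2 -> Fano 0.5
        times = np.array([0.05, 0.25, 0.27, 0.45, 0.47, 0.49])
        quanta = np.ones(6, int)
        series = QuantalSeries(times, quanta, 1.0)
        fano = fano_factor(series, StimulusProtocol.constant(30.0, 0.6))
        assert fano[30.0] == pytest.approx(0.5)

    def test_poisson_counts_fano_one(self):
        # 1e4 cycles of Poisson(4) counts -> Fano within 0.03 of 1
        rng = np.random.default_rng(0)
        n_cycles = 10_000
        counts = rng.poisson(4.0, n_cycles)
        times, quanta = [], []
        for i, c in enumerate(counts):
            if c:
                times.append(i * 0.2 + 0.05)
                quanta.append(c)
        series = QuantalSeries(np.array(times), np.array(quanta), 1.0)
        fano = fano_factor(series, StimulusProtocol.constant(40.0, n_cycles * 0.2))
        assert fano[40.0] == pytest.approx(1.0, abs=0.03)

    def test_needs_two_cycles(self):
        series = QuantalSeries(np.array([0.05]), np.array([1]), 1.0)
        with pytest.raises(ValueError):
            fano_factor(series, StimulusProtocol.constant(10.0, 0.2))


class TestEstimatorBias:
    def test_shuffled_information_positive_but_shrinks(self):
        # plug-in bias: I on shuffled labels > 0 and decreases with more bins
        rng = np.random.default_rng(5)
        biases = []
        for n in (200, 2000):
            binned = BinnedResponse(
                counts=rng.poisson(0.3, n), stimuli=rng.choice(np.arange(11.0), n)
            )
            raw = mutual_information(estimate_joint(binned)).I
            corrected = shuffle_corrected_information(binned, seed=1).I
            biases.append(raw - corrected)
        assert biases[0] > 0
        assert biases[1] < biases[0]

    def test_pipeline_information_not_above_ground_truth(
        self, decomposed_pm, cohort
    ):
        # data-processing-like check: information computed from recovered
        # quanta does not exceed ground truth information beyond estimator
        # noise (single fixed contrast here, so both are near zero)
        proto = StimulusProtocol.constant(100.0, 20.0)
        diffs = []
        for train, rec, series, _ in decomposed_pm:
            gt = QuantalSeries(train.event_times, train.event_quanta, 1.0)
            i_gt = mutual_information(estimate_joint(bin_quanta(gt, proto))).I
            i_est = mutual_information(
                estimate_joint(bin_quanta(series, proto))
            ).I
            diffs.append(i_est - i_gt)
        assert np.mean(diffs) < 0.05
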