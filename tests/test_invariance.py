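"""Response measure, distance metric, and the phase-invariance score."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpinv import synthetic_data as syn
from chirpinv.invariance import (
    build_tuning_curve,
    classify_chirp_sign,
    distance,
    invariance_score,
    normalize_trace,
    response_measure,
)
from chirpinv.pipeline import afferent_response_traces
from chirpinv.spiketrain import PSTH
from chirpinv.stimulus import CANONICAL_PHASES


# ---------------------------------------------------------------------------
# Independent literal implementations used as oracles


def brute_force_distance(x, y, convention="rms"):
    """Literal transcription of the distance definition, loop-based."""
    x = list(map(float, x))
    y = list(map(float, y))
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    xc = [v - mx for v in x]
    yc = [v - my for v in y]
    hr_x = (max(xc) - min(xc)) / 2.0
    hr_y = (max(yc) - min(yc)) / 2.0
    denom = max(hr_x, hr_y)
    scale = max(1.0, max(abs(v) for v in x), max(abs(v) for v in y))
    if denom <= 1e-12 * scale:
        return 0.0
    sq = sum((a - b) ** 2 for a, b in zip(xc, yc)) / len(x)
    if convention == "rms":
        return (sq ** 0.5) / denom
    return sq / denom


def brute_force_invariance(responses, stimuli, convention="rms"):
    """Literal ordered-pair transcription of the invariance definition."""
    labels = sorted(responses)

    def norm(v):
        v = [float(u) for u in v]
        m = sum(v) / len(v)
        c = [u - m for u in v]
        peak = max(abs(u) for u in c)
        return [u / peak for u in c] if peak > 0 else c

    total = 0.0
    count = 0
    for i in labels:
        for j in labels:
            if i == j:
                continue
            d_r = brute_force_distance(norm(responses[i]), norm(responses[j]), convention)
            d_s = brute_force_distance(norm(stimuli[i]), norm(stimuli[j]), convention)
            total += d_r / d_s
            count += 1
    return 1.0 - total / count


def _fake_psth(rate, binwidth=0.0001, origin=0.0):
    return PSTH(rate=np.asarray(rate, dtype=float), binwidth=binwidth, origin=origin,
                n_trials=1, smooth_window=0.006)


# ---------------------------------------------------------------------------


class TestResponseMeasure:
    def _psth_with_chirp_rate(self, chirp_rate, beat_rate=10.0):
        rate = np.full(20000, beat_rate)
        onset = 1.0
        sel = slice(round((onset + 0.0075) / 0.0001), round((onset + 0.0225) / 0.0001))
        rate[sel] = chirp_rate
        return _fake_psth(rate), onset

    def test_equal_rates_give_zero(self):
        psth, onset = self._psth_with_chirp_rate(10.0)
        assert response_measure(psth, onset).value == pytest.approx(0.0, abs=1e-12)

    def test_natural_log_convention(self):
        psth, onset = self._psth_with_chirp_rate(10.0 * np.e)
        assert response_measure(psth, onset).value == pytest.approx(1.0, rel=1e-9)

    def test_ts_window_is_20ms(self):
        # a 20 ms elevated window is fully covered at stage TS but only
        # partially drives the 15 ms afferent window... build an asymmetric
        # bump to verify the stage-dependent window length matters
        rate = np.full(20000, 10.0)
        onset = 1.0
        rate[round((onset + 0.005) / 0.0001):round((onset + 0.025) / 0.0001)] = 20.0
        by_stage = {
            stage: response_measure(_fake_psth(rate), onset, stage=stage).value
            for stage in ("afferent", "TS")
        }
        assert by_stage["afferent"] == pytest.approx(np.log(2.0), rel=1e-6)
        assert by_stage["TS"] == pytest.approx(np.log(2.0), rel=1e-6)
        # shrink the bump to 15 ms: the TS window now dilutes it
        rate2 = np.full(20000, 10.0)
        rate2[round((onset + 0.0075) / 0.0001):round((onset + 0.0225) / 0.0001)] = 20.0
        assert response_measure(_fake_psth(rate2), onset, stage="TS").value < response_measure(
            _fake_psth(rate2), onset, stage="afferent"
        ).value

    def test_silent_chirp_window_flagged_and_finite(self):
        rate = np.full(20000, 10.0)
        onset = 1.0
        rate[round((onset + 0.0) / 0.0001):round((onset + 0.04) / 0.0001)] = 0.0
        rv = response_measure(_fake_psth(rate), onset)
        assert np.isfinite(rv.value)
        assert rv.flagged

    def test_synthetic_afferent_signs(self, waves, config):
        """'+ chirps' excite and '-' chirps inhibit the model afferent."""
        model = syn.NeuronModel.default("afferent")
        _, responses, _ = afferent_response_traces(model, waves, 20, 5, config)
        for w in waves:
            if w.onset_phase < 180.0:
                assert responses[w.label].value > 0
            else:
                assert responses[w.label].value < 0


class TestClassifyChirpSign:
    def test_positive_negative_split(self):
        signs = classify_chirp_sign({"S1": 0.2, "S2": -0.3})
        assert signs == {"S1": "+", "S2": "-"}

    def test_tie_breaks_negative_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            signs = classify_chirp_sign({"S1": 0.0})
        assert signs["S1"] == "-"

    def test_gain_sign_flip_flips_classification(self, waves, config):
        pos = syn.NeuronModel.default("afferent")
        neg = syn.NeuronModel.default("afferent", gain=-pos.gain)
        _, rp, _ = afferent_response_traces(pos, waves, 10, 21, config)
        _, rn, _ = afferent_response_traces(neg, waves, 10, 21, config)
        sp = classify_chirp_sign({k: v.value for k, v in rp.items()})
        sn = classify_chirp_sign({k: v.value for k, v in rn.items()})
        assert all(sp[k] != sn[k] for k in sp)


class TestNormalizeTrace:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50),
        st.floats(0.1, 100.0),
        st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, values, a, b):
        x = np.asarray(values)
        nx, flag_x = normalize_trace(x)
        ny, flag_y = normalize_trace(a * x + b)
        assert flag_x == flag_y
        assert np.allclose(nx, ny, atol=1e-9)

    def test_constant_trace_flagged_zero(self):
        out, flag = normalize_trace(np.full(10, 3.7))
        assert flag
        assert np.all(out == 0.0)

    def test_sinusoid_peaks_at_unity(self):
        out, _ = normalize_trace(np.sin(np.linspace(0, 2 * np.pi, 1000)))
        assert out.max() == pytest.approx(1.0, abs=1e-4)
        assert out.min() == pytest.approx(-1.0, abs=1e-4)

    def test_output_bounded(self, rng):
        out, _ = normalize_trace(rng.normal(size=100))
        assert np.max(np.abs(out)) <= 1.0 + 1e-12


class TestDistance:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=50)
        assert distance(x, x) == 0.0

    def test_antisymmetric_pair_hand_value(self, rng):
        """x = -y, zero mean, half-range 1: D = 2 RMS(x)."""
        x = rng.normal(size=200)
        x -= x.mean()
        x /= (x.max() - x.min()) / 2.0  # half-range exactly 1
        rms = np.sqrt(np.mean(x ** 2))
        assert distance(x, -x) == pytest.approx(2.0 * rms, rel=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert distance(x, y) == distance(y, x)

    def test_both_constant_defined_as_zero(self):
        assert distance(np.ones(5), np.full(5, 2.0)) == 0.0

    @pytest.mark.parametrize("convention", ["rms", "squared"])
    def test_matches_brute_force_on_canonical_set(self, stim_windows, convention):
        labels = sorted(stim_windows)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                ours = distance(stim_windows[a], stim_windows[b], convention)
                oracle = brute_force_distance(stim_windows[a], stim_windows[b], convention)
                assert ours == pytest.approx(oracle, abs=1e-12)


class TestInvarianceScore:
    def test_identical_responses_score_one(self, stim_windows, rng):
        resp = {k: rng.standard_normal(40) for k in stim_windows}
        common = rng.standard_normal(40)
        resp = {k: common.copy() for k in stim_windows}
        score = invariance_score(resp, stim_windows)
        assert score.value == pytest.approx(1.0, abs=1e-12)

    def test_responses_equal_stimuli_score_zero(self, stim_windows):
        resp = {k: v.copy() for k, v in stim_windows.items()}
        score = invariance_score(resp, stim_windows)
        assert score.value == pytest.approx(0.0, abs=1e-12)

    def test_subset_pair_counts(self, stim_windows, rng):
        signs = {f"S{i}": "+" if i <= 4 else "-" for i in range(1, 9)}
        resp = {k: rng.standard_normal(30) for k in stim_windows}
        all_pairs = invariance_score(resp, stim_windows, "all", signs)
        same = invariance_score(resp, stim_windows, "++/--", signs)
        opposite = invariance_score(resp, stim_windows, "+-", signs)
        assert all_pairs.n_pairs == 56
        assert same.n_pairs == 24
        assert opposite.n_pairs == 32

    def test_degenerate_stimulus_pair_raises(self, rng):
        stim = {"S1": np.ones(10), "S2": np.ones(10)}
        resp = {"S1": rng.normal(size=10), "S2": rng.normal(size=10)}
        with pytest.raises(ValueError, match="degenerate"):
            invariance_score(resp, stim)

    def test_label_mismatch_raises(self, stim_windows, rng):
        resp = {"S1": rng.normal(size=10)}
        with pytest.raises(ValueError, match="labels"):
            invariance_score(resp, stim_windows)

    @pytest.mark.parametrize("convention", ["rms", "squared"])
    def test_matches_literal_oracle_on_random_fixtures(self, convention):
        """Vectorized implementation vs loop-based literal transcription on
        100 random fixtures, to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(5, 40)
            labels = [f"S{i}" for i in range(1, 9)]
            resp = {k: rng.standard_normal(n) for k in labels}
            stim = {k: rng.standard_normal(n) for k in labels}
            ours = invariance_score(resp, stim, convention=convention).value
            oracle = brute_force_invariance(resp, stim, convention)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_score_bounded_above_by_one(self, stim_windows, rng):
        for _ in range(20):
            resp = {k: rng.standard_normal(25) for k in stim_windows}
            assert invariance_score(resp, stim_windows).value <= 1.0

    def test_noise_monotonically_degrades_score(self, stim_windows):
        """Identical responses plus independent noise: expected score
        strictly decreases with the noise amplitude."""
        base = np.sin(np.linspace(0, np.pi, 300))
        means = []
        for amplitude in (0.05, 0.2, 0.8):
            scores = []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                resp = {
                    k: base + amplitude * rng.standard_normal(300) for k in stim_windows
                }
                scores.append(invariance_score(resp, stim_windows).value)
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


class TestTuningCurve:
    def test_flat_single_unit_curve(self):
        curve = build_tuning_curve({"u0": {p: 1.5 for p in CANONICAL_PHASES}})
        assert np.all(curve.mean == 1.5)
        assert np.all(curve.sem == 0.0)

    def test_missing_phase_raises(self):
        partial = {p: 1.0 for p in CANONICAL_PHASES[:-1]}
        with pytest.raises(ValueError, match="missing"):
            build_tuning_curve({"u0": partial})

    def test_normalized_curve_has_unit_peak(self, rng):
        resp = {
            f"u{i}": {p: rng.normal() for p in CANONICAL_PHASES} for i in range(4)
        }
        curve = build_tuning_curve(resp)
        assert np.max(np.abs(curve.normalized_mean)) == pytest.approx(1.0)

    def test_afferent_population_sign_change_at_180(self, waves, config):
        models = syn.make_population("afferent", 4, 77)
        per_unit = {}
        for u, m in enumerate(models):
            _, resp, _ = afferent_response_traces(m, waves, 15, 300 + u, config)
            per_unit[f"aff{u}"] = {
                w.onset_phase: resp[w.label].value for w in waves
            }
        curve = build_tuning_curve(per_unit)
        low = curve.phases < 180.0
        assert np.all(curve.mean[low] > 0)
        assert np.all(curve.mean[~low] < 0)


class TestDistanceScatter:
    """Per-pair response vs stimulus distances, mirroring the two coding
    regimes: faithful afferents sit on the diagonal, correlated activity
    falls below it."""

    @staticmethod
    def _ratios(responses, stim_windows):
        from itertools import combinations

        out = []
        for a, b in combinations(sorted(responses), 2):
            na, _ = normalize_trace(responses[a])
            nb, _ = normalize_trace(responses[b])
            sa, _ = normalize_trace(stim_windows[a])
            sb, _ = normalize_trace(stim_windows[b])
            out.append(distance(na, nb) / distance(sa, sb))
        return np.asarray(out)

    def test_afferent_pairs_near_diagonal_rho_below(self, waves, stim_windows, config):
        from chirpinv.pipeline import pair_correlation_traces

        model = syn.NeuronModel.default("afferent")
        aff_win, _, _ = afferent_response_traces(model, waves, 20, 55, config)
        aff_ratios = self._ratios(aff_win, stim_windows)
        assert 0.8 < aff_ratios.mean() < 1.2  # on the diagonal

        rho_win = pair_correlation_traces(model, model, waves, 20, 66, config)
        rho_ratios = self._ratios(rho_win, stim_windows)
        assert rho_ratios.mean() < 0.6  # well below the diagonal
        assert np.mean(rho_ratios < 1.0) >= 0.85
        assert rho_ratios.mean() < aff_ratios.mean()
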