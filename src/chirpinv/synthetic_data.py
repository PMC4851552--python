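"""Seeded generators for model spike trains and echo-response recordings.

The generators emulate the statistical structure of the electrosensory
hierarchy that the analysis assumes:

- **Primary (P-unit) afferents**: high baseline rate (~380 Hz), rate
  modulated by a mildly high-pass filtered copy of the AM (P-unit gain
  grows with AM frequency, so the fast chirp sweep drives them harder than
  the slow beat), independent spiking noise across neurons (no noise
  correlations).
- **ELL pyramidal cells** (hindbrain output): low baseline (~12.1 Hz),
  dual coding: a linear *tracking* component follows the high-pass AM
  drive (ON cells with positive sign, OFF cells negative), and a *burst*
  component fires a stereotyped transient — the fast-transient envelope of
  the drive — whose amplitude encodes the decoded drive strength for the
  presented waveform.  The low baseline rectifies responses of the
  non-preferred polarity at zero.
- **TS neurons** (midbrain): very low baseline (~3.35 Hz), driven by the
  rectified deviations of ON and OFF pyramidal rates above a threshold
  that beat-driven modulation does not reach, so chirps of either polarity
  excite them while the beat leaves them near baseline.
- **Echo-response recordings**: EOD-frequency traces in which the fish
  answers stimulus chirps with echo chirps whose probability is independent
  of the stimulus beat phase.

Spiking for the central stages is an inhomogeneous Poisson process with an
absolute refractory period, sampled by thinning; the hazard is compensated
for the dead time (``lambda = r / (1 - r * refractory)``) so the realized
rate matches the nominal rate trace.  Afferents instead spike as an
inhomogeneous gamma renewal process (order ``isi_shape``, default 4)
sampled by time rescaling: P-unit interspike intervals are far more
regular than Poisson (CV ~ 0.5), and that regularity sets the noise floor
of pairwise correlation measures.  The renewal density in rescaled time is
one event per unit, so the realized rate matches the rate trace exactly
with no dead-time cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from chirpinv.stimulus import CANONICAL_PHASES, AMWaveform

#: High-pass AM drive: weight of the normalized AM derivative and the
#: normalization corner frequency (Hz).  At the 4 Hz beat the derivative
#: term is negligible; at the ~60 Hz chirp sweep it raises the drive gain
#: by ~45%, emulating the rising AM-frequency tuning of the electrosensory
#: pathway.
HP_WEIGHT: float = 0.5
HP_CORNER_HZ: float = 30.0

#: TS rectification offset (Hz): ELL rate deviations must exceed their
#: baseline by this much before they excite TS.  Set well above the
#: beat-driven deviation of default ELL models (~6 Hz) and below the
#: chirp-burst deviations (~35-60 Hz), so the beat leaves TS at baseline.
TS_RECT_OFFSET_HZ: float = 15.0

#: Epoch (s, relative to chirp onset) over which the ELL burst component
#: decodes the drive strength: matches the response-measure window for
#: afferents and ELL cells (centered 15 ms after onset, 15 ms long).
DECODE_EPOCH: tuple[float, float] = (0.0075, 0.0225)

#: Scale of the decoded drive strength at which the pyramidal burst
#: saturates: bursts are threshold events with stereotyped amplitude, so
#: the burst amplitude is tanh(kappa / BURST_SATURATION) rather than
#: linear in kappa.
BURST_SATURATION: float = 0.2

__all__ = [
    "NeuronModel",
    "SpikeTrainSet",
    "EchoProtocol",
    "EchoExperimentTrace",
    "am_drive",
    "afferent_rate",
    "pyramidal_drive",
    "transient_envelope",
    "decoded_strength",
    "pyramidal_rate",
    "ts_rate",
    "simulate_afferent_trials",
    "simulate_afferent_pair",
    "simulate_pyramidal_trials",
    "simulate_ts_trials",
    "simulate_echo_experiment",
    "make_population",
    "eod_voltage_from_frequency",
    "write_spikes",
    "read_spikes",
    "STAGE_DEFAULTS",
]

#: Per-stage defaults.  Baselines follow the reported means for P-unit
#: afferents, ELL pyramidal cells, and TS neurons; gains are free
#: parameters of the generator chosen so afferents encode the AM
#: faithfully (deep rate modulation), pyramidal responses rectify at zero
#: for the non-preferred polarity, and TS chirp responses are strongly
#: suprathreshold while the beat leaves TS at baseline.
STAGE_DEFAULTS: dict[str, dict] = {
    "afferent": {
        "baseline_rate": 380.0, "baseline_sd": 72.0, "gain": 0.8,
        "refractory": 0.0, "isi_shape": 4.0,
    },
    "ELL_ON": {
        "baseline_rate": 12.1, "baseline_sd": 1.74, "gain": 4.0,
        "track_gain": 0.5, "refractory": 0.002, "isi_shape": 1.0,
    },
    "ELL_OFF": {
        "baseline_rate": 12.1, "baseline_sd": 1.74, "gain": 4.0,
        "track_gain": 0.5, "refractory": 0.002, "isi_shape": 1.0,
    },
    "TS": {
        "baseline_rate": 3.35, "baseline_sd": 3.27, "gain": 1.5,
        "refractory": 0.002, "isi_shape": 1.0,
    },
}

_STAGES = tuple(STAGE_DEFAULTS)


@dataclass(frozen=True)
class NeuronModel:
    """Rate-model parameters for one simulated neuron."""

    stage: str
    baseline_rate: float
    gain: float
    threshold: float = 0.0
    refractory: float = 0.001
    isi_shape: float = 1.0
    track_gain: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if self.isi_shape < 1.0:
            raise ValueError("isi_shape must be at least 1 (1 = Poisson)")

    @classmethod
    def default(cls, stage: str, seed: int | None = None, **overrides) -> "NeuronModel":
        params = STAGE_DEFAULTS[stage]
        kw = {
            "baseline_rate": params["baseline_rate"],
            "gain": params["gain"],
            "refractory": params["refractory"],
            "isi_shape": params["isi_shape"],
            "track_gain": params.get("track_gain", 0.0),
        }
        kw.update(overrides)
        return cls(stage=stage, seed=seed, **kw)


@dataclass
class SpikeTrainSet:
    """Spike times organized by neuron id x waveform label x trial."""

    spikes: dict[tuple[str, str], list[np.ndarray]]
    duration: float
    n_trials: int

    def trials(self, neuron_id: str, label: str) -> list[np.ndarray]:
        return self.spikes[(neuron_id, label)]

    def neuron_ids(self) -> list[str]:
        return sorted({k[0] for k in self.spikes})

    def labels(self) -> list[str]:
        return sorted({k[1] for k in self.spikes})

    def merge(self, other: "SpikeTrainSet") -> "SpikeTrainSet":
        if other.duration != self.duration or other.n_trials != self.n_trials:
            raise ValueError("incompatible spike-train sets")
        merged = dict(self.spikes)
        merged.update(other.spikes)
        return SpikeTrainSet(merged, self.duration, self.n_trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (neuron, label), trials in sorted(self.spikes.items()):
            for trial, times in enumerate(trials):
                for t in times:
                    rows.append((neuron, label, trial, t))
        return pd.DataFrame(
            rows, columns=["neuron_id", "waveform_label", "trial", "spike_time_s"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, duration: float, n_trials: int
    ) -> "SpikeTrainSet":
        spikes: dict[tuple[str, str], list[np.ndarray]] = {}
        for (neuron, label), group in frame.groupby(["neuron_id", "waveform_label"]):
            trials = [np.empty(0) for _ in range(n_trials)]
            for trial, sub in group.groupby("trial"):
                trials[int(trial)] = np.sort(sub["spike_time_s"].to_numpy())
            spikes[(str(neuron), str(label))] = trials
        return cls(spikes, duration, n_trials)


def _sample_gamma_renewal(
    rate: np.ndarray,
    sample_rate: float,
    duration: float,
    shape: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trial of inhomogeneous gamma-renewal spiking via time rescaling.

    Rescaled time ``Lambda(t) = integral r dt`` turns the process into a
    stationary renewal process with gamma(shape, 1/shape) intervals (unit
    mean, CV = 1/sqrt(shape)); event times map back through the inverse of
    ``Lambda``.
    """
    t = np.arange(rate.size) / sample_rate
    lam = np.concatenate([[0.0], np.cumsum((rate[:-1] + rate[1:]) / 2.0)]) / sample_rate
    total = lam[-1]
    if total <= 0:
        return np.empty(0)
    n_expect = int(total + 6 * np.sqrt(total) + 20)
    increments = rng.gamma(shape, 1.0 / shape, size=n_expect)
    rescaled = np.cumsum(increments)
    while rescaled.size and rescaled[-1] < total:
        increments = rng.gamma(shape, 1.0 / shape, size=n_expect)
        rescaled = np.concatenate([rescaled, rescaled[-1] + np.cumsum(increments)])
    rescaled = rescaled[rescaled < total]
    spikes = np.interp(rescaled, lam, t)
    return spikes[spikes < duration]


def _sample_refractory_poisson(
    rate: np.ndarray,
    sample_rate: float,
    duration: float,
    refractory: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One trial of refractory-Poisson spiking from a rate trace (thinning).

    The hazard is dead-time compensated so the realized mean rate matches
    the rate trace; ``r * refractory`` is capped at 0.95 to keep the
    compensation finite.
    """
    occupancy = np.minimum(rate * refractory, 0.95)
    hazard = rate / (1.0 - occupancy)
    bound = float(hazard.max())
    if bound <= 0:
        return np.empty(0)
    n_expect = int(bound * duration + 6 * np.sqrt(bound * duration) + 20)
    gaps = rng.exponential(1.0 / bound, size=n_expect)
    candidates = np.cumsum(gaps)
    while candidates.size and candidates[-1] < duration:
        gaps = rng.exponential(1.0 / bound, size=n_expect)
        candidates = np.concatenate([candidates, candidates[-1] + np.cumsum(gaps)])
    candidates = candidates[candidates < duration]
    u = rng.random(candidates.size)
    idx = np.minimum((candidates * sample_rate).astype(int), rate.size - 1)
    accepted = u < hazard[idx] / bound
    spikes = []
    last = -np.inf
    for t, ok in zip(candidates, accepted):
        if ok and t - last >= refractory:
            spikes.append(t)
            last = t
    return np.asarray(spikes)


def _check_trials(n_trials: int) -> None:
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")


def as_seedseq(seed) -> np.random.SeedSequence:
    """Coerce an int seed (or pass a SeedSequence through) for spawning."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def am_drive(
    wave: AMWaveform,
    smooth: float = 0.002,
    hp_weight: float = HP_WEIGHT,
    hp_corner: float = HP_CORNER_HZ,
) -> np.ndarray:
    """High-pass AM drive shared by the afferent and pyramidal stages.

    ``H(t) = S(t) + hp_weight * S'(t) / (2 pi hp_corner)``, boxcar smoothed
    over ``smooth`` seconds.  The derivative term leaves the slow beat
    essentially untouched while boosting the drive during the fast
    frequency sweep of a chirp.
    """
    fs = wave.sample_rate
    deriv = np.gradient(wave.samples) * fs / (2.0 * np.pi * hp_corner)
    drive = wave.samples + hp_weight * deriv
    width = max(1, int(round(smooth * fs)))
    return uniform_filter1d(drive, size=width, mode="nearest")


def afferent_rate(model: NeuronModel, wave: AMWaveform) -> np.ndarray:
    """Afferent rate trace: baseline modulated by the AM drive, rectified."""
    return np.maximum(
        model.threshold, model.baseline_rate * (1.0 + model.gain * am_drive(wave))
    )


def pyramidal_drive(wave: AMWaveform, smooth: float = 0.005) -> np.ndarray:
    """Smoothed AM-deviation drive for pyramidal cells (5 ms boxcar)."""
    return am_drive(wave, smooth=smooth)


def transient_envelope(
    wave: AMWaveform, slow: float = 0.025, rms_window: float = 0.010
) -> np.ndarray:
    """Envelope of the fast-transient content of the AM drive.

    The drive minus its 25 ms running mean isolates components faster than
    the beat; the sliding RMS (10 ms) of that residue is near zero during
    the undisturbed beat and rises during the chirp sweep in a way that is
    almost independent of the onset phase — the stereotyped temporal shape
    of pyramidal-cell bursts.
    """
    fs = wave.sample_rate
    drive = pyramidal_drive(wave)
    slow_part = uniform_filter1d(drive, max(1, int(round(slow * fs))), mode="nearest")
    fast = drive - slow_part
    power = uniform_filter1d(fast * fast, max(1, int(round(rms_window * fs))), mode="nearest")
    return np.sqrt(power)


def decoded_strength(wave: AMWaveform) -> float:
    """Signed drive strength over the decode epoch after chirp onset.

    The mean of the AM drive over the response epoch (15 ms window centered
    15 ms after onset): positive for waveforms that excite afferents
    ('+ chirps'), negative for those that inhibit them.  Sets the burst
    amplitude of model pyramidal cells.
    """
    fs = wave.sample_rate
    drive = pyramidal_drive(wave)
    i0 = int(round((wave.chirp_onset_time + DECODE_EPOCH[0]) * fs))
    i1 = int(round((wave.chirp_onset_time + DECODE_EPOCH[1]) * fs))
    return float(drive[i0:i1].mean())


def pyramidal_rate(model: NeuronModel, wave: AMWaveform, smooth: float = 0.005) -> np.ndarray:
    """ON/OFF pyramidal rate: tracking plus stereotyped burst component.

    ``r = max(0, b * (1 +/- [track_gain * H(t) + gain * tanh(kappa / k0) * E(t)]))``
    where ``H`` is the smoothed AM drive, ``E`` the fast-transient
    envelope, and ``kappa`` the decoded drive strength for this waveform
    (sign + for ON cells, - for OFF cells; ``k0`` the burst saturation).
    ON cells burst for '+ chirps' and are rectified silent for
    '- chirps'; OFF cells mirror them.
    """
    if model.stage not in ("ELL_ON", "ELL_OFF"):
        raise ValueError("model.stage must be ELL_ON or ELL_OFF")
    sign = 1.0 if model.stage == "ELL_ON" else -1.0
    drive = pyramidal_drive(wave, smooth)
    amp = np.tanh(decoded_strength(wave) / BURST_SATURATION)
    burst = model.gain * amp * transient_envelope(wave)
    mod = model.track_gain * drive + burst
    return np.maximum(model.threshold, model.baseline_rate * (1.0 + sign * mod))


def ts_rate(
    model: NeuronModel,
    on_drive: np.ndarray,
    off_drive: np.ndarray,
    on_baseline: float,
    off_baseline: float,
    rect_offset: float | None = None,
) -> np.ndarray:
    """TS rate: baseline plus rectified excitatory ON and OFF deviations.

    ``r = max(threshold, baseline + w * [(on - on_base - theta)+ +
    (off - off_base - theta)+])`` with ``w = model.gain`` and ``theta``
    the rectification offset.  Beat-driven ELL modulation stays below the
    offset, so the beat leaves TS at baseline while chirp bursts of either
    polarity excite it.
    """
    if rect_offset is None:
        rect_offset = TS_RECT_OFFSET_HZ
    if model.stage != "TS":
        raise ValueError("model.stage must be TS")
    if on_drive.shape != off_drive.shape:
        raise ValueError("ON and OFF drive traces must have equal length")
    exc = np.maximum(on_drive - on_baseline - rect_offset, 0.0) + np.maximum(
        off_drive - off_baseline - rect_offset, 0.0
    )
    return np.maximum(model.threshold, model.baseline_rate + model.gain * exc)


def _simulate_set(
    neuron_id: str,
    rate: np.ndarray,
    sample_rate: float,
    duration: float,
    label: str,
    model: NeuronModel,
    n_trials: int,
    seed,
) -> SpikeTrainSet:
    rng = np.random.default_rng(seed)
    if model.isi_shape > 1.0:
        trials = [
            _sample_gamma_renewal(rate, sample_rate, duration, model.isi_shape, rng)
            for _ in range(n_trials)
        ]
    else:
        trials = [
            _sample_refractory_poisson(rate, sample_rate, duration, model.refractory, rng)
            for _ in range(n_trials)
        ]
    return SpikeTrainSet({(neuron_id, label): trials}, duration, n_trials)


def simulate_afferent_trials(
    model: NeuronModel,
    wave: AMWaveform,
    n_trials: int,
    seed,
    neuron_id: str = "aff0",
) -> SpikeTrainSet:
    """Independent trials of one model afferent responding to one waveform."""
    if model.stage != "afferent":
        raise ValueError("model.stage must be afferent")
    _check_trials(n_trials)
    rate = afferent_rate(model, wave)
    return _simulate_set(
        neuron_id, rate, wave.sample_rate, wave.duration, wave.label,
        model, n_trials, seed,
    )


def simulate_afferent_pair(
    model_i: NeuronModel,
    model_j: NeuronModel,
    wave: AMWaveform,
    n_trials: int,
    seed,
    ids: tuple[str, str] = ("aff_i", "aff_j"),
) -> tuple[SpikeTrainSet, SpikeTrainSet]:
    """Two afferents with shared stimulus drive and independent spiking noise."""
    ss = as_seedseq(seed)
    seed_i, seed_j = ss.spawn(2)
    set_i = simulate_afferent_trials(model_i, wave, n_trials, seed_i, ids[0])
    set_j = simulate_afferent_trials(model_j, wave, n_trials, seed_j, ids[1])
    return set_i, set_j


def simulate_pyramidal_trials(
    model: NeuronModel,
    wave: AMWaveform,
    n_trials: int,
    seed,
    neuron_id: str = "ell0",
    smooth: float = 0.005,
) -> SpikeTrainSet:
    """Independent trials of one ON- or OFF-type pyramidal cell."""
    _check_trials(n_trials)
    rate = pyramidal_rate(model, wave, smooth)
    return _simulate_set(
        neuron_id, rate, wave.sample_rate, wave.duration, wave.label,
        model, n_trials, seed,
    )


def simulate_ts_trials(
    on_drive: np.ndarray,
    off_drive: np.ndarray,
    model: NeuronModel,
    n_trials: int,
    seed,
    sample_rate: float,
    label: str,
    on_baseline: float,
    off_baseline: float,
    neuron_id: str = "ts0",
) -> SpikeTrainSet:
    """Independent trials of one TS neuron driven by pyramidal rate traces."""
    _check_trials(n_trials)
    rate = ts_rate(model, on_drive, off_drive, on_baseline, off_baseline)
    duration = rate.size / sample_rate
    return _simulate_set(
        neuron_id, rate, sample_rate, duration, label,
        model, n_trials, seed,
    )


def make_population(stage: str, n: int, seed, jitter: bool = True) -> list[NeuronModel]:
    """Draw ``n`` neuron models with realistic baseline-rate heterogeneity.

    Baselines are drawn from a normal distribution with the stage's reported
    mean and SD, truncated below at 10% of the mean (at 0.5 Hz minimum for
    TS, whose reported SD is comparable to its mean).
    """
    params = STAGE_DEFAULTS[stage]
    rng = np.random.default_rng(seed)
    models = []
    floor = max(0.5, 0.1 * params["baseline_rate"])
    for _ in range(n):
        if jitter:
            base = float(rng.normal(params["baseline_rate"], params["baseline_sd"]))
            base = max(base, floor)
        else:
            base = params["baseline_rate"]
        models.append(
            NeuronModel(
                stage=stage,
                baseline_rate=base,
                gain=params["gain"],
                refractory=params["refractory"],
                isi_shape=params["isi_shape"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# Behavioral echo experiment


@dataclass(frozen=True)
class EchoProtocol:
    """Stimulus schedule for the echo-response experiment.

    Forty stimulus chirps per fish: each of the eight onset phases presented
    ``n_per_phase`` = 5 times in randomized order, separated by
    15 +/- 3 s (uniform), with recording starting 200 ms before the first
    onset and a 2 s analysis tail after each.
    """

    phases: tuple[float, ...] = CANONICAL_PHASES
    n_per_phase: int = 5
    inter_onset_mean: float = 15.0
    inter_onset_jitter: float = 3.0
    pre_record: float = 0.2
    tail: float = 3.0
    sample_rate: float = 1000.0
    eod_baseline: float = 800.0
    freq_noise_sd: float = 1.0


@dataclass
class EchoExperimentTrace:
    """A simulated EOD-frequency recording with ground-truth echo times."""

    eod_frequency: np.ndarray
    sample_rate: float
    stimulus_onsets: np.ndarray  # onset times (s)
    stimulus_phases: np.ndarray  # onset phase (deg) per stimulus
    true_echo_times: np.ndarray  # injected echo centers (s)
    true_echo_peaks: np.ndarray  # injected peak excursions (Hz)
    eod_baseline: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.eod_frequency.size) / self.sample_rate


def default_latency_sampler(rng: np.random.Generator) -> float:
    """Gamma-distributed echo latency, mean 0.4 s, truncated to (0, 1] s."""
    while True:
        lat = rng.gamma(4.0, 0.1)
        if 0.0 < lat <= 1.0:
            return lat


def simulate_echo_experiment(
    protocol: EchoProtocol | None = None,
    p_echo: float = 0.4,
    latency_sampler=None,
    seed=None,
) -> EchoExperimentTrace:
    """Simulate one fish's echo-response session.

    After each stimulus onset the fish emits an echo chirp with probability
    ``p_echo``, *independent of the stimulus onset phase*.  Echo excursions
    are Gaussian bumps in the EOD-frequency trace with small-chirp peak
    statistics (normal(60, 15) Hz truncated to [40, 140] Hz, width ~12 ms),
    so every injected echo exceeds the 30 Hz detection criterion.
    """
    if protocol is None:
        protocol = EchoProtocol()
    if latency_sampler is None:
        latency_sampler = default_latency_sampler
    if not 0.0 <= p_echo <= 1.0:
        raise ValueError("p_echo must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    phases = np.repeat(protocol.phases, protocol.n_per_phase)
    rng.shuffle(phases)
    n_stim = phases.size
    gaps = rng.uniform(
        protocol.inter_onset_mean - protocol.inter_onset_jitter,
        protocol.inter_onset_mean + protocol.inter_onset_jitter,
        size=n_stim,
    )
    onsets = protocol.pre_record + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    duration = onsets[-1] + protocol.tail
    n = int(round(duration * protocol.sample_rate))
    freq = np.full(n, protocol.eod_baseline)
    if protocol.freq_noise_sd > 0:
        freq = freq + rng.normal(0.0, protocol.freq_noise_sd, size=n)
    t = np.arange(n) / protocol.sample_rate
    echo_times = []
    echo_peaks = []
    for onset in onsets:
        if rng.random() < p_echo:
            lat = latency_sampler(rng)
            center = onset + lat
            peak = float(np.clip(rng.normal(60.0, 15.0), 40.0, 140.0))
            width = float(np.clip(rng.normal(0.012, 0.002), 0.008, 0.020))
            z = (t - center) / width
            near = np.abs(z) < 6.0
            freq[near] += peak * np.exp(-0.5 * z[near] ** 2)
            echo_times.append(center)
            echo_peaks.append(peak)
    return EchoExperimentTrace(
        eod_frequency=freq,
        sample_rate=protocol.sample_rate,
        stimulus_onsets=onsets,
        stimulus_phases=np.asarray(phases, dtype=float),
        true_echo_times=np.asarray(echo_times),
        true_echo_peaks=np.asarray(echo_peaks),
        eod_baseline=protocol.eod_baseline,
    )


def eod_voltage_from_frequency(
    freq: np.ndarray, sample_rate_in: float, sample_rate_out: float = 20_000.0
) -> tuple[np.ndarray, float]:
    """Synthesize a unit-amplitude EOD voltage carrier from a frequency trace."""
    t_in = np.arange(freq.size) / sample_rate_in
    n_out = int(round(t_in[-1] * sample_rate_out))
    t_out = np.arange(n_out) / sample_rate_out
    f_out = np.interp(t_out, t_in, freq)
    phase = 2.0 * np.pi * np.cumsum(f_out) / sample_rate_out
    return np.sin(phase), sample_rate_out


# ---------------------------------------------------------------------------
# I/O


def write_spikes(sts: SpikeTrainSet, path: str | Path, params: dict | None = None) -> None:
    """Write a spike set as delimited text with a JSON sidecar."""
    path = Path(path)
    sts.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {"duration": sts.duration, "n_trials": sts.n_trials}
    if params:
        sidecar.update(params)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_spikes(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SpikeTrainSet.from_frame(frame, sidecar["duration"], int(sidecar["n_trials"]))
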