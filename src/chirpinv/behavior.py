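"""Behavioral echo-response pipeline.

A restrained fish answers stimulus chirps with echo chirps of its own.  The
pipeline extracts the instantaneous EOD frequency from a recording (inverse
inter-zero-crossing intervals for voltage input), detects chirp events as
EOD-frequency excursions exceeding 30 Hz above baseline, types them as
small (type II) or big (type I), and quantifies the echo response per
stimulus presentation: echo-chirp rate in the 1 s window after stimulus
onset (``CR_chirp``), the rate in the 1-2 s beat window (``CR_beat``),
response latency, and the log rate ratio.  Pooled event PSTHs smoothed with
a 1 s boxcar provide the response input for behavioral invariance scores,
and a moving-block bootstrap (block size 27) provides standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencyTrace",
    "ChirpEvent",
    "EchoStats",
    "instantaneous_frequency",
    "detect_chirps",
    "classify_chirp_type",
    "echo_metrics",
    "behavioral_psth",
    "block_bootstrap_sem",
    "CHIRP_THRESHOLD_HZ",
    "BIG_CHIRP_THRESHOLD_HZ",
]

#: Minimum EOD-frequency excursion (Hz above baseline) that counts as a chirp.
CHIRP_THRESHOLD_HZ: float = 30.0

#: Excursions at or above this peak (Hz) are big (type I) chirps.  The
#: boundary between small and big chirps is not sharply standardized; 150 Hz
#: comfortably separates the two natural clusters and is configurable.
BIG_CHIRP_THRESHOLD_HZ: float = 150.0


@dataclass(frozen=True)
class FrequencyTrace:
    """Instantaneous EOD frequency (Hz) on a uniform time grid."""

    frequency: np.ndarray
    sample_rate: float
    origin: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.origin + np.arange(self.frequency.size) / self.sample_rate


@dataclass(frozen=True)
class ChirpEvent:
    """One detected chirp: time of maximal excursion, its size, and type."""

    time: float
    peak_excursion: float
    chirp_type: str  # "I" or "II"


@dataclass(frozen=True)
class EchoStats:
    """Echo-response metrics for one stimulus presentation."""

    cr_chirp: float  # events/s in (0, 1] s after onset
    cr_beat: float  # events/s in (1, 2] s after onset
    latency: float | None  # s to first event in (0, 1], None if none
    behavior_response: float  # ln(max(CR_chirp, floor)/max(CR_beat, floor))


def instantaneous_frequency(
    signal: np.ndarray,
    sample_rate: float,
    kind: str = "voltage",
    resample_rate: float | None = None,
) -> FrequencyTrace:
    """Instantaneous EOD frequency from a voltage or frequency trace.

    For voltage input the frequency is the inverse of the interval between
    successive upward zero crossings (located by linear interpolation),
    assigned at the left crossing and resampled to a uniform grid by
    previous-value interpolation.  Frequency-trace input passes through
    unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if kind == "frequency":
        return FrequencyTrace(frequency=signal, sample_rate=sample_rate)
    if kind != "voltage":
        raise ValueError("kind must be 'voltage' or 'frequency'")
    s0 = signal[:-1]
    s1 = signal[1:]
    up = np.nonzero((s0 < 0) & (s1 >= 0))[0]
    if up.size < 2:
        raise ValueError("fewer than 2 upward zero crossings in the voltage trace")
    # linear interpolation of the crossing instant inside each sample
    frac = -s0[up] / (s1[up] - s0[up])
    crossings = (up + frac) / sample_rate
    freqs = 1.0 / np.diff(crossings)
    if resample_rate is None:
        resample_rate = 1000.0
    n = int(np.floor(crossings[-1] * resample_rate)) + 1
    grid = np.arange(n) / resample_rate
    idx = np.searchsorted(crossings[:-1], grid, side="right") - 1
    idx = np.clip(idx, 0, freqs.size - 1)
    return FrequencyTrace(frequency=freqs[idx], sample_rate=resample_rate)


def detect_chirps(
    freq: FrequencyTrace,
    baseline_window: tuple[float, float],
    threshold: float = CHIRP_THRESHOLD_HZ,
    merge_gap: float = 0.020,
    big_threshold: float = BIG_CHIRP_THRESHOLD_HZ,
) -> list[ChirpEvent]:
    """Detect chirps as contiguous excursions above baseline exceeding 30 Hz.

    The baseline is the median EOD frequency over ``baseline_window``
    (absolute times).  Each contiguous supra-threshold excursion yields one
    event at its maximal excursion; events separated by less than 20 ms are
    merged (the larger peak wins).
    """
    t = freq.times
    sel = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(np.median(freq.frequency[sel]))
    excursion = freq.frequency - baseline
    above = excursion > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    events: list[ChirpEvent] = []
    for a, b in zip(starts, ends):
        k = a + int(np.argmax(excursion[a:b]))
        peak = float(excursion[k])
        ev = ChirpEvent(
            time=float(t[k]),
            peak_excursion=peak,
            chirp_type=classify_chirp_type(peak, big_threshold),
        )
        if events and ev.time - events[-1].time < merge_gap:
            if ev.peak_excursion > events[-1].peak_excursion:
                events[-1] = ev
        else:
            events.append(ev)
    return events


def classify_chirp_type(
    peak_excursion: float, big_threshold: float = BIG_CHIRP_THRESHOLD_HZ
) -> str:
    """Type I (big) if the peak excursion reaches the big-chirp threshold."""
    return "I" if peak_excursion >= big_threshold else "II"


def echo_metrics(
    events: list[ChirpEvent],
    stimulus_onset: float,
    trace_end: float,
    rate_floor: float = 1.0,
) -> EchoStats:
    """Echo-response rate, latency, and log rate ratio for one presentation.

    ``CR_chirp`` counts echo chirps in ``(onset, onset + 1 s]``; ``CR_beat``
    counts them in ``(onset + 1 s, onset + 2 s]``.  Latency is the time from
    onset to the first echo chirp in the response window (None if there is
    none).  The log ratio floors both rates at one event per window
    (1 /s by default) to stay finite when the beat window is empty.
    """
    if trace_end - stimulus_onset < 2.0:
        raise ValueError("need at least a 2 s tail after stimulus onset")
    times = np.asarray([ev.time for ev in events], dtype=float)
    rel = times - stimulus_onset
    in_chirp = rel[(rel > 0.0) & (rel <= 1.0)]
    in_beat = rel[(rel > 1.0) & (rel <= 2.0)]
    cr_chirp = float(in_chirp.size) / 1.0
    cr_beat = float(in_beat.size) / 1.0
    latency = float(in_chirp.min()) if in_chirp.size else None
    response = float(np.log(max(cr_chirp, rate_floor) / max(cr_beat, rate_floor)))
    return EchoStats(
        cr_chirp=cr_chirp, cr_beat=cr_beat, latency=latency, behavior_response=response
    )


def behavioral_psth(
    event_times: np.ndarray,
    n_presentations: int,
    span: tuple[float, float] = (-0.2, 2.0),
    binwidth: float = 0.01,
    smooth: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled echo-chirp rate around stimulus onset, 1 s boxcar smoothed.

    ``event_times`` are echo-chirp times relative to stimulus onset pooled
    over presentations (and fish).  Returns ``(times, rate)`` with the rate
    in events per second per presentation.  Edge bins average over the part
    of the boxcar inside the span, so the trace length is preserved (the
    smoothing window is wide relative to the span).
    """
    if n_presentations < 1:
        raise ValueError("n_presentations must be at least 1")
    event_times = np.asarray(event_times, dtype=float)
    start, end = span
    n_bins = int(round((end - start) / binwidth))
    idx = np.floor((event_times - start) / binwidth + 1e-12).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    rate = counts / (binwidth * n_presentations)
    width = max(1, int(round(smooth / binwidth)))
    if width > 1:
        kernel = np.ones(width)
        num = np.convolve(rate, kernel, mode="same")
        den = np.convolve(np.ones_like(rate), kernel, mode="same")
        rate = num / den
    times = start + (np.arange(n_bins) + 0.5) * binwidth
    return times, rate


def block_bootstrap_sem(
    series: np.ndarray,
    statistic=np.mean,
    block: int = 27,
    n_boot: int = 1000,
    seed=None,
) -> float:
    """Moving-block bootstrap standard error of a statistic.

    Contiguous blocks of ``block`` samples are resampled with replacement
    and concatenated to the original length; the SEM estimate is the
    standard deviation of the statistic over ``n_boot`` resamples.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < block:
        raise ValueError("series shorter than the block size")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block + 1
    stats = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        resampled = np.concatenate([series[s : s + block] for s in starts])[:n]
        stats[b] = statistic(resampled)
    return float(np.std(stats, ddof=1))
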