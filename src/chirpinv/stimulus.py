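"""Chirp-on-beat amplitude-modulation stimulus synthesis.

When two wave-type electric fish are close, interference of their electric
organ discharges (EODs) produces a sinusoidal amplitude modulation (the
*beat*) at the difference frequency ``f_beat``.  A small (type II) chirp is a
brief Gaussian excursion of the emitter's EOD frequency; seen by the
receiver, it transiently accelerates the beat and resets its phase.  The
same chirp can start at any phase of the beat cycle, and each onset phase
produces a markedly different AM waveform.

This module synthesizes the AM envelope directly as ``S(t) = sin(phi(t))``
with ``phi(t) = 2*pi * integral(f_beat + g(tau)) dtau + phi0``, where ``g``
is the Gaussian frequency excursion of the chirp.  The EOD carrier is not
modeled: every downstream statistic operates on the AM alone.

Conventions
-----------
*Chirp onset* is the time at which the frequency excursion begins: the
Gaussian center trails the onset mark by 2.25 standard deviations, so the
excursion is at ~8% of its peak at onset and the bulk of the perturbation
follows it.  *Beat phase* is referenced to the beat trough: 0 deg at the
AM minimum, 90 deg at the upward zero crossing, 180 deg at the beat peak.
The onset phase of a chirp is the total beat phase at ``chirp_onset_time``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "ChirpSpec",
    "BeatSpec",
    "AMWaveform",
    "CANONICAL_PHASES",
    "gaussian_frequency_excursion",
    "synthesize_am_waveform",
    "make_waveform_set",
    "beat_phase_at",
    "write_waveform",
    "read_waveform",
]

#: Canonical onset phases (degrees): 0 to 315 in 45-degree increments.
CANONICAL_PHASES: tuple[float, ...] = tuple(float(p) for p in range(0, 360, 45))

#: The Gaussian excursion center trails the chirp-onset mark by this many
#: standard deviations (the excursion is at ~4% of peak at onset).
CENTER_OFFSET_SIGMA: float = 2.5


@dataclass(frozen=True)
class ChirpSpec:
    """A small (type II) chirp: a Gaussian EOD-frequency excursion.

    Parameters
    ----------
    delta_f:
        Peak frequency excursion in Hz (default 60).
    sigma:
        Standard deviation of the Gaussian excursion in seconds
        (default 14 ms).
    onset_phase:
        Beat phase at chirp onset, degrees in [0, 360).
    """

    delta_f: float = 60.0
    sigma: float = 0.014
    onset_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_f < 0:
            raise ValueError("delta_f must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.onset_phase < 360.0:
            raise ValueError("onset_phase must lie in [0, 360)")

    @property
    def phase_advance_cycles(self) -> float:
        """Total beat-phase advance caused by the chirp, in cycles.

        Closed form of the Gaussian integral:
        ``delta_f * sigma * sqrt(2*pi)`` (about 2.106 cycles for the
        default 60 Hz / 14 ms chirp).
        """
        return self.delta_f * self.sigma * np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class BeatSpec:
    """The underlying beat: AM frequency, trace length and sampling rate."""

    f_beat: float = 4.0
    duration: float = 2.0
    sample_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.f_beat <= 0:
            raise ValueError("f_beat must be positive")
        if self.sample_rate < 2_000.0:
            raise ValueError("sample_rate must be at least 2 kHz")
        if self.duration < 2.0 / self.f_beat:
            raise ValueError("duration must cover at least one beat cycle on each side of the chirp")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.arange(n) / self.sample_rate


@dataclass(frozen=True)
class AMWaveform:
    """One sampled AM stimulus waveform with its chirp-onset bookkeeping."""

    samples: np.ndarray
    sample_rate: float
    chirp_onset_time: float
    onset_phase: float
    label: str
    f_beat: float
    delta_f: float = 60.0
    sigma: float = 0.014
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def window(self, start: float, length: float) -> np.ndarray:
        """Samples in the half-open interval [start, start + length)."""
        i0 = int(round(start * self.sample_rate))
        i1 = int(round((start + length) * self.sample_rate))
        if i0 < 0 or i1 > self.samples.size:
            raise ValueError("requested window extends beyond the waveform")
        return self.samples[i0:i1]

    def chirp_window(self, length: float = 0.030) -> np.ndarray:
        """The analysis window starting at chirp onset (default 30 ms)."""
        return self.window(self.chirp_onset_time, length)


def gaussian_frequency_excursion(
    spec: ChirpSpec, t: np.ndarray, center: float
) -> np.ndarray:
    """Gaussian EOD-frequency excursion ``g(t)`` in Hz.

    ``g(t) = delta_f * exp(-(t - center)^2 / (2 sigma^2))`` peaks at
    ``delta_f`` at ``t = center``.

    Raises
    ------
    ValueError
        If ``center`` falls outside the time grid.
    """
    t = np.asarray(t, dtype=float)
    if not (t[0] <= center <= t[-1]):
        raise ValueError(f"chirp center {center} s lies outside the time grid [{t[0]}, {t[-1]}] s")
    z = (t - center) / spec.sigma
    return spec.delta_f * np.exp(-0.5 * z * z)


def synthesize_am_waveform(
    beat: BeatSpec,
    chirp: ChirpSpec,
    chirp_onset_time: float | None = None,
    label: str = "S1",
) -> AMWaveform:
    """Synthesize the AM waveform for one chirp onset phase.

    The AM oscillates with instantaneous frequency ``f_beat + g(t)``; the
    integration constant is chosen so the total beat phase at
    ``chirp_onset_time`` equals ``chirp.onset_phase`` (0 deg at the beat
    trough).  The Gaussian excursion is centered ``CENTER_OFFSET_SIGMA``
    standard deviations after the onset mark.
    """
    if chirp_onset_time is None:
        chirp_onset_time = beat.duration / 2.0
    t = beat.time_grid()
    if not (t[0] < chirp_onset_time < t[-1]):
        raise ValueError("chirp_onset_time must lie strictly inside the trace")
    center = chirp_onset_time + CENTER_OFFSET_SIGMA * chirp.sigma
    if chirp.delta_f > 0:
        g = gaussian_frequency_excursion(chirp, t, center)
    else:
        g = np.zeros_like(t)
    phase = 2.0 * np.pi * cumulative_trapezoid(beat.f_beat + g, t, initial=0.0)
    phase_at_onset = np.interp(chirp_onset_time, t, phase)
    # trough reference: the sine argument lags the beat phase by 90 deg
    phi0 = np.deg2rad(chirp.onset_phase) - np.pi / 2.0 - phase_at_onset
    samples = np.sin(phase + phi0)
    return AMWaveform(
        samples=samples,
        sample_rate=beat.sample_rate,
        chirp_onset_time=float(chirp_onset_time),
        onset_phase=chirp.onset_phase,
        label=label,
        f_beat=beat.f_beat,
        delta_f=chirp.delta_f,
        sigma=chirp.sigma,
    )


def make_waveform_set(
    beat: BeatSpec | None = None,
    chirp_template: ChirpSpec | None = None,
    chirp_onset_time: float | None = None,
) -> list[AMWaveform]:
    """The canonical eight waveforms S1..S8 at onset phases 0, 45, ..., 315 deg."""
    if beat is None:
        beat = BeatSpec()
    if chirp_template is None:
        chirp_template = ChirpSpec()
    waves = []
    for i, phase in enumerate(CANONICAL_PHASES):
        chirp = ChirpSpec(
            delta_f=chirp_template.delta_f,
            sigma=chirp_template.sigma,
            onset_phase=phase,
        )
        waves.append(
            synthesize_am_waveform(beat, chirp, chirp_onset_time, label=f"S{i + 1}")
        )
    return waves


def beat_phase_at(wave: AMWaveform, t: float) -> float:
    """Read the beat phase (degrees in [0, 360)) back from the samples at ``t``.

    Uses ``arcsin`` on the sample value with the branch disambiguated by the
    local derivative sign, then converts to the package's trough-referenced
    convention (0 deg at the beat minimum).
    """
    idx = int(round(t * wave.sample_rate))
    idx = min(max(idx, 1), wave.samples.size - 2)
    s = float(np.clip(wave.samples[idx], -1.0, 1.0))
    ds = wave.samples[idx + 1] - wave.samples[idx - 1]
    phase = np.arcsin(s)
    if ds < 0:
        phase = np.pi - phase
    return float((np.rad2deg(phase) + 90.0) % 360.0)


# ---------------------------------------------------------------------------
# I/O: 2-column delimited text plus a JSON sidecar of the parameters.


def write_waveform(wave: AMWaveform, path: str | Path) -> None:
    path = Path(path)
    data = np.column_stack([wave.times, wave.samples])
    np.savetxt(path, data, fmt="%.8f", delimiter="\t", header="time_s\tamplitude", comments="")
    sidecar = {
        "f_beat": wave.f_beat,
        "delta_f": wave.delta_f,
        "sigma": wave.sigma,
        "onset_phase": wave.onset_phase,
        "chirp_onset_time": wave.chirp_onset_time,
        "sample_rate": wave.sample_rate,
        "label": wave.label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_waveform(path: str | Path) -> AMWaveform:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return AMWaveform(
        samples=data[:, 1],
        sample_rate=sidecar["sample_rate"],
        chirp_onset_time=sidecar["chirp_onset_time"],
        onset_phase=sidecar["onset_phase"],
        label=sidecar["label"],
        f_beat=sidecar["f_beat"],
        delta_f=sidecar["delta_f"],
        sigma=sidecar["sigma"],
    )
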