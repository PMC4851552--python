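"""Phase-invariance statistics: response measure, distances, scores, tuning.

The response of a unit to one chirp waveform is the log ratio of its firing
rate in a short window around the chirp to its rate during the undisturbed
beat.  The phase-invariance score compares, over all pairs of chirp
waveforms, the distance between the evoked responses to the distance
between the stimulus waveforms themselves:

    invariance = 1 - mean_{i != j} D(resp_i, resp_j) / D(S_i, S_j)

computed over a 30 ms window after chirp onset with all traces normalized
first.  A unit that faithfully re-encodes each waveform scores near 0; a
unit whose responses are identical for all onset phases scores 1.  The
score is at most 1 and can be negative when responses differ more than the
stimuli do.

Distance convention
-------------------
The default distance is the RMS difference of the mean-centered traces
divided by the larger of the two half-ranges.  A literal squared-numerator
variant (squared difference over half-range) is available via
``convention="squared"``; both conventions satisfy the analytic anchors
(identical responses -> 1, responses equal to stimuli -> 0) because the
numerator and denominator of the score ratio share the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from chirpinv.spiketrain import PSTH

__all__ = [
    "ResponseValue",
    "TuningCurve",
    "InvarianceScore",
    "T_CHIRP",
    "CHIRP_WINDOW",
    "response_measure",
    "classify_chirp_sign",
    "normalize_trace",
    "distance",
    "invariance_score",
    "build_tuning_curve",
]

#: Response-window duration (s) per processing stage: 15 ms for afferents
#: and ELL pyramidal cells, 20 ms for TS neurons.
T_CHIRP: dict[str, float] = {
    "afferent": 0.015,
    "ELL_ON": 0.015,
    "ELL_OFF": 0.015,
    "TS": 0.020,
}

#: Duration (s) of the chirp analysis window used for all distances.
CHIRP_WINDOW: float = 0.030

#: Offset (s) of the response-window center after chirp onset.
RESPONSE_CENTER_OFFSET: float = 0.015


@dataclass(frozen=True)
class ResponseValue:
    """Log firing-rate ratio for one unit and one waveform."""

    value: float
    label: str = ""
    unit_id: str = ""
    flagged: bool = False

    @property
    def sign(self) -> str:
        return "+" if self.value > 0 else "-"


@dataclass(frozen=True)
class InvarianceScore:
    """Phase-invariance score for one unit, pair subset, and input level."""

    value: float
    subset: str = "all"
    level: str = "single_unit"
    n_pairs: int = 0  # ordered pair count entering the mean


@dataclass(frozen=True)
class TuningCurve:
    """Responses as a function of beat phase, per unit and population mean."""

    phases: np.ndarray
    per_unit: np.ndarray  # (n_units, n_phases)
    unit_ids: tuple[str, ...]

    @property
    def mean(self) -> np.ndarray:
        return self.per_unit.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.per_unit.shape[0] < 2:
            return np.zeros(self.phases.size)
        return self.per_unit.std(axis=0, ddof=1) / np.sqrt(self.per_unit.shape[0])

    @property
    def normalized_mean(self) -> np.ndarray:
        """Population curve scaled to unit maximum absolute value."""
        m = self.mean
        peak = np.max(np.abs(m))
        return m / peak if peak > 0 else m


def response_measure(
    psth: PSTH,
    chirp_onset: float,
    stage: str = "afferent",
    rate_floor: float = 0.1,
    beat_exclusion: float = 0.1,
    log_base: str = "e",
    label: str = "",
    unit_id: str = "",
) -> ResponseValue:
    """Log ratio of chirp-window to beat firing rate for one waveform.

    ``FR_chirp`` is the mean PSTH over a window of duration ``T_CHIRP[stage]``
    centered 15 ms after chirp onset; ``FR_beat`` is the mean rate over all
    samples further than ``beat_exclusion`` (default 100 ms) from the chirp
    onset.  Rates are floored at ``rate_floor`` before the ratio so silent
    windows stay finite (the result is then flagged).
    """
    t_chirp = T_CHIRP[stage]
    start = chirp_onset + RESPONSE_CENTER_OFFSET - t_chirp / 2.0
    fr_chirp = psth.mean_rate(start, t_chirp)
    beat_sel = np.abs(psth.times - chirp_onset) > beat_exclusion
    if not beat_sel.any():
        raise ValueError("no beat-only samples available for FR_beat")
    fr_beat = float(psth.rate[beat_sel].mean())
    flagged = fr_chirp < rate_floor or fr_beat < rate_floor
    ratio = max(fr_chirp, rate_floor) / max(fr_beat, rate_floor)
    value = float(np.log(ratio)) if log_base == "e" else float(np.log10(ratio))
    return ResponseValue(value=value, label=label, unit_id=unit_id, flagged=flagged)


def classify_chirp_sign(population_responses: dict[str, float]) -> dict[str, str]:
    """'+' / '-' label per waveform from population-mean afferent responses.

    Waveforms whose population-mean response is positive (afferents excited)
    are '+ chirps'; the rest are '- chirps'.  Exact-zero responses break
    toward '-' with a warning.
    """
    signs = {}
    for label, value in population_responses.items():
        if value == 0.0:
            warnings.warn(f"tie (response exactly 0) for waveform {label}; classified '-'")
        signs[label] = "+" if value > 0 else "-"
    return signs


def normalize_trace(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Mean-subtract and scale by the maximum absolute deviation.

    Output lies in [-1, 1] and is invariant to affine transforms with
    positive scale.  Constant traces pass through as all-zero with the flag
    set.
    """
    x = np.asarray(x, dtype=float)
    centered = x - x.mean()
    peak = np.max(np.abs(centered))
    # relative tolerance: the mean of identical floats can leave ~1 ulp
    if peak <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        return np.zeros_like(centered), True
    return centered / peak, False


def distance(x: np.ndarray, y: np.ndarray, convention: str = "rms") -> float:
    """Distance between two traces over the chirp window.

    Default (``"rms"``): RMS difference of the mean-centered traces divided
    by the larger half-range ``(max - min) / 2``.  ``"squared"`` uses the
    literal squared difference in the numerator.  Symmetric; zero for
    identical traces; defined as 0 when both traces are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    hr = max(xc.max() - xc.min(), yc.max() - yc.min()) / 2.0
    scale = max(1.0, float(np.max(np.abs(x))), float(np.max(np.abs(y))))
    if hr <= 1e-12 * scale:  # both traces constant
        return 0.0
    sq = float(np.mean((xc - yc) ** 2))
    if convention == "rms":
        return float(np.sqrt(sq)) / hr
    if convention == "squared":
        return sq / hr
    raise ValueError(f"unknown distance convention {convention!r}")


def _select_pairs(
    labels: list[str], subset: str, signs: dict[str, str] | None
) -> list[tuple[str, str]]:
    pairs = list(combinations(labels, 2))
    if subset == "all":
        return pairs
    if signs is None:
        raise ValueError("subset selection requires waveform signs")
    if subset in ("++/--", "same_type"):
        return [(i, j) for i, j in pairs if signs[i] == signs[j]]
    if subset in ("+-", "opposite_type"):
        return [(i, j) for i, j in pairs if signs[i] != signs[j]]
    raise ValueError(f"unknown subset {subset!r}")


def invariance_score(
    responses: dict[str, np.ndarray],
    stimuli: dict[str, np.ndarray],
    subset: str = "all",
    signs: dict[str, str] | None = None,
    convention: str = "rms",
    normalize: bool = True,
    level: str = "single_unit",
) -> InvarianceScore:
    """Phase-invariance score from per-waveform response and stimulus traces.

    ``responses`` and ``stimuli`` map waveform labels to traces already
    restricted to the 30 ms chirp window (any per-kind sampling rate).  All
    traces are normalized, then 1 minus the mean of
    ``D(resp_i, resp_j) / D(S_i, S_j)`` over the selected unordered pairs is
    returned (identical to the ordered-pair mean since D is symmetric).

    Raises
    ------
    ValueError
        If the label sets differ or any selected stimulus pair has zero
        distance (degenerate stimulus set).
    """
    labels = sorted(responses)
    if sorted(stimuli) != labels:
        raise ValueError("responses and stimuli must cover the same waveform labels")
    if normalize:
        resp = {k: normalize_trace(v)[0] for k, v in responses.items()}
        stim = {k: normalize_trace(v)[0] for k, v in stimuli.items()}
    else:
        resp = {k: np.asarray(v, dtype=float) for k, v in responses.items()}
        stim = {k: np.asarray(v, dtype=float) for k, v in stimuli.items()}
    pairs = _select_pairs(labels, subset, signs)
    if not pairs:
        raise ValueError(f"no pairs selected for subset {subset!r}")
    ratios = []
    for i, j in pairs:
        d_stim = distance(stim[i], stim[j], convention)
        if d_stim == 0.0:
            raise ValueError(f"degenerate stimulus set: D({i}, {j}) = 0")
        ratios.append(distance(resp[i], resp[j], convention) / d_stim)
    return InvarianceScore(
        value=1.0 - float(np.mean(ratios)),
        subset=subset,
        level=level,
        n_pairs=2 * len(pairs),
    )


def build_tuning_curve(
    responses: dict[str, dict[float, float]],
    phases: tuple[float, ...] | None = None,
) -> TuningCurve:
    """Assemble per-unit tuning curves and the population mean +/- SEM.

    ``responses`` maps unit ids to ``{phase_deg: response_value}``; every
    unit must provide all canonical phases.
    """
    from chirpinv.stimulus import CANONICAL_PHASES

    if phases is None:
        phases = CANONICAL_PHASES
    unit_ids = tuple(sorted(responses))
    rows = []
    for unit in unit_ids:
        by_phase = responses[unit]
        missing = [p for p in phases if p not in by_phase]
        if missing:
            raise ValueError(f"unit {unit} is missing phases {missing}")
        rows.append([by_phase[p] for p in phases])
    return TuningCurve(
        phases=np.asarray(phases, dtype=float),
        per_unit=np.asarray(rows, dtype=float),
        unit_ids=unit_ids,
    )
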