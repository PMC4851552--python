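"""Core spike-train statistics: binarization, PSTHs, correlation traces.

The time-varying correlation coefficient rho(t) quantifies how synchronized
two neurons' spiking is around time t.  For a window of duration ``window``
centered at t, both spike trains are reduced to spike counts at a short
coincidence timescale (``binwidth``), per-trial window means are removed,
and the zero-lag correlation of the two count sequences is computed over
all (bin, trial) samples in the window; the absolute value is reported.
Whenever the common stimulus sweeps both firing rates rapidly — as a chirp
does for every onset phase — the fine-timescale counts co-modulate within
the window and rho(t) rises; shared excitation and shared inhibition both
count.  Because the measure is stimulus-locked, simultaneously recorded
and recombined (trial-shuffled) pairs give equivalent traces for neurons
without noise correlations.

A fixed-window 40 ms count correlation computed by an independent, literal
implementation serves as the oracle for the vectorized sliding estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BinarySequence",
    "PSTH",
    "CorrelationTrace",
    "binarize",
    "bin_counts",
    "compute_psth",
    "sliding_correlation",
    "count_correlation_oracle",
    "trial_count_correlation",
    "noise_count_correlation",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class BinarySequence:
    """Per-bin spike counts for one trial (half-open bins)."""

    counts: np.ndarray
    binwidth: float
    origin: float

    @property
    def times(self) -> np.ndarray:
        """Left edges of the bins."""
        return self.origin + np.arange(self.counts.size) * self.binwidth


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing rate in Hz, boxcar smoothed.

    ``origin`` is the time of the first retained bin: smoothing truncates
    half the boxcar from each edge of the trace.
    """

    rate: np.ndarray
    binwidth: float
    origin: float
    n_trials: int
    smooth_window: float

    @property
    def times(self) -> np.ndarray:
        return self.origin + (np.arange(self.rate.size) + 0.5) * self.binwidth

    def window(self, start: float, length: float) -> np.ndarray:
        """Rate samples in [start, start + length) (absolute time)."""
        i0 = int(round((start - self.origin) / self.binwidth))
        i1 = int(round((start + length - self.origin) / self.binwidth))
        if i0 < 0 or i1 > self.rate.size:
            raise ValueError("requested window extends beyond the PSTH")
        return self.rate[i0:i1]

    def mean_rate(self, start: float, length: float) -> float:
        return float(np.mean(self.window(start, length)))


@dataclass(frozen=True)
class CorrelationTrace:
    """Unsigned correlation rho per window-center time, with undefined mask."""

    rho: np.ndarray
    times: np.ndarray
    window: float
    step: float
    mask: np.ndarray  # True where rho is undefined (zero variance)

    def window_values(self, start: float, length: float) -> np.ndarray:
        sel = (self.times >= start) & (self.times < start + length)
        return self.rho[sel]


def binarize(
    spikes: np.ndarray, binwidth: float = 0.0005, span: tuple[float, float] = (0.0, None)
) -> BinarySequence:
    """Bin spike times into integer counts on half-open bins.

    Bin k covers ``[origin + k*binwidth, origin + (k+1)*binwidth)``; a spike
    exactly on an edge goes to the bin on its right.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    origin, end = span
    if end is None:
        spikes = np.asarray(spikes, dtype=float)
        end = spikes.max() + binwidth if spikes.size else origin + binwidth
    if end <= origin:
        raise ValueError("empty span")
    n_bins = int(np.ceil((end - origin) / binwidth - 1e-9))
    spikes = np.asarray(spikes, dtype=float)
    idx = np.floor((spikes - origin) / binwidth + 1e-12).astype(int)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return BinarySequence(counts=counts, binwidth=binwidth, origin=origin)


def bin_counts(
    trials: list[np.ndarray], binwidth: float, span: tuple[float, float]
) -> np.ndarray:
    """Stack per-trial binarized counts into a (n_trials, n_bins) array."""
    return np.stack([binarize(tr, binwidth, span).counts for tr in trials])


def compute_psth(
    trials: list[np.ndarray],
    duration: float,
    binwidth: float = 0.0001,
    smooth: float = 0.006,
    origin: float = 0.0,
) -> PSTH:
    """Trial-averaged PSTH smoothed with a centered boxcar filter.

    Before smoothing the histogram rate conserves the total spike count
    exactly; smoothing uses a boxcar of ``smooth`` seconds and the trace is
    truncated by half the boxcar at each edge (only fully covered bins are
    kept).  A one-bin boxcar is the identity.
    """
    if not trials:
        raise ValueError("at least one trial is required")
    counts = bin_counts(trials, binwidth, (origin, origin + duration))
    rate = counts.mean(axis=0) / binwidth
    width = max(1, int(round(smooth / binwidth)))
    if width > 1:
        kernel = np.full(width, 1.0 / width)
        rate = np.convolve(rate, kernel, mode="valid")
        new_origin = origin + (width // 2) * binwidth
    else:
        new_origin = origin
    return PSTH(
        rate=rate,
        binwidth=binwidth,
        origin=new_origin,
        n_trials=len(trials),
        smooth_window=smooth,
    )


def _sliding_window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of length-w windows along the last axis."""
    c = np.cumsum(x, axis=-1, dtype=float)
    c = np.concatenate([np.zeros(c.shape[:-1] + (1,)), c], axis=-1)
    return c[..., w:] - c[..., :-w]


def _pair_trials(
    trials_i: list[np.ndarray], trials_j: list[np.ndarray], pairing: str
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    if len(trials_i) != len(trials_j):
        raise ValueError("trial counts must match after pairing")
    if pairing == "simultaneous":
        return trials_i, trials_j
    if pairing == "recombined":
        # deterministic cyclic shift: destroys trial-wise noise alignment
        # while preserving the stimulus-locked structure
        return trials_i, trials_j[1:] + trials_j[:1]
    raise ValueError(f"unknown pairing {pairing!r}")


def sliding_correlation(
    trials_i: list[np.ndarray],
    trials_j: list[np.ndarray],
    duration: float,
    window: float = 0.03125,
    step: float = 0.00025,
    pairing: str = "simultaneous",
    origin: float = 0.0,
    binwidth: float = 0.002,
) -> CorrelationTrace:
    """Time-varying unsigned correlation coefficient of two spike-train sets.

    Spike trains are counted in bins of ``binwidth`` (the coincidence
    timescale, default 2 ms — a few EOD cycles) evaluated at every ``step``
    (bins overlap when ``binwidth > step``).  For each window position, the
    per-trial window means are removed and the Pearson correlation between
    the two count sequences is computed over all (bin, trial) samples
    within the window; the absolute value is returned.  Windows in which
    either neuron's counts have zero variance are masked as undefined.
    """
    if len(trials_i) < 3:
        raise ValueError("at least 3 trials are required")
    m = max(1, int(round(binwidth / step)))
    w = int(round(window / step)) - (m - 1)
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    trials_i, trials_j = _pair_trials(trials_i, trials_j, pairing)
    span = (origin, origin + duration)
    a = bin_counts(trials_i, step, span).astype(float)
    b = bin_counts(trials_j, step, span).astype(float)
    if m > 1:
        # counts at the coincidence timescale, evaluated every step
        a = _sliding_window_sums(a, m)
        b = _sliding_window_sums(b, m)
    sa = _sliding_window_sums(a, w)
    sb = _sliding_window_sums(b, w)
    sa2 = _sliding_window_sums(a * a, w)
    sb2 = _sliding_window_sums(b * b, w)
    sab = _sliding_window_sums(a * b, w)
    num = (sab - sa * sb / w).sum(axis=0)
    var_a = (sa2 - sa * sa / w).sum(axis=0)
    var_b = (sb2 - sb * sb / w).sum(axis=0)
    mask = (var_a <= 0) | (var_b <= 0)
    rho = np.zeros_like(num)
    good = ~mask
    rho[good] = np.abs(num[good]) / np.sqrt(var_a[good] * var_b[good])
    centers = origin + np.arange(rho.size) * step + window / 2.0
    return CorrelationTrace(rho=rho, times=centers, window=window, step=step, mask=mask)


def count_correlation_oracle(
    trials_i: list[np.ndarray],
    trials_j: list[np.ndarray],
    window_position: float,
    window: float = 0.040,
    step: float = 0.00025,
    binwidth: float = 0.002,
) -> float:
    """Fixed-window correlation coefficient by a direct, literal computation.

    For each trial the spikes falling in ``[window_position,
    window_position + window)`` are counted in bins of ``binwidth`` placed
    every ``step``, each trial's mean is removed, and products are
    accumulated in explicit loops.  The unsigned Pearson value over all
    (bin, trial) samples is returned.  Serves as the independent oracle for
    :func:`sliding_correlation`.
    """
    if len(trials_i) != len(trials_j) or len(trials_i) < 3:
        raise ValueError("matched sets of at least 3 trials are required")
    m = max(1, int(round(binwidth / step)))
    n_bins = int(round(window / step)) - (m - 1)
    num = 0.0
    var_i = 0.0
    var_j = 0.0
    for sp_i, sp_j in zip(trials_i, trials_j):
        vec_i = np.zeros(n_bins)
        vec_j = np.zeros(n_bins)
        for vec, spikes in ((vec_i, sp_i), (vec_j, sp_j)):
            for s in np.asarray(spikes, dtype=float):
                fine = int(np.floor((s - window_position) / step + 1e-12))
                # the spike contributes to every bin position overlapping it
                for k in range(fine - m + 1, fine + 1):
                    if 0 <= k < n_bins:
                        vec[k] += 1.0
        vec_i -= vec_i.mean()
        vec_j -= vec_j.mean()
        num += float(vec_i @ vec_j)
        var_i += float(vec_i @ vec_i)
        var_j += float(vec_j @ vec_j)
    if var_i <= 0 or var_j <= 0:
        return float("nan")
    return abs(num) / np.sqrt(var_i * var_j)


def trial_count_correlation(counts_i: np.ndarray, counts_j: np.ndarray) -> float:
    """Unsigned Pearson correlation of two per-trial count vectors."""
    counts_i = np.asarray(counts_i, dtype=float)
    counts_j = np.asarray(counts_j, dtype=float)
    if counts_i.size != counts_j.size or counts_i.size < 3:
        raise ValueError("matched vectors of at least 3 trials are required")
    di = counts_i - counts_i.mean()
    dj = counts_j - counts_j.mean()
    den = np.sqrt((di @ di) * (dj @ dj))
    if den == 0:
        return float("nan")
    return float(abs(di @ dj) / den)


def noise_count_correlation(
    trials_i: list[np.ndarray],
    trials_j: list[np.ndarray],
    duration: float,
    window: float = 0.040,
    origin: float = 0.0,
) -> np.ndarray:
    """Across-trial correlation of residual spike counts per 40 ms window.

    Counts in non-overlapping windows are corrected by their across-trial
    mean (the PSTH prediction); the signed Pearson correlation across trials
    is returned per window (NaN where either variance vanishes).  For
    neurons with shared stimulus drive but independent spiking noise the
    expected value is zero.
    """
    if len(trials_i) != len(trials_j):
        raise ValueError("trial counts must match")
    span = (origin, origin + duration)
    a = bin_counts(trials_i, window, span).astype(float)
    b = bin_counts(trials_j, window, span).astype(float)
    a -= a.mean(axis=0)
    b -= b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


# ---------------------------------------------------------------------------
# I/O


def write_trace(
    times: np.ndarray, values: np.ndarray, path: str | Path, params: dict | None = None
) -> None:
    """Write a (time, value) trace as delimited text with a JSON sidecar."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([times, values]),
        fmt="%.8f",
        delimiter="\t",
        header="time_s\tvalue",
        comments="",
    )
    if params is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(params, indent=2))


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return data[:, 0], data[:, 1]
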