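"""Respiratory-trace processing: from a bellows signal to 8-phase dose weights.

An amplitude-binned 4D image set sorts anatomy by breathing amplitude, so the
fraction of time the patient spends in each amplitude state is what weights
each phase's dose. The chain implemented here is:

``smooth_trace`` (decimating moving average) → ``segment_periods``
(peak-to-peak breathing periods) → ``amplitude_bin_pdf`` (per-period 8-phase
probability density function) → ``average_pdfs`` (patient-specific PDF).

Binning convention: the amplitude range of a period is split into 5 equal
levels. The top level is phase 0% (maximum inhale), the bottom level is phase
50% (end exhale); each intermediate level maps to two phases depending on the
limb of the cycle — descending (exhaling) → 12.5/25/37.5%, ascending
(inhaling) → 62.5/75/87.5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import N_PHASES, PHASE_LABELS

__all__ = [
    "BreathingTrace",
    "PeriodSegment",
    "PhasePDF",
    "smooth_trace",
    "segment_periods",
    "amplitude_bin_pdf",
    "average_pdfs",
    "pdf_from_trace",
]


@dataclass
class BreathingTrace:
    """Uniformly sampled respiratory signal (times in s, amplitudes in a.u.)."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
            raise ValueError("trace must be uniformly sampled (within 1e-6 s)")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class PeriodSegment:
    """One breathing period, peak (max inhale) to next peak."""

    start: int
    end: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.end <= self.start:
            raise ValueError("period segment must have positive duration")


@dataclass
class PhasePDF:
    """8 non-negative phase weights, ordered by phase label 0% … 87.5%, summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_PHASES,):
            raise ValueError(f"PhasePDF needs exactly {N_PHASES} weights")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("phase weights must be finite and non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase weights must sum to 1 (got {total!r})")

    def as_dict(self) -> dict[float, float]:
        return {label: float(w) for label, w in zip(PHASE_LABELS, self.weights)}


def smooth_trace(trace: BreathingTrace, window: int = 50) -> BreathingTrace:
    """Decimating moving average: one output sample per non-overlapping block.

    Each output amplitude is the mean of one block of ``window`` consecutive
    input samples; the output time is the block-center time. A trailing
    partial block is dropped.
    """
    window = int(window)
    if window < 1:
        raise ValueError("window must be a positive integer")
    n = len(trace)
    if n < window:
        raise ValueError(f"trace has {n} samples, fewer than window {window}")
    n_out = n // window
    amp = trace.amplitudes[: n_out * window].reshape(n_out, window).mean(axis=1)
    t = trace.times[: n_out * window].reshape(n_out, window).mean(axis=1)
    return BreathingTrace(t, amp)


def segment_periods(trace: BreathingTrace, min_separation_s: float = 1.0) -> list[PeriodSegment]:
    """Identify breathing peaks and return consecutive peak-to-peak periods.

    A peak is a local maximum at or above the trace mean, at least
    ``min_separation_s`` from its neighbours; on a plateau the first sample
    wins.
    """
    x = trace.amplitudes
    distance = max(1, int(round(min_separation_s / trace.dt)))
    peaks, props = find_peaks(x, height=x.mean(), distance=distance, plateau_size=1)
    # plateau ties -> first sample of the plateau
    peaks = props.get("left_edges", peaks)
    if len(peaks) < 2:
        raise ValueError("no periods detected (fewer than 2 breathing peaks)")
    segments = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        segments.append(PeriodSegment(int(a), int(b), float(trace.times[b] - trace.times[a])))
    return segments


# phase index per (level, limb): level 4 is the top amplitude level.
_DESCENDING = {4: 0, 3: 1, 2: 2, 1: 3, 0: 4}   # 0%, 12.5%, 25%, 37.5%, 50%
_ASCENDING = {4: 0, 3: 7, 2: 6, 1: 5, 0: 4}    # 0%, 87.5%, 75%, 62.5%, 50%


def amplitude_bin_pdf(trace: BreathingTrace, segment: PeriodSegment) -> PhasePDF:
    """Amplitude-bin one breathing period into the 8-phase PDF.

    The segment's amplitude range is split into 5 equal levels; each sample is
    assigned a phase from its level and limb (descending before the trough,
    ascending after), and the weight of a phase is the fraction of samples in
    it.
    """
    if segment.start < 0 or segment.end >= len(trace):
        raise ValueError("segment indices outside trace")
    seg = trace.amplitudes[segment.start : segment.end + 1]
    lo, hi = float(seg.min()), float(seg.max())
    if hi - lo <= 0:
        raise ValueError("flat segment: zero amplitude range")
    # samples of this period: [start, end) — the end peak opens the next period
    x = trace.amplitudes[segment.start : segment.end]
    level = np.minimum((5.0 * (x - lo) / (hi - lo)).astype(int), 4)
    trough = int(np.argmin(x))
    phase = np.empty(x.size, dtype=int)
    idx = np.arange(x.size)
    for lv in range(5):
        sel = level == lv
        phase[sel & (idx <= trough)] = _DESCENDING[lv]
        phase[sel & (idx > trough)] = _ASCENDING[lv]
    counts = np.bincount(phase, minlength=N_PHASES).astype(float)
    return PhasePDF(counts / counts.sum())


def average_pdfs(pdfs: list[PhasePDF]) -> PhasePDF:
    """Element-wise mean of per-period PDFs, renormalized to sum to 1."""
    if not pdfs:
        raise ValueError("cannot average an empty list of PDFs")
    mean = np.mean([p.weights for p in pdfs], axis=0)
    return PhasePDF(mean / mean.sum())


def pdf_from_trace(trace: BreathingTrace, window: int = 50) -> PhasePDF:
    """Full chain: smooth, segment into periods, bin each, average."""
    smoothed = smooth_trace(trace, window=window)
    segments = segment_periods(smoothed)
    pdfs = [amplitude_bin_pdf(smoothed, s) for s in segments]
    return average_pdfs(pdfs)
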