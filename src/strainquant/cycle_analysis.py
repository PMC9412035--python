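"""Peak/valley analysis of cyclic strain traces and per-sample amplitudes.

The stretcher applies a raised-cosine-like cyclic stretch, so the mean
strain trace oscillates between valley (rest) and peak (full stretch)
levels.  Peaks are local maxima with prominence at least a fraction of the
trace's total range and separated by at least 0.6 cycle periods; valleys
are found identically on the negated trace.  The strain amplitude of a
sample is the difference between the mean peak value and the mean valley
value — no per-cycle pairing — and the equibiaxial strain level is the
average of the xx and yy amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

#: default prominence threshold as a fraction of the series range
DEFAULT_PROMINENCE_FRAC = 0.25
#: minimum peak separation as a fraction of the cycle period
MIN_SEPARATION_FRAC = 0.6
#: xx/yy amplitude disagreement above which the qc flag is raised
ANISOTROPY_QC_THRESHOLD = 0.20
#: Savitzky-Golay window as a fraction of the cycle period, and its order
SMOOTH_WINDOW_FRAC = 0.4
SMOOTH_POLYORDER = 4


@dataclass
class PeakAnalysis:
    """Identified peaks/valleys of one strain trace and the amplitude."""

    peak_indices: np.ndarray
    peak_values: np.ndarray
    valley_indices: np.ndarray
    valley_values: np.ndarray

    @property
    def mean_peak(self) -> float:
        return float(np.mean(self.peak_values))

    @property
    def mean_valley(self) -> float:
        return float(np.mean(self.valley_values))

    @property
    def amplitude(self) -> float:
        """Mean peak strain minus mean valley strain (>= 0 for cyclic data)."""
        return self.mean_peak - self.mean_valley

    @property
    def n_cycles(self) -> int:
        return int(self.peak_indices.size)


@dataclass
class SampleStrainResult:
    """Per-sample strain amplitudes and the equibiaxial strain level."""

    A_xx: float
    A_yy: float
    n_cycles: int
    fps: float
    loading_freq: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def equibiaxial_level(self) -> float:
        return 0.5 * (self.A_xx + self.A_yy)

    @property
    def anisotropy(self) -> float:
        m = max(self.A_xx, self.A_yy)
        return abs(self.A_xx - self.A_yy) / m if m > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "A_xx": self.A_xx,
            "A_yy": self.A_yy,
            "equibiaxial_level": self.equibiaxial_level,
            "n_cycles": self.n_cycles,
            "anisotropy": self.anisotropy,
            "fps": self.fps,
            "loading_freq": self.loading_freq,
            "qc_flags": list(self.qc_flags),
        }


def _dominant_period(series: np.ndarray) -> float:
    """Cycle period in samples from the first prominent autocorrelation peak."""
    x = series - series.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    ac /= ac[0]
    peaks, _ = find_peaks(ac)
    if peaks.size == 0:
        raise ValueError("could not estimate a cycle period from the series")
    return float(peaks[np.argmax(ac[peaks])])


def _alternate(idx_p, val_p, idx_v, val_v):
    """Enforce strict peak/valley alternation.

    Consecutive same-type extrema (a peak with no valley between it and the
    next peak, or vice versa) are collapsed to the more extreme one.
    """
    events = [(i, v, +1) for i, v in zip(idx_p, val_p)] + [
        (i, v, -1) for i, v in zip(idx_v, val_v)
    ]
    events.sort()
    kept: list[tuple[int, float, int]] = []
    for ev in events:
        if kept and kept[-1][2] == ev[2]:
            better = ev[1] > kept[-1][1] if ev[2] > 0 else ev[1] < kept[-1][1]
            if better:
                kept[-1] = ev
        else:
            kept.append(ev)
    p = [(i, v) for i, v, s in kept if s > 0]
    v = [(i, v) for i, v, s in kept if s < 0]
    return (
        np.array([i for i, _ in p], dtype=int),
        np.array([x for _, x in p]),
        np.array([i for i, _ in v], dtype=int),
        np.array([x for _, x in v]),
    )


def find_cycles(
    series: np.ndarray,
    fps: float,
    loading_freq: float | None = None,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    smooth: bool = True,
) -> PeakAnalysis:
    """Peak analysis of one cyclic strain trace.

    Parameters
    ----------
    series : array
        Mean strain versus frame.
    fps : float
        Frame rate in Hz.
    loading_freq : float, optional
        Nominal loading frequency in Hz (1 Hz for the standard protocol).
        When given, the cycle period prior is ``fps / loading_freq``
        samples; otherwise the period is estimated from the series'
        dominant autocorrelation lag.
    prominence_frac : float
        Minimum peak prominence as a fraction of the series range.
    smooth : bool
        Apply a Savitzky-Golay filter (window 0.4 cycle periods, order 4)
        before peak detection.  Picking raw samples at noisy extrema biases
        the mean peak up and the mean valley down; the short quartic fit
        removes that bias while leaving a smooth waveform essentially
        unchanged.  The filter is linear, so the offset and positive-scaling
        invariances of the analysis hold exactly.

    Raises
    ------
    ValueError
        For a constant series or fewer than 3 retained peaks.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant series: no cycles to analyse")
    period = fps / loading_freq if loading_freq else _dominant_period(x)
    if smooth:
        win = int(round(SMOOTH_WINDOW_FRAC * period))
        win += 1 - win % 2  # must be odd
        win = max(win, SMOOTH_POLYORDER + 1 + SMOOTH_POLYORDER % 2)
        if win < x.size:
            x = savgol_filter(x, win, SMOOTH_POLYORDER)
    rng = np.ptp(x)
    if rng == 0:
        raise ValueError("constant series: no cycles to analyse")
    distance = max(1, int(round(MIN_SEPARATION_FRAC * period)))
    prominence = prominence_frac * rng
    idx_p, _ = find_peaks(x, prominence=prominence, distance=distance)
    idx_v, _ = find_peaks(-x, prominence=prominence, distance=distance)
    idx_p, val_p, idx_v, val_v = _alternate(idx_p, x[idx_p], idx_v, x[idx_v])
    if idx_p.size < 3:
        raise ValueError(
            f"only {idx_p.size} peaks retained; need >= 3 for a valid sample"
        )
    return PeakAnalysis(
        peak_indices=idx_p,
        peak_values=val_p,
        valley_indices=idx_v,
        valley_values=val_v,
    )


def equibiaxial_level(A_xx: float, A_yy: float) -> float:
    """Equibiaxial strain level: the mean of the xx and yy amplitudes."""
    if A_xx < 0 or A_yy < 0:
        raise ValueError("amplitudes must be non-negative")
    return 0.5 * (A_xx + A_yy)


def sample_result(
    pa_xx: PeakAnalysis,
    pa_yy: PeakAnalysis,
    fps: float,
    loading_freq: float | None = None,
) -> SampleStrainResult:
    """Combine xx and yy peak analyses into a per-sample result with qc."""
    A_xx, A_yy = pa_xx.amplitude, pa_yy.amplitude
    res = SampleStrainResult(
        A_xx=A_xx,
        A_yy=A_yy,
        n_cycles=min(pa_xx.n_cycles, pa_yy.n_cycles),
        fps=fps,
        loading_freq=loading_freq,
    )
    if res.anisotropy > ANISOTROPY_QC_THRESHOLD:
        res.qc_flags.append("anisotropy")
    return res
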