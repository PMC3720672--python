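"""Frequency-domain heart-rate-variability analysis of beat-to-beat series.

The pipeline implemented here turns a series of heart beats (R-peak times, or
equivalently the pulse-to-pulse intervals, PPI, in milliseconds) into the
standard short-term frequency-domain HRV indices:

* ``TP``  — total spectral power of the tachogram (ms^2),
* ``LFP`` — low-frequency power, 0.04-0.15 Hz (ms^2),
* ``HFP`` — high-frequency power, 0.15-0.4 Hz (ms^2), the respiratory
  sinus-arrhythmia band, modulated by the parasympathetic system,
* ``LFP/HFP`` — the sympathovagal balance ratio,

together with their natural-log transforms, which are what downstream
prognostic models consume.

Processing chain
----------------
1. (optional) R-peak detection on a raw single-lead ECG trace,
2. resampling of the irregular PPI tachogram onto an even grid by cubic-spline
   interpolation (2048 points over 288 s by default, ~7.111 Hz),
3. mean-removed, Hamming-tapered FFT periodogram scaled to a one-sided power
   spectral density in ms^2/Hz, compensated for the taper's incoherent power
   gain and renormalized so that the integral of the density over
   (0, Nyquist] equals the variance of the mean-removed tachogram exactly
   (Parseval contract),
4. trapezoidal integration of the density over the requested bands.

Only the Hamming-window attenuation is compensated; no additional correction
for the interpolation ("sampling") low-pass effect is applied, which slightly
attenuates components near the upper band edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, get_window, periodogram

from .exceptions import CoverageError, EmptySeriesError, InputError

__all__ = [
    "EcgTrace",
    "BeatSeries",
    "SpectrumConfig",
    "PowerSpectrum",
    "SpectralIndices",
    "detect_r_peaks",
    "resample_tachogram",
    "psd_estimate",
    "integrate_band",
    "compute_indices",
    "filter_ectopic",
]


@dataclass(frozen=True)
class EcgTrace:
    """A single-lead ECG voltage trace in arbitrary units."""

    samples: np.ndarray
    sampling_rate: float = 1024.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise InputError("an ECG trace needs at least 2 samples")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class BeatSeries:
    """Ordered beat times (s) and the PPI between consecutive beats (ms).

    ``ppi[k]`` is the interval between beat ``k`` and beat ``k + 1``, so
    ``len(ppi) == len(beat_times) - 1`` and successive beat times differ by
    ``ppi[k] / 1000`` (enforced to 1 microsecond).
    """

    beat_times: np.ndarray
    ppi: np.ndarray

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        ppi = np.asarray(self.ppi, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "ppi", ppi)
        if bt.size < 2:
            raise InputError("a beat series needs at least 2 beats")
        if ppi.size != bt.size - 1:
            raise InputError("len(ppi) must equal len(beat_times) - 1")
        if not np.all(ppi > 0):
            raise InputError("all PPI must be positive")
        if np.max(np.abs(np.diff(bt) - ppi / 1000.0)) > 1e-6:
            raise InputError("beat_times increments disagree with ppi (> 1 us)")

    @classmethod
    def from_beat_times(cls, beat_times) -> "BeatSeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(bt, np.diff(bt) * 1000.0)

    @classmethod
    def from_ppi(cls, ppi, start_time: float = 0.0) -> "BeatSeries":
        ppi = np.asarray(ppi, dtype=float)
        bt = start_time + np.concatenate([[0.0], np.cumsum(ppi) / 1000.0])
        return cls(bt, ppi)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (first to last beat)."""
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class SpectrumConfig:
    """Settings of the spectral estimator and the integration bands.

    Defaults follow standard short-term HRV practice: a 288-s segment
    resampled to 2048 points, Hamming taper, HF band 0.15-0.4 Hz, LF band
    0.04-0.15 Hz, and total power over (0, 0.4] Hz excluding the DC bin.
    ``offset_seconds`` shifts the analysis segment within a longer recording.
    """

    segment_seconds: float = 288.0
    n_points: int = 2048
    hf_band: tuple[float, float] = (0.15, 0.4)
    lf_band: tuple[float, float] = (0.04, 0.15)
    tp_band: tuple[float, float] = (0.0, 0.4)
    window: str = "hamming"
    offset_seconds: float = 0.0

    def __post_init__(self):
        if self.segment_seconds <= 0 or self.n_points < 4:
            raise InputError("segment_seconds must be > 0 and n_points >= 4")
        for name in ("hf_band", "lf_band", "tp_band"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise InputError(f"{name} must satisfy 0 <= lo < hi")
            if hi > self.sampling_rate / 2:
                raise InputError(
                    f"{name} upper edge {hi} Hz exceeds Nyquist "
                    f"{self.sampling_rate / 2:.3f} Hz"
                )
        if self.hf_band[0] < self.lf_band[1] and self.lf_band[0] < self.hf_band[1]:
            if not math.isclose(self.lf_band[1], self.hf_band[0]):
                raise InputError("lf_band and hf_band overlap")
        if max(self.hf_band[1], self.lf_band[1]) > self.tp_band[1] + 1e-12:
            raise InputError("component bands must lie within tp_band")

    @property
    def sampling_rate(self) -> float:
        """Effective tachogram rate in Hz (~7.111 at defaults)."""
        return self.n_points / self.segment_seconds


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density of a tachogram, in ms^2/Hz."""

    frequencies: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "density", d)
        if f.shape != d.shape or f.ndim != 1:
            raise InputError("frequencies and density must be 1-D and aligned")
        if f[0] != 0 or np.any(np.diff(f) <= 0):
            raise InputError("frequency grid must ascend from 0")
        if np.any(d < 0):
            raise InputError("spectral density must be non-negative")


def _ln(x: float) -> float:
    return math.log(x) if x > 0 else math.nan


@dataclass(frozen=True)
class SpectralIndices:
    """Band powers (ms^2) and their natural-log transforms for one patient.

    Log fields are NaN when the source quantity is zero or undefined.
    """

    tp: float
    lfp: float
    hfp: float
    lf_hf: float = field(default=math.nan)
    ln_tp: float = field(default=math.nan)
    ln_hfp: float = field(default=math.nan)
    ln_lf_hf: float = field(default=math.nan)

    @classmethod
    def from_band_powers(cls, tp: float, lfp: float, hfp: float) -> "SpectralIndices":
        lf_hf = lfp / hfp if hfp > 0 else math.nan
        return cls(
            tp=tp,
            lfp=lfp,
            hfp=hfp,
            lf_hf=lf_hf,
            ln_tp=_ln(tp),
            ln_hfp=_ln(hfp),
            ln_lf_hf=_ln(lf_hf) if lf_hf == lf_hf else math.nan,
        )


def detect_r_peaks(trace: EcgTrace, min_rr_ms: float = 300.0) -> BeatSeries:
    """Locate R peaks in an ECG trace and return the beat series.

    A simplified Pan-Tompkins emphasis is used: band-limited derivative,
    squaring, and a 150-ms moving-window integration, followed by peak
    picking with an adaptive amplitude threshold and a ``min_rr_ms``
    refractory period.  Each detection is then refined to the local maximum
    of the raw signal.  Adequate for clean or synthetic single-lead traces;
    not a clinical-grade detector.
    """
    x = trace.samples
    if not np.all(np.isfinite(x)):
        raise InputError("ECG trace contains non-finite samples")
    fs = trace.sampling_rate
    if x.size < 2 * fs:
        raise InputError("need at least 2 s of ECG signal")

    # derivative -> squaring -> moving-window integration (150 ms)
    deriv = np.gradient(x)
    sq = deriv * deriv
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    peak_level = np.percentile(integ, 99)
    if peak_level <= 0 or np.ptp(x) == 0:
        raise EmptySeriesError("no QRS-like activity found in trace")
    threshold = 0.3 * peak_level
    distance = max(int(round(min_rr_ms / 1000.0 * fs)), 1)
    locs, _ = find_peaks(integ, height=threshold, distance=distance)
    if locs.size < 2:
        raise EmptySeriesError("fewer than 2 R peaks detected")

    # refine to the raw-signal local maximum; window capped at half the
    # refractory period so it cannot reach a neighbouring beat
    half = int(round(min(0.150, min_rr_ms / 2000.0) * fs))
    refined = np.empty(locs.size, dtype=int)
    for i, loc in enumerate(locs):
        lo = max(loc - half, 0)
        hi = min(loc + half + 1, x.size)
        refined[i] = lo + int(np.argmax(x[lo:hi]))
    refined = np.unique(refined)
    beat_times = refined / fs
    keep = np.concatenate([[True], np.diff(beat_times) >= min_rr_ms / 1000.0 - 1e-9])
    beat_times = beat_times[keep]
    if beat_times.size < 2:
        raise EmptySeriesError("fewer than 2 R peaks after refractory filtering")
    return BeatSeries.from_beat_times(beat_times)


def filter_ectopic(beats: BeatSeries, tolerance: float = 0.2, window: int = 11) -> BeatSeries:
    """Drop beats whose PPI deviates more than ``tolerance`` (fraction) from a
    running median of ``window`` intervals.  Off by default in the pipeline;
    the deleted interval is merged into its successor so beat times stay
    consistent."""
    ppi = beats.ppi.copy()
    med = np.array(
        [
            np.median(ppi[max(0, k - window // 2): k + window // 2 + 1])
            for k in range(ppi.size)
        ]
    )
    bad = np.abs(ppi - med) > tolerance * med
    if not bad.any():
        return beats
    keep_times = np.concatenate([[True], ~bad])
    return BeatSeries.from_beat_times(beats.beat_times[keep_times])


def resample_tachogram(beats: BeatSeries, cfg: SpectrumConfig | None = None) -> np.ndarray:
    """Interpolate the PPI tachogram onto an even grid of ``cfg.n_points``
    instants spanning the first ``cfg.segment_seconds`` of the recording.

    Each PPI is anchored at the time of its opening beat and interpolated with
    a cubic spline, the standard smooth choice for HRV tachograms.  Raises
    :class:`CoverageError` if the recording is shorter than the segment.
    """
    cfg = cfg or SpectrumConfig()
    if beats.n_beats < 3:
        raise InputError("need at least 3 beats to build a tachogram")
    start = beats.beat_times[0] + cfg.offset_seconds
    if beats.beat_times[-1] - start < cfg.segment_seconds:
        raise CoverageError(
            f"recording spans {beats.duration:.1f} s from the requested offset; "
            f"{cfg.segment_seconds:.0f} s needed"
        )
    spline = CubicSpline(beats.beat_times[:-1], beats.ppi)
    t = start + np.arange(cfg.n_points) * (cfg.segment_seconds / cfg.n_points)
    return np.asarray(spline(t), dtype=float)


def psd_estimate(tachogram: np.ndarray, cfg: SpectrumConfig | None = None) -> PowerSpectrum:
    """Mean-removed, tapered FFT periodogram of an evenly spaced tachogram.

    The one-sided density (ms^2/Hz) is first compensated for the taper's
    mean-square (incoherent) gain and then rescaled so that its trapezoidal
    integral over (0, Nyquist] equals the variance of the mean-removed
    series exactly.  The second step matters because a taper reweights the
    samples: gain compensation preserves total power only in expectation,
    while band integrals are meaningful only if total power equals the
    series variance (Parseval contract).
    """
    cfg = cfg or SpectrumConfig()
    x = np.asarray(tachogram, dtype=float)
    if x.size != cfg.n_points:
        raise InputError(f"tachogram length {x.size} != n_points {cfg.n_points}")
    if not np.all(np.isfinite(x)):
        raise InputError("tachogram contains non-finite values")
    freqs, density = periodogram(
        x,
        fs=cfg.sampling_rate,
        window=get_window(cfg.window, x.size),
        detrend="constant",
        scaling="density",
    )
    variance = float(np.var(x))
    total = float(np.trapezoid(density, freqs))
    if variance > 0 and total > 0:
        density = density * (variance / total)
    return PowerSpectrum(freqs, density)


def integrate_band(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the density over the half-open band (lo, hi].

    The density is treated as piecewise linear on its frequency grid, with the
    band edges obtained by interpolation, which makes the integral exactly
    additive over adjacent bands.
    """
    lo, hi = float(band[0]), float(band[1])
    if not lo < hi:
        raise InputError(f"inverted or empty band ({lo}, {hi}]")
    f, d = spectrum.frequencies, spectrum.density
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-9:
        raise InputError(f"band ({lo}, {hi}] outside spectrum range ({f[0]}, {f[-1]}]")
    hi = min(hi, f[-1])
    inner = f[(f > lo) & (f < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, f, d)
    return float(np.trapezoid(vals, grid))


def compute_indices(beats: BeatSeries, cfg: SpectrumConfig | None = None) -> SpectralIndices:
    """Full chain: resample -> PSD -> band integration -> log transforms."""
    cfg = cfg or SpectrumConfig()
    tachogram = resample_tachogram(beats, cfg)
    spectrum = psd_estimate(tachogram, cfg)
    tp = integrate_band(spectrum, cfg.tp_band)
    lfp = integrate_band(spectrum, cfg.lf_band)
    hfp = integrate_band(spectrum, cfg.hf_band)
    return SpectralIndices.from_band_powers(tp=tp, lfp=lfp, hfp=hfp)
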