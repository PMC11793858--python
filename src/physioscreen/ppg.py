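"""PPG beat detection and the cardiac feature subset.

Per phase the pipeline derives, from the pulse waveform:

* 9 shape features — mean / sample-SD / median of per-beat amplitude,
  duration (foot-to-foot) and rise time (foot-to-peak), evaluated in 10 s
  windows and averaged across windows;
* 3 heart-rate features — mean / SD / median of the BPM trend;
* 7 + 2 HRV features — pNN50, band power of the BPM trend in the LF
  (0.04–0.15 Hz) and HF (0.15–0.4 Hz) bands and their ratio (mean and SD
  over short-time windows), plus the classical time-domain RMSSD and SDNN.

The BPM trend is the instantaneous rate 60/IBI linearly interpolated to a
uniform 4 Hz grid; band powers come from a short-time periodogram with 60 s
Hann windows and 50 % overlap, which resolves the 0.04 Hz band edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import ChannelRecording

logger = logging.getLogger(__name__)

PNN50_THRESHOLD_S = 0.050
RATIO_FLOOR = 1e-12  # avoids 0/0 in PLF/PHF when a band is numerically empty


@dataclass
class SpectralBands:
    """HRV band edges in Hz. The 0.15 Hz boundary belongs to the HF band
    (half-open partition, so PLF + PHF tiles 0.04–0.4 Hz exactly)."""

    plf: tuple = (0.04, 0.15)
    phf: tuple = (0.15, 0.40)

    def masks(self, freqs: np.ndarray):
        lf = (freqs >= self.plf[0]) & (freqs < self.plf[1])
        hf = (freqs >= self.phf[0]) & (freqs <= self.phf[1])
        return lf, hf


@dataclass
class BeatSeries:
    """Per-beat fiducials. ``durations`` and ``ibis`` are foot-to-foot
    differences (length n-1); the remaining arrays have length n."""

    beat_times: np.ndarray   # s, pulse feet
    peak_times: np.ndarray   # s
    amplitudes: np.ndarray   # signal units, peak value - foot value
    rise_times: np.ndarray   # s, foot -> peak

    def __post_init__(self) -> None:
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def durations(self) -> np.ndarray:
        return self.ibis

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


@dataclass
class BPMTrend:
    times: np.ndarray  # s, uniform grid
    bpm: np.ndarray    # beats/min

    @property
    def fs(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0]


# ----------------------------------------------------------------------
# beat detection
# ----------------------------------------------------------------------

def detect_beats(ppg: ChannelRecording, refractory_s: float = 0.3,
                 foot_fraction: float = 0.08) -> BeatSeries:
    """Adaptive-threshold beat detection.

    Peaks are picked on a 0.5–8 Hz band-passed copy with a refractory
    period, then refined on a lightly smoothed copy of the input; the foot
    of each pulse is the last crossing of ``foot_fraction`` of the pulse
    height above the local baseline (the minimum of the preceding
    inter-beat valley) before the peak.
    """
    if ppg.fs < 50:
        raise ValueError("beat detection requires fs >= 50 Hz")
    if ppg.n_samples / ppg.fs < 10:
        raise ValueError("beat detection requires at least 10 s of signal")
    fs = ppg.fs
    x = ppg.values
    sos = sps.butter(3, [0.5, 8.0], "bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)
    scale = np.percentile(np.abs(xb), 95)
    if scale <= 0 or np.ptp(x) == 0:
        raise ValueError("insufficient beats: flat input signal")
    peaks, _ = sps.find_peaks(xb, height=0.3 * scale, distance=max(int(refractory_s * fs), 1))
    if peaks.size < 2:
        raise ValueError("insufficient beats: fewer than 2 peaks detected")

    # smooth the raw signal just enough to de-noise fiducial refinement
    sos_s = sps.butter(2, min(10.0, 0.45 * fs), "lowpass", fs=fs, output="sos")
    xs = sps.sosfiltfilt(sos_s, x)

    med_ibi = float(np.median(np.diff(peaks))) / fs
    search = max(int(0.6 * med_ibi * fs), 2)
    feet, peak_t, amps, rises = [], [], [], []
    for p in peaks:
        # refine peak on the smoothed signal
        lo = max(p - int(0.1 * fs), 0)
        hi = min(p + int(0.1 * fs) + 1, xs.size)
        p_ref = lo + int(np.argmax(xs[lo:hi]))
        w0 = max(p_ref - search, 0)
        if w0 >= p_ref:
            continue
        valley = xs[w0:p_ref]
        # 10th percentile, not the minimum: a single low noise dip must not
        # anchor the baseline (it would pull the foot crossing early)
        base = float(np.percentile(valley, 10))
        height = xs[p_ref] - base
        if height <= 0:
            continue
        thr = base + foot_fraction * height
        below = np.nonzero(valley <= thr)[0]
        if below.size == 0:
            below = np.array([int(np.argmin(valley))])
        f = w0 + below[-1]
        feet.append(f)
        peak_t.append(p_ref)
        amps.append(xs[p_ref] - xs[f])
        rises.append((p_ref - f) / fs)
    feet = np.asarray(feet, dtype=int)
    if feet.size < 2:
        raise ValueError("insufficient beats: fewer than 2 complete beats")
    keep = np.concatenate([[True], np.diff(feet) > 0])
    feet, peak_t = feet[keep], np.asarray(peak_t)[keep]
    return BeatSeries(
        beat_times=ppg.start_time + feet / fs,
        peak_times=ppg.start_time + peak_t / fs,
        amplitudes=np.asarray(amps)[keep],
        rise_times=np.asarray(rises)[keep],
    )


# ----------------------------------------------------------------------
# shape features
# ----------------------------------------------------------------------

def _window_spans(windows):
    spans = []
    for w in windows:
        if isinstance(w, ChannelRecording):
            spans.append((w.start_time, w.start_time + w.n_samples / w.fs))
        else:
            spans.append((float(w[0]), float(w[1])))
    return spans


def ppg_shape_features(beats: BeatSeries, windows) -> dict:
    """9 shape features: {mean, std, median} × {amplitude, duration, rise_time}.

    Statistics are computed per window over the beats whose foot falls in
    the window (sample SD, ddof=1), then averaged across windows.  Windows
    with fewer than 2 beats are skipped with a warning.
    """
    spans = _window_spans(windows)
    per_window = {k: [] for k in (
        "ppg_amplitude_mean", "ppg_amplitude_std", "ppg_amplitude_median",
        "ppg_duration_mean", "ppg_duration_std", "ppg_duration_median",
        "ppg_rise_time_mean", "ppg_rise_time_std", "ppg_rise_time_median",
    )}
    durations = beats.durations  # defined for beats[:-1]
    n_used = 0
    for start, end in spans:
        in_w = (beats.beat_times >= start) & (beats.beat_times < end)
        idx = np.nonzero(in_w)[0]
        if idx.size < 2:
            logger.warning("shape-feature window [%.1f, %.1f) s has <2 beats; skipped", start, end)
            continue
        n_used += 1
        d_idx = idx[idx < durations.size]
        for name, vals in (
            ("amplitude", beats.amplitudes[idx]),
            ("duration", durations[d_idx]),
            ("rise_time", beats.rise_times[idx]),
        ):
            if vals.size < 2:
                continue
            per_window[f"ppg_{name}_mean"].append(float(np.mean(vals)))
            per_window[f"ppg_{name}_std"].append(float(np.std(vals, ddof=1)))
            per_window[f"ppg_{name}_median"].append(float(np.median(vals)))
    if n_used == 0:
        raise ValueError("no window contains >= 2 beats")
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in per_window.items()}


# ----------------------------------------------------------------------
# BPM trend and HRV
# ----------------------------------------------------------------------

def bpm_trend(beats: BeatSeries, grid_hz: float = 4.0) -> BPMTrend:
    """Instantaneous rate 60/IBI at each interval's closing beat, linearly
    interpolated to a uniform grid.  The grid spans only the beats where a
    rate is defined — no extrapolation."""
    if beats.n_beats < 3:
        raise ValueError("BPM trend requires at least 3 beats")
    rate_times = beats.beat_times[1:]
    rates = 60.0 / beats.ibis
    t0, t1 = rate_times[0], rate_times[-1]
    grid = t0 + np.arange(int(np.floor((t1 - t0) * grid_hz)) + 1) / grid_hz
    return BPMTrend(times=grid, bpm=np.interp(grid, rate_times, rates))


def pnn50(ibis) -> float:
    """Percentage of successive IBI differences exceeding 50 ms."""
    d = np.abs(np.diff(np.asarray(ibis, dtype=float)))
    if d.size == 0:
        return float("nan")
    return 100.0 * float(np.mean(d > PNN50_THRESHOLD_S))


def _stft_band_powers(trend: BPMTrend, bands: SpectralBands,
                      window_s: float = 60.0, overlap: float = 0.5):
    fs = trend.fs
    nperseg = int(round(window_s * fs))
    x = trend.bpm - np.mean(trend.bpm)
    if x.size < nperseg:
        return None
    freqs, times, sxx = sps.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant", scaling="density",
    )
    df = freqs[1] - freqs[0]
    lf_mask, hf_mask = bands.masks(freqs)
    plf = sxx[lf_mask].sum(axis=0) * df
    phf = sxx[hf_mask].sum(axis=0) * df
    return freqs, times, sxx, plf, phf


def bpm_spectrogram(trend: BPMTrend, window_s: float = 60.0, overlap: float = 0.5):
    """Short-time PSD of the mean-removed BPM trend.

    Returns ``(freqs, times, psd)`` with psd in BPM²/Hz, one column per
    60 s window (50 % overlap).
    """
    out = _stft_band_powers(trend, SpectralBands(), window_s, overlap)
    if out is None:
        raise ValueError(
            f"trend too short for spectrogram (needs >= {window_s} s, "
            f"has {trend.duration:.1f} s)"
        )
    freqs, times, sxx, _, _ = out
    return freqs, times, sxx


def hr_hrv_features(beats: BeatSeries, trend: BPMTrend,
                    bands: SpectralBands | None = None) -> dict:
    """HR (3), HRV spectral (6) + pNN50, RMSSD, SDNN — 12 named values.

    Spectral features need at least one 60 s window of trend; otherwise
    they are returned as NaN (flagged missing).
    """
    bands = bands or SpectralBands()
    ibis = beats.ibis
    out = {
        "bpm_mean": float(np.mean(trend.bpm)),
        "bpm_std": float(np.std(trend.bpm, ddof=1)),
        "bpm_median": float(np.median(trend.bpm)),
        "pnn50": pnn50(ibis),
        "rmssd": float(np.sqrt(np.mean(np.diff(ibis * 1000.0) ** 2))) if ibis.size > 1 else float("nan"),
        "sdnn": float(np.std(ibis * 1000.0, ddof=1)) if ibis.size > 1 else float("nan"),
    }
    spec = _stft_band_powers(trend, bands)
    names = ("plf_mean", "plf_std", "phf_mean", "phf_std",
             "lf_hf_ratio_mean", "lf_hf_ratio_std")
    if spec is None:
        logger.warning("trend shorter than one 60 s window; spectral HRV features missing")
        out.update({k: float("nan") for k in names})
        return out
    _, _, _, plf, phf = spec
    ratio = plf / np.maximum(phf, RATIO_FLOOR)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # single-column SD -> NaN
        out.update({
            "plf_mean": float(np.mean(plf)),
            "plf_std": float(np.std(plf, ddof=1)) if plf.size > 1 else float("nan"),
            "phf_mean": float(np.mean(phf)),
            "phf_std": float(np.std(phf, ddof=1)) if phf.size > 1 else float("nan"),
            "lf_hf_ratio_mean": float(np.mean(ratio)),
            "lf_hf_ratio_std": float(np.std(ratio, ddof=1)) if ratio.size > 1 else float("nan"),
        })
    return out
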