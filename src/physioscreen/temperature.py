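"""Skin-temperature features on the raw signal and its first derivative.

Seven statistics per series: initial value, final value, delta
(final − initial), mean, sample SD, variation over time (delta divided by
the phase duration) and the variation-over-time slope (first coefficient
of the least-squares line).

The derivative is estimated by zero-phase low-pass smoothing (default
0.1 Hz) followed by central finite differences; it is exact for linear
drifts away from the filter edges.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import ChannelRecording


def estimate_derivative(temp: ChannelRecording, smooth_hz: float = 0.1) -> ChannelRecording:
    """First time-derivative in °C/s on the same grid minus the endpoints."""
    if temp.n_samples / temp.fs < 30:
        raise ValueError("derivative estimation requires at least 30 s of signal")
    if not 0 < smooth_hz < temp.fs / 2:
        raise ValueError("smooth_hz must lie in (0, fs/2)")
    # remove the least-squares line before filtering: the slow low-pass has
    # long edge transients on drifting inputs, and re-adding the line's
    # slope afterwards makes the estimator exact for linear drifts
    t = np.arange(temp.n_samples) / temp.fs
    slope, intercept = np.polyfit(t, temp.values, 1)
    resid = temp.values - (slope * t + intercept)
    sos = sps.butter(4, smooth_hz, "lowpass", fs=temp.fs, output="sos")
    xs = sps.sosfiltfilt(sos, resid)
    d = (xs[2:] - xs[:-2]) * (temp.fs / 2.0) + slope
    return ChannelRecording(
        d, temp.fs, "temperature_derivative",
        start_time=temp.start_time + 1.0 / temp.fs, meta=dict(temp.meta),
    )


def _endpoint_value(values: np.ndarray, fs: float, where: str) -> float:
    """Endpoint level from a local linear fit over the first/last second.

    A least-squares line over the boundary second, evaluated at the
    segment endpoint: robust to sample noise like a plain 1 s mean, but
    exact for linear drifts (so delta keeps its closed form on ramps).
    """
    k = min(max(int(round(fs)) + 1, 2), values.size)
    if where == "initial":
        seg = values[:k]
        t = np.arange(k, dtype=float)
        t_eval = 0.0
    else:
        seg = values[-k:]
        t = np.arange(k, dtype=float)
        t_eval = float(k - 1)
    if k == 2:
        return float(seg[0] if where == "initial" else seg[-1])
    b, a = np.polyfit(t, seg, 1)
    return float(b * t_eval + a)


def temperature_features(series: ChannelRecording, which: str = "raw") -> dict:
    """The 7 temperature statistics, key-prefixed ``temp_`` (raw) or
    ``temp_deriv_`` (derivative).  Identities ``delta = final - initial``
    and ``variation = delta / duration`` hold exactly by construction."""
    if which not in ("raw", "derivative"):
        raise ValueError("which must be 'raw' or 'derivative'")
    x = series.values
    if x.size < 2:
        raise ValueError("temperature features require at least 2 samples")
    prefix = "temp_" if which == "raw" else "temp_deriv_"
    duration = series.duration
    initial = _endpoint_value(x, series.fs, "initial")
    final = _endpoint_value(x, series.fs, "final")
    delta = final - initial
    t = np.arange(x.size) / series.fs
    slope = float(np.polyfit(t, x, 1)[0])
    return {
        prefix + "initial": initial,
        prefix + "final": final,
        prefix + "delta": delta,
        prefix + "mean": float(np.mean(x)),
        prefix + "std": float(np.std(x, ddof=1)),
        prefix + "variation": delta / duration if duration > 0 else float("nan"),
        prefix + "variation_slope": slope,
    }
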