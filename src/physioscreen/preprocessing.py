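"""Acquisition-side filter chain, phase segmentation and windowing.

The emulated acquisition applies a 50 Hz mains notch and a 30 Hz low-pass
to every channel, plus a 0.1 Hz high-pass to the PPG only.  Filtering is
zero-phase (forward–backward second-order sections) because the analysis is
offline and feature timings must not be shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import ChannelRecording


@dataclass
class FilterSpec:
    """Filter chain parameters.

    The family/order are implementation defaults: 4th-order Butterworth
    sections for low- and high-pass, IIR notch with quality factor 30.
    """

    notch_hz: float | None = 50.0
    lowpass_hz: float | None = 30.0
    highpass_hz: float | None = None
    order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        for name, f in (("notch", self.notch_hz), ("lowpass", self.lowpass_hz),
                        ("highpass", self.highpass_hz)):
            if f is not None and not 0 < f < nyq:
                raise ValueError(f"{name} frequency {f} Hz violates Nyquist (fs={fs} Hz)")
        if self.highpass_hz is not None and self.lowpass_hz is not None:
            if not self.highpass_hz < self.lowpass_hz:
                raise ValueError("highpass cutoff must be below lowpass cutoff")


def ppg_filter_spec() -> FilterSpec:
    """Default PPG chain: notch 50, low-pass 30, high-pass 0.1 Hz."""
    return FilterSpec(highpass_hz=0.1)


def apply_filters(rec: ChannelRecording, spec: FilterSpec) -> ChannelRecording:
    """Apply the chain zero-phase; output has the same length, fs and timing."""
    spec.validate(rec.fs)
    x = rec.values
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
        x = signal.filtfilt(b, a, x)
    if spec.lowpass_hz is not None:
        sos = signal.butter(spec.order, spec.lowpass_hz, "lowpass", fs=rec.fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    if spec.highpass_hz is not None:
        sos = signal.butter(spec.order, spec.highpass_hz, "highpass", fs=rec.fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return rec.replace(values=np.asarray(x))


def segment_phases(rec: ChannelRecording, boundaries) -> list[ChannelRecording]:
    """Cut a recording into phases given ``[(start_s, end_s), ...]``.

    Boundaries are relative to the recording start, must be non-overlapping
    and in increasing order; each returned segment carries its phase index
    in ``meta["phase"]`` and its own ``start_time``.
    """
    segments = []
    prev_end = -np.inf
    total = rec.n_samples / rec.fs
    for i, (start, end) in enumerate(boundaries):
        if not start < end:
            raise ValueError(f"phase {i}: empty or reversed boundary ({start}, {end})")
        if start < prev_end:
            raise ValueError(f"phase {i}: overlaps the previous phase")
        if start < 0 or end > total + 0.5 / rec.fs:
            raise ValueError(
                f"phase {i}: boundary ({start}, {end}) s outside the record "
                f"(duration {total:.3f} s)"
            )
        i0 = int(round(start * rec.fs))
        i1 = min(int(round(end * rec.fs)), rec.n_samples)
        meta = dict(rec.meta)
        meta["phase"] = i
        segments.append(
            ChannelRecording(rec.values[i0:i1], rec.fs, rec.kind,
                             start_time=rec.start_time + start, meta=meta)
        )
        prev_end = end
    return segments


def make_windows(segment: ChannelRecording, width_s: float = 10.0,
                 step_s: float | None = None) -> list[ChannelRecording]:
    """Sliding windows over a segment; trailing partial window discarded.

    Non-overlapping by default (step = width).  Each window keeps its
    absolute ``start_time`` so beat times can be assigned to windows.
    """
    if step_s is None:
        step_s = width_s
    if width_s <= 0 or step_s <= 0:
        raise ValueError("width_s and step_s must be positive")
    seg_duration = segment.n_samples / segment.fs
    if width_s > seg_duration:
        raise ValueError(
            f"window width {width_s} s exceeds segment duration {seg_duration:.3f} s"
        )
    wn = int(round(width_s * segment.fs))
    sn = int(round(step_s * segment.fs))
    windows = []
    for i, i0 in enumerate(range(0, segment.n_samples - wn + 1, sn)):
        meta = dict(segment.meta)
        meta["window"] = i
        windows.append(
            ChannelRecording(segment.values[i0 : i0 + wn], segment.fs, segment.kind,
                             start_time=segment.start_time + i0 / segment.fs, meta=meta)
        )
    return windows
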