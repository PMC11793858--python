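"""Synthetic multimodal physiological cohorts with known class effects.

The generator emulates a stress / mental-workload protocol: each subject
performs four tests (Stroop and visual / auditory / dual N-Back), each test
consisting of a Rest phase followed by three task sub-phases.  Every phase
yields three channels — PPG, electrodermal activity (EDA) and skin
temperature — whose statistics are modulated by a latent cognitive-state
class in {0..4} (0 = relaxed baseline, 1–4 = increasing perceived
stress / workload).

Every planted quantity (beat times, skin-conductance-response events, tonic
curves, temperature trends, class labels) is returned as ground truth so
downstream detectors and the statistical screening can be validated against
known answers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .recording import ChannelRecording

# Frequencies of the two planted inter-beat-interval oscillations.  They sit
# in the middle of the conventional low-frequency (0.04-0.15 Hz) and
# high-frequency (0.15-0.4 Hz) heart-rate-variability bands, so band-power
# features have a known home for their energy.
LF_TONE_HZ = 0.10
HF_TONE_HZ = 0.25

DEFAULT_TESTS = ("stroop", "visual_nback", "auditory_nback", "dual_nback")

#: Default probability of classes 1..4 for task sub-phases.  Skewed toward
#: the middle of the scale: self-assessed workload ratings cluster around
#: moderate levels rather than spreading uniformly.
DEFAULT_LABEL_DISTRIBUTION = (0.15, 0.35, 0.35, 0.15)

N_CLASSES = 5


def _as_class_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape == ():
        arr = np.full(N_CLASSES, float(arr))
    if arr.shape != (N_CLASSES,):
        raise ValueError(f"{name} must be scalar or length-{N_CLASSES}, got shape {arr.shape}")
    return arr


@dataclass
class EffectSpec:
    """Per-class physiological parameters (index = class label 0..4).

    All ``*_per_class`` entries are length-5 arrays; index 0 is the relaxed
    baseline.  Units are SI-ish: seconds for intervals, µS for conductance,
    °C for temperature, events/min for SCR rate.
    """

    # --- cardiac ---
    ibi_mean_s: np.ndarray = (0.85, 0.81, 0.77, 0.73, 0.69)
    ibi_lf_amp_s: np.ndarray = (0.015, 0.022, 0.028, 0.034, 0.040)
    ibi_hf_amp_s: np.ndarray = (0.035, 0.030, 0.026, 0.022, 0.018)
    ibi_noise_sd_s: np.ndarray = 0.012
    # --- PPG pulse morphology ---
    pulse_amplitude: np.ndarray = (1.00, 1.03, 1.06, 1.09, 1.12)
    pulse_rise_time_s: np.ndarray = (0.150, 0.145, 0.140, 0.135, 0.130)
    pulse_duration_s: float = 0.40
    ppg_noise_sd: np.ndarray = 0.05
    # --- electrodermal ---
    scl_level_uS: np.ndarray = (2.0, 2.4, 2.8, 3.2, 3.6)
    scl_slope_uS_per_s: np.ndarray = (0.0, 0.0005, 0.001, 0.0015, 0.002)
    scr_rate_per_min: np.ndarray = (2.0, 3.5, 5.0, 6.5, 8.0)
    scr_amp_mean_uS: np.ndarray = 0.30
    scr_tau1_s: float = 0.7
    scr_tau2_s: float = 3.0
    eda_noise_sd_uS: np.ndarray = 0.01
    # --- temperature ---
    temp_initial_C: np.ndarray = 33.0
    temp_slope_C_per_s: np.ndarray = (-0.0005, -0.0010, -0.0015, -0.0020, -0.0025)
    temp_noise_sd_C: np.ndarray = 0.01
    temp_noise_ar: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "ibi_mean_s", "ibi_lf_amp_s", "ibi_hf_amp_s", "ibi_noise_sd_s",
            "pulse_amplitude", "pulse_rise_time_s", "ppg_noise_sd",
            "scl_level_uS", "scl_slope_uS_per_s", "scr_rate_per_min",
            "scr_amp_mean_uS", "eda_noise_sd_uS", "temp_initial_C",
            "temp_slope_C_per_s", "temp_noise_sd_C",
        ):
            setattr(self, name, _as_class_array(getattr(self, name), name))
        if np.any(self.scr_rate_per_min < 0):
            raise ValueError("SCR event rates must be >= 0")
        if np.any(self.ibi_noise_sd_s < 0) or np.any(self.ppg_noise_sd < 0):
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 < self.scr_tau1_s < self.scr_tau2_s:
            raise ValueError("Bateman kernel requires 0 < tau1 < tau2")
        if not 0 <= self.temp_noise_ar < 1:
            raise ValueError("temperature AR coefficient must lie in [0, 1)")

    @classmethod
    def null(cls) -> "EffectSpec":
        """Effect spec with NO class dependence (all classes at baseline)."""
        base = cls()
        kwargs = {}
        for name in (
            "ibi_mean_s", "ibi_lf_amp_s", "ibi_hf_amp_s",
            "pulse_amplitude", "pulse_rise_time_s",
            "scl_level_uS", "scl_slope_uS_per_s", "scr_rate_per_min",
            "temp_slope_C_per_s",
        ):
            kwargs[name] = np.full(N_CLASSES, getattr(base, name)[0])
        return cls(**kwargs)


@dataclass
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    The acquisition hardware the protocol emulates samples at 1200 Hz; the
    simulation default is 128 Hz, which keeps every filter of the
    acquisition chain (50 Hz notch, 30 Hz low-pass, 0.1 Hz PPG high-pass)
    below Nyquist while keeping full-cohort runs cheap.
    """

    n_participants: int = 28
    n_phases: int = 4
    tests: tuple = DEFAULT_TESTS
    phase_duration_s: float = 300.0
    fs: float = 128.0
    label_distribution: tuple = DEFAULT_LABEL_DISTRIBUTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases (Rest + >=1 task phase)")
        if self.phase_duration_s < 60:
            raise ValueError(
                "phase_duration_s must be >= 60 s (low-frequency HRV band "
                "needs at least one 60 s spectral window)"
            )
        p = np.asarray(self.label_distribution, dtype=float)
        if p.shape != (N_CLASSES - 1,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("label_distribution must be 4 non-negative probabilities summing to 1")


@dataclass
class GroundTruth:
    """Everything the simulator planted in one phase recording."""

    class_label: int
    beat_times: np.ndarray          # s, pulse onsets
    ibis: np.ndarray                # s
    scr_event_times: np.ndarray     # s
    scr_event_amplitudes: np.ndarray  # µS (kernel-peak scale, see eda module)
    tonic_curve: np.ndarray         # µS, same grid as the EDA channel
    temp_trend: np.ndarray          # °C, same grid as the temperature channel

    def __post_init__(self) -> None:
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.scr_event_amplitudes < 0):
            raise ValueError("SCR event amplitudes must be >= 0")


# ----------------------------------------------------------------------
# single-channel generators
# ----------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_ibi_series(effect: EffectSpec, cls: int, duration_s: float, seed=0) -> np.ndarray:
    """Inter-beat intervals with planted LF (0.10 Hz) and HF (0.25 Hz) tones.

    IBI(t) = µ(cls) + a_LF sin(2π·0.10·t) + a_HF sin(2π·0.25·t) + ε,
    with t the cumulative beat time and ε white Gaussian noise.  Intervals
    are emitted until their cumulative sum covers ``duration_s``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    mu = effect.ibi_mean_s[cls]
    a_lf = effect.ibi_lf_amp_s[cls]
    a_hf = effect.ibi_hf_amp_s[cls]
    sd = effect.ibi_noise_sd_s[cls]
    if mu <= 0:
        raise ValueError("mean IBI must be positive")
    if a_lf + a_hf + 4 * sd >= mu:
        raise ValueError(
            "IBI modulation too deep: amplitude sum + 4*sigma "
            f"({a_lf + a_hf + 4 * sd:.3f}) >= mean IBI ({mu:.3f})"
        )
    rng = _rng(seed)
    ibis = []
    t = 0.0
    while t < duration_s:
        ibi = (
            mu
            + a_lf * np.sin(2 * np.pi * LF_TONE_HZ * t)
            + a_hf * np.sin(2 * np.pi * HF_TONE_HZ * t)
            + rng.normal(0.0, sd)
        )
        # Gaussian tail beyond 4 sigma: physically a missed/ectopic beat,
        # clip to keep the series valid rather than emit an impossible IBI.
        ibi = max(ibi, mu - a_lf - a_hf - 4 * sd)
        ibis.append(ibi)
        t += ibi
    out = np.asarray(ibis)
    assert np.all(out > 0)
    return out


def _pulse_template(fs: float, amplitude: float, rise_s: float, duration_s: float) -> np.ndarray:
    """Unimodal pulse: half-cosine rise to ``amplitude``, exponential decay
    renormalised to reach exactly 0 at ``duration_s``."""
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    out = np.empty(n)
    rise = t <= rise_s
    out[rise] = amplitude * 0.5 * (1 - np.cos(np.pi * t[rise] / rise_s))
    s = t[~rise] - rise_s
    span = duration_s - rise_s
    tau = span / 4.0
    decay = (np.exp(-s / tau) - np.exp(-span / tau)) / (1 - np.exp(-span / tau))
    out[~rise] = amplitude * decay
    return out


def synthesize_ppg(ibis, effect: EffectSpec, cls: int, fs: float, seed=0):
    """Render a PPG waveform from an IBI series.

    Returns ``(ChannelRecording, beat_times)`` where ``beat_times`` are the
    pulse onsets (cumulative IBI sums, first beat at t = 0).
    """
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size == 0:
        raise ValueError("IBI series is empty")
    if np.any(ibis <= 0):
        raise ValueError("all IBIs must be positive")
    if fs < 50:
        raise ValueError("PPG synthesis requires fs >= 50 Hz")
    rise = effect.pulse_rise_time_s[cls]
    dur = effect.pulse_duration_s
    amp = effect.pulse_amplitude[cls]
    if not rise < dur:
        raise ValueError("pulse rise time must be shorter than pulse duration")
    if dur > ibis.min():
        raise ValueError(
            f"pulse duration {dur:.3f} s exceeds smallest IBI {ibis.min():.3f} s "
            "(overlapping templates)"
        )
    duration_s = float(ibis.sum())
    n = int(np.ceil(duration_s * fs))
    beat_times = np.concatenate([[0.0], np.cumsum(ibis)])
    template = _pulse_template(fs, amp, rise, dur)
    signal = np.zeros(n)
    for bt in beat_times:
        i0 = int(round(bt * fs))
        if i0 >= n:
            break
        seg = template[: n - i0]
        signal[i0 : i0 + seg.size] += seg
    rng = _rng(seed)
    sd = effect.ppg_noise_sd[cls]
    if sd > 0:
        signal = signal + rng.normal(0.0, sd, size=n)
    rec = ChannelRecording(signal, fs, "ppg", meta={"class": int(cls)})
    return rec, beat_times


def bateman_kernel(t, tau1: float, tau2: float) -> np.ndarray:
    """Biexponential SCR kernel k(t) = exp(-t/tau2) - exp(-t/tau1), tau1 < tau2."""
    t = np.asarray(t, dtype=float)
    out = np.exp(-t / tau2) - np.exp(-t / tau1)
    out[t < 0] = 0.0
    return out


def bateman_peak(tau1: float, tau2: float):
    """Closed-form (t*, k(t*)) of the Bateman kernel maximum."""
    t_star = tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)
    return t_star, float(np.exp(-t_star / tau2) - np.exp(-t_star / tau1))


def synthesize_eda(
    effect: EffectSpec,
    cls: int,
    duration_s: float,
    fs: float,
    seed=0,
    event_times=None,
    event_amplitudes=None,
):
    """EDA = tonic (level + slope·t) + Σ aᵢ·k(t−tᵢ)/max(k) + white noise.

    Events arrive as a homogeneous Poisson process with the class's rate
    unless explicit ``event_times`` (and optionally amplitudes, in µS of
    resulting peak height) are supplied.  Returns
    ``(ChannelRecording, event_times, event_amplitudes, tonic_curve)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    tonic = effect.scl_level_uS[cls] + effect.scl_slope_uS_per_s[cls] * t

    if event_times is None:
        rate_per_s = effect.scr_rate_per_min[cls] / 60.0
        n_events = rng.poisson(rate_per_s * duration_s)
        event_times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    else:
        event_times = np.sort(np.asarray(event_times, dtype=float))
    if event_amplitudes is None:
        mean_amp = effect.scr_amp_mean_uS[cls]
        event_amplitudes = rng.gamma(4.0, mean_amp / 4.0, size=event_times.size)
    else:
        event_amplitudes = np.asarray(event_amplitudes, dtype=float)
        if event_amplitudes.size != event_times.size:
            raise ValueError("event_times and event_amplitudes must match in length")

    tau1, tau2 = effect.scr_tau1_s, effect.scr_tau2_s
    _, k_max = bateman_peak(tau1, tau2)
    kernel_len = int(round(min(10 * tau2, duration_s) * fs)) + 1
    kernel = bateman_kernel(np.arange(kernel_len) / fs, tau1, tau2) / k_max
    phasic = np.zeros(n)
    for et, ea in zip(event_times, event_amplitudes):
        i0 = int(round(et * fs))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        phasic[i0 : i0 + seg.size] += ea * seg

    signal = tonic + phasic
    sd = effect.eda_noise_sd_uS[cls]
    if sd > 0:
        signal = signal + rng.normal(0.0, sd, size=n)
    rec = ChannelRecording(signal, fs, "eda", meta={"class": int(cls)})
    return rec, event_times, event_amplitudes, tonic


def synthesize_temperature(effect: EffectSpec, cls: int, duration_s: float, fs: float, seed=0):
    """Skin temperature: linear drift + AR(1) noise.

    Returns ``(ChannelRecording, trend_curve)``; the noiseless output at
    t = 0 equals the configured initial value.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _rng(seed)
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    trend = effect.temp_initial_C[cls] + effect.temp_slope_C_per_s[cls] * t
    sd = effect.temp_noise_sd_C[cls]
    signal = trend.copy()
    if sd > 0:
        rho = effect.temp_noise_ar
        innov = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + innov[i]
        signal = signal + noise
    rec = ChannelRecording(signal, fs, "temperature", meta={"class": int(cls)})
    return rec, trend


# ----------------------------------------------------------------------
# cohort assembly
# ----------------------------------------------------------------------

@dataclass
class PhaseRecording:
    subject: int
    test: str
    phase: int
    ppg: ChannelRecording
    eda: ChannelRecording
    temperature: ChannelRecording
    truth: GroundTruth


class CohortRecording:
    """Lazy container for a full simulated cohort.

    Labels and per-phase seeds are drawn eagerly (cheap, fully determined
    by ``config.seed``); the signal arrays of each phase are generated on
    demand by :meth:`get_phase` so a default-sized cohort never has to be
    held in memory at once.
    """

    def __init__(self, config: CohortConfig, effect: EffectSpec):
        self.config = config
        self.effect = effect
        root = np.random.SeedSequence(config.seed)
        label_rng = np.random.default_rng(root.spawn(1)[0])
        rows = []
        self._phase_seeds = {}
        p = np.asarray(config.label_distribution, dtype=float)
        for subject, test in itertools.product(range(config.n_participants), config.tests):
            for phase in range(config.n_phases):
                cls = 0 if phase == 0 else int(label_rng.choice(4, p=p)) + 1
                rows.append({"subject": subject, "test": test, "phase": phase, "class": cls})
        # spawn one child seed per phase, in a fixed order
        children = root.spawn(len(rows))
        for row, child in zip(rows, children):
            self._phase_seeds[(row["subject"], row["test"], row["phase"])] = child
        self.labels = pd.DataFrame(rows)

    def phase_keys(self):
        return list(self._phase_seeds.keys())

    def class_of(self, subject: int, test: str, phase: int) -> int:
        m = self.labels
        row = m[(m.subject == subject) & (m.test == test) & (m.phase == phase)]
        return int(row["class"].iloc[0])

    def get_phase(self, subject: int, test: str, phase: int) -> PhaseRecording:
        key = (subject, test, phase)
        if key not in self._phase_seeds:
            raise KeyError(f"no such phase: {key}")
        cls = self.class_of(subject, test, phase)
        cfg, eff = self.config, self.effect
        streams = self._phase_seeds[key].spawn(3)
        ibi_rng = np.random.default_rng(streams[0])
        ibis = simulate_ibi_series(eff, cls, cfg.phase_duration_s, ibi_rng)
        ppg, beat_times = synthesize_ppg(ibis, eff, cls, cfg.fs, ibi_rng)
        eda, ev_t, ev_a, tonic = synthesize_eda(
            eff, cls, cfg.phase_duration_s, cfg.fs, np.random.default_rng(streams[1])
        )
        temp, trend = synthesize_temperature(
            eff, cls, cfg.phase_duration_s, cfg.fs, np.random.default_rng(streams[2])
        )
        truth = GroundTruth(
            class_label=cls,
            beat_times=beat_times,
            ibis=ibis,
            scr_event_times=ev_t,
            scr_event_amplitudes=ev_a,
            tonic_curve=tonic,
            temp_trend=trend,
        )
        return PhaseRecording(subject, test, phase, ppg, eda, temp, truth)

    def iter_phases(self):
        for key in self.phase_keys():
            yield self.get_phase(*key)


def simulate_cohort(config: CohortConfig, effect: EffectSpec | None = None) -> CohortRecording:
    """Simulate a full cohort; see :class:`CohortRecording`."""
    return CohortRecording(config, effect if effect is not None else EffectSpec())


# ----------------------------------------------------------------------
# table-level simulation for validating the screening stage
# ----------------------------------------------------------------------

#: Multiplier applied to the pooled-SD effect size per class; monotone so
#: higher self-rated classes sit further from baseline.
CLASS_SHIFT_PROFILE = np.array([0.0, 1.0, 1.1, 1.2, 1.3])


def simulate_feature_table(
    feature_names,
    n_subjects: int = 28,
    n_phases: int = 4,
    tests=DEFAULT_TESTS,
    label_distribution=DEFAULT_LABEL_DISTRIBUTION,
    shifted_features=(),
    effect_sd: float = 0.0,
    seed=0,
):
    """Raw feature values drawn directly at the table level.

    Every feature is i.i.d. standard normal; features named in
    ``shifted_features`` additionally receive a monotone per-class mean
    shift of ``effect_sd * CLASS_SHIFT_PROFILE[class]`` pooled standard
    deviations.  With ``effect_sd = 0`` this is an exact null for the
    screening stage.  Returns ``(features_df, labels_df)`` in the long
    layout :func:`physioscreen.dataset.assemble_dataset` consumes.
    """
    rng = _rng(seed)
    p = np.asarray(label_distribution, dtype=float)
    feature_names = list(feature_names)
    shifted_mask = np.array([name in set(shifted_features) for name in feature_names])
    unknown = set(shifted_features) - set(feature_names)
    if unknown:
        raise ValueError(f"shifted features not in catalogue: {sorted(unknown)}")
    n_f = len(feature_names)
    subj, tst, ph, cls_col = [], [], [], []
    for subject, test in itertools.product(range(n_subjects), tests):
        for phase in range(n_phases):
            cls = 0 if phase == 0 else int(rng.choice(4, p=p)) + 1
            subj.append(subject)
            tst.append(test)
            ph.append(phase)
            cls_col.append(cls)
    n_rows = len(subj)
    values = rng.normal(0.0, 1.0, size=(n_rows, n_f))
    shifts = effect_sd * CLASS_SHIFT_PROFILE[np.asarray(cls_col)]
    values[:, shifted_mask] += shifts[:, None]
    labels = pd.DataFrame({"subject": subj, "test": tst, "phase": ph, "class": cls_col})
    features = pd.DataFrame(
        {
            "subject": np.repeat(subj, n_f),
            "test": np.repeat(tst, n_f),
            "phase": np.repeat(ph, n_f),
            "feature": np.tile(feature_names, n_rows),
            "value": values.ravel(),
        }
    )
    return features, labels


# ----------------------------------------------------------------------
# plain-text I/O
# ----------------------------------------------------------------------

def write_phase_csv(path, phase: PhaseRecording) -> None:
    """Write one phase as CSV (time_s, ppg, eda_uS, temp_C) + YAML sidecar."""
    n = min(phase.ppg.n_samples, phase.eda.n_samples, phase.temperature.n_samples)
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / phase.ppg.fs,
            "ppg": phase.ppg.values[:n],
            "eda_uS": phase.eda.values[:n],
            "temp_C": phase.temperature.values[:n],
        }
    )
    df.to_csv(path, index=False)
    sidecar = str(path) + ".yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "fs_hz": float(phase.ppg.fs),
                "subject": int(phase.subject),
                "test": str(phase.test),
                "phase": int(phase.phase),
                "class": int(phase.truth.class_label),
            },
            fh,
        )


def read_phase_csv(path):
    """Read a phase CSV + sidecar back into three ChannelRecordings."""
    with open(str(path) + ".yaml") as fh:
        meta = yaml.safe_load(fh)
    df = pd.read_csv(path)
    fs = float(meta["fs_hz"])
    recs = {
        "ppg": ChannelRecording(df["ppg"].to_numpy(), fs, "ppg", meta=dict(meta)),
        "eda": ChannelRecording(df["eda_uS"].to_numpy(), fs, "eda", meta=dict(meta)),
        "temperature": ChannelRecording(df["temp_C"].to_numpy(), fs, "temperature", meta=dict(meta)),
    }
    return recs, meta
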