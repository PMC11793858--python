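"""Electrodermal activity: convex tonic/phasic decomposition and features.

The skin-conductance signal is modelled as

    y = tonic + phasic + residual,
    phasic = k * q      (discrete convolution),
    tonic  = B c        (cubic B-spline basis, knot every 10 s),

with ``k`` a Bateman kernel ``exp(-t/tau2) - exp(-t/tau1)`` (tau1 < tau2)
normalised to unit peak and ``q >= 0`` a sparse non-negative driver of
sudomotor activity.  The decomposition solves the convex program

    minimize_{q >= 0, c}  1/2 ||y - k*q - Bc||^2 + alpha * 1'q
                          + gamma/2 * ||D2 c||^2

(the L1 driver penalty reduces to a linear term on the non-negative
orthant, so the whole objective is a smooth QP over a box) by accelerated
projected gradient (FISTA).  Convolutions are evaluated by FFT, so the
solver never materialises the n-by-n convolution matrix.

Features: SCL mean / SD / slope on the tonic component; SCR mean / SD of
peak amplitude and rise time plus the peak count per phase on the phasic
component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal as sps

from .recording import ChannelRecording
from .synthetic import bateman_kernel, bateman_peak

logger = logging.getLogger(__name__)

#: Minimum phasic peak height accepted as an SCR, in µS.
SCR_AMPLITUDE_FLOOR_US = 0.01


@dataclass
class EDADecomposition:
    """Tonic + phasic + residual = input (exact, pointwise, at ``fs``)."""

    signal: np.ndarray    # the (down-sampled) input the program was solved on
    tonic: np.ndarray     # µS
    phasic: np.ndarray    # µS, = kernel * driver
    driver: np.ndarray    # >= 0
    residual: np.ndarray  # µS
    fs: float
    objective: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        if np.any(self.driver < 0):
            raise ValueError("driver must be non-negative")


def _downsample(rec: ChannelRecording, target_fs: float):
    factor = max(int(round(rec.fs / target_fs)), 1)
    if factor == 1:
        return rec.values.copy(), rec.fs
    # line padding: zero padding would fake large edge transients that the
    # solver would then explain with spurious SCR events
    y = sps.resample_poly(rec.values, 1, factor, padtype="line")
    return y, rec.fs / factor


def _tonic_basis(n: int, fs: float, knot_spacing_s: float = 10.0) -> np.ndarray:
    t = np.arange(n) / fs
    n_interior = max(int(t[-1] // knot_spacing_s) - 1, 0)
    interior = np.linspace(0, t[-1], n_interior + 2)[1:-1] if n_interior else np.array([])
    k = 3
    knots = np.concatenate([np.repeat(t[0], k + 1), interior, np.repeat(t[-1], k + 1)])
    return interpolate.BSpline.design_matrix(t, knots, k).toarray()


def decompose_eda(
    eda: ChannelRecording,
    tau1: float = 0.7,
    tau2: float = 3.0,
    alpha: float = 0.02,
    gamma: float = 0.05,
    solve_fs: float = 8.0,
    max_iter: int = 4000,
    tol: float = 1e-7,
) -> EDADecomposition:
    """Solve the tonic/phasic convex program on a down-sampled copy.

    The input is decimated to ``solve_fs`` (default 8 Hz — far above the
    EDA bandwidth, far below the acquisition rate) for tractability; the
    returned decomposition lives on that grid.

    Raises
    ------
    RuntimeError
        if FISTA has not reached the relative-objective tolerance after
        ``max_iter`` iterations.
    """
    if not 0 < tau1 < tau2:
        raise ValueError("Bateman kernel requires 0 < tau1 < tau2")
    if eda.n_samples / eda.fs < 30:
        raise ValueError("EDA decomposition requires at least 30 s of signal")
    if solve_fs > 25:
        raise ValueError("solve_fs must be <= 25 Hz")
    y, fs = _downsample(eda, solve_fs)
    n = y.size
    _, k_peak = bateman_peak(tau1, tau2)
    k_len = min(int(round(10 * tau2 * fs)) + 1, n)
    kern = bateman_kernel(np.arange(k_len) / fs, tau1, tau2) / k_peak

    B = _tonic_basis(n, fs)
    m = B.shape[1]
    D2 = np.diff(np.eye(m), 2, axis=0)
    P = gamma * (D2.T @ D2)

    def conv(q):
        return sps.fftconvolve(q, kern)[:n]

    def conv_t(r):
        return sps.fftconvolve(r[::-1], kern)[:n][::-1]

    # Lipschitz constant of the smooth quadratic (largest eigenvalue of the
    # Hessian [A B]'[A B] + blockdiag(0, P)) via power iteration
    rng = np.random.default_rng(0)
    vq, vc = rng.normal(size=n), rng.normal(size=m)
    L = 1.0
    for _ in range(30):
        norm = np.sqrt(vq @ vq + vc @ vc)
        vq, vc = vq / norm, vc / norm
        r = conv(vq) + B @ vc
        wq = conv_t(r)
        wc = B.T @ r + P @ vc
        L = float(np.sqrt(wq @ wq + wc @ wc))
        vq, vc = wq, wc
    L = 1.05 * max(L, 1e-6)

    def objective(q, c):
        r = y - conv(q) - B @ c
        return 0.5 * r @ r + alpha * q.sum() + 0.5 * c @ P @ c

    # warm start: tonic-only weighted least squares fit
    c = np.linalg.lstsq(B.T @ B + P + 1e-10 * np.eye(m), B.T @ y, rcond=None)[0]
    q = np.zeros(n)
    obj0 = objective(q, c)  # zero-driver feasible point
    zq, zc = q.copy(), c.copy()
    t_acc = 1.0
    obj_prev = obj0
    converged = False
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        r = conv(zq) + B @ zc - y
        gq = conv_t(r) + alpha
        gc = B.T @ r + P @ zc
        q_new = np.maximum(zq - gq / L, 0.0)
        c_new = zc - gc / L
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t_acc**2))
        zq = q_new + (t_acc - 1) / t_new * (q_new - q)
        zc = c_new + (t_acc - 1) / t_new * (c_new - c)
        q, c, t_acc = q_new, c_new, t_new
        if it % 10 == 0 or it == max_iter:
            obj = objective(q, c)
            if obj > obj_prev:  # FISTA ripple: restart momentum
                zq, zc, t_acc = q.copy(), c.copy(), 1.0
            if abs(obj_prev - obj) <= tol * max(abs(obj0), 1.0):
                converged = True
                n_iter = it
                obj_prev = obj
                break
            obj_prev = obj
    if not converged:
        raise RuntimeError(
            f"EDA solver did not converge in {max_iter} iterations "
            f"(last relative objective change > {tol:g})"
        )
    phasic = conv(q)
    tonic = B @ c
    residual = y - tonic - phasic
    final_obj = objective(q, c)
    return EDADecomposition(
        signal=y, tonic=tonic, phasic=phasic, driver=q, residual=residual,
        fs=fs, objective=final_obj, n_iter=n_iter,
        converged=final_obj <= obj0 + 1e-9 * max(abs(obj0), 1.0),
    )


# ----------------------------------------------------------------------
# features
# ----------------------------------------------------------------------

def scl_features(tonic, fs: float) -> dict:
    """Mean (µS), sample SD (µS) and least-squares slope (µS/s) of the SCL."""
    tonic = np.asarray(tonic, dtype=float)
    if tonic.size < 2:
        raise ValueError("SCL features require at least 2 samples")
    t = np.arange(tonic.size) / fs
    slope = float(np.polyfit(t, tonic, 1)[0])
    return {
        "scl_mean": float(np.mean(tonic)),
        "scl_std": float(np.std(tonic, ddof=1)),
        "scl_slope": slope,
    }


def detect_scr_peaks(decomp: EDADecomposition,
                     amplitude_floor: float = SCR_AMPLITUDE_FLOOR_US):
    """Locate SCR peaks on the phasic component.

    A peak is a local maximum whose height above the preceding trough (the
    phasic minimum since the previous accepted peak) is at least the
    amplitude floor.  Returns ``(peak_times, amplitudes, rise_times)``.
    """
    phasic = decomp.phasic
    fs = decomp.fs
    idx, _ = sps.find_peaks(phasic, prominence=amplitude_floor / 2)
    peak_t, amps, rises = [], [], []
    prev = 0
    for p in idx:
        trough = prev + int(np.argmin(phasic[prev:p])) if p > prev else prev
        amp = phasic[p] - phasic[trough]
        if amp < amplitude_floor:
            continue
        peak_t.append(p / fs)
        amps.append(float(amp))
        rises.append((p - trough) / fs)
        prev = p
    return np.asarray(peak_t), np.asarray(amps), np.asarray(rises)


def scr_features(decomp: EDADecomposition, phase_duration_s: float | None = None,
                 amplitude_floor: float = SCR_AMPLITUDE_FLOOR_US) -> dict:
    """5 SCR features: mean/SD amplitude (µS), mean/SD rise time (s) and
    the peak count per phase.  With zero peaks the amplitude/rise features
    are missing (NaN) and the count is 0."""
    _, amps, rises = detect_scr_peaks(decomp, amplitude_floor)
    out = {"scr_peak_count": float(amps.size)}
    if amps.size == 0:
        logger.warning("no SCR peaks above %.3f µS; amplitude/rise features missing",
                       amplitude_floor)
        out.update({k: float("nan") for k in
                    ("scr_amplitude_mean", "scr_amplitude_std",
                     "scr_rise_time_mean", "scr_rise_time_std")})
        return out
    out["scr_amplitude_mean"] = float(np.mean(amps))
    out["scr_amplitude_std"] = float(np.std(amps, ddof=1)) if amps.size > 1 else float("nan")
    out["scr_rise_time_mean"] = float(np.mean(rises))
    out["scr_rise_time_std"] = float(np.std(rises, ddof=1)) if rises.size > 1 else float("nan")
    return out
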