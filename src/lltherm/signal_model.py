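"""Look-Locker partial-saturation-recovery signal model.

A saturation pulse (nominally 90°) nulls the longitudinal magnetization, after
which a train of small-flip-angle pulses ``alpha``, spaced by ``TR_alpha``,
samples the recovery.  Each readout pulse removes a fraction ``1 - cos(alpha)``
of the longitudinal magnetization, so the observed recovery is governed by an
*apparent* relaxation time ``T1* < T1``:

    1/T1* = 1/T1 - ln(cos alpha) / TR_alpha

The recovery sampled at the pulse times follows ``Mz(t) = A (1 - exp(-t/T1*))``
exactly, where the steady-state amplitude of the discrete train is

    A = M0 (1 - E) / (1 - E cos alpha),       E = exp(-TR_alpha / T1)

``A`` reduces to the familiar continuous-readout asymptote
``M0* = M0 T1*/T1`` in the limit ``TR_alpha << T1``.  Because saturation nulls
``Mz`` regardless of its history, truncating the pulse train (shorter TR on a
reacquisition) leaves the sampled curve unchanged — the property that makes
variable signal averaging possible.

All angles are accepted in degrees; all times in milliseconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueParams",
    "ApparentRecovery",
    "apparent_t1",
    "true_t1",
    "t1star_max",
    "steady_state_amplitudes",
    "train_amplitude",
    "recovery_curve",
    "sample_times",
    "simulate_sampled_train",
    "max_slices",
    "n_sampling_points",
]


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class SequenceParams:
    """Timing and flip-angle constants of the interleaved acquisition.

    Defaults reproduce a 0.1 T protocol: nominal readout flip angle 5°,
    TR_alpha = 25 ms, TE = 4 ms, maximum TR = 2000 ms, three interleaved
    slices whose per-slice saturation slots fill one TR_alpha.
    """

    alpha_nominal: float = 5.0  # readout flip angle, degrees
    TR_alpha: float = 25.0      # inter-pulse sampling interval, ms
    TE: float = 4.0             # echo time, ms (timing only; no T2* decay modeled)
    TR_max: float = 2000.0      # longest repetition time, ms
    n_slices: int = 3
    t_sat: float = 25.0 / 3.0   # per-slice saturation slot, ms
    t_line: float = 25.0 / 3.0  # per-slice line-readout slot, ms
    sat_angle: float = 90.0     # saturation flip angle, degrees

    def __post_init__(self):
        _check_positive(TR_alpha=self.TR_alpha, t_sat=self.t_sat, t_line=self.t_line)
        if not 0 < self.alpha_nominal < 90:
            raise ValueError("alpha_nominal must lie in (0, 90) degrees")
        if not 0 < self.sat_angle <= 180:
            raise ValueError("sat_angle must lie in (0, 180] degrees")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_slices > max_slices(self.TR_alpha, self.t_line):
            raise ValueError(
                f"n_slices={self.n_slices} exceeds the slice budget "
                f"{max_slices(self.TR_alpha, self.t_line)} for TR_alpha={self.TR_alpha}, "
                f"t_line={self.t_line}"
            )
        if self.TR_max < self.TR_alpha:
            raise ValueError("TR_max must be >= TR_alpha")

    @property
    def sat_train_duration(self) -> float:
        """Duration of the slice-selective saturation train, ms."""
        return self.n_slices * self.t_sat

    @property
    def n_points_max(self) -> int:
        """Readout time points fitting in TR_max after the saturation train."""
        return n_sampling_points(self.TR_max, self.TR_alpha)


@dataclass(frozen=True)
class TissueParams:
    """Longitudinal relaxation time and equilibrium magnetization of a sample."""

    T1: float           # ms
    M0: float = 1.0     # arbitrary units

    def __post_init__(self):
        _check_positive(T1=self.T1)
        if not np.isfinite(self.M0) or self.M0 < 0:
            raise ValueError("M0 must be non-negative and finite")


@dataclass(frozen=True)
class ApparentRecovery:
    """Apparent recovery parameters under a Look-Locker readout train.

    ``M0_star`` is the asymptote of a continuous readout train; ``M0_dstar``
    the per-TR steady-state amplitude reached within a finite TR.
    """

    T1_star: float   # ms
    M0_star: float   # arb.
    M0_dstar: float  # arb.

    def __post_init__(self):
        if not self.T1_star > 0:
            raise ValueError("T1_star must be positive")
        if not 0 <= self.M0_dstar <= self.M0_star * (1 + 1e-12):
            raise ValueError("require 0 <= M0_dstar <= M0_star")


def apparent_t1(T1, alpha, TR_alpha):
    """Apparent relaxation time T1* of a Look-Locker train.

    ``1/T1* = 1/T1 - ln(cos alpha)/TR_alpha``.  Accepts arrays for ``T1`` and
    ``alpha`` (broadcast).  Always smaller than both ``T1`` and
    :func:`t1star_max`.
    """
    _check_positive(T1=T1, TR_alpha=TR_alpha)
    alpha = np.asarray(alpha, dtype=float)
    if not np.all((alpha > 0) & (alpha < 90)):
        raise ValueError("alpha must lie in (0, 90) degrees")
    out = 1.0 / (1.0 / np.asarray(T1, dtype=float)
                 - np.log(np.cos(np.radians(alpha))) / TR_alpha)
    return out if out.ndim else float(out)


def true_t1(T1_star, alpha_actual, TR_alpha):
    """Invert :func:`apparent_t1`: recover T1 from T1* and the actual flip angle.

    Raises ``ValueError`` when ``T1_star >= t1star_max(alpha_actual, TR_alpha)``,
    where the conversion has a pole (non-physical apparent time).
    """
    _check_positive(T1_star=T1_star, TR_alpha=TR_alpha)
    ts = np.asarray(T1_star, dtype=float)
    bound = t1star_max(alpha_actual, TR_alpha)
    if np.any(ts >= bound):
        raise ValueError(
            f"T1_star must be < t1star_max={np.min(bound):.6g} ms for the given flip angle"
        )
    out = 1.0 / (1.0 / ts + np.log(np.cos(np.radians(np.asarray(alpha_actual, float)))) / TR_alpha)
    return out if out.ndim else float(out)


def t1star_max(alpha, TR_alpha):
    """Upper bound on T1*, reached in the limit T1 -> infinity.

    ``T1*_max = -TR_alpha / ln(cos alpha)``; strictly decreasing in ``alpha``
    and linear in ``TR_alpha``.  Used as the fit boundary for T1* estimation.
    """
    _check_positive(TR_alpha=TR_alpha)
    alpha = np.asarray(alpha, dtype=float)
    if not np.all((alpha > 0) & (alpha < 90)):
        raise ValueError("alpha must lie in (0, 90) degrees")
    out = -TR_alpha / np.log(np.cos(np.radians(alpha)))
    return out if out.ndim else float(out)


def steady_state_amplitudes(tissue: TissueParams, seq: SequenceParams) -> ApparentRecovery:
    """Continuous-readout steady-state amplitudes M0* and M0**.

    ``M0* = M0 T1*/T1`` (asymptote of an uninterrupted train, valid for
    ``TR_alpha << T1*``) and ``M0** = M0* (1 - exp(-TR_max/T1*))``, the value
    reached at the end of a finite repetition time.
    """
    if seq.TR_alpha > 0.2 * apparent_t1(tissue.T1, seq.alpha_nominal, seq.TR_alpha):
        warnings.warn(
            "TR_alpha is not small compared with T1*; the continuous-readout "
            "amplitudes M0*/M0** are first-order approximations — see train_amplitude "
            "for the exact discrete steady state",
            stacklevel=2,
        )
    ts = apparent_t1(tissue.T1, seq.alpha_nominal, seq.TR_alpha)
    m0s = tissue.M0 * ts / tissue.T1
    m0ds = m0s * (1.0 - math.exp(-seq.TR_max / ts))
    return ApparentRecovery(T1_star=ts, M0_star=m0s, M0_dstar=m0ds)


def train_amplitude(T1, M0, alpha, TR_alpha):
    """Exact steady-state amplitude of the discrete sampled train.

    ``A = M0 (1 - E) / (1 - E cos alpha)`` with ``E = exp(-TR_alpha/T1)``.
    The sampled longitudinal magnetization after perfect saturation is exactly
    ``Mz(t_k) = A (1 - exp(-t_k/T1*))`` at ``t_k = (k+1) TR_alpha``.
    Accepts arrays (broadcast).
    """
    _check_positive(T1=T1, TR_alpha=TR_alpha)
    T1 = np.asarray(T1, dtype=float)
    E = np.exp(-TR_alpha / T1)
    out = np.asarray(M0, float) * (1.0 - E) / (1.0 - E * np.cos(np.radians(np.asarray(alpha, float))))
    return out if out.ndim else float(out)


def recovery_curve(t, rec: ApparentRecovery):
    """Sampled-train recovery ``Mz(t) = M0** (1 - exp(-t/T1*))`` for ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = rec.M0_dstar * (1.0 - np.exp(-t / rec.T1_star))
    return out if out.ndim else float(out)


def sample_times(n_points: int, TR_alpha: float) -> np.ndarray:
    """Nominal sampling grid ``t_k = (k+1) TR_alpha``, k = 0..n_points-1, ms."""
    return (np.arange(n_points) + 1.0) * TR_alpha


def simulate_sampled_train(
    tissue: TissueParams,
    seq: SequenceParams,
    n_points: int,
    n_cycles: int | None = None,
    rtol: float = 1e-9,
    Mz_init: float | None = None,
):
    """Steady-state sampled transverse amplitudes of the interleaved train.

    Discrete recursion: at each cycle the slice is saturated (``Mz`` scaled by
    ``cos(sat_angle)``), then ``n_points`` readout pulses follow at intervals
    ``TR_alpha`` (relaxation toward ``M0`` between pulses; each pulse samples
    ``sin(alpha) Mz`` and scales ``Mz`` by ``cos(alpha)``); the remainder of
    the block — the saturation train of the next cycle — is pure relaxation.
    Cycles are iterated until two consecutive sample vectors agree to ``rtol``
    (or for exactly ``n_cycles`` when given), so the output is independent of
    the initial magnetization.

    With ``sat_angle = 90`` this reproduces the closed form
    ``sin(alpha) * train_amplitude * (1 - exp(-t_k/T1*))`` exactly; with an
    imperfect saturation pulse the residual magnetization carried across
    cycles perturbs the curve (the mechanism behind saturation-miscalibration
    T1 errors).

    Returns
    -------
    ndarray of shape (n_points,)
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    block_len = seq.sat_train_duration + n_points * seq.TR_alpha
    if block_len > seq.TR_max + 1e-9:
        raise ValueError(
            f"n_points={n_points} readouts plus the saturation train "
            f"({block_len:.6g} ms) exceed TR_max={seq.TR_max} ms"
        )
    E = math.exp(-seq.TR_alpha / tissue.T1)
    ca = math.cos(math.radians(seq.alpha_nominal))
    sa = math.sin(math.radians(seq.alpha_nominal))
    cs = math.cos(math.radians(seq.sat_angle))
    # relaxation over the saturation-train slot of the next cycle
    E_gap = math.exp(-seq.sat_train_duration / tissue.T1)
    M0 = tissue.M0

    Mz = M0 if Mz_init is None else float(Mz_init)
    prev = None
    max_cycles = n_cycles if n_cycles is not None else 10_000
    for _ in range(max_cycles):
        Mz *= cs
        s = np.empty(n_points)
        for k in range(n_points):
            Mz = M0 + (Mz - M0) * E
            s[k] = sa * Mz
            Mz *= ca
        Mz = M0 + (Mz - M0) * E_gap
        if n_cycles is None and prev is not None:
            scale = max(np.max(np.abs(s)), np.finfo(float).tiny)
            if np.max(np.abs(s - prev)) <= rtol * scale:
                return s
        prev = s
    if n_cycles is None:
        raise RuntimeError("sampled train did not reach steady state")
    return prev


def max_slices(TR_alpha: float, t_line: float) -> int:
    """Largest number of interleaved slices: ``floor(TR_alpha / t_line)``.

    One line of every slice must be read within a single inter-pulse interval.
    Returns 0 (with a warning) when a single slice does not fit.
    """
    _check_positive(TR_alpha=TR_alpha, t_line=t_line)
    n = int(math.floor(TR_alpha / t_line + 1e-9))
    if n < 1:
        warnings.warn("t_line exceeds TR_alpha: no slice fits in one interval", stacklevel=2)
    return n


def n_sampling_points(TR_max: float, TR_alpha: float, n_sat_slots: int = 1) -> int:
    """Readout time points per repetition time.

    The saturation train occupies ``n_sat_slots`` intervals of length
    ``TR_alpha`` (one, when the per-slice saturation slots of all interleaved
    slices fill a single interval); the rest of ``TR_max`` is available for
    readout pulses: ``floor(TR_max / TR_alpha) - n_sat_slots``.
    """
    _check_positive(TR_max=TR_max, TR_alpha=TR_alpha)
    n = int(math.floor(TR_max / TR_alpha + 1e-9)) - n_sat_slots
    if n < 1:
        raise ValueError("TR_max leaves no room for readout points")
    return n
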