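"""T1-based temperature calibration and mapping.

Over the mild-hyperthermia range, each aqueous sample's longitudinal
relaxation time follows a linear law ``T1_i = k_i T + c_i``.  A temperature
change is then ``Tb - Ta = (T1_b - T1_a) / k_i`` when the sample-specific
sensitivity ``k_i`` is known.  Across samples, the sensitivities themselves
are proportional to the reference relaxation time, ``k = K T1_a``, with a
single coefficient ``K`` (about 0.0265 per °C at 0.1 T), which turns the law
into a sample-independent conversion

    Tb - Ta = (1/K) (T1_b / T1_a - 1)

usable pixel-wise on two T1 maps without any per-sample calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .recon import T1Map

__all__ = [
    "CalibrationTable",
    "SensitivityModel",
    "TemperatureMap",
    "fit_sr_recovery",
    "fit_temperature_line",
    "fit_K",
    "temperature_map",
    "temperature_from_known_k",
]


@dataclass
class CalibrationTable:
    """Per-sample linear temperature laws and reference T1 values.

    ``table`` columns: ``sample``, ``slope`` (ms/°C), ``slope_err``,
    ``intercept`` (ms), ``intercept_err``, ``r2``, and optionally ``t1_ref``
    (ms) with ``temp_ref`` (°C) for the reference-temperature measurement.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"sample", "slope", "intercept"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"calibration table lacks columns: {sorted(missing)}")
        if np.any(self.table["slope"] <= 0):
            raise ValueError("temperature sensitivities (slopes) must be positive")
        if "r2" in self.table and np.any((self.table["r2"] < 0) | (self.table["r2"] > 1)):
            raise ValueError("r2 must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def t1_at(self, temperature: float) -> np.ndarray:
        """Evaluate every sample's line ``k_i T + c_i`` at a temperature, ms."""
        return (self.table["slope"] * temperature + self.table["intercept"]).to_numpy(float)

    def t1_ref(self) -> np.ndarray:
        """Reference T1 per sample: the ``t1_ref`` column when present, else
        the fitted line at ``temp_ref``."""
        if "t1_ref" in self.table:
            return self.table["t1_ref"].to_numpy(float)
        if "temp_ref" not in self.table:
            raise ValueError("table provides neither t1_ref nor temp_ref")
        return self.t1_at(float(self.table["temp_ref"].iloc[0]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        return cls(table=pd.read_csv(path))


@dataclass(frozen=True)
class SensitivityModel:
    """Global sensitivity coefficient ``K`` in ``k = K T1_a``, 1/°C."""

    K: float
    stderr: float = float("nan")
    method: str = "ols_through_origin"

    def __post_init__(self):
        if not self.K > 0:
            raise ValueError("K must be positive")


@dataclass
class TemperatureMap:
    """Per-pixel absolute temperature, °C, with a validity mask."""

    temperature: np.ndarray
    valid: np.ndarray
    reference_temp: float


def fit_sr_recovery(times, signals, return_stderr: bool = False):
    """Two-parameter saturation-recovery fit ``Mz(t) = M0 (1 - exp(-t/T1))``.

    Suited to logarithmically spaced spectroscopic sampling.  Returns
    ``(M0, T1)``; with ``return_stderr`` also their standard errors.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signals, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("at least 3 time points are required")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    m0_0 = max(y.max(), np.finfo(float).tiny)
    # crude T1 start: time to reach (1 - 1/e) of the plateau
    target = m0_0 * (1 - np.exp(-1))
    above = np.nonzero(y >= target)[0]
    t1_0 = t[above[0]] if above.size else t[-1] / 2
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, m0, t1: m0 * (1.0 - np.exp(-t / t1)),
            t, y, p0=[m0_0, max(t1_0, t[0])],
            bounds=([0, t[0] * 1e-3], [np.inf, t[-1] * 1e3]),
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"saturation-recovery fit did not converge: {err}") from err
    if return_stderr:
        return tuple(popt), tuple(np.sqrt(np.diag(pcov)))
    return float(popt[0]), float(popt[1])


def fit_temperature_line(temperatures, t1_values):
    """Ordinary least squares ``T1 = k T + c``; returns ``(k, c, r2)``."""
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(t1_values, dtype=float)
    if len(T) < 3:
        raise ValueError("at least 3 calibration points are required")
    if np.ptp(T) == 0:
        raise ValueError("temperatures are degenerate (constant)")
    res = stats.linregress(T, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_K(calib: CalibrationTable, weighted: bool = False) -> SensitivityModel:
    """Fit the proportionality ``k = K T1_a`` across samples.

    Through-origin least squares of the per-sample sensitivities on their
    reference T1 values; ``weighted`` uses inverse-variance weights from the
    ``slope_err`` column.  The through-origin form follows the model, which
    has no intercept.
    """
    if len(calib) == 0:
        raise ValueError("empty calibration table")
    k = calib.table["slope"].to_numpy(float)
    x = calib.t1_ref()
    if weighted:
        if "slope_err" not in calib.table:
            raise ValueError("weighted fit requires a slope_err column")
        w = 1.0 / calib.table["slope_err"].to_numpy(float) ** 2
        method = "wls_through_origin"
    else:
        w = np.ones_like(k)
        method = "ols_through_origin"
    K = float((w * k * x).sum() / (w * x * x).sum())
    resid = k - K * x
    dof = max(len(k) - 1, 1)
    stderr = float(np.sqrt((w * resid**2).sum() / dof / (w * x * x).sum()))
    return SensitivityModel(K=K, stderr=stderr, method=method)


def _as_map(m) -> T1Map:
    if isinstance(m, T1Map):
        return m
    arr = np.asarray(m, dtype=float)
    return T1Map(t1=arr, valid=np.isfinite(arr) & (arr > 0))


def temperature_map(t1_b, t1_a, Ta: float, model: SensitivityModel | float) -> TemperatureMap:
    """Sample-independent conversion ``Tb = Ta + (T1_b/T1_a - 1) / K``.

    ``t1_b``/``t1_a`` are :class:`~lltherm.recon.T1Map` or plain arrays on the
    same grid; pixels invalid in either input, or with ``T1_a <= 0``, are
    invalid in the output.
    """
    K = model.K if isinstance(model, SensitivityModel) else float(model)
    if not K > 0:
        raise ValueError("K must be positive")
    if not np.isfinite(Ta):
        raise ValueError("reference temperature must be finite")
    mb, ma = _as_map(t1_b), _as_map(t1_a)
    if mb.t1.shape != ma.t1.shape:
        raise ValueError("T1 map grids do not match")
    ok = mb.valid & ma.valid & (ma.t1 > 0)
    temp = np.full(mb.t1.shape, np.nan)
    temp[ok] = Ta + (mb.t1[ok] / ma.t1[ok] - 1.0) / K
    return TemperatureMap(temperature=temp, valid=ok, reference_temp=float(Ta))


def temperature_from_known_k(t1_b, t1_a, Ta: float, k_i: float) -> TemperatureMap:
    """Sample-specific conversion ``Tb = Ta + (T1_b - T1_a) / k_i``.

    Algebraically identical to :func:`temperature_map` when
    ``k_i = K * T1_a`` pixel-wise.
    """
    if not k_i > 0:
        raise ValueError("k_i must be positive")
    if not np.isfinite(Ta):
        raise ValueError("reference temperature must be finite")
    mb, ma = _as_map(t1_b), _as_map(t1_a)
    if mb.t1.shape != ma.t1.shape:
        raise ValueError("T1 map grids do not match")
    ok = mb.valid & ma.valid
    temp = np.full(mb.t1.shape, np.nan)
    temp[ok] = Ta + (mb.t1[ok] - ma.t1[ok]) / k_i
    return TemperatureMap(temperature=temp, valid=ok, reference_temp=float(Ta))
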