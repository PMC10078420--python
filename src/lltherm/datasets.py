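"""Bundled reference dataset: a 0.1 T MnCl2-doped-water phantom study.

Fifteen aqueous samples (S1..S15) spanning T1 from about 50 to 1750 ms were
calibrated spectroscopically against temperature; the first five were then
imaged with the interleaved Look-Locker sequence at six temperature points.
The tables ship with the package for worked examples, calibration defaults,
and validation of the statistics module:

- per-sample linear temperature laws (slope, intercept, r²),
- per-sample T1 estimates at the reference temperature for the constant
  (NA = 12) and variable averaging schemes, next to the calibrated values,
- per-sample mean T1 across the six measured temperatures (S1..S5),
- per-sample temperature estimates from the T1 maps at the five heated points.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .thermometry import CalibrationTable

__all__ = [
    "temperature_sensitivity_table",
    "reference_t1_table",
    "t1_vs_temperature_table",
    "temperature_estimates_table",
    "load_calibration",
]

REFERENCE_TEMPERATURE_C = 25.0  # nominal bath set point; measured 24.3 / 24.2 °C
SENSITIVITY_COEFFICIENT_K = 0.0265  # 1/°C, the study's printed global sensitivity


def _read(name: str) -> pd.DataFrame:
    with resources.files("lltherm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def temperature_sensitivity_table() -> pd.DataFrame:
    """Per-sample linear law T1_i = k_i T + c_i (slopes in ms/°C)."""
    return _read("temperature_sensitivity.csv")


def reference_t1_table() -> pd.DataFrame:
    """T1 estimates at the reference temperature: calibrated vs mapped
    (constant NA = 12 and variable averaging), with per-vial s.d."""
    return _read("reference_t1_estimates.csv")


def t1_vs_temperature_table() -> pd.DataFrame:
    """Mean mapped T1 of samples S1..S5 at six measured temperatures."""
    return _read("t1_vs_temperature.csv")


def temperature_estimates_table() -> pd.DataFrame:
    """Mean mapped temperature of S1..S5 at the five heated points."""
    return _read("temperature_estimates.csv")


def load_calibration(n_samples: int | None = None) -> CalibrationTable:
    """Bundled calibration as a :class:`~lltherm.thermometry.CalibrationTable`.

    The reference T1 per sample is the calibrated value at the measured
    reference temperature; ``n_samples`` restricts to the first samples
    (``n_samples=5`` reproduces the imaging subset).
    """
    sens = temperature_sensitivity_table().rename(
        columns={"slope_ms_per_c": "slope", "intercept_ms": "intercept"}
    )
    ref = reference_t1_table()
    table = sens.merge(
        ref[["sample", "measured_temp_c", "t1_calibrated_ms"]], on="sample"
    ).rename(columns={"t1_calibrated_ms": "t1_ref", "measured_temp_c": "temp_ref"})
    if n_samples is not None:
        table = table.iloc[:n_samples].reset_index(drop=True)
    return CalibrationTable(table=table)
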