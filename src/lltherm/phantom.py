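"""Digital vial phantoms and synthetic k-space acquisition.

The generator emulates a low-field (0.1 T) phantom experiment: MnCl2-doped
water vials immersed in a water bath, imaged with the interleaved
Look-Locker partial-saturation-recovery sequence on a 64 x 35 matrix.  It
produces, per averaging-schedule block and repeat, complex k-space with
Gaussian-weighted phase-encode undersampling and independent complex Gaussian
noise, so that magnitude images carry Rician noise — the regime the
reconstruction chain is designed for.

Vial T1 values may be set directly or derived from linear temperature laws
``T1_i = k_i T + c_i`` so that phantom temperature and thermometry output can
be cross-checked end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .schedule import AveragingSchedule, na_profile
from .signal_model import (
    SequenceParams,
    TissueParams,
    apparent_t1,
    sample_times,
    train_amplitude,
)

__all__ = [
    "VialGeometry",
    "DigitalPhantom",
    "FlipAngleMap",
    "KSpaceSeries",
    "default_geometry",
    "make_vial_phantom",
    "make_flip_angle_map",
    "gaussian_line_mask",
    "pixel_signals",
    "simulate_acquisition",
]

BATH_LABEL = 1
FIRST_VIAL_LABEL = 2


@dataclass(frozen=True)
class VialGeometry:
    """Disc layout: a circular bath containing non-overlapping vial discs."""

    grid_shape: tuple[int, int] = (64, 35)
    bath_center: tuple[float, float] = (31.5, 17.0)
    bath_radius: float = 13.5   # 8.1 cm jar diameter at 3 mm in-plane resolution
    vial_centers: tuple[tuple[float, float], ...] = ()
    vial_radius: float = 4.1    # 2.5 cm vial diameter at 3 mm resolution


def default_geometry(n_vials: int = 5, grid_shape: tuple[int, int] = (64, 35)) -> VialGeometry:
    """Five (or fewer) vial discs on a ring inside a circular bath."""
    cx, cy = (grid_shape[0] - 1) / 2.0, (grid_shape[1] - 1) / 2.0
    ring = 8.5
    angles = 2 * np.pi * np.arange(n_vials) / max(n_vials, 1) + np.pi / 2
    centers = tuple((cx + ring * np.cos(a), cy + ring * np.sin(a)) for a in angles)
    return VialGeometry(
        grid_shape=grid_shape,
        bath_center=(cx, cy),
        bath_radius=13.5,
        vial_centers=centers,
        vial_radius=4.1,
    )


@dataclass
class DigitalPhantom:
    """Integer label grid plus per-label tissue parameters.

    Label 0 is background (no signal); label 1 the water bath; labels >= 2
    the vials in order.
    """

    label_grid: np.ndarray
    vial_params: dict[int, TissueParams]
    temperature: float | None = None  # °C, when built from a calibration

    def __post_init__(self):
        labels = set(np.unique(self.label_grid)) - {0}
        missing = labels - set(self.vial_params)
        if missing:
            raise ValueError(f"labels without tissue parameters: {sorted(missing)}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def t1_grid(self) -> np.ndarray:
        out = np.zeros(self.label_grid.shape)
        for lab, tp in self.vial_params.items():
            out[self.label_grid == lab] = tp.T1
        return out

    def m0_grid(self) -> np.ndarray:
        out = np.zeros(self.label_grid.shape)
        for lab, tp in self.vial_params.items():
            out[self.label_grid == lab] = tp.M0
        return out

    def vial_labels(self) -> list[int]:
        return sorted(l for l in self.vial_params if l >= FIRST_VIAL_LABEL)


@dataclass(frozen=True)
class FlipAngleMap:
    """Per-pixel actual readout flip angle, degrees."""

    angles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise ValueError("flip angles must be positive and finite")
        object.__setattr__(self, "angles", a)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.angles.shape


@dataclass
class KSpaceSeries:
    """Multi-average complex k-space, organized per schedule block.

    ``data[b]`` has shape ``(n_slices, n_repeats_b, n_points_b, nx, ny)``
    with the DC line at index ``ny // 2`` (fftshift convention); repeats of a
    truncated block hold data only for its own time points.  Masked-out
    phase-encode lines are identically zero and flagged in ``line_mask``.
    """

    data: list[np.ndarray]
    schedule: AveragingSchedule
    seq: SequenceParams
    line_mask: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.data) != len(self.schedule.blocks):
            raise ValueError("one data array per schedule block required")
        for arr, (n_points, n_repeats) in zip(self.data, self.schedule.blocks):
            if arr.shape[:3] != (self.seq.n_slices, n_repeats, n_points):
                raise ValueError(
                    f"block array shape {arr.shape} inconsistent with schedule/sequence"
                )
        if self.line_mask.shape[0] != self.data[0].shape[-1]:
            raise ValueError("line_mask length must equal the phase-encode dimension")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data[0].shape[-2:]

    @property
    def times(self) -> np.ndarray:
        return sample_times(self.schedule.n_points_max, self.schedule.TR_alpha)


def _disc_mask(shape, center, radius):
    x, y = np.ogrid[: shape[0], : shape[1]]
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2


def make_vial_phantom(
    vial_t1s=None,
    geometry: VialGeometry | None = None,
    temperature: float | None = None,
    calibration=None,
    bath_t1: float = 3000.0,
    m0: float = 1.0,
) -> DigitalPhantom:
    """Build a disc phantom with literal or temperature-derived vial T1s.

    When ``calibration`` (a :class:`~lltherm.thermometry.CalibrationTable`) is
    given, per-vial T1 follows its linear law ``T1_i = k_i T + c_i`` at the
    requested ``temperature``; otherwise ``vial_t1s`` are used directly.
    Temperatures outside the calibrated 20-65 °C range only warn.
    """
    if calibration is not None:
        if temperature is None:
            raise ValueError("temperature is required when a calibration is given")
        if not 20.0 <= temperature <= 65.0:
            warnings.warn(
                f"temperature {temperature} °C outside the calibrated range [20, 65] °C",
                stacklevel=2,
            )
        vial_t1s = calibration.t1_at(temperature)
    vial_t1s = [] if vial_t1s is None else list(np.atleast_1d(vial_t1s).astype(float))
    if geometry is None:
        geometry = default_geometry(n_vials=len(vial_t1s))
    if len(geometry.vial_centers) < len(vial_t1s):
        raise ValueError("geometry provides fewer vial positions than T1 values")

    grid = np.zeros(geometry.grid_shape, dtype=int)
    grid[_disc_mask(geometry.grid_shape, geometry.bath_center, geometry.bath_radius)] = BATH_LABEL
    params = {BATH_LABEL: TissueParams(T1=bath_t1, M0=m0)}
    for i, t1 in enumerate(vial_t1s):
        mask = _disc_mask(geometry.grid_shape, geometry.vial_centers[i], geometry.vial_radius)
        if np.any(grid[mask] >= FIRST_VIAL_LABEL):
            raise ValueError(f"vial {i} overlaps a previously placed vial")
        grid[mask] = FIRST_VIAL_LABEL + i
        params[FIRST_VIAL_LABEL + i] = TissueParams(T1=float(t1), M0=m0)
    return DigitalPhantom(label_grid=grid, vial_params=params, temperature=temperature)


def make_flip_angle_map(
    grid_shape: tuple[int, int],
    mean: float = 4.8,
    sd: float = 0.6,
    correlation_length: float = 8.0,
    seed=None,
) -> FlipAngleMap:
    """Smooth random flip-angle field with exact sample mean and s.d.

    White Gaussian noise is low-pass filtered with a Gaussian kernel of width
    ``correlation_length`` pixels, standardized, and rescaled to the requested
    mean and standard deviation (the empirical moments of a transmit-field
    map, e.g. 4.8 ± 0.6° for a solenoid coil at nominal 5°).
    """
    from scipy.ndimage import gaussian_filter

    if mean <= 0 or sd < 0:
        raise ValueError("require mean > 0 and sd >= 0")
    if sd == 0:
        return FlipAngleMap(angles=np.full(grid_shape, float(mean)))
    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal(grid_shape), correlation_length, mode="wrap")
    field = (field - field.mean()) / field.std()
    angles = mean + sd * field
    floor = 0.05 * mean
    if np.any(angles < floor):
        warnings.warn("flip-angle field clipped at the low end; sd reduced slightly", stacklevel=2)
        angles = np.clip(angles, floor, None)
    return FlipAngleMap(angles=angles)


def gaussian_line_mask(n_lines: int, n_keep: int, width: float | None = None, seed=None) -> np.ndarray:
    """Phase-encode undersampling mask with Gaussian line weighting.

    Exactly ``n_keep`` of ``n_lines`` lines are retained, drawn without
    replacement with probabilities ``exp(-(i - c)^2 / (2 width^2))`` centered
    on the DC line ``c = n_lines // 2``, which is always kept (the fit's
    dynamic range requires the DC component).  ``width`` defaults to
    ``n_lines / 4``.
    """
    if not 1 <= n_keep <= n_lines:
        raise ValueError("require 1 <= n_keep <= n_lines")
    center = n_lines // 2
    mask = np.zeros(n_lines, dtype=bool)
    mask[center] = True
    if n_keep > 1:
        rng = np.random.default_rng(seed)
        if width is None:
            width = n_lines / 4.0
        idx = np.delete(np.arange(n_lines), center)
        w = np.exp(-((idx - center) ** 2) / (2.0 * width**2))
        chosen = rng.choice(idx, size=n_keep - 1, replace=False, p=w / w.sum())
        mask[chosen] = True
    return mask


def pixel_signals(
    phantom: DigitalPhantom,
    b1map: FlipAngleMap,
    seq: SequenceParams,
    n_points: int,
) -> np.ndarray:
    """Noise-free per-pixel transverse signal, shape ``(n_points, nx, ny)``.

    Uses the exact closed form of the steady-state sampled train with perfect
    saturation: ``sin(alpha_p) A_p (1 - exp(-t_k / T1*_p))``.  An imperfect
    saturation pulse (``seq.sat_angle != 90``) is propagated through the
    cycle recursion, vectorized over pixels, to its block-specific steady
    state.
    """
    if b1map.grid_shape != phantom.grid_shape:
        raise ValueError("flip-angle map grid does not match the phantom grid")
    t1 = phantom.t1_grid()
    m0 = phantom.m0_grid()
    support = t1 > 0
    alpha = b1map.angles
    t = sample_times(n_points, seq.TR_alpha)

    out = np.zeros((n_points,) + phantom.grid_shape)
    if not np.any(support):
        return out
    T1 = t1[support]
    M0 = m0[support]
    a = np.radians(alpha[support])

    if seq.sat_angle == 90.0:
        ts = apparent_t1(T1, np.degrees(a), seq.TR_alpha)
        amp = train_amplitude(T1, M0, np.degrees(a), seq.TR_alpha)
        sig = np.sin(a)[None, :] * amp[None, :] * (1.0 - np.exp(-t[:, None] / ts[None, :]))
    else:
        sig = _train_recursion(T1, M0, a, seq, n_points)
    out[:, support] = sig
    return out


def _train_recursion(T1, M0, alpha_rad, seq: SequenceParams, n_points, rtol=1e-10):
    """Vectorized steady-state cycle recursion for arbitrary saturation angle."""
    E = np.exp(-seq.TR_alpha / T1)
    E_gap = np.exp(-seq.sat_train_duration / T1)
    ca, sa = np.cos(alpha_rad), np.sin(alpha_rad)
    cs = np.cos(np.radians(seq.sat_angle))
    Mz = M0.astype(float).copy()
    prev = None
    for _ in range(10_000):
        Mz = Mz * cs
        s = np.empty((n_points, len(T1)))
        for k in range(n_points):
            Mz = M0 + (Mz - M0) * E
            s[k] = sa * Mz
            Mz = Mz * ca
        Mz = M0 + (Mz - M0) * E_gap
        if prev is not None and np.max(np.abs(s - prev)) <= rtol * max(np.max(np.abs(s)), 1e-300):
            return s
        prev = s
    raise RuntimeError("pixel train recursion did not converge")


def simulate_acquisition(
    phantom: DigitalPhantom,
    b1map: FlipAngleMap,
    schedule: AveragingSchedule,
    seq: SequenceParams,
    mask: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed=None,
) -> KSpaceSeries:
    """Simulate the multi-average undersampled k-space series.

    Per schedule block: the noise-free image stack (identical across repeats
    in steady state) is Fourier transformed along both in-plane axes (DC
    centered), phase-encode lines outside ``mask`` are zeroed, and
    independent complex Gaussian noise of standard deviation ``noise_sd`` per
    component is added to the sampled lines of every repeat.  All slices see
    the same 2-D phantom.  Deterministic for a fixed ``seed``.
    """
    nx, ny = phantom.grid_shape
    if mask is None:
        mask = np.ones(ny, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ny,):
        raise ValueError(f"line mask must have length {ny} (phase-encode lines)")
    rng = np.random.default_rng(seed)

    data = []
    for n_points, n_repeats in schedule.blocks:
        sig = pixel_signals(phantom, b1map, seq, n_points)  # (n_points, nx, ny)
        ks = np.fft.fftshift(np.fft.fft2(sig, axes=(-2, -1)), axes=(-2, -1))
        ks[..., ~mask] = 0.0
        block = np.broadcast_to(
            ks[None, None], (seq.n_slices, n_repeats, n_points, nx, ny)
        ).copy()
        if noise_sd > 0:
            shape = (seq.n_slices, n_repeats, n_points, nx, int(mask.sum()))
            noise = noise_sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
            block[..., mask] += noise
        data.append(block)
    return KSpaceSeries(
        data=data,
        schedule=schedule,
        seq=seq,
        line_mask=mask,
        noise_sd=noise_sd,
        seed=seed if isinstance(seed, int) else None,
    )
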