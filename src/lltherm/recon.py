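"""Reconstruction chain: apodization, zero-filling, averaging, segmentation,
bounded pixel-wise T1* fitting, and flip-angle-corrected T1 conversion.

Magnitude is taken per repeat and averaged in postprocessing (the acquisition
stores every repeat separately), with optional per-repeat background
subtraction to restore the fit's dynamic range on magnitude data; the
two-parameter model ``A (1 - exp(-t/T1*))`` is then fit per pixel with T1*
bounded above by ``T1*_max = -TR_alpha / ln(cos alpha_nominal)``, and T1 is
recovered per pixel through the apparent-relaxation relation using the local
flip angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .phantom import FlipAngleMap, KSpaceSeries
from .schedule import na_profile
from .signal_model import SequenceParams, t1star_max

__all__ = [
    "ImageSeries",
    "T1StarMap",
    "T1Map",
    "hamming_apodize",
    "zero_fill",
    "reconstruct_series",
    "background_subtract",
    "segment_vials",
    "fit_t1star",
    "t1_map",
]


@dataclass
class ImageSeries:
    """Averaged magnitude images, shape ``(n_slices, n_times, nx, ny)``."""

    images: np.ndarray
    times: np.ndarray       # ms, strictly increasing
    na: np.ndarray          # averages contributing to each time point

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.images.shape[1] != len(self.times) or len(self.na) != len(self.times):
            raise ValueError("images, times and na are inconsistent")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.images.shape[-2:]


@dataclass
class T1StarMap:
    """Per-pixel apparent relaxation time with fit diagnostics."""

    t1star: np.ndarray        # ms, (n_slices, nx, ny)
    amplitude: np.ndarray     # fitted A (per-TR steady-state amplitude), arb.
    valid: np.ndarray         # bool
    residual_norm: np.ndarray
    at_bound: np.ndarray      # bool: T1* pinned at the upper fit bound
    t1star_ci95: np.ndarray | None = None  # half-width of the 95% CI, ms
    amplitude_ci95: np.ndarray | None = None


@dataclass
class T1Map:
    """Per-pixel longitudinal relaxation time, ms."""

    t1: np.ndarray
    valid: np.ndarray


def _hamming_window(n: int) -> np.ndarray:
    w = np.hamming(n)
    return w / w.max()


def hamming_apodize(kspace: np.ndarray) -> np.ndarray:
    """Apply a separable, peak-normalized 2-D Hamming window over the last two
    axes of a DC-centered k-space array."""
    nx, ny = kspace.shape[-2:]
    win = np.outer(_hamming_window(nx), _hamming_window(ny))
    return kspace * win


def zero_fill(kspace: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Pad DC-centered k-space symmetrically to ``out_shape`` with exact zeros.

    The input block is centered so that the DC sample at ``n // 2`` stays at
    ``n_out // 2``; requesting a smaller shape is an error.
    """
    nx, ny = kspace.shape[-2:]
    ox, oy = out_shape
    if ox < nx or oy < ny:
        raise ValueError("zero_fill cannot shrink the matrix")
    out = np.zeros(kspace.shape[:-2] + (ox, oy), dtype=kspace.dtype)
    sx, sy = ox // 2 - nx // 2, oy // 2 - ny // 2
    out[..., sx:sx + nx, sy:sy + ny] = kspace
    return out


def _to_image(ks: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(ks, axes=(-2, -1)), axes=(-2, -1))


def reconstruct_series(
    ks: KSpaceSeries,
    out_shape: tuple[int, int] | None = None,
    apodize: bool = False,
    background_roi: np.ndarray | None = None,
    clip_negative: bool = True,
) -> ImageSeries:
    """Reconstruct averaged magnitude images from a multi-average k-space series.

    Per repeat: (optional) Hamming apodization, (optional) zero-fill to
    ``out_shape``, inverse 2-D transform, magnitude; (optional) subtraction of
    the mean over ``background_roi``, clipping negatives when requested.
    Repeats mapping to the same time point are then summed and divided by
    ``NA(k)``.  Zero-filled images are rescaled by the matrix-size ratio so
    that intensities remain comparable with the native grid.
    """
    nx, ny = ks.grid_shape
    if out_shape is None:
        out_shape = (nx, ny)
    scale = (out_shape[0] * out_shape[1]) / (nx * ny)
    na = na_profile(ks.schedule)
    if np.any(na == 0):
        raise ValueError("schedule leaves time points with zero repeats")
    n_slices = ks.seq.n_slices
    accum = np.zeros((n_slices, ks.schedule.n_points_max) + tuple(out_shape))

    if background_roi is not None:
        background_roi = np.asarray(background_roi, dtype=bool)
        if background_roi.shape != tuple(out_shape):
            raise ValueError("background ROI must match the output grid")
        if not background_roi.any():
            raise ValueError("background ROI is empty")

    for block, (n_points, _) in zip(ks.data, ks.schedule.blocks):
        k = hamming_apodize(block) if apodize else block
        if tuple(out_shape) != (nx, ny):
            k = zero_fill(k, out_shape)
        mag = np.abs(_to_image(k)) * scale
        if background_roi is not None:
            offsets = mag[..., background_roi].mean(axis=-1)
            mag = mag - offsets[..., None, None]
            if clip_negative:
                mag = np.clip(mag, 0.0, None)
        accum[:, :n_points] += mag.sum(axis=1)  # sum over repeats
    images = accum / na[None, :, None, None]
    return ImageSeries(images=images, times=ks.times.copy(), na=na)


def background_subtract(
    series: ImageSeries, roi: np.ndarray, clip_negative: bool = True
) -> ImageSeries:
    """Subtract the per-image mean over a background ROI from every image.

    The ROI must lie outside all vials; negative results are clipped at zero
    by default because magnitude data feed a non-negative recovery model.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.grid_shape:
        raise ValueError("ROI grid does not match the image grid")
    if not roi.any():
        raise ValueError("background ROI is empty")
    offsets = series.images[..., roi].mean(axis=-1)
    out = series.images - offsets[..., None, None]
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return ImageSeries(images=out, times=series.times.copy(), na=series.na.copy())


def segment_vials(
    reference_image: np.ndarray,
    seeds: list[tuple[int, int]],
    tolerance: float = 0.3,
    background_threshold: float | None = None,
    merge_overlaps: bool = True,
) -> np.ndarray:
    """Intensity-based region growing from one seed per vial.

    Each region is grown by 4-connected flood fill, admitting pixels within
    ``tolerance * reference_image[seed]`` of the seed intensity.  Seeds lying
    below ``background_threshold`` (default: 10% of the image maximum) are
    rejected.  Two seeds falling in one connected region merge into a single
    label by default; with ``merge_overlaps=False`` this raises instead.
    """
    from skimage.segmentation import flood

    if not 0 < tolerance <= 1:
        raise ValueError("tolerance must lie in (0, 1]")
    img = np.asarray(reference_image, dtype=float)
    if background_threshold is None:
        background_threshold = 0.1 * img.max()
    labels = np.zeros(img.shape, dtype=int)
    next_label = 1
    for seed in seeds:
        seed = tuple(int(v) for v in seed)
        if img[seed] < background_threshold:
            raise ValueError(f"seed {seed} lies in background (intensity below threshold)")
        region = flood(img, seed, tolerance=tolerance * img[seed], connectivity=1)
        overlap = np.unique(labels[region])
        overlap = overlap[overlap > 0]
        if overlap.size:
            if not merge_overlaps:
                raise ValueError(f"seed {seed} grows into an existing region")
            labels[region] = overlap[0]
        else:
            labels[region] = next_label
            next_label += 1
    return labels


def fit_recovery_curve(
    times,
    signals,
    *,
    alpha: float,
    TR_alpha: float,
    weights=None,
    grid_size: int = 400,
):
    """Fit ``A (1 - exp(-t/T1*))`` to a single recovery, T1* bounded above.

    Same profiled estimator as :func:`fit_t1star` (the amplitude is linear
    and solved in closed form at each candidate T1*): deterministic coarse
    log-grid search over ``(TR_alpha/10, T1*_max]`` refined by bounded scalar
    minimization.  Returns ``(amplitude, T1_star)``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signals, dtype=float)
    if len(t) < 3 or np.any(np.diff(t) <= 0):
        raise ValueError("need >= 3 strictly increasing time points")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    ts_max = t1star_max(alpha, TR_alpha)
    grid = np.geomspace(TR_alpha / 10.0, ts_max, grid_size)
    sse = np.array([_profiled_sse(ts, t, y, w)[0] for ts in grid])
    i = int(np.argmin(sse))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid_size - 1)]
    res = minimize_scalar(
        lambda ts: _profiled_sse(ts, t, y, w)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-6 * grid[i]},
    )
    ts_hat = float(res.x)
    _, amp = _profiled_sse(ts_hat, t, y, w)
    return float(amp), ts_hat


def _profiled_sse(ts, t, y, w):
    f = 1.0 - np.exp(-t / ts)
    wf = w * f
    denom = wf @ f
    amp = (w * y) @ f / denom if denom > 0 else 0.0
    r = y - amp * f
    return (w * r) @ r, amp


def fit_t1star(
    series: ImageSeries,
    seq: SequenceParams,
    mask: np.ndarray | None = None,
    weight_by_na: bool = False,
    compute_ci: bool = False,
    grid_size: int = 120,
) -> T1StarMap:
    """Bounded two-parameter fit of ``A (1 - exp(-t/T1*))`` per pixel.

    The amplitude enters linearly, so the fit profiles it out and minimizes
    over T1* alone: a deterministic coarse logarithmic grid over
    ``(TR_alpha/10, T1*_max]`` (vectorized across pixels) followed by bounded
    scalar refinement per pixel.  Optional weights ``NA(k)`` account for the
    lower noise of heavily averaged time points.  Pixels whose optimum pins at
    the T1*_max bound, or with non-positive amplitude, are flagged invalid.
    All-zero pixels are invalid, never an error.  With ``compute_ci`` the 95%
    confidence half-widths are derived from the Gauss-Newton covariance.
    """
    t = series.times
    if len(t) < 3:
        raise ValueError("at least 3 time points are required")
    y_all = series.images
    n_slices, n_t = y_all.shape[:2]
    grid_shape = series.grid_shape
    if mask is None:
        mask = y_all.max(axis=1).max(axis=0) > 0
    mask = np.asarray(mask, dtype=bool)

    w = series.na.astype(float) if weight_by_na else np.ones(n_t)
    ts_max = t1star_max(seq.alpha_nominal, seq.TR_alpha)
    ts_grid = np.geomspace(seq.TR_alpha / 10.0, ts_max, grid_size)
    F = 1.0 - np.exp(-t[None, :] / ts_grid[:, None])          # (g, n_t)
    denom = (w[None, :] * F * F).sum(axis=1)                  # (g,)

    shape = (n_slices,) + grid_shape
    t1star = np.zeros(shape)
    amplitude = np.zeros(shape)
    residual_norm = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    at_bound = np.zeros(shape, dtype=bool)
    ci_ts = np.zeros(shape) if compute_ci else None
    ci_amp = np.zeros(shape) if compute_ci else None

    for s in range(n_slices):
        Y = y_all[s][:, mask]                                  # (n_t, npix)
        if Y.size == 0:
            continue
        nonzero = Y.max(axis=0) > 0
        A_grid = (F * w[None, :]) @ Y / denom[:, None]         # (g, npix)
        sse = ((w[:, None] * Y * Y).sum(axis=0)[None, :]
               - A_grid**2 * denom[:, None])                   # (g, npix)
        best = np.argmin(sse, axis=0)

        ts_px = np.zeros(Y.shape[1])
        amp_px = np.zeros(Y.shape[1])
        res_px = np.zeros(Y.shape[1])
        bound_px = np.zeros(Y.shape[1], dtype=bool)
        ok_px = np.zeros(Y.shape[1], dtype=bool)
        ci_ts_px = np.zeros(Y.shape[1])
        ci_amp_px = np.zeros(Y.shape[1])

        for p in np.flatnonzero(nonzero):
            lo = ts_grid[max(best[p] - 1, 0)]
            hi = ts_grid[min(best[p] + 1, grid_size - 1)]
            y = Y[:, p]
            if hi > lo:
                res = minimize_scalar(
                    lambda ts: _profiled_sse(ts, t, y, w)[0],
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-7 * ts_grid[best[p]]},
                )
                ts_hat = float(res.x)
            else:
                ts_hat = float(ts_grid[best[p]])
            sse_hat, amp_hat = _profiled_sse(ts_hat, t, y, w)
            ts_px[p] = ts_hat
            amp_px[p] = amp_hat
            res_px[p] = np.sqrt(max(sse_hat, 0.0))
            # pins at either end are degenerate: the upper pin means no
            # recovery within the window (T1 unresolvable), the lower pin a
            # recovery already saturated at the first sample
            bound_px[p] = (ts_hat >= ts_max * (1 - 1e-3)) or (ts_hat <= ts_grid[0] * (1 + 1e-3))
            ok_px[p] = (amp_hat > 0) and not bound_px[p]
            if compute_ci and ok_px[p] and len(t) > 2:
                f = 1.0 - np.exp(-t / ts_hat)
                df = -amp_hat * t / ts_hat**2 * np.exp(-t / ts_hat)
                J = np.stack([f, df], axis=1)
                JtWJ = J.T @ (w[:, None] * J)
                try:
                    cov = np.linalg.inv(JtWJ) * sse_hat / (len(t) - 2)
                    ci_amp_px[p] = 1.96 * np.sqrt(max(cov[0, 0], 0.0))
                    ci_ts_px[p] = 1.96 * np.sqrt(max(cov[1, 1], 0.0))
                except np.linalg.LinAlgError:
                    pass

        t1star[s][mask] = ts_px
        amplitude[s][mask] = amp_px
        residual_norm[s][mask] = res_px
        valid[s][mask] = ok_px
        at_bound[s][mask] = bound_px
        if compute_ci:
            ci_ts[s][mask] = ci_ts_px
            ci_amp[s][mask] = ci_amp_px

    return T1StarMap(
        t1star=t1star, amplitude=amplitude, valid=valid,
        residual_norm=residual_norm, at_bound=at_bound,
        t1star_ci95=ci_ts, amplitude_ci95=ci_amp,
    )


def t1_map(t1star: T1StarMap, b1: FlipAngleMap, TR_alpha: float) -> T1Map:
    """Convert T1* to T1 with per-pixel knowledge of the actual flip angle.

    Pixels where T1* reaches or exceeds the local bound
    ``t1star_max(alpha_px, TR_alpha)`` are flagged invalid (the conversion
    has a pole there), as are pixels invalid in the input map.
    """
    alpha = b1.angles
    if alpha.shape != t1star.t1star.shape[-2:]:
        raise ValueError("flip-angle map grid does not match the T1* map")
    bound = t1star_max(alpha, TR_alpha)[None]
    ts = t1star.t1star
    ok = t1star.valid & (ts > 0) & (ts < bound * (1 - 1e-12))
    t1 = np.zeros_like(ts)
    lncos = np.log(np.cos(np.radians(alpha)))[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1[ok] = 1.0 / (1.0 / ts[ok] + (lncos / TR_alpha * np.ones_like(ts))[ok])
    return T1Map(t1=t1, valid=ok)
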