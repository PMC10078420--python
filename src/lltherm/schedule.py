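"""Variable signal-averaging schedules and their SNR consequences.

At low field, many signal averages (NA) are needed.  Because saturation nulls
the magnetization at the start of every repetition, a reacquisition may use a
*shorter* TR — a truncated readout train covering only the first part of the
recovery curve — and the time saved is reinvested in extra repeats of the
early time points, where the signal is weakest.  A schedule is an ordered set
of blocks ``(n_points, n_repeats)``: each block repeats a truncated
acquisition sampling the first ``n_points`` time points.  The per-time-point
average count is then ``NA(k) = sum of n_repeats over blocks with
n_points > k``, automatically non-increasing in ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_model import SequenceParams, TissueParams, apparent_t1, sample_times, train_amplitude

__all__ = [
    "AveragingSchedule",
    "na_profile",
    "schedule_from_profile",
    "build_schedule",
    "constant_schedule",
    "scan_duration",
    "snr_profile",
]


@dataclass(frozen=True)
class AveragingSchedule:
    """Ordered truncated-TR blocks defining a per-time-point NA profile.

    ``blocks`` are ``(n_points, n_repeats)`` pairs, kept longest-TR-first for
    determinism.  ``n_points_max`` is the length of the full (untruncated)
    readout train.
    """

    blocks: tuple[tuple[int, int], ...]
    TR_alpha: float = 25.0
    n_points_max: int = 79

    def __post_init__(self):
        if len(self.blocks) == 0:
            raise ValueError("schedule must contain at least one block")
        blocks = tuple((int(n), int(r)) for n, r in self.blocks)
        for n, r in blocks:
            if not 1 <= n <= self.n_points_max:
                raise ValueError(f"block n_points={n} outside [1, {self.n_points_max}]")
            if r < 1:
                raise ValueError("block n_repeats must be >= 1")
        object.__setattr__(self, "blocks", tuple(sorted(blocks, key=lambda b: -b[0])))

    @property
    def budget(self) -> int:
        """Total number of line-acquisition averages, summed over time points."""
        return int(sum(n * r for n, r in self.blocks))

    @property
    def n_repeats_total(self) -> int:
        return int(sum(r for _, r in self.blocks))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block_index": np.arange(len(self.blocks)),
                "n_points": [n for n, _ in self.blocks],
                "n_repeats": [r for _, r in self.blocks],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, TR_alpha: float = 25.0, n_points_max: int | None = None):
        df = pd.read_csv(path)
        blocks = tuple(zip(df["n_points"].astype(int), df["n_repeats"].astype(int)))
        if n_points_max is None:
            n_points_max = int(df["n_points"].max())
        return cls(blocks=blocks, TR_alpha=TR_alpha, n_points_max=n_points_max)

    def to_dict(self) -> dict:
        return {
            "TR_alpha": self.TR_alpha,
            "n_points_max": self.n_points_max,
            "blocks": [list(b) for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict):
        return cls(
            blocks=tuple(tuple(b) for b in d["blocks"]),
            TR_alpha=float(d["TR_alpha"]),
            n_points_max=int(d["n_points_max"]),
        )


def na_profile(schedule: AveragingSchedule) -> np.ndarray:
    """Per-time-point average counts ``NA(k)``, k = 0..n_points_max-1."""
    na = np.zeros(schedule.n_points_max, dtype=int)
    for n_points, n_repeats in schedule.blocks:
        na[:n_points] += n_repeats
    return na


def schedule_from_profile(na: np.ndarray, TR_alpha: float = 25.0) -> AveragingSchedule:
    """Decompose a non-increasing NA profile into truncated-TR blocks."""
    na = np.asarray(na, dtype=int)
    if na.ndim != 1 or len(na) == 0:
        raise ValueError("profile must be a non-empty 1-D array")
    if np.any(np.diff(na) > 0):
        raise ValueError("NA profile must be non-increasing")
    if na[0] < 1:
        raise ValueError("NA profile must be positive at the first time point")
    blocks = []
    ext = np.append(na, 0)
    for k in range(len(na)):
        drop = ext[k] - ext[k + 1]
        if drop > 0:
            blocks.append((k + 1, int(drop)))
    return AveragingSchedule(blocks=tuple(blocks), TR_alpha=TR_alpha, n_points_max=len(na))


def build_schedule(
    n_points_max: int,
    budget: int,
    head_points: int = 0,
    head_na: int | None = None,
    tail_points: int = 0,
    tail_na: int | None = None,
    TR_alpha: float = 25.0,
) -> AveragingSchedule:
    """Construct a variable-averaging schedule from printed constraints.

    The first ``head_points`` time points receive exactly ``head_na`` averages
    and the last ``tail_points`` exactly ``tail_na``; the interior is filled
    with a deterministic non-increasing staircase spreading the remaining
    budget as evenly as integer counts allow.  The returned profile sums to
    ``budget`` exactly.

    Raises ``ValueError`` naming the violated constraint when infeasible.
    """
    if head_points + tail_points > n_points_max:
        raise ValueError("head_points + tail_points exceed n_points_max")
    if (head_points > 0) != (head_na is not None):
        raise ValueError("head_points and head_na must be given together")
    if (tail_points > 0) != (tail_na is not None):
        raise ValueError("tail_points and tail_na must be given together")
    if head_na is not None and tail_na is not None and head_na < tail_na:
        raise ValueError("infeasible: head_na < tail_na breaks the non-increasing NA profile")

    na = np.zeros(n_points_max, dtype=int)
    used = 0
    if head_points:
        na[:head_points] = head_na
        used += head_points * head_na
    if tail_points:
        na[n_points_max - tail_points:] = tail_na
        used += tail_points * tail_na
    remaining = budget - used
    n_interior = n_points_max - head_points - tail_points
    lo = tail_na if tail_na is not None else 1
    hi = head_na if head_na is not None else None

    if n_interior == 0:
        if remaining != 0:
            raise ValueError("infeasible: budget does not match head/tail allocation")
    else:
        if remaining < lo * n_interior:
            raise ValueError("infeasible: budget too small for the interior floor (tail_na)")
        if hi is not None and remaining > hi * n_interior:
            raise ValueError("infeasible: budget exceeds the interior ceiling (head_na)")
        base, extra = divmod(remaining, n_interior)
        interior = np.full(n_interior, base, dtype=int)
        interior[:extra] += 1  # earlier points take the leftovers: stays non-increasing
        na[head_points:head_points + n_interior] = interior

    sched = schedule_from_profile(na, TR_alpha=TR_alpha)
    assert sched.budget == budget
    return sched


def constant_schedule(n_points: int, na: int, TR_alpha: float = 25.0) -> AveragingSchedule:
    """Conventional scheme: one full-length block repeated ``na`` times."""
    return AveragingSchedule(blocks=((n_points, na),), TR_alpha=TR_alpha, n_points_max=n_points)


def scan_duration(schedule: AveragingSchedule, n_lines: int, seq: SequenceParams) -> float:
    """Total acquisition time in seconds.

    Each phase-encode line is acquired once per repeat of each block; a repeat
    lasts the saturation train plus the truncated readout train:
    ``n_lines * sum_blocks n_repeats * (n_slices t_sat + n_points TR_alpha)``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    per_line_ms = sum(
        r * (seq.sat_train_duration + n * schedule.TR_alpha) for n, r in schedule.blocks
    )
    return n_lines * per_line_ms / 1000.0


def snr_profile(
    schedule: AveragingSchedule,
    tissue: TissueParams,
    seq: SequenceParams,
    noise_sd: float,
) -> np.ndarray:
    """Predicted SNR at each sampled time point after averaging.

    ``SNR(k) = sin(alpha) * Mz(t_k) * sqrt(NA(k)) / noise_sd`` with the exact
    steady-state train recovery; time points with ``NA(k) = 0`` report 0.
    """
    if not noise_sd > 0:
        raise ValueError("noise_sd must be positive")
    na = na_profile(schedule)
    t = sample_times(schedule.n_points_max, schedule.TR_alpha)
    ts = apparent_t1(tissue.T1, seq.alpha_nominal, schedule.TR_alpha)
    amp = train_amplitude(tissue.T1, tissue.M0, seq.alpha_nominal, schedule.TR_alpha)
    signal = np.sin(np.radians(seq.alpha_nominal)) * amp * (1.0 - np.exp(-t / ts))
    return signal * np.sqrt(na) / noise_sd
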