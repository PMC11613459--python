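"""Synthetic kymographs, profile series, and snapshot series with known truth.

Every generator returns ``(data, truth)`` where ``truth`` is a plain dict
of the generating parameters and the closed-form values of the metrics the
analysis stages are supposed to recover (period, lambda_N, I_Ratio, bleach
rate, growth slope).  This makes every stage of the analysis testable by
parameter recovery without any measured input: the generators emulate the
essential structure of projected fluorescence movies — alternating-pole
exponential gradients ``a exp(-lambda x) + c`` with a fixed period,
multiplicative photobleaching decay, and additive Gaussian noise — but not
optics (no point-spread function, no shot noise, no segmentation errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile_analysis import ProfileSeries, SnapshotSeries
from .simulator import Kymograph

__all__ = ["SyntheticSpec", "make_kymograph", "make_profile_series", "make_snapshot_series"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape, timing, degradation, and noise of one synthetic recording.

    The gradient is ``a exp(-lambda_ x) + c`` on normalized position, with
    its mirror on the opposite pole; intensity alternates between the two
    with ``period`` seconds per full cycle.  ``bleach_rate`` applies a
    multiplicative ``exp(-bleach_rate t)``; ``noise_sd`` is additive
    Gaussian in intensity units.  ``seed`` is mandatory: all randomness is
    derived from it.
    """

    a: float = 0.96
    lambda_: float = 2.89
    c: float = 0.17
    period: float = 10.0
    n_frames: int = 128
    frame_interval: float = 0.15625
    length_um: float = 3.0
    n_positions: int = 101
    bleach_rate: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.c < 0 or self.lambda_ < 0:
            raise ValueError("gradient parameters must be non-negative")
        if self.period <= 0 or self.frame_interval <= 0 or self.length_um <= 0:
            raise ValueError("period, frame_interval and length_um must be positive")
        if self.noise_sd < 0 or self.bleach_rate < 0:
            raise ValueError("noise_sd and bleach_rate must be non-negative")

    @property
    def i_ratio_true(self) -> float:
        """Closed-form midcell-to-pole ratio (a e^(-lambda/2) + c) / (a + c)."""
        return (self.a * np.exp(-self.lambda_ / 2.0) + self.c) / (self.a + self.c)

    def gradients(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        left = self.a * np.exp(-self.lambda_ * x) + self.c
        return left, left[::-1].copy()


def make_kymograph(spec: SyntheticSpec) -> tuple[Kymograph, dict]:
    """Kymograph alternating between the gradient and its mirror.

    ``I(x, t) = w(t) g(x) + (1 - w(t)) g(1 - x)`` with the sinusoidal
    weight ``w = 0.5 + 0.5 cos(2 pi t / period)``, so each pole peaks once
    per period and the spatial maximum alternates between cell halves.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(0.0, 1.0, spec.n_positions)
    times = np.arange(spec.n_frames) * spec.frame_interval
    left, right = spec.gradients(x)
    w = 0.5 + 0.5 * np.cos(2.0 * np.pi * times / spec.period)
    I = w[:, None] * left[None, :] + (1.0 - w[:, None]) * right[None, :]
    if spec.noise_sd > 0:
        I = I + rng.normal(0.0, spec.noise_sd, size=I.shape)
    peak = I.max()
    if peak > 0:
        I = I / peak
    kymo = Kymograph(
        times=times,
        positions=x * spec.length_um,
        intensity=I,
        length=spec.length_um,
        burn_in=0.0,
    )
    truth = {
        "period": spec.period,
        "lambda_N": spec.lambda_,
        "i_ratio": spec.i_ratio_true,
        "a": spec.a,
        "c": spec.c,
    }
    return kymo, truth


def make_profile_series(spec: SyntheticSpec, cell_id: str = "synthetic") -> tuple[ProfileSeries, dict]:
    """Experimental-style profile series with bleaching and noise.

    Each frame is the left or the right gradient — whichever pole the
    oscillation currently occupies (sign of ``cos(2 pi t / period)``) —
    scaled by ``exp(-bleach_rate t)`` plus additive Gaussian noise, which
    mimics a projected time-lapse movie sampled well below the oscillation
    frequency.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(0.0, 1.0, spec.n_positions)
    times = np.arange(spec.n_frames) * spec.frame_interval
    left, right = spec.gradients(x)
    on_left = np.cos(2.0 * np.pi * times / spec.period) >= 0.0
    I = np.where(on_left[:, None], left[None, :], right[None, :]).astype(float)
    I = I * np.exp(-spec.bleach_rate * times)[:, None]
    if spec.noise_sd > 0:
        I = I + rng.normal(0.0, spec.noise_sd, size=I.shape)
    series = ProfileSeries(
        times=times, positions=x, intensities=I,
        length_um=spec.length_um, cell_id=cell_id,
    )
    truth = {
        "bleach_rate": spec.bleach_rate,
        "lambda_N": spec.lambda_,
        "i_ratio": spec.i_ratio_true,
        "fraction_left": float(on_left.mean()),
    }
    return series, truth


def make_snapshot_series(
    spec: SyntheticSpec,
    n_cells: int = 20,
    n_rounds: int = 30,
    snapshot_interval: float = 900.0,
    growth_slope: float = 1.0,
    baseline: float = 1000.0,
    biexp: tuple[float, float, float, float] = (0.7, 0.05, 0.3, 0.005),
    reference_noise_sd: float = 0.0,
) -> tuple[SnapshotSeries, dict]:
    """Linearly growing per-cell totals under biexponential bleaching.

    Cell ``j`` has true total ``baseline_j + growth_slope * t`` (a.u.),
    multiplied by ``f(k) = a1 exp(-b1 k) + a2 exp(-b2 k)`` at exposure
    round ``k``; the normalized reference decay ``f(k)/f(0)`` is included
    (optionally with noise).  Baselines are jittered +/-10% across cells.
    """
    rng = np.random.default_rng(spec.seed)
    a1, b1, a2, b2 = biexp
    k = np.arange(n_rounds, dtype=float)
    f = a1 * np.exp(-b1 * k) + a2 * np.exp(-b2 * k)

    times = np.tile(k * snapshot_interval, (n_cells, 1))
    baselines = baseline * rng.uniform(0.9, 1.1, size=n_cells)
    true_totals = baselines[:, None] + growth_slope * times
    totals = true_totals * (f / f[0])[None, :]
    if spec.noise_sd > 0:
        totals = totals + rng.normal(0.0, spec.noise_sd * baseline, size=totals.shape)

    reference = f / f[0]
    if reference_noise_sd > 0:
        reference = reference + rng.normal(0.0, reference_noise_sd, size=reference.size)
        reference[0] = 1.0

    brackets = np.tile([0, n_rounds - 1], (n_cells, 1))
    series = SnapshotSeries(
        totals=totals, times=times, division_brackets=brackets, reference=reference
    )
    truth = {
        "growth_slope": growth_slope,
        "biexp": (a1 / (a1 + a2), b1, a2 / (a1 + a2), b2),
        "baseline_mean": float(baselines.mean()),
    }
    return series, truth
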