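"""Oscillation descriptors extracted from kymographs.

Three numbers summarize a simulated (or synthetic) Min oscillation:

* **period** — average time between consecutive temporal intensity maxima
  at a fixed grid position, averaged over positions with steady peaks;
* **lambda_N** — dimensionless decay constant of the exponential fit
  ``I(x) = a exp(-lambda_N x) + c`` to the pole-to-midcell gradient on the
  normalized cell length;
* **I_Ratio** — ratio of midcell to pole intensity of the merged
  (left/right averaged) gradient profile, a proxy for how much MinD (hence
  MinC) remains at the prospective division site.

A pattern classifier separates regular pole-to-pole oscillation from
late-onset and irregular regimes, and a biphasic fitter describes how
lambda_N first rises with cell length and then plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .simulator import Kymograph

__all__ = [
    "GradientFit",
    "OscillationMetrics",
    "BiphasicFit",
    "detect_period",
    "fit_gradient",
    "merged_pole_profiles",
    "pole_profile_symmetry",
    "compute_iratio",
    "classify_pattern",
    "fit_biphasic",
    "analyze",
]

#: relative spatial peak-to-trough range below which a profile is "flat"
#: and lambda_N is reported as 0 by convention
FLATNESS_THRESHOLD = 0.01

#: maximal relative change between consecutive temporal peaks for a grid
#: point to count as steadily oscillating
PEAK_STABILITY = 0.05


@dataclass(frozen=True)
class GradientFit:
    """Exponential gradient fit ``I(x) = a exp(-lambda_N x) + c``.

    ``x_range`` records the normalized-position interval (profile maximum to
    minimum) over which the curve was fitted.  ``lambda_N = 0`` with
    ``a = 0`` encodes the flat-profile convention.
    """

    a: float
    lambda_N: float
    c: float
    x_range: tuple[float, float] = (0.0, 1.0)
    residual: float = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.lambda_N * np.asarray(x)) + self.c


@dataclass(frozen=True)
class OscillationMetrics:
    """Per-(parameter set, length) summary of one kymograph."""

    period: float
    lambda_N: float
    i_ratio: float
    pattern_class: str


@dataclass(frozen=True)
class BiphasicFit:
    """Two-segment description of lambda_N versus cell length.

    ``mode`` is "biphasic" (rising linear segment followed by a plateau) or
    "stable" (constant throughout).  ``breakpoint`` is the length where the
    linear segment meets the plateau.
    """

    mode: str
    slope: float
    intercept: float
    plateau: float
    breakpoint: float
    sse: float


def _window_intensity(kymo: Kymograph, window: tuple[float, float] | None) -> tuple[np.ndarray, np.ndarray]:
    if window is None:
        window = (kymo.burn_in, float(kymo.times[-1]))
    t_min, t_max = window
    if t_min < kymo.times[0] - 1e-9 or t_max > kymo.times[-1] + 1e-9:
        raise ValueError(
            f"analysis window [{t_min}, {t_max}] outside stored trajectory "
            f"[{kymo.times[0]}, {kymo.times[-1]}]"
        )
    mask = (kymo.times >= t_min - 1e-9) & (kymo.times <= t_max + 1e-9)
    return kymo.times[mask], kymo.intensity[mask]


def detect_period(
    kymo: Kymograph,
    window: tuple[float, float] | None = None,
    aggregate: str = "median",
) -> float:
    """Average time between consecutive temporal maxima, per grid position.

    For each position the local temporal maxima within ``window`` (default:
    burn-in to end) are located; a position contributes only if every pair
    of consecutive peak amplitudes agrees to within 5% (otherwise the
    oscillation there is dampening or erratic).  The period is the
    ``aggregate`` over contributing positions of the mean inter-peak
    interval; 0.0 if no position qualifies.  The default is the median:
    positions near midcell see the traveling concentration wave twice per
    cycle and would otherwise drag a mean toward half the true period,
    while at least half of the positions lie inside the polar zones and
    report full cycles.
    """
    times, I = _window_intensity(kymo, window)
    grid_periods = []
    for ix in range(I.shape[1]):
        trace = I[:, ix]
        peaks, _ = signal.find_peaks(trace)
        if peaks.size < 2:
            continue
        amplitudes = trace[peaks]
        if np.any(amplitudes <= 0):
            continue
        rel_change = np.abs(np.diff(amplitudes)) / amplitudes[:-1]
        if np.any(rel_change >= PEAK_STABILITY):
            continue
        grid_periods.append(np.diff(times[peaks]).mean())
    if not grid_periods:
        return 0.0
    if aggregate == "median":
        return float(np.median(grid_periods))
    return float(np.mean(grid_periods))


def fit_gradient(
    x: np.ndarray,
    intensity: np.ndarray,
    flatness_threshold: float = FLATNESS_THRESHOLD,
) -> GradientFit:
    """Least-squares fit of ``a exp(-lambda_N x) + c`` to one profile.

    The fit is restricted to the interval from the profile maximum to the
    profile minimum, matching how the pole-to-midcell gradient is read off
    a peak-time profile.  The profile must be oriented with its maximum at
    smaller ``x`` (positions on the normalized [0, 1] scale).  A profile
    whose spatial peak-to-trough range is below ``flatness_threshold``
    times its mean is flat by convention: ``lambda_N = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and intensity must be 1D arrays of equal length")

    mean = y.mean()
    if mean <= 0 or (y.max() - y.min()) < flatness_threshold * mean:
        return GradientFit(a=0.0, lambda_N=0.0, c=float(mean), x_range=(float(x[0]), float(x[-1])))

    i_max = int(np.argmax(y))
    i_min = int(np.argmin(y))
    if i_max >= i_min:
        raise ValueError("profile must be oriented with the maximum before the minimum")
    sel = slice(i_max, i_min + 1)
    xs, ys = x[sel], y[sel]
    if xs.size < 4:
        raise ValueError(f"need at least 4 points between maximum and minimum, got {xs.size}")

    c0 = float(ys.min())
    a0 = float(ys.max() - c0)
    span = max(xs[-1] - xs[0], 1e-6)
    lam0 = np.log(max((ys[0] - c0 + 1e-12) / (ys[-1] - c0 + 1e-12), 1.01)) / span

    def model(xv, a, lam, c):
        return a * np.exp(-lam * xv) + c

    popt, _ = optimize.curve_fit(
        model, xs, ys, p0=(a0, lam0, c0), maxfev=20000,
        bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
    )
    resid = float(np.sum((model(xs, *popt) - ys) ** 2))
    return GradientFit(
        a=float(popt[0]), lambda_N=float(popt[1]), c=float(popt[2]),
        x_range=(float(xs[0]), float(xs[-1])), residual=resid,
    )


def _pole_peak_times(times: np.ndarray, I: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of temporal maxima of the left-most and right-most grid."""
    left_peaks, _ = signal.find_peaks(I[:, 0])
    right_peaks, _ = signal.find_peaks(I[:, -1])
    return left_peaks, right_peaks


def merged_pole_profiles(
    kymo: Kymograph, window: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Left/right pole peak-time profiles and their symmetrized merge.

    Returns ``(x_norm, left, mirrored_right, merged)`` where ``left`` is the
    average profile over left-pole peak frames, ``mirrored_right`` the
    space-reversed average over right-pole peak frames, and ``merged`` their
    mean.  Each profile is normalized to its own maximum before merging.
    """
    times, I = _window_intensity(kymo, window)
    left_peaks, right_peaks = _pole_peak_times(times, I)
    if left_peaks.size == 0 or right_peaks.size == 0:
        raise ValueError("no pole peak frames found; oscillation is not pole-to-pole")
    left = I[left_peaks].mean(axis=0)
    right = I[right_peaks].mean(axis=0)[::-1]
    left = left / left.max()
    right = right / right.max()
    merged = 0.5 * (left + right)
    return kymo.normalized_positions, left, right, merged


def _refined_profile(I: np.ndarray, k: int, pole_ix: int) -> np.ndarray:
    """Profile at the sub-frame peak time of the pole trace around frame ``k``.

    The pole-grid trace is locally a parabola; its vertex gives the peak
    time offset, and every grid point is quadratically interpolated there.
    """
    y0, y1, y2 = I[k - 1, pole_ix], I[k, pole_ix], I[k + 1, pole_ix]
    denom = y0 - 2.0 * y1 + y2
    off = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    a = 0.5 * (I[k - 1] + I[k + 1]) - I[k]
    b = 0.5 * (I[k + 1] - I[k - 1])
    return I[k] + b * off + a * off**2


def pole_profile_symmetry(
    kymo: Kymograph, window: tuple[float, float] | None = None
) -> float:
    """Largest left/right asymmetry of pole-peak profiles, in percent.

    For every left-pole intensity maximum in the window, the profile at its
    (sub-frame, quadratically refined) peak time is compared against the
    mirrored profile at the subsequent right-pole maximum, each normalized
    to its own peak.  Returns the maximum pointwise absolute difference
    over all such pairs, as a percentage of the profile maximum.  A stably
    oscillating cell is left/right symmetric, so this is small.
    """
    times, I = _window_intensity(kymo, window)
    left_peaks, right_peaks = _pole_peak_times(times, I)
    worst = np.nan
    for kl in left_peaks:
        later = right_peaks[right_peaks > kl]
        if later.size == 0:
            break
        kr = int(later[0])
        if kl < 1 or kr + 1 >= times.size:
            continue
        left = _refined_profile(I, int(kl), 0)
        right = _refined_profile(I, kr, -1)[::-1]
        diff = float(np.abs(left / left.max() - right / right.max()).max()) * 100.0
        worst = diff if np.isnan(worst) else max(worst, diff)
    if np.isnan(worst):
        raise ValueError("no complete left/right pole peak pair in the window")
    return worst


def compute_iratio(
    kymo: Kymograph,
    window: tuple[float, float] | None = None,
    require_alternation: bool = True,
) -> float:
    """Midcell-to-pole intensity ratio of the merged gradient profile.

    The merged profile (average of the left-pole profile and the mirrored
    right-pole profile at their peak times) is read at normalized positions
    0 and 0.5; the ratio ``I(0.5) / I(0)`` is returned.  Defined only for
    pole-to-pole oscillation: if the spatial maximum does not alternate
    between cell halves, NaN is returned.
    """
    if require_alternation and classify_pattern(kymo, window) != "pole_to_pole":
        return float("nan")
    x, _, _, merged = merged_pole_profiles(kymo, window)
    i_max = float(np.interp(0.0, x, merged))
    i_min = float(np.interp(0.5, x, merged))
    if i_max <= 0:
        return float("nan")
    return i_min / i_max


def classify_pattern(
    kymo: Kymograph,
    window: tuple[float, float] | None = None,
    alternation_tolerance: float = 0.9,
) -> str:
    """Classify the spatiotemporal oscillation regime of a kymograph.

    ``pole_to_pole``: the per-frame intensity maximum dwells alternately in
    the left and right cell halves, with at least ``alternation_tolerance``
    of the dwell intervals lasting 30-70% of the detected period.
    ``late_onset``: the same criterion holds only over the trailing half of
    the window.  ``none``: no temporal oscillation.  ``irregular``:
    anything else.
    """
    times, I = _window_intensity(kymo, window)
    span = I.max() - I.min()
    if span < 1e-3 * max(I.max(), 1e-300):
        return "none"

    period = detect_period(kymo, window)

    def _pole_to_pole(times_w: np.ndarray, I_w: np.ndarray, period_w: float) -> bool:
        if period_w <= 0 or times_w.size < 3:
            return False
        halves = (np.argmax(I_w, axis=1) >= I_w.shape[1] / 2).astype(int)
        # run-length encode the dwell half labels
        change = np.flatnonzero(np.diff(halves)) + 1
        bounds = np.concatenate(([0], change, [halves.size]))
        durations = np.diff(bounds) * (times_w[1] - times_w[0])
        if durations.size < 4:
            return False
        inner = durations[1:-1]  # first/last dwell are clipped by the window
        if inner.size == 0:
            return False
        # the alternation must fill the window: otherwise a flat or
        # one-sided stretch followed by clean cycles would still pass
        span = times_w[-1] - times_w[0]
        expected_inner = 2.0 * span / period_w - 2.0
        if inner.size < 0.8 * expected_inner:
            return False
        ok = (inner >= 0.3 * period_w) & (inner <= 0.7 * period_w)
        return ok.mean() >= alternation_tolerance

    if _pole_to_pole(times, I, period):
        return "pole_to_pole"

    # trailing half of the window: oscillation that needs time to lock in
    t_mid = times[0] + (times[-1] - times[0]) / 2
    mask = times >= t_mid
    if mask.sum() >= 3:
        sub = Kymograph(times[mask], kymo.positions, I[mask], length=kymo.length)
        tail_period = detect_period(sub, (float(times[mask][0]), float(times[-1])))
        if _pole_to_pole(times[mask], I[mask], tail_period):
            return "late_onset"

    if period <= 0:
        # peaks exist nowhere steadily; call a still-varying field irregular
        per_grid_peaks = max(
            (signal.find_peaks(I[:, ix])[0].size for ix in range(I.shape[1])), default=0
        )
        if per_grid_peaks < 2:
            return "none"
    return "irregular"


def time_collapsed_profile(kymo: Kymograph, window: tuple[float, float] | None = None) -> np.ndarray:
    """Time-averaged intensity profile over the analysis window."""
    _, I = _window_intensity(kymo, window)
    return I.mean(axis=0)


def gradient_lambda(kymo: Kymograph, window: tuple[float, float] | None = None) -> GradientFit:
    """lambda_N of a kymograph via the merged pole-peak profile.

    Falls back to the flat-profile convention (lambda_N = 0) when the
    time-collapsed profile shows no spatial structure, covering short cells
    that oscillate in time but not in space.
    """
    collapsed = time_collapsed_profile(kymo, window)
    mean = collapsed.mean()
    if mean <= 0 or (collapsed.max() - collapsed.min()) < FLATNESS_THRESHOLD * mean:
        return GradientFit(a=0.0, lambda_N=0.0, c=float(mean))
    try:
        x, _, _, merged = merged_pole_profiles(kymo, window)
    except ValueError:
        return GradientFit(a=0.0, lambda_N=0.0, c=float(mean))
    return fit_gradient(x, merged)


def fit_biphasic(lengths: np.ndarray, lambdas: np.ndarray) -> BiphasicFit:
    """Fit lambda_N versus length with a rising line followed by a plateau.

    Every admissible breakpoint (>= 2 points per segment) is scanned; the
    left segment is fitted by least-squares line ``a L + b``, the right by
    its mean, and the breakpoint minimizing the total squared residual is
    kept.  If a single constant fits the data as well as the best split,
    the "stable" model is returned instead.
    """
    L = np.asarray(lengths, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    keep = lam > 0
    L, lam = L[keep], lam[keep]
    if L.size < 4:
        raise ValueError("need at least 4 lengths with lambda_N > 0")
    order = np.argsort(L)
    L, lam = L[order], lam[order]

    const = float(lam.mean())
    sse_const = float(np.sum((lam - const) ** 2))

    best = None
    for k in range(2, L.size - 1):
        a, b = np.polyfit(L[:k], lam[:k], 1)
        sse_left = float(np.sum((a * L[:k] + b - lam[:k]) ** 2))
        c = float(lam[k:].mean())
        sse_right = float(np.sum((lam[k:] - c) ** 2))
        sse = sse_left + sse_right
        if best is None or sse < best[0]:
            breakpoint_ = (c - b) / a if abs(a) > 1e-12 else float(L[k])
            if not (L[0] <= breakpoint_ <= L[-1]):
                breakpoint_ = float(0.5 * (L[k - 1] + L[k]))
            best = (sse, float(a), float(b), c, float(breakpoint_))

    sse, a, b, c, breakpoint_ = best
    scale = max(float(np.sum(lam**2)), 1e-300)
    if sse_const <= sse + 1e-12 * scale:
        return BiphasicFit("stable", 0.0, const, const, float(L[0]), sse_const)
    return BiphasicFit("biphasic", a, b, c, breakpoint_, sse)


def analyze(kymo: Kymograph, window: tuple[float, float] | None = None) -> OscillationMetrics:
    """Full metric extraction for one kymograph."""
    period = detect_period(kymo, window)
    pattern = classify_pattern(kymo, window)
    lam = gradient_lambda(kymo, window).lambda_N if period > 0 else 0.0
    if pattern == "pole_to_pole":
        ir = compute_iratio(kymo, window, require_alternation=False)
    else:
        ir = float("nan")
    return OscillationMetrics(period=period, lambda_N=lam, i_ratio=ir, pattern_class=pattern)
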