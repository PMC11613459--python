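"""Analysis of measured 1D fluorescence intensity profiles.

These are the algorithms applied to microscopy-derived intensity profiles
of oscillating cells (per-frame intensity versus normalized axial
position): exponential photobleaching normalization of time-lapse series,
biexponential bleaching correction of repeated snapshots, the midcell
("center") intensity fraction, and a robust two-sided exponential
estimator of the midcell-to-pole intensity ratio I_Ratio.

Input series are tidy per-cell tables; see :class:`ProfileSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ProfileSeries",
    "SnapshotSeries",
    "TwoSidedFit",
    "BiexpCorrection",
    "photobleach_normalize",
    "center_fraction",
    "estimate_iratio_experimental",
    "biexp_snapshot_correction",
    "molecules_from_intensity",
]


@dataclass
class ProfileSeries:
    """Per-cell intensity profiles over time.

    ``times`` has one stamp per frame (s); ``positions`` is a common grid of
    normalized axial positions in [0, 1] (pole to pole); ``intensities`` is
    (n_frames, n_positions) in arbitrary units; ``length_um`` is the cell
    length.  ``bleach_rate`` records the fitted decay constant after
    :func:`photobleach_normalize`.
    """

    times: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray
    length_um: float
    cell_id: str = "cell"
    bleach_rate: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.times.size, self.positions.size):
            raise ValueError("intensities must have shape (n_frames, n_positions)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def totals(self) -> np.ndarray:
        """Per-frame total intensity, summed over positions."""
        return self.intensities.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (cell_id, frame, time_s, x_norm, intensity, length_um)."""
        n_f, n_x = self.intensities.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_id, n_f * n_x),
                "frame": np.repeat(np.arange(n_f), n_x),
                "time_s": np.repeat(self.times, n_x),
                "x_norm": np.tile(self.positions, n_f),
                "intensity": self.intensities.ravel(),
                "length_um": self.length_um,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cell_id: str | None = None) -> "ProfileSeries":
        if cell_id is not None:
            df = df[df["cell_id"] == cell_id]
        else:
            ids = df["cell_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"table holds {len(ids)} cells; pass cell_id")
            cell_id = ids[0]
        pivot = df.pivot_table(index="time_s", columns="x_norm", values="intensity")
        return cls(
            times=pivot.index.to_numpy(),
            positions=pivot.columns.to_numpy(),
            intensities=pivot.to_numpy(),
            length_um=float(df["length_um"].iloc[0]),
            cell_id=str(cell_id),
        )


@dataclass
class SnapshotSeries:
    """Repeated-exposure totals for a population of growing cells.

    ``totals[j, k]`` is the summed intensity of cell ``j`` at exposure
    round ``k`` (k = 0, 1, ...); ``times[j, k]`` the acquisition time (s);
    ``division_brackets[j] = (c1, c2)`` indexes the frames between two
    divisions of cell ``j``.  ``reference`` is a normalized bleaching decay
    observation (reference[0] = 1) used to fit the correction curve.
    """

    totals: np.ndarray
    times: np.ndarray
    division_brackets: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.division_brackets = np.asarray(self.division_brackets, dtype=int)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.totals.shape != self.times.shape:
            raise ValueError("totals and times must have equal shape")
        if np.any(self.division_brackets[:, 0] > self.division_brackets[:, 1]):
            raise ValueError("division bracket must satisfy c1 <= c2")


@dataclass(frozen=True)
class TwoSidedFit:
    """Result of the two-sided exponential I_Ratio estimator."""

    groups: np.ndarray  # "left"/"right" per retained frame
    x_grid: np.ndarray
    smooth_left: np.ndarray
    smooth_right: np.ndarray
    d_left: float
    d_right: float
    lambda_left: float
    lambda_right: float
    m_left: float
    m_right: float
    lambda_shared: float
    i_max: float
    i_min: float
    i_ratio: float


@dataclass(frozen=True)
class BiexpCorrection:
    """Biexponential bleaching fit and per-cell growth regressions."""

    a1: float
    b1: float
    a2: float
    b2: float
    corrected: np.ndarray
    alpha: np.ndarray  # per-cell slope (a.u./s)
    beta: np.ndarray  # per-cell intercept (a.u.)
    alpha_mean: float
    beta_mean: float

    def decay(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return self.a1 * np.exp(-self.b1 * k) + self.a2 * np.exp(-self.b2 * k)


def _fit_exponential_decay(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Fit ``s = a exp(-b t)`` (log-linear start, nonlinear polish)."""
    if np.any(s <= 0):
        raise ValueError("totals must be positive to fit an exponential decay")
    b0, log_a0 = np.polyfit(t, np.log(s), 1)
    p0 = (float(np.exp(log_a0)), float(-b0))
    popt, _ = optimize.curve_fit(lambda tv, a, b: a * np.exp(-b * tv), t, s, p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1])


def photobleach_normalize(
    series: ProfileSeries, printed_sign: bool = False
) -> ProfileSeries:
    """Remove the exponential photobleaching trend from a time-lapse series.

    Each profile is first shifted so its minimum is 0.  The per-frame
    totals ``S_j`` are then fitted to ``a exp(-b t)`` and every profile is
    divided by ``exp(-b_hat T_j)``, which leaves the corrected totals
    trend-free.  ``printed_sign=True`` instead multiplies by
    ``exp(-b_hat T_j)`` (the literal transcription of the procedure, which
    deepens rather than removes a decay; kept for comparison).
    """
    if series.times.size < 3:
        raise ValueError("need at least 3 frames to fit a bleaching trend")
    shifted = series.intensities - series.intensities.min(axis=1, keepdims=True)
    totals = shifted.sum(axis=1)
    _, b_hat = _fit_exponential_decay(series.times, totals)
    factor = np.exp(-b_hat * series.times)[:, None]
    corrected = shifted * factor if printed_sign else shifted / factor
    return replace(series, intensities=corrected, bleach_rate=float(b_hat))


def center_fraction(
    series: ProfileSeries, n_frames: int = 20, zone_halfwidth_um: float = 0.1
) -> float:
    """Fraction of profile intensity within +/-100 nm of the cell midpoint.

    Intensities are linearly interpolated at the zone edges
    ``x = 0.5 -+ zone_halfwidth / L``; the zone and total intensities are
    trapezoidal integrals, averaged over the first ``n_frames`` frames
    (all frames if fewer are available).
    """
    L = series.length_um
    if L <= 2 * zone_halfwidth_um:
        raise ValueError(
            f"cell length {L} um leaves no room for a +/-{zone_halfwidth_um} um midzone"
        )
    x_a = 0.5 - zone_halfwidth_um / L
    x_b = 0.5 + zone_halfwidth_um / L
    x = series.positions
    use = series.intensities[: min(n_frames, series.times.size)]

    center_vals = []
    total_vals = []
    for profile in use:
        i_a = float(np.interp(x_a, x, profile))
        i_b = float(np.interp(x_b, x, profile))
        inside = (x > x_a) & (x < x_b)
        xs = np.concatenate(([x_a], x[inside], [x_b]))
        ys = np.concatenate(([i_a], profile[inside], [i_b]))
        center_vals.append(np.trapezoid(ys, xs))
        total_vals.append(np.trapezoid(profile, x))
    return float(np.mean(center_vals) / np.mean(total_vals))


def _local_slope(x: np.ndarray, y: np.ndarray, x0: float, window: float) -> float:
    """Slope of a least-squares line through points with |x - x0| <= window."""
    mask = np.abs(x - x0) <= window
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 points within {window} of x={x0}")
    return float(np.polyfit(x[mask], y[mask], 1)[0])


def _local_linear_smooth(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian-kernel local linear regression evaluated on ``grid``.

    Local linear (rather than locally constant) smoothing is used so the
    estimate is unbiased to first order at the domain boundaries, where the
    pole intensity maxima sit.
    """
    out = np.empty(grid.size)
    for i, g in enumerate(grid):
        w = np.exp(-0.5 * ((x - g) / bandwidth) ** 2)
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 1e-300:
            out[i] = ym
        else:
            slope = (w * (x - xm) * (y - ym)).sum() / sxx
            out[i] = ym + slope * (g - xm)
    return out


def _two_means_1d(features: np.ndarray) -> np.ndarray:
    """Deterministic 2-means clustering of frame slope features.

    Initialized from the extreme frames (most negative and most positive
    pole-slope contrast) so the result carries no RNG sensitivity.
    Returns integer labels; label 0 is the cluster with the lower center.
    """
    contrast = features @ np.ones(features.shape[1]) if features.ndim > 1 else features
    centers = np.array([features[np.argmin(contrast)], features[np.argmax(contrast)]], dtype=float)
    labels = np.zeros(features.shape[0], dtype=int)
    for _ in range(100):
        dists = np.linalg.norm(features[:, None, :] - centers[None, :, :], axis=2)
        new_labels = np.argmin(dists, axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in (0, 1):
            if np.any(labels == c):
                centers[c] = features[labels == c].mean(axis=0)
    return labels


def estimate_iratio_experimental(
    series: ProfileSeries,
    slope_window: float = 0.05,
    bandwidth: float | None = None,
    grid_size: int = 201,
) -> TwoSidedFit:
    """Two-sided exponential estimate of I_Ratio from measured profiles.

    Pipeline: (1) the intensity slope of every frame is estimated at
    normalized positions 0.2 and 0.8 by local linear regression; 2-means
    clustering of the slope pairs splits the frames into left-peaked and
    right-peaked groups, and frames whose pooled slope magnitude falls in
    the lowest quartile (transition frames) are dropped.  (2) A Gaussian
    kernel smoother per group yields curves whose overall maximum is
    ``I_max``.  (3) Each group is fitted with ``d exp(-lambda |x - m|)``,
    ``m`` at the smoothed argmax.  (4) The shared decay ``lambda'`` is the
    group-size-weighted mean of the two rates, and amplitudes are refitted
    with ``lambda'`` fixed.  (5) ``I_min`` is the intensity at the
    intersection of the two refitted curves; ``I_Ratio = I_min / I_max``.
    """
    if series.times.size < 8:
        raise ValueError("need at least 8 frames spanning both pole states")
    x = series.positions
    I = series.intensities

    s02 = np.array([_local_slope(x, prof, 0.2, slope_window) for prof in I])
    s08 = np.array([_local_slope(x, prof, 0.8, slope_window) for prof in I])
    features = np.column_stack([s02, s08])
    labels = _two_means_1d(features)
    if labels.min() == labels.max():
        raise ValueError("all frames cluster to one side; need both pole states")

    # left-peaked frames decay toward larger x: negative slope contrast
    contrast_by_label = [features[labels == c].sum(axis=1).mean() for c in (0, 1)]
    left_label = int(np.argmin(contrast_by_label))

    # pooled first-quartile exclusion; ties at the boundary are retained so
    # a series of identical clean frames is not emptied
    magnitude = np.abs(s02) + np.abs(s08)
    keep = magnitude >= np.quantile(magnitude, 0.25)
    if not np.any(keep & (labels == left_label)) or not np.any(keep & (labels != left_label)):
        raise ValueError("slope-quartile exclusion removed one entire pole group")
    labels = labels[keep]
    frames = I[keep]

    if bandwidth is None:
        spacing = float(np.median(np.diff(x)))
        bandwidth = max(2.0 * spacing, 0.02)

    grid = np.linspace(0.0, 1.0, grid_size)
    groups = {}
    for side, label in (("left", left_label), ("right", 1 - left_label)):
        sel = frames[labels == label]
        xs = np.tile(x, sel.shape[0])
        ys = sel.ravel()
        smooth = _local_linear_smooth(xs, ys, grid, bandwidth)
        m_i = float(grid[np.argmax(smooth)])

        def model(xv, d, lam, m=m_i):
            return d * np.exp(-lam * np.abs(xv - m))

        d0 = float(smooth.max())
        popt, _ = optimize.curve_fit(
            model, xs, ys, p0=(d0, 2.0), bounds=([0, 0], [np.inf, np.inf]), maxfev=20000
        )
        groups[side] = {
            "n": sel.shape[0],
            "x": xs,
            "y": ys,
            "smooth": smooth,
            "m": m_i,
            "d": float(popt[0]),
            "lam": float(popt[1]),
        }

    gl, gr = groups["left"], groups["right"]
    lambda_shared = (gl["lam"] * gl["n"] + gr["lam"] * gr["n"]) / (gl["n"] + gr["n"])

    # refit amplitudes only, shared decay fixed
    for g in (gl, gr):
        basis = np.exp(-lambda_shared * np.abs(g["x"] - g["m"]))
        g["d_shared"] = float((basis * g["y"]).sum() / (basis * basis).sum())

    i_max = float(max(gl["smooth"].max(), gr["smooth"].max()))

    # intersection of d_L e^(-l|x-mL|) and d_R e^(-l|x-mR|) between the peaks
    m_l, m_r = gl["m"], gr["m"]
    if m_l >= m_r:
        m_l, m_r = m_r, m_l
        gl, gr = gr, gl
    x_star = 0.5 * (m_l + m_r) + np.log(gl["d_shared"] / gr["d_shared"]) / (2.0 * lambda_shared)
    if not (0.0 < x_star < 1.0):
        i_min = float("nan")
        i_ratio = float("nan")
    else:
        i_min = float(gl["d_shared"] * np.exp(-lambda_shared * (x_star - m_l)))
        i_ratio = i_min / i_max

    side_labels = np.where(labels == left_label, "left", "right")
    return TwoSidedFit(
        groups=side_labels,
        x_grid=grid,
        smooth_left=groups["left"]["smooth"],
        smooth_right=groups["right"]["smooth"],
        d_left=groups["left"]["d_shared"],
        d_right=groups["right"]["d_shared"],
        lambda_left=groups["left"]["lam"],
        lambda_right=groups["right"]["lam"],
        m_left=groups["left"]["m"],
        m_right=groups["right"]["m"],
        lambda_shared=float(lambda_shared),
        i_max=i_max,
        i_min=i_min,
        i_ratio=i_ratio,
    )


def biexp_snapshot_correction(series: SnapshotSeries) -> BiexpCorrection:
    """Biexponential bleaching correction of repeated-snapshot totals.

    The normalized reference decay is fitted with
    ``f(k) = a1 exp(-b1 k) + a2 exp(-b2 k)``; every cell's totals are
    divided by ``f_hat(k)``; corrected totals are regressed linearly on
    time within each cell's division bracket, and the per-cell slopes and
    intercepts are averaged into the population growth trend.
    """
    ref = series.reference
    k_ref = np.arange(ref.size, dtype=float)

    def model(k, a1, b1, a2, b2):
        return a1 * np.exp(-b1 * k) + a2 * np.exp(-b2 * k)

    try:
        popt, _ = optimize.curve_fit(
            model,
            k_ref,
            ref,
            p0=(0.6, 0.05, 0.4, 0.005),
            bounds=([0, 0, 0, 0], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=50000,
        )
    except RuntimeError as exc:
        resid = np.nan
        raise RuntimeError(f"biexponential fit did not converge: {exc}") from exc
    a1, b1, a2, b2 = map(float, popt)
    if b1 < b2:  # order components fast-first for reproducibility
        a1, b1, a2, b2 = a2, b2, a1, b1

    k_grid = np.arange(series.totals.shape[1], dtype=float)
    f_hat = model(k_grid, a1, b1, a2, b2)
    corrected = series.totals / f_hat[None, :]

    alphas, betas = [], []
    for j in range(corrected.shape[0]):
        c1, c2 = series.division_brackets[j]
        t = series.times[j, c1 : c2 + 1] - series.times[j, c1]
        y = corrected[j, c1 : c2 + 1]
        slope, intercept = np.polyfit(t, y, 1)
        alphas.append(float(slope))
        betas.append(float(intercept))

    alphas = np.array(alphas)
    betas = np.array(betas)
    return BiexpCorrection(
        a1=a1, b1=b1, a2=a2, b2=b2,
        corrected=corrected,
        alpha=alphas, beta=betas,
        alpha_mean=float(alphas.mean()), beta_mean=float(betas.mean()),
    )


def molecules_from_intensity(
    fit_slope: float,
    fit_intercept: float,
    anchor_time: float,
    anchor_molecules: float,
    times: np.ndarray,
    center_frac: float | None = None,
    fitted_range: tuple[float, float] | None = None,
) -> dict:
    """Convert a fitted intensity-versus-time line to molecule counts.

    The linear intensity trend ``fit_slope * t + fit_intercept`` is pinned
    to ``anchor_molecules`` at ``anchor_time`` (e.g. the population mean
    copy number at the midpoint of the doubling time); counts at ``times``
    follow by proportional scaling, and midcell-zone counts by multiplying
    with the center fraction.
    """
    import warnings as _warnings

    times = np.asarray(times, dtype=float)
    if fitted_range is not None and not (fitted_range[0] <= anchor_time <= fitted_range[1]):
        _warnings.warn(
            f"anchor time {anchor_time} lies outside the fitted range {fitted_range}",
            UserWarning,
            stacklevel=2,
        )
    anchor_intensity = fit_slope * anchor_time + fit_intercept
    if anchor_intensity <= 0:
        raise ValueError("fitted intensity at the anchor time is not positive")
    factor = anchor_molecules / anchor_intensity
    counts = factor * (fit_slope * times + fit_intercept)
    out = {"conversion_factor": float(factor), "molecules": counts}
    if center_frac is not None:
        out["midzone_molecules"] = counts * center_frac
    return out
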