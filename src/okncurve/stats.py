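"""Gaze-strategy statistics: tangent-point-referenced displacement, AOI
catch, kernel densities and modes, Hotelling T² regions, sign tests, the
slow-phase orientation histogram, and the half-yaw-rate consistency
analysis that separates future-path tracking from tangent-point fixation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from .segmentation import Segment


# ---------------------------------------------------------------------------
# displacement & AOI

def displacement_from_tp(gaze_hv: np.ndarray, tp_hv: np.ndarray) -> np.ndarray:
    """Element-wise gaze displacement from the tangent point (TP at origin)."""
    g = np.asarray(gaze_hv, dtype=float)
    t = np.asarray(tp_hv, dtype=float)
    if g.shape != t.shape:
        raise ValueError(f"shape mismatch: gaze {g.shape} vs tp {t.shape}")
    return g - t


def aoi_catch(displacements: np.ndarray, radius: float) -> float:
    """Percentage of samples within ``radius`` degrees of the tangent point."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = np.asarray(displacements, dtype=float)
    d = d[np.all(np.isfinite(d), axis=1)]
    if len(d) == 0:
        raise ValueError("no valid samples")
    r = np.hypot(d[:, 0], d[:, 1])
    return 100.0 * float(np.mean(r <= radius))


def aoi_catch_table(displacements: np.ndarray, radii=range(2, 11)) -> dict[int, float]:
    return {int(r): aoi_catch(displacements, float(r)) for r in radii}


def entry_vs_cornering_sign_test(differences: np.ndarray) -> float:
    """Exact two-sided binomial sign test (p = 1/2) on paired differences.

    Zero differences are dropped (reducing n); the p-value is the doubled
    smaller tail, capped at 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no non-zero differences")
    k = int(np.sum(d > 0))
    p = 2.0 * min(sps.binom.cdf(k, n, 0.5), sps.binom.sf(k - 1, n, 0.5))
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# kernel density estimation

@dataclass
class DensityEstimate2D:
    """Product-Gaussian KDE evaluated on a regular grid.

    ``values[i, j]`` is the density at ``(xgrid[i], ygrid[j])``. The
    original sample and bandwidths are retained so the continuous density
    can be re-evaluated anywhere (used for within-bin mode refinement).
    """

    xgrid: np.ndarray
    ygrid: np.ndarray
    values: np.ndarray
    bandwidth: tuple[float, float]
    points: np.ndarray

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Continuous KDE at arbitrary coordinates (broadcast 1-D)."""
        hx, hy = self.bandwidth
        px = self.points[:, 0][:, None]
        py = self.points[:, 1][:, None]
        x = np.atleast_1d(np.asarray(x, dtype=float))[None, :]
        y = np.atleast_1d(np.asarray(y, dtype=float))[None, :]
        kx = np.exp(-0.5 * ((x - px) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
        ky = np.exp(-0.5 * ((y - py) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
        return np.mean(kx * ky, axis=0)

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.values, self.ygrid, axis=1),
                                  self.xgrid))


def silverman_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman bandwidth for a 2-D sample.

    For d = 2 the rule h_j = sigma_j * (4 / (d + 2))^(1/(d+4)) * n^(-1/(d+4))
    reduces to h_j = sigma_j * n^(-1/6).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
        raise ValueError("need an (n, 2) sample with n >= 2")
    sd = p.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate sample: zero variance on an axis")
    f = len(p) ** (-1.0 / 6.0)
    return float(sd[0] * f), float(sd[1] * f)


def kde2d(
    points: np.ndarray,
    bandwidth: float | tuple[float, float],
    grid_step: float = 0.25,
    pad_bandwidths: float = 4.0,
) -> DensityEstimate2D:
    """Product-Gaussian KDE on a regular grid.

    The grid extends ``pad_bandwidths`` bandwidths beyond the data hull;
    the step is refined below ``grid_step`` when the bandwidth is small so
    the trapezoidal integral stays within 1 +- 0.01.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if p.shape[1] != 2 or len(p) < 1:
        raise ValueError("need an (n, 2) sample with n >= 1")
    if np.isscalar(bandwidth):
        hx = hy = float(bandwidth)
    else:
        hx, hy = (float(b) for b in bandwidth)
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive")

    def axis(lo, hi, h):
        step = min(grid_step, h / 3.0)
        lo, hi = lo - pad_bandwidths * h, hi + pad_bandwidths * h
        n = max(int(np.ceil((hi - lo) / step)) + 1, 2)
        return np.linspace(lo, hi, n)

    xg = axis(p[:, 0].min(), p[:, 0].max(), hx)
    yg = axis(p[:, 1].min(), p[:, 1].max(), hy)
    # separable evaluation: values = Kx^T Ky / n
    kx = np.exp(-0.5 * ((xg[None, :] - p[:, 0][:, None]) / hx) ** 2) \
        / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((yg[None, :] - p[:, 1][:, None]) / hy) ** 2) \
        / (hy * np.sqrt(2 * np.pi))
    values = kx.T @ ky / len(p)
    return DensityEstimate2D(xg, yg, values, (hx, hy), p)


@dataclass
class ModeEstimate:
    location: tuple[float, float]
    density: float
    flat: bool = False  # multiple grid nodes tied at the maximum


def estimate_mode(density: DensityEstimate2D) -> ModeEstimate:
    """Mode of a 2-D density: best grid node, then bounded continuous
    refinement of the KDE within that node's bin (derivative-free).

    The returned density is never below the best grid node's density; on
    a flat grid maximum the node with the smallest coordinates is used
    and the estimate is flagged.
    """
    vals = density.values
    i, j = np.unravel_index(int(np.argmax(vals)), vals.shape)
    vmax = vals[i, j]
    flat = bool(np.sum(np.isclose(vals, vmax, rtol=0, atol=1e-12)) > 1)
    dx = density.xgrid[1] - density.xgrid[0] if len(density.xgrid) > 1 else 1.0
    dy = density.ygrid[1] - density.ygrid[0] if len(density.ygrid) > 1 else 1.0
    x0, y0 = density.xgrid[i], density.ygrid[j]
    bounds = [(x0 - dx, x0 + dx), (y0 - dy, y0 + dy)]
    res = optimize.minimize(
        lambda z: -density.evaluate(z[0], z[1])[0],
        x0=np.array([x0, y0]),
        method="Powell",
        bounds=bounds,
    )
    refined = float(-res.fun)
    if np.isfinite(refined) and refined >= vmax:
        return ModeEstimate((float(res.x[0]), float(res.x[1])), refined, flat)
    return ModeEstimate((float(x0), float(y0)), float(vmax), flat)


# ---------------------------------------------------------------------------
# Hotelling T² confidence region for a bivariate mean

@dataclass
class ConfidenceEllipse:
    """Hotelling T² confidence region(s) for the mean of a 2-D sample.

    The region at confidence ``level`` is
    { mu : N (xbar - mu)' S^-1 (xbar - mu) <= 2(N-1)/(N-2) * F_{2,N-2}(level) }.
    """

    center: np.ndarray
    covariance: np.ndarray
    n: int
    levels: tuple[float, ...] = (0.95, 0.99, 0.999)

    def critical_value(self, level: float) -> float:
        nn = self.n
        return float(2.0 * (nn - 1) / (nn - 2) * sps.f.ppf(level, 2, nn - 2))

    def mahalanobis2(self, mu: np.ndarray) -> float:
        d = self.center - np.asarray(mu, dtype=float)
        return float(self.n * d @ np.linalg.solve(self.covariance, d))

    def contains(self, mu: np.ndarray, level: float = 0.95) -> bool:
        return self.mahalanobis2(mu) <= self.critical_value(level)

    def ellipse_points(self, level: float, n_points: int = 100) -> np.ndarray:
        """Boundary polyline of the region (for plotting)."""
        c = self.critical_value(level) / self.n
        L = np.linalg.cholesky(self.covariance * c)
        a = np.linspace(0, 2 * np.pi, n_points)
        return self.center + (L @ np.vstack([np.cos(a), np.sin(a)])).T


def hotelling_region(
    sample: np.ndarray, levels: tuple[float, ...] = (0.95, 0.99, 0.999)
) -> ConfidenceEllipse:
    p = np.asarray(sample, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 4:
        raise ValueError("need an (N, 2) sample with N >= 4")
    cov = np.cov(p.T, ddof=1)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("singular sample covariance")
    return ConfidenceEllipse(p.mean(axis=0), cov, len(p), tuple(levels))


# ---------------------------------------------------------------------------
# slow-phase orientation & yaw consistency

def sp_orientation_histogram(
    segments: list[Segment], n_bins: int = 36
) -> tuple[np.ndarray, np.ndarray, int]:
    """Histogram of slow-phase movement orientations over 0-360°.

    0° is up (positive vertical velocity), angles increase clockwise
    toward positive horizontal (into the curve). Returns (counts,
    bin_edges, n_zero_velocity_excluded); only SP-labelled segments are
    counted, zero-velocity segments are excluded and tallied separately.
    """
    sp = [s for s in segments if s.label == "SP"]
    if not sp:
        raise ValueError("no SP segments")
    ang = []
    n_zero = 0
    for s in sp:
        if s.slope_h == 0.0 and s.slope_v == 0.0:
            n_zero += 1
            continue
        ang.append(np.rad2deg(np.arctan2(s.slope_h, s.slope_v)) % 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(ang, bins=edges)
    return counts, edges, n_zero


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


@dataclass
class YawConsistency:
    """Per-subject comparison of half yaw rate against modal SP velocity."""

    differences: np.ndarray       # d_i = yaw_i/2 - |modal horizontal SP velocity|
    mean: float
    ci95: tuple[float, float]
    shapiro_w: float
    shapiro_p: float
    correlations: np.ndarray      # per-subject Pearson r (NaN if undefined)


def yaw_gaze_consistency(
    yaw_means: np.ndarray,
    modal_h_velocities: np.ndarray,
    per_subject_series: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> YawConsistency:
    """Half-yaw-rate consistency: d_i = omega_i/2 - |modal h velocity|_i.

    Future-path tracking predicts d_i ~ 0 (the 95% CI straddles zero);
    tangent-point fixation leaves d_i ~ omega/2. Magnitudes are used so
    left- and right-hand bends pool. Optional per-subject
    (yaw series, |SP horizontal velocity| series) pairs give per-subject
    Pearson correlations (NaN when either series is constant). The
    Shapiro-Wilk normality check on d_i is delegated to scipy.
    """
    w = np.asarray(yaw_means, dtype=float)
    m = np.asarray(modal_h_velocities, dtype=float)
    if len(w) != len(m) or len(w) < 2:
        raise ValueError("need matching per-subject arrays with n >= 2")
    d = np.abs(w) / 2.0 - np.abs(m)
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    if sd > 0 and n >= 4:  # Shapiro-Wilk needs a non-degenerate sample
        sw = sps.shapiro(d)
        shapiro_w, shapiro_p = float(sw.statistic), float(sw.pvalue)
    else:
        shapiro_w, shapiro_p = np.nan, np.nan
    corrs = np.full(n, np.nan)
    if per_subject_series is not None:
        if len(per_subject_series) != n:
            raise ValueError("per_subject_series length mismatch")
        for i, (yw, sv) in enumerate(per_subject_series):
            yw = np.asarray(yw, dtype=float)
            sv = np.asarray(sv, dtype=float)
            ok = np.isfinite(yw) & np.isfinite(sv)
            if ok.sum() >= 3 and np.ptp(yw[ok]) > 0 and np.ptp(sv[ok]) > 0:
                corrs[i] = float(sps.pearsonr(yw[ok], sv[ok]).statistic)
    return YawConsistency(d, mean, (mean - half, mean + half), shapiro_w,
                          shapiro_p, corrs)
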