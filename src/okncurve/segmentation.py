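"""Maximum-likelihood piecewise-linear segmentation of noisy gaze signals.

The gaze signal (horizontal and vertical angle vs. time) is modelled as a
sequence of linear episodes — optokinetic slow phases and saccadic quick
phases — observed through Gaussian axis-independent noise of known
standard deviation, with Poisson-distributed episode changes and
Poisson-distributed broadband outliers (tracker glitches) that replace
the true sample.

The penalized log-likelihood of a candidate partition is

    sum over non-outlier samples of the Gaussian log-density of the
    (h, v) residuals from the owning segment's per-axis regression lines
  + for every inter-sample gap: log(p_c) if a changepoint falls in it,
    log(1 - p_c) otherwise, with p_c = gap / expected_segment_length
  + for every sample: log(q) + 2*log(1 / (2*outlier_range)) if flagged
    as an outlier, log(1 - q) otherwise, with q = outlier_rate * dt
  - for every segment: 2 * log(n), n the segment's non-outlier sample
    count — the BIC approximation to marginalizing each segment's four
    fitted line parameters. Without this term, maximum-likelihood
    changepoint selection with known noise is inconsistent (every split
    buys four free parameters and an optimized location) and
    oversegments pure noise.

(dt = the series' median sampling interval). This score decomposes over
segments, gaps and samples, so the exact maximum over partitions for a
*fixed* outlier assignment is found by Optimal Partitioning dynamic
programming with PELT pruning. Outlier assignments are handled by
alternating the partitioning step with per-segment outlier reassignment
(block-coordinate ascent on the score); for short series the solver
instead searches outlier subsets of size <= 2 exhaustively, which makes
it exact there.

Invalid samples carry no information; runs of them longer than
``max_gap`` seconds split the series into independently segmented
chunks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

_LOG_2PI = float(np.log(2.0 * np.pi))

#: below this chunk length the solver searches outlier subsets exhaustively
SMALL_EXACT_N = 25
_MAX_OUTER_ITER = 5
_MAX_REFIT_ITER = 5
_MAX_PC = 0.5  # changepoint prior is capped below one half


@dataclass(frozen=True)
class SegmentationParams:
    expected_segment_length: float = 0.5  # s
    noise_sd: float = 0.5                 # degrees
    outlier_rate: float = 0.5             # events / s
    outlier_range: float = 30.0           # degrees
    min_segment_samples: int = 3
    beam_width: int = 10
    qp_speed_threshold: float = 40.0      # degrees / s
    max_gap: float = 0.5                  # s; longer invalid runs split the series

    def __post_init__(self) -> None:
        if self.expected_segment_length <= 0:
            raise ValueError("expected_segment_length must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.outlier_rate < 0:
            raise ValueError("outlier_rate must be non-negative")
        if self.outlier_range <= 0:
            raise ValueError("outlier_range must be positive")
        if self.min_segment_samples < 3:
            raise ValueError("min_segment_samples must be >= 3")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.qp_speed_threshold <= 0:
            raise ValueError("qp_speed_threshold must be positive")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass
class Segment:
    """A linear-regression episode over the half-open span [start_idx, end_idx).

    Slopes are in degrees/s; intercepts are the fitted angles at the
    segment's reference time ``t0`` (the time of its first sample).
    """

    start_idx: int
    end_idx: int
    slope_h: float
    slope_v: float
    intercept_h: float
    intercept_v: float
    t0: float
    label: str | None = None  # "SP" | "QP" after classification

    @property
    def speed(self) -> float:
        return float(np.hypot(self.slope_h, self.slope_v))

    def predict(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dt = np.asarray(t, dtype=float) - self.t0
        return self.intercept_h + self.slope_h * dt, self.intercept_v + self.slope_v * dt


@dataclass
class SegmentationResult:
    segments: list[Segment]
    outlier_idx: np.ndarray
    score: float

    def segment_of(self, idx: int) -> Segment | None:
        for seg in self.segments:
            if seg.start_idx <= idx < seg.end_idx:
                return seg
        return None


# ---------------------------------------------------------------------------
# sample bookkeeping

def _valid_arrays(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t = samples["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    valid = samples["valid"].to_numpy().astype(bool) if "valid" in samples else np.ones(len(samples), bool)
    finite = np.isfinite(samples["h"].to_numpy()) & np.isfinite(samples["v"].to_numpy())
    valid = valid & finite
    vidx = np.flatnonzero(valid)
    return (t[vidx], samples["h"].to_numpy(dtype=float)[vidx],
            samples["v"].to_numpy(dtype=float)[vidx], vidx)


def _chunk_slices(tv: np.ndarray, max_gap: float) -> list[slice]:
    if len(tv) == 0:
        return []
    brk = np.flatnonzero(np.diff(tv) > max_gap) + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [len(tv)]])
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


def _median_dt(tv: np.ndarray) -> float:
    d = np.diff(tv)
    if len(d) == 0:
        return 1.0 / 60.0
    return float(np.median(d))


def _priors(params: SegmentationParams, tv: np.ndarray) -> tuple[float, float, float]:
    """(q, log q-term for outliers, log(1-q)) with validation."""
    q = params.outlier_rate * _median_dt(tv)
    if q >= 1.0:
        raise ValueError("outlier_rate * sampling interval must be < 1")
    if q <= 0.0:
        q = 1e-12  # zero rate: outliers effectively forbidden, score stays finite
    nll_out = -np.log(q) + 2.0 * np.log(2.0 * params.outlier_range)
    return q, nll_out, float(np.log1p(-q))


def _gap_pc(tv: np.ndarray, params: SegmentationParams) -> np.ndarray:
    pc = np.diff(tv) / params.expected_segment_length
    return np.clip(pc, 1e-12, _MAX_PC)


# ---------------------------------------------------------------------------
# scoring

def segmentation_score(
    samples: pd.DataFrame,
    segments: list[Segment],
    outlier_idx: np.ndarray | list[int],
    params: SegmentationParams,
) -> float:
    """Penalized log-likelihood of a candidate partition (to be maximized).

    Residuals are taken from each segment's stored regression lines.
    Raises ``ValueError`` when the candidate violates the partition
    invariants (ordered disjoint segments jointly covering all valid
    samples, each with at least ``min_segment_samples`` non-outlier
    samples).
    """
    if not segments:
        raise ValueError("candidate partition has no segments")
    tv, hv, vv, vidx = _valid_arrays(samples)
    if len(tv) == 0:
        raise ValueError("no valid samples to score")
    out = np.zeros(len(samples), dtype=bool)
    out[np.asarray(outlier_idx, dtype=int)] = True
    outv = out[vidx]

    # coverage / ordering checks
    order = sorted(segments, key=lambda s: s.start_idx)
    covered = np.zeros(len(samples), dtype=bool)
    prev_end = -1
    for seg in order:
        if seg.start_idx < prev_end:
            raise ValueError("segments overlap")
        prev_end = seg.end_idx
        covered[seg.start_idx:seg.end_idx] = True
    if not covered[vidx].all():
        raise ValueError("segments do not cover all valid samples")

    sigma = params.noise_sd
    q, nll_out, log1mq = _priors(params, tv)
    ll = 0.0
    owner = np.full(len(tv), -1, dtype=int)
    for si, seg in enumerate(order):
        in_seg = (vidx >= seg.start_idx) & (vidx < seg.end_idx)
        owner[in_seg] = si
        use = in_seg & ~outv
        if use.sum() < params.min_segment_samples:
            raise ValueError("segment has fewer than min_segment_samples non-outlier samples")
        ph, pv = seg.predict(tv[use])
        rh = hv[use] - ph
        rv = vv[use] - pv
        nres = int(use.sum())
        ll += -nres * (_LOG_2PI + 2.0 * np.log(sigma)) \
              - (float(np.dot(rh, rh)) + float(np.dot(rv, rv))) / (2.0 * sigma * sigma) \
              - 2.0 * np.log(nres)
    # per-sample outlier prior
    n_out = int(outv.sum())
    ll += n_out * (-nll_out) + (len(tv) - n_out) * log1mq

    # changepoint prior over intra-chunk gaps
    pcs = _gap_pc(tv, params)
    for sl in _chunk_slices(tv, params.max_gap):
        for g in range(sl.start, sl.stop - 1):
            cp = owner[g + 1] != owner[g]
            ll += float(np.log(pcs[g]) if cp else np.log1p(-pcs[g]))
    return float(ll)


# ---------------------------------------------------------------------------
# chunk-level solver

def _prefix_sums(tc, h, v, w):
    def pre(a):
        return np.concatenate([[0.0], np.cumsum(a * w)])
    return {
        "n": pre(np.ones_like(tc)),
        "t": pre(tc), "tt": pre(tc * tc),
        "h": pre(h), "th": pre(tc * h), "hh": pre(h * h),
        "v": pre(v), "tv": pre(tc * v), "vv": pre(v * v),
    }


def _seg_nll_vec(P, i_arr, j, sigma):
    """Vectorized Gaussian NLL of OLS fits over segments [i, j) for an
    array of start indices, counting masked samples only."""
    n = P["n"][j] - P["n"][i_arr]
    st = P["t"][j] - P["t"][i_arr]
    stt = P["tt"][j] - P["tt"][i_arr]
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = stt - st * st / n
        sse = np.zeros_like(n)
        for (sy, sty, syy) in (("h", "th", "hh"), ("v", "tv", "vv")):
            s1 = P[sy][j] - P[sy][i_arr]
            s2 = P[sty][j] - P[sty][i_arr]
            s3 = P[syy][j] - P[syy][i_arr]
            sxy = s2 - st * s1 / n
            sse = sse + np.maximum(s3 - s1 * s1 / n - np.where(sxx > 0, sxy * sxy / sxx, 0.0), 0.0)
    # trailing term: per-segment parameter cost (BIC for 2 params x 2 axes)
    return n * (_LOG_2PI + 2.0 * np.log(sigma)) + sse / (2.0 * sigma * sigma) \
        + 2.0 * np.log(n)


def _pelt(tc, h, v, w, params):
    """Optimal partitioning of one chunk for a fixed inlier mask ``w``.

    Minimizes segment Gaussian NLL plus per-boundary changepoint
    penalties; PELT pruning with a safe margin keeps it exact. Returns
    the list of segment boundaries (start indices, local)."""
    n = len(tc)
    m = params.min_segment_samples
    sigma = params.noise_sd
    P = _prefix_sums(tc, h, v, w)
    pcs = _gap_pc(tc, params)  # tc strictly increasing; same gaps as t
    beta = np.concatenate([[0.0], np.log((1.0 - pcs) / pcs)])  # boundary at i uses gap i-1,i
    # pruning margin: changepoint penalty plus the worst-case slack of the
    # per-segment parameter cost (2 log n is subadditive only up to 2 log(n/4))
    margin = (float(beta.max()) if len(beta) else 0.0) + 2.0 * np.log(max(n, 4) / 4.0)

    F = np.full(n + 1, np.inf)
    F[0] = 0.0
    last = np.zeros(n + 1, dtype=int)
    cand = np.array([0], dtype=int)
    G = np.array([0.0])  # F[i] + boundary penalty at i
    for j in range(1, n + 1):
        counts = P["n"][j] - P["n"][cand]
        elig = counts >= m
        if elig.any():
            tot = np.full(len(cand), np.inf)
            tot[elig] = G[elig] + _seg_nll_vec(P, cand[elig], j, sigma)
            k = int(np.argmin(tot))
            F[j] = tot[k]
            last[j] = cand[k]
            keep = ~elig | (tot <= F[j] + margin)
            cand = cand[keep]
            G = G[keep]
        if j < n and np.isfinite(F[j]):
            cand = np.append(cand, j)
            G = np.append(G, F[j] + beta[j])
    if not np.isfinite(F[n]):
        raise ValueError("chunk too short to segment (fewer than min_segment_samples inliers)")
    bounds = []
    j = n
    while j > 0:
        i = int(last[j])
        bounds.append(i)
        j = i
    return bounds[::-1]


def _ols(tc, y, use):
    x = tc[use]
    yy = y[use]
    xm = x.mean()
    ym = yy.mean()
    den = float(np.dot(x - xm, x - xm))
    slope = float(np.dot(x - xm, yy - ym) / den) if den > 0 else 0.0
    return slope, ym - slope * xm  # intercept at tc = 0


def _refit_span(tc, h, v, s, e, inl0, params, nll_out, log1mq):
    """Iterative outlier reassignment within one segment span [s, e)."""
    sigma = params.noise_sd
    m = params.min_segment_samples
    c_in = _LOG_2PI + 2.0 * np.log(sigma) - log1mq  # residual-free inlier NLL
    seg_inl = inl0.copy()
    for _ in range(_MAX_REFIT_ITER):
        if seg_inl.sum() < m:
            seg_inl = np.ones(e - s, dtype=bool)
        bh, ah = _ols(tc[s:e], h[s:e], seg_inl)
        bv, av = _ols(tc[s:e], v[s:e], seg_inl)
        rh = h[s:e] - (ah + bh * tc[s:e])
        rv = v[s:e] - (av + bv * tc[s:e])
        nll_in = c_in + (rh * rh + rv * rv) / (2.0 * sigma * sigma)
        want_out = nll_in > nll_out
        # keep at least m inliers: force the best-fitting samples in
        if (~want_out).sum() < m:
            order = np.argsort(nll_in)
            want_out[order[:m]] = False
        new_prop = want_out & seg_inl  # currently inlier, proposed outlier
        if new_prop.sum() > params.beam_width:
            gains = np.where(new_prop, nll_in - nll_out, -np.inf)
            allowed = np.zeros(e - s, dtype=bool)
            allowed[np.argsort(gains)[::-1][: params.beam_width]] = True
            want_out = (want_out & ~new_prop) | (new_prop & allowed)
        new_inl = ~want_out
        if np.array_equal(new_inl, seg_inl):
            break
        seg_inl = new_inl
    return seg_inl


def _assign_outliers(tc, h, v, bounds, inl0, params, nll_out, log1mq):
    """Per-segment iterative outlier reassignment given fixed boundaries."""
    n = len(tc)
    inl = inl0.copy()
    for s, e in zip(bounds, bounds[1:] + [n]):
        inl[s:e] = _refit_span(tc, h, v, s, e, inl[s:e], params, nll_out, log1mq)
    return inl


def _segment_term(tc, h, v, s, e, seg_inl, params, nll_out, log1mq):
    """Score contribution of one segment span: Gaussian fit of inliers,
    parameter cost, and the span's per-sample outlier/inlier priors."""
    sigma = params.noise_sd
    n_in = int(seg_inl.sum())
    if n_in < params.min_segment_samples:
        return -np.inf
    bh, ah = _ols(tc[s:e], h[s:e], seg_inl)
    bv, av = _ols(tc[s:e], v[s:e], seg_inl)
    rh = (h[s:e] - (ah + bh * tc[s:e]))[seg_inl]
    rv = (v[s:e] - (av + bv * tc[s:e]))[seg_inl]
    return (
        -n_in * (_LOG_2PI + 2.0 * np.log(sigma))
        - (float(np.dot(rh, rh)) + float(np.dot(rv, rv))) / (2.0 * sigma * sigma)
        - 2.0 * np.log(n_in)
        - int((e - s) - n_in) * nll_out + n_in * log1mq
    )


def _chunk_score(tc, h, v, bounds, inl, params, nll_out, log1mq):
    """Exact chunk score (maximization scale) for boundaries + inlier mask,
    refitting OLS per segment on the inliers."""
    n = len(tc)
    ll = 0.0
    for s, e in zip(bounds, bounds[1:] + [n]):
        ll += _segment_term(tc, h, v, s, e, inl[s:e], params, nll_out, log1mq)
    pcs = _gap_pc(tc, params)
    is_cp = np.zeros(n - 1, dtype=bool) if n > 1 else np.zeros(0, dtype=bool)
    for b in bounds[1:]:
        is_cp[b - 1] = True
    ll += float(np.sum(np.where(is_cp, np.log(pcs), np.log1p(-pcs))))
    return float(ll)


def _repair_merges(tc, h, v, bounds, inl, params, nll_out, log1mq):
    """Greedy boundary-removal repair.

    The coordinate ascent can trap a gross outlier inside a spurious
    minimum-length segment (which can never flag it, as every segment
    must keep at least ``min_segment_samples`` inliers). Try removing
    each internal boundary, reassigning outliers within the merged span,
    and keep any merge that improves the exact score (evaluated locally:
    only the two adjacent segments and the boundary's changepoint term
    change).
    """
    n = len(tc)
    pcs = _gap_pc(tc, params)
    inl = inl.copy()

    def term(s, e, seg_inl):
        return _segment_term(tc, h, v, s, e, seg_inl, params, nll_out, log1mq)

    improved = True
    sweeps = 0
    while improved and sweeps < 3:
        improved = False
        sweeps += 1
        k = 1
        while k < len(bounds):
            s = bounds[k - 1]
            b = bounds[k]
            e = bounds[k + 1] if k + 1 < len(bounds) else n
            new_inl = _refit_span(tc, h, v, s, e, inl[s:e], params, nll_out, log1mq)
            beta_b = float(np.log1p(-pcs[b - 1]) - np.log(pcs[b - 1]))
            delta = (
                term(s, e, new_inl)
                - term(s, b, inl[s:b]) - term(b, e, inl[b:e])
                + beta_b
            )
            if delta > 1e-12:
                inl[s:e] = new_inl
                bounds = bounds[:k] + bounds[k + 1:]
                improved = True
            else:
                k += 1
    score = _chunk_score(tc, h, v, bounds, inl, params, nll_out, log1mq)
    return bounds, inl, score


def _segment_chunk(t, h, v, params):
    """Segment one contiguous chunk; returns (bounds, inlier mask)."""
    n = len(t)
    tc = t - t.mean()
    _, nll_out, log1mq = _priors(params, t)

    def iterative():
        inl = np.ones(n, dtype=bool)
        best = (-np.inf, None, None)
        for _ in range(_MAX_OUTER_ITER):
            bounds = _pelt(tc, h, v, inl.astype(float), params)
            new_inl = _assign_outliers(tc, h, v, bounds, inl, params, nll_out, log1mq)
            bounds, new_inl, score = _repair_merges(
                tc, h, v, bounds, new_inl, params, nll_out, log1mq
            )
            if score > best[0]:
                best = (score, bounds, new_inl)
            if np.array_equal(new_inl, inl):
                break
            inl = new_inl
        return best

    best = iterative()
    if n <= SMALL_EXACT_N:
        m = params.min_segment_samples
        max_out = min(2, n - m)
        for k in range(0, max_out + 1):
            for O in combinations(range(n), k):
                w = np.ones(n)
                inl = np.ones(n, dtype=bool)
                for o in O:
                    w[o] = 0.0
                    inl[o] = False
                try:
                    bounds = _pelt(tc, h, v, w, params)
                except ValueError:
                    continue
                score = _chunk_score(tc, h, v, bounds, inl, params, nll_out, log1mq)
                better = score > best[0] + 1e-9
                tied = abs(score - best[0]) <= 1e-9 and best[1] is not None and (
                    (len(bounds), k) < (len(best[1]), int((~best[2]).sum()))
                )
                if better or tied:
                    best = (score, bounds, inl)
    if best[1] is None:
        raise ValueError("chunk could not be segmented")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# public operations

def segment_gaze(samples: pd.DataFrame, params: SegmentationParams | None = None) -> SegmentationResult:
    """Partition a gaze series into maximum-likelihood linear segments.

    Returns segments in original-sample index coordinates (half-open
    spans), the detected outlier sample indices, and the partition's
    penalized log-likelihood, which always equals
    :func:`segmentation_score` re-evaluated on the returned candidate.
    """
    params = params or SegmentationParams()
    tv, hv, vv, vidx = _valid_arrays(samples)
    if len(tv) < params.min_segment_samples:
        raise ValueError(
            f"need at least {params.min_segment_samples} valid samples, got {len(tv)}"
        )
    segments: list[Segment] = []
    outliers: list[int] = []
    for sl in _chunk_slices(tv, params.max_gap):
        t, h, v = tv[sl], hv[sl], vv[sl]
        bounds, inl = _segment_chunk(t, h, v, params)
        ends = bounds[1:] + [len(t)]
        for s, e in zip(bounds, ends):
            use = inl[s:e]
            t0 = t[s]
            bh, ah = _ols(t[s:e] - t0, h[s:e], use)
            bv, av = _ols(t[s:e] - t0, v[s:e], use)
            start = int(vidx[sl.start + s])
            # end index: one past the last valid sample of the span
            end = int(vidx[sl.start + e - 1]) + 1
            segments.append(Segment(start, end, bh, bv, ah, av, float(t0)))
        outliers.extend(int(vidx[sl.start + k]) for k in np.flatnonzero(~inl))
    out_idx = np.array(sorted(outliers), dtype=int)
    score = segmentation_score(samples, segments, out_idx, params)
    return SegmentationResult(segments, out_idx, score)


def classify_segments(
    result: SegmentationResult, qp_speed_threshold: float = 40.0
) -> SegmentationResult:
    """Label segments as slow phases (SP) or quick phases (QP).

    A segment whose slope magnitude sqrt(slope_h^2 + slope_v^2) is at or
    above the threshold is a quick phase (ties go to QP).
    """
    segs = [
        replace(s, label="QP" if s.speed >= qp_speed_threshold else "SP")
        for s in result.segments
    ]
    return SegmentationResult(segs, result.outlier_idx.copy(), result.score)


def per_sample_velocity(result: SegmentationResult, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample gaze velocity: each valid non-outlier sample inherits its
    owning segment's slopes; outlier and invalid samples get no velocity.

    Returns a DataFrame (t, vel_h, vel_v, ok); raises when a valid sample
    is not covered by any segment.
    """
    n = len(samples)
    tv, _, _, vidx = _valid_arrays(samples)
    vel_h = np.full(n, np.nan)
    vel_v = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    out[result.outlier_idx] = True
    starts = np.array([s.start_idx for s in result.segments])
    ends = np.array([s.end_idx for s in result.segments])
    for i in vidx:
        k = np.flatnonzero((starts <= i) & (i < ends))
        if len(k) == 0:
            raise ValueError(f"valid sample {i} not covered by any segment")
        if out[i]:
            continue
        seg = result.segments[int(k[0])]
        vel_h[i] = seg.slope_h
        vel_v[i] = seg.slope_v
        ok[i] = True
    return pd.DataFrame({"t": samples["t"].to_numpy(), "vel_h": vel_h,
                         "vel_v": vel_v, "ok": ok})


def fitted_positions(result: SegmentationResult, samples: pd.DataFrame) -> pd.DataFrame:
    """Denoised gaze position: each valid non-outlier sample evaluated on
    its owning segment's regression lines (the segmentation signal used
    for position statistics instead of the raw noisy samples)."""
    n = len(samples)
    t = samples["t"].to_numpy(dtype=float)
    fh = np.full(n, np.nan)
    fv = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    out[result.outlier_idx] = True
    _, _, _, vidx = _valid_arrays(samples)
    vset = set(vidx.tolist())
    for seg in result.segments:
        for i in range(seg.start_idx, seg.end_idx):
            if i in vset and not out[i]:
                ph, pv = seg.predict(np.array([t[i]]))
                fh[i], fv[i] = ph[0], pv[0]
                ok[i] = True
    return pd.DataFrame({"t": t, "h": fh, "v": fv, "ok": ok})
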